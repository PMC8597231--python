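"""Local spliced realignment of problem reads (refinement phase).

After competitive selection, reads that are unmapped, soft-clipped,
gapped, or carry high-quality mismatches are re-examined: each is
realigned inside a 100 kb window anchored on its mate (or on its own
original position when the mate is unmapped), the new alignment is scored
(+1 per aligned base, -1 per gap open, -1 per gap-extend unit, +5 per
splice shorter than 100 kb), and the original is replaced only when the
candidate is an improvement.  Poly-A tails spuriously spliced onto
genomic A-runs are soft-clipped at the end.

The built-in realigner is a deliberately simple exact-seed-and-extend
search allowing mismatches and a single splice; it is pluggable, so a SAM
produced by an external spliced aligner can be substituted for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .competitive import fr_orientation
from .records import AlignmentRecord, compute_match_count, count_indels, revcomp
from .transcript_db import fetch

#: splices at or above this length receive no bonus
SPLICE_BONUS_MAX = 100_000
SPLICE_BONUS = 5


@dataclass
class RefinementCandidate:
    """A scored realignment proposal."""

    alignment: AlignmentRecord
    score: int
    splices: list[int] = field(default_factory=list)
    mismatches: int = 0


def score_alignment(ops) -> int:
    """Score an operation list.

    +1 per aligned base; each insertion or deletion of length L costs
    1 (open) + L (extend units); each splice of length < 100 kb earns +5.
    """
    score = 0
    for op, ln in ops:
        if ln < 0:
            raise ValueError(f"negative op length in {ops}")
        if op == "M":
            score += ln
        elif op in "ID":
            score -= 1 + ln
        elif op == "N":
            if ln < SPLICE_BONUS_MAX:
                score += SPLICE_BONUS
    return score


def splice_lengths(ops) -> list[int]:
    return [ln for op, ln in ops if op == "N"]


# ---------------------------------------------------------------------------
# Extraction of records of interest
# ---------------------------------------------------------------------------

def has_hq_mismatch(rec: AlignmentRecord, genome, min_qual: int = 20) -> bool:
    if not rec.mapped or not rec.seq:
        return False
    r, g = 0, rec.pos
    for op, ln in rec.ops:
        if op == "M":
            ref = fetch(genome, rec.chrom, g, g + ln)
            seg = rec.seq[r:r + ln].upper()
            for i, (a, b) in enumerate(zip(seg, ref)):
                if a != b and rec.base_qual(r + i) >= min_qual:
                    return True
            r += ln
            g += ln
        elif op in "IS":
            r += ln
        else:
            g += ln
    return False


def is_record_of_interest(rec: AlignmentRecord, genome, min_qual: int = 20) -> bool:
    """Unmapped, soft-clipped, gapped, or >=1 mismatch at base quality
    >= ``min_qual``."""
    if not rec.mapped:
        return True
    if any(op in "SID" for op, _ in rec.ops):
        return True
    return has_hq_mismatch(rec, genome, min_qual)


def extract_records_of_interest(records, genome, min_qual: int = 20):
    return [r for r in records if is_record_of_interest(r, genome, min_qual)]


# ---------------------------------------------------------------------------
# Realignment windows
# ---------------------------------------------------------------------------

def realignment_window(rec: AlignmentRecord, mate: AlignmentRecord | None,
                       contig_lengths: dict[str, int], window_kb: int = 100):
    """Genomic interval(s) to search for a better alignment.

    With a mapped mate: one window of ``window_kb`` on the side of the
    mate where a forward-reverse pair would place this read.  Otherwise,
    if the read itself was mapped: two windows of ``window_kb`` on either
    side of its original position.  Both unmapped: no window.
    """
    w = window_kb * 1000
    if mate is not None and mate.mapped:
        clen = contig_lengths[mate.chrom]
        if not mate.reverse_strand:
            lo, hi = mate.pos, min(mate.pos + w, clen)
        else:
            lo, hi = max(mate.end - w, 0), mate.end
        return [(mate.chrom, lo, hi)] if lo < hi else []
    if rec.mapped:
        clen = contig_lengths[rec.chrom]
        out = []
        lo = max(rec.pos - w, 0)
        if lo < rec.pos:
            out.append((rec.chrom, lo, rec.pos))
        hi = min(rec.pos + w, clen)
        if rec.pos < hi:
            out.append((rec.chrom, rec.pos, hi))
        return out
    return []


# ---------------------------------------------------------------------------
# Improvement rules
# ---------------------------------------------------------------------------

def is_improvement(original: RefinementCandidate | None,
                   candidate: RefinementCandidate,
                   orig_pair: tuple[bool, bool] | None = None,
                   cand_pair: tuple[bool, bool] | None = None) -> bool:
    """Accept the realignment?  Rules, in order:

    1. originally unmapped -> improvement;
    2. unequal scores -> the higher score wins;
    3. pair previously cross-chromosome, now same chromosome -> improvement;
    4. pair previously not forward-reverse, now forward-reverse -> improvement;
    5. otherwise not an improvement.

    ``orig_pair``/``cand_pair`` are ``(same_chrom, fr)`` tuples and may be
    omitted for single reads.
    """
    if original is None or not original.alignment.mapped:
        return True
    if candidate.score != original.score:
        return candidate.score > original.score
    if orig_pair is not None and cand_pair is not None:
        if not orig_pair[0] and cand_pair[0]:
            return True
        if not orig_pair[1] and cand_pair[1]:
            return True
    return False


# ---------------------------------------------------------------------------
# The built-in seed-and-extend spliced realigner
# ---------------------------------------------------------------------------

def _seed_offsets(n: int, seed_len: int):
    """Staggered seed offsets from one read end: a single sequencing error
    can break at most two overlapping seeds, never all three."""
    outs = [0]
    if n >= seed_len + seed_len // 2:
        outs.append(seed_len // 2)
    if n >= 2 * seed_len:
        outs.append(seed_len)
    return outs


def _hit_positions(hay: str, needle: str):
    out, i = [], hay.find(needle)
    while i >= 0:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


class SeedIndex:
    """Exact k-mer index over a genome, for repeated realignment calls."""

    def __init__(self, genome, contigs, seed_len: int = 16):
        self.seed_len = seed_len
        self.hits: dict[str, list[tuple[str, int]]] = {}
        for chrom in contigs:
            seq = fetch(genome, chrom, 0, len(genome[chrom]))
            for i in range(len(seq) - seed_len + 1):
                self.hits.setdefault(seq[i:i + seed_len], []).append((chrom, i))

    def lookup(self, kmer: str, chrom: str, lo: int, hi: int):
        return [p for c, p in self.hits.get(kmer, ()) if c == chrom and lo <= p < hi]


def _mismatch_prefix(read: str, ref: str):
    pre = [0]
    for a, b in zip(read, ref):
        pre.append(pre[-1] + (a != b))
    return pre


def _search(read, fetch_slice, left_starts, right_starts, lo, hi, *,
            min_anchor, min_intron, max_mismatch, max_pairs=64):
    """Enumerate gapless and single-splice placements; return the best
    (ops, pos, mm, internal_score) or None."""
    n = len(read)
    best = None

    def consider(pos, ops, mm):
        nonlocal best
        internal = score_alignment(ops) - 2 * mm
        if mm <= max_mismatch and (best is None or internal > best[3]):
            best = (ops, pos, mm, internal)

    for L in sorted(set(left_starts) | set(right_starts)):
        if L < lo or L + n > hi:
            continue
        ref = fetch_slice(L, L + n)
        mm = sum(a != b for a, b in zip(read, ref))
        consider(L, [("M", n)], mm)

    pairs = [(L, R) for L in set(left_starts) for R in set(right_starts)
             if R - L >= min_intron and L >= lo and R + n <= hi]
    for L, R in sorted(pairs)[:max_pairs]:
        pre_l = _mismatch_prefix(read, fetch_slice(L, L + n))
        pre_r = _mismatch_prefix(read, fetch_slice(R, R + n))
        for k in range(min_anchor, n - min_anchor + 1):
            mm = pre_l[k] + (pre_r[n] - pre_r[k])
            intron = R - L
            consider(L, [("M", k), ("N", intron), ("M", n - k)], mm)
    return best


def simple_spliced_realign(read: str, window: str, *, window_start: int = 0,
                           seed_len: int = 16, min_anchor: int = 12,
                           min_intron: int = 20, min_score: int | None = None,
                           max_mismatch: int | None = None):
    """Best local alignment of ``read`` inside ``window`` (one strand).

    Seeds on the first and last ``seed_len``-mers of the read, extends
    gaplessly, and exhaustively searches single splice points between any
    pair of seed placements.  Returns a :class:`RefinementCandidate` whose
    record position is ``window_start`` + the window offset, or ``None``
    when nothing scores at least ``min_score`` (default: half the read
    length).
    """
    n = len(read)
    if n < seed_len or len(window) < n:
        return None
    read = read.upper()
    window = window.upper()
    if max_mismatch is None:
        max_mismatch = max(2, n // 20)
    if min_score is None:
        min_score = n // 2
    left, right = set(), set()
    for off in _seed_offsets(n, seed_len):
        left.update(h - off for h in
                    _hit_positions(window, read[off:off + seed_len]))
        j = n - seed_len - off
        right.update(h - j for h in _hit_positions(window, read[j:j + seed_len]))
    best = _search(read, lambda a, b: window[a:b], left, right, 0, len(window),
                   min_anchor=min_anchor, min_intron=min_intron,
                   max_mismatch=max_mismatch)
    if best is None or best[3] < min_score:
        return None
    ops, pos, mm, _ = best
    rec = AlignmentRecord(read_id="", mapped=True, chrom=None,
                          pos=window_start + pos, ops=ops, seq=read,
                          match_count=n - mm, indel_count=0)
    return RefinementCandidate(rec, score_alignment(ops), splice_lengths(ops), mm)


def realign_in_window(read: str, chrom: str, lo: int, hi: int, genome,
                      index: SeedIndex, *, min_anchor: int = 12,
                      min_intron: int = 20, min_score: int | None = None,
                      max_mismatch: int | None = None):
    """Index-backed variant of :func:`simple_spliced_realign` (same
    contract, genomic coordinates)."""
    n = len(read)
    k = index.seed_len
    if n < k:
        return None
    read = read.upper()
    if max_mismatch is None:
        max_mismatch = max(2, n // 20)
    if min_score is None:
        min_score = n // 2
    left, right = set(), set()
    for off in _seed_offsets(n, k):
        left.update(h - off for h in
                    index.lookup(read[off:off + k], chrom, lo, hi))
        j = n - k - off
        right.update(h - j for h in index.lookup(read[j:j + k], chrom, lo, hi))
    best = _search(read, lambda a, b: fetch(genome, chrom, a, b), left, right,
                   lo, hi, min_anchor=min_anchor, min_intron=min_intron,
                   max_mismatch=max_mismatch)
    if best is None or best[3] < min_score:
        return None
    ops, pos, mm, _ = best
    rec = AlignmentRecord(read_id="", mapped=True, chrom=chrom, pos=pos,
                          ops=ops, seq=read, match_count=n - mm, indel_count=0)
    return RefinementCandidate(rec, score_alignment(ops), splice_lengths(ops), mm)


# ---------------------------------------------------------------------------
# Poly-A tail clipping
# ---------------------------------------------------------------------------

def _trim_read_bases(ops, k, from_right: bool):
    """Remove k read bases from one end; returns (ops, ref_consumed_dropped)."""
    seq_ops = list(ops)
    if from_right:
        seq_ops.reverse()
    out, need, ref_dropped = [], k, 0
    for op, ln in seq_ops:
        if need > 0:
            if op in "MIS":
                take = min(need, ln)
                need -= take
                if op == "M":
                    ref_dropped += take
                if ln > take:
                    out.append((op, ln - take))
            else:  # D/N inside the clipped region vanish
                ref_dropped += ln
        else:
            out.append((op, ln))
    # drop non-read-consuming ops left dangling at the clipped end
    while out and out[0][0] in "DN":
        ref_dropped += out[0][1]
        out.pop(0)
    if from_right:
        out.reverse()
    return out, ref_dropped


def clip_polyA(rec: AlignmentRecord, min_polyA: int = 6) -> AlignmentRecord:
    """Soft-clip a spliced poly-A tail.

    The 3' end of the read (strand-aware: trailing A's for forward
    records, leading T's for reverse ones, since SAM stores the
    reference-forward sequence) is converted to soft clip when it is a run
    of at least ``min_polyA`` bases whose alignment contains or is
    immediately preceded by a splice.  Splices inside the run are removed.
    """
    if not rec.mapped or not rec.seq:
        return rec
    seq = rec.seq.upper()
    if not rec.reverse_strand:
        run = len(seq) - len(seq.rstrip("A"))
        from_right = True
    else:
        run = len(seq) - len(seq.lstrip("T"))
        from_right = False
    if run < min_polyA:
        return rec

    # does a splice lie within the run's aligned span, or just 5' of it?
    ops = list(rec.ops)
    scan = list(reversed(ops)) if from_right else ops
    consumed, splice_in_run = 0, False
    for op, ln in scan:
        if op == "N" and consumed <= run:
            splice_in_run = True    # inside or immediately 5' of the run
            break
        if op in "MIS":
            consumed += ln
            if consumed > run:
                break
    if not splice_in_run:
        return rec

    new_ops, ref_dropped = _trim_read_bases(ops, run, from_right)
    out = rec.copy()
    if from_right:
        if new_ops and new_ops[-1][0] == "S":
            new_ops[-1] = ("S", new_ops[-1][1] + run)
        else:
            new_ops.append(("S", run))
    else:
        if new_ops and new_ops[0][0] == "S":
            new_ops[0] = ("S", new_ops[0][1] + run)
        else:
            new_ops.insert(0, ("S", run))
        out.pos = rec.pos + ref_dropped
    out.ops = new_ops
    out.indel_count = count_indels(new_ops)
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def refine(records, genome, contigs=None, *, window_kb: int = 100,
           min_qual: int = 20, min_polyA: int = 6, seed_len: int = 16,
           index: SeedIndex | None = None, realigner=None):
    """Refine a selected stream: realign records of interest and clip
    poly-A tails.  Returns a new list, same reads, same order.

    ``realigner(read_seq, chrom, lo, hi)`` may be supplied to plug in an
    external spliced aligner; it must return a RefinementCandidate or None.
    """
    if contigs is None:
        contigs = list(genome.keys())
    contig_lengths = {c: len(genome[c]) for c in contigs}
    if realigner is None:
        if index is None:
            index = SeedIndex(genome, contigs, seed_len)

        def realigner(read, chrom, lo, hi):
            return realign_in_window(read, chrom, lo, hi, genome, index)

    by_read: dict[str, dict[int, AlignmentRecord]] = {}
    for rec in records:
        by_read.setdefault(rec.read_id, {})[rec.mate_index] = rec

    def ref_lookup(chrom, a, b):
        return fetch(genome, chrom, a, b)

    out = []
    for rec in records:
        rec = rec.copy()
        mate = by_read[rec.read_id].get(3 - rec.mate_index)
        if is_record_of_interest(rec, genome, min_qual):
            windows = realignment_window(rec, mate, contig_lengths, window_kb)
            best = None
            for chrom, lo, hi in windows:
                for seq, flipped in ((rec.seq, False), (revcomp(rec.seq), True)):
                    cand = realigner(seq, chrom, lo, hi)
                    if cand is None:
                        continue
                    key = (cand.score - 2 * cand.mismatches, -cand.mismatches)
                    if best is None or key > best[1]:
                        best = ((cand, flipped), key)
            if best is not None:
                cand, flipped = best[0]
                orig = (RefinementCandidate(rec, score_alignment(rec.ops),
                                            splice_lengths(rec.ops))
                        if rec.mapped else None)
                orig_pair = cand_pair = None
                if mate is not None and mate.mapped:
                    orig_pair = (rec.mapped and rec.chrom == mate.chrom,
                                 fr_orientation(rec, mate))
                    probe = cand.alignment.copy()
                    probe.reverse_strand = (rec.reverse_strand != flipped
                                            if rec.mapped else flipped)
                    cand_pair = (probe.chrom == mate.chrom,
                                 fr_orientation(probe, mate))
                if is_improvement(orig, cand, orig_pair, cand_pair):
                    rec.mapped = True
                    rec.chrom = cand.alignment.chrom
                    rec.pos = cand.alignment.pos
                    rec.ops = list(cand.alignment.ops)
                    if flipped:
                        rec.seq = revcomp(rec.seq)
                        if rec.quals is not None:
                            rec.quals = rec.quals[::-1]
                        rec.reverse_strand = not rec.reverse_strand
                    rec.indel_count = count_indels(rec.ops)
        if rec.mapped:
            rec = clip_polyA(rec, min_polyA)
            rec.match_count = compute_match_count(rec, ref_lookup)
        out.append(rec)
    return out
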