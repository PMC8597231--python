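"""Core alignment record model and SAM input/output.

An :class:`AlignmentRecord` is one candidate mapping of one read (or one
mate of a pair) produced by some mapper/database source.  Coordinates are
0-based half-open throughout the package; conversion to SAM's 1-based
convention happens only at the pysam boundary.

CIGAR-like operations are kept as ``(op, length)`` tuples with op one of
``M`` (aligned), ``I`` (insertion to reference), ``D`` (deletion from
reference), ``N`` (splice/skip) and ``S`` (soft clip).  ``seq`` always
holds the reference-forward-strand read sequence, as in SAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pysam

OPS = "MIDNS"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignmentRecord:
    """One candidate mapping of a read mate from one source."""

    read_id: str
    mate_index: int = 1
    source_priority: int = 4
    mapped: bool = False
    chrom: str | None = None
    pos: int | None = None          # 0-based leftmost reference position
    reverse_strand: bool = False
    ops: list[tuple[str, int]] = field(default_factory=list)
    match_count: int = 0            # read bases aligned AND matching reference
    indel_count: int = 0            # number of I/D events
    duplicate_flag: bool = False
    seq: str = ""
    quals: list[int] | None = None  # per-base, same orientation as seq
    mapq: int = 60

    def copy(self) -> "AlignmentRecord":
        return replace(self, ops=list(self.ops),
                       quals=None if self.quals is None else list(self.quals))

    # -- derived geometry -------------------------------------------------
    @property
    def read_length(self) -> int:
        n = sum(ln for op, ln in self.ops if op in "MIS")
        return n if n else len(self.seq)

    @property
    def reference_span(self) -> int:
        return sum(ln for op, ln in self.ops if op in "MDN")

    @property
    def end(self) -> int:
        """One past the last reference base consumed."""
        if not self.mapped:
            raise ValueError("unmapped record has no end")
        return self.pos + self.reference_span

    def has_op(self, op: str) -> bool:
        return any(o == op for o, _ in self.ops)

    def aligned_pairs(self):
        """Yield ``(read_index, ref_pos)`` for every M-op base."""
        r, g = 0, self.pos
        for op, ln in self.ops:
            if op == "M":
                for i in range(ln):
                    yield r + i, g + i
                r += ln
                g += ln
            elif op in "IS":
                r += ln
            else:  # D, N
                g += ln

    def base_qual(self, read_index: int) -> int:
        return 40 if self.quals is None else self.quals[read_index]


def unmapped_record(read_id: str, mate_index: int, source_priority: int,
                    seq: str = "", quals: list[int] | None = None,
                    duplicate_flag: bool = False) -> AlignmentRecord:
    return AlignmentRecord(read_id=read_id, mate_index=mate_index,
                           source_priority=source_priority, mapped=False,
                           chrom=None, pos=None, ops=[], match_count=0,
                           indel_count=0, seq=seq, quals=quals,
                           duplicate_flag=duplicate_flag)


def count_indels(ops) -> int:
    return sum(1 for op, _ in ops if op in "ID")


def compute_match_count(rec: AlignmentRecord, ref_lookup) -> int:
    """Count aligned read bases that match the reference.

    ``ref_lookup(chrom, start, end)`` must return uppercase reference
    sequence.  Records with no sequence fall back to counting aligned
    bases (and the caller is expected to log that).
    """
    if not rec.mapped:
        return 0
    if not rec.seq:
        return sum(ln for op, ln in rec.ops if op == "M")
    n = 0
    r, g = 0, rec.pos
    for op, ln in rec.ops:
        if op == "M":
            ref = ref_lookup(rec.chrom, g, g + ln)
            seg = rec.seq[r:r + ln].upper()
            n += sum(a == b for a, b in zip(seg, ref))
            r += ln
            g += ln
        elif op in "IS":
            r += ln
        else:
            g += ln
    return n


# ---------------------------------------------------------------------------
# SAM I/O (pysam boundary)
# ---------------------------------------------------------------------------

_SOURCE_TAG = "XP"   # source priority of this candidate
_WINNER_TAG = "XW"   # priority of the winning source, on selected output


def _cigar_to_pysam(ops):
    code = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4}
    return [(code[op], ln) for op, ln in ops]


def _cigar_from_pysam(cigartuples):
    name = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S", 7: "M", 8: "M"}
    out = []
    for code, ln in cigartuples or []:
        if code == 5:  # hard clip: no read bases, drop
            continue
        if code not in name:
            raise ValueError(f"unsupported CIGAR op code {code}")
        op = name[code]
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


def write_sam(records, path, contigs: dict[str, int]) -> None:
    """Write records as a SAM text file.

    ``contigs`` maps reference name to length and fixes the header order.
    Mate/pairing flags are reconstructed from (read_id, mate_index).
    """
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": n, "LN": ln} for n, ln in contigs.items()]}
    names = {n: i for i, n in enumerate(contigs)}
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.query_sequence = rec.seq or None
            if rec.quals is not None:
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in rec.quals))
            flag = 0
            if rec.mate_index in (1, 2):
                flag |= 0x1 | (0x40 if rec.mate_index == 1 else 0x80)
            if not rec.mapped:
                flag |= 0x4
            if rec.reverse_strand:
                flag |= 0x10
            if rec.duplicate_flag:
                flag |= 0x400
            a.flag = flag
            if rec.mapped:
                a.reference_id = names[rec.chrom]
                a.reference_start = rec.pos
                a.mapping_quality = rec.mapq
                a.cigartuples = _cigar_to_pysam(rec.ops)
                aligned = sum(ln for op, ln in rec.ops if op == "M")
                gapped = sum(ln for op, ln in rec.ops if op in "ID")
                a.set_tag("NM", (aligned - rec.match_count) + gapped)
            a.set_tag(_SOURCE_TAG, rec.source_priority)
            out.write(a)


def read_sam(path, source_priority: int | None = None) -> list[AlignmentRecord]:
    """Read a SAM file into :class:`AlignmentRecord` objects.

    ``source_priority`` overrides any per-record XP tag (used when tagging
    whole files from the CLI, one file per mapper/database source).
    """
    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as f:
        for a in f:
            if a.is_secondary or a.is_supplementary:
                continue
            prio = source_priority
            if prio is None:
                prio = a.get_tag(_SOURCE_TAG) if a.has_tag(_SOURCE_TAG) else 4
            quals = (list(a.query_qualities)
                     if a.query_qualities is not None else None)
            rec = AlignmentRecord(
                read_id=a.query_name,
                mate_index=2 if a.is_read2 else 1,
                source_priority=prio,
                mapped=not a.is_unmapped,
                chrom=a.reference_name if not a.is_unmapped else None,
                pos=a.reference_start if not a.is_unmapped else None,
                reverse_strand=a.is_reverse,
                ops=_cigar_from_pysam(a.cigartuples) if not a.is_unmapped else [],
                duplicate_flag=a.is_duplicate,
                seq=a.query_sequence or "",
                quals=quals,
                mapq=a.mapping_quality,
            )
            rec.indel_count = count_indels(rec.ops)
            aligned = sum(ln for op, ln in rec.ops if op == "M")
            if rec.mapped and a.has_tag("NM"):
                gapped = sum(ln for op, ln in rec.ops if op in "ID")
                rec.match_count = aligned - (a.get_tag("NM") - gapped)
            else:
                # no mismatch information: aligned bases stand in for matches
                rec.match_count = aligned
            out.append(rec)
    return out
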