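"""Competitive selection of the best alignment among multi-source candidates.

Each read (mate) may have up to five candidate records, one per
mapper/database source.  The best *record* per mate is chosen first
(mapped beats unmapped, then more matching bases, then fewer indel
events); the best *pair* is then chosen among the ties using pair
geometry (same chromosome, closer on an integer log10 scale,
forward-reverse orientation, same source, then source priority).

The rules form a total preorder; ties after source priority are broken on
the ordered pair of priorities so that selection is deterministic and
independent of candidate input order.
"""

from __future__ import annotations

import math

from .records import AlignmentRecord

#: The default competitive configuration: five mapper/database sources in
#: priority order.  Priorities 1-3 are transcript-space databases whose
#: alignments are translated to the genome before selection.
SOURCE_TABLE: dict[int, tuple[str, str]] = {
    1: ("bwa", "transcript_db"),
    2: ("bwa", "alternate_exon_db"),
    3: ("bwa", "transcript_db_alt_annotation"),
    4: ("bwa", "genome"),
    5: ("star", "genome"),
}

N_SOURCES = len(SOURCE_TABLE)


def record_key(rec: AlignmentRecord):
    """Lexicographic quality key for one record (higher is better)."""
    return (1 if rec.mapped else 0, rec.match_count, -rec.indel_count)


def select_best_record(candidates: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """All candidates tied for best under the record preorder."""
    if not candidates:
        raise ValueError("select_best_record requires at least one candidate")
    best = max(record_key(c) for c in candidates)
    return [c for c in candidates if record_key(c) == best]


def distance_bucket(rec1: AlignmentRecord, rec2: AlignmentRecord) -> int:
    """floor(log10(pair distance)) with distance clamped to >= 1.

    Defined only for mapped records on the same chromosome; distance is
    between leftmost starts.
    """
    d = abs(rec2.pos - rec1.pos)
    return int(math.floor(math.log10(max(d, 1))))


def fr_orientation(rec1: AlignmentRecord, rec2: AlignmentRecord) -> bool:
    """Forward-reverse: upstream mate forward, downstream mate reverse."""
    if not (rec1.mapped and rec2.mapped) or rec1.chrom != rec2.chrom:
        return False
    up, down = (rec1, rec2) if rec1.pos <= rec2.pos else (rec2, rec1)
    return (not up.reverse_strand) and down.reverse_strand


def pair_key(rec1: AlignmentRecord, rec2: AlignmentRecord):
    """Lexicographic quality key for a candidate pair (higher is better)."""
    both = rec1.mapped and rec2.mapped
    same_chrom = both and rec1.chrom == rec2.chrom
    bucket = distance_bucket(rec1, rec2) if same_chrom else 0
    p1, p2 = rec1.source_priority, rec2.source_priority
    return (
        1 if same_chrom else 0,
        -bucket,
        1 if fr_orientation(rec1, rec2) else 0,
        1 if p1 == p2 else 0,
        -min(p1, p2),
        -p1, -p2,                       # final deterministic tie-break
    )


def select_best_pair(tied1, tied2):
    """Best (rec1, rec2) among tied-best candidates of each mate.

    If one mate is universally unmapped the rules degrade to record
    selection for the mapped mate (ties broken by source priority) and the
    unmapped mate rides along.
    """
    if not tied1 or not tied2:
        raise ValueError("select_best_pair requires candidates for both mates")

    def solo(tied):
        return max(tied, key=lambda r: (record_key(r), -r.source_priority))

    if all(not r.mapped for r in tied1):
        return solo(tied1), solo(tied2)
    if all(not r.mapped for r in tied2):
        return solo(tied1), solo(tied2)
    return max(((a, b) for a in tied1 for b in tied2),
               key=lambda ab: pair_key(*ab))


def select_pairs(candidates_by_source) -> list[AlignmentRecord]:
    """Run full selection over a set of per-source candidate records.

    ``candidates_by_source`` is an iterable of AlignmentRecord (any
    order); records are grouped by (read_id, mate_index).  Returns one
    record per read mate, each tagged with its winning source priority.
    """
    by_read: dict[str, dict[int, list[AlignmentRecord]]] = {}
    for rec in candidates_by_source:
        by_read.setdefault(rec.read_id, {}).setdefault(rec.mate_index, []).append(rec)

    out = []
    for read_id in by_read:
        mates = by_read[read_id]
        if len(mates) == 2:
            t1 = select_best_record(mates[1])
            t2 = select_best_record(mates[2])
            r1, r2 = select_best_pair(t1, t2)
            out.extend([r1, r2])
        else:
            for mate, cands in mates.items():
                tied = select_best_record(cands)
                out.append(max(tied,
                               key=lambda r: (record_key(r), -r.source_priority)))
    return out


def merge_selected(records) -> list[AlignmentRecord]:
    """Coordinate-sort selected records; reject duplicated read mates.

    Unmapped records sort after mapped ones.  The full sort key includes
    read id and mate so the output is byte-stable under input shuffling.
    """
    seen = set()
    for rec in records:
        key = (rec.read_id, rec.mate_index)
        if key in seen:
            raise ValueError(f"read mate {key} contributed more than once")
        seen.add(key)
    return sorted(records, key=lambda r: (
        not r.mapped, r.chrom or "", r.pos if r.pos is not None else -1,
        r.read_id, r.mate_index))
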