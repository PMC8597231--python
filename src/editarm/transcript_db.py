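"""Transcript models, custom mapping databases, and coordinate translation.

The competitive mapping strategy aligns reads not only to the genome but
also to *custom databases*: FASTA files in which each sequence is a
forward-strand concatenation of a chosen set of exons.  The exon set is
encoded in the sequence name, so any alignment against a custom sequence
can be translated back into spliced genomic coordinates without keeping
the annotation around.

Two database flavours are built here:

* one entry per annotated transcript (canonical splicing), and
* *alternate-exon fragments*: for each gene, every ordered pair of exons
  that is adjacent in no annotated transcript, with up to ``flank_bp`` of
  exonic sequence accumulated on each side of the novel junction (useful
  for exon-skipping reads).

All intervals are 0-based half-open on the forward genomic strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .records import revcomp

log = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Annotation inconsistent with the reference genome."""


class CorruptRecordError(ValueError):
    """Alignment inconsistent with the custom entry it claims to map to."""


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` and ``cds`` are sorted, non-overlapping genomic intervals;
    every CDS interval is contained in an exon.  For minus-strand genes
    the mRNA is the reverse complement of the forward-strand exon
    concatenation.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str                       # '+' or '-'
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c < b:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons {(a, b)},{(c, d)}")
        for c in self.cds:
            if not any(e[0] <= c[0] and c[1] <= e[1] for e in self.exons):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS {c} outside exons")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def spliced_sequence(self, genome) -> str:
        """mRNA sequence (5'->3' on the coding strand)."""
        fwd = "".join(fetch(genome, self.chrom, s, e) for s, e in self.exons)
        return fwd if self.strand == "+" else revcomp(fwd)

    def genomic_to_mrna(self, pos: int) -> int | None:
        """Map a genomic position to an mRNA offset, or None if intronic."""
        off = 0
        for s, e in self.exons:
            if s <= pos < e:
                f = off + (pos - s)
                return f if self.strand == "+" else self.length - 1 - f
            off += e - s
        return None

    def mrna_to_genomic(self, off: int) -> int:
        f = off if self.strand == "+" else self.length - 1 - off
        for s, e in self.exons:
            if f < e - s:
                return s + f
            f -= e - s
        raise IndexError(f"mRNA offset {off} beyond transcript {self.transcript_id}")


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Uppercase forward-strand slice from a dict or pyfaidx.Fasta-like genome."""
    seq = genome[chrom]
    if isinstance(seq, str):
        return seq[start:end].upper()
    return str(seq[start:end]).upper()


def contig_length(genome, chrom: str) -> int:
    return len(genome[chrom])


# ---------------------------------------------------------------------------
# refFlat I/O
# ---------------------------------------------------------------------------

def parse_refflat(path) -> list[TranscriptModel]:
    """Parse a refFlat-like TSV.

    Columns: geneName, name, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts, exonEnds (UCSC convention; positions
    already 0-based half-open, exon lists comma-terminated).
    """
    out = []
    with open(path) as f:
        for line in f:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            t = line.split("\t")
            gene, name, chrom, strand = t[0], t[1], t[2], t[3]
            cds_start, cds_end = int(t[6]), int(t[7])
            starts = [int(x) for x in t[9].rstrip(",").split(",") if x]
            ends = [int(x) for x in t[10].rstrip(",").split(",") if x]
            exons = list(zip(starts, ends))
            cds = []
            if cds_end > cds_start:
                for s, e in exons:
                    a, b = max(s, cds_start), min(e, cds_end)
                    if a < b:
                        cds.append((a, b))
            out.append(TranscriptModel(gene, name, chrom, strand, exons, cds))
    return out


def write_refflat(transcripts, path) -> None:
    with open(path, "w") as f:
        for t in transcripts:
            cs = t.cds[0][0] if t.cds else t.exons[0][0]
            ce = t.cds[-1][1] if t.cds else t.exons[0][0]
            f.write("\t".join([
                t.gene_id, t.transcript_id, t.chrom, t.strand,
                str(t.exons[0][0]), str(t.exons[-1][1]), str(cs), str(ce),
                str(len(t.exons)),
                ",".join(str(s) for s, _ in t.exons) + ",",
                ",".join(str(e) for _, e in t.exons) + ",",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Custom database entries
# ---------------------------------------------------------------------------

@dataclass
class CustomSequenceEntry:
    """One custom-database sequence: forward-strand exon concatenation.

    ``name`` is ``label|chrom|strand|s1-e1,s2-e2,...`` and is all that is
    needed to translate alignments back to the genome.
    """

    name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def sequence(self, genome) -> str:
        return "".join(fetch(genome, self.chrom, s, e) for s, e in self.exons)


def entry_name(label: str, chrom: str, strand: str, exons) -> str:
    return f"{label}|{chrom}|{strand}|" + ",".join(f"{s}-{e}" for s, e in exons)


def parse_entry_name(name: str) -> CustomSequenceEntry:
    label, chrom, strand, ivs = name.split("|")
    exons = [tuple(int(x) for x in iv.split("-")) for iv in ivs.split(",")]
    return CustomSequenceEntry(name, chrom, strand, exons)


def build_transcript_entries(transcripts, genome):
    """One custom entry per transcript.

    Returns ``(entries, rejected)`` where ``rejected`` lists the ids of
    transcripts with no exons.  An exon outside the genome bounds raises
    :class:`AnnotationError`.
    """
    entries, rejected = [], []
    for t in transcripts:
        if not t.exons:
            rejected.append(t.transcript_id)
            log.warning("transcript %s has no exons; rejected", t.transcript_id)
            continue
        n = contig_length(genome, t.chrom)
        for s, e in t.exons:
            if s < 0 or e > n:
                raise AnnotationError(
                    f"{t.transcript_id}: exon ({s},{e}) outside {t.chrom} (len {n})")
        entries.append(CustomSequenceEntry(
            entry_name(t.transcript_id, t.chrom, t.strand, t.exons),
            t.chrom, t.strand, list(t.exons)))
    return entries, rejected


@dataclass
class AlternateExonFragment:
    """A novel exon junction plus flanking exonic sequence."""

    gene_id: str
    junction: tuple[tuple[int, int], tuple[int, int]]  # (donor exon, acceptor exon)
    entry: CustomSequenceEntry
    flank_bp: int


def _flank_intervals(chain, idx, flank_bp, upstream: bool):
    """Accumulate up to flank_bp of exonic bases from chain[idx] walking
    away from the junction; truncates at the chain ends."""
    need = flank_bp
    ivs = []
    step = -1 if upstream else 1
    i = idx
    while need > 0 and 0 <= i < len(chain):
        s, e = chain[i]
        take = min(need, e - s)
        ivs.append((e - take, e) if upstream else (s, s + take))
        need -= take
        i += step
    if upstream:
        ivs.reverse()
    return ivs


def build_alternate_exon_fragments(transcripts, genome=None, flank_bp: int = 100):
    """Enumerate per-gene novel adjacent exon pairs with flanks.

    For each gene, every ordered pair of distinct non-overlapping exons
    (first ends before second starts) that is adjacent in no transcript of
    the gene becomes one fragment.  Flank sequence is accumulated along
    the gene's genomic exon chain when the junction exons are shorter than
    ``flank_bp``.  Single-exon genes yield nothing.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)

    out = []
    for gene_id in sorted(by_gene):
        txs = by_gene[gene_id]
        chain = sorted({e for t in txs for e in t.exons})
        if len(chain) < 2:
            continue
        adjacent = {(t.exons[i], t.exons[i + 1])
                    for t in txs for i in range(len(t.exons) - 1)}
        chrom, strand = txs[0].chrom, txs[0].strand
        for i, donor in enumerate(chain):
            for j in range(i + 1, len(chain)):
                acceptor = chain[j]
                if donor[1] > acceptor[0]:        # overlapping: no junction
                    continue
                if (donor, acceptor) in adjacent:
                    continue
                up = _flank_intervals(chain, i, flank_bp, upstream=True)
                down = _flank_intervals(chain, j, flank_bp, upstream=False)
                # the walk may re-enter the partner exon's territory only
                # via the chain, never across the junction itself
                exons = up + down
                name = entry_name(
                    f"{gene_id}:altex:{donor[0]}-{donor[1]}^{acceptor[0]}-{acceptor[1]}",
                    chrom, strand, exons)
                out.append(AlternateExonFragment(
                    gene_id, (donor, acceptor),
                    CustomSequenceEntry(name, chrom, strand, exons), flank_bp))
    return out


def write_entries_fasta(entries, genome, path) -> None:
    with open(path, "w") as f:
        for entry in entries:
            f.write(f">{entry.name}\n{entry.sequence(genome)}\n")


# ---------------------------------------------------------------------------
# Coordinate translation
# ---------------------------------------------------------------------------

def translate_to_genome(pos: int, ops, entry: CustomSequenceEntry):
    """Project an alignment in custom-entry coordinates to the genome.

    Returns ``(genomic_pos, genomic_ops)`` where splice (N) operations of
    exactly the intron lengths are inserted wherever the alignment crosses
    an encoded exon boundary.  Read-consuming content is preserved
    exactly.
    """
    span = sum(ln for op, ln in ops if op in "MDN")
    if pos < 0 or pos + span > entry.length:
        raise CorruptRecordError(
            f"alignment [{pos},{pos + span}) exceeds entry length {entry.length}")

    # cumulative transcript offset of each exon start
    offsets = []
    off = 0
    for s, e in entry.exons:
        offsets.append(off)
        off += e - s

    def to_genomic(t):  # transcript offset -> genomic position
        for (s, e), o in zip(entry.exons, offsets):
            if t < o + (e - s):
                return s + (t - o)
        # one-past-the-end maps to the end of the last exon
        return entry.exons[-1][1]

    gpos = to_genomic(pos)
    gops: list[tuple[str, int]] = []

    def push(op, ln):
        if ln <= 0:
            return
        if gops and gops[-1][0] == op:
            gops[-1] = (op, gops[-1][1] + ln)
        else:
            gops.append((op, ln))

    t = pos  # current transcript offset
    for op, ln in ops:
        if op in "IS":
            push(op, ln)
            continue
        if op == "N":
            raise CorruptRecordError("splice op in transcript-space alignment")
        # M or D: consumes transcript reference; split at exon boundaries
        remain = ln
        while remain > 0:
            # exon containing t
            k = 0
            while k + 1 < len(offsets) and offsets[k + 1] <= t:
                k += 1
            s, e = entry.exons[k]
            room = (offsets[k] + (e - s)) - t
            take = min(remain, room)
            push(op, take)
            t += take
            remain -= take
            if remain > 0:
                intron = entry.exons[k + 1][0] - e
                push("N", intron)
    return gpos, gops


def translate_to_transcript(gpos: int, gops, entry: CustomSequenceEntry):
    """Inverse of :func:`translate_to_genome` on its image.

    Drops N operations and maps the genomic start back to the transcript
    offset.  Raises if the alignment strays outside the encoded exons.
    """
    offsets = []
    off = 0
    for s, e in entry.exons:
        offsets.append(off)
        off += e - s

    def to_transcript(g):
        for (s, e), o in zip(entry.exons, offsets):
            if s <= g < e:
                return o + (g - s)
        raise CorruptRecordError(f"genomic position {g} not exonic in {entry.name}")

    tpos = to_transcript(gpos)
    tops: list[tuple[str, int]] = []
    for op, ln in gops:
        if op == "N":
            continue
        if tops and tops[-1][0] == op:
            tops[-1] = (op, tops[-1][1] + ln)
        else:
            tops.append((op, ln))
    return tpos, tops


def translate_record(rec, entries_by_name):
    """Translate a transcript-space AlignmentRecord to genomic coordinates.

    The record's ``chrom`` must be a custom entry name.  Sequence and
    orientation are untouched: custom entries are forward-strand
    concatenations, so the stored sequence is already genome-forward.
    """
    if not rec.mapped:
        return rec
    entry = entries_by_name[rec.chrom] if isinstance(entries_by_name, dict) \
        else parse_entry_name(rec.chrom)
    gpos, gops = translate_to_genome(rec.pos, rec.ops, entry)
    out = rec.copy()
    out.chrom = entry.chrom
    out.pos = gpos
    out.ops = gops
    return out
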