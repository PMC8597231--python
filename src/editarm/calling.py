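"""RNA-editing SNV calling: pileup, DNA-variant subtraction, coding
restriction, artifact filters, known-site rescue, and consequence
annotation.

An RNA editing event is an RNA-specific single-nucleotide variant: present
in the RNA-Seq pileup but absent from the same patient's germline/somatic
DNA variants and from public SNP catalogues.  Candidates are restricted to
coding regions, screened for sequencing/mapping artifacts (homopolymer
reverse-transcription errors, paralog/retro-copy mis-mapping, transcript
model mis-annotation), and classified by edit chemistry (A-to-I appears as
A>G on the coding strand, C-to-U as C>T) and coding consequence.

A site whose filter-flag set is empty is a PASS call.  Known database
sites missed de novo can be *rescued* on cohort evidence: at least
``min_alt`` mutant reads in at least ``min_samples`` samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
import pysam
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .records import revcomp
from .transcript_db import fetch

log = logging.getLogger(__name__)

FLAG_GERMLINE = "germline"
FLAG_SOMATIC = "somatic"
FLAG_KNOWN_SNP = "known_snp"
FLAG_NON_CDS = "non_cds"
FLAG_HOMOPOLYMER = "homopolymer"
FLAG_PARALOG = "paralog_suspect"
FLAG_TX_MODEL = "transcript_model_suspect"


@dataclass
class VariantCandidate:
    chrom: str
    pos: int                 # 0-based
    ref_allele: str
    alt_allele: str
    total_reads: int
    alt_reads: int
    mean_alt_base_quality: float
    strand_of_gene: str = "unknown"   # '+', '-', 'unknown'


@dataclass
class EditingSiteCall(VariantCandidate):
    edit_class: str = "noncanonical"  # 'A-to-I', 'C-to-U', 'noncanonical'
    strand_ambiguous: bool = False
    consequence: str | None = None    # synonymous/missense/nonsense/stop-loss
    gene: str | None = None
    provenance: str = "de_novo"       # or 'rescued_known'
    filter_flags: set[str] = field(default_factory=set)

    @property
    def is_pass(self) -> bool:
        return not self.filter_flags


# ---------------------------------------------------------------------------
# Pileup SNV calling
# ---------------------------------------------------------------------------

def _usable(rec, min_map_q):
    return rec.mapped and not rec.duplicate_flag and rec.mapq >= min_map_q


def pileup_call(records, genome, min_alt_reads: int = 3, min_base_q: int = 20,
                min_map_q: int = 1) -> list[VariantCandidate]:
    """Per-position allele counts over aligned (M) bases of non-duplicate,
    quality-passing reads; emits one candidate per non-reference allele
    reaching ``min_alt_reads``.  Soft-clipped bases never count."""
    counts: dict[tuple[str, int], dict[str, list[int]]] = {}
    for rec in records:
        if not _usable(rec, min_map_q):
            continue
        seq = rec.seq.upper()
        for r, g in rec.aligned_pairs():
            q = rec.base_qual(r)
            if q < min_base_q:
                continue
            base = seq[r]
            if base == "N":
                continue
            counts.setdefault((rec.chrom, g), {}).setdefault(base, []).append(q)

    out = []
    for (chrom, pos), alleles in sorted(counts.items()):
        try:
            ref = fetch(genome, chrom, pos, pos + 1)
        except KeyError:
            raise KeyError(f"contig {chrom} absent from reference genome")
        total = sum(len(v) for v in alleles.values())
        for alt in sorted(alleles):
            if alt == ref:
                continue
            quals = alleles[alt]
            if len(quals) >= min_alt_reads:
                out.append(VariantCandidate(
                    chrom, pos, ref, alt, total, len(quals),
                    sum(quals) / len(quals)))
    return out


def collect_alt_supporting(records, keys, min_base_q: int = 20,
                           min_map_q: int = 1):
    """One pass over the reads gathering alt-supporting reads for many
    sites at once.

    ``keys`` is an iterable of ``(chrom, pos, alt)``; returns a dict
    mapping each key to a list of ``(record, read_offset)``.
    """
    wanted: dict[tuple[str, int], list[tuple[str, tuple]]] = {}
    out: dict[tuple, list] = {}
    for key in keys:
        chrom, pos, alt = key
        out.setdefault(key, [])
        wanted.setdefault((chrom, pos), []).append((alt, key))
    for rec in records:
        if not _usable(rec, min_map_q):
            continue
        seq = rec.seq.upper()
        for r, g in rec.aligned_pairs():
            hits = wanted.get((rec.chrom, g))
            if not hits or rec.base_qual(r) < min_base_q:
                continue
            for alt, key in hits:
                if seq[r] == alt:
                    out[key].append((rec, r))
    return out


def alt_supporting_reads(records, chrom, pos, alt, min_base_q: int = 20,
                         min_map_q: int = 1):
    """Reads contributing the alt allele at a site (with the read offset
    of the variant base)."""
    return collect_alt_supporting(records, [(chrom, pos, alt)],
                                  min_base_q, min_map_q)[(chrom, pos, alt)]


# ---------------------------------------------------------------------------
# DNA variant subtraction
# ---------------------------------------------------------------------------

def load_vcf_alleles(path) -> set[tuple[str, int, str, str]]:
    """(chrom, 0-based pos, ref, alt) for every SNV in a VCF."""
    out = set()
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1:
                    out.add((rec.chrom, rec.pos - 1, rec.ref.upper(), alt.upper()))
    return out


def subtract_dna_variants(candidates, germline=None, somatic=None,
                          snp_table=None, match_allele: bool = True):
    """Flag candidates matching DNA variants or known SNPs.

    ``germline``/``somatic``/``snp_table`` are allele sets from
    :func:`load_vcf_alleles` (or ``None``).  Matching is position+allele
    by default; ``match_allele=False`` switches to position-only.
    """
    def hit(table, c):
        if table is None:
            return False
        if match_allele:
            return (c.chrom, c.pos, c.ref_allele, c.alt_allele) in table
        return any(t[0] == c.chrom and t[1] == c.pos for t in table)

    flags = []
    for c in candidates:
        f = set()
        if hit(germline, c):
            f.add(FLAG_GERMLINE)
        if hit(somatic, c):
            f.add(FLAG_SOMATIC)
        if hit(snp_table, c):
            f.add(FLAG_KNOWN_SNP)
        flags.append(f)
    return flags


# ---------------------------------------------------------------------------
# CDS restriction
# ---------------------------------------------------------------------------

def build_cds_tree(transcripts) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for t in transcripts:
        tree = trees.setdefault(t.chrom, IntervalTree())
        for s, e in t.cds:
            tree.addi(s, e, (t.gene_id, t.strand))
    return trees


def restrict_to_cds(candidates, transcripts):
    """Assign gene strand from the covering CDS; flag non-CDS candidates.

    Returns ``(flags, genes)`` aligned with ``candidates``; candidates in
    CDS of genes on both strands keep strand 'unknown' and gain a
    transcript-model flag rather than being dropped.
    """
    trees = build_cds_tree(transcripts)
    flags, genes = [], []
    for c in candidates:
        f = set()
        hits = trees[c.chrom][c.pos] if c.chrom in trees else set()
        strands = {d for _, _, (_, d) in hits}
        gene_ids = sorted({g for _, _, (g, _) in hits})
        if not hits:
            f.add(FLAG_NON_CDS)
            c.strand_of_gene = "unknown"
            genes.append(None)
        else:
            genes.append(gene_ids[0])
            if len(strands) == 1:
                c.strand_of_gene = strands.pop()
            else:
                c.strand_of_gene = "unknown"
                f.add(FLAG_TX_MODEL)
        flags.append(f)
    return flags, genes


# ---------------------------------------------------------------------------
# Artifact filters
# ---------------------------------------------------------------------------

def homopolymer_filter(candidate, genome, min_run: int = 4,
                       max_gap: int = 1) -> bool:
    """True when the variant sits just past the end of a homopolymer.

    Reverse-transcriptase slippage errors concentrate within one base of
    the 3' end of a homopolymer read along the antisense strand; since the
    gene strand may be unknown at this stage the rule is applied to both
    ends of any run of ``min_run`` identical bases near the site (for one
    of the two strands that end is the antisense-strand 3' end).  The
    variant may be separated from the run by up to ``max_gap`` bases.
    """
    chrom, pos = candidate.chrom, candidate.pos
    lo = max(pos - (min_run + max_gap + 1), 0)
    hi = min(pos + (min_run + max_gap + 1) + 1, len(genome[chrom]))
    ctx = fetch(genome, chrom, lo, hi)
    center = pos - lo
    masked = ctx[:center] + "." + ctx[center + 1:]

    runs = []
    i = 0
    while i < len(masked):
        j = i
        while j < len(masked) and masked[j] == masked[i] and masked[i] in "ACGT":
            j += 1
        if j - i >= min_run:
            runs.append((i, j))          # [i, j)
        i = max(j, i + 1)
    for s, e in runs:
        if e <= center and center - e <= max_gap:        # run on the left
            return True
        if s > center and s - center - 1 <= max_gap:     # run on the right
            return True
    return False


def _best_gapless_placement(read: str, seq: str):
    """(score, start, strand) of the best gapless placement of read in
    seq, scanning both orientations; score = matching bases."""
    import numpy as np
    best = (-1, -1, "+")
    n = len(read)
    if len(seq) < n:
        return best
    seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(seq_arr, n)
    for strand, r in (("+", read), ("-", revcomp(read))):
        r_arr = np.frombuffer(r.encode(), dtype=np.uint8)
        scores = (windows == r_arr).sum(axis=1)
        i = int(scores.argmax())
        if scores[i] > best[0]:
            best = (int(scores[i]), i, strand)
    return best


def _may_beat(read: str, seq_f: str, seq_r: str, max_mismatch: int) -> bool:
    """Pigeonhole gate: a placement with <= max_mismatch mismatches must
    contain one of max_mismatch+1 disjoint read chunks exactly."""
    n = len(read)
    k = max(int(max_mismatch), 0) + 1
    step = max(n // k, 1)
    for i in range(0, k * step, step):
        chunk = read[i:i + step]
        if chunk and (chunk in seq_f or chunk in seq_r):
            return True
    return False


def paralog_suspect_filter(candidate, supporting, paralog_db: dict[str, str],
                           genome, min_fraction: float = 0.5) -> bool:
    """True when alt-supporting reads re-place onto a paralogous sequence.

    ``supporting`` is the output of :func:`alt_supporting_reads`.  A read
    votes "suspect" when some database sequence admits a placement with at
    least as many matching bases as the read's current genomic placement
    *and* the database base aligned to the variant offset equals the alt
    allele (i.e. the apparent variant is the paralog's reference).  The
    candidate is flagged when the voting fraction reaches
    ``min_fraction``.
    """
    if not paralog_db:
        log.warning("paralog database missing; paralog filter skipped")
        return False
    if not supporting:
        return False
    alt = candidate.alt_allele
    db = [(seq.upper(), revcomp(seq.upper())) for seq in paralog_db.values()]
    votes = 0
    for rec, r_off in supporting:
        read = rec.seq.upper()
        ref = fetch(genome, rec.chrom, rec.pos, rec.end)
        cur = sum(1 for r, g in rec.aligned_pairs()
                  if read[r] == ref[g - rec.pos])
        for seq_f, seq_r in db:
            if not _may_beat(read, seq_f, seq_r, len(read) - cur):
                continue
            score, start, strand = _best_gapless_placement(read, seq_f)
            if score < cur:
                continue
            off = r_off if strand == "+" else len(read) - 1 - r_off
            db_base = seq_f[start + off]
            want = alt if strand == "+" else revcomp(alt)
            if db_base == want:
                votes += 1
                break
    return votes / len(supporting) >= min_fraction


def transcript_model_suspect(supporting, pos, window: int = 5,
                             min_fraction: float = 0.5) -> bool:
    """Flag sites where most alt-supporting reads are soft-clipped within
    ``window`` bp of the site — the signature of a missing exon in the
    transcript model."""
    if not supporting:
        return False
    votes = 0
    for rec, _ in supporting:
        for clip_pos in _soft_clip_boundaries(rec):
            if abs(clip_pos - pos) <= window:
                votes += 1
                break
    return votes / len(supporting) >= min_fraction


def _soft_clip_boundaries(rec):
    out = []
    if rec.ops and rec.ops[0][0] == "S":
        out.append(rec.pos)
    if rec.ops and rec.ops[-1][0] == "S":
        out.append(rec.end)
    return out


# ---------------------------------------------------------------------------
# Edit class and consequence
# ---------------------------------------------------------------------------

_CANON = {("A", "G"): "A-to-I", ("C", "T"): "C-to-U"}


def classify_edit_type(ref: str, alt: str, strand_of_gene: str):
    """Return ``(edit_class, ambiguous)``.

    A>G on a + gene (T>C on a -) is A-to-I; C>T on a + (G>A on a -) is
    C-to-U.  With unknown strand the site is classified by whichever
    orientation yields a canonical class, and marked ambiguous (only when
    the call depended on picking an orientation).
    """
    ref, alt = ref.upper(), alt.upper()
    fwd = _CANON.get((ref, alt))
    rev = _CANON.get((revcomp(ref), revcomp(alt)))
    if strand_of_gene == "+":
        return (fwd or "noncanonical"), False
    if strand_of_gene == "-":
        return (rev or "noncanonical"), False
    if fwd and rev:          # cannot happen for SNVs, kept for safety
        return fwd, True
    if fwd:
        return fwd, True
    if rev:
        return rev, True
    return "noncanonical", False


_SEVERITY = {"synonymous": 0, "missense": 1, "stop-loss": 2, "nonsense": 3}


def annotate_consequence(chrom, pos, ref, alt, transcripts, genome) -> str:
    """Coding consequence of the substitution; worst across transcripts.

    The codon is reconstructed on the coding strand of each transcript
    whose CDS contains the site.  stop gained -> nonsense, stop lost ->
    stop-loss, amino-acid change -> missense, else synonymous.
    """
    worst = None
    for t in transcripts:
        if t.chrom != chrom or not any(s <= pos < e for s, e in t.cds):
            continue
        cds_fwd = "".join(fetch(genome, chrom, s, e) for s, e in t.cds)
        off = 0
        for s, e in t.cds:
            if s <= pos < e:
                off += pos - s
                break
            off += e - s
        alt_fwd = cds_fwd[:off] + alt.upper() + cds_fwd[off + 1:]
        if t.strand == "-":
            cds_ref, cds_alt = revcomp(cds_fwd), revcomp(alt_fwd)
            coff = len(cds_fwd) - 1 - off
        else:
            cds_ref, cds_alt = cds_fwd, alt_fwd
            coff = off
        ci = coff // 3
        ref_codon = cds_ref[3 * ci:3 * ci + 3]
        alt_codon = cds_alt[3 * ci:3 * ci + 3]
        if len(ref_codon) < 3:
            continue
        aa_ref = str(Seq(ref_codon).translate())
        aa_alt = str(Seq(alt_codon).translate())
        if aa_ref == aa_alt:
            cons = "synonymous"
        elif aa_alt == "*":
            cons = "nonsense"
        elif aa_ref == "*":
            cons = "stop-loss"
        else:
            cons = "missense"
        if worst is None or _SEVERITY[cons] > _SEVERITY[worst]:
            worst = cons
    if worst is None:
        raise ValueError(f"site {chrom}:{pos} not in any CDS")
    return worst


# ---------------------------------------------------------------------------
# Known-site rescue
# ---------------------------------------------------------------------------

def read_known_sites(path) -> pd.DataFrame:
    """Known editing-site TSV: chrom, pos (1-based), ref, alt, gene,
    strand.  Malformed rows are skipped with a log entry.  Returned
    positions are 0-based."""
    rows = []
    with open(path) as f:
        for ln, line in enumerate(f, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            t = line.split("\t")
            try:
                rows.append(dict(chrom=t[0], pos=int(t[1]) - 1,
                                 ref=t[2].upper(), alt=t[3].upper(),
                                 gene=t[4], strand=t[5]))
            except (IndexError, ValueError):
                log.warning("skipping malformed known-site row %d: %r", ln, line)
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "gene", "strand"])


def rescue_known_sites(known: pd.DataFrame, reports_by_sample: dict,
                       min_alt: int = 3, min_samples: int = 2):
    """Rescue known sites supported by >= ``min_alt`` mutant reads in
    >= ``min_samples`` samples.

    ``reports_by_sample`` maps sample id to a read-report DataFrame
    indexed like the output of :func:`editarm.quantify.read_report`.
    Returns :class:`EditingSiteCall` objects with provenance
    ``rescued_known``.
    """
    out = []
    for _, row in known.iterrows():
        n_supporting = 0
        tot_alt = tot_cov = 0
        for rep in reports_by_sample.values():
            sel = rep[(rep["chrom"] == row.chrom) & (rep["pos"] == row.pos)
                      & (rep["alt"] == row.alt)]
            if sel.empty:
                continue
            alt_reads = int(sel["mutant_reads"].iloc[0])
            if alt_reads >= min_alt:
                n_supporting += 1
                tot_alt += alt_reads
                tot_cov += int(sel["coverage"].iloc[0])
        if n_supporting >= min_samples:
            cls, amb = classify_edit_type(row.ref, row.alt, row.strand)
            out.append(EditingSiteCall(
                chrom=row.chrom, pos=row.pos, ref_allele=row.ref,
                alt_allele=row.alt, total_reads=tot_cov, alt_reads=tot_alt,
                mean_alt_base_quality=float("nan"),
                strand_of_gene=row.strand, edit_class=cls,
                strand_ambiguous=amb, gene=row.gene,
                provenance="rescued_known"))
    return out


# ---------------------------------------------------------------------------
# One-sample calling pipeline
# ---------------------------------------------------------------------------

def call_editing_sites(records, genome, transcripts, *, germline=None,
                       somatic=None, snp_table=None,
                       paralog_db: dict[str, str] | None = None,
                       min_alt_reads: int = 3, min_base_q: int = 20,
                       min_map_q: int = 1, homopolymer_min_run: int = 4,
                       paralog_min_fraction: float = 0.5,
                       match_allele: bool = True) -> list[EditingSiteCall]:
    """De novo editing calls for one sample's refined alignments.

    ``germline``/``somatic``/``snp_table`` are allele sets (see
    :func:`load_vcf_alleles`).  Every candidate is returned with its
    filter flags; PASS calls are those with an empty flag set.
    """
    candidates = pileup_call(records, genome, min_alt_reads, min_base_q,
                             min_map_q)
    dna_flags = subtract_dna_variants(candidates, germline, somatic,
                                      snp_table, match_allele)
    cds_flags, genes = restrict_to_cds(candidates, transcripts)
    support = collect_alt_supporting(
        records, [(c.chrom, c.pos, c.alt_allele) for c in candidates],
        min_base_q, min_map_q)

    calls = []
    for cand, f_dna, f_cds, gene in zip(candidates, dna_flags, cds_flags, genes):
        flags = f_dna | f_cds
        supporting = support[(cand.chrom, cand.pos, cand.alt_allele)]
        if homopolymer_filter(cand, genome, homopolymer_min_run):
            flags.add(FLAG_HOMOPOLYMER)
        if paralog_db and paralog_suspect_filter(
                cand, supporting, paralog_db, genome, paralog_min_fraction):
            flags.add(FLAG_PARALOG)
        if transcript_model_suspect(supporting, cand.pos):
            flags.add(FLAG_TX_MODEL)
        cls, amb = classify_edit_type(cand.ref_allele, cand.alt_allele,
                                      cand.strand_of_gene)
        cons = None
        if FLAG_NON_CDS not in flags:
            cons = annotate_consequence(cand.chrom, cand.pos, cand.ref_allele,
                                        cand.alt_allele, transcripts, genome)
        calls.append(EditingSiteCall(
            chrom=cand.chrom, pos=cand.pos, ref_allele=cand.ref_allele,
            alt_allele=cand.alt_allele, total_reads=cand.total_reads,
            alt_reads=cand.alt_reads,
            mean_alt_base_quality=cand.mean_alt_base_quality,
            strand_of_gene=cand.strand_of_gene, edit_class=cls,
            strand_ambiguous=amb, consequence=cons, gene=gene,
            provenance="de_novo", filter_flags=flags))
    return calls


def review_report(calls) -> pd.DataFrame:
    """TSV-able table of flagged (non-PASS) sites for review."""
    rows = [dict(chrom=c.chrom, pos=c.pos + 1, ref=c.ref_allele,
                 alt=c.alt_allele, gene=c.gene, edit_class=c.edit_class,
                 alt_reads=c.alt_reads, total_reads=c.total_reads,
                 flags=",".join(sorted(c.filter_flags)))
            for c in calls if c.filter_flags]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene",
                                       "edit_class", "alt_reads",
                                       "total_reads", "flags"])


def write_calls_vcf(calls, contigs: dict[str, int], path) -> None:
    """Write PASS calls as VCF with edit class/consequence/provenance INFO."""
    header = pysam.VariantHeader()
    for name, ln in contigs.items():
        header.contigs.add(name, length=ln)
    header.info.add("EDIT_CLASS", 1, "String", "Editing chemistry class")
    header.info.add("CONSEQUENCE", 1, "String", "Coding consequence")
    header.info.add("PROVENANCE", 1, "String", "de_novo or rescued_known")
    header.info.add("GENE", 1, "String", "Gene symbol")
    with pysam.VariantFile(path, "w", header=header) as out:
        for c in sorted((c for c in calls if c.is_pass),
                        key=lambda c: (c.chrom, c.pos)):
            rec = out.new_record(contig=c.chrom, start=c.pos, stop=c.pos + 1,
                                 alleles=(c.ref_allele, c.alt_allele))
            rec.info["EDIT_CLASS"] = c.edit_class.replace("-", "_")
            if c.consequence:
                rec.info["CONSEQUENCE"] = c.consequence.replace("-", "_")
            rec.info["PROVENANCE"] = c.provenance
            if c.gene:
                rec.info["GENE"] = c.gene
            out.write(rec)
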