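"""Seeded synthetic data: genome, annotation, variants, reads, truth.

The generator emulates the structures the editing pipeline has to cope
with: a small multi-gene genome with introns and complete ORFs, one
intronless retro-copy (processed pseudogene) of a multi-exon gene,
homopolymer runs adjacent to designated artifact sites, heterozygous
germline SNPs, and paired RNA reads carrying A-to-I / C-to-U edits at
per-site rates on top of base-call errors.  Candidate alignments for the
competitive selector are emitted directly (per mapper/database source),
with deliberate degradations — soft-clipped junction reads and retro-copy
mis-placements — so that selection and refinement have real work to do.

Everything is driven by ``numpy`` generators seeded from ``(seed, stream)``
pairs, one stream per entity, so outputs are byte-stable under a fixed
seed and adding one feature does not perturb the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

from .calling import homopolymer_filter, VariantCandidate
from .records import AlignmentRecord, revcomp, unmapped_record
from .transcript_db import (CustomSequenceEntry, TranscriptModel,
                            build_transcript_entries, translate_to_genome)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in _STOPS]


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a desk-scale cohort: 5 spliced genes, 30 editing
    sites at rates 0.05-0.5 (roughly 90% A-to-I), 20 heterozygous SNPs,
    an expressed-gene retro-copy trap, 101 bp paired reads at 50x
    transcript depth with a 0.2% substitution error rate.
    """

    n_genes: int = 5
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_length: tuple[int, int] = (150, 300)
    intron_length: tuple[int, int] = (200, 600)
    n_edit_sites: int = 30
    edit_rate_range: tuple[float, float] = (0.05, 0.5)
    c_to_u_fraction: float = 0.1
    n_germline_snps: int = 20
    het_fraction: float = 1.0
    retrocopy: bool = True
    retrocopy_identity: float = 0.997
    n_planted_divergences: int = 3
    homopolymer_length: int = 6
    n_homopolymer_sites: int = 1
    artifact_edit_rate: float = 0.08
    read_length: int = 101
    fragment_mean: float = 280.0
    fragment_sd: float = 40.0
    depth: int = 50
    base_error: float = 0.002
    duplicate_rate: float = 0.02
    junction_softclip_rate: float = 0.10
    retro_misplace_rate: float = 0.5
    per_molecule: bool = False

    def validate(self):
        if self.exon_length[0] < self.read_length:
            raise SimConfigError(
                f"shortest exon ({self.exon_length[0]}) shorter than read "
                f"length ({self.read_length})")
        for r in (self.edit_rate_range[0], self.edit_rate_range[1],
                  self.base_error, self.duplicate_rate,
                  self.junction_softclip_rate, self.retro_misplace_rate,
                  self.artifact_edit_rate):
            if not 0.0 <= r <= 1.0:
                raise SimConfigError(f"rate {r} outside [0, 1]")


@dataclass
class GeneTruth:
    index: int
    gene_id: str
    strand: str
    mrna: str                       # coding-strand transcript sequence
    mrna_exon_lens: list[int]       # exon lengths in mRNA order
    junctions: list[int]            # mRNA offsets of exon boundaries
    model: TranscriptModel
    entry: CustomSequenceEntry


@dataclass
class SimReference:
    config: SimConfig
    seed: int
    genome: dict[str, str]
    contigs: dict[str, int]
    genes: list[GeneTruth]
    transcripts: list[TranscriptModel]       # includes the retro-copy gene
    entries_by_name: dict[str, CustomSequenceEntry]
    truth_sites: pd.DataFrame    # chrom,pos,ref,alt,gene,strand,mrna_offset,rate,edit_class,kind,in_known_db
    truth_snps: pd.DataFrame     # chrom,pos,ref,alt,gene,genotype,mrna_offset,mrna_alt
    known_sites: pd.DataFrame    # chrom,pos,ref,alt,gene,strand,is_true_edit
    paralog_db: dict[str, str]
    retro_pad: int = 0
    retro_gene_index: int = 0
    retro_zone: tuple[int, int] | None = None   # mRNA offsets on gene 0
    junction0: int | None = None


@dataclass
class FragmentTruth:
    fid: str
    gene: int
    start: int            # mRNA offset of fragment start
    frag_len: int
    hap: int
    r1_seq: str           # as sequenced (r1 = sense, r2 = antisense)
    r2_seq: str
    r1_edits: list[int] = field(default_factory=list)   # truth site row ids
    r2_edits: list[int] = field(default_factory=list)
    retro: bool = False
    r1_softclip: bool = False
    r2_softclip: bool = False
    duplicate: bool = False


@dataclass
class SampleReads:
    sample_id: str
    fragments: list[FragmentTruth]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _rand_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _other_base(rng, b: str) -> str:
    choices = [x for x in "ACGT" if x != b]
    return choices[rng.integers(0, 3)]


def _apply_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if not len(hits):
        return seq
    s = list(seq)
    for i in hits:
        s[i] = _other_base(rng, s[i])
    return "".join(s)


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _make_orf(rng, n_codons: int) -> str:
    body = [_SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS),
                                                  size=n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


def make_reference(config: SimConfig | None = None, seed: int = 1) -> SimReference:
    """Build the genome, annotation, variant truth, and paralog database."""
    config = config or SimConfig()
    config.validate()
    rng = _rng(seed, 0)

    pad = 400
    chr1_parts = [_rand_seq(rng, pad)]
    cursor = pad
    genes: list[GeneTruth] = []

    for gi in range(config.n_genes):
        strand = "+" if gi % 2 == 0 else "-"
        n_ex = int(rng.integers(config.exons_per_gene[0],
                                config.exons_per_gene[1] + 1))
        lens = [int(rng.integers(config.exon_length[0],
                                 config.exon_length[1] + 1))
                for _ in range(n_ex)]
        total = sum(lens)
        lens[-1] += (-total) % 3
        total = sum(lens)
        mrna = _make_orf(rng, total // 3)

        if gi == 1 and config.n_homopolymer_sites > 0:
            mrna = _plant_homopolymers(rng, mrna, config)

        # lay the gene on chr1: forward concat is the mRNA for '+' genes,
        # its reverse complement for '-' genes
        fwd = mrna if strand == "+" else revcomp(mrna)
        exon_ivs = []
        off = 0
        mrna_lens = lens if strand == "+" else lens[::-1]
        for k, ln in enumerate(lens):
            chr1_parts.append(fwd[off:off + ln])
            exon_ivs.append((cursor, cursor + ln))
            cursor += ln
            off += ln
            if k < n_ex - 1:
                intron = int(rng.integers(config.intron_length[0],
                                          config.intron_length[1] + 1))
                chr1_parts.append(_rand_seq(rng, intron))
                cursor += intron
        chr1_parts.append(_rand_seq(rng, pad))
        cursor += pad

        model = TranscriptModel(f"GENE{gi}", f"GENE{gi}.1", "chr1", strand,
                                exon_ivs, exon_ivs)
        junctions = list(np.cumsum(mrna_lens)[:-1])
        genes.append(GeneTruth(gi, f"GENE{gi}", strand, mrna,
                               list(mrna_lens), [int(j) for j in junctions],
                               model, None))

    genome = {"chr1": "".join(chr1_parts)}

    # retro-copy of gene 0 on its own contig (an expressed-paralog trap)
    retro_pad = 300
    retro_zone = junction0 = None
    transcripts = [g.model for g in genes]
    if config.retrocopy:
        g0 = genes[0]
        junction0 = g0.junctions[len(g0.junctions) // 2]
        # exclude SNP/edit placement from everything a retro-misplaced
        # fragment can touch, so no true variant leaks onto the retro contig
        reach = int(config.fragment_mean + 4 * config.fragment_sd)
        retro_zone = (junction0 - reach, junction0 + reach)
        retro = list(g0.mrna)
        rng_r = _rng(seed, 1)
        n_rand = int(round(len(retro) * (1 - config.retrocopy_identity)))
        rand_pos = rng_r.choice(len(retro), size=n_rand, replace=False)
        planted = [junction0 - 40, junction0 + 15, junction0 + 45][
            :config.n_planted_divergences]
        for p in list(rand_pos) + planted:
            p = int(p)
            if 3 <= p < len(retro) - 3:
                retro[p] = _other_base(rng_r, retro[p])
        retro_seq = "".join(retro)
        genome["chr2"] = (_rand_seq(rng_r, retro_pad) + retro_seq
                          + _rand_seq(rng_r, retro_pad))
        retro_model = TranscriptModel(
            "GENE0P", "GENE0P.1", "chr2", "+",
            [(retro_pad, retro_pad + len(retro_seq))],
            [(retro_pad, retro_pad + len(retro_seq))])
        transcripts.append(retro_model)

    entries, _ = build_transcript_entries(transcripts, genome)
    by_name = {e.name: e for e in entries}
    for g in genes:
        g.entry = by_name[[n for n in by_name if n.startswith(g.model.transcript_id + "|")][0]]

    snps = _place_snps(config, seed, genes, genome, retro_zone)
    sites = _place_edit_sites(config, seed, genes, genome, snps, retro_zone)

    if config.retrocopy:
        sites = pd.concat([sites, _divergence_truth(genes[0], genome,
                                                    retro_pad, retro_zone,
                                                    junction0)],
                          ignore_index=True)

    known = _known_table(config, seed, sites, snps, genes, genome)
    paralog_db = {t.transcript_id: t.spliced_sequence(genome)
                  for t in transcripts}

    return SimReference(
        config=config, seed=seed, genome=genome,
        contigs={c: len(s) for c, s in genome.items()},
        genes=genes, transcripts=transcripts, entries_by_name=by_name,
        truth_sites=sites, truth_snps=snps, known_sites=known,
        paralog_db=paralog_db, retro_pad=retro_pad,
        retro_zone=retro_zone, junction0=junction0)


def _plant_homopolymers(rng, mrna: str, config: SimConfig) -> str:
    """Insert codon-aligned T-runs followed by a C codon; the base just 3'
    of each run is the designated artifact-test site."""
    L = config.homopolymer_length + (-config.homopolymer_length) % 3
    out = list(mrna)
    n_codons = len(mrna) // 3
    for k in range(config.n_homopolymer_sites):
        ci = n_codons // 2 + 4 * k
        start = 3 * ci
        out[start:start + L] = "T" * L
        out[start + L:start + L + 3] = "CAG"     # artifact site: the C
    return "".join(out)


def _in_zone(off, zone):
    return zone is not None and zone[0] <= off < zone[1]


def _mrna_alt_to_genomic(gene: GeneTruth, off: int, alt: str):
    pos = gene.model.mrna_to_genomic(off)
    ref = gene.mrna[off]
    if gene.strand == "-":
        return pos, revcomp(ref), revcomp(alt)
    return pos, ref, alt


def _place_snps(config, seed, genes, genome, retro_zone):
    rng = _rng(seed, 2)
    lens = np.array([len(g.mrna) for g in genes], dtype=float)
    rows, used = [], set()
    tries = 0
    while len(rows) < config.n_germline_snps and tries < 10_000:
        tries += 1
        gi = int(rng.choice(len(genes), p=lens / lens.sum()))
        g = genes[gi]
        off = int(rng.integers(3, len(g.mrna) - 3))
        if gi == 0 and _in_zone(off, retro_zone):
            continue
        if any(abs(off - o) < 4 for gg, o in used if gg == gi):
            continue
        alt_mrna = _other_base(rng, g.mrna[off])
        pos, ref, alt = _mrna_alt_to_genomic(g, off, alt_mrna)
        gt = "het" if rng.random() < config.het_fraction else "hom"
        used.add((gi, off))
        rows.append(dict(chrom="chr1", pos=pos, ref=ref, alt=alt,
                         gene=g.gene_id, genotype=gt, mrna_offset=off,
                         mrna_alt=alt_mrna))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene",
                                       "genotype", "mrna_offset", "mrna_alt"])


def _context_clear(genome, chrom, pos):
    probe = VariantCandidate(chrom, pos, "N", "N", 0, 0, 0.0)
    return not homopolymer_filter(probe, genome)


def _place_edit_sites(config, seed, genes, genome, snps, retro_zone):
    rng = _rng(seed, 3)
    lens = np.array([len(g.mrna) for g in genes], dtype=float)
    margin = config.read_length + 20
    snp_keys = {(r.gene, r.mrna_offset) for r in snps.itertuples()}
    rows, used = [], set()
    tries = 0
    while len(rows) < config.n_edit_sites and tries < 50_000:
        tries += 1
        cls = "C-to-U" if rng.random() < config.c_to_u_fraction else "A-to-I"
        want_ref, want_alt = ("C", "T") if cls == "C-to-U" else ("A", "G")
        gi = int(rng.choice(len(genes), p=lens / lens.sum()))
        g = genes[gi]
        if len(g.mrna) <= 2 * margin:
            continue
        off = int(rng.integers(margin, len(g.mrna) - margin))
        if g.mrna[off] != want_ref:
            continue
        if gi == 0 and _in_zone(off, retro_zone):
            continue
        if (g.gene_id, off) in snp_keys or (gi, off) in used \
                or any(abs(off - o) < 6 for gg, o in used if gg == gi):
            continue
        pos, ref, alt = _mrna_alt_to_genomic(g, off, want_alt)
        if not _context_clear(genome, "chr1", pos):
            continue
        used.add((gi, off))
        rate = float(rng.uniform(*config.edit_rate_range))
        rows.append(dict(chrom="chr1", pos=pos, ref=ref, alt=alt,
                         gene=g.gene_id, strand=g.strand, mrna_offset=off,
                         rate=rate, edit_class=cls, kind="edit",
                         gene_index=gi))
    # designated homopolymer artifact sites (RT-error emulation) on gene 1
    g1 = genes[1] if len(genes) > 1 else None
    if g1 is not None and config.n_homopolymer_sites > 0:
        L = config.homopolymer_length + (-config.homopolymer_length) % 3
        n_codons = len(g1.mrna) // 3
        for k in range(config.n_homopolymer_sites):
            off = 3 * (n_codons // 2 + 4 * k) + L
            pos, ref, alt = _mrna_alt_to_genomic(g1, off, "T")  # C>T artifact
            rows.append(dict(chrom="chr1", pos=pos, ref=ref, alt=alt,
                             gene=g1.gene_id, strand=g1.strand,
                             mrna_offset=off, rate=config.artifact_edit_rate,
                             edit_class="C-to-U", kind="artifact_homopolymer",
                             gene_index=1))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene",
                                       "strand", "mrna_offset", "rate",
                                       "edit_class", "kind", "gene_index"])


def _divergence_truth(g0, genome, retro_pad, retro_zone, junction0):
    """Positions where the retro-copy differs from gene 0, as expected
    artifact variant calls on the retro contig (alt = gene 0's base)."""
    retro = genome["chr2"][retro_pad:retro_pad + len(g0.mrna)]
    rows = []
    for off, (a, b) in enumerate(zip(g0.mrna, retro)):
        if a != b:
            rows.append(dict(chrom="chr2", pos=retro_pad + off, ref=b, alt=a,
                             gene="GENE0P", strand="+", mrna_offset=off,
                             rate=0.0, edit_class="noncanonical",
                             kind="paralog_divergence", gene_index=0))
    return pd.DataFrame(rows)


def _known_table(config, seed, sites, snps, genes, genome):
    """60% of the true edit sites plus unedited decoy sites."""
    rng = _rng(seed, 4)
    true_edits = sites[sites["kind"] == "edit"]
    n_known = int(round(0.6 * len(true_edits)))
    idx = sorted(rng.choice(true_edits.index, size=n_known, replace=False))
    rows = [dict(chrom=r.chrom, pos=r.pos, ref=r.ref, alt=r.alt, gene=r.gene,
                 strand=r.strand, is_true_edit=True)
            for r in true_edits.loc[idx].itertuples()]
    # decoys: adenosines never edited in the simulation
    margin = config.read_length + 20
    made, tries = 0, 0
    taken = {(r.chrom, r.pos) for r in sites.itertuples()}
    taken |= {(r.chrom, r.pos) for r in snps.itertuples()}
    while made < 5 and tries < 5000:
        tries += 1
        g = genes[int(rng.integers(0, len(genes)))]
        off = int(rng.integers(margin, len(g.mrna) - margin))
        if g.mrna[off] != "A":
            continue
        pos, ref, alt = _mrna_alt_to_genomic(g, off, "G")
        if ("chr1", pos) in taken:
            continue
        taken.add(("chr1", pos))
        rows.append(dict(chrom="chr1", pos=pos, ref=ref, alt=alt,
                         gene=g.gene_id, strand=g.strand, is_true_edit=False))
        made += 1
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene",
                                       "strand", "is_true_edit"])


# ---------------------------------------------------------------------------
# RNA read simulation
# ---------------------------------------------------------------------------

def _spans(span, junction, anchor=8):
    return span[0] + anchor <= junction <= span[1] - anchor


def simulate_reads(ref: SimReference, sample_index: int = 0) -> SampleReads:
    """Paired RNA reads for one cohort sample.

    Fragments are sampled uniformly per transcript at the configured
    depth; R1 is the sense read.  Heterozygous SNPs ride on haplotype 1;
    each covering read carries an edit with the site's rate independently
    (``per_molecule`` couples both mates of a fragment); base errors are
    applied last.  Degradation flags (junction soft-clip, retro-copy
    misplacement) are drawn here and consumed by
    :func:`write_candidate_alignments`.
    """
    cfg = ref.config
    rng = _rng(ref.seed, 1000 + sample_index)
    rl = cfg.read_length
    sites = ref.truth_sites
    frags: list[FragmentTruth] = []

    for g in ref.genes:
        L = len(g.mrna)
        gene_sites = sites[(sites["gene_index"] == g.index)
                           & (sites["chrom"] == "chr1")]
        snp_rows = ref.truth_snps[ref.truth_snps["gene"] == g.gene_id]
        hap1 = list(g.mrna)          # haplotype 1 carries every SNP alt
        for r in snp_rows.itertuples():
            hap1[r.mrna_offset] = r.mrna_alt
        haps = ["".join(_hom_apply(g.mrna, snp_rows)), "".join(hap1)]

        max_frag = min(L, int(cfg.fragment_mean + 4 * cfg.fragment_sd))
        n_frag = int(round(cfg.depth * L / (2 * rl)))
        for f in range(n_frag):
            frag_len = int(np.clip(rng.normal(cfg.fragment_mean,
                                              cfg.fragment_sd), rl, max_frag))
            start = int(rng.integers(0, L - frag_len + 1))
            hap = int(rng.integers(0, 2))
            fid = f"S{sample_index}_G{g.index}_F{f}"
            frag = _make_fragment(ref, rng, g, haps[hap], hap, start,
                                  frag_len, fid, gene_sites)
            frags.append(frag)
            if rng.random() < cfg.duplicate_rate:
                frags.append(replace(frag, fid=fid + "d", duplicate=True))
    return SampleReads(sample_id=f"sample{sample_index}", fragments=frags)


def _hom_apply(mrna, snp_rows):
    out = list(mrna)
    for r in snp_rows.itertuples():
        if r.genotype == "hom":
            out[r.mrna_offset] = r.mrna_alt
    return out


def _make_fragment(ref, rng, g, hap_seq, hap, start, frag_len, fid,
                   gene_sites) -> FragmentTruth:
    cfg = ref.config
    rl = cfg.read_length
    spans = [(start, start + rl), (start + frag_len - rl, start + frag_len)]
    segs, edits = [], [[], []]
    mol_draw = {}
    for m, (a, b) in enumerate(spans):
        seg = list(hap_seq[a:b])
        for s in gene_sites.itertuples():
            off = s.mrna_offset
            if a <= off < b:
                if cfg.per_molecule:
                    hit = mol_draw.setdefault(s.Index, rng.random() < s.rate)
                else:
                    hit = rng.random() < s.rate
                if hit:
                    # seg is mRNA (coding strand): use the coding-strand alt
                    seg[off - a] = (s.alt if g.strand == "+"
                                    else revcomp(s.alt))
                    edits[m].append(s.Index)
        segs.append("".join(seg))

    r1 = _apply_errors(rng, segs[0], cfg.base_error)
    r2 = _apply_errors(rng, revcomp(segs[1]), cfg.base_error)

    retro = False
    if cfg.retrocopy and g.index == 0 and ref.junction0 is not None:
        if any(_spans(sp, ref.junction0) for sp in spans):
            retro = rng.random() < cfg.retro_misplace_rate
    sc = [False, False]
    if not retro:
        for m, sp in enumerate(spans):
            if any(_spans(sp, j) for j in g.junctions):
                sc[m] = rng.random() < cfg.junction_softclip_rate
    return FragmentTruth(fid=fid, gene=g.index, start=start,
                         frag_len=frag_len, hap=hap, r1_seq=r1, r2_seq=r2,
                         r1_edits=edits[0], r2_edits=edits[1], retro=retro,
                         r1_softclip=sc[0], r2_softclip=sc[1])


# ---------------------------------------------------------------------------
# Candidate alignment emission (the stand-in for running five aligners)
# ---------------------------------------------------------------------------

def _match_count(stored: str, ref_seq: str) -> int:
    return sum(a == b for a, b in zip(stored, ref_seq))


def _entry_placement(g: GeneTruth, span, read_seq, sense: bool):
    """(entry_pos, stored_seq, reverse) for a read over mRNA ``span``."""
    L = len(g.mrna)
    reverse = (g.strand == "+") != sense
    stored = revcomp(read_seq) if reverse else read_seq
    pos = span[0] if g.strand == "+" else L - span[1]
    return pos, stored, reverse


def _genomic_blocks(gpos, gops):
    """M blocks of a spliced alignment as (read_off, genome_pos, length)."""
    blocks, r, p = [], 0, gpos
    for op, ln in gops:
        if op == "M":
            blocks.append((r, p, ln))
            r += ln
            p += ln
        elif op in "DN":
            p += ln
        else:
            r += ln
    return blocks


def _softclip_at_junction(gpos, gops, stored, genome, chrom):
    """BWA-like unspliced version: keep the longest M block, clip the rest."""
    blocks = _genomic_blocks(gpos, gops)
    r_off, b_pos, b_len = max(blocks, key=lambda b: b[2])
    ops = []
    if r_off:
        ops.append(("S", r_off))
    ops.append(("M", b_len))
    rest = len(stored) - r_off - b_len
    if rest:
        ops.append(("S", rest))
    mc = _match_count(stored[r_off:r_off + b_len],
                      genome[chrom][b_pos:b_pos + b_len])
    return b_pos, ops, mc


def write_candidate_alignments(ref: SimReference, reads: SampleReads,
                               sources=(1, 4, 5)) -> dict[int, list[AlignmentRecord]]:
    """Per-source candidate records emulating multi-source mapping.

    Source 1 (transcript database, custom-entry coordinates): perfect
    placements, except that retro-misplaced fragments come back unmapped.
    Source 4 (genome, BWA-like): gapless placements; junction-spanning
    reads are soft-clipped to their longest exonic anchor; retro-misplaced
    fragments land full length on the retro-copy contig.  Source 5
    (genome, STAR-like): true spliced placements, with the configured
    fraction of junction reads degraded to soft-clips.  With all
    degradation rates at zero the three sources agree on every read.
    """
    cfg = ref.config
    rl = cfg.read_length
    out: dict[int, list[AlignmentRecord]] = {s: [] for s in sources}
    entry_seqs = {g.index: g.entry.sequence(ref.genome) for g in ref.genes}

    for frag in reads.fragments:
        g = ref.genes[frag.gene]
        spans = [(frag.start, frag.start + rl),
                 (frag.start + frag.frag_len - rl,
                  frag.start + frag.frag_len)]
        seqs = [frag.r1_seq, frag.r2_seq]
        for m in (0, 1):
            sense = m == 0
            span, read_seq = spans[m], seqs[m]
            epos, stored, rev = _entry_placement(g, span, read_seq, sense)
            gpos, gops = translate_to_genome(epos, [("M", rl)], g.entry)
            entry_seq = entry_seqs[g.index]
            softclip = frag.r1_softclip if m == 0 else frag.r2_softclip

            def rec(prio, chrom, pos, ops, mc, reverse):
                return AlignmentRecord(
                    read_id=frag.fid, mate_index=m + 1, source_priority=prio,
                    mapped=True, chrom=chrom, pos=pos, reverse_strand=reverse,
                    ops=list(ops), match_count=mc,
                    indel_count=0, duplicate_flag=frag.duplicate,
                    seq=stored, quals=None, mapq=60)

            # --- source 1: transcript database -------------------------
            if 1 in out:
                if frag.retro:
                    out[1].append(unmapped_record(frag.fid, m + 1, 1,
                                                  seq=read_seq,
                                                  duplicate_flag=frag.duplicate))
                else:
                    mc = _match_count(stored, entry_seq[epos:epos + rl])
                    out[1].append(rec(1, g.entry.name, epos, [("M", rl)],
                                      mc, rev))

            # --- source 4: BWA-like genome ------------------------------
            if 4 in out:
                if frag.retro:
                    rpos = ref.retro_pad + span[0]
                    rstored = read_seq if sense else revcomp(read_seq)
                    mc = _match_count(
                        rstored, ref.genome["chr2"][rpos:rpos + rl])
                    out[4].append(rec(4, "chr2", rpos, [("M", rl)], mc,
                                      not sense))
                elif len(gops) == 1:
                    mc = _match_count(stored,
                                      ref.genome["chr1"][gpos:gpos + rl])
                    out[4].append(rec(4, "chr1", gpos, gops, mc, rev))
                else:
                    p, ops, mc = _softclip_at_junction(
                        gpos, gops, stored, ref.genome, "chr1")
                    out[4].append(rec(4, "chr1", p, ops, mc, rev))

            # --- source 5: STAR-like genome ----------------------------
            if 5 in out:
                degraded = softclip or (frag.retro and len(gops) > 1)
                if degraded and len(gops) > 1:
                    p, ops, mc = _softclip_at_junction(
                        gpos, gops, stored, ref.genome, "chr1")
                    out[5].append(rec(5, "chr1", p, ops, mc, rev))
                else:
                    mc = sum(_match_count(
                        stored[r:r + ln],
                        ref.genome["chr1"][p:p + ln])
                        for r, p, ln in _genomic_blocks(gpos, gops))
                    out[5].append(rec(5, "chr1", gpos, gops, mc, rev))
    return out


# ---------------------------------------------------------------------------
# DNA reads
# ---------------------------------------------------------------------------

def simulate_dna_reads(ref: SimReference, sample_index: int = 0,
                       depth: int = 30):
    """Paired DNA reads as genome-space records: SNP genotypes, no edits."""
    cfg = ref.config
    rng = _rng(ref.seed, 5000 + sample_index)
    rl = cfg.read_length
    haps = {}
    for chrom, seq in ref.genome.items():
        h0, h1 = list(seq), list(seq)
        for r in ref.truth_snps[ref.truth_snps["chrom"] == chrom].itertuples():
            h1[r.pos] = r.alt
            if r.genotype == "hom":
                h0[r.pos] = r.alt
        haps[chrom] = ("".join(h0), "".join(h1))

    records = []
    for chrom, seq in ref.genome.items():
        clen = len(seq)
        n_frag = int(round(depth * clen / (2 * rl)))
        for f in range(n_frag):
            frag_len = int(np.clip(rng.normal(cfg.fragment_mean,
                                              cfg.fragment_sd), rl, clen))
            start = int(rng.integers(0, clen - frag_len + 1))
            hap = int(rng.integers(0, 2))
            hseq = haps[chrom][hap]
            r1 = _apply_errors(rng, hseq[start:start + rl], cfg.base_error)
            r2f = hseq[start + frag_len - rl:start + frag_len]
            r2 = _apply_errors(rng, revcomp(r2f), cfg.base_error)
            fid = f"D{sample_index}_{chrom}_F{f}"
            records.append(AlignmentRecord(
                read_id=fid, mate_index=1, source_priority=4, mapped=True,
                chrom=chrom, pos=start, ops=[("M", rl)], seq=r1,
                match_count=rl, reverse_strand=False))
            records.append(AlignmentRecord(
                read_id=fid, mate_index=2, source_priority=4, mapped=True,
                chrom=chrom, pos=start + frag_len - rl, ops=[("M", rl)],
                seq=revcomp(r2), match_count=rl, reverse_strand=True))
    return records


# ---------------------------------------------------------------------------
# Cohort-report shortcut for cohort-level statistics
# ---------------------------------------------------------------------------

def simulate_cohort_reports(seed: int, n_sites: int = 40,
                            groups: dict[str, str] | None = None,
                            group_rates: dict[str, float] | None = None,
                            tumor_only_sites: int = 3,
                            coverage: int = 50, error: float = 0.002):
    """Binomial-draw per-sample read reports for cohort-level statistics.

    A lightweight generator for the cohort module: sites x samples mutant
    counts are drawn directly as Binomial(coverage, rate) with
    group-specific rate multipliers; the first ``tumor_only_sites`` sites
    are edited only in samples whose group name starts with ``tumor``.
    Returns ``(reports_by_sample, groups, truth)``.
    """
    from .quantify import high_confidence

    rng = _rng(seed, 9000)
    if groups is None:
        groups = {f"t{i}": "tumor_brain" for i in range(4)}
        groups.update({f"n{i}": "normal_brain" for i in range(6)})
    if group_rates is None:
        group_rates = {g: (1.5 if "brain" in g else 1.0) for g in
                       set(groups.values())}
    base_rates = rng.uniform(0.1, 0.4, size=n_sites)
    tumor_only = np.zeros(n_sites, dtype=bool)
    tumor_only[:tumor_only_sites] = True

    reports = {}
    for sample in sorted(groups):
        grp = groups[sample]
        mult = group_rates.get(grp, 1.0)
        rows = []
        for i in range(n_sites):
            rate = min(base_rates[i] * mult, 0.95)
            if tumor_only[i] and not grp.startswith("tumor"):
                rate = 0.0
            cov = int(rng.poisson(coverage))
            mut = int(rng.binomial(cov, min(rate + error / 3, 1.0))) if cov else 0
            rows.append(dict(chrom="chr1", pos=1000 + i, ref="A", alt="G",
                             coverage=cov, mutant_reads=mut,
                             vaf=mut / cov if cov else np.nan,
                             spliced_coverage=0, spliced_mutant=0,
                             spliced_vaf=np.nan,
                             evaluable=cov >= 10,
                             high_conf=high_confidence(cov, mut)))
        reports[sample] = pd.DataFrame(rows)
    truth = pd.DataFrame({"pos": 1000 + np.arange(n_sites),
                          "rate": base_rates, "tumor_only": tumor_only})
    return reports, groups, truth


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_reference_fasta(ref: SimReference, path) -> None:
    with open(path, "w") as f:
        for chrom, seq in ref.genome.items():
            f.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                f.write(seq[i:i + 70] + "\n")


def write_germline_vcf(ref: SimReference, path) -> None:
    header = pysam.VariantHeader()
    for chrom, ln in ref.contigs.items():
        header.contigs.add(chrom, length=ln)
    header.info.add("GT_TRUTH", 1, "String", "Simulated genotype")
    with pysam.VariantFile(path, "w", header=header) as out:
        for r in ref.truth_snps.sort_values(["chrom", "pos"]).itertuples():
            rec = out.new_record(contig=r.chrom, start=r.pos, stop=r.pos + 1,
                                 alleles=(r.ref, r.alt))
            rec.info["GT_TRUTH"] = r.genotype
            out.write(rec)


def write_empty_vcf(ref: SimReference, path) -> None:
    header = pysam.VariantHeader()
    for chrom, ln in ref.contigs.items():
        header.contigs.add(chrom, length=ln)
    with pysam.VariantFile(path, "w", header=header):
        pass


def write_known_sites_tsv(ref: SimReference, path) -> None:
    df = ref.known_sites.copy()
    df["pos"] = df["pos"] + 1          # 1-based on disk
    df[["chrom", "pos", "ref", "alt", "gene", "strand"]].to_csv(
        path, sep="\t", index=False, header=False)


def write_truth_tables(ref: SimReference, sites_path, snps_path) -> None:
    ref.truth_sites.to_csv(sites_path, sep="\t", index=False)
    ref.truth_snps.to_csv(snps_path, sep="\t", index=False)


def write_fastq(reads: SampleReads, r1_path, r2_path, qual_char="I") -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for frag in reads.fragments:
            q = qual_char * len(frag.r1_seq)
            f1.write(f"@{frag.fid}/1\n{frag.r1_seq}\n+\n{q}\n")
            f2.write(f"@{frag.fid}/2\n{frag.r2_seq}\n+\n{q}\n")
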