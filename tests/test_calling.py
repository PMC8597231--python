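"""SNV pileup, DNA subtraction, artifact filters, classification, rescue."""

import numpy as np
import pandas as pd
import pytest

from editarm.calling import (FLAG_GERMLINE, FLAG_NON_CDS, FLAG_TX_MODEL,
                             VariantCandidate, annotate_consequence,
                             classify_edit_type, homopolymer_filter,
                             paralog_suspect_filter, pileup_call,
                             rescue_known_sites, restrict_to_cds,
                             subtract_dna_variants)
from editarm.records import AlignmentRecord, revcomp
from editarm.transcript_db import TranscriptModel


def read_at(pos, seq, read_id, quals=None, dup=False, mapq=60, chrom="chr1"):
    return AlignmentRecord(read_id=read_id, mate_index=1, mapped=True,
                           chrom=chrom, pos=pos, ops=[("M", len(seq))],
                           seq=seq, quals=quals, duplicate_flag=dup,
                           mapq=mapq)


def cand(chrom="chr1", pos=10, ref="A", alt="G", total=20, alt_reads=5):
    return VariantCandidate(chrom, pos, ref, alt, total, alt_reads, 30.0)


class TestPileup:
    def _genome(self):
        return {"chr1": "ACGT" * 25}

    def test_counts_ref_and_alt_reads(self):
        genome = self._genome()
        ref_base = genome["chr1"][50]           # 'C'
        reads = [read_at(45, genome["chr1"][45:56], f"r{i}")
                 for i in range(20)]
        alt_seq = genome["chr1"][45:50] + "T" + genome["chr1"][51:56]
        reads += [read_at(45, alt_seq, f"a{i}") for i in range(3)]
        out = pileup_call(reads, genome, min_alt_reads=3)
        assert len(out) == 1
        c = out[0]
        assert (c.pos, c.ref_allele, c.alt_allele) == (50, ref_base, "T")
        assert (c.total_reads, c.alt_reads) == (23, 3)

    def test_low_quality_alt_bases_excluded(self):
        genome = self._genome()
        alt_seq = genome["chr1"][45:50] + "T" + genome["chr1"][51:56]
        quals = [30] * 5 + [10] + [30] * 5
        reads = [read_at(45, alt_seq, f"a{i}", quals=quals) for i in range(5)]
        assert pileup_call(reads, genome, min_alt_reads=3) == []

    def test_duplicate_only_alt_support_excluded(self):
        genome = self._genome()
        alt_seq = genome["chr1"][45:50] + "T" + genome["chr1"][51:56]
        reads = [read_at(45, alt_seq, f"a{i}", dup=True) for i in range(5)]
        assert pileup_call(reads, genome, min_alt_reads=3) == []


class TestSubtraction:
    def test_germline_position_and_allele_flagged(self):
        germ = {("chr1", 10, "A", "G")}
        flags = subtract_dna_variants([cand()], germline=germ)
        assert flags == [{FLAG_GERMLINE}]

    def test_different_alt_allele_not_flagged(self):
        germ = {("chr1", 10, "A", "T")}
        assert subtract_dna_variants([cand()], germline=germ) == [set()]
        # position-only mode does flag it
        assert subtract_dna_variants([cand()], germline=germ,
                                     match_allele=False) == [{FLAG_GERMLINE}]

    def test_no_tables_no_flags(self):
        assert subtract_dna_variants([cand()]) == [set()]


class TestCdsRestriction:
    def _transcripts(self):
        plus = TranscriptModel("GP", "GP.1", "chr1", "+",
                               [(100, 200)], [(100, 200)])
        minus = TranscriptModel("GM", "GM.1", "chr1", "-",
                                [(150, 260)], [(150, 260)])
        return plus, minus

    def test_intronic_candidate_flagged_non_cds(self):
        plus, _ = self._transcripts()
        flags, genes = restrict_to_cds([cand(pos=500)], [plus])
        assert flags == [{FLAG_NON_CDS}] and genes == [None]

    def test_minus_strand_cds_sets_strand(self):
        _, minus = self._transcripts()
        c = cand(pos=220)
        flags, genes = restrict_to_cds([c], [minus])
        assert flags == [set()] and c.strand_of_gene == "-"
        assert genes == ["GM"]

    def test_opposite_strand_overlap_kept_with_ambiguity(self):
        plus, minus = self._transcripts()
        c = cand(pos=170)
        flags, _ = restrict_to_cds([c], [plus, minus])
        assert flags == [{FLAG_TX_MODEL}]
        assert c.strand_of_gene == "unknown"


class TestHomopolymerFilter:
    def _genome(self, context):
        return {"chr1": "GCGCGCGCGC" + context + "GCGCGCGCGC"}

    def test_variant_3prime_of_t_run_flagged(self):
        genome = self._genome("TTTTA")       # variant at the A, run left
        c = cand(pos=14, ref="A", alt="G")
        assert homopolymer_filter(c, genome, min_run=4)

    def test_run_of_three_passes(self):
        genome = self._genome("GTTTA")
        c = cand(pos=14, ref="A", alt="G")
        assert not homopolymer_filter(c, genome, min_run=4)

    def test_no_adjacent_run_passes(self):
        genome = self._genome("GTCTA")
        c = cand(pos=14, ref="A", alt="G")
        assert not homopolymer_filter(c, genome, min_run=4)

    def test_one_spacer_base_still_flagged(self):
        genome = self._genome("TTTTCA")      # run, spacer C, variant A
        c = cand(pos=15, ref="A", alt="G")
        assert homopolymer_filter(c, genome, min_run=4)


class TestParalogFilter:
    def _setup(self, n_suspect, n_clean):
        """Reads placed on a 'retro' contig; suspects match a paralog
        transcript whose reference base equals the alt allele."""
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        tx = "".join(bases[rng.integers(0, 4, size=400)])
        # retro diverges from the paralog at the variant site and at two
        # retro-specific positions
        retro = list(tx)
        for p in (200, 225, 230):
            retro[p] = "C" if tx[p] != "C" else "G"
        retro = "".join(retro)
        genome = {"chr2": retro}
        alt = tx[200]
        c = VariantCandidate("chr2", 200, retro[200], alt, 10, n_suspect, 30)
        supporting = []
        for i in range(n_suspect):      # reads carrying the paralog's content
            supporting.append((read_at(150, tx[150:251], f"s{i}",
                                       chrom="chr2"), 50))
        for i in range(n_clean):        # retro-specific reads with the alt
            seq = retro[150:200] + alt + retro[201:251]
            supporting.append((read_at(150, seq, f"c{i}", chrom="chr2"), 50))
        return c, supporting, {"TX": tx}, genome

    def test_majority_replacement_flagged(self):
        c, sup, db, genome = self._setup(3, 0)
        assert paralog_suspect_filter(c, sup, db, genome)

    def test_unique_best_placement_passes(self):
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        genome = {"chr2": "".join(bases[rng.integers(0, 4, size=400)])}
        seq = genome["chr2"][100:201]
        seq = seq[:50] + ("A" if seq[50] != "A" else "T") + seq[51:]
        c = VariantCandidate("chr2", 150, genome["chr2"][150], seq[50],
                             5, 2, 30)
        sup = [(read_at(100, seq, f"r{i}", chrom="chr2"), 50)
               for i in range(2)]
        db = {"TX": "".join(bases[rng.integers(0, 4, size=400)])}
        assert not paralog_suspect_filter(c, sup, db, genome)

    def test_below_threshold_fraction_passes(self):
        c, sup, db, genome = self._setup(2, 3)   # 40% suspect
        assert not paralog_suspect_filter(c, sup, db, genome,
                                          min_fraction=0.5)


class TestEditClass:
    @pytest.mark.parametrize("ref,alt,strand,expect", [
        ("A", "G", "+", "A-to-I"),
        ("T", "C", "-", "A-to-I"),
        ("C", "T", "+", "C-to-U"),
        ("G", "A", "-", "C-to-U"),
        ("G", "C", "+", "noncanonical"),
        ("A", "G", "-", "noncanonical"),
    ])
    def test_classification_table(self, ref, alt, strand, expect):
        assert classify_edit_type(ref, alt, strand)[0] == expect

    def test_unknown_strand_classified_with_ambiguity(self):
        cls, amb = classify_edit_type("T", "C", "unknown")
        assert cls == "A-to-I" and amb

    @pytest.mark.parametrize("ref,alt", [(a, b) for a in "ACGT"
                                         for b in "ACGT" if a != b])
    def test_reverse_complement_strand_flip_invariance(self, ref, alt):
        plus = classify_edit_type(ref, alt, "+")[0]
        minus = classify_edit_type(revcomp(ref), revcomp(alt), "-")[0]
        assert plus == minus


class TestConsequence:
    def _genome_tx(self, cds_seq, strand="+"):
        pad = "G" * 10
        if strand == "-":
            genomic = revcomp(cds_seq)
        else:
            genomic = cds_seq
        genome = {"chr1": pad + genomic + pad}
        tx = TranscriptModel("G", "G.1", "chr1", strand,
                             [(10, 10 + len(cds_seq))],
                             [(10, 10 + len(cds_seq))])
        return genome, tx

    def test_stop_gained_is_nonsense(self):
        genome, tx = self._genome_tx("ATGTGGTAA")     # M W *
        # TGG -> TGA at codon 2, third base
        assert annotate_consequence("chr1", 15, "G", "A", [tx],
                                    genome) == "nonsense"

    def test_third_position_wobble_is_synonymous(self):
        genome, tx = self._genome_tx("ATGCCATAA")     # CCA=P -> CCG=P
        assert annotate_consequence("chr1", 15, "A", "G", [tx],
                                    genome) == "synonymous"

    def test_stop_codon_edited_away_is_stop_loss(self):
        genome, tx = self._genome_tx("ATGTGGTGA")     # TGA -> TGG
        assert annotate_consequence("chr1", 18, "A", "G", [tx],
                                    genome) == "stop-loss"

    def test_minus_strand_codon_reconstruction(self):
        genome, tx = self._genome_tx("ATGAAATAA", strand="-")
        # coding AAA(K); genomic holds revcomp; edit coding A>G at codon 2
        # first base -> GAA (E): missense.  Genomic position of coding
        # offset 3 on '-' is 10 + (9 - 1 - 3).
        pos = 10 + (9 - 1 - 3)
        assert annotate_consequence("chr1", pos, "T", "C", [tx],
                                    genome) == "missense"

    def test_site_outside_cds_is_contract_violation(self):
        genome, tx = self._genome_tx("ATGAAATAA")
        with pytest.raises(ValueError):
            annotate_consequence("chr1", 2, "G", "A", [tx], genome)


def _report(chrom, pos, alt, mutant, coverage=50):
    return pd.DataFrame([dict(chrom=chrom, pos=pos, ref="A", alt=alt,
                              coverage=coverage, mutant_reads=mutant)])


class TestRescue:
    def _known(self):
        return pd.DataFrame([dict(chrom="chr1", pos=100, ref="A", alt="G",
                                  gene="GX", strand="+")])

    def test_two_samples_at_threshold_rescued(self):
        reports = {f"s{i}": _report("chr1", 100, "G", m)
                   for i, m in enumerate([3, 4, 0])}
        out = rescue_known_sites(self._known(), reports)
        assert len(out) == 1
        assert out[0].provenance == "rescued_known"
        assert out[0].edit_class == "A-to-I"

    def test_single_qualifying_sample_not_rescued(self):
        reports = {f"s{i}": _report("chr1", 100, "G", m)
                   for i, m in enumerate([3, 2, 2])}
        assert rescue_known_sites(self._known(), reports) == []

    def test_empty_known_table_rescues_nothing(self):
        known = pd.DataFrame(columns=["chrom", "pos", "ref", "alt",
                                      "gene", "strand"])
        reports = {"s0": _report("chr1", 100, "G", 5)}
        assert rescue_known_sites(known, reports) == []
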