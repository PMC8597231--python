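"""Synthetic-data generator: determinism, structure, rates, degradations."""

import numpy as np
import pytest
from scipy import stats

from editarm import simgen
from editarm.records import revcomp
from editarm.simgen import (SimConfig, SimConfigError, make_reference,
                            simulate_dna_reads, simulate_reads,
                            write_candidate_alignments)


class TestReference:
    def test_byte_identical_under_fixed_seed(self, tmp_path, sim_reference):
        again = make_reference(seed=1)
        assert again.genome == sim_reference.genome
        assert again.truth_sites.equals(sim_reference.truth_sites)
        assert again.truth_snps.equals(sim_reference.truth_snps)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        simgen.write_reference_fasta(sim_reference, p1)
        simgen.write_reference_fasta(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self, sim_reference):
        other = make_reference(seed=2)
        assert other.genome != sim_reference.genome

    def test_retrocopy_contig_holds_spliced_transcript(self):
        cfg = SimConfig(retrocopy_identity=1.0, n_planted_divergences=0)
        ref = make_reference(cfg, seed=3)
        assert ref.genes[0].mrna in ref.genome["chr2"]

    def test_retrocopy_high_identity_with_divergences(self, sim_reference):
        ref = sim_reference
        core = ref.genome["chr2"][ref.retro_pad:
                                  ref.retro_pad + len(ref.genes[0].mrna)]
        mm = sum(a != b for a, b in zip(core, ref.genes[0].mrna))
        assert 0 < mm <= 0.02 * len(core)
        div = ref.truth_sites[ref.truth_sites.kind == "paralog_divergence"]
        assert len(div) == mm

    def test_orfs_complete_and_stop_free(self, sim_reference):
        from Bio.Seq import Seq
        for g in sim_reference.genes:
            assert len(g.mrna) % 3 == 0
            assert g.mrna.startswith("ATG")
            aa = str(Seq(g.mrna).translate())
            assert aa.endswith("*") and "*" not in aa[:-1]
            assert g.model.cds_length % 3 == 0

    def test_truth_positions_match_genome_alleles(self, sim_reference):
        ref = sim_reference
        for r in ref.truth_sites.itertuples():
            assert ref.genome[r.chrom][r.pos] == r.ref
            assert r.ref != r.alt
        for r in ref.truth_snps.itertuples():
            assert ref.genome[r.chrom][r.pos] == r.ref

    def test_homopolymer_adjacent_artifact_site(self, sim_reference):
        art = sim_reference.truth_sites[
            sim_reference.truth_sites.kind == "artifact_homopolymer"]
        assert len(art) == 1
        row = art.iloc[0]
        ctx = sim_reference.genome[row.chrom][row.pos - 7:row.pos + 8]
        assert "A" * 4 in ctx or "T" * 4 in ctx

    def test_infeasible_exon_length_rejected(self):
        with pytest.raises(SimConfigError):
            make_reference(SimConfig(exon_length=(80, 90)), seed=1)


class TestReads:
    def test_deterministic_per_seed_and_sample(self, sim_reference):
        a = simulate_reads(sim_reference, 0)
        b = simulate_reads(sim_reference, 0)
        assert [f.r1_seq for f in a.fragments] == [f.r1_seq for f in b.fragments]
        c = simulate_reads(sim_reference, 1)
        assert [f.r1_seq for f in a.fragments] != [f.r1_seq for f in c.fragments]

    def test_zero_depth_yields_no_fragments(self, sim_reference):
        cfg = SimConfig(depth=0)
        ref = make_reference(cfg, seed=3)
        assert simulate_reads(ref, 0).fragments == []

    def test_edit_rate_recovered_within_binomial_ci(self, sim_reference):
        """Observed alt fraction among covering reads (pooled over four
        samples per site for power) sits inside the exact binomial 99% CI
        of the simulated per-site rate."""
        ref = sim_reference
        rl = ref.config.read_length
        samples = [simulate_reads(ref, i) for i in (6, 7, 8, 9)]
        edits = ref.truth_sites[(ref.truth_sites.kind == "edit")
                                & (ref.truth_sites.rate >= 0.2)]
        checked = 0
        for site in edits.itertuples():
            g = ref.genes[site.gene_index]
            alt_mrna = site.alt if g.strand == "+" else revcomp(site.alt)
            n = alt = 0
            for reads in samples:
                for f in reads.fragments:
                    if f.gene != site.gene_index or f.duplicate:
                        continue
                    spans = [(f.start, f.start + rl, f.r1_seq, False),
                             (f.start + f.frag_len - rl,
                              f.start + f.frag_len, f.r2_seq, True)]
                    for a, b, seq, is_r2 in spans:
                        if a <= site.mrna_offset < b:
                            n += 1
                            mrna_seq = revcomp(seq) if is_r2 else seq
                            alt += mrna_seq[site.mrna_offset - a] == alt_mrna
            lo, hi = stats.binom.interval(0.99, n, site.rate)
            assert lo <= alt <= hi, f"site {site.pos}: {alt}/{n} vs {site.rate}"
            checked += 1
        assert checked >= 5

    def test_zero_rate_known_decoys_stay_unedited(self, sim_reference):
        reads = simulate_reads(sim_reference, 2)
        assert all(not f.r1_edits or
                   set(f.r1_edits) <= set(sim_reference.truth_sites.index)
                   for f in reads.fragments)
        decoys = sim_reference.known_sites[~sim_reference.known_sites
                                           .is_true_edit]
        assert len(decoys) > 0   # decoys exist and are absent from truth
        truth_keys = {(r.chrom, r.pos)
                      for r in sim_reference.truth_sites.itertuples()}
        assert all((d.chrom, d.pos) not in truth_keys
                   for d in decoys.itertuples())

    def test_het_snp_alt_fraction_near_half_in_dna(self, sim_reference):
        ref = sim_reference
        dna = simulate_dna_reads(ref, 0, depth=40)
        for r in ref.truth_snps.head(5).itertuples():
            n = alt = 0
            for rec in dna:
                if rec.chrom != r.chrom:
                    continue
                if rec.pos <= r.pos < rec.pos + len(rec.seq):
                    n += 1
                    alt += rec.seq[r.pos - rec.pos] == r.alt
            lo, hi = stats.binom.interval(0.999, n, 0.5)
            assert lo <= alt <= hi


class TestCandidateAlignments:
    def test_junction_read_softclipped_in_genome_source_only(self,
                                                             sim_reference):
        reads = simulate_reads(sim_reference, 0)
        src = write_candidate_alignments(sim_reference, reads)
        by_key = {}
        for prio in (1, 4, 5):
            for r in src[prio]:
                by_key.setdefault((r.read_id, r.mate_index), {})[prio] = r
        n_checked = 0
        for frag in reads.fragments:
            if frag.retro:
                continue
            g = sim_reference.genes[frag.gene]
            rl = sim_reference.config.read_length
            span = (frag.start, frag.start + rl)
            if any(simgen._spans(span, j) for j in g.junctions):
                recs = by_key[(frag.fid, 1)]
                assert recs[4].has_op("S")          # BWA-like clips
                assert not recs[1].has_op("S")      # transcript source: full
                assert recs[1].mapped
                n_checked += 1
        assert n_checked > 10

    def test_retro_fragments_placed_on_retro_contig(self, sim_reference):
        reads = simulate_reads(sim_reference, 0)
        src = write_candidate_alignments(sim_reference, reads)
        retro_ids = {f.fid for f in reads.fragments if f.retro}
        assert retro_ids
        for r in src[4]:
            if r.read_id in retro_ids:
                assert r.chrom == "chr2"
        for r in src[1]:
            if r.read_id in retro_ids:
                assert not r.mapped

    def test_no_degradation_sources_agree_with_transcript_source(self):
        from editarm.pipeline import process_sample
        from editarm.transcript_db import translate_record
        cfg = SimConfig(junction_softclip_rate=0.0, retro_misplace_rate=0.0,
                        duplicate_rate=0.0, base_error=0.0)
        ref = make_reference(cfg, seed=6)
        reads = simulate_reads(ref, 0)
        src = write_candidate_alignments(ref, reads)
        selected = process_sample(src, ref.genome, ref.entries_by_name)
        truth = {(r.read_id, r.mate_index):
                 translate_record(r, ref.entries_by_name)
                 for r in src[1]}
        for rec in selected:
            t = truth[(rec.read_id, rec.mate_index)]
            assert (rec.chrom, rec.pos, rec.ops) == (t.chrom, t.pos, t.ops)
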