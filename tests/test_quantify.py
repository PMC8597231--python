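"""Read reports, confidence rules, control sites, rank-sum comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from editarm.quantify import (Site, compare_overall_vs_mrna,
                              estimate_background, exact_rank_sum_p,
                              find_control_sites, high_confidence,
                              is_evaluable, read_report)
from editarm.records import AlignmentRecord


def read_at(pos, seq, read_id, mate=1, ops=None, dup=False):
    return AlignmentRecord(read_id=read_id, mate_index=mate, mapped=True,
                           chrom="chr1", pos=pos,
                           ops=ops or [("M", len(seq))], seq=seq,
                           duplicate_flag=dup)


GENOME = {"chr1": "ACGT" * 300}


class TestReadReport:
    def _reads(self, n_ref, n_alt, n_third=0, spliced_alt=0, spliced_ref=0):
        """Reads over pos 50 (ref 'G'); spliced ones carry an N op."""
        base = GENOME["chr1"][45:56]
        alt_seq = base[:5] + "T" + base[6:]
        third = base[:5] + "C" + base[6:]
        reads = []
        for i in range(n_ref):
            ops = [("M", 11), ("N", 200)] if i < spliced_ref else None
            reads.append(read_at(45, base, f"ref{i}", ops=ops))
        for i in range(n_alt):
            ops = [("M", 11), ("N", 200)] if i < spliced_alt else None
            reads.append(read_at(45, alt_seq, f"alt{i}", ops=ops))
        reads += [read_at(45, third, f"th{i}") for i in range(n_third)]
        return reads

    def test_vaf_counting(self):
        df = read_report([Site("chr1", 50, "G", "T")], self._reads(40, 10))
        row = df.iloc[0]
        assert (row.coverage, row.mutant_reads) == (50, 10)
        assert row.vaf == pytest.approx(0.20)

    def test_zero_coverage_vaf_undefined(self):
        df = read_report([Site("chr1", 50, "G", "T")], [])
        assert df.iloc[0].coverage == 0
        assert np.isnan(df.iloc[0].vaf)

    def test_third_allele_counts_coverage_not_mutant(self):
        df = read_report([Site("chr1", 50, "G", "T")],
                         self._reads(10, 5, n_third=5))
        row = df.iloc[0]
        assert (row.coverage, row.mutant_reads) == (20, 5)

    def test_spliced_counts_from_spliced_reads(self):
        reads = self._reads(30 - 3, 3, spliced_alt=3, spliced_ref=9)
        df = read_report([Site("chr1", 50, "G", "T")], reads)
        row = df.iloc[0]
        assert (row.spliced_coverage, row.spliced_mutant) == (12, 3)
        assert row.spliced_vaf == pytest.approx(0.25)

    def test_unspliced_read_with_spliced_mate_included(self):
        base = GENOME["chr1"][45:56]
        plain = read_at(45, base, "p", mate=1)
        mate = read_at(300, GENOME["chr1"][300:311], "p", mate=2,
                       ops=[("M", 11), ("N", 500)])
        df = read_report([Site("chr1", 50, "G", "T")], [plain, mate])
        assert df.iloc[0].spliced_coverage == 1

    def test_no_spliced_reads_vaf_undefined(self):
        df = read_report([Site("chr1", 50, "G", "T")], self._reads(10, 2))
        assert np.isnan(df.iloc[0].spliced_vaf)

    def test_spliced_never_exceeds_overall(self, sim_reference):
        from editarm import simgen
        from editarm.pipeline import process_sample
        reads = simgen.simulate_reads(sim_reference, 3)
        src = simgen.write_candidate_alignments(sim_reference, reads)
        refined = process_sample(src, sim_reference.genome,
                                 sim_reference.entries_by_name)
        sites = [Site(r.chrom, r.pos, r.ref, r.alt)
                 for r in sim_reference.truth_sites.itertuples()]
        df = read_report(sites, refined)
        assert (df.spliced_coverage <= df.coverage).all()
        assert (df.spliced_mutant <= df.mutant_reads).all()


class TestConfidenceRules:
    @pytest.mark.parametrize("cov,expect", [(10, True), (9, False),
                                            (0, False)])
    def test_evaluability_boundary(self, cov, expect):
        assert is_evaluable(cov) is expect

    @pytest.mark.parametrize("cov,mut,expect", [
        (150, 3, True), (150, 2, False),
        (50, 2, True), (50, 1, False),
        (15, 1, True), (15, 0, False),
        (100, 2, True), (101, 2, False),   # 100 sits in the middle band
        (19, 1, True), (20, 1, False),
    ])
    def test_high_confidence_bands(self, cov, mut, expect):
        assert high_confidence(cov, mut) is expect

    def test_monotone_in_mutant_reads(self):
        for cov in range(0, 200, 7):
            flags = [high_confidence(cov, m) for m in range(cov + 1)]
            assert flags == sorted(flags)   # once true, stays true


class TestControlSites:
    def test_nearest_same_ref_base_found(self):
        genome = {"chr1": "CCAAGTACC"}
        s = Site("chr1", 3, "A", "G")       # A at 3; A at 2 and 6
        assert find_control_sites([s], genome) == {s: 2}

    def test_no_same_ref_within_two_bp(self):
        genome = {"chr1": "CCGGAGGCC"}
        s = Site("chr1", 4, "A", "G")
        assert find_control_sites([s], genome) == {}

    def test_tie_broken_upstream(self):
        genome = {"chr1": "CCCAAACCC"}      # A at 3 and 5 tie around site 4
        s = Site("chr1", 4, "A", "G")
        assert find_control_sites([s], genome) == {s: 3}


class TestBackgroundEstimation:
    def _simulate(self, error, n=400, seed=0):
        rng = np.random.default_rng(seed)
        cov = rng.integers(101, 300, size=n)
        edit = pd.DataFrame({"coverage": cov,
                             "mutant_reads": rng.binomial(cov, 0.1)})
        ctrl = pd.DataFrame({"coverage": cov,
                             "mutant_reads": rng.binomial(cov, error)})
        return edit, ctrl

    def test_higher_threshold_raises_tp_fraction(self):
        edit, ctrl = self._simulate(error=0.005)
        table = estimate_background(edit, ctrl, ((101, None),), (2, 3))
        tp = table.set_index("threshold")["tp_fraction"]
        assert tp[3] > tp[2]

    def test_zero_error_gives_tp_one(self):
        edit, ctrl = self._simulate(error=0.0)
        table = estimate_background(edit, ctrl)
        defined = table[table["defined"]]
        assert (defined["tp_fraction"] == 1.0).all()

    def test_controls_dominate_at_threshold_one(self):
        rng = np.random.default_rng(1)
        cov = rng.integers(101, 300, size=300)
        edit = pd.DataFrame({"coverage": cov,
                             "mutant_reads": rng.binomial(cov, 0.02)})
        ctrl = pd.DataFrame({"coverage": cov,
                             "mutant_reads": rng.binomial(cov, 0.02)})
        table = estimate_background(edit, ctrl, ((101, None),), (1,))
        assert table["tp_fraction"].iloc[0] == pytest.approx(0.0, abs=0.05)

    def test_empty_bin_flagged_undefined(self):
        edit = pd.DataFrame({"coverage": [5], "mutant_reads": [1]})
        ctrl = pd.DataFrame({"coverage": [5], "mutant_reads": [0]})
        table = estimate_background(edit, ctrl, ((101, None),), (1,))
        assert not table["defined"].iloc[0]
        assert np.isnan(table["tp_fraction"].iloc[0])


def _oracle_two_sided_p(x, y):
    """Independent enumeration: rank-sum deviation over all assignments,
    built from scratch with midranks."""
    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        r = (i + j + 1) / 2.0
        for k in range(i, j):
            ranks[order[k]] = r
        i = j
    n1 = len(x)
    mu = n1 * (len(pooled) + 1) / 2.0
    obs = abs(sum(ranks[:n1]) - mu)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(sum(ranks[i] for i in comb) - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestRankSum:
    def test_textbook_example_exact_p(self):
        assert exact_rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_vectors_p_one(self):
        diff, p = compare_overall_vs_mrna([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert diff == 0 and p == 1.0

    def test_insufficient_samples_undefined(self):
        diff, p = compare_overall_vs_mrna([0.1, 0.2], [0.1, 0.2, 0.3])
        assert np.isnan(diff) and np.isnan(p)

    def test_matches_scipy_exact_on_tie_free_data(self):
        rng = np.random.default_rng(21)
        for _ in range(60):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 13 - n1))
            vals = rng.permutation(100)[:n1 + n2].tolist()
            x, y = vals[:n1], vals[n1:]
            p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="exact").pvalue
            assert exact_rank_sum_p(x, y) == pytest.approx(p_scipy)

    def test_matches_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(22)
        for _ in range(40):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 13 - n1))
            x = rng.integers(0, 4, size=n1).tolist()
            y = rng.integers(0, 4, size=n2).tolist()
            assert exact_rank_sum_p(x, y) == pytest.approx(
                _oracle_two_sided_p(x, y))

    def test_shifted_groups_significant(self):
        rng = np.random.default_rng(23)
        overall = (0.3 + 0.05 * rng.standard_normal(20)).tolist()
        spliced = (0.15 + 0.05 * rng.standard_normal(20)).tolist()
        diff, p = compare_overall_vs_mrna(overall, spliced)
        assert diff > 0 and p < 0.05

    def test_paired_mode_runs_signed_rank(self):
        x = [0.3, 0.35, 0.4, 0.32, 0.38]
        y = [0.1, 0.15, 0.2, 0.12, 0.18]
        diff, p = compare_overall_vs_mrna(x, y, paired=True)
        assert diff > 0 and p < 0.1
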