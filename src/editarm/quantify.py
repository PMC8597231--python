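"""Per-site read reports, coverage-dependent confidence calls, background
error estimation from adjacent control sites, and junction-corrected
(spliced-mRNA) editing levels.

The variant allele fraction (VAF) at a site is mutant reads / total reads.
A site is *evaluable* with at least 10 reads of coverage.  The
*high-confidence* rule is coverage-dependent: with more than 100 reads at
least 3 mutant reads are required, with 20-100 reads at least 2, and below
20 reads a single mutant read suffices (thresholds derived from background
error rates at adjacent control sites of the same reference allele within
2 bp of each editing site).

The *spliced* (junction-corrected) VAF restricts counting to reads whose
record or mate contains a splice operation — a proxy for mature mRNA as
opposed to intron-retaining pre-mRNA.  Overall and spliced VAFs across
samples are compared per site with a two-sided Wilcoxon rank-sum test
(exact enumeration for small samples), with Benjamini-Hochberg FDR across
sites.
"""

from __future__ import annotations

import itertools
import math
from collections import namedtuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .transcript_db import fetch

Site = namedtuple("Site", "chrom pos ref alt")   # pos 0-based

REPORT_COLUMNS = ["chrom", "pos", "ref", "alt", "coverage", "mutant_reads",
                  "vaf", "spliced_coverage", "spliced_mutant", "spliced_vaf",
                  "evaluable", "high_conf"]


def read_sites_tsv(path) -> list[Site]:
    """Site list TSV with 1-based positions (chrom, pos, ref, alt, ...)."""
    out = []
    with open(path) as f:
        for line in f:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            t = line.split("\t")
            out.append(Site(t[0], int(t[1]) - 1, t[2].upper(), t[3].upper()))
    return out


# ---------------------------------------------------------------------------
# Read reports
# ---------------------------------------------------------------------------

def _spliced_read_ids(records) -> set[tuple[str, int]]:
    """(read_id, mate) keys of reads that are spliced or whose mate is."""
    spliced_mates: dict[str, set[int]] = {}
    mates_seen: dict[str, set[int]] = {}
    for rec in records:
        mates_seen.setdefault(rec.read_id, set()).add(rec.mate_index)
        if rec.mapped and rec.has_op("N"):
            spliced_mates.setdefault(rec.read_id, set()).add(rec.mate_index)
    out = set()
    for read_id, spliced in spliced_mates.items():
        for mate in mates_seen[read_id]:
            out.add((read_id, mate))
    return out


def read_report(sites, records, min_base_q: int = 20, min_map_q: int = 1,
                min_cov: int = 10) -> pd.DataFrame:
    """Count coverage and mutant reads at each site for one sample.

    Bases must be aligned (M), non-duplicate, with base quality >=
    ``min_base_q`` and mapping quality >= ``min_map_q``.  Third-allele
    bases count toward coverage but never toward mutant reads.  Spliced
    counterparts are restricted to reads where the record or its mate
    carries a splice operation; an orphan mate is judged by its own
    operations.
    """
    wanted: dict[tuple[str, int], list[int]] = {}
    for i, s in enumerate(sites):
        wanted.setdefault((s.chrom, s.pos), []).append(i)

    cov = np.zeros(len(sites), dtype=int)
    mut = np.zeros(len(sites), dtype=int)
    scov = np.zeros(len(sites), dtype=int)
    smut = np.zeros(len(sites), dtype=int)
    spliced_keys = _spliced_read_ids(records)

    for rec in records:
        if not rec.mapped or rec.duplicate_flag or rec.mapq < min_map_q:
            continue
        is_spliced = (rec.read_id, rec.mate_index) in spliced_keys
        seq = rec.seq.upper()
        for r, g in rec.aligned_pairs():
            idxs = wanted.get((rec.chrom, g))
            if not idxs:
                continue
            if rec.base_qual(r) < min_base_q:
                continue
            base = seq[r]
            for i in idxs:
                cov[i] += 1
                if is_spliced:
                    scov[i] += 1
                if base == sites[i].alt:
                    mut[i] += 1
                    if is_spliced:
                        smut[i] += 1

    df = pd.DataFrame({
        "chrom": [s.chrom for s in sites],
        "pos": [s.pos for s in sites],
        "ref": [s.ref for s in sites],
        "alt": [s.alt for s in sites],
        "coverage": cov, "mutant_reads": mut,
        "spliced_coverage": scov, "spliced_mutant": smut,
    })
    df["vaf"] = np.where(cov > 0, mut / np.maximum(cov, 1), np.nan)
    df["spliced_vaf"] = np.where(scov > 0, smut / np.maximum(scov, 1), np.nan)
    df["evaluable"] = df["coverage"] >= min_cov
    df["high_conf"] = [high_confidence(c, m) for c, m in zip(cov, mut)]
    return df[REPORT_COLUMNS]


def is_evaluable(coverage: int, min_cov: int = 10) -> bool:
    """At least ``min_cov`` (default 10) reads of coverage."""
    return coverage >= min_cov


def high_confidence(coverage: int, mutant_reads: int) -> bool:
    """Coverage-dependent mutant-read thresholds.

    coverage > 100: >= 3 mutant reads; 20 <= coverage <= 100: >= 2;
    coverage < 20: >= 1.  (Coverage exactly 100 falls in the middle band.)
    """
    if coverage > 100:
        return mutant_reads >= 3
    if coverage >= 20:
        return mutant_reads >= 2
    return mutant_reads >= 1


# ---------------------------------------------------------------------------
# Adjacent-control background error estimation
# ---------------------------------------------------------------------------

def find_control_sites(sites, genome, max_offset: int = 2):
    """Nearest same-reference-allele position within ``max_offset`` bp.

    Returns ``{site: control_pos}`` omitting sites with no eligible
    neighbour; distance ties are broken upstream-first.
    """
    out = {}
    for s in sites:
        clen = len(genome[s.chrom])
        for d in range(1, max_offset + 1):
            found = None
            for p in (s.pos - d, s.pos + d):       # upstream first on ties
                if 0 <= p < clen and fetch(genome, s.chrom, p, p + 1) == s.ref:
                    found = p
                    break
            if found is not None:
                out[s] = found
                break
    return out


def estimate_background(edit_reports: pd.DataFrame,
                        control_reports: pd.DataFrame,
                        coverage_bins=((101, None), (20, 100), (1, 19)),
                        thresholds=(1, 2, 3)) -> pd.DataFrame:
    """True-positive fraction per (coverage bin, mutant-read threshold).

    Both inputs carry one row per site x sample observation with columns
    ``coverage`` and ``mutant_reads`` (control rows count non-reference
    reads at the control position).  For each bin and threshold,
    TP = 1 - (control observations meeting threshold) /
             (editing observations meeting threshold);
    an empty denominator yields NaN (flagged by the ``defined`` column).
    """
    rows = []
    for lo, hi in coverage_bins:
        e = edit_reports[(edit_reports["coverage"] >= lo)
                         & ((hi is None) | (edit_reports["coverage"] <= (hi or 0)))]
        c = control_reports[(control_reports["coverage"] >= lo)
                            & ((hi is None) | (control_reports["coverage"] <= (hi or 0)))]
        for thr in thresholds:
            n_e = int((e["mutant_reads"] >= thr).sum())
            n_c = int((c["mutant_reads"] >= thr).sum())
            tp = 1.0 - n_c / n_e if n_e > 0 else float("nan")
            rows.append(dict(cov_lo=lo, cov_hi=hi, threshold=thr,
                             n_edit=n_e, n_control=n_c, tp_fraction=tp,
                             defined=n_e > 0))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (overall vs spliced VAF)
# ---------------------------------------------------------------------------

def exact_rank_sum_p(x, y) -> float:
    """Two-sided exact rank-sum p by exhaustive enumeration.

    Enumerates all C(n1+n2, n1) assignments of the pooled midranks and
    counts those at least as extreme as observed, measured by
    |U - n1*n2/2|.  Handles ties through midranks; for tie-free data this
    equals the classical exact Mann-Whitney two-sided p.
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(x + y)
    mu = n1 * n2 / 2.0
    const = n1 * (n1 + 1) / 2.0
    obs = abs(sum(ranks[:n1]) - const - mu)
    count = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = sum(ranks[i] for i in idx) - const
        total += 1
        if abs(u - mu) >= obs - 1e-9:
            count += 1
    return count / total


def _normal_rank_sum_p(x, y) -> float:
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(list(x) + list(y))
    u = sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie-corrected variance
    _, counts = np.unique(np.asarray(list(x) + list(y)), return_counts=True)
    n = n1 + n2
    tie = ((counts ** 3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie)
    if var <= 0:
        return 1.0
    z = (u - mu) / math.sqrt(var)
    return 2 * stats.norm.sf(abs(z))


def compare_overall_vs_mrna(overall, spliced, min_samples: int = 3,
                            exact_max_n: int = 10, paired: bool = False):
    """Per-site comparison of overall and spliced (mRNA) editing levels.

    Returns ``(mean_difference, p_value)`` with difference =
    mean(overall) - mean(spliced); a positive value means editing is
    depleted in spliced mRNA.  Uses the exact rank-sum when both groups
    have at most ``exact_max_n`` values, else a normal approximation with
    tie correction.  ``paired=True`` switches to the signed-rank test on
    per-sample differences (the samples must then be aligned).  Fewer than
    ``min_samples`` defined values in either group yields (nan, nan).
    """
    x = [v for v in overall if v == v]
    y = [v for v in spliced if v == v]
    if len(x) < min_samples or len(y) < min_samples:
        return float("nan"), float("nan")
    diff = float(np.mean(x) - np.mean(y))
    if paired:
        if len(x) != len(y):
            raise ValueError("paired comparison requires aligned samples")
        d = np.asarray(x) - np.asarray(y)
        if np.all(d == 0):
            return diff, 1.0
        return diff, float(stats.wilcoxon(x, y).pvalue)
    if x == y:
        return diff, 1.0
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        return diff, exact_rank_sum_p(x, y)
    return diff, _normal_rank_sum_p(x, y)


def spliced_comparison_table(reports_by_sample: dict[str, pd.DataFrame],
                             min_samples: int = 3) -> pd.DataFrame:
    """Overall-vs-spliced VAF comparison for every site across samples,
    with Benjamini-Hochberg FDR over the sites with a defined test."""
    samples = sorted(reports_by_sample)
    frames = [reports_by_sample[s].set_index(["chrom", "pos", "ref", "alt"])
              for s in samples]
    sites = frames[0].index
    rows = []
    for key in sites:
        overall = [f.loc[key, "vaf"] for f in frames]
        spliced = [f.loc[key, "spliced_vaf"] for f in frames]
        both = [(o, s) for o, s in zip(overall, spliced)
                if o == o and s == s]
        diff, p = compare_overall_vs_mrna([o for o, _ in both],
                                          [s for _, s in both],
                                          min_samples=min_samples)
        rows.append(dict(chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                         n_samples=len(both), mean_difference=diff, p=p))
    df = pd.DataFrame(rows)
    df["fdr"] = np.nan
    ok = df["p"].notna()
    if ok.any():
        df.loc[ok, "fdr"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    return df
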