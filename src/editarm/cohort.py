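"""Cross-sample cohort summaries of RNA editing.

Works from per-sample read-report tables (see
:func:`editarm.quantify.read_report`): per-sample editing burden, the
fraction of the site panel expressed per group, per-site group median VAFs
over positively edited samples, a tissue-specificity matrix of row-
normalised VAFs, and tumor-specific site detection against a normal
cohort.

The specificity matrix distinguishes two kinds of "no signal": a cell
whose locus is expressed but unedited (value 0) and a cell with fewer than
10 reads of coverage (NOT_EXPRESSED, NaN internally, ``NE`` in the TSV
export), matching the cream/blue distinction of cohort heatmaps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MIN_COVERAGE = 10
NOT_EXPRESSED = "NE"

_SITE_KEY = ["chrom", "pos", "ref", "alt"]


def _indexed(report: pd.DataFrame) -> pd.DataFrame:
    return report.set_index(_SITE_KEY)


def burden_per_sample(reports_by_sample: dict[str, pd.DataFrame]) -> pd.Series:
    """Number of high-confidence edited sites per sample."""
    return pd.Series({s: int(rep["high_conf"].sum())
                      for s, rep in reports_by_sample.items()},
                     name="burden").sort_index()


def percent_expressed_per_group(reports_by_sample, groups: dict[str, str],
                                min_samples: int = 3,
                                min_cov: int = MIN_COVERAGE) -> pd.Series:
    """Fraction of panel sites covered >= ``min_cov`` in >= ``min_samples``
    samples of each group; an empty group yields NaN."""
    out = {}
    for group in sorted(set(groups.values())):
        members = [s for s, g in groups.items() if g == group]
        frames = [_indexed(reports_by_sample[s])["coverage"] >= min_cov
                  for s in members]
        if not frames:
            out[group] = float("nan")
            continue
        n_expr = pd.concat(frames, axis=1).sum(axis=1)
        out[group] = float((n_expr >= min_samples).mean())
    return pd.Series(out, name="fraction_expressed")


def median_site_vaf_per_group(reports_by_sample, groups: dict[str, str],
                              min_covered_samples: int = 3,
                              min_cov: int = MIN_COVERAGE) -> pd.DataFrame:
    """Per-site median VAF per group over positively edited samples.

    Zero-VAF samples are excluded: the median runs over samples with a
    high-confidence positive call.  A site is reported for a group only
    when at least ``min_covered_samples`` of its samples have >=
    ``min_cov`` reads there; otherwise the cell is NaN.
    """
    cols = {}
    for group in sorted(set(groups.values())):
        members = [s for s, g in groups.items() if g == group]
        frames = [_indexed(reports_by_sample[s]) for s in members]
        covered = pd.concat([(f["coverage"] >= min_cov) for f in frames],
                            axis=1).sum(axis=1)
        vafs = pd.concat(
            [f["vaf"].where(f["high_conf"] & (f["mutant_reads"] > 0))
             for f in frames], axis=1)
        med = vafs.median(axis=1, skipna=True)
        med[covered < min_covered_samples] = np.nan
        cols[group] = med
    return pd.DataFrame(cols)


def specificity_matrix(reports_by_sample, groups: dict[str, str] | None = None,
                       min_cov: int = MIN_COVERAGE):
    """Sites x samples matrix of VAF as a fraction of the row maximum.

    Cells with coverage below ``min_cov`` are NOT_EXPRESSED (NaN).  The
    row maximum is taken over expressed cells of all samples; rows with no
    positive expressed cell stay at 0 (or all-NaN when nothing is
    expressed).  Returns ``(matrix, groups_series)``.
    """
    samples = sorted(reports_by_sample)
    vaf = pd.concat({s: _indexed(reports_by_sample[s])["vaf"] for s in samples},
                    axis=1)
    cov = pd.concat({s: _indexed(reports_by_sample[s])["coverage"]
                     for s in samples}, axis=1)
    vals = vaf.where(cov >= min_cov)
    row_max = vals.max(axis=1, skipna=True)
    scaled = vals.div(row_max.where(row_max > 0, 1.0), axis=0)
    group_series = (pd.Series({s: groups.get(s) for s in samples})
                    if groups else pd.Series(index=samples, dtype=object))
    return scaled, group_series


def matrix_to_tsv(matrix: pd.DataFrame, path) -> None:
    """Export with distinct sentinels: NE for not-expressed cells."""
    out = matrix.copy().astype(object)
    out[matrix.isna()] = NOT_EXPRESSED
    out.to_csv(path, sep="\t")


def tumor_specific_sites(cancer_reports: dict[str, pd.DataFrame],
                         normal_reports: dict[str, pd.DataFrame],
                         min_cov: int = MIN_COVERAGE) -> pd.DataFrame:
    """Sites edited with high confidence in >= 1 cancer sample and in no
    evaluable normal sample.

    A site with no evaluable normal sample at all is still listed but
    carries ``low_power=True`` (absence of evidence, not evidence of
    absence).
    """
    c_hc = pd.concat([_indexed(r)["high_conf"] for r in
                      cancer_reports.values()], axis=1).sum(axis=1)
    n_hc = pd.concat([_indexed(r)["high_conf"] for r in
                      normal_reports.values()], axis=1).sum(axis=1)
    n_eval = pd.concat([(_indexed(r)["coverage"] >= min_cov) for r in
                        normal_reports.values()], axis=1).sum(axis=1)
    keep = (c_hc >= 1) & (n_hc == 0)
    df = pd.DataFrame({
        "n_cancer_high_conf": c_hc[keep].astype(int),
        "n_normal_evaluable": n_eval[keep].astype(int),
    })
    df["low_power"] = df["n_normal_evaluable"] == 0
    return df.reset_index()
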