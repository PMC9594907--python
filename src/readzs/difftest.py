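"""Omnibus test for cell type-specific read-position shifts.

For each window, cells are grouped by ontology (cell type).  With n_i
eligible cells in group i, group median theta_i and sample variance s2_i of
the per-cell scores, the statistic

    T = sum_i (n_i / s2_i) * (theta_i - theta_bar)^2,
    theta_bar = (sum_i n_i * theta_i / s2_i) / (sum_i n_i / s2_i)

is compared first against its asymptotic chi-squared(I-1) null as a cheap
prefilter, and — only when p_chi < 0.05 — against a label-permutation null
to obtain a two-sided p_perm = 2*min(cdf, 1-cdf) with
cdf = #{T_perm < T_obs}/J.  Benjamini-Hochberg is then applied across the
windows that received a p_perm.

Eligibility follows the read-depth rules: a (window, ontology) group needs
at least ``min_cells`` cells each with at least ``min_counts`` reads, and a
window is testable only with two or more such groups.  All reads still
participate in ranking upstream; the filters act here, at the median stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSummary",
    "summarize_groups",
    "test_statistic",
    "permutation_test",
    "bh_adjust",
    "effect_size",
    "run_difftest",
]

RESULT_COLUMNS = [
    "window_id",
    "T",
    "p_chi",
    "p_perm",
    "q",
    "effect_size",
    "n_ontologies",
    "significant",
]


@dataclass(frozen=True)
class GroupSummary:
    """Median score summary for one (window, ontology) group."""

    window_id: str
    ontology: str
    n: int
    median_z: float
    var_z: float


def summarize_groups(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    min_counts: int = 10,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Eligible per-(window, ontology) summaries: n, median z, variance of z.

    ``metadata`` maps cell -> ontology.  Cells below ``min_counts`` reads in
    the window are excluded; groups with fewer than ``min_cells`` eligible
    cells are dropped.  The returned frame keeps only windows with >= 2
    eligible ontologies (the testability requirement). Lower thresholds
    (e.g. 5 counts in 10 cells) suit shallow libraries.
    """
    joined = scores.merge(metadata[["cell", "ontology"]], on="cell", how="inner")
    eligible = joined[joined["n_reads"] >= min_counts]
    if eligible.empty:
        return pd.DataFrame(
            columns=["window_id", "ontology", "n", "median_z", "var_z"]
        )
    g = eligible.groupby(["window_id", "ontology"], sort=True, observed=True)["z"]
    summary = g.agg(n="size", median_z="median", var_z="var").reset_index()
    summary = summary[summary["n"] >= min_cells]
    n_onts = summary.groupby("window_id", observed=True)["ontology"].transform("size")
    return summary[n_onts >= 2].reset_index(drop=True)


def test_statistic(
    n: np.ndarray, median_z: np.ndarray, var_z: np.ndarray
) -> float:
    """Precision-weighted dispersion of group medians (the T statistic)."""
    if len(n) < 2:
        raise ValueError("need at least two groups")
    if np.any(var_z <= 0):
        raise ValueError("all group variances must be positive")
    w = n / var_z
    theta_bar = float((w * median_z).sum() / w.sum())
    return float((w * (median_z - theta_bar) ** 2).sum())


def _group_stats(z: np.ndarray, codes: np.ndarray, n_groups: int):
    """Per-group (n, median, variance) from integer-coded labels."""
    ns = np.bincount(codes, minlength=n_groups)
    medians = np.empty(n_groups)
    variances = np.empty(n_groups)
    for g in range(n_groups):
        zg = z[codes == g]
        medians[g] = np.median(zg)
        variances[g] = zg.var(ddof=1) if zg.size > 1 else 0.0
    return ns, medians, variances


def permutation_test(
    z: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 100,
    alpha_prefilter: float = 0.05,
    rng: np.random.Generator | None = None,
    max_redraws: int = 50,
) -> tuple[float, float | None, float]:
    """(p_chi, p_perm, T) for one window's eligible cells.

    ``z`` and ``labels`` cover the frozen eligible-cell set; labels shuffle
    over exactly these cells.  p_chi is the upper tail of chi-squared(I-1)
    at the observed T.  p_perm is computed only when p_chi passes the
    prefilter; group medians and variances are recomputed from scratch in
    every permutation.  A permutation producing a zero-variance group is
    redrawn (bounded).
    """
    if rng is None:
        rng = np.random.default_rng()
    codes, groups = pd.factorize(labels, sort=True)
    n_groups = len(groups)
    ns, medians, variances = _group_stats(z, codes, n_groups)
    if np.any(variances <= 0):
        raise ValueError("observed groups must have positive variance")
    t_obs = test_statistic(ns, medians, variances)
    p_chi = float(stats.chi2.sf(t_obs, df=n_groups - 1))
    if p_chi >= alpha_prefilter:
        return p_chi, None, t_obs

    below = 0
    done = 0
    redraws = 0
    while done < n_permutations:
        perm = rng.permutation(codes)
        ns_p, med_p, var_p = _group_stats(z, perm, n_groups)
        if np.any(var_p <= 0):
            redraws += 1
            if redraws > max_redraws * n_permutations:
                raise RuntimeError("too many degenerate permutations")
            continue
        if test_statistic(ns_p, med_p, var_p) < t_obs:
            below += 1
        done += 1
    cdf = below / n_permutations
    return p_chi, 2.0 * min(cdf, 1.0 - cdf), t_obs


def bh_adjust(pvalues: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def effect_size(median_z: np.ndarray) -> float:
    """Range (max - min) of the per-ontology medians; the ranking key."""
    return float(np.max(median_z) - np.min(median_z))


def run_difftest(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    min_counts: int = 10,
    min_cells: int = 20,
    n_permutations: int = 100,
    alpha_prefilter: float = 0.05,
    fdr_threshold: float = 0.05,
    seed: int | None = None,
    strict_bh: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test every eligible window; returns (results, group medians).

    By default BH runs over the windows that received a p_perm, and windows
    screened out by the chi-squared prefilter carry p_chi but no q.  With
    ``strict_bh=True`` the prefiltered windows enter the BH pool with their
    p_chi instead — the conservative variant.
    """
    rng = np.random.default_rng(seed)
    summary = summarize_groups(scores, metadata, min_counts, min_cells)
    if summary.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS), summary

    joined = scores.merge(metadata[["cell", "ontology"]], on="cell", how="inner")
    eligible = joined[joined["n_reads"] >= min_counts]
    testable = set(summary["window_id"])
    ok_groups = summary.set_index(["window_id", "ontology"]).index

    rows = []
    for wid, wdf in eligible.groupby("window_id", sort=True, observed=True):
        if wid not in testable:
            continue
        mask = [(wid, o) in ok_groups for o in wdf["ontology"]]
        keep = wdf[mask]
        z = keep["z"].to_numpy(dtype=float)
        labels = keep["ontology"].to_numpy()
        try:
            p_chi, p_perm, t_obs = permutation_test(
                z, labels, n_permutations, alpha_prefilter, rng
            )
        except ValueError:
            continue
        med = summary.loc[summary["window_id"] == wid, "median_z"].to_numpy()
        rows.append(
            {
                "window_id": wid,
                "T": t_obs,
                "p_chi": p_chi,
                "p_perm": p_perm,
                "effect_size": effect_size(med),
                "n_ontologies": int(len(med)),
            }
        )
    results = pd.DataFrame(rows)
    if results.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS), summary

    results["p_perm"] = pd.to_numeric(results["p_perm"], errors="coerce")
    if strict_bh:
        pool = results["p_perm"].fillna(results["p_chi"])
        results["q"] = bh_adjust(pool)
    else:
        results["q"] = np.nan
        has_perm = results["p_perm"].notna()
        if has_perm.any():
            results.loc[has_perm, "q"] = bh_adjust(results.loc[has_perm, "p_perm"])
    results["significant"] = results["q"].fillna(1.0) < fdr_threshold
    return results[RESULT_COLUMNS], summary
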