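"""Correlate per-cell scores with pseudotime; classify 3'UTR length change.

For each window (optionally within each cell type), the Spearman
correlation between the per-cell score and pseudotime is computed over
cells with at least ``min_reads`` reads in the window; a window is tested
only if at least ``min_cells`` such cells exist.  P-values are
Bonferroni-corrected by the number of windows actually tested (per stratum
when stratified).

Because ranks ascend with genomic coordinate on both strands, the
correlation sign is gene-orientation-corrected by multiplying by -1 on
minus-strand windows.  Among significant windows that overlap an annotated
3'UTR, a negative sign-corrected correlation means reads drift toward the
gene's 5' side over pseudotime — 3'UTR shortening — and a positive one
means lengthening.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["correlate", "call_regulated", "run_pseudotime"]

CORRELATION_COLUMNS = [
    "window_id",
    "ontology",
    "strand",
    "rho",
    "p",
    "p_bonf",
    "n_cells",
    "rho_signed",
]

# Below this many cells the t-approximation to Spearman's null is unreliable;
# fall back to a seeded permutation p-value.
_EXACT_N = 30


def _spearman(z: np.ndarray, t: np.ndarray, rng: np.random.Generator):
    rho, p = stats.spearmanr(z, t)
    if np.isnan(rho):
        return np.nan, np.nan
    if z.size < _EXACT_N:
        res = stats.permutation_test(
            (z,),
            lambda x: stats.spearmanr(x, t).statistic,
            permutation_type="pairings",
            n_resamples=9999,
            alternative="two-sided",
            rng=rng,
        )
        p = float(res.pvalue)
    return float(rho), float(p)


def correlate(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    min_reads: int = 5,
    min_cells: int = 300,
    stratify_by_ontology: bool = False,
    time_range: tuple[float, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Spearman correlation of score vs pseudotime per window (and stratum).

    ``metadata`` needs columns cell, pseudotime and, when stratifying,
    ontology.  ``time_range=(lo, hi)`` restricts cells to a pseudotime
    sub-interval before testing (e.g. the earliest quarter of a trajectory
    to resolve fine-scale regulation).  Windows with constant score or
    constant pseudotime are skipped.  The Bonferroni factor is the number
    of (window, stratum) tests actually performed.
    """
    rng = np.random.default_rng(seed)
    cols = ["cell", "pseudotime"] + (
        ["ontology"] if stratify_by_ontology else []
    )
    joined = scores.merge(metadata[cols], on="cell", how="inner")
    joined = joined[joined["n_reads"] >= min_reads]
    joined = joined.dropna(subset=["pseudotime"])
    if time_range is not None:
        lo, hi = time_range
        joined = joined[(joined["pseudotime"] >= lo) & (joined["pseudotime"] <= hi)]

    keys = ["window_id"] + (["ontology"] if stratify_by_ontology else [])
    rows = []
    for key, wdf in joined.groupby(keys, sort=True, observed=True):
        if not isinstance(key, tuple):
            key = (key,)
        if len(wdf) < min_cells:
            continue
        z = wdf["z"].to_numpy(dtype=float)
        t = wdf["pseudotime"].to_numpy(dtype=float)
        if np.all(z == z[0]) or np.all(t == t[0]):
            continue
        rho, p = _spearman(z, t, rng)
        if np.isnan(rho):
            continue
        strand = wdf["strand"].iloc[0] if "strand" in wdf else "+"
        rows.append(
            {
                "window_id": key[0],
                "ontology": key[1] if stratify_by_ontology else "all",
                "strand": strand,
                "rho": rho,
                "p": p,
                "n_cells": int(len(wdf)),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=CORRELATION_COLUMNS)
    n_tests = len(out)
    out["p_bonf"] = np.minimum(out["p"] * n_tests, 1.0)
    out["rho_signed"] = np.where(out["strand"] == "-", -out["rho"], out["rho"])
    return out[CORRELATION_COLUMNS]


def call_regulated(
    results: pd.DataFrame,
    utr_windows: set[str],
    rho_threshold: float = 0.3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Attach lengthening/shortening calls to correlation results.

    A window is significant when |rho| exceeds ``rho_threshold`` (0.3 for
    deep mammalian trajectories; 0.1 has been used for shallower plant
    data) and the Bonferroni-corrected p is below ``alpha``.  Among
    significant windows overlapping an annotated 3'UTR (``utr_windows``),
    the sign-corrected correlation classifies the drift: negative =
    shortening, positive = lengthening.  Everything else is 'ns'.
    """
    out = results.copy()
    sig = (out["rho"].abs() > rho_threshold) & (out["p_bonf"] < alpha)
    in_utr = out["window_id"].isin(utr_windows)
    call = np.full(len(out), "ns", dtype=object)
    call[(sig & in_utr & (out["rho_signed"] > 0)).to_numpy()] = "lengthening"
    call[(sig & in_utr & (out["rho_signed"] < 0)).to_numpy()] = "shortening"
    out["call"] = call
    return out


def run_pseudotime(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    utr_windows: set[str] | None = None,
    min_reads: int = 5,
    min_cells: int = 300,
    rho_threshold: float = 0.3,
    alpha: float = 0.05,
    stratify_by_ontology: bool = False,
    time_range: tuple[float, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Correlate then classify; convenience wrapper for the CLI."""
    res = correlate(
        scores,
        metadata,
        min_reads=min_reads,
        min_cells=min_cells,
        stratify_by_ontology=stratify_by_ontology,
        time_range=time_range,
        seed=seed,
    )
    return call_regulated(res, utr_windows or set(), rho_threshold, alpha)
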