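"""Cross-dataset concordance of cell-type orderings via the Spearman footrule.

If a window's read-position shifts between cell types are real biology, the
cell types should keep the same ordering of median scores in an independent
dataset.  For window j shared by two datasets, rank the m_j shared cell
types by median score (descending; ties broken by ontology name) in each
dataset, giving R_ij and R'_ij.  The concordance statistic is

    chi = sum_j (1/m_j) * sum_i |R_ij - R'_ij|

— small chi means concordant orderings.  A null is simulated by permuting,
independently within each window, the rank vector of the second dataset;
the p-value is the lower-tail probability P(chi_null <= chi_obs) with the
+1 finite-sample correction.  When every window has exactly two cell types
the null is Binomial(N, 1/2) and the p-value is computed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankProfile",
    "ConcordanceResult",
    "rank_profiles",
    "footrule_chi",
    "concordance_pvalue",
]


@dataclass(frozen=True)
class RankProfile:
    """Cell-type ranks (1..m, by median score descending) for one window."""

    window_id: str
    ranks: dict[str, int]

    @property
    def m(self) -> int:
        return len(self.ranks)


@dataclass(frozen=True)
class ConcordanceResult:
    chi: float
    p: float
    n_windows: int
    n_permutations: int
    exact: bool = False


def rank_profiles(medians: pd.DataFrame) -> dict[str, RankProfile]:
    """Build per-window rank profiles from a (window, ontology, median) table.

    Expects columns window_id, ontology, median_z (the difftest medians
    output).  Ranks descend with the median: the ontology with the highest
    median gets rank 1.  Median ties break on ontology name so profiles are
    deterministic.
    """
    out = {}
    for wid, wdf in medians.groupby("window_id", sort=True, observed=True):
        ordered = wdf.sort_values(
            ["median_z", "ontology"], ascending=[False, True]
        )["ontology"].tolist()
        if len(ordered) < 2:
            continue
        out[wid] = RankProfile(wid, {o: r for r, o in enumerate(ordered, start=1)})
    return out


def _paired(
    profiles1: dict[str, RankProfile], profiles2: dict[str, RankProfile]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Re-ranked pairs over the shared ontologies of each shared window."""
    pairs = []
    for wid in sorted(set(profiles1) & set(profiles2)):
        p1, p2 = profiles1[wid], profiles2[wid]
        shared = sorted(set(p1.ranks) & set(p2.ranks))
        if len(shared) < 2:
            continue
        # restrict to shared ontologies, then re-rank 1..m within each dataset
        r1 = stats.rankdata([p1.ranks[o] for o in shared], method="ordinal")
        r2 = stats.rankdata([p2.ranks[o] for o in shared], method="ordinal")
        pairs.append((np.asarray(r1, float), np.asarray(r2, float)))
    return pairs


def footrule_chi(
    profiles1: dict[str, RankProfile], profiles2: dict[str, RankProfile]
) -> float:
    """Observed chi over the windows and ontologies shared by both datasets."""
    pairs = _paired(profiles1, profiles2)
    if not pairs:
        raise ValueError("no comparable windows between the two datasets")
    return float(sum(np.abs(r1 - r2).sum() / len(r1) for r1, r2 in pairs))


def concordance_pvalue(
    profiles1: dict[str, RankProfile],
    profiles2: dict[str, RankProfile],
    n_permutations: int = 5000,
    rng_seed: int | None = None,
) -> ConcordanceResult:
    """Lower-tail permutation p-value for the observed chi.

    Permutes the second dataset's rank vector within each window,
    independently per window and per iteration.  With all windows at m = 2
    (where only 2^N distinct permutations exist) the null is exact:
    each window contributes 0 or 1 with probability 1/2, so chi_null is
    Binomial(N, 1/2).
    """
    rng = np.random.default_rng(rng_seed)
    pairs = _paired(profiles1, profiles2)
    if not pairs:
        raise ValueError("no comparable windows between the two datasets")
    chi_obs = float(sum(np.abs(r1 - r2).sum() / len(r1) for r1, r2 in pairs))
    n_windows = len(pairs)

    ms = [len(r1) for r1, _ in pairs]
    if all(m == 2 for m in ms) and n_permutations > 2**n_windows:
        p = float(stats.binom.cdf(np.floor(chi_obs + 1e-9), n_windows, 0.5))
        return ConcordanceResult(chi_obs, p, n_windows, n_permutations, exact=True)

    at_or_below = 0
    for _ in range(n_permutations):
        chi_null = 0.0
        for r1, r2 in pairs:
            chi_null += np.abs(r1 - rng.permutation(r2)).sum() / len(r1)
        if chi_null <= chi_obs:
            at_or_below += 1
    p = (1 + at_or_below) / (n_permutations + 1)
    return ConcordanceResult(chi_obs, p, n_windows, n_permutations)
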