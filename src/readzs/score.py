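"""Per-cell, per-window z-score of read positions.

Within one stranded window, every genomic position that carries at least
one read (from any cell) receives a rank: positions are sorted by
coordinate and ranked 1..P with no gaps, however far apart they are on the
genome.  With m_ir the number of reads of cell i at rank r and
N = sum_i sum_r m_ir the window total,

    mu    = (1/N) * sum_i sum_r r * m_ir
    sigma = sqrt((1/N) * sum_i sum_r m_ir * (r - mu)^2)      (population SD)
    rtil  = (r - mu) / sigma
    z_i   = (1/N_i) * sum_r m_ir * rtil

where N_i is cell i's read count in the window.  Under exchangeable read
positions E[z_i] = 0 and Var(z_i) ~ 1/N_i, so z_i * sqrt(N_i) is roughly
standard normal; a negative z_i means cell i's reads sit upstream (in
genomic coordinate) of the population average.  The weighted cell scores
always satisfy sum_i N_i * z_i = 0 exactly.

Ranks ascend with genomic coordinate on both strands; biological
orientation is restored downstream by multiplying correlations by -1 on
minus-strand windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "rank_positions",
    "window_moments",
    "cell_scores",
    "score_counts",
]

SCORE_COLUMNS = ["window_id", "chrom", "strand", "cell", "sample", "z", "n_reads"]


def rank_positions(window_counts: pd.DataFrame) -> dict[int, int]:
    """Map each observed position to its rank 1..P (ascending coordinate).

    All reads at a position share its rank; only positions present in the
    data are ranked, with no gaps between consecutive ranks.
    """
    positions = np.sort(window_counts["position"].unique())
    if positions.size == 0:
        raise ValueError("window has no observed positions")
    return {int(p): r for r, p in enumerate(positions, start=1)}


def window_moments(
    window_counts: pd.DataFrame, ranks: dict[int, int]
) -> tuple[float, float]:
    """Population mean and SD of the read ranks over all cells in the window."""
    r = window_counts["position"].map(ranks).to_numpy(dtype=float)
    m = window_counts["count"].to_numpy(dtype=float)
    n_total = m.sum()
    if n_total < 1:
        raise ValueError("window has no reads")
    mu = float((r * m).sum() / n_total)
    sigma = float(np.sqrt((m * (r - mu) ** 2).sum() / n_total))
    return mu, sigma


def cell_scores(
    window_counts: pd.DataFrame,
    ranks: dict[int, int],
    mu: float,
    sigma: float,
) -> pd.DataFrame:
    """Per-cell score z_i and read count N_i for one window.

    Requires sigma > 0; a window whose reads all sit at one position is
    unscorable and the caller should drop it.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive; single-position window is unscorable")
    df = window_counts
    rtil = (df["position"].map(ranks).to_numpy(dtype=float) - mu) / sigma
    m = df["count"].to_numpy(dtype=float)
    contrib = pd.DataFrame({"cell": df["cell"].to_numpy(), "wz": rtil * m, "m": m})
    agg = contrib.groupby("cell", sort=True).sum()
    return pd.DataFrame(
        {
            "cell": agg.index.to_numpy(),
            "z": (agg["wz"] / agg["m"]).to_numpy(),
            "n_reads": agg["m"].astype(int).to_numpy(),
        }
    )


def score_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Score every window in a counts table.

    Cells are scored whenever they have at least one read; read-depth
    eligibility filters belong to the testing stage, keeping the score a
    pure function of the counts.  Windows with a single observed position
    (sigma = 0) are skipped.
    """
    out = []
    for wid, wdf in counts.groupby("window_id", sort=True, observed=True):
        ranks = rank_positions(wdf)
        mu, sigma = window_moments(wdf, ranks)
        if sigma == 0:
            continue
        scores = cell_scores(wdf, ranks, mu, sigma)
        scores.insert(0, "window_id", wid)
        scores.insert(1, "chrom", wdf["chrom"].iloc[0])
        scores.insert(2, "strand", wdf["strand"].iloc[0])
        sample_of = wdf.drop_duplicates("cell").set_index("cell")["sample"]
        scores["sample"] = scores["cell"].map(sample_of)
        out.append(scores[SCORE_COLUMNS])
    if not out:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    return pd.concat(out, ignore_index=True)
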