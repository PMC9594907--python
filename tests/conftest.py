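import numpy as np
import pandas as pd
import pytest


def make_counts(entries, window_id="w", chrom="chr1", strand="+", start=0, end=5000):
    """Counts table from (cell, position, count) triples."""
    rows = [
        {
            "window_id": window_id,
            "chrom": chrom,
            "strand": strand,
            "start": start,
            "end": end,
            "cell": cell,
            "sample": "s",
            "position": pos,
            "count": count,
        }
        for cell, pos, count in entries
    ]
    return pd.DataFrame(rows)


def random_counts(rng, n_cells=8, n_positions=6, max_count=4, **kw):
    """A random small counts table with at least two distinct positions."""
    positions = np.sort(rng.choice(np.arange(0, 5000), size=n_positions, replace=False))
    entries = []
    for c in range(n_cells):
        used = rng.choice(positions, size=rng.integers(1, n_positions + 1), replace=False)
        for p in used:
            entries.append((f"c{c}", int(p), int(rng.integers(1, max_count + 1))))
    return make_counts(entries, **kw)


def naive_scores(counts):
    """Independent brute-force evaluation of the four scoring equations.

    Dict-and-loop arithmetic, no shared code with the implementation.
    """
    positions = sorted({int(p) for p in counts["position"]})
    rank = {p: i + 1 for i, p in enumerate(positions)}
    total = 0
    weighted = 0.0
    for row in counts.itertuples(index=False):
        total += row.count
        weighted += rank[row.position] * row.count
    mu = weighted / total
    ss = 0.0
    for row in counts.itertuples(index=False):
        ss += row.count * (rank[row.position] - mu) ** 2
    sigma = (ss / total) ** 0.5
    out = {}
    for cell in sorted(counts["cell"].unique()):
        sub = counts[counts["cell"] == cell]
        n_i = int(sub["count"].sum())
        z = sum(
            row.count * (rank[row.position] - mu) / sigma
            for row in sub.itertuples(index=False)
        ) / n_i
        out[cell] = (z, n_i)
    return out


@pytest.fixture
def worked_counts():
    """Cell A: 2 reads at position 10; cell B: one read each at 20 and 30."""
    return make_counts([("A", 10, 2), ("B", 20, 1), ("B", 30, 1)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
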