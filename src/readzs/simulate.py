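"""Synthetic scRNA-seq datasets with the read-position structure the method assumes.

The generator emulates what 3'-biased droplet libraries look like near a
gene end: read starts pile up in one or more approximately Gaussian peaks
(the insert-length smear of ~350 bp libraries is realised as the peak SD,
150 bp by default), cells carry few reads each (Poisson counts), cell
types or pseudotime shift the mixing proportions between peaks, and UMI
duplicates inflate the raw read count.  Windows are stranded and reads
never straddle window boundaries by construction, so the simulated truth
is exact.

Two output routes exist: ``simulate_counts`` produces the deduplicated
counts table directly (fast path for statistical tests), while
``simulate_celltype_dataset`` / ``simulate_pseudotime_dataset`` emit SAM
text plus metadata and truth tables so the full ingest path is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimSpec",
    "simulate_counts",
    "simulate_celltype_dataset",
    "simulate_pseudotime_dataset",
    "write_annotation_fixture",
]

READ_LEN = 90


@dataclass
class SimSpec:
    """Study-condition parameters for one simulated window.

    ``peaks`` are (mean bp, sd bp) components of the read-start
    distribution; ``mixing`` gives each ontology's peak proportions.  Reads
    per cell are Poisson(``reads_per_cell_mean``) plus ``reads_per_cell_min``.
    For pseudotime simulations the distal peak's usage in a cell at time t
    is ``distal_intercept + distal_slope * t`` (clipped to [0, 1]); distal
    means the peak furthest in the direction of transcription.
    """

    peaks: list[tuple[float, float]] = field(
        default_factory=lambda: [(1500.0, 150.0), (2500.0, 150.0)]
    )
    mixing: dict[str, list[float]] = field(
        default_factory=lambda: {"typeA": [0.8, 0.2], "typeB": [0.2, 0.8]}
    )
    n_cells: int = 30
    reads_per_cell_mean: float = 15.0
    reads_per_cell_min: int = 0
    umi_dup_rate: float = 0.0
    distal_intercept: float = 0.2
    distal_slope: float = 0.6
    strand: str = "+"
    chrom: str = "chr1"
    chrom_length: int = 100_000
    window_size: int = 5000
    window_index: int = 0
    sample: str = "sim"
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for ont, props in self.mixing.items():
            p = np.asarray(props, dtype=float)
            if len(p) != len(self.peaks):
                raise ValueError(f"{ont}: {len(p)} proportions for {len(self.peaks)} peaks")
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"{ont}: proportions must be >=0 and sum to 1")
        if any(sd <= 0 for _, sd in self.peaks):
            raise ValueError("peak sds must be positive")

    @property
    def window_start(self) -> int:
        return self.window_index * self.window_size

    @property
    def window_id(self) -> str:
        return f"{self.chrom}:{self.strand}:{self.window_index}"


def _draw_positions(
    rng: np.random.Generator, spec: SimSpec, proportions: np.ndarray, n: int
) -> np.ndarray:
    comp = rng.choice(len(spec.peaks), size=n, p=proportions)
    means = np.array([m for m, _ in spec.peaks])
    sds = np.array([s for _, s in spec.peaks])
    pos = rng.normal(means[comp], sds[comp])
    lo = spec.window_start
    hi = spec.window_start + spec.window_size - READ_LEN - 1
    return np.clip(np.rint(pos), lo, hi).astype(int)


def _cell_reads(rng: np.random.Generator, spec: SimSpec) -> int:
    return int(rng.poisson(spec.reads_per_cell_mean)) + spec.reads_per_cell_min


def simulate_counts(
    spec: SimSpec,
    pseudotime: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(counts table, metadata) for one window, bypassing SAM round-tripping.

    With ``pseudotime=True`` each cell draws t ~ Uniform(0,1) and its
    distal-peak usage follows ``spec``'s linear model; otherwise each
    ontology in ``spec.mixing`` contributes ``spec.n_cells`` cells with that
    ontology's fixed proportions.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    means = np.array([m for m, _ in spec.peaks])
    distal_idx = int(np.argmax(means) if spec.strand == "+" else np.argmin(means))

    rows, meta = [], []
    if pseudotime:
        for c in range(spec.n_cells):
            cell = f"cell{c:05d}"
            t = float(rng.uniform())
            p_distal = float(np.clip(spec.distal_intercept + spec.distal_slope * t, 0, 1))
            props = np.full(len(spec.peaks), (1 - p_distal) / max(len(spec.peaks) - 1, 1))
            props[distal_idx] = p_distal
            n = _cell_reads(rng, spec)
            if n > 0:
                rows.append((cell, _draw_positions(rng, spec, props, n)))
            meta.append({"cell": cell, "sample": spec.sample, "ontology": "all", "pseudotime": t})
    else:
        c = 0
        for ont in sorted(spec.mixing):
            props = np.asarray(spec.mixing[ont], dtype=float)
            for _ in range(spec.n_cells):
                cell = f"cell{c:05d}"
                c += 1
                n = _cell_reads(rng, spec)
                if n > 0:
                    rows.append((cell, _draw_positions(rng, spec, props, n)))
                meta.append({"cell": cell, "sample": spec.sample, "ontology": ont})

    recs = []
    for cell, positions in rows:
        pos, cnt = np.unique(positions, return_counts=True)
        for p, m in zip(pos, cnt):
            recs.append(
                (
                    spec.window_id,
                    spec.chrom,
                    spec.strand,
                    spec.window_start,
                    spec.window_start + spec.window_size,
                    cell,
                    spec.sample,
                    int(p),
                    int(m),
                )
            )
    counts = pd.DataFrame(
        recs,
        columns=[
            "window_id", "chrom", "strand", "start", "end",
            "cell", "sample", "position", "count",
        ],
    )
    return counts, pd.DataFrame(meta)


def _sam_text(spec: SimSpec, molecules: list[tuple[str, str, int]], rng: np.random.Generator) -> str:
    """SAM records (with UMI duplicates at ``umi_dup_rate``) for molecules
    given as (cell, umi, pos)."""
    flag = 16 if spec.strand == "-" else 0
    seq = "A" * READ_LEN
    qual = "I" * READ_LEN
    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{spec.chrom}\tLN:{spec.chrom_length}",
    ]
    records = []
    for i, (cell, umi, pos) in enumerate(molecules):
        n_copies = 1 + (1 if rng.uniform() < spec.umi_dup_rate else 0)
        for j in range(n_copies):
            records.append(
                (
                    pos,
                    f"read{i:07d}.{j}\t{flag}\t{spec.chrom}\t{pos + 1}\t255\t"
                    f"{READ_LEN}M\t*\t0\t0\t{seq}\t{qual}\tCB:Z:{cell}\tUB:Z:{umi}",
                )
            )
    records.sort(key=lambda r: r[0])
    lines.extend(r[1] for r in records)
    return "\n".join(lines) + "\n"


def _counts_to_sam(
    counts: pd.DataFrame, meta: pd.DataFrame, spec: SimSpec, rng: np.random.Generator
) -> str:
    molecules = []
    umi_counter = 0
    for row in counts.itertuples(index=False):
        for _ in range(row.count):
            molecules.append((row.cell, f"U{umi_counter:08d}", row.position))
            umi_counter += 1
    return _sam_text(spec, molecules, rng)


def simulate_celltype_dataset(
    spec: SimSpec,
) -> tuple[str, pd.DataFrame, pd.DataFrame]:
    """(SAM text, metadata, truth) for a cell type-structured window.

    The truth table records each ontology's true peak proportions and the
    expected effect direction (which ontology skews downstream).
    """
    rng = np.random.default_rng(spec.rng_seed)
    counts, meta = simulate_counts(spec, pseudotime=False, rng=rng)
    sam = _counts_to_sam(counts, meta, spec, rng)
    means = np.array([m for m, _ in spec.peaks])
    rows = []
    for ont in sorted(spec.mixing):
        props = np.asarray(spec.mixing[ont], dtype=float)
        rows.append(
            {
                "window_id": spec.window_id,
                "ontology": ont,
                "proportions": ",".join(f"{p:g}" for p in props),
                "expected_mean_position": float((props * means).sum()),
            }
        )
    truth = pd.DataFrame(rows)
    truth["differential"] = truth["expected_mean_position"].nunique() > 1
    return sam, meta, truth


def simulate_pseudotime_dataset(
    spec: SimSpec,
) -> tuple[str, pd.DataFrame, pd.DataFrame]:
    """(SAM text, metadata with pseudotime, truth) for a drifting window.

    The truth table records the expected sign of the sign-corrected
    correlation: rising distal usage is lengthening (positive) regardless
    of strand, because the sign correction folds the strand back in.
    """
    rng = np.random.default_rng(spec.rng_seed)
    counts, meta = simulate_counts(spec, pseudotime=True, rng=rng)
    sam = _counts_to_sam(counts, meta, spec, rng)
    expected = int(np.sign(spec.distal_slope))
    truth = pd.DataFrame(
        [
            {
                "window_id": spec.window_id,
                "distal_slope": spec.distal_slope,
                "expected_rho_signed_sign": expected,
                "expected_call": {1: "lengthening", -1: "shortening", 0: "ns"}[expected],
            }
        ]
    )
    return sam, meta, truth


def write_annotation_fixture(
    genes: list[tuple[str, int, int, str, str]],
    utrs: list[tuple[str, int, int, str, str]],
) -> str:
    """GFF3 text from 0-based half-open gene and 3'UTR intervals.

    Both lists hold (chrom, start, end, strand, id).  Coordinates convert
    to GFF3's 1-based inclusive on write, so the round trip through the
    annotation loader reproduces the designed intervals exactly.
    """
    lines = ["##gff-version 3"]
    for chrom, start, end, strand, gid in genes:
        lines.append(
            f"{chrom}\tsim\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t"
            f"ID={gid};gene_name={gid}"
        )
    for chrom, start, end, strand, uid in utrs:
        lines.append(
            f"{chrom}\tsim\tthree_prime_UTR\t{start + 1}\t{end}\t.\t{strand}\t.\tID={uid}"
        )
    return "\n".join(lines) + "\n"
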