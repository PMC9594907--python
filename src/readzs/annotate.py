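"""Intersect windows and peaks with gene / 3'UTR annotations.

Gene and three_prime_UTR features are read from GFF3 (converted to the
package-wide 0-based half-open convention) or BED6.  Windows are annotated
with the genes and 3'UTRs covering at least a fraction of the window
(default 25%), with the count of same-strand 3'UTR ends falling in the
window shifted 300 bp downstream, and with whether any gene overlaps at
all.  Called peaks get their distance to the closest same-strand 3'UTR end
on each side and a flag for a gene within 600 bp downstream; the
downstream distances, conditioned on being under ~2 kb (to dodge intronic
internal-priming artefacts), are summarised as quantiles and a binned
histogram comparable to the expected insert-length distribution of the
library.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "Feature",
    "load_annotations",
    "load_bed_features",
    "annotate_windows",
    "count_downstream_utr_ends",
    "nearest_utr_distances",
    "annotate_peaks",
    "distance_summary",
    "join_on_gene",
]


@dataclass(frozen=True)
class Feature:
    """A gene or three_prime_UTR interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    kind: str  # 'gene' or 'three_prime_UTR'
    id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"degenerate feature {self.id}: [{self.start},{self.end})")

    @property
    def utr_end_coord(self) -> int:
        """The transcript-terminal coordinate: end on +, start on -."""
        return self.end if self.strand == "+" else self.start


def load_annotations(gff3_path: str | Path) -> list[Feature]:
    """Gene and three_prime_UTR features from a GFF3 file.

    GFF3 is 1-based inclusive; coordinates are converted on read.  Gene
    identifiers come from the ``gene_name`` attribute (falling back to
    ``Name`` then ``ID``); 3'UTRs use ``ID``.  Features missing an
    identifier are skipped with a warning; other feature types are dropped.
    """
    features: list[Feature] = []
    skipped = 0
    with open(gff3_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.featuretype not in ("gene", "three_prime_UTR"):
                continue
            attrs = feat.attributes
            if feat.featuretype == "gene":
                ident = (
                    attrs.get("gene_name") or attrs.get("Name") or attrs.get("ID")
                )
            else:
                ident = attrs.get("ID") or attrs.get("Name")
            if not ident:
                skipped += 1
                continue
            features.append(
                Feature(
                    chrom=feat.seqid,
                    start=feat.start - 1,  # 1-based inclusive -> 0-based half-open
                    end=feat.end,
                    strand=feat.strand,
                    kind=feat.featuretype,
                    id=ident[0],
                )
            )
    if skipped:
        logger.warning("skipped %d features lacking an identifier", skipped)
    return features


def load_bed_features(bed_path: str | Path, kind: str) -> list[Feature]:
    """Features from a BED6 file (already 0-based half-open)."""
    out = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            out.append(
                Feature(chrom, int(start), int(end), strand.strip(), kind, name)
            )
    return out


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _trees_by_chrom(features: list[Feature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for f in features:
        trees[f.chrom].addi(f.start, f.end, f)
    return trees


def annotate_windows(
    windows: pd.DataFrame,
    features: list[Feature],
    min_frac: float = 0.25,
    frac_of: str = "window",
    shift: int = 300,
) -> pd.DataFrame:
    """Per-window gene/UTR assignment and downstream-UTR-end count.

    ``windows`` needs columns window_id, chrom, strand, start, end.  A gene
    or 3'UTR is assigned when the overlap reaches ``min_frac`` of the
    window length (``frac_of='feature'`` measures against the feature
    instead).  ``window_has_gene`` is true on ANY gene overlap, regardless
    of strand or fraction.  ``num_3UTR_300bp_downstream`` counts same-strand
    3'UTR end coordinates inside the window shifted ``shift`` bp downstream.
    """
    trees = _trees_by_chrom(features)
    utrs = [f for f in features if f.kind == "three_prime_UTR"]
    rows = []
    for w in windows.itertuples(index=False):
        wlen = w.end - w.start
        genes, wutrs = [], []
        has_gene = False
        for iv in trees.get(w.chrom, IntervalTree()).overlap(w.start, w.end):
            f: Feature = iv.data
            ov = _overlap(w.start, w.end, f.start, f.end)
            if f.kind == "gene" and ov > 0:
                has_gene = True
            denom = wlen if frac_of == "window" else (f.end - f.start)
            if ov >= min_frac * denom:
                (genes if f.kind == "gene" else wutrs).append(f.id)
        n_down = count_downstream_utr_ends(
            (w.chrom, w.strand, w.start, w.end), utrs, shift=shift
        )
        rows.append(
            {
                "window_id": w.window_id,
                "genes": ",".join(sorted(set(genes))),
                "utrs": ",".join(sorted(set(wutrs))),
                "num_3UTR_300bp_downstream": n_down,
                "window_has_gene": has_gene,
            }
        )
    return pd.DataFrame(rows)


def count_downstream_utr_ends(
    window: tuple[str, str, int, int],
    utr_features: list[Feature],
    shift: int = 300,
) -> int:
    """Same-strand 3'UTR ends in the window shifted ``shift`` bp downstream.

    Downstream means +shift on the plus strand and -shift on the minus
    strand (clamped at zero); membership uses the half-open shifted
    interval.
    """
    chrom, strand, start, end = window
    if strand == "+":
        lo, hi = start + shift, end + shift
    else:
        lo, hi = max(0, start - shift), max(0, end - shift)
    return sum(
        1
        for f in utr_features
        if f.kind == "three_prime_UTR"
        and f.chrom == chrom
        and f.strand == strand
        and lo <= f.utr_end_coord < hi
    )


def nearest_utr_distances(
    peak_pos: int,
    strand: str,
    utr_end_coords: np.ndarray,
) -> tuple[float, float]:
    """(upstream_dist, downstream_dist) in bp to the closest 3'UTR ends.

    ``utr_end_coords`` are same-strand, same-chromosome end coordinates.
    Downstream means increasing coordinate on the plus strand and
    decreasing on the minus strand; a side with no end is NaN.
    """
    ends = np.asarray(utr_end_coords, dtype=float)
    delta = ends - peak_pos
    if strand == "-":
        delta = -delta
    up = -delta[delta < 0]
    down = delta[delta > 0]
    return (
        float(up.min()) if up.size else float("nan"),
        float(down.min()) if down.size else float("nan"),
    )


def annotate_peaks(
    peaks: pd.DataFrame,
    features: list[Feature],
    downstream_gene_bp: int = 600,
) -> pd.DataFrame:
    """Distance columns and downstream-gene flag for called peaks.

    ``peaks`` needs columns window_id, chrom, strand, mean.  The peak
    position is the component mean rounded to the nearest bp.
    ``peak_has_600bp_downstream_gene`` is true when the strand-aware
    interval from the peak to ``downstream_gene_bp`` beyond it (clamped at
    0) overlaps any same-strand gene.
    """
    utr_ends: dict[tuple[str, str], np.ndarray] = {}
    for f in features:
        if f.kind != "three_prime_UTR":
            continue
        utr_ends.setdefault((f.chrom, f.strand), [])
        utr_ends[(f.chrom, f.strand)].append(f.utr_end_coord)  # type: ignore[attr-defined]
    utr_ends = {k: np.sort(np.asarray(v)) for k, v in utr_ends.items()}
    gene_trees = _trees_by_chrom([f for f in features if f.kind == "gene"])

    rows = []
    for p in peaks.itertuples(index=False):
        pos = int(round(p.mean))
        ends = utr_ends.get((p.chrom, p.strand), np.empty(0))
        up, down = nearest_utr_distances(pos, p.strand, ends)
        if p.strand == "+":
            lo, hi = pos, pos + downstream_gene_bp
        else:
            lo, hi = max(0, pos - downstream_gene_bp), pos
        has_gene = False
        if hi > lo:
            for iv in gene_trees.get(p.chrom, IntervalTree()).overlap(lo, hi):
                if iv.data.strand == p.strand:
                    has_gene = True
                    break
        rows.append(
            {
                "window_id": p.window_id,
                "mean": p.mean,
                "upstream_3UTR_dist": up,
                "downstream_3UTR_dist": down,
                "peak_has_600bp_downstream_gene": has_gene,
            }
        )
    return pd.DataFrame(rows)


def distance_summary(
    peak_annotations: pd.DataFrame,
    max_dist: float = 2000,
    bins: int = 100,
) -> tuple[pd.Series, pd.DataFrame]:
    """Quantiles and histogram of peak-to-downstream-3'UTR-end distances.

    Only peaks with a same-strand gene within 600 bp downstream and a
    finite downstream distance below ``max_dist`` enter the summary; the
    cap excludes distances dominated by intronic internal priming.
    Returns (quantile series at 25/50/75%, histogram table with bin edges,
    counts, density and CDF).
    """
    df = peak_annotations
    mask = (
        df["peak_has_600bp_downstream_gene"]
        & df["downstream_3UTR_dist"].notna()
        & (df["downstream_3UTR_dist"] < max_dist)
    )
    d = df.loc[mask, "downstream_3UTR_dist"].to_numpy(dtype=float)
    if d.size == 0:
        return pd.Series(dtype=float), pd.DataFrame(
            columns=["bin_left", "bin_right", "count", "density", "cdf"]
        )
    quantiles = pd.Series(d).quantile([0.25, 0.5, 0.75])
    counts, edges = np.histogram(d, bins=bins)
    density = counts / counts.sum() / np.diff(edges)
    hist = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "density": density,
            "cdf": np.cumsum(counts) / counts.sum(),
        }
    )
    return quantiles, hist


def join_on_gene(
    a: pd.DataFrame, b: pd.DataFrame, gene_col: str = "gene", how: str = "inner"
) -> pd.DataFrame:
    """Join two result tables on identical gene symbols (suffixe _a/_b).

    A thin convenience for cross-dataset or cross-species comparison where
    orthology reduces to an exact symbol match.
    """
    return a.merge(b, on=gene_col, how=how, suffixes=("_a", "_b"))
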