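"""Linkage-disequilibrium decay: pairwise r² versus physical distance.

r² is the squared Pearson correlation of alt-allele dosage vectors
across strains (a genotype-based estimator, appropriate for unphased
diploids; missing genotypes are pairwise-deleted).  The decay curve
aggregates all intra-chromosome pairs up to ``max_dist``, averages r²
per exact distance and smooths the distance-ordered series with a
centered moving average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import GenotypeMatrix

logger = logging.getLogger(__name__)


def pair_r2(a: np.ndarray, b: np.ndarray) -> float | None:
    """Squared dosage correlation of two sites, or None when undefined.

    Undefined when fewer than 2 strains are called at both sites or
    either site is monomorphic among the shared strains.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    ok = (a >= 0) & (b >= 0)
    if ok.sum() < 2:
        return None
    x, y = a[ok], b[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return None
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return r * r


@dataclass
class LDCurve:
    """Distance-binned LD decay: raw means and a moving-average smooth."""

    distances: np.ndarray      # unique pair distances, ascending
    mean_r2: np.ndarray        # mean r2 at each distance
    smoothed_r2: np.ndarray    # centered moving average over the distance axis
    n_pairs: np.ndarray        # pairs contributing at each distance
    window: int
    max_dist: int
    n_samples: int

    def __post_init__(self) -> None:
        if not (len(self.distances) == len(self.mean_r2)
                == len(self.smoothed_r2) == len(self.n_pairs)):
            raise ValueError("curve arrays must be aligned")

    @property
    def total_pairs(self) -> int:
        return int(self.n_pairs.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "distance": self.distances,
            "mean_r2": self.mean_r2,
            "smoothed_r2": self.smoothed_r2,
            "n_pairs": self.n_pairs,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def decay_curve(gm: GenotypeMatrix, max_dist: int = 300_000, window: int = 50) -> LDCurve:
    """LD decay over all intra-chromosome site pairs within ``max_dist``.

    Monomorphic-in-sample pairs are skipped; an input with no scorable
    pair yields an empty curve (logged), not an error.
    """
    if max_dist < 1 or window < 1:
        raise ValueError("max_dist and window must be >= 1")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for chrom in gm.chromosome_names:
        sub = gm.for_chromosome(chrom)
        pos = sub.positions
        order = np.argsort(pos, kind="mergesort")
        pos = pos[order]
        dos = sub.dosages[order].astype(float)
        dos[dos < 0] = np.nan
        n_sites = pos.size
        # precompute per-site mean/std over called strains
        for i in range(n_sites):
            hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
            for j in range(i + 1, hi):
                dist = int(pos[j] - pos[i])
                r2 = _pair_r2_nan(dos[i], dos[j])
                if r2 is None:
                    continue
                sums[dist] = sums.get(dist, 0.0) + r2
                counts[dist] = counts.get(dist, 0) + 1
    if not counts:
        logger.info("no scorable site pairs; returning empty LD curve")
        empty = np.empty(0)
        return LDCurve(empty.astype(np.int64), empty, empty, empty.astype(np.int64),
                       window, max_dist, len(gm.samples))
    dists = np.array(sorted(counts), dtype=np.int64)
    mean_r2 = np.array([sums[d] / counts[d] for d in dists])
    smoothed = (
        pd.Series(mean_r2).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return LDCurve(
        distances=dists,
        mean_r2=mean_r2,
        smoothed_r2=smoothed,
        n_pairs=np.array([counts[d] for d in dists], dtype=np.int64),
        window=window,
        max_dist=max_dist,
        n_samples=len(gm.samples),
    )


def _pair_r2_nan(x: np.ndarray, y: np.ndarray) -> float | None:
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return None
    a, b = x[ok], y[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return None
    r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return r * r


def plot_curve(curves: dict[str, LDCurve], path=None, raw_inset_bp: int = 2000):
    """Overlay smoothed decay curves per strain group (optional matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, curve in curves.items():
        if curve.distances.size:
            ax.plot(curve.distances, curve.smoothed_r2, label=name)
    ax.set_xlabel("distance (bp)")
    ax.set_ylabel(r"mean $r^2$ (smoothed)")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
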