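"""Per-category rarefaction: discovery potential of functional categories.

For a functional category c, let P_c be the set of predicted gene families
and W_c^p the corpus gene count of family p, so the category's gene multiset
G_c has N = sum_p W_c^p members. Drawing n genes uniformly without
replacement from G_c and counting distinct families gives the rarefaction
statistic P_c^n; its mean over bootstrap replicates, with percentile
confidence intervals, traces how quickly new families keep appearing as
sampling deepens. A curve that plateaus marks a "saturated" category; a
curve still rising at the largest n marks high discovery potential.

Sampling without replacement is the default so that n = N recovers exactly
|P_c| and the mean admits the hypergeometric closed form
E[P_c^n] = sum_p [1 - C(N - W_p, n) / C(N, n)]; with-replacement sampling
is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


class EmptyPoolError(ValueError):
    pass


@dataclass
class CategoryGenePool:
    """All genes predicted for one category, tagged by family."""

    category: str
    family_counts: dict[str, int]  # W_c^p per family p

    def __post_init__(self) -> None:
        if not self.family_counts:
            raise EmptyPoolError(f"category {self.category!r}: no families")
        if any(c < 1 for c in self.family_counts.values()):
            raise EmptyPoolError(f"category {self.category!r}: family with count < 1")

    @property
    def n_genes(self) -> int:
        return sum(self.family_counts.values())

    @property
    def n_families(self) -> int:
        return len(self.family_counts)

    def expanded(self) -> np.ndarray:
        """G_c as an array of family indices (one entry per gene)."""
        return np.repeat(np.arange(self.n_families), list(self.family_counts.values()))


def pool_from_predictions(predictions: pd.DataFrame, counts: Mapping[str, int],
                          category: str) -> CategoryGenePool:
    """Build a pool from reliable prediction rows and vocabulary counts."""
    toks = predictions.loc[predictions["predicted_category"] == category, "token"]
    fam = {t: int(counts[t]) for t in toks if t in counts}
    return CategoryGenePool(category=category, family_counts=fam)


def default_size_grid(n_genes: int, lo: int = 1_000, hi: int = 1_000_000,
                      per_decade: int = 20) -> np.ndarray:
    """Logarithmic sample-size grid, clipped to the pool size.

    The working range is [1e3, 1e6]; pools smaller than ``lo`` fall back to
    a short grid ending at the pool size.
    """
    hi = min(hi, n_genes)
    if hi <= lo:
        return np.unique(np.maximum(1, np.linspace(1, n_genes, 10).astype(int)))
    n_points = max(2, int(round(per_decade * np.log10(hi / lo))) + 1)
    grid = np.unique(np.round(np.logspace(np.log10(lo), np.log10(hi), n_points)).astype(int))
    return grid


@dataclass
class RarefactionCurve:
    category: str
    sizes: np.ndarray
    mean: np.ndarray  # mean P_c^n per size
    lo: np.ndarray  # 2.5 percentile
    hi: np.ndarray  # 97.5 percentile
    n_bootstrap: int
    seed: int
    with_replacement: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.sizes, "mean": self.mean, "lo": self.lo, "hi": self.hi})


def expected_unique_families(pool: CategoryGenePool, n: int) -> float:
    """Closed-form E[P_c^n] under without-replacement sampling (hypergeometric)."""
    total = pool.n_genes
    counts = np.array(list(pool.family_counts.values()))
    # P(family absent from sample) = C(N - W_p, n) / C(N, n) = hypergeom pmf at 0
    p_absent = np.array([hypergeom.pmf(0, total, w, n) for w in counts])
    return float(np.sum(1.0 - p_absent))


def rarefy(
    pool: CategoryGenePool,
    sizes: Optional[Sequence[int]] = None,
    n_bootstrap: int = 10_000,
    seed: int = 0,
    with_replacement: bool = False,
) -> RarefactionCurve:
    """Bootstrap the rarefaction curve of one category pool.

    For each subsample size n, ``n_bootstrap`` independent uniform draws of
    n genes from G_c are taken and the number of distinct families counted;
    the curve reports the replicate mean and the 2.5/97.5 percentile CI.
    Reproducible from the seed.
    """
    genes = pool.expanded()
    total = genes.shape[0]
    if sizes is None:
        grid = default_size_grid(total)
    else:
        grid = np.unique(np.asarray(sizes, dtype=int))
        if (grid < 1).any():
            raise ValueError("sizes must be positive")
        grid = np.minimum(grid, total)
        grid = np.unique(grid)
    rng = np.random.default_rng(seed)
    n_fam = pool.n_families
    means = np.empty(len(grid))
    los = np.empty(len(grid))
    his = np.empty(len(grid))
    seen = np.zeros(n_fam, dtype=bool)
    for gi, n in enumerate(grid):
        uniques = np.empty(n_bootstrap)
        if not with_replacement and n == total:
            uniques[:] = n_fam  # exhaustive draw recovers every family
        else:
            for b in range(n_bootstrap):
                idx = rng.choice(total, size=n, replace=with_replacement)
                seen[:] = False
                seen[genes[idx]] = True
                uniques[b] = seen.sum()
        means[gi] = uniques.mean()
        los[gi], his[gi] = np.percentile(uniques, [2.5, 97.5])
    return RarefactionCurve(category=pool.category, sizes=grid, mean=means,
                            lo=los, hi=his, n_bootstrap=n_bootstrap, seed=seed,
                            with_replacement=with_replacement)


def discovery_slope(curve: RarefactionCurve) -> float:
    """Relative rise of the mean curve over its final decade of n.

    0 for a plateaued (saturated) category; approaches 0.9 for the identity
    curve P_c^n = n (every gene its own family). Uses log-n interpolation
    when n_max/10 falls between grid points; for curves spanning less than
    a decade, the full span is used.
    """
    if len(curve.sizes) < 2:
        raise ValueError("curve needs >= 2 sizes")
    n_max = float(curve.sizes[-1])
    n_ref = max(n_max / 10.0, float(curve.sizes[0]))
    mean_ref = float(np.interp(np.log10(n_ref), np.log10(curve.sizes.astype(float)), curve.mean))
    mean_max = float(curve.mean[-1])
    if mean_max == 0:
        return 0.0
    return (mean_max - mean_ref) / mean_max
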