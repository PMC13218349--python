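"""Paired nonparametric inference, corrections, power and spatial nulls.

Conventions: effect sizes for signed-rank comparisons use the Rosenthal
formula r = |z| / sqrt(n); achieved power is estimated by Monte-Carlo
simulation of normally distributed paired differences tested with a
two-sided Wilcoxon signed-rank test; spatial correlations between
parcellated maps are tested against a spin null that rotates the parcel
centroids on the sphere and reassigns values one-to-one by proximity,
preserving each map's spatial autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import special_ortho_group
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedTestResult",
    "SpinTestResult",
    "PowerResult",
    "wilcoxon_paired",
    "effect_size_r",
    "fdr_adjust",
    "simes_adjust",
    "mc_power",
    "spin_permutation",
    "spin_correlation",
]


@dataclass
class PairedTestResult:
    z: float
    p: float
    r_effect: float
    n: int
    statistic: float


@dataclass
class SpinTestResult:
    observed: float
    null: np.ndarray
    p: float
    n_rotations: int

    @property
    def threshold_95(self) -> float:
        return float(np.percentile(np.abs(self.null), 95))


@dataclass
class PowerResult:
    power: float
    n_iter: int
    alpha: float
    mean_diff: float
    sd_diff: float
    n: int


def wilcoxon_paired(x, y=None, method: str = "approx") -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired data.

    Zero differences are dropped (Wilcoxon's rule).  ``method='approx'``
    uses the tie-corrected normal approximation with continuity
    correction, so a z statistic exists even for small samples;
    ``method='exact'`` takes the p-value from the exact null
    distribution (the z statistic is still the normal-approximation
    one).  The effect size is r = |z| / sqrt(n) with n the retained
    pairs.
    """
    x = np.asarray(x, float)
    if y is not None:
        d = x - np.asarray(y, float)
    else:
        d = x
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise ValueError("need >= 5 nonzero differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= (counts ** 3 - counts).sum() / 48.0
    dev = w_plus - mean
    cc = 0.5 * np.sign(dev)
    z = (dev - cc) / np.sqrt(var) if var > 0 else 0.0
    if method == "approx":
        p = 2.0 * sps.norm.sf(abs(z))
    elif method == "exact":
        p = float(sps.wilcoxon(d, method="exact").pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PairedTestResult(z=float(z), p=float(min(p, 1.0)),
                            r_effect=effect_size_r(z, n), n=n,
                            statistic=float(w_plus))


def effect_size_r(z: float, n: int) -> float:
    """Rosenthal effect size r = |z| / sqrt(n) for a signed-rank z."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float(abs(z) / np.sqrt(n))


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def simes_adjust(pvals) -> float:
    """Simes global p-value: min over i of m * p_(i) / i."""
    pvals = np.sort(np.asarray(pvals, float))
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pvals.size
    return float(np.min(m * pvals / np.arange(1, m + 1)))


def mc_power(mean_diff: float, sd_diff: float, n: int, alpha: float = 0.05,
             n_iter: int = 5000, seed: int = 0,
             method: str = "exact") -> PowerResult:
    """Monte-Carlo power of the two-sided paired Wilcoxon test.

    Simulates ``n_iter`` samples of ``n`` paired differences from
    Normal(mean_diff, sd_diff^2) and reports the rejection fraction at
    ``alpha``.  ``method`` selects the p-value convention of
    :func:`wilcoxon_paired` (default the exact small-sample null, as in
    R's ``wilcox.test`` for tie-free data).
    """
    if sd_diff <= 0:
        raise ValueError("sd_diff must be positive")
    if n < 5:
        raise ValueError("n must be >= 5")
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_iter):
        d = rng.normal(mean_diff, sd_diff, n)
        if np.all(d == 0):
            continue
        if method == "exact":
            p = sps.wilcoxon(d, method="exact").pvalue
        else:
            p = wilcoxon_paired(d, method=method).p
        rej += p < alpha
    return PowerResult(power=rej / n_iter, n_iter=n_iter, alpha=alpha,
                       mean_diff=mean_diff, sd_diff=sd_diff, n=n)


def spin_permutation(centroids: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """One-to-one parcel reassignment after rotating the centroids.

    The assignment minimizes the total distance between original and
    rotated centroids, so the permuted map preserves the value multiset
    exactly.  ``perm[i]`` is the parcel whose value parcel ``i`` receives.
    """
    rotated = centroids @ rotation.T
    cost = cdist(centroids, rotated)
    rows, cols = linear_sum_assignment(cost)
    return cols[np.argsort(rows)]


def spin_correlation(map_a, map_b, centroids, n_rot: int = 1000,
                     seed: int = 0, corr: str = "pearson") -> SpinTestResult:
    """Spatial correlation of two parcel maps with a spin-test null.

    The null rotates the centroids with uniform random 3-D rotations and
    permutes ``map_b`` by nearest-parcel reassignment; the two-sided
    p-value is ``(1 + #{|null| >= |observed|}) / (n_rot + 1)``.
    """
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    centroids = np.asarray(centroids, float)
    if not (a.size == b.size == centroids.shape[0]):
        raise ValueError("maps and geometry must be aligned")
    if a.size < 10:
        raise ValueError("need at least 10 parcels")
    if cdist(centroids, centroids)[~np.eye(a.size, dtype=bool)].min() == 0:
        raise ValueError("degenerate geometry: coincident centroids")
    cfun = sps.pearsonr if corr == "pearson" else sps.spearmanr
    observed = float(cfun(a, b)[0])
    rots = special_ortho_group.rvs(3, size=n_rot,
                                   random_state=np.random.default_rng(seed))
    rots = rots.reshape(-1, 3, 3)
    null = np.empty(n_rot)
    for i in range(n_rot):
        perm = spin_permutation(centroids, rots[i])
        null[i] = cfun(a, b[perm])[0]
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (n_rot + 1.0)
    return SpinTestResult(observed=observed, null=null, p=float(p),
                          n_rotations=n_rot)
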