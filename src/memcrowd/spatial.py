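"""Point-pattern statistics against a complete-spatial-randomness null.

Nearest-neighbour distance distributions, radial cross-counts and the pair
distribution function g(r) for same-type and cross-type maxima patterns,
together with a matched-density "ideal gas" (CSR) reference.  Reference
points closer than a margin to the window boundary are excluded
(minus-sampling), while neighbours may lie anywhere in the window, so
annulus counts stay unbiased.

For a CSR pattern of intensity lambda the nearest-neighbour distance has the
closed-form density p(r) = 2 pi lambda r exp(-pi lambda r^2); it is exposed
both as a formula and as a seeded Monte-Carlo envelope machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .points import PointPattern

DEFAULT_BIN_WIDTH_NM = 25.0


@dataclass
class DistanceHistogram:
    """Binned distance statistics over half-open bins [lo, hi)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_reference_points: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts must have one entry per bin")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def density(self) -> np.ndarray:
        """Probability density over the binned range (integrates to 1)."""
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts)
        return self.counts / total / self.bin_widths


@dataclass
class CsrReference:
    """Monte-Carlo CSR envelopes matched to an observed pattern."""

    mode: str
    density_per_um2: float
    window: tuple[float, float]
    n_replicates: int
    seed: int
    nn_mean: np.ndarray
    nn_lo: np.ndarray
    nn_hi: np.ndarray
    g_mean: np.ndarray
    g_lo: np.ndarray
    g_hi: np.ndarray
    bin_edges: np.ndarray = field(repr=False)


def _included_reference(pattern: PointPattern, margin_nm: float) -> np.ndarray:
    """Boolean mask of reference points at least margin_nm from every edge."""
    if margin_nm < 0:
        raise ValueError("margin_nm must be non-negative")
    w, h = pattern.window
    p = pattern.points
    return (
        (p[:, 0] >= margin_nm)
        & (p[:, 0] <= w - margin_nm)
        & (p[:, 1] >= margin_nm)
        & (p[:, 1] <= h - margin_nm)
    )


def nn_distances(
    reference: PointPattern,
    target: PointPattern | None = None,
    margin_nm: float = 0.0,
) -> np.ndarray:
    """Nearest-neighbour distances (nm) with minus-sampling border correction.

    For each reference point farther than ``margin_nm`` from every window
    edge, the Euclidean distance to the nearest target point.  With
    ``target=None`` (or the same pattern) the same-type statistic is
    computed, excluding the point itself.
    """
    same = target is None or target is reference
    tgt = reference if same else target
    if len(tgt) == 0 or (same and len(reference) < 2):
        raise ValueError("target pattern has no usable points")
    keep = _included_reference(reference, margin_nm)
    if not keep.any():
        warnings.warn("all reference points excluded by the margin", stacklevel=2)
        return np.empty(0)
    tree = cKDTree(tgt.points)
    if same:
        d, _ = tree.query(reference.points[keep], k=2)
        return d[:, 1]
    d, _ = tree.query(reference.points[keep], k=1)
    return np.asarray(d, dtype=float)


def csr_nn_pdf(lambda_per_um2: float, r_nm: float | np.ndarray) -> np.ndarray:
    """Closed-form CSR nearest-neighbour density p(r) = 2 pi lam r exp(-pi lam r^2).

    ``lambda_per_um2`` is the point density per square micrometre; the
    returned density is per nm over distances ``r_nm`` in nm.
    """
    if lambda_per_um2 <= 0:
        raise ValueError("lambda must be positive")
    lam = lambda_per_um2 * 1e-6  # per nm^2
    r = np.asarray(r_nm, dtype=float)
    return 2.0 * np.pi * lam * r * np.exp(-np.pi * lam * r**2)


def csr_nn_cdf(lambda_per_um2: float, r_nm: float | np.ndarray) -> np.ndarray:
    """CSR nearest-neighbour CDF 1 - exp(-pi lam r^2)."""
    if lambda_per_um2 <= 0:
        raise ValueError("lambda must be positive")
    lam = lambda_per_um2 * 1e-6
    r = np.asarray(r_nm, dtype=float)
    return 1.0 - np.exp(-np.pi * lam * r**2)


def csr_nn_mode_nm(lambda_per_um2: float) -> float:
    """Most likely CSR nearest-neighbour distance, 1/sqrt(2 pi lam)."""
    if lambda_per_um2 <= 0:
        raise ValueError("lambda must be positive")
    return 1.0 / np.sqrt(2.0 * np.pi * lambda_per_um2 * 1e-6)


def csr_nn_mean_nm(lambda_per_um2: float) -> float:
    """Mean CSR nearest-neighbour distance, 1/(2 sqrt(lam))."""
    if lambda_per_um2 <= 0:
        raise ValueError("lambda must be positive")
    return 1.0 / (2.0 * np.sqrt(lambda_per_um2 * 1e-6))


def _pair_distances(
    reference: PointPattern,
    target: PointPattern | None,
    max_r: float,
    margin_nm: float,
) -> tuple[np.ndarray, int]:
    """All reference-target distances up to max_r, excluding self-pairs."""
    same = target is None or target is reference
    tgt = reference if same else target
    keep = _included_reference(reference, margin_nm)
    n_ref = int(keep.sum())
    if n_ref == 0:
        warnings.warn("all reference points excluded by the margin", stacklevel=2)
        return np.empty(0), 0
    if len(tgt) == 0:
        return np.empty(0), n_ref
    tree = cKDTree(tgt.points)
    dists = []
    for i in np.flatnonzero(keep):
        p = reference.points[i]
        js = tree.query_ball_point(p, max_r)
        for j in js:
            if same and j == i:
                continue
            dists.append(float(np.hypot(*(tgt.points[j] - p))))
    return np.asarray(dists), n_ref


def radial_cross_counts(
    reference: PointPattern,
    target: PointPattern | None,
    bin_edges: np.ndarray,
    margin_nm: float = 0.0,
) -> DistanceHistogram:
    """Mean number of target points per annulus [lo, hi) around reference points."""
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    d, n_ref = _pair_distances(reference, target, float(bin_edges[-1]), margin_nm)
    counts, _ = np.histogram(d, bins=bin_edges)
    mean_counts = counts / n_ref if n_ref else counts.astype(float)
    return DistanceHistogram(bin_edges, mean_counts, n_ref)


def pair_distribution(
    reference: PointPattern,
    target: PointPattern | None,
    bin_edges: np.ndarray,
    margin_nm: float = 0.0,
) -> DistanceHistogram:
    """Pair distribution function g(r): observed vs ideal-gas annulus counts.

    g(r) = (mean observed count per reference point in [lo, hi)) divided by
    lambda_target pi (hi^2 - lo^2); g = 1 is ideal-gas behaviour, g > 1
    aggregation, g < 1 exclusion.
    """
    same = target is None or target is reference
    tgt = reference if same else target
    lam = tgt.density_per_um2 * 1e-6  # per nm^2
    if lam == 0:
        raise ValueError("target density is zero; g(r) undefined")
    raw = radial_cross_counts(reference, target, bin_edges, margin_nm)
    edges = raw.bin_edges
    expected = lam * np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    if same:
        # the reference point itself is not its own neighbour: expectation
        # uses the density of the remaining n-1 points
        expected = expected * (len(tgt) - 1) / len(tgt) if len(tgt) > 1 else expected
    g = raw.counts / expected
    return DistanceHistogram(edges, g, raw.n_reference_points)


def nn_histogram(
    reference: PointPattern,
    target: PointPattern | None,
    bin_edges: np.ndarray,
    margin_nm: float = 0.0,
) -> DistanceHistogram:
    """Histogram of nearest-neighbour distances over half-open bins."""
    d = nn_distances(reference, target, margin_nm)
    counts, _ = np.histogram(d, bins=np.asarray(bin_edges, dtype=float))
    return DistanceHistogram(np.asarray(bin_edges, dtype=float), counts, len(d))


def csr_reference(
    pattern: PointPattern,
    n_replicates: int = 100,
    seed: int = 0,
    bin_edges: np.ndarray | None = None,
    margin_nm: float | None = None,
) -> CsrReference:
    """Matched-density ideal-gas reference with pointwise 95% envelopes.

    Generates ``n_replicates`` uniform patterns with exactly the observed
    point count in the observed window (binomial process), runs the same
    nearest-neighbour and pair-distribution statistics with the same margin,
    and returns the pointwise mean and 2.5/97.5 percentile envelopes.
    ``margin_nm`` defaults to the largest analyzed distance (max bin edge),
    the standard minus-sampling correction.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if bin_edges is None:
        bin_edges = np.arange(0.0, 500.0 + DEFAULT_BIN_WIDTH_NM, DEFAULT_BIN_WIDTH_NM)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if margin_nm is None:
        margin_nm = float(bin_edges[-1])
    rng = np.random.default_rng(seed)
    w, h = pattern.window
    n = len(pattern)
    nn_rows, g_rows = [], []
    for _ in range(n_replicates):
        pts = rng.uniform([0, 0], [w, h], size=(n, 2))
        rep = PointPattern(pts, pattern.window, channel="csr")
        nn_rows.append(nn_histogram(rep, None, bin_edges, margin_nm).counts)
        g_rows.append(pair_distribution(rep, None, bin_edges, margin_nm).counts)
    nn_arr = np.asarray(nn_rows)
    g_arr = np.asarray(g_rows)
    return CsrReference(
        mode="monte_carlo",
        density_per_um2=pattern.density_per_um2,
        window=pattern.window,
        n_replicates=n_replicates,
        seed=seed,
        nn_mean=nn_arr.mean(axis=0),
        nn_lo=np.percentile(nn_arr, 2.5, axis=0),
        nn_hi=np.percentile(nn_arr, 97.5, axis=0),
        g_mean=g_arr.mean(axis=0),
        g_lo=np.percentile(g_arr, 2.5, axis=0),
        g_hi=np.percentile(g_arr, 97.5, axis=0),
        bin_edges=bin_edges,
    )
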