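"""Angular-frequency spectral density (AFSD) of triangle trajectories.

A trajectory's shape is summarized by how its speed oscillates per full
tracing (2*pi radians of tangent-direction displacement) in the
Frenet-Serret frame.  An approximately elliptical orbit oscillates in speed
and curvature twice per rotation and so carries spectral mass near angular
frequency 2; pentagon-like curvature patterns carry mass near 5.

Pipeline per triangle:

1. tangent angle phi = atan2(vy, vx) from smoothly differentiated positions;
   absolute instantaneous curvature k = |dphi/dt| / speed;
2. theta = cumulative unsigned angular displacement over curved frames
   (stationary and straight segments are excluded; the retained fraction is
   the triangle's curved-movement weight);
3. log speed is resampled uniformly in theta, a second-order polynomial
   trend is removed (detrending also closes the endpoints for the FFT), and
   the one-sided FFT amplitude spectrum is taken over angular frequency
   (cycles per 2*pi radians);
4. the amplitude spectrum is interpolated onto a fixed 1001-point grid on
   [0.02, 10] and normalized to unit trapezoidal area.

Red and blue spectra are combined by a weighted mean with the
curved-movement weights, and the combined density is summarized as areas in
nine fixed angular-frequency bins.  Group differences across the five words
are tested pointwise with one-way F statistics and cluster-level inference
by resampling the maximal cluster statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kinematics import DifferentiatorSpec, smooth_differentiate
from .trajectory_model import AnimationRecording, WordCategory

__all__ = [
    "GRID_MIN",
    "GRID_MAX",
    "N_GRID",
    "default_grid",
    "DEFAULT_BIN_EDGES",
    "SpectralBins",
    "SpectralProfile",
    "ClusterTestResult",
    "DegenerateTrajectoryError",
    "curvature_and_frenet_speed",
    "afsd_spectrum",
    "combine_triangles",
    "bin_areas",
    "spectral_profile",
    "cluster_ftest",
]

GRID_MIN = 0.02
GRID_MAX = 10.0
N_GRID = 1001

#: Nine angular-frequency bins (cycles per 2*pi rad).  Bin 2 (1.61-2.39) is
#: centred on elliptical trajectory components, bin 6 (4.79-5.19) on
#: pentagon-like ones.
DEFAULT_BIN_EDGES: tuple[tuple[float, float], ...] = (
    (0.21, 1.49),
    (1.61, 2.39),
    (2.64, 2.87),
    (3.04, 3.40),
    (3.91, 4.27),
    (4.79, 5.19),
    (6.19, 6.68),
    (7.6, 7.93),
    (8.75, 10.0),
)


def default_grid(n: int = N_GRID) -> np.ndarray:
    """Uniform angular-frequency grid on [0.02, 10]."""
    return np.linspace(GRID_MIN, GRID_MAX, n)


class DegenerateTrajectoryError(ValueError):
    """Raised when a trajectory carries no usable curvature signal."""


@dataclass(frozen=True)
class SpectralBins:
    edges: tuple[tuple[float, float], ...] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for lo, hi in self.edges:
            if not lo < hi:
                raise ValueError(f"bin ({lo}, {hi}) not increasing")
            if lo < prev_hi:
                raise ValueError("bins overlap")
            prev_hi = hi

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class SpectralProfile:
    """Unit-area AFSD of one recording on the standard grid."""

    animation_id: str
    grid: np.ndarray
    density_red: np.ndarray
    density_blue: np.ndarray
    weight_red: float
    weight_blue: float
    combined_density: np.ndarray
    bin_areas: np.ndarray
    degenerate: bool = False


@dataclass(frozen=True)
class ClusterTestResult:
    pointwise_F: np.ndarray
    f_critical: float
    clusters: tuple[dict, ...]  # {start_idx, end_idx, cluster_stat, p_value}
    n_boot: int
    alpha: float

    @property
    def significant_clusters(self) -> tuple[dict, ...]:
        return tuple(c for c in self.clusters if c["p_value"] <= self.alpha)


def curvature_and_frenet_speed(
    xy: np.ndarray,
    spec: DifferentiatorSpec | None = None,
    speed_threshold: float = 0.01,
    angular_rate_threshold: float = 1e-4,
    min_samples: int = 32,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Angular displacement, log speed and curved-movement weight of one path.

    Parameters
    ----------
    xy:
        (n, 2) positions in pixels (one triangle's centroid path).
    speed_threshold:
        frames with speed (px/frame) at or below this are stationary.
    angular_rate_threshold:
        frames with |dphi| (rad/frame) at or below this are straight-line
        movement; both classes are excluded from the theta parametrization.

    Returns ``(theta, log_v, weight)``: cumulative unsigned tangent-angle
    displacement (radians, starting at 0) at the retained frames, the log
    speed at those frames, and the retained fraction of frames.
    """
    spec = spec or DifferentiatorSpec()
    xy = np.asarray(xy, dtype=float)
    vx = smooth_differentiate(xy[:, 0], 1.0, spec)
    vy = smooth_differentiate(xy[:, 1], 1.0, spec)
    v = np.hypot(vx, vy)
    phi = np.unwrap(np.arctan2(vy, vx))
    dphi = smooth_differentiate(phi, 1.0, spec)
    # two filter passes bias up to 2*half_width samples at each end
    trim = 2 * spec.half_width
    v, dphi = v[trim:-trim], dphi[trim:-trim]
    curved = (v > speed_threshold) & (np.abs(dphi) > angular_rate_threshold)
    weight = float(np.mean(curved))
    if int(curved.sum()) < min_samples:
        raise DegenerateTrajectoryError(
            "trajectory has no usable curvature signal "
            f"({int(curved.sum())} curved frames)"
        )
    theta = np.concatenate([[0.0], np.cumsum(np.abs(dphi[curved]))[:-1]])
    log_v = np.log(v[curved])
    return theta, log_v, weight


def afsd_spectrum(
    theta: np.ndarray,
    log_v: np.ndarray,
    grid: np.ndarray | None = None,
    n_resample: int = 4096,
) -> tuple[np.ndarray, bool]:
    """Unit-area amplitude spectral density of log speed over theta.

    Returns ``(density, degenerate)``.  ``degenerate`` is True when the
    detrended signal has (numerically) no oscillatory content, in which case
    the density is the uniform unit-area density on the grid and should be
    excluded from group comparisons.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    theta = np.asarray(theta, dtype=float)
    log_v = np.asarray(log_v, dtype=float)
    span = float(theta[-1] - theta[0])
    if span < 2 * np.pi:
        raise DegenerateTrajectoryError(
            f"angular displacement spans {span:.3f} rad < 2*pi; "
            "at least one full tracing is required"
        )
    theta_u = np.linspace(theta[0], theta[-1], n_resample)
    x = np.interp(theta_u, theta, log_v)
    # second-order polynomial detrend: removes drift and closes endpoints
    coef = np.polynomial.polynomial.polyfit(theta_u - theta_u[0], x, 2)
    resid = x - np.polynomial.polynomial.polyval(theta_u - theta_u[0], coef)
    # below ~1e-4 the residual is numerical-differentiation noise, not
    # speed oscillation (log-speed units are dimensionless)
    if float(np.std(resid)) < 1e-4:
        uniform = np.full(grid.size, 1.0 / (grid[-1] - grid[0]))
        return uniform, True
    amp = np.abs(np.fft.rfft(resid)) * 2.0 / resid.size
    # FFT bin k corresponds to k cycles over the theta span; angular
    # frequency is cycles per 2*pi radians.
    freqs = np.arange(amp.size) * 2 * np.pi / span
    density = np.interp(grid, freqs, amp)
    area = np.trapezoid(density, grid)
    if area <= 0 or not np.isfinite(area):
        uniform = np.full(grid.size, 1.0 / (grid[-1] - grid[0]))
        return uniform, True
    return density / area, False


def combine_triangles(
    density_red: np.ndarray,
    density_blue: np.ndarray,
    weight_red: float,
    weight_blue: float,
) -> np.ndarray:
    """Curved-movement-weighted mean of the two triangles' densities."""
    if weight_red < 0 or weight_blue < 0:
        raise ValueError("weights must be non-negative")
    total = weight_red + weight_blue
    if total == 0:
        raise DegenerateTrajectoryError("both triangle weights are zero")
    d_r = np.asarray(density_red, dtype=float)
    d_b = np.asarray(density_blue, dtype=float)
    if d_r.shape != d_b.shape:
        raise ValueError("densities must share a grid")
    return (weight_red * d_r + weight_blue * d_b) / total


def bin_areas(
    density: np.ndarray,
    grid: np.ndarray | None = None,
    bins: SpectralBins | None = None,
) -> np.ndarray:
    """Trapezoidal area of the density inside each angular-frequency bin.

    Bin edges falling between grid points are handled by linear
    interpolation of the density at the edge.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    bins = bins or SpectralBins()
    density = np.asarray(density, dtype=float)
    areas = np.empty(len(bins))
    for i, (lo, hi) in enumerate(bins.edges):
        lo_c = max(lo, grid[0])
        hi_c = min(hi, grid[-1])
        if hi_c <= lo_c:
            areas[i] = 0.0
            continue
        inner = grid[(grid > lo_c) & (grid < hi_c)]
        xs = np.concatenate([[lo_c], inner, [hi_c]])
        ys = np.interp(xs, grid, density)
        areas[i] = np.trapezoid(ys, xs)
    return areas


def spectral_profile(
    rec: AnimationRecording,
    spec: DifferentiatorSpec | None = None,
    grid: np.ndarray | None = None,
    bins: SpectralBins | None = None,
) -> SpectralProfile:
    """Full AFSD pipeline for one recording (both triangles combined)."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    densities, weights, degenerate = [], [], []
    for xy in (rec.red_xy, rec.blue_xy):
        theta, log_v, w = curvature_and_frenet_speed(xy, spec=spec)
        d, degen = afsd_spectrum(theta, log_v, grid=grid)
        densities.append(d)
        weights.append(0.0 if degen else w)
        degenerate.append(degen)
    if all(degenerate):
        combined = densities[0]
    else:
        combined = combine_triangles(
            densities[0], densities[1], weights[0], weights[1]
        )
    return SpectralProfile(
        animation_id=rec.animation_id,
        grid=grid,
        density_red=densities[0],
        density_blue=densities[1],
        weight_red=weights[0],
        weight_blue=weights[1],
        combined_density=combined,
        bin_areas=bin_areas(combined, grid=grid, bins=bins),
        degenerate=all(degenerate),
    )


def _pointwise_f(data: np.ndarray, group_idx: np.ndarray, k: int) -> np.ndarray:
    """One-way F statistic across groups at every grid point (vectorized)."""
    n = data.shape[0]
    grand = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum(axis=0)
    ss_between = np.zeros_like(grand)
    for g in range(k):
        rows = data[group_idx == g]
        ss_between += rows.shape[0] * (rows.mean(axis=0) - grand) ** 2
    ss_within = ss_total - ss_between
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return np.where(np.isfinite(f), f, 0.0)


def _clusters_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous runs of True, as inclusive (start, end) pairs."""
    runs = []
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    for s, e in idx.reshape(-1, 2):
        runs.append((int(s), int(e - 1)))
    return runs


def _max_cluster_stat(
    f: np.ndarray, f_crit: float, statistic: str
) -> float:
    best = 0.0
    for s, e in _clusters_from_mask(f > f_crit):
        stat = float(f[s : e + 1].sum()) if statistic == "mass" else float(e - s + 1)
        best = max(best, stat)
    return best


def cluster_ftest(
    spectra: np.ndarray,
    labels,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    statistic: str = "mass",
    resampling: str = "permutation",
) -> ClusterTestResult:
    """Cluster-corrected F-test for word differences in spectral density.

    Pointwise one-way F statistics across the word groups are thresholded at
    the pointwise critical value ``F_{1-alpha}(k-1, N-k)``; maximal
    contiguous supra-threshold runs form candidate clusters, whose statistic
    (``mass`` = sum of F over the run, or ``extent`` = run length) is
    referred to the null distribution of the maximal cluster statistic over
    ``n_boot`` label resamples (``permutation`` or ``bootstrap`` with
    replacement).  A cluster is significant when its resampling p-value is
    at most ``alpha``.

    Parameters
    ----------
    spectra:
        (n_animations, n_points) combined densities on a shared grid.
    labels:
        word label per animation (any hashable; typically WordCategory).
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2:
        raise ValueError("spectra must be a 2-D (animations x grid) array")
    if n_boot <= 0:
        raise ValueError("n_boot must be a positive integer")
    if statistic not in ("mass", "extent"):
        raise ValueError(f"unknown cluster statistic {statistic!r}")
    if resampling not in ("permutation", "bootstrap"):
        raise ValueError(f"unknown resampling scheme {resampling!r}")
    labels = [lab.value if isinstance(lab, WordCategory) else lab for lab in labels]
    uniq = sorted(set(labels))
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 groups")
    group_idx = np.array([uniq.index(lab) for lab in labels])
    counts = np.bincount(group_idx, minlength=k)
    if counts.min() < 2:
        raise ValueError("need at least 2 animations per group")
    n = spectra.shape[0]
    f_crit = float(stats.f.ppf(1 - alpha, k - 1, n - k))

    f_obs = _pointwise_f(spectra, group_idx, k)
    observed = _clusters_from_mask(f_obs > f_crit)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_boot)
    for b in range(n_boot):
        if resampling == "permutation":
            idx = rng.permutation(n)
        else:
            idx = rng.integers(0, n, size=n)
        f_b = _pointwise_f(spectra[idx], group_idx, k)
        null_max[b] = _max_cluster_stat(f_b, f_crit, statistic)

    clusters = []
    for s, e in observed:
        stat = (
            float(f_obs[s : e + 1].sum()) if statistic == "mass" else float(e - s + 1)
        )
        p = (1 + int(np.sum(null_max >= stat))) / (1 + n_boot)
        clusters.append(
            {"start_idx": s, "end_idx": e, "cluster_stat": stat, "p_value": p}
        )
    return ClusterTestResult(
        pointwise_F=f_obs,
        f_critical=f_crit,
        clusters=tuple(clusters),
        n_boot=n_boot,
        alpha=alpha,
    )
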