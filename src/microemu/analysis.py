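"""Structural and dynamic observables from MD trajectories.

Structure: the radial distribution function g(r) (minimum-image pair
histogram), the structure factor S(q) either by Fourier transform of g(r) - 1
or directly from box-commensurate wavevectors, and peak metrics (height,
position, S(0)) matching the way scattering analyses summarize S(q).

Dynamics: multiple-time-origin mean-squared displacement on log-spaced lags,
the ballistic/diffusive crossover time from the intersection of the two
log-log asymptotes, diffusion-coefficient fits (normal MSD = 6 D t and
anomalous MSD = 6 D_a t^alpha), and the linear trend of D against the number
of grafted chains.

Lengths are reduced (droplet radii); conversions to Angstrom use the droplet
radius carried in the trajectory metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .md import Trajectory

__all__ = [
    "RDF",
    "StructureFactorCurve",
    "MSDCurve",
    "RegimeFit",
    "DiffusionTrend",
    "compute_rdf",
    "sq_from_rdf",
    "sq_direct",
    "compute_msd",
    "detect_crossover",
    "fit_diffusion",
    "diffusion_trend",
    "peak_metrics",
]


@dataclass
class RDF:
    r: np.ndarray            # bin centers, reduced
    g: np.ndarray
    bin_width: float
    n_frames: int
    rho: float
    low_statistics: bool = False


@dataclass
class StructureFactorCurve:
    q: np.ndarray            # reduced (1/R)
    S: np.ndarray
    S0_estimate: float | None = None
    S_max: float | None = None
    q_max: float | None = None
    d_angstrom: float | None = None


@dataclass
class MSDCurve:
    t: np.ndarray            # lag times, reduced
    msd: np.ndarray
    n_origins: np.ndarray


@dataclass
class RegimeFit:
    D: float
    alpha: float
    window: tuple[float, float]
    residual: float


@dataclass
class DiffusionTrend:
    slope: float
    intercept: float
    slope_stderr: float
    intercept_stderr: float
    points: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# g(r)

@njit(cache=True)
def _pair_hist(frames, L, r_max, n_bins):
    hist = np.zeros(n_bins)
    inv_dr = n_bins / r_max
    for fi in range(frames.shape[0]):
        pos = frames[fi]
        N = pos.shape[0]
        for i in range(N - 1):
            for j in range(i + 1, N):
                dx = pos[i, 0] - pos[j, 0]
                dx -= L * np.rint(dx / L)
                dy = pos[i, 1] - pos[j, 1]
                dy -= L * np.rint(dy / L)
                dz = pos[i, 2] - pos[j, 2]
                dz -= L * np.rint(dz / L)
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                if r < r_max:
                    k = int(r * inv_dr)
                    if k < n_bins:
                        hist[k] += 2.0
    return hist


def rdf_from_frames(frames: np.ndarray, L: float, n_bins: int = 200,
                    min_frames_warn: int = 50) -> RDF:
    """Pair-histogram g(r) from wrapped frames, normalized by ideal-gas shells."""
    frames = np.ascontiguousarray(frames)
    n_frames, N, _ = frames.shape
    r_max = L / 2.0
    hist = _pair_hist(frames, L, r_max, n_bins)
    edges = np.linspace(0.0, r_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho = N / L**3
    ideal = shell * rho * N * n_frames
    g = hist / ideal
    return RDF(r=centers, g=g, bin_width=edges[1] - edges[0], n_frames=n_frames,
               rho=rho, low_statistics=n_frames < min_frames_warn)


def compute_rdf(traj: Trajectory, n_bins: int = 200, frame_stride: int = 1) -> RDF:
    frames = traj.wrapped[::frame_stride]
    return rdf_from_frames(frames, traj.L, n_bins=n_bins)


# ---------------------------------------------------------------------------
# S(q)

def sq_from_rdf(rdf: RDF, rho: float, q_grid: np.ndarray,
                taper_fraction: float = 0.25) -> StructureFactorCurve:
    """S(q) = 1 + rho * int (g-1) sinc(qr) 4 pi r^2 dr with a cosine taper.

    The taper (raised cosine over the outer ``taper_fraction`` of the r range)
    suppresses truncation ripple from the finite histogram range; if the
    transform still turns negative anywhere the taper is widened once, with a
    warning.  ``S0`` is a quadratic extrapolation through the three lowest q
    points.
    """
    r, h = rdf.r, rdf.g - 1.0
    q = np.asarray(q_grid, dtype=float)
    qr = np.outer(q, r)
    kernel = np.where(qr > 1e-12, np.sin(qr) / np.where(qr > 1e-12, qr, 1.0), 1.0)

    def transform(frac):
        window = np.ones_like(r)
        r_t = r[-1] * (1.0 - frac)
        outer = r > r_t
        window[outer] = 0.5 * (1.0 + np.cos(np.pi * (r[outer] - r_t) / (r[-1] - r_t)))
        hw = h * window
        return 1.0 + 4.0 * np.pi * rho * (kernel * (hw * r * r)) @ np.gradient(r)

    S = transform(taper_fraction)
    if np.any(S < 0):
        import warnings

        warnings.warn("truncation ripple (negative S); widening the taper",
                      RuntimeWarning, stacklevel=2)
        S = transform(min(2.0 * taper_fraction, 0.8))
    curve = StructureFactorCurve(q=q, S=S)
    _fill_peak_metrics(curve)
    coef = np.polynomial.polynomial.polyfit(q[:3], S[:3], 2)
    curve.S0_estimate = float(coef[0])
    return curve


def sq_direct(traj: Trajectory, n_max: int = 8, frame_stride: int = 5) -> StructureFactorCurve:
    """Direct estimator S(q) = <|sum_j exp(i q.r_j)|^2>/N on commensurate q.

    Wavevectors are 2 pi/L * (nx, ny, nz) with |n| <= n_max, binned by |q|.
    """
    frames = traj.wrapped[::frame_stride]
    L = traj.L
    base = 2.0 * np.pi / L
    ns = []
    for nx in range(0, n_max + 1):
        for ny in range(-n_max, n_max + 1):
            for nz in range(-n_max, n_max + 1):
                if nx == 0 and (ny < 0 or (ny == 0 and nz <= 0)):
                    continue
                n2 = nx * nx + ny * ny + nz * nz
                if 0 < n2 <= n_max * n_max:
                    ns.append((nx, ny, nz))
    nvec = np.array(ns, dtype=float)
    qvec = base * nvec                            # (M, 3)
    qmag = np.linalg.norm(qvec, axis=1)
    N = frames.shape[1]
    acc = np.zeros(qvec.shape[0])
    for frame in frames:
        phase = frame @ qvec.T                    # (N, M)
        acc += (np.cos(phase).sum(axis=0) ** 2 + np.sin(phase).sum(axis=0) ** 2) / N
    acc /= frames.shape[0]
    # bin by |q|
    order = np.argsort(qmag)
    qs, Ss, counts = [], [], []
    for qi, si in zip(qmag[order], acc[order]):
        if qs and abs(qi - qs[-1]) < 1e-9 * base:
            Ss[-1] += si
            counts[-1] += 1
        else:
            qs.append(qi)
            Ss.append(si)
            counts.append(1)
    q = np.array(qs)
    S = np.array(Ss) / np.array(counts)
    curve = StructureFactorCurve(q=q, S=S)
    _fill_peak_metrics(curve)
    if q.size >= 3:
        coef = np.polynomial.polynomial.polyfit(q[:3], S[:3], 2)
        curve.S0_estimate = float(coef[0])
    return curve


def _parabolic_peak(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Vertex of the parabola through the 3 points around the discrete max."""
    k = int(np.argmax(y[1:-1])) + 1
    x0, x1, x2 = x[k - 1], x[k], x[k + 1]
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = (y0 - 2 * y1 + y2)
    if denom == 0:
        return float(x1), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    xp = x1 + delta * (x1 - x0)
    yp = y1 - 0.25 * (y0 - y2) * delta
    return float(xp), float(yp)


def _fill_peak_metrics(curve: StructureFactorCurve, R_angstrom: float = 62.0) -> None:
    if curve.S.size < 3:
        return
    qp, sp = _parabolic_peak(curve.q, curve.S)
    curve.q_max = qp
    curve.S_max = sp
    curve.d_angstrom = 2.0 * np.pi / qp * R_angstrom


def peak_metrics(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(position, height) of the main interior peak by parabolic interpolation."""
    interior = y[1:-1]
    if interior.size == 0 or np.argmax(y) in (0, y.size - 1):
        raise ValueError("curve has no interior maximum")
    return _parabolic_peak(x, y)


# ---------------------------------------------------------------------------
# dynamics

def compute_msd(traj: Trajectory, n_lags: int = 60, origin_stride: int = 5) -> MSDCurve:
    """Multiple-time-origin MSD on log-spaced lags from unwrapped coordinates."""
    pos = traj.unwrapped
    n_frames = pos.shape[0]
    if n_frames < 4:
        raise ValueError("too few frames for an MSD")
    dt_frame = traj.times[1] - traj.times[0]
    lags = np.unique(np.round(np.logspace(0, np.log10(n_frames - 1), n_lags)).astype(int))
    msd = np.empty(lags.size)
    n_origins = np.empty(lags.size, dtype=int)
    for i, lag in enumerate(lags):
        a = pos[lag::origin_stride]
        b = pos[: n_frames - lag : origin_stride]
        m = min(a.shape[0], b.shape[0])
        disp = a[:m] - b[:m]
        msd[i] = np.mean(np.sum(disp * disp, axis=-1))
        n_origins[i] = m
    return MSDCurve(t=lags * dt_frame, msd=msd, n_origins=n_origins)


def fit_diffusion(msd: MSDCurve, window: tuple[float, float],
                  mode: str = "normal") -> RegimeFit:
    """Fit MSD = 6 D t (normal) or log MSD = log 6 D_a + alpha log t (anomalous)."""
    lo, hi = window
    sel = (msd.t >= lo) & (msd.t <= hi) & (msd.msd > 0)
    if sel.sum() < 5:
        raise ValueError("fit window contains fewer than 5 points")
    t, y = msd.t[sel], msd.msd[sel]
    if mode == "normal":
        D = float(np.sum(t * y) / np.sum(t * t) / 6.0)
        resid = float(np.sqrt(np.mean((y - 6 * D * t) ** 2)))
        return RegimeFit(D=D, alpha=1.0, window=(lo, hi), residual=resid)
    if mode == "anomalous":
        lt, ly = np.log(t), np.log(y)
        alpha, b = np.polyfit(lt, ly, 1)
        D = float(np.exp(b) / 6.0)
        resid = float(np.sqrt(np.mean((ly - (alpha * lt + b)) ** 2)))
        return RegimeFit(D=D, alpha=float(alpha), window=(lo, hi), residual=resid)
    raise ValueError(f"unknown mode {mode!r}")


def ballistic_intercept(msd: MSDCurve, window: tuple[float, float] = (0.0, 0.1)) -> float:
    """Amplitude A of the slope-2 log-log line MSD = A t^2 on the early window.

    For an equilibrated system A -> 3 T*/m (equipartition).
    """
    sel = (msd.t > window[0]) & (msd.t <= window[1]) & (msd.msd > 0)
    if sel.sum() < 2:
        raise ValueError("too few early-time points for the ballistic fit")
    return float(np.exp(np.mean(np.log(msd.msd[sel]) - 2.0 * np.log(msd.t[sel]))))


def detect_crossover(msd: MSDCurve, late_window: tuple[float, float],
                     mode: str = "normal") -> float:
    """Crossover time t1 between the ballistic and late-time asymptotes.

    The early-time line has slope fixed at 2 (amplitude from
    :func:`ballistic_intercept`); the late-time line has slope 1 (``normal``)
    or free alpha (``anomalous``, dense plateau).  t1 solves
    A t^2 = 6 D t^alpha.
    """
    span = msd.t[-1] / msd.t[0]
    if span < 1e3:
        raise ValueError("MSD must span at least 3 decades in lag time")
    A = ballistic_intercept(msd)
    late = fit_diffusion(msd, late_window, mode=mode)
    t1 = (6.0 * late.D / A) ** (1.0 / (2.0 - late.alpha))
    if not np.isfinite(t1) or t1 <= 0:
        raise ValueError("ballistic and late-time regimes indistinguishable")
    return float(t1)


def plateau_window(msd: MSDCurve, t_min: float = 0.15,
                   span: float = 10 ** 0.5, n_candidates: int = 16) -> tuple[float, float]:
    """Most-linear log-log window between ballistic and diffusive regimes.

    Scans half-decade candidate windows between ``t_min`` and a tenth of the
    longest lag and returns the one with the smallest residual of a free
    power-law fit with exponent < 1 (the caging plateau).
    """
    t_hi_max = msd.t[-1] / 10.0
    best, best_resid = None, np.inf
    for lo in np.geomspace(t_min, max(t_hi_max / span, t_min * 1.5), n_candidates):
        window = (lo, lo * span)
        try:
            fit = fit_diffusion(msd, window, mode="anomalous")
        except ValueError:
            continue
        if fit.alpha < 1.0 and fit.residual < best_resid:
            best, best_resid = window, fit.residual
    if best is None:
        raise ValueError("no sub-diffusive plateau window found")
    return best


def diffusion_trend(points: list[tuple[float, float]]) -> DiffusionTrend:
    """Ordinary least-squares line D(N_p) = slope * N_p + intercept."""
    if len(points) < 3:
        raise ValueError("need at least 3 (N_p, D) points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("rank-deficient fit: all N_p values identical")
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    resid = y - (slope * x + intercept)
    if n > 2:
        s2 = np.sum(resid**2) / (n - 2)
        se_slope = float(np.sqrt(s2 / sxx))
        se_int = float(np.sqrt(s2 * (1.0 / n + xm**2 / sxx)))
    else:
        se_slope = se_int = np.nan
    return DiffusionTrend(slope=slope, intercept=intercept,
                          slope_stderr=se_slope, intercept_stderr=se_int,
                          points=list(points))
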