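"""Small-angle neutron scattering: model spectra, synthetic data, and fits.

The droplets scatter as polydisperse homogeneous spheres on an absolute
intensity scale:

    I(q) = Phi * v * (Delta rho)^2 * P(q) * S(q)     [cm^-1]

with ``Phi`` the droplet volume fraction, ``v`` the dry aggregate volume in
cm^3, ``Delta rho`` the scattering-length-density contrast in cm^-2, ``P``
the orientation/size-averaged form factor normalized to P(0) = 1, and ``S``
the inter-droplet structure factor (unity for a dilute, uncorrelated
suspension).

Polydispersity is a Gaussian distribution of radii (mean ``R_bar``, standard
deviation ``dR``, truncated at +-4 dR and R > 0) averaged with v(R)^2
weighting — the intensity-weighted convention — and renormalized so the
q -> 0 limit stays exactly 1.  Synthetic spectra carry independent
multiplicative lognormal noise per q point at the instrument's absolute-scale
accuracy (10% by default).

Fitting recovers (R_bar, dR, scale) by weighted least squares in the Porod
representation q^4 I/Phi, restricted to the high-q band where S(q) ~ 1;
dividing a measured spectrum by the fitted form factor then yields the
experimental structure factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import least_squares

__all__ = [
    "SANSModelParams",
    "SANSSpectrum",
    "FormFactorFit",
    "sphere_form_factor",
    "polydisperse_form_factor",
    "model_intensity",
    "porod_curve",
    "generate_spectrum",
    "fit_form_factor",
    "extract_structure_factor",
]

_A3_TO_CM3 = 1e-24


@dataclass(frozen=True)
class SANSModelParams:
    phi: float = 0.0698
    R_bar: float = 62.0          # Angstrom
    dR: float = 6.2              # Angstrom
    delta_rho: float = 6.83e10   # cm^-2
    q_min: float = 0.004         # 1/Angstrom
    q_max: float = 0.16
    n_q: int = 120
    noise_frac: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.phi < 1:
            raise ValueError("phi must lie in (0, 1)")
        if not self.R_bar > 3 * self.dR > 0:
            raise ValueError("require R_bar > 3 dR > 0")
        if not 0 < self.q_min < self.q_max:
            raise ValueError("require 0 < q_min < q_max")

    @property
    def v_cm3(self) -> float:
        """Dry aggregate volume (4/3) pi R_bar^3, in cm^3."""
        return 4.0 / 3.0 * np.pi * self.R_bar**3 * _A3_TO_CM3

    def q_grid(self) -> np.ndarray:
        return np.geomspace(self.q_min, self.q_max, self.n_q)


@dataclass
class SANSSpectrum:
    q: np.ndarray          # 1/Angstrom
    I: np.ndarray          # cm^-1
    sigma_I: np.ndarray    # cm^-1
    params: SANSModelParams | None = None
    label: str = "synthetic"

    def write_csv(self, path) -> None:
        header = "q_invA,I_invcm,sigma_invcm"
        if self.params is not None:
            meta = ", ".join(f"{k}={v}" for k, v in vars(self.params).items())
            header = f"# {meta}\n" + header
        np.savetxt(path, np.column_stack([self.q, self.I, self.sigma_I]),
                   delimiter=",", header=header, comments="")


@dataclass
class FormFactorFit:
    R_bar_hat: float
    dR_hat: float
    scale_hat: float
    residual_norm: float
    covariance: np.ndarray
    q_fit_min: float


def sphere_form_factor(q, R):
    """Normalized sphere form factor [3 (sin x - x cos x)/x^3]^2, x = qR.

    ``R`` may be a scalar or an array broadcastable against ``q``.
    """
    if np.any(np.asarray(R) <= 0):
        raise ValueError("R must be positive")
    scalar = np.isscalar(q)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    x = q * R
    amp = np.ones_like(x)
    nz = np.abs(x) > 1e-4
    xs = x[nz]
    amp[nz] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    # series for small x keeps the q -> 0 limit analytic
    small = ~nz
    amp[small] = 1.0 - x[small] ** 2 / 10.0
    out = amp**2
    return float(out[0]) if scalar else out


def _gauss_nodes(R_bar: float, dR: float, n_nodes: int):
    lo = max(R_bar - 4.0 * dR, 1e-6)
    hi = R_bar + 4.0 * dR
    if lo <= 0:
        raise ValueError("polydispersity too large: truncation reaches R <= 0")
    x, w = leggauss(n_nodes)
    R = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    w = w * 0.5 * (hi - lo)
    gauss = np.exp(-0.5 * ((R - R_bar) / dR) ** 2)
    return R, w * gauss


def polydisperse_form_factor(q, R_bar: float, dR: float, n_nodes: int = 64):
    """Gaussian-polydisperse, v(R)^2-weighted sphere form factor, P(0) = 1."""
    if dR <= 0:
        return sphere_form_factor(q, R_bar)
    if R_bar <= 3 * dR:
        raise ValueError("require R_bar > 3 dR")
    scalar = np.isscalar(q)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    R, w = _gauss_nodes(R_bar, dR, n_nodes)
    wv2 = w * R**6                       # v(R)^2 ~ R^6
    P = sphere_form_factor(q[:, None], R[None, :])
    out = (P * wv2).sum(axis=1) / wv2.sum()
    return float(out[0]) if scalar else out


def model_intensity(q, p: SANSModelParams, S=None) -> SANSSpectrum:
    """Absolute-scale intensity Phi v (d rho)^2 P(q) S(q), cm^-1.

    ``S`` may be None (S = 1), a callable S(q) with q in 1/Angstrom, or a
    (q, S) tuple to be interpolated.
    """
    q = np.asarray(q, dtype=float)
    P = polydisperse_form_factor(q, p.R_bar, p.dR)
    if S is None:
        Sq = np.ones_like(q)
    elif callable(S):
        Sq = np.asarray(S(q), dtype=float)
    else:
        qs, Ss = S
        Sq = np.interp(q, qs, Ss)
    I = p.phi * p.v_cm3 * p.delta_rho**2 * P * Sq
    return SANSSpectrum(q=q, I=I, sigma_I=np.zeros_like(I), params=p, label="model")


def porod_curve(spec: SANSSpectrum, phi: float) -> tuple[np.ndarray, np.ndarray]:
    """Porod representation (q, q^4 I(q)/Phi); pointwise, no smoothing."""
    return spec.q, spec.q**4 * spec.I / phi


def generate_spectrum(p: SANSModelParams, S=None) -> SANSSpectrum:
    """Synthetic measured spectrum: model curve x lognormal noise at noise_frac.

    The lognormal is parameterized to have unit mean, so noisy replicates
    average back to the model curve; sigma_I = noise_frac * I(model).
    """
    q = p.q_grid()
    model = model_intensity(q, p, S=S)
    rng = np.random.default_rng(p.seed)
    if p.noise_frac > 0:
        s = np.sqrt(np.log1p(p.noise_frac**2))
        noise = rng.lognormal(mean=-0.5 * s**2, sigma=s, size=q.size)
    else:
        noise = np.ones_like(q)
    I = model.I * noise
    return SANSSpectrum(q=q, I=I, sigma_I=p.noise_frac * model.I, params=p,
                        label="synthetic")


def fit_form_factor(spec: SANSSpectrum, phi: float,
                    q_fit_min: float = 0.04,
                    x0: tuple[float, float] = (55.0, 5.0)) -> FormFactorFit:
    """Weighted least squares of scale * P(q; R_bar, dR) in the Porod plane.

    Only q >= ``q_fit_min`` enters (the structure-factor peak lives below it
    at both studied volume fractions); the spectrum must cover the first
    form-factor oscillation (q up to at least 6/R_bar of the initial guess).
    """
    q_all = spec.q
    if q_all.max() < 6.0 / x0[0]:
        raise ValueError(
            "spectrum does not cover the first form-factor oscillation; "
            f"need q up to {6.0 / x0[0]:.3f} 1/A, have {q_all.max():.3f}"
        )
    sel = q_all >= q_fit_min
    if sel.sum() < 10:
        raise ValueError("too few points above q_fit_min for a stable fit")
    q = q_all[sel]
    y = q**4 * spec.I[sel] / phi
    sig = np.where(spec.sigma_I[sel] > 0, q**4 * spec.sigma_I[sel] / phi, 1.0)
    # scale0 from the low-q level of I/Phi against P ~ 1
    scale0 = float(np.median(spec.I[sel] / phi / polydisperse_form_factor(q, *x0)))

    def resid(theta):
        lg_scale, R_bar, dR = theta
        P = polydisperse_form_factor(q, R_bar, dR)
        return (q**4 * np.exp(lg_scale) * P - y) / sig

    res = least_squares(resid, x0=[np.log(scale0), x0[0], x0[1]],
                        bounds=([-np.inf, 10.0, 0.1], [np.inf, 200.0, 40.0]))
    if not res.success:
        raise RuntimeError(f"form-factor fit failed: {res.message}")
    J = res.jac
    dof = max(res.fun.size - 3, 1)
    cov = np.linalg.pinv(J.T @ J) * 2 * res.cost / dof
    return FormFactorFit(
        R_bar_hat=float(res.x[1]),
        dR_hat=float(res.x[2]),
        scale_hat=float(np.exp(res.x[0])),
        residual_norm=float(np.sqrt(2 * res.cost)),
        covariance=cov,
        q_fit_min=q_fit_min,
    )


def extract_structure_factor(spec: SANSSpectrum, fit: FormFactorFit,
                             p: SANSModelParams,
                             p_floor: float = 5e-3):
    """S(q) = I(q) / (Phi v (d rho)^2 P(q)) with masked form-factor minima.

    Returns (q, S, sigma_S, mask) where ``mask`` flags points kept (P above
    ``p_floor``); masked points are reported but not extrapolated.
    """
    P = polydisperse_form_factor(spec.q, fit.R_bar_hat, fit.dR_hat)
    denom = p.phi * p.v_cm3 * p.delta_rho**2 * P
    mask = P > p_floor
    S = np.where(mask, spec.I / denom, np.nan)
    sigma_S = np.where(mask, spec.sigma_I / denom, np.nan)
    return spec.q, S, sigma_S, mask
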