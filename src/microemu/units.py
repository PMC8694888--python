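"""Reduced-unit conventions shared by the MD, HNC and analysis layers.

Lengths are measured in droplet radii R, energies in k_BT, masses in the
droplet mass m = 1.  The derived time unit is tau = R*sqrt(m/k_BT), so
velocities come out in R/tau, diffusion coefficients in R^2/tau, pressures in
k_BT/R^3 and isothermal compressibilities in R^3/k_BT.
"""

from __future__ import annotations

import numpy as np

#: contact diameter in reduced length units (sigma = 2R)
SIGMA_REDUCED = 2.0


def number_density(phi: float, R_reduced: float = 1.0) -> float:
    """Droplet number density from the hard-core volume fraction.

    rho = 3 phi / (4 pi R^3); with R = 1 (reduced) this is the density in
    droplets per R^3.
    """
    if not 0 < phi < 0.74:
        raise ValueError("volume fraction must lie in (0, 0.74)")
    return 3.0 * phi / (4.0 * np.pi * R_reduced**3)


def box_length(N: int, phi: float) -> float:
    """Cubic box edge (in units of R) holding N droplets at volume fraction phi."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return (4.0 * np.pi * N / (3.0 * phi)) ** (1.0 / 3.0)


def q_reduced_to_inverse_angstrom(q_reduced, R_angstrom: float):
    """Convert a wavevector from 1/R units to 1/Angstrom."""
    return np.asarray(q_reduced) / R_angstrom


def r_reduced_to_angstrom(r_reduced, R_angstrom: float):
    return np.asarray(r_reduced) * R_angstrom
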