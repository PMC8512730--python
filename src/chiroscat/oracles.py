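"""Independent reference computations used to validate the coupled-dipole
engine: the Lorenz--Mie series for a homogeneous sphere, a closed-form
two-dipole solution, and Rayleigh/Born limits.

These oracles share no code with the engine's scattering path: the Mie
series is evaluated from Riccati--Bessel recurrences, and the two-dipole
solution from an explicit 6x6 block inversion of the coupling equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import DipoleModel, NucleosomePose, NucleosomeShape, voxelize
from . import dda

__all__ = ["MieResult", "mie_sphere", "two_dipole_closed_form", "compare_mie_dda", "MieDDAReport"]


@dataclass
class MieResult:
    """Mie efficiencies and angular amplitude functions for one sphere."""

    x: float
    m: complex
    Q_ext: float
    Q_sca: float
    theta_deg: np.ndarray
    S1: np.ndarray
    S2: np.ndarray

    @property
    def Q_abs(self) -> float:
        return self.Q_ext - self.Q_sca

    @property
    def S11(self) -> np.ndarray:
        """Unpolarized phase function (unnormalized): (|S1|^2 + |S2|^2)/2."""
        return 0.5 * (np.abs(self.S1) ** 2 + np.abs(self.S2) ** 2)


def mie_sphere(m: complex, x: float, theta_deg: np.ndarray | None = None) -> MieResult:
    """Lorenz--Mie series for a homogeneous sphere.

    ``x = k a`` is the size parameter at the medium wavenumber and ``m`` the
    refractive index relative to the medium.  The series is truncated at
    ``ceil(x + 4 x^(1/3) + 2)`` terms.  Amplitude conventions match
    Bohren--Huffman with an exp(-i omega t) time dependence, so S11 here is
    directly comparable to the engine's m11.
    """
    if not (np.isfinite(x) and x > 0):
        raise ValueError(f"size parameter must be positive, got {x}")
    m = complex(m)
    if theta_deg is None:
        theta_deg = np.arange(0.0, 180.0 + 0.5, 1.0)
    theta_deg = np.asarray(theta_deg, dtype=float)
    nmax = int(math.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))

    # Logarithmic derivative D_n(mx) by downward recurrence.
    mx = m * x
    nstart = nmax + max(15, int(round(abs(mx))) + 16)
    D = np.zeros(nstart + 1, dtype=complex)
    for n in range(nstart, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)
    D = D[1 : nmax + 1]

    # Riccati-Bessel psi, chi by upward recurrence.
    n_arr = np.arange(1, nmax + 1)
    psi = np.zeros(nmax + 1)
    chi = np.zeros(nmax + 1)
    psi_m1, chi_m1 = math.cos(x), -math.sin(x)  # psi_{-1}, chi_{-1}
    psi[0], chi[0] = math.sin(x), math.cos(x)  # psi_0, chi_0
    for n in range(1, nmax + 1):
        psi[n] = (2 * n - 1) / x * psi[n - 1] - psi_m1
        chi[n] = (2 * n - 1) / x * chi[n - 1] - chi_m1
        psi_m1, chi_m1 = psi[n - 1], chi[n - 1]
    xi = psi - 1j * chi  # outgoing Riccati-Bessel x h1(x), chi = -x y(x)

    an = np.zeros(nmax, dtype=complex)
    bn = np.zeros(nmax, dtype=complex)
    for i, n in enumerate(n_arr):
        da = D[i] / m + n / x
        db = D[i] * m + n / x
        an[i] = (da * psi[n] - psi[n - 1]) / (da * xi[n] - xi[n - 1])
        bn[i] = (db * psi[n] - psi[n - 1]) / (db * xi[n] - xi[n - 1])
    if not (np.all(np.isfinite(an)) and np.all(np.isfinite(bn))):
        raise ValueError("Mie series diverged (non-finite expansion coefficients)")

    fac = 2.0 * n_arr + 1.0
    q_ext = 2.0 / x**2 * float(np.sum(fac * (an + bn).real))
    q_sca = 2.0 / x**2 * float(np.sum(fac * (np.abs(an) ** 2 + np.abs(bn) ** 2)))

    # Angular functions pi_n, tau_n by upward recurrence.
    mu = np.cos(np.deg2rad(theta_deg))
    s1 = np.zeros(len(mu), dtype=complex)
    s2 = np.zeros(len(mu), dtype=complex)
    pi_nm1 = np.zeros(len(mu))
    pi_n = np.ones(len(mu))
    for i, n in enumerate(n_arr):
        tau_n = n * mu * pi_n - (n + 1) * pi_nm1
        f = fac[i] / (n * (n + 1))
        s1 += f * (an[i] * pi_n + bn[i] * tau_n)
        s2 += f * (an[i] * tau_n + bn[i] * pi_n)
        pi_np1 = ((2 * n + 1) * mu * pi_n - (n + 1) * pi_nm1) / n
        pi_nm1, pi_n = pi_n, pi_np1
    return MieResult(x=x, m=m, Q_ext=q_ext, Q_sca=q_sca, theta_deg=theta_deg, S1=s1, S2=s2)


def two_dipole_closed_form(
    separation: np.ndarray, alpha: complex, wave: "dda.PlaneWave"
) -> tuple[np.ndarray, np.ndarray]:
    """Exact two-dipole solution by explicit 6x6 block inversion.

    Dipole 0 sits at the origin, dipole 1 at ``separation``; both carry the
    scalar polarizability ``alpha``.  Returns (P, E_inc) as (2, 3) arrays.
    """
    sep = np.asarray(separation, dtype=float).reshape(3)
    if np.linalg.norm(sep) == 0:
        raise ValueError("separation must be non-zero")
    k = wave.k
    g = dda.green_tensor(sep, k)  # G(r0 - r1) = G(r1 - r0): G is even in r
    positions = np.stack([np.zeros(3), sep])
    e_inc = wave.field_at(positions)
    A = np.zeros((6, 6), dtype=complex)
    A[:3, :3] = np.eye(3)
    A[3:, 3:] = np.eye(3)
    A[:3, 3:] = -alpha * g
    A[3:, :3] = -alpha * g
    b = alpha * e_inc.ravel()
    if abs(np.linalg.det(A)) < 1e-300:
        raise ValueError("singular two-dipole coupling matrix")
    p = np.linalg.solve(A, b).reshape(2, 3)
    return p, e_inc


@dataclass
class MieDDAReport:
    """Discrepancies between a voxelized-sphere DDA run and the Mie series."""

    dipoles_per_diameter: int
    n_dipoles: int
    q_ext_dda: float
    q_ext_mie: float
    s11_max_rel_err: float

    @property
    def q_ext_rel_err(self) -> float:
        return abs(self.q_ext_dda - self.q_ext_mie) / abs(self.q_ext_mie)


def compare_mie_dda(
    m: complex,
    x: float,
    dipoles_per_diameter: int,
    lambda_vac: float = 300.0,
    host_index: float = 1.33,
    theta_deg: np.ndarray | None = None,
    tol: float = 1e-6,
) -> MieDDAReport:
    """Run the engine on a voxelized sphere and compare with the Mie oracle.

    The sphere radius follows from the size parameter at the medium
    wavenumber, ``a = x / k``.  The pointwise S11 error is relative to the
    local Mie value.
    """
    if dipoles_per_diameter < 8:
        raise ValueError("need at least 8 dipoles per diameter")
    if theta_deg is None:
        theta_deg = np.arange(0.0, 180.0 + 0.5, 2.0)
    k = 2.0 * math.pi * host_index / lambda_vac
    radius = x / k
    pose = NucleosomePose(np.zeros(3), np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
    shape = NucleosomeShape(kind="sphere", diameter=2.0 * radius)
    model = voxelize([pose], shape, dipoles_per_diameter, rel_index=m, host_index=host_index)
    run = dda.scattering_run(model, lambda_vac=lambda_vac, theta_deg=theta_deg, tol=tol)
    mie = mie_sphere(m, x, theta_deg)
    s11_dda = run.mueller.m11
    err = float(np.max(np.abs(s11_dda - mie.S11) / mie.S11))
    return MieDDAReport(
        dipoles_per_diameter=dipoles_per_diameter,
        n_dipoles=model.n_dipoles,
        q_ext_dda=run.cross.Q_ext,
        q_ext_mie=mie.Q_ext,
        s11_max_rel_err=err,
    )
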