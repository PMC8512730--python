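"""Polarimetric observables: Stokes vectors, angle-resolved Mueller matrices,
circular intensity differential scattering (CIDS), and orientation averaging.

CIDS at scattering angle theta is the normalized difference of scattered
intensities under left- and right-circularly polarized incidence,

    CIDS(theta) = (I_L - I_R) / (I_L + I_R),

which for a Mueller matrix M reduces to ``m14 / m11`` under this package's
polarization convention (left circular = Jones (1, +i)/sqrt(2), Stokes
V = +1).  The total scattered intensity for unpolarized incidence is m11.

Orientation averaging models a particle tumbling in liquid: Mueller matrices
are averaged over particle orientations (z-y-z Euler angles) with a product
quadrature -- uniform in alpha and gamma, Gauss--Legendre in cos(beta) --
and the averaged CIDS is the ratio of averaged elements, i.e. the CIDS of
the ensemble intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "StokesVector",
    "MuellerAngular",
    "CIDSProfile",
    "OrientationQuadrature",
    "CIDS_SIGN",
    "cids_from_mueller",
    "cids_direct",
    "total_intensity",
    "make_quadrature",
    "orientation_average",
]

#: Sign relating CIDS to m14/m11 under the fixed circular-polarization
#: convention (left = Jones (1, +i)/sqrt(2) on the incident basis, V = +1).
#: Verified against the two-illumination route in the test suite.
CIDS_SIGN = +1.0


@dataclass(frozen=True)
class StokesVector:
    """Real (I, Q, U, V) polarization state; V encodes circular polarization."""

    I: float
    Q: float = 0.0
    U: float = 0.0
    V: float = 0.0

    def __post_init__(self) -> None:
        if self.I < 0:
            raise ValueError("Stokes I must be non-negative")
        if self.Q**2 + self.U**2 + self.V**2 > self.I**2 * (1.0 + 1e-9):
            raise ValueError("unphysical Stokes vector: I^2 < Q^2 + U^2 + V^2")

    def as_array(self) -> np.ndarray:
        return np.array([self.I, self.Q, self.U, self.V])


@dataclass
class MuellerAngular:
    """4x4 real Mueller matrices on a strictly increasing scattering-angle grid."""

    theta_deg: np.ndarray
    matrices: np.ndarray  # (T, 4, 4)

    def __post_init__(self) -> None:
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.shape != (len(self.theta_deg), 4, 4):
            raise ValueError("matrices must have shape (len(theta), 4, 4)")
        if np.any(np.diff(self.theta_deg) <= 0):
            raise ValueError("theta grid must be strictly increasing")

    def element(self, i: int, j: int) -> np.ndarray:
        """Element m_ij (1-based, m11 ... m44) versus angle."""
        return self.matrices[:, i - 1, j - 1]

    @property
    def m11(self) -> np.ndarray:
        return self.matrices[:, 0, 0]

    @property
    def m14(self) -> np.ndarray:
        return self.matrices[:, 0, 3]

    def apply(self, stokes_in: StokesVector) -> np.ndarray:
        """Scattered Stokes vectors (T, 4) for an incident Stokes state."""
        return self.matrices @ stokes_in.as_array()


@dataclass
class CIDSProfile:
    """Differential circular scattering versus angle, optionally with the
    underlying left/right intensities."""

    theta_deg: np.ndarray
    cids: np.ndarray
    IL: Optional[np.ndarray] = None
    IR: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        self.cids = np.asarray(self.cids, dtype=float)
        if self.cids.shape != self.theta_deg.shape:
            raise ValueError("cids must be defined on the theta grid")
        if not np.all(np.isfinite(self.cids)):
            raise ValueError("CIDS must be finite")
        if np.any(np.abs(self.cids) > 1.0 + 1e-9):
            raise ValueError("CIDS is a normalized ratio and must lie in [-1, 1]")

    @property
    def max_abs(self) -> float:
        return float(np.abs(self.cids).max())


def cids_from_mueller(mueller: MuellerAngular) -> CIDSProfile:
    """CIDS(theta) = m14/m11 (up to the fixed convention sign).

    Requires m11 > 0 on the whole grid; the equivalent two-illumination
    intensities IL = m11 + m14 and IR = m11 - m14 are attached.
    """
    m11 = mueller.m11
    if np.any(m11 <= 0.0):
        raise ValueError("m11 must be strictly positive to normalize CIDS")
    m14 = mueller.m14
    cids = CIDS_SIGN * m14 / m11
    return CIDSProfile(mueller.theta_deg, cids, IL=m11 + m14, IR=m11 - m14)


def cids_direct(IL: np.ndarray, IR: np.ndarray, theta_deg: Optional[np.ndarray] = None) -> CIDSProfile:
    """CIDS from explicitly computed left/right scattered intensities."""
    IL = np.asarray(IL, dtype=float)
    IR = np.asarray(IR, dtype=float)
    if IL.shape != IR.shape:
        raise ValueError("IL and IR must share a grid")
    if np.any(IL < 0) or np.any(IR < 0):
        raise ValueError("intensities must be non-negative")
    tot = IL + IR
    if np.any(tot == 0.0):
        raise ValueError("IL + IR vanishes somewhere: CIDS is undefined there")
    if theta_deg is None:
        theta_deg = np.arange(len(IL), dtype=float)
    return CIDSProfile(theta_deg, (IL - IR) / tot, IL=IL, IR=IR)


def total_intensity(mueller: MuellerAngular) -> np.ndarray:
    """Total scattered intensity for unpolarized incidence: m11(theta)."""
    return mueller.m11.copy()


@dataclass
class OrientationQuadrature:
    """Euler-angle nodes (alpha, beta, gamma) and normalized positive weights."""

    nodes: np.ndarray  # (Q, 3)
    weights: np.ndarray  # (Q,)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if len(self.nodes) != len(self.weights):
            raise ValueError("one weight per node required")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


def make_quadrature(n_alpha: int, n_beta: int, n_gamma: int) -> OrientationQuadrature:
    """Product quadrature over SO(3) in z-y-z Euler angles.

    Uniform grids in alpha, gamma over [0, 2 pi); Gauss--Legendre nodes in
    cos(beta) over [-1, 1].  Even ``n_alpha`` makes the node set closed under
    the mirror involution (alpha, beta, gamma) -> (-alpha - pi, pi - beta,
    gamma), which lets the averaged CIDS of an achiral particle cancel
    exactly rather than merely to quadrature error.
    """
    if min(n_alpha, n_beta, n_gamma) < 1:
        raise ValueError("quadrature counts must be >= 1")
    alphas = 2.0 * math.pi * np.arange(n_alpha) / n_alpha
    x, w = np.polynomial.legendre.leggauss(n_beta)
    betas = np.arccos(x)
    gammas = 2.0 * math.pi * np.arange(n_gamma) / n_gamma
    nodes = []
    weights = []
    for a in alphas:
        for b, wb in zip(betas, w):
            for g in gammas:
                nodes.append((a, b, g))
                weights.append(wb / 2.0 / n_alpha / n_gamma)
    return OrientationQuadrature(np.array(nodes), np.array(weights))


def orientation_average(
    target,
    lambda_vac: float = 300.0,
    quadrature: Optional[OrientationQuadrature] = None,
    theta_deg: Optional[np.ndarray] = None,
    tol: float = 1e-5,
    dipoles_per_longest: int = 24,
    rel_index: complex = 1.68 / 1.33,
    host_index: float = 1.33,
    born: bool = False,
):
    """Orientation-averaged Mueller matrix of a solenoid spec, composite
    model, pose list, or pre-voxelized dipole model.

    The particle is rotated (z-y-z Euler angles) under fixed lab incidence
    and scattering plane; per-orientation Mueller matrices are weight-summed.
    Averaged CIDS should then be formed from the averaged elements, which
    equals the CIDS of the ensemble intensities (<IL> - <IR>)/(<IL> + <IR>).
    The angle grid defaults to [0, 180] in 1-degree steps.

    Returns ``(MuellerAngular, mean CrossSections)``.
    """
    from . import dda, geometry  # local import to keep module layering acyclic

    if isinstance(target, geometry.DipoleModel):
        model = target
    else:
        if isinstance(target, geometry.SolenoidSpec):
            poses, shape = geometry.nucleosome_poses(target), target.shape
        elif isinstance(target, geometry.CompositeModel):
            poses, shape = geometry.composite_poses(target), target.segments[0][0].shape
        else:
            poses = list(target)
            shape = geometry.NucleosomeShape()
        model = geometry.voxelize(poses, shape, dipoles_per_longest, rel_index=rel_index, host_index=host_index)

    if quadrature is None:
        quadrature = make_quadrature(8, 8, 4)
    if theta_deg is None:
        theta_deg = np.arange(0.0, 180.0 + 0.5, 1.0)
    theta_deg = np.asarray(theta_deg, dtype=float)

    k = 2.0 * math.pi * host_index / lambda_vac
    interaction = None
    if not born and model.n_dipoles > 1:
        interaction = dda.LatticeInteraction(model, k)

    msum = np.zeros((len(theta_deg), 4, 4))
    c_ext = c_sca = c_abs = 0.0
    a_eff = None
    for (a, b, g), w in zip(quadrature.nodes, quadrature.weights):
        frame = geometry.euler_zyz(a, b, g)
        try:
            run = dda.scattering_run(
                model,
                lambda_vac=lambda_vac,
                theta_deg=theta_deg,
                tol=tol,
                born=born,
                frame=frame,
                interaction=interaction,
            )
        except dda.DDAConvergenceError as err:
            raise dda.DDAConvergenceError(
                f"solver failed at orientation node (alpha={a:.4f}, beta={b:.4f}, gamma={g:.4f}): {err}",
                err.residual_history,
            ) from err
        msum += w * run.mueller.matrices
        c_ext += w * run.cross.C_ext
        c_sca += w * run.cross.C_sca
        c_abs += w * run.cross.C_abs
        a_eff = run.cross.a_eff
    avg = MuellerAngular(theta_deg, msum)
    cross = dda.CrossSections(C_ext=c_ext, C_sca=c_sca, C_abs=c_abs, a_eff=a_eff)
    return avg, cross
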