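"""Continuous chromatin-solenoid models and their cubic-lattice dipole discretization.

The 30 nm chromatin fiber is modeled as a one-start solenoid: nucleosomes
(isotropic dielectric cylinders 11 nm diameter x 5.5 nm height, or 11 nm
spheres) arranged on a helix of radius ``R`` and per-turn axial rise
(pitch) ``P``, six nucleosomes per turn.  The helix axis is the lab z axis.
All lengths are in nanometres, all angles in radians.

A continuous model (a list of :class:`NucleosomePose` plus a
:class:`NucleosomeShape`) is voxelized onto a cubic lattice to obtain the
:class:`DipoleModel` consumed by the coupled-dipole solver.  The lattice is
centred on the model's bounding box so that any y -> -y or z -> -z mirror
symmetry of the continuous model is inherited exactly by the lattice; this
makes the achirality statements (zero differential scattering of circularly
polarized light for mirror-symmetric structures) hold to solver tolerance
rather than discretization error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NucleosomeShape",
    "SolenoidSpec",
    "NucleosomePose",
    "CompositeModel",
    "DipoleModel",
    "nucleosome_poses",
    "composite_poses",
    "stack_opposite_handed",
    "voxelize",
    "mirror_model",
    "rotate_poses",
    "euler_zyz",
]

RIGHT = 1
LEFT = -1

_ORIENTATION_MODES = ("radial", "tangential", "axial")


@dataclass(frozen=True)
class NucleosomeShape:
    """Solid used for a single nucleosome.

    ``cylinder``: symmetry axis given by the pose axis, ``diameter`` across
    the flat face, ``height`` along the axis.  ``sphere``: ``diameter`` only.
    """

    kind: str = "cylinder"
    diameter: float = 11.0
    height: float = 5.5

    def __post_init__(self) -> None:
        if self.kind not in ("cylinder", "sphere"):
            raise ValueError(f"unknown nucleosome shape kind {self.kind!r}")
        if not (np.isfinite(self.diameter) and self.diameter > 0):
            raise ValueError(f"diameter must be positive and finite, got {self.diameter}")
        if self.kind == "cylinder" and not (np.isfinite(self.height) and self.height > 0):
            raise ValueError(f"cylinder height must be positive and finite, got {self.height}")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter


@dataclass(frozen=True)
class SolenoidSpec:
    """Chiral parameter set of a chromatin solenoid.

    Parameters
    ----------
    radius:
        Helix radius R (distance of nucleosome centers from the z axis), nm.
    pitch:
        Axial rise per full turn P, nm.  Pitch 0 degenerates to a planar
        ring of nucleosomes, which is achiral.
    handedness:
        +1 for a right-handed helix, -1 for left-handed.
    turns:
        Number of full helical turns (T >= 1).
    nucleosomes_per_turn:
        Nucleosomes per turn (default 6).
    phase0:
        Azimuth of nucleosome 0, rad.
    orientation_mode:
        How the cylinder axis of each nucleosome is oriented: ``radial``
        (outward radial direction, the default -- the flat faces then contain
        the local tangent direction and their normal is perpendicular to the
        helix axis), ``tangential`` (along the helix tangent) or ``axial``
        (along the helix axis).
    tilt:
        Extra rotation of the nucleosome frame about the local helix tangent,
        rad (exposes the "changed nucleosome orientation" variant).
    shape:
        Nucleosome solid.
    rotating_frame_at_axis:
        Only relevant for radius 0.  By default a radius-0 stack uses one
        fixed frame for every nucleosome (axis +x), which is genuinely
        achiral; set True to keep the azimuth-rotating frames instead
        (a screw-chiral stack).
    """

    radius: float = 10.0
    pitch: float = 11.0
    handedness: int = RIGHT
    turns: int = 1
    nucleosomes_per_turn: int = 6
    phase0: float = 0.0
    orientation_mode: str = "radial"
    tilt: float = 0.0
    shape: NucleosomeShape = field(default_factory=NucleosomeShape)
    rotating_frame_at_axis: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.radius) and self.radius >= 0):
            raise ValueError(f"radius must be finite and >= 0, got {self.radius}")
        if not (np.isfinite(self.pitch) and self.pitch >= 0):
            raise ValueError(f"pitch must be finite and >= 0, got {self.pitch}")
        if self.handedness not in (RIGHT, LEFT):
            raise ValueError(f"handedness must be +1 or -1, got {self.handedness}")
        if not (isinstance(self.turns, (int, np.integer)) and self.turns >= 1):
            raise ValueError(f"turns must be an integer >= 1, got {self.turns}")
        if not (isinstance(self.nucleosomes_per_turn, (int, np.integer)) and self.nucleosomes_per_turn >= 1):
            raise ValueError(f"nucleosomes_per_turn must be an integer >= 1, got {self.nucleosomes_per_turn}")
        if self.orientation_mode not in _ORIENTATION_MODES:
            raise ValueError(f"orientation_mode must be one of {_ORIENTATION_MODES}, got {self.orientation_mode!r}")
        if not np.isfinite(self.phase0) or not np.isfinite(self.tilt):
            raise ValueError("phase0 and tilt must be finite")

    def flipped(self) -> "SolenoidSpec":
        """Same solenoid with the opposite handedness."""
        return replace(self, handedness=-self.handedness)


@dataclass
class NucleosomePose:
    """Rigid placement of one nucleosome: center, symmetry axis, and an
    in-face reference direction orthogonal to the axis."""

    center: np.ndarray
    axis: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        for name, v in (("axis", self.axis), ("reference", self.reference)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a unit vector")
        if abs(float(self.axis @ self.reference)) > 1e-9:
            raise ValueError("axis and reference must be orthogonal")


@dataclass(frozen=True)
class CompositeModel:
    """Stack of solenoid segments: (spec, axial offset nm, azimuth offset rad)."""

    segments: tuple

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError("composite model needs at least one segment")
        for spec, dz, dphi in self.segments:
            if not (np.isfinite(dz) and np.isfinite(dphi)):
                raise ValueError("segment offsets must be finite")


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotate v about a unit axis by angle."""
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - c)


def nucleosome_poses(spec: SolenoidSpec) -> list[NucleosomePose]:
    """Place ``turns * nucleosomes_per_turn`` nucleosomes on the helix.

    Nucleosome k sits at azimuth ``phi_k = phase0 + 2 pi k / n`` and height
    ``z_k = P k / n``; its xy position is ``(R cos phi_k, h R sin phi_k)``
    with h the handedness sign, so flipping handedness reflects the pose set
    through the xz plane exactly.
    """
    R, P, h = spec.radius, spec.pitch, float(spec.handedness)
    n = spec.nucleosomes_per_turn
    poses: list[NucleosomePose] = []
    fixed_frame = (
        R == 0.0
        and not spec.rotating_frame_at_axis
        and spec.orientation_mode in ("radial", "tangential")
    )
    for k in range(spec.turns * n):
        phi = spec.phase0 + 2.0 * math.pi * k / n
        c, s = math.cos(phi), math.sin(phi)
        center = np.array([R * c, h * R * s, P * k / n])
        radial = np.array([c, h * s, 0.0])
        # Helix tangent d(center)/d(phi), normalized; at R=0 it is the z axis.
        tvec = np.array([-R * s, h * R * c, P / (2.0 * math.pi)])
        tnorm = np.linalg.norm(tvec)
        tangent = tvec / tnorm if tnorm > 0 else np.array([0.0, 0.0, 1.0])
        if fixed_frame:
            axis = np.array([1.0, 0.0, 0.0])
            reference = np.array([0.0, 0.0, 1.0])
        elif spec.orientation_mode == "radial":
            axis = radial
            reference = np.array([0.0, 0.0, 1.0])
        elif spec.orientation_mode == "tangential":
            axis = tangent
            reference = radial - (radial @ tangent) * tangent
            reference = reference / np.linalg.norm(reference)
        else:  # axial
            axis = np.array([0.0, 0.0, 1.0])
            reference = radial
        if spec.tilt != 0.0:
            taxis = tangent if tnorm > 0 else np.array([0.0, 0.0, 1.0])
            axis = _rodrigues(axis, taxis, spec.tilt)
            reference = _rodrigues(reference, taxis, spec.tilt)
        poses.append(NucleosomePose(center, axis, reference))
    return poses


def composite_poses(model: CompositeModel) -> list[NucleosomePose]:
    """Poses of all segments, each azimuth-rolled and lifted by its offsets."""
    poses: list[NucleosomePose] = []
    for spec, dz, dphi in model.segments:
        seg = nucleosome_poses(replace(spec, phase0=spec.phase0 + dphi))
        for p in seg:
            poses.append(NucleosomePose(p.center + np.array([0.0, 0.0, dz]), p.axis, p.reference))
    return poses


def stack_opposite_handed(spec: SolenoidSpec) -> CompositeModel:
    """One turn of ``spec`` with one opposite-handed turn stacked on top.

    The second segment continues the stack at axial offset P with its azimuth
    chosen so that the composite pose set is an exact mirror image of itself
    through the horizontal mid-plane ``z = P (2n - 1) / (2n)``: the composite
    is provably achiral, which is the construction under which its
    orientation-averaged differential circular scattering vanishes exactly.
    """
    if spec.turns != 1:
        raise ValueError(f"opposite-handed stack is defined for one-turn specs, got turns={spec.turns}")
    n = spec.nucleosomes_per_turn
    dphi = -2.0 * spec.phase0 - 2.0 * math.pi * (n - 1) / n
    return CompositeModel(segments=((spec, 0.0, 0.0), (spec.flipped(), spec.pitch, dphi)))


def euler_zyz(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix of the intrinsic z-y-z Euler rotation Rz(a) Ry(b) Rz(g)."""
    ca, sa = math.cos(alpha), math.sin(alpha)
    cb, sb = math.cos(beta), math.sin(beta)
    cg, sg = math.cos(gamma), math.sin(gamma)
    rz_a = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    ry_b = np.array([[cb, 0.0, sb], [0.0, 1.0, 0.0], [-sb, 0.0, cb]])
    rz_g = np.array([[cg, -sg, 0.0], [sg, cg, 0.0], [0.0, 0.0, 1.0]])
    return rz_a @ ry_b @ rz_g


def rotate_poses(
    poses: Sequence[NucleosomePose], alpha: float, beta: float, gamma: float
) -> list[NucleosomePose]:
    """Rigidly rotate all poses by the intrinsic z-y-z Euler rotation.

    (0, 0, 0) is the identity; the laboratory incidence direction stays fixed,
    so this rotates the particle relative to the incident beam.
    """
    rot = euler_zyz(alpha, beta, gamma)
    return [NucleosomePose(rot @ p.center, rot @ p.axis, rot @ p.reference) for p in poses]


# ---------------------------------------------------------------------------
# Voxelization


def _solid_bbox(pose: NucleosomePose, shape: NucleosomeShape) -> tuple[np.ndarray, np.ndarray]:
    if shape.kind == "sphere":
        r = shape.radius
        return pose.center - r, pose.center + r
    # Axis-aligned extent of an arbitrarily oriented cylinder.
    a = pose.axis
    half = shape.radius * np.sqrt(np.maximum(0.0, 1.0 - a * a)) + 0.5 * shape.height * np.abs(a)
    return pose.center - half, pose.center + half


def _inside_solid(points: np.ndarray, pose: NucleosomePose, shape: NucleosomeShape) -> np.ndarray:
    """Closed-solid membership test for an (N, 3) array of points."""
    rel = points - pose.center
    if shape.kind == "sphere":
        return np.einsum("ij,ij->i", rel, rel) <= shape.radius**2
    t = rel @ pose.axis
    perp2 = np.einsum("ij,ij->i", rel, rel) - t * t
    return (np.abs(t) <= 0.5 * shape.height) & (perp2 <= shape.radius**2)


@dataclass
class DipoleModel:
    """Cubic-lattice dipole discretization of a scatterer.

    Site (i, j, k) sits at ``origin + spacing * (i, j, k)``.  ``rel_index`` is
    the refractive index of the material relative to the host medium
    (scalar, or one value per site).
    """

    spacing: float
    origin: np.ndarray
    sites: np.ndarray
    rel_index: complex = 1.68 / 1.33
    host_index: float = 1.33

    def __post_init__(self) -> None:
        if not (np.isfinite(self.spacing) and self.spacing > 0):
            raise ValueError(f"spacing must be positive and finite, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.sites = np.asarray(self.sites, dtype=np.int64).reshape(-1, 3)
        if len(self.sites) == 0:
            raise ValueError("dipole model has no sites")
        uniq = np.unique(self.sites, axis=0)
        if len(uniq) != len(self.sites):
            raise ValueError("dipole model contains duplicate sites")
        m = np.atleast_1d(np.asarray(self.rel_index, dtype=complex))
        if np.any(np.abs(m - 1.0) >= 2.0):
            warnings.warn(
                "relative refractive index violates |m - 1| < 2; the coupled-dipole "
                "approximation is unreliable in this regime",
                stacklevel=2,
            )

    @property
    def n_dipoles(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) physical dipole positions, nm."""
        return self.origin + self.spacing * self.sites

    @property
    def volume(self) -> float:
        """Discretized volume N d^3, nm^3."""
        return self.n_dipoles * self.spacing**3


def voxelize(
    poses: Sequence[NucleosomePose],
    shape: NucleosomeShape,
    dipoles_per_longest: int,
    rel_index: complex = 1.68 / 1.33,
    host_index: float = 1.33,
) -> DipoleModel:
    """Voxelize the union of nucleosome solids onto a cubic lattice.

    The lattice constant is ``d = (largest bounding-box extent) /
    dipoles_per_longest``; a site is occupied iff its center lies inside at
    least one solid (union semantics, closed solids).  The lattice is centred
    on the bounding box, so cell centers come in exact ``+/-`` pairs about the
    box center along every axis and mirror symmetries of the continuous model
    survive discretization exactly.
    """
    poses = list(poses)
    if not poses:
        raise ValueError("voxelize needs at least one nucleosome pose")
    if not (isinstance(dipoles_per_longest, (int, np.integer)) and dipoles_per_longest >= 4):
        raise ValueError(f"dipoles_per_longest must be an integer >= 4, got {dipoles_per_longest}")

    los, his = zip(*(_solid_bbox(p, shape) for p in poses))
    lo = np.min(np.array(los), axis=0)
    hi = np.max(np.array(his), axis=0)
    extent = hi - lo
    d = float(extent.max()) / dipoles_per_longest
    center = 0.5 * (lo + hi)
    ncells = np.maximum(1, np.ceil(extent / d - 1e-9).astype(int))

    axes = [center[a] + (np.arange(ncells[a]) + 0.5 - ncells[a] / 2.0) * d for a in range(3)]
    occupied = np.zeros(tuple(ncells), dtype=bool)
    for pose in poses:
        slo, shi = _solid_bbox(pose, shape)
        sel = []
        for a in range(3):
            idx = np.nonzero((axes[a] >= slo[a] - 0.5 * d) & (axes[a] <= shi[a] + 0.5 * d))[0]
            if idx.size == 0:
                sel = None
                break
            sel.append((idx[0], idx[-1] + 1))
        if sel is None:
            continue
        (i0, i1), (j0, j1), (k0, k1) = sel
        gx, gy, gz = np.meshgrid(axes[0][i0:i1], axes[1][j0:j1], axes[2][k0:k1], indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        inside = _inside_solid(pts, pose, shape).reshape(gx.shape)
        occupied[i0:i1, j0:j1, k0:k1] |= inside

    sites = np.argwhere(occupied)
    if len(sites) == 0:
        if shape.kind == "cylinder":
            offender = "height" if shape.height < shape.diameter else "diameter"
            size = min(shape.height, shape.diameter)
        else:
            offender, size = "diameter", shape.diameter
        raise ValueError(
            f"voxelization produced no occupied sites: nucleosome {offender} "
            f"({size} nm) is thinner than one lattice cell (d = {d:.4g} nm)"
        )
    origin = np.array([axes[0][0], axes[1][0], axes[2][0]])
    order = np.lexsort((sites[:, 2], sites[:, 1], sites[:, 0]))
    return DipoleModel(spacing=d, origin=origin, sites=sites[order], rel_index=rel_index, host_index=host_index)


def mirror_model(model: DipoleModel, plane: str = "xz") -> DipoleModel:
    """Exact mirror image of a dipole model through the xz or xy plane.

    Site indices along the mirrored axis are negated and the origin adjusted
    so physical positions are exact reflections; spacing and the remaining
    indices are untouched.  Mirroring reverses the chirality of the model.
    """
    if plane not in ("xz", "xy"):
        raise ValueError(f"plane must be 'xz' or 'xy', got {plane!r}")
    axis = 1 if plane == "xz" else 2
    sites = model.sites.copy()
    sites[:, axis] = -sites[:, axis]
    origin = model.origin.copy()
    origin[axis] = -origin[axis]
    order = np.lexsort((sites[:, 2], sites[:, 1], sites[:, 0]))
    rel = model.rel_index
    if np.ndim(rel) == 1:
        rel = np.asarray(rel)[order]
    return DipoleModel(
        spacing=model.spacing, origin=origin, sites=sites[order], rel_index=rel, host_index=model.host_index
    )
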