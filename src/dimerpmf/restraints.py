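"""Umbrella and orientational restraints.

Two restraints act on the toy dimer system:

* a harmonic umbrella bias on the distance between the two proteins'
  centres of mass (the reaction coordinate), and
* a torque-only rotational restraint per protein that pins its in-plane
  orientation without exerting net translational force.

The rotational restraint is a pivot-free "radial motion" potential in the
spirit of the enforced-rotation family of Kutzner et al.: each restrained
particle is penalized for displacement along the tangential direction of its
*reference* radius from the body's centre of mass,

    E = (k_rot / 2) * sum_i [ s_i . (x_i - x_c) ]^2 ,
    s_i = (v x rho_i) / sqrt(|rho_i|^2 + eps'),   rho_i = Omega (y_i - y_c),

with v the out-of-plane rotation axis, y_i the reference particle positions,
y_c their centre of mass, Omega a rotation matrix (identity for a fixed
orientation) and eps' a small regularizer removing the singularity for
particles on the axis.  Because the potential depends only on positions
relative to the instantaneous centre of mass, the restraint forces sum to
zero exactly; their resultant is a pure torque about the centre of mass
directed along +/- v, and the radial component of each particle force
vanishes up to O(eps').
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import planar_rotation_fit, rotation_matrix, wrap_angle

__all__ = [
    "HarmonicBias",
    "RotationalRestraint",
    "RestraintSet",
    "umbrella_energy_force",
    "rotational_energy_forces",
    "rotational_drift",
    "orientation_angles",
]


@dataclass(frozen=True)
class HarmonicBias:
    """Harmonic umbrella bias ``E = k/2 (d - center)**2`` on the inter-COM separation."""

    center: float
    force_constant: float

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if self.center < 0:
            raise ValueError("center separation must be >= 0")

    def energy(self, d: float | np.ndarray) -> np.ndarray:
        return 0.5 * self.force_constant * (np.asarray(d, dtype=float) - self.center) ** 2


@dataclass(frozen=True)
class RotationalRestraint:
    """Torque-only orientational restraint for one rigid body.

    Parameters
    ----------
    reference_positions
        (N, 2) lab-frame reference coordinates of the restrained particles.
    force_constant
        k_rot, energy / length^2.
    epsilon
        eps', small area-scale regularizer (> 0).
    rotation_matrix
        2x2 orthogonal matrix Omega describing the motion of the restraint
        (identity = hold the starting orientation fixed).
    axis
        Unit rotation axis; the planar implementation requires +/- z.
    body
        Which protein this restraint references (0 or 1).
    """

    reference_positions: np.ndarray
    force_constant: float
    epsilon: float = 1e-4
    rotation: np.ndarray = field(default_factory=lambda: np.eye(2))
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    body: int = 0

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference_positions, dtype=float)
        object.__setattr__(self, "reference_positions", ref)
        if ref.ndim != 2 or ref.shape[1] != 2 or ref.shape[0] < 3:
            raise ValueError("reference_positions must be (N>=3, 2)")
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        axis = np.asarray(self.axis, dtype=float)
        if not np.isclose(np.linalg.norm(axis), 1.0):
            raise ValueError("axis must be a unit vector")
        if not np.allclose(np.abs(axis), [0.0, 0.0, 1.0]):
            raise ValueError("planar implementation supports only the out-of-plane axis +/- z")
        om = np.asarray(self.rotation, dtype=float)
        if om.shape != (2, 2) or not np.allclose(om.T @ om, np.eye(2), atol=1e-10):
            raise ValueError("rotation must be 2x2 orthogonal")
        if not np.isclose(np.linalg.det(om), 1.0):
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", om)
        object.__setattr__(self, "axis", axis)

    def tangent_directions(self) -> np.ndarray:
        """Regularized tangential unit directions s_i of the rotated reference."""
        ref = self.reference_positions
        rho = (ref - ref.mean(axis=0)) @ self.rotation.T
        if np.all(np.hypot(rho[:, 0], rho[:, 1]) < 1e-12):
            raise ValueError("degenerate reference: all particles lie on the rotation axis")
        sign = self.axis[2]
        perp = sign * np.column_stack([-rho[:, 1], rho[:, 0]])  # v x rho
        norm = np.sqrt(np.sum(rho**2, axis=1) + self.epsilon)
        return perp / norm[:, None]

    def effective_torsion_constant(self) -> float:
        """kappa such that E(rigid rotation by phi) = kappa/2 * sin(phi)^2.

        For a rigid body the particle-based potential collapses onto the
        single orientation degree of freedom; the torque used by the toy
        integrator is ``-kappa sin(phi) cos(phi)``.
        """
        ref = self.reference_positions
        rho = ref - ref.mean(axis=0)
        r2 = np.sum(rho**2, axis=1)
        return float(self.force_constant * np.sum(r2**2 / (r2 + self.epsilon)))


@dataclass(frozen=True)
class RestraintSet:
    """Bundle of restraints applied in one umbrella window."""

    umbrella: HarmonicBias | None = None
    rotational: tuple[RotationalRestraint, ...] = ()

    def __post_init__(self) -> None:
        rot = tuple(self.rotational)
        bodies = [r.body for r in rot]
        if len(bodies) != len(set(bodies)):
            raise ValueError("each rotational restraint must reference a distinct body")
        if len(rot) > 2:
            raise ValueError("at most two rotational restraints (one per protein)")
        object.__setattr__(self, "rotational", rot)

    def for_body(self, body: int) -> RotationalRestraint | None:
        for r in self.rotational:
            if r.body == body:
                return r
        return None


def umbrella_energy_force(separation: float, bias: HarmonicBias) -> tuple[float, float]:
    """Energy and scalar restoring force of the umbrella at a given separation.

    The force is the component along the inter-COM line in the direction of
    increasing separation; the caller apportions it equally and oppositely to
    the two centres of mass.
    """
    d = float(separation)
    if d < 0:
        raise ValueError("separation must be >= 0")
    dd = d - bias.center
    return 0.5 * bias.force_constant * dd * dd, -bias.force_constant * dd


def rotational_energy_forces(
    current_positions: np.ndarray, restraint: RotationalRestraint
) -> tuple[float, np.ndarray]:
    """Energy and per-particle forces of the torque-only rotational restraint.

    Contract (the testable content): the forces sum to zero exactly
    (translation invariance of the COM-relative construction), their net
    torque about the centre of mass is along +/- the rotation axis, and the
    radial force components vanish as eps' -> 0.
    """
    x = np.asarray(current_positions, dtype=float)
    ref = restraint.reference_positions
    if x.shape != ref.shape:
        raise ValueError("current positions must match the reference shape")
    s = restraint.tangent_directions()
    n = x.shape[0]
    xc = x.mean(axis=0)
    r = x - xc
    g = np.sum(s * r, axis=1)  # tangential displacements
    k = restraint.force_constant
    energy = 0.5 * k * float(np.sum(g**2))
    grad = k * (g[:, None] * s)  # dE/dx_j, direct term
    grad -= grad.sum(axis=0) / n  # COM coupling: makes sum(force) == 0 exactly
    return energy, -grad


def rotational_drift(trajectory, restraint: RotationalRestraint, body: int | None = None) -> np.ndarray:
    """Per-frame best-fit rotation angle (degrees) of a body against its restraint reference.

    Uses the 2D least-squares (Kabsch-style) rotation of the body's ring
    particles onto ``restraint.reference_positions``; raises on degenerate or
    mirror-image geometry rather than reporting a silent angle.
    """
    b = restraint.body if body is None else body
    if b >= trajectory.n_proteins:
        raise ValueError(f"body {b} not present in trajectory")
    ref = restraint.reference_positions
    angles = np.empty(trajectory.n_frames)
    for i in range(trajectory.n_frames):
        ring = trajectory.ring_positions(i)[b]
        angles[i] = planar_rotation_fit(ref, ring)
    return np.degrees(angles)


def orientation_angles(
    com_a: np.ndarray,
    com_b: np.ndarray,
    marker_a: np.ndarray,
    marker_b: np.ndarray,
) -> tuple[float, float]:
    """Orientation angles (degrees, in [0, 360)) of two proteins.

    Each angle is measured counter-clockwise (viewed from the declared
    extracellular side) from the line running from that protein's centre of
    mass through the partner's centre of mass, to the vector from the centre
    of mass through the protein's marker particle.
    """
    com_a = np.asarray(com_a, dtype=float)
    com_b = np.asarray(com_b, dtype=float)
    sep = com_b - com_a
    if np.hypot(*sep) < 1e-12:
        raise ValueError("coincident centres of mass")
    out = []
    for com, marker, line in ((com_a, marker_a, sep), (com_b, marker_b, -sep)):
        arm = np.asarray(marker, dtype=float) - com
        theta = np.arctan2(arm[1], arm[0]) - np.arctan2(line[1], line[0])
        out.append(float(np.degrees(wrap_angle(theta)) % 360.0))
    return out[0], out[1]


def restraint_set_for_orientation(
    body_refs: np.ndarray,
    coms: np.ndarray,
    angles: np.ndarray,
    k_rot: float,
    epsilon: float = 1e-4,
    umbrella: HarmonicBias | None = None,
) -> RestraintSet:
    """Build a RestraintSet pinning each body at its current pose.

    ``body_refs`` is (P, M, 2) in the body frame; ``coms``/(P, 2) and
    ``angles``/(P,) give the poses whose lab-frame particle positions become
    the restraint references.
    """
    rots = []
    if k_rot > 0:
        for p in range(coms.shape[0]):
            lab = body_refs[p] @ rotation_matrix(angles[p]).T + coms[p]
            rots.append(
                RotationalRestraint(
                    reference_positions=lab,
                    force_constant=k_rot,
                    epsilon=epsilon,
                    body=p,
                )
            )
    return RestraintSet(umbrella=umbrella, rotational=tuple(rots))
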