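"""Synthetic toy-membrane generator and exact 1D reference systems.

The toy membrane is a quasi-2D periodic box containing up to two rigid
elliptical protein bodies (rings of particles) and many repulsive lipid
discs, evolved by overdamped (first-order) Langevin dynamics at fixed
temperature.  It emulates the *statistical* structure of coarse-grained
bilayer simulations — thermal motion, lipid packing shells around embedded
proteins, harmonic centre-of-mass umbrella biases and torque-only
orientational restraints — without any chemistry.  All quantities are in
dimensionless toy units; a declared nm-equivalent scale factor is recorded
in outputs so that no toy number can masquerade as a physical value.

Exact 1D potentials (:class:`PotentialSpec1D`), a seeded Boltzmann sampler
and the closed-form free energy :func:`exact_free_energy_1d` provide the
independent analytic oracles against which the WHAM estimator is validated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import _dynamics
from .geometry import ellipse_ring, minimum_image, rotation_matrix, planar_rotation_fit
from .restraints import HarmonicBias, RestraintSet, restraint_set_for_orientation
from .wham import UmbrellaWindow

__all__ = [
    "ToyConfig",
    "Frame",
    "Trajectory",
    "PotentialSpec1D",
    "PlacementError",
    "IntegrationError",
    "simulate_toy_membrane",
    "sample_boltzmann_1d",
    "exact_free_energy_1d",
    "generate_umbrella_dataset",
]


class PlacementError(RuntimeError):
    """Initial lipid placement could not avoid hard overlaps."""


class IntegrationError(RuntimeError):
    """A non-finite force appeared during integration."""


@dataclass(frozen=True)
class ToyConfig:
    """Parameters of the toy membrane.

    Lengths are in toy units (the lipid disc diameter is the natural unit);
    energies in units of k_B*T at ``temperature = 1``.  ``nm_per_unit`` is a
    bookkeeping scale recorded in output headers, not a physical claim.
    """

    box_side: float = 16.0
    n_lipids: int = 190
    lipid_diameter: float = 1.0
    protein_semi_axes: tuple[float, float] = (2.0, 1.2)
    n_body_particles: int = 28
    temperature: float = 1.0
    friction: float = 1.0
    timestep: float = 5.0e-4
    n_steps: int = 30_000
    seed: int = 0
    # --- emulation knobs beyond the core set ---
    stride: int = 12
    n_equil: int = 3_000
    repulsion_strength: float = 200.0
    ring_particle_diameter: float = 0.6
    protein_attraction: float = 0.5  # inter-protein ring-pair cohesion depth
    protein_attraction_range: float = 0.3
    transverse_restraint: float = 10.0  # off-axis COM restraint in two-protein runs
    com_friction: float = 6.0
    rot_friction: float = 20.0
    nm_per_unit: float = 0.47

    def __post_init__(self) -> None:
        a, b = self.protein_semi_axes
        if not (a >= b > 0):
            raise ValueError("protein_semi_axes must satisfy wide >= narrow > 0")
        if self.box_side <= 2.0 * (a + 2.0 * self.lipid_diameter):
            raise ValueError("box_side too small for the protein plus a lipid shell")
        if self.n_lipids < 0:
            raise ValueError("n_lipids must be >= 0")
        if self.timestep <= 0 or self.friction <= 0:
            raise ValueError("timestep and friction must be > 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0 (0 = zero-noise limit)")
        if self.n_steps <= 0 or self.stride <= 0 or self.n_equil < 0:
            raise ValueError("n_steps/stride must be > 0, n_equil >= 0")
        if self.n_body_particles < 3:
            raise ValueError("need at least 3 body particles")

    # interaction diameters
    @property
    def sigma_ll(self) -> float:
        return self.lipid_diameter

    @property
    def sigma_lr(self) -> float:
        return 0.5 * (self.lipid_diameter + self.ring_particle_diameter)

    @property
    def sigma_rr(self) -> float:
        return self.ring_particle_diameter

    def body_reference(self) -> np.ndarray:
        """Body-frame ring coordinates of one protein."""
        return ellipse_ring(self.protein_semi_axes, self.n_body_particles)

    def replace(self, **kw) -> "ToyConfig":
        return dataclasses.replace(self, **kw)

    def to_mapping(self) -> dict:
        d = dataclasses.asdict(self)
        d["protein_semi_axes"] = tuple(self.protein_semi_axes)
        return d


@dataclass(frozen=True)
class Frame:
    """One stored configuration: particle positions with body/role labels."""

    time: float
    positions: np.ndarray  # (N, 2)
    body_label: tuple[str, ...]  # protein_A / protein_B / lipid
    lipid_id: np.ndarray  # (N,) int, -1 for protein particles
    leaflet: tuple[str, ...]  # upper / lower / '-'


_BODY_NAMES = ("protein_A", "protein_B")


@dataclass
class Trajectory:
    """Time-ordered toy-membrane state.

    Coordinates are stored *unwrapped* (free diffusion observables remain
    meaningful); every distance computed from them goes through the
    minimum-image convention with ``box_side``.
    """

    times: np.ndarray  # (F,)
    lipid_xy: np.ndarray  # (F, L, 2)
    leaflet: np.ndarray  # (L,) 0 = upper, 1 = lower
    protein_com: np.ndarray  # (F, P, 2)
    protein_angle: np.ndarray  # (F, P)
    body_ref: np.ndarray  # (P, M, 2)
    box_side: float
    seed: int
    config: ToyConfig | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_lipids(self) -> int:
        return self.lipid_xy.shape[1]

    @property
    def n_proteins(self) -> int:
        return self.protein_com.shape[1]

    def ring_positions(self, frame: int) -> np.ndarray:
        """(P, M, 2) lab-frame ring-particle positions at one frame."""
        out = np.empty_like(self.body_ref)
        for p in range(self.n_proteins):
            r = rotation_matrix(self.protein_angle[frame, p])
            out[p] = self.body_ref[p] @ r.T + self.protein_com[frame, p]
        return out

    def separations(self) -> np.ndarray:
        """Minimum-image inter-COM separation series (requires two proteins)."""
        if self.n_proteins != 2:
            raise ValueError("separation series needs exactly two proteins")
        delta = minimum_image(self.protein_com[:, 1] - self.protein_com[:, 0], self.box_side)
        return np.hypot(delta[:, 0], delta[:, 1])

    def frame(self, i: int) -> Frame:
        rings = self.ring_positions(i)
        parts = [rings[p] for p in range(self.n_proteins)] + [self.lipid_xy[i]]
        positions = np.concatenate(parts, axis=0) if parts else np.empty((0, 2))
        labels: list[str] = []
        lipid_id: list[int] = []
        leaflet: list[str] = []
        m = self.body_ref.shape[1]
        for p in range(self.n_proteins):
            labels += [_BODY_NAMES[p]] * m
            lipid_id += [-1] * m
            leaflet += ["-"] * m
        for j in range(self.n_lipids):
            labels.append("lipid")
            lipid_id.append(j)
            leaflet.append("upper" if self.leaflet[j] == 0 else "lower")
        return Frame(
            time=float(self.times[i]),
            positions=positions,
            body_label=tuple(labels),
            lipid_id=np.array(lipid_id),
            leaflet=tuple(leaflet),
        )

    def to_tsv(self, path) -> None:
        """Columnar TSV: frame, time, body_label, lipid_id, leaflet, x, y."""
        with open(path, "w") as fh:
            fh.write("# dimerpmf toy trajectory\n")
            fh.write(f"# seed = {self.seed}\n")
            fh.write(f"# box_side = {self.box_side}\n")
            if self.config is not None:
                fh.write(f"# nm_per_unit = {self.config.nm_per_unit}\n")
            fh.write("frame\ttime\tbody_label\tlipid_id\tleaflet\tx\ty\n")
            for i in range(self.n_frames):
                fr = self.frame(i)
                for k in range(fr.positions.shape[0]):
                    fh.write(
                        f"{i}\t{fr.time:.6g}\t{fr.body_label[k]}\t{fr.lipid_id[k]}\t"
                        f"{fr.leaflet[k]}\t{fr.positions[k, 0]:.8g}\t{fr.positions[k, 1]:.8g}\n"
                    )

    @classmethod
    def from_tsv(cls, path) -> "Trajectory":
        import pandas as pd

        box = None
        seed = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if "box_side" in line:
                    box = float(line.split("=")[1])
                elif "seed" in line:
                    seed = int(line.split("=")[1])
        if box is None:
            raise ValueError("trajectory TSV lacks a '# box_side = ...' header")
        df = pd.read_csv(path, sep="\t", comment="#")
        frames = np.sort(df["frame"].unique())
        lip = df[df.body_label == "lipid"]
        lipid_ids = np.sort(lip["lipid_id"].unique())
        nl = len(lipid_ids)
        bodies = [b for b in _BODY_NAMES if (df.body_label == b).any()]
        times = np.empty(len(frames))
        lipid_xy = np.empty((len(frames), nl, 2))
        leaflet = np.zeros(nl, dtype=int)
        first = df[df.frame == frames[0]]
        for j, lid in enumerate(lipid_ids):
            row = first[(first.body_label == "lipid") & (first.lipid_id == lid)].iloc[0]
            leaflet[j] = 0 if row["leaflet"] == "upper" else 1
        coms = np.empty((len(frames), len(bodies), 2))
        angles = np.empty((len(frames), len(bodies)))
        body_ref = None
        for fi, f in enumerate(frames):
            sub = df[df.frame == f]
            times[fi] = sub["time"].iloc[0]
            lsub = sub[sub.body_label == "lipid"].set_index("lipid_id")
            lipid_xy[fi] = lsub.loc[lipid_ids, ["x", "y"]].to_numpy()
            for p, b in enumerate(bodies):
                ring = sub[sub.body_label == b][["x", "y"]].to_numpy()
                coms[fi, p] = ring.mean(axis=0)
                if fi == 0:
                    if body_ref is None:
                        body_ref = np.empty((len(bodies), ring.shape[0], 2))
                    body_ref[p] = ring - ring.mean(axis=0)
                    angles[fi, p] = 0.0
                else:
                    angles[fi, p] = planar_rotation_fit(body_ref[p], ring)
        if body_ref is None:
            body_ref = np.empty((0, 0, 2))
        return cls(
            times=times,
            lipid_xy=lipid_xy,
            leaflet=leaflet,
            protein_com=coms,
            protein_angle=angles,
            body_ref=body_ref,
            box_side=box,
            seed=seed,
        )

    def to_npz(self, path) -> None:
        np.savez_compressed(
            path,
            times=self.times,
            lipid_xy=self.lipid_xy,
            leaflet=self.leaflet,
            protein_com=self.protein_com,
            protein_angle=self.protein_angle,
            body_ref=self.body_ref,
            box_side=self.box_side,
            seed=self.seed,
        )

    @classmethod
    def from_npz(cls, path) -> "Trajectory":
        z = np.load(path)
        return cls(
            times=z["times"],
            lipid_xy=z["lipid_xy"],
            leaflet=z["leaflet"],
            protein_com=z["protein_com"],
            protein_angle=z["protein_angle"],
            body_ref=z["body_ref"],
            box_side=float(z["box_side"]),
            seed=int(z["seed"]),
        )


# ---------------------------------------------------------------------------
# orientation convention
# ---------------------------------------------------------------------------

def _body_angles_from_orientations(orientations: tuple[float, float]) -> np.ndarray:
    """Map orientation angles (deg; 0 = wide face toward the partner) to
    internal body rotations (rad).

    The marker particle sits at the tip of the narrow semi-axis (body-frame
    +y, on the wide face).  Protein A sees its partner along +x, protein B
    along -x.
    """
    th_a, th_b = (np.radians(o) for o in orientations)
    return np.array([th_a - np.pi / 2.0, th_b + np.pi / 2.0])


def _place_lipids(
    rng: np.random.Generator,
    config: ToyConfig,
    coms: np.ndarray,
    angles: np.ndarray,
    delipidated: bool,
) -> np.ndarray:
    """Jittered-lattice lipid placement excluding protein interiors.

    Bounded retries with progressively denser lattices; raises
    :class:`PlacementError` if the box cannot host the requested count.
    """
    box = config.box_side
    n = config.n_lipids
    if n == 0:
        return np.empty((0, 2))
    a, b = config.protein_semi_axes
    margin = config.sigma_lr
    # progressively denser lattices, never below ~0.85 lipid diameters:
    # a lattice tighter than that would itself be a hard-overlap start
    for spacing in (1.1, 1.0, 0.9, 0.85):
        nx = int(np.ceil(box / (spacing * config.lipid_diameter)))
        s = box / nx
        xs = (np.arange(nx) + 0.5) * s
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        pts = pts + rng.uniform(-0.25 * s, 0.25 * s, size=pts.shape)
        keep = np.ones(len(pts), dtype=bool)
        for p in range(coms.shape[0]):
            rel = minimum_image(pts - coms[p], box)
            body = rel @ rotation_matrix(angles[p])  # rotate into body frame
            keep &= (body[:, 0] / (a + margin)) ** 2 + (body[:, 1] / (b + margin)) ** 2 > 1.0
        if delipidated and coms.shape[0] == 2:
            mid = 0.5 * (coms[0] + coms[1])
            axis = minimum_image(coms[1] - coms[0], box)
            half_len = 0.5 * np.hypot(*axis)
            u = axis / (2.0 * half_len)
            rel = minimum_image(pts - mid, box)
            along = rel @ u
            across = rel @ np.array([-u[1], u[0]])
            keep &= ~((np.abs(along) < half_len) & (np.abs(across) < a + margin))
        pts = pts[keep]
        if len(pts) >= n:
            idx = rng.permutation(len(pts))[:n]
            return pts[idx]
    raise PlacementError(
        f"could not place {n} lipids without hard overlap (box {box}, {coms.shape[0]} proteins)"
    )


def simulate_toy_membrane(
    config: ToyConfig,
    restraints: RestraintSet | None = None,
    seed: int | None = None,
    *,
    n_proteins: int = 2,
    orientations: tuple[float, float] = (0.0, 0.0),
    initial_separation: float | None = None,
    delipidated: bool = False,
    lipidated: bool = False,
) -> Trajectory:
    """Run the seeded overdamped Langevin toy membrane.

    Identical ``(config, restraints, seed)`` yield a bit-identical
    trajectory.  Proteins move as rigid bodies under the net force and
    torque accumulated on their ring particles; lipids interact through
    short-range soft repulsion.

    ``orientations`` follow the project-wide convention: degrees,
    counter-clockwise viewed from the extracellular side, 0 = wide face
    toward the partner.  When a rotational restraint is supplied its
    reference pose takes precedence over ``orientations``.
    """
    if seed is None:
        seed = config.seed
    if n_proteins not in (0, 1, 2):
        raise ValueError("n_proteins must be 0, 1 or 2")
    restraints = restraints or RestraintSet()
    rng = np.random.default_rng(seed)
    box = config.box_side

    body_ref_one = config.body_reference()
    body_ref = np.repeat(body_ref_one[None], n_proteins, axis=0)

    bias = restraints.umbrella
    if n_proteins == 2:
        if initial_separation is None:
            initial_separation = bias.center if bias is not None else 0.45 * box
        coms = np.array(
            [
                [box / 2.0 - initial_separation / 2.0, box / 2.0],
                [box / 2.0 + initial_separation / 2.0, box / 2.0],
            ]
        )
        angles = _body_angles_from_orientations(orientations)
    elif n_proteins == 1:
        coms = np.array([[box / 2.0, box / 2.0]])
        angles = np.array([0.0])
    else:
        coms = np.empty((0, 2))
        angles = np.empty(0)

    kappa = np.zeros(n_proteins)
    ref_angle = angles.copy()
    for p in range(n_proteins):
        rr = restraints.for_body(p)
        if rr is not None:
            kappa[p] = rr.effective_torsion_constant()
            ref = rr.reference_positions
            ref_angle[p] = planar_rotation_fit(body_ref[p], ref - ref.mean(axis=0))
            angles[p] = ref_angle[p]

    if delipidated and lipidated:
        raise ValueError("a window cannot be both delipidated and lipidated")
    lipid_xy = _place_lipids(rng, config, coms, angles, delipidated)
    if lipidated and n_proteins == 2 and config.n_lipids > 0:
        # seed the lipidated state: move the lipid farthest from the dimer
        # to the interface midpoint, so both occupation states get sampled
        mid = 0.5 * (coms[0] + coms[1])
        far = np.argmax(np.sum(minimum_image(lipid_xy - mid, box) ** 2, axis=1))
        lipid_xy[far] = mid
    leaflet = np.arange(config.n_lipids) % 2

    kernel_seed = int(seed) % (2**31 - 1)
    times, rec_lip, rec_com, rec_ang, bad_step = _dynamics.run_brownian(
        kernel_seed,
        config.n_equil,
        config.n_steps,
        config.stride,
        lipid_xy.astype(float),
        coms.astype(float),
        angles.astype(float),
        body_ref.astype(float),
        float(box),
        float(config.timestep),
        float(config.temperature),
        float(config.friction),
        float(config.com_friction),
        float(config.rot_friction),
        float(config.repulsion_strength),
        float(config.sigma_ll),
        float(config.sigma_lr),
        float(config.sigma_rr),
        float(bias.force_constant) if bias is not None else 0.0,
        float(bias.center) if bias is not None else 0.0,
        kappa.astype(float),
        ref_angle.astype(float),
        float(config.protein_attraction),
        float(config.protein_attraction_range),
        float(config.transverse_restraint) if n_proteins == 2 else 0.0,
    )
    if bad_step >= 0:
        raise IntegrationError(f"non-finite force at integration step {bad_step}")
    meta = {
        "seed": seed,
        "orientations": tuple(orientations) if n_proteins == 2 else None,
        "delipidated": bool(delipidated),
        "nm_per_unit": config.nm_per_unit,
    }
    return Trajectory(
        times=times,
        lipid_xy=rec_lip,
        leaflet=leaflet,
        protein_com=rec_com,
        protein_angle=rec_ang,
        body_ref=body_ref,
        box_side=box,
        seed=seed,
        config=config,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# exact 1D reference systems
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PotentialSpec1D:
    """Analytic 1D potential used as a WHAM oracle.

    kinds: ``flat``; ``harmonic`` (params a, m); ``double_well`` (params
    barrier, m1, m2 — quartic with minima at m1 < m2 and central barrier
    height ``barrier``); ``tabulated`` (params x, u with strictly increasing
    x, linear interpolation).
    """

    kind: str
    params: dict = field(default_factory=dict)
    domain: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
            raise ValueError("domain must be a finite increasing interval")
        if self.kind not in ("flat", "harmonic", "double_well", "tabulated"):
            raise ValueError(f"unknown potential kind {self.kind!r}")
        if self.kind == "tabulated":
            x = np.asarray(self.params["x"], dtype=float)
            u = np.asarray(self.params["u"], dtype=float)
            if not (np.all(np.diff(x) > 0) and np.all(np.isfinite(u))):
                raise ValueError("tabulated potential needs strictly increasing x and finite u")

    def energy(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "flat":
            return np.zeros_like(x)
        if self.kind == "harmonic":
            return 0.5 * self.params["a"] * (x - self.params["m"]) ** 2
        if self.kind == "double_well":
            h = self.params["barrier"]
            m1, m2 = self.params["m1"], self.params["m2"]
            c = 0.5 * (m1 + m2)
            w = 0.5 * (m2 - m1)
            return h * ((x - c) ** 2 - w**2) ** 2 / w**4
        return np.interp(x, np.asarray(self.params["x"]), np.asarray(self.params["u"]))


def sample_boltzmann_1d(
    spec: PotentialSpec1D,
    bias: HarmonicBias | None,
    n: int,
    seed: int,
    temperature: float = 1.0,
    grid_points: int = 4001,
) -> np.ndarray:
    """I.i.d. draws from the normalized biased Boltzmann density.

    Inverse-CDF sampling on a fine grid over the potential's domain;
    deterministic for a given seed.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    lo, hi = spec.domain
    x = np.linspace(lo, hi, grid_points)
    u = spec.energy(x)
    if bias is not None:
        u = u + bias.energy(x)
    logw = -u / temperature
    logw -= logw.max()
    w = np.exp(logw)
    dz = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(x))])
    if not np.isfinite(dz[-1]) or dz[-1] <= 0:
        raise ValueError("biased Boltzmann density is not integrable on the domain")
    cdf = dz / dz[-1]
    # enforce strict monotonicity for the inverse interpolation
    cdf = np.maximum.accumulate(cdf + np.arange(grid_points) * 1e-15)
    rng = np.random.default_rng(seed)
    return np.interp(rng.random(n), cdf, x)


def exact_free_energy_1d(spec: PotentialSpec1D, bin_edges, temperature: float = 1.0):
    """Exact binned free energy F(bin) = -T ln ∫_bin exp(-U/T) dx.

    Returned unreferenced; apply :func:`dimerpmf.wham.zero_reference` to pin
    a zero.  Quadrature: 65-point trapezoid per bin.
    """
    from .wham import PMFProfile  # local import to avoid cycle at module load

    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 entries")
    f = np.empty(len(edges) - 1)
    for i in range(len(edges) - 1):
        xs = np.linspace(edges[i], edges[i + 1], 65)
        w = np.exp(-spec.energy(xs) / temperature)
        integral = np.trapezoid(w, xs)
        if integral <= 0:
            raise ValueError(f"bin {i} has zero Boltzmann measure")
        f[i] = -temperature * np.log(integral)
    return PMFProfile(edges=edges, free_energy=f, metadata={"source": "exact_free_energy_1d"})


# ---------------------------------------------------------------------------
# umbrella dataset generation
# ---------------------------------------------------------------------------


def contact_distance(config: ToyConfig, orientations: tuple[float, float]) -> float:
    """Smallest collinear COM separation at which the two rings do not overlap.

    Bisection on the minimal inter-ring particle distance; used to start
    compressed umbrella windows from a physical (non-interpenetrating)
    configuration and let the bias press the bodies together.
    """
    ref = config.body_reference()
    phis = _body_angles_from_orientations(orientations)
    ra = ref @ rotation_matrix(phis[0]).T
    rb = ref @ rotation_matrix(phis[1]).T

    def min_gap(d: float) -> float:
        delta = ra[:, None, :] - (rb[None, :, :] + np.array([d, 0.0]))
        return float(np.min(np.hypot(delta[..., 0], delta[..., 1]))) - config.sigma_rr

    lo, hi = 0.1, config.box_side / 2.0
    if min_gap(hi) < 0:
        raise ValueError("bodies overlap even at half the box size")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_gap(mid) >= 0:
            hi = mid
        else:
            lo = mid
    return hi


def _child_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


def generate_umbrella_dataset(
    system: ToyConfig | PotentialSpec1D,
    centers,
    k_umb: float,
    n_samples: int,
    seed: int,
    *,
    temperature: float = 1.0,
    k_rot: float = 50.0,
    rot_epsilon: float = 1e-4,
    orientations: tuple[float, float] = (0.0, 0.0),
    delipidated: bool = False,
    lipidated: bool = False,
    keep_lipids: bool = False,
) -> list[UmbrellaWindow]:
    """One umbrella window per bias center, with per-window derived seeds.

    For a :class:`PotentialSpec1D` the reaction-coordinate series are exact
    Boltzmann draws; for a :class:`ToyConfig` each window is a restrained
    two-protein toy simulation and the series is the minimum-image inter-COM
    separation.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        raise ValueError("centers must be non-empty")
    if not np.all(np.diff(centers) > 0):
        raise ValueError("centers must be strictly increasing")
    seeds = _child_seeds(seed, centers.size)
    windows: list[UmbrellaWindow] = []
    if isinstance(system, PotentialSpec1D):
        for c, s in zip(centers, seeds):
            bias = HarmonicBias(center=float(c), force_constant=k_umb)
            samples = sample_boltzmann_1d(system, bias, n_samples, s, temperature)
            windows.append(
                UmbrellaWindow(
                    bias=bias,
                    samples=samples,
                    temperature=temperature,
                    metadata={"seed": s, "delipidated": False},
                )
            )
        return windows
    if not isinstance(system, ToyConfig):
        raise TypeError("system must be a ToyConfig or PotentialSpec1D")
    config = system.replace(n_steps=n_samples * system.stride)
    body_ref = np.repeat(config.body_reference()[None], 2, axis=0)
    box = config.box_side
    d_touch = contact_distance(config, orientations)
    for c, s in zip(centers, seeds):
        bias = HarmonicBias(center=float(c), force_constant=k_umb)
        # compressed windows start at contact, pressed inward by the bias
        d_init = max(float(c), d_touch + 0.1)
        coms = np.array([[box / 2 - d_init / 2, box / 2], [box / 2 + d_init / 2, box / 2]])
        angles = _body_angles_from_orientations(orientations)
        rset = restraint_set_for_orientation(
            body_ref, coms, angles, k_rot, epsilon=rot_epsilon, umbrella=bias
        )
        traj = simulate_toy_membrane(
            config,
            rset,
            seed=s,
            n_proteins=2,
            orientations=orientations,
            initial_separation=d_init,
            delipidated=delipidated,
            lipidated=lipidated,
        )
        if not keep_lipids:
            # keep only the rigid-body series (all SASA analysis needs);
            # the lipid coordinates of every window would dominate memory
            traj = Trajectory(
                times=traj.times,
                lipid_xy=np.empty((traj.n_frames, 0, 2)),
                leaflet=np.empty(0, dtype=int),
                protein_com=traj.protein_com,
                protein_angle=traj.protein_angle,
                body_ref=traj.body_ref,
                box_side=traj.box_side,
                seed=traj.seed,
                config=traj.config,
                metadata=traj.metadata,
            )
        windows.append(
            UmbrellaWindow(
                bias=bias,
                samples=traj.separations(),
                temperature=config.temperature,
                metadata={
                    "seed": s,
                    "delipidated": bool(delipidated),
                    "lipidated": bool(lipidated),
                    "orientations": tuple(orientations),
                    "trajectory": traj,
                },
            )
        )
    return windows
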