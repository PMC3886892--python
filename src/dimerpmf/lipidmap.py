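"""Lipid-shell density analysis around a single protein and the
overlay-based prediction of restrained metastable separations.

The signature computation: accumulate the lipid density field in the frame
of a freely diffusing protein, project it along the direction the partner
protein would approach from, detect the annular shell peaks r_1 < r_2 < ...
and predict the inter-protein separations at which n = 1, 2, 3 lipids pack
optimally between the two proteins by overlaying the radial profile with
its x-reversed copy:

    n = 1 : first peak on first reversed peak        ->  s = 2 r_1
    n = 2 : first peak on second reversed peak       ->  s = r_1 + r_2
    n = 3 : (1st, 3rd) and (2nd, 2nd) pairs, least   ->  s = (r_1 + r_3 + 2 r_2) / 2
            squares over the two prescribed pairings

The predicted separation is the position of the reversed profile's origin
edge, i.e. where the second protein's centre of mass would sit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .geometry import minimum_image, planar_rotation_fit, rotation_matrix
from .toygen import Trajectory

__all__ = [
    "DensityMap2D",
    "RadialProfile",
    "PeakSet",
    "SeparationPrediction",
    "align_frames",
    "accumulate_density",
    "radial_projection",
    "mean_profile",
    "detect_peaks",
    "predict_separations",
]


@dataclass(frozen=True)
class DensityMap2D:
    """Square density grid centred on a protein's centre of mass.

    ``channels`` maps channel labels (e.g. leaflets) to accumulated counts
    on a (B, B) grid; cell [i, j] covers x in [x_i, x_i + bin), y likewise,
    with the protein COM at the grid centre.
    """

    side: float
    bin_size: float
    channels: dict
    n_frames: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    def total(self) -> np.ndarray:
        return sum(self.channels.values())

    def mean_density(self, channel: str = "both", per_area: bool = False) -> np.ndarray:
        """Mean counts per cell per frame; ``per_area`` converts to number
        density (counts per unit area per frame).  Raw counts are the
        default; normalization is opt-in."""
        counts = self.total() if channel == "both" else self.channels[channel]
        dens = counts / max(self.n_frames, 1)
        if per_area:
            dens = dens / (self.bin_size**2)
        return dens

    def write(self, path, channel: str = "both") -> None:
        import json

        header = {
            "side": self.side,
            "bin_size": self.bin_size,
            "n_frames": self.n_frames,
            "channel": channel,
            **{k: v for k, v in self.provenance.items() if isinstance(v, (int, float, str))},
        }
        with open(path, "w") as fh:
            fh.write("# dimerpmf density map " + json.dumps(header) + "\n")
            np.savetxt(fh, self.mean_density(channel), fmt="%.8g", delimiter="\t")


@dataclass(frozen=True)
class RadialProfile:
    """Mean density along lines emanating from the protein COM."""

    r: np.ndarray
    density: np.ndarray
    provenance: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# dimerpmf radial profile\n")
            for k, v in self.provenance.items():
                if isinstance(v, (int, float, str, tuple)):
                    fh.write(f"# {k} = {v}\n")
            fh.write("r\tdensity\n")
            for r, d in zip(self.r, self.density):
                fh.write(f"{r:.8g}\t{d:.8g}\n")


@dataclass(frozen=True)
class PeakSet:
    positions: np.ndarray  # strictly increasing
    heights: np.ndarray
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "heights", np.asarray(self.heights, dtype=float))
        if p.size > 1 and not np.all(np.diff(p) > 0):
            raise ValueError("peak positions must be strictly increasing")


@dataclass(frozen=True)
class SeparationPrediction:
    n_intervening_lipids: int
    separation: float
    matched_pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.n_intervening_lipids < 1:
            raise ValueError("n_intervening_lipids must be >= 1")
        if self.separation <= 0:
            raise ValueError("predicted separation must be > 0")


def align_frames(trajectory: Trajectory, body: int = 0, reference_frame: int = 0) -> Trajectory:
    """Rigidly transform every frame so the chosen protein superposes on its
    pose in ``reference_frame``; lipids are carried by the same transform.

    The per-frame transform is the least-squares planar rotation (about the
    protein COM) plus the COM translation; a reflection-optimal fit raises.
    Lipid coordinates are re-expressed through the minimum image relative to
    the protein before transforming, so periodic wrapping cannot tear the
    density field.
    """
    if body >= trajectory.n_proteins:
        raise ValueError(f"body {body} not present")
    if not (0 <= reference_frame < trajectory.n_frames):
        raise ValueError("reference frame not in trajectory")
    box = trajectory.box_side
    ref_ring = trajectory.ring_positions(reference_frame)[body]
    ref_com = trajectory.protein_com[reference_frame, body]
    new_lip = np.empty_like(trajectory.lipid_xy)
    new_com = np.empty_like(trajectory.protein_com)
    new_ang = np.empty_like(trajectory.protein_angle)
    for i in range(trajectory.n_frames):
        ring = trajectory.ring_positions(i)[body]
        com = trajectory.protein_com[i, body]
        dphi = planar_rotation_fit(ref_ring - ref_com, ring - com)
        rot = rotation_matrix(-dphi)
        rel = minimum_image(trajectory.lipid_xy[i] - com, box)
        new_lip[i] = ref_com + rel @ rot.T
        for p in range(trajectory.n_proteins):
            relp = minimum_image(trajectory.protein_com[i, p] - com, box)
            new_com[i, p] = ref_com + rot @ relp
            new_ang[i, p] = trajectory.protein_angle[i, p] - dphi
    return Trajectory(
        times=trajectory.times.copy(),
        lipid_xy=new_lip,
        leaflet=trajectory.leaflet,
        protein_com=new_com,
        protein_angle=new_ang,
        body_ref=trajectory.body_ref,
        box_side=box,
        seed=trajectory.seed,
        config=trajectory.config,
        metadata={**trajectory.metadata, "aligned_to": (body, reference_frame)},
    )


def accumulate_density(
    trajectory: Trajectory,
    region_side: float = 6.0,
    bin_size: float | None = None,
    channels: tuple[str, ...] = ("upper", "lower"),
    body: int = 0,
    stride: int = 1,
) -> DensityMap2D:
    """Accumulate per-channel lipid counts on a square grid around a protein.

    ``bin_size`` must divide ``region_side``; default region_side / 120.
    Frames (taken at ``stride``) are weighted equally.  The grid is built
    from minimum-image displacements to the protein COM, so the trajectory
    need not be pre-wrapped (but should be pre-aligned for a meaningful
    orientation-resolved map).
    """
    if trajectory.n_frames == 0 or trajectory.n_lipids == 0:
        raise ValueError("empty trajectory")
    if bin_size is None:
        bin_size = region_side / 120.0
    nb = region_side / bin_size
    if abs(nb - round(nb)) > 1e-9:
        raise ValueError("bin_size must divide region_side")
    nb = int(round(nb))
    edges = np.linspace(-region_side / 2.0, region_side / 2.0, nb + 1)
    leaf_names = np.where(trajectory.leaflet == 0, "upper", "lower")
    sel_masks = {}
    for ch in channels:
        if ch == "both":
            sel_masks[ch] = np.ones(trajectory.n_lipids, dtype=bool)
        elif ch in ("upper", "lower"):
            sel_masks[ch] = leaf_names == ch
        else:
            raise ValueError(f"unknown channel {ch!r}")
    counts = {ch: np.zeros((nb, nb)) for ch in channels}
    frames = range(0, trajectory.n_frames, stride)
    n_used = 0
    box = trajectory.box_side
    for i in frames:
        rel = minimum_image(trajectory.lipid_xy[i] - trajectory.protein_com[i, body], box)
        for ch, mask in sel_masks.items():
            h, _, _ = np.histogram2d(rel[mask, 0], rel[mask, 1], bins=(edges, edges))
            counts[ch] += h
        n_used += 1
    return DensityMap2D(
        side=region_side,
        bin_size=bin_size,
        channels=counts,
        n_frames=n_used,
        provenance={"body": body, "stride": stride, "n_frames": n_used},
    )


def radial_projection(
    density_map: DensityMap2D,
    direction: float,
    half_window: float = 15.0,
    line_spacing: float = 1.0,
    line_length: float = 4.0,
    channel: str = "both",
    radial_step: float | None = None,
    per_area: bool = False,
) -> RadialProfile:
    """Project the 2D density onto lines emanating from the COM.

    Lines at ``direction ± k·line_spacing`` (degrees) within ``half_window``
    sample the map by bilinear interpolation at regular radii and are
    averaged into one profile.  Angles follow the project convention
    (counter-clockwise, extracellular view, degrees).
    """
    if half_window <= 0:
        raise ValueError("half_window must be > 0")
    if line_spacing > 2.0 * half_window:
        raise ValueError("line spacing must be <= the full angular window")
    if line_length > density_map.side / 2.0 + 1e-9:
        raise ValueError("line length exceeds the density region")
    if radial_step is None:
        radial_step = density_map.bin_size / 2.0
    dens = density_map.mean_density(channel, per_area=per_area)
    nb = density_map.n_bins
    r = np.arange(radial_step / 2.0, line_length, radial_step)
    offsets = np.arange(0.0, half_window + 1e-9, line_spacing)
    angles = np.radians(direction + np.concatenate([-offsets[:0:-1], offsets]))
    acc = np.zeros_like(r)
    for th in angles:
        x = r * np.cos(th)
        y = r * np.sin(th)
        # map (x, y) to fractional grid indices; cell centers at (i + 0.5)*bin - side/2
        ix = (x + density_map.side / 2.0) / density_map.bin_size - 0.5
        iy = (y + density_map.side / 2.0) / density_map.bin_size - 0.5
        acc += ndimage.map_coordinates(
            dens, np.vstack([ix, iy]), order=1, mode="nearest"
        )
    prof = acc / len(angles)
    return RadialProfile(
        r=r,
        density=prof,
        provenance={
            "direction": direction,
            "half_window": half_window,
            "line_spacing": line_spacing,
            "line_length": line_length,
            "n_lines": int(len(angles)),
            "channel": channel,
            "per_area": per_area,
        },
    )


def mean_profile(profiles) -> RadialProfile:
    """Unweighted arithmetic mean of radial profiles with identical bins."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    r0 = profiles[0].r
    for p in profiles[1:]:
        if p.r.shape != r0.shape or not np.allclose(p.r, r0):
            raise ValueError("profiles have mismatched radial bins")
    dens = np.mean([p.density for p in profiles], axis=0)
    return RadialProfile(
        r=r0.copy(),
        density=dens,
        provenance={"mean_of": [p.provenance.get("channel", "?") for p in profiles]},
    )


def detect_peaks(
    profile: RadialProfile, min_prominence: float = 0.05, min_separation: float = 0.2
) -> PeakSet:
    """Shell peaks of a radial profile with sub-bin parabolic refinement."""
    if profile.r.size == 0:
        raise ValueError("empty profile")
    dr = float(np.mean(np.diff(profile.r))) if profile.r.size > 1 else 1.0
    distance = max(int(np.round(min_separation / dr)), 1)
    idx, props = find_peaks(profile.density, prominence=min_prominence, distance=distance)
    positions = []
    heights = []
    for i in idx:
        if 0 < i < profile.r.size - 1:
            y0, y1, y2 = profile.density[i - 1 : i + 2]
            denom = y0 - 2.0 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-300 else 0.0
            shift = float(np.clip(shift, -0.5, 0.5))
            positions.append(profile.r[i] + shift * dr)
            heights.append(y1 - 0.25 * (y0 - y2) * shift)
        else:
            positions.append(float(profile.r[i]))
            heights.append(float(profile.density[i]))
    return PeakSet(
        positions=np.array(positions),
        heights=np.array(heights),
        parameters={"min_prominence": min_prominence, "min_separation": min_separation},
    )


def predict_separations(peaks: PeakSet, n_intervening: int) -> SeparationPrediction:
    """Predict the optimally packed inter-protein separation for
    ``n_intervening`` lipids from the shell-peak positions.

    The radial profile is conceptually overlaid with its x-reversed copy
    whose origin sits at trial separation s (reversed peak j lands at
    s - r_j); s is chosen so the prescribed peak pairs coincide.  The
    pairings are defined for n = 1, 2, 3 only; the n = 3 case is
    overdetermined and resolved by least squares over its two pairs.
    """
    r = peaks.positions
    if n_intervening < 1:
        raise ValueError("n_intervening must be >= 1")
    if n_intervening > 3:
        raise ValueError("peak pairings are defined only up to 3 intervening lipids")
    if r.size < n_intervening:
        raise ValueError(
            f"need at least {n_intervening} peaks for n={n_intervening}, have {r.size}"
        )
    if n_intervening == 1:
        s = 2.0 * r[0]
        pairs = ((1, 1),)
    elif n_intervening == 2:
        s = r[0] + r[1]
        pairs = ((1, 2),)
    else:
        # pairs (1,3) and (2,2): s - r_3 = r_1 and s - r_2 = r_2; least squares
        s = 0.5 * ((r[0] + r[2]) + 2.0 * r[1])
        pairs = ((1, 3), (2, 2))
    return SeparationPrediction(
        n_intervening_lipids=n_intervening, separation=float(s), matched_pairs=pairs
    )
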