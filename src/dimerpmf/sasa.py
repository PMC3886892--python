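"""Probe-accessible surface area and buried-area analysis.

Areas are computed by a deterministic Shrake–Rupley construction: each
particle is a sphere whose probe-inflated surface is sampled by a fixed
Fibonacci point set; the accessible fraction of test points times the
inflated sphere's area gives that particle's contribution.  The toy bodies
are rings of spheres at their in-plane coordinates with a fixed
out-of-plane coordinate (single layer), and the probe plays the role of a
lipid: the buried area

    buried(d) = area_A(d) + area_B(d) - area_complex(d)

is the lipid-inaccessible interface created on association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SurfaceAreaRecord",
    "DepthAreaPoint",
    "fibonacci_sphere",
    "accessible_area",
    "buried_area",
    "buried_area_profile",
    "area_at_minimum",
    "depth_vs_area",
    "write_pdb",
]


@dataclass(frozen=True)
class SurfaceAreaRecord:
    separation: float
    area_a: float
    area_b: float
    area_complex: float
    buried: float
    probe_radius: float
    n_frames: int = 1


@dataclass(frozen=True)
class DepthAreaPoint:
    label: str
    buried_area: float
    well_depth: float


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere point set (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def accessible_area(
    centers: np.ndarray,
    radii: np.ndarray | float,
    probe_radius: float,
    n_points: int = 960,
) -> float:
    """Shrake–Rupley probe-accessible area of a set of spheres.

    For each sphere, the fraction of test points on its probe-inflated
    surface not inside any other inflated sphere, times that sphere's
    inflated area.  Deterministic for a fixed point count.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n = centers.shape[0]
    if centers.shape[1] != 3:
        raise ValueError("centers must be (N, 3)")
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (n,)).copy()
    if np.any(radii <= 0) or probe_radius < 0:
        raise ValueError("radii must be > 0 and probe_radius >= 0")
    if n > 1:
        d2 = np.sum((centers[:, None] - centers[None]) ** 2, axis=-1)
        if np.min(d2[~np.eye(n, dtype=bool)]) < 1e-16:
            raise ValueError("coincident particle centers")
    sphere = fibonacci_sphere(n_points)
    inflated = radii + probe_radius
    total = 0.0
    for i in range(n):
        pts = centers[i] + inflated[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            cutoff = inflated[i] + inflated[j]
            if np.sum((centers[j] - centers[i]) ** 2) >= cutoff * cutoff:
                continue
            d2 = np.sum((pts - centers[j]) ** 2, axis=1)
            accessible &= d2 >= inflated[j] ** 2
            if not accessible.any():
                break
        total += accessible.mean() * 4.0 * np.pi * inflated[i] ** 2
    return float(total)


def _ring_spheres(ring_xy: np.ndarray) -> np.ndarray:
    """Lift in-plane ring coordinates to 3D (single layer at z = 0)."""
    xy = np.asarray(ring_xy, dtype=float)
    return np.column_stack([xy, np.zeros(len(xy))])


def buried_area(
    ring_a: np.ndarray,
    ring_b: np.ndarray,
    particle_radius: float,
    probe_radius: float,
    n_points: int = 960,
    separation: float | None = None,
) -> SurfaceAreaRecord:
    """Buried (probe-inaccessible) area of a two-body configuration.

    ``buried = area_A + area_B - area_complex`` on a common probe.
    """
    a3 = _ring_spheres(ring_a)
    b3 = _ring_spheres(ring_b)
    area_a = accessible_area(a3, particle_radius, probe_radius, n_points)
    area_b = accessible_area(b3, particle_radius, probe_radius, n_points)
    area_ab = accessible_area(np.vstack([a3, b3]), particle_radius, probe_radius, n_points)
    if separation is None:
        separation = float(np.linalg.norm(a3.mean(axis=0) - b3.mean(axis=0)))
    return SurfaceAreaRecord(
        separation=separation,
        area_a=area_a,
        area_b=area_b,
        area_complex=area_ab,
        buried=area_a + area_b - area_ab,
        probe_radius=probe_radius,
    )


def buried_area_profile(
    window_trajectories,
    particle_radius: float,
    probe_radius: float,
    minimum_location: float,
    n_points: int = 960,
    frame_stride: int = 1,
) -> pd.DataFrame:
    """Frame-averaged buried area per window, versus distance from the PMF minimum.

    ``window_trajectories`` is an iterable of (window_center, Trajectory)
    pairs ordered by separation; the abscissa is window_center minus the
    PMF minimum location (removing the protein-radius offset between
    orientations), and dispersion is the standard deviation over frames.
    """
    if minimum_location is None or not np.isfinite(minimum_location):
        raise ValueError("a finite PMF minimum location is required")
    rows = []
    mono_area: dict[int, float] = {}
    cutoff = None
    for center, traj in window_trajectories:
        if traj.n_proteins != 2:
            raise ValueError("buried-area profile needs two-protein trajectories")
        # a rigid body's isolated area is pose-independent: compute once
        for p in (0, 1):
            if p not in mono_area:
                rings = traj.ring_positions(0)
                mono_area[p] = accessible_area(
                    _ring_spheres(rings[p]), particle_radius, probe_radius, n_points
                )
        vals = []
        for i in range(0, traj.n_frames, frame_stride):
            rings = traj.ring_positions(i)
            if cutoff is None:
                cutoff = 2.0 * (particle_radius + probe_radius)
            gap2 = np.min(
                np.sum((rings[0][:, None] - rings[1][None]) ** 2, axis=-1)
            )
            if gap2 > cutoff * cutoff:
                # no inflated sphere of one body can exclude a point of the
                # other: area_complex = area_A + area_B exactly, buried = 0
                vals.append(0.0)
                continue
            a3 = _ring_spheres(rings[0])
            b3 = _ring_spheres(rings[1])
            area_ab = accessible_area(
                np.vstack([a3, b3]), particle_radius, probe_radius, n_points
            )
            vals.append(mono_area[0] + mono_area[1] - area_ab)
        vals = np.asarray(vals)
        rows.append(
            {
                "window_center": float(center),
                "distance_from_minimum": float(center) - float(minimum_location),
                "mean_buried": float(vals.mean()),
                "std_buried": float(vals.std(ddof=0)),
                "n_frames": len(vals),
            }
        )
    return pd.DataFrame(rows)


def area_at_minimum(profile: pd.DataFrame, fit_half_range: float = 0.3):
    """Buried area at the PMF minimum from a straight-line fit near it.

    Ordinary least squares of mean buried area on distance-from-minimum over
    ``|x| <= fit_half_range``; returns (area, one_sided_flag) where the flag
    marks an extrapolated (all points on one side of zero) fit.
    """
    x = profile["distance_from_minimum"].to_numpy()
    y = profile["mean_buried"].to_numpy()
    sel = np.abs(x) <= fit_half_range + 1e-12
    if sel.sum() < 3:
        raise ValueError("fewer than 3 points within the fit range")
    xs, ys = x[sel], y[sel]
    slope, intercept = np.polyfit(xs, ys, 1)
    one_sided = bool(np.all(xs > 0) or np.all(xs < 0))
    return float(intercept), one_sided


def depth_vs_area(points) -> tuple[float, float, float]:
    """OLS of well depth on buried area across orientation configurations.

    Returns (slope, intercept, pearson_r).  Deeper wells at larger buried
    area give a negative correlation (depths are negative energies).
    """
    points = list(points)
    if len(points) < 3:
        raise ValueError("need at least 3 configurations")
    area = np.array([p.buried_area for p in points])
    depth = np.array([p.well_depth for p in points])
    if np.ptp(area) < 1e-12:
        raise ValueError("degenerate input: identical buried areas")
    from scipy.stats import linregress

    fit = linregress(area, depth)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def write_pdb(path, ring_xy_list, particle_radius: float) -> None:
    """Export toy bodies as pseudo-atom spheres (radius in the B-factor column).

    A documented convenience for cross-checking against third-party SASA
    tools; coordinates are toy units written as-is.
    """
    with open(path, "w") as fh:
        serial = 1
        for chain, ring in zip("ABCDEFGH", ring_xy_list):
            for x, y in np.asarray(ring, dtype=float):
                fh.write(
                    f"ATOM  {serial:5d}  C   TOY {chain}{serial % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{0.0:8.3f}{1.00:6.2f}{particle_radius:6.2f}"
                    f"          C  \n"
                )
                serial += 1
        fh.write("END\n")
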