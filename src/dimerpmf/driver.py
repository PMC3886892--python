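"""End-to-end experiment recipes: four orientational configurations ->
PMFs -> minima/barriers -> lipid-shell predictions -> buried-area analysis.

The canonical plan mirrors the study design: umbrella windows along the
inter-COM separation for four restrained orientation pairs (wide-wide
parallel and anti-parallel, wide-narrow, narrow-narrow), WHAM per
configuration, quadratic minima, a single-protein run for the lipid-shell
overlay predictions, per-window buried-area profiles, and the well-depth
versus buried-area regression.  Everything is seeded from one master seed
and every output carries a provenance header; re-running a plan reproduces
its manifest bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import landscape, lipidmap, sasa
from .toygen import ToyConfig, contact_distance, generate_umbrella_dataset, simulate_toy_membrane
from .wham import UmbrellaPMF

__all__ = [
    "ExperimentPlan",
    "canonical_orientations",
    "run_experiment",
    "run_unrestrained_control",
]

log = logging.getLogger("dimerpmf")


def canonical_orientations() -> tuple[tuple[str, float, float], ...]:
    """The four canonical orientation presets (label, theta_A, theta_B).

    Angles in degrees, 0 = wide face toward the partner: wide-wide parallel,
    wide-wide anti-parallel, wide-narrow, narrow-narrow.
    """
    return (
        ("wide_wide_parallel", 0.0, 0.0),
        ("wide_wide_antiparallel", 0.0, 180.0),
        ("wide_narrow", 0.0, 90.0),
        ("narrow_narrow", 90.0, 90.0),
    )


@dataclass(frozen=True)
class ExperimentPlan:
    """Everything needed to reproduce one full landscape experiment."""

    toy: ToyConfig = field(default_factory=ToyConfig)
    orientation_configs: tuple = field(default_factory=canonical_orientations)
    window_centers: tuple = ()
    fine_window_offsets: tuple = ()
    k_umb: float = 30.0
    k_umb_fine: float = 200.0
    lipidated_offsets: tuple = ()
    k_rot: float = 50.0
    rot_epsilon: float = 1e-4
    n_samples_per_window: int = 1600
    bin_width: float = 0.05
    reference_separation: float = 7.0
    prominence: float = 0.25
    barrier_range: tuple[float, float] = (4.6, 6.6)
    probe_radius: float | None = None
    sasa_fit_half_range: float = 0.3
    sasa_frame_stride: int = 200
    sasa_n_points: int = 480
    density_n_samples: int = 4000
    density_region_side: float = 7.0
    density_direction: float = 90.0
    density_half_window: float = 15.0
    density_line_spacing: float = 1.0
    density_line_length: float = 3.5
    peak_min_prominence: float = 0.05  # number-density units (per-area profile)
    peak_min_separation: float = 0.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.window_centers:
            centers = np.round(np.arange(2.6, 7.0 + 1e-9, 0.2), 10)
            object.__setattr__(self, "window_centers", tuple(centers))
        if not self.fine_window_offsets:
            # finer, stiffer windows across the lipidation/delipidation zone,
            # placed relative to each orientation's contact distance
            # span contact through the one- and two-lipid packing zone;
            # 0.05 spacing across the steep contact flank (where the mean
            # force shifts the biased distribution by more than 0.1 per
            # window), 0.1 beyond it
            offsets = np.concatenate(
                [
                    np.arange(-0.2, 0.45 + 1e-9, 0.05),
                    np.arange(0.5, 2.4 + 1e-9, 0.1),
                ]
            )
            object.__setattr__(self, "fine_window_offsets", tuple(np.round(offsets, 10)))
        if not self.lipidated_offsets:
            # duplicated windows across the bistable lipidation zone, started
            # with a lipid seeded at the interface so both occupation states
            # are pooled into WHAM
            object.__setattr__(
                self, "lipidated_offsets", tuple(np.round(np.arange(0.4, 2.0 + 1e-9, 0.2), 10))
            )
        c = np.asarray(self.window_centers)
        if c.size == 0 or not np.all(np.diff(c) > 0):
            raise ValueError("window grid must be non-empty and strictly increasing")
        if not self.orientation_configs:
            raise ValueError("at least one orientation configuration required")

    @property
    def effective_probe_radius(self) -> float:
        # probe = one "lipid": twice the body-particle radius, as for a
        # coarse-grained lipid-sized probe
        if self.probe_radius is not None:
            return self.probe_radius
        return self.toy.ring_particle_diameter

    def to_mapping(self) -> dict:
        d = dataclasses.asdict(self)
        d["toy"] = self.toy.to_mapping()
        d["effective_probe_radius"] = self.effective_probe_radius
        return d


def _config_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


def _analyze_configuration(plan: ExperimentPlan, label, theta, seed, k_rot):
    d_touch = contact_distance(plan.toy, theta)
    fine = np.round(d_touch + np.asarray(plan.fine_window_offsets, dtype=float), 10)
    fine = fine[(fine > 0) & (fine <= plan.reference_separation)]
    coarse = np.asarray(plan.window_centers, dtype=float)
    coarse = coarse[coarse >= d_touch - 0.5]
    if fine.size:
        # keep coarse windows outside the (denser, stiffer) fine grid's span
        coarse = coarse[(coarse < fine.min() - 0.05) | (coarse > fine.max() - 0.05)]
    log.info(
        "configuration %s: contact %.2f, %d coarse + %d fine windows",
        label, d_touch, coarse.size, fine.size,
    )
    windows = generate_umbrella_dataset(
        plan.toy,
        coarse,
        plan.k_umb,
        plan.n_samples_per_window,
        seed,
        k_rot=k_rot,
        rot_epsilon=plan.rot_epsilon,
        orientations=theta,
    )
    if fine.size:
        windows += generate_umbrella_dataset(
            plan.toy,
            fine,
            plan.k_umb_fine,
            plan.n_samples_per_window,
            seed + 1_000_003,
            k_rot=k_rot,
            rot_epsilon=plan.rot_epsilon,
            orientations=theta,
        )
    lipidated = np.round(d_touch + np.asarray(plan.lipidated_offsets, dtype=float), 10)
    lipidated = lipidated[(lipidated > 0) & (lipidated <= plan.reference_separation)]
    if lipidated.size:
        windows += generate_umbrella_dataset(
            plan.toy,
            lipidated,
            plan.k_umb_fine,
            plan.n_samples_per_window,
            seed + 2_000_003,
            k_rot=k_rot,
            rot_epsilon=plan.rot_epsilon,
            orientations=theta,
            lipidated=True,
        )
    model = UmbrellaPMF(windows, bin_width=plan.bin_width)
    res = model.fit(reference_separation=plan.reference_separation)
    # the outermost bins beyond the last window center are sparse
    # extrapolation territory; minima are only trusted inside the scan
    minima = [
        m
        for m in res.minima(prominence=plan.prominence)
        if m.location <= plan.reference_separation - 0.3
    ]
    barrier = res.barrier(
        (max(plan.barrier_range[0], d_touch + 0.4), plan.barrier_range[1])
    )
    depth = min((m.depth for m in minima), default=np.nan)
    min_loc = (
        min(minima, key=lambda m: m.depth).location if minima else np.nan
    )
    particle_radius = plan.toy.ring_particle_diameter / 2.0
    trajs = [(w.bias.center, w.metadata["trajectory"]) for w in windows]
    profile = sasa.buried_area_profile(
        trajs,
        particle_radius,
        plan.effective_probe_radius,
        minimum_location=min_loc,
        n_points=plan.sasa_n_points,
        frame_stride=plan.sasa_frame_stride,
    )
    area_min, one_sided = sasa.area_at_minimum(profile, plan.sasa_fit_half_range)
    return {
        "label": label,
        "orientations": theta,
        "seed": seed,
        "results": res,
        "minima": minima,
        "barrier": barrier,
        "well_depth": float(depth),
        "minimum_location": float(min_loc),
        "buried_area_profile": profile,
        "buried_area_at_minimum": float(area_min),
        "area_fit_one_sided": one_sided,
    }


def single_protein_shell_analysis(plan: ExperimentPlan, seed: int):
    """Lipid-shell density around one freely diffusing protein and the
    overlay predictions for 1-3 intervening lipids."""
    cfg = plan.toy.replace(n_steps=plan.density_n_samples * plan.toy.stride)
    traj = simulate_toy_membrane(cfg, None, seed=seed, n_proteins=1)
    aligned = lipidmap.align_frames(traj, body=0, reference_frame=0)
    dmap = lipidmap.accumulate_density(
        aligned,
        region_side=plan.density_region_side,
        channels=("upper", "lower"),
    )
    profiles = [
        lipidmap.radial_projection(
            dmap,
            plan.density_direction,
            half_window=plan.density_half_window,
            line_spacing=plan.density_line_spacing,
            line_length=plan.density_line_length,
            channel=ch,
            per_area=True,
        )
        for ch in ("upper", "lower")
    ]
    prof = lipidmap.mean_profile(profiles)
    peaks = lipidmap.detect_peaks(
        prof,
        min_prominence=plan.peak_min_prominence,
        min_separation=plan.peak_min_separation,
    )
    predictions = {}
    for n in (1, 2, 3):
        if peaks.positions.size >= n:
            predictions[n] = lipidmap.predict_separations(peaks, n)
    return {
        "trajectory_seed": seed,
        "density_map": dmap,
        "profile": prof,
        "peaks": peaks,
        "predictions": predictions,
    }


def run_experiment(plan: ExperimentPlan, outdir=None) -> dict:
    """Execute the full pipeline for every orientation configuration.

    Returns a bundle with per-configuration PMF results, minima, barriers,
    buried-area tables, the single-protein shell analysis with separation
    predictions, and the depth-versus-area regression.  If ``outdir`` is
    given, all tables are written as TSV with provenance headers plus a
    machine-readable ``manifest.json``.
    """
    seeds = _config_seeds(plan.master_seed, len(plan.orientation_configs) + 1)
    configs = []
    for (label, ta, tb), seed in zip(plan.orientation_configs, seeds):
        try:
            configs.append(_analyze_configuration(plan, label, (ta, tb), seed, plan.k_rot))
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"stage 'configuration {label}' failed: {exc}") from exc
    try:
        shell = single_protein_shell_analysis(plan, seeds[-1])
    except Exception as exc:
        raise RuntimeError(f"stage 'single-protein shell analysis' failed: {exc}") from exc

    points = [
        sasa.DepthAreaPoint(c["label"], c["buried_area_at_minimum"], c["well_depth"])
        for c in configs
        if np.isfinite(c["well_depth"])
    ]
    depth_area = None
    if len(points) >= 3:
        try:
            depth_area = sasa.depth_vs_area(points)
        except ValueError:
            depth_area = None

    bundle = {
        "plan": plan,
        "configurations": configs,
        "shell": shell,
        "depth_area_points": points,
        "depth_vs_area": depth_area,
    }
    if outdir is not None:
        _write_bundle(plan, bundle, outdir)
    return bundle


def run_unrestrained_control(plan: ExperimentPlan, outdir=None) -> dict:
    """The same pipeline with the rotational restraint switched off
    (k_rot = 0) for both proteins; wide-wide starting orientation."""
    seeds = _config_seeds(plan.master_seed, len(plan.orientation_configs) + 2)
    cfg = _analyze_configuration(
        plan, "unrestrained_control", (0.0, 0.0), seeds[-1], k_rot=0.0
    )
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        _write_config_outputs(plan, cfg, outdir)
        manifest = {
            "plan": plan.to_mapping(),
            "control": {"seed": cfg["seed"], "k_rot": 0.0},
        }
        with open(os.path.join(outdir, "control_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonable)
    return cfg


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_config_outputs(plan: ExperimentPlan, c: dict, outdir) -> list[str]:
    files = []
    head = {"label": c["label"], "seed": c["seed"], "orientations": c["orientations"],
            "nm_per_unit": plan.toy.nm_per_unit}
    pmf_path = os.path.join(outdir, f"pmf_{c['label']}.tsv")
    c["results"].profile.to_tsv(pmf_path, extra_header=head)
    files.append(pmf_path)
    min_path = os.path.join(outdir, f"minima_{c['label']}.tsv")
    landscape.write_minima_tsv(min_path, c["minima"], provenance={**head, "input": pmf_path})
    files.append(min_path)
    sasa_path = os.path.join(outdir, f"buried_area_{c['label']}.tsv")
    with open(sasa_path, "w") as fh:
        fh.write("# dimerpmf buried-area profile\n")
        for k, v in head.items():
            fh.write(f"# {k} = {v}\n")
        fh.write(f"# probe_radius = {plan.effective_probe_radius}\n")
        c["buried_area_profile"].to_csv(fh, sep="\t", index=False)
    files.append(sasa_path)
    return files


def _write_bundle(plan: ExperimentPlan, bundle: dict, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"plan": plan.to_mapping(), "files": [], "seeds": {}}
    for c in bundle["configurations"]:
        manifest["files"] += _write_config_outputs(plan, c, outdir)
        manifest["seeds"][c["label"]] = c["seed"]
    shell = bundle["shell"]
    prof_path = os.path.join(outdir, "shell_profile.tsv")
    shell["profile"].to_tsv(prof_path)
    manifest["files"].append(prof_path)
    map_path = os.path.join(outdir, "density_map.tsv")
    shell["density_map"].write(map_path)
    manifest["files"].append(map_path)
    manifest["seeds"]["single_protein"] = shell["trajectory_seed"]
    manifest["predictions"] = {
        str(n): p.separation for n, p in shell["predictions"].items()
    }
    manifest["shell_peaks"] = shell["peaks"].positions.tolist()
    manifest["well_depths"] = {
        c["label"]: c["well_depth"] for c in bundle["configurations"]
    }
    manifest["buried_area_at_minimum"] = {
        c["label"]: c["buried_area_at_minimum"] for c in bundle["configurations"]
    }
    if bundle["depth_vs_area"] is not None:
        slope, intercept, r = bundle["depth_vs_area"]
        manifest["depth_vs_area"] = {"slope": slope, "intercept": intercept, "pearson_r": r}
    manifest["files"] = sorted(manifest["files"])
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonable)
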