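"""Quantitative anatomy of a PMF: minima, well depth and the outer barrier.

Local minima are discrete bins strictly lower than both neighbours, filtered
by prominence; each retained candidate is refined by a least-squares
parabola over a small window, giving a sub-bin vertex location and depth.
The outer barrier — the point where the lipid shells of the two proteins
begin to overlap — is the highest local maximum in a declared search range
beyond the outermost minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelextrema, peak_prominences

from .wham import PMFProfile

__all__ = [
    "MinimumRecord",
    "BarrierRecord",
    "CurvatureError",
    "find_local_minima",
    "fit_minima",
    "quadratic_fit_minimum",
    "well_depth",
    "find_barrier",
]


class CurvatureError(ValueError):
    """A quadratic fit produced non-positive curvature: not a minimum at this scale."""


@dataclass(frozen=True)
class MinimumRecord:
    location: float
    depth: float
    curvature: float
    fit_window: tuple[float, float]
    classification: str  # "global" or "local"
    location_sensitivity: float = float("nan")  # |Δlocation| for fit window ±1 bin


@dataclass(frozen=True)
class BarrierRecord:
    location: float
    height: float


def _supported(pmf: PMFProfile) -> tuple[np.ndarray, np.ndarray]:
    mask = pmf.support
    return pmf.centers[mask], pmf.free_energy[mask]


def find_local_minima(pmf: PMFProfile, prominence_threshold: float = 0.25) -> np.ndarray:
    """Indices (into the supported bins) of prominent discrete local minima.

    A candidate is an interior bin strictly lower than both neighbours whose
    prominence (computed on the negated profile, as for peaks) reaches the
    threshold.  Sorted by location; may be empty.
    """
    _, f = _supported(pmf)
    if f.size < 3:
        raise ValueError("need at least 3 supported bins")
    cand = argrelextrema(f, np.less)[0]
    if cand.size == 0:
        return cand
    prom = peak_prominences(-f, cand)[0]
    return cand[prom >= prominence_threshold]


def quadratic_fit_minimum(
    pmf: PMFProfile, candidate_index: int, half_window: float | None = None
) -> MinimumRecord:
    """Refine a discrete minimum by a least-squares parabola.

    ``half_window`` is in reaction-coordinate units; default two bins on
    each side of the candidate.  The vertex abscissa (sub-bin resolution) is
    the reported location; fits with non-positive curvature, or vertices
    escaping the fit window, are rejected.  The record also reports how much
    the location moves when the window grows/shrinks by one bin.
    """
    x, f = _supported(pmf)
    width = pmf.bin_width
    if half_window is None:
        half_window = 2.0 * width

    def _fit(hw: float):
        sel = np.abs(x - x[candidate_index]) <= hw + 1e-12
        if sel.sum() < 3:
            raise ValueError("fewer than 3 bins inside the fit window")
        a, b, c = np.polyfit(x[sel], f[sel], 2)
        if a <= 0:
            raise CurvatureError(
                f"fitted curvature {2 * a:.3g} <= 0 around x={x[candidate_index]:.4g}"
            )
        loc = -b / (2.0 * a)
        lo, hi = x[sel][0], x[sel][-1]
        if not (lo <= loc <= hi):
            raise CurvatureError(f"fitted vertex {loc:.4g} escapes the window [{lo:.4g}, {hi:.4g}]")
        return loc, float(np.polyval([a, b, c], loc)), 2.0 * a, (float(lo), float(hi))

    loc, depth, curv, window = _fit(half_window)
    sens = np.nan
    deltas = []
    for hw in (half_window - width, half_window + width):
        if hw >= 1.5 * width:
            try:
                deltas.append(abs(_fit(hw)[0] - loc))
            except (ValueError, CurvatureError):
                pass
    if deltas:
        sens = float(max(deltas))
    return MinimumRecord(
        location=float(loc),
        depth=float(depth),
        curvature=float(curv),
        fit_window=window,
        classification="local",
        location_sensitivity=sens,
    )


def fit_minima(pmf: PMFProfile, prominence: float = 0.25, half_window: float | None = None):
    """All prominent minima refined by quadratic fits, with the deepest
    classified ``global``; candidates whose fits are rejected (non-positive
    curvature, runaway vertex) are skipped."""
    return _classified_minima(pmf, prominence, half_window)


def _classified_minima(pmf: PMFProfile, prominence: float, half_window: float | None = None):
    idx = find_local_minima(pmf, prominence)
    records = []
    for i in idx:
        try:
            records.append(quadratic_fit_minimum(pmf, int(i), half_window))
        except CurvatureError:
            continue
    if records:
        deepest = min(range(len(records)), key=lambda j: records[j].depth)
        records = [
            MinimumRecord(
                r.location,
                r.depth,
                r.curvature,
                r.fit_window,
                "global" if j == deepest else "local",
                r.location_sensitivity,
            )
            for j, r in enumerate(records)
        ]
    return records


def well_depth(pmf: PMFProfile, prominence: float = 0.25) -> float:
    """Depth (negative energy, relative to the zero reference) of the deepest fitted minimum."""
    if pmf.reference_separation is None:
        raise ValueError("well_depth requires a zero-referenced PMF")
    records = _classified_minima(pmf, prominence)
    if not records:
        raise ValueError("no minima found")
    return min(r.depth for r in records)


def find_barrier(pmf: PMFProfile, search_range: tuple[float, float]) -> BarrierRecord | None:
    """Highest local maximum inside ``search_range``; None if there is none.

    Height is measured relative to the profile's zero reference.
    """
    x, f = _supported(pmf)
    lo, hi = search_range
    if lo >= hi or lo < x[0] or hi > x[-1]:
        raise ValueError("search range must lie within the sampled support")
    peaks = argrelextrema(f, np.greater)[0]
    peaks = [p for p in peaks if lo <= x[p] <= hi]
    if not peaks:
        return None
    best = max(peaks, key=lambda p: f[p])
    return BarrierRecord(location=float(x[best]), height=float(f[best]))


def write_minima_tsv(path, records, provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("# dimerpmf minima table\n")
        for k, v in (provenance or {}).items():
            fh.write(f"# {k} = {v}\n")
        fh.write("location\tdepth\tcurvature\tfit_lo\tfit_hi\tclass\tlocation_sensitivity\n")
        for r in records:
            fh.write(
                f"{r.location:.6g}\t{r.depth:.6g}\t{r.curvature:.6g}\t"
                f"{r.fit_window[0]:.6g}\t{r.fit_window[1]:.6g}\t{r.classification}\t"
                f"{r.location_sensitivity:.6g}\n"
            )
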