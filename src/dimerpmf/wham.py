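"""Weighted histogram analysis method (WHAM) for umbrella-sampled PMFs.

Given K umbrella windows with harmonic biases w_k(x) and N_k samples of the
reaction coordinate x (here: the inter-protein centre-of-mass separation),
WHAM self-consistently solves, on a shared grid of bins i,

    p_i = ( sum_k n_ki ) / ( sum_k N_k exp[(f_k - w_k(x_i)) / T] )
    exp(-f_k / T) = sum_i exp(-w_k(x_i) / T) p_i

for the unbiased bin probabilities p_i and per-window free-energy shifts
f_k.  The PMF is F_i = -T ln(p_i / width_i), reported with an explicit zero
reference.  Bins never visited are reported as gaps, not interpolated, and
support that is disconnected is an error: the method never invents free
energies.

The module-level functions implement the individual steps; the
:class:`UmbrellaPMF` model / :class:`PMFResults` pair packages them in the
estimator-fit-results idiom, with overlap diagnostics and the split-half
convergence assessment as the (only) statistical error estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .restraints import HarmonicBias

__all__ = [
    "UmbrellaWindow",
    "HistogramSet",
    "PMFProfile",
    "WhamError",
    "build_histograms",
    "overlap_diagnostics",
    "solve_wham",
    "zero_reference",
    "split_half_convergence",
    "UmbrellaPMF",
    "PMFResults",
    "read_pull_series",
]


class WhamError(RuntimeError):
    """Disconnected support, empty windows or non-convergence."""


@dataclass(frozen=True)
class UmbrellaWindow:
    """One biased simulation: its harmonic bias and reaction-coordinate series."""

    bias: HarmonicBias
    samples: np.ndarray
    temperature: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.size == 0 or not np.all(np.isfinite(s)):
            raise ValueError("samples must be non-empty and finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def delipidated(self) -> bool:
        return bool(self.metadata.get("delipidated", False))


@dataclass(frozen=True)
class HistogramSet:
    """Per-window histograms on shared, strictly increasing bin edges."""

    edges: np.ndarray  # (B+1,)
    counts: np.ndarray  # (K, B)
    totals: np.ndarray  # (K,) in-range sample counts
    out_of_range: np.ndarray  # (K,) samples outside the edges, reported not dropped
    bias_centers: np.ndarray  # (K,)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)


@dataclass(frozen=True)
class PMFProfile:
    """Free energy versus separation with a declared zero reference.

    ``free_energy`` is NaN on gap bins (never sampled); the sampled support
    carries finite values only.
    """

    edges: np.ndarray
    free_energy: np.ndarray
    reference_separation: float | None = None
    iterations: int | None = None
    residual: float | None = None
    window_shifts: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(np.mean(np.diff(self.edges)))

    @property
    def support(self) -> np.ndarray:
        return np.isfinite(self.free_energy)

    def to_tsv(self, path, extra_header: dict | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("# dimerpmf PMF profile\n")
            fh.write(f"# reference_separation = {self.reference_separation}\n")
            fh.write(f"# iterations = {self.iterations}\n")
            fh.write(f"# residual = {self.residual}\n")
            for k, v in (extra_header or {}).items():
                fh.write(f"# {k} = {v}\n")
            fh.write("# columns: center\tfree_energy\n")
            for c, f in zip(self.centers, self.free_energy):
                fh.write(f"{c:.8g}\t{f:.8g}\n")


def build_histograms(windows, bin_width: float, bin_range=None) -> HistogramSet:
    """Histogram every window onto one shared grid.

    The grid spans all samples (or the explicit ``bin_range``) with edges
    aligned to integer multiples of ``bin_width`` so identical data always
    land on identical grids.  Out-of-range samples are counted and reported,
    never silently dropped from the totals.
    """
    windows = list(windows)
    if not windows:
        raise WhamError("need at least one window")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    for k, w in enumerate(windows):
        if np.asarray(w.samples).size == 0:
            raise WhamError(f"window {k} is empty")
    allmin = min(float(np.min(w.samples)) for w in windows)
    allmax = max(float(np.max(w.samples)) for w in windows)
    if bin_range is not None:
        lo, hi = bin_range
    else:
        lo = np.floor(allmin / bin_width) * bin_width
        hi = np.ceil(allmax / bin_width + 1e-9) * bin_width
    nbins = max(int(np.round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(nbins + 1)
    counts = np.empty((len(windows), nbins))
    totals = np.empty(len(windows))
    oor = np.empty(len(windows), dtype=int)
    for k, w in enumerate(windows):
        c, _ = np.histogram(w.samples, bins=edges)
        counts[k] = c
        totals[k] = c.sum()
        oor[k] = w.samples.size - int(c.sum())
    return HistogramSet(
        edges=edges,
        counts=counts,
        totals=totals,
        out_of_range=oor,
        bias_centers=np.array([w.bias.center for w in windows]),
    )


def overlap_diagnostics(hists: HistogramSet, threshold: float = 0.05):
    """Histogram-intersection fraction for each adjacent pair of windows.

    Windows are ordered by bias center; for each neighbouring pair the
    overlap is the summed minimum of the two normalized histograms, in
    [0, 1].  Pairs below ``threshold`` are flagged.
    """
    order = np.argsort(hists.bias_centers, kind="stable")
    fractions = []
    flagged = []
    for a, b in zip(order[:-1], order[1:]):
        pa = hists.counts[a] / max(hists.totals[a], 1.0)
        pb = hists.counts[b] / max(hists.totals[b], 1.0)
        frac = float(np.minimum(pa, pb).sum())
        fractions.append(frac)
        if frac < threshold:
            flagged.append((int(a), int(b)))
    return np.array(fractions), flagged


def _support_or_raise(counts_total: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Contiguous sampled support, or an error naming the gap.

    The support is the contiguous occupied island carrying the most counts.
    Isolated stray bins (a handful of tail samples beyond an empty bin) are
    excluded and reported as gaps rather than solved — their free energies
    would be inventions.  A second island carrying substantial weight means
    the windows genuinely fail to bridge a region: that is an error.
    """
    occupied = counts_total > 0
    if not occupied.any():
        raise WhamError("no occupied bins")
    # contiguous islands of occupied bins
    padded = np.concatenate([[False], occupied, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    weights = np.array([counts_total[s:e].sum() for s, e in zip(starts, ends)])
    main = int(np.argmax(weights))
    grand = counts_total.sum()
    significant = max(0.005 * grand, 8.0)
    for i, w in enumerate(weights):
        if i != main and w >= significant:
            lo_i, hi_i = sorted([i, main])
            lo = edges[ends[lo_i]]
            hi = edges[starts[hi_i]]
            raise WhamError(
                f"disconnected sampling support: no samples in [{lo:.4g}, {hi:.4g}] "
                f"between two populated regions — add windows or widen bins"
            )
    support = np.zeros_like(occupied)
    support[starts[main] : ends[main]] = occupied[starts[main] : ends[main]]
    return support


def solve_wham(
    hists: HistogramSet,
    biases,
    temperature: float,
    tolerance: float = 1e-6,
    max_iter: int = 100_000,
) -> PMFProfile:
    """Self-consistent WHAM iteration on a histogram set.

    Converged when the largest absolute change of any window shift f_k
    (energy units, gauge-fixed to f_0 = 0) falls below ``tolerance``.
    Deterministic given its inputs and invariant under window permutation.
    """
    biases = list(biases)
    if len(biases) != hists.counts.shape[0]:
        raise ValueError("one bias per window required")
    if temperature <= 0 or tolerance <= 0:
        raise ValueError("temperature and tolerance must be > 0")
    occupied = _support_or_raise(hists.counts.sum(axis=0), hists.edges)

    centers = hists.centers[occupied]
    widths = hists.widths[occupied]
    counts = hists.counts[:, occupied]
    n_tot = counts.sum(axis=0)
    n_k = hists.totals
    # log bias weights: (K, B)
    log_c = np.array([-(b.energy(centers)) / temperature for b in biases])
    log_nk = np.log(n_k)
    g = np.zeros(len(biases))  # f_k / T
    log_ntot = np.log(n_tot)
    residual = np.inf
    for it in range(1, max_iter + 1):
        denom = logsumexp(log_nk[:, None] + g[:, None] + log_c, axis=0)
        log_p = log_ntot - denom
        log_p -= logsumexp(log_p)
        g_new = -logsumexp(log_c + log_p[None, :], axis=1)
        g_new -= g_new[0]
        residual = float(np.max(np.abs(g_new - g)) * temperature)
        g = g_new
        if residual < tolerance:
            break
    else:
        raise WhamError(
            f"WHAM did not converge in {max_iter} iterations (residual {residual:.3g})"
        )
    free = np.full(hists.counts.shape[1], np.nan)
    free[occupied] = -temperature * (log_p - np.log(widths))
    return PMFProfile(
        edges=hists.edges,
        free_energy=free,
        iterations=it,
        residual=residual,
        window_shifts=g * temperature,
        metadata={"temperature": temperature, "tolerance": tolerance},
    )


def zero_reference(pmf: PMFProfile, reference_separation: float) -> PMFProfile:
    """Pin the PMF to zero at the bin containing the reference separation.

    Idempotent; the reference bin value is exactly 0 after application.
    """
    edges = pmf.edges
    if not (edges[0] <= reference_separation <= edges[-1]):
        raise ValueError(
            f"reference {reference_separation} outside binned range [{edges[0]}, {edges[-1]}]"
        )
    idx = min(int(np.searchsorted(edges, reference_separation, side="right")) - 1, len(edges) - 2)
    ref_val = pmf.free_energy[idx]
    if not np.isfinite(ref_val):
        raise ValueError("reference separation falls in an unsampled gap bin")
    return replace(
        pmf,
        free_energy=pmf.free_energy - ref_val,
        reference_separation=float(reference_separation),
    )


def split_half_convergence(
    windows,
    bin_width: float,
    tolerance: float = 1e-6,
    reference_separation: float | None = None,
):
    """Convergence assessment from two disjoint contiguous halves of the data.

    Each window's sample series is split in time into first and second
    halves; two complete WHAM solutions are computed on a common grid, both
    zero-referenced identically, and the maximum absolute pointwise
    difference over the common sampled support is reported.
    """
    windows = list(windows)
    halves: tuple[list, list] = ([], [])
    for k, w in enumerate(windows):
        n = w.samples.size
        if n < 2:
            raise WhamError(f"window {k} too short to split")
        halves[0].append(replace(w, samples=w.samples[: n // 2]))
        halves[1].append(replace(w, samples=w.samples[n // 2 :]))
    full = build_histograms(windows, bin_width)
    lo, hi = full.edges[0], full.edges[-1]
    profiles = []
    for half in halves:
        hists = build_histograms(half, bin_width, bin_range=(lo, hi))
        prof = solve_wham(hists, [w.bias for w in half], half[0].temperature, tolerance)
        profiles.append(prof)
    common = profiles[0].support & profiles[1].support
    if not common.any():
        raise WhamError("the two halves share no sampled support; nothing to compare")
    if reference_separation is None:
        reference_separation = float(profiles[0].centers[np.flatnonzero(common)[-1]])
    p1 = zero_reference(profiles[0], reference_separation)
    p2 = zero_reference(profiles[1], reference_separation)
    disc = float(np.nanmax(np.abs(p1.free_energy[common] - p2.free_energy[common])))
    return p1, p2, disc


def read_pull_series(path) -> np.ndarray:
    """Read a generic two-column (time, separation) TSV pull series.

    Lines starting with '#' are comments; the second column is returned.
    Covers externally produced reaction-coordinate series.
    """
    data = np.loadtxt(path, comments="#", usecols=(0, 1))
    if data.ndim == 1:
        data = data[None, :]
    return data[:, 1]


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------


class UmbrellaPMF:
    """WHAM estimator of a potential of mean force from umbrella windows.

    Parameters
    ----------
    windows
        Iterable of :class:`UmbrellaWindow`.  Lipidated and delipidated
        windows at the same center may be pooled freely; the provenance flag
        on each window is preserved.
    bin_width
        Shared histogram bin width (reaction-coordinate units).
    temperature
        Simulation temperature (energy units).  Defaults to the common
        window temperature, which must be unanimous.

    Examples
    --------
    >>> model = UmbrellaPMF(windows, bin_width=0.05)
    >>> res = model.fit(reference_separation=7.0)
    >>> res.profile.free_energy  # zero at 7.0
    """

    def __init__(self, windows, bin_width: float = 0.02, temperature: float | None = None):
        self.windows = list(windows)
        if not self.windows:
            raise WhamError("need at least one window")
        temps = {w.temperature for w in self.windows}
        if temperature is None:
            if len(temps) != 1:
                raise ValueError("windows disagree on temperature; pass it explicitly")
            temperature = temps.pop()
        self.temperature = float(temperature)
        self.bin_width = float(bin_width)

    @classmethod
    def from_tsv(cls, paths, biases, temperature: float = 1.0, bin_width: float = 0.02):
        """Build from per-window two-column (time, separation) TSV files."""
        windows = [
            UmbrellaWindow(bias=b, samples=read_pull_series(p), temperature=temperature)
            for p, b in zip(paths, biases)
        ]
        return cls(windows, bin_width=bin_width, temperature=temperature)

    def fit(
        self,
        tolerance: float = 1e-6,
        max_iter: int = 100_000,
        reference_separation: float | None = None,
    ) -> "PMFResults":
        hists = build_histograms(self.windows, self.bin_width)
        raw = solve_wham(
            hists, [w.bias for w in self.windows], self.temperature, tolerance, max_iter
        )
        profile = raw
        if reference_separation is not None:
            profile = zero_reference(raw, reference_separation)
        overlap, flagged = overlap_diagnostics(hists)
        return PMFResults(self, hists, raw, profile, overlap, flagged)


class PMFResults:
    """Fitted PMF with diagnostics and landscape analysis."""

    def __init__(self, model, hists, raw_profile, profile, overlap, flagged_pairs):
        self.model = model
        self.histograms = hists
        self.raw_profile = raw_profile
        self.profile = profile
        self.overlap = overlap
        self.flagged_pairs = flagged_pairs
        self.iterations = raw_profile.iterations
        self.residual = raw_profile.residual

    # --- landscape delegation -------------------------------------------
    def minima(self, prominence: float = 0.25, half_window: float | None = None):
        from . import landscape

        return landscape.fit_minima(self.profile, prominence, half_window)

    def well_depth(self, prominence: float = 0.25) -> float:
        from . import landscape

        return landscape.well_depth(self.profile, prominence)

    def barrier(self, search_range):
        from . import landscape

        return landscape.find_barrier(self.profile, search_range)

    def split_half(self, tolerance: float = 1e-6):
        ref = self.profile.reference_separation
        return split_half_convergence(
            self.model.windows, self.model.bin_width, tolerance, reference_separation=ref
        )

    def summary(self) -> str:
        lines = [
            "Umbrella-sampling PMF (WHAM)",
            "=" * 40,
            f"windows:            {len(self.model.windows)}"
            f" ({sum(w.delipidated for w in self.model.windows)} delipidated)",
            f"temperature:        {self.model.temperature:g}",
            f"bin width:          {self.model.bin_width:g}",
            f"bins (sampled):     {int(self.profile.support.sum())} / {self.profile.centers.size}",
            f"iterations:         {self.iterations}",
            f"final residual:     {self.residual:.3g}",
            f"min pair overlap:   {self.overlap.min():.3f}" if self.overlap.size else "",
            f"flagged pairs:      {self.flagged_pairs}",
            f"zero reference:     {self.profile.reference_separation}",
        ]
        try:
            mins = self.minima()
            lines.append("minima (location, depth, curvature):")
            for m in mins:
                lines.append(
                    f"  {m.location:8.4f}  {m.depth:8.3f}  {m.curvature:8.3f}  [{m.classification}]"
                )
        except Exception:
            lines.append("minima:             (none resolved)")
        return "\n".join(s for s in lines if s)

    def plot(self, ax=None, **kw):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.profile.centers, self.profile.free_energy, **kw)
        ax.set_xlabel("inter-COM separation")
        ax.set_ylabel("free energy (T)")
        return ax
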