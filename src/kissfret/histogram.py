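"""FRET-efficiency histograms: binning, donor-only subtraction, 3-Gaussian fit.

Implements the histogram branch of the smFRET analysis: apparent
efficiencies from the first frames of each molecule are binned at a width of
exactly 0.05, the donor-only peak near E = 0 is fitted with a single
Gaussian and subtracted, and the remaining distribution is decomposed into
three Gaussian components (U, K, M in ascending mean).  State fractions are
the ratios of the areas under the individual components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .synth import IntensityTrace

__all__ = [
    "FretTrace",
    "GaussianComponent",
    "HistogramModel",
    "apparent_fret",
    "build_histogram",
    "subtract_donor_only",
    "fit_three_gaussians",
]

BIN_WIDTH = 0.05


class HistogramError(ValueError):
    pass


class FitError(RuntimeError):
    """Nonlinear fit failed; carries the last iterate in ``last_params``."""

    def __init__(self, message: str, last_params: np.ndarray | None = None):
        super().__init__(message)
        self.last_params = last_params


@dataclass
class FretTrace:
    """Per-frame apparent FRET efficiencies of one molecule."""

    efficiency: np.ndarray
    molecule_id: str = ""
    excluded: bool = False

    def __len__(self) -> int:
        return len(self.efficiency)


@dataclass(frozen=True)
class GaussianComponent:
    mean: float
    sigma: float
    area: float
    label: str = ""
    donor_only: bool = False
    degenerate: bool = False

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return (self.area / (self.sigma * np.sqrt(2 * np.pi))
                * np.exp(-0.5 * ((x - self.mean) / self.sigma) ** 2))


@dataclass
class HistogramModel:
    """0.05-binned FRET histogram with optional fitted components."""

    bin_edges: np.ndarray
    counts: np.ndarray
    components: list[GaussianComponent] = field(default_factory=list)
    fractions: dict[str, float] = field(default_factory=dict)
    warning: str | None = None

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, BIN_WIDTH, rtol=0, atol=1e-9):
            raise HistogramError("bin width must be exactly 0.05")
        if self.fractions:
            total = sum(self.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise HistogramError("state fractions must sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_count(self) -> float:
        return float(self.counts.sum())


def apparent_fret(
    trace: IntensityTrace,
    first_n_frames: int = 20,
    intensity_threshold: float | None = None,
) -> FretTrace:
    """Apparent efficiency ``E_t = A_t / (D_t + A_t)`` over the first frames.

    Frames whose total intensity falls below ``intensity_threshold``
    (default: 20% of the median pre-selection total, i.e. post-donor-bleach
    background frames) are dropped.  If every frame is dropped the trace is
    returned empty and flagged for exclusion.
    """
    if len(trace) == 0:
        raise HistogramError("empty trace")
    if first_n_frames < 1:
        raise HistogramError("first_n_frames must be >= 1")
    donor = trace.donor[:first_n_frames].astype(float)
    acceptor = trace.acceptor[:first_n_frames].astype(float)
    total = donor + acceptor
    if intensity_threshold is None:
        intensity_threshold = 0.2 * np.median(trace.donor + trace.acceptor)
    keep = total > max(intensity_threshold, 1e-12)
    if not keep.any():
        return FretTrace(np.empty(0), trace.molecule_id, excluded=True)
    eff = acceptor[keep] / total[keep]
    return FretTrace(eff, trace.molecule_id)


def build_histogram(
    traces: Sequence[FretTrace] | Sequence[np.ndarray],
    range: tuple[float, float] = (-0.2, 1.2),
) -> HistogramModel:
    """Bin efficiencies at a width of exactly 0.05 over ``range``.

    Bins follow the half-open convention ``[a, a + 0.05)``; values outside
    the range are not counted.
    """
    if len(traces) == 0:
        raise HistogramError("need at least one trace")
    values = np.concatenate([
        t.efficiency if isinstance(t, FretTrace) else np.asarray(t, float)
        for t in traces
        if not (isinstance(t, FretTrace) and t.excluded)
    ])
    lo, hi = range
    n_bins = int(round((hi - lo) / BIN_WIDTH))
    if not np.isclose(lo + n_bins * BIN_WIDTH, hi):
        raise HistogramError("range must span a whole number of 0.05 bins")
    edges = lo + BIN_WIDTH * np.arange(n_bins + 1)
    # half-open bins with a small guard so values exactly on an edge land in
    # the upper bin despite floating-point division error
    idx = np.floor((values - lo) / BIN_WIDTH + 1e-9).astype(int)
    valid = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[valid], minlength=n_bins).astype(float)
    return HistogramModel(bin_edges=edges, counts=counts)


def _gauss(x: np.ndarray, amp: float, mean: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mean) / sigma) ** 2)


def subtract_donor_only(
    hist: HistogramModel,
    cut: float = 0.25,
) -> HistogramModel:
    """Fit a Gaussian to the donor-only peak (bin centers < ``cut``) and
    subtract it from the whole histogram.

    The resulting counts are floored at zero and the fitted component is
    stored tagged donor-only.  If no low-E peak is resolvable (fitted mean
    beyond ``cut`` or vanishing amplitude) the histogram is returned
    unchanged with a warning flag.
    """
    x = hist.bin_centers
    low = x < cut
    if hist.counts[low].sum() <= 0:
        return replace(hist, warning="no mass below donor-only cut")
    x_low, y_low = x[low], hist.counts[low]
    amp0 = float(y_low.max())
    mu0 = float(x_low[np.argmax(y_low)])

    def resid(p):
        return _gauss(x_low, *p) - y_low

    sol = least_squares(resid, x0=[amp0, mu0, 0.05],
                        bounds=([0, -0.3, 0.01], [np.inf, 0.5, 0.3]),
                        max_nfev=50_000)
    amp, mu, sigma = sol.x
    if mu > cut or amp < 1e-3 * max(1.0, hist.counts.max()):
        return replace(hist, warning="no resolvable donor-only peak")
    model = _gauss(x, amp, mu, sigma)
    counts = np.clip(hist.counts - model, 0.0, None)
    comp = GaussianComponent(mean=float(mu), sigma=float(sigma),
                             area=float(amp * sigma * np.sqrt(2 * np.pi)) / BIN_WIDTH,
                             label="donor_only", donor_only=True)
    return HistogramModel(bin_edges=hist.bin_edges, counts=counts,
                          components=hist.components + [comp])


def fit_three_gaussians(
    hist: HistogramModel,
    init_means: Sequence[float] = (0.38, 0.69, 0.86),
    sigma_bounds: tuple[float, float] = (0.02, 0.2),
    mean_window: float = 0.12,
    shared_sigma: bool = True,
) -> HistogramModel:
    """Decompose the histogram into three Gaussian state components.

    Unweighted nonlinear least squares of a 3-Gaussian sum to the bin
    counts.  Each component's mean is constrained to ``mean_window`` around
    its initialization so the components keep their state identity; they are
    ordered by ascending mean and labeled U, K, M, and fractions are the
    ratios of the component areas.

    By default the three components share one width: all states are recorded
    at the same total intensity and integration time, so their apparent
    widths are set by the same shot-noise/jitter budget, and with peak
    separations of ~2 sigma the area split is statistically unidentifiable
    if each width floats freely (a slightly wider neighbour absorbs a large
    area fraction at negligible cost).  ``shared_sigma=False`` restores
    independent widths.  A component collapsing to the sigma lower bound or
    below 1% of the total area is flagged degenerate rather than dropped.
    """
    x = hist.bin_centers
    y = hist.counts
    if y.sum() <= 0:
        raise HistogramError("histogram is empty")
    init_means = list(init_means)
    if len(init_means) != 3:
        raise HistogramError("need exactly three initial means")

    def fit_subset(subset, shared):
        """LS fit of a sum of Gaussians at the init means in ``subset``."""
        k = len(subset)
        if shared:
            def unpack(p):
                return [(p[i], p[k + i], p[2 * k]) for i in range(k)]
            p0 = ([max(float(np.interp(init_means[i], x, y)), 1.0)
                   for i in subset]
                  + [init_means[i] for i in subset] + [0.08])
            lo = ([0.0] * k + [init_means[i] - mean_window for i in subset]
                  + [sigma_bounds[0]])
            hi = ([np.inf] * k + [init_means[i] + mean_window for i in subset]
                  + [sigma_bounds[1]])
        else:
            def unpack(p):
                return [(p[3 * i], p[3 * i + 1], p[3 * i + 2])
                        for i in range(k)]
            p0, lo, hi = [], [], []
            for i in subset:
                p0 += [max(float(np.interp(init_means[i], x, y)), 1.0),
                       init_means[i], 0.08]
                lo += [0.0, init_means[i] - mean_window, sigma_bounds[0]]
                hi += [np.inf, init_means[i] + mean_window, sigma_bounds[1]]

        def resid(p):
            a = np.zeros_like(x)
            for amp, mu, sigma in unpack(p):
                a = a + _gauss(x, amp, mu, sigma)
            return a - y

        sol = least_squares(resid, x0=p0, bounds=(lo, hi), max_nfev=50_000)
        if not sol.success:
            raise FitError("Gaussian component fit did not converge", sol.x)
        return unpack(sol.x), float((resid(sol.x) ** 2).sum()), len(p0)

    from itertools import combinations
    from scipy.stats import f as f_dist

    # parsimony: grow the component count only while an F-test on the SSE
    # reduction justifies it -- overlapping shared-width components
    # otherwise overfit histogram noise by splitting a single peak
    n_bins = len(x)
    best = {}
    for k in (1, 2, 3):
        cands = [fit_subset(s, shared_sigma)
                 for s in combinations(range(3), k)]
        best[k] = min(zip(cands, combinations(range(3), k)),
                      key=lambda c: c[0][1])
    chosen_k = 1
    for k in (2, 3):
        (fit_small, sse_small, p_small), _ = best[chosen_k]
        (fit_big, sse_big, p_big), _ = best[k]
        df = max(n_bins - p_big, 1)
        f_stat = ((sse_small - sse_big) / max(p_big - p_small, 1)
                  / max(sse_big / df, 1e-300))
        if f_dist.sf(f_stat, p_big - p_small, df) < 0.05:
            chosen_k = k
        else:
            break
    (params, _, _), subset = best[chosen_k]

    comps = []
    fitted = dict(zip(subset, params))
    shared_width = params[0][2]
    for i, init in enumerate(init_means):
        if i in fitted:
            amp, mu, sigma = fitted[i]
            comps.append((float(mu), float(sigma),
                          float(amp * sigma * np.sqrt(2 * np.pi)) / BIN_WIDTH))
        else:  # component not supported by the data: zero area, flagged below
            comps.append((float(init), float(shared_width), 0.0))
    comps.sort(key=lambda c: c[0])
    total_area = sum(c[2] for c in comps)
    components, fractions = [], {}
    for (mu, sigma, area), label in zip(comps, ("U", "K", "M")):
        degenerate = sigma <= sigma_bounds[0] + 1e-6 or area < 0.01 * total_area
        components.append(GaussianComponent(mean=mu, sigma=sigma, area=area,
                                            label=label, degenerate=degenerate))
        fractions[label] = area / total_area
    # exact renormalization against fp drift
    norm = sum(fractions.values())
    fractions = {k: v / norm for k, v in fractions.items()}
    donor_comps = [c for c in hist.components if c.donor_only]
    return HistogramModel(bin_edges=hist.bin_edges, counts=hist.counts,
                          components=donor_comps + components,
                          fractions=fractions, warning=hist.warning)


def initial_cost(hist: HistogramModel,
                 init_means: Sequence[float] = (0.38, 0.69, 0.86)) -> float:
    """Sum of squared residuals of the 3-Gaussian model at the initial guess.

    Exposed so the accepted-step property (final cost never exceeds the
    starting cost) can be checked without re-deriving the initialization.
    """
    x, y = hist.bin_centers, hist.counts
    total = np.zeros_like(x)
    for m in init_means:
        amp0 = max(float(np.interp(m, x, y)), 1.0)
        total = total + _gauss(x, amp0, m, 0.08)
    return float(((total - y) ** 2).sum())


def fitted_cost(hist: HistogramModel) -> float:
    """Sum of squared residuals of the fitted state components."""
    state = [c for c in hist.components if not c.donor_only]
    x = hist.bin_centers
    model = sum(c.pdf(x) * BIN_WIDTH for c in state)
    return float(((model - hist.counts) ** 2).sum())
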