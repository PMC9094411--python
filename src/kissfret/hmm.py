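"""Trace QC, bleach detection, stitching, and Gaussian-emission HMM.

Automated surrogate for the manual trace selection of the experiment
(anticorrelated dye behaviour, single-step photobleaching) followed by a
from-scratch three-state hidden Markov model with Gaussian emissions: scaled
forward-backward recursions, Baum-Welch training with a monotone
log-likelihood guarantee, and Viterbi decoding.  QC-passing traces are
truncated at the first bleach event and stitched (up to 50,000 datapoints)
into one trace per condition before fitting, mirroring the experimental
analysis; segment boundaries between molecules are recorded so that
joint-crossing dwells can be censored downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .histogram import FretTrace
from .synth import IntensityTrace

__all__ = [
    "QcThresholds",
    "BleachResult",
    "QcResult",
    "HmmModel",
    "StitchedTrace",
    "detect_bleach",
    "qc_trace",
    "stitch_traces",
    "fit_hmm",
    "viterbi_path",
    "forward_backward",
]


class HmmError(RuntimeError):
    pass


@dataclass(frozen=True)
class QcThresholds:
    """Config-exposed thresholds of the automated trace QC.

    ``anticorrelation_max``: maximum allowed donor/acceptor Pearson
    correlation for a dynamic trace (more negative = stronger
    anticorrelation).  ``static_cv_max``: maximum coefficient of variation of
    the total intensity for a static trace to pass without anticorrelation.
    ``bleach_drop``: a step qualifies as a bleach when the post-step level
    falls below this fraction of the pre-step level.  ``multistep_ratio``: a
    second step at least this fraction of the first flags a multi-step trace.
    ``min_acceptor_fraction``: minimum mean acceptor share of the total
    intensity; below it the trace is classed donor-only.
    """

    anticorrelation_max: float = -0.3
    static_cv_max: float = 0.15
    bleach_drop: float = 0.35
    multistep_ratio: float = 0.5
    min_acceptor_fraction: float = 0.10
    min_frames: int = 10


@dataclass
class BleachResult:
    donor_frame: int | None
    acceptor_frame: int | None
    multistep: bool = False

    @property
    def first_frame(self) -> int | None:
        frames = [f for f in (self.donor_frame, self.acceptor_frame) if f is not None]
        return min(frames) if frames else None


@dataclass
class QcResult:
    passed: bool
    reasons: list[str]
    bleach: BleachResult


def _best_step(x: np.ndarray) -> tuple[int, float, float, float]:
    """Least-squares single change-point fit of a piecewise-constant signal.

    Returns ``(index, pre_mean, post_mean, sse_gain)`` where the step occurs
    at ``index`` (first frame of the post level) and ``sse_gain`` is the SSE
    reduction relative to a constant fit.
    """
    n = len(x)
    csum = np.cumsum(x)
    csq = np.cumsum(x ** 2)
    ks = np.arange(1, n)
    pre_mean = csum[:-1] / ks
    post_mean = (csum[-1] - csum[:-1]) / (n - ks)
    sse = (csq[-1]
           - ks * pre_mean ** 2
           - (n - ks) * post_mean ** 2)
    const_sse = csq[-1] - n * (csum[-1] / n) ** 2
    best = int(np.argmin(sse))
    return best + 1, float(pre_mean[best]), float(post_mean[best]), float(const_sse - sse[best])


def detect_bleach(
    trace: IntensityTrace,
    thresholds: QcThresholds = QcThresholds(),
) -> BleachResult:
    """Locate single-step photobleaching events by change-point analysis.

    Donor bleaching is a downward step of the total intensity to background;
    acceptor bleaching is a downward step of the acceptor channel with a
    compensating donor rise (total roughly conserved).  Two comparable
    downward steps of the total mark the trace as not single-molecule
    (multi-step) rather than returning a bleach frame.
    """
    if len(trace) < thresholds.min_frames:
        raise HmmError(f"trace too short for bleach detection (<{thresholds.min_frames})")
    total = trace.donor + trace.acceptor

    donor_frame = None
    k, pre, post, _ = _best_step(total)
    step = pre - post
    if step > 0 and post < thresholds.bleach_drop * pre and k > 1:
        donor_frame = k
        # multi-step check: a second comparable downward step on either side
        for segment in (total[:k], total[k:]):
            if len(segment) < 6:
                continue
            k2, pre2, post2, _ = _best_step(segment)
            step2 = pre2 - post2
            if (step2 >= thresholds.multistep_ratio * step
                    and post2 < 0.75 * pre2):
                return BleachResult(None, None, multistep=True)

    # acceptor bleach: search the pre-donor-bleach span
    end = donor_frame if donor_frame is not None else len(trace)
    acceptor_frame = None
    if end >= thresholds.min_frames:
        acc = trace.acceptor[:end]
        don = trace.donor[:end]
        k, pre_a, post_a, _ = _best_step(acc)
        drop = pre_a - post_a
        if (drop > 0 and post_a < thresholds.bleach_drop * max(pre_a, 1e-9)
                and pre_a > 0.05 * np.mean(total[:end])):
            pre_d = don[:k].mean()
            post_d = don[k:].mean()
            if post_d - pre_d > 0.3 * drop:
                acceptor_frame = k
    return BleachResult(donor_frame, acceptor_frame)


def qc_trace(
    trace: IntensityTrace,
    thresholds: QcThresholds = QcThresholds(),
) -> QcResult:
    """Pass/fail trace selection with enumerated failure reasons.

    Pass requires single-step (or no) bleaching, an acceptor signal above the
    donor-only level, and either donor/acceptor anticorrelation (dynamic
    traces) or a quiet total intensity (static traces) over the pre-bleach
    span.
    """
    reasons: list[str] = []
    if len(trace) < thresholds.min_frames:
        return QcResult(False, ["too short"], BleachResult(None, None))
    bleach = detect_bleach(trace, thresholds)
    if bleach.multistep:
        return QcResult(False, ["multi-step bleaching (not single molecule)"], bleach)
    end = bleach.first_frame if bleach.first_frame is not None else len(trace)
    if end < thresholds.min_frames:
        reasons.append("too few pre-bleach frames")
        return QcResult(False, reasons, bleach)
    donor = trace.donor[:end]
    acceptor = trace.acceptor[:end]
    total = donor + acceptor
    if acceptor.mean() < thresholds.min_acceptor_fraction * total.mean():
        reasons.append("no acceptor signal")
        return QcResult(False, reasons, bleach)
    corr = float(np.corrcoef(donor, acceptor)[0, 1]) if donor.std() > 0 and acceptor.std() > 0 else 0.0
    cv = float(total.std() / total.mean()) if total.mean() > 0 else np.inf
    if corr <= thresholds.anticorrelation_max or cv <= thresholds.static_cv_max:
        return QcResult(True, [], bleach)
    reasons.append("no anticorrelated dye behaviour")
    return QcResult(False, reasons, bleach)


@dataclass
class StitchedTrace:
    """Concatenation of pre-bleach efficiency traces, capped at 50,000 points.

    ``joints`` are the interior frame indices where one molecule ends and the
    next begins.
    """

    efficiency: np.ndarray
    joints: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(j <= 0 or j >= len(self.efficiency) for j in self.joints):
            raise HmmError("joints must be interior indices")
        if any(b <= a for a, b in zip(self.joints, self.joints[1:])):
            raise HmmError("joints must be strictly increasing")

    def __len__(self) -> int:
        return len(self.efficiency)


def stitch_traces(
    traces: Sequence[FretTrace] | Sequence[np.ndarray],
    cap: int = 50_000,
) -> StitchedTrace:
    """Concatenate traces in input order up to ``cap`` datapoints.

    Truncation happens only at whole-trace boundaries: the first trace that
    would push the total past the cap (and everything after it) is dropped.
    """
    arrays = [t.efficiency if isinstance(t, FretTrace) else np.asarray(t, float)
              for t in traces
              if not (isinstance(t, FretTrace) and t.excluded)]
    arrays = [a for a in arrays if len(a) > 0]
    if not arrays:
        raise HmmError("no traces to stitch")
    kept, joints, total = [], [], 0
    for a in arrays:
        if total + len(a) > cap:
            break
        if kept:
            joints.append(total)
        kept.append(a)
        total += len(a)
    if not kept:
        raise HmmError("first trace alone exceeds the stitching cap")
    return StitchedTrace(np.concatenate(kept), joints)


@dataclass
class HmmModel:
    """Gaussian-emission hidden Markov model (states ordered by index)."""

    startprob: np.ndarray
    transmat: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    loglik_history: list[float] = field(default_factory=list)
    converged: bool = False
    collapsed_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.allclose(self.transmat.sum(axis=1), 1.0, rtol=0, atol=1e-12):
            raise HmmError("transition matrix rows must sum to 1")
        if abs(self.startprob.sum() - 1.0) > 1e-12:
            raise HmmError("initial probabilities must sum to 1")
        if np.any(self.sigmas <= 0):
            raise HmmError("emission sigmas must be > 0")

    @property
    def n_states(self) -> int:
        return len(self.means)


def _emission_prob(model_means, model_sigmas, x: np.ndarray) -> np.ndarray:
    z = (x[:, None] - model_means[None, :]) / model_sigmas[None, :]
    b = np.exp(-0.5 * z ** 2) / (model_sigmas[None, :] * np.sqrt(2 * np.pi))
    return np.clip(b, 1e-300, None)


def _forward_backward_scaled(startprob, transmat, b):
    """Scaled alpha/beta recursions; returns (alpha, beta, scale, loglik)."""
    T, S = b.shape
    alpha = np.zeros((T, S))
    scale = np.zeros(T)
    alpha[0] = startprob * b[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ transmat) * b[t]
        scale[t] = alpha[t].sum()
        if scale[t] <= 0 or not np.isfinite(scale[t]):
            raise HmmError("non-finite likelihood in forward recursion")
        alpha[t] /= scale[t]
    beta = np.zeros((T, S))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = transmat @ (b[t + 1] * beta[t + 1]) / scale[t + 1]
    return alpha, beta, scale, float(np.log(scale).sum())


def forward_backward(model: HmmModel, x: np.ndarray) -> tuple[np.ndarray, float]:
    """Posterior state probabilities per frame and the log-likelihood."""
    x = np.asarray(x, float)
    b = _emission_prob(model.means, model.sigmas, x)
    alpha, beta, scale, ll = _forward_backward_scaled(model.startprob, model.transmat, b)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, ll

def forward_loglik_logspace(model: HmmModel, x: np.ndarray) -> float:
    """Log-space forward recursion; numerical-stability cross-check."""
    from scipy.special import logsumexp
    x = np.asarray(x, float)
    logb = np.log(_emission_prob(model.means, model.sigmas, x))
    loga = np.log(np.clip(model.transmat, 1e-300, None))
    v = np.log(np.clip(model.startprob, 1e-300, None)) + logb[0]
    for t in range(1, len(x)):
        v = logsumexp(v[:, None] + loga, axis=0) + logb[t]
    return float(logsumexp(v))


def fit_hmm(
    trace: StitchedTrace | np.ndarray,
    n_states: int = 3,
    seed: int | None = 0,
    init_means: Sequence[float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    min_sigma: float = 0.01,
) -> HmmModel:
    """Baum-Welch training of the Gaussian-emission HMM.

    Emission means initialize at (0.38, 0.69, 0.86) -- the three FRET states
    -- with a small seeded jitter; a five-state fit (means spread uniformly)
    exists only to check that no extra states emerge.  The log-likelihood is
    non-decreasing per iteration; convergence at delta < ``tol`` or
    ``max_iter`` iterations.  States whose means approach within 0.02 are
    flagged collapsed with a warning.
    """
    x = np.asarray(trace.efficiency if isinstance(trace, StitchedTrace) else trace, float)
    if len(x) < 100:
        raise HmmError("need at least 100 frames to fit")
    rng = np.random.default_rng(seed)
    if init_means is None:
        init_means = ((0.38, 0.69, 0.86) if n_states == 3
                      else tuple(np.linspace(0.3, 0.9, n_states)))
    means = np.asarray(init_means, float) + rng.normal(0, 0.01, n_states)
    sigmas = np.full(n_states, 0.1)
    startprob = np.full(n_states, 1.0 / n_states)
    transmat = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1))
    np.fill_diagonal(transmat, 0.9)

    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        b = _emission_prob(means, sigmas, x)
        alpha, beta, scale, ll = _forward_backward_scaled(startprob, transmat, b)
        if not np.isfinite(ll):
            raise HmmError("non-finite likelihood")
        history.append(ll)
        if len(history) > 1 and history[-1] - history[-2] < tol:
            converged = True
            break
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        # xi summed over time (vectorized over t)
        weighted = b[1:] * beta[1:] / scale[1:, None]
        xi_sum = transmat * (alpha[:-1].T @ weighted)
        startprob = gamma[0] / gamma[0].sum()
        transmat = xi_sum / np.clip(xi_sum.sum(axis=1, keepdims=True), 1e-300, None)
        transmat /= transmat.sum(axis=1, keepdims=True)
        w = gamma.sum(axis=0)
        means = (gamma * x[:, None]).sum(axis=0) / np.clip(w, 1e-300, None)
        var = (gamma * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / np.clip(w, 1e-300, None)
        sigmas = np.sqrt(np.clip(var, min_sigma ** 2, None))

    collapsed = [(i, j) for i in range(n_states) for j in range(i + 1, n_states)
                 if abs(means[i] - means[j]) < 0.02]
    if collapsed:
        warnings.warn(f"HMM states collapsed: {collapsed}", stacklevel=2)
    order = np.argsort(means)
    model = HmmModel(
        startprob=startprob[order],
        transmat=transmat[np.ix_(order, order)],
        means=means[order],
        sigmas=sigmas[order],
        loglik_history=history,
        converged=converged,
        collapsed_pairs=collapsed,
    )
    return model


def viterbi_path(model: HmmModel, trace: StitchedTrace | np.ndarray) -> np.ndarray:
    """Globally most probable state sequence (indices into model states).

    Ties break toward the lower-index (lower-mean) state: the backtracking
    argmax returns the first maximizer.
    """
    x = np.asarray(trace.efficiency if isinstance(trace, StitchedTrace) else trace, float)
    logb = np.log(_emission_prob(model.means, model.sigmas, x))
    loga = np.log(np.clip(model.transmat, 1e-300, None))
    T, S = logb.shape
    delta = np.zeros((T, S))
    psi = np.zeros((T, S), dtype=int)
    delta[0] = np.log(np.clip(model.startprob, 1e-300, None)) + logb[0]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + loga
        psi[t] = np.argmax(cand, axis=0)
        delta[t] = cand[psi[t], np.arange(S)] + logb[t]
    path = np.zeros(T, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path
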