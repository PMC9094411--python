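"""Dwell-time extraction and mono-exponential rate estimation.

From a Viterbi state-label sequence, a dwell is a maximal run of one state
that ends in an observed transition; its duration is the run length times
the frame time.  Runs truncated by the start or end of the stitched trace or
by a stitching joint do not end in a real transition and are censored.  Per
transition X->Y, the dwell-time histogram is fitted with a mono-exponential
decay A*exp(-k*t) to give the rate constant k with a standard error from the
fit covariance; transitions with too few events (or failed fits) are
reported "not determined" (n.d.) instead of a number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .kinetics import STATES

__all__ = [
    "DwellTable",
    "RateEstimate",
    "extract_dwells",
    "fit_dwell_rate",
    "branch_rate_estimates",
    "rate_table",
    "format_rate_table",
]

TRANSITIONS = [(x, y) for x in STATES for y in STATES if x != y]


@dataclass
class DwellTable:
    """Completed dwells plus censored (truncated) runs.

    ``records`` columns: from_state, to_state, duration (s), start_frame.
    ``censored`` columns: state, duration (s), start_frame.
    """

    records: pd.DataFrame
    censored: pd.DataFrame
    frame_time: float

    def durations(self, from_state: str, to_state: str) -> np.ndarray:
        sel = (self.records["from_state"] == from_state) & \
              (self.records["to_state"] == to_state)
        return self.records.loc[sel, "duration"].to_numpy()

    def counts(self) -> dict[tuple[str, str], int]:
        return {t: len(self.durations(*t)) for t in TRANSITIONS}

    @property
    def total_time(self) -> float:
        return float(self.records["duration"].sum() + self.censored["duration"].sum())


@dataclass
class RateEstimate:
    """Fitted rate constant for one transition, or n.d."""

    transition: tuple[str, str]
    k: float | None
    stderr: float | None
    n: int
    nd: bool

    def formatted(self) -> str:
        if self.nd:
            return f"n.d. (n = {self.n})"
        return f"{self.k:.1f} ± {self.stderr:.2f} (n = {self.n})"


def extract_dwells(
    labels: Sequence[int] | np.ndarray,
    frame_time: float,
    joints: Sequence[int] = (),
    states: Sequence[str] = STATES,
) -> DwellTable:
    """Split a label sequence into completed and censored dwells.

    ``joints`` are stitch boundaries (first frame of the next molecule); a
    run that ends at a joint or at the end of the trace is censored, and the
    label change across a joint is not counted as a transition.  Total
    completed plus censored dwell time equals the trace duration.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    boundaries = set(int(j) for j in joints) | {0, n}
    records, censored = [], []
    run_start = 0
    for t in range(1, n + 1):
        at_boundary = t in boundaries
        changed = t < n and labels[t] != labels[t - 1]
        if not at_boundary and not changed:
            continue
        duration = (t - run_start) * frame_time
        state = states[labels[run_start]]
        if at_boundary:  # truncated by trace end or stitch joint
            censored.append({"state": state, "duration": duration,
                             "start_frame": run_start})
        else:
            records.append({"from_state": state, "to_state": states[labels[t]],
                            "duration": duration, "start_frame": run_start})
        run_start = t
    return DwellTable(
        records=pd.DataFrame(records, columns=["from_state", "to_state",
                                               "duration", "start_frame"]),
        censored=pd.DataFrame(censored, columns=["state", "duration",
                                                 "start_frame"]),
        frame_time=frame_time,
    )


def fit_dwell_rate(
    durations: np.ndarray | Sequence[float],
    transition: tuple[str, str] = ("U", "K"),
    min_n: int = 30,
    frame_time: float = 0.1,
    method: str = "ls",
) -> RateEstimate:
    """Mono-exponential rate from a set of dwell durations.

    ``method="ls"`` (default, matching the experimental procedure) bins the
    dwells at the frame time and fits ``A*exp(-k*t)`` by least squares;
    ``method="mle"`` is the closed-form geometric-distribution estimator
    ``k = -ln(1 - 1/m_bar)/dt`` (``m_bar`` = mean dwell in frames), provided
    as a cross-check for the frame-discretization bias.  The n.d. flag is set
    when ``n < min_n`` or the fit fails.
    """
    durations = np.asarray(durations, float)
    n = len(durations)
    if n < min_n:
        return RateEstimate(transition, None, None, n, nd=True)

    if method == "mle":
        m_bar = durations.mean() / frame_time
        if m_bar <= 1.0:
            return RateEstimate(transition, None, None, n, nd=True)
        k = -np.log(1.0 - 1.0 / m_bar) / frame_time
        # delta-method standard error from the geometric variance
        p = 1.0 / m_bar
        se_p = np.sqrt(p ** 2 * (1 - p) / n)
        se_k = se_p / ((1 - p) * frame_time)
        return RateEstimate(transition, float(k), float(se_k), n, nd=False)

    if method != "ls":
        raise ValueError(f"unknown method {method!r}")

    frames = np.round(durations / frame_time).astype(int)
    m_max = frames.max()
    counts = np.bincount(frames, minlength=m_max + 1)[1:]
    t_centers = frame_time * np.arange(1, m_max + 1)
    nonzero = counts > 0
    if nonzero.sum() < 3:
        return RateEstimate(transition, None, None, n, nd=True)
    k0 = 1.0 / max(durations.mean(), frame_time)
    try:
        popt, pcov = curve_fit(
            lambda t, a, k: a * np.exp(-k * t),
            t_centers, counts,
            p0=[counts[0] * np.exp(k0 * frame_time), k0],
            maxfev=10_000,
        )
    except RuntimeError:
        return RateEstimate(transition, None, None, n, nd=True)
    k = float(popt[1])
    se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else None
    if k <= 0 or se is None or not np.isfinite(k):
        return RateEstimate(transition, None, None, n, nd=True)
    return RateEstimate(transition, k, se, n, nd=False)


def branch_rate_estimates(
    table: DwellTable,
    min_n: int = 30,
    method: str = "ls",
    states: Sequence[str] = STATES,
) -> list[RateEstimate]:
    """Six per-transition rate constants from one segmentation.

    In a memoryless three-state scheme the dwell time in X is exponential
    with the TOTAL exit rate regardless of destination, so per-destination
    dwell histograms share one decay constant and cannot yield distinct
    k_XY on their own.  The per-transition rates reported here therefore
    follow the kinetic convention consistent with the published tables: the
    pooled dwell histogram of state X is fitted mono-exponentially for the
    exit rate, which is apportioned by the observed branching fractions,
    ``k_XY = k_X,exit * n_XY / n_X``.  The standard error combines the exit
    fit error with the binomial branching error; the n.d. flag follows the
    per-transition count.
    """
    out = []
    for x in states:
        per_dest = {y: table.durations(x, y) for y in states if y != x}
        ns = {y: len(d) for y, d in per_dest.items()}
        n_tot = sum(ns.values())
        pooled = (np.concatenate(list(per_dest.values())) if n_tot
                  else np.empty(0))
        exit_est = fit_dwell_rate(pooled, (x, "*"), min_n=min_n,
                                  frame_time=table.frame_time, method=method)
        for y in states:
            if y == x:
                continue
            n = ns[y]
            if exit_est.nd or n < min_n:
                out.append(RateEstimate((x, y), None, None, n, nd=True))
                continue
            frac = n / n_tot
            k = exit_est.k * frac
            se = float(np.sqrt((exit_est.stderr * frac) ** 2
                               + exit_est.k ** 2 * frac * (1 - frac) / n_tot))
            out.append(RateEstimate((x, y), float(k), se, n, nd=False))
    order = {t: i for i, t in enumerate(TRANSITIONS)}
    return sorted(out, key=lambda e: order[e.transition])


def rate_table(
    dwell_tables: Mapping[str, DwellTable],
    min_n: int = 30,
    method: str = "ls",
) -> pd.DataFrame:
    """Six rate estimates per condition, tidy layout.

    Columns: condition, from_state, to_state, k, stderr, n, nd, formatted.
    Rates follow the branching convention of :func:`branch_rate_estimates`.
    """
    rows = []
    for condition, table in dwell_tables.items():
        for est in branch_rate_estimates(table, min_n=min_n, method=method):
            rows.append({
                "condition": condition,
                "from_state": est.transition[0],
                "to_state": est.transition[1],
                "k": est.k, "stderr": est.stderr, "n": est.n, "nd": est.nd,
                "formatted": est.formatted(),
            })
    return pd.DataFrame(rows)


def format_rate_table(tidy: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy rate table into rows = transitions, columns = conditions,
    with cells formatted ``k ± se (n = ...)`` as in the published tables."""
    tidy = tidy.copy()
    tidy["transition"] = ("k_" + tidy["from_state"] + "," + tidy["to_state"]
                          + " [1/s]")
    wide = tidy.pivot(index="transition", columns="condition", values="formatted")
    order = [f"k_{x},{y} [1/s]" for x, y in TRANSITIONS]
    return wide.reindex(order)
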