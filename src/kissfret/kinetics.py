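"""Three-state continuous-time Markov kinetics of riboswitch folding.

The guanidine-II riboswitch aptamer interconverts between three
conformations: an open, unfolded state (U), the kissing-loop state (K) in
which the P1 and P2 hairpin loops base-pair, and a compact Mg2+-dependent
state (M) with an alternative secondary structure.  Each state is directly
accessible from every other state, so the kinetic scheme is a fully
connected three-state continuous-time Markov chain with six rate constants
k_XY (s^-1).

This module defines the :class:`KineticModel`, its generator matrix and
stationary distribution, and a Gillespie sampler producing continuous-time
state paths used by the synthetic-trace generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "STATES",
    "RATE_KEYS",
    "KineticModel",
    "StatePath",
    "build_generator",
    "stationary_distribution",
    "sample_state_path",
    "MG_TITRATION_RATES",
    "GDM_TITRATION_RATES",
]

#: Canonical state ordering used throughout the package.
STATES: tuple[str, str, str] = ("U", "K", "M")

#: Flat config keys for the six rate constants, in s^-1.
RATE_KEYS: dict[str, tuple[str, str]] = {
    "kUK": ("U", "K"),
    "kKU": ("K", "U"),
    "kUM": ("U", "M"),
    "kMU": ("M", "U"),
    "kKM": ("K", "M"),
    "kMK": ("M", "K"),
}


class KineticsError(ValueError):
    """Invalid kinetic model or sampling request."""


@dataclass(frozen=True)
class KineticModel:
    """Fully connected three-state kinetic scheme.

    Parameters
    ----------
    rates
        Mapping from ordered state pair ``(X, Y)`` (``X != Y``) to the rate
        constant ``k_XY`` in s^-1.  Missing pairs are treated as 0.
    """

    rates: Mapping[tuple[str, str], float]
    states: tuple[str, ...] = STATES

    def __post_init__(self) -> None:
        for (x, y), k in self.rates.items():
            if x not in self.states or y not in self.states or x == y:
                raise KineticsError(f"invalid transition pair ({x!r}, {y!r})")
            if not np.isfinite(k) or k < 0:
                raise KineticsError(
                    f"rate k_{x},{y} must be finite and >= 0, got {k!r}"
                )

    def rate(self, x: str, y: str) -> float:
        return float(self.rates.get((x, y), 0.0))

    @classmethod
    def from_config(cls, section: Mapping[str, float]) -> "KineticModel":
        """Build a model from flat keys ``kUK, kKU, kUM, kMU, kKM, kMK``."""
        missing = [k for k in RATE_KEYS if k not in section]
        if missing:
            raise KineticsError(f"missing rate keys: {', '.join(missing)}")
        return cls({RATE_KEYS[k]: float(section[k]) for k in RATE_KEYS})

    def to_config(self) -> dict[str, float]:
        return {key: self.rate(*pair) for key, pair in RATE_KEYS.items()}


@dataclass
class StatePath:
    """A continuous-time realization of the kinetic scheme.

    ``segments`` is an ordered sequence of ``(state, dwell_seconds)`` with
    consecutive segments in different states; dwells sum to ``duration``.
    """

    segments: list[tuple[str, float]]
    duration: float

    def __post_init__(self) -> None:
        if any(d <= 0 for _, d in self.segments):
            raise KineticsError("dwell durations must be > 0")
        total = sum(d for _, d in self.segments)
        if not np.isclose(total, self.duration, rtol=0, atol=1e-9 * max(1.0, self.duration)):
            raise KineticsError("dwell sum does not equal total duration")

    @property
    def n_transitions(self) -> int:
        return len(self.segments) - 1

    def occupancy(self, states: Sequence[str] = STATES) -> np.ndarray:
        """Fraction of total time spent in each state."""
        occ = np.zeros(len(states))
        index = {s: i for i, s in enumerate(states)}
        for state, dwell in self.segments:
            occ[index[state]] += dwell
        return occ / self.duration

    def frame_occupancies(self, frame_time: float, n_frames: int,
                          states: Sequence[str] = STATES) -> np.ndarray:
        """Per-frame fractional state occupancies, shape ``(n_frames, n_states)``.

        Frame ``t`` covers ``[t*frame_time, (t+1)*frame_time)``; the entry is
        the fraction of that interval spent in each state.
        """
        if n_frames * frame_time > self.duration + 1e-9:
            raise KineticsError(
                f"path of {self.duration} s cannot cover {n_frames} frames "
                f"of {frame_time} s"
            )
        index = {s: i for i, s in enumerate(states)}
        occ = np.zeros((n_frames, len(states)))
        t0 = 0.0
        for state, dwell in self.segments:
            t1 = t0 + dwell
            f0 = int(t0 / frame_time)
            f1 = min(int(np.ceil(t1 / frame_time)), n_frames)
            for f in range(f0, f1):
                lo = max(t0, f * frame_time)
                hi = min(t1, (f + 1) * frame_time)
                if hi > lo:
                    occ[f, index[state]] += (hi - lo) / frame_time
            t0 = t1
            if t0 >= n_frames * frame_time:
                break
        # guard against fp rounding: rows must sum to 1
        occ /= occ.sum(axis=1, keepdims=True)
        return occ


def build_generator(model: KineticModel) -> np.ndarray:
    """Return the 3x3 rate generator Q (s^-1).

    Off-diagonal entry ``(X, Y)`` is ``k_XY``; the diagonal carries minus the
    sum of outgoing rates, so rows sum to zero exactly.
    """
    n = len(model.states)
    q = np.zeros((n, n))
    for i, x in enumerate(model.states):
        for j, y in enumerate(model.states):
            if i != j:
                q[i, j] = model.rate(x, y)
        q[i, i] = -q[i].sum()
    return q


def _reachable(q: np.ndarray, start: int) -> set[int]:
    seen = {start}
    frontier = [start]
    while frontier:
        i = frontier.pop()
        for j in range(q.shape[0]):
            if j != i and q[i, j] > 0 and j not in seen:
                seen.add(j)
                frontier.append(j)
    return seen


def stationary_distribution(model: KineticModel) -> np.ndarray:
    """Equilibrium occupancies pi solving ``pi Q = 0``, normalized to 1.

    Raises
    ------
    KineticsError
        If the chain is reducible (some state unreachable).
    """
    q = build_generator(model)
    n = q.shape[0]
    for start in range(n):
        missing = set(range(n)) - _reachable(q, start)
        if missing:
            names = ", ".join(model.states[i] for i in sorted(missing))
            raise KineticsError(
                f"chain is reducible: state(s) {names} unreachable from "
                f"{model.states[start]}"
            )
    # solve pi Q = 0 with sum(pi) = 1: replace one equation by normalization
    a = q.T.copy()
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(a, b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def sample_state_path(
    model: KineticModel,
    duration: float,
    initial: str | None = "stationary",
    seed: int | np.random.Generator | None = None,
) -> StatePath:
    """Gillespie realization of the kinetic scheme.

    Dwell times in state X are exponential with rate equal to the sum of
    outgoing rates from X; the successor is chosen proportionally to the
    individual rates.  ``initial`` may be a state label or ``"stationary"``
    (draw from the stationary distribution).  An absorbing state yields a
    single segment spanning the full duration.
    """
    if duration <= 0:
        raise KineticsError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = model.states
    if initial is None or initial == "stationary":
        pi = stationary_distribution(model)
        state = states[rng.choice(len(states), p=pi)]
    else:
        if initial not in states:
            raise KineticsError(f"unknown initial state {initial!r}")
        state = initial

    segments: list[tuple[str, float]] = []
    t = 0.0
    while t < duration:
        out = [(y, model.rate(state, y)) for y in states if y != state]
        total = sum(k for _, k in out)
        if total <= 0:  # absorbing
            segments.append((state, duration - t))
            break
        dwell = rng.exponential(1.0 / total)
        if t + dwell >= duration:
            segments.append((state, duration - t))
            break
        segments.append((state, dwell))
        t += dwell
        probs = np.array([k for _, k in out]) / total
        state = out[rng.choice(len(out), p=probs)][0]
    return StatePath(segments, duration)


def _col(kUK, kKU, kUM, kMU, kKM, kMK):
    vals = dict(kUK=kUK, kKU=kKU, kUM=kUM, kMU=kMU, kKM=kKM, kMK=kMK)
    return {k: v for k, v in vals.items()}


#: Experimentally reported transition rates (s^-1) for the E. coli
#: guanidine-II riboswitch aptamer across a Mg2+ titration (no Gdm+).
#: ``None`` marks transitions that were not determined (n.d.) because too
#: few transitions were observed for a reliable dwell-time fit.  Columns
#: with ``None`` entries do not define a complete kinetic model.
MG_TITRATION_RATES: dict[str, dict[str, float | None]] = {
    "0mM": _col(5.6, 1.1, None, None, 0.7, None),
    "0.5mM": _col(5.8, 1.0, 0.8, 0.8, 0.6, 1.2),
    "1mM": _col(3.2, 1.6, 1.6, 0.6, 0.9, 0.7),
    "3mM": _col(4.6, 1.5, 2.0, 0.8, 1.4, 0.4),
    "5mM": _col(4.0, 2.2, 3.6, 0.8, 2.2, 0.6),
}

#: Transition counts n backing MG_TITRATION_RATES (same layout).
MG_TITRATION_COUNTS: dict[str, dict[str, int]] = {
    "0mM": _col(313, 291, 21, 43, 73, 51),
    "0.5mM": _col(626, 575, 423, 476, 168, 115),
    "1mM": _col(637, 511, 339, 466, 367, 240),
    "3mM": _col(541, 439, 221, 324, 315, 212),
    "5mM": _col(366, 336, 110, 140, 272, 243),
}

#: Reported transition rates (s^-1) for the Gdm+ ligand titration at a
#: constant 1 mM Mg2+.  All columns except 30 mM are complete models.
GDM_TITRATION_RATES: dict[str, dict[str, float | None]] = {
    "0": _col(3.2, 1.6, 1.6, 0.6, 0.9, 0.7),
    "30nM": _col(3.5, 1.0, 2.4, 0.3, 0.8, 0.2),
    "1uM": _col(2.9, 0.8, 1.5, 0.3, 0.7, 0.2),
    "30uM": _col(3.7, 1.9, 1.4, 0.4, 1.0, 0.3),
    "1mM": _col(3.7, 1.2, 3.3, 0.4, 1.5, 0.4),
    "30mM": _col(6.4, 1.4, 5.0, 0.6, None, None),
}

GDM_TITRATION_COUNTS: dict[str, dict[str, int]] = {
    "0": _col(737, 729, 79, 86, 71, 64),
    "30nM": _col(730, 696, 95, 129, 143, 109),
    "1uM": _col(929, 903, 917, 223, 162, 135),
    "30uM": _col(934, 846, 215, 303, 428, 340),
    "1mM": _col(682, 632, 107, 157, 402, 353),
    "30mM": _col(933, 930, 49, 51, 26, 23),
}


def complete_model(column: Mapping[str, float | None]) -> KineticModel:
    """Build a KineticModel from a titration column; rejects n.d. columns."""
    if any(v is None for v in column.values()):
        raise KineticsError(
            "column contains n.d. entries and does not define a full model"
        )
    return KineticModel.from_config({k: float(v) for k, v in column.items()})
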