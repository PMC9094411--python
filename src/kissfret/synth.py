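"""Synthetic donor/acceptor intensity traces for a three-state folder.

Renders continuous-time state paths into camera-frame intensity traces the
way a TIRF experiment records them: 100 ms frame integration, state-specific
mean FRET efficiencies (U/K/M at 0.38/0.69/0.86 by default), additive
Gaussian camera noise per channel, a donor-only subpopulation (molecules
lacking an active acceptor), and irreversible single-step photobleaching of
either dye with exponentially distributed bleach times.

The generated cohorts carry full ground truth (state path, bleach frames,
population flags), which downstream modules use as the recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import STATES, KineticModel, StatePath, stationary_distribution, sample_state_path

__all__ = [
    "PhotophysicsParams",
    "IntensityTrace",
    "Cohort",
    "render_trace",
    "make_cohort",
    "write_cohort",
    "read_cohort",
]

MANIFEST_VERSION = 1


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class PhotophysicsParams:
    """Camera and dye parameters of the emulated recording.

    ``noise_sigma`` defaults to ``total_intensity / 12`` (EMCCD-like additive
    Gaussian noise); ``state_sigma_e`` is the apparent-efficiency spread of
    each state, which absorbs shot noise and dye-orientation broadening.
    Bleach lifetimes are the means of the exponential bleach-time
    distributions.
    """

    frame_time: float = 0.1  # s
    total_intensity: float = 1000.0  # counts/frame
    noise_sigma: float | None = None  # counts/frame; None -> total/12
    state_efficiencies: Mapping[str, float] = field(
        default_factory=lambda: {"U": 0.38, "K": 0.69, "M": 0.86}
    )
    state_sigma_e: Mapping[str, float] | float = 0.08
    donor_bleach_lifetime: float = 60.0  # s
    acceptor_bleach_lifetime: float = 40.0  # s
    donor_only_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.frame_time <= 0:
            raise SynthError("frame_time must be > 0")
        if self.donor_bleach_lifetime <= 0 or self.acceptor_bleach_lifetime <= 0:
            raise SynthError("bleach lifetimes must be > 0")
        if not 0 <= self.donor_only_fraction <= 1:
            raise SynthError("donor_only_fraction must be in [0, 1]")
        for s, e in self.state_efficiencies.items():
            if not 0 <= e <= 1:
                raise SynthError(f"state efficiency E_{s}={e} outside [0, 1]")

    @property
    def sigma(self) -> float:
        return self.total_intensity / 12.0 if self.noise_sigma is None else self.noise_sigma

    def sigma_e(self, state: str) -> float:
        if isinstance(self.state_sigma_e, Mapping):
            return float(self.state_sigma_e[state])
        return float(self.state_sigma_e)


@dataclass
class IntensityTrace:
    """Per-frame donor/acceptor counts for one molecule.

    ``true_efficiency`` is the noise-free apparent efficiency the renderer
    targeted per frame (ground truth, pre-bleach).
    """

    donor: np.ndarray
    acceptor: np.ndarray
    frame_time: float
    donor_bleach_frame: int | None = None
    acceptor_bleach_frame: int | None = None
    ground_truth_path: StatePath | None = None
    true_efficiency: np.ndarray | None = None
    molecule_id: str = ""
    donor_only: bool = False

    def __post_init__(self) -> None:
        if len(self.donor) != len(self.acceptor):
            raise SynthError("donor and acceptor channels differ in length")
        for name, f in (("donor", self.donor_bleach_frame),
                        ("acceptor", self.acceptor_bleach_frame)):
            if f is not None and not 0 <= f <= len(self.donor):
                raise SynthError(f"{name} bleach frame {f} outside trace")

    def __len__(self) -> int:
        return len(self.donor)

    @property
    def first_bleach_frame(self) -> int | None:
        frames = [f for f in (self.donor_bleach_frame, self.acceptor_bleach_frame)
                  if f is not None]
        return min(frames) if frames else None


def render_trace(
    path: StatePath,
    params: PhotophysicsParams,
    n_frames: int,
    seed: int | np.random.Generator | None = None,
    donor_only: bool = False,
    donor_bleach_frame: int | None = None,
    acceptor_bleach_frame: int | None = None,
    sample_bleach: bool = True,
) -> IntensityTrace:
    """Render a state path into a donor/acceptor intensity trace.

    The per-frame target efficiency is the dwell-time-weighted mean of the
    state efficiencies over the frame plus a Gaussian apparent-E jitter whose
    variance is the occupancy-weighted combination of the per-state spreads.
    After acceptor bleaching all intensity moves to the donor channel
    (apparent E -> 0); after donor bleaching both channels carry background
    noise only.  Explicit ``*_bleach_frame`` arguments override sampling.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_frames * params.frame_time > path.duration + 1e-9:
        raise SynthError("path does not cover the requested number of frames")

    occ = path.frame_occupancies(params.frame_time, n_frames)
    means = np.array([params.state_efficiencies[s] for s in STATES])
    # state_sigma_e is the APPARENT per-state E spread; deconvolve the
    # channel-noise contribution so the rendered apparent width matches it
    rel_noise = params.sigma / params.total_intensity
    chan_sd = rel_noise * np.sqrt((1 - means) ** 2 + means ** 2)
    sigmas = np.sqrt(np.clip(
        np.array([params.sigma_e(s) for s in STATES]) ** 2 - chan_sd ** 2,
        0.0, None))
    e_true = occ @ means
    jitter_sd = np.sqrt((occ ** 2) @ (sigmas ** 2))
    e_true = e_true + rng.normal(0.0, 1.0, n_frames) * jitter_sd

    if donor_only:
        e_true = np.zeros(n_frames)
        acceptor_bleach_frame = None

    def _sample_bleach(lifetime: float) -> int | None:
        t = rng.exponential(lifetime)
        f = int(t / params.frame_time)
        return f if f < n_frames else None

    if sample_bleach:
        if donor_bleach_frame is None:
            donor_bleach_frame = _sample_bleach(params.donor_bleach_lifetime)
        if not donor_only and acceptor_bleach_frame is None:
            acceptor_bleach_frame = _sample_bleach(params.acceptor_bleach_lifetime)

    e_signal = e_true.copy()
    total = np.full(n_frames, params.total_intensity)
    if acceptor_bleach_frame is not None:
        e_signal[acceptor_bleach_frame:] = 0.0
    if donor_bleach_frame is not None:
        total[donor_bleach_frame:] = 0.0

    noise = params.sigma
    donor = total * (1.0 - e_signal) + rng.normal(0.0, 1.0, n_frames) * noise
    acceptor = total * e_signal + rng.normal(0.0, 1.0, n_frames) * noise
    return IntensityTrace(
        donor=donor,
        acceptor=acceptor,
        frame_time=params.frame_time,
        donor_bleach_frame=donor_bleach_frame,
        acceptor_bleach_frame=acceptor_bleach_frame,
        ground_truth_path=path,
        true_efficiency=e_true,
        donor_only=donor_only,
    )


@dataclass
class Cohort:
    """A set of rendered traces plus the ground-truth manifest table."""

    traces: list[IntensityTrace]
    truth: pd.DataFrame
    params: PhotophysicsParams
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.traces)


def make_cohort(
    model: KineticModel,
    params: PhotophysicsParams,
    n_molecules: int,
    movie_length_frames: int,
    static_fraction: float = 0.0,
    seed: int | None = None,
    state_probs: Sequence[float] | None = None,
) -> Cohort:
    """Generate a reproducible cohort of molecules.

    A fraction ``donor_only_fraction`` of molecules carries no acceptor; of
    the remainder, ``static_fraction`` stay in a single state for the whole
    movie.  Initial (and static) states are drawn from the stationary
    distribution of ``model`` unless ``state_probs`` overrides it.  Each
    molecule gets its own deterministic substream derived from ``seed``.
    """
    if n_molecules < 1:
        raise SynthError("n_molecules must be >= 1")
    if not 0 <= static_fraction <= 1:
        raise SynthError("static_fraction must be in [0, 1]")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_molecules + 1)
    assign_rng = np.random.default_rng(children[0])

    probs = (np.asarray(state_probs, dtype=float)
             if state_probs is not None else stationary_distribution(model))
    probs = probs / probs.sum()
    duration = movie_length_frames * params.frame_time

    traces: list[IntensityTrace] = []
    rows = []
    for m in range(n_molecules):
        rng = np.random.default_rng(children[m + 1])
        donor_only = assign_rng.random() < params.donor_only_fraction
        static = (not donor_only) and assign_rng.random() < static_fraction
        if static:
            state = STATES[assign_rng.choice(3, p=probs)]
            path = StatePath([(state, duration)], duration)
        else:
            initial = STATES[assign_rng.choice(3, p=probs)]
            path = sample_state_path(model, duration, initial=initial, seed=rng)
        trace = render_trace(path, params, movie_length_frames, seed=rng,
                             donor_only=donor_only)
        mol_id = f"mol_{m:04d}"
        trace.molecule_id = mol_id
        traces.append(trace)
        occ = path.occupancy()
        rows.append({
            "molecule_id": mol_id,
            "donor_only": donor_only,
            "static": static,
            "initial_state": path.segments[0][0],
            "n_transitions": path.n_transitions,
            "occ_U": occ[0], "occ_K": occ[1], "occ_M": occ[2],
            "donor_bleach_frame": trace.donor_bleach_frame,
            "acceptor_bleach_frame": trace.acceptor_bleach_frame,
        })
    truth = pd.DataFrame(rows)
    return Cohort(traces=traces, truth=truth, params=params, seed=seed)


# ---------------------------------------------------------------------------
# Cohort I/O: one TSV per molecule (frame, donor, acceptor) + a manifest TSV.

def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write trace TSVs and the versioned ground-truth manifest.

    Returns the manifest path.  Manifest schema (v1): one row per molecule
    with the ground-truth columns of ``Cohort.truth`` plus ``trace_file``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for trace in cohort.traces:
        fname = f"{trace.molecule_id}.tsv"
        df = pd.DataFrame({
            "frame": np.arange(len(trace)),
            "donor": trace.donor,
            "acceptor": trace.acceptor,
        })
        df.to_csv(directory / fname, sep="\t", index=False, float_format="%.4f")
        files.append(fname)
    manifest = cohort.truth.copy()
    manifest.insert(1, "trace_file", files)
    manifest_path = directory / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write(f"# kissfret cohort manifest v{MANIFEST_VERSION}\n")
        fh.write(f"# frame_time={cohort.params.frame_time}\n")
        manifest.to_csv(fh, sep="\t", index=False)
    return manifest_path


def read_cohort(manifest_path: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`.

    Ground-truth state paths are not round-tripped (only the manifest
    summary); bleach frames and population flags are restored.
    """
    manifest_path = Path(manifest_path)
    frame_time = None
    with open(manifest_path) as fh:
        header_lines = 0
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            if line.startswith("# frame_time="):
                frame_time = float(line.split("=", 1)[1])
    if frame_time is None:
        raise SynthError(f"{manifest_path} lacks the frame_time header")
    truth = pd.read_csv(manifest_path, sep="\t", skiprows=header_lines)
    traces = []
    for _, row in truth.iterrows():
        df = pd.read_csv(manifest_path.parent / row["trace_file"], sep="\t")
        def _frame(v):
            return None if pd.isna(v) else int(v)
        traces.append(IntensityTrace(
            donor=df["donor"].to_numpy(),
            acceptor=df["acceptor"].to_numpy(),
            frame_time=frame_time,
            donor_bleach_frame=_frame(row["donor_bleach_frame"]),
            acceptor_bleach_frame=_frame(row["acceptor_bleach_frame"]),
            molecule_id=row["molecule_id"],
            donor_only=bool(row["donor_only"]),
        ))
    params = PhotophysicsParams(frame_time=frame_time)
    return Cohort(traces=traces, truth=truth.drop(columns=["trace_file"]),
                  params=params)
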