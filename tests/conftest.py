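import numpy as np
import pytest

import kissfret as kf

#: Gdm+ titration, 0 mM column at 1 mM Mg2+ -- a fully determined six-rate
#: condition used throughout as the reference kinetic scheme (s^-1).
RATES_0MM_GDM = dict(kUK=3.2, kKU=1.6, kUM=1.6, kMU=0.6, kKM=0.9, kMK=0.7)


@pytest.fixture(scope="session")
def model_0mm():
    return kf.KineticModel.from_config(RATES_0MM_GDM)


@pytest.fixture(scope="session")
def default_params():
    return kf.PhotophysicsParams()


@pytest.fixture(scope="session")
def hairpin():
    from kissfret.geometry import ideal_hairpin
    return ideal_hairpin(n_bp=4)


@pytest.fixture(scope="session")
def hairpin_topology(hairpin):
    from kissfret.gomodel import build_topology
    structure, pairing = hairpin
    return build_topology(structure, pairing=pairing)


@pytest.fixture(scope="session")
def analyzed_cohort(model_0mm, default_params):
    """One QC'd, stitched, HMM-segmented cohort shared by pipeline tests."""
    from kissfret.histogram import apparent_fret
    from kissfret.hmm import qc_trace, stitch_traces

    cohort = kf.make_cohort(model_0mm, default_params, n_molecules=120,
                            movie_length_frames=400, seed=5)
    fret, truth_labels, pure = [], [], []
    for trace in cohort.traces:
        qc = qc_trace(trace)
        if not qc.passed:
            continue
        end = qc.bleach.first_frame or len(trace)
        ft = apparent_fret(trace, first_n_frames=end)
        if ft.excluded:
            continue
        occ = trace.ground_truth_path.frame_occupancies(
            default_params.frame_time, end)
        fret.append(ft)
        truth_labels.append(occ.argmax(1))
        pure.append(occ.max(1) > 0.999)
    stitched = stitch_traces(fret)
    n = len(stitched)
    hmm_model = kf.fit_hmm(stitched, seed=0)
    labels = kf.viterbi_path(hmm_model, stitched)
    return {
        "cohort": cohort,
        "stitched": stitched,
        "model": hmm_model,
        "labels": labels,
        "truth_labels": np.concatenate(truth_labels)[:n],
        "pure_frames": np.concatenate(pure)[:n],
    }
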