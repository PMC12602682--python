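"""Shared fixtures and data builders for the test suite.

All fixtures are generated programmatically with fixed seeds; the heavier
simulated dataset is session-scoped so the reduction/rotation/inference
tests share one realisation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pupilpca as pp


def make_recording(n_subjects=2, n_trials=3, times=None, pupil_fn=None,
                   conditions=None, seed=0):
    """Small handcrafted Recording: evenly spaced samples per trial."""
    rng = np.random.default_rng(seed)
    if times is None:
        times = np.arange(-500.0, 1000.0, 100.0)
    rows = []
    for s in range(n_subjects):
        for t in range(n_trials):
            if pupil_fn is not None:
                pupil = pupil_fn(s, t, times)
            else:
                pupil = rng.normal(0.0, 1.0, len(times))
            row = {"subject": f"s{s + 1}", "trial": t + 1,
                   "time": times, "pupil": pupil}
            if conditions:
                for name, fn in conditions.items():
                    row[name] = fn(s, t)
            rows.append(pd.DataFrame(row))
    cond_names = list(conditions) if conditions else []
    return pp.Recording(pd.concat(rows, ignore_index=True), conditions=cond_names)


def make_long_recording(rng, n_subjects=12, trials=16, n_times=1, n_levels=8,
                        subject_sd=0.3, noise_sd=1.0, beta=0.0, effect_window=None):
    """Vectorised builder of an epoched Recording for inference tests.

    ``beta`` is the per-level-step effect of the numeric condition on pupil
    size; when `effect_window` (lo, hi in ms) is given the effect applies
    only to timepoints inside it.
    """
    times = np.arange(n_times) * 10.0
    n = n_subjects * trials
    subj = np.repeat([f"s{i:02d}" for i in range(n_subjects)], trials * n_times)
    trial = np.tile(np.repeat(np.arange(trials), n_times), n_subjects)
    x = np.concatenate([rng.permuted(np.resize(np.arange(1.0, n_levels + 1), trials))
                        for _ in range(n_subjects)])
    xc = x - (n_levels + 1) / 2
    y = (rng.normal(0.0, noise_sd, n * n_times)
         + np.repeat(rng.normal(0.0, subject_sd, n_subjects), trials * n_times))
    if beta != 0.0:
        gain = np.ones(n_times)
        if effect_window is not None:
            gain = ((times >= effect_window[0]) & (times < effect_window[1])).astype(float)
        y = y + np.repeat(xc, n_times) * beta * np.tile(gain, n)
    df = pd.DataFrame({"subject": subj, "trial": trial,
                       "time": np.tile(times, n), "pupil": y,
                       "Luminance": np.repeat(x, n_times)})
    return pp.Recording(df, conditions=["Luminance"])


@pytest.fixture(scope="session")
def mat64():
    """Random 6 trials x 4 timepoints TrialMatrix for decomposition oracles."""
    rng = np.random.default_rng(7)
    values = rng.normal(0.0, 1.0, (6, 4)) + np.array([1.0, -0.5, 0.2, 0.8])
    meta = pd.DataFrame({"subject": ["a", "a", "a", "b", "b", "b"],
                         "trial": [1, 2, 3, 1, 2, 3],
                         "Luminance": [1, 2, 3, 1, 2, 3]})
    return pp.TrialMatrix(values=values, row_meta=meta,
                          col_times=np.array([0.0, 10.0, 20.0, 30.0]))


@pytest.fixture(scope="session")
def default_sim():
    """One realisation of the default simulation, run through the pipeline."""
    rec, truth = pp.simulate_dataset(pp.SimulationSpec(seed=20260101))
    rec = pp.interpolate_gaps(rec)
    tm = pp.to_trial_matrix(rec)
    return {"rec": rec, "truth": truth, "tm": tm}


@pytest.fixture(scope="session")
def default_pca(default_sim):
    return pp.TemporalPCA(default_sim["tm"], ncomp=3).fit()


@pytest.fixture(scope="session")
def default_rpca(default_sim):
    return pp.RotatedPCA(default_sim["tm"], ncomp=3).fit()
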