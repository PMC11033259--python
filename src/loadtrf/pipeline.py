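"""Convenience wrappers chaining the analysis stages for one subject.

These are thin compositions of the public module functions — preprocess,
band-limit the regressor into the same analysis band, split into trials,
cross-validate the ridge constant on the training portion, fit, evaluate
on the held-out trials, and run the circular-shift null under the
identical protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import (
    EvalResult,
    LagSpec,
    TRFModel,
    shifted_control,
    train_test_individual,
)
from .features import Regressor, align_regressor
from .preprocessing import (
    Recording,
    TrialSet,
    bandpass_regressor,
    preprocess,
    split_trials,
)


@dataclass
class SubjectResult:
    model: TRFModel
    evaluation: EvalResult
    null: EvalResult | None
    trials: TrialSet


def prepare_trials(
    recording: Recording,
    stimulus: Regressor,
    band: tuple[float, float] = (1.0, 10.0),
    fs_out: float = 250.0,
    n_trials: int = 10,
    run_preprocess: bool = True,
    **preprocess_kwargs,
) -> TrialSet | None:
    """Clean one recording, band-limit the stimulus, and split into trials.

    Returns None when the subject fails the quality gate.
    """
    if run_preprocess:
        cleaned, _ = preprocess(recording, band[0], band[1], fs_out=fs_out,
                                **preprocess_kwargs)
        if cleaned is None:
            return None
    else:
        cleaned = recording
    stim = bandpass_regressor(stimulus, band[0], band[1])
    if abs(stim.fs - cleaned.fs) > 1e-9:
        from .preprocessing import resample_to

        stim = resample_to(stim, cleaned.fs)
    stim, cleaned = align_regressor(stim, cleaned)
    return split_trials(stim, cleaned, n_trials)


def fit_subject(
    recording: Recording,
    stimulus: Regressor,
    lag_spec: LagSpec | None = None,
    band: tuple[float, float] = (1.0, 10.0),
    n_trials: int = 10,
    test_fraction: float = 0.2,
    shift_s: float = 2.0,
    grid: np.ndarray | None = None,
    run_null: bool = True,
    run_preprocess: bool = True,
    **preprocess_kwargs,
) -> SubjectResult | None:
    """Individual TRF analysis of one subject, with optional shifted null."""
    lag_spec = lag_spec or LagSpec(fs=recording.fs if not run_preprocess else 250.0)
    trials = prepare_trials(recording, stimulus, band, lag_spec.fs, n_trials,
                            run_preprocess, **preprocess_kwargs)
    if trials is None:
        return None
    model, result = train_test_individual(trials, lag_spec, test_fraction, grid=grid)
    null = None
    if run_null:
        null = shifted_control(trials, lag_spec, shift_s,
                               test_fraction=test_fraction, grid=grid)
    return SubjectResult(model, result, null, trials)
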