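"""Ridge temporal-response-function (TRF) estimation and evaluation.

The forward model is ``R(t) = sum_tau TRF(tau) S(t - tau) + eps(t)``:
the neural response at each channel is a lagged linear functional of a
univariate stimulus feature.  With ``S`` the time-lagged design matrix,
the ridge solution is ``TRF = (S'S + lambda*I)^-1 S'R``; an intercept
column is included and left unpenalized, which keeps the
``lambda -> inf`` limit well-defined (prediction collapses to the
per-channel mean).

Regularization is chosen by leave-one-trial-out cross-validation over a
21-point grid ``10^-5 ... 10^5`` (exponent step 0.5), maximizing the
grand-mean Pearson correlation between predicted and held-out responses.
Chance level is calibrated with a circular-shift control: the response
is rotated by 2 s within each trial, destroying stimulus-response
alignment while preserving signal statistics.

Lags span -200 ... 1000 ms by default: auditory/linguistic processing
relevant here completes within a second, and modest acausal lags let the
estimate express anticipatory or smearing structure without biasing the
causal part.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg

from .features import Regressor
from .preprocessing import TrialSet

logger = logging.getLogger(__name__)


def default_lambda_grid() -> np.ndarray:
    """The 21-value regularization grid: exponents -5.0, -4.5, ..., 5.0."""
    return 10.0 ** np.arange(-5.0, 5.0 + 1e-9, 0.5)


@dataclass(frozen=True)
class LagSpec:
    """Lag window for the TRF, in milliseconds, at sampling rate ``fs``."""

    tmin_ms: float = -200.0
    tmax_ms: float = 1000.0
    fs: float = 250.0

    def __post_init__(self) -> None:
        if self.tmin_ms > self.tmax_ms:
            raise ValueError("tmin must not exceed tmax")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def lag_samples(self) -> np.ndarray:
        lo = int(round(self.tmin_ms / 1000.0 * self.fs))
        hi = int(round(self.tmax_ms / 1000.0 * self.fs))
        return np.arange(lo, hi + 1)

    @property
    def lag_ms(self) -> np.ndarray:
        return self.lag_samples * 1000.0 / self.fs

    @property
    def n_lags(self) -> int:
        return self.lag_samples.size


@dataclass
class DesignMatrix:
    """Time-lagged stimulus matrix with a leading intercept column.

    ``X[t, 1 + j]`` holds ``S(t - lag_j)``; shifts running off either end
    are zero-padded so every row stays aligned across lags.
    """

    X: np.ndarray
    lag_ms: np.ndarray
    fs: float
    has_intercept: bool = True

    @property
    def n_times(self) -> int:
        return self.X.shape[0]


def build_design_matrix(
    stimulus: Regressor | np.ndarray, lag_spec: LagSpec, intercept: bool = True
) -> DesignMatrix:
    """Expand a univariate stimulus into its lagged design matrix."""
    if isinstance(stimulus, Regressor):
        if abs(stimulus.fs - lag_spec.fs) > 1e-9:
            raise ValueError(
                f"stimulus fs {stimulus.fs} != lag spec fs {lag_spec.fs}"
            )
        s = stimulus.values
    else:
        s = np.asarray(stimulus, dtype=float)
    if s.size == 0:
        raise ValueError("empty stimulus")
    n = s.size
    lags = lag_spec.lag_samples
    cols = np.zeros((n, lags.size + (1 if intercept else 0)))
    off = 1 if intercept else 0
    if intercept:
        cols[:, 0] = 1.0
    for j, k in enumerate(lags):
        if k == 0:
            cols[:, off + j] = s
        elif 0 < k < n:
            cols[k:, off + j] = s[: n - k]
        elif -n < k < 0:
            cols[: n + k, off + j] = s[-k:]
        # |k| >= n: the shifted copy is entirely outside; column stays zero
    return DesignMatrix(cols, lag_spec.lag_ms, lag_spec.fs, has_intercept=intercept)


@dataclass
class TRFModel:
    """Fitted forward model: per-channel lag weights plus bias.

    ``weights`` is channels x lags; ``bias`` per channel; ``lam`` the
    ridge constant used; ``lag_ms`` the lag axis.
    """

    weights: np.ndarray
    bias: np.ndarray
    lam: float
    lag_ms: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    direction: str = "forward"

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.bias = np.atleast_1d(np.asarray(self.bias, dtype=float))
        self.lag_ms = np.asarray(self.lag_ms, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite TRF weights")
        if self.weights.shape != (self.bias.size, self.lag_ms.size):
            raise ValueError(
                f"weights {self.weights.shape} inconsistent with "
                f"{self.bias.size} channels x {self.lag_ms.size} lags"
            )
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.weights.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in model") from None
        return self.weights[i]


def _penalty_matrix(n_cols: int, has_intercept: bool) -> np.ndarray:
    m = np.eye(n_cols)
    if has_intercept:
        m[0, 0] = 0.0
    return m


def _ridge_solve(gram: np.ndarray, xty: np.ndarray, lam: float,
                 has_intercept: bool) -> np.ndarray:
    a = gram + lam * _penalty_matrix(gram.shape[0], has_intercept)
    try:
        c, low = linalg.cho_factor(a)
        return linalg.cho_solve((c, low), xty)
    except linalg.LinAlgError:
        raise ValueError(
            "normal equations are singular (rank-deficient design with "
            "lambda = 0?); use a positive regularization constant"
        ) from None


def fit_ridge(
    design: DesignMatrix,
    response: np.ndarray,
    lam: float,
    channel_labels: Sequence[str] | None = None,
) -> TRFModel:
    """Solve ``(S'S + lambda*M) w = S'R`` per channel.

    ``response`` has time on its rows (``n_times x n_channels``).  The
    intercept diagonal of ``M`` is zero, leaving the bias unpenalized.
    """
    r = np.asarray(response, dtype=float)
    if r.ndim == 1:
        r = r[:, None]
    if r.shape[0] != design.n_times:
        raise ValueError(
            f"design has {design.n_times} rows but response has {r.shape[0]}"
        )
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    gram = design.X.T @ design.X
    xty = design.X.T @ r
    w = _ridge_solve(gram, xty, lam, design.has_intercept)
    if design.has_intercept:
        bias, weights = w[0], w[1:]
    else:
        bias, weights = np.zeros(r.shape[1]), w
    return TRFModel(
        weights.T, bias, lam, design.lag_ms, design.fs,
        channel_labels=list(channel_labels) if channel_labels else [],
    )


def predict(stimulus: Regressor | np.ndarray, model: TRFModel) -> np.ndarray:
    """Forward prediction: design matrix times weights plus bias.

    Returns a channels x time array of predicted responses.
    """
    lag_spec = _lag_spec_of(model)
    if isinstance(stimulus, Regressor) and abs(stimulus.fs - model.fs) > 1e-9:
        raise ValueError(f"stimulus fs {stimulus.fs} != model fs {model.fs}")
    design = build_design_matrix(stimulus, lag_spec, intercept=False)
    return model.weights @ design.X.T + model.bias[:, None]


def _lag_spec_of(model: TRFModel) -> LagSpec:
    return LagSpec(model.lag_ms[0], model.lag_ms[-1], model.fs)


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r between two (n x k) arrays; NaN where degenerate."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    num = np.sum(a * b, axis=0)
    den = np.sqrt(np.sum(a * a, axis=0) * np.sum(b * b, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


@dataclass
class CVResult:
    """Leave-one-trial-out cross-validation over the lambda grid."""

    lambda_grid: np.ndarray
    mean_r: np.ndarray  # one grand-mean r per lambda
    best_lambda: float
    fold_trials: list[int] = field(default_factory=list)  # held-out trial per fold

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        self.mean_r = np.asarray(self.mean_r, dtype=float)


@dataclass
class EvalResult:
    """Correlation between predicted and actual held-out responses."""

    r_per_channel: np.ndarray  # mean over test trials
    per_trial: np.ndarray  # n_test_trials x n_channels
    channel_labels: list[str] = field(default_factory=list)
    test_trials: list[int] = field(default_factory=list)
    train_trials: list[int] = field(default_factory=list)
    cv: CVResult | None = None

    @property
    def mean_r(self) -> float:
        return float(np.nanmean(self.r_per_channel))

    def channel_r(self, label: str) -> float:
        return float(self.r_per_channel[self.channel_labels.index(label)])


def _trial_sufficient_stats(trials: TrialSet, lag_spec: LagSpec):
    designs = [build_design_matrix(s, lag_spec) for s in trials.stimuli]
    resps = [r.T for r in trials.responses]  # time x channels
    grams = [d.X.T @ d.X for d in designs]
    xtys = [d.X.T @ r for d, r in zip(designs, resps)]
    return designs, resps, grams, xtys


def crossval_lambda(
    train_trials: TrialSet,
    lag_spec: LagSpec,
    grid: np.ndarray | None = None,
) -> CVResult:
    """Leave-one-trial-out CV of the ridge constant.

    For each lambda, each training trial in turn is held out, the model
    fit on the rest, and the held-out trial predicted; ``mean_r`` is the
    grand mean of the per-channel Pearson correlations over folds and
    channels.  Degenerate (zero-variance) channel segments contribute
    NaN and are ignored.  Ties break toward the smaller lambda.
    """
    if train_trials.n_trials < 2:
        raise ValueError("leave-one-out CV needs at least 2 trials")
    grid = default_lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    designs, resps, grams, xtys = _trial_sufficient_stats(train_trials, lag_spec)
    g_tot = sum(grams)
    b_tot = sum(xtys)
    fold_r = np.full((len(grid), train_trials.n_trials), np.nan)
    for f in range(train_trials.n_trials):
        g_f = g_tot - grams[f]
        b_f = b_tot - xtys[f]
        for li, lam in enumerate(grid):
            w = _ridge_solve(g_f, b_f, lam, True)
            pred = designs[f].X @ w
            r = _pearson_columns(pred, resps[f])
            fold_r[li, f] = np.nanmean(r)
    mean_r = np.nanmean(fold_r, axis=1)
    best = int(np.argmax(mean_r))  # argmax takes the first (smallest) maximizer
    return CVResult(grid, mean_r, float(grid[best]),
                    fold_trials=list(range(train_trials.n_trials)))


def _fit_on_trials(trials: TrialSet, idx: Sequence[int], lag_spec: LagSpec,
                   lam: float) -> TRFModel:
    sub = trials.subset(list(idx))
    _, resps, grams, xtys = _trial_sufficient_stats(sub, lag_spec)
    w = _ridge_solve(sum(grams), sum(xtys), lam, True)
    return TRFModel(w[1:].T, w[0], lam, lag_spec.lag_ms, lag_spec.fs,
                    channel_labels=trials.channel_labels)


def _evaluate(model: TRFModel, trials: TrialSet, idx: Sequence[int],
              lag_spec: LagSpec) -> tuple[np.ndarray, np.ndarray]:
    per_trial = []
    for i in idx:
        pred = predict(trials.stimuli[i], model)
        r = _pearson_columns(pred.T, trials.responses[i].T)
        if np.any(~np.isfinite(r)):
            logger.info("trial %d: %d degenerate channel(s) skipped in r",
                        i, int(np.sum(~np.isfinite(r))))
        per_trial.append(r)
    per_trial = np.array(per_trial)
    return np.nanmean(per_trial, axis=0), per_trial


def train_test_individual(
    trials: TrialSet,
    lag_spec: LagSpec,
    test_fraction: float = 0.2,
    test_trials: Sequence[int] | None = None,
    grid: np.ndarray | None = None,
) -> tuple[TRFModel, EvalResult]:
    """Within-subject protocol: 80/20 split, lambda by LOO-CV, refit, test.

    The held-out trials default to the last ``test_fraction`` of the
    trial sequence and never enter any CV fold; lambda is chosen on the
    training trials, the model refit on all of them at the best lambda,
    and the evaluation is the per-test-trial Pearson r averaged.
    """
    n = trials.n_trials
    if n < 5:
        raise ValueError(f"need at least 5 trials for a train/test split, got {n}")
    if test_trials is None:
        n_test = max(1, int(round(n * test_fraction)))
        test_idx = list(range(n - n_test, n))
    else:
        test_idx = sorted(set(int(i) for i in test_trials))
    train_idx = [i for i in range(n) if i not in test_idx]
    if len(train_idx) < 2:
        raise ValueError("too few training trials after the split")
    cv = crossval_lambda(trials.subset(train_idx), lag_spec, grid)
    cv.fold_trials = [train_idx[i] for i in cv.fold_trials]
    model = _fit_on_trials(trials, train_idx, lag_spec, cv.best_lambda)
    r_chan, per_trial = _evaluate(model, trials, test_idx, lag_spec)
    result = EvalResult(r_chan, per_trial, trials.channel_labels,
                        test_trials=test_idx, train_trials=train_idx, cv=cv)
    return model, result


def shifted_control(
    trials: TrialSet,
    lag_spec: LagSpec,
    shift_s: float = 2.0,
    **kwargs,
) -> EvalResult:
    """Null evaluation: circularly rotate the response 2 s within each trial.

    The rotation destroys stimulus-response alignment while preserving
    the signal's spectrum and amplitude statistics; the identical
    train/test protocol then yields the chance-level correlation.
    """
    shift = int(round(shift_s * trials.fs))
    shifted_resps = []
    for resp in trials.responses:
        if shift_s > 0 and resp.shape[1] < shift:
            raise ValueError(
                f"trial of {resp.shape[1]} samples shorter than shift {shift}"
            )
        shifted_resps.append(np.roll(resp, shift, axis=1))
    shifted = TrialSet(trials.stimuli, shifted_resps, trials.fs, trials.channel_labels)
    _, result = train_test_individual(shifted, lag_spec, **kwargs)
    return result


def train_test_generic(
    subjects: Sequence[TrialSet],
    lag_spec: LagSpec,
    grid: np.ndarray | None = None,
    method: str = "average",
) -> list[tuple[TRFModel, EvalResult]]:
    """Leave-one-subject-out generic models.

    For each held-out subject, the group-level best lambda maximizes the
    mean of the other subjects' LOO-CV curves; a TRF is fit on each of
    those subjects' full data at that lambda and the fits are averaged
    (``method="average"``; ``method="pooled"`` instead solves one ridge
    on the pooled normal equations).  The generic model is evaluated on
    every trial of the held-out subject.
    """
    if len(subjects) < 3:
        raise ValueError("generic modeling needs at least 3 subjects")
    labels0 = subjects[0].channel_labels
    for s in subjects[1:]:
        if s.channel_labels != labels0:
            raise ValueError("subjects have mismatched channel sets")
    if method not in ("average", "pooled"):
        raise ValueError(f"unknown generic method {method!r}")
    grid = default_lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    curves = [crossval_lambda(s, lag_spec, grid).mean_r for s in subjects]
    fit_cache: dict[tuple[int, float], TRFModel] = {}

    results = []
    for held in range(len(subjects)):
        others = [i for i in range(len(subjects)) if i != held]
        group_curve = np.nanmean([curves[i] for i in others], axis=0)
        lam = float(grid[int(np.argmax(group_curve))])
        if method == "average":
            models = []
            for i in others:
                key = (i, lam)
                if key not in fit_cache:
                    fit_cache[key] = _fit_on_trials(
                        subjects[i], range(subjects[i].n_trials), lag_spec, lam
                    )
                models.append(fit_cache[key])
            weights = np.mean([m.weights for m in models], axis=0)
            bias = np.mean([m.bias for m in models], axis=0)
            generic = TRFModel(weights, bias, lam, lag_spec.lag_ms, lag_spec.fs,
                               channel_labels=labels0)
        else:
            g_tot = 0
            b_tot = 0
            for i in others:
                _, _, grams, xtys = _trial_sufficient_stats(subjects[i], lag_spec)
                g_tot = g_tot + sum(grams)
                b_tot = b_tot + sum(xtys)
            # lambda was selected per subject; pooling n-1 subjects scales
            # the Gram by n-1, so the penalty scales with it
            w = _ridge_solve(g_tot, b_tot, lam * len(others), True)
            generic = TRFModel(w[1:].T, w[0], lam, lag_spec.lag_ms, lag_spec.fs,
                               channel_labels=labels0)
        r_chan, per_trial = _evaluate(
            generic, subjects[held], range(subjects[held].n_trials), lag_spec
        )
        results.append(
            (generic,
             EvalResult(r_chan, per_trial, labels0,
                        test_trials=list(range(subjects[held].n_trials)),
                        train_trials=others))
        )
    return results


def grand_average(models: Sequence[TRFModel], channel: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Across-model mean TRF and SEM (= sd / sqrt(n)) for one channel.

    Returns ``(mean, sem, lag_ms)``.
    """
    if not models:
        raise ValueError("no models to average")
    lag0 = models[0].lag_ms
    for m in models[1:]:
        if m.lag_ms.shape != lag0.shape or not np.allclose(m.lag_ms, lag0):
            raise ValueError("models have mixed lag axes")
    curves = np.array([m.channel(channel) for m in models])
    mean = curves.mean(axis=0)
    sem = curves.std(axis=0, ddof=1) / np.sqrt(len(models)) if len(models) > 1 else np.zeros_like(mean)
    return mean, sem, lag0.copy()
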