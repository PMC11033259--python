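"""ERP-like component features of TRFs and their behavioral statistics.

The lag range of a TRF is divided into four windows — 0–150 ms (N1/P1),
150–250 ms (N2/P2), 250–350 ms (N3/P3) and >350 ms (late negativity /
positivity) — and within each window both the signed maximum and minimum
weight and their latencies are extracted, analogous to ERP component
scoring.  These features are then correlated (Pearson r with two-tailed
p) against per-subject behavioral measures: the NASA-TLX task-load index
and a post-test comprehension score, both on a 0–100 scale.  Group
contrasts use a pooled-variance two-sample t-test, whose df is
``n_a + n_b - 2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import TRFModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComponentWindow:
    """Half-open latency window ``[lo_ms, hi_ms)`` with a short label."""

    label: str
    lo_ms: float
    hi_ms: float

    def name(self, polarity: str) -> str:
        """Component name in the conventional ERP style (P1, N2, ...)."""
        prefix = "P" if polarity == "positive" else "N"
        if self.label == "late":
            return "Late Positivity" if polarity == "positive" else "Late Negativity"
        return f"{prefix}{self.label}"


def default_windows(tmax_ms: float = 1000.0) -> list[ComponentWindow]:
    """The four component windows partitioning [0, tmax)."""
    return [
        ComponentWindow("1", 0.0, 150.0),
        ComponentWindow("2", 150.0, 250.0),
        ComponentWindow("3", 250.0, 350.0),
        ComponentWindow("late", 350.0, tmax_ms),
    ]


@dataclass(frozen=True)
class ComponentFeature:
    """Signed extremum of a TRF within one latency window."""

    subject: str
    condition: str
    regressor: str
    channel: str
    window: str
    polarity: str  # "positive" | "negative"
    amplitude: float
    latency: float  # ms

    @property
    def component(self) -> str:
        w = next(w for w in default_windows(max(self.latency + 1, 1000.0))
                 if w.label == self.window)
        return w.name(self.polarity)


@dataclass(frozen=True)
class BehavioralRecord:
    """Per subject x condition NASA-TLX and post-test scores, 0–100."""

    subject: str
    condition: str
    nasa_tlx: float
    post_test: float

    def __post_init__(self) -> None:
        for name in ("nasa_tlx", "post_test"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} = {v} outside [0, 100] for {self.subject}")


def window_extremum(
    weights: np.ndarray,
    lag_ms: np.ndarray,
    lo_ms: float,
    hi_ms: float,
    polarity: str,
) -> tuple[float, float]:
    """(amplitude, latency_ms) of the window's max or min weight.

    The window is half-open, ``lo_ms <= lag < hi_ms``; ties break toward
    the earliest latency.
    """
    mask = (lag_ms >= lo_ms) & (lag_ms < hi_ms)
    if not np.any(mask):
        raise ValueError(f"no lags inside window [{lo_ms}, {hi_ms}) ms")
    w = np.asarray(weights, dtype=float)[mask]
    lags = np.asarray(lag_ms, dtype=float)[mask]
    idx = int(np.argmax(w)) if polarity == "positive" else int(np.argmin(w))
    return float(w[idx]), float(lags[idx])


def extract_components(
    model: TRFModel,
    channel: str,
    windows: Sequence[ComponentWindow] | None = None,
    subject: str = "",
    condition: str = "",
    regressor: str = "",
) -> list[ComponentFeature]:
    """Both-polarity extrema of one channel's TRF in each latency window."""
    weights = model.channel(channel)  # KeyError if absent
    if windows is None:
        windows = default_windows(float(model.lag_ms[-1]))
    if model.lag_ms[-1] < 350.0:
        raise ValueError("model lag axis must cover at least [0, 350] ms")
    out = []
    for win in windows:
        for polarity in ("positive", "negative"):
            amp, lat = window_extremum(
                weights, model.lag_ms, win.lo_ms, win.hi_ms, polarity
            )
            out.append(
                ComponentFeature(subject, condition, regressor, channel,
                                 win.label, polarity, amp, lat)
            )
    return out


def ttest_two_sample(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, int, float]:
    """Pooled-variance Student t-test; returns ``(t, df, p_two_tailed)``."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero pooled variance; t-test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), int(a.size + b.size - 2), float(p)


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Sample Pearson r with two-tailed p from the t distribution on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), int(x.size)


def features_to_frame(features: Iterable[ComponentFeature]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject": f.subject, "condition": f.condition,
                "regressor": f.regressor, "channel": f.channel,
                "window": f.window, "polarity": f.polarity,
                "component": f.component,
                "amplitude": f.amplitude, "latency": f.latency,
            }
            for f in features
        ]
    )


def behavior_to_frame(records: Iterable[BehavioralRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"subject": r.subject, "condition": r.condition,
             "nasa_tlx": r.nasa_tlx, "post_test": r.post_test}
            for r in records
        ]
    )


REPORT_COLUMNS = ["Component", "Feature", "Ch", "Stimulus",
                  "Behavioral measure", "Condition", "r", "p value", "n"]


def build_feature_behavior_report(
    features: Iterable[ComponentFeature] | pd.DataFrame,
    behavior: Iterable[BehavioralRecord] | pd.DataFrame,
    measures: Sequence[str] = ("nasa_tlx", "post_test"),
    pooled: bool = False,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Correlate every TRF feature cell against the behavioral measures.

    One row per (component window x polarity, feature kind, channel,
    regressor, behavioral measure, condition): Pearson r, two-tailed p,
    and the n of subjects entering the cell.  p-values are uncorrected
    by default; ``bh_correction`` adds a Benjamini-Hochberg column.
    ``pooled=True`` adds rows with condition "all" computed across both
    conditions.  Cells with fewer than 3 subjects or zero variance are
    skipped (logged).
    """
    feat = features if isinstance(features, pd.DataFrame) else features_to_frame(features)
    beh = behavior if isinstance(behavior, pd.DataFrame) else behavior_to_frame(behavior)
    if feat.empty or beh.empty:
        raise ValueError("empty features or behavior table")
    merged = feat.merge(beh, on=["subject", "condition"], how="inner")
    if merged.empty:
        raise ValueError("no overlapping subject/condition keys between "
                         "features and behavioral records")

    conditions = [(c, merged[merged["condition"] == c])
                  for c in sorted(merged["condition"].unique())]
    if pooled:
        conditions.append(("all", merged))

    rows = []
    for cond_label, sub in conditions:
        cells = sub.groupby(["window", "polarity", "channel", "regressor"],
                            sort=True)
        for (window, polarity, channel, regressor), cell in cells:
            comp_name = cell["component"].iloc[0]
            for kind, col in (("amp", "amplitude"), ("lat", "latency")):
                for measure in measures:
                    x = cell[col].to_numpy(dtype=float)
                    y = cell[measure].to_numpy(dtype=float)
                    try:
                        r, p, n = pearson_with_p(x, y)
                    except ValueError as exc:
                        logger.info(
                            "skipping cell %s/%s/%s/%s/%s (%s): %s",
                            comp_name, kind, channel, regressor, measure,
                            cond_label, exc,
                        )
                        continue
                    rows.append({
                        "Component": comp_name, "Feature": kind, "Ch": channel,
                        "Stimulus": regressor, "Behavioral measure": measure,
                        "Condition": cond_label, "r": r, "p value": p, "n": n,
                    })
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if bh_correction and not report.empty:
        from statsmodels.stats.multitest import multipletests

        report["p value (BH)"] = multipletests(
            report["p value"].to_numpy(), method="fdr_bh"
        )[1]
    return report
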