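"""Readers and writers shared across the pipeline.

Recordings travel as a CSV matrix (rows = samples, columns = channels,
header row of 10–20 labels) plus a JSON sidecar carrying the sampling
rate, subject, condition, units and clean mask; EDF files are read
through MNE when available.  TRF models, evaluation tables, regressors
and reports are TSV; word streams are Praat TextGrids; behavioral
records are CSV (subject, condition, nasa_tlx, post_test).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .components import BehavioralRecord
from .encoding import EvalResult, TRFModel
from .features import Regressor, WordToken
from .preprocessing import Recording


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------


def save_recording(recording: Recording, path: str | Path) -> Path:
    """Write a recording as CSV + JSON sidecar; returns the sidecar path.

    Samples are serialized with ``repr`` round-trip precision, so a
    save/load cycle is bit-identical.
    """
    path = Path(path)
    df = pd.DataFrame(recording.samples.T, columns=recording.channel_labels)
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "fs": recording.fs,
        "subject_id": recording.subject_id,
        "condition": recording.condition,
        "units": "uV",
        "clean_mask": [bool(v) for v in recording.clean_mask],
    }, indent=1))
    return sidecar


def load_recording(path: str | Path, sidecar: str | Path | None = None) -> Recording:
    """Read a recording from CSV+sidecar or from an EDF file."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _load_edf(path)
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar {sidecar} not found for {path}")
    meta = json.loads(sidecar.read_text())
    if meta.get("units", "uV") != "uV":
        raise ValueError(f"{sidecar}: expected µV units, got {meta.get('units')!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    rec = Recording(
        df.to_numpy(dtype=float).T,
        fs=float(meta["fs"]),
        channel_labels=[str(c) for c in df.columns],
        subject_id=str(meta.get("subject_id", "")),
        condition=str(meta.get("condition", "")),
    )
    if "clean_mask" in meta:
        rec.clean_mask = np.asarray(meta["clean_mask"], dtype=bool)
    return rec


def _load_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - env dependent
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        raw.get_data() * 1e6,  # MNE loads volts; recordings are µV
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


# ---------------------------------------------------------------------------
# Behavioral records
# ---------------------------------------------------------------------------


def save_behavior(records: Iterable[BehavioralRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"subject": r.subject, "condition": r.condition,
          "nasa_tlx": r.nasa_tlx, "post_test": r.post_test} for r in records]
    ).to_csv(path, index=False)


def load_behavior(path: str | Path) -> list[BehavioralRecord]:
    df = pd.read_csv(path)
    required = {"subject", "condition", "nasa_tlx", "post_test"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        BehavioralRecord(str(row.subject), str(row.condition),
                         float(row.nasa_tlx), float(row.post_test))
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# TRF models, evaluations, regressors
# ---------------------------------------------------------------------------


def save_trf(model: TRFModel, path: str | Path, manifest: dict | None = None) -> Path:
    """TSV (rows = lags in ms, columns = channels) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(model.weights.T, columns=model.channel_labels)
    df.insert(0, "lag_ms", model.lag_ms)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "lambda": model.lam,
        "fs": model.fs,
        "lag_window_ms": [float(model.lag_ms[0]), float(model.lag_ms[-1])],
        "bias": [float(b) for b in model.bias],
        "direction": model.direction,
        "training": manifest or {},
    }, indent=1))
    return sidecar


def load_trf(path: str | Path, sidecar: str | Path | None = None) -> TRFModel:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    lag_ms = df.pop("lag_ms").to_numpy(dtype=float)
    return TRFModel(
        df.to_numpy(dtype=float).T,
        np.asarray(meta["bias"], dtype=float),
        float(meta["lambda"]),
        lag_ms,
        float(meta["fs"]),
        channel_labels=[str(c) for c in df.columns],
    )


def eval_to_frame(result: EvalResult, **extra) -> pd.DataFrame:
    rows = []
    for ti, trial in zip(result.test_trials, result.per_trial):
        for ch, r in zip(result.channel_labels, trial):
            rows.append({"trial": ti, "channel": ch, "r": r, **extra})
    return pd.DataFrame(rows)


def save_eval(result: EvalResult, path: str | Path, **extra) -> None:
    eval_to_frame(result, **extra).to_csv(path, sep="\t", index=False)


def save_regressor(regressor: Regressor, path: str | Path) -> None:
    """Two-column TSV: time_s, value."""
    t = np.arange(regressor.n_samples) / regressor.fs + regressor.t0
    pd.DataFrame({"time_s": t, "value": regressor.values}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def load_regressor(path: str | Path, name: str = "regressor") -> Regressor:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    fs = 1.0 / np.median(np.diff(t))
    return Regressor(df["value"].to_numpy(dtype=float), fs, name=name, t0=float(t[0]))


# ---------------------------------------------------------------------------
# TextGrid writing (long text format)
# ---------------------------------------------------------------------------


def write_textgrid(tokens: Sequence[WordToken], path: str | Path,
                   xmax: float | None = None, tier_name: str = "words") -> None:
    """Write word tokens as a one-tier Praat TextGrid (long format).

    Gaps between words become empty-label intervals so the tier tiles
    [0, xmax] completely.
    """
    tokens = sorted(tokens, key=lambda t: t.onset)
    if xmax is None:
        xmax = tokens[-1].offset if tokens else 1.0
    intervals: list[tuple[float, float, str]] = []
    cursor = 0.0
    for tok in tokens:
        if tok.onset > cursor:
            intervals.append((cursor, tok.onset, ""))
        intervals.append((tok.onset, tok.offset, tok.word))
        cursor = tok.offset
    if cursor < xmax:
        intervals.append((cursor, xmax, ""))

    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier_name}"',
        "        xmin = 0",
        f"        xmax = {xmax}",
        f"        intervals: size = {len(intervals)}",
    ]
    for i, (a, b, label) in enumerate(intervals, start=1):
        lines += [
            f"        intervals [{i}]:",
            f"            xmin = {a}",
            f"            xmax = {b}",
            f'            text = "{label.replace(chr(34), chr(34) * 2)}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ground truth sidecars
# ---------------------------------------------------------------------------


def save_ground_truth(truths: dict, path: str | Path) -> None:
    """JSON sidecar of per-regressor ground-truth kernels for test oracles."""
    payload = {}
    for name, truth in truths.items():
        payload[name] = {
            "components": [
                {"latency": c.latency, "amplitude": c.amplitude, "width": c.width}
                for c in truth.components
            ],
            "topography": [float(g) for g in truth.topography],
            "lag_window_ms": [truth.lag_spec.tmin_ms, truth.lag_spec.tmax_ms],
            "fs": truth.lag_spec.fs,
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_ground_truth(path: str | Path) -> dict:
    from .encoding import LagSpec
    from .synth import GroundTruthTRF, KernelComponent

    payload = json.loads(Path(path).read_text())
    out = {}
    for name, entry in payload.items():
        out[name] = GroundTruthTRF(
            tuple(KernelComponent(**c) for c in entry["components"]),
            np.asarray(entry["topography"], dtype=float),
            LagSpec(entry["lag_window_ms"][0], entry["lag_window_ms"][1], entry["fs"]),
        )
    return out
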