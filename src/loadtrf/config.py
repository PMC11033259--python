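"""Run configuration and manifests.

Every analysis parameter defaults to the reproduction value (1–10 Hz
band, 100 µV threshold, 250 Hz, 10 trials, -200…1000 ms lags, the
21-point lambda grid, 20% held-out test data, 2-s circular shift, the
four component windows).  Configurations round-trip through YAML
unchanged and reject unknown keys by name.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__


@dataclass
class RunConfig:
    # paths (optional; the simulate/all stages need none)
    eeg: str | None = None
    audio: str | None = None
    textgrid: str | None = None
    frequency_table: str | None = None
    behavior: str | None = None
    output_dir: str = "loadtrf_out"

    # preprocessing
    band_low_hz: float = 1.0
    band_high_hz: float = 10.0
    epoch_s: float = 1.0
    window_ms: float = 200.0
    std_threshold_uv: float = 100.0
    bad_channel_seconds: float = 100.0
    min_clean_s: float = 100.0
    fs_out_hz: float = 250.0

    # encoding
    n_trials: int = 10
    lag_tmin_ms: float = -200.0
    lag_tmax_ms: float = 1000.0
    lambda_exp_min: float = -5.0
    lambda_exp_max: float = 5.0
    lambda_exp_step: float = 0.5
    test_fraction: float = 0.2
    shift_s: float = 2.0
    generic_method: str = "average"  # or "pooled"
    envelope_mode: str = "faithful"  # or "broadband"

    # components / statistics
    channels_of_interest: list[str] = field(default_factory=lambda: ["Fz", "Cz"])
    bh_correction: bool = False

    # simulation
    n_per_group: int = 3
    duration_s: float = 120.0  # must clear the 100-s clean-data gate
    n_channels: int = 32
    snr_db: float = 0.0
    spectral_exponent: float = 1.0
    artifact_rate_per_min: float = 0.0
    group_offset_nasa: float = 20.0
    group_offset_post: float = -15.0
    couplings: list[dict] = field(default_factory=list)
    regressors: list[str] = field(default_factory=lambda: ["envelope"])

    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def lambda_grid(self):
        import numpy as np

        return 10.0 ** np.arange(
            self.lambda_exp_min, self.lambda_exp_max + 1e-9, self.lambda_exp_step
        )

    def lag_spec(self):
        from .encoding import LagSpec

        return LagSpec(self.lag_tmin_ms, self.lag_tmax_ms, self.fs_out_hz)


@dataclass
class RunManifest:
    """Provenance record emitted with every run: enough to re-execute."""

    config: dict
    version: str = __version__
    input_checksums: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def start(self) -> "RunManifest":
        self.started = _dt.datetime.now(_dt.timezone.utc).isoformat()
        return self

    def finish(self) -> "RunManifest":
        self.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
        return self

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))
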