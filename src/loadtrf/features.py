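"""Stimulus regressors for forward encoding models of continuous speech.

Two univariate regressors drive the analysis:

* the **audio envelope** — magnitude of the analytic (Hilbert) signal of
  the band-limited (1–10 Hz) speech waveform, tracking slow amplitude
  modulations of the narration;
* the **word frequency** regressor — a step function equal to
  ``6.33 - log10(wf)`` over each word's duration and zero elsewhere, so
  rarer (higher-surprisal) words get larger values.  The constant 6.33
  sits just above the maximum log10 frequency of the SUBTLEX-style
  corpus table (6.329), so even the most frequent word keeps a small
  positive value.

Word timings come from Praat TextGrid annotations (both the long and the
short text dialects are parsed); corpus frequencies from a two-column
TSV (word, log10_wf).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .preprocessing import Recording

logger = logging.getLogger(__name__)

#: Surprisal ceiling: just above the corpus maximum log10 frequency (6.329).
#: Fixed by convention, not recomputed from whatever table is supplied.
WF_CEILING = 6.33


@dataclass
class Regressor:
    """Univariate stimulus feature series aligned to the EEG time base.

    Parameters
    ----------
    values : 1-D array of feature values.
    fs : sampling rate in Hz.
    name : e.g. ``"envelope"`` or ``"word_frequency"``.
    t0 : offset in seconds of the regressor's first sample relative to
        the EEG clock (positive = regressor starts later).
    """

    values: np.ndarray
    fs: float
    name: str = "regressor"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("regressor values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("regressor contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class WordToken:
    """A single word interval: ``[onset, offset)`` in seconds."""

    onset: float
    offset: float
    word: str
    log10_wf: float = 0.0

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError(
                f"word {self.word!r}: onset {self.onset} must precede offset {self.offset}"
            )
        if self.log10_wf < 0:
            raise ValueError(f"word {self.word!r}: log10_wf must be >= 0")


class FrequencyTable:
    """Word -> log10 corpus-frequency lookup (case-insensitive).

    Lookups of out-of-vocabulary words return 0 (hence a regressor value
    of ``WF_CEILING``, the maximum-surprisal convention) and are logged.
    """

    def __init__(self, mapping: Mapping[str, float]):
        if not mapping:
            raise ValueError("frequency table is empty")
        self._table: dict[str, float] = {}
        for word, value in mapping.items():
            key = word.strip().lower()
            value = float(value)
            if value < 0:
                raise ValueError(f"negative log10_wf for {word!r}")
            if key in self._table and self._table[key] != value:
                raise ValueError(
                    f"duplicate word {key!r} with conflicting values "
                    f"{self._table[key]} and {value}"
                )
            self._table[key] = value

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, word: str) -> bool:
        return word.strip().lower() in self._table

    @property
    def words(self) -> list[str]:
        return list(self._table)

    @property
    def max_log10_wf(self) -> float:
        return max(self._table.values())

    def lookup(self, word: str) -> float:
        key = word.strip().lower()
        try:
            return self._table[key]
        except KeyError:
            logger.warning("word %r not in frequency table; using log10_wf = 0", word)
            return 0.0


def _bandpass_sos(low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz invalid for fs={fs} (Nyquist {nyq})")
    return butter(order, [low / nyq, high / nyq], btype="band", output="sos")


def compute_envelope(
    audio: np.ndarray,
    fs_audio: float,
    fs_out: float = 250.0,
    band: tuple[float, float] = (1.0, 10.0),
    mode: str = "faithful",
) -> Regressor:
    """Audio-envelope regressor.

    ``mode="faithful"`` follows the reproduction order: band-pass the
    waveform to 1–10 Hz, polyphase-resample to ``fs_out``, then take the
    magnitude of the analytic signal.  ``mode="broadband"`` is the more
    conventional order (|Hilbert| of the raw audio, then low-pass and
    resample) offered behind this flag.
    """
    from .preprocessing import _resample_series  # local import, avoids cycle

    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be a single channel")
    if fs_audio <= 2 * band[1]:
        raise ValueError(f"audio rate {fs_audio} too low for band {band}")
    if mode not in ("faithful", "broadband"):
        raise ValueError(f"unknown envelope mode {mode!r}")

    if not np.any(audio):
        logger.warning("compute_envelope: all-zero audio; returning zero regressor")
        n_out = int(round(audio.size * fs_out / fs_audio))
        return Regressor(np.zeros(n_out), fs_out, name="envelope")

    if mode == "faithful":
        filtered = sosfiltfilt(_bandpass_sos(band[0], band[1], fs_audio), audio)
        resampled = _resample_series(filtered, fs_audio, fs_out)
        env = np.abs(hilbert(resampled))
    else:
        env_full = np.abs(hilbert(audio))
        nyq = fs_audio / 2.0
        sos = butter(4, band[1] / nyq, btype="low", output="sos")
        env = _resample_series(sosfiltfilt(sos, env_full), fs_audio, fs_out)
        env = np.clip(env, 0.0, None)
    return Regressor(env, fs_out, name="envelope")


def word_frequency_regressor(
    tokens: Sequence[WordToken],
    table: FrequencyTable | None,
    duration_s: float,
    fs: float = 250.0,
) -> Regressor:
    """Step regressor: ``WF_CEILING - log10_wf`` over each word, 0 elsewhere.

    Sample assignment is half-open: the sample at ``round(onset*fs)`` is
    included, the one at ``round(offset*fs)`` excluded, so contiguous
    words never double-count a sample.  If ``table`` is given it
    overrides each token's stored ``log10_wf``.
    """
    n = int(round(duration_s * fs))
    values = np.zeros(n)
    ordered = sorted(tokens, key=lambda t: t.onset)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.onset < prev.offset:
            raise ValueError(
                f"overlapping tokens: {prev.word!r} [{prev.onset}, {prev.offset}) and "
                f"{cur.word!r} [{cur.onset}, {cur.offset})"
            )
    for tok in ordered:
        if tok.offset > duration_s:
            raise ValueError(
                f"token {tok.word!r} ends at {tok.offset} s, beyond duration {duration_s} s"
            )
        wf = table.lookup(tok.word) if table is not None else tok.log10_wf
        i0 = int(round(tok.onset * fs))
        i1 = int(round(tok.offset * fs))
        values[i0:i1] = WF_CEILING - wf
    return Regressor(values, fs, name="word_frequency")


# ---------------------------------------------------------------------------
# Praat TextGrid parsing (long and short text dialects)
# ---------------------------------------------------------------------------

_NUM = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")
_QUOTED = re.compile(r'"((?:[^"]|"")*)"')


class TextGridError(ValueError):
    """Malformed TextGrid file."""


def _tg_tokens(lines: list[str]) -> Iterable[tuple[int, str]]:
    """Yield (line_number, token) pairs: quoted strings or bare numbers."""
    for lineno, line in enumerate(lines, start=1):
        pos = 0
        while pos < len(line):
            m_q = _QUOTED.search(line, pos)
            m_n = _NUM.search(line, pos)
            # skip numbers that are part of key names like "item [1]" or "xmin ="
            if m_q and (not m_n or m_q.start() <= m_n.start()):
                yield lineno, '"' + m_q.group(1) + '"'
                pos = m_q.end()
            elif m_n:
                yield lineno, m_n.group(0)
                pos = m_n.end()
            else:
                break


def read_textgrid(path: str | Path, tier: str | None = None) -> list[WordToken]:
    """Parse a Praat TextGrid and return the word tokens of one interval tier.

    Both the long ("ooTextFile" with ``xmin =`` keys) and short (bare
    values) dialects are accepted.  Empty-label intervals are skipped.
    If ``tier`` is None the first interval tier is used; otherwise the
    tier with that name.
    """
    path = Path(path)
    raw = path.read_text(encoding="utf-8", errors="replace")
    lines = raw.splitlines()
    header = "".join(lines[:2])
    if "ooTextFile" not in header or "TextGrid" not in raw[:400]:
        raise TextGridError(f"{path}: line 1: not a Praat TextGrid header")

    # Strip key names from the long format so both dialects reduce to the
    # same token stream: numbers and quoted strings in a fixed order.
    body: list[str] = []
    for line in lines[2:]:
        stripped = line.strip()
        if stripped.startswith(("item", "intervals [", "points [")):
            # structural lines carry only an index; drop them entirely
            continue
        stripped = re.sub(r"^\s*(intervals|points):\s*size\s*=", "size =", stripped)
        stripped = re.sub(r"^\s*\w+\s*=\s*", "", stripped)
        body.append(stripped)

    toks = list(_tg_tokens(body))
    pos = 0

    def take(expect: str) -> tuple[int, str]:
        nonlocal pos
        if pos >= len(toks):
            raise TextGridError(f"{path}: unexpected end of file (expected {expect})")
        item = toks[pos]
        pos += 1
        return item

    if "<exists>" not in raw:
        raise TextGridError(f"{path}: TextGrid declares no tiers (missing <exists>)")
    take("file xmin")
    take("file xmax")
    _, n_tiers_tok = take("tier count")
    n_tiers = int(float(n_tiers_tok))

    chosen: list[WordToken] | None = None
    for _ in range(n_tiers):
        lineno, klass = take("tier class")
        klass = klass.strip('"')
        _, name = take("tier name")
        name = name.strip('"')
        take("tier xmin")
        take("tier xmax")
        _, size_tok = take("interval count")
        size = int(float(size_tok))
        tokens: list[WordToken] = []
        if klass == "IntervalTier":
            for _ in range(size):
                ln_a, a = take("interval xmin")
                ln_b, b = take("interval xmax")
                _, label = take("interval label")
                xmin, xmax = float(a), float(b)
                if xmax < xmin:
                    raise TextGridError(
                        f"{path}: line {ln_b}: interval [{xmin}, {xmax}] has offset < onset"
                    )
                label = label.strip('"').replace('""', '"').strip()
                if label and xmax > xmin:
                    tokens.append(WordToken(xmin, xmax, label))
        elif klass == "TextTier":
            for _ in range(size):
                take("point time")
                take("point mark")
            continue
        else:
            raise TextGridError(f"{path}: line {lineno}: unknown tier class {klass!r}")
        if tier is None or name == tier:
            chosen = tokens
            if tier is not None or chosen:
                break
            # first tier empty and no name requested: keep looking
    if chosen is None:
        wanted = f"tier {tier!r}" if tier else "an interval tier with words"
        raise TextGridError(f"{path}: no {wanted} found")
    return chosen


def read_frequency_table(path: str | Path) -> FrequencyTable:
    """Read a TSV with columns ``word`` and ``log10_wf`` into a FrequencyTable."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "word" not in cols or "log10_wf" not in cols:
        raise ValueError(f"{path}: expected columns 'word' and 'log10_wf', got {list(df.columns)}")
    return FrequencyTable(dict(zip(df[cols["word"]].astype(str), df[cols["log10_wf"]])))


def align_regressor(regressor: Regressor, recording: "Recording") -> tuple[Regressor, "Recording"]:
    """Trim a regressor and a recording to their common overlap.

    The regressor's ``t0`` gives the EEG-clock time of its first sample;
    the recording is taken to start at time 0.  Both must share a
    sampling rate.  Returns trimmed copies of equal length.
    """
    if abs(regressor.fs - recording.fs) > 1e-9:
        raise ValueError(
            f"sampling rates differ: regressor {regressor.fs} Hz vs recording {recording.fs} Hz"
        )
    fs = recording.fs
    shift = int(round(regressor.t0 * fs))  # regressor sample i is EEG sample i + shift
    reg_lo = max(0, -shift)
    rec_lo = max(0, shift)
    n = min(regressor.n_samples - reg_lo, recording.n_samples - rec_lo)
    if n <= 0:
        raise ValueError("regressor and recording do not overlap in time")
    new_reg = replace(regressor, values=regressor.values[reg_lo : reg_lo + n], t0=0.0)
    new_rec = recording.with_samples(recording.samples[:, rec_lo : rec_lo + n])
    return new_reg, new_rec
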