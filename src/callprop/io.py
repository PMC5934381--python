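"""WAV, config and marker-table I/O.

All audio on disk is RIFF PCM, 16-bit, mono. Foreign sample rates are accepted
on read (the rate travels with the Waveform); stereo files are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from callprop.types import PCM16_FULL_SCALE, Waveform

_PCM16_SCALE = 32768.0


def write_wav(path: str | Path, wave: Waveform) -> Path:
    """Export as 16-bit PCM mono; peaks above PCM16 full scale are an error."""
    peak = float(np.max(np.abs(wave.samples)))
    if peak > PCM16_FULL_SCALE + 1e-12:
        raise ValueError(f"peak {peak:.6f} would clip at 16-bit export")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.round(wave.samples * _PCM16_SCALE).astype(np.int16)
    wavfile.write(path, int(round(wave.sample_rate)), data)
    return path


def read_wav(path: str | Path) -> Waveform:
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: only mono WAV supported, got {data.ndim} channels")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _PCM16_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return Waveform(np.clip(samples, -1.0, 1.0), float(rate))


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Stable SHA-256 of a config mapping (canonical JSON serialization)."""
    canon = json.dumps(cfg, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()


def write_markers(path: str | Path, markers: pd.DataFrame) -> Path:
    """Sidecar marker table: columns (label, start_s, stop_s)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    markers.to_csv(path, index=False)
    return path


def read_markers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"label", "start_s", "stop_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: marker table needs columns {sorted(required)}")
    return df
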