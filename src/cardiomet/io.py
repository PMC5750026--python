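"""File I/O: WAV audio, CSV tables and JSON provenance sidecars.

Every generated file can be accompanied by a JSON sidecar recording the
generating spec and seed so a run is reproducible from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["read_wav", "write_wav", "write_sidecar", "read_sidecar", "file_digest"]


def read_wav(path):
    """Read a WAV file and return ``(samples_float, sample_rate)``.

    Integer PCM (16/24/32-bit) is rescaled to [-1, 1); float files are
    returned as-is.  Multi-channel files are averaged to mono.
    """
    sr, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return data, int(sr)


def write_wav(path, samples, sample_rate: int, subtype: str = "float32") -> None:
    """Write mono audio as WAV (``subtype`` 'float32' or 'pcm16')."""
    samples = np.asarray(samples, dtype=np.float64)
    if subtype == "float32":
        wavfile.write(path, int(sample_rate), samples.astype(np.float32))
    elif subtype == "pcm16":
        peak = max(np.max(np.abs(samples)), 1e-12)
        scaled = np.clip(samples / peak, -1, 1) * 32767
        wavfile.write(path, int(sample_rate), scaled.astype(np.int16))
    else:
        raise ValueError(f"unsupported WAV subtype {subtype!r}")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_sidecar(data_path, spec=None, seed=None, **extra) -> Path:
    """Write ``<data_path>.json`` recording the generating spec and seed."""
    data_path = Path(data_path)
    meta = {"file": data_path.name, "seed": seed, "spec": _jsonable(spec)}
    meta.update({k: _jsonable(v) for k, v in extra.items()})
    if data_path.exists():
        meta["sha256"] = file_digest(data_path)
    side = data_path.with_suffix(data_path.suffix + ".json")
    side.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return side


def read_sidecar(data_path) -> dict:
    data_path = Path(data_path)
    side = data_path.with_suffix(data_path.suffix + ".json")
    return json.loads(side.read_text())


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
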