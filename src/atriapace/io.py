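"""CSV round-tripping of recordings, trajectories, and run manifests."""
from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .exceptions import DataError
from .protocol import Recording

__all__ = ["read_recording_csv", "write_recording_csv", "write_manifest"]

_CHANNELS = ("ecg", "lap", "cs")


def write_recording_csv(path: Union[str, Path], rec: Recording,
                        float_format: str = "%.6g") -> Path:
    """Write a recording as CSV with columns time_ms, ecg, lap, cs."""
    path = Path(path)
    t = np.arange(len(rec)) / rec.sample_rate * 1000.0
    df = pd.DataFrame({"time_ms": t, "ecg": rec.ecg, "lap": rec.lap,
                       "cs": rec.cs})
    df.to_csv(path, index=False, float_format=float_format)
    return path


def read_recording_csv(path: Union[str, Path],
                       patient_id: str = None) -> Recording:
    """Read a recording written by :func:`write_recording_csv`.

    The sample rate is inferred from the time_ms column; the three channel
    columns are required.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("time_ms",) + _CHANNELS if c not in df.columns]
    if missing:
        raise DataError(f"recording CSV lacks columns: {missing}")
    t = df["time_ms"].to_numpy()
    if len(t) < 2:
        raise DataError("recording too short")
    dt = np.median(np.diff(t))
    fs = 1000.0 / dt
    return Recording(sample_rate=fs, ecg=df["ecg"].to_numpy(),
                     lap=df["lap"].to_numpy(), cs=df["cs"].to_numpy(),
                     patient_id=patient_id or path.stem)


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def write_manifest(out_dir: Union[str, Path], config: dict, seed,
                   outputs: dict) -> Path:
    """Write a reproducibility manifest (config hash, seed, versions,
    output-file hashes) next to the run outputs."""
    import atriapace
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    file_hashes = {}
    for name, p in outputs.items():
        p = Path(p)
        if p.exists():
            file_hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "config_hash": _hash_obj(config),
        "seed": seed,
        "versions": {
            "atriapace": atriapace.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": file_hashes,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
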