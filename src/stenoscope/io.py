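"""Audio and cohort-manifest I/O.

WAV support covers RIFF integer PCM (8/16/32-bit) and IEEE float, read
through :mod:`scipy.io.wavfile`. Integer codes are mapped to floats in
[-1, 1] by dividing by ``2**(bits-1)``. Manifests are CSV tables with a
``participant_id,stenosis_pct,path[,age,sex]`` header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .records import PCGRecord, stenosis_to_class

log = logging.getLogger(__name__)

_INT_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31}

REQUIRED_MANIFEST_COLUMNS = ("participant_id", "stenosis_pct", "path")


def read_wav(path: Union[str, Path], participant_id: Optional[str] = None) -> PCGRecord:
    """Read a WAV file into a :class:`PCGRecord` with float samples in [-1, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fs, data = wavfile.read(str(path))
    if data.size == 0:
        raise ValueError(f"{path}: zero-length audio")
    if data.ndim > 1:
        log.warning("%s: %d channels, keeping channel 0", path, data.shape[1])
        data = data[:, 0]
    if data.dtype in _INT_SCALE:
        samples = data.astype(float) / _INT_SCALE[data.dtype]
    elif data.dtype == np.dtype("uint8"):
        samples = (data.astype(float) - 128.0) / 128.0
    elif data.dtype.kind == "f":
        samples = data.astype(float)
    else:
        raise ValueError(f"{path}: unsupported WAV encoding {data.dtype}")
    return PCGRecord(samples=samples, fs=float(fs), participant_id=participant_id or path.stem)


def write_wav(path: Union[str, Path], record: PCGRecord, subtype: str = "float32") -> None:
    """Write a record as WAV. ``subtype`` is ``"float32"`` or ``"pcm16"``."""
    path = Path(path)
    if subtype == "float32":
        wavfile.write(str(path), int(round(record.fs)), record.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(record.samples, -1.0, 32767 / 32768)
        wavfile.write(
            str(path), int(round(record.fs)), np.round(clipped * 32768).astype(np.int16)
        )
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")


@dataclass
class CohortManifest:
    """Validated cohort table (one row per participant)."""

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table
        missing = [c for c in REQUIRED_MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing required columns: {missing}")
        dupes = df["participant_id"][df["participant_id"].duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate participant ids: {sorted(set(dupes))}")
        bad = df[(df["stenosis_pct"] < 0) | (df["stenosis_pct"] > 100)]
        if len(bad):
            raise ValueError(
                f"stenosis_pct outside [0, 100] for: {list(bad['participant_id'])}"
            )
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def participant_ids(self) -> list[str]:
        return list(self.table["participant_id"])

    def labels(self) -> pd.Series:
        return self.table["stenosis_pct"].map(stenosis_to_class)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.table.to_csv(path, index=False)


def load_manifest(path: Union[str, Path]) -> CohortManifest:
    """Load and validate a cohort manifest CSV."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    if len(df):
        df["stenosis_pct"] = df["stenosis_pct"].astype(float)
    manifest = CohortManifest(df)
    log.info("loaded manifest with %d participants from %s", len(manifest), path)
    return manifest


def manifest_from_rows(rows: Iterable[dict]) -> CohortManifest:
    rows = list(rows)
    if not rows:
        return CohortManifest(
            pd.DataFrame(columns=list(REQUIRED_MANIFEST_COLUMNS))
        )
    return CohortManifest(pd.DataFrame(rows))
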