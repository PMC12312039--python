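"""Delimited-text readers/writers, atlas table, and the run manifest.

All interchange is TSV with a header row: landmark tables (frame, t_s,
p1x..p6y), EAR/closure traces (t_s, value), drowsigram tables (t_s, state,
perclos, valid), ROI x time matrices (first column roi_id, remaining
columns the volume times), atlas label tables (roi_id, roi_name,
hemisphere, network) and the long-format band-power tables.  Readers check
the declared schema and fail with named columns before any computation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ocular import LANDMARK_COLUMNS
from .states import NETWORK_NAMES

__all__ = [
    "default_atlas",
    "read_atlas",
    "read_landmarks",
    "read_timeseries",
    "write_timeseries",
    "write_table",
    "read_table",
    "RunManifest",
]


def default_atlas(n_rois: int = 164) -> pd.DataFrame:
    """Synthetic ROI label table with seven-network assignments.

    Stands in for an anatomical parcellation (164 regions by default, the
    size of the AAL3 labelling) when no real atlas table is supplied: ROIs
    are split as evenly as possible across the seven canonical functional
    networks, alternating hemispheres.
    """
    counts = np.full(7, n_rois // 7)
    counts[: n_rois % 7] += 1
    rows = []
    i = 0
    for net, cnt in zip(NETWORK_NAMES, counts):
        for _ in range(cnt):
            i += 1
            hemi = "L" if i % 2 else "R"
            rows.append({"roi_id": f"roi-{i:03d}",
                         "roi_name": f"synthetic_{net}_{i:03d}_{hemi}",
                         "hemisphere": hemi, "network": net})
    return pd.DataFrame(rows)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} "
                         f"(header line 1: {list(df.columns)[:6]}...)")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_atlas(path) -> pd.DataFrame:
    atlas = read_table(path)
    _require_columns(atlas, ["roi_id", "network"], path)
    if atlas["roi_id"].duplicated().any():
        dup = atlas.loc[atlas["roi_id"].duplicated(), "roi_id"].iloc[0]
        raise ValueError(f"{path}: duplicate roi_id {dup!r}")
    unknown = set(atlas["network"]) - set(NETWORK_NAMES)
    if unknown:
        raise ValueError(f"{path}: network labels outside the declared "
                         f"vocabulary: {sorted(unknown)}")
    return atlas


def read_landmarks(path) -> pd.DataFrame:
    df = read_table(path)
    _require_columns(df, ["t_s", *LANDMARK_COLUMNS], path)
    if np.any(np.diff(df["t_s"].to_numpy()) <= 0):
        raise ValueError(f"{path}: t_s must be strictly increasing")
    return df


def read_timeseries(path, max_gap_tol: float = 1e-6):
    """Read an ROI x time TSV: first column roi_id, header row of times.

    Returns ``(roi_ids, t_s, values)`` with values shaped (n_roi, n_time).
    The time grid must be uniform to within ``max_gap_tol``.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "roi_id":
        raise ValueError(f"{path}: first column must be 'roi_id', "
                         f"got {df.columns[0]!r}")
    try:
        t_s = np.array([float(c) for c in df.columns[1:]])
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric time header: {e}") from None
    dt = np.diff(t_s)
    if dt.size and (dt <= 0).any():
        raise ValueError(f"{path}: time header not increasing")
    if dt.size and np.ptp(dt) > max_gap_tol:
        raise ValueError(f"{path}: time grid has gaps larger than tolerance")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return df["roi_id"].tolist(), t_s, values


def write_timeseries(roi_ids, t_s, values, path) -> Path:
    df = pd.DataFrame(np.asarray(values), columns=[f"{t:.6g}" for t in t_s])
    df.insert(0, "roi_id", list(roi_ids))
    return write_table(df, path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Machine-readable record of a pipeline run.

    Lists the configuration echo, random seed, per-stage decisions
    (thresholds, model families, df method) and a checksum for every file
    written, so a run can be audited and reproduced bit for bit.
    """

    config: dict
    seed: int
    decisions: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # name -> {path, sha256}

    def add_output(self, name: str, path) -> None:
        path = Path(path)
        self.outputs[name] = {"path": str(path), "sha256": _sha256(path)}

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {"config": self.config, "seed": self.seed,
                   "decisions": self.decisions, "outputs": self.outputs}
        path.write_text(json.dumps(payload, indent=2, default=_jsonable))
        return path

    @classmethod
    def read(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(config=d["config"], seed=d["seed"],
                   decisions=d.get("decisions", {}),
                   outputs=d.get("outputs", {}))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
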