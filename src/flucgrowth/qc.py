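"""Track-table I/O, cell-volume geometry, and quality control.

A track table is a delimited-text table with one row per cell per frame and
mandatory columns ``track_id, time_s, length_um, width_um`` (plus optional
``condition`` and ``replicate_day`` labels).  Cell volume is computed from
the measured length and width by approximating the cell as a cylinder with
hemispherical caps.  QC flags frames whose size measurements fall outside
plausible bounds or whose frame-to-frame volume step is too large to be
growth (and is not a division), then drops tracks left with too few clean
frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterator, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "volume_from_dims", "length_from_volume", "CellTrack", "QCCriteria",
    "QCReport", "apply_qc", "read_tracks", "write_tracks", "iter_tracks",
]

MANDATORY_COLUMNS = ("track_id", "time_s", "length_um", "width_um")


def volume_from_dims(length, width):
    """Cell volume (µm³) of a cylinder with hemispherical caps.

    V = pi (w/2)^2 (l - w) + (4/3) pi (w/2)^3, for length >= width > 0
    (equal length and width is the degenerate sphere).
    """
    l = np.asarray(length, dtype=float)
    w = np.asarray(width, dtype=float)
    if np.any(w <= 0) or np.any(l <= 0):
        raise ValueError("length and width must be positive")
    if np.any(l < w - 1e-12):
        raise ValueError("length must be at least the width "
                         "(sphere is the degenerate minimum)")
    out = np.pi * (w / 2.0) ** 2 * (l - w) + (np.pi / 6.0) * w ** 3
    return out if out.ndim else float(out)


def length_from_volume(volume, width):
    """Invert :func:`volume_from_dims` for the length at a given width."""
    v = np.asarray(volume, dtype=float)
    w = np.asarray(width, dtype=float)
    sphere = (np.pi / 6.0) * w ** 3
    if np.any(v < sphere - 1e-12):
        raise ValueError("volume below that of a sphere of the given width")
    out = w + (v - sphere) / (np.pi * (w / 2.0) ** 2)
    return out if out.ndim else float(out)


@dataclass
class CellTrack:
    """One cell's time-stamped length/width trajectory."""

    track_id: object
    times: np.ndarray        # s, strictly increasing
    lengths: np.ndarray      # µm
    widths: np.ndarray       # µm
    condition: str = ""
    replicate_day: str = ""

    @property
    def volumes(self) -> np.ndarray:
        return volume_from_dims(self.lengths, self.widths)

    def __len__(self) -> int:
        return len(self.times)


def iter_tracks(table: pd.DataFrame) -> Iterator[CellTrack]:
    """Yield :class:`CellTrack` views of a track table, one per track_id."""
    for tid, g in table.groupby("track_id", sort=True):
        g = g.sort_values("time_s")
        yield CellTrack(
            track_id=tid,
            times=g["time_s"].to_numpy(float),
            lengths=g["length_um"].to_numpy(float),
            widths=g["width_um"].to_numpy(float),
            condition=str(g["condition"].iloc[0]) if "condition" in g else "",
            replicate_day=str(g["replicate_day"].iloc[0])
            if "replicate_day" in g else "",
        )


@dataclass(frozen=True)
class QCCriteria:
    """Size bounds and noise filters applied before growth analysis.

    The thresholds are surrogates chosen to pass clean synthetic tracks and
    reject gross segmentation/tracking errors; they are deliberately loose
    relative to the physiological size range of *E. coli*.
    """

    min_length: float = 1.0    # µm
    max_length: float = 12.0   # µm
    min_width: float = 0.4     # µm
    max_width: float = 4.0     # µm
    max_rel_step: float = 0.5  # |dV|/V per frame, divisions excepted
    min_frames: int = 5        # unflagged frames required to keep a track
    division_drop: float = 0.25  # relative volume drop classified a division

    def __post_init__(self):
        if not (0 < self.min_length < self.max_length):
            raise ValueError("length bounds must be positive and ordered")
        if not (0 < self.min_width < self.max_width):
            raise ValueError("width bounds must be positive and ordered")
        if self.max_rel_step <= 0:
            raise ValueError("max_rel_step must be positive")
        if self.min_frames < 2:
            raise ValueError("min_frames must be at least 2")


@dataclass
class QCReport:
    """Per-condition QC counts and retention fractions."""

    per_condition: dict = field(default_factory=dict)

    def to_json(self, **kw) -> str:
        return json.dumps({"per_condition": self.per_condition}, **kw)

    @property
    def total_frames_in(self) -> int:
        return sum(c["frames_in"] for c in self.per_condition.values())

    @property
    def total_frames_out(self) -> int:
        return sum(c["frames_out"] for c in self.per_condition.values())


def _flag_frames(table: pd.DataFrame, crit: QCCriteria) -> pd.DataFrame:
    t = table.sort_values(["track_id", "time_s"]).reset_index(drop=True)
    l = t["length_um"].to_numpy(float)
    w = t["width_um"].to_numpy(float)
    size_bad = ((l < crit.min_length) | (l > crit.max_length)
                | (w < crit.min_width) | (w > crit.max_width) | (l < w))
    v = np.pi * (w / 2.0) ** 2 * np.maximum(l - w, 0.0) + (np.pi / 6) * w ** 3
    # relative step to previous frame within the same track
    vs = pd.Series(v)
    prev = vs.groupby(t["track_id"].to_numpy()).shift(1)
    rel = (vs - prev) / prev
    is_division = rel <= -crit.division_drop
    step_bad = rel.abs().gt(crit.max_rel_step) & ~is_division
    step_bad = step_bad.fillna(False).to_numpy()
    t = t.copy()
    t["_flag_size"] = size_bad
    t["_flag_step"] = step_bad
    return t


def apply_qc(table: pd.DataFrame,
             criteria: Optional[QCCriteria] = None,
             ) -> Tuple[pd.DataFrame, QCReport]:
    """Flag bad frames and drop under-sampled tracks.

    Frames violating the size bounds, or showing a non-division volume step
    beyond ``max_rel_step``, are removed; tracks retaining fewer than
    ``min_frames`` clean frames are dropped entirely.  Returns the retained
    table (flagged frames removed) and a :class:`QCReport` with per-condition
    counts.  The operation is idempotent.
    """
    if table is None or len(table) == 0:
        raise ValueError("empty track table")
    criteria = criteria or QCCriteria()
    t = _flag_frames(table, criteria)
    flagged = t["_flag_size"] | t["_flag_step"]
    clean = t[~flagged]
    sizes = clean.groupby("track_id")["time_s"].size()
    keep_ids = set(sizes[sizes >= criteria.min_frames].index)
    out = clean[clean["track_id"].isin(keep_ids)].drop(
        columns=["_flag_size", "_flag_step"]).reset_index(drop=True)

    cond_in = table["condition"] if "condition" in table else \
        pd.Series(["all"] * len(table), index=table.index)
    report = QCReport()
    t_cond = t["condition"] if "condition" in t else \
        pd.Series(["all"] * len(t), index=t.index)
    o_cond = out["condition"] if "condition" in out else \
        pd.Series(["all"] * len(out), index=out.index)
    for cond in sorted(set(map(str, cond_in.unique()))):
        m_in = t_cond.astype(str) == cond
        m_out = o_cond.astype(str) == cond
        frames_in = int(m_in.sum())
        frames_out = int(m_out.sum())
        report.per_condition[cond] = {
            "frames_in": frames_in,
            "frames_out": frames_out,
            "tracks_in": int(t.loc[m_in, "track_id"].nunique()),
            "tracks_out": int(out.loc[m_out, "track_id"].nunique())
            if frames_out else 0,
            "flagged_size": int(t.loc[m_in, "_flag_size"].sum()),
            "flagged_step": int(t.loc[m_in, "_flag_step"].sum()),
            "frame_retention": frames_out / frames_in if frames_in else 0.0,
        }
    return out, report


def write_tracks(table: pd.DataFrame, path, provenance: Optional[str] = None
                 ) -> None:
    """Write a track table as comma-delimited text (optional '#' header)."""
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"track table missing mandatory columns: {missing}")
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        table.to_csv(fh, index=False)


def read_tracks(path) -> pd.DataFrame:
    """Read a track table, validating schema and per-track time ordering.

    Raises ``ValueError`` naming any missing mandatory column, or the
    track_id of the first track whose times are not strictly increasing.
    Unknown columns are preserved.
    """
    table = pd.read_csv(path, comment="#")
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"track table {path} missing mandatory columns: {missing}")
    for tid, g in table.groupby("track_id", sort=False):
        dt = np.diff(g["time_s"].to_numpy(float))
        if np.any(dt <= 0):
            raise ValueError(
                f"times not strictly increasing for track_id {tid!r}")
    return table
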