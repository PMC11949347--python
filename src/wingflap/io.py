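"""On-disk container for depth/RGB sequences and the morphometrics table.

A sequence is a plain directory — one 16-bit grayscale PNG per depth frame
(unsigned millimetres, 0 = no return), one 8-bit PNG per RGB frame, and a
JSON manifest carrying rig metadata, timestamps (integer microseconds) and
optional ground truth.  Everything is lossless and inspectable with
standard image tools, unlike the proprietary capture containers such
recordings usually arrive in.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .bundle import DEPTH_SCALE_CM, GroundTruth, SequenceBundle
from .rig import CameraRig

MANIFEST_NAME = "manifest.json"
FORMAT_NAME = "wingflap-sequence"

#: canonical morphometrics column order
MORPHO_COLUMNS = [
    "hen_id", "weight_kg", "folded_wing_cm",
    "extended_primary_cm", "extended_phalange_cm", "max_height_cm",
]
REQUIRED_MEASURES = MORPHO_COLUMNS[1:5]


# ---------------------------------------------------------------------------
# sequence container
# ---------------------------------------------------------------------------

def _cm_to_mm_u16(frame_cm: np.ndarray) -> np.ndarray:
    mm = np.rint(np.asarray(frame_cm, dtype=np.float64) / DEPTH_SCALE_CM)
    if mm.min() < 0 or mm.max() > np.iinfo(np.uint16).max:
        raise ValueError("depth out of uint16 millimetre range")
    return mm.astype(np.uint16)


def write_sequence(bundle: SequenceBundle, path: Union[str, Path]) -> Path:
    """Write a bundle to ``path`` and return the manifest location."""
    path = Path(path)
    (path / "depth").mkdir(parents=True, exist_ok=True)
    (path / "rgb").mkdir(parents=True, exist_ok=True)

    depth_files, rgb_files = [], []
    for i in range(bundle.n_depth):
        name = f"depth/depth_{i:06d}.png"
        iio.imwrite(path / name, _cm_to_mm_u16(bundle.depth_frames[i]))
        depth_files.append(name)
    for j in range(bundle.n_rgb):
        name = f"rgb/rgb_{j:06d}.png"
        iio.imwrite(path / name, bundle.rgb_frames[j])
        rgb_files.append(name)

    manifest = {
        "format": FORMAT_NAME,
        "version": 1,
        "depth_scale_cm_per_unit": DEPTH_SCALE_CM,
        "rig": bundle.rig.to_dict(),
        "depth": {
            "files": depth_files,
            "timestamps_us": [int(round(t * 1e6)) for t in bundle.depth_timestamps],
        },
        "rgb": {
            "files": rgb_files,
            "timestamps_us": [int(round(t * 1e6)) for t in bundle.rgb_timestamps],
        },
        "ground_truth": None if bundle.ground_truth is None else {
            "max_height_cm": [float(v) for v in bundle.ground_truth.max_height_cm],
            "peak_frame_index": int(bundle.ground_truth.peak_frame_index),
        },
        "provenance": dict(bundle.meta),
    }
    manifest_path = path / MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path


def read_sequence(path: Union[str, Path]) -> SequenceBundle:
    """Read a sequence directory back into memory, validating as it goes.

    Every frame file the manifest references must exist; a truncated stream
    raises immediately, naming the missing file.
    """
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {path}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format") != FORMAT_NAME:
        raise ValueError(f"not a {FORMAT_NAME} directory: {path}")
    scale = float(manifest["depth_scale_cm_per_unit"])
    rig = CameraRig.from_dict(manifest["rig"])

    def _load(entry: dict, kind: str) -> tuple[np.ndarray, np.ndarray]:
        files, ts_us = entry["files"], entry["timestamps_us"]
        if len(files) != len(ts_us):
            raise ValueError(f"{kind}: file count does not match timestamp count")
        frames = []
        for name in files:
            f = path / name
            if not f.exists():
                raise FileNotFoundError(f"{kind} frame listed in manifest is missing: {name}")
            frames.append(iio.imread(f))
        ts = np.asarray(ts_us, dtype=np.int64) / 1e6
        return (np.stack(frames) if frames else
                np.empty((0,), dtype=float)), ts

    depth_u16, depth_ts = _load(manifest["depth"], "depth")
    rgb, rgb_ts = _load(manifest["rgb"], "rgb")
    depth = depth_u16.astype(np.float64) * scale

    gt = manifest.get("ground_truth")
    ground_truth = None
    if gt is not None:
        ground_truth = GroundTruth(np.asarray(gt["max_height_cm"], dtype=float),
                                   int(gt["peak_frame_index"]))
    return SequenceBundle(
        depth_frames=depth,
        depth_timestamps=depth_ts,
        rgb_frames=rgb,
        rgb_timestamps=rgb_ts,
        rig=rig,
        ground_truth=ground_truth,
        meta=dict(manifest.get("provenance", {})),
    )


# ---------------------------------------------------------------------------
# morphometrics table
# ---------------------------------------------------------------------------

@dataclass
class HenMorphometrics:
    """One hen's body weight, three wing measures and (optionally) the
    maximum wing-flap height measured by the pipeline.

    Wing measures, all from the left wing: ``folded_wing_cm`` runs from the
    carpal joint to the longest primary-feather tip on the folded wing;
    ``extended_primary_cm`` and ``extended_phalange_cm`` run from the body
    to the primary-feather tip and to the distal phalange tip of the fully
    extended wing.  Feathers extend past bone, so a physically consistent
    record has ``extended_primary_cm >= extended_phalange_cm``.
    """

    hen_id: str
    weight_kg: float
    folded_wing_cm: float
    extended_primary_cm: float
    extended_phalange_cm: float
    max_height_cm: Optional[float] = None
    flags: tuple = ()

    def validate(self) -> "HenMorphometrics":
        flags = list(self.flags)
        for name in REQUIRED_MEASURES:
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v <= 0:
                flags.append(f"nonpositive:{name}")
        if (np.isfinite(self.extended_primary_cm) and np.isfinite(self.extended_phalange_cm)
                and self.extended_primary_cm < self.extended_phalange_cm):
            flags.append("inconsistent:extended_primary_cm<extended_phalange_cm")
        if self.max_height_cm is not None and not (
                np.isfinite(self.max_height_cm) and self.max_height_cm > 0):
            flags.append("nonpositive:max_height_cm")
        self.flags = tuple(flags)
        return self

    @property
    def ok(self) -> bool:
        return not self.flags


def _normalise(name: str) -> str:
    return str(name).strip().lower().replace(" ", "_")


def _frame_to_records(df: pd.DataFrame) -> List[HenMorphometrics]:
    records = []
    for i, row in df.reset_index(drop=True).iterrows():
        hen_id = row.get("hen_id")
        if hen_id is None or (isinstance(hen_id, float) and np.isnan(hen_id)):
            hen_id = f"hen_{i + 1:02d}"
        mh = row.get("max_height_cm")
        if mh is not None and isinstance(mh, float) and np.isnan(mh):
            mh = None
        rec = HenMorphometrics(
            hen_id=str(hen_id),
            weight_kg=float(row["weight_kg"]),
            folded_wing_cm=float(row["folded_wing_cm"]),
            extended_primary_cm=float(row["extended_primary_cm"]),
            extended_phalange_cm=float(row["extended_phalange_cm"]),
            max_height_cm=None if mh is None else float(mh),
        ).validate()
        records.append(rec)
    return records


def read_morphometrics(
    path: Union[str, Path],
    column_map: Optional[dict] = None,
) -> List[HenMorphometrics]:
    """Read a per-hen morphometrics table (CSV, or XLSX with any number of
    worksheets, merged on hen id).

    ``column_map`` maps source column names to the canonical ones
    (``hen_id``, ``weight_kg``, ``folded_wing_cm``, ``extended_primary_cm``,
    ``extended_phalange_cm``, ``max_height_cm``) for files whose headers
    differ.  Rows violating positivity or wing-consistency invariants are
    returned flagged, never dropped.
    """
    path = Path(path)
    column_map = {_normalise(k): v for k, v in (column_map or {}).items()}

    def _prep(df: pd.DataFrame) -> pd.DataFrame:
        df = df.rename(columns=lambda c: column_map.get(_normalise(c), _normalise(c)))
        return df

    if path.suffix.lower() in (".xlsx", ".xls"):
        sheets = pd.read_excel(path, sheet_name=None)
        usable = []
        for name, df in sheets.items():
            df = _prep(df)
            if any(c in df.columns for c in REQUIRED_MEASURES + ["max_height_cm"]):
                usable.append(df)
        if not usable:
            raise ValueError(
                f"no worksheet in {path.name} contains recognised columns; "
                f"expected some of {MORPHO_COLUMNS} (pass column_map to rename)")
        df = usable[0]
        for other in usable[1:]:
            if "hen_id" in df.columns and "hen_id" in other.columns:
                df = df.merge(other, on="hen_id", how="outer")
            else:
                extra = [c for c in other.columns if c not in df.columns]
                df = pd.concat([df.reset_index(drop=True),
                                other[extra].reset_index(drop=True)], axis=1)
    else:
        try:
            df = _prep(pd.read_csv(path))
        except pd.errors.EmptyDataError:
            warnings.warn(f"morphometrics file {path.name} is empty")
            return []

    if df.empty:
        warnings.warn(f"morphometrics file {path.name} has no rows")
        return []
    missing = [c for c in REQUIRED_MEASURES if c not in df.columns]
    if missing:
        raise ValueError(f"morphometrics table is missing required columns: {missing}")
    return _frame_to_records(df)


def write_morphometrics(records: Iterable[HenMorphometrics], path: Union[str, Path]) -> Path:
    """Write records to the canonical CSV layout."""
    path = Path(path)
    rows = []
    for r in records:
        d = {k: getattr(r, k) for k in MORPHO_COLUMNS}
        rows.append(d)
    pd.DataFrame(rows, columns=MORPHO_COLUMNS).to_csv(path, index=False)
    return path


def morphometrics_frame(records: Iterable[HenMorphometrics]) -> pd.DataFrame:
    """Records as a DataFrame in canonical column order."""
    return pd.DataFrame(
        [{k: getattr(r, k) for k in MORPHO_COLUMNS} for r in records],
        columns=MORPHO_COLUMNS,
    )
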