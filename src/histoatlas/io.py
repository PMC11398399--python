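"""Readers and writers for the standard formats the pipeline touches.

NIfTI-1 for volumes, 4D atlases and vector fields (with an intent code
distinguishing velocity from displacement); FreeSurfer-style colour lookup
tables; CSV cohorts; YAML tissue-clustering configuration.

Coordinate convention, used everywhere: 0-based voxel indices, sampling at
voxel centres, ``world = affine @ (i, j, k, 1)``, RAS orientation assumed
on write.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import LabelVolume, ProbAtlas, Volume
from .segment import TissueClustering
from .stats import REQUIRED_COLUMNS, CohortTable

log = logging.getLogger("histoatlas")

INTENT_VELOCITY = 1007  # NIFTI_INTENT_VECTOR, velocity flavour via description
INTENT_DISPLACEMENT = 1006


def read_volume(path):
    """Read a NIfTI volume as ``(data, affine, header)``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return data, np.asarray(img.affine), img.header


def write_volume(path, data, affine=None, dtype=None):
    """Write an array as NIfTI-1; integer inputs keep an integer dtype."""
    data = np.asarray(data)
    if dtype is not None:
        data = data.astype(dtype)
    elif np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, np.eye(4) if affine is None else np.asarray(affine))
    nib.save(img, str(path))
    return Path(path)


def write_label_volume(path, vol: LabelVolume):
    return write_volume(path, vol.data, vol.affine)


def read_label_volume(path) -> LabelVolume:
    data, affine, _ = read_volume(path)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path}: label volume has non-integer values")
        data = data.astype(np.int32)
    return LabelVolume(np.asarray(data), affine)


def write_atlas(path, atlas: ProbAtlas):
    """Probabilistic atlas as a 4D NIfTI (label axis last) + label list."""
    p = write_volume(path, atlas.probs.astype(np.float32), atlas.affine)
    side = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_labels.txt")
    side.write_text("\n".join(str(int(l)) for l in atlas.labels) + "\n")
    return p


def read_atlas(path) -> ProbAtlas:
    data, affine, _ = read_volume(path)
    side = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_labels.txt")
    if side.exists():
        labels = np.array([int(x) for x in side.read_text().split()])
    else:
        labels = np.arange(data.shape[-1])
    return ProbAtlas(np.asarray(data, float), labels, affine)


def write_field(path, field, affine=None, kind: str = "velocity"):
    data = np.asarray(field, dtype=np.float32)
    img = nib.Nifti1Image(data, np.eye(4) if affine is None else np.asarray(affine))
    img.header["intent_code"] = (
        INTENT_VELOCITY if kind == "velocity" else INTENT_DISPLACEMENT
    )
    img.header["descrip"] = f"histoatlas {kind} field (voxel units)".encode()
    nib.save(img, str(path))
    return Path(path)


def read_field(path):
    data, affine, header = read_volume(path)
    kind = (
        "velocity"
        if int(header["intent_code"]) == INTENT_VELOCITY
        else "displacement"
    )
    return np.asarray(data, float), affine, kind


# ---------------------------------------------------------------------------
# label lookup tables (FreeSurfer-style colour LUT)

@dataclass
class LabelLUT:
    """Rows of (id, name, R, G, B, A)."""

    entries: list  # list of (int, str, int, int, int, int)

    def __post_init__(self):
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate label ids in LUT: {dup}")
        for e in self.entries:
            if e[0] < 0:
                raise ValueError(f"negative label id: {e[0]}")
            if any(not 0 <= c <= 255 for c in e[2:6]):
                raise ValueError(f"colour out of range for label {e[0]}")

    @property
    def ids(self):
        return [e[0] for e in self.entries]

    def name(self, label_id: int) -> str:
        for e in self.entries:
            if e[0] == label_id:
                return e[1]
        raise KeyError(label_id)


def read_lut(path) -> LabelLUT:
    """Parse a whitespace-separated colour table; '#' starts a comment.

    Unknown trailing columns are ignored (with a log notice).
    """
    entries = []
    noticed = False
    for ln in Path(path).read_text().splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        parts = ln.split()
        if len(parts) < 6:
            raise ValueError(f"LUT line has fewer than 6 columns: {ln!r}")
        if len(parts) > 6 and not noticed:
            log.info("LUT has extra trailing columns; ignoring them")
            noticed = True
        entries.append(
            (
                int(parts[0]),
                parts[1],
                int(parts[2]),
                int(parts[3]),
                int(parts[4]),
                int(parts[5]),
            )
        )
    return LabelLUT(entries)


def write_lut(path, lut: LabelLUT):
    lines = ["# id name R G B A"]
    for e in lut.entries:
        lines.append(f"{e[0]} {e[1]} {e[2]} {e[3]} {e[4]} {e[5]}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


# ---------------------------------------------------------------------------
# cohorts and clustering config

def read_cohort(path) -> CohortTable:
    """CSV with subject_id, age_years, sex, icv_mm3 and ``*_mm3`` ROI columns."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing required columns: {missing}")
    table = CohortTable(df)
    if not table.roi_columns:
        raise ValueError("cohort file has no ROI columns (suffix _mm3)")
    return table


def write_cohort(path, cohort: CohortTable):
    cohort.df.to_csv(path, index=False)
    return Path(path)


def read_clustering(path) -> TissueClustering:
    """YAML with ``classes: [names...]`` and ``labels: {id: class index or name}``."""
    cfg = yaml.safe_load(Path(path).read_text())
    names = tuple(cfg["classes"])
    mapping = {}
    for lab, cls in cfg["labels"].items():
        if isinstance(cls, str):
            cls = names.index(cls)
        mapping[int(lab)] = int(cls)
    return TissueClustering(mapping, names)


def write_clustering(path, clustering: TissueClustering):
    cfg = {
        "classes": list(clustering.class_names),
        "labels": {int(k): int(v) for k, v in clustering.label_to_class.items()},
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
    return Path(path)


def write_run_log(out_dir, command: str, params: dict):
    """Structured reproducibility record written beside every CLI output."""
    import platform
    import time as _time

    from . import __version__

    rec = {
        "command": command,
        "parameters": params,
        "version": __version__,
        "python": platform.python_version(),
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    p = Path(out_dir) / f"{command}_run.json"
    p.write_text(json.dumps(rec, indent=2, default=str) + "\n")
    return p
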