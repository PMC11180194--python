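"""Recordings container: HDF5 layout, manifest CSV and ground-truth sidecar.

Layout::

    /patients/<pid>/trajectories/<tid>/sites/<k>
        datasets: lfp, spk   (float32)
        attrs:    fs, depth_mm, subregion ∈ {pre, motor, nonmotor}

Depth increases with penetration.  The manifest CSV carries one row per
trajectory with its site count and subregion boundary depths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["SiteRecord", "write_container", "read_container",
           "write_manifest", "write_sidecar", "read_sidecar"]

SUBREGIONS = ("pre", "motor", "nonmotor")


@dataclass
class SiteRecord:
    """One 4-s recording site: the atomic unit of all signal operations."""

    patient: str
    trajectory: str
    site_index: int
    depth_mm: float
    subregion: str
    fs: float
    lfp: np.ndarray
    spk: np.ndarray

    def __post_init__(self) -> None:
        if self.subregion not in SUBREGIONS:
            raise ValueError(f"unknown subregion {self.subregion!r}")

    @property
    def duration_s(self) -> float:
        return len(self.lfp) / self.fs


def write_container(path: str | Path, sites: list[SiteRecord]) -> None:
    with h5py.File(path, "w") as h5:
        for s in sites:
            grp = h5.require_group(
                f"patients/{s.patient}/trajectories/{s.trajectory}"
                f"/sites/{s.site_index}")
            grp.create_dataset("lfp", data=np.asarray(s.lfp, np.float32))
            grp.create_dataset("spk", data=np.asarray(s.spk, np.float32))
            grp.attrs["fs"] = s.fs
            grp.attrs["depth_mm"] = s.depth_mm
            grp.attrs["subregion"] = s.subregion


def read_container(path: str | Path) -> list[SiteRecord]:
    """Read all sites, ordered by (patient, trajectory, site index)."""
    sites: list[SiteRecord] = []
    with h5py.File(path, "r") as h5:
        for pid in sorted(h5["patients"]):
            pgrp = h5[f"patients/{pid}/trajectories"]
            for tid in sorted(pgrp):
                sgrp = pgrp[f"{tid}/sites"]
                for k in sorted(sgrp, key=int):
                    g = sgrp[k]
                    sites.append(SiteRecord(
                        patient=pid, trajectory=tid, site_index=int(k),
                        depth_mm=float(g.attrs["depth_mm"]),
                        subregion=str(g.attrs["subregion"]),
                        fs=float(g.attrs["fs"]),
                        lfp=g["lfp"][:], spk=g["spk"][:]))
    return sites


def write_manifest(path: str | Path, sites: list[SiteRecord]) -> pd.DataFrame:
    rows = []
    df = pd.DataFrame([{
        "patient": s.patient, "trajectory": s.trajectory,
        "depth_mm": s.depth_mm, "subregion": s.subregion} for s in sites])
    for (pid, tid), g in df.groupby(["patient", "trajectory"], sort=True):
        row = {"patient": pid, "trajectory": tid, "n_sites": len(g)}
        for sub in SUBREGIONS:
            sel = g[g.subregion == sub]
            row[f"{sub}_start_mm"] = sel.depth_mm.min() if len(sel) else np.nan
            row[f"{sub}_end_mm"] = sel.depth_mm.max() if len(sel) else np.nan
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(path, index=False)
    return manifest


def write_sidecar(path: str | Path, truth: dict) -> None:
    """Ground-truth sidecar recording every drawn generator parameter."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=_jsonable)


def read_sidecar(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
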