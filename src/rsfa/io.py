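"""Readers and writers for the package's on-disk formats.

NIfTI (via nibabel) for 4D BOLD, masks and 3D maps; tab-separated text for
cohort tables, motion tables, event tables, waveforms and feature tables;
HDF5 for multichannel sensor runs; JSON for mediation results.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .bands import SensorRun
from .cardiac import Waveform
from .fluctuation import BoldRun, RsfaMap
from .mediation import MediationResult


def _affine(voxel_size_mm: float = 3.0) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= voxel_size_mm
    return aff


def save_nifti(values: np.ndarray, path: str | Path, voxel_size_mm: float = 3.0) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float64), _affine(voxel_size_mm)), path)
    return path


def load_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_bold_run(run: BoldRun, out_dir: str | Path, prefix: str = "run") -> dict[str, Path]:
    """BOLD data + masks as NIfTI, motion as TSV; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bold": save_nifti(run.data, out_dir / f"{prefix}_bold.nii.gz"),
        "gm_mask": save_nifti(run.gm_mask.astype(float), out_dir / f"{prefix}_gm.nii.gz"),
        "wm_mask": save_nifti(run.wm_mask.astype(float), out_dir / f"{prefix}_wm.nii.gz"),
        "csf_mask": save_nifti(run.csf_mask.astype(float), out_dir / f"{prefix}_csf.nii.gz"),
    }
    motion_path = out_dir / f"{prefix}_motion.tsv"
    run.motion.to_csv(motion_path, sep="\t", index=False)
    paths["motion"] = motion_path
    return paths


def load_bold_run(paths: dict[str, str | Path], tr: float) -> BoldRun:
    return BoldRun(
        data=load_nifti(paths["bold"]),
        tr=tr,
        gm_mask=load_nifti(paths["gm_mask"]) > 0.5,
        wm_mask=load_nifti(paths["wm_mask"]) > 0.5,
        csf_mask=load_nifti(paths["csf_mask"]) > 0.5,
        motion=pd.read_csv(paths["motion"], sep="\t"),
    )


def save_rsfa_map(rsfa: RsfaMap, path: str | Path) -> Path:
    return save_nifti(np.where(rsfa.mask, rsfa.values, 0.0), path)


def save_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_waveform(w: Waveform, path: str | Path) -> Path:
    t = np.arange(len(w.values)) / w.fs
    return save_table(pd.DataFrame({"time_s": t, "value": w.values}), path)


def load_waveform(path: str | Path, modality: str = "pulseox") -> Waveform:
    table = load_table(path)
    t = table["time_s"].to_numpy(float)
    fs = float(np.round(1.0 / np.median(np.diff(t)), 6))
    return Waveform(values=table["value"].to_numpy(float), fs=fs, modality=modality)


def save_sensor_run(run: SensorRun, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=run.data)
        f.attrs["fs"] = run.fs
        f.create_dataset(
            "channel_ids", data=np.array(run.channel_ids, dtype=h5py.string_dtype())
        )
    return path


def load_sensor_run(path: str | Path) -> SensorRun:
    with h5py.File(path, "r") as f:
        return SensorRun(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            channel_ids=[s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_ids"][()]],
        )


def save_mediation_result(result: MediationResult, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "paths": {k: dataclasses.asdict(v) for k, v in result.paths.items()},
        "n": result.n,
        "B": result.B,
        "alpha": result.alpha,
        "seed": result.seed,
        "classification": result.classification,
        "proportion_mediated_pct": result.proportion_mediated_pct,
        "n_discarded_draws": result.n_discarded_draws,
    }

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    path.write_text(json.dumps(payload, indent=2, default=_default, allow_nan=True))
    return path
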