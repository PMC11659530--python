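"""Format plumbing: NIfTI-1 volumes, FSL-style .bval, CSV tables, manifests.

Volumes are NIfTI-1 throughout; masks are 0/1 on the DWI grid and no
resampling is ever performed.  Every pipeline run writes a JSON manifest
echoing the configuration, the package version and per-file SHA-256
checksums so a run is reproducible from its manifest.
"""
from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acquisition import read_bval, write_bval
from .phantom import LesionPhantom
from .signal_models import DwiSeries, ParameterMapSet

CONFIG_KEYS = {
    "out", "n_patients", "n_positive", "grid_shape", "snr_at_b0", "seed",
    "n_total", "exclusion_counts", "model", "k_max", "nex_weighted",
    "adc_b_pair", "alpha", "inclusion_threshold", "jitter_tau",
}


def load_config(path) -> dict:
    """Flat key-value YAML config; unknown keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    unknown = set(cfg) - CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, files) -> Path:
    out_dir = Path(out_dir)
    manifest = {
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.items()},
        "checksums": {str(Path(f).relative_to(out_dir)): sha256_of(f)
                      for f in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def save_nifti(path, data, affine=None) -> Path:
    affine = np.eye(4) if affine is None else affine
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))
    return Path(path)


def save_mask(path, mask, affine=None) -> Path:
    affine = np.eye(4) if affine is None else affine
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nib.save(img, str(path))
    return Path(path)


def load_dwi(dwi_path, bval_path, nex=None) -> DwiSeries:
    """Read a 4D NIfTI plus its .bval sidecar."""
    dwi_path, bval_path = Path(dwi_path), Path(bval_path)
    if not bval_path.exists():
        raise FileNotFoundError(f"missing b-value sidecar: {bval_path}")
    img = nib.load(str(dwi_path))
    scheme = read_bval(bval_path, nex=nex)
    return DwiSeries(data=np.asarray(img.dataobj, dtype=float), scheme=scheme,
                     affine=img.affine)


def load_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def save_phantom(phantom: LesionPhantom, out_dir, patient_id: str) -> list:
    """Write one patient's DWI, .bval, masks and truth maps; returns paths."""
    out_dir = Path(out_dir)
    pdir = out_dir / patient_id
    pdir.mkdir(parents=True, exist_ok=True)
    written = []
    written.append(save_nifti(pdir / "dwi.nii.gz", phantom.dwi))
    bval = pdir / "dwi.bval"
    write_bval(bval, phantom.scheme)
    written.append(bval)
    written.append(save_mask(pdir / "roi_observer1.nii.gz",
                             phantom.roi_observer1))
    written.append(save_mask(pdir / "roi_observer2.nii.gz",
                             phantom.roi_observer2))
    written.append(save_mask(pdir / "necrosis.nii.gz", phantom.necrosis_mask))
    for name, vol in phantom.truth.items():
        written.append(save_nifti(pdir / f"truth_{name}.nii.gz", vol))
    meta = pdir / "phantom.json"
    meta.write_text(json.dumps({"group": phantom.group, "seed": phantom.seed,
                                "nex": list(phantom.scheme.nex)}) + "\n")
    written.append(meta)
    return written


def save_parameter_maps(maps: ParameterMapSet, out_dir) -> list:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, vol in maps.maps.items():
        written.append(save_nifti(out_dir / f"{name}.nii.gz", vol,
                                  affine=maps.affine))
    written.append(save_mask(out_dir / "fitted_mask.nii.gz",
                             maps.fitted_mask, affine=maps.affine))
    report = out_dir / "fit_report.json"
    report.write_text(json.dumps({
        "n_fitted": int(maps.fitted_mask.sum()),
        "n_failed": int(maps.n_failed),
        "parameters": list(maps.maps),
    }, indent=2) + "\n")
    written.append(report)
    return written


def roster_to_frame(roster) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": r.patient_id, "age": r.age, "sex": r.sex,
        "max_diameter": r.max_diameter, "cea": r.cea,
        "lnm_label": r.lnm_label if r.lnm_label is not None else "",
        "exclusion_flag": r.exclusion_flag,
    } for r in roster])


def write_report_bundle(report: dict, out_dir) -> list:
    """Write the statistics bundle: one CSV per table (floats at 3 decimals)
    plus a full-precision JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    names = {"table1": "table1.csv", "table2_univariate": "table2_univariate.csv",
             "table2_multivariate": "table2_multivariate.csv",
             "table3": "table3.csv", "delong": "delong_matrix.csv"}
    for key, fname in names.items():
        path = out_dir / fname
        report[key].to_csv(path, index=False, float_format="%.3f")
        written.append(path)
    payload = {k: df.to_dict(orient="records") for k, df in report.items()}
    jpath = out_dir / "report.json"
    jpath.write_text(json.dumps(payload, indent=2, default=float) + "\n")
    written.append(jpath)
    return written
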