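"""NIfTI and CSV input/output with provenance headers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .segmentation import SoSVolume, TissueLabelVolume

__all__ = [
    "write_sos_nifti",
    "read_sos_nifti",
    "write_labels_nifti",
    "read_labels_nifti",
    "write_csv",
    "read_csv",
    "provenance",
    "spec_to_json",
    "spec_from_json",
]


def _affine(voxel_size) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


def write_sos_nifti(vol: SoSVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.voxel_size))
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def read_sos_nifti(path: str | Path) -> SoSVolume:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SoSVolume(values=np.asarray(img.get_fdata(), dtype=np.float64),
                     voxel_size=zooms)


def write_labels_nifti(labels: TissueLabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(labels.labels.astype(np.uint8), _affine(labels.voxel_size))
    img.header.set_zooms(labels.voxel_size)
    nib.save(img, str(path))


def read_labels_nifti(path: str | Path) -> TissueLabelVolume:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return TissueLabelVolume(
        labels=np.asarray(img.dataobj, dtype=np.uint8), voxel_size=zooms)


def provenance(seed: int | None = None, config: Any = None) -> dict:
    """Provenance block recorded in every output artifact."""
    block = {"package": "mammocycle", "version": __version__}
    if seed is not None:
        block["seed"] = int(seed)
    if config is not None:
        if is_dataclass(config) and not isinstance(config, type):
            config = asdict(config)
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
        block["config_sha256"] = digest[:16]
    return block


def write_csv(df: pd.DataFrame, path: str | Path,
              prov: Mapping[str, Any] | None = None) -> None:
    """Write a CSV with '#'-prefixed provenance header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (prov or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def spec_to_json(spec: Any, path: str | Path) -> None:
    if is_dataclass(spec) and not isinstance(spec, type):
        spec = asdict(spec)
    Path(path).write_text(json.dumps(spec, indent=2, default=str) + "\n")


def spec_from_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
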