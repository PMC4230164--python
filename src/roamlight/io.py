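"""Standard-format I/O: NIfTI volumes with JSON sidecars, TSV tables, configs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import nibabel as nib
import numpy as np
import pandas as pd


def save_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path,
               sidecar: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
    if sidecar is not None:
        side = path.with_suffix("").with_suffix(".json") \
            if path.name.endswith(".nii.gz") else path.with_suffix(".json")
        side.write_text(json.dumps(sidecar, indent=2, default=_jsonable))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_cluster_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Cluster TSV with columns label, x_mm, y_mm, z_mm, t_value, KE, p_corrected."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["label", "x_mm", "y_mm", "z_mm", "t_value", "KE", "p_corrected"]
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def load_manifest(dataset_dir: str | Path) -> dict:
    return json.loads((Path(dataset_dir) / "manifest.json").read_text())


def iter_subject_runs(dataset_dir: str | Path) -> Iterator[tuple[dict, list[np.ndarray]]]:
    """Yield (subject manifest entry, list of 4-D run arrays) for each subject."""
    root = Path(dataset_dir)
    manifest = load_manifest(root)
    for sub in manifest["subjects"]:
        runs = [np.asarray(nib.load(str(root / rel)).dataobj, dtype=float)
                for rel in sub["runs"]]
        yield sub, runs


def load_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON key-value configuration file."""
    import yaml

    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def dump_config(config: dict, path: str | Path) -> Path:
    import yaml

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".json":
        path.write_text(json.dumps(config, indent=2, default=_jsonable))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=False))
    return path
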