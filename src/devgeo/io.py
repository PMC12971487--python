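"""Readers and writers for the pipeline's on-disk formats.

Events and confounds travel as BIDS-style TSV; condition patterns as plain
matrix TSV with a JSON label sidecar or as NIfTI stacks (one volume per
condition); RSMs as square TSV matrices with a JSON sidecar recording
labels, metric and provenance. A reader for the deposited RSM pickle
dialect (a dict of condition-square arrays) is included for working with
released derivatives.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from devgeo.rsm import RSM
from devgeo.stimuli import EventTable


# --- events ---------------------------------------------------------------


def write_events_tsv(events: EventTable, path: str | Path) -> Path:
    path = Path(path)
    cols = ["onset", "duration", "trial_type", "condition", "run"]
    events.events[cols].to_csv(path, sep="\t", index=False)
    meta = {"tr": events.tr, "n_frames": events.n_frames}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def read_events_tsv(path: str | Path) -> EventTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration"):
        if col not in df.columns:
            raise ValueError(f"events file {path.name}: missing column {col!r}")
    if "condition" not in df.columns:
        if "trial_type" not in df.columns:
            raise ValueError(
                f"events file {path.name}: need a condition or trial_type column"
            )
        codes, _ = pd.factorize(df["trial_type"])
        df["condition"] = codes
    if "run" not in df.columns:
        df["run"] = 0
    sidecar = path.with_suffix(".json")
    tr, n_frames = 0.656, 0
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        tr = float(meta.get("tr", tr))
        n_frames = int(meta.get("n_frames", 0))
    if n_frames == 0:
        n_frames = int(np.ceil((df["onset"] + df["duration"]).max() / tr)) + 20
    return EventTable(events=df, tr=tr, n_frames=n_frames)


# --- confounds ------------------------------------------------------------


def write_confounds_tsv(
    fwd: np.ndarray, path: str | Path, motion_params: np.ndarray | None = None
) -> Path:
    path = Path(path)
    df = pd.DataFrame({"framewise_displacement": np.asarray(fwd, dtype=float)})
    if motion_params is not None:
        mp = np.asarray(motion_params, dtype=float)
        names = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        for i in range(mp.shape[1]):
            df[names[i] if i < 6 else f"motion_{i}"] = mp[:, i]
    df.to_csv(path, sep="\t", index=False)
    return path


def read_confounds_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    df = pd.read_csv(path, sep="\t")
    if "framewise_displacement" not in df.columns:
        raise ValueError(
            f"confounds file {Path(path).name}: missing column 'framewise_displacement'"
        )
    fwd = df["framewise_displacement"].to_numpy(dtype=float)
    motion_cols = [c for c in df.columns if c.startswith(("trans_", "rot_", "motion_"))]
    motion = df[motion_cols].to_numpy(dtype=float) if motion_cols else None
    return fwd, motion


# --- matrices (patterns, RSMs, activations) -------------------------------


def write_matrix_tsv(
    matrix: np.ndarray,
    path: str | Path,
    labels: list[str] | None = None,
    meta: dict | None = None,
) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter="\t", fmt="%.17g")
    sidecar = dict(meta or {})
    if labels is not None:
        sidecar["labels"] = list(labels)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    m = np.loadtxt(path, delimiter="\t")
    if m.ndim == 1:
        m = m[None, :]
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return m, meta


def write_rsm(rsm: RSM, path: str | Path) -> Path:
    prov = rsm.provenance if isinstance(rsm.provenance, str) else [
        [list(map(str, p)) for p in pair] if isinstance(pair, tuple) else str(pair)
        for pair in rsm.provenance
    ]
    return write_matrix_tsv(
        rsm.values,
        path,
        labels=rsm.labels,
        meta={"metric": rsm.metric, "provenance": prov},
    )


def read_rsm(path: str | Path) -> RSM:
    m, meta = read_matrix_tsv(path)
    return RSM(
        values=m,
        metric=meta.get("metric", "pearson-similarity"),
        labels=meta.get("labels"),
        provenance=meta.get("provenance", []),
    )


def read_rdm_pickle(path: str | Path, key: str | None = None) -> RSM:
    """Read the deposited RSM pickle dialect.

    The container is a pickled dict mapping names to square arrays (or a
    bare square array). ``key`` selects an entry; with one entry it is
    optional.
    """
    with open(path, "rb") as fh:
        obj = pickle.load(fh)
    if isinstance(obj, np.ndarray):
        return RSM(values=obj)
    if isinstance(obj, dict):
        if key is None:
            if len(obj) != 1:
                raise ValueError(
                    f"pickle holds {len(obj)} RSMs; specify key from {sorted(obj)}"
                )
            key = next(iter(obj))
        arr = np.asarray(obj[key], dtype=float)
        return RSM(values=(arr + arr.T) / 2.0)
    raise ValueError("unrecognized RSM pickle payload")


# --- NIfTI patterns -------------------------------------------------------


def write_patterns_nifti(patterns: np.ndarray, path: str | Path) -> Path:
    """Condition patterns as a 4D NIfTI (one volume per condition)."""
    import nibabel as nib

    p = np.asarray(patterns, dtype=float)
    n_cond, n_vox = p.shape
    side = int(np.ceil(n_vox ** (1 / 3)))
    vol = np.zeros((side, side, side, n_cond))
    flat = vol.reshape(-1, n_cond)
    flat[:n_vox] = p.T
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header["descrip"] = b"devgeo condition patterns"
    path = Path(path)
    nib.save(img, str(path))
    meta = {"n_conditions": int(n_cond), "n_voxels": int(n_vox)}
    Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json").write_text(
        json.dumps(meta)
    )
    return path


def read_patterns_nifti(path: str | Path) -> np.ndarray:
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    meta_path = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
    n_vox = None
    if meta_path.exists():
        n_vox = json.loads(meta_path.read_text()).get("n_voxels")
    flat = data.reshape(-1, data.shape[-1]).T
    return flat[:, :n_vox] if n_vox else flat


# --- activation manifests -------------------------------------------------


def write_activations(activations, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"layers": list(activations.layer_names)}
    for name in activations.layer_names:
        write_matrix_tsv(activations.matrices[name], directory / f"{name}.tsv")
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def read_activations(directory: str | Path):
    from devgeo.dnn import LayerActivations

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    layers = tuple(manifest["layers"])
    matrices = {name: read_matrix_tsv(directory / f"{name}.tsv")[0] for name in layers}
    return LayerActivations(layer_names=layers, matrices=matrices)
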