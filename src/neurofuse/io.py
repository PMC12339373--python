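"""On-disk formats: subjects tables, parcellations, time series,
connectivity containers, model parameters and run manifests.

Small artifacts are plain delimited text (TSV); whole cohorts of
connectivity matrices go into a single HDF5 container keyed by
subject/modality/band with the normalization state stored as metadata.
All writers round-trip losslessly at 1e-12 for matrices.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, RoiTimeSeries
from .interpret import NETWORK_NAMES, Parcellation

__all__ = [
    "SubjectsTable",
    "RunManifest",
    "read_subjects",
    "read_parcellation",
    "default_parcellation",
    "read_timeseries",
    "write_timeseries",
    "write_matrix",
    "read_matrix",
    "write_connectivity_container",
    "read_connectivity_container",
    "save_params",
    "load_params",
]

_REQUIRED_SUBJECT_COLS = ("subject_id", "arm", "hamd_baseline", "hamd_week8")
_ARMS = ("sertraline", "placebo")


@dataclass
class SubjectsTable:
    """Validated cohort table with the computed ΔHAMD outcome."""

    frame: pd.DataFrame

    @property
    def delta_hamd(self) -> np.ndarray:
        return self.frame["delta_hamd"].to_numpy(dtype=float)

    @property
    def subject_ids(self) -> list[str]:
        return self.frame["subject_id"].tolist()

    def scales(self) -> dict[str, np.ndarray]:
        extra = [c for c in self.frame.columns
                 if c not in _REQUIRED_SUBJECT_COLS + ("delta_hamd",)]
        return {c: self.frame[c].to_numpy(dtype=float) for c in extra}


@dataclass
class RunManifest:
    """Everything needed to re-execute a run: config, seeds, fold map."""

    config: dict
    seeds: list[int]
    fold_map: dict = field(default_factory=dict)
    software_version: str = ""
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))
    metrics: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=_jsonable))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def read_subjects(path) -> SubjectsTable:
    """Read and validate a delimited subjects table; computes ΔHAMD."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep)
    if frame.empty:
        raise ValueError(f"{path}: empty subjects table")
    missing = [c for c in _REQUIRED_SUBJECT_COLS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    dup = frame["subject_id"][frame["subject_id"].duplicated()]
    if len(dup):
        row = int(dup.index[0]) + 2  # 1-based with header
        raise ValueError(f"{path} row {row}: duplicate subject id {dup.iloc[0]!r}")
    for i, row in frame.iterrows():
        if row["arm"] not in _ARMS:
            raise ValueError(f"{path} row {i + 2}: invalid arm {row['arm']!r}")
        for col in ("hamd_baseline", "hamd_week8"):
            if not np.isfinite(row[col]) or row[col] < 0:
                raise ValueError(f"{path} row {i + 2}: invalid {col} {row[col]!r}")
    frame = frame.copy()
    frame["delta_hamd"] = frame["hamd_baseline"] - frame["hamd_week8"]
    return SubjectsTable(frame)


def write_subjects(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_parcellation(path) -> Parcellation:
    """Read a TSV parcellation (roi_index, roi_label, network)."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("roi_index", "roi_label", "network"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col}")
    idx = frame["roi_index"].to_numpy()
    if len(np.unique(idx)) != len(idx):
        raise ValueError(f"{path}: duplicated roi_index")
    expected = np.arange(len(idx))
    if not np.array_equal(np.sort(idx), expected):
        raise ValueError(f"{path}: roi_index must be 0-based and contiguous")
    frame = frame.sort_values("roi_index")
    unknown = set(frame["network"]) - set(NETWORK_NAMES)
    if unknown:
        raise ValueError(f"{path}: unknown network name(s) {sorted(unknown)}")
    return Parcellation(frame["roi_label"].tolist(), frame["network"].tolist())


def default_parcellation(n_rois: int = 100) -> Parcellation:
    """Packaged 100-ROI (or 20-ROI fast-mode) 7-network fixture.

    The assignment is a synthetic stand-in with network sizes roughly in
    atlas proportion; it is NOT the real cortical atlas labelling.
    """
    name = {100: "synthetic_parcellation_100.tsv", 20: "synthetic_parcellation_20.tsv"}.get(n_rois)
    if name is None:
        raise ValueError("packaged parcellations exist for 100 and 20 ROIs")
    with resources.as_file(resources.files("neurofuse") / "data" / name) as p:
        return read_parcellation(p)


def read_timeseries(path, subject_id: str, modality: str, sampling_rate=None) -> RoiTimeSeries:
    """Delimited T×N time series with a header row of ROI labels."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep)
    return RoiTimeSeries(subject_id, modality, frame.to_numpy(dtype=float), sampling_rate)


def write_timeseries(ts: RoiTimeSeries, path) -> None:
    cols = [f"roi_{i}" for i in range(ts.n_rois)]
    pd.DataFrame(ts.data, columns=cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_matrix(m: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(m), delimiter="\t", fmt="%.17g")


def read_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def write_connectivity_container(path, matrices: list[ConnectivityMatrix]) -> None:
    """All of a cohort's connectivity in one HDF5 file.

    Layout: /<subject>/<modality>[/<band>] datasets with
    ``normalization_state`` stored as an attribute.
    """
    with h5py.File(path, "w") as f:
        for c in matrices:
            key = f"{c.subject_id}/{c.modality}"
            if c.band:
                key += f"/{c.band}"
            ds = f.create_dataset(key, data=c.values)
            ds.attrs["normalization_state"] = ",".join(c.normalization_state)
            ds.attrs["subject_id"] = c.subject_id
            ds.attrs["modality"] = c.modality
            if c.band:
                ds.attrs["band"] = c.band


def read_connectivity_container(path) -> list[ConnectivityMatrix]:
    out = []

    def visit(_, obj):
        if isinstance(obj, h5py.Dataset):
            out.append(
                ConnectivityMatrix(
                    str(obj.attrs["subject_id"]),
                    str(obj.attrs["modality"]),
                    obj[()],
                    str(obj.attrs["normalization_state"]).split(","),
                    str(obj.attrs["band"]) if "band" in obj.attrs else None,
                )
            )

    with h5py.File(path, "r") as f:
        f.visititems(visit)
    out.sort(key=lambda c: (c.subject_id, c.modality, c.band or ""))
    return out


def save_params(params, path) -> None:
    """Serialize trained fusion-model parameters (config + seed embedded)."""
    from .model import MODALITIES

    arrays = {}
    for m in MODALITIES:
        for k, v in params.gnn[m].items():
            arrays[f"gnn_{m}_{k}"] = v
        arrays[f"scale_{m}"] = params.scale[m]
        arrays[f"proj_{m}"] = params.proj[m]
    for k, v in params.mlp.items():
        arrays[f"mlp_{k}"] = v
    arrays["agg_raw"] = params.agg_raw
    arrays["y_scale"] = np.array([params.y_mean, params.y_std])
    arrays["seed"] = np.array([-1 if params.seed is None else params.seed])
    arrays["config_json"] = np.frombuffer(
        json.dumps(params.config.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_params(path):
    from .model import MODALITIES, FusionConfig, FusionModelParams

    with np.load(path) as z:
        config = FusionConfig.from_dict(json.loads(bytes(z["config_json"]).decode()))
        gnn = {m: {k: z[f"gnn_{m}_{k}"] for k in ("W1", "b1", "W2", "b2")} for m in MODALITIES}
        scale = {m: z[f"scale_{m}"] for m in MODALITIES}
        proj = {m: z[f"proj_{m}"] for m in MODALITIES}
        mlp = {k: z[f"mlp_{k}"] for k in ("V1", "c1", "V2", "c2", "V3", "c3")}
        y_mean, y_std = z["y_scale"]
        seed = int(z["seed"][0])
        return FusionModelParams(
            config, gnn, scale, proj, z["agg_raw"], mlp,
            float(y_mean), float(y_std), None if seed < 0 else seed,
        )
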