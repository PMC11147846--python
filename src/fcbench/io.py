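"""Plain-text and binary I/O for matrices, atlases and cohorts.

Matrices travel as TSV (header row = parcel labels, one row per parcel) for
human inspection, or inside a single HDF5 container for speed. A cohort on
disk is a JSON manifest listing subject ids and relative file paths, next to
the atlas TSV and one matrix file per subject/modality.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    FC,
    SC_COUNTS,
    Atlas,
    Cohort,
    ConnectivityMatrix,
    Subject,
)


def write_matrix_tsv(path, matrix: ConnectivityMatrix):
    labels = matrix.atlas.labels if matrix.atlas else [f"p{i}" for i in range(matrix.p)]
    df = pd.DataFrame(matrix.values, index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", index_label="parcel")


def read_matrix_tsv(path, kind: str, atlas: Atlas | None = None) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ConnectivityMatrix(df.to_numpy(dtype=float), kind, atlas)


def write_atlas_tsv(path, atlas: Atlas):
    pd.DataFrame(
        {"parcel_label": list(atlas.labels), "network": list(atlas.networks)}
    ).to_csv(path, sep="\t", index=False)


def read_atlas_tsv(path, name: str = "from_file") -> Atlas:
    df = pd.read_csv(path, sep="\t")
    return Atlas(
        labels=tuple(df["parcel_label"].astype(str)),
        networks=tuple(df["network"].astype(str)),
        name=name,
    )


def write_time_series_tsv(path, ts: np.ndarray, atlas: Atlas | None = None):
    labels = atlas.labels if atlas else [f"p{i}" for i in range(ts.shape[1])]
    pd.DataFrame(ts, columns=list(labels)).to_csv(path, sep="\t", index=False)


def read_time_series_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", float_precision="round_trip").to_numpy(dtype=float)


def write_cohort(directory, cohort: Cohort, seed: int | None = None,
                 store_time_series: bool = False):
    """Write a cohort as manifest + atlas + per-subject TSV matrices.

    The manifest records the generating seed (if any) so every simulated
    cohort on disk is reproducible from its own metadata.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_atlas_tsv(d / "atlas.tsv", cohort.atlas)
    entries = []
    cognition = {}
    for s in cohort:
        entry = {"subject_id": s.subject_id}
        if s.efc is not None:
            entry["efc"] = f"{s.subject_id}_efc.tsv"
            write_matrix_tsv(d / entry["efc"], s.efc)
        if s.sc is not None:
            entry["sc"] = f"{s.subject_id}_sc.tsv"
            write_matrix_tsv(d / entry["sc"], s.sc)
        if store_time_series and s.time_series is not None:
            entry["time_series"] = f"{s.subject_id}_ts.tsv"
            write_time_series_tsv(d / entry["time_series"], s.time_series, cohort.atlas)
        if s.cognition is not None:
            cognition[s.subject_id] = s.cognition
        entries.append(entry)
    if cognition:
        pd.DataFrame(
            {"subject_id": list(cognition), "cognition": list(cognition.values())}
        ).to_csv(d / "cognition.tsv", sep="\t", index=False, float_format="%.17g")
    manifest = {
        "atlas": "atlas.tsv",
        "atlas_name": cohort.atlas.name,
        "seed": seed,
        "subjects": entries,
        "cognition": "cognition.tsv" if cognition else None,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(directory) -> Cohort:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    atlas = read_atlas_tsv(d / manifest["atlas"], manifest.get("atlas_name", "from_file"))
    cognition = {}
    if manifest.get("cognition"):
        cg = pd.read_csv(d / manifest["cognition"], sep="\t", float_precision="round_trip")
        cognition = dict(zip(cg["subject_id"].astype(str), cg["cognition"]))
    cohort = Cohort(atlas=atlas)
    for entry in manifest["subjects"]:
        sid = str(entry["subject_id"])
        sub = Subject(subject_id=sid)
        if "efc" in entry:
            sub.efc = read_matrix_tsv(d / entry["efc"], FC, atlas)
        if "sc" in entry:
            sub.sc = read_matrix_tsv(d / entry["sc"], SC_COUNTS, atlas)
        if "time_series" in entry:
            sub.time_series = read_time_series_tsv(d / entry["time_series"])
        if sid in cognition:
            sub.cognition = float(cognition[sid])
        cohort.add(sub)
    return cohort


def write_cohort_h5(path, cohort: Cohort, seed: int | None = None):
    """Single-file binary container: one group per subject, atlas in attrs."""
    with h5py.File(path, "w") as f:
        f.attrs["atlas_labels"] = list(cohort.atlas.labels)
        f.attrs["atlas_networks"] = list(cohort.atlas.networks)
        f.attrs["atlas_name"] = cohort.atlas.name
        if seed is not None:
            f.attrs["seed"] = seed
        for s in cohort:
            g = f.create_group(s.subject_id)
            if s.efc is not None:
                g.create_dataset("efc", data=s.efc.values)
            if s.sc is not None:
                g.create_dataset("sc", data=s.sc.values)
            if s.time_series is not None:
                g.create_dataset("time_series", data=s.time_series)
            if s.cognition is not None:
                g.attrs["cognition"] = s.cognition


def read_cohort_h5(path) -> Cohort:
    with h5py.File(path, "r") as f:
        atlas = Atlas(
            labels=tuple(str(x) for x in f.attrs["atlas_labels"]),
            networks=tuple(str(x) for x in f.attrs["atlas_networks"]),
            name=str(f.attrs.get("atlas_name", "from_file")),
        )
        cohort = Cohort(atlas=atlas)
        for sid in f:
            g = f[sid]
            sub = Subject(subject_id=sid)
            if "efc" in g:
                sub.efc = ConnectivityMatrix(g["efc"][...], FC, atlas)
            if "sc" in g:
                sub.sc = ConnectivityMatrix(g["sc"][...], SC_COUNTS, atlas)
            if "time_series" in g:
                sub.time_series = g["time_series"][...]
            if "cognition" in g.attrs:
                sub.cognition = float(g.attrs["cognition"])
            cohort.add(sub)
    return cohort
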