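"""Readers and writers: HDF5 cohorts and feature sets, YAML specs, EDF."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .features import EEGRecording, FeatureMatrix
from .simulate import BlobSpec, CohortSpec

__all__ = [
    "save_cohort",
    "load_cohort",
    "save_features",
    "load_features",
    "load_spec",
    "read_edf",
]


def save_cohort(subjects: list, path, fs: float) -> None:
    """Write per-subject awake/fatigue recordings to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = fs
        for subj in subjects:
            grp = f.create_group(subj["subject_id"])
            for cls in ("awake", "fatigue"):
                grp.create_dataset(cls, data=subj[cls].data, compression="gzip")


def load_cohort(path) -> list:
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["fs"])
        subjects = []
        for sid in f:
            subjects.append(
                {
                    "subject_id": sid,
                    "awake": EEGRecording(f[sid]["awake"][()], fs),
                    "fatigue": EEGRecording(f[sid]["fatigue"][()], fs),
                }
            )
    return subjects


def save_features(feature_matrices: list, path) -> None:
    """Write per-subject FeatureMatrix objects with a JSON layout sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for fm in feature_matrices:
            grp = f.create_group(fm.subject_id)
            grp.create_dataset("features", data=fm.features, compression="gzip")
            if fm.labels is not None:
                grp.create_dataset("labels", data=fm.labels)
            grp.attrs["layout"] = fm.layout
    sidecar = {
        "subjects": [fm.subject_id for fm in feature_matrices],
        "n_features": int(feature_matrices[0].n_features) if feature_matrices else 0,
        "layout": feature_matrices[0].layout if feature_matrices else "",
        "bands": list(feature_matrices[0].band_names) if feature_matrices else [],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_features(path) -> list:
    out = []
    with h5py.File(path, "r") as f:
        for sid in f:
            grp = f[sid]
            labels = grp["labels"][()] if "labels" in grp else None
            out.append(
                FeatureMatrix(
                    grp["features"][()], labels,
                    layout=grp.attrs.get("layout", ""), subject_id=sid,
                )
            )
    return out


def load_spec(path, kind: str):
    """Load a BlobSpec/CohortSpec from YAML (`kind` is 'blob' or 'cohort')."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    cls = {"blob": BlobSpec, "cohort": CohortSpec}[kind]
    return cls(**data)


def read_edf(path, picks: list | None = None) -> EEGRecording:
    """Read a multichannel EDF recording (requires the optional `mne` extra)."""
    import mne  # heavy optional dependency, imported lazily

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if picks:
        raw = raw.pick(picks)
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(data, float(raw.info["sfreq"]), list(raw.ch_names))
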