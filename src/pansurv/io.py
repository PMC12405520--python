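"""Cohort manifest and feature-bag container I/O.

The manifest is a delimited table with one row per slide; the bag container is
an HDF5 file per slide holding ``features`` (float32 N x D) and ``coords``
(int32 N x 2) datasets plus provenance attributes.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    Cohort,
    DimensionError,
    FeatureBag,
    IntegrityError,
    PatientRecord,
    SchemaError,
    SurvivalLabel,
    ValidationError,
    CancerTypeCode,
    encode_clinical,
)

REQUIRED_COLUMNS = ("patient_id", "slide_id", "cancer_type", "time", "event")
OPTIONAL_COLUMNS = ("age", "sex", "stage", "endpoint")

BAG_SCHEMA_VERSION = "1"


def read_manifest(
    path: str | Path,
    schema: dict[str, str] | None = None,
) -> tuple[Cohort, pd.DataFrame]:
    """Read a slide-level manifest into a Cohort skeleton (no bags loaded).

    Patients are grouped by ``patient_id``; cancer labels are mapped to indices
    0..K-1 in sorted-label order.  ``schema`` optionally renames columns
    (standard name -> column name in the file).

    Returns the cohort (with empty placeholder bags replaced lazily by the
    caller) and the slide table, which keeps the patient -> slide mapping.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest missing required column(s): {missing}")

    dup = df.duplicated(subset=["patient_id", "slide_id"])
    if dup.any():
        rows = df.loc[dup, ["patient_id", "slide_id"]].values.tolist()
        raise IntegrityError(f"duplicate (patient_id, slide_id) rows: {rows}")

    bad_time = df[~(pd.to_numeric(df["time"], errors="coerce") > 0)]
    if len(bad_time):
        raise ValidationError(
            f"nonpositive or invalid survival time in rows {bad_time.index.tolist()}"
        )

    labels = tuple(sorted(df["cancer_type"].astype(str).unique()))
    label_to_index = {lab: i for i, lab in enumerate(labels)}
    K = len(labels)

    patients: list[PatientRecord] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        first = grp.iloc[0]
        clinical = encode_clinical(
            age=first.get("age") if "age" in grp.columns else None,
            sex=first.get("sex") if "sex" in grp.columns else None,
            stage=first.get("stage") if "stage" in grp.columns else None,
        )
        endpoint = str(first["endpoint"]) if "endpoint" in grp.columns else "OS"
        label = str(first["cancer_type"])
        bags = [
            FeatureBag(
                slide_id=str(r.slide_id),
                features=np.zeros((1, 1), dtype=np.float32),
                coords=np.zeros((1, 2), dtype=np.int32),
                encoder_name="<stub>",
            )
            for r in grp.itertuples()
        ]
        patients.append(
            PatientRecord(
                patient_id=str(pid),
                bags=bags,
                clinical=clinical,
                cancer=CancerTypeCode(index=label_to_index[label], label=label, K=K),
                survival=SurvivalLabel(
                    time=float(first["time"]), event=int(first["event"]), endpoint=endpoint
                ),
            )
        )
    cohort = Cohort(patients=patients, K=K, D=1, cancer_labels=labels)
    return cohort, df


def write_manifest(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to a slide-level manifest (inverse of read_manifest)."""
    rows = []
    for p in cohort.patients:
        age = p.clinical.values[0] * 100.0 if not p.clinical.missing_mask[0] else np.nan
        if p.clinical.values[1] == 1:
            sex = "female"
        elif p.clinical.values[2] == 1:
            sex = "male"
        else:
            sex = np.nan
        stage_slots = p.clinical.values[3:7]
        stage = (
            ("I", "II", "III", "IV")[int(np.argmax(stage_slots))]
            if stage_slots.any()
            else np.nan
        )
        for b in p.bags:
            rows.append(
                dict(
                    patient_id=p.patient_id,
                    slide_id=b.slide_id,
                    cancer_type=p.cancer.label,
                    age=age,
                    sex=sex,
                    stage=stage,
                    time=p.survival.time,
                    event=p.survival.event,
                    endpoint=p.survival.endpoint,
                )
            )
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def write_bag(path: str | Path, bag: FeatureBag) -> None:
    """Write one slide's bag to an HDF5 container (lossless float32 round-trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.features.astype(np.float32))
        f.create_dataset("coords", data=bag.coords.astype(np.int32))
        f.attrs["slide_id"] = bag.slide_id
        f.attrs["patch_size_px"] = int(bag.patch_size_px)
        f.attrs["magnification"] = bag.magnification
        f.attrs["encoder_name"] = bag.encoder_name
        f.attrs["schema_version"] = BAG_SCHEMA_VERSION


def read_bag(path: str | Path, expected_dim: int | None = None) -> FeatureBag:
    """Read a bag container; optionally enforce the cohort-level feature dim."""
    if not os.path.exists(path):
        raise SchemaError(f"bag container not found: {path}")
    try:
        with h5py.File(path, "r") as f:
            for ds in ("features", "coords"):
                if ds not in f:
                    raise SchemaError(f"bag container {path} missing dataset {ds!r}")
            features = f["features"][()]
            coords = f["coords"][()]
            attrs = dict(f.attrs)
    except OSError as e:
        raise SchemaError(f"unreadable bag container {path}: {e}") from e
    bag = FeatureBag(
        slide_id=str(attrs.get("slide_id", Path(path).stem)),
        features=features,
        coords=coords,
        patch_size_px=int(attrs.get("patch_size_px", 224)),
        magnification=str(attrs.get("magnification", "10x")),
        encoder_name=str(attrs.get("encoder_name", "unknown")),
    )
    if expected_dim is not None and bag.dim != expected_dim:
        raise DimensionError(
            f"bag {bag.slide_id!r} has D={bag.dim}, cohort expects D={expected_dim}"
        )
    return bag


def attach_bags(cohort: Cohort, bag_dir: str | Path) -> Cohort:
    """Load every patient's bag containers from ``bag_dir`` (named <slide_id>.h5)."""
    bag_dir = Path(bag_dir)
    D: int | None = None
    for p in cohort.patients:
        loaded = []
        for b in p.bags:
            bag = read_bag(bag_dir / f"{b.slide_id}.h5", expected_dim=D)
            if D is None:
                D = bag.dim
            loaded.append(bag)
        p.bags = loaded
    cohort.D = int(D) if D is not None else cohort.D
    return cohort
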