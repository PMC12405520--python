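"""Domain types for multicancer survival cohorts built from slide feature bags.

A cohort is a set of patients; each patient owns one or more per-slide feature
bags (the N x D matrix of patch embeddings produced by a patch encoder), an
encoded clinical covariate vector, a cancer-type code on a fixed one-hot basis,
and a right-censored survival label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ENDPOINTS = ("OS", "DSS", "DFI")

#: Fixed clinical encoding layout (M = 8):
#: [age/100, sex_female, sex_male, stage_I, stage_II, stage_III, stage_IV,
#:  stage_missing].  Missing age/sex encode as zeros with the missing mask set;
#: a missing stage gets its own explicit slot so cancers without a conventional
#: staging system remain representable.
CLINICAL_FEATURES = (
    "age_scaled",
    "sex_female",
    "sex_male",
    "stage_I",
    "stage_II",
    "stage_III",
    "stage_IV",
    "stage_missing",
)
M_CLINICAL = len(CLINICAL_FEATURES)

_STAGES = ("I", "II", "III", "IV")


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


class SchemaError(ValueError):
    """Raised when a manifest or container is missing required structure."""


class IntegrityError(ValueError):
    """Raised on duplicate keys or inconsistent bookkeeping."""


class DimensionError(ValueError):
    """Raised when feature dimensions disagree."""


@dataclass(frozen=True)
class SurvivalLabel:
    """Right-censored time-to-event outcome, time in months."""

    time: float
    event: int
    endpoint: str = "OS"

    def __post_init__(self):
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValidationError(f"survival time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValidationError(f"event must be 0 or 1, got {self.event}")
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(
                f"endpoint must be one of {ENDPOINTS}, got {self.endpoint!r}"
            )


@dataclass(frozen=True)
class ClinicalVector:
    """Encoded clinical covariates C (1 x M) with an explicit missingness mask."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    missing_mask: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(
            self, "missing_mask", np.asarray(self.missing_mask, dtype=int)
        )
        if not (len(self.values) == len(self.feature_names) == len(self.missing_mask)):
            raise ValidationError("clinical vector fields must share one length")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("encoded clinical values must be finite")

    def __len__(self):
        return len(self.values)


@dataclass(frozen=True)
class CancerTypeCode:
    """Cancer type on a fixed one-hot basis of K types (sorted-label order)."""

    index: int
    label: str
    K: int

    def __post_init__(self):
        if not 0 <= self.index < self.K:
            raise ValidationError(f"cancer index {self.index} outside [0, {self.K})")

    @property
    def onehot(self) -> np.ndarray:
        v = np.zeros(self.K)
        v[self.index] = 1.0
        return v


@dataclass
class FeatureBag:
    """One slide's N x D patch-embedding matrix plus tile coordinates.

    Coordinates are 0-based level-0 pixel origins of each tile, column-first
    (x = column, y = row); a tile covers the half-open square
    [x, x + patch_size_px) x [y, y + patch_size_px).
    """

    slide_id: str
    features: np.ndarray
    coords: np.ndarray
    patch_size_px: int = 224
    magnification: str = "10x"
    encoder_name: str = "unknown"

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int32)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValidationError("features must be an N x D matrix with N >= 1")
        if self.coords.shape != (self.features.shape[0], 2):
            raise ValidationError("coords must be N x 2, aligned with features")
        if not np.all(np.isfinite(self.features)):
            raise ValidationError(f"non-finite features in bag {self.slide_id!r}")
        if len({tuple(c) for c in self.coords.tolist()}) != len(self.coords):
            raise ValidationError(f"duplicate tile coords in bag {self.slide_id!r}")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


@dataclass
class PatientRecord:
    patient_id: str
    bags: list[FeatureBag]
    clinical: ClinicalVector
    cancer: CancerTypeCode
    survival: SurvivalLabel

    def __post_init__(self):
        if len(self.bags) < 1:
            raise ValidationError(f"patient {self.patient_id!r} has no bags")
        dims = {b.dim for b in self.bags}
        if len(dims) > 1:
            raise DimensionError(
                f"patient {self.patient_id!r} mixes feature dims {sorted(dims)}"
            )


@dataclass
class Cohort:
    """A list of patients sharing a cancer-label basis (size K) and feature dim D."""

    patients: list[PatientRecord]
    K: int
    D: int
    cancer_labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate patient ids: {dupes}")
        for p in self.patients:
            if p.cancer.index >= self.K:
                raise ValidationError(
                    f"patient {p.patient_id!r} cancer index {p.cancer.index} >= K={self.K}"
                )

    def __len__(self):
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


def encode_clinical(
    age: float | None = None,
    sex: str | None = None,
    stage: str | None = None,
) -> ClinicalVector:
    """Encode (age, sex, stage) into the fixed M=8 layout.

    Any field may be missing (None or NaN).  Missing age encodes as 0 with the
    missing mask set; missing sex leaves both sex slots 0; missing stage sets
    the dedicated ``stage_missing`` slot.
    """
    values = np.zeros(M_CLINICAL)
    mask = np.zeros(M_CLINICAL, dtype=int)

    if age is None or (isinstance(age, float) and np.isnan(age)):
        mask[0] = 1
    else:
        values[0] = float(age) / 100.0

    if sex is None or (isinstance(sex, float) and np.isnan(sex)):
        mask[1] = mask[2] = 1
    else:
        s = str(sex).strip().lower()
        if s in ("female", "f"):
            values[1] = 1.0
        elif s in ("male", "m"):
            values[2] = 1.0
        else:
            raise ValidationError(f"unrecognized sex {sex!r}")

    if stage is None or (isinstance(stage, float) and np.isnan(stage)):
        values[7] = 1.0
    else:
        s = str(stage).strip().upper()
        if s in ("", "NA", "NAN", "MISSING", "NONE"):
            values[7] = 1.0
        elif s in _STAGES:
            values[3 + _STAGES.index(s)] = 1.0
        else:
            raise ValidationError(f"unrecognized stage {stage!r}")

    return ClinicalVector(values=values, feature_names=CLINICAL_FEATURES, missing_mask=mask)


def pool_patient_bag(record: PatientRecord) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Merge all of a patient's bags into one (sum N_i) x D matrix.

    Rows follow bag order, then within-bag row order.  Returns the merged
    matrix and a provenance list mapping each merged row to (slide_id, row).
    """
    if not record.bags:
        raise ValidationError("cannot pool an empty bag list")
    merged = np.concatenate([b.features for b in record.bags], axis=0)
    provenance = [
        (b.slide_id, i) for b in record.bags for i in range(b.n)
    ]
    return merged, provenance
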