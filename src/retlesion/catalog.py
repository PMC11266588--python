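"""Dataset naming convention, catalogues and cohort summary statistics.

Every image in the published infant-retina database is named by a fixed
underscore-separated grammar::

    ID_sex_GAxx_BWxxxx_PAxx_DGx_PFx_device_Sxx_n.jpg

encoding patient id, sex, gestational age (weeks), birth weight (grams),
postconceptual age (weeks), diagnosis code, plus-form, imaging device,
series (examination) number and the image index within the series.  This
module decodes/encodes that grammar, catalogues a dataset stored either as
a folder tree or as the accompanying metadata workbook, and computes the
cohort summary statistics (patient-level gestational age and birth weight,
series-level postconceptual age, categorical counts).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ImageMetadata",
    "DatasetCatalog",
    "SummaryStats",
    "FilenameError",
    "parse_filename",
    "format_filename",
    "scan_dataset",
    "diagnosis_label",
    "summarize",
]

#: Device tokens as they appear in filenames, mapped to the integer device
#: code used in the metadata workbook (1 Clarity RetCam 3, 2 Natus RetCam
#: Envision, 3 Phoenix ICON).  Bare digits are accepted as-is.
DEVICE_TOKENS = {"RC3": 1, "RE": 2, "ICON": 3, "1": 1, "2": 2, "3": 3}
_DEVICE_CANONICAL = {1: "RC3", 2: "RE", 3: "ICON"}

#: Diagnosis code vocabulary (code -> clinical label).
DIAGNOSIS_LABELS = {
    0: "Physiological",
    1: "ROP 0",
    2: "ROP 1",
    3: "ROP 2",
    4: "ROP 3",
    5: "ROP 4A",
    6: "ROP 4B",
    7: "ROP 5",
    8: "A-ROP",
    9: "St.p. ROP",
    10: "Hamartomas",
    11: "Haemorrhage",
    12: "Hypoplasia n.II",
    13: "Toxoplasma",
}

PLUS_FORM_LABELS = {0: "normal", 1: "pre-plus", 2: "plus"}

_IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png"}


class FilenameError(ValueError):
    """A filename does not follow the dataset naming convention."""


class ValidationError(ValueError):
    """Metadata fields violate the documented invariants."""


@dataclass(frozen=True)
class ImageMetadata:
    """Decoded attributes of one fundus image."""

    patient_id: int
    sex: str
    gestational_age_weeks: int
    birth_weight_g: int
    postconceptual_age_weeks: int
    diagnosis_code: int
    plus_form: int
    device: int
    device_token: str
    series: int
    image_index: int
    path: str | None = None

    def validate(self) -> "ImageMetadata":
        if self.patient_id < 1:
            raise ValidationError(f"patient_id must be positive, got {self.patient_id}")
        if self.sex not in ("F", "M"):
            raise ValidationError(f"sex must be F or M, got {self.sex!r}")
        if not 20 <= self.gestational_age_weeks <= 45:
            raise ValidationError(
                f"gestational_age_weeks out of range [20, 45]: {self.gestational_age_weeks}"
            )
        if not 300 <= self.birth_weight_g <= 5000:
            raise ValidationError(
                f"birth_weight_g out of range [300, 5000]: {self.birth_weight_g}"
            )
        if self.postconceptual_age_weeks < self.gestational_age_weeks:
            raise ValidationError(
                "postconceptual_age_weeks must be >= gestational_age_weeks"
            )
        if self.diagnosis_code not in DIAGNOSIS_LABELS:
            raise ValidationError(f"diagnosis_code out of range 0..13: {self.diagnosis_code}")
        if self.plus_form not in (0, 1, 2):
            raise ValidationError(f"plus_form must be 0, 1 or 2, got {self.plus_form}")
        if self.device not in (1, 2, 3):
            raise ValidationError(f"device must be 1, 2 or 3, got {self.device}")
        if self.series < 1 or self.image_index < 1:
            raise ValidationError("series and image_index must be positive")
        return self


def _int_field(token: str, prefix: str, name: str) -> int:
    if not token.startswith(prefix):
        raise FilenameError(f"expected token {name!r} with prefix {prefix!r}, got {token!r}")
    body = token[len(prefix):]
    if not body.isdigit():
        raise FilenameError(f"non-numeric {name} field: {token!r}")
    return int(body)


def parse_filename(name: str) -> ImageMetadata:
    """Decode a convention-compliant base filename into :class:`ImageMetadata`.

    Accepts the name with or without an image extension; the underscore is
    the sole field separator.  The device token is normalised to the
    integer code while the verbatim token is retained.
    """
    base = name
    for suffix in _IMAGE_SUFFIXES:
        if base.lower().endswith(suffix):
            base = base[: -len(suffix)]
            break
    tokens = base.split("_")
    if len(tokens) != 10:
        raise FilenameError(
            f"expected 10 underscore-separated fields, got {len(tokens)} in {name!r}"
        )
    (t_id, t_sex, t_ga, t_bw, t_pa, t_dg, t_pf, t_dev, t_s, t_n) = tokens
    if not t_id.isdigit():
        raise FilenameError(f"non-numeric patient id token: {t_id!r}")
    if t_sex not in ("F", "M"):
        raise FilenameError(f"sex token must be F or M, got {t_sex!r}")
    if t_dev not in DEVICE_TOKENS:
        raise FilenameError(f"unknown device token: {t_dev!r}")
    if not t_s.startswith("S") or not t_s[1:].isdigit():
        raise FilenameError(f"malformed series token: {t_s!r}")
    if not t_n.isdigit():
        raise FilenameError(f"non-numeric image index token: {t_n!r}")

    meta = ImageMetadata(
        patient_id=int(t_id),
        sex=t_sex,
        gestational_age_weeks=_int_field(t_ga, "GA", "gestational age"),
        birth_weight_g=_int_field(t_bw, "BW", "birth weight"),
        postconceptual_age_weeks=_int_field(t_pa, "PA", "postconceptual age"),
        diagnosis_code=_int_field(t_dg, "DG", "diagnosis code"),
        plus_form=_int_field(t_pf, "PF", "plus form"),
        device=DEVICE_TOKENS[t_dev],
        device_token=t_dev,
        series=int(t_s[1:]),
        image_index=int(t_n),
    )
    try:
        meta.validate()
    except ValidationError as exc:  # surface the offending token
        raise FilenameError(f"{name!r}: {exc}") from exc
    return meta


def format_filename(meta: ImageMetadata, extension: str = "") -> str:
    """Emit the canonical filename for validated metadata.

    Patient id is zero-padded to width 3, series to width 2; the stored
    device token is used verbatim (falling back to the canonical token for
    the device code).
    """
    meta.validate()
    token = meta.device_token or _DEVICE_CANONICAL[meta.device]
    stem = (
        f"{meta.patient_id:03d}_{meta.sex}"
        f"_GA{meta.gestational_age_weeks}_BW{meta.birth_weight_g}"
        f"_PA{meta.postconceptual_age_weeks}_DG{meta.diagnosis_code}"
        f"_PF{meta.plus_form}_{token}_S{meta.series:02d}_{meta.image_index}"
    )
    return stem + extension


def diagnosis_label(code: int) -> str:
    """Clinical label for a diagnosis code (0..13)."""
    try:
        return DIAGNOSIS_LABELS[int(code)]
    except (KeyError, TypeError) as exc:
        raise KeyError(f"diagnosis code out of range 0..13: {code!r}") from exc


@dataclass
class DatasetCatalog:
    """An ordered collection of per-image metadata records."""

    records: list[ImageMetadata] = field(default_factory=list)
    source: str = "folder_tree"
    skipped: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "source": self.source,
            "skipped": self.skipped,
            "records": [asdict(r) for r in self.records],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _tree_records(root: Path) -> tuple[list[ImageMetadata], list[str]]:
    records: dict[str, ImageMetadata] = {}
    skipped: list[str] = []
    for path in sorted(root.rglob("*")):
        if not path.is_file() or path.suffix.lower() not in _IMAGE_SUFFIXES:
            if path.is_file():
                skipped.append(str(path))
            continue
        if path.name in records:  # mirrored layout duplicate
            continue
        try:
            meta = parse_filename(path.name)
        except FilenameError:
            skipped.append(str(path))
            continue
        records[path.name] = ImageMetadata(**{**asdict(meta), "path": str(path)})
    return list(records.values()), skipped


_WORKBOOK_COLUMNS = {
    "ID": "patient_id",
    "SEX": "sex",
    "GESTATIONAL_AGE": "gestational_age_weeks",
    "BIRTH_WEIGHT": "birth_weight_g",
    "POSTCONCEPTUAL_AGE": "postconceptual_age_weeks",
    "DIAGNOSIS_CODE": "diagnosis_code",
    "PLUS_FORM": "plus_form",
    "DEVICE": "device",
    "SERIES_NUMBER": "series",
}


def _workbook_records(path: Path) -> list[ImageMetadata]:
    frame = pd.read_excel(path)
    frame.columns = [str(c).strip().upper() for c in frame.columns]
    missing = set(_WORKBOOK_COLUMNS) - set(frame.columns)
    if missing:
        raise IOError(f"workbook {path} lacks required columns: {sorted(missing)}")
    records: list[ImageMetadata] = []
    counters: dict[tuple[int, int], int] = {}
    for _, row in frame.iterrows():
        device = int(row["DEVICE"])
        key = (int(row["ID"]), int(row["SERIES_NUMBER"]))
        if "IMAGE_NUMBER" in frame.columns and not pd.isna(row.get("IMAGE_NUMBER")):
            idx = int(row["IMAGE_NUMBER"])
        else:
            counters[key] = counters.get(key, 0) + 1
            idx = counters[key]
        records.append(
            ImageMetadata(
                patient_id=int(row["ID"]),
                sex=str(row["SEX"]).strip(),
                gestational_age_weeks=int(row["GESTATIONAL_AGE"]),
                birth_weight_g=int(row["BIRTH_WEIGHT"]),
                postconceptual_age_weeks=int(row["POSTCONCEPTUAL_AGE"]),
                diagnosis_code=int(row["DIAGNOSIS_CODE"]),
                plus_form=int(row["PLUS_FORM"]),
                device=device,
                device_token=str(device),
                series=key[1],
                image_index=idx,
                path=str(path),
            ).validate()
        )
    return records


def scan_dataset(root: str | Path) -> DatasetCatalog:
    """Catalogue a dataset folder tree or a metadata workbook.

    Folder trees may use any of the mirrored layouts (``images``,
    ``images_stack``, ``images_stack_without_captions``); duplicates across
    layouts are removed by basename.  Files that do not parse are collected
    into :attr:`DatasetCatalog.skipped` rather than aborting the scan.
    """
    root = Path(root)
    if root.is_file() and root.suffix.lower() in (".xlsx", ".xls"):
        return DatasetCatalog(records=_workbook_records(root), source="workbook")
    if not root.is_dir():
        raise IOError(f"dataset root {root} is neither a directory nor a workbook")
    records, skipped = _tree_records(root)
    if not records:
        import warnings

        warnings.warn(f"no convention-named images found under {root}", stacklevel=2)
    return DatasetCatalog(records=records, source="folder_tree", skipped=skipped)


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 rounded away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class VariableStats:
    mean: float
    min: float
    max: float
    std: float  # population (n denominator)

    @property
    def mean_rounded(self) -> int:
        return round_half_up(self.mean)

    @property
    def std_rounded(self) -> int:
        return round_half_up(self.std)


@dataclass
class SummaryStats:
    """Cohort summary in the shape of the published overview table.

    Gestational age and birth weight are patient-level (one value per
    unique patient), postconceptual age is series-level (one value per
    unique (patient, series) pair), counts are image/series/patient-level.
    """

    gestational_age: VariableStats
    birth_weight: VariableStats
    postconceptual_age: VariableStats
    n_patients: int
    n_images: int
    n_series: int
    patients_by_sex: dict[str, int]
    images_by_sex: dict[str, int]
    series_by_sex: dict[str, int]
    patients_by_device: dict[int, int]
    images_by_device: dict[int, int]
    series_by_device: dict[int, int]
    images_by_plus_form: dict[int, int]
    images_by_diagnosis: dict[int, int]
    patients_by_diagnosis: dict[int, int]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _stats(values: Sequence[float]) -> VariableStats:
    import numpy as np

    arr = np.asarray(list(values), dtype=float)
    return VariableStats(
        mean=float(arr.mean()),
        min=float(arr.min()),
        max=float(arr.max()),
        std=float(arr.std(ddof=0)),
    )


def summarize(catalog: DatasetCatalog) -> SummaryStats:
    """Compute the cohort overview statistics from a catalogue.

    Patient-level attributes (sex, device, gestational age, birth weight)
    are taken from each patient's first record; repeating a patient's
    images therefore changes image counts but never the patient-level
    statistics.
    """
    if not catalog.records:
        raise ValueError("cannot summarise an empty catalog")
    frame = catalog.to_dataframe()

    patients = frame.drop_duplicates("patient_id")
    series = frame.drop_duplicates(["patient_id", "series"])

    def counts(df: pd.DataFrame, col: str) -> dict:
        return {k: int(v) for k, v in df[col].value_counts().items()}

    patients_by_diag = {
        int(code): int(frame.loc[frame.diagnosis_code == code, "patient_id"].nunique())
        for code in sorted(frame.diagnosis_code.unique())
    }

    return SummaryStats(
        gestational_age=_stats(patients.gestational_age_weeks),
        birth_weight=_stats(patients.birth_weight_g),
        postconceptual_age=_stats(series.postconceptual_age_weeks),
        n_patients=int(patients.shape[0]),
        n_images=int(frame.shape[0]),
        n_series=int(series.shape[0]),
        patients_by_sex=counts(patients, "sex"),
        images_by_sex=counts(frame, "sex"),
        series_by_sex=counts(series, "sex"),
        patients_by_device=counts(patients, "device"),
        images_by_device=counts(frame, "device"),
        series_by_device=counts(series, "device"),
        images_by_plus_form=counts(frame, "plus_form"),
        images_by_diagnosis=counts(frame, "diagnosis_code"),
        patients_by_diagnosis=patients_by_diag,
    )
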