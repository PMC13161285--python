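"""Sample data model, CSV interchange, and the bundled clavicle dataset.

The unit of observation is a single bone specimen with a known postmortem
interval (PMI, years) and a measured peak chemiluminescence intensity
(Ipeak, arbitrary units).  A :class:`LuminolDataset` is an ordered,
id-unique collection of such specimens; every regression stage downstream
consumes one.

The bundled dataset transcribes the published measurements for 24 human
clavicles (PMI 7 to ~500 years).  The ~500-year specimen's PMI is only
approximate and is flagged so that fitting entry points can exclude it by
default: the 53 -> 500 year gap contains no intermediate data and would
force an extrapolation that inflates model uncertainty.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BoneSample",
    "LuminolDataset",
    "DatasetError",
    "SchemaError",
    "RowError",
    "load_fixture",
    "read_dataset",
    "write_dataset",
    "exclude_samples",
]

VALID_SEX = ("F", "M", "unknown")

#: Canonical CSV column order; the last five are optional on input.
CSV_COLUMNS = (
    "sample_id",
    "pmi_years",
    "ipeak_au",
    "exposure_s",
    "correction_factor",
    "age_at_death",
    "sex",
    "pmi_approximate",
)
REQUIRED_COLUMNS = ("sample_id", "pmi_years", "ipeak_au")


class DatasetError(ValueError):
    """Base error for dataset construction and I/O."""


class SchemaError(DatasetError):
    """A required column is missing or the file has no usable header."""


class RowError(DatasetError):
    """One or more data rows failed validation; message lists line numbers."""


@dataclass(frozen=True)
class BoneSample:
    """One specimen: PMI in years and peak luminol intensity in A.U.

    ``ipeak_au`` is the exposure-corrected maximum emission of the
    chemiluminescence reaction.  ``pmi_approximate`` marks specimens whose
    PMI is only known to order of magnitude (the archaeological ~500-year
    clavicle in the bundled data).
    """

    sample_id: int
    pmi_years: float
    ipeak_au: float
    exposure_s: float | None = None
    correction_factor: float | None = None
    age_at_death: int | None = None
    sex: str = "unknown"
    pmi_approximate: bool = False

    def __post_init__(self) -> None:
        if int(self.sample_id) <= 0:
            raise DatasetError(f"sample_id must be positive, got {self.sample_id}")
        if not (self.pmi_years > 0 and math.isfinite(self.pmi_years)):
            raise DatasetError(
                f"sample {self.sample_id}: pmi_years must be positive, got {self.pmi_years}"
            )
        if not (self.ipeak_au > 0 and math.isfinite(self.ipeak_au)):
            raise DatasetError(
                f"sample {self.sample_id}: ipeak_au must be positive, got {self.ipeak_au}"
            )
        for name in ("exposure_s", "correction_factor"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise DatasetError(f"sample {self.sample_id}: {name} must be positive, got {v}")
        if self.age_at_death is not None and self.age_at_death <= 0:
            raise DatasetError(f"sample {self.sample_id}: age_at_death must be positive")
        if self.sex not in VALID_SEX:
            raise DatasetError(
                f"sample {self.sample_id}: sex must be one of {VALID_SEX}, got {self.sex!r}"
            )


@dataclass(frozen=True)
class LuminolDataset:
    """Ordered collection of :class:`BoneSample` with unique ids."""

    samples: tuple[BoneSample, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate sample ids: {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def ids(self) -> np.ndarray:
        return np.array([s.sample_id for s in self.samples], dtype=int)

    @property
    def pmi(self) -> np.ndarray:
        return np.array([s.pmi_years for s in self.samples], dtype=float)

    @property
    def ipeak(self) -> np.ndarray:
        return np.array([s.ipeak_au for s in self.samples], dtype=float)

    @property
    def is_sorted_by_pmi(self) -> bool:
        p = self.pmi
        return bool(np.all(np.diff(p) >= 0))

    @property
    def approximate_ids(self) -> frozenset[int]:
        """Ids of samples whose PMI is flagged approximate."""
        return frozenset(s.sample_id for s in self.samples if s.pmi_approximate)

    def sorted_by_pmi(self) -> "LuminolDataset":
        ordered = tuple(sorted(self.samples, key=lambda s: (s.pmi_years, s.sample_id)))
        return replace(self, samples=ordered)

    def subset(self, ids: Iterable[int]) -> "LuminolDataset":
        keep = set(ids)
        return replace(self, samples=tuple(s for s in self.samples if s.sample_id in keep))

    def get(self, sample_id: int) -> BoneSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"no sample with id {sample_id}")


def load_fixture() -> LuminolDataset:
    """Return the bundled 24-clavicle dataset, sorted by PMI.

    Ipeak values are stored exactly as published and are treated as already
    exposure-corrected; the published correction-factor column is not
    unambiguously recoverable and is left missing.  Sample 24 carries
    ``pmi_years = 500.0`` with ``pmi_approximate`` set.
    """
    ref = resources.files("luminolpmi.data").joinpath("clavicle_luminol.csv")
    with resources.as_file(ref) as path:
        ds = read_dataset(path)
    return replace(
        ds.sorted_by_pmi(),
        provenance=(
            "bundled clavicle dataset (24 samples); sample 24 PMI ~500 y is approximate"
        ),
    )


def _parse_float(text: str, column: str, line: int, errors: list[str]) -> float | None:
    text = text.strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        errors.append(f"line {line}: column {column!r}: unparseable number {text!r}")
        return None


def read_dataset(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> LuminolDataset:
    """Read a dataset from CSV.

    Parameters
    ----------
    path
        CSV file with a header row.  Required columns: ``sample_id``,
        ``pmi_years``, ``ipeak_au``.  Optional: ``exposure_s``,
        ``correction_factor``, ``age_at_death``, ``sex``,
        ``pmi_approximate``.
    schema
        Optional mapping from canonical column names to the names used in
        the file, e.g. ``{"pmi_years": "PMI"}``.

    Raises
    ------
    SchemaError
        If a required column is absent.
    RowError
        Listing the line number of every invalid row (non-positive PMI or
        Ipeak, unparseable numbers, duplicate ids).
    """
    path = Path(path)
    rename = dict(schema or {})
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        header = {rename.get(c, c): c for c in (reader.fieldnames)}
        # header maps canonical -> file column name
        inverse = {}
        for canon in CSV_COLUMNS:
            file_col = rename.get(canon, canon)
            if file_col in reader.fieldnames:
                inverse[canon] = file_col
        missing = [c for c in REQUIRED_COLUMNS if c not in inverse]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

        samples: list[BoneSample] = []
        errors: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            def cell(canon: str) -> str:
                return (row.get(inverse[canon]) or "") if canon in inverse else ""

            sid = _parse_float(cell("sample_id"), "sample_id", lineno, errors)
            pmi = _parse_float(cell("pmi_years"), "pmi_years", lineno, errors)
            ipk = _parse_float(cell("ipeak_au"), "ipeak_au", lineno, errors)
            exp = _parse_float(cell("exposure_s"), "exposure_s", lineno, errors)
            cf = _parse_float(cell("correction_factor"), "correction_factor", lineno, errors)
            age = _parse_float(cell("age_at_death"), "age_at_death", lineno, errors)
            sex = cell("sex").strip() or "unknown"
            approx = cell("pmi_approximate").strip() in ("1", "true", "True", "yes")
            if sid is None or pmi is None or ipk is None:
                if not errors or not errors[-1].startswith(f"line {lineno}"):
                    errors.append(f"line {lineno}: missing required value")
                continue
            try:
                samples.append(
                    BoneSample(
                        sample_id=int(sid),
                        pmi_years=pmi,
                        ipeak_au=ipk,
                        exposure_s=exp,
                        correction_factor=cf,
                        age_at_death=None if age is None else int(age),
                        sex=sex,
                        pmi_approximate=approx,
                    )
                )
            except DatasetError as exc:
                errors.append(f"line {lineno}: {exc}")
        if errors:
            raise RowError("; ".join(errors))
    try:
        return LuminolDataset(samples=tuple(samples), provenance=str(path))
    except DatasetError as exc:  # duplicate ids
        raise RowError(str(exc)) from exc


def _fmt(v: float | int | None) -> str:
    if v is None:
        return ""
    if isinstance(v, int):
        return str(v)
    return repr(float(v))


def write_dataset(ds: LuminolDataset, path: str | Path) -> None:
    """Write a dataset to CSV at full float precision (round-trip safe)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for s in ds.samples:
            writer.writerow(
                [
                    s.sample_id,
                    _fmt(s.pmi_years),
                    _fmt(s.ipeak_au),
                    _fmt(s.exposure_s),
                    _fmt(s.correction_factor),
                    _fmt(s.age_at_death),
                    s.sex,
                    int(s.pmi_approximate),
                ]
            )


def exclude_samples(ds: LuminolDataset, ids: Iterable[int]) -> LuminolDataset:
    """Return a copy of ``ds`` without the listed sample ids.

    The exclusion is recorded in the new dataset's provenance; the original
    is untouched.  Unknown ids raise :class:`DatasetError` naming them.
    """
    drop = set(int(i) for i in ids)
    known = set(int(i) for i in ds.ids)
    unknown = sorted(drop - known)
    if unknown:
        raise DatasetError(f"cannot exclude unknown sample id(s): {unknown}")
    if not drop:
        return ds
    kept = tuple(s for s in ds.samples if s.sample_id not in drop)
    note = f"excluded samples {sorted(drop)}"
    provenance = f"{ds.provenance}; {note}" if ds.provenance else note
    return LuminolDataset(samples=kept, provenance=provenance)


def drop_approximate(ds: LuminolDataset) -> LuminolDataset:
    """Exclude samples whose PMI is flagged approximate (if any)."""
    ids = ds.approximate_ids
    return exclude_samples(ds, ids) if ids else ds
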