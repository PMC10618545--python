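"""Domain types and CSV readers/writers for imaging-based drug screens.

The interchange formats are plain UTF-8 comma-separated files with one
header row (see README for the column dictionary):

* ``wells.csv``       — per-well, per-timepoint image-feature aggregates
* ``platemap.csv``    — well role / sample / drug / concentration layout
* ``drugs.csv``       — drug library with the 5-point concentration series
* ``clinical.csv``    — per-patient clinical metadata
* ``dss_matrix.csv``  — drugs x samples drug-sensitivity-score matrix

All concentrations are nanomolar.  Well addresses use alphanumeric 384-well
labels A01..P24; numeric indexing is never exposed.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ROLES = ("neg_control", "pos_control", "treatment")
FORMATS = ("3D", "2D")
PARAMETERS = ("TMRM", "POPO1")

_WELL_RE = re.compile(r"^([A-P])0*([1-9][0-9]?)$")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class PlateValidationError(ValueError):
    """A record violates a plate-level invariant (bad address, negative
    aggregate, control well carrying a drug, ...)."""


def normalize_well(well: str) -> str:
    """Canonicalize a 384-well address to zero-padded form (``A1`` -> ``A01``).

    Raises :class:`PlateValidationError` for addresses outside rows A-P or
    columns 1-24.
    """
    m = _WELL_RE.match(str(well).strip().upper())
    if not m:
        raise PlateValidationError(f"invalid 384-well address: {well!r}")
    row, col = m.group(1), int(m.group(2))
    if not 1 <= col <= 24:
        raise PlateValidationError(f"column out of range for 384-well plate: {well!r}")
    return f"{row}{col:02d}"


# Channel aggregate columns.  For 2D plates the volume-named columns carry
# the corresponding area aggregates; the ``format`` field disambiguates.
AGGREGATE_COLUMNS = (
    "tmrm_volume",
    "popo1_volume",
    "popo1_area",
    "hoechst_volume",
    "hoechst_area",
    "caspase_volume",
    "inv_brightfield_intensity",
)
OPTIONAL_AGGREGATES = ("caspase_volume",)

WELL_IDENTITY_COLUMNS = (
    "plate_id",
    "well",
    "sample_id",
    "format",
    "timepoint_h",
    "role",
    "drug_id",
    "conc_nM",
)
WELL_COLUMNS = WELL_IDENTITY_COLUMNS + AGGREGATE_COLUMNS


@dataclass
class WellFeatures:
    """Per-well, per-timepoint channel aggregates from image analysis.

    Aggregates are nonnegative arbitrary imaging units; a missing channel is
    ``None``.  ``conc_nM`` is ``None`` for control wells.
    """

    plate_id: str
    well: str
    sample_id: str
    format: str
    timepoint_h: float
    role: str
    drug_id: str | None = None
    conc_nM: float | None = None
    tmrm_volume: float | None = None
    popo1_volume: float | None = None
    popo1_area: float | None = None
    hoechst_volume: float | None = None
    hoechst_area: float | None = None
    caspase_volume: float | None = None
    inv_brightfield_intensity: float | None = None

    def __post_init__(self) -> None:
        self.well = normalize_well(self.well)
        if self.format not in FORMATS:
            raise PlateValidationError(
                f"{self.plate_id}/{self.well}: unknown format {self.format!r}"
            )
        if self.role not in ROLES:
            raise PlateValidationError(
                f"{self.plate_id}/{self.well}: unknown role {self.role!r}"
            )
        if self.drug_id in ("", None) or (
            isinstance(self.drug_id, float) and math.isnan(self.drug_id)
        ):
            self.drug_id = None
        if self.conc_nM is not None and (
            isinstance(self.conc_nM, float) and math.isnan(self.conc_nM)
        ):
            self.conc_nM = None
        if self.role == "treatment":
            if self.drug_id is None or self.conc_nM is None or self.conc_nM <= 0:
                raise PlateValidationError(
                    f"{self.plate_id}/{self.well}: treatment well requires "
                    f"drug_id and conc_nM > 0"
                )
        else:
            if self.drug_id is not None:
                raise PlateValidationError(
                    f"{self.plate_id}/{self.well}: control well must not carry a drug"
                )
        for name in AGGREGATE_COLUMNS:
            v = getattr(self, name)
            if v is None:
                continue
            if isinstance(v, float) and math.isnan(v):
                setattr(self, name, None)
                continue
            if v < 0:
                raise PlateValidationError(
                    f"{self.plate_id}/{self.well}: negative aggregate {name}={v}"
                )


def wells_to_frame(wells: Iterable[WellFeatures]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(w) for w in wells], columns=WELL_COLUMNS)
    return df


def frame_to_wells(df: pd.DataFrame) -> list[WellFeatures]:
    recs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        recs.append(WellFeatures(**{k: d[k] for k in WELL_COLUMNS}))
    return recs


def read_well_features(path: str | Path) -> list[WellFeatures]:
    """Read ``wells.csv`` into validated :class:`WellFeatures` records.

    Unknown columns are ignored with a logged warning; a missing required
    column raises :class:`SchemaError` naming the column; a negative channel
    aggregate raises :class:`PlateValidationError` naming the well.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = [c for c in WELL_COLUMNS if c not in OPTIONAL_AGGREGATES]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    unknown = [c for c in df.columns if c not in WELL_COLUMNS]
    if unknown:
        log.warning("ignoring unknown columns in %s: %s", path, unknown)
    for col in WELL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return frame_to_wells(df[list(WELL_COLUMNS)])


def write_well_features(wells: Iterable[WellFeatures], path: str | Path) -> None:
    wells_to_frame(wells).to_csv(path, index=False)


@dataclass
class PlateMapEntry:
    plate_id: str
    well: str
    role: str
    sample_id: str
    drug_id: str | None = None
    conc_nM: float | None = None
    replicate_index: int = 1

    def __post_init__(self) -> None:
        self.well = normalize_well(self.well)
        if self.role not in ROLES:
            raise PlateValidationError(f"unknown role {self.role!r} for {self.well}")


@dataclass
class PlateMap:
    """Mapping from well address to role/sample/drug/concentration."""

    entries: list[PlateMapEntry]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(e) for e in self.entries])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlateMap":
        entries = []
        for row in df.itertuples(index=False):
            d = row._asdict()
            drug = d.get("drug_id")
            if isinstance(drug, float) and math.isnan(drug):
                drug = None
            conc = d.get("conc_nM")
            if isinstance(conc, float) and math.isnan(conc):
                conc = None
            entries.append(
                PlateMapEntry(
                    plate_id=d["plate_id"],
                    well=d["well"],
                    role=d["role"],
                    sample_id=d["sample_id"],
                    drug_id=drug,
                    conc_nM=conc,
                    replicate_index=int(d.get("replicate_index", 1)),
                )
            )
        return cls(entries)

    def validate(self) -> None:
        """Check per-plate control counts and 5-point dose series."""
        df = self.to_frame()
        for plate_id, g in df.groupby("plate_id"):
            for role in ("neg_control", "pos_control"):
                n = int((g["role"] == role).sum())
                if n < 2:
                    raise PlateValidationError(
                        f"plate {plate_id}: only {n} {role} wells (need >= 2)"
                    )
        tr = df[df["role"] == "treatment"]
        for (sample, drug), g in tr.groupby(["sample_id", "drug_id"]):
            n = g["conc_nM"].nunique()
            if n != 5:
                raise PlateValidationError(
                    f"series ({sample}, {drug}): {n} distinct concentrations (need 5)"
                )


def read_platemap(path: str | Path) -> PlateMap:
    return PlateMap.from_frame(pd.read_csv(path, float_precision="round_trip"))


def write_platemap(pm: PlateMap, path: str | Path) -> None:
    pm.to_frame().to_csv(path, index=False)


@dataclass
class DrugLibrary:
    """Drug panel with per-drug class/phase annotation and a 5-point
    log-spaced nanomolar concentration series."""

    table: pd.DataFrame  # drug_id, drug_class, phase, conc1_nM..conc5_nM

    CONC_COLUMNS = tuple(f"conc{i}_nM" for i in range(1, 6))

    def __post_init__(self) -> None:
        for col in ("drug_id",) + self.CONC_COLUMNS:
            if col not in self.table.columns:
                raise SchemaError(f"drug library missing column {col!r}")
        for row in self.table.itertuples(index=False):
            concs = [getattr(row, c) for c in self.CONC_COLUMNS]
            if not all(np.diff(concs) > 0):
                raise PlateValidationError(
                    f"drug {row.drug_id}: concentrations not strictly increasing"
                )

    @property
    def drug_ids(self) -> list[str]:
        return list(self.table["drug_id"])

    def concentrations(self, drug_id: str) -> np.ndarray:
        row = self.table.loc[self.table["drug_id"] == drug_id]
        if row.empty:
            raise KeyError(f"unknown drug {drug_id!r}")
        return row.iloc[0][list(self.CONC_COLUMNS)].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugLibrary":
        return cls(pd.read_csv(path, float_precision="round_trip"))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class ClinicalRecord:
    """Per-patient clinical metadata.

    ``recist`` is CR/PR/P or ``None`` and ``pfi_months`` is ``None`` for
    patients lost to follow-up; ``excluded`` patients are omitted from all
    association outputs.
    """

    patient_id: str
    sample_ids: list[str] = field(default_factory=list)
    histology: str = ""
    figo_stage: str = ""
    ca125: float | None = None
    recist: str | None = None
    pfi_months: float | None = None
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.recist in ("", "NA", None):
            self.recist = None
        elif self.recist not in ("CR", "PR", "P"):
            raise PlateValidationError(
                f"patient {self.patient_id}: unknown RECIST class {self.recist!r}"
            )
        if self.pfi_months is not None and (
            isinstance(self.pfi_months, float) and math.isnan(self.pfi_months)
        ):
            self.pfi_months = None


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read ``clinical.csv``; NA-tolerant for recist/pfi; duplicate
    ``patient_id`` raises."""
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise SchemaError("missing required column: 'patient_id'")
    dupes = df["patient_id"][df["patient_id"].duplicated()]
    if len(dupes):
        raise PlateValidationError(f"duplicate patient_id: {sorted(set(dupes))}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        raw_samples = d.get("sample_ids", "")
        if isinstance(raw_samples, float) and math.isnan(raw_samples):
            raw_samples = ""
        samples = [s for s in str(raw_samples).split(";") if s]
        recist = d.get("recist")
        if isinstance(recist, float) and math.isnan(recist):
            recist = None
        ca125 = d.get("ca125")
        if isinstance(ca125, float) and math.isnan(ca125):
            ca125 = None
        records.append(
            ClinicalRecord(
                patient_id=str(d["patient_id"]),
                sample_ids=samples,
                histology=str(d.get("histology", "") or ""),
                figo_stage=str(d.get("figo_stage", "") or ""),
                ca125=ca125,
                recist=recist,
                pfi_months=d.get("pfi_months"),
                excluded=bool(d.get("excluded", False)),
            )
        )
    return records


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["sample_ids"] = ";".join(r.sample_ids)
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_dss_matrix(results: pd.DataFrame, path: str | Path) -> None:
    """Serialize a drugs x samples DSS matrix.

    ``results`` is long-form with columns sample_id, drug_id, dss and an
    optional qc_pass flag; QC-failed entries are written as empty cells
    (missing, never zero).  Conflicting duplicates raise.
    """
    df = results.copy()
    if "qc_pass" in df.columns:
        df.loc[~df["qc_pass"].astype(bool), "dss"] = np.nan
    dup = df.duplicated(subset=["drug_id", "sample_id"], keep=False)
    if dup.any():
        conflicting = df[dup].groupby(["drug_id", "sample_id"])["dss"].nunique()
        if (conflicting > 1).any():
            bad = conflicting[conflicting > 1].index.tolist()
            raise PlateValidationError(f"conflicting duplicate DSS entries: {bad}")
        df = df.drop_duplicates(subset=["drug_id", "sample_id"])
    mat = df.pivot(index="drug_id", columns="sample_id", values="dss")
    mat.index.name = "drug_id"
    mat.to_csv(path, float_format="%.6f")


def read_dss_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="drug_id")


@dataclass
class ScreenDataset:
    """A complete screen: well features + plate map + drug library +
    clinical table, with provenance metadata."""

    wells: list[WellFeatures]
    platemap: PlateMap
    drug_library: DrugLibrary
    clinical: list[ClinicalRecord]
    meta: dict = field(default_factory=dict)

    def wells_frame(self) -> pd.DataFrame:
        return wells_to_frame(self.wells)

    def missing_wells(self) -> pd.DataFrame:
        """Wells referenced by the plate map lacking a feature row for both
        imaging timepoints.  The pipeline never silently drops wells."""
        wf = self.wells_frame()
        have = wf.groupby(["plate_id", "well"])["timepoint_h"].nunique()
        rows = []
        for e in self.platemap.entries:
            n = have.get((e.plate_id, e.well), 0)
            if n < 2:
                rows.append(
                    {"plate_id": e.plate_id, "well": e.well, "n_timepoints": int(n)}
                )
        return pd.DataFrame(rows, columns=["plate_id", "well", "n_timepoints"])

    def save(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "wells": outdir / "wells.csv",
            "platemap": outdir / "platemap.csv",
            "drugs": outdir / "drugs.csv",
            "clinical": outdir / "clinical.csv",
        }
        write_well_features(self.wells, paths["wells"])
        write_platemap(self.platemap, paths["platemap"])
        self.drug_library.to_csv(paths["drugs"])
        write_clinical(self.clinical, paths["clinical"])
        return paths

    @classmethod
    def load(cls, indir: str | Path, meta: dict | None = None) -> "ScreenDataset":
        indir = Path(indir)
        return cls(
            wells=read_well_features(indir / "wells.csv"),
            platemap=read_platemap(indir / "platemap.csv"),
            drug_library=DrugLibrary.from_csv(indir / "drugs.csv"),
            clinical=read_clinical(indir / "clinical.csv"),
            meta=meta or {},
        )
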