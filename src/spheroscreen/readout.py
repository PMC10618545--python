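"""Viability, death and growth readouts from well-level channel aggregates.

Two dyes carry the assay: TMRM accumulates in polarized mitochondria and
marks live cells, POPO-1 is membrane-impermeant and marks dead cells.
The cell-health readout is the TMRM signal over the composite spheroid
signal (sum of all fluorescence channels plus inverted brightfield); the
cell-death readout is the POPO-1 area over the Hoechst nuclear area.  Both
are dimensionless ratios, so they are invariant to a common rescaling of a
well's aggregates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate import WellFeatures, wells_to_frame

log = logging.getLogger(__name__)

# Channels entering the composite signal.  For 2D plates these columns carry
# area aggregates and the formulas are unchanged.
COMPOSITE_CHANNELS = (
    "tmrm_volume",
    "popo1_volume",
    "hoechst_volume",
    "caspase_volume",
    "inv_brightfield_intensity",
)

POPO1_SUBSTITUTE_BELOW = 0.1
POPO1_SUBSTITUTE_VALUE = 0.95


def composite_volume(features: WellFeatures) -> float:
    """Composite spheroid signal: sum over available fluorescence channels
    plus inverted brightfield; absent channels contribute 0."""
    values = [getattr(features, c) for c in COMPOSITE_CHANNELS]
    present = [v for v in values if v is not None and not math.isnan(v)]
    if not present:
        raise ValueError(
            f"{features.plate_id}/{features.well}: no channel aggregates present"
        )
    return float(sum(present))


def tmrm_parameter(features: WellFeatures) -> float:
    """Cell-health ratio: TMRM signal / composite signal; NaN when the
    composite is 0 (well excluded downstream)."""
    comp = composite_volume(features)
    if comp == 0:
        log.warning(
            "%s/%s: composite signal is 0; TMRM ratio undefined",
            features.plate_id,
            features.well,
        )
        return float("nan")
    tmrm = features.tmrm_volume or 0.0
    return float(tmrm / comp)


def popo1_parameter(features: WellFeatures) -> float:
    """Cell-death ratio: POPO-1 area / Hoechst area; NaN when the Hoechst
    area is 0."""
    hoechst = features.hoechst_area
    if hoechst is None or hoechst == 0 or math.isnan(hoechst):
        return float("nan")
    popo1 = features.popo1_area or 0.0
    return float(popo1 / hoechst)


def substitute_popo1_positive_control(
    control_values: list[float] | np.ndarray,
) -> list[float]:
    """Rescue degraded positive-control POPO-1 ratios.

    Dead-cell migration toward well edges can collapse the POPO-1 ratio in
    positive-control wells; any value strictly under 0.1 is replaced by 0.95.
    Values >= 0.1 pass through unchanged.
    """
    out = []
    n_sub = 0
    for v in control_values:
        if not math.isnan(v) and v < POPO1_SUBSTITUTE_BELOW:
            out.append(POPO1_SUBSTITUTE_VALUE)
            n_sub += 1
        else:
            out.append(float(v))
    if n_sub:
        log.info("substituted %d positive-control POPO-1 values", n_sub)
    return out


def count_popo1_substitutions(control_values) -> int:
    return int(sum(1 for v in control_values if not math.isnan(v) and v < POPO1_SUBSTITUTE_BELOW))


def fold_growth(value_t2: float, value_t72: float) -> float:
    """Fold change of a DMSO-well TMRM aggregate between the 2 h and 72 h
    imaging timepoints (area for 2D, volume for 3D); NaN if baseline is 0."""
    if value_t2 == 0 or math.isnan(value_t2):
        return float("nan")
    return float(value_t72 / value_t2)


@dataclass
class IFReadout:
    """Immunofluorescence composition readout: fraction of the well area
    that is epithelial cancer (CK8/18+) out of total cell area (CellMask+)."""

    sample_id: str
    cancer_fraction: float
    clamped: bool = False


def cancer_fraction(ck_area: float, cellmask_area: float) -> tuple[float, bool]:
    """CK8/18 area over CellMask area, clamped to [0, 1].

    Returns ``(fraction, clamped)``; NaN fraction when the CellMask area is 0.
    Segmentation slop can put the epithelial area slightly above the total
    area, hence the clamp flag.
    """
    if cellmask_area == 0 or math.isnan(cellmask_area):
        return float("nan"), False
    frac = ck_area / cellmask_area
    if frac > 1.0:
        return 1.0, True
    if frac < 0.0:
        return 0.0, True
    return float(frac), False


def well_readouts(wells: list[WellFeatures] | pd.DataFrame) -> pd.DataFrame:
    """Per-well, per-timepoint readout table.

    Columns: identity fields + tmrm_ratio, popo1_ratio, composite_volume.
    Positive-control POPO-1 substitution is *not* applied here; it is a
    control-group operation done by the QC/normalization stage.
    """
    df = wells_to_frame(wells) if not isinstance(wells, pd.DataFrame) else wells.copy()
    comp_cols = [c for c in COMPOSITE_CHANNELS if c in df.columns]
    comp = df[comp_cols].sum(axis=1, min_count=1)
    if comp.isna().any():
        bad = df.loc[comp.isna(), "well"].tolist()
        raise ValueError(f"wells with no channel aggregates: {bad}")
    tmrm = df["tmrm_volume"].fillna(0.0)
    out = df[
        ["plate_id", "well", "sample_id", "format", "timepoint_h", "role", "drug_id", "conc_nM"]
    ].copy()
    out["composite_volume"] = comp
    out["tmrm_ratio"] = np.where(comp > 0, tmrm / comp.replace(0, np.nan), np.nan)
    hoechst = df["hoechst_area"]
    popo1 = df["popo1_area"].fillna(0.0)
    out["popo1_ratio"] = np.where(
        hoechst.fillna(0) > 0, popo1 / hoechst.replace(0, np.nan), np.nan
    )
    return out


def sample_fold_growth(wells: list[WellFeatures] | pd.DataFrame) -> pd.DataFrame:
    """Mean DMSO-well fold growth (72 h vs 2 h TMRM aggregate) per
    (sample, format).

    Wells are matched across timepoints by (plate, well); wells missing
    either timepoint are skipped.
    """
    df = wells_to_frame(wells) if not isinstance(wells, pd.DataFrame) else wells
    neg = df[df["role"] == "neg_control"]
    wide = neg.pivot_table(
        index=["sample_id", "format", "plate_id", "well"],
        columns="timepoint_h",
        values="tmrm_volume",
    )
    if 2 not in wide.columns or 72 not in wide.columns:
        return pd.DataFrame(columns=["sample_id", "format", "fold_growth", "n_wells"])
    wide = wide.dropna(subset=[2, 72])
    wide = wide[wide[2] > 0]
    folds = (wide[72] / wide[2]).rename("fold")
    agg = (
        folds.groupby(level=["sample_id", "format"])
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "fold_growth", "size": "n_wells"})
    )
    return agg
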