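"""Plate quality control and control-based normalization.

Assay quality per (sample, parameter) is gated by the screening-window
Z'-factor,

    Z' = 1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg|,

computed on pooled 72 h control wells (DMSO negative, benzethonium-chloride
positive); a sample/parameter combination passes when Z' > 0.4 (strict).
Treatment wells are then normalized to percent inhibition anchored at the
control means: negative-control mean -> 0 %, positive-control mean -> 100 %.
No clamping is applied before curve fitting; the constrained 4PL asymptotes
absorb over/undershoot.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .readout import (
    count_popo1_substitutions,
    substitute_popo1_positive_control,
)

log = logging.getLogger(__name__)

ZPRIME_GATE = 0.4

#: Response direction per readout parameter: drug effect lowers the TMRM
#: (viability) ratio and raises the POPO-1 (death) ratio.
DIRECTIONS = {"TMRM": "viability_decreases", "POPO1": "death_increases"}


def zprime(neg_values, pos_values) -> float:
    """Z'-factor of the control separation window (sample sd, ddof=1).

    Returns ``-inf`` (with a warning) when the group means coincide.
    """
    neg = np.asarray(neg_values, dtype=float)
    pos = np.asarray(pos_values, dtype=float)
    if neg.size < 2 or pos.size < 2:
        raise ValueError("need >= 2 values per control group")
    mu_n, mu_p = neg.mean(), pos.mean()
    if mu_n == mu_p:
        warnings.warn("control means coincide; Z' undefined", stacklevel=2)
        return float("-inf")
    sd_n = neg.std(ddof=1)
    sd_p = pos.std(ddof=1)
    return float(1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n))


def percent_inhibition(value, neg_mean: float, pos_mean: float, direction: str):
    """Map a raw readout value to percent inhibition (unclamped).

    ``viability_decreases`` (TMRM): 100 (neg - value) / (neg - pos).
    ``death_increases`` (POPO-1):   100 (value - neg) / (pos - neg).
    Control means must differ.
    """
    if neg_mean == pos_mean:
        raise ValueError("degenerate controls: neg_mean == pos_mean")
    value = np.asarray(value, dtype=float)
    if direction == "viability_decreases":
        out = 100.0 * (neg_mean - value) / (neg_mean - pos_mean)
    elif direction == "death_increases":
        out = 100.0 * (value - neg_mean) / (pos_mean - neg_mean)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(out) if out.ndim == 0 else out


@dataclass
class QCEntry:
    sample_id: str
    parameter: str
    zprime: float
    n_neg: int
    n_pos: int
    n_substituted: int
    passed: bool
    evaluable: bool = True


def _control_values(readouts: pd.DataFrame, sample: str, parameter: str, role: str):
    col = "tmrm_ratio" if parameter == "TMRM" else "popo1_ratio"
    sel = readouts[
        (readouts["sample_id"] == sample)
        & (readouts["role"] == role)
        & (readouts["timepoint_h"] == 72)
    ]
    return sel[col].dropna().to_numpy()


def qc_gate(readouts: pd.DataFrame, threshold: float = ZPRIME_GATE) -> pd.DataFrame:
    """Per-(sample, parameter) Z' gating on pooled 72 h controls.

    Positive-control POPO-1 ratios pass through the degraded-control
    substitution rule before Z' is computed.  Samples with missing controls
    are flagged unevaluable (and fail).  Returns the QC report frame.
    """
    entries = []
    for sample in sorted(readouts["sample_id"].unique()):
        for parameter in ("TMRM", "POPO1"):
            neg = _control_values(readouts, sample, parameter, "neg_control")
            pos = _control_values(readouts, sample, parameter, "pos_control")
            n_sub = 0
            if parameter == "POPO1" and pos.size:
                n_sub = count_popo1_substitutions(pos)
                pos = np.asarray(substitute_popo1_positive_control(pos))
            if neg.size < 2 or pos.size < 2:
                entries.append(
                    QCEntry(sample, parameter, float("nan"), neg.size, pos.size, n_sub,
                            passed=False, evaluable=False)
                )
                log.warning("sample %s/%s: missing controls, unevaluable", sample, parameter)
                continue
            z = zprime(neg, pos)
            entries.append(
                QCEntry(sample, parameter, z, int(neg.size), int(pos.size), n_sub,
                        passed=bool(z > threshold))
            )
    return pd.DataFrame([e.__dict__ for e in entries])


def normalize_responses(readouts: pd.DataFrame) -> pd.DataFrame:
    """Percent inhibition for every treatment well at 72 h, per parameter.

    Control anchors are the per-sample pooled 72 h control means (POPO-1
    positive controls substituted first).  Long-form output with columns
    sample_id, plate_id, well, format, drug_id, conc_nM, parameter,
    percent_inhibition.
    """
    frames = []
    for sample, g in readouts.groupby("sample_id"):
        treat = g[(g["role"] == "treatment") & (g["timepoint_h"] == 72)]
        for parameter, col in (("TMRM", "tmrm_ratio"), ("POPO1", "popo1_ratio")):
            neg = _control_values(readouts, sample, parameter, "neg_control")
            pos = _control_values(readouts, sample, parameter, "pos_control")
            if parameter == "POPO1" and pos.size:
                pos = np.asarray(substitute_popo1_positive_control(pos))
            if neg.size < 2 or pos.size < 2 or neg.mean() == pos.mean():
                continue
            out = treat[["plate_id", "well", "sample_id", "format", "drug_id", "conc_nM"]].copy()
            out["parameter"] = parameter
            out["percent_inhibition"] = percent_inhibition(
                treat[col].to_numpy(), neg.mean(), pos.mean(), DIRECTIONS[parameter]
            )
            frames.append(out)
    if not frames:
        return pd.DataFrame(
            columns=["plate_id", "well", "sample_id", "format", "drug_id", "conc_nM",
                     "parameter", "percent_inhibition"]
        )
    return pd.concat(frames, ignore_index=True)
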