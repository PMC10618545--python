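"""Cohort-level association analyses and long-term washout summaries.

Effective-drug counts and drug-specific DSS values are compared between
clinical groups — RECIST complete responders (CR) versus partial/progressive
(PR/P), and platinum-sensitivity split by progression-free interval
(PFI <= 12 vs > 12 months) — with the two-tailed Mann-Whitney U test (exact
when group sizes permit).  Patients with both tissue and ascites samples
contribute one value (the mean over their samples); excluded patients and
patients with a missing endpoint never enter a group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .plate import ClinicalRecord

PFI_SPLIT_MONTHS = 12.0

ENDPOINTS = ("RECIST_CRvsPRP", "PFI_le12_vs_gt12")


@dataclass
class GroupComparison:
    endpoint: str
    variable: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    method: str  # "exact" | "asymptotic"
    direction: str  # "A>B" | "A<B" | "none"


def mann_whitney(group_a, group_b, *, endpoint: str = "custom",
                 variable: str = "") -> GroupComparison:
    """Two-tailed Mann-Whitney U test; U reported for group A.

    The exact permutation distribution is used when there are no ties and
    min(nA, nB) <= 10 (two-tailed p = min(1, 2 x one-tailed tail
    probability)); otherwise the normal approximation with midranks and tie
    correction.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and min(a.size, b.size) <= 10) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(res.statistic)
    mid = a.size * b.size / 2.0
    direction = "A>B" if u > mid else ("A<B" if u < mid else "none")
    return GroupComparison(endpoint=endpoint, variable=variable,
                           n_a=int(a.size), n_b=int(b.size),
                           u_statistic=u, p_value=float(res.pvalue),
                           method=method, direction=direction)


def _per_patient_values(values_by_sample: pd.Series,
                        clinical: list[ClinicalRecord]) -> dict[str, float]:
    """Aggregate sample-level values to one value per non-excluded patient
    (mean over the patient's samples with data)."""
    out: dict[str, float] = {}
    for rec in clinical:
        if rec.excluded:
            continue
        vals = [values_by_sample[s] for s in rec.sample_ids
                if s in values_by_sample.index and not math.isnan(values_by_sample[s])]
        if vals:
            out[rec.patient_id] = float(np.mean(vals))
    return out


def group_dss_by_clinical(
    values_by_sample: pd.Series,
    clinical: list[ClinicalRecord],
    endpoint: str,
) -> tuple[list[float], list[float]]:
    """Split per-patient values into the two clinical endpoint groups.

    ``values_by_sample`` maps sample_id -> value (e.g. carboplatin DSS or an
    effective-drug count).  For RECIST the groups are (CR, PR/P); for PFI
    they are (<= 12 months, > 12 months).  Endpoint-NA and excluded patients
    are dropped; an empty endpoint raises.
    """
    per_patient = _per_patient_values(values_by_sample, clinical)
    by_id = {r.patient_id: r for r in clinical}
    group_a: list[float] = []
    group_b: list[float] = []
    for pid, value in per_patient.items():
        rec = by_id[pid]
        if endpoint == "RECIST_CRvsPRP":
            if rec.recist is None:
                continue
            (group_a if rec.recist == "CR" else group_b).append(value)
        elif endpoint == "PFI_le12_vs_gt12":
            if rec.pfi_months is None:
                continue
            if rec.pfi_months <= PFI_SPLIT_MONTHS:
                group_a.append(value)
            else:
                group_b.append(value)
        else:
            raise ValueError(f"unknown endpoint {endpoint!r}")
    if not group_a and not group_b:
        raise ValueError(f"no patients with resolvable endpoint {endpoint!r}")
    return group_a, group_b


def effective_counts_per_sample(dss_long: pd.DataFrame, *, parameter: str = "TMRM",
                                cutoff: float = 8.0) -> pd.Series:
    """Number of effective drugs (DSS strictly > cutoff) per sample."""
    sub = dss_long[(dss_long["parameter"] == parameter)]
    counts = (
        sub.assign(eff=sub["dss"] > cutoff)
        .groupby("sample_id")["eff"]
        .sum()
        .astype(int)
    )
    return counts


def drug_dss_per_sample(dss_long: pd.DataFrame, drug_id: str, *,
                        parameter: str = "TMRM") -> pd.Series:
    sub = dss_long[(dss_long["parameter"] == parameter)
                   & (dss_long["drug_id"] == drug_id)]
    return sub.set_index("sample_id")["dss"]


@dataclass
class PairedComparison:
    n_pairs: int
    t_statistic: float
    p_value: float
    mean_difference: float
    degenerate: bool = False


def paired_format_comparison(values_a, values_b) -> PairedComparison:
    """Two-tailed paired t-test between matched measurements (e.g. 3D vs 2D
    fold growth for the same samples).

    Identical pairs give t = 0, p = 1.  A constant nonzero difference with
    zero variance is degenerate: p = 0 sentinel with the degenerate flag.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size != b.size:
        raise ValueError("paired comparison needs equal-length vectors")
    if a.size < 2:
        raise ValueError("need >= 2 pairs")
    diff = a - b
    mean_diff = float(diff.mean())
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(mean_diff, 0.0):
            return PairedComparison(a.size, 0.0, 1.0, 0.0)
        return PairedComparison(a.size, float("inf") if mean_diff > 0 else float("-inf"),
                                0.0, mean_diff, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedComparison(a.size, float(t), float(p), mean_diff)


def per_drug_format_difference(dss_2d: pd.DataFrame, dss_3d: pd.DataFrame, *,
                               report_threshold: float = 1.0) -> pd.DataFrame:
    """Mean per-drug DSS difference (2D - 3D) over paired samples; only
    drugs with |difference| > ``report_threshold`` are flagged for report."""
    m2 = dss_2d.groupby("drug_id")["dss"].mean()
    m3 = dss_3d.groupby("drug_id")["dss"].mean()
    diff = (m2 - m3).dropna().rename("dss_difference_2d_minus_3d").reset_index()
    diff["reported"] = diff["dss_difference_2d_minus_3d"].abs() > report_threshold
    return diff


@dataclass
class LongTermSummary:
    arm: str
    dose_level: str
    washout_day: int
    fold_change_day14: float
    regrowth: bool
    flagged: bool = False


REGROWTH_FRACTION = 0.20  # of the series dynamic range


def summarize_longterm(series: pd.DataFrame, *, max_gap_h: float = 24.0) -> list[LongTermSummary]:
    """Summarize washout time series per arm.

    ``series`` is long form with columns arm, dose_level, washout_day,
    time_h, tmrm_area on an 8 h grid over 14 days.  For each arm the
    day-14 fold change versus treatment start is reported, together with a
    regrowth flag: after the washout day the series attains a local minimum
    and subsequently increases by more than 20 % of its dynamic range.
    Series with sampling gaps over 24 h are flagged.
    """
    out = []
    for (arm, dose, wday), g in series.groupby(["arm", "dose_level", "washout_day"]):
        g = g.sort_values("time_h")
        t = g["time_h"].to_numpy(dtype=float)
        y = g.groupby("time_h")["tmrm_area"].mean()
        t = y.index.to_numpy(dtype=float)
        v = y.to_numpy(dtype=float)
        flagged = bool(np.any(np.diff(t) > max_gap_h))
        fold = float(v[-1] / v[0]) if v[0] > 0 else float("nan")
        post = v[t >= wday * 24.0]
        regrowth = False
        if post.size >= 3:
            i_min = int(np.argmin(post))
            dyn = float(v.max() - v.min())
            if dyn > 0 and i_min < post.size - 1:
                rebound = float(post[i_min:].max() - post[i_min])
                regrowth = rebound > REGROWTH_FRACTION * dyn
        out.append(LongTermSummary(arm=arm, dose_level=str(dose), washout_day=int(wday),
                                   fold_change_day14=fold, regrowth=bool(regrowth),
                                   flagged=flagged))
    return out


def association_report(
    dss_long: pd.DataFrame,
    clinical: list[ClinicalRecord],
    *,
    parameter: str = "TMRM",
    carboplatin_drug: str = "carboplatin",
    hit_cutoff: float = 8.0,
) -> pd.DataFrame:
    """Standard cohort association battery.

    Four comparisons: effective-drug count and carboplatin DSS, each split
    by RECIST (CR vs PR/P) and by PFI (<= 12 vs > 12 months).
    """
    counts = effective_counts_per_sample(dss_long, parameter=parameter, cutoff=hit_cutoff)
    carbo = drug_dss_per_sample(dss_long, carboplatin_drug, parameter=parameter)
    rows = []
    for variable, values in (("effective_drug_count", counts.astype(float)),
                             (f"{carboplatin_drug}_dss", carbo)):
        for endpoint in ENDPOINTS:
            try:
                ga, gb = group_dss_by_clinical(values, clinical, endpoint)
                comp = mann_whitney(ga, gb, endpoint=endpoint, variable=variable)
            except ValueError:
                continue
            rows.append(comp.__dict__)
    return pd.DataFrame(rows)
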