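"""Synthetic screen generator with serialized ground truth.

Every pipeline stage is testable without real microscope exports: this
module fabricates 384-well screens (11 DMSO negative and 10 benzethonium
chloride positive control wells per plate, 5-dose series for each library
drug, imaging at 2 h and 72 h), 6x6 combination matrices with injected
interaction deltas, washout time series on an 8 h grid over 14 days, and a
Table-1-style clinical cohort (16 patients / 20 samples by default) whose
carboplatin sensitivity is linked to the platinum-sensitivity PFI split.

Well features are constructed so the readout formulas are exactly
invertible in expectation: a well's composite signal V is drawn lognormally
and the TMRM signal is V * kappa * v * (1 + eps), where kappa is the
baseline viability ratio, v the viability factor implied by the true
inhibition curve at that dose, and eps multiplicative noise; the inverted
brightfield channel absorbs the remainder so channel sums reproduce V.
Hence readout -> normalize -> fit recovers the generating curve up to
noise.  All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning (one child stream per stage), so
regeneration is bit-stable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dose_response import Curve4PL, dss, fourpl
from .plate import (
    ClinicalRecord,
    DrugLibrary,
    PlateMap,
    PlateMapEntry,
    ScreenDataset,
    WellFeatures,
)
from .synergy import CombinationMatrix, zip_expected

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# drug library

#: Printed dose ranges (nM) for drugs whose grids the combination figures
#: specify; everything else gets 10-fold steps over 4 decades.
DRUG_DOSE_RANGES: dict[str, tuple[float, float]] = {
    "carboplatin": (10.0, 100000.0),
    "cisplatin": (10.0, 100000.0),
    "afatinib": (0.2, 2000.0),
    "A-1331852": (0.5, 1000.0),
}
DEFAULT_DOSE_RANGE = (1.0, 10000.0)

_LIBRARY_SPEC = [
    # (drug_id, class, phase)
    ("carboplatin", "platinum chemotherapy", "approved"),
    ("cisplatin", "platinum chemotherapy", "approved"),
    ("oxaliplatin", "platinum chemotherapy", "approved"),
    ("paclitaxel", "taxane", "approved"),
    ("docetaxel", "taxane", "approved"),
    ("gemcitabine", "antimetabolite", "approved"),
    ("5-fluorouracil", "antimetabolite", "approved"),
    ("pemetrexed", "antimetabolite", "approved"),
    ("doxorubicin", "anthracycline", "approved"),
    ("dactinomycin", "transcription inhibitor", "approved"),
    ("vinorelbine", "vinca alkaloid", "approved"),
    ("eribulin", "microtubule inhibitor", "approved"),
    ("SN-38", "topoisomerase I inhibitor", "approved"),
    ("topotecan", "topoisomerase I inhibitor", "approved"),
    ("etoposide", "topoisomerase II inhibitor", "approved"),
    ("A-1331852", "Bcl-xL inhibitor", "preclinical"),
    ("navitoclax", "Bcl-2/Bcl-xL inhibitor", "phase 2"),
    ("venetoclax", "Bcl-2 inhibitor", "approved"),
    ("S-63845", "Mcl-1 inhibitor", "preclinical"),
    ("afatinib", "EGFR inhibitor", "approved"),
    ("gefitinib", "EGFR inhibitor", "approved"),
    ("erlotinib", "EGFR inhibitor", "approved"),
    ("lapatinib", "EGFR/HER2 inhibitor", "approved"),
    ("trametinib", "MEK inhibitor", "approved"),
    ("selumetinib", "MEK inhibitor", "approved"),
    ("SCH772984", "ERK inhibitor", "preclinical"),
    ("AZD5363", "AKT inhibitor", "phase 3"),
    ("ipatasertib", "AKT inhibitor", "phase 3"),
    ("alpelisib", "PI3K inhibitor", "approved"),
    ("buparlisib", "PI3K inhibitor", "phase 3"),
    ("everolimus", "mTOR inhibitor", "approved"),
    ("temsirolimus", "mTOR inhibitor", "approved"),
    ("sapanisertib", "mTOR kinase inhibitor", "phase 2"),
    ("olaparib", "PARP inhibitor", "approved"),
    ("niraparib", "PARP inhibitor", "approved"),
    ("rucaparib", "PARP inhibitor", "approved"),
    ("talazoparib", "PARP inhibitor", "approved"),
    ("adavosertib", "WEE1 inhibitor", "phase 2"),
    ("prexasertib", "CHK1 inhibitor", "phase 2"),
    ("berzosertib", "ATR inhibitor", "phase 2"),
    ("ceralasertib", "ATR inhibitor", "phase 2"),
    ("dinaciclib", "CDK inhibitor", "phase 2"),
    ("palbociclib", "CDK4/6 inhibitor", "approved"),
    ("abemaciclib", "CDK4/6 inhibitor", "approved"),
    ("alisertib", "Aurora A inhibitor", "phase 3"),
    ("barasertib", "Aurora B inhibitor", "phase 2"),
    ("volasertib", "PLK1 inhibitor", "phase 3"),
    ("PF-03758309", "PAK inhibitor", "phase 1"),
    ("bortezomib", "proteasome inhibitor", "approved"),
    ("carfilzomib", "proteasome inhibitor", "approved"),
    ("panobinostat", "HDAC inhibitor", "approved"),
    ("vorinostat", "HDAC inhibitor", "approved"),
    ("entinostat", "HDAC inhibitor", "phase 3"),
    ("birinapant", "IAP antagonist", "phase 2"),
    ("lenvatinib", "multi-kinase inhibitor", "approved"),
    ("sunitinib", "multi-kinase inhibitor", "approved"),
    ("pazopanib", "multi-kinase inhibitor", "approved"),
    ("cabozantinib", "multi-kinase inhibitor", "approved"),
]
assert len(_LIBRARY_SPEC) == 58


def drug_concentrations(drug_id: str) -> np.ndarray:
    lo, hi = DRUG_DOSE_RANGES.get(drug_id, DEFAULT_DOSE_RANGE)
    return np.geomspace(lo, hi, 5)


def default_drug_library(n_drugs: int = 58) -> DrugLibrary:
    """The packaged 58-drug repurposing panel (or its first ``n_drugs``)."""
    rows = []
    for drug_id, cls, phase in _LIBRARY_SPEC[:n_drugs]:
        concs = drug_concentrations(drug_id)
        row = {"drug_id": drug_id, "drug_class": cls, "phase": phase}
        row.update({f"conc{i+1}_nM": c for i, c in enumerate(concs)})
        rows.append(row)
    return DrugLibrary(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# configuration and truth model

@dataclass
class ScreenConfig:
    """Study conditions for the simulated cohort screen.

    Defaults reproduce the reference design: 16 patients contributing 20
    samples (4 tissue+ascites pairs), the 58-drug / 5-concentration library,
    384-well plates with 11 negative and 10 positive control wells, two
    imaging timepoints, 5 % multiplicative noise, 3D fold growth ~2.0 vs
    ~1.3 in 2D, and a carboplatin true-DSS separation of 10 units (sd 4)
    between the PFI <= 12 and > 12 month classes.
    """

    n_patients: int = 16
    n_paired_samples: int = 4
    n_drugs: int = 58
    n_neg_controls: int = 11
    n_pos_controls: int = 10
    n_2d_samples: int = 11
    noise_cv: float = 0.05
    kappa: float = 0.4
    pos_residual_viability: float = 0.05
    popo1_neg_ratio: float = 0.05
    popo1_pos_ratio: float = 0.95
    growth_3d_mean: float = 2.0
    growth_3d_sd: float = 0.3
    growth_2d_mean: float = 1.3
    growth_2d_sd: float = 0.15
    p_effective_cr: float = 0.135
    p_effective_prp: float = 0.055
    effective_dss_range: tuple[float, float] = (10.0, 40.0)
    carbo_dss_mean_pfi_le12: float = 7.0
    carbo_dss_mean_pfi_gt12: float = 17.0
    carbo_dss_sd: float = 4.0
    sample_heterogeneity_sd: float = 1.5
    format_effect_sd: float = 0.08
    degraded_samples: tuple[str, ...] = ()
    degraded_noise_factor: float = 8.0
    popo1_pos_dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        wells_needed = self.n_neg_controls + self.n_pos_controls + 5 * self.n_drugs
        if wells_needed > 384:
            raise ValueError(
                f"layout needs {wells_needed} wells; a 384-well plate has 384"
            )


#: Drugs whose true DSS is linked to the PFI class, with the relative
#: strength of the link (1.0 = the configured carboplatin shift).
PFI_LINKED_DRUGS = {"carboplatin": 1.0, "cisplatin": 0.6, "adavosertib": 0.5}


@dataclass
class TruthModel:
    """Serializable ground truth for a generated dataset."""

    curves: dict = field(default_factory=dict)   # "sample|format|drug" -> params
    samples: dict = field(default_factory=dict)  # sample -> growth/kappa/noise
    clinical_link: dict = field(default_factory=dict)
    combo: dict | None = None
    longterm: dict | None = None
    config: dict = field(default_factory=dict)

    @staticmethod
    def curve_key(sample_id: str, fmt: str, drug_id: str) -> str:
        return f"{sample_id}|{fmt}|{drug_id}"

    def true_dss_frame(self, fmt: str = "3D") -> pd.DataFrame:
        rows = []
        for key, params in self.curves.items():
            sample, f, drug = key.split("|")
            if f == fmt:
                rows.append({"sample_id": sample, "drug_id": drug,
                             "true_dss": params["true_dss"]})
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


# ---------------------------------------------------------------------------
# clinical cohort

_HISTOLOGIES = ["HGSOC", "HGS tubal cancer", "HGS peritoneal cancer",
                "LGSOC", "MOC"]
_HIST_WEIGHTS = [0.45, 0.25, 0.10, 0.10, 0.10]
_STAGES = ["2B", "3A", "3C", "4A", "4B"]
_STAGE_WEIGHTS = [0.05, 0.10, 0.55, 0.15, 0.15]


def generate_clinical(config: ScreenConfig, seed_or_rng) -> list[ClinicalRecord]:
    """Table-1-style cohort: RECIST 11 CR / 4 PR / 1 P at n=16, PFI split
    7 vs 7 with two patients lost to follow-up, one excluded patient (a
    different primary tumour discovered post hoc) among the PFI-unknowns."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    n = config.n_patients
    patient_ids = [f"PT{i+1:02d}" for i in range(n)]
    paired = set(patient_ids[: config.n_paired_samples])

    # RECIST classes, proportional to 11 CR / 4 PR / 1 P at n = 16
    n_cr = max(1, round(n * 11 / 16))
    n_p = 1 if n >= 6 else 0
    n_pr = n - n_cr - n_p
    recist = ["CR"] * n_cr + ["PR"] * n_pr + ["P"] * n_p
    recist = list(rng.permutation(recist))

    # PFI classes correlated with RECIST: the two follow-up losses are one
    # CR (the excluded patient) and one PR/P; PR/P patients preferentially
    # fall in the short-PFI class.
    order = sorted(range(n), key=lambda i: (recist[i] == "CR", i))
    na_idx: list[int] = []
    cr_indices = [i for i in order if recist[i] == "CR"]
    prp_indices = [i for i in order if recist[i] != "CR"]
    if n >= 8:
        na_idx = [cr_indices[-1], prp_indices[-1]]
    remaining = [i for i in order if i not in na_idx]
    n_short = len(remaining) // 2
    short_idx = set(remaining[:n_short])  # PR/P first => correlated split

    excluded_idx = na_idx[0] if na_idx else -1

    records = []
    for i, pid in enumerate(patient_ids):
        if pid in paired:
            samples = [f"{pid}-T", f"{pid}-A"]
        else:
            samples = [f"{pid}-T" if i % 2 == 0 else f"{pid}-A"]
        if i in na_idx:
            pfi = None
        elif i in short_idx:
            pfi = float(np.round(rng.uniform(2.0, 12.0), 1))
        else:
            pfi = float(np.round(rng.uniform(13.0, 40.0), 1))
        is_excluded = i == excluded_idx
        histology = ("Struma ovarii with papillary thyroid cancer" if is_excluded
                     else str(rng.choice(_HISTOLOGIES, p=_HIST_WEIGHTS)))
        records.append(
            ClinicalRecord(
                patient_id=pid,
                sample_ids=samples,
                histology=histology,
                figo_stage=str(rng.choice(_STAGES, p=_STAGE_WEIGHTS)),
                ca125=float(np.round(rng.lognormal(math.log(700.0), 0.9), 0)),
                recist=recist[i],
                pfi_months=pfi,
                excluded=is_excluded,
            )
        )
    return records


# ---------------------------------------------------------------------------
# truth construction

def asymptote_for_dss(target: float, b: float, c: float,
                      conc_range: tuple[float, float],
                      t: float = 10.0) -> float:
    """Invert the DSS formula for the top asymptote a (d = 0 fixed).

    DSS is continuous and increasing in a on (t, 100]; the target is capped
    just under the attainable maximum for the given (b, c, range).
    """
    def f(a: float) -> float:
        return dss(Curve4PL(a=a, d=0.0, b=b, c=c, rmse=0.0, converged=True,
                            conc_range=conc_range), t)

    max_dss = f(100.0)
    if target <= 0.0:
        return 0.0
    target = min(target, max_dss - 1e-3)
    if target <= 0.0:
        return 0.0
    return float(brentq(lambda a: f(a) - target, t + 1e-9, 100.0, xtol=1e-10))


def _cohort_truth_targets(config: ScreenConfig, clinical: list[ClinicalRecord],
                          library: DrugLibrary, rng: np.random.Generator):
    """Per-(sample, drug) target true DSS implementing the clinical links."""
    carbo_shift = config.carbo_dss_mean_pfi_gt12 - config.carbo_dss_mean_pfi_le12
    targets: dict[tuple[str, str], float] = {}
    link: dict[str, dict] = {}
    for rec in clinical:
        p_eff = (config.p_effective_cr if rec.recist == "CR"
                 else config.p_effective_prp if rec.recist in ("PR", "P")
                 else 0.5 * (config.p_effective_cr + config.p_effective_prp))
        if rec.pfi_months is None:
            pfi_class = "unknown"
            base_le12 = rng.random() < 0.5
        else:
            pfi_class = "le12" if rec.pfi_months <= 12.0 else "gt12"
            base_le12 = pfi_class == "le12"
        patient_targets: dict[str, float] = {}
        for drug_id in library.drug_ids:
            if drug_id in PFI_LINKED_DRUGS:
                strength = PFI_LINKED_DRUGS[drug_id]
                mean = (config.carbo_dss_mean_pfi_le12 if base_le12
                        else config.carbo_dss_mean_pfi_le12 + strength * carbo_shift)
                val = rng.normal(mean, config.carbo_dss_sd)
            elif rng.random() < p_eff:
                val = rng.uniform(*config.effective_dss_range)
            else:
                val = rng.uniform(0.0, 5.0)
            patient_targets[drug_id] = float(np.clip(val, 0.0, 60.0))
        link[rec.patient_id] = {"pfi_class": pfi_class, "p_effective": p_eff}
        for sample in rec.sample_ids:
            for drug_id, v in patient_targets.items():
                jitter = rng.normal(0.0, config.sample_heterogeneity_sd)
                targets[(sample, drug_id)] = float(np.clip(v + jitter, 0.0, 60.0))
    return targets, link


def generate_cohort_dss(config: ScreenConfig, seed: int):
    """Lightweight cohort: clinical table plus per-(sample, drug) *true*
    DSS values implementing the configured clinical links, without plate
    simulation.  Used for cohort-power studies."""
    ss = np.random.SeedSequence(seed)
    rng_clin, rng_truth = [np.random.default_rng(s) for s in ss.spawn(2)]
    clinical = generate_clinical(config, rng_clin)
    library = default_drug_library(config.n_drugs)
    targets, link = _cohort_truth_targets(config, clinical, library, rng_truth)
    rows = [{"sample_id": s, "drug_id": d, "parameter": "TMRM", "dss": v}
            for (s, d), v in targets.items()]
    return pd.DataFrame(rows), clinical, link


# ---------------------------------------------------------------------------
# screen generation

_ROWS = "ABCDEFGHIJKLMNOP"


def _well_name(idx: int) -> str:
    return f"{_ROWS[idx // 24]}{idx % 24 + 1:02d}"


def generate_screen(config: ScreenConfig | None = None, seed: int = 0):
    """Generate a full cohort screen.

    Returns ``(ScreenDataset, TruthModel)``.  One 3D plate per sample, plus
    a 2D plate for the first ``n_2d_samples`` samples; each plate carries
    the configured control wells and one 5-dose series per library drug,
    imaged at 2 h and 72 h.  Fully reproducible from the seed.
    """
    config = config or ScreenConfig()
    ss = np.random.SeedSequence(seed)
    rng_clin, rng_truth, rng_wells = [np.random.default_rng(s) for s in ss.spawn(3)]

    clinical = generate_clinical(config, rng_clin)
    library = default_drug_library(config.n_drugs)
    targets, link = _cohort_truth_targets(config, clinical, library, rng_truth)

    truth = TruthModel(config=dataclasses.asdict(config), clinical_link=link)
    samples = [s for rec in clinical for s in rec.sample_ids]

    # per-sample assay parameters
    for sample in samples:
        truth.samples[sample] = {
            "growth_3d": float(max(0.5, rng_truth.normal(config.growth_3d_mean,
                                                         config.growth_3d_sd))),
            "growth_2d": float(max(0.5, rng_truth.normal(config.growth_2d_mean,
                                                         config.growth_2d_sd))),
            "kappa": config.kappa,
            "noise_cv": config.noise_cv
            * (config.degraded_noise_factor if sample in config.degraded_samples else 1.0),
        }

    # truth curves: solve the top asymptote for the target DSS
    curve_cache: dict[tuple[str, str], dict] = {}
    for sample in samples:
        for drug_id in library.drug_ids:
            concs = library.concentrations(drug_id)
            x1, x2 = math.log10(concs[0]), math.log10(concs[-1])
            b = float(rng_truth.uniform(0.8, 2.0))
            c = float(rng_truth.uniform(x1 + 0.5, 0.5 * (x1 + x2)))
            a = asymptote_for_dss(targets[(sample, drug_id)], b, c, (x1, x2))
            if a == 0.0:
                a = float(rng_truth.uniform(0.0, 8.0))
            curve = {"a": a, "b": b, "c": c, "d": 0.0,
                     "true_dss": dss(Curve4PL(a=a, d=0.0, b=b, c=c, rmse=0.0,
                                              converged=True, conc_range=(x1, x2)))}
            curve_cache[(sample, drug_id)] = curve
            truth.curves[TruthModel.curve_key(sample, "3D", drug_id)] = curve
    for sample in samples[: config.n_2d_samples]:
        for drug_id in library.drug_ids:
            c3 = curve_cache[(sample, drug_id)]
            factor = float(rng_truth.lognormal(0.0, config.format_effect_sd))
            a2 = float(np.clip(c3["a"] * factor, 0.0, 100.0))
            concs = library.concentrations(drug_id)
            x1, x2 = math.log10(concs[0]), math.log10(concs[-1])
            truth.curves[TruthModel.curve_key(sample, "2D", drug_id)] = {
                "a": a2, "b": c3["b"], "c": c3["c"], "d": 0.0,
                "true_dss": dss(Curve4PL(a=a2, d=0.0, b=c3["b"], c=c3["c"],
                                         rmse=0.0, converged=True,
                                         conc_range=(x1, x2))),
            }

    wells: list[WellFeatures] = []
    map_entries: list[PlateMapEntry] = []
    for sample in samples:
        formats = ["3D"] + (["2D"] if sample in samples[: config.n_2d_samples] else [])
        for fmt in formats:
            plate_id = f"{sample}-{fmt}"
            _simulate_plate(config, truth, library, sample, fmt, plate_id,
                            rng_wells, wells, map_entries)

    dataset = ScreenDataset(
        wells=wells,
        platemap=PlateMap(map_entries),
        drug_library=library,
        clinical=clinical,
        meta={"seed": seed, "generator": "spheroscreen.simulate.generate_screen"},
    )
    return dataset, truth


def _simulate_plate(config, truth, library, sample, fmt, plate_id, rng,
                    wells, map_entries):
    kappa = truth.samples[sample]["kappa"]
    cv = truth.samples[sample]["noise_cv"]
    growth = truth.samples[sample]["growth_3d" if fmt == "3D" else "growth_2d"]
    v_pos = config.pos_residual_viability
    r_neg, r_pos = config.popo1_neg_ratio, config.popo1_pos_ratio

    layout: list[tuple[str, str | None, float | None]] = []
    layout += [("neg_control", None, None)] * config.n_neg_controls
    layout += [("pos_control", None, None)] * config.n_pos_controls
    for drug_id in library.drug_ids:
        for conc in library.concentrations(drug_id):
            layout.append(("treatment", drug_id, float(conc)))

    for idx, (role, drug_id, conc) in enumerate(layout):
        well = _well_name(idx)
        map_entries.append(PlateMapEntry(plate_id=plate_id, well=well, role=role,
                                         sample_id=sample, drug_id=drug_id,
                                         conc_nM=conc))
        v_base = rng.lognormal(math.log(1.0e4), 0.25)
        hoechst_area_base = rng.lognormal(math.log(2.0e3), 0.2)
        for timepoint, vol, grown in ((2.0, v_base, False),
                                      (72.0, v_base * growth, True)):
            if not grown:
                viability = 1.0
            elif role == "neg_control":
                viability = 1.0
            elif role == "pos_control":
                viability = v_pos
            else:
                params = truth.curves[TruthModel.curve_key(sample, fmt, drug_id)]
                pi = fourpl(math.log10(conc), params["a"], params["d"],
                            params["b"], params["c"])
                viability = 1.0 - (pi / 100.0) * (1.0 - v_pos)
            death = float(np.clip((1.0 - viability) / (1.0 - v_pos), 0.0, 1.0))

            tmrm = vol * kappa * viability * (1.0 + rng.normal(0.0, cv))
            hoechst = vol * 0.25 * (1.0 + rng.normal(0.0, cv))
            popo1_vol = vol * 0.08 * (0.2 + 0.8 * death) * (1.0 + rng.normal(0.0, cv))
            tmrm = max(tmrm, 0.0)
            hoechst = max(hoechst, 0.0)
            popo1_vol = max(popo1_vol, 0.0)
            inv_bf = max(vol - tmrm - hoechst - popo1_vol, 0.0)

            popo1_ratio = r_neg + death * (r_pos - r_neg)
            if (role == "pos_control" and grown
                    and rng.random() < config.popo1_pos_dropout_rate):
                popo1_ratio = rng.uniform(0.0, 0.08)  # edge-migration dropout
            hoechst_area = hoechst_area_base * (1.0 + rng.normal(0.0, cv))
            popo1_area = hoechst_area * popo1_ratio * (1.0 + rng.normal(0.0, cv))

            wells.append(
                WellFeatures(
                    plate_id=plate_id, well=well, sample_id=sample, format=fmt,
                    timepoint_h=timepoint, role=role, drug_id=drug_id,
                    conc_nM=conc,
                    tmrm_volume=tmrm, popo1_volume=popo1_vol,
                    popo1_area=max(popo1_area, 0.0),
                    hoechst_volume=hoechst, hoechst_area=max(hoechst_area, 0.0),
                    caspase_volume=None,
                    inv_brightfield_intensity=inv_bf,
                )
            )


# ---------------------------------------------------------------------------
# combination matrices

@dataclass
class ComboConfig:
    """Ground truth for one simulated 6x6 combination matrix (defaults:
    the afatinib + carboplatin design with its printed dose ranges)."""

    sample_id: str = "PT01-T"
    drug1_id: str = "afatinib"
    drug2_id: str = "carboplatin"
    curve1: tuple[float, float, float] = (85.0, 1.2, None)  # a, b, c (None = grid mid)
    curve2: tuple[float, float, float] = (75.0, 1.0, None)
    n_replicates: int = 3
    noise_cv: float = 0.05
    baseline_pct: float = 2.0

    def doses(self, which: int) -> np.ndarray:
        return drug_concentrations(self.drug1_id if which == 1 else self.drug2_id)


def _combo_curve(spec, concs) -> tuple[float, float, float]:
    a, b, c = spec
    if c is None:
        c = 0.5 * (math.log10(concs[0]) + math.log10(concs[-1]))
    return float(a), float(b), float(c)


def generate_combination(config: ComboConfig | None = None, seed: int = 0,
                         delta_field="zero"):
    """Simulate a replicated combination matrix with a known interaction.

    ``delta_field`` is ``"zero"`` (Bliss-independent surface), ``("uniform",
    v)`` (a constant delta v on the fraction scale injected into every
    positive-dose cell), or ``("localized", v)`` (delta concentrated on the
    high-dose quadrant).  Returns ``(CombinationMatrix, truth_dict)``.
    """
    config = config or ComboConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    c1 = config.doses(1)
    c2 = config.doses(2)
    a1, b1, m1 = _combo_curve(config.curve1, c1)
    a2, b2, m2 = _combo_curve(config.curve2, c2)

    y1 = fourpl(np.log10(c1), a1, 0.0, b1, m1) / 100.0
    y2 = fourpl(np.log10(c2), a2, 0.0, b2, m2) / 100.0

    delta = np.zeros((5, 5))
    if delta_field != "zero":
        kind, v = delta_field
        if kind == "uniform":
            delta[:, :] = v
        elif kind == "localized":
            delta[2:, 2:] = v
        else:
            raise ValueError(f"unknown delta field {kind!r}")

    truth_pct = np.zeros((6, 6))
    truth_pct[1:, 0] = 100.0 * y1
    truth_pct[0, 1:] = 100.0 * y2
    truth_pct[1:, 1:] = 100.0 * (zip_expected(y1[:, None], y2[None, :]) + delta)

    n_rep = config.n_replicates
    responses = np.empty((6, 6, n_rep))
    for k in range(n_rep):
        noise = rng.normal(0.0, config.noise_cv, size=(6, 6)) if config.noise_cv > 0 \
            else np.zeros((6, 6))
        responses[:, :, k] = (truth_pct + config.baseline_pct) * (1.0 + noise)
    if (responses < -20.0).any() or (responses > 120.0).any():
        log.warning("combination responses clipped to [-20, 120]")
        responses = np.clip(responses, -20.0, 120.0)

    matrix = CombinationMatrix(
        sample_id=config.sample_id, drug1_id=config.drug1_id,
        drug2_id=config.drug2_id, conc1_nM=c1, conc2_nM=c2, responses=responses,
    )
    truth = {
        "curve1": {"a": a1, "b": b1, "c": m1, "d": 0.0},
        "curve2": {"a": a2, "b": b2, "c": m2, "d": 0.0},
        "delta_mean": float(delta.mean()),
        "delta_field": delta_field if delta_field == "zero" else list(delta_field),
        "baseline_pct": config.baseline_pct,
        "seed": seed,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# long-term washout series

@dataclass
class LongTermConfig:
    """Washout-assay dynamics: logistic growth with arm-specific kill
    rates on an 8 h grid over 14 days.  Monotherapy kill stops at washout
    (cytostatic: survivors regrow); the combination is cytotoxic and the
    residual signal keeps decaying after washout."""

    initial_area: float = 100.0
    carrying_capacity: float = 1200.0
    growth_rate_per_h: float = 0.010
    kill_drug1: dict = field(default_factory=lambda: {"low": 0.004, "high": 0.008})
    kill_drug2: dict = field(default_factory=lambda: {"low": 0.012, "high": 0.020})
    kill_combination: dict = field(default_factory=lambda: {"low": 0.030, "high": 0.040})
    post_washout_decay_combination: float = 0.010
    washout_days: tuple[int, ...] = (3, 5)
    dose_levels: tuple[str, ...] = ("low", "high")
    duration_days: int = 14
    step_h: float = 8.0
    noise_cv: float = 0.02
    n_replicates: int = 1


def generate_longterm(config: LongTermConfig | None = None, seed: int = 0):
    """Simulate washout time series for control, both monotherapies and the
    combination, at each dose level and washout day.  Returns ``(long-form
    DataFrame, truth_dict)``; each series has 1 + 14*24/8 = 43 points."""
    config = config or LongTermConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    times = np.arange(0.0, config.duration_days * 24.0 + config.step_h / 2,
                      config.step_h)
    rows = []
    arms = [("control", {None: 0.0}), ("drug1", config.kill_drug1),
            ("drug2", config.kill_drug2), ("combination", config.kill_combination)]
    for arm, kills in arms:
        dose_levels = ["none"] if arm == "control" else list(config.dose_levels)
        for dose in dose_levels:
            kill = kills.get(dose if arm != "control" else None, 0.0)
            for wday in config.washout_days:
                for rep in range(1, config.n_replicates + 1):
                    area = config.initial_area
                    for t in times:
                        exposed = t < wday * 24.0 and arm != "control"
                        if arm == "combination" and not exposed and t >= wday * 24.0:
                            rate = -config.post_washout_decay_combination
                        else:
                            grow = (config.growth_rate_per_h
                                    * (1.0 - area / config.carrying_capacity))
                            rate = grow - (kill if exposed else 0.0)
                        obs = area * (1.0 + (rng.normal(0.0, config.noise_cv)
                                             if config.noise_cv > 0 else 0.0))
                        rows.append({"arm": arm, "dose_level": dose,
                                     "washout_day": wday, "replicate": rep,
                                     "time_h": float(t),
                                     "tmrm_area": max(obs, 0.0)})
                        area = max(area * (1.0 + config.step_h * rate), 1e-9)
    truth = {"config": dataclasses.asdict(config), "seed": seed}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# curve-recovery fixtures

def random_truth_curves(n: int, seed: int,
                        conc_range_nM: tuple[float, float] = (1.0, 10000.0)):
    """Random plausible inhibition curves over a 5-dose log grid, for
    fit/score recovery studies.  Returns (concs, list of Curve4PL)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    concs = np.geomspace(conc_range_nM[0], conc_range_nM[1], 5)
    x1, x2 = math.log10(concs[0]), math.log10(concs[-1])
    curves = []
    for _ in range(n):
        a = rng.uniform(25.0, 100.0)
        b = rng.uniform(0.8, 2.5)
        c = rng.uniform(x1 + 0.5, x2 - 0.5)
        d = 0.0
        curves.append(Curve4PL(a=float(a), d=d, b=float(b), c=float(c),
                               rmse=0.0, converged=True, conc_range=(x1, x2)))
    return concs, curves


def noisy_responses(curve: Curve4PL, concs_nM, cv: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Observed percent-inhibition responses: curve value with
    multiplicative Gaussian noise of the given CV (on the % scale,
    floored at 1 percentage point of sd)."""
    y = fourpl(np.log10(np.asarray(concs_nM, dtype=float)),
               curve.a, curve.d, curve.b, curve.c)
    sd = np.maximum(cv * np.abs(y), 1.0)
    return y + rng.normal(0.0, sd)
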