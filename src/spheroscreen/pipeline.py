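"""End-to-end orchestration: screen and combination runs with manifests.

A run executes readout -> QC gating -> normalization -> 4PL fitting -> DSS
-> hit calling (-> association when a clinical table is present), writes
every stage table as CSV, and records a machine-readable ``manifest.json``
(package and library versions, seed, thresholds, per-stage counts) that
suffices to replay the run.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .clinical import association_report
from .dose_response import screen_dss
from .plate import ScreenDataset, write_dss_matrix
from .qc import normalize_responses, qc_gate
from .readout import sample_fold_growth, well_readouts
from .simulate import ScreenConfig, generate_screen
from .synergy import score_combinations, zip_results_long


@dataclass
class Thresholds:
    """Decision thresholds; defaults are the platform's printed values."""

    zprime_gate: float = 0.4
    dss_hit: float = 8.0
    dss_activity_t: float = 10.0
    zip_bounds: float = 10.0


@dataclass
class RunConfig:
    outdir: str = "results"
    seed: int = 0
    input_dir: str | None = None       # load a CSV bundle ...
    simulate: dict | None = None       # ... or simulate (ScreenConfig overrides)
    combo_csv: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thresholds, **raw)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and offender."""


def _manifest(config: RunConfig, counts: dict) -> dict:
    return {
        "spheroscreen_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "thresholds": dataclasses.asdict(config.thresholds),
        "counts": counts,
    }


def run_screen(config: RunConfig) -> dict:
    """Execute the full screen pipeline; returns the manifest dict.

    Outputs under ``config.outdir``: readouts.csv, qc_report.csv,
    normalized.csv, dss_long.csv, dss_matrix.csv (TMRM), growth.csv,
    associations.csv (when clinical data allow), manifest.json, and — in
    simulate mode — the generated input bundle plus truth.json.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    if config.simulate is not None:
        sim = ScreenConfig(**{k: v for k, v in config.simulate.items()
                              if k != "enabled"})
        dataset, truth = generate_screen(sim, seed=config.seed)
        dataset.save(outdir / "inputs")
        truth.to_json(outdir / "inputs" / "truth.json")
    elif config.input_dir is not None:
        dataset = ScreenDataset.load(config.input_dir)
    else:
        raise StageError("input: neither input_dir nor simulate block given")

    counts["wells"] = len(dataset.wells)
    missing = dataset.missing_wells()
    counts["wells_missing_timepoint"] = int(len(missing))

    try:
        readouts = well_readouts(dataset.wells)
    except ValueError as exc:
        raise StageError(f"readout: {exc}") from exc
    readouts.to_csv(outdir / "readouts.csv", index=False)

    qc = qc_gate(readouts, threshold=config.thresholds.zprime_gate)
    qc.to_csv(outdir / "qc_report.csv", index=False)
    counts["samples_qc_pass_tmrm"] = int(qc[(qc.parameter == "TMRM")]["passed"].sum())
    counts["samples_qc_pass_popo1"] = int(qc[(qc.parameter == "POPO1")]["passed"].sum())

    normalized = normalize_responses(readouts)
    normalized.to_csv(outdir / "normalized.csv", index=False)
    counts["normalized_wells"] = int(len(normalized))

    dss_long = screen_dss(
        normalized, qc,
        activity_threshold=config.thresholds.dss_activity_t,
        hit_cutoff=config.thresholds.dss_hit,
    )
    dss_long.to_csv(outdir / "dss_long.csv", index=False)
    counts["curves_fit"] = int(len(dss_long))
    counts["curves_qc_failed"] = int((~dss_long["curve_qc"]).sum())
    counts["dss_reported"] = int(dss_long["dss"].notna().sum())
    counts["hits"] = int(dss_long["hit"].sum())

    # the reporting matrix and clinical associations use the 3D cell-health
    # (TMRM) scores; 2D rows feed only the paired format comparison
    tmrm = dss_long[(dss_long["parameter"] == "TMRM")
                    & (dss_long["format"] == "3D")]
    write_dss_matrix(tmrm[["sample_id", "drug_id", "dss", "qc_pass"]],
                     outdir / "dss_matrix.csv")

    growth = sample_fold_growth(dataset.wells_frame())
    growth.to_csv(outdir / "growth.csv", index=False)

    if dataset.clinical:
        try:
            assoc = association_report(tmrm, dataset.clinical,
                                       hit_cutoff=config.thresholds.dss_hit)
            assoc.to_csv(outdir / "associations.csv", index=False)
            counts["association_tests"] = int(len(assoc))
        except ValueError:
            counts["association_tests"] = 0

    manifest = _manifest(config, counts)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def run_combination(config: RunConfig, combo_long: pd.DataFrame | None = None) -> dict:
    """Score every combination matrix in a long-form table (or CSV given by
    ``config.combo_csv``); writes zip_results.csv + manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if combo_long is None:
        if config.combo_csv is None:
            raise StageError("combination: no input table given")
        combo_long = pd.read_csv(config.combo_csv)
    try:
        summary, results = score_combinations(combo_long)
    except ValueError as exc:
        raise StageError(f"combination: {exc}") from exc
    long = zip_results_long(results)
    long.to_csv(outdir / "zip_results.csv", index=False)
    summary.to_csv(outdir / "zip_summary.csv", index=False)
    counts = {
        "matrices": int(len(summary)),
        "synergistic": int((summary["interaction_class"] == "synergistic").sum()),
        "additive": int((summary["interaction_class"] == "additive").sum()),
        "antagonistic": int((summary["interaction_class"] == "antagonistic").sum()),
    }
    manifest = _manifest(config, counts)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
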