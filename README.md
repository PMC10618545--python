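# spheroscreen

Analysis pipeline for **ex vivo drug-sensitivity screening** of
patient-derived 3D (spheroid) and 2D cultures read out by live-cell
imaging — the functional-precision-medicine workflow used to rank drugs
and drug combinations for individual cancer patients within days of
surgery.

It is written for screening-lab analysts and computational biologists who
receive *well-level image-feature exports* (channel volumes/areas per well
and timepoint) and need, per patient sample:

* **viability/death readouts** — cell health as TMRM signal over the
  composite spheroid signal; cell death as POPO-1 area over Hoechst area;
* **plate quality control** — Z′-factor on DMSO (negative) and
  benzethonium-chloride (positive) controls, gate Z′ > 0.4;
* **dose–response fitting and scoring** — constrained four-parameter
  logistic curves on log10 concentration and a **drug sensitivity score
  (DSS)**, the normalized area of the fitted inhibition curve above a 10 %
  activity threshold, with effective drugs called at DSS > 8;
* **combination synergy** — **ZIP** delta surfaces on 5×5 dose matrices
  (zero-dose margins on-plate, technical triplicates), classified
  synergistic / additive / antagonistic at ±10;
* **clinical association** — effective-drug counts and per-drug DSS
  compared between RECIST and progression-free-interval (PFI ≤ 12 vs > 12
  months) groups with exact Mann–Whitney U tests, paired 3D-vs-2D format
  comparisons, and washout time-series summaries;
* **synthetic screens with known ground truth** — a first-class generator
  that fabricates complete plate bundles, combination matrices, washout
  series and a linked clinical cohort, so every stage is testable without
  any real data.

## The models in brief

Concentration–response is the 4PL on x = log10(conc/nM):

    y(x) = d + (a − d) / (1 + 10^{b(c − x)}),   0 ≤ d ≤ a ≤ 100,  b > 0

and the drug sensitivity score over the tested range [x1, x2] with
activity threshold t = 10 %:

    DSS = 100 · ∫ max(y(x) − t, 0) dx / ((100 − t)(x2 − x1)) ∈ [0, 100].

Plate quality is Z′ = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋|. Combination cells are
scored against Bliss independence y₁ + y₂ − y₁y₂ using the ZIP recipe
(monotherapy 4PL fits, then bottom-pinned directional refits); the summary
is the mean delta over the positive-dose block in percentage points. See
`docs/methods.md` for the full account, defaults and limitations.

## Worked example

```python
import numpy as np
from spheroscreen import fit_4pl, dss, zprime, mann_whitney

# five-point carboplatin series, percent inhibition after normalization
concs = np.geomspace(10, 100_000, 5)          # nM
resp = [2.1, 11.8, 46.9, 74.0, 79.2]
curve = fit_4pl(concs, resp)
print(curve.a, curve.b, curve.c)   # top asymptote, slope, log10 EC50
print(dss(curve))                  # drug sensitivity score

print(zprime([0.41, 0.39, 0.40, 0.42, 0.38],
             [0.021, 0.018, 0.025, 0.020, 0.019]))

r = mann_whitney([4.2, 5.1, 6.9, 7.7, 8.0, 9.3, 11.2],
                 [12.8, 14.1, 15.5, 17.0, 18.2, 19.9, 22.4])
print(r.u_statistic, r.p_value)
```

prints (rounded)

```
80.01 0.93 2.84
38.32
0.854
0.0 0.0006
```

— the curve tops out at 80 % inhibition with EC50 ≈ 10^2.84 ≈ 690 nM;
DSS 38.3 is a strong hit (cut-off 8). The control separation gives
Z′ = 0.854 (passes the 0.4 gate). The 7-vs-7 comparison has U = 0 and
exact two-tailed p = 0.0006.

A full simulated screen from the command line:

```sh
spheroscreen run-screen --seed 7 --outdir results/demo
```

writes the generated input bundle plus `readouts.csv`, `qc_report.csv`,
`normalized.csv`, `dss_long.csv`, `dss_matrix.csv` (drugs × samples),
`growth.csv`, `associations.csv` and a replayable `manifest.json`.
Subcommands `simulate`, `readout`, `qc`, `dss`, `synergy`, `associate`,
`longterm` and `run-combination` expose the individual stages; thresholds
default to Z′ > 0.4, DSS > 8, ZIP ±10 and are overridable via a YAML
config.

## File formats

All interchange is plain UTF-8 CSV with one header row; concentrations in
nM; 384-well addresses A01–P24.

| file | columns |
|---|---|
| `wells.csv` | plate_id, well, sample_id, format (3D/2D), timepoint_h, role (neg_control/pos_control/treatment), drug_id, conc_nM, tmrm_volume, popo1_volume, popo1_area, hoechst_volume, hoechst_area, caspase_volume, inv_brightfield_intensity |
| `platemap.csv` | plate_id, well, role, sample_id, drug_id, conc_nM, replicate_index |
| `drugs.csv` | drug_id, drug_class, phase, conc1_nM … conc5_nM |
| `clinical.csv` | patient_id, sample_ids (`;`-separated), histology, figo_stage, ca125, recist (CR/PR/P/blank), pfi_months, excluded |
| `combo.csv` | sample_id, drug1_id, drug2_id, conc1_nM, conc2_nM (0 = untreated margin), replicate, response |

For 2D plates the volume-named columns carry the corresponding area
aggregates. QC-failed entries in `dss_matrix.csv` are empty cells, never
zeros.

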