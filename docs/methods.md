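# Methods

`spheroscreen` analyses ex vivo drug-sensitivity screens of patient-derived
3D (spheroid) and 2D cultures read out by live-cell imaging. This note
records the models, the tunable parameters and their defaults, what the
synthetic-data generator does and does not emulate, and the numerical and
design choices a maintainer would want to know.

## Readouts

Each well is summarized by channel aggregates exported from image analysis.
Two dye-based parameters carry the assay:

* **Cell health (TMRM)** — TMRM accumulates in polarized mitochondria of
  live cells. The readout is `tmrm_volume / composite_volume`, where the
  composite spheroid signal is the sum of all available fluorescence
  channel aggregates plus the inverted brightfield intensity. Because the
  TMRM signal is one of the composite's summands, the ratio lies in [0, 1]
  for nonnegative aggregates, and all ratios are invariant to a common
  rescaling of a well's aggregates (exposure changes cancel).
* **Cell death (POPO-1)** — POPO-1 is membrane-impermeant and stains dead
  cells; the readout is `popo1_area / hoechst_area`.

The composite is defined at the aggregate level (a sum of whatever channel
aggregates the upstream segmentation exports) so any imaging backend can
feed the pipeline; no pixel-level processing happens here. 2D plates reuse
the identical formulas with area aggregates carried in the volume-named
columns.

Positive-control wells (benzethonium chloride, full kill) occasionally show
collapsed POPO-1 ratios because dead cells migrate to the well edge; any
positive-control POPO-1 ratio strictly below 0.1 is replaced by 0.95 before
QC and normalization, and substitutions are counted in the QC report.

Degenerate denominators (zero composite or Hoechst area) yield NA readouts;
such wells are excluded downstream rather than silently dropped.

## Plate quality control and normalization

Assay quality per (sample, parameter) uses the standard screening-window
Z′-factor on pooled 72 h control wells,

    Z′ = 1 − 3(σ_pos + σ_neg) / |μ_pos − μ_neg|   (sample sd, ddof = 1),

with the gate **Z′ > 0.4 (strict)**. Controls are pooled across a sample's
plates because one Z′ is reported per sample and parameter. Failing
(sample, parameter) combinations are carried through with missing DSS
values — never zeros.

Treatment wells at 72 h are normalized to percent inhibition anchored at
the control means: for the viability-decreasing TMRM parameter
`100·(μ_neg − x)/(μ_neg − μ_pos)`; for the death-increasing POPO-1
parameter `100·(x − μ_neg)/(μ_pos − μ_neg)`. Normalization is affine
invariant and is deliberately **not clamped**: clamping before curve
fitting biases slope estimates, and the constrained 4PL asymptotes absorb
over/undershoot instead.

## Concentration–response model and DSS

Responses are fitted on x = log10(concentration/nM) with a constrained
four-parameter logistic

    y(x) = d + (a − d) / (1 + 10^{b (c − x)}),

with 0 ≤ d ≤ a ≤ 100 (enforced by parameterizing d as a fraction of a),
slope b ∈ [0.2, 10] (positive: inhibition does not decrease with dose) and
midpoint c = log10 EC50 allowed one decade beyond the tested range. The fit
is a deterministic multi-start bounded least squares (analytic Jacobian):
c starts at the quartiles of the log-dose range, b at {0.5, 1, 2}, the top
and bottom start at the response extremes; the lowest-SSR solution wins
with ties broken toward the smallest slope. Termination at the iteration
cap inside a flat slope-valley (a frequent, benign outcome for
plateau-shaped series) is accepted as converged; only hard failures are
not. Zero-dose wells never enter the log axis; they inform normalization
only.

Curve-level QC excludes fits that did not converge, have RMSE > 30
percentage points, or where the observed responses clearly decrease with
dose while the constrained fit is pinned flat (empirical trend < −10 with
fitted dynamic range a − d < 1).

The **drug sensitivity score** summarizes a fitted curve as the normalized
area above an activity threshold t (default 10 %) over the tested log10
range [x1, x2]:

    DSS = 100 · ∫ max(y(x) − t, 0) dx / ((100 − t)(x2 − x1)).

The integral is evaluated in closed form (the logistic antiderivative with
an analytic threshold crossing); adaptive quadrature agrees to 1e-5 and is
used as the independent cross-check in the tests. A flat 100 % curve scores
100; anything below threshold scores 0. A drug is *effective* for a sample
when **DSS > 8 (strict)**. Several DSS variants exist in the literature;
this normalized-area definition is self-contained and reproduces the
qualitative scale on which the DSS > 8 cut-off is meaningful — no numeric
parity with any external scoring service is claimed.

## Combination synergy (ZIP)

A combination experiment is a 6×6 grid — five positive concentrations per
drug plus the zero dose, so monotherapy margins and the untreated corner
sit on the same plate — in technical triplicate. Scoring:

1. average technical replicates per cell;
2. background-correct by re-zeroing on the untreated corner; fractions are
   clamped to [0, 1] wherever they enter an independence product;
3. fit 4PL curves to both monotherapy margins (falling back to the observed
   margin, flagged, if a fit fails);
4. for each fixed dose of one drug, refit along the other drug's axis with
   the bottom asymptote pinned at the fixed partner's fitted monotherapy
   effect;
5. δ(cell) = mean of the two directional fitted values − (y1 + y2 − y1·y2),
   on the fraction scale, with y1, y2 the fitted monotherapy effects.

One deliberate refinement: each directional fit **retains the mean of its
residuals** (the fitted vector is shifted by mean(observed − fitted)). A
bottom-pinned logistic cannot represent a uniformly shifted sigmoid — the
very signature of strong synergy — and plain least squares would attenuate
exactly the excess being measured. The correction is identically zero on
surfaces the model represents (e.g. exact Bliss independence), preserves
the per-cell smoothing of the fits, and makes the matrix-level mean δ
unbiased; with it, injected uniform deltas are recovered to well within
±1.5 percentage points at 5 % CV triplicate noise, and noise-free
independent surfaces score |summary| < 1e-5.

The summary score is the mean δ over the 5×5 positive-dose block × 100
(percentage points; a single score per combination, not a
most-synergistic-region score). Classification: **synergistic > +10,
antagonistic < −10, additive on the closed interval [−10, 10]**. Scoring is
symmetric in the drug order.

## Clinical association

Cohort comparisons use the two-tailed Mann–Whitney U test: exact (via the
permutation distribution, two-tailed p = min(1, 2 × one-tailed tail
probability)) when there are no ties and min(nA, nB) ≤ 10, otherwise the
normal approximation with midranks and tie correction. The implementation
delegates to `scipy.stats.mannwhitneyu`; the tests verify it against a
brute-force enumeration over all label assignments.

Endpoints: RECIST complete response (CR) versus partial response or
progression (PR/P), and the platinum-sensitivity split at progression-free
interval ≤ 12 versus > 12 months. Patients with both tissue and ascites
samples contribute one value per comparison (the mean over their samples);
excluded patients and patients with a missing endpoint never enter a group.
Tests are reported unadjusted (no multiple-testing correction across the
panel), matching how such cohort summaries are conventionally reported at
this scale.

Format comparisons (3D vs 2D) use a two-tailed paired t-test on per-sample
fold growth (DMSO-well TMRM aggregate at 72 h over 2 h), with explicit
degenerate branches: identical pairs give t = 0, p = 1; a constant nonzero
difference with zero variance returns a p = 0 sentinel with a flag.
Per-drug mean DSS differences (2D − 3D) are reported when |Δ| > 1.

Washout time series (8 h grid over 14 days) are summarized per arm by the
day-14 fold change versus treatment start and a regrowth flag: after the
washout day the series attains a minimum and subsequently rebounds by more
than 20 % of its dynamic range. The 20 % threshold is this package's own
operationalization of qualitatively described regrowth. Series with
sampling gaps over 24 h are flagged.

## Synthetic-data generator

The generator fabricates every input the pipeline consumes, with the
serialized `TruthModel` carrying the exact generating quantities, so that
recovery can be asserted end to end.

**Design defaults** mirror the emulated study: 16 patients / 20 samples
(four tissue + ascites pairs), a 58-drug library with five log-spaced
concentrations each (10-fold steps over 1–10⁴ nM unless a drug has a
specific printed range, e.g. carboplatin 10–10⁵ nM, afatinib 0.2–2000 nM,
A-1331852 0.5–1000 nM), 384-well plates with 11 DMSO and 10 positive
control wells, imaging at 2 h and 72 h, and paired 2D plates for 11
samples.

**Well construction.** A well's composite signal V is lognormal; the TMRM
signal is V·κ·v·(1 + ε) with baseline viability ratio κ = 0.4, viability
factor v = 1 − (PI/100)(1 − v_pos) implied by the true inhibition curve at
the well's dose (v_pos = 0.05 is the positive-control residual), and
multiplicative noise ε ~ N(0, CV) with CV = 5 % by default. The inverted
brightfield channel absorbs the remainder so channel sums reproduce V
exactly, making every readout formula invertible in expectation: the
percent-inhibition of a noise-free treated well equals the generating
curve's value exactly. POPO-1/Hoechst areas encode the complementary death
fraction between ratios 0.05 (alive) and 0.95 (dead). Fold growth is
sampled per sample: 3D ~ N(2.0, 0.3), 2D ~ N(1.3, 0.15) — the direction
(3D grows faster) is the emulated finding; the magnitudes are this
package's choice of realistic values.

**Truth curves.** Per (sample, drug) a target true DSS is drawn and the
4PL top asymptote is solved for it by bisection (slope ~ U(0.8, 2),
midpoint uniform in the lower half of the dose range, bottom 0), so true
DSS values are controlled exactly. Sensitivity structure: each drug is
effective (target DSS ~ U(10, 40)) with probability 0.135 for CR patients
and 0.055 for PR/P patients — calibrated so the cohort averages ~8
effective drugs per patient, the emulated cohort's stated average — and
three drugs (carboplatin 1.0×, cisplatin 0.6×, adavosertib 0.5×) carry a
PFI-linked true-DSS shift: carboplatin means 7 vs 17 DSS units (sd 4) for
PFI ≤ 12 vs > 12 months. A 2D format effect multiplies the top asymptote
lognormally (sd 0.08). One patient is excluded (a different primary tumour
found post hoc) and two are lost to follow-up (missing PFI), giving RECIST
groups of 11 CR / 4 PR / 1 P and PFI groups of 7 vs 7.

**Combinations** are built as the Bliss/ZIP expectation of two known
monotherapy curves plus an injected delta field (zero, uniform, or
localized to the high-dose quadrant), a constant plate background (2
percentage points) and multiplicative replicate noise, in triplicate.
**Washout series** follow logistic growth (rate 0.01/h toward a carrying
capacity) with arm-specific kill rates during exposure; monotherapy kill
stops at washout (cytostatic — survivors regrow), while the combination is
cytotoxic and keeps decaying after washout.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning (one child stream per stage, fixed
iteration order), so regeneration is byte-identical on one platform.

**What the generator does not emulate:** spatial plate effects (edge
wells, drift — off by default and not implemented), non-multiplicative or
heavy-tailed imaging noise, segmentation failures, culture heterogeneity
beyond a per-sample scalar, correlations between drugs sharing a
mechanism, and any real pharmacology. Passing recovery tests therefore
demonstrates that the analysis inverts its own generative model under
realistic noise — not that it is robust to every artefact of real screens.

## Problem sizes and reproduction

The test suite runs on scaled-down screens (3–5 samples, 5–8 drugs) chosen
so the full suite completes in a few minutes; the statistical conclusions
(recovery medians over 200 curves, 100-seed power fraction, 100
noise-free synergy nulls) use the sizes stated above.
`scripts/acceptance.py` additionally runs one full default cohort screen
(16 patients / 20 samples / 58 drugs, 3D plus 11 paired 2D plates) and a
scaled determinism check; determinism is size-independent because a single
seeded generator drives generation in fixed order.

## Known limitations

* DSS values are comparable within this package's definition only; other
  DSS variants integrate over different bounds and scale differently.
* The ZIP summary averages the whole positive-dose block; locally confined
  synergy is diluted (the localized injection illustrates this).
* Exact Mann–Whitney p-values switch to the normal approximation in the
  presence of ties, which is conservative for very small groups with many
  ties.
* Curve QC rules (RMSE cap, inverted-trend rejection) are minimal by
  design; pathological-but-smooth fits pass.
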