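"""ZIP (zero interaction potency) synergy scoring of dose-combination
matrices.

A combination experiment is a 6x6 grid: 5 positive concentrations per drug
plus the zero dose, so the monotherapy margins and the untreated corner sit
on the same plate, in technical triplicate.  Scoring follows the ZIP
recipe: replicates are averaged; responses are re-zeroed on the untreated
corner (background correction); 4PL curves are fitted to both monotherapy
margins; then, for each fixed dose of one drug, the response along the
other drug's axis is refitted with the bottom asymptote pinned at the fixed
partner's fitted monotherapy effect.  The delta surface is

    delta(i, j) = mean(directional fits) - (y1 + y2 - y1 y2)

on the fraction scale, where y1, y2 are the fitted monotherapy effects and
the subtrahend is the Bliss-independence expectation.  The summary score is
the mean delta over the 5x5 positive-dose block, in percentage points;
combinations are called synergistic above +10, antagonistic below -10, and
additive on the closed interval in between.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import fit_4pl, fourpl

log = logging.getLogger(__name__)

ZIP_SYNERGY_THRESHOLD = 10.0


def zip_expected(y1, y2):
    """Bliss-independence expectation y1 + y2 - y1*y2 on the fraction
    scale; inputs are clamped to [0, 1]."""
    y1 = np.clip(np.asarray(y1, dtype=float), 0.0, 1.0)
    y2 = np.clip(np.asarray(y2, dtype=float), 0.0, 1.0)
    out = y1 + y2 - y1 * y2
    return float(out) if out.ndim == 0 else out


@dataclass
class CombinationMatrix:
    """Replicated 6x6 dose-combination response grid (percent inhibition).

    ``responses`` has shape (6, 6, n_rep); index 0 on each axis is the zero
    dose, so ``responses[1:, 0]`` / ``responses[0, 1:]`` are the monotherapy
    margins and ``responses[0, 0]`` the untreated corner.
    """

    sample_id: str
    drug1_id: str
    drug2_id: str
    conc1_nM: np.ndarray  # 5 positive doses, strictly increasing
    conc2_nM: np.ndarray
    responses: np.ndarray  # (6, 6, n_rep), % inhibition
    background_corrected: bool = False

    def __post_init__(self) -> None:
        self.conc1_nM = np.asarray(self.conc1_nM, dtype=float)
        self.conc2_nM = np.asarray(self.conc2_nM, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        for name, grid in (("conc1_nM", self.conc1_nM), ("conc2_nM", self.conc2_nM)):
            if grid.shape != (5,) or not np.all(np.diff(grid) > 0) or np.any(grid <= 0):
                raise ValueError(f"{name}: need 5 strictly increasing positive doses")
        if self.responses.ndim == 2:
            self.responses = self.responses[:, :, None]
        if self.responses.shape[:2] != (6, 6):
            raise ValueError(
                "responses must be a 6x6 grid including the zero-dose margins"
            )
        if np.isnan(self.responses).all(axis=2).any():
            raise ValueError(
                f"{self.sample_id} {self.drug1_id}+{self.drug2_id}: "
                "missing cells in the combination matrix"
            )

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "CombinationMatrix":
        """Build from long form (sample_id, drug1_id, drug2_id, conc1_nM,
        conc2_nM, replicate, response); zero doses are rows with conc 0."""
        sample = df["sample_id"].iloc[0]
        d1, d2 = df["drug1_id"].iloc[0], df["drug2_id"].iloc[0]
        c1 = np.sort(df.loc[df["conc1_nM"] > 0, "conc1_nM"].unique())
        c2 = np.sort(df.loc[df["conc2_nM"] > 0, "conc2_nM"].unique())
        reps = np.sort(df["replicate"].unique())
        grid = np.full((6, 6, reps.size), np.nan)
        idx1 = {0.0: 0, **{v: i + 1 for i, v in enumerate(c1)}}
        idx2 = {0.0: 0, **{v: i + 1 for i, v in enumerate(c2)}}
        ridx = {r: k for k, r in enumerate(reps)}
        for row in df.itertuples(index=False):
            grid[idx1[row.conc1_nM], idx2[row.conc2_nM], ridx[row.replicate]] = row.response
        return cls(sample_id=sample, drug1_id=d1, drug2_id=d2,
                   conc1_nM=c1, conc2_nM=c2, responses=grid)

    def to_long(self) -> pd.DataFrame:
        c1 = np.concatenate([[0.0], self.conc1_nM])
        c2 = np.concatenate([[0.0], self.conc2_nM])
        rows = []
        for i in range(6):
            for j in range(6):
                for k in range(self.responses.shape[2]):
                    v = self.responses[i, j, k]
                    if not np.isnan(v):
                        rows.append(
                            {"sample_id": self.sample_id, "drug1_id": self.drug1_id,
                             "drug2_id": self.drug2_id, "conc1_nM": c1[i],
                             "conc2_nM": c2[j], "replicate": k + 1, "response": v}
                        )
        return pd.DataFrame(rows)

    def swapped(self) -> "CombinationMatrix":
        return CombinationMatrix(
            sample_id=self.sample_id, drug1_id=self.drug2_id, drug2_id=self.drug1_id,
            conc1_nM=self.conc2_nM.copy(), conc2_nM=self.conc1_nM.copy(),
            responses=np.swapaxes(self.responses, 0, 1).copy(),
            background_corrected=self.background_corrected,
        )


@dataclass
class ZIPResult:
    sample_id: str
    drug1_id: str
    drug2_id: str
    delta_surface: np.ndarray  # (5, 5), fraction scale
    summary: float  # mean delta x 100, percentage points
    interaction_class: str
    margin_fallback: bool = False
    flags: list[str] = field(default_factory=list)


def classify_interaction(summary: float, threshold: float = ZIP_SYNERGY_THRESHOLD) -> str:
    if summary > threshold:
        return "synergistic"
    if summary < -threshold:
        return "antagonistic"
    return "additive"


def _margin_effect(concs, margin_pct):
    """Fit a monotherapy margin; fall back to the observed margin values
    when the fit fails.  Returns (fitted % at each dose, curve|None, fellback)."""
    curve = fit_4pl(concs, margin_pct)
    if curve.converged:
        return fourpl(np.log10(concs), curve.a, curve.d, curve.b, curve.c), curve, False
    log.warning("monotherapy margin fit failed; using observed margin")
    return np.asarray(margin_pct, dtype=float), None, True


def _directional_fit(concs, responses_pct, bottom_pct):
    """Refit along one drug's axis with the bottom pinned at the fixed
    partner's monotherapy effect; fall back to the observed responses.

    The fitted vector retains the mean of its residuals: a bottom-pinned
    4PL cannot represent a uniformly shifted sigmoid (strong synergy), and
    plain least squares would attenuate exactly the excess the delta
    surface is meant to measure.  Adding mean(observed - fitted) back
    keeps the fit's per-cell smoothing while leaving the matrix-level
    summary unbiased; on a surface the model represents exactly the
    correction is zero.
    """
    y = np.asarray(responses_pct, dtype=float)
    curve = fit_4pl(concs, y, fixed_bottom=float(np.clip(bottom_pct, 0, 100)))
    if curve.converged:
        pred = fourpl(np.log10(concs), curve.a, curve.d, curve.b, curve.c)
        return pred + float(np.mean(y - pred)), False
    return y, True


def zip_delta_surface(matrix: CombinationMatrix) -> ZIPResult:
    """Compute the ZIP delta surface, summary score and interaction class
    for one combination matrix.  Deterministic given the input."""
    flags: list[str] = []
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(matrix.responses, axis=2)  # (6, 6) %

    # background correction: re-zero on the untreated corner
    corner = mean[0, 0]
    corrected = mean - corner

    margin1 = corrected[1:, 0]
    margin2 = corrected[0, 1:]
    y1_fit_pct, _, fb1 = _margin_effect(matrix.conc1_nM, margin1)
    y2_fit_pct, _, fb2 = _margin_effect(matrix.conc2_nM, margin2)
    fallback = fb1 or fb2
    if fallback:
        flags.append("margin_fallback")

    # fraction-scale fitted monotherapy effects, clamped for the
    # independence product
    y1f = np.clip(y1_fit_pct / 100.0, 0.0, 1.0)
    y2f = np.clip(y2_fit_pct / 100.0, 0.0, 1.0)

    # directional fits: along drug1 for each fixed drug2 dose, and vice versa
    fit_along_1 = np.empty((5, 5))
    for j in range(5):
        vals, fb = _directional_fit(matrix.conc1_nM, corrected[1:, j + 1], y2_fit_pct[j])
        if fb:
            flags.append(f"directional_fallback_d1_at_j{j}")
        fit_along_1[:, j] = vals
    fit_along_2 = np.empty((5, 5))
    for i in range(5):
        vals, fb = _directional_fit(matrix.conc2_nM, corrected[i + 1, 1:], y1_fit_pct[i])
        if fb:
            flags.append(f"directional_fallback_d2_at_i{i}")
        fit_along_2[i, :] = vals

    fitted = 0.5 * (fit_along_1 + fit_along_2) / 100.0
    expected = zip_expected(y1f[:, None], y2f[None, :])
    delta = fitted - expected

    summary = float(np.mean(delta) * 100.0)
    return ZIPResult(
        sample_id=matrix.sample_id, drug1_id=matrix.drug1_id, drug2_id=matrix.drug2_id,
        delta_surface=delta, summary=summary,
        interaction_class=classify_interaction(summary),
        margin_fallback=fallback, flags=flags,
    )


def zip_summary_and_classify(delta_surface: np.ndarray,
                             threshold: float = ZIP_SYNERGY_THRESHOLD) -> tuple[float, str]:
    """Mean delta over the positive-dose block x 100 and its class."""
    summary = float(np.mean(np.asarray(delta_surface, dtype=float)) * 100.0)
    return summary, classify_interaction(summary, threshold)


def score_combinations(df_long: pd.DataFrame) -> tuple[pd.DataFrame, list[ZIPResult]]:
    """Score every (sample, drug1, drug2) matrix in a long-form combination
    table; returns a summary frame and the full results."""
    results = []
    rows = []
    for (sample, d1, d2), g in df_long.groupby(["sample_id", "drug1_id", "drug2_id"]):
        res = zip_delta_surface(CombinationMatrix.from_long(g))
        results.append(res)
        rows.append(
            {"sample_id": sample, "drug1_id": d1, "drug2_id": d2,
             "zip_summary": res.summary, "interaction_class": res.interaction_class,
             "margin_fallback": res.margin_fallback}
        )
    return pd.DataFrame(rows), results


def zip_results_long(results: list[ZIPResult]) -> pd.DataFrame:
    """Delta surfaces in long form (one row per positive-dose cell) plus the
    per-matrix summary and class, for ``zip_results.csv``."""
    rows = []
    for r in results:
        for i in range(5):
            for j in range(5):
                rows.append(
                    {"sample_id": r.sample_id, "drug1_id": r.drug1_id,
                     "drug2_id": r.drug2_id, "dose1_index": i + 1,
                     "dose2_index": j + 1, "delta": r.delta_surface[i, j],
                     "zip_summary": r.summary,
                     "interaction_class": r.interaction_class}
                )
    return pd.DataFrame(rows)
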