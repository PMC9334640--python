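"""Ion-mobility restraint scoring: penalty, combined score, rescoring, confidence.

A model whose predicted CCS agrees with the measured value within a lower
bound LB (default 10 Å²) pays no penalty; disagreement beyond an upper bound
UB (default 100 Å²) pays the full penalty (default 100 score units); in
between, a cubic smoothstep fades the penalty in:

    penalty = max_penalty * (2x³ − 3x² + 1),  x = −(ΔCCS − UB)/(UB − LB)

The combined score of a model is its externally supplied base energy (a
Rosetta-style all-atom score; lower is better) plus this penalty.  Ensemble
rescoring sorts by the combined score, and the confidence metric is the mean
combined score of the best 100 models per residue, with scores below −2.54
flagged as high confidence.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DEFAULT_ROTATIONS, compute_ccs

CONFIDENCE_THRESHOLD = -2.54
CONFIDENCE_TOP_K = 100


@dataclass(frozen=True)
class PenaltyParams:
    """Bounds of the CCS-deviation fade penalty (Å² / score units)."""

    lb: float = 10.0
    ub: float = 100.0
    max_penalty: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.lb < self.ub:
            raise ValueError("need 0 <= lb < ub")
        if self.max_penalty <= 0:
            raise ValueError("max_penalty must be positive")


def im_penalty(delta_ccs, params: PenaltyParams = PenaltyParams()):
    """Restraint penalty for an absolute CCS deviation (vectorized over ΔCCS).

    Zero below LB, ``max_penalty`` above UB, the cubic fade in between; the
    fade takes the same values as the flat branches at the exact bounds, so
    the function is continuous and monotone nondecreasing.
    """
    delta = np.asarray(delta_ccs, dtype=float)
    if (delta < 0).any():
        raise ValueError("delta_ccs must be non-negative")
    x = -(delta - params.ub) / (params.ub - params.lb)
    fade = params.max_penalty * (2 * x ** 3 - 3 * x ** 2 + 1)
    out = np.where(delta < params.lb, 0.0,
                   np.where(delta > params.ub, params.max_penalty, fade))
    return float(out) if np.isscalar(delta_ccs) else out


@dataclass
class ScoredModel:
    """One decoy after rescoring with the IM restraint."""

    model_id: str
    base_score: float
    ccs_pred: float
    delta_ccs: float
    penalty: float
    im_score: float


def im_score(base_score: float, ccs_pred: float, ccs_exp: float,
             params: PenaltyParams = PenaltyParams(),
             model_id: str = "") -> ScoredModel:
    """Combine a base energy with the CCS-deviation penalty."""
    if ccs_pred <= 0 or ccs_exp <= 0:
        raise ValueError("CCS values must be positive")
    delta = abs(ccs_pred - ccs_exp)
    penalty = im_penalty(delta, params)
    return ScoredModel(model_id=model_id, base_score=float(base_score),
                       ccs_pred=float(ccs_pred), delta_ccs=float(delta),
                       penalty=float(penalty),
                       im_score=float(base_score) + float(penalty))


@dataclass
class RescoreTable:
    """A rescored decoy ensemble, best (lowest combined score) first."""

    entries: pd.DataFrame  # columns: model_id, base_score, ccs_pred, delta_ccs, penalty, im_score, rank
    ccs_exp: float
    params: PenaltyParams
    gas: str = "nitrogen"

    @property
    def best(self) -> pd.Series:
        return self.entries.iloc[0]

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def rescore_ensemble(base_scores: pd.DataFrame, ccs_values: pd.DataFrame,
                     ccs_exp: float,
                     params: PenaltyParams = PenaltyParams(),
                     gas: str = "nitrogen") -> RescoreTable:
    """Join base energies with predicted CCS and rank by combined score.

    ``base_scores`` needs columns (model_id, base_score); ``ccs_values``
    needs (model_id, ccs_pred).  Ties in the combined score break by
    model_id so the ranking is deterministic.
    """
    if ccs_exp <= 0:
        raise ValueError("ccs_exp must be positive")
    bs = base_scores[["model_id", "base_score"]].copy()
    cv = ccs_values[["model_id", "ccs_pred"]].copy()
    if len(bs) == 0:
        raise ValueError("need at least one model")
    missing = sorted(set(bs.model_id) ^ set(cv.model_id))
    if missing:
        raise KeyError(f"model ids present in only one table: {missing}")
    df = bs.merge(cv, on="model_id")
    df["delta_ccs"] = (df.ccs_pred - ccs_exp).abs()
    df["penalty"] = im_penalty(df.delta_ccs.to_numpy(), params)
    df["im_score"] = df.base_score + df.penalty
    df = df.sort_values(["im_score", "model_id"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return RescoreTable(entries=df, ccs_exp=ccs_exp, params=params, gas=gas)


def rescore_structures(base_scores: pd.DataFrame, models, ccs_exp: float,
                       params: PenaltyParams = PenaltyParams(),
                       gas: str = "nitrogen",
                       rotations: int = DEFAULT_ROTATIONS,
                       seed: int = 0) -> RescoreTable:
    """Rescore an ensemble of structures, predicting each model's CCS first."""
    ccs_values = pd.DataFrame({
        "model_id": [m.source_id for m in models],
        "ccs_pred": [compute_ccs(m, gas=gas, rotations=rotations, seed=seed).ccs
                     for m in models],
    })
    return rescore_ensemble(base_scores, ccs_values, ccs_exp, params, gas)


@dataclass
class ConfidenceResult:
    score_per_residue: float
    top_k_used: int
    threshold: float
    label: str  # "high" | "low"


def confidence_score(table: RescoreTable, n_residues: int,
                     top_k: int = CONFIDENCE_TOP_K,
                     threshold: float = CONFIDENCE_THRESHOLD) -> ConfidenceResult:
    """Mean combined score of the best ``top_k`` models per residue.

    Scores strictly below the threshold flag a high-confidence prediction.
    With fewer than ``top_k`` models the mean is over all of them (warned).
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    n = len(table.entries)
    if n == 0:
        raise ValueError("empty rescore table")
    k = min(top_k, n)
    if n < top_k:
        warnings.warn(f"only {n} models available; averaging all of them "
                      f"instead of the top {top_k}")
    spr = float(table.entries.im_score.iloc[:k].mean()) / n_residues
    return ConfidenceResult(score_per_residue=spr, top_k_used=k,
                            threshold=threshold,
                            label="high" if spr < threshold else "low")


def scaled_confidence(score_per_residue: float,
                      threshold: float = CONFIDENCE_THRESHOLD,
                      span: float = 2.0,
                      lo_anchor: float | None = None,
                      hi_anchor: float | None = None) -> float:
    """Affine map of the per-residue score to [0, 1] (1 = most confident).

    This is a presentation convention of this package, not a measured
    quantity: by default the threshold maps to 0.5 and the map reaches 0/1
    one ``span``/2 score unit per residue on either side, clamped.
    Anchors may be given explicitly (``lo_anchor`` < ``hi_anchor`` on the
    score scale; lo maps to 1 since lower scores are better).
    """
    if lo_anchor is None:
        lo_anchor = threshold - span / 2
    if hi_anchor is None:
        hi_anchor = threshold + span / 2
    if not lo_anchor < hi_anchor:
        raise ValueError("need lo_anchor < hi_anchor")
    t = (hi_anchor - score_per_residue) / (hi_anchor - lo_anchor)
    return float(np.clip(t, 0.0, 1.0))


def perturb_ccs(ccs_exp: float, percent: float, mode: str = "noise",
                rng: np.random.Generator | None = None) -> float:
    """Inject uncertainty into a reference CCS value.

    ``noise`` multiplies by (1 + u), u uniform on ±percent/100 (models
    measurement error); ``reduce`` shrinks deterministically by percent
    (models gas-phase compaction of the target value).
    """
    if not 0 <= percent <= 100:
        raise ValueError("percent must be in [0, 100]")
    if mode == "reduce":
        return ccs_exp * (1 - percent / 100)
    if mode == "noise":
        rng = rng or np.random.default_rng()
        u = rng.uniform(-percent / 100, percent / 100)
        return ccs_exp * (1 + u)
    raise ValueError("mode must be 'noise' or 'reduce'")


def read_base_scores(path: str | Path) -> pd.DataFrame:
    """Read per-model base energies from a score table.

    Two dialects: a Rosetta-style whitespace score file (header line starting
    ``SCORE:`` with ``total_score`` and ``description`` columns) or a CSV with
    ``model_id`` and ``base_score`` columns.
    """
    path = Path(path)
    text = path.read_text()
    score_lines = [ln for ln in text.splitlines() if ln.startswith("SCORE:")]
    if score_lines:
        header = score_lines[0].split()[1:]
        if "total_score" not in header or "description" not in header:
            raise ValueError(f"{path}: score file lacks total_score/description")
        rows = [ln.split()[1:] for ln in score_lines[1:]]
        df = pd.DataFrame(rows, columns=header)
        return pd.DataFrame({"model_id": df.description,
                             "base_score": df.total_score.astype(float)})
    df = pd.read_csv(io.StringIO(text))
    if not {"model_id", "base_score"} <= set(df.columns):
        raise ValueError(f"{path}: CSV needs model_id and base_score columns")
    return df[["model_id", "base_score"]]
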