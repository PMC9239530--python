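"""TAILORx risk stratification and concordance statistics.

RS strata follow the TAILORx cutoffs: low (<= 15), intermediate (16-25),
high (26-100). Predicted scores are real-valued and unclamped, so the
stratum edges are applied directly (score < 16 is low, 16 <= score < 26
is intermediate, score >= 26 is high). Agreement between observed and
predicted strata is summarized by concordance and one-/two-step
discordance on a 3x3 confusion matrix ordered high/intermediate/low.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

LOW, INTERMEDIATE, HIGH = "low", "intermediate", "high"

#: category order used for step distances (low < intermediate < high)
CATEGORY_ORDER = [LOW, INTERMEDIATE, HIGH]

#: row/column order of printed confusion matrices (high first)
MATRIX_ORDER = [HIGH, INTERMEDIATE, LOW]

_LEVEL = {c: i for i, c in enumerate(CATEGORY_ORDER)}


def stratify_rs(score: float) -> str:
    """Risk category of an RS value (raw predictions allowed).

    The high stratum starts at 26 (the categories are defined as
    low <= 15, intermediate 16-25, high 26-100), so fractional predicted
    scores in the open gaps (15, 16) and (25, 26) fall to the lower
    stratum: 15.4 is low and 25.4 is intermediate.
    """
    if score >= 26:
        return HIGH
    if score >= 16:
        return INTERMEDIATE
    return LOW


def confusion3(gt: Sequence[str], pred: Sequence[str]) -> pd.DataFrame:
    """3x3 confusion matrix, rows = ground truth, high/intermediate/low."""
    if len(gt) != len(pred):
        raise ValueError("gt and pred must have equal length")
    m = pd.DataFrame(0, index=MATRIX_ORDER, columns=MATRIX_ORDER, dtype=int)
    for g, p in zip(gt, pred):
        if g not in _LEVEL or p not in _LEVEL:
            raise ValueError(f"unknown risk category in ({g!r}, {p!r})")
        m.loc[g, p] += 1
    m.index.name, m.columns.name = "gt", "pred"
    return m


def _as_matrix(m) -> np.ndarray:
    a = m.to_numpy() if isinstance(m, pd.DataFrame) else np.asarray(m)
    if a.shape != (3, 3) or (a < 0).any():
        raise ValueError("expected a non-negative 3x3 matrix")
    return a.astype(float)


def agreement_stats(m) -> dict[str, float]:
    """Concordance and step-discordance fractions of a 3x3 matrix.

    Concordance is the diagonal fraction; one-step (two-step)
    discordance is the fraction of pairs one (two) ordered categories
    apart. The three fractions sum to 1 exactly.
    """
    a = _as_matrix(m)
    n = a.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    idx = np.arange(3)
    dist = np.abs(idx[:, None] - idx[None, :])
    return {
        "concordance": float(a[dist == 0].sum() / n),
        "one_step": float(a[dist == 1].sum() / n),
        "two_step": float(a[dist == 2].sum() / n),
    }


def chemo_recommendation(rs: float, age: float,
                         high_cut: float = 26,
                         intermediate_cut: float = 16,
                         intermediate_age_max: float = 50) -> bool:
    """Chemotherapy recommendation from RS and age.

    True when rs >= 26, or when the patient is <= 50 years old with
    rs >= 16; False otherwise. The default thresholds reconstruct the
    TAILORx-derived decision rule (younger patients with intermediate
    scores may still benefit); they are parameters, not quotations.
    """
    if age <= 0:
        raise ValueError("age must be positive")
    return rs >= high_cut or (age <= intermediate_age_max and rs >= intermediate_cut)


def recommendation_discordance(
    gt_rec: Sequence[bool], pred_rec: Sequence[bool]
) -> tuple[pd.DataFrame, int]:
    """2x2 recommendation matrix (rows = RS No/Yes, cols = predicted
    No/Yes) and the number of discordant cases (off-diagonal sum)."""
    if len(gt_rec) != len(pred_rec):
        raise ValueError("gt and pred must have equal length")
    labels = ["no", "yes"]
    m = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for g, p in zip(gt_rec, pred_rec):
        m.iloc[int(bool(g)), int(bool(p))] += 1
    m.index.name, m.columns.name = "rs", "pred"
    discordant = int(m.iloc[0, 1] + m.iloc[1, 0])
    return m, discordant
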