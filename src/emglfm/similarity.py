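"""Linear Fit Method (LFM) curve similarity.

The LFM scores the resemblance of two activation curves by regressing one on
the other and reporting the coefficient of determination R² of the simple
linear fit.  For a one-predictor regression with intercept, R² equals the
squared Pearson correlation, so the score is symmetric in its arguments and
invariant under affine rescaling of either curve.  Curves must share a common
time base (here: 100 points per movement phase, 300 for the concatenated
full trial) before they are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FULL_TRIAL = "full_trial"
PHASES = ("reaching", "holding", "transport")
SCOPES = PHASES + (FULL_TRIAL,)


class ZeroVarianceCurveError(ValueError):
    """Raised when a curve is flat: the linear-fit R² is then undefined.

    A constant envelope almost always indicates an upstream processing fault
    (dead channel, mis-segmentation), so it is reported loudly instead of
    being mapped to a similarity of zero.
    """


@dataclass(frozen=True)
class SimilarityScore:
    subject: str
    group: str
    session: int
    muscle: str
    scope: str
    r_squared: float


def lfm_r_squared(curve_a, curve_b) -> float:
    """Linear Fit Method similarity between two equal-length curves.

    Returns the R² of the ordinary least-squares line relating the two
    curves, i.e. their squared Pearson correlation.  Identical curves score
    exactly 1.0.

    Raises
    ------
    ValueError
        If the curves differ in length or contain non-finite values.
    ZeroVarianceCurveError
        If either curve is constant.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("curves must be one-dimensional")
    if a.shape != b.shape:
        raise ValueError(f"curve lengths differ: {a.size} vs {b.size}")
    if a.size < 3:
        raise ValueError("need at least 3 points for a meaningful fit")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("curves must be finite")

    da = a - a.mean()
    db = b - b.mean()
    saa = float(np.dot(da, da))
    sbb = float(np.dot(db, db))
    if saa == 0.0 or sbb == 0.0:
        raise ZeroVarianceCurveError("zero-variance curve: LFM R² undefined")
    sab = float(np.dot(da, db))
    r2 = (sab * sab) / (saa * sbb)
    # guard against rounding pushing the score an epsilon past 1
    return min(r2, 1.0)


def _r2_last_axis(curves: np.ndarray, model: np.ndarray) -> np.ndarray:
    """Vectorized LFM R² of stacked curves against one model curve.

    ``curves`` has the curve on its last axis; ``model`` is 1-D of the same
    length.  Used for bulk scoring; semantics match :func:`lfm_r_squared`.
    """
    c = curves - curves.mean(axis=-1, keepdims=True)
    m = model - model.mean()
    scc = np.einsum("...i,...i->...", c, c)
    smm = float(np.dot(m, m))
    scm = np.einsum("...i,i->...", c, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (scm * scm) / (scc * smm)
    return np.minimum(r2, 1.0)


def score_study(curves: pd.DataFrame, model_curves: dict) -> pd.DataFrame:
    """Score every trainee curve against the matching model curve.

    Parameters
    ----------
    curves
        Long-format table with columns ``subject, group, session, muscle,
        scope, values`` where ``values`` holds the curve as a 1-D array
        (100 points for a phase, 300 for the full trial).
    model_curves
        Mapping ``(muscle, scope) -> 1-D array`` of the expert's curves.

    Returns
    -------
    DataFrame with columns subject, group, session, muscle, scope, r_squared;
    one row per input curve.  Raises ``KeyError`` if a model curve is missing.
    """
    rows = []
    for rec in curves.itertuples(index=False):
        key = (rec.muscle, rec.scope)
        if key not in model_curves:
            raise KeyError(f"no model curve for muscle={rec.muscle} scope={rec.scope}")
        rows.append(
            SimilarityScore(
                subject=rec.subject,
                group=rec.group,
                session=int(rec.session),
                muscle=rec.muscle,
                scope=rec.scope,
                r_squared=lfm_r_squared(rec.values, model_curves[key]),
            )
        )
    return pd.DataFrame([vars(r) for r in rows])


def similarity_delta(scores: pd.DataFrame, first: int = 1, last: int = 6) -> pd.DataFrame:
    """Per-subject similarity gain Δ = R²(S_last) − R²(S_first).

    Because R² is already a bounded, dimensionless fraction, the plain
    difference between the final and initial sessions is the standardized
    convergence metric; it lies in [−1, 1].
    """
    wide = scores.pivot_table(
        index=["subject", "group", "muscle", "scope"],
        columns="session",
        values="r_squared",
    )
    for s in (first, last):
        if s not in wide.columns:
            raise ValueError(f"session {s} missing from similarity table")
    out = wide.reset_index()[["subject", "group", "muscle", "scope"]].copy()
    out["delta_r_squared"] = (wide[last] - wide[first]).to_numpy()
    if out["delta_r_squared"].isna().any():
        raise ValueError("some subjects lack S1 or S6 similarity scores")
    return out
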