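"""Two-sample testing and volcano-style significance classification.

Each bait-vs-reference contrast is scored per protein with an
equal-variance two-sample Student's t test on the (imputed) log
intensities.  A protein is called significantly up- or down-regulated when
it passes a combined cutoff: raw p-value below ``p_max`` (default 0.05) and
an absolute fold change of at least ``min_log2_diff`` in log2 units
(default 3).  Because the intensity matrix is log10 by default, the
difference of group means is converted with d_log2 = d * log2(base), so
the default log10-unit cutoff is 3 * log10(2) ~ 0.9031.  A strict-figure
mode (``difference_units="matrix"``) instead applies the cutoff directly in
matrix units, since figure legends stating "difference 3" can also be read
that way.

P-values are raw by default; Benjamini-Hochberg q-values are available as
an option and never change the classification unless the caller
re-classifies on them.
"""

from __future__ import annotations

import math
import sys
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import DesignSpec
from .preprocess import IntensityMatrix

_TINY_P = sys.float_info.min  # underflow clamp before -log10


@dataclass
class ThresholdSpec:
    """Combined p-value / fold-change significance cutoff.

    ``s0 = 0`` gives the rectangular AND-rule; ``s0 > 0`` the SAM-style
    hyperbolic curve -log10(p) > -log10(p_max) + s0 / (|d_log2| - d0).
    """

    p_max: float = 0.05
    min_log2_diff: float = 3.0
    s0: float = 0.0
    difference_units: str = "log2"  # log2 | matrix

    def __post_init__(self) -> None:
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must be in (0, 1)")
        if self.min_log2_diff < 0 or self.s0 < 0:
            raise ValueError("min_log2_diff and s0 must be >= 0")
        if self.difference_units not in ("log2", "matrix"):
            raise ValueError("difference_units must be 'log2' or 'matrix'")


def student_t_test(a, b) -> tuple[float, int, float]:
    """Pooled-variance two-sample Student's t test (two-sided).

    Returns ``(t, df, p)`` with df = len(a) + len(b) - 2.  With zero pooled
    variance: equal means give (0, df, 1); unequal means give an infinite t
    and p clamped to the smallest positive float, with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0:
        if diff == 0:
            return 0.0, df, 1.0
        warnings.warn("zero pooled variance with unequal means; p underflows", stacklevel=2)
        return math.copysign(math.inf, diff), df, _TINY_P
    se = math.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def _to_log2(d: float | np.ndarray, log_base: int) -> float | np.ndarray:
    if log_base == 2:
        return d
    return d / math.log10(2)


def classify_significance(
    d: float, p: float, thr: ThresholdSpec | None = None, log_base: int = 10
) -> str:
    """Classify one protein as ``up``, ``down`` or ``not_significant``.

    ``d`` is the difference of group means in matrix log units; the effect
    cutoff is applied after conversion to log2 units (unless
    ``difference_units="matrix"``).
    """
    thr = thr or ThresholdSpec()
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    d_eff = d if thr.difference_units == "matrix" else _to_log2(d, log_base)
    if abs(d_eff) < thr.min_log2_diff:
        return "not_significant"
    if thr.s0 == 0:
        significant = p < thr.p_max
    else:
        if abs(d_eff) == thr.min_log2_diff:
            return "not_significant"
        curve = -math.log10(thr.p_max) + thr.s0 / (abs(d_eff) - thr.min_log2_diff)
        significant = -math.log10(max(p, _TINY_P)) > curve
    if not significant:
        return "not_significant"
    return "up" if d_eff > 0 else "down"


def compare(
    matrix: IntensityMatrix,
    design: DesignSpec,
    comparison: tuple[str, str],
    thr: ThresholdSpec | None = None,
) -> pd.DataFrame:
    """Per-protein differential test for one condition pair (A vs B).

    Returns a DataFrame sorted by ``neg_log10_p`` descending with columns
    protein, difference (mean_A - mean_B, matrix log units), t, df, p,
    neg_log10_p, class, n_imputed_A, n_imputed_B.  The frame's ``attrs``
    carry the up/down/total summary counts.
    """
    thr = thr or ThresholdSpec()
    cond_a, cond_b = comparison
    samples_a = [s for s in design.samples_of(cond_a) if s in matrix.samples]
    samples_b = [s for s in design.samples_of(cond_b) if s in matrix.samples]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(f"conditions {cond_a!r}/{cond_b!r} need >= 2 samples each in the matrix")

    A = matrix.values[samples_a].to_numpy(dtype=float)
    B = matrix.values[samples_b].to_numpy(dtype=float)
    if np.isnan(A).any() or np.isnan(B).any():
        raise ValueError("matrix still contains missing values; impute first")
    na, nb = A.shape[1], B.shape[1]
    df_ = na + nb - 2
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    pooled_var = ((na - 1) * A.var(axis=1, ddof=1) + (nb - 1) * B.var(axis=1, ddof=1)) / df_
    diff = mean_a - mean_b
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # zero pooled variance: equal means -> t=0, p=1; unequal -> +/-inf, tiny p
    t = np.where((se == 0) & (diff == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_)
    p = np.clip(p, _TINY_P, 1.0)
    neg_log10_p = -np.log10(p)

    classes = [
        classify_significance(d_i, p_i, thr, matrix.log_base)
        for d_i, p_i in zip(diff, p)
    ]
    imput = matrix.imputed
    result = pd.DataFrame(
        {
            "protein": matrix.proteins,
            "difference": diff,
            "t": t,
            "df": df_,
            "p": p,
            "neg_log10_p": neg_log10_p,
            "class": classes,
            "n_imputed_A": imput[samples_a].sum(axis=1).to_numpy(),
            "n_imputed_B": imput[samples_b].sum(axis=1).to_numpy(),
        }
    )
    result = result.sort_values("neg_log10_p", ascending=False, kind="mergesort").reset_index(drop=True)
    result.attrs["comparison"] = {"A": cond_a, "B": cond_b}
    result.attrs["summary"] = {
        "n_proteins": len(result),
        "up": int((result["class"] == "up").sum()),
        "down": int((result["class"] == "down").sum()),
    }
    return result


def adjust_p(result: pd.DataFrame, method: str = "none") -> pd.DataFrame:
    """Optionally add Benjamini-Hochberg q-values (classification unchanged)."""
    if method == "none":
        return result
    if method != "benjamini_hochberg":
        raise ValueError(f"unknown method: {method!r}")
    out = result.copy()
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out.attrs.update(result.attrs)
    return out
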