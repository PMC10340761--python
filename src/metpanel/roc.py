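"""Direction-aware ROC analysis with DeLong confidence intervals and Youden
cutoffs.

Markers here have an a-priori direction fixed by modality rather than learned
from the data: a low expression value is the risk signal (``low_positive``,
event ``value <= cutoff``) and a high methylation value is the risk signal
(``high_positive``, event ``value > cutoff``).  All curves, AUCs and cutoffs
respect that orientation; the AUC is never silently flipped above 0.5.

The AUC equals the pairwise concordance probability (ties counted 1/2), its
variance comes from DeLong's structural components, and the operating cutoff
maximizes Youden's J = sensitivity + specificity - 1 over the observed marker
values, breaking ties toward higher specificity.  Cutoffs are reported as
observed data values with the direction-appropriate inequality ("<= v" for
expression, "> v" for methylation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import registry
from .registry import HIGH_POSITIVE, LOW_POSITIVE

__all__ = [
    "RocResult",
    "empirical_auc",
    "roc_points",
    "delong_ci",
    "youden_cutoff",
    "analyze_marker",
    "roc_summary",
]


@dataclass
class RocResult:
    """Full ROC analysis of one marker."""

    marker: str
    direction: str
    thresholds: np.ndarray = field(repr=False)
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    p_vs_half: float
    cutoff: float
    sensitivity: float  # percent, at the cutoff
    specificity: float  # percent, at the cutoff
    youden_j: float
    n_pos: int
    n_neg: int

    @property
    def cutoff_rule(self) -> str:
        op = "≤" if self.direction == LOW_POSITIVE else ">"
        return f"{op}{self.cutoff:g}"


def _check_inputs(values, outcome):
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcome)
    if v.shape != y.shape:
        raise ValueError("values and outcome must have the same length")
    y = y.astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("both outcome classes must be present")
    if not np.all(np.isfinite(v)):
        raise ValueError("marker values must be finite")
    return v, y.astype(bool)


def _orient(values: np.ndarray, direction: str) -> np.ndarray:
    """Map values to scores where *higher score = more metastasis-like*."""
    if direction == LOW_POSITIVE:
        return -values
    if direction == HIGH_POSITIVE:
        return values
    raise ValueError(f"unknown direction {direction!r}")


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def empirical_auc(values, outcome, direction: str = HIGH_POSITIVE) -> float:
    """Empirical AUC as the pairwise concordance probability (ties 1/2):
    the probability that a random positive sample scores higher than a random
    negative one, after orienting values by ``direction``."""
    v, pos = _check_inputs(values, outcome)
    s = _orient(v, direction)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = _midranks(s)
    u1 = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n1 * n0))


def roc_points(
    values, outcome, direction: str = HIGH_POSITIVE
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical ROC curve over all distinct observed thresholds.

    Returns ``(thresholds, fpr, tpr)`` ordered from the all-negative corner
    (0, 0) to the all-positive corner (1, 1); the two sentinel corners carry
    NaN thresholds.  The positive call at threshold t is ``value <= t``
    (low_positive) or ``value > t`` (high_positive).
    """
    v, pos = _check_inputs(values, outcome)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    uniq = np.unique(v)
    if direction == LOW_POSITIVE:
        thr = uniq  # increasing t: more samples called positive
        tpr = np.array([(v[pos] <= t).mean() for t in thr])
        fpr = np.array([(v[~pos] <= t).mean() for t in thr])
    elif direction == HIGH_POSITIVE:
        thr = uniq[::-1]  # decreasing t: more samples called positive
        tpr = np.array([(v[pos] > t).mean() for t in thr])
        fpr = np.array([(v[~pos] > t).mean() for t in thr])
    else:
        raise ValueError(f"unknown direction {direction!r}")
    thr = np.concatenate([[np.nan], thr, [np.nan]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    return thr, fpr, tpr


def delong_ci(
    values, outcome, direction: str = HIGH_POSITIVE, alpha: float = 0.05
) -> tuple[float, float, float, float]:
    """DeLong AUC inference: ``(auc, ci_low, ci_high, p_vs_half)``.

    The variance comes from the structural components of the Mann–Whitney
    kernel; the CI is the normal interval clipped to [0, 1] and the p-value a
    two-sided z-test of AUC = 0.5.  For a degenerate AUC of exactly 0 or 1
    the variance is zero; a warning is issued and the CI collapses.
    """
    v, pos = _check_inputs(values, outcome)
    s = _orient(v, direction)
    x, y = s[pos], s[~pos]  # positive / negative scores
    m, n = x.size, y.size
    tx = _midranks(x)
    ty = _midranks(y)
    tz = _midranks(np.concatenate([x, y]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n          # per-positive components
    v10 = 1.0 - (tz[m:] - ty) / m    # per-negative components
    var = (np.var(v01, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v10, ddof=1) / n if n > 1 else 0.0
    )
    se = float(np.sqrt(max(var, 0.0)))
    z = sps.norm.ppf(1 - alpha / 2)
    if se == 0.0:
        warnings.warn(
            f"degenerate AUC = {auc:g}: DeLong variance is zero, CI collapses"
        )
        lo = hi = float(np.clip(auc, 0.0, 1.0))
        p = 1.0 if auc == 0.5 else 0.0
        return float(auc), lo, hi, p
    lo = float(np.clip(auc - z * se, 0.0, 1.0))
    hi = float(np.clip(auc + z * se, 0.0, 1.0))
    p = float(2.0 * sps.norm.sf(abs(auc - 0.5) / se))
    return float(auc), lo, hi, p


def youden_cutoff(
    values, outcome, direction: str = HIGH_POSITIVE
) -> tuple[float, float, float, float]:
    """Cutoff maximizing Youden's J over the observed marker values.

    Returns ``(cutoff, sensitivity_pct, specificity_pct, j)``.  Ties in J are
    broken toward the higher-specificity operating point; the cutoff is always
    an observed value, and the positive call is ``value <= cutoff``
    (low_positive) or ``value > cutoff`` (high_positive).
    """
    v, pos = _check_inputs(values, outcome)
    uniq = np.unique(v)
    if direction == LOW_POSITIVE:
        sens = np.array([(v[pos] <= t).mean() for t in uniq])
        spec = np.array([(v[~pos] > t).mean() for t in uniq])
    elif direction == HIGH_POSITIVE:
        sens = np.array([(v[pos] > t).mean() for t in uniq])
        spec = np.array([(v[~pos] <= t).mean() for t in uniq])
    else:
        raise ValueError(f"unknown direction {direction!r}")
    j = sens + spec - 1.0
    best_j = j.max()
    candidates = np.flatnonzero(np.isclose(j, best_j, rtol=0, atol=1e-12))
    best = candidates[np.argmax(spec[candidates])]
    return (
        float(uniq[best]),
        float(100.0 * sens[best]),
        float(100.0 * spec[best]),
        float(j[best]),
    )


def analyze_marker(
    values, outcome, direction: str, marker: str = ""
) -> RocResult:
    """Complete ROC analysis of one marker: curve, DeLong AUC inference and
    Youden operating point."""
    v, pos = _check_inputs(values, outcome)
    thr, fpr, tpr = roc_points(v, pos, direction)
    auc, lo, hi, p = delong_ci(v, pos, direction)
    cutoff, sens, spec, j = youden_cutoff(v, pos, direction)
    return RocResult(
        marker=marker,
        direction=direction,
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        p_vs_half=p,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        youden_j=j,
        n_pos=int(pos.sum()),
        n_neg=int((~pos).sum()),
    )


def roc_summary(
    cohort: pd.DataFrame, directions: dict[str, str] | None = None
) -> tuple[pd.DataFrame, dict[str, RocResult]]:
    """ROC analysis of every marker column of a cohort table.

    ``directions`` overrides the modality defaults (expression low_positive,
    methylation high_positive).  Markers with missing values are analyzed on
    their complete cases.  Returns a summary table (one row per marker, in
    the layout of a per-marker ROC report: AUC, 95% CI, p vs 0.5, cutoff rule,
    sensitivity, specificity) together with the full per-marker results.
    """
    marker_cols = [c for c in cohort.columns if c not in ("sample_id", "outcome")]
    y = (cohort["outcome"] == "met").to_numpy(dtype=float)
    known = registry.modalities()
    results: dict[str, RocResult] = {}
    rows = []
    for marker in marker_cols:
        if directions is not None and marker in directions:
            direction = directions[marker]
        elif marker in known:
            direction = registry.default_direction(known[marker])
        else:
            raise KeyError(
                f"direction of marker {marker!r} unknown; pass it via `directions`"
            )
        v = pd.to_numeric(cohort[marker], errors="coerce").to_numpy(dtype=float)
        keep = np.isfinite(v)
        res = analyze_marker(v[keep], y[keep], direction, marker)
        results[marker] = res
        rows.append(
            {
                "marker": marker,
                "direction": direction,
                "auc": res.auc,
                "auc_ci_low": res.auc_ci_low,
                "auc_ci_high": res.auc_ci_high,
                "p_vs_half": res.p_vs_half,
                "cutoff": res.cutoff,
                "cutoff_rule": res.cutoff_rule,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
                "youden_j": res.youden_j,
                "n_met": res.n_pos,
                "n_nonmet": res.n_neg,
            }
        )
    return pd.DataFrame(rows), results
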