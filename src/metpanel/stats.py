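"""Per-marker association screening.

For every marker the screen reports the two group medians, a two-sided
Mann–Whitney U test (exact for small tie-free samples, normal approximation
with tie and continuity correction otherwise), the Benjamini–Hochberg adjusted
p-value, and the Wald p-value of a univariate logistic regression of
metastasis status on the marker.

Expression markers enter the logistic model on the log2(RQ) scale — fold
changes span orders of magnitude and the logistic fit, unlike rank tests, is
not invariant to monotone transforms — while methylation markers are fitted on
the raw percent scale.  BH adjustment is applied within marker families
(by default one family per modality, mirroring how the study grouped its
comparisons); rank tests and medians are unaffected by the transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from . import registry

__all__ = [
    "MannWhitneyResult",
    "LogisticFit",
    "mann_whitney",
    "bh_adjust",
    "logistic_univariate",
    "screen_markers",
]

#: Largest per-group size at which the exact U distribution is enumerated.
EXACT_MAX_N = 8

#: |slope| beyond which a converged logistic fit is treated as separated
#: (on the scales used here true slopes are O(1)).
SEPARATION_BETA = 50.0


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float  # U of the first group
    p_value: float
    method: str


@dataclass(frozen=True)
class LogisticFit:
    beta: float
    p_wald: float
    separated: bool


def mann_whitney(
    values_group1, values_group0, mode: str = "auto"
) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test; returns U of ``values_group1``.

    ``mode='auto'`` uses exact enumeration when both groups have at most
    ``EXACT_MAX_N`` observations and the pooled sample is tie-free, otherwise
    the normal approximation with tie correction and continuity correction.
    If every pooled value is identical the test is vacuous: U = n1*n0/2,
    p = 1, with a warning.
    """
    x1 = np.asarray(values_group1, dtype=float)
    x0 = np.asarray(values_group0, dtype=float)
    if x1.size == 0 or x0.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x1, x0])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; U test is vacuous")
        return MannWhitneyResult(x1.size * x0.size / 2.0, 1.0, "degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (min(x1.size, x0.size) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "normal_approx":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(
        x1, x0, alternative="two-sided", method=method, use_continuity=True
    )
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), method)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def logistic_univariate(values, outcome, log2_transform: bool = False) -> LogisticFit:
    """Univariate logistic regression of a binary outcome on one marker.

    Fits ``outcome ~ intercept + x`` by Newton/IRLS and returns the slope and
    its two-sided Wald p-value.  Complete (or quasi-complete) separation is
    detected and flagged instead of reporting a meaningless p-value.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes must be present")
    if not np.all(np.isfinite(x)):
        raise ValueError("marker values must be finite")
    if log2_transform:
        if np.any(x <= 0):
            raise ValueError("log2 transform requires positive values")
        x = np.log2(x)
    design = sm.add_constant(x)
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            result = sm.Logit(y, design).fit(disp=0, maxiter=200)
        beta = float(result.params[1])
        p = float(result.pvalues[1])
        if abs(beta) > SEPARATION_BETA or not result.mle_retvals.get("converged", True):
            separated = True
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        separated = True
        beta, p = np.nan, np.nan
    if separated:
        return LogisticFit(np.nan, np.nan, True)
    return LogisticFit(beta, p, False)


def _resolve_modalities(markers, modalities: Mapping[str, str] | None) -> dict[str, str]:
    known = registry.modalities()
    out = {}
    for m in markers:
        if modalities is not None and m in modalities:
            out[m] = modalities[m]
        elif m in known:
            out[m] = known[m]
        else:
            raise KeyError(
                f"modality of marker {m!r} is unknown; pass it via `modalities`"
            )
    return out


def screen_markers(
    cohort: pd.DataFrame,
    modalities: Mapping[str, str] | None = None,
    fdr_family: str = "by-modality",
    max_missing_fraction: float = 0.5,
) -> pd.DataFrame:
    """Screen every marker column of a cohort table for association with
    metastasis.

    Parameters
    ----------
    cohort
        Table with ``sample_id``, ``outcome`` (``met``/``nonmet``) and one
        numeric column per marker; NaN marker values are dropped pairwise.
    modalities
        Marker -> ``expression``/``methylation``; study markers are resolved
        automatically.
    fdr_family
        ``"by-modality"`` adjusts expression and methylation p-values as two
        separate BH families; ``"global"`` adjusts all markers together.
    max_missing_fraction
        Markers missing in more than this fraction of samples are excluded
        (with a warning).

    Returns
    -------
    DataFrame with one row per marker: medians, U, raw/adjusted Mann–Whitney
    p, logistic slope and Wald p (NaN + ``logit_separated`` flag when the fit
    separates), and group sizes.
    """
    if fdr_family not in ("by-modality", "global"):
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    marker_cols = [c for c in cohort.columns if c not in ("sample_id", "outcome")]
    if not marker_cols:
        raise ValueError("cohort has no marker columns")
    mods = _resolve_modalities(marker_cols, modalities)
    y_all = (cohort["outcome"] == "met").to_numpy(dtype=float)

    rows = []
    for marker in marker_cols:
        v = pd.to_numeric(cohort[marker], errors="coerce").to_numpy(dtype=float)
        keep = np.isfinite(v)
        if keep.mean() < 1.0 - max_missing_fraction:
            warnings.warn(
                f"marker {marker!r} excluded: "
                f"{100 * (1 - keep.mean()):.0f}% missing values"
            )
            continue
        v, y = v[keep], y_all[keep]
        met, nonmet = v[y == 1], v[y == 0]
        mw = mann_whitney(met, nonmet)
        fit = logistic_univariate(v, y, log2_transform=mods[marker] == "expression")
        rows.append(
            {
                "marker": marker,
                "modality": mods[marker],
                "n_met": int(met.size),
                "n_nonmet": int(nonmet.size),
                "median_met": float(np.median(met)),
                "median_nonmet": float(np.median(nonmet)),
                "u_statistic": mw.u_statistic,
                "p_mw_raw": mw.p_value,
                "logit_beta": fit.beta,
                "p_logit": fit.p_wald,
                "logit_separated": fit.separated,
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        raise ValueError("no marker passed the missingness filter")
    result["p_mw_adjusted"] = np.nan
    if fdr_family == "global":
        result["p_mw_adjusted"] = bh_adjust(result["p_mw_raw"])
    else:
        for _, idx in result.groupby("modality").groups.items():
            result.loc[idx, "p_mw_adjusted"] = bh_adjust(result.loc[idx, "p_mw_raw"])
    cols = [
        "marker", "modality", "n_met", "n_nonmet", "median_nonmet", "median_met",
        "u_statistic", "p_mw_raw", "p_mw_adjusted", "logit_beta", "p_logit",
        "logit_separated",
    ]
    return result[cols]
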