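"""Count-rule marker panels — the core classifier of the package.

Each marker is binarized into an *event* at its cutoff: an expression marker
fires when its RQ is at or below the cutoff (expression loss), a methylation
marker when its MI is strictly above the cutoff (hypermethylation).  A sample
is called high metastatic potential when at least ``k`` of the panel's ``m``
events fire.  The three built-in panels mirror the study's rules:

* ``expression``  — CA9, NDUFA4L2, EGLN3, BHLHE41; k = 3 of 4
* ``methylation`` — MIR125B-1, MIR137, MIR375, MIR193A, MIR34B/C; k = 4 of 5
* ``combined``    — all nine markers; k = 6 of 9

Performance is reported as a full confusion matrix with sensitivity,
specificity, PPV and NPV (exact Clopper–Pearson 95% CIs), plus the AUC of the
raw event count used as an ordinal score.  :func:`reconstruct_confusion`
inverts published sensitivity/specificity percentages back to integer counts,
which lets published panel characteristics be checked for internal
consistency and lets their predictive values be recomputed from group sizes.

:class:`CountRulePanelClassifier` wraps the same rule as a scikit-learn
estimator whose ``fit`` learns per-marker Youden cutoffs from training data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from statsmodels.stats.proportion import proportion_confint

from . import registry, roc
from .errors import InconsistencyError
from .registry import HIGH_POSITIVE, LOW_POSITIVE

__all__ = [
    "PanelMarker",
    "PanelDefinition",
    "PanelPerformance",
    "builtin_panels",
    "call_events",
    "classify_count_rule",
    "panel_performance",
    "reconstruct_confusion",
    "round_half_up",
    "CountRulePanelClassifier",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` decimals (the convention
    of the published tables), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PanelMarker:
    name: str
    direction: str  # low_positive / high_positive
    cutoff: float

    def fires(self, value: float) -> bool:
        if self.direction == LOW_POSITIVE:
            return value <= self.cutoff
        if self.direction == HIGH_POSITIVE:
            return value > self.cutoff
        raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class PanelDefinition:
    """A k-of-m count-rule panel: ordered markers with their event cutoffs and
    the event-count threshold for a positive call."""

    name: str
    markers: tuple[PanelMarker, ...]
    k_events: int

    def __post_init__(self) -> None:
        if not 1 <= self.k_events <= len(self.markers):
            raise ValueError(
                f"panel {self.name!r}: k_events={self.k_events} outside "
                f"1..{len(self.markers)}"
            )
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError(f"panel {self.name!r}: duplicate markers")


_BUILTIN_RULES = {
    "expression": (registry.EXPRESSION_PANEL_MARKERS, 3),
    "methylation": (registry.METHYLATION_PANEL_MARKERS, 4),
    "combined": (registry.COMBINED_PANEL_MARKERS, 6),
}


def builtin_panels(cutoffs: Mapping[str, float] | None = None) -> dict[str, PanelDefinition]:
    """The three study panels.  ``cutoffs`` maps marker name to cutoff;
    by default the published per-marker cutoffs are used."""
    cutoffs = dict(cutoffs) if cutoffs is not None else registry.published_cutoffs()
    mods = registry.modalities()
    panels = {}
    for panel_name, (members, k) in _BUILTIN_RULES.items():
        markers = tuple(
            PanelMarker(m, registry.default_direction(mods[m]), cutoffs[m])
            for m in members
        )
        panels[panel_name] = PanelDefinition(panel_name, markers, k)
    return panels


def call_events(
    cohort: pd.DataFrame, panel: PanelDefinition
) -> tuple[pd.DataFrame, int]:
    """Binary event matrix for a panel over a cohort.

    Returns ``(events, n_excluded)``: one row per sample with complete data on
    all panel markers (index = sample_id, one 0/1 column per marker, plus the
    retained ``outcome`` if the cohort has one); samples missing any panel
    marker are excluded and counted.
    """
    absent = [m.name for m in panel.markers if m.name not in cohort.columns]
    if absent:
        raise KeyError(f"panel {panel.name!r}: markers absent from cohort: {absent}")
    values = cohort[[m.name for m in panel.markers]].apply(pd.to_numeric, errors="coerce")
    complete = values.notna().all(axis=1)
    n_excluded = int((~complete).sum())
    sub = values[complete]
    events = pd.DataFrame(index=cohort.loc[complete, "sample_id"])
    for m in panel.markers:
        col = sub[m.name].to_numpy(dtype=float)
        events[m.name] = (
            (col <= m.cutoff) if m.direction == LOW_POSITIVE else (col > m.cutoff)
        ).astype(int)
    if "outcome" in cohort.columns:
        events["outcome"] = cohort.loc[complete, "outcome"].to_numpy()
    return events, n_excluded


def classify_count_rule(
    events: pd.DataFrame | np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the k-of-m rule to an event matrix.

    Returns ``(predictions, counts)``: the binary high-risk call
    (row event count >= k) and the raw event count as an ordinal score.
    """
    if isinstance(events, pd.DataFrame):
        mat = events.drop(columns=["outcome"], errors="ignore").to_numpy()
    else:
        mat = np.asarray(events)
    if mat.ndim != 2:
        raise ValueError("event matrix must be 2-D")
    if not np.isin(mat, (0, 1)).all():
        raise ValueError("event matrix must be binary")
    m = mat.shape[1]
    if not 1 <= k <= m:
        raise ValueError(f"k={k} outside 1..{m}")
    counts = mat.sum(axis=1).astype(int)
    return (counts >= k).astype(int), counts


def _rate_ci(count: int, nobs: int) -> tuple[float, float, float]:
    """Percent rate with exact Clopper–Pearson 95% CI; NaNs when undefined."""
    if nobs == 0:
        return math.nan, math.nan, math.nan
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="beta")
    return 100.0 * count / nobs, 100.0 * float(lo), 100.0 * float(hi)


@dataclass(frozen=True)
class PanelPerformance:
    """Diagnostic performance of a count-rule panel; rates in percent with
    exact (Clopper–Pearson) 95% CIs, NaN where a denominator is empty."""

    panel: str
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]
    auc_count_score: float
    n_excluded_missing: int = 0

    def to_dict(self) -> dict:
        d = {
            "panel": self.panel,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "auc_count_score": self.auc_count_score,
            "n_excluded_missing": self.n_excluded_missing,
        }
        for rate in ("sensitivity", "specificity", "ppv", "npv"):
            d[rate] = getattr(self, rate)
            d[f"{rate}_ci_low"], d[f"{rate}_ci_high"] = getattr(self, f"{rate}_ci")
        return d


def panel_performance(
    predictions,
    count_scores,
    outcome,
    panel: str = "",
    n_excluded_missing: int = 0,
) -> PanelPerformance:
    """Confusion counts and diagnostic rates of a panel's calls.

    ``outcome`` is 0/1 (1 = metastatic) or ``met``/``nonmet`` strings.  The
    AUC of the ordinal event count (concordance over thresholds 0..m) is
    reported alongside the binary rule's operating point.
    """
    pred = np.asarray(predictions, dtype=int)
    counts = np.asarray(count_scores, dtype=float)
    y = np.asarray(outcome)
    if y.dtype.kind in "OU":
        y = (y == "met").astype(int)
    y = y.astype(int)
    if pred.shape != y.shape or counts.shape != y.shape:
        raise ValueError("predictions, count_scores and outcome must align")
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("both outcome classes must be present")
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = _rate_ci(tp, tp + fn)
    spec = _rate_ci(tn, tn + fp)
    ppv = _rate_ci(tp, tp + fp)
    npv = _rate_ci(tn, tn + fn)
    auc = roc.empirical_auc(counts, y, HIGH_POSITIVE)
    return PanelPerformance(
        panel=panel,
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens[0], sensitivity_ci=(sens[1], sens[2]),
        specificity=spec[0], specificity_ci=(spec[1], spec[2]),
        ppv=ppv[0], ppv_ci=(ppv[1], ppv[2]),
        npv=npv[0], npv_ci=(npv[1], npv[2]),
        auc_count_score=auc,
        n_excluded_missing=n_excluded_missing,
    )


def reconstruct_confusion(
    sens_pct: float, spec_pct: float, n_pos: int, n_neg: int
) -> tuple[int, int, int, int]:
    """Invert published sensitivity/specificity percentages to integer
    confusion counts ``(tp, fp, tn, fn)`` given the group sizes.

    ``tp = round(sens * n_pos / 100)`` and ``tn = round(spec * n_neg / 100)``
    (half-up); the reconstruction must round back (half-up, 2 decimals) to the
    stated percentages, otherwise the published numbers are internally
    inconsistent and :class:`InconsistencyError` is raised.
    """
    if not (0 <= sens_pct <= 100 and 0 <= spec_pct <= 100):
        raise ValueError("percentages must be in [0, 100]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("group sizes must be >= 1")
    tp = int(round_half_up(sens_pct * n_pos / 100.0))
    tn = int(round_half_up(spec_pct * n_neg / 100.0))
    fn, fp = n_pos - tp, n_neg - tn
    sens_back = round_half_up(100.0 * tp / n_pos, 2)
    spec_back = round_half_up(100.0 * tn / n_neg, 2)
    if sens_back != round_half_up(sens_pct, 2) or spec_back != round_half_up(spec_pct, 2):
        raise InconsistencyError(
            f"stated sens/spec {sens_pct}/{spec_pct} do not round-trip: "
            f"reconstruction gives {sens_back}/{spec_back} at n={n_pos}/{n_neg}"
        )
    return tp, fp, tn, fn


class CountRulePanelClassifier(ClassifierMixin, BaseEstimator):
    """k-of-m count-rule panel as a scikit-learn classifier.

    ``fit`` binarizes each marker at a cutoff — learned from the training data
    by maximizing Youden's J, or fixed via ``cutoffs`` — and ``predict`` calls
    a sample positive when at least ``k`` marker events fire.
    ``decision_function`` returns the raw event count (0..m).

    Parameters
    ----------
    markers : sequence of str, optional
        Marker columns to use; default: every feature seen in ``fit``.
    directions : mapping marker -> {"low_positive", "high_positive"}, optional
        Event direction per marker.  Markers of the study registry default to
        their modality's direction (expression low, methylation high);
        any other marker must be listed here.
    cutoffs : "auto" or mapping marker -> float
        ``"auto"`` learns Youden cutoffs from the training data; a mapping
        fixes them (e.g. the published values).
    k : int, optional
        Event-count threshold; default ``floor(m/2) + 1`` (a majority).
    pos_label : optional
        Label of the metastatic class; default: ``"met"`` if present in ``y``,
        else the larger class label.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels.
    cutoffs_ : dict
        Per-marker cutoff in effect after ``fit``.
    directions_ : dict
        Per-marker event direction in effect after ``fit``.
    k_ : int
        Event-count threshold in effect.
    """

    def __init__(
        self,
        markers: Sequence[str] | None = None,
        directions: Mapping[str, str] | None = None,
        cutoffs: str | Mapping[str, float] = "auto",
        k: int | None = None,
        pos_label=None,
    ):
        self.markers = markers
        self.directions = directions
        self.cutoffs = cutoffs
        self.k = k
        self.pos_label = pos_label

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

    def fit(self, X, y):
        frame = self._as_frame(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("CountRulePanelClassifier requires exactly two classes")
        if self.pos_label is not None:
            if self.pos_label not in self.classes_:
                raise ValueError(f"pos_label {self.pos_label!r} not among classes")
            self.pos_label_ = self.pos_label
        elif "met" in self.classes_:
            self.pos_label_ = "met"
        else:
            self.pos_label_ = self.classes_[-1]
        y01 = (y == self.pos_label_).astype(float)

        markers = list(self.markers) if self.markers is not None else list(frame.columns)
        absent = [m for m in markers if m not in frame.columns]
        if absent:
            raise KeyError(f"markers absent from X: {absent}")
        known = registry.modalities()
        directions = {}
        for m in markers:
            if self.directions is not None and m in self.directions:
                directions[m] = self.directions[m]
            elif m in known:
                directions[m] = registry.default_direction(known[m])
            else:
                raise KeyError(
                    f"direction of marker {m!r} unknown; pass it via `directions`"
                )
        if isinstance(self.cutoffs, str):
            if self.cutoffs != "auto":
                raise ValueError(f"cutoffs must be 'auto' or a mapping, got {self.cutoffs!r}")
            cutoffs = {}
            for m in markers:
                v = frame[m].to_numpy(dtype=float)
                cutoffs[m], _, _, _ = roc.youden_cutoff(v, y01, directions[m])
        else:
            missing = [m for m in markers if m not in self.cutoffs]
            if missing:
                raise KeyError(f"no cutoff provided for markers: {missing}")
            cutoffs = {m: float(self.cutoffs[m]) for m in markers}

        self.markers_ = markers
        self.directions_ = directions
        self.cutoffs_ = cutoffs
        self.k_ = self.k if self.k is not None else len(markers) // 2 + 1
        if not 1 <= self.k_ <= len(markers):
            raise ValueError(f"k={self.k_} outside 1..{len(markers)}")
        self.n_features_in_ = frame.shape[1]
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        return self

    def _events(self, X) -> np.ndarray:
        frame = self._as_frame(X)
        absent = [m for m in self.markers_ if m not in frame.columns]
        if absent:
            raise KeyError(f"markers absent from X: {absent}")
        cols = []
        for m in self.markers_:
            v = frame[m].to_numpy(dtype=float)
            fires = (
                v <= self.cutoffs_[m]
                if self.directions_[m] == LOW_POSITIVE
                else v > self.cutoffs_[m]
            )
            cols.append(fires.astype(int))
        return np.column_stack(cols)

    def decision_function(self, X) -> np.ndarray:
        """Event count per sample (0..m); higher = more metastasis-like."""
        self._check_fitted()
        return self._events(X).sum(axis=1)

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        positive = self.decision_function(X) >= self.k_
        neg_label = self.classes_[self.classes_ != self.pos_label_][0]
        return np.where(positive, self.pos_label_, neg_label)

    def _check_fitted(self) -> None:
        if not hasattr(self, "cutoffs_"):
            raise RuntimeError("classifier is not fitted; call fit() first")
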