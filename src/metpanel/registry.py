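"""Reference values for the ccRCC metastasis marker study that this package models.

The study cohort comprised 80 paired tumor/normal kidney tissue samples from
clear cell renal cell carcinoma (ccRCC) patients, 31 with distant metastases at
surgery and 49 without.  Two marker families were assayed in every tumor:

* relative mRNA expression (RQ, tumor vs. paired normal, GAPDH-normalized) of
  four protein-coding HIF1-target genes — CA9, NDUFA4L2, EGLN3, BHLHE41 —
  whose expression drops in metastatic tumors, and
* promoter methylation index (MI, percent methylation from quantitative
  methylation-specific PCR) of nine miRNA genes, of which MIR125B-1, MIR137,
  MIR375, MIR193A and MIR34B/C are hypermethylated in metastatic tumors.

This module holds the published per-group medians, single-marker ROC AUCs and
optimal cutoffs, and the cohort demographics, plus the calibration helpers the
synthetic-cohort generator uses to turn (median, AUC) pairs into distribution
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError

EXPRESSION = "expression"
METHYLATION = "methylation"

#: Direction of a marker "event": expression markers fire when the value is at
#: or below the cutoff (low_positive), methylation markers when strictly above
#: it (high_positive).
LOW_POSITIVE = "low_positive"
HIGH_POSITIVE = "high_positive"


@dataclass(frozen=True)
class StudyMarker:
    """Published summary statistics for one marker in the study cohort.

    ``auc``/``cutoff`` are ``None`` for markers that did not reach the
    AUC > 0.7 screening bar and therefore have no published ROC row.
    """

    name: str
    modality: str
    median_nonmet: float
    median_met: float
    auc: float | None = None
    cutoff: float | None = None


STUDY_MARKERS: tuple[StudyMarker, ...] = (
    StudyMarker("CA9", EXPRESSION, 92.7, 17.8, 0.789, 51.3),
    StudyMarker("NDUFA4L2", EXPRESSION, 41.1, 6.5, 0.753, 22.0),
    StudyMarker("EGLN3", EXPRESSION, 11.4, 2.8, 0.818, 4.2),
    StudyMarker("BHLHE41", EXPRESSION, 3.2, 1.6, 0.751, 2.6),
    StudyMarker("MIR125B-1", METHYLATION, 36.27, 66.34, 0.827, 55.18),
    StudyMarker("MIR137", METHYLATION, 38.10, 61.84, 0.716, 57.62),
    StudyMarker("MIR375", METHYLATION, 38.99, 66.19, 0.706, 64.29),
    StudyMarker("MIR193A", METHYLATION, 38.99, 67.58, 0.776, 34.65),
    StudyMarker("MIR34B/C", METHYLATION, 35.26, 59.23, 0.732, 50.35),
    StudyMarker("MIR1258", METHYLATION, 2.97, 5.19, 0.644, 7.15),
    StudyMarker("MIR107", METHYLATION, 1.62, 2.57),
    StudyMarker("MIR203A", METHYLATION, 3.11, 3.42),
    StudyMarker("MIR132", METHYLATION, 2.9, 4.17),
)

#: Members of the three built-in count-rule panels, in panel order.
EXPRESSION_PANEL_MARKERS = ("CA9", "NDUFA4L2", "EGLN3", "BHLHE41")
METHYLATION_PANEL_MARKERS = ("MIR125B-1", "MIR137", "MIR375", "MIR193A", "MIR34B/C")
COMBINED_PANEL_MARKERS = EXPRESSION_PANEL_MARKERS + METHYLATION_PANEL_MARKERS

STUDY_N_MET = 31
STUDY_N_NONMET = 49


@dataclass(frozen=True)
class PublishedPanel:
    """Published operating characteristics of one count-rule panel on the
    study cohort (percent sensitivity/specificity of the binary rule, and the
    panel AUC as printed)."""

    sensitivity: float
    specificity: float
    auc: float


PUBLISHED_PANELS: dict[str, PublishedPanel] = {
    "expression": PublishedPanel(74.19, 79.59, 0.769),
    "methylation": PublishedPanel(70.97, 81.63, 0.763),
    "combined": PublishedPanel(87.10, 95.92, 0.915),
}

#: Markers without a published ROC row get this modest separability when
#: simulated; it corresponds to the non-significant rank-sum tests they showed
#: at n = 31/49.
DEFAULT_WEAK_AUC = 0.60


@dataclass(frozen=True)
class StudyGroup:
    """Demographics of one outcome group of the study cohort."""

    n: int
    n_male: int
    n_female: int
    mean_age: float
    sd_age: float


STUDY_GROUPS: dict[str, StudyGroup] = {
    "met": StudyGroup(n=31, n_male=16, n_female=15, mean_age=59.3, sd_age=7.7),
    "nonmet": StudyGroup(n=49, n_male=31, n_female=18, mean_age=61.3, sd_age=8.9),
}


def overall_male_percent() -> float:
    """Percentage of male patients across both outcome groups."""
    n_male = sum(g.n_male for g in STUDY_GROUPS.values())
    n = sum(g.n for g in STUDY_GROUPS.values())
    return 100.0 * n_male / n


def overall_mean_age() -> float:
    """Size-weighted mean of the per-group mean ages, in years."""
    n = sum(g.n for g in STUDY_GROUPS.values())
    return sum(g.n * g.mean_age for g in STUDY_GROUPS.values()) / n


def marker_by_name(name: str) -> StudyMarker:
    for m in STUDY_MARKERS:
        if m.name == name:
            return m
    raise KeyError(f"unknown study marker {name!r}")


@lru_cache(maxsize=1)
def modalities() -> dict[str, str]:
    """Mapping marker name -> modality for all study markers."""
    return {m.name: m.modality for m in STUDY_MARKERS}


def default_direction(modality: str) -> str:
    """Event direction implied by a modality (expression low, methylation high)."""
    if modality == EXPRESSION:
        return LOW_POSITIVE
    if modality == METHYLATION:
        return HIGH_POSITIVE
    raise ValueError(f"unknown modality {modality!r}")


def published_cutoffs() -> dict[str, float]:
    """Published optimal cutoff per marker (markers with a ROC row only)."""
    return {m.name: m.cutoff for m in STUDY_MARKERS if m.cutoff is not None}


# ---------------------------------------------------------------------------
# Dispersion calibration.
#
# The study reports per-group medians and single-marker AUCs but no spread, so
# the simulator's dispersion defaults are solved so that the *theoretical* AUC
# between the two group distributions equals the published AUC.
# ---------------------------------------------------------------------------


def lognormal_sigma_for_auc(median0: float, median1: float, auc: float) -> float:
    """Log-scale (natural log) s.d. giving the target AUC between two
    log-normal groups with the given medians and a common sigma.

    For X_g = exp(mu_g + sigma * Z), AUC = Phi(|mu_1 - mu_0| / (sigma*sqrt(2))).
    """
    if not 0.5 < auc < 1.0:
        raise ConfigurationError(f"target AUC must be in (0.5, 1), got {auc}")
    if median0 <= 0 or median1 <= 0:
        raise ConfigurationError("log-normal medians must be positive")
    delta = abs(math.log(median1) - math.log(median0))
    return delta / (math.sqrt(2.0) * stats.norm.ppf(auc))


def beta_shape_for_median(median_pct: float, concentration: float) -> float:
    """First shape parameter ``a`` of Beta(a, concentration - a) whose median
    equals ``median_pct / 100``, found by root bisection."""
    if not 0.0 < median_pct < 100.0:
        raise ConfigurationError(
            f"methylation median must lie strictly inside (0, 100), got {median_pct}"
        )
    p = median_pct / 100.0
    lo, hi = 1e-8 * concentration, (1 - 1e-8) * concentration

    def f(a: float) -> float:
        return stats.beta.median(a, concentration - a) - p

    return optimize.brentq(f, lo, hi, xtol=1e-12)


def _beta_pair_auc(median_nonmet: float, median_met: float, concentration: float) -> float:
    """P(X_met > X_nonmet) for median-matched Beta groups sharing a concentration.

    Computed in quantile form, AUC = E_u[ F_nonmet(Q_met(u)) ], by fixed-order
    Gauss-Legendre quadrature — the integrand is smooth on (0, 1) even for
    sharply concentrated shapes.
    """
    a0 = beta_shape_for_median(median_nonmet, concentration)
    a1 = beta_shape_for_median(median_met, concentration)
    d0 = stats.beta(a0, concentration - a0)
    d1 = stats.beta(a1, concentration - a1)
    nodes, weights = np.polynomial.legendre.leggauss(256)
    u = 0.5 * (nodes + 1.0)
    return float(0.5 * np.sum(weights * d0.cdf(d1.ppf(u))))


def beta_concentration_for_auc(
    median_nonmet: float, median_met: float, auc: float
) -> float:
    """Common Beta concentration (a + b) giving the target AUC between the
    methylation groups, found by root bisection.

    The target is always expressed as the direction-aware AUC (> 0.5); for
    methylation markers the metastatic group has the higher median.
    """
    if not 0.5 < auc < 1.0:
        raise ConfigurationError(f"target AUC must be in (0.5, 1), got {auc}")
    if median_met < median_nonmet:
        median_nonmet, median_met = median_met, median_nonmet

    def f(kappa: float) -> float:
        return _beta_pair_auc(median_nonmet, median_met, kappa) - auc

    return optimize.brentq(f, 0.05, 5000.0, xtol=1e-6)


def calibrated_dispersion(marker: StudyMarker) -> float:
    """Default simulator dispersion for a study marker.

    Log-scale s.d. for expression markers, Beta concentration for methylation
    markers, chosen so the theoretical group-separation AUC matches the
    published one (or :data:`DEFAULT_WEAK_AUC` when none was published).
    """
    target = marker.auc if marker.auc is not None else DEFAULT_WEAK_AUC
    if marker.modality == EXPRESSION:
        return lognormal_sigma_for_auc(marker.median_nonmet, marker.median_met, target)
    return beta_concentration_for_auc(marker.median_nonmet, marker.median_met, target)
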