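"""Synthetic cohort generator.

The per-sample measurements of the ccRCC study are not publicly deposited, so
this module generates cohorts whose group structure matches the published
summary statistics: 31 metastatic and 49 non-metastatic samples, per-group
medians as published for every marker, and dispersions calibrated so that each
marker's theoretical single-marker AUC matches its published value (see
:mod:`metpanel.registry`).

Distributions
-------------
* Expression (RQ, fold change > 0): log-normal, parameterized by the group
  median (``exp`` of the log-mean) and a common log-scale s.d. — medians, not
  means, are what the study reports.
* Methylation (MI, percent in [0, 100]): Beta rescaled to [0, 100] with a
  common concentration ``a + b`` per marker; the first shape parameter is
  solved numerically per group so the distribution median equals the target.

Determinism: one global seed; each marker draws from a substream derived
deterministically from ``(seed, marker name)``, so adding or removing a marker
never perturbs the values of the others.

The generator can also emit raw Ct tables (:func:`simulate_ct_tables`) that
invert the quantification equations exactly, giving the quantification module
a round-trip oracle.
"""

from __future__ import annotations

import hashlib
import math
from functools import lru_cache
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import registry
from .errors import ConfigurationError

__all__ = [
    "MarkerSimSpec",
    "SimulationConfig",
    "study_marker_specs",
    "simulate_cohort",
    "simulate_ct_tables",
]

#: Fixed Ct anchors for the raw-Ct inversion; only Ct differences enter the
#: quantification equations, so these are arbitrary.
CT_REF = 20.0
CT_TARGET_NORMAL = 24.0
CT_METH_BASE = 25.0


class MarkerSimSpec(BaseModel):
    """Simulation parameters for a single marker.

    ``dispersion`` is the log-scale (natural log) standard deviation for
    expression markers and the Beta concentration (a + b) for methylation
    markers.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    modality: Literal["expression", "methylation"]
    median_nonmet: float
    median_met: float
    dispersion: float

    @model_validator(mode="after")
    def _check_ranges(self) -> "MarkerSimSpec":
        if self.dispersion <= 0:
            raise ValueError(f"marker {self.name!r}: dispersion must be > 0")
        if self.modality == "expression":
            if self.median_nonmet <= 0 or self.median_met <= 0:
                raise ValueError(
                    f"marker {self.name!r}: expression medians must be > 0"
                )
        else:
            for v in (self.median_nonmet, self.median_met):
                if not 0.0 <= v <= 100.0:
                    raise ValueError(
                        f"marker {self.name!r}: methylation medians must be in [0, 100]"
                    )
        return self


@lru_cache(maxsize=1)
def _study_marker_specs_cached() -> tuple[MarkerSimSpec, ...]:
    return tuple(
        MarkerSimSpec(
            name=m.name,
            modality=m.modality,
            median_nonmet=m.median_nonmet,
            median_met=m.median_met,
            dispersion=registry.calibrated_dispersion(m),
        )
        for m in registry.STUDY_MARKERS
    )


def study_marker_specs() -> tuple[MarkerSimSpec, ...]:
    """Default simulation specs: all 13 study markers at published medians,
    dispersions calibrated to the published single-marker AUCs."""
    return _study_marker_specs_cached()


class SimulationConfig(BaseModel):
    """Full description of a synthetic cohort; the seed determines the output."""

    model_config = ConfigDict(frozen=True)

    n_metastatic: int = Field(default=registry.STUDY_N_MET, ge=1)
    n_nonmetastatic: int = Field(default=registry.STUDY_N_NONMET, ge=1)
    markers: tuple[MarkerSimSpec, ...] = Field(default_factory=study_marker_specs)
    seed: int = Field(default=0, ge=0)
    emit_raw_ct: bool = False

    @field_validator("markers")
    @classmethod
    def _unique_names(cls, v: tuple[MarkerSimSpec, ...]) -> tuple[MarkerSimSpec, ...]:
        names = [m.name for m in v]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        if not names:
            raise ValueError("at least one marker is required")
        return v


def _marker_rng(seed: int, name: str) -> np.random.Generator:
    # Substream keyed on (seed, sha256(name)); stable across sessions, unlike
    # the builtin hash().
    digest = int.from_bytes(hashlib.sha256(name.encode()).digest()[:8], "little")
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, digest])))


def _draw_group(spec: MarkerSimSpec, n: int, rng: np.random.Generator, group: str) -> np.ndarray:
    median = spec.median_met if group == "met" else spec.median_nonmet
    if spec.modality == "expression":
        return rng.lognormal(mean=math.log(median), sigma=spec.dispersion, size=n)
    if not 0.0 < median < 100.0:
        raise ConfigurationError(
            f"marker {spec.name!r}: cannot simulate a methylation marker with a "
            f"boundary median ({median}); the Beta family degenerates there"
        )
    a = registry.beta_shape_for_median(median, spec.dispersion)
    return 100.0 * rng.beta(a, spec.dispersion - a, size=n)


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a cohort table: one row per sample, columns ``sample_id``,
    ``outcome`` (``met`` / ``nonmet``) and one column per marker.

    Metastatic samples come first.  Identical configs (including seed) give
    identical tables.
    """
    n1, n0 = config.n_metastatic, config.n_nonmetastatic
    n = n1 + n0
    out = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:03d}" for i in range(n)],
            "outcome": ["met"] * n1 + ["nonmet"] * n0,
        }
    )
    for spec in config.markers:
        rng = _marker_rng(config.seed, spec.name)
        met = _draw_group(spec, n1, rng, "met")
        nonmet = _draw_group(spec, n0, rng, "nonmet")
        out[spec.name] = np.concatenate([met, nonmet])
    return out


def _expression_ct_rows(sample_id: str, assay: str, rq: float) -> list[dict]:
    ddct = -math.log2(rq)
    return [
        {"sample_id": sample_id, "assay": assay, "reaction": "target_tumor",
         "ct": CT_TARGET_NORMAL + ddct},
        {"sample_id": sample_id, "assay": assay, "reaction": "ref_tumor", "ct": CT_REF},
        {"sample_id": sample_id, "assay": assay, "reaction": "target_normal",
         "ct": CT_TARGET_NORMAL},
        {"sample_id": sample_id, "assay": assay, "reaction": "ref_normal", "ct": CT_REF},
    ]


def _methylation_ct_rows(sample_id: str, assay: str, mi: float) -> list[dict]:
    # MI = 100 * 2^-CtM / (2^-CtM + 2^-CtU)  =>  CtU - CtM = log2(MI / (100 - MI)).
    # The stronger reaction is anchored at CT_METH_BASE; a boundary MI means the
    # other reaction never amplified ("undetermined", stored as NaN).
    if mi <= 0.0:
        ct_m, ct_u = math.nan, CT_METH_BASE
    elif mi >= 100.0:
        ct_m, ct_u = CT_METH_BASE, math.nan
    else:
        d = math.log2(mi / (100.0 - mi))
        if d >= 0:
            ct_m, ct_u = CT_METH_BASE, CT_METH_BASE + d
        else:
            ct_m, ct_u = CT_METH_BASE - d, CT_METH_BASE
    return [
        {"sample_id": sample_id, "assay": assay, "reaction": "meth", "ct": ct_m},
        {"sample_id": sample_id, "assay": assay, "reaction": "unmeth", "ct": ct_u},
    ]


def simulate_ct_tables(config: SimulationConfig) -> pd.DataFrame:
    """Emit a long-format raw Ct table that the quantification module maps back
    to exactly the cohort of :func:`simulate_cohort` (same config).

    For expression markers the four-reaction quadruple encodes the simulated RQ
    through the comparative-Ct identity; for methylation markers the M/U pair
    encodes the simulated MI.  The ACTB unconverted-template control is emitted
    as "no amplification" (NaN Ct) for every sample, i.e. conversion QC passes.

    Requires ``config.emit_raw_ct``.
    """
    if not config.emit_raw_ct:
        raise ConfigurationError("simulate_ct_tables requires emit_raw_ct=True")
    cohort = simulate_cohort(config)
    rows: list[dict] = []
    for _, sample in cohort.iterrows():
        sid = sample["sample_id"]
        for spec in config.markers:
            value = float(sample[spec.name])
            if spec.modality == "expression":
                rows.extend(_expression_ct_rows(sid, spec.name, value))
            else:
                rows.extend(_methylation_ct_rows(sid, spec.name, value))
        rows.append(
            {"sample_id": sid, "assay": "ACTB", "reaction": "actb_unconverted",
             "ct": math.nan}
        )
    return pd.DataFrame(rows, columns=["sample_id", "assay", "reaction", "ct"])
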