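"""Table I/O and the end-to-end pipeline.

All data exchange is CSV/TSV.  Cohort tables are wide (``sample_id``,
``outcome``, one numeric column per marker; ``NA`` for missing).  Raw Ct
tables are long (``sample_id, assay, reaction, ct``) with the reserved token
``Undetermined`` for reactions that never crossed threshold.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import panel as panel_mod
from . import quantify as quantify_mod
from . import roc as roc_mod
from . import stats as stats_mod
from .errors import ConfigurationError, DataValidationError
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger("metpanel")

UNDETERMINED_TOKEN = "Undetermined"
_NA_TOKENS = {"", "na", "nan", "n/a"}

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_ct_table",
    "write_ct_table",
    "RunConfig",
    "run_full_pipeline",
]


def _parse_numeric_column(col: pd.Series, name: str, path) -> pd.Series:
    raw = col.astype(object)
    out = pd.to_numeric(col, errors="coerce")
    for i, (orig, parsed) in enumerate(zip(raw, out)):
        if pd.isna(parsed) and not (
            pd.isna(orig) or str(orig).strip().lower() in _NA_TOKENS
        ):
            raise DataValidationError(
                f"{path}: unparseable value {orig!r} in column {name!r}, row {i}"
            )
    return out


def read_cohort(
    path,
    positive_label: str = "met",
    negative_label: str = "nonmet",
) -> pd.DataFrame:
    """Read and validate a wide cohort CSV.

    Requires ``sample_id`` and ``outcome`` columns; outcome labels are mapped
    onto the canonical ``met``/``nonmet``.  Duplicate sample ids and
    unparseable numerics raise :class:`DataValidationError`; ``NA`` tokens
    become missing values.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    for col in ("sample_id", "outcome"):
        if col not in df.columns:
            raise DataValidationError(f"{path}: missing required column {col!r}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise DataValidationError(
            f"{path}: duplicate sample_id values: {sorted(dup.unique())}"
        )
    mapping = {positive_label: "met", negative_label: "nonmet"}
    bad = set(df["outcome"].astype(str)) - set(mapping)
    if bad:
        raise DataValidationError(
            f"{path}: unrecognized outcome labels {sorted(bad)}; expected "
            f"{positive_label!r}/{negative_label!r}"
        )
    df["outcome"] = df["outcome"].astype(str).map(mapping)
    for col in df.columns:
        if col in ("sample_id", "outcome"):
            continue
        df[col] = _parse_numeric_column(df[col], col, path)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, na_rep="NA")


def read_ct_table(path) -> pd.DataFrame:
    """Read a long-format Ct CSV; the ``Undetermined`` token becomes NaN,
    anything else non-numeric is an error."""
    df = pd.read_csv(path, dtype={"sample_id": str, "assay": str, "reaction": str})
    required = {"sample_id", "assay", "reaction", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: missing columns {sorted(missing)}")
    raw = df["ct"].astype(object)
    ct = pd.to_numeric(df["ct"], errors="coerce")
    for i, (orig, parsed) in enumerate(zip(raw, ct)):
        if pd.isna(parsed) and not (
            pd.isna(orig) or str(orig).strip().lower() == UNDETERMINED_TOKEN.lower()
        ):
            raise DataValidationError(
                f"{path}: unparseable Ct value {orig!r} in row {i}"
            )
        if not pd.isna(parsed) and parsed <= 0:
            raise DataValidationError(f"{path}: non-positive Ct {parsed} in row {i}")
    df["ct"] = ct
    return df


def write_ct_table(ct: pd.DataFrame, path) -> None:
    out = ct.copy()
    out["ct"] = out["ct"].map(
        lambda v: UNDETERMINED_TOKEN if pd.isna(v) else repr(float(v))
    )
    out.to_csv(path, index=False)


def _sanitize(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "-" for c in name)


class RunConfig(BaseModel):
    """Declarative configuration of a full pipeline run."""

    model_config = ConfigDict(frozen=True)

    simulate: bool = False
    cohort_csv: str | None = None
    ct_csv: str | None = None
    labels_csv: str | None = None  # sample_id,outcome — required with ct_csv
    seed: int = Field(default=0, ge=0)
    qc_threshold: float = quantify_mod.DEFAULT_QC_THRESHOLD
    fdr_family: str = "by-modality"
    out_dir: str = "metpanel_out"
    panel_cutoffs: str = "auto"  # "auto" (Youden from data) or "published"

    def resolve_cohort(self) -> pd.DataFrame:
        sources = [self.simulate, self.cohort_csv is not None, self.ct_csv is not None]
        if sum(sources) != 1:
            raise ConfigurationError(
                "exactly one of simulate / cohort_csv / ct_csv must be given"
            )
        if self.simulate:
            return simulate_cohort(SimulationConfig(seed=self.seed))
        if self.cohort_csv is not None:
            return read_cohort(self.cohort_csv)
        if self.labels_csv is None:
            raise ConfigurationError(
                "a raw Ct run needs outcome labels: provide labels_csv "
                "(columns sample_id, outcome)"
            )
        ct = read_ct_table(self.ct_csv)
        wide, log = quantify_mod.quantify_ct_table(ct, self.qc_threshold)
        for _, row in log.iterrows():
            logger.warning(
                "missing value: sample %s assay %s (%s)",
                row["sample_id"], row["assay"], row["reason"],
            )
        labels = pd.read_csv(self.labels_csv, dtype={"sample_id": str})
        for col in ("sample_id", "outcome"):
            if col not in labels.columns:
                raise DataValidationError(
                    f"{self.labels_csv}: missing required column {col!r}"
                )
        merged = labels[["sample_id", "outcome"]].merge(wide, on="sample_id", how="inner")
        if merged.empty:
            raise DataValidationError("no sample_id overlap between Ct table and labels")
        return merged


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the whole analysis: cohort -> marker screen -> per-marker ROC
    -> count-rule panels; writes all artifacts plus ``summary.json`` into
    ``config.out_dir`` and returns the summary dict.

    Panel cutoffs are the data-derived Youden cutoffs (``panel_cutoffs =
    "auto"``, default) or the published study cutoffs (``"published"``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("stage: cohort")
    cohort = config.resolve_cohort()
    write_cohort(cohort, out / "cohort.csv")

    logger.info("stage: marker screen")
    screen = stats_mod.screen_markers(cohort, fdr_family=config.fdr_family)
    screen.to_csv(out / "marker_stats.tsv", sep="\t", index=False)

    logger.info("stage: ROC")
    summary_df, roc_results = roc_mod.roc_summary(cohort)
    summary_df.to_csv(out / "roc_summary.tsv", sep="\t", index=False)
    for marker, res in roc_results.items():
        pd.DataFrame(
            {"threshold": res.thresholds, "fpr": res.fpr, "tpr": res.tpr}
        ).to_csv(out / f"roc_{_sanitize(marker)}.tsv", sep="\t", index=False)

    logger.info("stage: panels")
    if config.panel_cutoffs == "auto":
        cutoffs = {m: r.cutoff for m, r in roc_results.items()}
    elif config.panel_cutoffs == "published":
        cutoffs = None
    else:
        raise ConfigurationError(
            f"panel_cutoffs must be 'auto' or 'published', got {config.panel_cutoffs!r}"
        )
    panel_reports = {}
    calls_frames = []
    for name, pdef in panel_mod.builtin_panels(cutoffs).items():
        events, n_excl = panel_mod.call_events(cohort, pdef)
        pred, counts = panel_mod.classify_count_rule(events, pdef.k_events)
        perf = panel_mod.panel_performance(
            pred, counts, events["outcome"].to_numpy(), name, n_excl
        )
        panel_reports[name] = perf.to_dict()
        calls_frames.append(
            pd.DataFrame(
                {"sample_id": events.index, "panel": name, "count": counts,
                 "call": np.where(pred == 1, "high_risk", "low_risk")}
            )
        )
    pd.concat(calls_frames).to_csv(out / "panel_calls.csv", index=False)
    with open(out / "panel_report.json", "w") as fh:
        json.dump(panel_reports, fh, indent=2)

    summary = {
        "n_samples": int(len(cohort)),
        "n_met": int((cohort["outcome"] == "met").sum()),
        "n_nonmet": int((cohort["outcome"] == "nonmet").sum()),
        "seed": config.seed,
        "markers": screen.to_dict(orient="records"),
        "roc": summary_df.to_dict(orient="records"),
        "panels": panel_reports,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    logger.info("pipeline complete: %s", out)
    return summary
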