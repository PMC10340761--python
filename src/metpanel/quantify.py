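"""Quantification of raw qPCR measurements.

Two scales come out of this module:

* **RQ** — relative expression by the comparative-Ct method,
  ``RQ = E^(-ddCt)`` with ``ddCt = (Ct_target - Ct_ref)_tumor -
  (Ct_target - Ct_ref)_normal``, reference gene GAPDH, amplification
  efficiency E = 2 by default.  RQ = 1 means equal target abundance in tumor
  and paired normal tissue.
* **MI** — methylation index from quantitative methylation-specific PCR:
  ``MI = 100 * Q_M / (Q_M + Q_U)`` with ``Q = E^(-Ct)`` for the
  methylated-specific (M) and unmethylated-specific (U) reactions.  MI = 0
  means no methylation (only U amplifies), MI = 100 complete methylation.

A reaction that never crosses threshold is *undetermined* (NaN in memory, the
token ``Undetermined`` in files); it is never silently coerced to a late Ct.
An undetermined M or U reaction contributes Q = 0, which is what places MI on
its boundaries.  Bisulfite-conversion completeness is checked per sample via
an ACTB reaction specific to the *unconverted* template: any amplification
below the QC threshold means incomplete conversion and fails the sample's
methylation measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataValidationError

__all__ = [
    "ExpressionCt",
    "MethylationCt",
    "QuantifiedMarker",
    "rq_from_ct",
    "mi_from_ct",
    "conversion_qc",
    "quantify_ct_table",
    "DEFAULT_QC_THRESHOLD",
    "DEFAULT_EFFICIENCY",
]

DEFAULT_QC_THRESHOLD = 35.0
DEFAULT_EFFICIENCY = 2.0

EXPRESSION_REACTIONS = ("target_tumor", "ref_tumor", "target_normal", "ref_normal")
METHYLATION_REACTIONS = ("meth", "unmeth")


def _is_undetermined(ct: float | None) -> bool:
    return ct is None or (isinstance(ct, float) and math.isnan(ct))


@dataclass(frozen=True)
class ExpressionCt:
    """Raw Ct quadruple for one expression assay on one sample; ``None``/NaN
    encodes an undetermined reaction."""

    sample_id: str
    assay: str
    ct_target_tumor: float | None
    ct_ref_tumor: float | None
    ct_target_normal: float | None
    ct_ref_normal: float | None


@dataclass(frozen=True)
class MethylationCt:
    """Raw Ct pair (plus optional conversion control) for one methylation assay."""

    sample_id: str
    assay: str
    ct_methylated: float | None
    ct_unmethylated: float | None
    ct_actb_unconverted: float | None = None


@dataclass(frozen=True)
class QuantifiedMarker:
    """One quantified marker value; ``value`` is None when missing, with the
    reason recorded."""

    sample_id: str
    marker: str
    modality: str
    value: float | None
    qc_pass: bool = True
    reason: str | None = None


def rq_from_ct(record: ExpressionCt, efficiency: float = DEFAULT_EFFICIENCY) -> QuantifiedMarker:
    """Relative expression RQ from a Ct quadruple.

    All four reactions must be determined; otherwise the value is missing with
    a reason naming the offending reaction(s).
    """
    cts = {
        "target_tumor": record.ct_target_tumor,
        "ref_tumor": record.ct_ref_tumor,
        "target_normal": record.ct_target_normal,
        "ref_normal": record.ct_ref_normal,
    }
    bad = [name for name, ct in cts.items() if _is_undetermined(ct)]
    if bad:
        return QuantifiedMarker(
            record.sample_id, record.assay, "expression", None,
            reason=f"undetermined Ct: {', '.join(bad)}",
        )
    ddct = (cts["target_tumor"] - cts["ref_tumor"]) - (
        cts["target_normal"] - cts["ref_normal"]
    )
    return QuantifiedMarker(
        record.sample_id, record.assay, "expression", float(efficiency ** -ddct)
    )


def mi_from_ct(record: MethylationCt, efficiency: float = DEFAULT_EFFICIENCY) -> QuantifiedMarker:
    """Methylation index MI (percent) from the M/U reaction pair.

    An undetermined reaction contributes zero quantity, so MI is exactly 0
    when only U amplifies and exactly 100 when only M amplifies.  Both
    undetermined gives a missing value.
    """
    m_undet = _is_undetermined(record.ct_methylated)
    u_undet = _is_undetermined(record.ct_unmethylated)
    if m_undet and u_undet:
        return QuantifiedMarker(
            record.sample_id, record.assay, "methylation", None,
            reason="both M and U reactions undetermined",
        )
    q_m = 0.0 if m_undet else efficiency ** -record.ct_methylated
    q_u = 0.0 if u_undet else efficiency ** -record.ct_unmethylated
    return QuantifiedMarker(
        record.sample_id, record.assay, "methylation", 100.0 * q_m / (q_m + q_u)
    )


def conversion_qc(
    ct_actb_unconverted: float | None, ct_threshold: float = DEFAULT_QC_THRESHOLD
) -> bool:
    """Bisulfite-conversion QC: passes iff the unconverted-template ACTB
    reaction shows no meaningful amplification (undetermined, or Ct at/above
    the threshold)."""
    if _is_undetermined(ct_actb_unconverted):
        return True
    return ct_actb_unconverted >= ct_threshold


def _pivot_sample_assay(group: pd.DataFrame) -> dict[str, float]:
    dup = group["reaction"].duplicated()
    if dup.any():
        raise DataValidationError(
            f"duplicate reaction rows for sample {group['sample_id'].iat[0]!r}, "
            f"assay {group['assay'].iat[0]!r}"
        )
    return dict(zip(group["reaction"], group["ct"]))


def quantify_ct_table(
    ct: pd.DataFrame,
    qc_threshold: float = DEFAULT_QC_THRESHOLD,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn a long-format Ct table into a wide per-sample marker table.

    Parameters
    ----------
    ct
        Long table with columns ``sample_id, assay, reaction, ct``; reaction
        names follow the expression quadruple / methylation pair convention,
        plus ``actb_unconverted`` rows (assay ``ACTB``) for conversion QC.
        NaN Ct encodes an undetermined reaction.
    qc_threshold
        Ct at/above which the unconverted-ACTB reaction counts as clean.

    Returns
    -------
    (wide, log)
        ``wide``: one row per sample, one column per assay (NaN = missing).
        Methylation values of samples failing conversion QC are set missing.
        ``log``: one row per missing/failed value with the reason.
    """
    required = {"sample_id", "assay", "reaction", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise DataValidationError(f"Ct table missing columns: {sorted(missing)}")

    qc_by_sample: dict[str, bool] = {}
    actb = ct[ct["reaction"] == "actb_unconverted"]
    for _, row in actb.iterrows():
        qc_by_sample[row["sample_id"]] = conversion_qc(row["ct"], qc_threshold)

    records: dict[str, dict[str, float]] = {}
    log_rows: list[dict] = []
    body = ct[ct["reaction"] != "actb_unconverted"]
    for (sid, assay), group in body.groupby(["sample_id", "assay"], sort=False):
        cts = _pivot_sample_assay(group)
        reactions = set(cts)
        if reactions <= set(METHYLATION_REACTIONS) and reactions:
            rec = MethylationCt(sid, assay, cts.get("meth"), cts.get("unmeth"))
            q = mi_from_ct(rec, efficiency)
            if q.value is not None and not qc_by_sample.get(sid, True):
                q = QuantifiedMarker(
                    sid, assay, "methylation", None, qc_pass=False,
                    reason="bisulfite conversion QC failed (unconverted ACTB amplified)",
                )
        elif reactions <= set(EXPRESSION_REACTIONS):
            rec = ExpressionCt(
                sid, assay,
                cts.get("target_tumor"), cts.get("ref_tumor"),
                cts.get("target_normal"), cts.get("ref_normal"),
            )
            q = rq_from_ct(rec, efficiency)
        else:
            raise DataValidationError(
                f"assay {assay!r} for sample {sid!r} mixes or misnames reactions: "
                f"{sorted(reactions)}"
            )
        records.setdefault(sid, {})[assay] = np.nan if q.value is None else q.value
        if q.value is None:
            log_rows.append(
                {"sample_id": sid, "assay": assay, "qc_pass": q.qc_pass,
                 "reason": q.reason}
            )

    wide = pd.DataFrame.from_dict(records, orient="index").rename_axis("sample_id")
    wide = wide.reset_index()
    log = pd.DataFrame(log_rows, columns=["sample_id", "assay", "qc_pass", "reason"])
    return wide, log
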