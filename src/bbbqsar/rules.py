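"""Prediction for query compounds: log BB, permeation category, AD, rule filters.

A fitted model is applied to new compounds to give a predicted log BB and a
categorical blood-brain-barrier permeation call:

* ``readily_crosses``      — predicted log BB > 0.3
* ``limited_or_moderate``  — -1 <= predicted log BB <= 0.3
* ``poorly_distributed``   — predicted log BB < -1

Category boundaries are half-open: exactly 0.3 or exactly -1 falls in
``limited_or_moderate``.  Each query is also placed inside or outside the
model's leverage applicability domain, and screened against six published
drug-likeness filters (Lipinski rule of five, Ghose, Clark,
van de Waterbeemd, Kelder, Ajay).  Sub-criteria needing log P are skipped —
never silently passed — when log P is not supplied; this package does not
estimate log P.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .domain import warning_leverage, compute_leverages
from .model import LogBBResults

__all__ = [
    "Prediction",
    "RuleReport",
    "RuleVerdict",
    "CATEGORY_THRESHOLDS",
    "categorize",
    "predict_log_bb",
    "check_druglikeness",
    "batch_predict",
]

#: (lower, upper) bounds of the merged intermediate category.
CATEGORY_THRESHOLDS = (-1.0, 0.3)


def categorize(
    log_bb: float,
    *,
    upper: float = CATEGORY_THRESHOLDS[1],
    lower: float = CATEGORY_THRESHOLDS[0],
) -> str:
    """Permeation category from predicted log BB (boundaries inclusive below)."""
    if log_bb > upper:
        return "readily_crosses"
    if log_bb < lower:
        return "poorly_distributed"
    return "limited_or_moderate"


@dataclass(frozen=True)
class RuleVerdict:
    """One rule's outcome with its evaluated and skipped sub-criteria."""

    name: str
    passed: bool
    failed_criteria: tuple[str, ...] = ()
    skipped_criteria: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class RuleReport:
    """Verdicts of the six drug-likeness filters for one compound."""

    ro5: RuleVerdict
    ghose: RuleVerdict
    clark: RuleVerdict
    vdwaterbeemd: RuleVerdict
    kelder: RuleVerdict
    ajay: RuleVerdict

    def as_dict(self) -> dict[str, bool]:
        return {
            v.name: v.passed
            for v in (self.ro5, self.ghose, self.clark, self.vdwaterbeemd,
                      self.kelder, self.ajay)
        }


@dataclass
class Prediction:
    """Model output for one query compound."""

    log_bb_pred: float
    category: str
    leverage: float
    in_ad: bool
    rules: Optional[RuleReport] = None
    descriptors: dict = field(default_factory=dict)


def _verdict(name: str, checks: list[tuple[str, Optional[bool]]], notes=()) -> RuleVerdict:
    failed = tuple(label for label, ok in checks if ok is False)
    skipped = tuple(label for label, ok in checks if ok is None)
    return RuleVerdict(
        name=name,
        passed=not failed,
        failed_criteria=failed,
        skipped_criteria=skipped,
        notes=tuple(notes),
    )


def check_druglikeness(
    *,
    mw: float,
    tpsa: float,
    hbd: int,
    hba: int,
    nrb: int,
    log_p: Optional[float] = None,
) -> RuleReport:
    """Screen a compound against the six drug-likeness filters.

    log P is optional; rules that reference it (Ro5, Ajay) mark that
    sub-criterion skipped when it is absent.
    """
    for name, value in (("hbd", hbd), ("hba", hba), ("nrb", nrb)):
        if value < 0:
            raise ValueError(f"{name} must be a non-negative count, got {value}")
    if mw <= 0 or tpsa < 0:
        raise ValueError("mw must be positive and tpsa non-negative")

    logp = (lambda label, ok: (label, None if log_p is None else ok))
    ro5 = _verdict("ro5", [
        ("MW < 500", mw < 500),
        ("HBD < 5", hbd < 5),
        ("HBA <= 10", hba <= 10),
        logp("logP < 5", log_p is not None and log_p < 5),
    ])
    ghose = _verdict("ghose", [("160 <= MW <= 480", 160 <= mw <= 480)])
    clark = _verdict("clark", [("MW <= 480", mw <= 480)])
    vdw = _verdict("vdwaterbeemd", [
        ("MW <= 450", mw <= 450),
        ("TPSA <= 90", tpsa <= 90),
    ])
    kelder_notes = []
    if tpsa > 60:
        kelder_notes.append("TPSA exceeds the stricter 60 A^2 bound of the 60-70 band")
    kelder = _verdict("kelder", [("TPSA <= 70", tpsa <= 70)], notes=kelder_notes)
    ajay = _verdict("ajay", [
        ("200 <= MW <= 400", 200 <= mw <= 400),
        ("HBA <= 4", hba <= 4),
        ("HBD <= 3", hbd <= 3),
        ("NRB <= 7", nrb <= 7),
        logp("logP <= 5.2", log_p is not None and log_p <= 5.2),
    ])
    return RuleReport(ro5=ro5, ghose=ghose, clark=clark, vdwaterbeemd=vdw,
                      kelder=kelder, ajay=ajay)


def predict_log_bb(
    results: LogBBResults,
    descriptors: dict,
    *,
    coef_precision: Optional[int] = None,
    upper: float = CATEGORY_THRESHOLDS[1],
    lower: float = CATEGORY_THRESHOLDS[0],
) -> Prediction:
    """Predict log BB for one compound and assess it against the model's AD.

    ``descriptors`` maps descriptor names to values and must cover every
    model predictor (``hb_total`` may be given via ``hbd`` + ``hba``).
    """
    desc = dict(descriptors)
    if "hb_total" not in desc and {"hbd", "hba"} <= desc.keys():
        desc["hb_total"] = desc["hbd"] + desc["hba"]
    missing = [p for p in results.predictor_names if p not in desc]
    if missing:
        raise KeyError(f"missing predictor(s): {missing}")
    x = np.array([desc[p] for p in results.predictor_names], dtype=float)
    value = float(results.predict(x[None, :], coef_precision=coef_precision)[0])
    h_star = warning_leverage(results.p, results.n)
    leverage = float(
        compute_leverages(results.model.design, np.concatenate([[1.0], x])[None, :])[0]
    )
    rules = None
    if {"mw", "tpsa", "hbd", "hba", "nrb"} <= desc.keys():
        rules = check_druglikeness(
            mw=desc["mw"], tpsa=desc["tpsa"], hbd=int(desc["hbd"]),
            hba=int(desc["hba"]), nrb=int(desc["nrb"]),
            log_p=desc.get("log_p"),
        )
    return Prediction(
        log_bb_pred=value,
        category=categorize(value, upper=upper, lower=lower),
        leverage=leverage,
        in_ad=leverage <= h_star,
        rules=rules,
        descriptors=desc,
    )


def batch_predict(
    results: LogBBResults,
    query: pd.DataFrame,
    *,
    coef_precision: Optional[int] = None,
) -> pd.DataFrame:
    """Vectorised prediction + AD + rule screening for a query table.

    Returns the query with appended columns ``log_bb_pred``, ``category``,
    ``leverage``, ``in_ad`` and one boolean column per rule verdict.  Rows
    that fail (missing predictor, invalid counts) are collected in an
    ``error`` column rather than aborting the batch.  An empty query returns
    an empty frame with a warning.
    """
    import warnings

    if query.empty:
        warnings.warn("empty query table: nothing to predict", stacklevel=2)
        return query.copy()
    out = query.copy()
    records = []
    for _, row in query.iterrows():
        try:
            pred = predict_log_bb(results, row.to_dict(),
                                  coef_precision=coef_precision)
            rec = {
                "log_bb_pred": pred.log_bb_pred,
                "category": pred.category,
                "leverage": pred.leverage,
                "in_ad": pred.in_ad,
                "error": "",
            }
            if pred.rules is not None:
                rec.update(pred.rules.as_dict())
            records.append(rec)
        except (KeyError, ValueError) as exc:
            records.append({"error": str(exc)})
    extra = pd.DataFrame(records, index=query.index)
    return pd.concat([out, extra], axis=1)
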