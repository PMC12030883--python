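"""Confidence-scored screening: structural alerts x consensus model.

Alert-based calls know only two states — Active (>= 1 alert matched) or
Inconclusive (no alert; absence of an alert is not evidence of safety).  The
consensus model calls Active, Inactive, or Inconclusive (outside the
applicability domain).  The two calls combine into a confidence score:

    =====================  ============  =====  ==================
    alerts                 model         score  category
    =====================  ============  =====  ==================
    Active                 Active         2     Likely-toxicant
    Active                 Inconclusive   1     Possible-toxicant
    Inconclusive           Active         1     Possible-toxicant
    Inconclusive           Inconclusive   0     Unresolved
    Active                 Inactive      -1     Conflict
    Inconclusive           Inactive      NA     Predicted-inactive
    =====================  ============  =====  ==================

The last row has no published score: the four printed scores are reserved
for combinations involving at least one Active or double-Inconclusive call,
so a molecule with no alert that the model calls Inactive is reported as NA /
Predicted-inactive rather than overloading 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .alerts import AlertRule, match_alerts
from .chemistry import MoleculeRecord
from .consensus import ConsensusClassifier

ALERT_CALLS = ("Active", "Inconclusive")
ML_CALLS = ("Active", "Inactive", "Inconclusive")

_SCORE_TABLE = {
    ("Active", "Active"): (2, "Likely-toxicant"),
    ("Active", "Inconclusive"): (1, "Possible-toxicant"),
    ("Inconclusive", "Active"): (1, "Possible-toxicant"),
    ("Inconclusive", "Inconclusive"): (0, "Unresolved"),
    ("Active", "Inactive"): (-1, "Conflict"),
    ("Inconclusive", "Inactive"): (None, "Predicted-inactive"),
}


def integrate(alert_call: str, ml_call: str) -> tuple[int | None, str]:
    """Map one (alert_call, ml_call) pair to (confidence score, category).

    The mapping is total over the declared call domains; score None renders
    as "NA" in reports.
    """
    if alert_call not in ALERT_CALLS:
        raise ValueError(f"alert_call must be in {ALERT_CALLS}, got {alert_call!r}")
    if ml_call not in ML_CALLS:
        raise ValueError(f"ml_call must be in {ML_CALLS}, got {ml_call!r}")
    return _SCORE_TABLE[(alert_call, ml_call)]


@dataclass
class ScreeningResult:
    record_id: object
    smiles: str | None
    matched_alerts: tuple[int, ...]
    alert_call: str
    ml_call: str
    y_mean: float | None
    cons_std: float | None
    confidence_score: int | None
    final_category: str


@dataclass
class ScreeningSummary:
    """Tallies of one screening run plus the alert ranking among score-2 hits."""

    n_screened: int
    by_score: dict       # {"2": n, "1": n, "0": n, "-1": n, "NA": n}
    by_category: dict
    alert_ranking_score2: list[tuple[int, int]]  # (alert_id, n occurrences)

    def to_dict(self) -> dict:
        return {
            "n_screened": self.n_screened,
            "by_score": self.by_score,
            "by_category": self.by_category,
            "alert_ranking_score2": [
                {"alert_id": aid, "n": n} for aid, n in self.alert_ranking_score2
            ],
        }


def _score_key(score: int | None) -> str:
    return "NA" if score is None else str(score)


def screen(
    records: Iterable[MoleculeRecord],
    rules: Sequence[AlertRule],
    model: ConsensusClassifier,
) -> tuple[list[ScreeningResult], ScreeningSummary]:
    """Screen a chemical list with alerts plus the consensus model.

    One result per record; molecules that cannot be featurized get an
    Inconclusive model call.  The summary counts each score and category and
    ranks alerts by occurrence among the score-2 (Likely-toxicant) hits.
    """
    records = list(records)
    preds = model.predict_detail(records)
    results: list[ScreeningResult] = []
    by_score = {k: 0 for k in ("2", "1", "0", "-1", "NA")}
    by_category: dict[str, int] = {}
    alert_counts: dict[int, int] = {}
    for rec, pred in zip(records, preds):
        hits = tuple(match_alerts(rec.structure, rules)) if rec.structure is not None else ()
        alert_call = "Active" if hits else "Inconclusive"
        score, category = integrate(alert_call, pred.call)
        results.append(ScreeningResult(
            record_id=rec.record_id, smiles=rec.smiles, matched_alerts=hits,
            alert_call=alert_call, ml_call=pred.call, y_mean=pred.y_mean,
            cons_std=pred.cons_std, confidence_score=score,
            final_category=category,
        ))
        by_score[_score_key(score)] += 1
        by_category[category] = by_category.get(category, 0) + 1
        if score == 2:
            for aid in hits:
                alert_counts[aid] = alert_counts.get(aid, 0) + 1
    ranking = sorted(alert_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    summary = ScreeningSummary(
        n_screened=len(results), by_score=by_score, by_category=by_category,
        alert_ranking_score2=ranking,
    )
    return results, summary


def results_frame(results: Sequence[ScreeningResult]) -> pd.DataFrame:
    """Report table: one row per screened chemical."""
    return pd.DataFrame(
        {
            "record_id": [r.record_id for r in results],
            "smiles": [r.smiles for r in results],
            "matched_alerts": [";".join(str(a) for a in r.matched_alerts)
                               for r in results],
            "alert_call": [r.alert_call for r in results],
            "ml_call": [r.ml_call for r in results],
            "y_mean": [r.y_mean for r in results],
            "cons_std": [r.cons_std for r in results],
            "confidence_score": [_score_key(r.confidence_score) for r in results],
            "final_category": [r.final_category for r in results],
        }
    )
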