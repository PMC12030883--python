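"""Published structural-alert libraries and the substructure profiler.

Ships the 13 respiratory-irritation and 18 respiratory-sensitization alerts
as versioned CSV resources, compiles each alert SMILES into an RDKit
substructure query, and profiles labeled datasets: per-alert occurrence
counts (a molecule counts at most once per alert, however many times the
substructure occurs in it) and the set-level positive predictive value over
molecules flagged by at least one alert.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem

from .chemistry import MoleculeRecord

ENDPOINTS = ("irritation", "sensitization")


@dataclass(frozen=True)
class AlertRule:
    """One structural alert with its source-data occurrence statistics.

    ``n_tot`` is the number of molecules in the source set containing the
    substructure; ``n_true`` the number of those that are active.  ``ppv`` is
    ``n_true / n_tot`` (None when n_tot == 0 — never coerced to 0 or 1).
    """

    alert_id: int
    pattern: str
    endpoint: str
    n_tot: int
    n_true: int
    chemical_class: str = ""
    toolbox_alerts: str = ""

    def __post_init__(self):
        if not (0 <= self.n_true <= self.n_tot):
            raise ValueError(
                f"alert {self.endpoint}#{self.alert_id}: "
                f"need 0 <= n_true ({self.n_true}) <= n_tot ({self.n_tot})"
            )
        if self.query is None:  # compiled lazily but validated eagerly
            raise ValueError(
                f"alert {self.endpoint}#{self.alert_id}: "
                f"pattern {self.pattern!r} is not a valid substructure query"
            )

    @property
    def query(self) -> Chem.Mol | None:
        return compile_query(self.pattern)

    @property
    def ppv(self) -> float | None:
        return compute_ppv(self.n_true, self.n_tot)

    def matches(self, mol: Chem.Mol) -> bool:
        return mol.HasSubstructMatch(self.query)


_QUERY_CACHE: dict[str, Chem.Mol | None] = {}


def compile_query(pattern: str) -> Chem.Mol | None:
    """Compile an alert SMILES into a substructure query.

    Alert patterns are plain SMILES, not SMARTS: atoms constrain element and
    aromaticity, bonds constrain order, and implicit hydrogens are left
    unconstrained, so an open valence acts as a wildcard attachment point.
    Radical electrons that the parser assigns to open-valence bracket atoms
    (e.g. trivalent Si in a chlorosilane fragment) are cleared — they are an
    artifact of writing a substructure as plain SMILES, not a constraint.
    """
    if pattern not in _QUERY_CACHE:
        q = Chem.MolFromSmiles(pattern)
        if q is not None and q.GetNumAtoms() == 0:
            q = None
        if q is not None:
            for atom in q.GetAtoms():
                atom.SetNumRadicalElectrons(0)
        _QUERY_CACHE[pattern] = q
    return _QUERY_CACHE[pattern]


_compile_query = compile_query


def compute_ppv(n_true: int, n_tot: int) -> float | None:
    """Positive predictive value n_true/n_tot; None (undefined) when n_tot=0."""
    if n_true < 0 or n_tot < n_true:
        raise ValueError(f"need 0 <= n_true <= n_tot, got ({n_true}, {n_tot})")
    if n_tot == 0:
        return None
    return n_true / n_tot


def load_alert_table(endpoint: str) -> list[AlertRule]:
    """Load the packaged alert table for one endpoint.

    Returns the published rows verbatim: 13 rules for irritation, 18 for
    sensitization, with occurrence counts and chemical classes as printed.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}, got {endpoint!r}")
    ref = resources.files("respiscreen") / "data" / f"alerts_{endpoint}.csv"
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, keep_default_na=False)
    return [
        AlertRule(
            alert_id=int(row.alert_id),
            pattern=row.smiles,
            endpoint=row.endpoint,
            n_tot=int(row.n_tot),
            n_true=int(row.n_true),
            chemical_class=row.chemical_class,
            toolbox_alerts=row.toolbox_alerts,
        )
        for row in table.itertuples()
    ]


def load_alert_csv(path) -> list[AlertRule]:
    """Load alert rules from a user CSV with the packaged-table schema."""
    table = pd.read_csv(path, keep_default_na=False)
    return [
        AlertRule(
            alert_id=int(row.alert_id),
            pattern=row.smiles,
            endpoint=str(getattr(row, "endpoint", "") or "none"),
            n_tot=int(getattr(row, "n_tot", 0)),
            n_true=int(getattr(row, "n_true", 0)),
            chemical_class=str(getattr(row, "chemical_class", "")),
        )
        for row in table.itertuples()
    ]


def match_alerts(mol: Chem.Mol | str, rules: Sequence[AlertRule]) -> list[int]:
    """Alert ids whose pattern occurs as a subgraph of the molecule."""
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparsable SMILES: {mol!r}")
        mol = parsed
    return [rule.alert_id for rule in rules if rule.matches(mol)]


@dataclass
class AlertProfile:
    """Per-alert and set-level occurrence statistics on one labeled dataset."""

    per_alert: pd.DataFrame  # columns alert_id, n_tot, n_true, ppv
    set_tp: int
    set_fp: int

    @property
    def set_ppv(self) -> float | None:
        return compute_ppv(self.set_tp, self.set_tp + self.set_fp)


def profile_dataset(
    records: Iterable[MoleculeRecord],
    rules: Sequence[AlertRule],
) -> AlertProfile:
    """Recompute alert occurrence statistics on a labeled molecule set.

    Every record must be labeled active or inactive.  Set-level TP/FP count
    molecules matched by >= 1 alert (union over alerts), following the
    convention that one or more alerts flags the chemical.
    """
    # duplicated rules must not inflate counts
    seen_ids: set[int] = set()
    uniq_rules = []
    for rule in rules:
        if rule.alert_id not in seen_ids:
            seen_ids.add(rule.alert_id)
            uniq_rules.append(rule)

    n_tot = {r.alert_id: 0 for r in uniq_rules}
    n_true = {r.alert_id: 0 for r in uniq_rules}
    set_tp = set_fp = 0
    for rec in records:
        if rec.label not in ("active", "inactive"):
            raise ValueError(
                f"record {rec.record_id} is unlabeled; profiling needs labels"
            )
        if rec.structure is None:
            raise ValueError(f"record {rec.record_id} has no curated structure")
        hits = match_alerts(rec.structure, uniq_rules)
        for aid in hits:
            n_tot[aid] += 1
            if rec.label == "active":
                n_true[aid] += 1
        if hits:
            if rec.label == "active":
                set_tp += 1
            else:
                set_fp += 1
    per_alert = pd.DataFrame(
        {
            "alert_id": [r.alert_id for r in uniq_rules],
            "n_tot": [n_tot[r.alert_id] for r in uniq_rules],
            "n_true": [n_true[r.alert_id] for r in uniq_rules],
        }
    )
    per_alert["ppv"] = [
        compute_ppv(t, n) if n else math.nan
        for t, n in zip(per_alert.n_true, per_alert.n_tot)
    ]
    return AlertProfile(per_alert=per_alert, set_tp=set_tp, set_fp=set_fp)
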