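"""Data-driven structural-alert mining.

Fragments every molecule of a labeled set into its connected substructures
(rings kept intact), tabulates how often each fragment occurs in active vs
inactive molecules, and extracts a precision-ranked rule set by greedy
covering of the actives.  The scheme follows the fragment-based alert miners
used in toxicology (SARpy and kin): substructures of 4-20 heavy atoms
supported by at least 4 active compounds, selected by positive predictive
value.

Fragment definition
-------------------
A fragment is a connected induced subgraph of the heavy-atom graph that is
*closed under ring bonds*: if it contains one atom of a ring system it
contains the whole ring system.  For acyclic molecules this is exactly the
set of all connected induced subgraphs (equivalently, everything reachable by
recursively breaking single bonds); rings are never opened, so mined alerts
can contain intact rings but never ring slivers.  Broken bonds become
unconstrained attachment points: a fragment is used downstream as a plain
SMILES substructure query, so any substitution is tolerated at open valences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from sklearn.base import BaseEstimator

from .alerts import AlertRule, compile_query
from .chemistry import MoleculeRecord


@dataclass(frozen=True)
class MiningConfig:
    """Mining thresholds.

    min_atoms/max_atoms: heavy-atom bounds on emitted fragments (default 4-20).
    min_support_active: minimum number of active molecules containing a
        fragment for it to become a rule (default 4).
    min_precision: floor on n_active/(n_active+n_inactive) for rule selection;
        the published alert sets show set-level precision >= 0.9, and 0.8 is
        the default floor at which comparable per-rule precision emerges on
        synthetic benchmarks.
    max_rules: optional cap on the number of rules extracted.
    """

    min_atoms: int = 4
    max_atoms: int = 20
    min_support_active: int = 4
    min_precision: float = 0.8
    max_rules: int | None = None

    def __post_init__(self):
        if not (1 <= self.min_atoms <= self.max_atoms):
            raise ValueError("need 1 <= min_atoms <= max_atoms")
        if self.min_support_active < 1:
            raise ValueError("min_support_active must be >= 1")
        if not (0.0 <= self.min_precision <= 1.0):
            raise ValueError("min_precision must be in [0, 1]")


@dataclass
class FragmentStats:
    """Occurrence statistics of one candidate fragment (molecule-level)."""

    fragment: str
    n_active: int
    n_inactive: int
    size: int
    active_ids: frozenset = field(default_factory=frozenset, repr=False)
    inactive_ids: frozenset = field(default_factory=frozenset, repr=False)

    @property
    def precision(self) -> float:
        return self.n_active / (self.n_active + self.n_inactive)


# ---------------------------------------------------------------------------
# fragment enumeration


def _ring_contracted_graph(mol: Chem.Mol):
    """Contract ring systems into super-nodes.

    Returns (nodes, adjacency) where each node is a tuple of atom indices
    (singleton for acyclic atoms, a whole fused ring system for ring atoms)
    and adjacency lists connect nodes joined by at least one non-ring bond.
    """
    n = mol.GetNumAtoms()
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for bond in mol.GetBonds():
        if bond.IsInRing():
            union(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    nodes = [tuple(sorted(g)) for g in groups.values()]
    nodes.sort()
    node_of_atom = {}
    for k, node in enumerate(nodes):
        for a in node:
            node_of_atom[a] = k
    adj: list[set[int]] = [set() for _ in nodes]
    for bond in mol.GetBonds():
        if bond.IsInRing():
            continue
        u = node_of_atom[bond.GetBeginAtomIdx()]
        v = node_of_atom[bond.GetEndAtomIdx()]
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    return nodes, adj


def _connected_node_subsets(adj: list[set[int]], weight: list[int], max_weight: int):
    """Enumerate every connected subset of nodes with total weight <= max.

    ESU-style enumeration: each subset is generated exactly once, rooted at
    its minimum node index.
    """
    results: list[list[int]] = []

    def extend(sub: set[int], closed: set[int], ext: set[int], root: int, w: int):
        results.append(sorted(sub))
        ext = sorted(ext)
        while ext:
            v = ext.pop()
            wv = w + weight[v]
            if wv > max_weight:
                continue
            # ext members are neighbors of sub, hence already in `closed`,
            # so processed siblings can never re-enter via v's neighbors
            new_ext = set(ext) | {
                u for u in adj[v] if u > root and u not in closed
            }
            extend(sub | {v}, closed | adj[v] | {v}, new_ext, root, wv)

    for v in range(len(adj)):
        if weight[v] <= max_weight:
            extend({v}, {v} | adj[v], {u for u in adj[v] if u > v}, v, weight[v])
    return results


def fragment_smiles(mol: Chem.Mol, atom_indices: Sequence[int]) -> str | None:
    """Canonical SMILES of the induced subgraph on ``atom_indices``.

    Stereochemistry is dropped; the text is round-tripped through the parser
    so that identical substructures from different parent molecules compare
    equal.  Returns None for the rare fragment whose SMILES does not survive
    the round trip.
    """
    smi = Chem.MolFragmentToSmiles(mol, atomsToUse=list(atom_indices),
                                   isomericSmiles=False, canonical=True)
    frag = Chem.MolFromSmiles(smi)
    if frag is None:
        return None
    return Chem.MolToSmiles(frag)


def enumerate_fragments(mol: Chem.Mol | str, config: MiningConfig | None = None) -> set[str]:
    """All ring-closed connected fragments of a molecule within size bounds."""
    config = config or MiningConfig()
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparsable SMILES: {mol!r}")
        mol = parsed
    if mol.GetNumAtoms() < config.min_atoms:
        return set()
    nodes, adj = _ring_contracted_graph(mol)
    weight = [len(node) for node in nodes]
    out: set[str] = set()
    for subset in _connected_node_subsets(adj, weight, config.max_atoms):
        atoms = [a for k in subset for a in nodes[k]]
        if len(atoms) < config.min_atoms:
            continue
        smi = fragment_smiles(mol, atoms)
        if smi is not None:
            out.add(smi)
    return out


# ---------------------------------------------------------------------------
# tabulation and rule extraction


def _labeled_mols(records) -> tuple[list[str], list[Chem.Mol], list[int]]:
    """Normalize records/(smiles, y) input to (ids, mols, 0/1 labels)."""
    ids, mols, y = [], [], []
    for rec in records:
        if not isinstance(rec, MoleculeRecord):
            raise TypeError("expected MoleculeRecord collection")
        if rec.label not in ("active", "inactive"):
            raise ValueError(f"record {rec.record_id} must be labeled active/inactive")
        if rec.structure is None:
            raise ValueError(f"record {rec.record_id} has no curated structure")
        ids.append(rec.record_id)
        mols.append(rec.structure)
        y.append(1 if rec.label == "active" else 0)
    return ids, mols, y


def tabulate_fragments(
    records: Iterable[MoleculeRecord],
    config: MiningConfig | None = None,
) -> list[FragmentStats]:
    """Per-fragment molecule-level occurrence counts over a labeled set.

    A fragment occurring several times in one molecule counts that molecule
    once.  Fragments contained in fewer than ``min_support_active`` active
    molecules are pruned.
    """
    config = config or MiningConfig()
    ids, mols, y = _labeled_mols(records)
    active_ids: dict[str, set] = {}
    inactive_ids: dict[str, set] = {}
    for rid, mol, label in zip(ids, mols, y):
        for frag in enumerate_fragments(mol, config):
            bucket = active_ids if label == 1 else inactive_ids
            bucket.setdefault(frag, set()).add(rid)
    stats = []
    for frag, act in active_ids.items():
        if len(act) < config.min_support_active:
            continue
        inact = inactive_ids.get(frag, set())
        qfrag = Chem.MolFromSmiles(frag)
        stats.append(FragmentStats(
            fragment=frag,
            n_active=len(act),
            n_inactive=len(inact),
            size=qfrag.GetNumAtoms(),
            active_ids=frozenset(act),
            inactive_ids=frozenset(inact),
        ))
    stats.sort(key=lambda s: (-s.precision, -s.size, -s.n_active, s.fragment))
    return stats


def fragment_table(stats: Sequence[FragmentStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fragment": [s.fragment for s in stats],
            "n_active": [s.n_active for s in stats],
            "n_inactive": [s.n_inactive for s in stats],
            "precision": [s.precision for s in stats],
            "size": [s.size for s in stats],
        }
    )


def extract_alerts(
    records: Sequence[MoleculeRecord],
    config: MiningConfig | None = None,
    endpoint: str = "none",
) -> list[AlertRule]:
    """Greedy precision-ranked covering of the active molecules.

    Candidate fragments must meet the support and precision floors on the
    full input set.  The covering loop repeatedly selects the candidate
    maximizing (precision, then larger size, then active support, then
    lexicographic canonical text) among those still matching at least one
    uncovered active, and removes the actives it matches; it stops when no
    candidate covers anything new.  Two deliberate asymmetries: support is
    judged on the full set, so a toxicophore partially covered by a more
    specific variant is not starved below the floor; and among
    equal-precision candidates the *most specific* (largest) fragment wins,
    because small generic fragments that straddle several distinct
    toxicophores (for instance a bare C-C-C-N chain shared by an amine and
    an isocyanate class) would otherwise absorb them into one over-general
    rule.  Emitted rules carry occurrence counts recomputed by substructure
    matching on the full input set, so their PPVs have exactly the semantics
    of the published tables.
    """
    config = config or MiningConfig()
    stats = tabulate_fragments(records, config)
    candidates = [s for s in stats
                  if s.precision >= config.min_precision
                  and s.n_active >= config.min_support_active]
    uncovered = {s for frag in candidates for s in frag.active_ids}
    chosen: list[FragmentStats] = []
    while candidates and uncovered:
        if config.max_rules is not None and len(chosen) >= config.max_rules:
            break
        best = None
        best_key = None
        for s in candidates:
            if not (s.active_ids & uncovered):
                continue
            key = (-s.precision, -s.size, -s.n_active, s.fragment)
            if best_key is None or key < best_key:
                best, best_key = s, key
        if best is None:
            break
        chosen.append(best)
        uncovered -= best.active_ids
        candidates.remove(best)

    ids, mols, y = _labeled_mols(records)
    rules = []
    for k, s in enumerate(chosen, start=1):
        query = compile_query(s.fragment)
        n_tot = n_true = 0
        for mol, label in zip(mols, y):
            if mol.HasSubstructMatch(query):
                n_tot += 1
                n_true += label
        rules.append(AlertRule(
            alert_id=k, pattern=s.fragment, endpoint=endpoint,
            n_tot=n_tot, n_true=n_true, chemical_class="mined",
        ))
    return rules


class AlertMiner(BaseEstimator):
    """Mine structural alerts from SMILES with binary activity labels.

    scikit-learn style: ``fit(X, y)`` takes SMILES strings (or RDKit mols)
    and 0/1 labels and stores the extracted rules in ``rules_``;
    ``transform`` produces the molecule-by-rule hit matrix and ``predict``
    flags molecules matching at least one rule.

    Parameters mirror :class:`MiningConfig`.
    """

    def __init__(self, min_atoms: int = 4, max_atoms: int = 20,
                 min_support_active: int = 4, min_precision: float = 0.8,
                 max_rules: int | None = None, endpoint: str = "none"):
        self.min_atoms = min_atoms
        self.max_atoms = max_atoms
        self.min_support_active = min_support_active
        self.min_precision = min_precision
        self.max_rules = max_rules
        self.endpoint = endpoint

    def _config(self) -> MiningConfig:
        return MiningConfig(
            min_atoms=self.min_atoms, max_atoms=self.max_atoms,
            min_support_active=self.min_support_active,
            min_precision=self.min_precision, max_rules=self.max_rules,
        )

    def fit(self, X, y):
        records = _records_from_xy(X, y)
        config = self._config()
        self.fragment_stats_ = tabulate_fragments(records, config)
        self.rules_ = extract_alerts(records, config, endpoint=self.endpoint)
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "rules_")
        import numpy as np

        mols = [_as_mol(x) for x in X]
        out = np.zeros((len(mols), len(self.rules_)), dtype=int)
        for i, mol in enumerate(mols):
            for j, rule in enumerate(self.rules_):
                if mol is not None and rule.matches(mol):
                    out[i, j] = 1
        return out

    def predict(self, X):
        return self.transform(X).any(axis=1).astype(int)


def _as_mol(x) -> Chem.Mol | None:
    if isinstance(x, Chem.Mol):
        return x
    if isinstance(x, MoleculeRecord):
        return x.structure
    return Chem.MolFromSmiles(x)


def _records_from_xy(X, y) -> list[MoleculeRecord]:
    if y is None:
        if all(isinstance(x, MoleculeRecord) for x in X):
            return list(X)
        raise ValueError("y is required unless X is a labeled record collection")
    records = []
    for i, (x, label) in enumerate(zip(X, y)):
        mol = _as_mol(x)
        records.append(MoleculeRecord(
            record_id=x.record_id if isinstance(x, MoleculeRecord) else f"mol{i + 1}",
            raw_input=x if isinstance(x, str) else "",
            structure=mol,
            label="active" if int(label) == 1 else "inactive",
        ))
    return records
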