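"""Shared fixtures: tiny hand-written chemical sets and brute-force oracles."""

from __future__ import annotations

import itertools

import pytest
from rdkit import Chem

from respiscreen import GeneratorConfig, generate_dataset, records_from_smiles
from respiscreen.chemistry import curate


def brute_force_fragments(smiles: str, min_atoms: int, max_atoms: int) -> set[str]:
    """Independent fragment oracle: enumerate *all* atom subsets, keep the
    connected ones closed under ring bonds, canonicalize.

    Exhaustive over the powerset, so only usable on small molecules; the
    production enumerator works on a ring-contracted graph instead.
    """
    from respiscreen.mining import fragment_smiles

    mol = Chem.MolFromSmiles(smiles)
    n = mol.GetNumAtoms()
    adj = {i: set() for i in range(n)}
    ring_bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        adj[i].add(j)
        adj[j].add(i)
        if b.IsInRing():
            ring_bonds.append((i, j))
    out: set[str] = set()
    for r in range(min_atoms, min(max_atoms, n) + 1):
        for sub in itertools.combinations(range(n), r):
            s = set(sub)
            stack, seen = [sub[0]], {sub[0]}
            while stack:
                v = stack.pop()
                for u in adj[v]:
                    if u in s and u not in seen:
                        seen.add(u)
                        stack.append(u)
            if seen != s:
                continue
            if any((i in s) != (j in s) for i, j in ring_bonds):
                continue
            frag = fragment_smiles(mol, sub)
            if frag is not None:
                out.add(frag)
    return out


def brute_force_auc(scores, labels) -> float:
    """Pairwise AUC oracle: fraction of active/inactive pairs ranked right,
    ties counting one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


@pytest.fixture
def three_molecule_profile_set():
    """Two actives matching the anhydride alert, one clean inactive."""
    records = records_from_smiles(
        ["CC(=O)OC(=O)C", "CCC(=O)OC(=O)CC", "CCO"],
        labels=["active", "active", "inactive"],
    )
    curated, _ = curate(records)
    return curated


@pytest.fixture
def small_planted_dataset():
    """Zero-noise planted set, small enough for exhaustive checks."""
    cfg = GeneratorConfig(n_active=12, n_inactive=12, motifs_per_dataset=2, seed=11)
    return generate_dataset(cfg)


@pytest.fixture
def sdf_file(tmp_path):
    """Hand-built 3-entry SDF (ethanol, benzene, acetic acid)."""
    path = tmp_path / "three.sdf"
    blocks = []
    for name, smi in [("ethanol", "CCO"), ("benzene", "c1ccccc1"),
                      ("acetic_acid", "CC(=O)O")]:
        mol = Chem.MolFromSmiles(smi)
        mol.SetProp("_Name", name)
        blocks.append(Chem.MolToMolBlock(mol) + "$$$$\n")
    path.write_text("".join(blocks))
    return path
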