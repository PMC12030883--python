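"""Synthetic labeled chemical sets with planted alert substructures.

Real GHS-derived irritation/sensitization sets cannot be redistributed, so
benchmarking and testing run on constructed datasets in which ground truth is
exact: actives are alert-free scaffolds with a known alert substructure
grafted on via a single bond, inactives are alert-free scaffolds, and a
manifest records which motif (if any) each molecule carries.  Controlled
noise corrupts the construction in both directions — a fraction of actives
carry no motif (planting noise) and a fraction of inactives do (decoy
noise) — emulating the label noise of weight-of-evidence hazard data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .alerts import load_alert_table
from .chemistry import MoleculeRecord, make_dedup_key

#: Alert-free scaffolds: plain hydrocarbons and aliphatic ethers.  Verified
#: against both packaged alert tables (every alert pattern contains a
#: heteroatom motif these scaffolds lack); a test re-checks this at each run.
DEFAULT_SCAFFOLDS: tuple[str, ...] = (
    "CCCCC", "CCCCCC", "CCCCCCC", "CCCCCCCC",
    "CC(C)CC", "CC(C)CCC", "CC(C)(C)CC", "CCC(CC)CC",
    "C1CCCC1", "C1CCCCC1", "C1CCCCCC1",
    "CC1CCCC1", "CC1CCCCC1", "CCC1CCCCC1",
    "c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "CCCc1ccccc1",
    "Cc1ccccc1C", "Cc1ccc(C)cc1", "Cc1cccc(C)c1", "c1ccc2ccccc2c1",
    "CCOCC", "CCCOCCC", "CCOCCC", "COCCOC", "CCOCCOCC",
    "C1CCOC1", "C1CCOCC1", "CC1CCOCC1",
    "CC=CCC", "CCC=CC",
)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a small curated hazard set: balanced classes, three
    distinct planted alerts, and noise-free planting (noise rates are the
    dials the benchmarks sweep).
    """

    n_active: int = 60
    n_inactive: int = 60
    motif_pool: Sequence[str] | None = None  # default: packaged alert patterns
    motifs_per_dataset: int = 3
    planting_noise: float = 0.0
    decoy_noise: float = 0.0
    scaffold_pool: Sequence[str] = DEFAULT_SCAFFOLDS
    seed: int = 0
    endpoint: str = "irritation"

    def __post_init__(self):
        if not (0.0 <= self.planting_noise <= 1.0):
            raise ValueError("planting_noise must be in [0, 1]")
        if not (0.0 <= self.decoy_noise <= 1.0):
            raise ValueError("decoy_noise must be in [0, 1]")


@dataclass
class Manifest:
    """Ground truth for one generated dataset."""

    motifs: list[str]
    entries: list[dict] = field(default_factory=list)  # record_id, label, motif

    @property
    def n_active(self) -> int:
        return sum(1 for e in self.entries if e["label"] == "active")

    @property
    def n_inactive(self) -> int:
        return sum(1 for e in self.entries if e["label"] == "inactive")

    def motif_of(self, record_id: str) -> str | None:
        for e in self.entries:
            if e["record_id"] == record_id:
                return e["motif"]
        raise KeyError(record_id)


def default_motif_pool(endpoint: str = "irritation") -> list[str]:
    return [rule.pattern for rule in load_alert_table(endpoint)]


def _free_valence_atoms(mol: Chem.Mol, carbon_only: bool = False) -> list[int]:
    out = []
    for atom in mol.GetAtoms():
        if atom.GetTotalNumHs() < 1:
            continue
        if carbon_only and atom.GetAtomicNum() != 6:
            continue
        out.append(atom.GetIdx())
    return out


def graft(scaffold: Chem.Mol, motif: Chem.Mol, rng: np.random.Generator) -> Chem.Mol:
    """Attach a motif to a scaffold by one single bond.

    The attachment point on the scaffold is a carbon with a free valence; on
    the motif, a carbon with a free valence is preferred (falling back to any
    atom with one) so the heteroatom core of the motif stays untouched and
    the motif remains an exact subgraph of the product.
    """
    s_sites = _free_valence_atoms(scaffold, carbon_only=True)
    m_sites = _free_valence_atoms(motif, carbon_only=True) or _free_valence_atoms(motif)
    if not s_sites or not m_sites:
        raise ValueError(
            f"cannot graft {Chem.MolToSmiles(motif)!r} onto "
            f"{Chem.MolToSmiles(scaffold)!r}: no attachment-capable atom"
        )
    si = int(rng.choice(s_sites))
    mi = int(rng.choice(m_sites))
    combo = Chem.RWMol(Chem.CombineMols(scaffold, motif))
    combo.AddBond(si, scaffold.GetNumAtoms() + mi, Chem.BondType.SINGLE)
    product = combo.GetMol()
    Chem.SanitizeMol(product)
    return product


def _decorate(mol: Chem.Mol, rng: np.random.Generator, max_methyls: int = 2) -> Chem.Mol:
    """Add 0..max_methyls methyl groups at random carbons (diversity only).

    Methyl decoration cannot create an alert match: every packaged alert
    pattern contains a heteroatom arrangement untouched by adding carbons to
    a hydrocarbon/ether scaffold.
    """
    k = int(rng.integers(0, max_methyls + 1))
    for _ in range(k):
        sites = _free_valence_atoms(mol, carbon_only=True)
        if not sites:
            break
        rw = Chem.RWMol(mol)
        new_idx = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(int(rng.choice(sites)), new_idx, Chem.BondType.SINGLE)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
    return mol


def _matches_any(mol: Chem.Mol, queries: Sequence[Chem.Mol]) -> bool:
    return any(mol.HasSubstructMatch(q) for q in queries)


def generate_dataset(config: GeneratorConfig) -> tuple[list[MoleculeRecord], Manifest]:
    """Generate a labeled set with planted motifs and its ground-truth manifest.

    Actives (beyond the planting-noise fraction) are scaffolds carrying one
    chosen motif; inactives (beyond the decoy-noise fraction) are motif-free.
    The motif-free count is exactly ``round(planting_noise * n_active)`` and
    symmetrically for decoys.  Byte-identical output for identical config.
    """
    rng = np.random.default_rng(config.seed)
    pool = list(config.motif_pool) if config.motif_pool is not None else \
        default_motif_pool(config.endpoint)
    motif_smiles = [
        pool[i] for i in rng.choice(len(pool),
                                    size=min(config.motifs_per_dataset, len(pool)),
                                    replace=False)
    ]
    motifs = []
    for smi in motif_smiles:
        q = Chem.MolFromSmiles(smi)
        if q is None:
            raise ValueError(f"motif {smi!r} is not valid SMILES")
        motifs.append(q)

    # scaffolds must be clean w.r.t. the *entire* motif pool, so noise-free
    # molecules stay motif-free under any chosen subset
    pool_queries = [Chem.MolFromSmiles(s) for s in pool]
    scaffolds = []
    for smi in config.scaffold_pool:
        m = Chem.MolFromSmiles(smi)
        if m is not None and not _matches_any(m, pool_queries):
            scaffolds.append(m)
    if not scaffolds:
        raise ValueError("no scaffold in the pool is free of the motif pool")

    n_bare_active = round(config.planting_noise * config.n_active)
    n_decoy = round(config.decoy_noise * config.n_inactive)

    records: list[MoleculeRecord] = []
    manifest = Manifest(motifs=motif_smiles)
    seen: set[str] = set()

    def emit(mol: Chem.Mol, label: str, motif: str | None, rid: str):
        rec = MoleculeRecord(
            record_id=rid, raw_input=Chem.MolToSmiles(mol), structure=mol,
            dedup_key=make_dedup_key(mol), label=label,
            endpoint=config.endpoint, provenance="synthetic",
        )
        records.append(rec)
        manifest.entries.append({"record_id": rid, "label": label, "motif": motif})

    def make_unique(build) -> Chem.Mol:
        mol = build()
        for _ in range(60):
            smi = Chem.MolToSmiles(mol)
            if smi not in seen:
                break
            mol = build()
        seen.add(Chem.MolToSmiles(mol))
        return mol

    for i in range(config.n_active):
        rid = f"act{i + 1}"
        if i < config.n_active - n_bare_active:
            k = i % len(motifs)
            mol = make_unique(lambda: graft(
                _decorate(scaffolds[int(rng.integers(len(scaffolds)))], rng),
                motifs[k], rng))
            emit(mol, "active", motif_smiles[k], rid)
        else:  # planting noise: active without any motif
            mol = make_unique(lambda: _decorate(
                scaffolds[int(rng.integers(len(scaffolds)))], rng, max_methyls=3))
            emit(mol, "active", None, rid)

    for i in range(config.n_inactive):
        rid = f"inact{i + 1}"
        if i < n_decoy:  # decoy noise: inactive carrying a motif
            k = int(rng.integers(len(motifs)))
            mol = make_unique(lambda: graft(
                _decorate(scaffolds[int(rng.integers(len(scaffolds)))], rng),
                motifs[k], rng))
            emit(mol, "inactive", motif_smiles[k], rid)
        else:
            mol = make_unique(lambda: _decorate(
                scaffolds[int(rng.integers(len(scaffolds)))], rng, max_methyls=3))
            emit(mol, "inactive", None, rid)

    return records, manifest


# ---------------------------------------------------------------------------
# feature-separable sets for model benchmarks

_FAMILY_A = ("BrCCCC", "BrCCCCC", "BrCC(C)C", "Brc1ccccc1", "BrCc1ccccc1",
             "BrCC1CCCCC1", "BrCCCBr", "BrC1CCCCC1")
_FAMILY_B = ("OCCCC", "OCCCCC", "OCC(C)C", "OCC1CCCCC1", "CCOCC",
             "OCCOCC", "OC1CCCCC1", "OCCCO")


def generate_feature_separable_set(
    n: int, separation: float = 1.0, seed: int = 0,
) -> list[MoleculeRecord]:
    """Binary-labeled molecules whose classes come from two structure families.

    At ``separation`` 1.0 every active is drawn from the brominated family
    and every inactive from the hydroxyl/ether family, so fingerprint
    supports are disjoint and any sane learner separates them; at 0.0 the
    family is independent of the label and features carry no signal.
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    if not (0.0 <= separation <= 1.0):
        raise ValueError("separation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fam_a = [Chem.MolFromSmiles(s) for s in _FAMILY_A]
    fam_b = [Chem.MolFromSmiles(s) for s in _FAMILY_B]
    records = []
    for i in range(n):
        label = "active" if i < (n + 1) // 2 else "inactive"
        follows = rng.random() < 0.5 + separation / 2.0
        family = fam_a if (label == "active") == follows else fam_b
        base = family[int(rng.integers(len(family)))]
        mol = _decorate(base, rng, max_methyls=3)
        records.append(MoleculeRecord(
            record_id=f"sep{i + 1}", raw_input=Chem.MolToSmiles(mol),
            structure=mol, dedup_key=make_dedup_key(mol), label=label,
            provenance="synthetic-separable",
        ))
    return records
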