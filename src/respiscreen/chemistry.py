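"""Structure ingestion, curation and deduplication.

The curation pipeline mirrors standard QSAR-ready preparation of GHS-style
hazard datasets: counterions are stripped from salts, remaining structures are
charge-neutralized where chemically valid, and mixtures, inorganics and
metallo-organics are rejected.  Surviving structures are canonicalized and
deduplicated on an InChIKey, with conflicting activity labels resolved in
favour of the positive call (negative calls in such collections are usually
based on indirect evidence).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import inchi
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Elements compatible with an organic structure; anything else is treated as
#: a metal and triggers inorganic/metallo-organic rejection.  Si is allowed
#: because chlorosilanes are bona fide respiratory irritants.
ORGANIC_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"]
)

LABELS = ("active", "inactive", "unlabeled")
ENDPOINTS = ("irritation", "sensitization", "none")

_LABEL_SYNONYMS = {
    "active": "active", "positive": "active", "pos": "active", "1": "active",
    "true": "active", "toxic": "active",
    "inactive": "inactive", "negative": "inactive", "neg": "inactive",
    "0": "inactive", "false": "inactive", "nontoxic": "inactive",
    "": "unlabeled", "na": "unlabeled", "none": "unlabeled",
    "unlabeled": "unlabeled",
}


def normalize_label(raw: str | None) -> str:
    if raw is None:
        return "unlabeled"
    key = str(raw).strip().lower()
    if key not in _LABEL_SYNONYMS:
        raise ValueError(f"unrecognized activity label: {raw!r}")
    return _LABEL_SYNONYMS[key]


@dataclass
class MoleculeRecord:
    """One chemical: raw input, curated structure and bookkeeping."""

    record_id: str
    raw_input: str
    structure: Chem.Mol | None = None
    dedup_key: str | None = None
    label: str = "unlabeled"
    endpoint: str = "none"
    provenance: str = ""

    @property
    def smiles(self) -> str | None:
        """Canonical SMILES of the curated structure (None if unparsable)."""
        if self.structure is None:
            return None
        return Chem.MolToSmiles(self.structure)


@dataclass
class CurationReport:
    """Per-category accounting for one curation + deduplication pass."""

    n_input: int = 0
    n_rejected_mixture: int = 0
    n_rejected_inorganic: int = 0
    n_rejected_organometallic: int = 0
    n_unparsable: int = 0
    n_duplicates_merged: int = 0
    n_output: int = 0
    rejections: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        rejected = (
            self.n_rejected_mixture
            + self.n_rejected_inorganic
            + self.n_rejected_organometallic
            + self.n_unparsable
        )
        return self.n_output == self.n_input - rejected - self.n_duplicates_merged

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_rejected_mixture": self.n_rejected_mixture,
            "n_rejected_inorganic": self.n_rejected_inorganic,
            "n_rejected_organometallic": self.n_rejected_organometallic,
            "n_unparsable": self.n_unparsable,
            "n_duplicates_merged": self.n_duplicates_merged,
            "n_output": self.n_output,
        }


@dataclass
class CurationConfig:
    """Knobs for the curation pipeline.

    neutralize: attempt to remove formal charges (ionized acids/bases);
        zwitterions that cannot be neutralized without a valence violation are
        kept and logged, not rejected.
    require_carbon: structures without a carbon atom are rejected as inorganic.
    allowed_elements: element symbols compatible with an organic structure.
    """

    neutralize: bool = True
    require_carbon: bool = True
    allowed_elements: frozenset[str] = ORGANIC_ELEMENTS


# ---------------------------------------------------------------------------
# parsing


def parse_structures(
    source: str | Path,
    fmt: str | None = None,
    smiles_column: str = "smiles",
    id_column: str = "record_id",
    label_column: str = "label",
    endpoint: str = "none",
    provenance: str = "",
) -> list[MoleculeRecord]:
    """Read molecules from a SMILES list, a CSV table, or an SDF.

    The format is taken from the file extension unless ``fmt`` is one of
    ``smiles``, ``csv`` or ``sdf``.  Unparsable entries are kept as records
    with ``structure=None`` so that curation can count them; they are never
    silently dropped.
    """
    path = Path(source)
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"smi": "smiles", "smiles": "smiles", "txt": "smiles",
               "csv": "csv", "tsv": "csv", "sdf": "sdf"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}; pass fmt=")
    if fmt == "smiles":
        return _parse_smiles_file(path, endpoint, provenance)
    if fmt == "csv":
        return _parse_csv(path, smiles_column, id_column, label_column,
                          endpoint, provenance)
    if fmt == "sdf":
        return _parse_sdf(path, endpoint, provenance)
    raise ValueError(f"unknown format {fmt!r}")


def records_from_smiles(
    smiles: Sequence[str],
    labels: Sequence[str] | None = None,
    ids: Sequence[str] | None = None,
    endpoint: str = "none",
    provenance: str = "",
) -> list[MoleculeRecord]:
    """Build records directly from in-memory SMILES (convenience entry point)."""
    out = []
    for i, smi in enumerate(smiles):
        rec = MoleculeRecord(
            record_id=ids[i] if ids is not None else f"mol{i + 1}",
            raw_input=smi,
            structure=Chem.MolFromSmiles(smi),
            label=normalize_label(labels[i]) if labels is not None else "unlabeled",
            endpoint=endpoint,
            provenance=provenance,
        )
        out.append(rec)
    return out


def _parse_smiles_file(path: Path, endpoint: str, provenance: str):
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smi = parts[0]
            rid = parts[1] if len(parts) > 1 else f"mol{i + 1}"
            records.append(MoleculeRecord(
                record_id=rid, raw_input=smi,
                structure=Chem.MolFromSmiles(smi),
                endpoint=endpoint, provenance=provenance or str(path),
            ))
    return records


def _parse_csv(path: Path, smiles_column, id_column, label_column,
               endpoint, provenance):
    records = []
    delim = "\t" if path.suffix.lower() == ".tsv" else ","
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            return records
        if smiles_column not in reader.fieldnames:
            raise ValueError(
                f"CSV {path.name!r} lacks a {smiles_column!r} column "
                f"(found {reader.fieldnames})"
            )
        for i, row in enumerate(reader):
            smi = (row.get(smiles_column) or "").strip()
            records.append(MoleculeRecord(
                record_id=(row.get(id_column) or f"mol{i + 1}").strip(),
                raw_input=smi,
                structure=Chem.MolFromSmiles(smi) if smi else None,
                label=normalize_label(row.get(label_column)),
                endpoint=(row.get("endpoint") or endpoint).strip() or "none",
                provenance=provenance or str(path),
            ))
    return records


def _parse_sdf(path: Path, endpoint: str, provenance: str):
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        rid = f"mol{i + 1}"
        label = "unlabeled"
        raw = ""
        if mol is not None:
            if mol.HasProp("_Name") and mol.GetProp("_Name").strip():
                rid = mol.GetProp("_Name").strip()
            if mol.HasProp("label"):
                label = normalize_label(mol.GetProp("label"))
            raw = Chem.MolToSmiles(mol)
        records.append(MoleculeRecord(
            record_id=rid, raw_input=raw, structure=mol, label=label,
            endpoint=endpoint, provenance=provenance or str(path),
        ))
    return records


# ---------------------------------------------------------------------------
# curation

_UNCHARGER = rdMolStandardize.Uncharger()


def _has_carbon(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def _disallowed_elements(mol: Chem.Mol, allowed: frozenset[str]) -> set[str]:
    return {a.GetSymbol() for a in mol.GetAtoms() if a.GetSymbol() not in allowed}


def _curate_one(mol: Chem.Mol, config: CurationConfig) -> tuple[Chem.Mol | None, str]:
    """Curate a single parsed molecule.

    Returns (curated mol, "ok"/"zwitterion") or (None, rejection reason).
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if _has_carbon(f)]
    if config.require_carbon and not organic:
        return None, "inorganic"
    # counterion removal: fragments without carbon are salts/solvents
    if len(organic) > 1:
        return None, "mixture"
    kept = organic[0] if organic else frags[0]
    bad = _disallowed_elements(kept, config.allowed_elements)
    if bad:
        return None, f"organometallic:{','.join(sorted(bad))}"
    try:
        Chem.SanitizeMol(kept)
    except Exception:
        return None, "unparsable"
    if config.neutralize:
        kept = _UNCHARGER.uncharge(kept)
    status = "ok"
    if Chem.GetFormalCharge(kept) != 0:
        status = "zwitterion"  # kept, but flagged in the rejection log
    return kept, status


def make_dedup_key(mol: Chem.Mol) -> str:
    """Collision-safe canonical key for a standardized structure.

    InChIKey (layered hash of the standardized connection table, including the
    stereo layer when present); canonical SMILES fallback for structures InChI
    cannot represent.
    """
    try:
        key = inchi.MolToInchiKey(mol)
    except Exception:
        key = ""
    return key if key else "SMI:" + Chem.MolToSmiles(mol)


def curate(
    records: Iterable[MoleculeRecord],
    config: CurationConfig | None = None,
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Apply desalting, neutralization and rejection rules to parsed records.

    Rejection is an accounted outcome, never an exception; every input record
    lands either in the output or in exactly one report category.
    """
    config = config or CurationConfig()
    report = CurationReport()
    out: list[MoleculeRecord] = []
    for rec in records:
        report.n_input += 1
        if rec.structure is None:
            report.n_unparsable += 1
            report.rejections.append((rec.record_id, "unparsable", rec.raw_input))
            continue
        mol, status = _curate_one(rec.structure, config)
        if mol is None:
            if status == "mixture":
                report.n_rejected_mixture += 1
            elif status == "inorganic":
                report.n_rejected_inorganic += 1
            elif status.startswith("organometallic"):
                report.n_rejected_organometallic += 1
            else:
                report.n_unparsable += 1
            report.rejections.append((rec.record_id, status, rec.raw_input))
            continue
        if status == "zwitterion":
            report.rejections.append((rec.record_id, "kept-zwitterion", rec.raw_input))
        out.append(replace(rec, structure=mol, dedup_key=make_dedup_key(mol)))
    report.n_output = len(out)
    return out, report


def deduplicate(
    records: Iterable[MoleculeRecord],
    report: CurationReport | None = None,
) -> list[MoleculeRecord]:
    """Merge records sharing a dedup_key; a positive label wins any conflict.

    Output order follows first appearance of each key, so the resulting
    (dedup_key, label) set is independent of input order.
    """
    merged: dict[str, MoleculeRecord] = {}
    n_merged = 0
    for rec in records:
        if rec.dedup_key is None:
            raise ValueError(f"record {rec.record_id} is not curated (no dedup_key)")
        prev = merged.get(rec.dedup_key)
        if prev is None:
            merged[rec.dedup_key] = rec
            continue
        n_merged += 1
        if rec.label == "active" and prev.label != "active":
            merged[rec.dedup_key] = replace(rec, record_id=prev.record_id)
        elif prev.label == "unlabeled" and rec.label == "inactive":
            merged[rec.dedup_key] = replace(rec, record_id=prev.record_id)
    if report is not None:
        report.n_duplicates_merged += n_merged
        report.n_output = len(merged)
    return list(merged.values())


def curate_and_deduplicate(
    records: Iterable[MoleculeRecord],
    config: CurationConfig | None = None,
) -> tuple[list[MoleculeRecord], CurationReport]:
    curated, report = curate(records, config)
    unique = deduplicate(curated, report)
    return unique, report


# ---------------------------------------------------------------------------
# output


def write_curated_csv(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "smiles", "dedup_key", "label", "endpoint"])
        for rec in records:
            writer.writerow([rec.record_id, rec.smiles, rec.dedup_key,
                             rec.label, rec.endpoint])


def write_report_json(report: CurationReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")


def write_rejection_log(report: CurationReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, reason, raw in report.rejections:
            fh.write(f"{rid}\t{reason}\t{raw}\n")
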