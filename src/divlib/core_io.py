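"""Structure parsing, canonicalization, deduplication and tabular I/O.

Every other module consumes :class:`CompoundSet` objects produced here.
Salt/solvent handling keeps the largest organic fragment (heavy-atom count,
ties by molecular weight). Stereochemistry is preserved in stored structures
but ignored for deduplication keys, matching the stereo-insensitive
fingerprints used downstream.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

#: candidate structure-column names, tried case-insensitively in order
STRUCTURE_COLUMN_CANDIDATES = ("smiles", "canonical_smiles", "structure", "smi")


class ParseError(ValueError):
    """A structure string that RDKit could not parse."""

    def __init__(self, text: str, reason: str = "unparseable SMILES"):
        self.text = text
        self.reason = reason
        super().__init__(f"{reason}: {text!r}")


@dataclass
class RejectedRow:
    row: int
    input: str
    reason: str


@dataclass
class CompoundRecord:
    """One molecule plus its provenance, computed properties and flags."""

    id: str
    smiles_input: str
    smiles_canonical: str
    sublibrary_id: Optional[str] = None
    complexity: Optional[str] = None  # "simple" | "complex"
    properties: Optional[object] = None  # properties.PropertyVector
    flags: set = field(default_factory=set)
    metadata: dict = field(default_factory=dict)

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles_canonical)
        if m is None:  # pragma: no cover - canonical strings always reparse
            raise ParseError(self.smiles_canonical, "stored canonical SMILES failed to reparse")
        return m

    @property
    def key(self) -> str:
        """Stereo-insensitive canonical key used for dedup/novelty joins."""
        return self.metadata.setdefault(
            "_key", Chem.MolToSmiles(self.mol(), isomericSmiles=False)
        )


@dataclass
class CompoundSet:
    """An ordered collection of records with a provenance trail."""

    records: list[CompoundRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    rejects: list[RejectedRow] = field(default_factory=list)
    stats: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def canonical_multiset(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.smiles_canonical] = out.get(r.smiles_canonical, 0) + 1
        return out

    def with_records(self, records: Sequence[CompoundRecord], stage: str) -> "CompoundSet":
        return CompoundSet(records=list(records), provenance=self.provenance + [stage])

    def subset_by_ids(self, ids: Iterable[str], stage: str) -> "CompoundSet":
        wanted = set(ids)
        return self.with_records([r for r in self.records if r.id in wanted], stage)


def parse_structure(text: str) -> Chem.Mol:
    """Parse a SMILES string into a molecule graph.

    Aromaticity is perceived and salts/solvents are stripped down to the
    largest organic fragment (heavy atoms, ties by molecular weight).
    Raises :class:`ParseError` for unparseable input.
    """
    if not text or not text.strip():
        raise ParseError(text, "empty structure string")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ParseError(text)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Descriptors.MolWt(m)))
    return mol


def canonicalize(mol: Chem.Mol) -> str:
    """Canonical (stereo-preserving) SMILES; invariant to input atom order."""
    return Chem.MolToSmiles(mol)


def canonical_key(mol: Chem.Mol) -> str:
    """Stereo-insensitive canonical SMILES used as the dedup/novelty key."""
    return Chem.MolToSmiles(mol, isomericSmiles=False)


def record_from_smiles(
    id: str,
    smiles: str,
    sublibrary_id: Optional[str] = None,
    complexity: Optional[str] = None,
    metadata: Optional[dict] = None,
) -> CompoundRecord:
    mol = parse_structure(smiles)
    return CompoundRecord(
        id=id,
        smiles_input=smiles,
        smiles_canonical=canonicalize(mol),
        sublibrary_id=sublibrary_id,
        complexity=complexity,
        metadata=dict(metadata or {}),
    )


def _detect_structure_column(header: list[str], rows: list[dict]) -> str:
    lowered = {c.lower(): c for c in header}
    for cand in STRUCTURE_COLUMN_CANDIDATES:
        if cand in lowered:
            return lowered[cand]
    # fall back: the column whose values parse most often over the first rows
    best, best_rate = None, 0.0
    for col in header:
        sample = [r.get(col, "") for r in rows[:50]]
        sample = [s for s in sample if s]
        if not sample:
            continue
        ok = sum(1 for s in sample if Chem.MolFromSmiles(s) is not None)
        rate = ok / len(sample)
        if rate > best_rate:
            best, best_rate = col, rate
    if best is None or best_rate < 0.5:
        raise ValueError(
            f"could not locate a structure column; tried {STRUCTURE_COLUMN_CANDIDATES} "
            f"and per-column parse detection over header {header}"
        )
    return best


def read_compound_table(
    path: str | Path,
    format: str = "csv",
    smiles_column: str = "SMILES",
    id_column: str = "ID",
) -> CompoundSet:
    """Read a compound table (CSV or SDF) into a CompoundSet.

    Unparseable rows are quarantined on ``result.rejects`` with their row
    number and reason rather than aborting the read. If the named SMILES
    column is absent from a CSV, the structure column is auto-detected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = CompoundSet(provenance=[f"read:{path.name}"])
    if format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                warnings.warn(f"{path}: empty file, returning empty set")
                return out
            rows = list(reader)
        header = list(reader.fieldnames)
        col = smiles_column if smiles_column in header else _detect_structure_column(header, rows)
        idcol = id_column if id_column in header else None
        for i, row in enumerate(rows):
            smi = (row.get(col) or "").strip()
            rid = row[idcol].strip() if idcol and row.get(idcol) else f"{path.stem}-{i + 1}"
            meta = {k: v for k, v in row.items() if k not in (col, idcol)}
            try:
                rec = record_from_smiles(rid, smi, metadata=meta)
            except ParseError as exc:
                out.rejects.append(RejectedRow(row=i + 2, input=smi, reason=exc.reason))
                continue
            out.records.append(rec)
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                out.rejects.append(RejectedRow(row=i + 1, input="<molblock>", reason="unparseable molblock"))
                continue
            rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"{path.stem}-{i + 1}"
            meta = {k: mol.GetProp(k) for k in mol.GetPropNames()}
            smi = canonicalize(mol)
            out.records.append(
                CompoundRecord(id=rid, smiles_input=smi, smiles_canonical=smi, metadata=meta)
            )
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'sdf')")
    if not out.records and not out.rejects:
        warnings.warn(f"{path}: no records read")
    return out


def write_compound_table(cs: CompoundSet, path: str | Path, format: str = "csv") -> None:
    """Write a CompoundSet as CSV (ID,SMILES,+metadata) or SDF V2000."""
    path = Path(path)
    if format == "csv":
        meta_cols: list[str] = []
        for r in cs.records:
            for k in r.metadata:
                if not k.startswith("_") and k not in meta_cols:
                    meta_cols.append(k)
        extra = ["SUBLIBRARY", "COMPLEXITY", "FLAGS"]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["ID", "SMILES", *extra, *meta_cols])
            for r in cs.records:
                writer.writerow(
                    [
                        r.id,
                        r.smiles_canonical,
                        r.sublibrary_id or "",
                        r.complexity or "",
                        ";".join(sorted(r.flags)),
                        *[r.metadata.get(c, "") for c in meta_cols],
                    ]
                )
    elif format == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for r in cs.records:
                mol = r.mol()
                mol.SetProp("_Name", r.id)
                for k, v in r.metadata.items():
                    if not k.startswith("_"):
                        mol.SetProp(k, str(v))
                writer.write(mol)
        finally:
            writer.close()
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'sdf')")


def write_rejects(cs: CompoundSet, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "input", "reason"])
        for rj in cs.rejects:
            writer.writerow([rj.row, rj.input, rj.reason])


def deduplicate(cs: CompoundSet) -> CompoundSet:
    """Drop records sharing a stereo-insensitive canonical key, keeping the
    first occurrence. The removed count lands in ``result.stats``."""
    seen: set[str] = set()
    kept: list[CompoundRecord] = []
    for r in cs.records:
        k = r.key
        if k in seen:
            continue
        seen.add(k)
        kept.append(r)
    out = cs.with_records(kept, "deduplicate")
    out.stats["n_duplicates_removed"] = len(cs) - len(kept)
    return out
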