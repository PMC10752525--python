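"""Physicochemical property vectors, charge classification and staged windows.

The solubility forecast index (SFI) is clogD(pH 7.4) plus the aromatic ring
count. clogD is approximated as slogP minus a fixed ionization penalty of
1.0 for records classified acid or base (monoprotic ionization at pH 7.4
shifts logD down); the function is pluggable for callers with a real
predictor. Charge classification is by substructure pattern, not pKa.
All filter windows are closed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from importlib import resources
from typing import Callable, Optional

import yaml
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from divlib.core_io import CompoundSet

ACID = "acid"
BASE = "base"
NEUTRAL = "neutral"

#: acidic ionizable groups: carboxylic acid, tetrazole, acyl sulfonamide
_ACID_SMARTS = (
    "[CX3](=O)[OX2H1]",
    "c1nnn[nH]1",
    "c1nn[nH]n1",
    "[SX4](=[OX1])(=[OX1])[NX3H][CX3]=[OX1]",
)
#: basic amines (aliphatic 1°/2°/3°), amidines, guanidines; amides, anilines
#: and azole/aromatic nitrogens are excluded
_BASE_SMARTS = (
    "[NX3;+0;H2,H1,H0;!$(N-c);!$(N-C=[O,N,S]);!$(N-S(=O)=O);!$(N-[!#6;!#1]);!$(N=*)]",
    "[NX3][CX3]=[NX2]",
    "[NX3][CX3](=[NX2])[NX3]",
)

_ACID_PATTERNS = [Chem.MolFromSmarts(s) for s in _ACID_SMARTS]
_BASE_PATTERNS = [Chem.MolFromSmarts(s) for s in _BASE_SMARTS]


@dataclass
class PropertyVector:
    mwt: float
    slogp: float
    clogd: float
    tpsa: float
    hbd: int
    hba: int
    rotb: int
    arom_rings: int
    sp3_fraction: float
    sfi: float
    charge_class: str

    def get(self, name: str) -> float:
        return getattr(self, name)


NUMERIC_FIELDS = tuple(f.name for f in fields(PropertyVector) if f.name != "charge_class")


def classify_charge(mol: Chem.Mol) -> str:
    """Assign acid / base / neutral by ionizable-group patterns at pH 7.4.

    Acid takes precedence over base when both match (zwitterions such as
    amino acids classify as acid).
    """
    for p in _ACID_PATTERNS:
        if p is not None and mol.HasSubstructMatch(p):
            return ACID
    for p in _BASE_PATTERNS:
        if p is not None and mol.HasSubstructMatch(p):
            return BASE
    return NEUTRAL


def compute_sfi(clogd: float, arom_rings: int) -> float:
    """Solubility forecast index: clogD + aromatic ring count."""
    if arom_rings < 0:
        raise ValueError("arom_rings must be non-negative")
    return clogd + arom_rings


def default_clogd(slogp: float, charge_class: str) -> float:
    """slogP minus a 1.0 ionization penalty for acids/bases (documented approximation)."""
    return slogp - (1.0 if charge_class in (ACID, BASE) else 0.0)


def compute_properties(
    mol: Chem.Mol, clogd_fn: Callable[[float, str], float] = default_clogd
) -> PropertyVector:
    """Compute the full property vector for one molecule; deterministic."""
    slogp = Crippen.MolLogP(mol)
    charge = classify_charge(mol)
    clogd = clogd_fn(slogp, charge)
    arom = rdMolDescriptors.CalcNumAromaticRings(mol)
    return PropertyVector(
        mwt=Descriptors.MolWt(mol),
        slogp=slogp,
        clogd=clogd,
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        rotb=rdMolDescriptors.CalcNumRotatableBonds(
            mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
        ),
        arom_rings=arom,
        sp3_fraction=rdMolDescriptors.CalcFractionCSP3(mol),
        sfi=compute_sfi(clogd, arom),
        charge_class=charge,
    )


def annotate_properties(cs: CompoundSet) -> CompoundSet:
    """Fill ``record.properties`` in place for every record; returns the set."""
    for r in cs.records:
        if r.properties is None:
            r.properties = compute_properties(r.mol())
    return cs


@dataclass
class PropertyWindow:
    """Named closed ranges over numeric PropertyVector fields."""

    name: str
    ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for field_name, (lo, hi) in self.ranges.items():
            if field_name not in NUMERIC_FIELDS:
                raise ValueError(
                    f"window {self.name!r} names unknown property field {field_name!r}; "
                    f"known fields: {NUMERIC_FIELDS}"
                )
            if lo > hi:
                raise ValueError(f"window {self.name!r}: range for {field_name} has lower > upper")

    def failing_fields(self, pv: PropertyVector) -> list[str]:
        out = []
        for field_name, (lo, hi) in self.ranges.items():
            v = pv.get(field_name)
            if not (lo <= v <= hi):
                out.append(field_name)
        return out

    def passes(self, pv: PropertyVector) -> bool:
        return not self.failing_fields(pv)


_INF = float("inf")


def load_windows(path=None) -> dict[str, PropertyWindow]:
    """Load staged windows from YAML (defaults ship with the package).

    Stages: ``wide``, ``crude``, ``agreed``. Missing bounds mean unbounded.
    """
    if path is None:
        text = resources.files("divlib").joinpath("data/windows.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out = {}
    for stage, spec in raw.items():
        ranges = {}
        for field_name, bounds in spec.items():
            lo = bounds.get("min", -_INF)
            hi = bounds.get("max", _INF)
            ranges[field_name] = (float(lo), float(hi))
        out[stage] = PropertyWindow(name=stage, ranges=ranges)
    return out


def apply_property_filter(cs: CompoundSet, window: PropertyWindow) -> CompoundSet:
    """Keep records whose every windowed field lies within its closed range.

    Per-field rejection counts land in ``result.stats['rejected_by_field']``;
    each rejected record id and its first failing field are recorded in
    ``result.stats['rejections']``.
    """
    kept = []
    by_field: dict[str, int] = {f: 0 for f in window.ranges}
    rejections: list[tuple[str, str]] = []
    for r in cs.records:
        if r.properties is None:
            r.properties = compute_properties(r.mol())
        failing = window.failing_fields(r.properties)
        if failing:
            for f in failing:
                by_field[f] += 1
            rejections.append((r.id, failing[0]))
        else:
            kept.append(r)
    out = cs.with_records(kept, f"window:{window.name}")
    out.stats["rejected_by_field"] = by_field
    out.stats["rejections"] = rejections
    return out
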