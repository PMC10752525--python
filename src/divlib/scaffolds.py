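"""Bemis-Murcko scaffold / generic-framework decomposition and statistics.

A scaffold is the molecule's ring systems plus connecting linkers with side
chains removed (exocyclic double bonds retained, the common convention); a
framework further abstracts every atom to carbon and every bond to single.
Acyclic molecules have no scaffold and are tallied in a separate bucket,
excluded from the uniqueness denominator by default.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from divlib.core_io import CompoundSet

SCAFFOLD = "scaffold"
FRAMEWORK = "framework"


def murcko_scaffold(mol: Chem.Mol) -> str:
    """Canonical SMILES of the Bemis-Murcko scaffold; '' for acyclic input."""
    scaf = MurckoScaffold.GetScaffoldForMol(mol)
    if scaf is None or scaf.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaf, isomericSmiles=False)


def murcko_framework(mol: Chem.Mol) -> str:
    """Generic framework: scaffold with all atoms carbon, all bonds single."""
    scaf = MurckoScaffold.GetScaffoldForMol(mol)
    if scaf is None or scaf.GetNumAtoms() == 0:
        return ""
    generic = MurckoScaffold.MakeScaffoldGeneric(scaf)
    return Chem.MolToSmiles(generic, isomericSmiles=False)


def _decompose(cs: CompoundSet, mode: str) -> tuple[Counter, int]:
    if mode not in (SCAFFOLD, FRAMEWORK):
        raise ValueError(f"mode must be '{SCAFFOLD}' or '{FRAMEWORK}', got {mode!r}")
    fn = murcko_scaffold if mode == SCAFFOLD else murcko_framework
    counter: Counter = Counter()
    n_acyclic = 0
    for r in cs.records:
        s = fn(r.mol())
        if s == "":
            n_acyclic += 1
        else:
            counter[s] += 1
    return counter, n_acyclic


@dataclass
class ScaffoldReport:
    n_compounds: int
    n_acyclic: int
    n_distinct_scaffolds: int
    n_distinct_frameworks: int
    unique_fraction: float  # percent
    singleton_fraction: float  # percent of scaffolds occurring exactly once
    mode: str
    counts: dict[str, int] = field(repr=False, default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_compounds": self.n_compounds,
            "n_acyclic": self.n_acyclic,
            "n_distinct_scaffolds": self.n_distinct_scaffolds,
            "n_distinct_frameworks": self.n_distinct_frameworks,
            "unique_fraction": self.unique_fraction,
            "singleton_fraction": self.singleton_fraction,
            "mode": self.mode,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def counts_to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["scaffold_smiles", "count"])
            for smi, c in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0])):
                w.writerow([smi, c])


def scaffold_report(
    cs: CompoundSet, mode: str = SCAFFOLD, include_acyclic: bool = False
) -> ScaffoldReport:
    """Distinct-scaffold statistics for a set.

    ``unique_fraction`` is 100 * distinct / denominator where the
    denominator is the cyclic compound count (all compounds when
    ``include_acyclic``, in which case the acyclic bucket counts as one
    extra distinct entry). ``singleton_fraction`` is the alternative
    reading — percent of scaffolds occurring exactly once — reported
    alongside.
    """
    if len(cs) == 0:
        raise ValueError("scaffold_report requires a non-empty set")
    counter, n_acyclic = _decompose(cs, mode)
    frame_counter, _ = (counter, n_acyclic) if mode == FRAMEWORK else _decompose(cs, FRAMEWORK)
    denom = len(cs) if include_acyclic else len(cs) - n_acyclic
    distinct = len(counter) + (1 if include_acyclic and n_acyclic else 0)
    unique_fraction = 100.0 * distinct / denom if denom else 0.0
    singletons = sum(1 for c in counter.values() if c == 1)
    singleton_fraction = 100.0 * singletons / len(counter) if counter else 0.0
    return ScaffoldReport(
        n_compounds=len(cs),
        n_acyclic=n_acyclic,
        n_distinct_scaffolds=len(counter) if mode == SCAFFOLD else len(_decompose(cs, SCAFFOLD)[0]),
        n_distinct_frameworks=len(frame_counter),
        unique_fraction=unique_fraction,
        singleton_fraction=singleton_fraction,
        mode=mode,
        counts=dict(counter),
    )


@dataclass
class AddedValueReport:
    n_base: int
    new_a: int
    new_b: int
    mode: str

    @property
    def ratio(self) -> float:
        """new_a / new_b; inf when b adds nothing but a does."""
        if self.new_b == 0:
            return float("inf") if self.new_a else float("nan")
        return self.new_a / self.new_b


def added_value(
    base: CompoundSet, addition_a: CompoundSet, addition_b: CompoundSet, mode: str = FRAMEWORK
) -> AddedValueReport:
    """Count scaffolds/frameworks each addition brings that the base lacks."""
    base_set = set(_decompose(base, mode)[0])
    new_a = len(set(_decompose(addition_a, mode)[0]) - base_set)
    new_b = len(set(_decompose(addition_b, mode)[0]) - base_set)
    return AddedValueReport(n_base=len(base_set), new_a=new_a, new_b=new_b, mode=mode)
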