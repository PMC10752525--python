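"""Basis-set and capped super-set enumeration from two-component reactions.

A basis set represents an |A| x |B| combinatorial space with |A| + |B| - 1
products: every A-block coupled to the lowest-MW B-block, plus every other
B-block coupled to the lowest-MW A-block. "Lowest MW" ties are broken
lexicographically by canonical SMILES. Super-sets sample block PAIRS (not
materialized products) so caps are respected without enumerating the full
cross-product.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

import yaml
from rdkit import Chem
from rdkit.Chem import Descriptors, rdChemReactions

from divlib.core_io import CompoundRecord, CompoundSet, RejectedRow, canonicalize, parse_structure


@dataclass
class ReactionDef:
    reaction_id: str
    transform: str  # reaction SMARTS, role A reactant first
    role_a_name: str
    role_b_name: str
    _rxn: object = field(repr=False, compare=False, default=None)

    def rxn(self):
        if self._rxn is None:
            self._rxn = rdChemReactions.ReactionFromSmarts(self.transform)
            if self._rxn is None or self._rxn.GetNumReactantTemplates() != 2:
                raise ValueError(f"reaction {self.reaction_id}: transform must take two reactants")
        return self._rxn


@dataclass
class BuildingBlock:
    id: str
    smiles: str
    role: str
    cost_tier: str = "standard"  # "standard" | "expensive"
    mw: float = 0.0

    def __post_init__(self):
        if self.mw == 0.0:
            self.mw = Descriptors.MolWt(parse_structure(self.smiles))


@dataclass
class SublibraryDef:
    reaction: ReactionDef
    blocks_a: list[BuildingBlock]
    blocks_b: list[BuildingBlock]
    complexity: str = "simple"  # "simple" | "complex"
    sublibrary_id: Optional[str] = None

    def __post_init__(self):
        if not self.blocks_a or not self.blocks_b:
            raise ValueError("both block lists must be non-empty")
        if self.sublibrary_id is None:
            self.sublibrary_id = self.reaction.reaction_id


#: representative two-component chemistries shipped as fixtures
DEFAULT_REACTIONS = {
    "amide": ReactionDef(
        "amide",
        "[C:1](=[O:2])[OX2H1].[NX3;H2,H1;!$(N[C,S]=[O,S,N]):3]>>[C:1](=[O:2])[N:3]",
        "acid",
        "amine",
    ),
    "sulfonamide": ReactionDef(
        "sulfonamide",
        "[SX4:1](=[OX1:2])(=[OX1:3])[Cl].[NX3;H2,H1;!$(N[C,S]=[O,S,N]):4]>>[S:1](=[O:2])(=[O:3])[N:4]",
        "sulfonyl_chloride",
        "amine",
    ),
    "reductive_amination": ReactionDef(
        "reductive_amination",
        "[CX3;H1:1]=[OX1].[NX3;H2,H1;!$(N[C,S]=[O,S,N]):2]>>[C:1][N:2]",
        "aldehyde",
        "amine",
    ),
    "n_arylation": ReactionDef(
        "n_arylation",
        "[c:1][Br].[NX3;H2,H1;!$(N[C,S]=[O,S,N]):2]>>[c:1][N:2]",
        "aryl_bromide",
        "amine",
    ),
}


def _lowest_mw(blocks: list[BuildingBlock]) -> BuildingBlock:
    # ties by canonical SMILES so the choice is reproducible
    return min(blocks, key=lambda b: (b.mw, canonicalize(parse_structure(b.smiles))))


def run_pair(lib: SublibraryDef, a: BuildingBlock, b: BuildingBlock) -> Chem.Mol:
    """Apply the reaction to one block pair; raises ValueError on failure."""
    mol_a, mol_b = parse_structure(a.smiles), parse_structure(b.smiles)
    products = lib.reaction.rxn().RunReactants((mol_a, mol_b))
    if not products:
        raise ValueError(f"reaction {lib.reaction.reaction_id} produced nothing for ({a.id},{b.id})")
    prod = products[0][0]
    Chem.SanitizeMol(prod)
    return prod


def _product_record(lib: SublibraryDef, a: BuildingBlock, b: BuildingBlock) -> CompoundRecord:
    mol = run_pair(lib, a, b)
    smi = canonicalize(mol)
    return CompoundRecord(
        id=f"{lib.sublibrary_id}:{a.id}+{b.id}",
        smiles_input=smi,
        smiles_canonical=smi,
        sublibrary_id=lib.sublibrary_id,
        complexity=lib.complexity,
        metadata={"block_a": a.id, "block_b": b.id},
    )


def _emit(lib: SublibraryDef, pairs, out: CompoundSet) -> None:
    for a, b in pairs:
        try:
            out.records.append(_product_record(lib, a, b))
        except (ValueError, Chem.rdchem.KekulizeException) as exc:
            out.rejects.append(RejectedRow(row=-1, input=f"{a.id}+{b.id}", reason=str(exc)))
    out.stats["n_failed_pairs"] = len(out.rejects)


def build_basis_set(lib: SublibraryDef) -> CompoundSet:
    """|A| + |B| - 1 basis products: all of A against the lowest-MW B-block,
    plus B minus its lowest-MW member against the lowest-MW A-block."""
    small_a, small_b = _lowest_mw(lib.blocks_a), _lowest_mw(lib.blocks_b)
    pairs = [(a, small_b) for a in lib.blocks_a]
    pairs += [(small_a, b) for b in lib.blocks_b if b is not small_b]
    out = CompoundSet(provenance=[f"basis:{lib.sublibrary_id}"])
    _emit(lib, pairs, out)
    return out


def enumerate_superset(lib: SublibraryDef, cap: int, seed: int) -> CompoundSet:
    """Full cross-product if it fits under ``cap``, else exactly ``cap``
    distinct block pairs sampled uniformly (reproducible for a seed)."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    na, nb = len(lib.blocks_a), len(lib.blocks_b)
    total = na * nb
    if total <= cap:
        pairs = [(a, b) for a in lib.blocks_a for b in lib.blocks_b]
    else:
        rng = random.Random(seed)
        flat = rng.sample(range(total), cap)
        pairs = [(lib.blocks_a[i // nb], lib.blocks_b[i % nb]) for i in flat]
    out = CompoundSet(provenance=[f"superset:{lib.sublibrary_id}:cap={cap},seed={seed}"])
    _emit(lib, pairs, out)
    return out


def sample_representatives(
    lib_products: CompoundSet, n_low: int = 3, n_rand: int = 5, seed: int = 0
) -> CompoundSet:
    """Triage-review sample: the ``n_low`` lowest-MW products (ties by
    canonical string) plus ``n_rand`` uniform picks from the remainder."""
    from divlib.properties import compute_properties

    def mwt(r: CompoundRecord) -> float:
        if r.properties is not None:
            return r.properties.mwt
        return compute_properties(r.mol()).mwt

    ranked = sorted(lib_products.records, key=lambda r: (mwt(r), r.smiles_canonical))
    low = ranked[:n_low]
    rest = ranked[n_low:]
    rng = random.Random(seed)
    rand = rng.sample(rest, min(n_rand, len(rest)))
    return lib_products.with_records(low + rand, f"representatives:{n_low}+{n_rand}")


def load_reactions_config(path) -> dict[str, ReactionDef]:
    """Reactions YAML: mapping reaction_id -> {transform, role_a, role_b}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for rid, spec in raw.items():
        rdef = ReactionDef(rid, spec["transform"], spec["role_a"], spec["role_b"])
        rdef.rxn()  # validate eagerly
        out[rid] = rdef
    return out


def load_blocks_csv(path) -> list[BuildingBlock]:
    """Building-block CSV: id,smiles,role[,cost_tier]."""
    import csv as _csv

    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in _csv.DictReader(fh):
            out.append(
                BuildingBlock(
                    id=row["id"],
                    smiles=row["smiles"],
                    role=row["role"],
                    cost_tier=row.get("cost_tier", "standard") or "standard",
                )
            )
    return out
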