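"""Seeded synthetic fixtures: building blocks, labeled sublibrary pools and
exclusion sets with known planted structure.

Structures come from a grammar (ring cores x decorations x bridge/linker
rules), never random strings, so everything is valid by construction and the
planted labels — alert-bearing, acid/base/neutral, simple/complex,
in-window, exclusion overlap — are controllable and recorded in a truth
table for recovery tests.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from divlib.core_io import CompoundRecord, CompoundSet, canonical_key, canonicalize, parse_structure
from divlib.enumeration import BuildingBlock
from divlib.properties import PropertyWindow, compute_properties, load_windows
from divlib.similarity import fingerprint, tanimoto
from divlib.utils import largest_remainder

import numpy as np

# --- grammar -----------------------------------------------------------------
# cores: (decorated-format with {d} slot, plain form, aromatic?)
AROMATIC_CORES = [
    ("c1ccc({d})cc1", "c1ccccc1"),
    ("c1cc({d})ncc1", "c1ccncc1"),
    ("c1nc({d})ccn1", "c1ccncn1"),
    ("c1cc({d})oc1", "c1ccoc1"),
    ("c1cc({d})[nH]n1", "c1cc[nH]n1"),
    ("c1oc({d})nc1", "c1ocnc1"),
    ("c1ccc2oc({d})cc2c1", "c1ccc2occc2c1"),
    ("c1ccc2[nH]c({d})cc2c1", "c1ccc2[nH]ccc2c1"),
]
SATURATED_CORES = [
    ("C1CCC({d})CC1", "C1CCCCC1"),
    ("C1CCC({d})OC1", "C1CCOCC1"),
    ("C1CC({d})OC1", "C1CCOC1"),
    ("C1CC({d})C1", "C1CCC1"),
    ("C1CC2({d})CCOC2C1", "C1CC2CCOC2C1"),
    ("C1CC2CCC({d})(C1)C2", "C1CC2CCC1C2"),
]

#: neutral decorations; second element marks aromatic-core-only attachment
NEUTRAL_DECORATIONS = [
    ("C", False), ("CC", False), ("OC", False), ("OCC", False),
    ("C(C)C", False), ("C(F)(F)F", False), ("C#N", False), ("CO", False),
    ("F", True), ("Cl", True), ("N2CCOCC2", True), ("OC(F)F", True),
    ("c2ccccc2", False), ("c2ccncc2", False), ("C(=O)N(C)C", False),
    ("NC(C)=O", True), ("Cc2ccccc2", False), ("Cc2ccncc2", False),
    ("OCc2ccccc2", False),
]
ACID_DECORATIONS = [("C(=O)O", False), ("CC(=O)O", False), ("CCC(=O)O", False)]
BASE_DECORATIONS = [("CN", False), ("CCN", False), ("CNC", False), ("N2CCNCC2", True)]
ALERT_DECORATIONS = [("[N+](=O)[O-]", True), ("SC", False), ("SCC", False)]

_ATOM_RE = re.compile(r"Cl|Br|\[nH\]|[cnosCNOSF]")

LINKERS = ["", "C", "CC"]
#: bridge SMILES per sublibrary chemistry tag
BRIDGES = {
    "amide": "C(=O)N",
    "sulfonamide": "S(=O)(=O)N",
    "urea": "NC(=O)N",
    "aryl_amine": "N",
}
_BRIDGE_CYCLE = ["amide", "sulfonamide", "amide", "urea", "aryl_amine", "amide"]


@dataclass
class FixtureSpec:
    """Knobs controlling generated pool structure; fully seeded."""

    n_sublibraries: int = 4
    size_per_sublibrary: int = 200
    redundancy: float = 0.3  # 0 = use all cores, 1 = single core (high similarity)
    frac_alert: float = 0.05
    charge_fractions: dict = field(
        default_factory=lambda: {"neutral": 0.60, "base": 0.33, "acid": 0.07}
    )
    frac_complex: float = 0.3
    in_window_fraction: float = 0.8
    window: str = "agreed"
    max_attempts: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.n_sublibraries < 1 or self.size_per_sublibrary < 1:
            raise ValueError("sizes must be >= 1")
        for name, v in [
            ("redundancy", self.redundancy),
            ("frac_alert", self.frac_alert),
            ("frac_complex", self.frac_complex),
            ("in_window_fraction", self.in_window_fraction),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        tot = sum(self.charge_fractions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("charge fractions must sum to 1")
        if self.frac_alert > 0.999 and self.frac_alert < 1.0:
            pass
        if self.frac_alert == 1.0 and not ALERT_DECORATIONS:
            raise ValueError("alert fraction 1 with an alert-free grammar")


def _label_sequence(fractions: dict[str, float], n: int, rng: random.Random) -> list[str]:
    """Exact planned counts per label (largest remainder), shuffled."""
    labels = list(fractions)
    counts = largest_remainder(np.array([fractions[l] for l in labels]), n)
    seq = [l for l, c in zip(labels, counts) for _ in range(c)]
    rng.shuffle(seq)
    return seq


def _decorate(fmt_pair: tuple[str, str], dec: str | None, aromatic: bool) -> str:
    decorated_fmt, plain = fmt_pair
    if not dec:
        return plain
    return decorated_fmt.format(d=dec)


def _pick_decoration(options, aromatic_core: bool, rng: random.Random) -> str:
    usable = [d for d, arom_only in options if aromatic_core or not arom_only]
    return rng.choice(usable)


def _assemble(
    chemistry: str,
    cores_left,
    cores_right,
    charge: str,
    alert: bool,
    rng: random.Random,
) -> str:
    left_pair, left_arom = rng.choice(cores_left)
    right_pair, right_arom = rng.choice(cores_right)
    # charge decoration goes on one randomly chosen side, alert (if any) on
    # the other, so planted labels never displace each other
    charge_side = rng.randrange(2)
    decs = []
    for side, arom in ((0, left_arom), (1, right_arom)):
        if charge in ("acid", "base") and side == charge_side:
            options = ACID_DECORATIONS if charge == "acid" else BASE_DECORATIONS
            decs.append(_pick_decoration(options, arom, rng))
        elif alert and side == 1 - charge_side:
            decs.append(_pick_decoration(ALERT_DECORATIONS, arom, rng))
        else:
            dec = _pick_decoration(NEUTRAL_DECORATIONS, arom, rng) if rng.random() < 0.8 else ""
            decs.append(dec)
    bridge = BRIDGES[chemistry]
    link_a = rng.choice(LINKERS)
    link_b = rng.choice(LINKERS)
    if chemistry == "aryl_amine" and not left_arom:
        # direct N bridge off a saturated core would be a basic amine;
        # force an amide instead so neutral stays neutral
        bridge = BRIDGES["amide"]
    return (
        _decorate(left_pair, decs[0], left_arom)
        + link_a
        + bridge
        + link_b
        + _decorate(right_pair, decs[1], right_arom)
    )


def _core_subset(cores, redundancy: float, rng: random.Random):
    k = max(1, round((1.0 - redundancy) * len(cores)))
    return rng.sample(cores, k)


def generate_pool(spec: FixtureSpec) -> tuple[list[tuple[str, CompoundSet]], pd.DataFrame]:
    """Generate labeled sublibrary pools plus a truth table.

    Planted counts per label are exact by construction (largest-remainder
    planning), realized labels are re-measured and both are recorded. Every
    record carries computed properties.
    """
    rng = random.Random(spec.seed)
    window = load_windows()[spec.window]
    n_complex = round(spec.frac_complex * spec.n_sublibraries)
    pools: list[tuple[str, CompoundSet]] = []
    truth_rows = []
    for li in range(spec.n_sublibraries):
        lib_id = f"SL{li + 1:03d}"
        is_complex = li >= spec.n_sublibraries - n_complex
        chemistry = _BRIDGE_CYCLE[li % len(_BRIDGE_CYCLE)]
        arom = [(p, True) for p in _core_subset(AROMATIC_CORES, spec.redundancy, rng)]
        sat = [(p, False) for p in _core_subset(SATURATED_CORES, spec.redundancy, rng)]
        if is_complex:
            # complex chemistry skews saturated / fused (higher sp3)
            cores_left = sat + arom[:2]
            cores_right = sat + arom[:2]
        else:
            cores_left = arom
            cores_right = arom + sat[:2]
        n = spec.size_per_sublibrary
        charges = _label_sequence(spec.charge_fractions, n, rng)
        alerts = _label_sequence({"y": spec.frac_alert, "n": 1 - spec.frac_alert}, n, rng)
        windows = _label_sequence(
            {"y": spec.in_window_fraction, "n": 1 - spec.in_window_fraction}, n, rng
        )
        seen: set[str] = set()
        records = []
        for ci in range(n):
            want_window = windows[ci] == "y"
            mwt_lo, mwt_hi = window.ranges.get("mwt", (0.0, float("inf")))
            best = None
            fallback = None
            for _attempt in range(spec.max_attempts):
                smi = _assemble(chemistry, cores_left, cores_right, charges[ci], alerts[ci] == "y", rng)
                # string-level heavy-atom pre-gate (~13.2 Da per heavy atom)
                # avoids parsing assemblies far outside the target MW band
                if want_window:
                    est = 13.2 * len(_ATOM_RE.findall(smi))
                    if not (mwt_lo - 45 <= est <= mwt_hi + 45):
                        if fallback is None:
                            fallback = smi
                        continue
                mol = Chem.MolFromSmiles(smi)
                if mol is None:  # pragma: no cover - grammar is valid by construction
                    continue
                # cheap molecular-weight gate before the full property vector
                if want_window and not (mwt_lo <= Descriptors.MolWt(mol) <= mwt_hi):
                    if fallback is None:
                        fallback = smi
                    continue
                key = canonical_key(mol)
                if key in seen:
                    continue
                pv = compute_properties(mol)
                best = (smi, mol, key, pv)
                if not want_window or window.passes(pv):
                    break
            if best is None and fallback is not None:
                smi = fallback
                mol = Chem.MolFromSmiles(smi)
                if mol is not None:
                    key = canonical_key(mol)
                    if key not in seen:
                        best = (smi, mol, key, compute_properties(mol))
            if best is None:
                continue
            smi, mol, key, pv = best
            seen.add(key)
            rid = f"{lib_id}-{ci + 1:05d}"
            rec = CompoundRecord(
                id=rid,
                smiles_input=smi,
                smiles_canonical=canonicalize(mol),
                sublibrary_id=lib_id,
                complexity="complex" if is_complex else "simple",
                properties=pv,
            )
            records.append(rec)
            truth_rows.append(
                {
                    "id": rid,
                    "sublibrary": lib_id,
                    "smiles": rec.smiles_canonical,
                    "charge_intent": charges[ci],
                    "charge_realized": pv.charge_class,
                    "alert_intent": alerts[ci] == "y",
                    "complexity": rec.complexity,
                    "window_intent": want_window,
                    "window_realized": window.passes(pv),
                }
            )
        pools.append((lib_id, CompoundSet(records=records, provenance=[f"synthetic:{lib_id}"])))
    truth = pd.DataFrame(truth_rows)
    return pools, truth


# --- building blocks ---------------------------------------------------------

_ROLE_PREFIXES = {
    "amine": ["NC", "NCC", "CNC"],
    "acid": ["OC(=O)", "OC(=O)C", "OC(=O)CC"],
    "aldehyde": ["O=C", "O=CC"],
    "sulfonyl_chloride": ["ClS(=O)(=O)", "ClS(=O)(=O)C"],
    "aryl_bromide": ["Br"],
}


def generate_blocks(
    n_per_role: int, roles: tuple[str, ...] = ("amine", "acid"), seed: int = 0
) -> dict[str, list[BuildingBlock]]:
    """Role-appropriate building blocks from the grammar; reproducible."""
    if n_per_role < 1:
        raise ValueError("n_per_role must be >= 1")
    rng = random.Random(seed)
    out: dict[str, list[BuildingBlock]] = {}
    for role in roles:
        if role not in _ROLE_PREFIXES:
            raise ValueError(f"unknown role {role!r}; known: {sorted(_ROLE_PREFIXES)}")
        cores = AROMATIC_CORES + SATURATED_CORES
        if role == "aryl_bromide":
            cores = AROMATIC_CORES
        combos = []
        for prefix in _ROLE_PREFIXES[role]:
            for pair in cores:
                arom = pair in AROMATIC_CORES
                for dec, arom_only in [("", False)] + NEUTRAL_DECORATIONS:
                    if arom_only and not arom:
                        continue
                    combos.append((prefix, pair, dec, arom))
        rng.shuffle(combos)
        blocks, seen = [], set()
        for prefix, pair, dec, arom in combos:
            smi = prefix + _decorate(pair, dec, arom)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            key = canonical_key(mol)
            if key in seen:
                continue
            seen.add(key)
            blocks.append(
                BuildingBlock(id=f"{role}-{len(blocks) + 1:04d}", smiles=smi, role=role)
            )
            if len(blocks) == n_per_role:
                break
        if len(blocks) < n_per_role:
            raise ValueError(
                f"grammar exhausted for role {role!r}: {len(blocks)} < {n_per_role}"
            )
        out[role] = blocks
    return out


# --- exclusion sets ----------------------------------------------------------


def generate_exclusion(
    pool: CompoundSet, overlap_fraction: float, seed: int, n_decoys: int | None = None
) -> tuple[CompoundSet, list[str]]:
    """Exclusion set with planted near-duplicates of pool members.

    Near-duplicates are single-substituent edits verified > 0.5 Tanimoto to
    their source (resampled until true). Returns the exclusion set and the
    ids of pool members with a planted near-duplicate.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0,1]")
    rng = random.Random(seed)
    n_overlap = round(overlap_fraction * len(pool))
    chosen = rng.sample(list(pool.records), n_overlap) if n_overlap else []
    records = []
    planted_ids: list[str] = []
    for i, src in enumerate(chosen):
        src_fp = fingerprint(src.mol())
        for suffix in ("C", "CC", "O", "CO", ""):
            cand = src.smiles_input + suffix if suffix else src.smiles_canonical
            mol = Chem.MolFromSmiles(cand)
            if mol is None:
                continue
            if suffix and tanimoto(fingerprint(mol), src_fp) <= 0.5:
                continue
            smi = canonicalize(mol)
            records.append(
                CompoundRecord(id=f"EXCL-{i + 1:05d}", smiles_input=cand, smiles_canonical=smi)
            )
            planted_ids.append(src.id)
            break
    if n_decoys is None:
        n_decoys = max(10, n_overlap)
    decoy_spec = FixtureSpec(
        n_sublibraries=1,
        size_per_sublibrary=n_decoys,
        redundancy=0.0,
        frac_alert=0.0,
        in_window_fraction=0.0,
        seed=rng.randrange(2**31),
    )
    decoy_pool, _ = generate_pool(decoy_spec)
    for j, rec in enumerate(decoy_pool[0][1].records):
        records.append(
            CompoundRecord(
                id=f"DECOY-{j + 1:05d}",
                smiles_input=rec.smiles_input,
                smiles_canonical=rec.smiles_canonical,
            )
        )
    return CompoundSet(records=records, provenance=["synthetic-exclusion"]), planted_ids
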