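import collections

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divlib.core_io import canonical_key, parse_structure
from divlib.enumeration import (
    DEFAULT_REACTIONS,
    BuildingBlock,
    SublibraryDef,
    build_basis_set,
    enumerate_superset,
    run_pair,
    sample_representatives,
)
from divlib.synthetic_data import generate_blocks


@pytest.fixture(scope="module")
def blocks():
    return generate_blocks(30, ("amine", "acid"), seed=5)


def amide_lib(blocks, na, nb):
    return SublibraryDef(
        reaction=DEFAULT_REACTIONS["amide"],
        blocks_a=blocks["acid"][:na],
        blocks_b=blocks["amine"][:nb],
    )


class TestBasisSet:
    def test_worked_example_counts(self):
        # 100 amines x 200 acids -> 299 basis products
        blocks = generate_blocks(200, ("amine", "acid"), seed=1)
        lib = SublibraryDef(
            reaction=DEFAULT_REACTIONS["amide"],
            blocks_a=blocks["acid"][:200],
            blocks_b=blocks["amine"][:100],
        )
        cs = build_basis_set(lib)
        assert len(cs) + len(cs.rejects) == 299
        assert len(cs.rejects) == 0

    def test_floor_one_one(self, blocks):
        assert len(build_basis_set(amide_lib(blocks, 1, 1))) == 1

    def test_matches_bruteforce_rule(self, blocks):
        # oracle: explicit enumeration of the rule for |A|=3, |B|=2
        lib = amide_lib(blocks, 3, 2)
        small_a = min(lib.blocks_a, key=lambda b: (b.mw, canonical_key(parse_structure(b.smiles))))
        small_b = min(lib.blocks_b, key=lambda b: (b.mw, canonical_key(parse_structure(b.smiles))))
        expected_pairs = {(a.id, small_b.id) for a in lib.blocks_a}
        expected_pairs |= {(small_a.id, b.id) for b in lib.blocks_b if b is not small_b}
        cs = build_basis_set(lib)
        got = {(r.metadata["block_a"], r.metadata["block_b"]) for r in cs}
        assert got == expected_pairs
        assert len(cs) == 4

    @settings(max_examples=25, deadline=None)
    @given(na=st.integers(1, 12), nb=st.integers(1, 12))
    def test_size_law(self, na, nb):
        blocks = generate_blocks(12, ("amine", "acid"), seed=2)
        lib = amide_lib(blocks, na, nb)
        cs = build_basis_set(lib)
        assert len(cs) + len(cs.rejects) == na + nb - 1

    def test_products_parse(self, blocks):
        for r in build_basis_set(amide_lib(blocks, 5, 5)):
            assert parse_structure(r.smiles_canonical) is not None


class TestSuperset:
    def test_below_cap_full_cross_product(self, blocks):
        lib = amide_lib(blocks, 3, 3)
        cs = enumerate_superset(lib, cap=100, seed=0)
        assert len(cs) + len(cs.rejects) == 9

    def test_cap_and_reproducibility(self, blocks):
        lib = amide_lib(blocks, 10, 10)
        a = enumerate_superset(lib, cap=50, seed=42)
        b = enumerate_superset(lib, cap=50, seed=42)
        assert len(a) + len(a.rejects) == 50
        assert a.ids() == b.ids()

    def test_no_duplicate_pairs(self, blocks):
        lib = amide_lib(blocks, 10, 10)
        cs = enumerate_superset(lib, cap=60, seed=1)
        pairs = [(r.metadata["block_a"], r.metadata["block_b"]) for r in cs]
        assert len(pairs) == len(set(pairs))

    def test_sampling_uniformity(self, blocks):
        # chi-square oracle over 10,000 single draws from 10 pairs
        from scipy.stats import chisquare

        lib = amide_lib(blocks, 10, 1)
        counts = collections.Counter()
        for s in range(10_000):
            cs = enumerate_superset(lib, cap=1, seed=s)
            counts[cs.records[0].metadata["block_a"]] += 1
        _, p = chisquare(list(counts.values()))
        assert p > 1e-4

    def test_cap_below_one(self, blocks):
        with pytest.raises(ValueError):
            enumerate_superset(amide_lib(blocks, 2, 2), cap=0, seed=0)


class TestRepresentatives:
    def test_eight_from_hundred(self, blocks):
        lib = amide_lib(blocks, 25, 4)
        cs = enumerate_superset(lib, cap=100, seed=0)
        reps = sample_representatives(cs, seed=0)
        assert len(reps) == 8

    def test_small_set_clamp(self, blocks):
        cs = enumerate_superset(amide_lib(blocks, 3, 2), cap=100, seed=0)
        reps = sample_representatives(cs, n_low=3, n_rand=5, seed=0)
        assert len(reps) == len(cs)

    def test_lowest_three_match_sort_oracle(self, blocks):
        from divlib.properties import compute_properties

        cs = enumerate_superset(amide_lib(blocks, 6, 6), cap=100, seed=0)
        reps = sample_representatives(cs, n_low=3, n_rand=0, seed=0)
        ranked = sorted(
            cs.records,
            key=lambda r: (compute_properties(r.mol()).mwt, r.smiles_canonical),
        )
        assert reps.ids() == [r.id for r in ranked[:3]]


class TestReactions:
    def test_all_default_reactions_fire(self):
        role_examples = {
            "acid": "OC(=O)Cc1ccccc1",
            "amine": "NCCc1ccccc1",
            "sulfonyl_chloride": "ClS(=O)(=O)c1ccccc1",
            "aldehyde": "O=Cc1ccccc1",
            "aryl_bromide": "Brc1ccccc1",
        }
        for rid, rdef in DEFAULT_REACTIONS.items():
            lib = SublibraryDef(
                reaction=rdef,
                blocks_a=[BuildingBlock("a", role_examples[rdef.role_a_name], rdef.role_a_name)],
                blocks_b=[BuildingBlock("b", role_examples[rdef.role_b_name], rdef.role_b_name)],
            )
            mol = run_pair(lib, lib.blocks_a[0], lib.blocks_b[0])
            assert mol.GetNumHeavyAtoms() > 0, rid

    def test_failed_pair_quarantined(self, blocks):
        # an "acid" block that is not an acid at all
        bad = BuildingBlock("bad", "c1ccccc1", "acid")
        lib = SublibraryDef(
            reaction=DEFAULT_REACTIONS["amide"],
            blocks_a=[bad],
            blocks_b=blocks["amine"][:1],
        )
        cs = build_basis_set(lib)
        assert len(cs) == 0
        assert len(cs.rejects) == 1

    def test_empty_blocks_rejected(self, blocks):
        with pytest.raises(ValueError):
            SublibraryDef(
                reaction=DEFAULT_REACTIONS["amide"], blocks_a=[], blocks_b=blocks["amine"][:1]
            )
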