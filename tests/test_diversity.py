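import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divlib.core_io import CompoundSet, record_from_smiles
from divlib.diversity import QuotaPlan, allocate_quotas, diversity_select, maxmin_select
from divlib.similarity import fingerprint, tanimoto
from divlib.utils import derive_seed
from divlib.synthetic_data import FixtureSpec, generate_pool
from tests.conftest import make_set


def min_pairwise_distance(cs):
    fps = [fingerprint(r.mol()) for r in cs]
    return min(
        1.0 - tanimoto(a, b) for a, b in itertools.combinations(fps, 2)
    )


@pytest.fixture(scope="module")
def pool20():
    pools, _ = generate_pool(FixtureSpec(n_sublibraries=1, size_per_sublibrary=20, seed=21))
    return pools[0][1]


class TestMaxMin:
    def test_k_equals_pool(self, pool20):
        sel = maxmin_select(pool20, len(pool20), seed=0)
        assert sorted(sel.ids()) == sorted(pool20.ids())

    def test_k_out_of_range(self, pool20):
        with pytest.raises(ValueError):
            maxmin_select(pool20, 0, seed=0)
        with pytest.raises(ValueError):
            maxmin_select(pool20, len(pool20) + 1, seed=0)

    def test_duplicate_avoided(self):
        # pool {A, A', C}: A' identical to A; k=2 must give {A, C} whichever
        # of A/A' seeds the pick
        cs = CompoundSet(
            records=[
                record_from_smiles("A", "CCO"),
                record_from_smiles("Aprime", "OCC"),
                record_from_smiles("C", "c1ccc2occc2c1"),
            ]
        )
        for seed in range(5):
            sel = maxmin_select(cs, 2, seed=seed)
            keys = {r.key for r in sel}
            assert len(keys) == 2
            assert record_from_smiles("x", "c1ccc2occc2c1").key in keys

    def test_per_step_exhaustive_oracle(self, pool20):
        # oracle: at each greedy step, re-derive the argmax by brute force
        for seed in (0, 7):
            sel = maxmin_select(pool20, 8, seed=seed)
            fps = {r.id: fingerprint(r.mol()) for r in pool20}
            picked = [sel.records[0].id]
            candidates = sorted(
                (r for r in pool20.records), key=lambda r: r.smiles_canonical
            )
            for step_rec in sel.records[1:]:
                best_id, best_d = None, -1.0
                for cand in candidates:
                    if cand.id in picked:
                        continue
                    d = min(1.0 - tanimoto(fps[cand.id], fps[p]) for p in picked)
                    if d > best_d:
                        best_id, best_d = cand.id, d
                assert step_rec.id == best_id
                picked.append(best_id)

    def test_deterministic(self, pool20):
        assert maxmin_select(pool20, 5, seed=3).ids() == maxmin_select(pool20, 5, seed=3).ids()

    def test_diversity_dominance_over_random_subsets(self, pool20):
        # statistical: MaxMin min-distance beats 200 random same-size subsets
        sel = maxmin_select(pool20, 5, seed=1)
        d_sel = min_pairwise_distance(sel)
        rng = random.Random(0)
        better = 0
        for _ in range(200):
            sub = pool20.with_records(rng.sample(pool20.records, 5), "rand")
            if min_pairwise_distance(sub) > d_sel:
                better += 1
        assert better == 0

    def test_duplicate_insensitivity(self, pool20):
        sel = maxmin_select(pool20, 6, seed=2)
        dup = record_from_smiles("DUP", sel.records[0].smiles_canonical)
        bigger = pool20.with_records(list(pool20.records) + [dup], "plus-dup")
        sel2 = maxmin_select(bigger, 6, seed=2)
        assert [r.key for r in sel2] == [r.key for r in sel]


class TestAllocateQuotas:
    def _libs(self, sizes, seed=31):
        pools, _ = generate_pool(
            FixtureSpec(n_sublibraries=len(sizes), size_per_sublibrary=max(sizes), seed=seed)
        )
        return [
            (lib_id, cs.with_records(cs.records[:n], "trim"))
            for (lib_id, cs), n in zip(pools, sizes)
        ]

    def test_symmetric_libraries_equal_quotas(self):
        libs = self._libs([40, 40])
        sims = {lib_id: 0.3 for lib_id, _ in libs}
        plan = allocate_quotas(libs, total=30, mean_similarities=sims)
        quotas = [r.quota for r in plan.rows]
        assert abs(quotas[0] - quotas[1]) <= 1
        assert sum(quotas) == 30

    def test_fully_redundant_library_zero_weight(self):
        libs = self._libs([40, 40])
        sims = {libs[0][0]: 1.0, libs[1][0]: 0.2}
        plan = allocate_quotas(libs, total=30, mean_similarities=sims)
        assert plan.rows[0].quota == 0
        assert plan.rows[1].quota == 30

    def test_total_conserved_random_configs(self):
        rng = random.Random(5)
        libs = self._libs([50, 30, 20, 40], seed=32)
        for _ in range(100):
            total = rng.randint(4, 120)
            sims = {lib_id: rng.random() * 0.9 for lib_id, _ in libs}
            plan = allocate_quotas(libs, total=total, mean_similarities=sims)
            assert plan.total + plan.shortfall == max(total, 4)
            for row in plan.rows:
                assert 0 <= row.quota <= row.pool_size

    def test_quota_never_exceeds_pool(self):
        libs = self._libs([5, 40])
        plan = allocate_quotas(libs, total=40, mean_similarities={l: 0.1 for l, _ in libs})
        for row in plan.rows:
            assert row.quota <= row.pool_size
        assert plan.total == 40

    def test_infeasible_total_reports_shortfall(self):
        libs = self._libs([5, 5])
        plan = allocate_quotas(libs, total=30, mean_similarities={l: 0.1 for l, _ in libs})
        assert plan.total == 10
        assert plan.shortfall == 20

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            allocate_quotas([("a", make_set([]))], total=5)

    def test_csv_round_trip(self, tmp_path):
        libs = self._libs([20, 30])
        plan = allocate_quotas(libs, total=25, mean_similarities={l: 0.2 for l, _ in libs})
        p = tmp_path / "plan.csv"
        plan.to_csv(p)
        back = QuotaPlan.from_csv(p)
        assert [(r.sublibrary_id, r.quota) for r in back.rows] == [
            (r.sublibrary_id, r.quota) for r in plan.rows
        ]


@pytest.fixture(scope="module")
def libs():
    pools, _ = generate_pool(FixtureSpec(n_sublibraries=2, size_per_sublibrary=30, seed=41))
    return pools


class TestDiversitySelect:
    def test_output_size_is_quota_sum(self, libs):
        plan = allocate_quotas(libs, total=5, mean_similarities={l: 0.2 for l, _ in libs})
        sel = diversity_select(libs, plan, seed=9)
        assert len(sel) == 5

    def test_deterministic(self, libs):
        plan = allocate_quotas(libs, total=8, mean_similarities={l: 0.2 for l, _ in libs})
        a = diversity_select(libs, plan, seed=9)
        b = diversity_select(libs, plan, seed=9)
        assert a.ids() == b.ids()

    def test_compositional_with_independent_runs(self, libs):
        plan = allocate_quotas(libs, total=8, mean_similarities={l: 0.2 for l, _ in libs})
        sel = diversity_select(libs, plan, seed=9)
        for lib_id, cs in libs:
            expected = maxmin_select(cs, plan.quota_for(lib_id), derive_seed(9, lib_id))
            got = [r.id for r in sel if r.sublibrary_id == lib_id]
            assert got == expected.ids()

    def test_provenance_records_origin(self, libs):
        plan = allocate_quotas(libs, total=6, mean_similarities={l: 0.2 for l, _ in libs})
        sel = diversity_select(libs, plan, seed=1)
        assert all(r.sublibrary_id in {l for l, _ in libs} for r in sel)


@settings(max_examples=50, deadline=None)
@given(
    sizes=st.lists(st.integers(1, 30), min_size=1, max_size=5),
    total=st.integers(0, 100),
    sims=st.lists(st.floats(0, 1), min_size=5, max_size=5),
)
def test_quota_conservation_property(sizes, total, sims):
    libs = [
        (f"L{i}", make_set(["CCO"] * 1, prefix=f"L{i}-")) for i in range(len(sizes))
    ]
    # fabricate pool sizes without building molecules: reuse one record n times
    libs = [
        (lib_id, cs.with_records(cs.records * n, "expand"))
        for (lib_id, cs), n in zip(libs, sizes)
    ]
    mean_sims = {f"L{i}": sims[i] for i in range(len(sizes))}
    plan = allocate_quotas(libs, total=total, mean_similarities=mean_sims)
    capacity = sum(sizes)
    expected_total = min(max(total, len(sizes)), capacity)
    assert plan.total == expected_total
    for row, n in zip(plan.rows, sizes):
        assert 0 <= row.quota <= n
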