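"""Quota allocation across sublibraries and greedy MaxMin diverse selection.

MaxMin: the first pick is pseudo-random from the seed; each subsequent pick
maximizes its minimum Tanimoto distance (1 - similarity) to everything
already picked, with ties broken by canonical-string order. Selection runs
over canonical-key-unique structures, so inserting duplicates of pool
members never changes the outcome.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import DataStructs

from divlib.core_io import CompoundSet
from divlib.similarity import fingerprints_for, mean_pairwise_similarity
from divlib.utils import clamped_apportion, derive_seed


def maxmin_select(pool: CompoundSet, k: int, seed: int) -> CompoundSet:
    """Greedy MaxMin diverse subset of size ``k``; deterministic for a seed."""
    if not 1 <= k <= len(pool):
        raise ValueError(f"k={k} out of range for pool of {len(pool)}")
    # collapse duplicate structures; keep first record per key
    uniq_idx: list[int] = []
    seen: set[str] = set()
    for i, r in enumerate(pool.records):
        if r.key not in seen:
            seen.add(r.key)
            uniq_idx.append(i)
    if k > len(uniq_idx):
        raise ValueError(
            f"k={k} exceeds the {len(uniq_idx)} structurally unique pool members"
        )
    # stable candidate order by canonical string so argmax tie-break is
    # lexicographic by canonical SMILES
    uniq_idx.sort(key=lambda i: pool.records[i].smiles_canonical)
    records = [pool.records[i] for i in uniq_idx]
    fps = fingerprints_for(pool.with_records(records, "maxmin-candidates"))
    n = len(records)

    rng = random.Random(seed)
    first = rng.randrange(n)
    picked = [first]
    min_dist = 1.0 - np.asarray(DataStructs.BulkTanimotoSimilarity(fps[first], fps))
    min_dist[first] = -1.0  # never re-pick
    while len(picked) < k:
        nxt = int(np.argmax(min_dist))  # first max = lexicographically smallest
        picked.append(nxt)
        dist = 1.0 - np.asarray(DataStructs.BulkTanimotoSimilarity(fps[nxt], fps))
        np.minimum(min_dist, dist, out=min_dist)
        min_dist[nxt] = -1.0
    out = pool.with_records([records[i] for i in picked], f"maxmin:k={k},seed={seed}")
    return out


@dataclass
class QuotaRow:
    sublibrary_id: str
    pool_size: int
    mean_similarity: float
    quota: int


@dataclass
class QuotaPlan:
    rows: list[QuotaRow]
    requested_total: int
    shortfall: int = 0

    @property
    def total(self) -> int:
        return sum(r.quota for r in self.rows)

    def quota_for(self, sublibrary_id: str) -> int:
        for r in self.rows:
            if r.sublibrary_id == sublibrary_id:
                return r.quota
        raise KeyError(sublibrary_id)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["sublibrary_id", "pool_size", "mean_sim", "quota"])
            for r in self.rows:
                w.writerow([r.sublibrary_id, r.pool_size, f"{r.mean_similarity:.6f}", r.quota])

    @classmethod
    def from_csv(cls, path: str | Path) -> "QuotaPlan":
        rows = []
        with open(path, newline="", encoding="utf-8") as fh:
            for rec in csv.DictReader(fh):
                rows.append(
                    QuotaRow(
                        sublibrary_id=rec["sublibrary_id"],
                        pool_size=int(rec["pool_size"]),
                        mean_similarity=float(rec["mean_sim"]),
                        quota=int(rec["quota"]),
                    )
                )
        return cls(rows=rows, requested_total=sum(r.quota for r in rows))


def allocate_quotas(
    libraries: list[tuple[str, CompoundSet]],
    total: int,
    exponent: float = 1.0,
    mean_similarities: dict[str, float] | None = None,
) -> QuotaPlan:
    """Redundancy-aware proportional quotas.

    quota_i is proportional to pool_size_i**exponent * (1 - mean_similarity_i),
    normalized to ``total`` with largest-remainder rounding, clamped to pool
    sizes with deterministic redistribution. Precomputed mean similarities
    may be passed to skip the pairwise computation.
    """
    if not libraries or all(len(cs) == 0 for _, cs in libraries):
        raise ValueError("all sublibrary pools are empty")
    n_nonempty = sum(1 for _, cs in libraries if len(cs) > 0)
    if total < n_nonempty:
        total = n_nonempty  # clamp: at least one per non-empty library
    sizes = np.array([len(cs) for _, cs in libraries], dtype=int)
    means_list = []
    for lib_id, cs in libraries:
        if len(cs) < 2:
            means_list.append(0.0)
        elif mean_similarities is not None and lib_id in mean_similarities:
            means_list.append(float(mean_similarities[lib_id]))
        else:
            means_list.append(mean_pairwise_similarity(cs))
    means = np.array(means_list)
    weights = np.where(sizes > 0, sizes.astype(float) ** exponent * (1.0 - means), 0.0)
    if weights.sum() == 0:
        # all pools fully redundant: fall back to size-proportional
        weights = sizes.astype(float)
    quotas, shortfall = clamped_apportion(weights, sizes, min(total, int(sizes.sum())))
    if shortfall > 0:
        # positive-weight pools exhausted; spill the rest into remaining
        # capacity (size-proportional) so the requested total is conserved
        residual = (sizes - quotas).astype(float)
        extra, shortfall = clamped_apportion(residual, sizes - quotas, shortfall)
        quotas = quotas + extra
    shortfall += max(0, total - int(sizes.sum()))
    rows = [
        QuotaRow(lib_id, int(sz), float(m), int(q))
        for (lib_id, _), sz, m, q in zip(libraries, sizes, means, quotas)
    ]
    return QuotaPlan(rows=rows, requested_total=total, shortfall=shortfall)


def diversity_select(
    libraries: list[tuple[str, CompoundSet]], plan: QuotaPlan, seed: int
) -> CompoundSet:
    """Union of per-sublibrary MaxMin selections under a quota plan.

    Each sublibrary gets its own seed derived from (seed, sublibrary_id), so
    per-library results equal independent ``maxmin_select`` runs.
    """
    out_records = []
    provenance = []
    for lib_id, cs in libraries:
        q = plan.quota_for(lib_id)
        if q == 0:
            continue
        sel = maxmin_select(cs, q, derive_seed(seed, lib_id))
        for r in sel.records:
            if r.sublibrary_id is None:
                r.sublibrary_id = lib_id
        out_records.extend(sel.records)
        provenance.append(f"maxmin[{lib_id}]:k={q}")
    return CompoundSet(records=out_records, provenance=[f"diversity_select:seed={seed}"] + provenance)
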