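"""Circular fingerprints, Tanimoto similarity, pairwise statistics and
novelty filtering against exclusion sets.

Defaults match the stereo-insensitive 1024-bit radius-2 circular
fingerprints used throughout the pipeline. Pairwise statistics are exact
(blocked row-at-a-time computation, never sampled) and counted over ordered
pairs excluding self-pairs, i.e. n*(n-1) values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from divlib.core_io import CompoundRecord, CompoundSet

DEFAULT_RADIUS = 2
DEFAULT_NBITS = 1024

_GENERATORS: dict[tuple[int, int], object] = {}


def _generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _GENERATORS:
        _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return _GENERATORS[key]


@dataclass
class Fingerprint:
    """Fixed-length circular-fingerprint bitset supporting Tanimoto comparison."""

    bits: object  # rdkit ExplicitBitVect
    n_bits: int = DEFAULT_NBITS
    radius: int = DEFAULT_RADIUS

    def popcount(self) -> int:
        return self.bits.GetNumOnBits()

    def on_bits(self) -> set[int]:
        return set(self.bits.GetOnBits())


def fingerprint(mol: Chem.Mol, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_NBITS) -> Fingerprint:
    """Circular fingerprint; deterministic and invariant to input atom order."""
    return Fingerprint(bits=_generator(radius, n_bits).GetFingerprint(mol), n_bits=n_bits, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a AND b| / |a OR b|; symmetric, 1.0 for identical bit patterns."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    return DataStructs.TanimotoSimilarity(a.bits, b.bits)


def fingerprints_for(cs: CompoundSet, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_NBITS) -> list:
    """Raw bitvect list for a set, cached on each record's metadata."""
    cache_key = f"_fp_{radius}_{n_bits}"
    out = []
    for r in cs.records:
        fp = r.metadata.get(cache_key)
        if fp is None:
            fp = _generator(radius, n_bits).GetFingerprint(r.mol())
            r.metadata[cache_key] = fp
        out.append(fp)
    return out


@dataclass
class SimilarityStats:
    n: int
    mean: float
    bin_edges: np.ndarray
    counts: np.ndarray
    ordered: bool = True

    @property
    def n_values(self) -> int:
        return self.n * (self.n - 1) if self.ordered else self.n * (self.n - 1) // 2


def pairwise_stats(cs: CompoundSet, bins: int = 50) -> SimilarityStats:
    """Exact mean + histogram of all ordered-pair similarities (self excluded).

    Histogram bins are uniform over [0, 1], right-closed (a similarity of
    exactly an upper edge falls in that bin; 0 falls in the first).
    Computed row-by-row so memory stays O(n) for large sets.
    """
    n = len(cs)
    if n < 2:
        raise ValueError("pairwise_stats needs at least 2 compounds")
    fps = fingerprints_for(cs)
    counts = np.zeros(bins, dtype=np.int64)
    total = 0.0
    for i in range(n):
        row = np.asarray(DataStructs.BulkTanimotoSimilarity(fps[i], fps))
        row = np.delete(row, i)
        total += float(row.sum())
        idx = np.clip(np.ceil(row * bins).astype(int) - 1, 0, bins - 1)
        counts += np.bincount(idx, minlength=bins)
    n_vals = n * (n - 1)
    return SimilarityStats(
        n=n,
        mean=total / n_vals,
        bin_edges=np.linspace(0.0, 1.0, bins + 1),
        counts=counts,
    )


def mean_pairwise_similarity(cs: CompoundSet) -> float:
    """Mean ordered-pair similarity; 0.0 for sets smaller than 2."""
    if len(cs) < 2:
        return 0.0
    return pairwise_stats(cs).mean


def novelty_filter(
    cs: CompoundSet, exclusion: CompoundSet, threshold: float = 0.5
) -> CompoundSet:
    """Remove records STRICTLY more similar than ``threshold`` to any
    exclusion member.

    A max-similarity of exactly ``threshold`` is retained. Removal reasons
    (nearest exclusion member and its similarity) are recorded in
    ``result.stats['removals']`` as (id, nearest_excluded_id, similarity).
    """
    if len(exclusion) == 0:
        warnings.warn("empty exclusion set: retaining all records")
        out = cs.with_records(cs.records, "novelty:empty-exclusion")
        out.stats["removals"] = []
        return out
    excl_fps = fingerprints_for(exclusion)
    excl_ids = exclusion.ids()
    kept = []
    removals: list[tuple[str, str, float]] = []
    own_fps = fingerprints_for(cs)
    for r, fp in zip(cs.records, own_fps):
        sims = np.asarray(DataStructs.BulkTanimotoSimilarity(fp, excl_fps))
        j = int(np.argmax(sims))
        if sims[j] > threshold:
            removals.append((r.id, excl_ids[j], float(sims[j])))
        else:
            kept.append(r)
    out = cs.with_records(kept, f"novelty:>{threshold}")
    out.stats["removals"] = removals
    return out


def exact_match_filter(cs: CompoundSet, catalog: CompoundSet) -> CompoundSet:
    """Remove records whose stereo-insensitive canonical key appears in a
    catalog (stand-in for commercial-availability removal; exact-match join,
    not similarity)."""
    catalog_keys = {r.key for r in catalog.records}
    kept = [r for r in cs.records if r.key not in catalog_keys]
    out = cs.with_records(kept, "catalog-exact-match")
    out.stats["n_removed"] = len(cs) - len(kept)
    return out


def record_fingerprint(r: CompoundRecord) -> Fingerprint:
    return fingerprint(r.mol())
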