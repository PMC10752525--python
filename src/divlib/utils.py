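"""Shared helpers: deterministic seed derivation and largest-remainder rounding."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master: int, label: str) -> int:
    """Derive a per-stage/per-sublibrary seed from a master seed and a label.

    Deterministic and stable across platforms, so any stage of a seeded run
    can be re-executed in isolation with the same randomness.
    """
    digest = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31 - 1)


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Classic largest-remainder (Hamilton) rounding; ties on the fractional
    part are broken by index order. Zero-weight entries get zero. The result
    always sums to ``total`` (when any weight is positive).
    """
    weights = np.asarray(weights, dtype=float)
    if total < 0:
        raise ValueError("total must be non-negative")
    if weights.ndim != 1 or (weights < 0).any():
        raise ValueError("weights must be a 1-D non-negative array")
    wsum = weights.sum()
    if wsum == 0:
        if total > 0:
            raise ValueError("cannot apportion a positive total over zero weights")
        return np.zeros(len(weights), dtype=int)
    raw = weights / wsum * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if short > 0:
        # stable argsort => index order breaks fractional-part ties
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def clamped_apportion(weights: np.ndarray, caps: np.ndarray, total: int) -> tuple[np.ndarray, int]:
    """Largest-remainder apportionment with per-entry caps.

    Entries hitting their cap are frozen and the excess is redistributed over
    the remaining entries until stable. Returns ``(allocation, shortfall)``
    where shortfall > 0 means the caps could not absorb the full total.
    """
    weights = np.asarray(weights, dtype=float).copy()
    caps = np.asarray(caps, dtype=int)
    alloc = np.zeros(len(weights), dtype=int)
    remaining = int(total)
    active = (weights > 0) & (caps > 0)
    while remaining > 0 and active.any():
        sub = largest_remainder(np.where(active, weights, 0.0), remaining)
        sub = np.minimum(sub, caps - alloc)
        alloc += sub
        remaining = total - int(alloc.sum())
        newly_full = alloc >= caps
        if (active & newly_full).any():
            active &= ~newly_full
        elif sub.sum() == 0:
            break
    return alloc, remaining
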