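"""End-to-end selection funnel: alerts -> staged windows -> per-library caps
-> diversity quotas -> agreed window + novelty -> catalog removal ->
composition-constrained final draw, with a stage-by-stage ledger.

A master seed fans out to per-stage seeds through a recorded deterministic
schedule, so any stage can be re-run in isolation and two runs with the same
config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import random
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from divlib.alerts import AlertSet, load_alert_set, filter_alerts
from divlib.core_io import CompoundSet, deduplicate
from divlib.diversity import allocate_quotas, diversity_select
from divlib.properties import annotate_properties, apply_property_filter, load_windows
from divlib.similarity import exact_match_filter, novelty_filter
from divlib.utils import derive_seed, largest_remainder

DEFAULT_CHARGE_TARGETS = {"neutral": 0.60, "base": 0.33, "acid": 0.07}


@dataclass
class FunnelConfig:
    alert_files: list[str] = field(default_factory=lambda: ["pains", "reactive", "extra"])
    windows_file: str | None = None  # None = packaged defaults
    include_sublibraries: list[str] | None = None  # triage include list; None = all
    exclude_sublibraries: list[str] = field(default_factory=list)
    crude_cap: int = 250_000  # per-library cap at the crude stage
    quota_total: int | None = None  # None = quota_fraction of the post-crude pool
    quota_fraction: float = 0.8
    quota_exponent: float = 1.0
    novelty_threshold: float = 0.5
    charge_targets: dict = field(default_factory=lambda: dict(DEFAULT_CHARGE_TARGETS))
    simple_fraction: float = 0.7
    final_size: int = 30_000
    reserve_size: int = 15_000
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.charge_targets.values()) - 1.0) > 1e-9:
            raise ValueError("charge targets must sum to 1")
        if not 0.0 <= self.simple_fraction <= 1.0:
            raise ValueError("simple_fraction must be in [0,1]")

    @classmethod
    def from_yaml(cls, path) -> "FunnelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class StageRecord:
    name: str
    params: dict
    n_in: int
    n_out: int
    details: dict = field(default_factory=dict)


@dataclass
class FunnelResult:
    stages: list[StageRecord]
    final: CompoundSet
    reserve: CompoundSet
    quota_plan: object = None

    def ledger(self) -> list[dict]:
        return [
            {"stage": s.name, "params": s.params, "n_in": s.n_in, "n_out": s.n_out, **(
                {"details": s.details} if s.details else {})}
            for s in self.stages
        ]

    def ledger_to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.ledger(), indent=2, default=str))


class InfeasibleCompositionError(ValueError):
    pass


def _stratified_draw(
    by_stratum: dict[tuple, list], targets: dict[tuple, int], rng: random.Random
) -> tuple[list, dict[tuple, int]]:
    chosen = []
    shortfall: dict[tuple, int] = {}
    for stratum, want in targets.items():
        avail = by_stratum.get(stratum, [])
        take = min(want, len(avail))
        if take < want:
            shortfall[stratum] = want - take
        picked = rng.sample(avail, take)
        chosen.extend(picked)
        for r in picked:
            avail.remove(r)
    return chosen, shortfall


def _composition_targets(
    pool_records, size: int, simple_fraction: float, charge_targets: dict[str, float]
) -> dict[tuple, int]:
    """Per-(complexity, charge) targets; complexity marginals exact (+-1 by
    rounding), charge split within each complexity by largest remainder."""
    comp_counts = largest_remainder(
        np.array([simple_fraction, 1.0 - simple_fraction]), size
    )
    charge_names = list(charge_targets)
    targets: dict[tuple, int] = {}
    for comp, comp_n in zip(("simple", "complex"), comp_counts):
        charge_counts = largest_remainder(
            np.array([charge_targets[c] for c in charge_names]), int(comp_n)
        )
        for cname, cn in zip(charge_names, charge_counts):
            targets[(comp, cname)] = int(cn)
    return targets


def compose_final(
    pool: CompoundSet,
    charge_targets: dict[str, float] | None = None,
    simple_fraction: float = 0.7,
    size: int = 30_000,
    reserve: int = 15_000,
    seed: int = 0,
) -> tuple[CompoundSet, CompoundSet]:
    """Stratified random draw of (final, reserve) hitting the simple:complex
    ratio exactly (+-1) and charge fractions as closely as the pool allows.

    Stratum shortfalls are relaxed proportionally: the deficit is
    redistributed first across charge classes within the same complexity,
    then across complexity (with a warning, since the ratio then slips).
    """
    charge_targets = dict(charge_targets or DEFAULT_CHARGE_TARGETS)
    if size + reserve > len(pool):
        raise InfeasibleCompositionError(
            f"final+reserve = {size + reserve} exceeds pool of {len(pool)}"
        )
    annotate_properties(pool)
    by_stratum: dict[tuple, list] = {}
    for r in sorted(pool.records, key=lambda r: r.id):
        comp = r.complexity or "simple"
        stratum = (comp, r.properties.charge_class)
        by_stratum.setdefault(stratum, []).append(r)

    def draw(n: int, rng: random.Random, label: str) -> tuple[list, dict]:
        targets = _composition_targets(pool.records, n, simple_fraction, charge_targets)
        chosen, shortfall = _stratified_draw(by_stratum, targets, rng)
        reported = {f"{comp}/{charge}": v for (comp, charge), v in shortfall.items()}
        # relax within complexity, then across
        for (comp, charge), missing in list(shortfall.items()):
            if not missing:
                continue
            warnings.warn(
                f"{label}: stratum ({comp},{charge}) short by {missing}; relaxing proportionally"
            )
            donors = [s for s in by_stratum if s[0] == comp and by_stratum[s]]
            donors += [s for s in by_stratum if s[0] != comp and by_stratum[s]]
            for s in donors:
                while missing and by_stratum[s]:
                    r = by_stratum[s][rng.randrange(len(by_stratum[s]))]
                    by_stratum[s].remove(r)
                    chosen.append(r)
                    missing -= 1
                if not missing:
                    break
            if missing:
                raise InfeasibleCompositionError(
                    f"{label}: pool exhausted, still short {missing} after relaxation"
                )
        return chosen, reported

    rng = random.Random(seed)
    final_records, final_short = draw(size, rng, "final")
    reserve_records, reserve_short = draw(reserve, rng, "reserve")
    final = pool.with_records(sorted(final_records, key=lambda r: r.id), f"final:{size}")
    final.stats["shortfalls"] = final_short
    res = pool.with_records(sorted(reserve_records, key=lambda r: r.id), f"reserve:{reserve}")
    res.stats["shortfalls"] = reserve_short
    return final, res


def _cap_pool(cs: CompoundSet, cap: int, seed: int) -> CompoundSet:
    if len(cs) <= cap:
        return cs
    rng = random.Random(seed)
    picked = rng.sample(sorted(cs.records, key=lambda r: r.id), cap)
    return cs.with_records(sorted(picked, key=lambda r: r.id), f"cap:{cap}")


def run_funnel(
    config: FunnelConfig,
    pools: list[tuple[str, CompoundSet]],
    exclusion: CompoundSet | None = None,
    catalog: CompoundSet | None = None,
) -> FunnelResult:
    """Execute the full selection funnel over per-sublibrary pools."""
    if not pools or all(len(cs) == 0 for _, cs in pools):
        raise ValueError("pools are empty")
    stages: list[StageRecord] = []
    windows = load_windows(config.windows_file)

    def log(name: str, params: dict, n_in: int, n_out: int, **details):
        stages.append(StageRecord(name, params, n_in, n_out, details=dict(details)))

    # triage include/exclude of whole sublibraries (auditable config list)
    n_in = sum(len(cs) for _, cs in pools)
    if config.include_sublibraries is not None:
        pools = [(l, cs) for l, cs in pools if l in set(config.include_sublibraries)]
    pools = [(l, cs) for l, cs in pools if l not in set(config.exclude_sublibraries)]
    log(
        "triage",
        {"include": config.include_sublibraries, "exclude": config.exclude_sublibraries},
        n_in,
        sum(len(cs) for _, cs in pools),
    )

    # per-sublibrary dedup + alert removal + wide window
    alert_sets = [load_alert_set(p) for p in config.alert_files]

    def per_lib(fn, pools, stage_name, params, **details_from):
        nonlocal stages
        n_before = sum(len(cs) for _, cs in pools)
        out = [(l, fn(l, cs)) for l, cs in pools]
        out = [(l, cs) for l, cs in out]
        log(stage_name, params, n_before, sum(len(cs) for _, cs in out))
        return out

    pools = per_lib(lambda l, cs: deduplicate(cs), pools, "deduplicate", {})

    def alert_stage(l, cs):
        for aset in alert_sets:
            cs = filter_alerts(cs, aset, mode="remove")
        return cs

    pools = per_lib(alert_stage, pools, "alerts", {"files": list(config.alert_files)})

    pools = per_lib(
        lambda l, cs: apply_property_filter(annotate_properties(cs), windows["wide"]),
        pools,
        "window:wide",
        {"window": windows["wide"].ranges},
    )
    pools = per_lib(
        lambda l, cs: apply_property_filter(cs, windows["crude"]),
        pools,
        "window:crude",
        {"window": windows["crude"].ranges},
    )
    pools = per_lib(
        lambda l, cs: _cap_pool(cs, config.crude_cap, derive_seed(config.seed, f"cap:{l}")),
        pools,
        "crude-cap",
        {"cap": config.crude_cap},
    )

    pools = [(l, cs) for l, cs in pools if len(cs) > 0]
    if not pools:
        raise ValueError("no compounds survive the alert/window stages")

    # diversity quotas driven by per-library redundancy
    pool_total = sum(len(cs) for _, cs in pools)
    quota_total = config.quota_total or int(round(config.quota_fraction * pool_total))
    plan = allocate_quotas(pools, quota_total, exponent=config.quota_exponent)
    selected = diversity_select(pools, plan, derive_seed(config.seed, "diversity"))
    log(
        "diversity",
        {"quota_total": quota_total, "exponent": config.quota_exponent},
        pool_total,
        len(selected),
        quotas={r.sublibrary_id: r.quota for r in plan.rows},
    )

    # agreed window + novelty
    n = len(selected)
    selected = apply_property_filter(selected, windows["agreed"])
    log("window:agreed", {"window": windows["agreed"].ranges}, n, len(selected))

    if exclusion is not None and len(exclusion) > 0:
        n = len(selected)
        selected = novelty_filter(selected, exclusion, config.novelty_threshold)
        log(
            "novelty",
            {"threshold": config.novelty_threshold, "n_exclusion": len(exclusion)},
            n,
            len(selected),
        )

    if catalog is not None and len(catalog) > 0:
        n = len(selected)
        selected = exact_match_filter(selected, catalog)
        log("catalog-removal", {"n_catalog": len(catalog)}, n, len(selected))

    # cross-sublibrary dedup before the final draw
    n = len(selected)
    selected = deduplicate(selected)
    log("global-dedup", {}, n, len(selected))

    final, reserve = compose_final(
        selected,
        charge_targets=config.charge_targets,
        simple_fraction=config.simple_fraction,
        size=config.final_size,
        reserve=config.reserve_size,
        seed=derive_seed(config.seed, "compose_final"),
    )
    log(
        "compose_final",
        {
            "size": config.final_size,
            "reserve": config.reserve_size,
            "simple_fraction": config.simple_fraction,
            "charge_targets": config.charge_targets,
        },
        len(selected),
        len(final),
        shortfalls={"final": final.stats["shortfalls"], "reserve": reserve.stats["shortfalls"]},
    )
    return FunnelResult(stages=stages, final=final, reserve=reserve, quota_plan=plan)


def audit(result: FunnelResult, config: FunnelConfig, exclusion: CompoundSet | None = None) -> dict:
    """Post-hoc re-check: no final member matches a remove-mode alert or
    exceeds the novelty threshold; returns violation counts (all zero on a
    healthy run)."""
    out = {"alert_violations": 0, "novelty_violations": 0}
    alert_sets = [load_alert_set(p) for p in config.alert_files]
    from divlib.alerts import match_alerts

    for r in result.final.records:
        if any(match_alerts(r.mol(), a) for a in alert_sets):
            out["alert_violations"] += 1
    if exclusion is not None and len(exclusion) > 0:
        survivors = novelty_filter(result.final, exclusion, config.novelty_threshold)
        out["novelty_violations"] = len(result.final) - len(survivors)
    return out
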