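"""SMARTS structural-alert sets (PAINS, reactive/toxic, project extras).

Alert files are CSV with columns ``alert_id,smarts,description``; the loader
also accepts the two-column ``smarts,name`` layout used by common public
PAINS distributions. A file containing any malformed SMARTS refuses to load
— alerts must not silently vanish.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdkit import Chem

from divlib.core_io import CompoundSet

#: alert fixtures shipped with the package
BUILTIN_ALERT_FILES = {
    "pains": "data/alerts_pains.csv",
    "reactive": "data/alerts_reactive_toxic.csv",
    "extra": "data/alerts_extra.csv",
}


class AlertLoadError(ValueError):
    """Raised when an alert file contains malformed SMARTS."""

    def __init__(self, path, offenders: list[tuple[int, str]]):
        self.offenders = offenders
        lines = "; ".join(f"line {n}: {s!r}" for n, s in offenders)
        super().__init__(f"{path}: malformed SMARTS ({lines})")


@dataclass
class Alert:
    alert_id: str
    smarts: str
    description: str
    pattern: Chem.Mol = field(repr=False, compare=False, default=None)


@dataclass
class AlertSet:
    name: str
    patterns: list[Alert]
    source: str = ""

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)


def load_alert_set(path: str | Path, name: str | None = None) -> AlertSet:
    """Load and compile an alert CSV; fails listing every malformed line."""
    if isinstance(path, str) and path in BUILTIN_ALERT_FILES:
        text = resources.files("divlib").joinpath(BUILTIN_ALERT_FILES[path]).read_text()
        name = name or path
        source = f"builtin:{path}"
    else:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text(encoding="utf-8")
        name = name or path.stem
        source = str(path)
    rows = list(csv.reader(text.splitlines()))
    if not rows:
        return AlertSet(name=name, patterns=[], source=source)
    header = [c.strip().lower() for c in rows[0]]
    if "smarts" in header:
        smarts_i = header.index("smarts")
        id_i = header.index("alert_id") if "alert_id" in header else None
        desc_i = header.index("description") if "description" in header else (
            header.index("name") if "name" in header else None
        )
        body = rows[1:]
        start_line = 2
    else:
        # headerless two-column smarts,name layout
        smarts_i, id_i, desc_i = 0, None, 1
        body = rows
        start_line = 1
    alerts: list[Alert] = []
    offenders: list[tuple[int, str]] = []
    seen_ids: set[str] = set()
    for n, row in enumerate(body, start=start_line):
        if not row or not row[smarts_i].strip():
            continue
        smarts = row[smarts_i].strip()
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            offenders.append((n, smarts))
            continue
        aid = row[id_i].strip() if id_i is not None and len(row) > id_i else f"{name}-{n}"
        if aid in seen_ids:
            raise AlertLoadError(path, [(n, f"duplicate alert_id {aid}")])
        seen_ids.add(aid)
        desc = row[desc_i].strip() if desc_i is not None and len(row) > desc_i else ""
        alerts.append(Alert(alert_id=aid, smarts=smarts, description=desc, pattern=patt))
    if offenders:
        raise AlertLoadError(path, offenders)
    return AlertSet(name=name, patterns=alerts, source=source)


def match_alerts(mol: Chem.Mol, alerts: AlertSet) -> list[str]:
    """Return ids of every alert with at least one substructure match."""
    return [a.alert_id for a in alerts.patterns if mol.HasSubstructMatch(a.pattern)]


def filter_alerts(cs: CompoundSet, alerts: AlertSet, mode: str = "remove") -> CompoundSet:
    """Flag or remove alert-bearing records.

    ``flag`` annotates matching records' ``flags``; ``remove`` drops them.
    Per-alert hit counts (binary per compound, per the presence-based
    filtering convention) land in ``result.stats['alert_hits']``.
    """
    if mode not in ("flag", "remove"):
        raise ValueError(f"mode must be 'flag' or 'remove', got {mode!r}")
    hits: dict[str, int] = {a.alert_id: 0 for a in alerts.patterns}
    kept = []
    n_matching = 0
    for r in cs.records:
        matched = match_alerts(r.mol(), alerts)
        for aid in matched:
            hits[aid] += 1
        if matched:
            n_matching += 1
            r.flags.update(f"alert:{aid}" for aid in matched)
            if mode == "remove":
                continue
        kept.append(r)
    out = cs.with_records(kept, f"alerts:{alerts.name}:{mode}")
    out.stats["alert_hits"] = hits
    out.stats["n_matching"] = n_matching
    return out
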