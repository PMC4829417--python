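"""Tabular field-record types, CSV I/O, rank scaling and information-use tallies.

The package works from four kinds of field records: a phenotype table
(one row per individual), proximity scans (one row per sampled group),
directed dyadic interactions (grooming / dominance), and per-experiment
diffusion logs recording the order in which troop members acquired
social information about a food patch, plus subsequent patch entries
(application) and feeding (exploitation).

All files are comma-separated UTF-8 with one record per row;
multi-member associate lists are semicolon-joined within a cell.
Timestamps are ordinal integers — only event order is ever used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: Reserved id for an acquirer that could not be identified in the field.
#: Such individuals are dropped from tallies and likelihoods with a warning.
UNKNOWN_ID = "UNKNOWN"

PROXIMITY_RULES = ("ten_m", "five_m_chain", "nearest_neighbour")
INTERACTION_TYPES = ("groom", "dominance")
SEXES = ("female", "male")
#: Numeric covariate coding for sex.
SEX_CODES = {"female": 0, "male": 1}
DISCOVERY_POSITIONS = ("leading_edge", "side", "middle_back")

#: Age (years) at which an individual is classed as adult. Metadata only;
#: age always enters models as a continuous variable.
ADULT_AGE = 6.0


class RecordError(ValueError):
    """A record violates its schema or an invariant."""


class IntegrityError(ValueError):
    """Records are individually valid but mutually inconsistent."""


def relative_rank(r: int, n: int) -> float:
    """Scale absolute rank ``r`` in a troop of ``n`` to [0, 1].

    Computed as ``1 - (1 - r)/(1 - n)``: rank 1 (most dominant) maps to
    1.0 and rank ``n`` to 0.0, which makes ranks comparable between
    troops of different sizes.
    """
    if n < 2:
        raise RecordError(f"troop size n={n} must be >= 2")
    if not 1 <= r <= n:
        raise RecordError(f"absolute rank r={r} outside 1..{n}")
    return 1.0 - (1.0 - r) / (1.0 - n)


@dataclass(frozen=True)
class PhenotypeRecord:
    """One individual's phenotype: sex, age, dominance rank and boldness.

    ``boldness`` is the seconds spent investigating a novel food item.
    ``age_class`` is derived metadata; age is analysed continuously.
    """

    individual_id: str
    troop_id: str
    sex: str
    age: float
    absolute_rank: int
    boldness: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise RecordError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.age > 0:
            raise RecordError(f"age must be > 0, got {self.age}")
        if self.absolute_rank < 1:
            raise RecordError(f"absolute_rank must be >= 1, got {self.absolute_rank}")
        if self.boldness < 0:
            raise RecordError(f"boldness must be >= 0, got {self.boldness}")

    @property
    def age_class(self) -> str:
        return "adult" if self.age >= ADULT_AGE else "juvenile"

    @property
    def sex_code(self) -> int:
        return SEX_CODES[self.sex]


@dataclass(frozen=True)
class ScanRecord:
    """One proximity scan: a focal individual and its associates.

    An empty associate list means the focal was alone under the rule.
    Nearest-neighbour scans list at most one associate.
    """

    scan_id: str
    troop_id: str
    timestamp: int
    rule: str
    focal_id: str
    associates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rule not in PROXIMITY_RULES:
            raise RecordError(f"rule must be one of {PROXIMITY_RULES}, got {self.rule!r}")
        if self.focal_id in self.associates:
            raise RecordError(f"focal {self.focal_id!r} cannot be its own associate")
        if len(set(self.associates)) != len(self.associates):
            raise RecordError(f"duplicate associates in scan {self.scan_id!r}")
        if self.rule == "nearest_neighbour" and len(self.associates) > 1:
            raise RecordError(
                f"nearest_neighbour scan {self.scan_id!r} lists "
                f"{len(self.associates)} associates; at most 1 allowed"
            )

    @property
    def group(self) -> frozenset[str]:
        return frozenset((self.focal_id, *self.associates))


@dataclass(frozen=True)
class InteractionRecord:
    """One directed dyadic interaction (grooming bout or dominance event)."""

    event_id: str
    troop_id: str
    timestamp: int
    type: str
    actor_id: str
    recipient_id: str

    def __post_init__(self) -> None:
        if self.type not in INTERACTION_TYPES:
            raise RecordError(f"type must be one of {INTERACTION_TYPES}, got {self.type!r}")
        if self.actor_id == self.recipient_id:
            raise RecordError(f"actor == recipient in event {self.event_id!r}")


@dataclass(frozen=True)
class ApplicationEvent:
    """One patch entry: did the entrant feed, co-feed, and was there protest?"""

    individual_id: str
    fed: bool = False
    cofeed: bool = False
    protested: bool = False


@dataclass
class DiffusionLog:
    """One diffusion experiment: acquisition order, entries and feeding.

    ``acquisition_events`` is the ordered list of tie groups of socially
    informed acquirers; the discoverer is recorded separately and never
    appears in a tie group.  ``application_events`` are patch entries in
    order; a discoverer's own entry of the patch it found is not an
    application event.  ``discovery_position`` records where in the
    troop's spatial spread the discoverer was (optional metadata).
    """

    task_id: str
    troop_id: str
    discoverer_id: str
    acquisition_events: list[frozenset[str]] = field(default_factory=list)
    application_events: list[ApplicationEvent] = field(default_factory=list)
    discovery_position: str | None = None

    def __post_init__(self) -> None:
        self.acquisition_events = [frozenset(g) for g in self.acquisition_events]
        if self.discovery_position is not None and self.discovery_position not in DISCOVERY_POSITIONS:
            raise RecordError(
                f"discovery_position must be one of {DISCOVERY_POSITIONS}, "
                f"got {self.discovery_position!r}"
            )
        seen: set[str] = set()
        for g in self.acquisition_events:
            if not g:
                raise RecordError(f"empty tie group in task {self.task_id!r}")
            if self.discoverer_id in g:
                raise RecordError(
                    f"discoverer {self.discoverer_id!r} appears in an "
                    f"acquisition tie group of task {self.task_id!r}"
                )
            dup = seen & g
            if dup:
                raise RecordError(
                    f"individual(s) {sorted(dup)} appear in more than one "
                    f"tie group of task {self.task_id!r}"
                )
            seen |= g
        informed = seen | {self.discoverer_id}
        for ev in self.application_events:
            if ev.individual_id not in informed:
                raise IntegrityError(
                    f"{ev.individual_id!r} entered the patch in task "
                    f"{self.task_id!r} without prior acquisition or discovery"
                )

    @property
    def acquirers(self) -> set[str]:
        out: set[str] = set()
        for g in self.acquisition_events:
            out |= g
        return out

    @property
    def n_informed(self) -> int:
        """Total informed individuals, discoverer included."""
        return 1 + sum(len(g) for g in self.acquisition_events)


@dataclass(frozen=True)
class InformationCounts:
    """Per-individual tallies along the information-use sequence.

    Counts cover socially informed events only: occasions on which the
    individual discovered the patch itself are excluded from the three
    sequence counts and tallied in ``n_discovered``.
    """

    individual_id: str
    n_acquired: int = 0
    n_applied: int = 0
    n_exploited: int = 0
    n_discovered: int = 0

    def __post_init__(self) -> None:
        for name in ("n_acquired", "n_applied", "n_exploited", "n_discovered"):
            if getattr(self, name) < 0:
                raise RecordError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Tallies and summaries
# ---------------------------------------------------------------------------

def tally_counts(logs: Iterable[DiffusionLog]) -> list[InformationCounts]:
    """Count socially informed acquisition / application / exploitation events.

    Discovery occasions are excluded from the sequence counts (a
    discoverer's patch knowledge on that occasion is personal, not
    social) and counted separately. Unidentified acquirers are dropped
    with a warning.
    """
    acc: dict[str, dict[str, int]] = {}

    def bump(ind: str, key: str) -> None:
        acc.setdefault(ind, {"n_acquired": 0, "n_applied": 0, "n_exploited": 0, "n_discovered": 0})
        acc[ind][key] += 1

    for log in logs:
        bump(log.discoverer_id, "n_discovered")
        for g in log.acquisition_events:
            for ind in g:
                if ind == UNKNOWN_ID:
                    warnings.warn(
                        f"task {log.task_id!r}: unidentified acquirer dropped from tallies",
                        stacklevel=2,
                    )
                    continue
                bump(ind, "n_acquired")
        for ev in log.application_events:
            if ev.individual_id == UNKNOWN_ID:
                continue
            if ev.individual_id == log.discoverer_id:
                # personal, not social, information on this occasion
                continue
            bump(ev.individual_id, "n_applied")
            if ev.fed:
                bump(ev.individual_id, "n_exploited")
    return [
        InformationCounts(individual_id=ind, **vals)
        for ind, vals in sorted(acc.items())
    ]


def counts_frame(counts: Sequence[InformationCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [c.individual_id for c in counts],
            "n_acquired": [c.n_acquired for c in counts],
            "n_applied": [c.n_applied for c in counts],
            "n_exploited": [c.n_exploited for c in counts],
            "n_discovered": [c.n_discovered for c in counts],
        }
    )


def cofeed_summary(logs: Iterable[DiffusionLog]) -> dict:
    """Summarise patch entries, co-feeding and tolerated co-feeding.

    Tolerated co-feeds are co-feeding occasions with no vocal protest.
    Percentages are of all patch entries, reported to one decimal place;
    with zero entries they are reported missing (None).
    """
    entries = cofeeds = protested = 0
    for log in logs:
        for ev in log.application_events:
            entries += 1
            if ev.cofeed:
                cofeeds += 1
                if ev.protested:
                    protested += 1
    tolerated = cofeeds - protested
    if entries == 0:
        pct_cofeed = pct_tolerated = None
    else:
        pct_cofeed = round(100.0 * cofeeds / entries, 1)
        pct_tolerated = round(100.0 * tolerated / entries, 1)
    return {
        "n_entries": entries,
        "n_cofeed": cofeeds,
        "n_protested": protested,
        "n_tolerated": tolerated,
        "pct_cofeed": pct_cofeed,
        "pct_tolerated": pct_tolerated,
    }


def discovery_position_summary(logs: Iterable[DiffusionLog]) -> dict:
    """Tally where in the troop spread the patch discoverer was."""
    counts = {pos: 0 for pos in DISCOVERY_POSITIONS}
    total = 0
    for log in logs:
        if log.discovery_position is not None:
            counts[log.discovery_position] += 1
            total += 1
    pct = {
        pos: (round(100.0 * c / total, 1) if total else None)
        for pos, c in counts.items()
    }
    return {"n_experiments": total, "counts": counts, "pct": pct}


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_PHENOTYPE_COLS = ["individual_id", "troop_id", "sex", "age", "absolute_rank", "boldness"]
_SCAN_COLS = ["scan_id", "troop_id", "timestamp", "rule", "focal_id", "associates"]
_INTERACTION_COLS = ["event_id", "troop_id", "timestamp", "type", "actor_id", "recipient_id"]
_DIFFUSION_COLS = [
    "task_id", "troop_id", "event_kind", "event_index", "individual_id",
    "fed", "cofeed", "protested", "discovery_position",
]

SCHEMAS = {
    "phenotypes": _PHENOTYPE_COLS,
    "scans": _SCAN_COLS,
    "interactions": _INTERACTION_COLS,
    "diffusions": _DIFFUSION_COLS,
}


def _check_header(df: pd.DataFrame, schema: str, path) -> None:
    want = SCHEMAS[schema]
    if list(df.columns) != want:
        raise RecordError(
            f"{path}: header {list(df.columns)} does not match the "
            f"{schema!r} schema {want}"
        )


def _bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("1", "true", "t", "yes")


def read_table(path, schema: str):
    """Read one of the documented CSV schemas into validated records.

    ``schema`` is one of ``phenotypes``, ``scans``, ``interactions``,
    ``diffusions``.  Malformed rows are rejected with their row number.
    Row order is preserved; diffusion rows are grouped into one
    :class:`DiffusionLog` per task in order of first appearance.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df, schema, path)

    records: list = []
    if schema == "diffusions":
        return _rows_to_logs(df, path)
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            if schema == "phenotypes":
                records.append(
                    PhenotypeRecord(
                        individual_id=row.individual_id,
                        troop_id=row.troop_id,
                        sex=row.sex,
                        age=float(row.age),
                        absolute_rank=int(row.absolute_rank),
                        boldness=float(row.boldness),
                    )
                )
            elif schema == "scans":
                assoc = tuple(a for a in str(row.associates).split(";") if a)
                records.append(
                    ScanRecord(
                        scan_id=row.scan_id,
                        troop_id=row.troop_id,
                        timestamp=int(row.timestamp),
                        rule=row.rule,
                        focal_id=row.focal_id,
                        associates=assoc,
                    )
                )
            else:
                records.append(
                    InteractionRecord(
                        event_id=row.event_id,
                        troop_id=row.troop_id,
                        timestamp=int(row.timestamp),
                        type=row.type,
                        actor_id=row.actor_id,
                        recipient_id=row.recipient_id,
                    )
                )
        except (RecordError, ValueError) as exc:
            raise RecordError(f"{path}, row {i}: {exc}") from exc
    return records


def _rows_to_logs(df: pd.DataFrame, path) -> list[DiffusionLog]:
    logs: dict[str, dict] = {}
    order: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        t = row.task_id
        if t not in logs:
            logs[t] = {
                "troop_id": row.troop_id,
                "discoverer": None,
                "position": None,
                "acq": {},   # event_index -> set of ids
                "app": [],   # (event_index, ApplicationEvent)
            }
            order.append(t)
        entry = logs[t]
        kind = row.event_kind
        try:
            idx = int(row.event_index)
            if kind == "discovery":
                entry["discoverer"] = row.individual_id
                entry["position"] = row.discovery_position or None
            elif kind == "acquisition":
                entry["acq"].setdefault(idx, set()).add(row.individual_id)
            elif kind == "application":
                entry["app"].append(
                    (idx, ApplicationEvent(
                        individual_id=row.individual_id,
                        fed=_bool(row.fed),
                        cofeed=_bool(row.cofeed),
                        protested=_bool(row.protested),
                    ))
                )
            else:
                raise RecordError(f"unknown event_kind {kind!r}")
        except (RecordError, ValueError) as exc:
            raise RecordError(f"{path}, row {i}: {exc}") from exc

    out = []
    for t in order:
        e = logs[t]
        if e["discoverer"] is None:
            raise RecordError(f"{path}: task {t!r} has no discovery row")
        acq = [frozenset(e["acq"][k]) for k in sorted(e["acq"])]
        app = [ev for _, ev in sorted(e["app"], key=lambda p: p[0])]
        out.append(
            DiffusionLog(
                task_id=t,
                troop_id=e["troop_id"],
                discoverer_id=e["discoverer"],
                acquisition_events=acq,
                application_events=app,
                discovery_position=e["position"],
            )
        )
    return out


def write_table(records: Sequence, path, schema: str) -> None:
    """Write records back to the documented CSV schema (lossless round trip)."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    rows: list[dict] = []
    if schema == "phenotypes":
        for r in records:
            rows.append(
                dict(individual_id=r.individual_id, troop_id=r.troop_id, sex=r.sex,
                     age=r.age, absolute_rank=r.absolute_rank, boldness=r.boldness)
            )
    elif schema == "scans":
        for r in records:
            rows.append(
                dict(scan_id=r.scan_id, troop_id=r.troop_id, timestamp=r.timestamp,
                     rule=r.rule, focal_id=r.focal_id, associates=";".join(r.associates))
            )
    elif schema == "interactions":
        for r in records:
            rows.append(
                dict(event_id=r.event_id, troop_id=r.troop_id, timestamp=r.timestamp,
                     type=r.type, actor_id=r.actor_id, recipient_id=r.recipient_id)
            )
    else:
        for log in records:
            rows.append(
                dict(task_id=log.task_id, troop_id=log.troop_id, event_kind="discovery",
                     event_index=0, individual_id=log.discoverer_id, fed=False,
                     cofeed=False, protested=False,
                     discovery_position=log.discovery_position or "")
            )
            for k, g in enumerate(log.acquisition_events, start=1):
                for ind in sorted(g):
                    rows.append(
                        dict(task_id=log.task_id, troop_id=log.troop_id,
                             event_kind="acquisition", event_index=k, individual_id=ind,
                             fed=False, cofeed=False, protested=False, discovery_position="")
                    )
            for k, ev in enumerate(log.application_events, start=1):
                rows.append(
                    dict(task_id=log.task_id, troop_id=log.troop_id,
                         event_kind="application", event_index=k,
                         individual_id=ev.individual_id, fed=ev.fed, cofeed=ev.cofeed,
                         protested=ev.protested, discovery_position="")
                )
    pd.DataFrame(rows, columns=SCHEMAS[schema]).to_csv(path, index=False)


def phenotype_frame(records: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    """Phenotypes as a DataFrame with derived covariate columns.

    Adds ``sex_code`` (female=0, male=1), ``relative_rank`` (within
    troop) and ``age_class``.  Checks that absolute ranks within each
    troop form a permutation of 1..n.
    """
    df = pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "troop_id": [r.troop_id for r in records],
            "sex": [r.sex for r in records],
            "age": [r.age for r in records],
            "absolute_rank": [r.absolute_rank for r in records],
            "boldness": [r.boldness for r in records],
        }
    )
    if df["individual_id"].duplicated().any():
        dup = df.loc[df["individual_id"].duplicated(), "individual_id"].tolist()
        raise IntegrityError(f"duplicate individual ids: {dup}")
    rel = pd.Series(index=df.index, dtype=float)
    for troop, sub in df.groupby("troop_id"):
        n = len(sub)
        ranks = sorted(sub["absolute_rank"])
        if ranks != list(range(1, n + 1)):
            raise IntegrityError(
                f"troop {troop!r}: absolute ranks are not a permutation of 1..{n}"
            )
        rel.loc[sub.index] = [relative_rank(r, n) for r in sub["absolute_rank"]]
    df["relative_rank"] = rel
    df["sex_code"] = df["sex"].map(SEX_CODES)
    df["age_class"] = ["adult" if a >= ADULT_AGE else "juvenile" for a in df["age"]]
    return df.set_index("individual_id", drop=False)
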