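"""Association networks from field records, and weighted centrality.

Five association rules are supported per troop: two symmetric proximity
rules scored with the simple ratio index (10 m radius and 5 m chain),
and three directed count rules (nearest neighbour, grooming, dominance)
that can also be symmetrized by summing given and received counts —
eight candidate matrices per troop in total.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .records import InteractionRecord, ScanRecord

#: The eight candidate network rules (per troop).
SRI_RULES = ("ten_m", "five_m_chain")
DIRECTED_RULES = ("nn_directed", "groom_directed", "dom_directed")
UNDIRECTED_COUNT_RULES = ("nn_undirected", "groom_undirected", "dom_undirected")
ALL_RULES = SRI_RULES + DIRECTED_RULES + UNDIRECTED_COUNT_RULES

#: map a count rule to the record source it is built from
_COUNT_SOURCES = {
    "nn_directed": ("scan", "nearest_neighbour"),
    "groom_directed": ("interaction", "groom"),
    "dom_directed": ("interaction", "dominance"),
}


class NetworkError(ValueError):
    """Invalid network construction input."""


@dataclass
class AssociationMatrix:
    """A weighted, possibly directed, per-troop adjacency matrix.

    ``weights[i, j]`` is the edge from ``ids[i]`` to ``ids[j]``.  SRI
    rules produce weights in [0, 1]; count rules produce nonnegative
    integers. The diagonal is always zero.
    """

    troop_id: str
    rule: str
    ids: tuple[str, ...]
    weights: np.ndarray
    directed: bool

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        w = np.asarray(self.weights, dtype=float)
        n = len(self.ids)
        if w.shape != (n, n):
            raise NetworkError(f"weights shape {w.shape} does not match {n} ids")
        if np.any(np.diag(w) != 0):
            raise NetworkError("diagonal must be zero")
        if np.any(w < 0):
            raise NetworkError("weights must be nonnegative")
        if not self.directed and not np.allclose(w, w.T):
            raise NetworkError("undirected matrix must be symmetric")
        self.weights = w

    def index_of(self, individual_id: str) -> int:
        return self.ids.index(individual_id)

    def to_edge_frame(self) -> pd.DataFrame:
        """Long edge list (nonzero edges only; one row per ordered or
        unordered dyad depending on directedness)."""
        rows = []
        n = len(self.ids)
        for i in range(n):
            js = range(n) if self.directed else range(i + 1, n)
            for j in js:
                if i != j and self.weights[i, j] != 0:
                    rows.append((self.ids[i], self.ids[j], self.weights[i, j], self.directed))
        return pd.DataFrame(rows, columns=["id_a", "id_b", "weight", "directed"])


def _merge_groups(groups: list[set[str]]) -> list[set[str]]:
    """Union overlapping member sets (transitive closure within a scan)."""
    merged: list[set[str]] = []
    for g in groups:
        g = set(g)
        keep = []
        for m in merged:
            if m & g:
                g |= m
            else:
                keep.append(m)
        keep.append(g)
        merged = keep
    return merged


def scan_occasions(scans: list[ScanRecord]) -> list[list[set[str]]]:
    """Group scans by scan_id into sampling occasions.

    Each occasion is a list of disjoint groups; records sharing a
    scan_id that list overlapping members are merged transitively
    (chain-rule groups may be recorded in parts).
    """
    by_id: dict[str, list[set[str]]] = {}
    order: list[str] = []
    for s in scans:
        if s.scan_id not in by_id:
            by_id[s.scan_id] = []
            order.append(s.scan_id)
        by_id[s.scan_id].append(set(s.group))
    return [_merge_groups(by_id[k]) for k in order]


def sri_matrix(scans: list[ScanRecord], rule: str, ids: list[str] | None = None) -> AssociationMatrix:
    """Simple ratio index matrix from proximity scans.

    For each dyad (A, B): ``SRI = x / (x + y_ab + y_a + y_b)`` where
    ``x`` counts occasions with A and B in the same group, ``y_ab``
    occasions where both were observed but in separate groups, and
    ``y_a`` (``y_b``) occasions where only A (only B) was observed.
    Occasions where neither was observed do not enter the index.
    """
    if rule not in SRI_RULES:
        raise NetworkError(f"SRI applies to rules {SRI_RULES}, got {rule!r}")
    bad = [s for s in scans if s.rule != rule]
    if bad:
        raise NetworkError(f"{len(bad)} scans do not carry rule {rule!r}")
    troops = {s.troop_id for s in scans}
    if len(troops) != 1:
        raise NetworkError(f"scans span troops {sorted(troops)}; build one troop at a time")
    troop = troops.pop()

    observed: set[str] = set()
    for s in scans:
        observed |= set(s.group)
    if ids is None:
        ids = sorted(observed)
    else:
        missing = sorted(set(ids) - observed)
        if missing:
            raise NetworkError(
                f"SRI undefined for never-observed individual(s): {missing}"
            )
    idx = {a: i for i, a in enumerate(ids)}
    n = len(ids)

    x = np.zeros((n, n))
    both = np.zeros((n, n))  # occasions where both observed (any group)
    seen = np.zeros(n)
    for occ in scan_occasions(scans):
        members = [np.array(sorted(idx[a] for a in g if a in idx), dtype=int) for g in occ]
        all_obs = np.concatenate(members) if members else np.array([], dtype=int)
        if all_obs.size == 0:
            continue
        seen[all_obs] += 1
        both[np.ix_(all_obs, all_obs)] += 1
        for m in members:
            x[np.ix_(m, m)] += 1
    np.fill_diagonal(x, 0)
    np.fill_diagonal(both, 0)
    # denominator = occasions where A or B (or both) observed
    denom = seen[:, None] + seen[None, :] - both
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, x / np.where(denom > 0, denom, 1), 0.0)
    np.fill_diagonal(w, 0.0)
    return AssociationMatrix(troop_id=troop, rule=rule, ids=tuple(ids), weights=w, directed=False)


def directed_count_matrix(records, rule: str, ids: list[str] | None = None) -> AssociationMatrix:
    """Directed count matrix: w(A, B) = number of events with A as actor.

    For nearest-neighbour scans the 'actor' is the focal naming B as
    its neighbour; for interactions it is the groomer / aggressor.
    """
    if rule not in _COUNT_SOURCES:
        raise NetworkError(f"rule must be one of {sorted(_COUNT_SOURCES)}, got {rule!r}")
    source, subtype = _COUNT_SOURCES[rule]

    pairs: list[tuple[str, str]] = []
    participants: set[str] = set()
    troops: set[str] = set()
    for r in records:
        troops.add(r.troop_id)
        if source == "scan":
            if not isinstance(r, ScanRecord) or r.rule != subtype:
                raise NetworkError(f"record {r!r} is not a {subtype} scan")
            participants.add(r.focal_id)
            participants |= set(r.associates)
            if r.associates:
                pairs.append((r.focal_id, r.associates[0]))
        else:
            if not isinstance(r, InteractionRecord) or r.type != subtype:
                raise NetworkError(f"record {r!r} is not a {subtype} interaction")
            participants |= {r.actor_id, r.recipient_id}
            pairs.append((r.actor_id, r.recipient_id))
    if len(troops) > 1:
        raise NetworkError(f"records span troops {sorted(troops)}; build one troop at a time")
    troop = troops.pop() if troops else ""
    if ids is None:
        ids = sorted(participants)
    idx = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    w = np.zeros((n, n))
    for a, b in pairs:
        if a in idx and b in idx:
            w[idx[a], idx[b]] += 1
    return AssociationMatrix(troop_id=troop, rule=rule, ids=tuple(ids), weights=w, directed=True)


_SYMMETRIZED_RULE = {
    "nn_directed": "nn_undirected",
    "groom_directed": "groom_undirected",
    "dom_directed": "dom_undirected",
}


def symmetrize(m: AssociationMatrix) -> AssociationMatrix:
    """Sum interactions given and received: w'(A,B) = w(A,B) + w(B,A).

    Calling on an already-undirected matrix is a no-op with a warning.
    """
    if not m.directed:
        warnings.warn(f"matrix with rule {m.rule!r} is already undirected; no-op", stacklevel=2)
        return m
    return replace(
        m,
        rule=_SYMMETRIZED_RULE.get(m.rule, m.rule),
        weights=m.weights + m.weights.T,
        directed=False,
    )


def strength(m: AssociationMatrix) -> pd.Series:
    """Sum of an individual's weighted edges.

    For directed matrices this sums edges given and received (in + out),
    matching strength on the symmetrized matrix; set
    ``strength(m, ...)`` convention via :func:`strength_out` if only
    outgoing edges are wanted.
    """
    w = m.weights
    vals = w.sum(axis=1) + w.sum(axis=0) if m.directed else w.sum(axis=1)
    return pd.Series(vals, index=list(m.ids), name=f"strength_{m.rule}")


def strength_out(m: AssociationMatrix) -> pd.Series:
    """Out-strength only (edges given); equals strength for undirected."""
    return pd.Series(m.weights.sum(axis=1), index=list(m.ids), name=f"strength_out_{m.rule}")


def to_graph(m: AssociationMatrix) -> nx.Graph | nx.DiGraph:
    """networkx graph with edge ``weight`` and shortest-path ``distance``.

    Distance is 1/weight (strong associations are short paths);
    zero-weight dyads are non-edges.
    """
    g: nx.Graph | nx.DiGraph = nx.DiGraph() if m.directed else nx.Graph()
    g.add_nodes_from(m.ids)
    n = len(m.ids)
    for i in range(n):
        js = range(n) if m.directed else range(i + 1, n)
        for j in js:
            w = m.weights[i, j]
            if i != j and w > 0:
                g.add_edge(m.ids[i], m.ids[j], weight=w, distance=1.0 / w)
    return g


def betweenness(m: AssociationMatrix) -> pd.Series:
    """Weighted shortest-path betweenness (unnormalized, endpoints excluded).

    Edge length is 1/weight; unreachable pairs contribute nothing, and
    equal-length shortest paths split their count fractionally.
    """
    g = to_graph(m)
    bc = nx.betweenness_centrality(g, weight="distance", normalized=False)
    return pd.Series([bc[a] for a in m.ids], index=list(m.ids), name=f"betweenness_{m.rule}")


def centrality_table(m: AssociationMatrix) -> pd.DataFrame:
    """Strength and betweenness per individual for one matrix."""
    return pd.DataFrame(
        {
            "individual_id": list(m.ids),
            "rule": m.rule,
            "strength": strength(m).to_numpy(),
            "betweenness": betweenness(m).to_numpy(),
        }
    )


def spearman_screen(columns: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations over the same individuals.

    Reports, per column pair, the test statistic ``S`` (sum of squared
    rank differences, with average ranks for ties), ``rho`` and a
    two-sided p-value from the t approximation. A constant column makes
    rho undefined; such pairs are reported with missing values.
    """
    if len(columns) < 4:
        raise ValueError(f"need >= 4 paired observations, got {len(columns)}")
    rows = []
    for a, b in itertools.combinations(columns.columns, 2):
        xa = columns[a].to_numpy(dtype=float)
        xb = columns[b].to_numpy(dtype=float)
        n = len(xa)
        if np.all(xa == xa[0]) or np.all(xb == xb[0]):
            rows.append((a, b, n, np.nan, np.nan, np.nan))
            continue
        ra = stats.rankdata(xa)
        rb = stats.rankdata(xb)
        s = float(np.sum((ra - rb) ** 2))
        rho = float(stats.spearmanr(xa, xb).statistic)
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
        rows.append((a, b, n, s, rho, p))
    return pd.DataFrame(rows, columns=["var_a", "var_b", "n", "S", "rho", "p"])


def build_troop_networks(
    scans: list[ScanRecord],
    interactions: list[InteractionRecord],
    ids: list[str],
) -> dict[str, AssociationMatrix]:
    """All eight candidate matrices for one troop, keyed by rule."""
    by_rule = {r: [s for s in scans if s.rule == r] for r in
               ("ten_m", "five_m_chain", "nearest_neighbour")}
    by_type = {t: [i for i in interactions if i.type == t] for t in ("groom", "dominance")}
    out: dict[str, AssociationMatrix] = {}
    out["ten_m"] = sri_matrix(by_rule["ten_m"], "ten_m", ids=ids)
    out["five_m_chain"] = sri_matrix(by_rule["five_m_chain"], "five_m_chain", ids=ids)
    out["nn_directed"] = directed_count_matrix(by_rule["nearest_neighbour"], "nn_directed", ids=ids)
    out["groom_directed"] = directed_count_matrix(by_type["groom"], "groom_directed", ids=ids)
    out["dom_directed"] = directed_count_matrix(by_type["dominance"], "dom_directed", ids=ids)
    for d in DIRECTED_RULES:
        out[_SYMMETRIZED_RULE[d]] = symmetrize(out[d])
    return out
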