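"""Order-of-acquisition diffusion analysis (OADA).

OADA asks which social network, if any, shaped the order in which
individuals acquired a piece of information.  Each acquisition event
contributes a partial-likelihood factor: the acquirer's acquisition
rate divided by the summed rates of all still-naive troop members (the
risk set).  A naive individual i's rate combines a social term — s
times its summed network connection T_i to already-informed
individuals — with an asocial baseline exp(Gamma_i), where Gamma_i is a
linear predictor over individual-level variables (ILVs):

    additive        R_i = s * T_i + exp(Gamma_i)
    multiplicative  R_i = exp(Gamma_i) * (s * T_i + 1)
    asocial         R_i = exp(Gamma_i)

Because each factor is a ratio of rates within one diffusion, any
per-task baseline rate cancels: separate experiments (tasks) enter as
independent likelihood factors, and troop membership selects which
matrix supplies the connections.

The social transmission parameter is optimized on the unbounded rate
scale s in [0, inf) and additionally reported on the bounded scale
s/(1+s) in [0, 1).  Models are compared by AICc with k = number of ILV
coefficients plus one for s in social models, and n = the total number
of acquisition events.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .networks import AssociationMatrix
from .records import UNKNOWN_ID, DiffusionLog

#: Individual-level variables usable in the acquisition-rate model,
#: mapped to their phenotype-frame columns.  Rank enters on the
#: relative (within-troop, [0,1]) scale; sex is coded female=0, male=1.
ILV_COLUMNS = {
    "rank": "relative_rank",
    "sex": "sex_code",
    "age": "age",
    "boldness": "boldness",
}
ALL_ILVS = ("rank", "sex", "age", "boldness")

FORMS = ("additive", "multiplicative", "asocial")
TIE_METHODS = ("breslow", "exact")

#: Fixed multi-start grid over the unbounded social parameter.
S_START_GRID = (0.0, 1.0, 10.0, 100.0, 1000.0)

_GAMMA_CLIP = 50.0  # linear-predictor clip guarding exp overflow
_MAX_EXACT_TIE = 6


class OADAError(ValueError):
    pass


def s_bounded_from_unbounded(s: float) -> float:
    """Map s in [0, inf) to [0, 1): the share of the acquisition rate
    that is social when T_i = 1 and the baseline is 1."""
    return s / (1.0 + s)


def s_unbounded_from_bounded(sb: float) -> float:
    if not 0.0 <= sb < 1.0:
        raise OADAError(f"bounded s must be in [0, 1), got {sb}")
    return sb / (1.0 - sb)


@dataclass(frozen=True)
class OADASpec:
    """One candidate model: a network rule (or none), a functional form,
    an ILV subset and a tie method."""

    network_rule: str | None
    form: str
    ilvs: tuple[str, ...] = ()
    tie_method: str = "breslow"

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise OADAError(f"form must be one of {FORMS}, got {self.form!r}")
        if self.tie_method not in TIE_METHODS:
            raise OADAError(f"tie_method must be one of {TIE_METHODS}")
        if (self.form == "asocial") != (self.network_rule is None):
            raise OADAError("asocial form requires network_rule=None and vice versa")
        unknown = [v for v in self.ilvs if v not in ILV_COLUMNS]
        if unknown:
            raise OADAError(f"unknown ILV(s) {unknown}; available: {sorted(ILV_COLUMNS)}")
        object.__setattr__(self, "ilvs", tuple(self.ilvs))

    @property
    def social(self) -> bool:
        return self.form != "asocial"

    @property
    def k(self) -> int:
        return len(self.ilvs) + (1 if self.social else 0)

    def label(self) -> str:
        net = self.network_rule or "-"
        ilvs = "+".join(self.ilvs) if self.ilvs else "none"
        return f"{self.form}:{net}:{ilvs}"


@dataclass
class OADAFit:
    """A fitted model: transmission parameter (both scales), ILV
    coefficients, log-likelihood and AICc."""

    spec: OADASpec
    s_unbounded: float
    betas: dict[str, float]
    loglik: float
    k: int
    n_events: int
    converged: bool = True
    message: str = ""

    @property
    def s_bounded(self) -> float:
        return s_bounded_from_unbounded(self.s_unbounded)

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n_events)


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction."""
    if n - k - 1 <= 0:
        return math.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def transmission_term(
    individual_id: str,
    informed: set[str],
    m: AssociationMatrix,
    direction: str = "outgoing",
) -> float:
    """Summed connection of a naive individual to the informed set.

    For directed matrices the default sums the naive individual's
    outgoing edges toward informed individuals (it attends to those it
    associates to); ``direction='incoming'`` sums edges received.
    """
    if individual_id in informed:
        raise OADAError(f"{individual_id!r} is already informed")
    i = m.index_of(individual_id)
    total = 0.0
    for k in informed:
        j = m.index_of(k)
        if m.directed and direction == "incoming":
            total += m.weights[j, i]
        else:
            total += m.weights[i, j]
    return total


# ---------------------------------------------------------------------------
# Precomputed event structure
# ---------------------------------------------------------------------------

@dataclass
class _Event:
    risk: np.ndarray        # indices (into matrix ids) of naive individuals
    acq_pos: np.ndarray     # positions within `risk` of the (tied) acquirers
    T: np.ndarray           # social transmission term per risk-set member


@dataclass
class _DiffusionData:
    events: list[_Event]
    X: np.ndarray           # n_individuals x n_ilvs covariates (matrix id order)
    n_events: int           # acquiring individuals (tied each count once)
    # concatenated per-event arrays for the vectorized Breslow path
    risk_concat: np.ndarray = None  # type: ignore[assignment]
    T_concat: np.ndarray = None     # type: ignore[assignment]
    offsets: np.ndarray = None      # type: ignore[assignment]
    acq_concat: np.ndarray = None   # type: ignore[assignment]
    group_sizes: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.events:
            self.risk_concat = np.concatenate([ev.risk for ev in self.events])
            self.T_concat = np.concatenate([ev.T for ev in self.events])
            sizes = np.array([ev.risk.size for ev in self.events])
            self.offsets = np.concatenate(([0], np.cumsum(sizes)[:-1]))
            self.acq_concat = np.concatenate(
                [ev.acq_pos + off for ev, off in zip(self.events, self.offsets)]
            )
            self.group_sizes = np.array([ev.acq_pos.size for ev in self.events])
        else:
            self.risk_concat = np.empty(0, dtype=int)
            self.T_concat = np.empty(0)
            self.offsets = np.empty(0, dtype=int)
            self.acq_concat = np.empty(0, dtype=int)
            self.group_sizes = np.empty(0, dtype=int)


def _covariates(phenotypes: pd.DataFrame, ids: tuple[str, ...], ilvs: tuple[str, ...]) -> np.ndarray:
    X = np.empty((len(ids), len(ilvs)))
    for j, v in enumerate(ilvs):
        col = ILV_COLUMNS[v]
        for i, ind in enumerate(ids):
            if ind not in phenotypes.index or pd.isna(phenotypes.loc[ind, col]):
                raise OADAError(f"missing covariate {v!r} for individual {ind!r}")
            X[i, j] = phenotypes.loc[ind, col]
    return X


def _prepare_diffusion(
    log: DiffusionLog,
    m: AssociationMatrix | None,
    phenotypes: pd.DataFrame,
    ilvs: tuple[str, ...],
    direction: str,
) -> _DiffusionData:
    """Walk one diffusion once, recording risk sets, acquirer positions
    and transmission terms; likelihood evaluation then only needs (s, beta)."""
    if m is not None:
        ids = m.ids
        w = m.weights if not (m.directed and direction == "incoming") else m.weights.T
    else:
        ids = tuple(sorted(phenotypes.loc[phenotypes["troop_id"] == log.troop_id, "individual_id"]))
        w = None
    index = {a: i for i, a in enumerate(ids)}
    n = len(ids)

    if log.discoverer_id not in index:
        raise OADAError(f"discoverer {log.discoverer_id!r} not among troop ids for task {log.task_id!r}")
    naive = np.ones(n, dtype=bool)
    naive[index[log.discoverer_id]] = False
    T = w[:, index[log.discoverer_id]].copy() if w is not None else np.zeros(n)

    events: list[_Event] = []
    n_events = 0
    for g in log.acquisition_events:
        known = sorted(a for a in g if a != UNKNOWN_ID)
        if len(known) < len(g):
            warnings.warn(
                f"task {log.task_id!r}: unidentified acquirer dropped from the likelihood",
                stacklevel=3,
            )
        missing = [a for a in known if a not in index]
        if missing:
            raise OADAError(f"acquirer(s) {missing} of task {log.task_id!r} not among troop ids")
        if known:
            risk = np.flatnonzero(naive)
            if risk.size == 0:
                raise OADAError(f"task {log.task_id!r}: acquisition event with empty risk set")
            pos_of = {idx: p for p, idx in enumerate(risk)}
            acq_idx = [index[a] for a in known]
            for a in acq_idx:
                if a not in pos_of:
                    raise OADAError(
                        f"task {log.task_id!r}: {ids[a]!r} acquires but is no longer naive"
                    )
            events.append(_Event(risk=risk, acq_pos=np.array([pos_of[a] for a in acq_idx]),
                                 T=T[risk].copy()))
            n_events += len(acq_idx)
        for a in known:
            i = index[a]
            naive[i] = False
            if w is not None:
                T = T + w[:, i]
    X = _covariates(phenotypes, ids, ilvs)
    return _DiffusionData(events=events, X=X, n_events=n_events)


def _event_loglik(ev: _Event, R: np.ndarray, tie_method: str) -> float:
    acq = ev.acq_pos
    if np.any(R[acq] <= 0):
        return -np.inf
    denom = float(R.sum())
    if len(acq) == 1 or tie_method == "breslow":
        return float(np.sum(np.log(R[acq]))) - len(acq) * math.log(denom)
    if len(acq) > _MAX_EXACT_TIE:
        raise OADAError(
            f"exact tie handling supports tie groups of <= {_MAX_EXACT_TIE}; got {len(acq)}"
        )
    # exact: average of the sequential probabilities over all orderings
    probs = []
    for perm in itertools.permutations(acq):
        d = denom
        p = 1.0
        for a in perm:
            p *= R[a] / d
            d -= R[a]
        probs.append(p)
    return math.log(sum(probs) / len(probs))


def _loglik(
    data: list[_DiffusionData],
    spec: OADASpec,
    s: float,
    beta: np.ndarray,
) -> float:
    total = 0.0
    for d in data:
        if not d.events:
            continue
        if beta.size:
            gam = np.clip(d.X @ beta, -_GAMMA_CLIP, _GAMMA_CLIP)
            expg = np.exp(gam)
        else:
            expg = None
        if spec.tie_method == "breslow":
            # vectorized: shared pre-event denominators make tied and
            # untied events a single segmented-sum computation
            e = expg[d.risk_concat] if expg is not None else 1.0
            if spec.form == "additive":
                R = s * d.T_concat + e if expg is not None else s * d.T_concat + 1.0
            elif spec.form == "multiplicative":
                R = (s * d.T_concat + 1.0) * e
            else:
                R = e if expg is not None else np.ones_like(d.T_concat)
            R = np.asarray(R, dtype=float)
            if np.any(R[d.acq_concat] <= 0):
                return -np.inf
            seg = np.add.reduceat(R, d.offsets)
            total += float(np.log(R[d.acq_concat]).sum() - (d.group_sizes * np.log(seg)).sum())
            continue
        for ev in d.events:
            e = expg[ev.risk] if expg is not None else 1.0
            if spec.form == "additive":
                R = s * ev.T + e if expg is not None else s * ev.T + 1.0
            elif spec.form == "multiplicative":
                R = (s * ev.T + 1.0) * e
            else:
                R = e if expg is not None else np.ones_like(ev.T)
            total += _event_loglik(ev, np.asarray(R, dtype=float), spec.tie_method)
    return total


def diffusion_loglik(
    log: DiffusionLog,
    m: AssociationMatrix | None,
    spec: OADASpec,
    phenotypes: pd.DataFrame,
    s: float = 0.0,
    betas: dict[str, float] | None = None,
    direction: str = "outgoing",
) -> float:
    """Partial log-likelihood of one diffusion at given parameter values.

    The discoverer is seeded as informed before the first event; at
    each event the contribution is the acquirer's rate over the summed
    rates of the naive risk set, with tie groups handled by the spec's
    tie method (Breslow: shared pre-event denominator; exact: averaged
    over tie orderings).
    """
    betas = betas or {}
    beta = np.array([betas.get(v, 0.0) for v in spec.ilvs])
    data = _prepare_diffusion(log, m if spec.social else None, phenotypes, spec.ilvs, direction)
    return _loglik([data], spec, s, beta)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _prepare_all(
    logs: list[DiffusionLog],
    networks: dict[str, AssociationMatrix] | None,
    phenotypes: pd.DataFrame,
    spec: OADASpec,
    direction: str,
) -> list[_DiffusionData]:
    data = []
    for log in logs:
        m = None
        if spec.social:
            if networks is None or log.troop_id not in networks:
                raise OADAError(f"no matrix for troop {log.troop_id!r}")
            m = networks[log.troop_id]
        data.append(_prepare_diffusion(log, m, phenotypes, spec.ilvs, direction))
    return data


def fit_oada(
    logs: list[DiffusionLog],
    networks: dict[str, AssociationMatrix] | None,
    spec: OADASpec,
    phenotypes: pd.DataFrame,
    direction: str = "outgoing",
    tol: float = 1e-8,
) -> OADAFit:
    """Maximize the combined partial likelihood over (s, betas).

    ``networks`` maps troop id to that troop's matrix for the spec's
    rule (ignored for asocial models).  Each diffusion is an
    independent likelihood factor; the total log-likelihood sums over
    experiments and troops.  Optimization is a deterministic multi-start
    (fixed grid over s, zero-start betas) of bound-constrained
    L-BFGS-B, so refits are reproducible; non-convergence of every
    start is flagged on the returned fit rather than raised.
    """
    data = _prepare_all(logs, networks, phenotypes, spec, direction)
    n_events = sum(d.n_events for d in data)
    n_ilv = len(spec.ilvs)

    if not spec.social and n_ilv == 0:
        ll = _loglik(data, spec, 0.0, np.empty(0))
        return OADAFit(spec=spec, s_unbounded=0.0, betas={}, loglik=ll,
                       k=0, n_events=n_events)

    def negll(params: np.ndarray) -> float:
        if spec.social:
            s, beta = params[0], params[1:]
        else:
            s, beta = 0.0, params
        v = _loglik(data, spec, s, beta)
        return math.inf if not np.isfinite(v) else -v

    bounds = ([(0.0, None)] if spec.social else []) + [(None, None)] * n_ilv
    starts = (
        [np.concatenate(([s0], np.zeros(n_ilv))) for s0 in S_START_GRID]
        if spec.social
        else [np.zeros(n_ilv)]
    )
    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    if spec.social:
        s_hat, beta_hat = float(best.x[0]), best.x[1:]
    else:
        s_hat, beta_hat = 0.0, best.x
    fit = OADAFit(
        spec=spec,
        s_unbounded=s_hat,
        betas={v: float(b) for v, b in zip(spec.ilvs, beta_hat)},
        loglik=-float(best.fun),
        k=spec.k,
        n_events=n_events,
        converged=any_converged,
        message="" if any_converged else str(best.message),
    )
    if not any_converged:
        warnings.warn(f"OADA fit {spec.label()} did not converge: {best.message}", stacklevel=2)
    return fit


# ---------------------------------------------------------------------------
# Model tables, comparison, subset search, averaging
# ---------------------------------------------------------------------------

@dataclass
class ModelTable:
    """Fitted candidates ranked by AICc, with Akaike weights."""

    fits: list[OADAFit] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            rows.append(
                dict(
                    model=f.spec.label(),
                    form=f.spec.form,
                    network=f.spec.network_rule or "-",
                    ilvs="+".join(f.spec.ilvs) if f.spec.ilvs else "none",
                    df=f.k,
                    loglik=f.loglik,
                    aicc=f.aicc,
                    s_unbounded=f.s_unbounded if f.spec.social else np.nan,
                    s_bounded=f.s_bounded if f.spec.social else np.nan,
                    converged=f.converged,
                )
            )
        df = pd.DataFrame(rows)
        if len(df):
            df = df.sort_values("aicc", kind="mergesort").reset_index(drop=True)
            df["delta_aicc"] = df["aicc"] - df["aicc"].min()
            rel = np.exp(-0.5 * df["delta_aicc"].to_numpy())
            df["akaike_weight"] = rel / rel.sum()
        for model, err in self.errors.items():
            df = pd.concat(
                [df, pd.DataFrame([dict(model=model, converged=False, error=err)])],
                ignore_index=True,
            )
        return df

    def best(self) -> OADAFit:
        if not self.fits:
            raise OADAError("no fitted models in table")
        return min(self.fits, key=lambda f: f.aicc)


def compare_networks(
    logs: list[DiffusionLog],
    networks_by_rule: dict[str, dict[str, AssociationMatrix]],
    phenotypes: pd.DataFrame,
    forms: tuple[str, ...] = ("additive", "multiplicative"),
    ilvs: tuple[str, ...] = ALL_ILVS,
    tie_method: str = "breslow",
    direction: str = "outgoing",
) -> ModelTable:
    """Fit one social model per (network rule, form) plus one asocial
    model, all with the same ILVs, and rank them by AICc."""
    table = ModelTable()
    for rule, per_troop in networks_by_rule.items():
        for form in forms:
            spec = OADASpec(network_rule=rule, form=form, ilvs=ilvs, tie_method=tie_method)
            try:
                table.fits.append(fit_oada(logs, per_troop, spec, phenotypes, direction=direction))
            except OADAError as exc:
                table.errors[spec.label()] = str(exc)
    asocial = OADASpec(network_rule=None, form="asocial", ilvs=ilvs, tie_method=tie_method)
    table.fits.append(fit_oada(logs, None, asocial, phenotypes, direction=direction))
    return table


def ilv_subset_search(
    logs: list[DiffusionLog],
    networks: dict[str, AssociationMatrix],
    rule: str,
    phenotypes: pd.DataFrame,
    forms: tuple[str, ...] = ("additive", "multiplicative"),
    ilv_pool: tuple[str, ...] = ALL_ILVS,
    tie_method: str = "breslow",
    direction: str = "outgoing",
) -> ModelTable:
    """All-subsets ILV search on one network: every ILV combination
    crossed with every form."""
    table = ModelTable()
    for r in range(len(ilv_pool) + 1):
        for subset in itertools.combinations(ilv_pool, r):
            for form in forms:
                spec = OADASpec(network_rule=rule, form=form, ilvs=subset, tie_method=tie_method)
                try:
                    table.fits.append(
                        fit_oada(logs, networks, spec, phenotypes, direction=direction)
                    )
                except OADAError as exc:
                    table.errors[spec.label()] = str(exc)
    return table


def model_average(table: ModelTable, threshold: float = 2.0) -> dict[str, float]:
    """Full-model average of ILV coefficients over models with
    delta-AICc <= threshold.

    Akaike weights are renormalized over the retained set and a
    coefficient of 0 is substituted where an ILV is absent from a
    model, so averaged effects shrink toward zero for rarely retained
    variables.
    """
    if not table.fits:
        raise OADAError("cannot average an empty model table")
    best_aicc = min(f.aicc for f in table.fits)
    retained = [f for f in table.fits if f.aicc - best_aicc <= threshold]
    rel = np.array([math.exp(-0.5 * (f.aicc - best_aicc)) for f in retained])
    wts = rel / rel.sum()
    ilvs = sorted({v for f in retained for v in f.spec.ilvs})
    return {
        v: float(sum(w * f.betas.get(v, 0.0) for w, f in zip(wts, retained)))
        for v in ilvs
    }
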