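"""Synthetic populations, records and diffusions with known ground truth.

The generator emulates the design of a two-troop field study: troops of
46 and 48 individuals over two years of age, 24 proximity scans per
individual per rule, grooming and dominance interaction totals of the
observed order of magnitude, and 25 diffusion experiments per troop in
which information spreads over a designated true network under the same
acquisition-rate model the analysis fits.  Every generator is a pure
function of (scenario, seed).

A latent pairwise affinity (Gaussian kernel over 2-D latent positions)
is shared by all three proximity rules and the grooming network, so the
candidate matrices are mutually correlated as in field data, while
diffusion follows only the designated true matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .networks import build_troop_networks
from .oada import s_unbounded_from_bounded
from .records import (
    UNKNOWN_ID,
    ApplicationEvent,
    DiffusionLog,
    InteractionRecord,
    PhenotypeRecord,
    ScanRecord,
    phenotype_frame,
)

#: Troop compositions (adult female, adult male, juvenile female,
#: juvenile male) used for the two default troop sizes.
_COMPOSITIONS = {46: (18, 8, 6, 14), 48: (19, 10, 2, 17)}

_TROOP_NAMES = ("J", "L", "M", "N", "P", "Q")


def _composition(size: int) -> tuple[int, int, int, int]:
    if size in _COMPOSITIONS:
        return _COMPOSITIONS[size]
    # fall back to the pooled class fractions of the two default troops
    fracs = (37 / 94, 18 / 94, 8 / 94, 31 / 94)
    counts = [int(round(f * size)) for f in fracs]
    counts[0] += size - sum(counts)
    return tuple(counts)  # type: ignore[return-value]


@dataclass
class SimScenario:
    """Ground-truth configuration for one synthetic study.

    Defaults reproduce the field design scale: two troops of 46 and 48,
    25 diffusions per troop, 24 scans per individual per proximity
    rule, ~29 grooming and ~16 dominance events initiated per
    individual, diffusions truncated at a random informed count with
    median ≈ 10 (range-clipped to 2–27), and about 2 unidentifiable
    acquirers per 50 diffusions.
    """

    seed: int = 0
    troop_sizes: tuple[int, ...] = (46, 48)
    n_diffusions_per_troop: int = 25
    scans_per_individual_per_rule: int = 24
    true_rule: str = "ten_m"
    s_bounded_true: float = 0.9
    form_true: str = "multiplicative"
    ilv_betas_true: dict = dc_field(
        default_factory=lambda: {"rank": 0.26, "sex": 0.15, "age": -0.01, "boldness": 0.0}
    )
    count_betas_true: dict = dc_field(
        default_factory=lambda: {
            "n_acquired": {"intercept": 0.23, "proximity_strength": 0.66},
            "n_applied": {
                "intercept": -1.30, "proximity_strength": 0.65,
                "grooming_strength": 0.01, "sex_code": 0.84,
            },
            "n_exploited": {
                "intercept": -2.43, "grooming_strength": 0.02,
                "sex_code": 0.73, "boldness": 0.01, "relative_rank": 1.39,
            },
        }
    )
    association_model: dict = dc_field(
        default_factory=lambda: {
            "length_scale": 1.0,
            "p_ten_m": 0.15,        # per-scan inclusion scale, 10 m radius
            "p_five_m": 0.08,       # tighter radius, 5 m chain
            "age_boldness_rho": -0.55,
            "boldness_log_mean": math.log(15.0),
            "boldness_log_sd": 0.8,
        }
    )
    grooming_per_individual: float = 29.0
    dominance_per_individual: float = 16.0
    truncation_log_median: float = math.log(10.0)
    truncation_log_sd: float = 0.55
    truncation_min: int = 2
    truncation_max: int = 27
    unknown_rate: float = 0.04      # per diffusion
    tie_rate: float = 0.05          # chance an acquisition event is a tie pair

    def troop_name(self, i: int) -> str:
        return _TROOP_NAMES[i] if i < len(_TROOP_NAMES) else f"T{i}"


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

def gen_population(scenario: SimScenario, rng: np.random.Generator) -> list[PhenotypeRecord]:
    """Draw phenotypes for every troop.

    Sex and age-class mix follow the default troop compositions; adult
    ages are uniform on 6–25 y, juvenile ages on 2–6 y.  Boldness
    (seconds investigating a novel food) is lognormal and negatively
    correlated with age through a Gaussian copula, mirroring the
    field-observed age–boldness correlation.  Absolute ranks are a
    uniform random permutation within each troop.
    """
    am = scenario.association_model
    rho = am["age_boldness_rho"]
    records: list[PhenotypeRecord] = []
    for t, size in enumerate(scenario.troop_sizes):
        troop = scenario.troop_name(t)
        af, ad_m, jf, jm = _composition(size)
        sexes = ["female"] * af + ["male"] * ad_m + ["female"] * jf + ["male"] * jm
        is_adult = [True] * (af + ad_m) + [False] * (jf + jm)
        z_age = rng.standard_normal(size)
        z_b = rho * z_age + math.sqrt(1 - rho**2) * rng.standard_normal(size)
        from scipy.stats import norm

        u_age = norm.cdf(z_age)
        ages = [
            (6.0 + 19.0 * u) if adult else (2.0 + 4.0 * u)
            for u, adult in zip(u_age, is_adult)
        ]
        boldness = np.exp(am["boldness_log_mean"] + am["boldness_log_sd"] * z_b)
        ranks = rng.permutation(size) + 1
        for i in range(size):
            records.append(
                PhenotypeRecord(
                    individual_id=f"{troop}{i + 1:02d}",
                    troop_id=troop,
                    sex=sexes[i],
                    age=round(float(ages[i]), 2),
                    absolute_rank=int(ranks[i]),
                    boldness=round(float(boldness[i]), 1),
                )
            )
    return records


def latent_affinity(scenario: SimScenario, size: int, rng: np.random.Generator) -> np.ndarray:
    """Pairwise affinity in (0, 1]: Gaussian kernel over 2-D latent positions."""
    ell = scenario.association_model["length_scale"]
    z = rng.standard_normal((size, 2))
    d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2)
    a = np.exp(-d2 / (2.0 * ell**2))
    np.fill_diagonal(a, 0.0)
    return a


# ---------------------------------------------------------------------------
# Scans and interactions
# ---------------------------------------------------------------------------

def gen_scans_and_interactions(
    scenario: SimScenario,
    population: list[PhenotypeRecord],
    rng: np.random.Generator,
) -> tuple[list[ScanRecord], list[InteractionRecord], dict[str, np.ndarray]]:
    """Draw proximity scans and dyadic interactions for every troop.

    Scan co-membership probabilities increase monotonically with latent
    affinity (so the estimated association indices rank-correlate with
    the latent truth); grooming partners are affinity-weighted with
    lognormal actor heterogeneity; dominance events are weakly
    affinity-weighted and usually directed down the hierarchy.
    Returns the records plus the per-troop latent affinity matrices.
    """
    am = scenario.association_model
    scans: list[ScanRecord] = []
    interactions: list[InteractionRecord] = []
    affinities: dict[str, np.ndarray] = {}
    ts = 0
    by_troop: dict[str, list[PhenotypeRecord]] = {}
    for r in population:
        by_troop.setdefault(r.troop_id, []).append(r)

    for troop, members in by_troop.items():
        n = len(members)
        ids = [m.individual_id for m in members]
        aff = latent_affinity(scenario, n, rng)
        affinities[troop] = aff
        n_scans = scenario.scans_per_individual_per_rule

        rule_probs = {
            "ten_m": am["p_ten_m"] * aff,
            "five_m_chain": am["p_five_m"] * aff**1.5,
        }
        for rule in ("ten_m", "five_m_chain", "nearest_neighbour"):
            p = rule_probs.get(rule, am["p_five_m"] * aff**1.5)
            for i in range(n):
                draws = rng.random((n_scans, n)) < p[i]
                draws[:, i] = False
                for k in range(n_scans):
                    near = np.flatnonzero(draws[k])
                    if rule == "nearest_neighbour":
                        if near.size:
                            wts = aff[i, near] / aff[i, near].sum()
                            assoc: tuple[str, ...] = (ids[int(rng.choice(near, p=wts))],)
                        else:
                            assoc = ()
                    else:
                        assoc = tuple(ids[j] for j in near)
                    ts += 1
                    scans.append(
                        ScanRecord(
                            scan_id=f"{troop}-{rule}-{i:02d}-{k:02d}",
                            troop_id=troop,
                            timestamp=ts,
                            rule=rule,
                            focal_id=ids[i],
                            associates=assoc,
                        )
                    )

        # grooming: actor heterogeneity x affinity
        n_groom = int(round(scenario.grooming_per_individual * n))
        gamma = rng.lognormal(0.0, 0.5, size=n)
        w = gamma[:, None] * (aff + 1e-9)
        np.fill_diagonal(w, 0.0)
        flat = (w / w.sum()).ravel()
        picks = rng.choice(n * n, size=n_groom, p=flat)
        for e, pick in enumerate(picks):
            a, b = divmod(int(pick), n)
            ts += 1
            interactions.append(
                InteractionRecord(
                    event_id=f"{troop}-groom-{e:04d}", troop_id=troop, timestamp=ts,
                    type="groom", actor_id=ids[a], recipient_id=ids[b],
                )
            )

        # dominance: affinity-weighted pair, actor usually the higher rank
        ranks = np.array([m.absolute_rank for m in members])
        n_dom = int(round(scenario.dominance_per_individual * n))
        wd = (aff + 0.05) ** 0.3
        np.fill_diagonal(wd, 0.0)
        iu = np.triu_indices(n, k=1)
        pw = wd[iu] / wd[iu].sum()
        picks = rng.choice(len(iu[0]), size=n_dom, p=pw)
        down = rng.random(n_dom) < 0.9
        for e, (pick, d) in enumerate(zip(picks, down)):
            a, b = int(iu[0][pick]), int(iu[1][pick])
            hi, lo = (a, b) if ranks[a] < ranks[b] else (b, a)  # rank 1 = highest
            actor, recip = (hi, lo) if d else (lo, hi)
            ts += 1
            interactions.append(
                InteractionRecord(
                    event_id=f"{troop}-dom-{e:04d}", troop_id=troop, timestamp=ts,
                    type="dominance", actor_id=ids[actor], recipient_id=ids[recip],
                )
            )
    return scans, interactions, affinities


# ---------------------------------------------------------------------------
# Diffusions
# ---------------------------------------------------------------------------

def _ilv_gamma(phen: pd.DataFrame, betas: dict[str, float]) -> np.ndarray:
    g = np.zeros(len(phen))
    colmap = {"rank": "relative_rank", "sex": "sex_code", "age": "age", "boldness": "boldness"}
    for ilv, b in betas.items():
        g += b * phen[colmap[ilv]].to_numpy(dtype=float)
    return g


def simulate_diffusion(
    scenario: SimScenario,
    phen_troop: pd.DataFrame,
    weights: np.ndarray,
    ids: tuple[str, ...],
    task_id: str,
    rng: np.random.Generator,
    directed: bool = False,
) -> DiffusionLog:
    """Simulate one diffusion experiment on the true network.

    The discoverer is drawn with probability increasing in rank and
    (for a given rank) higher for younger males; subsequent acquirers
    are drawn sequentially with probability proportional to the
    acquisition rate under the true (s, ILV) model, occasionally as
    tied pairs; the diffusion stops once a randomly drawn informed
    count (patch depletion) is reached.  Application and exploitation
    flags are then drawn per informed individual with rank- and
    sex-dependent probabilities.
    """
    n = len(ids)
    phen = phen_troop.loc[list(ids)]
    relrank = phen["relative_rank"].to_numpy(dtype=float)
    male = phen["sex_code"].to_numpy(dtype=float)
    age = phen["age"].to_numpy(dtype=float)

    s = s_unbounded_from_bounded(scenario.s_bounded_true)
    gam = np.clip(_ilv_gamma(phen, scenario.ilv_betas_true), -50, 50)
    expg = np.exp(gam)

    # discoverer: dominant, young, male individuals find patches first
    wd = np.exp(1.5 * relrank + 0.8 * male - 0.08 * age)
    disc = int(rng.choice(n, p=wd / wd.sum()))

    m_target = int(round(math.exp(rng.normal(scenario.truncation_log_median,
                                             scenario.truncation_log_sd))))
    m_target = max(scenario.truncation_min, min(m_target, scenario.truncation_max, n))

    w = weights  # w[i, j]: naive i's attention toward informed j
    naive = np.ones(n, dtype=bool)
    naive[disc] = False
    T = w[:, disc].astype(float).copy()
    events: list[frozenset[str]] = []
    order: list[int] = []
    informed_count = 1
    while informed_count < m_target:
        risk = np.flatnonzero(naive)
        if risk.size == 0:
            break
        if scenario.form_true == "additive":
            R = s * T[risk] + expg[risk]
        elif scenario.form_true == "multiplicative":
            R = expg[risk] * (s * T[risk] + 1.0)
        else:
            R = expg[risk]
        if R.sum() <= 0:
            break
        remaining = m_target - informed_count
        tie = scenario.tie_rate > 0 and remaining >= 2 and risk.size >= 2 \
            and rng.random() < scenario.tie_rate
        k_draw = 2 if tie else 1
        chosen = rng.choice(risk.size, size=k_draw, replace=False, p=R / R.sum())
        group = [int(risk[c]) for c in np.atleast_1d(chosen)]
        events.append(frozenset(ids[g] for g in group))
        for g in group:
            naive[g] = False
            T = T + w[:, g]
            order.append(g)
        informed_count += len(group)

    # occasionally one acquirer could not be identified in the field
    if events and rng.random() < scenario.unknown_rate:
        j = int(rng.integers(len(events)))
        g = sorted(events[j])
        drop = g[int(rng.integers(len(g)))]
        events[j] = frozenset([UNKNOWN_ID if x == drop else x for x in g])
        order = [o for o in order if ids[o] != drop]

    # application (patch entry) and exploitation (feeding)
    apps: list[ApplicationEvent] = []
    for i in order:
        p_apply = _sigmoid(-0.3 + 0.9 * male[i] + 1.0 * relrank[i])
        if rng.random() >= p_apply:
            continue
        fed = rng.random() < _sigmoid(-1.2 + 1.8 * relrank[i] + 0.6 * male[i])
        cofeed = rng.random() < 0.048
        protested = cofeed and rng.random() < (5.0 / 14.0)
        apps.append(ApplicationEvent(individual_id=ids[i], fed=fed,
                                     cofeed=cofeed, protested=protested))

    position = str(rng.choice(["leading_edge", "side", "middle_back"],
                              p=[0.56, 0.22, 0.22]))
    return DiffusionLog(
        task_id=task_id,
        troop_id=str(phen["troop_id"].iloc[0]),
        discoverer_id=ids[disc],
        acquisition_events=events,
        application_events=apps,
        discovery_position=position,
    )


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# ---------------------------------------------------------------------------
# Count responses
# ---------------------------------------------------------------------------

def gen_count_responses(
    phen: pd.DataFrame,
    strengths: pd.DataFrame,
    count_betas: dict,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw per-individual information-use counts from log-link Poisson
    models with the supplied coefficients.

    ``strengths`` supplies ``proximity_strength`` and
    ``grooming_strength`` columns indexed by individual; the remaining
    predictors come from the phenotype frame.  Coefficient keys are
    predictor column names plus ``intercept``.
    """
    df = phen.join(strengths)
    out = pd.DataFrame(index=df.index)
    out["individual_id"] = df["individual_id"]
    out["troop_id"] = df["troop_id"]
    for response, betas in count_betas.items():
        eta = np.full(len(df), float(betas.get("intercept", 0.0)))
        for pred, b in betas.items():
            if pred == "intercept":
                continue
            eta += b * df[pred].to_numpy(dtype=float)
        lam = np.exp(np.clip(eta, -30, 30))
        out[response] = rng.poisson(lam)
    return out


# ---------------------------------------------------------------------------
# End-to-end dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    scenario: SimScenario
    population: list[PhenotypeRecord]
    phenotypes: pd.DataFrame
    scans: list[ScanRecord]
    interactions: list[InteractionRecord]
    networks: dict[str, dict]            # troop -> rule -> AssociationMatrix
    diffusions: list[DiffusionLog]
    counts: pd.DataFrame
    affinities: dict[str, np.ndarray]

    def networks_by_rule(self) -> dict[str, dict]:
        rules = next(iter(self.networks.values())).keys()
        return {r: {t: self.networks[t][r] for t in self.networks} for r in rules}

    def truth(self) -> dict:
        sc = self.scenario
        return {
            "seed": sc.seed,
            "true_rule": sc.true_rule,
            "s_bounded_true": sc.s_bounded_true,
            "form_true": sc.form_true,
            "ilv_betas_true": sc.ilv_betas_true,
            "count_betas_true": sc.count_betas_true,
        }


def simulate_study(scenario: SimScenario) -> SimulatedStudy:
    """Generate a full synthetic study: population, records, networks,
    diffusion experiments and count responses, all from one seed."""
    rng = np.random.default_rng(scenario.seed)
    population = gen_population(scenario, rng)
    phen = phenotype_frame(population)
    scans, interactions, affinities = gen_scans_and_interactions(scenario, population, rng)

    networks: dict[str, dict] = {}
    for t in sorted({r.troop_id for r in population}):
        ids = sorted(p.individual_id for p in population if p.troop_id == t)
        t_scans = [s for s in scans if s.troop_id == t]
        t_inter = [i for i in interactions if i.troop_id == t]
        networks[t] = build_troop_networks(t_scans, t_inter, ids)

    diffusions: list[DiffusionLog] = []
    for t in networks:
        m = networks[t][scenario.true_rule]
        phen_troop = phen[phen["troop_id"] == t]
        for d in range(scenario.n_diffusions_per_troop):
            diffusions.append(
                simulate_diffusion(
                    scenario, phen_troop, m.weights, m.ids,
                    task_id=f"{t}-patch-{d + 1:02d}", rng=rng, directed=m.directed,
                )
            )

    strengths = pd.DataFrame(index=phen.index)
    prox, groom = [], []
    from .networks import strength

    for ind in phen.index:
        t = phen.loc[ind, "troop_id"]
        prox.append(strength(networks[t]["ten_m"]).loc[ind])
        groom.append(strength(networks[t]["groom_directed"]).loc[ind])
    strengths["proximity_strength"] = prox
    strengths["grooming_strength"] = groom

    counts = gen_count_responses(phen, strengths, scenario.count_betas_true, rng)
    return SimulatedStudy(
        scenario=scenario, population=population, phenotypes=phen,
        scans=scans, interactions=interactions, networks=networks,
        diffusions=diffusions, counts=counts, affinities=affinities,
    )
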