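"""End-to-end orchestration: records -> networks -> OADA -> constraints.

`run_pipeline` is a pure function of (inputs, config, seed): it loads
(or simulates) the four record tables, builds the eight candidate
association matrices per troop, screens centralities, runs the network
comparison and ILV subset search, model-averages the supported models,
tallies information-use counts, fits the constraint count models, and
writes every table as CSV (6 significant digits, so reruns diff
cleanly) plus a JSON run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .constraints import ALPHA, DEFAULT_PREDICTORS, RESPONSES, backward_eliminate, collinearity_screen
from .networks import ALL_RULES, centrality_table, spearman_screen, strength
from .oada import ALL_ILVS, compare_networks, ilv_subset_search, model_average
from .records import (
    cofeed_summary,
    counts_frame,
    discovery_position_summary,
    phenotype_frame,
    read_table,
    tally_counts,
    write_table,
)
from .synthetic import SimScenario, simulate_study

log = logging.getLogger("socdiff")

_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration for a full run.

    Either ``simulate`` holds scenario overrides (synthetic study) or
    the four ``*_csv`` paths point at field-style record tables.
    """

    output_dir: str
    seed: int = 0
    simulate: dict | None = None
    phenotypes_csv: str | None = None
    scans_csv: str | None = None
    interactions_csv: str | None = None
    diffusions_csv: str | None = None
    rules: tuple[str, ...] = ALL_RULES
    forms: tuple[str, ...] = ("additive", "multiplicative")
    ilvs: tuple[str, ...] = ALL_ILVS
    delta_aicc_threshold: float = 2.0
    alpha: float = ALPHA
    tie_method: str = "breslow"
    engine: str = "fixed"
    run_ilv_search: bool = True

    def __post_init__(self) -> None:
        bad = [r for r in self.rules if r not in ALL_RULES]
        if bad:
            raise ValueError(f"unknown network rule(s) {bad}; valid: {ALL_RULES}")
        if self.delta_aicc_threshold <= 0:
            raise ValueError("delta_aicc_threshold must be > 0")
        if self.simulate is None:
            for name in ("phenotypes_csv", "scans_csv", "interactions_csv", "diffusions_csv"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"either a simulate block or {name} is required")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("rules", "forms", "ilvs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": dataclasses.asdict(config)}
    timings: dict[str, float] = {}

    def stage(name: str):
        log.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name: str) -> None:
        timings[name] = time.perf_counter() - timings[name]
        log.debug("stage %s finished in %.2fs", name, timings[name])

    # ---- inputs ---------------------------------------------------------
    name = stage("load")
    try:
        if config.simulate is not None:
            scenario = SimScenario(seed=config.seed, **config.simulate)
            study = simulate_study(scenario)
            phen = study.phenotypes
            logs = study.diffusions
            networks = study.networks
            write_table(study.population, out / "phenotypes.csv", "phenotypes")
            write_table(study.scans, out / "scans.csv", "scans")
            write_table(study.interactions, out / "interactions.csv", "interactions")
            write_table(logs, out / "diffusions.csv", "diffusions")
            (out / "truth.json").write_text(json.dumps(study.truth(), indent=2))
        else:
            phenos = read_table(config.phenotypes_csv, "phenotypes")
            scans = read_table(config.scans_csv, "scans")
            interactions = read_table(config.interactions_csv, "interactions")
            logs = read_table(config.diffusions_csv, "diffusions")
            phen = phenotype_frame(phenos)
            from .networks import build_troop_networks

            networks = {}
            for t in sorted(phen["troop_id"].unique()):
                ids = sorted(phen.loc[phen["troop_id"] == t, "individual_id"])
                networks[t] = build_troop_networks(
                    [s for s in scans if s.troop_id == t],
                    [i for i in interactions if i.troop_id == t],
                    ids,
                )
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc
    done(name)

    troops = sorted(networks)
    rules = [r for r in config.rules]

    # ---- networks and centrality ---------------------------------------
    name = stage("networks")
    try:
        cent_frames = []
        edges = []
        for t in troops:
            for r in rules:
                m = networks[t][r]
                ct = centrality_table(m)
                ct.insert(0, "troop_id", t)
                cent_frames.append(ct)
                e = m.to_edge_frame()
                e.insert(0, "rule", r)
                e.insert(0, "troop_id", t)
                edges.append(e)
                _write(m.to_edge_frame(), out / f"network_{r}_{t}.csv")
        centrality = pd.concat(cent_frames, ignore_index=True)
        _write(centrality, out / "centrality.csv")
        screens = []
        for t in troops:
            for r in rules:
                sub = centrality[(centrality["troop_id"] == t) & (centrality["rule"] == r)]
                sc = spearman_screen(sub[["strength", "betweenness"]])
                sc.insert(0, "rule", r)
                sc.insert(0, "troop_id", t)
                screens.append(sc)
        strength_betweenness = pd.concat(screens, ignore_index=True)
        _write(strength_betweenness, out / "strength_betweenness_screen.csv")
        bundle["centrality"] = centrality
        bundle["strength_betweenness_screen"] = strength_betweenness
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc
    done(name)

    # ---- OADA -----------------------------------------------------------
    name = stage("compare_networks")
    try:
        by_rule = {r: {t: networks[t][r] for t in troops} for r in rules}
        table = compare_networks(
            logs, by_rule, phen, forms=config.forms, ilvs=config.ilvs,
            tie_method=config.tie_method,
        )
        comparison = table.frame()
        _write(comparison, out / "network_comparison.csv")
        bundle["network_comparison"] = comparison
        best = table.best()
        bundle["best_network"] = best.spec.network_rule
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc
    done(name)

    if config.run_ilv_search and bundle["best_network"] is not None:
        name = stage("ilv_search")
        try:
            rule = bundle["best_network"]
            search = ilv_subset_search(
                logs, by_rule[rule], rule, phen, forms=config.forms,
                ilv_pool=config.ilvs, tie_method=config.tie_method,
            )
            search_frame = search.frame()
            _write(search_frame, out / "ilv_search.csv")
            averaged = model_average(search, threshold=config.delta_aicc_threshold)
            avg_frame = pd.DataFrame(
                {"ilv": list(averaged), "beta_averaged": list(averaged.values())}
            )
            _write(avg_frame, out / "ilv_model_average.csv")
            bundle["ilv_search"] = search_frame
            bundle["ilv_model_average"] = avg_frame
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        done(name)

    # ---- tallies and constraint models ---------------------------------
    name = stage("constraints")
    try:
        counts = counts_frame(tally_counts(logs))
        bundle["cofeed_summary"] = cofeed_summary(logs)
        bundle["discovery_positions"] = discovery_position_summary(logs)
        (out / "cofeed_summary.json").write_text(json.dumps(bundle["cofeed_summary"], indent=2))
        (out / "discovery_positions.json").write_text(
            json.dumps(bundle["discovery_positions"], indent=2)
        )
        phen_cols = phen[
            ["individual_id", "troop_id", "relative_rank", "boldness", "age", "sex_code"]
        ].reset_index(drop=True)
        data = counts.merge(phen_cols, on="individual_id", how="inner", suffixes=("", "_phen"))
        strengths = {
            ind: (
                strength(networks[t]["ten_m"]).get(ind, 0.0),
                strength(networks[t]["groom_directed"]).get(ind, 0.0),
            )
            for t in troops
            for ind in networks[t]["ten_m"].ids
        }
        data["proximity_strength"] = [strengths[i][0] for i in data["individual_id"]]
        data["grooming_strength"] = [strengths[i][1] for i in data["individual_id"]]
        _write(data, out / "information_counts.csv")
        bundle["counts"] = data

        screen = collinearity_screen(data[list(DEFAULT_PREDICTORS)])
        _write(screen, out / "phenotype_collinearity.csv")
        bundle["phenotype_collinearity"] = screen

        fits = {}
        term_frames = []
        for response in RESPONSES:
            fit = backward_eliminate(
                data, response, DEFAULT_PREDICTORS, alpha=config.alpha, engine=config.engine
            )
            fits[response] = fit
            term_frames.append(fit.term_frame())
        terms = pd.concat(term_frames, ignore_index=True)
        _write(terms, out / "constraint_models.csv")
        bundle["constraint_models"] = terms
        bundle["constraint_fits"] = fits
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc
    done(name)

    # ---- run log --------------------------------------------------------
    bundle["run_log"] = {
        "socdiff_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "run_log.json").write_text(json.dumps(bundle["run_log"], indent=2))
    write_report(bundle, out / "report.txt")
    return bundle


def write_report(bundle: dict, path) -> None:
    """Human-readable one-page-per-table summary of a pipeline bundle."""
    lines: list[str] = []
    lines.append("Social-information diffusion report")
    lines.append("=" * 60)

    comparison = bundle.get("network_comparison")
    lines.append("\n-- Network comparison (ranked by AICc) --")
    if comparison is None or not len(comparison):
        lines.append("no models fitted")
    else:
        cols = ["model", "form", "network", "df", "loglik", "aicc",
                "delta_aicc", "akaike_weight", "s_unbounded", "s_bounded"]
        cols = [c for c in cols if c in comparison.columns]
        lines.append(comparison[cols].to_string(index=False, float_format=lambda v: f"{v:.6g}"))

    search = bundle.get("ilv_search")
    if search is not None and len(search):
        lines.append("\n-- ILV subset search (best network) --")
        cols = [c for c in ["model", "df", "loglik", "aicc", "delta_aicc",
                            "akaike_weight", "s_unbounded", "s_bounded"] if c in search.columns]
        lines.append(search[cols].head(12).to_string(index=False, float_format=lambda v: f"{v:.6g}"))
    avg = bundle.get("ilv_model_average")
    if avg is not None and len(avg):
        lines.append("\n-- Model-averaged ILV effects (delta AICc <= threshold) --")
        lines.append(avg.to_string(index=False, float_format=lambda v: f"{v:.6g}"))

    terms = bundle.get("constraint_models")
    if terms is not None and len(terms):
        lines.append("\n-- Minimal constraint count models --")
        lines.append(terms.to_string(index=False, float_format=lambda v: f"{v:.6g}"))

    cofeed = bundle.get("cofeed_summary")
    if cofeed:
        lines.append("\n-- Patch entries and co-feeding --")
        lines.append(json.dumps(cofeed))
    pos = bundle.get("discovery_positions")
    if pos:
        lines.append("\n-- Discoverer positions --")
        lines.append(json.dumps(pos))
    Path(path).write_text("\n".join(lines) + "\n")
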