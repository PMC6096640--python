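"""Whole-program simulation: burn-in, conventional variants and the
two-part program with rapid recurrent genomic selection.

A program is advanced one year at a time.  The product development (PD)
pipeline is a six-stage conveyor (cross -> doubled haploids -> headrow ->
preliminary -> advanced -> elite); each stage is phenotyped at its own
precision and the configured stages feed the genomic-selection training
set.  Metrics are always recorded on the year's new doubled-haploid
lines, before headrow selection, so conventional and two-part programs
are compared on the same kind of material.

Conventional variants differ only in how parents (and one stage
advancement) are chosen: ``conv`` by phenotype, ``convp`` by GEBV at the
preliminary stage, ``convh`` by GEBV at the headrow stage.

The two-part program adds a population improvement (PI) component: ``k``
recurrent genomic-selection cycles per year on outbred germplasm, under a
per-cycle budget (crosses, candidates, parent bounds) that either splits
a fixed yearly genotyping budget across cycles (constrained) or repeats
the full-size cycle ``k`` times (unconstrained).  Once a year the best PI
germplasm seeds the PD crossing block, and once a year the newest PD
doubled haploids re-enter the PI candidate pool.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .config import SimConfig
from .genome import (
    GeneticMap,
    HaplotypePopulation,
    TraitArchitecture,
    genetic_values,
    genic_variance,
    make_crosses,
    make_dh_lines,
    simulate_founders,
)
from .ocs import (
    InfeasiblePlanError,
    OcsProblem,
    ibs_coancestry,
    optimize,
    truncation_plan,
)
from .prediction import (
    EstimationError,
    PredictionModel,
    TrainingSet,
    accuracy,
    predict,
    train,
)

__all__ = [
    "CycleBudget",
    "ProgramState",
    "plan_budget",
    "run_burnin",
    "run_conventional",
    "run_two_part",
    "run_scenario_grid",
    "summarize_program",
]

log = logging.getLogger(__name__)

# full-size yearly genotyping budget that is split across cycles
BASE_CROSSES = 64
BASE_CANDIDATES = 640


@dataclass(frozen=True)
class CycleBudget:
    """Per-cycle resources of the population improvement component."""

    cycles_per_year: int
    crosses_per_cycle: int
    candidates_per_cycle: int
    min_parents: int
    max_parents: int
    constrained: bool


def plan_budget(k: int, constrained: bool = True) -> CycleBudget:
    """Split the yearly budget of 64 crosses / 640 candidates across ``k``
    recurrent selection cycles (constrained), or repeat the full-size
    cycle ``k`` times (unconstrained)."""
    if not 1 <= k <= 6:
        raise ValueError("cycles per year must be between 1 and 6")
    if constrained:
        crosses = math.ceil(BASE_CROSSES / k)
        candidates = math.ceil(BASE_CANDIDATES / k)
    else:
        crosses = BASE_CROSSES
        candidates = BASE_CANDIDATES
    return CycleBudget(
        cycles_per_year=k,
        crosses_per_cycle=crosses,
        candidates_per_cycle=candidates,
        min_parents=2 * math.ceil(crosses / 4),
        max_parents=2 * crosses,
        constrained=constrained,
    )


@dataclass
class Cohort:
    pop: HaplotypePopulation | None = None
    phenotype: np.ndarray | None = None

    @property
    def n(self) -> int:
        return 0 if self.pop is None else self.pop.n


@dataclass
class ProgramState:
    """Everything needed to advance a breeding program by one year."""

    config: SimConfig
    gmap: GeneticMap
    trait: TraitArchitecture
    rng: np.random.Generator
    year: int = 0
    cohorts: dict = field(default_factory=dict)
    training: TrainingSet | None = None
    model: PredictionModel | None = None
    pi_candidates: HaplotypePopulation | None = None
    ref: dict | None = None  # year-20 standardisation constants
    rows: list = field(default_factory=list)

    def branch(self) -> "ProgramState":
        """Deep copy for scenario branching.  The copied generator carries
        the same stream state, so branches run under common random
        numbers, which sharpens paired scenario comparisons."""
        return copy.deepcopy(self)


def _phenotype(state: ProgramState, pop: HaplotypePopulation, stage: str) -> np.ndarray:
    g = genetic_values(pop, state.trait)
    sd = math.sqrt(state.config.residual_variance(stage))
    return g + state.rng.normal(0.0, sd, size=pop.n)


def _top_k(values: np.ndarray, ids: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest values; ties break by id (stable)."""
    order = np.lexsort((ids, -values))
    return order[: min(k, values.size)]


def _select_cohort(state, cohort: Cohort, k: int, new_stage: str,
                   criterion: np.ndarray | None = None) -> Cohort:
    """Advance the top-k of a cohort into the next stage, re-phenotyped."""
    if cohort.n == 0:
        return Cohort()
    crit = cohort.phenotype if criterion is None else criterion
    idx = _top_k(crit, cohort.pop.ids, k)
    pop = cohort.pop.subset(idx, cohort=new_stage)
    return Cohort(pop, _phenotype(state, pop, new_stage))


def _gebv(state: ProgramState, pop: HaplotypePopulation) -> np.ndarray:
    return predict(state.model, pop)


def _retrain(state: ProgramState) -> None:
    """Yearly model refresh; a degenerate system keeps last year's model."""
    try:
        state.model = train(state.training)
    except EstimationError as e:
        log.warning("year %d: retraining failed (%s); keeping previous model",
                    state.year, e)


def _add_training_records(state: ProgramState) -> None:
    cfg = state.config
    for stage in cfg.training_stages:
        coh = state.cohorts.get(stage)
        if coh is None or coh.n == 0:
            continue
        state.training.add_records(
            coh.pop.ids,
            coh.pop.marker_dosages(),
            coh.phenotype,
            cfg.stage_weights[stage],
            state.year,
            stage,
        )


def _record_metrics(state: ProgramState, metric_pop: HaplotypePopulation) -> None:
    g = genetic_values(metric_pop, state.trait)
    p = metric_pop.allele_frequencies(state.trait.causal_indices)
    gv = genic_variance(p, state.trait.alpha)
    if state.model is not None:
        acc = accuracy(_gebv(state, metric_pop), g)
    else:
        acc = float("nan")
    state.rows.append(
        {
            "year": state.year,
            "mean_raw": float(g.mean()),
            "sd_raw": float(g.std(ddof=1)) if g.size > 1 else 0.0,
            "genic_var": gv,
            "accuracy": acc,
        }
    )


def _even_split(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _random_pairs(ids: np.ndarray, n_crosses: int, rng: np.random.Generator):
    """Random distinct-parent pairs, avoiding duplicate pairs when the
    parent set allows it."""
    pairs = []
    seen = set()
    for _ in range(n_crosses):
        for _attempt in range(100):
            i, j = rng.choice(ids.size, size=2, replace=False)
            pair = (ids[i], ids[j])
            if pair not in seen:
                break
        pairs.append(pair)
        seen.add(pair)
    return pairs


# ---------------------------------------------------------------------------
# yearly advances


def _advance_conventional(state: ProgramState, variant: str, collect_training: bool) -> None:
    cfg = state.config
    state.year += 1
    old = state.cohorts

    # -- parent selection on last year's material ---------------------------
    if variant == "conv":
        pool_cohorts = [old.get(s) for s in ("preliminary", "advanced", "elite")]
        pool_cohorts = [c for c in pool_cohorts if c is not None and c.n > 0]
        pop = HaplotypePopulation.concatenate([c.pop for c in pool_cohorts])
        crit = np.concatenate([c.phenotype for c in pool_cohorts])
    elif variant == "convp":
        coh = old["preliminary"]
        pop, crit = coh.pop, _gebv(state, coh.pop)
    elif variant == "convh":
        coh = old["headrow"]
        pop, crit = coh.pop, _gebv(state, coh.pop)
    else:
        raise ValueError(f"unknown conventional variant {variant!r}")
    sel = _top_k(crit, pop.ids, cfg.conv_n_parents)
    parents = pop.subset(sel)
    pairs = _random_pairs(parents.ids, cfg.pd_crosses, state.rng)
    new_f1 = make_crosses(parents, pairs, 1, state.rng,
                          id_prefix=f"y{state.year}f", cohort="f1")

    # -- pipeline advance (top-down, consuming last year's cohorts) ---------
    new = {}
    new["elite"] = _select_cohort(state, old.get("advanced", Cohort()),
                                  cfg.n_elite, "elite")
    prelim_crit = None
    if variant == "convp" and old.get("preliminary", Cohort()).n > 0:
        prelim_crit = _gebv(state, old["preliminary"].pop)
    new["advanced"] = _select_cohort(state, old.get("preliminary", Cohort()),
                                     cfg.n_advanced, "advanced", prelim_crit)
    head_crit = None
    if variant == "convh" and old.get("headrow", Cohort()).n > 0:
        head_crit = _gebv(state, old["headrow"].pop)
    new["preliminary"] = _select_cohort(state, old.get("headrow", Cohort()),
                                        cfg.n_preliminary, "preliminary", head_crit)
    dh_coh = old.get("dh", Cohort())
    if dh_coh.n:
        new["headrow"] = Cohort(dh_coh.pop, _phenotype(state, dh_coh.pop, "headrow"))
    else:
        new["headrow"] = Cohort()
    f1_coh = old.get("f1", Cohort())
    if f1_coh.n:
        dh_pop = make_dh_lines(
            f1_coh.pop, f1_coh.pop.ids.tolist(), cfg.dh_per_cross, state.rng,
            id_prefix=f"y{state.year}d", cohort="dh",
        )
        new["dh"] = Cohort(dh_pop)
    else:
        new["dh"] = Cohort()
    new["f1"] = Cohort(new_f1)
    state.cohorts = new

    if collect_training:
        _add_training_records(state)
    if variant in ("convp", "convh"):
        _retrain(state)
    if new["dh"].n:
        _record_metrics(state, new["dh"].pop)


def _alternating_pools(gebv: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Split hermaphroditic candidates into two pools alternating by GEBV
    rank, so the pools are balanced in quality."""
    order = np.lexsort((ids, -gebv))
    pool = np.empty(ids.size, dtype="<U1")
    pool[order[0::2]] = "F"
    pool[order[1::2]] = "M"
    return pool


def _pi_cycle(state: ProgramState, candidates: HaplotypePopulation,
              selection: str, budget: CycleBudget, degrees: float,
              cycle_tag: str):
    """One recurrent-selection cycle: predict, plan, cross."""
    cfg = state.config
    gebv = _gebv(state, candidates)
    if selection in ("ts", "ts+"):
        n_parents = budget.min_parents if selection == "ts" else budget.max_parents
        plan = truncation_plan(candidates.ids, gebv, n_parents,
                               budget.crosses_per_cycle, state.rng)
    elif selection == "ocs":
        pool = _alternating_pools(gebv, candidates.ids)
        problem = OcsProblem(
            candidates.ids, gebv, ibs_coancestry(candidates.marker_dosages()),
            pool, budget.crosses_per_cycle, penalty_degrees=degrees,
        )
        seed = int(state.rng.integers(2**31))
        plan = optimize(problem, cfg.ocs_de, rng_seed=seed)
    else:
        raise ValueError(f"unknown two-part selection {selection!r}")
    counts = _even_split(budget.candidates_per_cycle, len(plan.crosses))
    progeny = make_crosses(candidates, plan.crosses, counts, state.rng,
                           id_prefix=cycle_tag, cohort="pi")
    return progeny, plan, gebv


def _advance_two_part(state: ProgramState, selection: str, budget: CycleBudget,
                      degrees: float) -> None:
    cfg = state.config
    state.year += 1
    _retrain(state)

    # newest PD doubled haploids join the candidate pool once a year
    candidates = state.pi_candidates
    dh_coh = state.cohorts.get("dh", Cohort())
    if dh_coh.n:
        candidates = HaplotypePopulation.concatenate(
            [candidates, dh_coh.pop] if candidates is not None else [dh_coh.pop]
        )
    if candidates is None or candidates.n < 2:
        raise InfeasiblePlanError("population improvement has no candidates")

    last_plan = None
    for cyc in range(budget.cycles_per_year):
        tag = f"y{state.year}c{cyc}p"
        try:
            progeny, plan, gebv = _pi_cycle(state, candidates, selection,
                                            budget, degrees, tag)
            last_plan = plan
        except InfeasiblePlanError as e:
            log.warning("year %d cycle %d: infeasible plan (%s); "
                        "recycling previous candidates", state.year, cyc, e)
            progeny = candidates
        candidates = progeny
    state.pi_candidates = candidates

    # -- best PI germplasm seeds the PD crossing block ----------------------
    gebv_final = _gebv(state, candidates)
    n_seed_parents = min(2 * cfg.pd_crosses, 2 * (candidates.n // 2))
    seed_plan = truncation_plan(candidates.ids, gebv_final, n_seed_parents,
                                cfg.pd_crosses, state.rng,
                                max_per_parent=max(4, math.ceil(
                                    2 * cfg.pd_crosses / n_seed_parents)))
    new_f1 = make_crosses(candidates, seed_plan.crosses, 1, state.rng,
                          id_prefix=f"y{state.year}f", cohort="f1")

    # -- PD pipeline advance (identical conveyor, no own crossing) ----------
    old = state.cohorts
    new = {}
    new["elite"] = _select_cohort(state, old.get("advanced", Cohort()),
                                  cfg.n_elite, "elite")
    new["advanced"] = _select_cohort(state, old.get("preliminary", Cohort()),
                                     cfg.n_advanced, "advanced")
    new["preliminary"] = _select_cohort(state, old.get("headrow", Cohort()),
                                        cfg.n_preliminary, "preliminary")
    dh_old = old.get("dh", Cohort())
    new["headrow"] = (Cohort(dh_old.pop, _phenotype(state, dh_old.pop, "headrow"))
                      if dh_old.n else Cohort())
    f1_coh = old.get("f1", Cohort())
    if f1_coh.n:
        dh_pop = make_dh_lines(f1_coh.pop, f1_coh.pop.ids.tolist(),
                               cfg.dh_per_cross, state.rng,
                               id_prefix=f"y{state.year}d", cohort="dh")
        new["dh"] = Cohort(dh_pop)
    else:
        new["dh"] = Cohort()
    new["f1"] = Cohort(new_f1)
    state.cohorts = new

    _add_training_records(state)

    # -- joint metric population: PD doubled haploids plus a direct DH
    #    sample of the current PI germplasm --------------------------------
    pops = []
    if new["dh"].n:
        pops.append(new["dh"].pop)
    if cfg.pi_metric_dh > 0 and candidates.n:
        k = min(cfg.pi_metric_dh, candidates.n)
        pick = state.rng.choice(candidates.n, size=k, replace=False)
        pi_dh = make_dh_lines(candidates.subset(pick),
                              candidates.ids[pick].tolist(), 1, state.rng,
                              id_prefix=f"y{state.year}q", cohort="pi_dh")
        pops.append(pi_dh)
    if pops:
        _record_metrics(state, HaplotypePopulation.concatenate(pops))


# ---------------------------------------------------------------------------
# program drivers


def run_burnin(config: SimConfig, rng_seed: int) -> ProgramState:
    """Twenty years (configurable) of the conventional phenotypic program.

    The genomic-selection training set is initiated with the records of
    the last ``burnin_training_years`` years, and the final year's
    doubled-haploid cohort fixes the standardisation constants (genetic
    mean and SD, genic SD) against which all later gains and diversity
    losses are expressed.
    """
    ss = np.random.SeedSequence(rng_seed)
    founder_seed, stream_seed = ss.spawn(2)
    rng = np.random.default_rng(stream_seed)
    gmap = GeneticMap.regular(
        config.n_chromosomes, config.n_causal_per_chrom,
        config.n_markers_per_chrom, config.chrom_length_m,
    )
    founders = simulate_founders(
        config.n_founders, gmap,
        int(founder_seed.generate_state(1)[0] % 2**31),
        config.maf_floor, config.founder_mating_generations,
    )
    trait = TraitArchitecture.sample(gmap, founders, rng,
                                     config.genic_variance_init,
                                     config.trait_intercept)
    n_markers = gmap.marker_indices.size
    state = ProgramState(config, gmap, trait, rng,
                         training=TrainingSet(n_markers))
    # bootstrap: disjoint founder subsets stand in for the trial stages,
    # founder-derived doubled haploids prime the conveyor, and a first
    # crossing block among random founders fills the F1 slot
    start = 0
    for stage, size in (("preliminary", config.n_preliminary),
                        ("advanced", config.n_advanced),
                        ("elite", config.n_elite)):
        take = min(size, max(founders.n - start, 0))
        if take == 0:
            break
        sub = founders.subset(np.arange(start, start + take), cohort=stage)
        state.cohorts[stage] = Cohort(sub, _phenotype(state, sub, stage))
        start += take
    dh0 = make_dh_lines(founders, founders.ids.tolist(),
                        max(1, config.pd_crosses * config.dh_per_cross
                            // founders.n),
                        rng, id_prefix="y0d", cohort="dh")
    state.cohorts["dh"] = Cohort(dh0)
    pairs0 = _random_pairs(founders.ids, config.pd_crosses, rng)
    f10 = make_crosses(founders, pairs0, 1, rng, id_prefix="y0f", cohort="f1")
    state.cohorts["f1"] = Cohort(f10)
    for year in range(1, config.burnin_years + 1):
        collect = year > config.burnin_years - config.burnin_training_years
        _advance_conventional(state, "conv", collect)
    dh = state.cohorts["dh"]
    if dh.n == 0:  # pragma: no cover - config must allow a full pipeline
        raise InfeasiblePlanError("burn-in produced no doubled-haploid cohort")
    g = genetic_values(dh.pop, trait)
    p = dh.pop.allele_frequencies(trait.causal_indices)
    state.ref = {
        "mean": float(g.mean()),
        "sd": float(g.std(ddof=1)),
        "genic_sd": math.sqrt(genic_variance(p, trait.alpha)),
    }
    return state


def _series(state: ProgramState) -> pd.DataFrame:
    """Metric rows standardised against the burn-in reference year."""
    ref = state.ref
    df = pd.DataFrame(state.rows)
    df = df[df["year"] >= state.config.burnin_years].reset_index(drop=True)
    df["genetic_mean"] = (df["mean_raw"] - ref["mean"]) / ref["sd"]
    df["genetic_sd"] = df["sd_raw"] / ref["sd"]
    df["genic_sd"] = np.sqrt(df["genic_var"]) / ref["genic_sd"]
    return df[["year", "genetic_mean", "genetic_sd", "genic_sd",
               "genic_var", "accuracy"]]


def run_conventional(state: ProgramState, variant: str, years: int) -> pd.DataFrame:
    """Advance a post-burn-in conventional program and return its metric
    series (the burn-in reference year is included as the baseline row)."""
    if state.ref is None:
        raise ValueError("run_burnin must complete before evaluation years")
    if variant not in ("conv", "convp", "convh"):
        raise ValueError(f"unknown conventional variant {variant!r}")
    _record_baseline(state)
    if variant in ("convp", "convh"):
        _retrain(state)
    for _ in range(years):
        _advance_conventional(state, variant, collect_training=True)
    return _series(state)


def run_two_part(state: ProgramState, selection: str, k: int,
                 constrained: bool = True, degrees: float | None = None,
                 years: int = 20) -> pd.DataFrame:
    """Advance a post-burn-in two-part program (``selection`` in
    {"ts", "ts+", "ocs"}) and return its metric series."""
    if state.ref is None:
        raise ValueError("run_burnin must complete before evaluation years")
    budget = plan_budget(k, constrained)
    if degrees is None:
        degrees = state.config.ocs_degrees
    _record_baseline(state)
    # the population improvement component starts from the newest PD
    # doubled haploids (dashed-line initialisation)
    state.pi_candidates = None
    for _ in range(years):
        _advance_two_part(state, selection, budget, degrees)
    return _series(state)


def _record_baseline(state: ProgramState) -> None:
    """Record the reference-year row once, at the scenario branch point."""
    if any(r["year"] == state.config.burnin_years for r in state.rows):
        return
    dh = state.cohorts["dh"]
    sy = state.year
    state.year = state.config.burnin_years
    _record_metrics(state, dh.pop)
    state.year = sy


def summarize_program(series: pd.DataFrame) -> dict:
    """Scalar summaries of one program trajectory: final standardised
    gain, final relative genic SD, realised Ne and conversion efficiency."""
    final = series.iloc[-1]
    out = {
        "gain": float(final["genetic_mean"]),
        "genic_sd": float(final["genic_sd"]),
        "accuracy": float(final["accuracy"]),
    }
    gv = series["genic_var"].to_numpy()
    yr = series["year"].to_numpy()
    keep = gv > 0  # a program can run its diversity down to exactly zero
    if keep.sum() >= 3:
        ne = _metrics.estimate_Ne(gv[keep], yr[keep])
        out["delta_C"] = ne.delta_C
        out["Ne"] = ne.Ne if ne.defined else float("nan")
    else:
        out["delta_C"] = float("nan")
        out["Ne"] = float("nan")
    try:
        eff = _metrics.estimate_efficiency(
            series["genetic_mean"].to_numpy(),
            1.0 - series["genic_sd"].to_numpy(),
        )
        out["efficiency"] = eff.slope
    except ValueError:
        out["efficiency"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# scenario grid


@dataclass(frozen=True)
class Scenario:
    """One cell of the comparison grid."""

    name: str
    program: str  # conv | convp | convh | ts | ts+ | ocs
    k: int = 1
    constrained: bool = True
    degrees: float | None = None


def run_scenario_grid(
    config: SimConfig,
    scenarios: list[Scenario],
    replicates: int = 10,
    years: int = 20,
    rng_seed: int = 1,
) -> dict:
    """Replicates x scenarios sweep under common burn-ins.

    Each replicate runs one burn-in and branches every scenario from the
    same state (common random numbers).  Returns a dict with the tidy
    per-year table (``tidy``), the replicate-aggregated table (``agg``)
    and per-replicate scalar summaries (``summary``).  Scenario failures
    are logged and skipped; the grid continues.
    """
    tidy_rows = []
    summary_rows = []
    for rep in range(replicates):
        rep_seed = rng_seed + rep  # documented splitting rule
        burn = run_burnin(config, rep_seed)
        for sc in scenarios:
            st = burn.branch()
            try:
                if sc.program in ("conv", "convp", "convh"):
                    series = run_conventional(st, sc.program, years)
                else:
                    series = run_two_part(st, sc.program, sc.k, sc.constrained,
                                          sc.degrees, years)
            except Exception:  # noqa: BLE001 - partial failures logged
                log.exception("replicate %d scenario %s failed", rep, sc.name)
                continue
            for _, row in series.iterrows():
                for metric in ("genetic_mean", "genetic_sd", "genic_sd",
                               "genic_var", "accuracy"):
                    tidy_rows.append(
                        {"replicate": rep, "scenario": sc.name,
                         "year": int(row["year"]), "metric": metric,
                         "value": float(row[metric])}
                    )
            summ = summarize_program(series)
            summ.update({"replicate": rep, "scenario": sc.name})
            summary_rows.append(summ)
    tidy = pd.DataFrame(tidy_rows)
    summary = pd.DataFrame(summary_rows)
    per_rep = [g for _, g in tidy.groupby("replicate")]
    agg = (_metrics.summarize_replicates(per_rep)
           if len(per_rep) >= 2 else tidy)
    return {"tidy": tidy, "agg": agg, "summary": summary}
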