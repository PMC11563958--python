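"""Breeding calendars: the burn-in and the five recurrent-selection schemes.

Every calendar is pipelined: a new cohort is crossed each year, so at
steady state one cohort reaches the parent-recycling yield trial
(Stage 1) every year.  The recycling cohort supplies that year's
performance metrics and the parent set used for the following year's
crosses.  Cycle length is the scheme's name: a cohort crossed in year t
recycles in year t + recycle_age, and the parents it produces are first
used in year t + recycle_age + 1.

The burn-in runs the phenotypic baseline calendar at reduced selection
pressure (80 parents drawn from the last two yield-trial stages) for 40
years to build a realistic base population; the five evaluation schemes
then branch from an identical copy of that state.
"""

from __future__ import annotations

import importlib.resources
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import trait as tr
from .genome import (GeneticMap, GenomeSpec, Population, as_rng, make_crosses,
                     sample_half_diallel_crosses, advance_ssd,
                     simulate_founders)
from .gs import (CohortData, TrainingPopulation, fit_rrblup, marker_matrix,
                 predict_gebv, sample_training_set, update_between_cohort_tp)

__all__ = [
    "SchemeConfig",
    "BurninConfig",
    "SchemeState",
    "SCHEMES",
    "load_schedules",
    "run_burnin",
    "run_scheme",
    "select_top",
    "select_within_family",
    "recycle_parents",
]

SCHEMES = ("baseline", "5-year", "3-year", "2-year-wp", "2-year-bp")


def load_schedules(path=None) -> dict:
    """Load the declarative stage tables (the shipped ones by default)."""
    if path is None:
        text = (importlib.resources.files("breedsim") / "schedules.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


_SCHEDULES = load_schedules()


@dataclass(frozen=True)
class SchemeConfig:
    """Stage sizes and trial dimensions of an evaluation scheme."""

    scheme: str = "2-year-wp"
    n_parents: int = 40
    n_crosses: int = 30
    progeny_per_cross: int = 240
    mas_survivors_per_family: int = 40   # -> 1,200 Stage-1 lines
    est_size: int = 200
    stage2_size: int = 30
    n_locations: int = 4
    n_reps: int = 2
    h2_row: float = 0.001
    h2_plot: float = 0.10
    tp_window: int = 3                   # between-cohort sliding window

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; one of {SCHEMES}")
        if self.mas_survivors_per_family > self.progeny_per_cross:
            raise ValueError("cannot keep more lines per family than produced")
        n_stage1 = self.n_crosses * self.mas_survivors_per_family
        for name, k in (("est_size", self.est_size),
                        ("n_parents", self.n_parents),
                        ("stage2_size", self.stage2_size)):
            if k > n_stage1:
                raise ValueError(f"{name}={k} exceeds the Stage-1 size {n_stage1}")
        if self.est_size < self.n_crosses:
            raise ValueError("training set cannot cover every family")

    @property
    def n_stage1(self) -> int:
        return self.n_crosses * self.mas_survivors_per_family

    def scaled(self, factor: float) -> "SchemeConfig":
        """Shrink the nursery expansion, keeping every selection endpoint.

        Only ``progeny_per_cross`` scales; the within-family nursery
        selection it feeds operates at near-zero heritability, so the
        loss of within-family candidates is the least consequential
        reduction available.  Stage-1 size, crosses, parents, training
        set and Stage 2 stay at full size, preserving all selection
        intensities.
        """
        return replace(
            self,
            progeny_per_cross=max(self.mas_survivors_per_family,
                                  round(self.progeny_per_cross * factor)),
        )


@dataclass(frozen=True)
class BurninConfig:
    """Stage sizes of the 40-year phenotypic burn-in."""

    n_founders: int = 80
    n_crosses: int = 100
    progeny_per_cross: int = 120         # -> 12,000 F6 lines
    lst_survivors_per_family: int = 25   # -> 2,500 after LST
    oyt_survivors: int = 600             # Stage-1 trial size
    stage2_size: int = 50
    n_parents: int = 80
    years: int = 40
    training_size: int = 200             # per-year block kept for 2-year-bp
    n_locations: int = 4
    n_reps: int = 2
    h2_row: float = 0.001
    h2_plot: float = 0.10

    def __post_init__(self):
        if self.lst_survivors_per_family > self.progeny_per_cross:
            raise ValueError("cannot keep more lines per family than produced")
        if self.oyt_survivors > self.n_crosses * self.lst_survivors_per_family:
            raise ValueError("oyt_survivors exceeds the LST survivor count")
        if self.n_parents > self.oyt_survivors + self.stage2_size:
            raise ValueError("parent pool smaller than n_parents")

    def scaled(self, factor: float) -> "BurninConfig":
        """Shrink the nursery expansion only (see SchemeConfig.scaled)."""
        return replace(
            self,
            progeny_per_cross=max(self.lst_survivors_per_family,
                                  round(self.progeny_per_cross * factor)),
        )


# ---------------------------------------------------------------------------
# selection operations


def _top_indices(ids: np.ndarray, scores: np.ndarray, n: int) -> np.ndarray:
    """Indices of the n best scores; ties broken by ascending id."""
    order = np.lexsort((ids, -scores))
    return np.sort(order[:n])


def select_top(pop: Population, scores, n: int, **overrides) -> Population:
    """Truncation selection, descending score, stable id tie-break."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape[0] != pop.n:
        raise ValueError("scores must align with the population")
    if n > pop.n:
        raise ValueError(f"cannot select {n} from {pop.n} lines")
    return pop.subset(_top_indices(pop.ids, scores, n), **overrides)


def select_within_family(pop: Population, scores, n_per_family: int,
                         **overrides) -> Population:
    """Independent truncation inside each family."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape[0] != pop.n:
        raise ValueError("scores must align with the population")
    keep = []
    for fam in np.unique(pop.family):
        rows = np.flatnonzero(pop.family == fam)
        if n_per_family > rows.size:
            raise ValueError(
                f"family {fam} has {rows.size} lines, need {n_per_family}"
            )
        best = _top_indices(pop.ids[rows], scores[rows], n_per_family)
        keep.append(rows[best])
    return pop.subset(np.sort(np.concatenate(keep)), **overrides)


def recycle_parents(candidates: Population, scores, n_parents: int) -> Population:
    """Top-n unique lines by GEBV (or phenotype) become next-cycle parents."""
    if candidates.n < n_parents:
        raise ValueError(
            f"only {candidates.n} candidates for {n_parents} parents"
        )
    return select_top(candidates, scores, n_parents, stage="PARENTS")


# ---------------------------------------------------------------------------
# pipelined state


@dataclass
class Cohort:
    born: int                 # absolute crossing year
    calendar: str             # key into the schedule table
    cfg: object               # SchemeConfig or BurninConfig
    pop: Population
    data: dict = field(default_factory=dict)

    def copy(self) -> "Cohort":
        return Cohort(self.born, self.calendar, self.cfg, self.pop.copy(),
                      dict(self.data))


@dataclass
class RecyclingEvent:
    """One cohort reaching its Stage-1 recycling point."""

    year: int
    candidates: Population
    scores: np.ndarray
    criterion: str            # 'gebv' or 'phenotype'


@dataclass
class SchemeState:
    """Everything needed to continue a simulation from a given year."""

    gmap: GeneticMap
    arch: tr.TraitArchitecture
    year: int
    env_w: np.ndarray                     # w indexed by absolute year
    cohorts: list = field(default_factory=list)
    parents: Population | None = None
    base_pop: Population | None = None
    base_scores: np.ndarray | None = None
    tp_blocks: deque = field(default_factory=lambda: deque(maxlen=3))
    tp: TrainingPopulation | None = None
    burnin_records: list = field(default_factory=list)
    schedules: dict = field(default_factory=lambda: _SCHEDULES)

    def copy(self) -> "SchemeState":
        return SchemeState(
            gmap=self.gmap,
            arch=self.arch,
            year=self.year,
            env_w=self.env_w,
            cohorts=[c.copy() for c in self.cohorts],
            parents=self.parents.copy() if self.parents is not None else None,
            base_pop=self.base_pop.copy() if self.base_pop is not None else None,
            base_scores=(None if self.base_scores is None
                         else self.base_scores.copy()),
            tp_blocks=deque((CohortData(b.tag, b.Z, b.y) for b in self.tp_blocks),
                            maxlen=self.tp_blocks.maxlen),
            tp=self.tp.copy() if self.tp is not None else None,
            burnin_records=list(self.burnin_records),
            schedules=self.schedules,
        )


def _env_draw(state: SchemeState, year: int) -> tr.EnvironmentDraw:
    return tr.EnvironmentDraw(year=year, w=float(state.env_w[year]))


def _phenotype(state, pop, cfg, h2, n_loc, n_reps, rng):
    env = _env_draw(state, state.year)
    return tr.phenotype(pop, state.arch, h2, n_loc, n_reps, env, rng)


def _run_steps(state: SchemeState, cohort: Cohort, steps, rng):
    """Execute one cohort's steps for the current year.

    Returns a RecyclingEvent if this cohort hit its Stage-1 this year.
    """
    cfg = cohort.cfg
    event = None
    for step in steps:
        (action, arg), = step.items()
        if action == "ssd":
            cohort.pop = advance_ssd(cohort.pop, state.gmap, int(arg), rng)
        elif action in ("mas", "lst"):
            per_fam = (cfg.mas_survivors_per_family if action == "mas"
                       else cfg.lst_survivors_per_family)
            phen = _phenotype(state, cohort.pop, cfg, cfg.h2_row, 1, 1, rng)
            cohort.pop = select_within_family(cohort.pop, phen, per_fam,
                                              stage="LST")
        elif action == "oyt":
            phen = _phenotype(state, cohort.pop, cfg, cfg.h2_plot, 1, 1, rng)
            cohort.pop = select_top(cohort.pop, phen, cfg.oyt_survivors,
                                    stage="OYT")
        elif action == "seed_amp":
            cohort.pop.stage = "SA"
        elif action == "stage1":
            event = _stage1(state, cohort, rng)
        elif action == "est":
            _est_update_tp(state, cohort, rng)
        elif action == "stage2":
            _stage2(state, cohort, rng)
        else:
            raise ValueError(f"unknown schedule action {action!r}")
    return event


def _stage1(state: SchemeState, cohort: Cohort, rng) -> RecyclingEvent:
    cfg = cohort.cfg
    schedule = state.schedules[cohort.calendar]
    criterion = schedule["criterion"]
    pop = cohort.pop
    pop.stage = "STAGE1"

    if criterion == "phenotype":
        # the full candidate set only sees the single-season Stage-1 plot
        # trial; multi-location testing is reserved for the later stages
        # (and, in GS schemes, for the EST sample)
        scores = _phenotype(state, pop, cfg, cfg.h2_plot, 1, 1, rng)
        cohort.data["stage1_phen"] = scores
        kind = "phenotype"
    elif criterion == "within_cohort":
        est_rows = sample_training_set(pop, cfg.est_size, rng)
        est = pop.subset(est_rows, stage="EST")
        y = _phenotype(state, est, cfg, cfg.h2_plot, cfg.n_locations,
                       cfg.n_reps, rng)
        model = fit_rrblup(marker_matrix(est, state.gmap.marker_idx), y)
        scores = predict_gebv(model, marker_matrix(pop, state.gmap.marker_idx))
        kind = "gebv"
    elif criterion == "between_cohort":
        if state.tp is None or not state.tp.cohorts:
            raise RuntimeError("between-cohort prediction without training data")
        model = fit_rrblup(state.tp.Z, state.tp.y)
        scores = predict_gebv(model, marker_matrix(pop, state.gmap.marker_idx))
        kind = "gebv"
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    cohort.data["scores"] = scores
    stage2_n = min(cfg.stage2_size, pop.n)
    cohort.data["stage2_rows"] = _top_indices(pop.ids, scores, stage2_n)
    return RecyclingEvent(year=state.year, candidates=pop, scores=scores,
                          criterion=kind)


def _est_update_tp(state: SchemeState, cohort: Cohort, rng):
    """Phenotype a family-covering training sample; roll it into the TP."""
    cfg = cohort.cfg
    rows = sample_training_set(cohort.pop, cfg.est_size, rng)
    est = cohort.pop.subset(rows, stage="EST")
    y = _phenotype(state, est, cfg, cfg.h2_plot, cfg.n_locations, cfg.n_reps,
                   rng)
    block = CohortData(tag=cohort.born, Z=marker_matrix(est, state.gmap.marker_idx),
                       y=y)
    state.tp = update_between_cohort_tp(state.tp, block)


def _stage2(state: SchemeState, cohort: Cohort, rng):
    cfg = cohort.cfg
    rows = cohort.data.get("stage2_rows")
    if rows is None:  # burn-in calendar: pick on the Stage-1 phenotype now
        rows = _top_indices(cohort.pop.ids, cohort.data["scores"],
                            min(cfg.stage2_size, cohort.pop.n))
    stage2 = cohort.pop.subset(rows, stage="STAGE2")
    phen = _phenotype(state, stage2, cfg, cfg.h2_plot, cfg.n_locations,
                      cfg.n_reps, rng)
    cohort.pop = stage2
    cohort.data["stage2_phen"] = phen


def _max_age(schedule) -> int:
    return max(int(a) for a in schedule["stages"])


def _advance_year(state: SchemeState, new_cfg, new_calendar: str, rng):
    """One simulated year: cross a new cohort, then harvest oldest-first.

    A cohort is kept through the year of its last scheduled stage so that
    same-year bookkeeping (e.g. the burn-in parent pool) can still see it.
    """
    state.year += 1
    events = []

    if state.parents is not None and new_cfg is not None:
        plan = sample_half_diallel_crosses(state.parents, new_cfg.n_crosses, rng)
        f1 = make_crosses(state.parents, state.gmap, plan,
                          new_cfg.progeny_per_cross, rng)
        f1.year = state.year
        state.cohorts.append(Cohort(born=state.year, calendar=new_calendar,
                                    cfg=new_cfg, pop=f1))

    survivors = []
    for cohort in sorted(state.cohorts, key=lambda c: c.born):
        age = state.year - cohort.born
        schedule = state.schedules[cohort.calendar]
        steps = schedule["stages"].get(age, [])
        ev = _run_steps(state, cohort, steps, rng)
        if ev is not None:
            events.append((cohort, ev))
        if age <= _max_age(schedule):
            survivors.append(cohort)
    state.cohorts = survivors
    return events


# ---------------------------------------------------------------------------
# burn-in


def run_burnin(genome_spec: GenomeSpec, trait_spec: tr.TraitSpec,
               cfg: BurninConfig, seed) -> SchemeState:
    """Simulate founders and the pipelined phenotypic burn-in.

    Returns the state at the end of the burn-in: the base population is
    the final Stage-1 cohort, and the last three years' 200-line
    training blocks are retained for between-cohort prediction.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_founder, s_trait, s_env, s_ops = ss.spawn(4)
    founders, gmap = simulate_founders(
        genome_spec, int(s_founder.generate_state(1)[0] % (2**31 - 1)))
    arch = tr.assign_trait(founders, gmap, trait_spec, s_trait)
    # one environmental covariate per calendar year, burn-in and beyond
    env_w = as_rng(s_env).standard_normal(cfg.years + 101)
    rng = as_rng(s_ops)

    state = SchemeState(gmap=gmap, arch=arch, year=0, env_w=env_w,
                        parents=founders)
    state.tp_blocks = deque(maxlen=3)

    for _ in range(cfg.years):
        events = _advance_year(state, cfg, "burnin", rng)
        _burnin_bookkeeping(state, cfg, events, rng)

    if state.base_pop is None:
        raise RuntimeError("burn-in too short: no cohort reached Stage 1")
    state.tp = TrainingPopulation(cohorts=list(state.tp_blocks),
                                  window=3)
    return state


def _burnin_bookkeeping(state, cfg, events, rng):
    """Parent recycling from the last two yield-trial stages, plus records."""
    pools, pool_scores = [], []
    for cohort, ev in events:
        pools.append(ev.candidates)
        pool_scores.append(ev.scores)
        state.base_pop = ev.candidates
        state.base_scores = ev.scores
        # retain a family-covering training block for between-cohort GS
        rows = sample_training_set(ev.candidates, cfg.training_size, rng)
        block = CohortData(
            tag=cohort.born,
            Z=marker_matrix(ev.candidates.subset(rows), state.gmap.marker_idx),
            y=ev.scores[rows],
        )
        state.tp_blocks.append(block)
        gv = tr.genetic_values(ev.candidates, state.arch)
        state.burnin_records.append({
            "year": state.year, "mean_gv": float(gv.mean()),
            "var_gv": float(gv.var()), "n": ev.candidates.n,
        })
    for cohort in state.cohorts:
        if "stage2_phen" in cohort.data and cohort.pop.stage == "STAGE2" \
                and state.year - cohort.born == _max_age(state.schedules["burnin"]):
            pools.append(cohort.pop)
            pool_scores.append(cohort.data["stage2_phen"])
    if pools:
        pool = Population.concatenate(pools, stage="YIELD_TRIALS")
        scores = np.concatenate(pool_scores)
        state.parents = recycle_parents(pool, scores, cfg.n_parents)


# ---------------------------------------------------------------------------
# evaluation schemes


def run_scheme(state: SchemeState, cfg: SchemeConfig, years: int = 30,
               seed=0):
    """Run one evaluation scheme from a burn-in state.

    The input state is not modified; every scheme branched from the same
    state therefore starts from a bit-identical base population.  Returns
    a list of per-year metric dicts (year 0 is the base population).
    """
    from .metrics import summarize_recycling_population  # cycle-free import

    state = state.copy()
    rng = as_rng(seed)
    schedule = state.schedules[cfg.scheme]
    recycle_age = schedule["recycle_age"]
    start_year = state.year

    # hand-off: scheme parents are selected from the base population on
    # its Stage-1 phenotypes; burn-in cohorts that cannot reach Stage 1
    # before the first scheme cohort does are discarded unfinished
    state.parents = recycle_parents(state.base_pop, state.base_scores,
                                    cfg.n_parents)
    state.cohorts = [
        c for c in state.cohorts
        if (c.born + state.schedules["burnin"]["recycle_age"]) - start_year
        in range(1, recycle_age + 1)
    ]

    records = [summarize_recycling_population(
        state.base_pop, state.base_scores, state.arch, year=0,
        criterion="phenotype")]

    for rel_year in range(1, years + 1):
        events = _advance_year(state, cfg, cfg.scheme, rng)
        scheme_events = [ev for c, ev in events if c.calendar == cfg.scheme]
        legacy_events = [ev for c, ev in events if c.calendar == "burnin"]
        ev = scheme_events[0] if scheme_events else (
            legacy_events[0] if legacy_events else None)
        if ev is None:
            continue
        state.parents = recycle_parents(ev.candidates, ev.scores,
                                        cfg.n_parents)
        records.append(summarize_recycling_population(
            ev.candidates, ev.scores, state.arch, year=rel_year,
            criterion=ev.criterion))

    base_mean = records[0]["mean_gv"]
    for row in records:
        row["mean_gv_centered"] = row["mean_gv"] - base_mean
        row["scheme"] = cfg.scheme
        row["gei_variance"] = state.arch.spec.gei_variance
    return records
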