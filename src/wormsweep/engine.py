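"""The full experiment loop: populations, replicates and parameter grids.

A run evolves ``n_populations`` independent populations for ``generations``
generations each, ranks the final populations by mean relative fitness,
and computes the s and f statistics on the top ``n_top`` (default 3) — the
in-silico counterpart of sequencing the three evolved lines with the
strongest phenotypic recovery.  Replicate runs (default 200) give the
expected distributions, 95% CIs and empirical p-values for observed s/f.

Randomness: one root ``numpy.random.SeedSequence`` per run; replicate and
population substreams are spawned from it, so results are bit-reproducible
given (seed, config) and identical under serial or parallel execution.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fitness import QTLModel, null_model, population_fitness
from .genome import GenomeLayout, PopulationState, build_founder_population, default_layout
from .mating import OutcrossingSchedule, assign_sexes, produce_offspring
from .stats import StatSummary, stat_f, stat_s, window_freqs

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of one simulated evolution experiment.

    Defaults follow the experimental design: 20 populations of N = 1000
    (alternatives 200/500/2000), 50 generations, founded with 10
    hermaphrodites + 12 males per background, top 3 populations scored.
    """

    layout: GenomeLayout = field(default_factory=default_layout)
    qtl_model: QTLModel = field(default_factory=null_model)
    schedule: OutcrossingSchedule = field(default_factory=OutcrossingSchedule)
    n_populations: int = 20
    generations: int = 50
    N: int = 1000
    founders_per_bg: tuple[int, int] = (10, 12)
    backgrounds: tuple[int, ...] = (0, 1, 2, 3, 4)
    n_top: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_top > self.n_populations:
            raise ValueError("n_top cannot exceed n_populations")
        if self.N < self.n_top:
            raise ValueError("N must be at least n_top")
        if self.generations < 1 or self.n_populations < 1 or self.N < 1:
            raise ValueError("generations, n_populations and N must be positive")


@dataclass
class ReplicateResult:
    """s/f outcome of one replicate run."""

    s: float
    f: float
    mean_fitness_top: list[float]
    window_freqs: np.ndarray | None = None  # (n_top, 5, W) when requested


def advance_generation(
    pop: PopulationState,
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """One generation cycle: fitness → sex assignment → N offspring.

    Founder sexes (generation 0) are part of the founding composition and
    are kept; from generation 1 on each worm's phenotypic sex is redrawn as
    male with probability equal to the schedule's outcrossing rate for the
    current generation.
    """
    fitness = population_fitness(pop, config.qtl_model)
    if pop.generation > 0:
        assign_sexes(pop, config.schedule.rate(pop.generation), rng)
    return produce_offspring(pop, fitness, config.N, rng)


def evolve_population(
    config: ExperimentConfig, seed: np.random.SeedSequence
) -> PopulationState:
    """Found one population and evolve it for ``config.generations``."""
    rng = np.random.default_rng(seed)
    pop = build_founder_population(
        config.layout, config.founders_per_bg, config.backgrounds
    )
    for _ in range(config.generations):
        pop = advance_generation(pop, config, rng)
    return pop


def run_experiment(
    config: ExperimentConfig,
    seed: np.random.SeedSequence | int | None = None,
    keep_window_freqs: bool = False,
) -> ReplicateResult:
    """One replicate: evolve all populations, rank, score the top ``n_top``.

    Ranking is by mean relative fitness of the final generation; exact ties
    (certain under the null model) are broken by a seeded shuffle so the
    choice of "top" populations is reproducible but unbiased.
    """
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(config.seed if seed is None else seed)
    pop_seeds = seed.spawn(config.n_populations + 1)
    finals = [evolve_population(config, s) for s in pop_seeds[: config.n_populations]]
    mean_fit = np.array(
        [population_fitness(p, config.qtl_model).mean() for p in finals]
    )
    tie_rng = np.random.default_rng(pop_seeds[-1])
    order = tie_rng.permutation(config.n_populations)
    top = order[np.argsort(-mean_fit[order], kind="stable")][: config.n_top]
    tables = [window_freqs(finals[i]) for i in top]
    return ReplicateResult(
        s=stat_s(tables),
        f=stat_f(tables),
        mean_fitness_top=[float(mean_fit[i]) for i in top],
        window_freqs=np.stack(tables) if keep_window_freqs else None,
    )


def run_replicates(
    config: ExperimentConfig,
    n_replicates: int = 200,
    seed: int | np.random.SeedSequence | None = None,
) -> list[ReplicateResult]:
    """Independent seeded replicates of :func:`run_experiment`.

    Each replicate runs on its own spawned substream, so the result list is
    order-stable given the root seed regardless of execution order.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(config.seed if seed is None else seed)
    out = []
    t0 = time.perf_counter()
    for i, sub in enumerate(seed.spawn(n_replicates)):
        out.append(run_experiment(config, sub))
        if log.isEnabledFor(logging.INFO):
            log.info(
                "replicate %d/%d done (%.2fs elapsed)",
                i + 1, n_replicates, time.perf_counter() - t0,
            )
    return out


def summarize_replicates(
    results: list[ReplicateResult],
    observed_s: float | None = None,
    observed_f: float | None = None,
) -> dict[str, StatSummary]:
    """CI and (optionally) empirical-p summaries for s and f."""
    s_vals = [r.s for r in results]
    f_vals = [r.f for r in results]
    return {
        "s": StatSummary.from_values("s", s_vals, observed_s),
        "f": StatSummary.from_values("f", f_vals, observed_f),
    }


def results_frame(results: list[ReplicateResult], **meta) -> pd.DataFrame:
    """One row per replicate (plus constant metadata columns)."""
    df = pd.DataFrame(
        {
            "replicate": np.arange(len(results)),
            "s": [r.s for r in results],
            "f": [r.f for r in results],
        }
    )
    for k, v in meta.items():
        df[k] = v
    return df


def summary_row(
    results: list[ReplicateResult],
    model_id: str,
    max_fitness: float,
    schedule: OutcrossingSchedule,
    observed_s: float | None = None,
    observed_f: float | None = None,
) -> dict:
    """One scenario row in the standard results-table layout."""
    summ = summarize_replicates(results, observed_s, observed_f)
    return {
        "model_id": model_id,
        "max_fitness": max_fitness,
        "schedule": schedule.describe(),
        "n_replicates": len(results),
        "s_mean": summ["s"].mean,
        "s_ci_low": summ["s"].ci_low,
        "s_ci_high": summ["s"].ci_high,
        "p_s": summ["s"].p_observed,
        "f_mean": summ["f"].mean,
        "f_ci_low": summ["f"].ci_low,
        "f_ci_high": summ["f"].ci_high,
        "p_f": summ["f"].p_observed,
    }


#: Outcrossing scenarios of the original parameter search.
DEFAULT_SCHEDULES: tuple[OutcrossingSchedule, ...] = (
    OutcrossingSchedule("constant", 0.01),
    OutcrossingSchedule("constant", 0.05),
    OutcrossingSchedule("constant", 0.10),
    OutcrossingSchedule("step", 0.05, 0.01, 25),
    OutcrossingSchedule("step", 0.10, 0.01, 25),
)

#: Maximum-relative-fitness values of the original parameter search.
DEFAULT_MAX_FITNESS: tuple[float, ...] = (1.1, 1.5, 2.0, 4.0, 10.0)


def grid_cells(
    models, schedules=DEFAULT_SCHEDULES, max_fitness_values=DEFAULT_MAX_FITNESS
) -> list[tuple[str, float, OutcrossingSchedule]]:
    """Enumerate scenario cells: model × Wmax × schedule; the null model
    collapses the Wmax axis (fitness is 1 regardless) to one cell per
    schedule, matching the results-table layout (a single null row)."""
    cells = []
    for model_id in models:
        wmaxes = (1.0,) if model_id == "null" else tuple(max_fitness_values)
        for wmax in wmaxes:
            for sched in schedules:
                cells.append((model_id, wmax, sched))
    return cells


def run_grid(
    base: ExperimentConfig,
    models: dict[str, "QTLModel | float | None"],
    schedules=DEFAULT_SCHEDULES,
    max_fitness_values=DEFAULT_MAX_FITNESS,
    n_replicates: int = 200,
    observed_s: float | None = None,
    observed_f: float | None = None,
    model_loader=None,
) -> pd.DataFrame:
    """Sweep scenarios: each QTL model × Wmax × schedule, plus the null model
    once per schedule (at Wmax 1).  Returns one summary row per cell.

    ``models`` maps model_id → loader argument; ``model_loader(model_id,
    wmax)`` must return a :class:`QTLModel` (defaults to the packaged example
    maps).  Include ``"null"`` to add the neutral rows.
    """
    from .fitness import load_example_model

    loader = model_loader or load_example_model
    rows = []
    root = np.random.SeedSequence(base.seed)
    cells = grid_cells(models, schedules, max_fitness_values)
    for (model_id, wmax, sched), sub in zip(cells, root.spawn(len(cells))):
        cfg = replace(base, qtl_model=loader(model_id, wmax), schedule=sched)
        res = run_replicates(cfg, n_replicates, seed=sub)
        rows.append(summary_row(res, model_id, wmax, sched, observed_s, observed_f))
        log.info("grid cell done: %s Wmax=%g %s", model_id, wmax, sched.describe())
    return pd.DataFrame(rows)
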