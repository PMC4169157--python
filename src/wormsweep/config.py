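"""Structured run configuration: YAML parsing, validation, defaults.

Every parameter defaults to the experiment's design value where one
exists: N = 1000, 20 populations, 50 generations, 200 replicates, fixation
threshold 0.9, SNP quality >= 30, max depth 100, min depth 10, 200-kb
windows.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .engine import ExperimentConfig
from .fitness import QTLModel, build_qtl_model, load_example_model, null_model
from .genome import GenomeLayout, default_layout
from .mating import OutcrossingSchedule


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class RunConfig:
    """Validated top-level configuration for every wormsweep command."""

    # experiment block
    n_populations: int = 20
    generations: int = 50
    N: int = 1000
    founders_per_bg: tuple[int, int] = (10, 12)
    n_top: int = 3
    n_replicates: int = 200
    seed: int = 0
    # schedule block
    schedule_kind: str = "constant"
    rate0: float = 0.01
    rate1: float | None = None
    switch_generation: int = 25
    # qtl block
    qtl_model: str = "null"  # example model id or path to a TSV map
    max_fitness: float = 1.0
    # statistics block
    fixation_threshold: float = 0.9
    observed_s: float | None = None
    observed_f: float | None = None
    # genomics block
    min_quality: float = 30.0
    max_depth: int = 100
    min_depth: int = 10
    novel_freq_threshold: float = 0.9
    window_size: int = 200_000
    # synth block
    diagnostic_density: float = 750.0
    depth: float = 30.0
    error_rate: float = 0.002
    # custom genome layout: list of [name, n_windows]; None = default worm grid
    layout: tuple[tuple[str, int], ...] | None = None
    log_level: str = "INFO"


_BLOCKS = {
    "experiment": {
        "n_populations", "generations", "N", "founders_per_bg", "n_top",
        "n_replicates", "seed",
    },
    "schedule": {"schedule_kind", "rate0", "rate1", "switch_generation"},
    "qtl": {"qtl_model", "max_fitness"},
    "statistics": {"fixation_threshold", "observed_s", "observed_f"},
    "genomics": {
        "min_quality", "max_depth", "min_depth", "novel_freq_threshold",
        "window_size",
    },
    "synth": {"diagnostic_density", "depth", "error_rate"},
}
_TOP_LEVEL = {"layout", "log_level"} | set(_BLOCKS)


def _flatten(raw: dict) -> dict:
    flat = {}
    for key, value in raw.items():
        if key in _BLOCKS:
            if not isinstance(value, dict):
                raise ConfigError(f"block {key!r} must be a mapping")
            for k, v in value.items():
                if k not in _BLOCKS[key]:
                    raise ConfigError(f"unknown key {k!r} in block {key!r}")
                flat[k] = v
        elif key in _TOP_LEVEL:
            flat[key] = value
        else:
            raise ConfigError(f"unknown top-level key {key!r}")
    return flat


def parse_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; flag overrides win over the file.

    An empty (or absent) config yields the full design defaults.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
    flat = _flatten(raw)
    flat.update(overrides or {})
    known = {f.name for f in fields(RunConfig)}
    for k in flat:
        if k not in known:
            raise ConfigError(f"unknown key {k!r}")
    if "founders_per_bg" in flat:
        flat["founders_per_bg"] = tuple(flat["founders_per_bg"])
    if flat.get("layout") is not None:
        flat["layout"] = tuple((str(n), int(w)) for n, w in flat["layout"])
    cfg = RunConfig(**flat)
    _validate(cfg)
    return cfg


def _validate(cfg: RunConfig) -> None:
    checks = [
        (cfg.N >= 1, "N", "must be >= 1"),
        (cfg.n_populations >= 1, "n_populations", "must be >= 1"),
        (cfg.generations >= 1, "generations", "must be >= 1"),
        (cfg.n_replicates >= 1, "n_replicates", "must be >= 1"),
        (cfg.n_top >= 1, "n_top", "must be >= 1"),
        (cfg.n_top <= cfg.n_populations, "n_top", "cannot exceed n_populations"),
        (cfg.max_fitness >= 1.0, "max_fitness", "must be >= 1"),
        (0.0 <= cfg.rate0 <= 1.0, "rate0", "must be in [0, 1]"),
        (0.0 < cfg.fixation_threshold <= 1.0, "fixation_threshold",
         "must be in (0, 1]"),
        (cfg.min_quality >= 0, "min_quality", "must be >= 0"),
        (cfg.max_depth >= 1, "max_depth", "must be >= 1"),
        (cfg.min_depth >= 0, "min_depth", "must be >= 0"),
        (cfg.window_size >= 1, "window_size", "must be >= 1"),
        (cfg.diagnostic_density > 0, "diagnostic_density", "must be > 0"),
        (cfg.depth >= 1, "depth", "must be >= 1"),
        (0.0 <= cfg.error_rate <= 0.1, "error_rate", "must be in [0, 0.1]"),
        (cfg.schedule_kind in ("constant", "step"), "schedule_kind",
         "must be 'constant' or 'step'"),
    ]
    for ok, key, constraint in checks:
        if not ok:
            raise ConfigError(f"{key}: {constraint}")


def build_layout(cfg: RunConfig) -> GenomeLayout:
    if cfg.layout is None:
        return default_layout()
    return GenomeLayout(chromosomes=cfg.layout, window_size_bp=cfg.window_size)


def build_schedule(cfg: RunConfig) -> OutcrossingSchedule:
    return OutcrossingSchedule(
        kind=cfg.schedule_kind,
        rate0=cfg.rate0,
        rate1=cfg.rate1,
        switch_generation=cfg.switch_generation,
    )


def build_model(cfg: RunConfig, layout: GenomeLayout | None = None) -> QTLModel:
    """Resolve the qtl block: packaged example id, 'null', or a TSV path."""
    name = cfg.qtl_model
    if name == "null":
        return null_model()
    try:
        return load_example_model(name, cfg.max_fitness)
    except KeyError:
        import pandas as pd

        df = pd.read_csv(name, sep="\t")
        return build_qtl_model(df, cfg.max_fitness, layout=layout, model_id=name)


def build_experiment(cfg: RunConfig) -> ExperimentConfig:
    layout = build_layout(cfg)
    return ExperimentConfig(
        layout=layout,
        qtl_model=build_model(cfg, layout),
        schedule=build_schedule(cfg),
        n_populations=cfg.n_populations,
        generations=cfg.generations,
        N=cfg.N,
        founders_per_bg=cfg.founders_per_bg,
        n_top=cfg.n_top,
        seed=cfg.seed,
    )


def manifest(cfg: RunConfig) -> dict:
    """Everything needed to reproduce a run bit-for-bit."""
    from . import __version__

    return {"package": "wormsweep", "version": __version__, "config": asdict(cfg)}
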