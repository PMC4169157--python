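"""Multiplicative QTL fitness model.

Fitness quantitative trait loci live at window positions; each locus favors
one founder background.  A worm's relative fitness starts at 1.0 and is
multiplied by the locus multiplier once for every favored allele it carries
(0, 1 or 2 per locus).  Under the equal-effects parameterization the
per-allele multiplier is chosen so the optimal genotype — homozygous favored
at every locus — has a specified maximum relative fitness Wmax:

    multiplier = Wmax ** (1 / (2 * n_loci))

e.g. Wmax = 2 with two diploid loci gives 2^(1/4) ≈ 1.189 per allele, and
1.189^4 ≈ 2 for the double homozygote.  An empty locus list is the neutral
null model (all fitness 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .genome import FOUNDER_LABELS, GenomeLayout, PopulationState, WormGenotype

#: QTL model fixtures shipped with the package: locus counts per model id.
EXAMPLE_MODEL_LOCI = {"model1": 83, "model2": 22, "model3": 16, "model4": 11}


@dataclass(frozen=True)
class QTLLocus:
    chromosome: str
    window: int
    favored_background: int
    multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.multiplier < 1.0:
            raise ValueError("locus multiplier must be >= 1")
        if not 0 <= self.favored_background < len(FOUNDER_LABELS):
            raise ValueError("favored_background must encode a founder background")


@dataclass(frozen=True)
class QTLModel:
    """A set of fitness loci plus the maximum relative fitness they realize."""

    loci: tuple[QTLLocus, ...]
    max_fitness: float
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.max_fitness < 1.0:
            raise ValueError("max_fitness must be >= 1")
        seen = {(l.chromosome, l.window) for l in self.loci}
        if len(seen) != len(self.loci):
            raise ValueError("duplicate (chromosome, window) loci in QTL model")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def is_null(self) -> bool:
        return not self.loci

    def arrays(self, layout: GenomeLayout):
        """(flat window indices, favored backgrounds, log multipliers)."""
        idx = np.array(
            [layout.flat_index(l.chromosome, l.window) for l in self.loci], dtype=np.intp
        )
        fav = np.array([l.favored_background for l in self.loci], dtype=np.int8)
        logm = np.array([np.log(l.multiplier) for l in self.loci])
        return idx, fav, logm


@lru_cache(maxsize=64)
def _cached_arrays(model: QTLModel, layout: GenomeLayout):
    return model.arrays(layout)


def per_allele_multiplier(max_fitness: float, n_loci: int) -> float:
    """Equal-effects per-allele multiplier for ``n_loci`` diploid loci.

    Returns ``max_fitness ** (1 / (2 n_loci))``; 1.0 for the null model.
    """
    if max_fitness < 1.0:
        raise ValueError("max_fitness must be >= 1")
    if n_loci < 0:
        raise ValueError("n_loci must be >= 0")
    if n_loci == 0:
        return 1.0
    return float(max_fitness ** (1.0 / (2 * n_loci)))


def build_qtl_model(
    spec: pd.DataFrame | list[tuple[str, int, int]],
    max_fitness: float,
    layout: GenomeLayout | None = None,
    model_id: str = "",
) -> QTLModel:
    """Build an equal-effects model from ``(chromosome, window,
    favored_background)`` rows (DataFrame with those columns, or tuples;
    backgrounds may be labels or integer codes)."""
    if isinstance(spec, pd.DataFrame):
        rows = list(spec[["chromosome", "window", "favored_background"]].itertuples(index=False))
    else:
        rows = list(spec)
    mult = per_allele_multiplier(max_fitness, len(rows))
    loci = []
    for chrom, window, bg in rows:
        if isinstance(bg, str):
            bg = FOUNDER_LABELS.index(bg)
        if layout is not None:
            layout.flat_index(str(chrom), int(window))  # validates bounds
        loci.append(QTLLocus(str(chrom), int(window), int(bg), mult))
    return QTLModel(loci=tuple(loci), max_fitness=float(max_fitness), model_id=model_id)


#: Reference mosaic of chromosome-scale fixed blocks used by the packaged
#: example maps: (windows, background) runs per chromosome, qualitatively
#: mimicking the block-fixation pattern of the evolved lines.
REFERENCE_MOSAIC: dict[str, tuple[tuple[int, str], ...]] = {
    "I": ((76, "CB4856"),),
    "II": ((39, "N2"), (38, "MY2")),
    "III": ((69, "JU258"),),
    "IV": ((88, "AB1"),),
    "V": ((53, "CB4856"), (52, "N2")),
    "X": ((89, "MY2"),),
}


def _mosaic_background(chrom: str, window: int) -> str:
    off = 0
    for n, bg in REFERENCE_MOSAIC[chrom]:
        if window < off + n:
            return bg
        off += n
    raise IndexError(f"window {window} beyond mosaic for {chrom}")


def synthetic_qtl_map(
    n_loci: int, layout: GenomeLayout | None = None, phase: float = 0.5
) -> pd.DataFrame:
    """Construct a deterministic equal-effects QTL map over the reference
    mosaic.

    Loci are apportioned across chromosomes in proportion to window counts
    (largest remainder) and placed at evenly spaced windows — locus i of k
    on a w-window chromosome sits at ``int((i + phase) * w / k)`` — each
    favoring the mosaic background at its window.  ``phase`` shifts the
    placement grid and exists for map-sensitivity analyses; the packaged
    fixtures are the ``phase=0.5`` maps.
    """
    from .genome import default_layout

    layout = layout or default_layout()
    if not 0.0 <= phase < 1.0:
        raise ValueError("phase must be in [0, 1)")
    widths = [w for _, w in layout.chromosomes]
    quotas = [n_loci * w / sum(widths) for w in widths]
    counts = [int(q) for q in quotas]
    order = sorted(
        range(len(widths)), key=lambda i: quotas[i] - counts[i], reverse=True
    )
    for i in order[: n_loci - sum(counts)]:
        counts[i] += 1
    rows = []
    for (chrom, w), k in zip(layout.chromosomes, counts):
        for i in range(k):
            win = min(int((i + phase) * w / k), w - 1)
            rows.append((chrom, win, _mosaic_background(chrom, win)))
    return pd.DataFrame(rows, columns=["chromosome", "window", "favored_background"])


def null_model() -> QTLModel:
    """Neutral model: no fitness QTL, every worm has fitness 1."""
    return QTLModel(loci=(), max_fitness=1.0, model_id="null")


def load_example_model(model_id: str, max_fitness: float) -> QTLModel:
    """Load a packaged QTL map fixture (``model1``..``model4``) or ``null``.

    The fixtures are synthetic stand-ins with the experiment's model sizes
    (83/22/16/11): loci are spread across the six chromosomes in proportion
    to window counts, each favoring the background of a fixed reference
    mosaic of chromosome-scale blocks, mimicking the block-fixation pattern
    of the evolved lines.  The experiment's exact inferred locus positions
    are not reproduced.
    """
    if model_id == "null":
        return null_model()
    if model_id not in EXAMPLE_MODEL_LOCI:
        raise KeyError(f"unknown example model {model_id!r}")
    path = resources.files("wormsweep") / "data" / "qtl_models" / f"{model_id}.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    model = build_qtl_model(df, max_fitness, model_id=model_id)
    assert model.n_loci == EXAMPLE_MODEL_LOCI[model_id]
    return model


def population_fitness(pop: PopulationState, model: QTLModel) -> np.ndarray:
    """Relative fitness of every worm in the population (vectorised).

    log w_i = sum over loci of (favored alleles carried at the locus) x
    log(multiplier); the null model returns all ones.
    """
    n = pop.census_size
    if model.is_null:
        return np.ones(n)
    idx, fav, logm = _cached_arrays(model, pop.layout)
    matches = (pop.haplotypes[:, :, idx] == fav[None, None, :]).sum(axis=1)  # (n, L)
    return np.exp(matches @ logm)


def worm_fitness(worm: WormGenotype, model: QTLModel) -> float:
    """Relative fitness of a single worm under the QTL model."""
    pop = PopulationState(
        layout=worm.layout,
        haplotypes=worm.haplotypes[None, :, :],
        male=np.array([worm.male]),
    )
    return float(population_fitness(pop, model)[0])
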