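"""Sex assignment, parent sampling and single-crossover tetrad meiosis.

The mating system is androdioecious: hermaphrodites self unless a male sires
the brood.  Reproduction follows the two-parent rule: the first parent is
drawn from the whole population weighted by relative fitness; a hermaphrodite
first parent selfs, a male first parent outcrosses with a fitness-weighted
hermaphrodite mother.

Meiosis is obligate-single-crossover: every tetrad undergoes exactly one
crossover per chromosome, at a breakpoint uniform over the inter-window
boundaries.  The crossover involves two of the four chromatids, so a randomly
sampled gamete chromatid is recombinant with probability 1/2 and otherwise an
intact parental haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeLayout, PopulationState, WormGenotype

try:  # compiled gamete assembly; the numpy path below is semantically identical
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


@dataclass(frozen=True)
class OutcrossingSchedule:
    """Per-generation outcrossing-rate schedule.

    ``constant``: rate0 throughout.  ``step``: rate0 until
    ``switch_generation`` (exclusive), rate1 from then on — e.g. the
    experiment's variable scenarios start at 0.05 or 0.10 and drop to 0.01
    at generation 25.
    """

    kind: str = "constant"
    rate0: float = 0.01
    rate1: float | None = None
    switch_generation: int = 25

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "step"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        rates = [self.rate0] + ([self.rate1] if self.kind == "step" else [])
        if self.kind == "step" and self.rate1 is None:
            raise ValueError("step schedule requires rate1")
        for r in rates:
            if not 0.0 <= r <= 1.0:
                raise ValueError("outcrossing rates must be in [0, 1]")
        if self.kind == "step" and self.switch_generation < 1:
            raise ValueError("switch_generation must be positive")

    def rate(self, generation: int) -> float:
        if self.kind == "constant" or generation < self.switch_generation:
            return self.rate0
        return float(self.rate1)

    def describe(self) -> str:
        if self.kind == "constant":
            return f"constant {self.rate0:g}"
        return f"{self.rate0:g}→{self.rate1:g}@g{self.switch_generation}"


def assign_sexes(
    pop: PopulationState, rate: float, rng: np.random.Generator
) -> PopulationState:
    """Redraw each worm's phenotypic sex: male with probability ``rate``.

    Genotypes are untouched (maleness here is environmentally/mutationally
    induced, not chromosomal).  Mutates and returns ``pop``.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    pop.male = rng.random(pop.census_size) < rate
    return pop


def make_gametes(
    haplotypes: np.ndarray,
    parents: np.ndarray,
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one gamete from each worm in ``parents`` (vectorised meiosis).

    Per chromosome and per gamete: a start haplotype is chosen uniformly; with
    probability 1/2 the sampled chromatid is recombinant, switching to the
    other haplotype at a breakpoint uniform over the ``w - 1`` inter-window
    boundaries.  Single-window chromosomes have no interior boundary and
    reduce to free Mendelian segregation.

    Parameters
    ----------
    haplotypes : (N, 2, W) int8 array of the parental generation.
    parents : (n,) integer indices into the first axis.
    """
    n = parents.shape[0]
    n_chrom = len(layout.chromosomes)
    widths = np.array(layout.n_windows, dtype=np.int64)
    offsets = np.array(layout.offsets, dtype=np.int64)
    # One draw per (gamete, chromosome) encodes the whole meiosis:
    # u & 1 -> start haplotype, u & 2 -> recombinant chromatid,
    # (u >> 2) + 1 -> breakpoint.  switch_at == w means "no switch".
    starts = np.empty((n, n_chrom), dtype=np.uint16)
    switch_ats = np.empty((n, n_chrom), dtype=np.uint16)
    for c, w in enumerate(widths):
        u = rng.integers(0, 4 * (w - 1) if w > 1 else 2, size=n, dtype=np.uint16)
        starts[:, c] = u & 1
        switch_ats[:, c] = np.where(u & 2, (u >> 2) + 1, w)
    out = np.empty((n, layout.total_windows), dtype=haplotypes.dtype)
    if _assemble_gametes is not None:
        _assemble_gametes(out, haplotypes, parents.astype(np.int64),
                          starts, switch_ats, offsets, widths)
        return out
    hap_a = haplotypes[parents, 0, :]
    hap_b = haplotypes[parents, 1, :]
    for c, (off, w) in enumerate(zip(offsets, widths)):
        s = slice(off, off + w)
        windows = np.arange(w, dtype=np.uint16)
        choice = (windows[None, :] >= switch_ats[:, c, None]) ^ (
            starts[:, c, None].astype(bool)
        )
        out[:, s] = np.where(choice, hap_b[:, s], hap_a[:, s])
    return out


def _assemble_gametes_py(out, haps, parents, starts, switch_ats, offsets, widths):
    """Copy parental haplotype segments into gametes (compiled when numba
    is available): up to the breakpoint from the start haplotype, after it
    from the other."""
    n = parents.shape[0]
    for i in range(n):
        p = parents[i]
        for c in range(widths.shape[0]):
            off, w = offsets[c], widths[c]
            a = starts[i, c]
            b = 1 - a
            cut = off + switch_ats[i, c]
            for j in range(off, cut):  # element loops beat slice machinery
                out[i, j] = haps[p, a, j]
            for j in range(cut, off + w):
                out[i, j] = haps[p, b, j]


_assemble_gametes = njit(cache=False)(_assemble_gametes_py) if njit else None


def make_gamete(
    parent: WormGenotype, layout: GenomeLayout, rng: np.random.Generator
) -> np.ndarray:
    """Single-worm convenience wrapper around :func:`make_gametes`."""
    return make_gametes(
        parent.haplotypes[None, :, :], np.zeros(1, dtype=np.intp), layout, rng
    )[0]


class ReproductionError(RuntimeError):
    """Raised when a generation cannot be produced (no hermaphrodites)."""


def produce_offspring(
    pop: PopulationState,
    fitness: np.ndarray,
    n_offspring: int,
    rng: np.random.Generator,
) -> PopulationState:
    """Build the next (non-overlapping) generation of exactly ``n_offspring``.

    Each offspring unites two gametes: one from a fitness-weighted first
    parent, the second from the same worm (selfing, if the first parent is a
    hermaphrodite) or from a fitness-weighted hermaphrodite mother (if it is
    a male).  Gametes from the same worm come from independent meioses.
    Offspring sexes are assigned later, at the start of their own generation.
    """
    if fitness.shape != (pop.census_size,):
        raise ValueError("fitness must align with the population")
    if np.any(fitness <= 0):
        raise ValueError("fitness values must be positive")
    herm_idx = np.flatnonzero(~pop.male)
    if herm_idx.size == 0:
        raise ReproductionError(
            f"no hermaphrodites at generation {pop.generation}; population collapsed"
        )
    p = fitness / fitness.sum()
    first = rng.choice(pop.census_size, size=n_offspring, p=p)
    second = first.copy()
    sired = pop.male[first]
    n_out = int(sired.sum())
    if n_out:
        p_herm = fitness[herm_idx] / fitness[herm_idx].sum()
        second[sired] = herm_idx[rng.choice(herm_idx.size, size=n_out, p=p_herm)]
    # interleave the two parents of each brood so a selfing worm's two
    # meioses read the same haplotypes back-to-back (cache locality)
    parents = np.empty(2 * n_offspring, dtype=np.intp)
    parents[0::2] = first
    parents[1::2] = second
    both = make_gametes(pop.haplotypes, parents, pop.layout, rng)
    haps = both.reshape(n_offspring, 2, pop.layout.total_windows)
    return PopulationState(
        layout=pop.layout,
        haplotypes=haps,
        male=np.zeros(n_offspring, dtype=bool),
        generation=pop.generation + 1,
    )
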