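"""Genome layout, founder backgrounds and population containers.

The simulator tracks ancestry at the resolution of 200-kb genomic windows:
each haplotype is a vector of founder-background labels, one per window.
All worms are genotypically XX (maleness in these populations is phenotypic,
induced by the temperature-sensitive sex-determination genotype), so the six
chromosomes are inherited identically and no separate sex-chromosome logic
is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: The five founder wild-isolate backgrounds, in their stable integer encoding.
FOUNDER_LABELS: tuple[str, ...] = ("N2", "CB4856", "AB1", "MY2", "JU258")
N_BACKGROUNDS: int = len(FOUNDER_LABELS)

HERMAPHRODITE, MALE = False, True

# C. elegans chromosome lengths (bp), WormBase release WS235.  Frozen so the
# default layout is reproducible without the reference genome on disk.
_WS235_LENGTHS = {
    "I": 15_072_434,
    "II": 15_279_421,
    "III": 13_783_801,
    "IV": 17_493_829,
    "V": 20_924_180,
    "X": 17_718_942,
}


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome/window grid shared by the simulator and the pool-seq analysis.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, n_windows)`` pairs.  Window indices are dense and
        0-based within each chromosome.
    window_size_bp
        Physical window size; 1-based bp position ``pos`` maps to window
        ``(pos - 1) // window_size_bp`` (matching VCF coordinates).
    """

    chromosomes: tuple[tuple[str, int], ...]
    window_size_bp: int = 200_000

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("layout needs at least one chromosome")
        if self.window_size_bp <= 0:
            raise ValueError("window_size_bp must be positive")
        for name, w in self.chromosomes:
            if w <= 0:
                raise ValueError(f"chromosome {name!r}: n_windows must be positive")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def n_windows(self) -> tuple[int, ...]:
        return tuple(w for _, w in self.chromosomes)

    @property
    def total_windows(self) -> int:
        return sum(self.n_windows)

    @property
    def offsets(self) -> tuple[int, ...]:
        """Start index of each chromosome in the flat window axis."""
        out, s = [], 0
        for _, w in self.chromosomes:
            out.append(s)
            s += w
        return tuple(out)

    def chrom_slice(self, name: str) -> slice:
        for (n, w), off in zip(self.chromosomes, self.offsets):
            if n == name:
                return slice(off, off + w)
        raise KeyError(name)

    def flat_index(self, chrom: str, window: int) -> int:
        for (n, w), off in zip(self.chromosomes, self.offsets):
            if n == chrom:
                if not 0 <= window < w:
                    raise IndexError(f"window {window} out of range for {chrom}")
                return off + window
        raise KeyError(chrom)

    def window_of(self, chrom: str, pos_1based: int) -> int:
        """Window index (within chromosome) of a 1-based bp position."""
        if pos_1based < 1:
            raise ValueError("positions are 1-based")
        return (pos_1based - 1) // self.window_size_bp

    def chrom_length_bp(self, name: str) -> int:
        """Physical span covered by a chromosome's windows."""
        return dict(self.chromosomes)[name] * self.window_size_bp


def default_layout() -> GenomeLayout:
    """The six-chromosome C. elegans grid of 200-kb windows.

    Window counts are ceil(WS235 chromosome length / 200 kb):
    I 76, II 77, III 69, IV 88, V 105, X 89 (504 total), all within the
    69-105 range the simulated genome is built from.
    """
    chroms = tuple(
        (name, -(-length // 200_000)) for name, length in _WS235_LENGTHS.items()
    )
    return GenomeLayout(chromosomes=chroms, window_size_bp=200_000)


@dataclass
class PopulationState:
    """One simulated population at one (non-overlapping) generation.

    ``haplotypes`` has shape ``(census, 2, total_windows)`` with int8 founder
    labels; ``male`` is a boolean phenotypic-sex vector.
    """

    layout: GenomeLayout
    haplotypes: np.ndarray
    male: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        h = self.haplotypes
        if h.ndim != 3 or h.shape[1] != 2 or h.shape[2] != self.layout.total_windows:
            raise ValueError("haplotypes must have shape (census, 2, total_windows)")
        if self.male.shape != (h.shape[0],):
            raise ValueError("sex vector length must match census")

    @property
    def census_size(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_hermaphrodites(self) -> int:
        return int((~self.male).sum())

    @property
    def n_males(self) -> int:
        return int(self.male.sum())

    def worm(self, i: int) -> "WormGenotype":
        return WormGenotype(self.layout, self.haplotypes[i], bool(self.male[i]))


@dataclass
class WormGenotype:
    """Single-worm view: two window-label haplotypes plus phenotypic sex."""

    layout: GenomeLayout
    haplotypes: np.ndarray  # (2, total_windows) int8
    male: bool = False

    def chromosome(self, name: str) -> np.ndarray:
        return self.haplotypes[:, self.layout.chrom_slice(name)]

    @property
    def is_homozygous(self) -> bool:
        return bool(np.array_equal(self.haplotypes[0], self.haplotypes[1]))


class FoundingError(ValueError):
    """Raised when a founding composition cannot reproduce."""


def build_founder_population(
    layout: GenomeLayout,
    founders_per_bg: tuple[int, int] = (10, 12),
    backgrounds: tuple[int, ...] = tuple(range(N_BACKGROUNDS)),
) -> PopulationState:
    """Generation-0 population: ``(n_herm, n_male)`` worms of each founder
    background, each homozygous for its own background at every window.

    Raises :class:`FoundingError` if no hermaphrodite is present anywhere
    (a male-only population cannot reproduce).
    """
    n_herm, n_male = founders_per_bg
    if n_herm < 0 or n_male < 0:
        raise ValueError("founder counts must be non-negative")
    if n_herm == 0:
        raise FoundingError("at least one hermaphrodite founder is required")
    if not all(0 <= b < N_BACKGROUNDS for b in backgrounds):
        raise ValueError("backgrounds must be valid founder codes")
    per_bg = n_herm + n_male
    n_bg = len(backgrounds)
    census = n_bg * per_bg
    haps = np.empty((census, 2, layout.total_windows), dtype=np.int8)
    male = np.empty(census, dtype=bool)
    for i, bg in enumerate(backgrounds):
        rows = slice(i * per_bg, (i + 1) * per_bg)
        haps[rows] = bg
        male[rows] = False
        male.reshape(n_bg, per_bg)[i, n_herm:] = True
    return PopulationState(layout=layout, haplotypes=haps, male=male, generation=0)
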