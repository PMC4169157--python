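"""Window-frequency tables, the s and f statistics, and replicate summaries.

The experiment's two genome-wide test statistics compare the three
highest-fitness populations of a run:

* ``s`` — the proportion of windows whose "dominant" founder background (the
  one at highest frequency) is the same in all three populations;
* ``f`` — the mean, over the three populations, of the proportion of windows
  whose dominant background is at frequency >= 0.9 ("fixed").

Expected distributions, 95% CIs and empirical p-values for observed values
are obtained from replicate simulations (200 replicates in the original
design).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import N_BACKGROUNDS, PopulationState

#: Dominant-background frequency at or above which a window counts as fixed.
FIXATION_THRESHOLD = 0.9


def window_freqs(pop: PopulationState) -> np.ndarray:
    """Founder-background frequencies per window over all 2N haplotypes.

    Returns a ``(5, total_windows)`` array whose columns sum to 1; every
    entry is a multiple of 1/(2N).
    """
    flat = pop.haplotypes.reshape(-1, pop.layout.total_windows)
    return np.stack([(flat == b).mean(axis=0) for b in range(N_BACKGROUNDS)])


def dominant_allele(freqs: np.ndarray) -> np.ndarray:
    """Index of the dominant (highest-frequency) background per window.

    Accepts a ``(5,)`` vector or ``(5, W)`` table; ties break to the lowest
    background index (numpy argmax convention), deterministically.
    """
    return np.argmax(freqs, axis=0)


def _check_tables(tables) -> list[np.ndarray]:
    tables = [np.asarray(t) for t in tables]
    shapes = {t.shape for t in tables}
    if len(shapes) != 1:
        raise ValueError("window-frequency tables have mismatched layouts")
    return tables


def stat_s(tables) -> float:
    """Proportion of windows with the same dominant background in all tables."""
    tables = _check_tables(tables)
    doms = np.stack([dominant_allele(t) for t in tables])
    return float(np.all(doms == doms[0], axis=0).mean())


def stat_f(tables, threshold: float = FIXATION_THRESHOLD) -> float:
    """Mean proportion of fixed windows (dominant frequency >= threshold)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    tables = _check_tables(tables)
    return float(np.mean([(t.max(axis=0) >= threshold).mean() for t in tables]))


def ci95(values) -> tuple[float, float]:
    """Empirical 95% CI: 2.5th/97.5th percentiles of the replicate values,
    with linear interpolation between closest order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 replicate values for a CI")
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def empirical_p(observed: float, values) -> float:
    """Two-tailed add-one empirical p-value of an observed statistic.

    ``p = min(1, 2 * min(#{v <= obs} + 1, #{v >= obs} + 1) / (n + 1))``.
    With 200 replicates an observation outside the whole simulated
    distribution gives p = 2/201 ≈ 0.01, the smallest value reportable.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 1:
        raise ValueError("need at least one simulated value")
    le = int((values <= observed).sum()) + 1
    ge = int((values >= observed).sum()) + 1
    return min(1.0, 2.0 * min(le, ge) / (n + 1))


def format_p(p: float, floor: float = 0.01) -> str:
    """Render a p-value the way the summary tables print it (``<0.01`` floor)."""
    return f"<{floor:g}" if p < floor else f"{p:.2f}"


@dataclass
class StatSummary:
    """Replicate distribution summary for one statistic (s or f)."""

    stat_name: str
    values: np.ndarray
    ci_low: float
    ci_high: float
    p_observed: float | None = None

    @classmethod
    def from_values(
        cls, stat_name: str, values, observed: float | None = None
    ) -> "StatSummary":
        values = np.asarray(values, dtype=float)
        lo, hi = ci95(values)
        p = empirical_p(observed, values) if observed is not None else None
        return cls(stat_name, values, lo, hi, p)

    @property
    def mean(self) -> float:
        return float(self.values.mean())
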