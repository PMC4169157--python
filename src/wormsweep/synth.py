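"""Synthetic pooled-sequencing data with known ground truth.

Emulates the end product of the experiment's sequencing: a five-founder
diagnostic SNP panel at ~1 diagnostic SNP per 750 bp, and pooled samples
whose reads are drawn from a known window-level mosaic of founder
ancestries at ~9-30x depth.  Every generated VCF comes with a truth table,
so diagnostic-SNP recovery, window ancestry painting and novel-mutation
detection can be scored exactly.

Depth is Poisson per site; a read shows the wrong allele of a biallelic
site with probability ``error_rate``, and a specific alternate base arises
at an invariant site with probability ``error_rate / 3`` (miscalls spread
over three bases).  Read-level artifacts (mapping, indels) are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .genome import FOUNDER_LABELS, GenomeLayout, default_layout

_BASES = np.array(list("ACGT"))

# Fixed substream keys under spec.seed, so sites are shared by all
# generators for a given spec while counts/noise stay independent.
_SITES_KEY, _PANEL_KEY, _POOL_KEY = 11, 13, 17


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the emulated sequencing experiment.

    ``diagnostic_density`` is the mean spacing in bp between diagnostic SNPs
    genome-wide (all backgrounds pooled); ``depth`` the mean per-site
    coverage; ``error_rate`` the per-read miscall probability.
    """

    layout: GenomeLayout = field(default_factory=default_layout)
    diagnostic_density: float = 750.0
    depth: float = 30.0
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diagnostic_density <= 0:
            raise ValueError("diagnostic_density must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")


def diagnostic_sites(spec: SynthSpec) -> pd.DataFrame:
    """Plant diagnostic SNP sites: a Poisson process at the spec density.

    Site positions, ref/alt alleles and the owning background are a
    deterministic function of ``spec.seed`` alone, so founder panels and
    pooled samples generated from the same spec agree on the site map.
    Returns columns chrom, pos, ref, alt, background.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _SITES_KEY]))
    rows = []
    for name, _ in spec.layout.chromosomes:
        length = spec.layout.chrom_length_bp(name)
        n = rng.poisson(length / spec.diagnostic_density)
        pos = np.sort(rng.choice(length, size=min(n, length), replace=False)) + 1
        bg = rng.integers(0, len(FOUNDER_LABELS), size=pos.size)
        ref = rng.integers(0, 4, size=pos.size)
        alt = (ref + rng.integers(1, 4, size=pos.size)) % 4
        for p, b, r, a in zip(pos, bg, ref, alt):
            rows.append((name, int(p), _BASES[r], _BASES[a], FOUNDER_LABELS[b]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "background"])


def write_vcf(
    path: str,
    layout: GenomeLayout,
    samples: list[str],
    records,
) -> None:
    """Write a minimal multi-sample VCF with DP/AD FORMAT fields.

    ``records``: iterable of ``(chrom, pos, ref, alt, qual, per_sample)``
    with ``per_sample`` a list of ``(depth, alt_count)`` aligned to
    ``samples``.  Output is deterministic for deterministic input.
    """
    header = pysam.VariantHeader()
    for name, _ in layout.chromosomes:
        header.contigs.add(name, length=layout.chrom_length_bp(name))
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Reads supporting each allele")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for chrom, pos, ref, alt, qual, per_sample in records:
            rec = out.new_record(
                contig=chrom, start=pos - 1, alleles=(ref, alt), qual=qual
            )
            for s, (dp, ad) in zip(samples, per_sample):
                rec.samples[s]["DP"] = int(dp)
                rec.samples[s]["AD"] = (int(dp) - int(ad), int(ad))
            out.write(rec)


def _counts(rng, depth: float, p_alt: float) -> tuple[int, int]:
    dp = rng.poisson(depth)
    return dp, (rng.binomial(dp, p_alt) if dp else 0)


def make_founder_panel(
    spec: SynthSpec,
    out_vcf: str,
    monitor_positions: list[tuple[str, int, str, str]] = (),
) -> pd.DataFrame:
    """Write the five-founder panel VCF; return the planted truth table.

    At each diagnostic site the owning background's sample reads the
    diagnostic (alt) allele at frequency ``1 - error_rate`` and the other
    four at ``error_rate``.  ``monitor_positions`` — ``(chrom, pos, ref,
    alt)`` tuples away from diagnostic sites — add invariant records (alt
    reads only via error) so downstream absence checks have coverage there.
    """
    sites = diagnostic_sites(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _PANEL_KEY]))
    e = spec.error_rate
    records = []
    for row in sites.itertuples(index=False):
        per_sample = [
            _counts(rng, spec.depth, (1 - e) if s == row.background else e)
            for s in FOUNDER_LABELS
        ]
        records.append((row.chrom, row.pos, row.ref, row.alt, 60.0, per_sample))
    for chrom, pos, ref, alt in monitor_positions:
        per_sample = [_counts(rng, spec.depth, e / 3) for _ in FOUNDER_LABELS]
        records.append((chrom, pos, ref, alt, 60.0, per_sample))
    records.sort(key=lambda r: (spec.layout.names.index(r[0]), r[1]))
    write_vcf(out_vcf, spec.layout, list(FOUNDER_LABELS), records)
    return sites


def _window_weights(spec: SynthSpec, mosaic) -> dict[str, np.ndarray]:
    """Normalize a mosaic to per-chromosome (n_windows, 5) weight arrays.

    ``mosaic`` maps chromosome name to either an int array of background
    codes (pure blocks) or a (n_windows, 5) array of mixture weights
    summing to 1 per window.
    """
    out = {}
    for name, w in spec.layout.chromosomes:
        arr = np.asarray(mosaic[name])
        if arr.ndim == 1:
            if arr.shape != (w,):
                raise ValueError(f"mosaic for {name} must cover {w} windows")
            weights = np.zeros((w, len(FOUNDER_LABELS)))
            weights[np.arange(w), arr.astype(int)] = 1.0
        else:
            if arr.shape != (w, len(FOUNDER_LABELS)):
                raise ValueError(f"mosaic for {name} must be ({w}, 5)")
            if not np.allclose(arr.sum(axis=1), 1.0):
                raise ValueError(f"mosaic weights for {name} must sum to 1 per window")
            weights = arr.astype(float)
        out[name] = weights
    return out


def make_mosaic_pool(
    spec: SynthSpec,
    mosaic,
    out_vcf: str,
    novel_mutations: list[tuple[str, int, float]] = (),
    sample: str = "pool",
    monitor_positions: list[tuple[str, int, str, str]] = (),
) -> pd.DataFrame:
    """Write a pooled-sample VCF over a known ancestry mosaic; return truth.

    At each diagnostic site the pool's diagnostic-allele frequency is the
    owning background's weight in the site's window, blurred by sequencing
    error; alt reads are binomial at Poisson depth.  ``novel_mutations`` are
    ``(chrom, pos, frequency)`` alleles injected at non-diagnostic positions
    (a diagnostic position raises, keeping the truth unambiguous).

    The truth table has one row per emitted record with its expected
    alt-allele frequency and, for diagnostic sites, the owning background.
    """
    sites = diagnostic_sites(spec)
    weights = _window_weights(spec, mosaic)
    diag_pos = {(c, p) for c, p in zip(sites["chrom"], sites["pos"])}
    for chrom, pos, _ in novel_mutations:
        if (chrom, pos) in diag_pos:
            raise ValueError(f"novel mutation collides with diagnostic site {chrom}:{pos}")
    salt = sum(map(ord, sample))  # distinct pools from one spec stay independent
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _POOL_KEY, salt]))
    e = spec.error_rate
    bg_index = {b: i for i, b in enumerate(FOUNDER_LABELS)}
    records, truth = [], []
    for row in sites.itertuples(index=False):
        win = spec.layout.window_of(row.chrom, row.pos)
        wgt = weights[row.chrom][win, bg_index[row.background]]
        p_alt = wgt * (1 - e) + (1 - wgt) * e
        dp, ad = _counts(rng, spec.depth, p_alt)
        records.append((row.chrom, row.pos, row.ref, row.alt, 60.0, [(dp, ad)]))
        truth.append((row.chrom, row.pos, row.ref, row.alt, row.background,
                      "diagnostic", p_alt))
    mut_rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, _POOL_KEY, salt, 1])
    )
    for chrom, pos, freq in novel_mutations:
        ref, alt_ = mutation_alleles(chrom, pos)
        p_alt = freq * (1 - e) + (1 - freq) * e / 3
        dp, ad = _counts(mut_rng, spec.depth, p_alt)
        records.append((chrom, pos, ref, alt_, 60.0, [(dp, ad)]))
        truth.append((chrom, pos, ref, alt_, None, "novel", freq))
    for chrom, pos, ref, alt_ in monitor_positions:
        if (chrom, pos) in diag_pos:
            continue
        dp, ad = _counts(mut_rng, spec.depth, e / 3)
        records.append((chrom, pos, ref, alt_, 60.0, [(dp, ad)]))
        truth.append((chrom, pos, ref, alt_, None, "monitor", 0.0))
    order = {n: i for i, n in enumerate(spec.layout.names)}
    records.sort(key=lambda r: (order[r[0]], r[1]))
    write_vcf(out_vcf, spec.layout, [sample], records)
    truth_df = pd.DataFrame(
        truth, columns=["chrom", "pos", "ref", "alt", "background", "kind",
                        "expected_freq"]
    )
    return truth_df.sort_values(
        ["chrom", "pos"],
        key=lambda s: s.map(order) if s.name == "chrom" else s,
        kind="stable",
    ).reset_index(drop=True)


def mutation_alleles(chrom: str, pos: int) -> tuple[str, str]:
    """Deterministic ref/alt pair for an injected mutation site.

    A plain arithmetic hash (process-independent) so evolved, ancestor and
    founder records for the same site share alleles and merge cleanly.
    """
    h = (pos * 2654435761 + sum(map(ord, chrom))) & 0xFFFFFFFF
    r = h % 4
    a = (r + 1 + (h >> 8) % 3) % 4
    return str(_BASES[r]), str(_BASES[a])
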