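"""Pooled-resequencing ancestry analysis.

Given SNP calls for the five founder strains, a pooled ancestor and evolved
pooled samples, this module

1. filters calls (site quality >= 30, per-sample depth <= 100x by default,
   biallelic SNPs only);
2. identifies diagnostic SNPs — alleles unique to one founder background at
   sites with >= 10x coverage in every background;
3. paints ancestry by averaging each background's diagnostic-allele
   frequencies in non-overlapping 200-kb windows of a pooled sample;
4. screens for novel mutations: alleles nearly fixed (> 90% frequency) in an
   evolved line but absent (at >= 10x depth) from the pooled ancestor and
   all five founders.

Pooled allele frequencies are read proportions; read mapping and SNP calling
are upstream of this module, which consumes multi-sample VCF with per-sample
``DP`` and ``AD`` FORMAT fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genome import FOUNDER_LABELS

log = logging.getLogger(__name__)

SITE_KEY = ["chrom", "pos", "ref", "alt"]


@dataclass(frozen=True)
class SNPRecord:
    """One biallelic SNP call with per-sample depth and alt-read counts."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    qual: float
    depth: dict[str, int]
    alt_count: dict[str, int]


@dataclass
class SNPTable:
    """A filtered call set: one row per site, per-sample ``dp:S``/``ad:S``
    columns holding depth and alt-read count for sample S."""

    df: pd.DataFrame
    samples: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.df)

    def depths(self) -> np.ndarray:
        """(n_sites, n_samples) depth matrix."""
        return self.df[[f"dp:{s}" for s in self.samples]].to_numpy()

    def alt_counts(self) -> np.ndarray:
        return self.df[[f"ad:{s}" for s in self.samples]].to_numpy()

    def alt_freqs(self) -> np.ndarray:
        """Per-sample alt-read proportions (NaN where depth is 0)."""
        dp = self.depths().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(dp > 0, self.alt_counts() / dp, np.nan)

    def record(self, i: int) -> SNPRecord:
        row = self.df.iloc[i]
        return SNPRecord(
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            qual=float(row["qual"]),
            depth={s: int(row[f"dp:{s}"]) for s in self.samples},
            alt_count={s: int(row[f"ad:{s}"]) for s in self.samples},
        )


class VCFFormatError(ValueError):
    """Raised when required per-sample FORMAT annotations are missing."""


def load_snps(
    vcf_path: str, min_quality: float = 30.0, max_depth: int = 100
) -> SNPTable:
    """Load and filter biallelic SNPs from a multi-sample VCF.

    Keeps records with QUAL >= ``min_quality`` and depth <= ``max_depth`` in
    every sample (the high-depth cut guards against collapsed paralogous
    repeats).  Multiallelic records and indels are dropped and counted in a
    log message.  Requires per-sample ``DP`` and ``AD`` FORMAT fields.
    """
    vcf = VCF(vcf_path)
    samples = tuple(vcf.samples)
    rows = []
    n_not_snp = n_qual = n_depth = 0
    for v in vcf:
        if (not v.is_snp) or len(v.ALT) != 1:
            n_not_snp += 1
            continue
        qual = v.QUAL if v.QUAL is not None else 0.0
        if qual < min_quality:
            n_qual += 1
            continue
        dp = ad = None
        try:
            dp = v.format("DP")
            field = "AD"
            ad = v.format("AD")
        except KeyError:
            pass
        if dp is None or ad is None:
            field = "DP" if dp is None else "AD"
            raise VCFFormatError(
                f"{vcf_path}: FORMAT field {field!r} missing at {v.CHROM}:{v.POS} "
                f"(samples {', '.join(samples)})"
            )
        dp = np.clip(dp[:, 0], 0, None)
        if (dp > max_depth).any():
            n_depth += 1
            continue
        alt = np.clip(ad[:, 1], 0, None)
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0], qual, *dp, *alt))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual"]
                      + [f"dp:{s}" for s in samples] + [f"ad:{s}" for s in samples])
    log.info(
        "%s: kept %d SNPs (dropped %d non-biallelic-SNP, %d low-quality, "
        "%d high-depth records)", vcf_path, len(df), n_not_snp, n_qual, n_depth,
    )
    return SNPTable(df=df, samples=samples)


def find_diagnostic_snps(
    panel: SNPTable,
    backgrounds: dict[str, str] | None = None,
    min_depth: int = 10,
    min_diag_freq: float = 0.9,
    max_other_freq: float = 0.05,
) -> pd.DataFrame:
    """Identify SNP alleles unique to one founder background.

    A site contributes at most one diagnostic SNP: an allele (ref or alt)
    whose read frequency is >= ``min_diag_freq`` in exactly one background
    and <= ``max_other_freq`` in the other four, with every background
    covered at >= ``min_depth``.  The founder strains are inbred, so the
    frequency slack only absorbs sequencing error and residual
    heterozygosity.

    Returns a DataFrame with the site columns plus ``diagnostic_background``
    (label) and ``diagnostic_allele`` ('ref' or 'alt').
    """
    backgrounds = backgrounds or {s: s for s in panel.samples}
    bgs = [backgrounds[s] for s in panel.samples]
    if sorted(bgs) != sorted(FOUNDER_LABELS):
        raise ValueError("panel must cover the five founder backgrounds exactly once")
    dp = panel.depths()
    af = panel.alt_freqs()
    covered = (dp >= min_depth).all(axis=1)
    n_skipped = int((~covered).sum())
    if n_skipped:
        log.info("skipped %d sites with < %dx coverage in some background",
                 n_skipped, min_depth)
    out_bg, out_allele, out_idx = [], [], []
    for j, bg in enumerate(bgs):
        others = [k for k in range(len(bgs)) if k != j]
        alt_unique = (
            covered
            & (af[:, j] >= min_diag_freq)
            & (af[:, others] <= max_other_freq).all(axis=1)
        )
        ref_unique = (
            covered
            & (1 - af[:, j] >= min_diag_freq)
            & (1 - af[:, others] <= max_other_freq).all(axis=1)
        )
        for mask, allele in ((alt_unique, "alt"), (ref_unique, "ref")):
            idx = np.flatnonzero(mask)
            out_idx.extend(idx)
            out_bg.extend([bg] * len(idx))
            out_allele.extend([allele] * len(idx))
    diag = panel.df.iloc[out_idx, : 5].copy()
    diag["diagnostic_background"] = out_bg
    diag["diagnostic_allele"] = out_allele
    return diag.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def window_ancestry(
    sample: SNPTable,
    diagnostics: pd.DataFrame,
    sample_name: str | None = None,
    window_size: int = 200_000,
    depth_weighted: bool = False,
) -> pd.DataFrame:
    """Mean diagnostic-allele frequency per background in 200-kb windows.

    For each diagnostic SNP covered (depth >= 1) in the pooled sample, the
    diagnostic-allele read proportion estimates that background's local
    frequency; per window and background these are averaged (unweighted by
    default; ``depth_weighted`` switches to a total-reads estimator).
    Windows are half-open ``[k*window_size, (k+1)*window_size)`` on 1-based
    positions via ``pos - 1``.  A background with no informative SNP in a
    window gets NaN (missing), never 0.

    Returns wide rows: sample, chrom, window_start, window_end,
    ``freq_<bg>`` and ``n_<bg>`` for each founder background.
    """
    if sample_name is None:
        if len(sample.samples) != 1:
            raise ValueError("sample_name required for multi-sample tables")
        sample_name = sample.samples[0]
    dp_col, ad_col = f"dp:{sample_name}", f"ad:{sample_name}"
    merged = diagnostics.merge(
        sample.df[SITE_KEY + [dp_col, ad_col]], on=SITE_KEY, how="inner"
    )
    merged = merged[merged[dp_col] >= 1].copy()
    af = merged[ad_col] / merged[dp_col]
    merged["diag_freq"] = np.where(merged["diagnostic_allele"] == "alt", af, 1 - af)
    merged["window_start"] = ((merged["pos"] - 1) // window_size) * window_size
    rows = []
    grouped = merged.groupby(["chrom", "window_start"], sort=True)
    for (chrom, wstart), g in grouped:
        row = {
            "sample": sample_name,
            "chrom": chrom,
            "window_start": int(wstart),
            "window_end": int(wstart) + window_size,
        }
        for bg in FOUNDER_LABELS:
            gb = g[g["diagnostic_background"] == bg]
            row[f"n_{bg}"] = len(gb)
            if not len(gb):
                row[f"freq_{bg}"] = np.nan
            elif depth_weighted:
                reads = gb["diag_freq"] * gb[dp_col]
                row[f"freq_{bg}"] = float(reads.sum() / gb[dp_col].sum())
            else:
                row[f"freq_{bg}"] = float(gb["diag_freq"].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def detect_novel_mutations(
    evolved: dict[str, SNPTable],
    ancestor: SNPTable,
    founders: SNPTable,
    freq_threshold: float = 0.9,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Screen for novel substitutions fixed during the experiment.

    A call requires, at one site: alt frequency strictly > ``freq_threshold``
    in at least one evolved line (at >= ``min_depth`` coverage there), and
    zero alt reads with >= ``min_depth`` coverage in the pooled ancestor and
    in every founder strain.  Sites missing from the ancestor or founder
    call sets cannot satisfy the coverage requirement and are not called.

    Returns one row per (site, line): chromosome, position, ref, alt, line,
    frequency, evolved_depth, ancestor_depth, min_founder_depth.
    """
    anc_name = ancestor.samples[0]
    anc = ancestor.df[SITE_KEY + [f"dp:{anc_name}", f"ad:{anc_name}"]].rename(
        columns={f"dp:{anc_name}": "anc_dp", f"ad:{anc_name}": "anc_ad"}
    )
    fdf = founders.df[SITE_KEY].copy()
    fdp = founders.depths()
    fad = founders.alt_counts()
    fdf["founder_min_dp"] = fdp.min(axis=1)
    fdf["founder_alt_total"] = fad.sum(axis=1)
    calls = []
    for line, table in evolved.items():
        s = table.samples[0]
        df = table.df
        dp = df[f"dp:{s}"]
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(dp > 0, df[f"ad:{s}"] / dp, 0.0)
        cand = df.loc[(freq > freq_threshold) & (dp >= min_depth), SITE_KEY].copy()
        cand["frequency"] = freq[(freq > freq_threshold) & (dp >= min_depth)]
        cand["evolved_depth"] = dp[(freq > freq_threshold) & (dp >= min_depth)].values
        cand = cand.merge(anc, on=SITE_KEY, how="inner")
        cand = cand[(cand["anc_dp"] >= min_depth) & (cand["anc_ad"] == 0)]
        cand = cand.merge(fdf, on=SITE_KEY, how="inner")
        cand = cand[
            (cand["founder_min_dp"] >= min_depth) & (cand["founder_alt_total"] == 0)
        ]
        for _, r in cand.iterrows():
            calls.append(
                {
                    "chromosome": r["chrom"],
                    "position": int(r["pos"]),
                    "ref": r["ref"],
                    "alt": r["alt"],
                    "line": line,
                    "frequency": float(r["frequency"]),
                    "evolved_depth": int(r["evolved_depth"]),
                    "ancestor_depth": int(r["anc_dp"]),
                    "min_founder_depth": int(r["founder_min_dp"]),
                }
            )
    cols = ["chromosome", "position", "ref", "alt", "line", "frequency",
            "evolved_depth", "ancestor_depth", "min_founder_depth"]
    return pd.DataFrame(calls, columns=cols)
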