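"""Nucleotide diversity, Watterson's theta and Tajima's D.

Statistics are computed from per-site alt-allele counts over n haplotypes
(n = 2 x number of diploid samples; unphased calls are valid input because
pi, theta_w and D depend only on allele frequencies, not phase), per
chromosome and in non-overlapping windows (50 kbp by default), with
covered-bases accounting: the per-bp denominators count only bp where every
sample meets the coverage threshold.

Definitions, for S segregating sites and a site with c alt alleles of n:

    pi_site  = 2 c (n - c) / (n (n - 1))        (mean pairwise difference)
    a1       = sum_{i=1}^{n-1} 1/i
    theta_w  = S / a1
    D        = (pi_sum - S/a1) / sqrt(e1 S + e2 S (S - 1))

with e1, e2 the standard normalising constants (Tajima 1989).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CoverageMask, GenotypeMatrix


def harmonic(n_minus_1: int) -> float:
    return float(sum(1.0 / i for i in range(1, n_minus_1 + 1)))


def site_pi(alt_count: int, haplotypes: int) -> float:
    """Unbiased per-site heterozygosity 2c(m-c)/(m(m-1))."""
    m = haplotypes
    if m < 2:
        raise ValueError("need at least 2 haplotypes")
    c = alt_count
    if not 0 <= c <= m:
        raise ValueError(f"alt count {c} outside 0..{m}")
    return 2.0 * c * (m - c) / (m * (m - 1))


def tajima_constants(n: int) -> dict:
    if n < 2:
        raise ValueError("need n >= 2 haplotypes")
    a1 = harmonic(n - 1)
    a2 = float(sum(1.0 / i**2 for i in range(1, n)))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def tajima_d(S: int, pi_sum: float, n: int) -> float:
    """Tajima's D; NaN when S == 0 or the variance term degenerates."""
    if S <= 0:
        return math.nan
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi_sum - S / k["a1"]) / math.sqrt(var)


@dataclass
class WindowStat:
    chrom: str
    start: int  # 0-based half-open
    end: int
    covered_bases: int
    S: int
    pi_sum: float
    theta_w: float
    tajima_d: float

    def per_bp(self, scale: float = 1.0) -> tuple:
        """(pi, theta_w) per covered bp, times ``scale`` (NaN if uncovered)."""
        if self.covered_bases == 0:
            return math.nan, math.nan
        return (
            scale * self.pi_sum / self.covered_bases,
            scale * self.theta_w / self.covered_bases,
        )


def windowed_stats(
    matrix: GenotypeMatrix,
    masks: CoverageMask | None = None,
    window: int = 50_000,
    chrom_lengths: dict | None = None,
    samples: list | None = None,
) -> pd.DataFrame:
    """Per-window S, pi_sum, theta_w and Tajima's D over complete-case sites.

    ``matrix`` should already hold the analysis site set (e.g. complete-case
    polymorphic SNPs). ``covered_bases`` counts bp where every selected
    sample is covered; without masks it equals the window width.
    """
    if samples is not None:
        matrix = matrix.select_samples(samples)
    n_hap = 2 * matrix.n_samples
    if chrom_lengths is None:
        if masks is not None:
            chrom_lengths = dict(masks.chrom_lengths)
        else:
            chrom_lengths = (
                matrix.sites.groupby("chrom", sort=False)["pos"].max().astype(int).to_dict()
            )
    alt = matrix.alt_allele_counts()
    seg = (alt > 0) & (alt < n_hap)
    pi_site = np.array([site_pi(int(c), n_hap) for c in alt])
    rows = []
    for chrom, length in chrom_lengths.items():
        on_c = (matrix.sites["chrom"] == chrom).to_numpy()
        pos0 = matrix.sites["pos"].to_numpy()[on_c] - 1
        seg_c = seg[on_c]
        pi_c = pi_site[on_c]
        cov_track = (
            masks.all_samples_track(chrom, matrix.samples)
            if masks is not None
            else np.ones(int(length), dtype=bool)
        )
        for start in range(0, int(length), window):
            end = min(start + window, int(length))
            in_w = (pos0 >= start) & (pos0 < end)
            S = int((seg_c & in_w).sum())
            pi_sum = float(pi_c[in_w & seg_c].sum())
            rows.append(
                WindowStat(
                    chrom=chrom,
                    start=start,
                    end=end,
                    covered_bases=int(cov_track[start:end].sum()),
                    S=S,
                    pi_sum=pi_sum,
                    theta_w=S / tajima_constants(n_hap)["a1"],
                    tajima_d=tajima_d(S, pi_sum, n_hap),
                )
            )
    df = pd.DataFrame([vars(w) for w in rows])
    df["n_haplotypes"] = n_hap
    return df


def chromosome_stats(window_df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate window statistics to the chromosome level.

    Chromosome S and pi_sum are sums over windows; theta_w and D are
    recomputed from the aggregates. Per-bp columns (x1000, a per-kbp
    equivalent) use covered bases as denominator.
    """
    n_hap = int(window_df["n_haplotypes"].iloc[0]) if len(window_df) else 0
    rows = []
    for chrom, grp in window_df.groupby("chrom", sort=False):
        S = int(grp["S"].sum())
        pi_sum = float(grp["pi_sum"].sum())
        covered = int(grp["covered_bases"].sum())
        a1 = tajima_constants(n_hap)["a1"]
        rows.append(
            {
                "chrom": chrom,
                "covered_bases": covered,
                "S": S,
                "pi_sum": pi_sum,
                "theta_w": S / a1,
                "tajima_d": tajima_d(S, pi_sum, n_hap),
                "pi_per_kbp": 1000.0 * pi_sum / covered if covered else math.nan,
                "theta_w_per_kbp": 1000.0 * (S / a1) / covered if covered else math.nan,
            }
        )
    total = {
        "chrom": "genome",
        "covered_bases": int(window_df["covered_bases"].sum()),
        "S": int(window_df["S"].sum()),
        "pi_sum": float(window_df["pi_sum"].sum()),
    }
    if len(window_df):
        a1 = tajima_constants(n_hap)["a1"]
        total["theta_w"] = total["S"] / a1
        total["tajima_d"] = tajima_d(total["S"], total["pi_sum"], n_hap)
        cov = total["covered_bases"]
        total["pi_per_kbp"] = 1000.0 * total["pi_sum"] / cov if cov else math.nan
        total["theta_w_per_kbp"] = 1000.0 * total["theta_w"] / cov if cov else math.nan
        rows.append(total)
    return pd.DataFrame(rows)


def write_bedgraph(window_df: pd.DataFrame, column: str, path) -> None:
    with open(path, "w") as fh:
        for _, row in window_df.iterrows():
            v = row[column]
            if isinstance(v, float) and math.isnan(v):
                v = "NA"
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{v}\n")
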