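"""Variant-density region classification, coverage-aware.

Windows of the genome are classified from the full clone-vs-reference
variant set: very-low-variability windows (<= 1 SNP/kbp — candidate
identity-by-descent tracts with the reference lineage), very-high windows
(>= 1 SNP per 50 bp, i.e. 20/kbp), and the INDEL analogues (< 0.2 and
> 2 INDEL/kbp). Rates are computed over covered bases so coverage holes do
not masquerade as low-variability regions, and a rank correlation between
per-window variant counts and low-coverage bp checks that density structure
is not a coverage artefact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CoverageMask, GenotypeMatrix

LOW_SNP_RATE = 1.0  # SNP per kbp, inclusive upper bound for LOW
HIGH_SNP_RATE = 20.0  # SNP per kbp (1 per 50 bp), inclusive lower bound for HIGH
LOW_INDEL_RATE = 0.2
HIGH_INDEL_RATE = 2.0


@dataclass
class DensityRegion:
    chrom: str
    start: int  # 0-based half-open
    end: int
    region_class: str  # LOW | HIGH | LOW_INDEL | HIGH_INDEL
    variant_count: int
    rate_per_kbp: float


def classify_windows(
    matrix: GenotypeMatrix,
    masks: CoverageMask | None = None,
    window: int = 50_000,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Per-window SNP/INDEL rates over covered bases, with class labels.

    Returns one row per window with snp_class / indel_class in
    {LOW, NORMAL, HIGH, UNCLASSIFIED}; UNCLASSIFIED marks windows with zero
    covered bases.
    """
    if chrom_lengths is None:
        chrom_lengths = (
            dict(masks.chrom_lengths)
            if masks is not None
            else matrix.sites.groupby("chrom", sort=False)["pos"].max().astype(int).to_dict()
        )
    vtype = matrix.sites["vtype"].to_numpy()
    rows = []
    for chrom, length in chrom_lengths.items():
        on_c = (matrix.sites["chrom"] == chrom).to_numpy()
        pos0 = matrix.sites["pos"].to_numpy()[on_c] - 1
        is_snp = vtype[on_c] == "SNP"
        if masks is not None:
            # callable bp: covered in >= 1 sample (variants can be called
            # wherever any sample has depth); per-sample low-coverage bp are
            # summed for the coverage-independence check
            n_mask_samples = len(masks.intervals)
            cov_count = masks.coverage_count_track(chrom)
            cov = cov_count > 0
        else:
            n_mask_samples = 1
            cov_count = np.ones(int(length), dtype=np.int16)
            cov = np.ones(int(length), dtype=bool)
        for start in range(0, int(length), window):
            end = min(start + window, int(length))
            in_w = (pos0 >= start) & (pos0 < end)
            n_snp = int((in_w & is_snp).sum())
            n_indel = int((in_w & ~is_snp).sum())
            covered = int(cov[start:end].sum())
            low_cov_sum = int(
                n_mask_samples * (end - start) - cov_count[start:end].sum()
            )
            if covered == 0:
                snp_rate = indel_rate = np.nan
                snp_class = indel_class = "UNCLASSIFIED"
            else:
                snp_rate = n_snp / (covered / 1000.0)
                indel_rate = n_indel / (covered / 1000.0)
                snp_class = (
                    "LOW"
                    if snp_rate <= LOW_SNP_RATE
                    else "HIGH"
                    if snp_rate >= HIGH_SNP_RATE
                    else "NORMAL"
                )
                indel_class = (
                    "LOW"
                    if indel_rate < LOW_INDEL_RATE
                    else "HIGH"
                    if indel_rate > HIGH_INDEL_RATE
                    else "NORMAL"
                )
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "covered_bases": covered,
                    "low_coverage_bases": low_cov_sum,
                    "n_snp": n_snp,
                    "n_indel": n_indel,
                    "snp_rate_per_kbp": snp_rate,
                    "indel_rate_per_kbp": indel_rate,
                    "snp_class": snp_class,
                    "indel_class": indel_class,
                }
            )
    return pd.DataFrame(rows)


def merge_regions(window_df: pd.DataFrame, column: str, target_class: str) -> list:
    """Merge adjacent same-class windows into maximal DensityRegion runs."""
    regions = []
    count_col = "n_indel" if column == "indel_class" else "n_snp"
    for chrom, grp in window_df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        current = None
        for _, row in grp.iterrows():
            if row[column] == target_class:
                if current is not None and current.end == row["start"]:
                    current.end = int(row["end"])
                    current.variant_count += int(row[count_col])
                else:
                    if current is not None:
                        regions.append(current)
                    current = DensityRegion(
                        chrom=chrom,
                        start=int(row["start"]),
                        end=int(row["end"]),
                        region_class=target_class,
                        variant_count=int(row[count_col]),
                        rate_per_kbp=float(row["snp_rate_per_kbp"])
                        if column == "snp_class"
                        else float(row["indel_rate_per_kbp"]),
                    )
            else:
                if current is not None:
                    regions.append(current)
                    current = None
        if current is not None:
            regions.append(current)
    return regions


def class_totals_mbp(window_df: pd.DataFrame) -> dict:
    """Total extent (Mbp) of each SNP and INDEL density class."""
    out = {}
    for column, prefix in (("snp_class", "snp"), ("indel_class", "indel")):
        for cls in ("LOW", "NORMAL", "HIGH"):
            sel = window_df[window_df[column] == cls]
            out[f"{prefix}_{cls}_mbp"] = float((sel["end"] - sel["start"]).sum() / 1e6)
    return out


def density_coverage_independence(
    window_df: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Spearman rho between per-window variant count and low-coverage bp,
    with a permutation p-value. Constant inputs give NaN."""
    counts = (window_df["n_snp"] + window_df["n_indel"]).to_numpy(float)
    lowcov = window_df["low_coverage_bases"].to_numpy(float)
    if len(counts) < 3 or np.ptp(counts) == 0 or np.ptp(lowcov) == 0:
        return {"rho": float("nan"), "p_value": float("nan"), "n_windows": len(counts)}
    rho = stats.spearmanr(counts, lowcov).statistic
    rng = np.random.default_rng(seed)
    r_counts = stats.rankdata(counts)
    r_low = stats.rankdata(lowcov)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(r_low)
        r = np.corrcoef(r_counts, perm)[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    return {
        "rho": float(rho),
        "p_value": (hits + 1) / (n_permutations + 1),
        "n_windows": len(counts),
    }
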