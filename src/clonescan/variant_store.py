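"""Post-calling filter cascade for multi-sample variant sets.

The cascade mirrors a conventional hard-filtering recipe for joint-genotyped
short variants on a clonal panel, applied in a fixed order:

1. site quality   — per-genotype DP < 5 masks that genotype to missing; a
                    site is removed when its summed DP < 5 or its QD < 20
                    (or the QD annotation is absent).
2. biallelic      — only records with exactly one ALT allele are kept.
3. SNP near INDEL — SNPs within 15 bp (POS-to-POS, inclusive) of any INDEL
                    present in the incoming record set are removed.
4. INDEL rules    — INDELs longer than 100 bp are removed; then every INDEL
                    closer than 50 bp to another INDEL is removed (both
                    members of a too-close pair go).
5. missingness    — sites with missing genotypes in more than half of the
                    samples are removed.

Each record is attributed to the FIRST stage that rejects it, so the
:class:`FilterReport` counts are conserved: input = retained + sum(removed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import GenotypeMatrix, MISSING
from .vcfio import read_vcf, write_vcf  # noqa: F401  (re-exported module surface)

DEFAULT_MIN_DP = 5
DEFAULT_MIN_QD = 20.0
DEFAULT_SNP_INDEL_WINDOW = 15
DEFAULT_INDEL_MIN_GAP = 50
DEFAULT_INDEL_MAX_LEN = 100
DEFAULT_MAX_MISSING_FRACTION = 0.5


@dataclass
class FilterReport:
    """Per-stage removal counts for one cascade run."""

    input: int = 0
    dp_fail: int = 0
    qd_fail: int = 0
    multiallelic: int = 0
    snp_near_indel: int = 0
    indel_too_long: int = 0
    indel_spacing: int = 0
    missingness: int = 0
    retained: int = 0
    genotypes_masked_low_dp: int = 0
    qd_missing: int = 0

    _STAGES = (
        "dp_fail",
        "qd_fail",
        "multiallelic",
        "snp_near_indel",
        "indel_too_long",
        "indel_spacing",
        "missingness",
    )

    def conserved(self) -> bool:
        return self.input == self.retained + sum(getattr(self, s) for s in self._STAGES)

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            **{s: getattr(self, s) for s in self._STAGES},
            "retained": self.retained,
            "genotypes_masked_low_dp": self.genotypes_masked_low_dp,
        }

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tcount\n")
            for k, v in self.to_dict().items():
                fh.write(f"{k}\t{v}\n")


def indel_lengths(matrix: GenotypeMatrix) -> np.ndarray:
    ref_len = matrix.sites["ref"].str.len().to_numpy()
    alt_len = matrix.sites["alt"].str.len().to_numpy()
    return np.abs(alt_len - ref_len)


def filter_site_quality(
    matrix: GenotypeMatrix,
    min_dp: int = DEFAULT_MIN_DP,
    min_qd: float = DEFAULT_MIN_QD,
    report: FilterReport | None = None,
) -> GenotypeMatrix:
    """Mask low-depth genotypes and drop low-quality sites.

    A genotype with DP < ``min_dp`` is set to missing. A site is removed when
    its summed depth over samples is below ``min_dp`` or its QD is below
    ``min_qd``; sites lacking the QD annotation are rejected (counted under
    ``qd_missing``) with a warning.
    """
    report = report if report is not None else FilterReport()
    gt = matrix.gt.copy()
    low_dp = (matrix.dp < min_dp) & (gt != MISSING)
    report.genotypes_masked_low_dp += int(low_dp.sum())
    gt[low_dp] = MISSING
    masked = GenotypeMatrix(matrix.samples, matrix.sites, gt, matrix.dp)

    dp_site = matrix.dp.sum(axis=1)
    dp_ok = dp_site >= min_dp
    qd = matrix.sites["qd"].to_numpy()
    qd_missing = np.isnan(qd)
    if qd_missing.any():
        warnings.warn(
            f"{int(qd_missing.sum())} record(s) lack the QD annotation and were rejected",
            stacklevel=2,
        )
    qd_ok = ~qd_missing & (qd >= min_qd)
    report.dp_fail += int((~dp_ok).sum())
    report.qd_fail += int((dp_ok & ~qd_ok).sum())
    report.qd_missing += int((dp_ok & qd_missing).sum())
    return masked.select_sites(dp_ok & qd_ok)


def filter_biallelic(matrix: GenotypeMatrix, report: FilterReport | None = None) -> GenotypeMatrix:
    """Keep only records with exactly one ALT allele."""
    report = report if report is not None else FilterReport()
    keep = ~matrix.sites["alt"].str.contains(",").to_numpy()
    report.multiallelic += int((~keep).sum())
    return matrix.select_sites(keep)


def filter_snp_near_indel(
    matrix: GenotypeMatrix,
    window_bp: int = DEFAULT_SNP_INDEL_WINDOW,
    report: FilterReport | None = None,
) -> GenotypeMatrix:
    """Remove SNPs within ``window_bp`` of any INDEL in the incoming set.

    Distance is measured POS-to-POS, boundary inclusive (a SNP exactly
    ``window_bp`` away is removed). The INDEL reference set is the record set
    as given, before any INDEL-specific filtering.
    """
    report = report if report is not None else FilterReport()
    vtype = matrix.sites["vtype"].to_numpy()
    chrom = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    keep = np.ones(matrix.n_sites, dtype=bool)
    for c in np.unique(chrom):
        on_c = chrom == c
        indel_pos = np.sort(pos[on_c & (vtype == "INDEL")])
        if indel_pos.size == 0:
            continue
        snp_idx = np.flatnonzero(on_c & (vtype == "SNP"))
        snp_pos = pos[snp_idx]
        left = np.searchsorted(indel_pos, snp_pos - window_bp, side="left")
        right = np.searchsorted(indel_pos, snp_pos + window_bp, side="right")
        keep[snp_idx[right > left]] = False
    report.snp_near_indel += int((~keep).sum())
    return matrix.select_sites(keep)


def filter_indel_rules(
    matrix: GenotypeMatrix,
    min_gap: int = DEFAULT_INDEL_MIN_GAP,
    max_len: int = DEFAULT_INDEL_MAX_LEN,
    report: FilterReport | None = None,
) -> GenotypeMatrix:
    """Apply INDEL length and spacing rules.

    INDELs with |len(alt) - len(ref)| > ``max_len`` are removed first; then
    any surviving INDEL whose nearest INDEL neighbour on the same chromosome
    is closer than ``min_gap`` bp (POS-to-POS) is removed — both members of a
    too-close pair. A pair exactly ``min_gap`` apart is retained.
    """
    report = report if report is not None else FilterReport()
    vtype = matrix.sites["vtype"].to_numpy()
    is_indel = vtype == "INDEL"
    too_long = is_indel & (indel_lengths(matrix) > max_len)
    report.indel_too_long += int(too_long.sum())
    matrix = matrix.select_sites(~too_long)

    vtype = matrix.sites["vtype"].to_numpy()
    chrom = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    keep = np.ones(matrix.n_sites, dtype=bool)
    for c in np.unique(chrom):
        idx = np.flatnonzero((chrom == c) & (vtype == "INDEL"))
        if idx.size < 2:
            continue
        order = np.argsort(pos[idx], kind="stable")
        idx = idx[order]
        p = pos[idx]
        gap = np.diff(p)
        close = gap < min_gap
        bad = np.zeros(idx.size, dtype=bool)
        bad[:-1] |= close
        bad[1:] |= close
        keep[idx[bad]] = False
    report.indel_spacing += int((~keep).sum())
    return matrix.select_sites(keep)


def filter_missingness(
    matrix: GenotypeMatrix,
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
    report: FilterReport | None = None,
) -> GenotypeMatrix:
    """Remove sites with missing genotypes in more than half the samples.

    Strictly "above": with 8 samples, 4 missing is kept, 5 is removed.
    """
    report = report if report is not None else FilterReport()
    n_missing = (matrix.gt == MISSING).sum(axis=1)
    keep = n_missing <= max_missing_fraction * matrix.n_samples
    report.missingness += int((~keep).sum())
    return matrix.select_sites(keep)


def apply_filter_cascade(
    matrix: GenotypeMatrix,
    min_dp: int = DEFAULT_MIN_DP,
    min_qd: float = DEFAULT_MIN_QD,
    snp_indel_window: int = DEFAULT_SNP_INDEL_WINDOW,
    indel_min_gap: int = DEFAULT_INDEL_MIN_GAP,
    indel_max_len: int = DEFAULT_INDEL_MAX_LEN,
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the full fixed-order cascade and return (filtered, report)."""
    report = FilterReport(input=matrix.n_sites)
    m = matrix.sort()
    m = filter_site_quality(m, min_dp, min_qd, report)
    m = filter_biallelic(m, report)
    m = filter_snp_near_indel(m, snp_indel_window, report)
    m = filter_indel_rules(m, indel_min_gap, indel_max_len, report)
    m = filter_missingness(m, max_missing_fraction, report)
    report.retained = m.n_sites
    assert report.conserved(), "filter report counts not conserved"
    return m, report
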