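"""Core in-memory containers shared across the pipeline.

The central object is :class:`GenotypeMatrix`, a samples x sites table of
unphased diploid genotype calls with per-site metadata (chromosome, position,
alleles, variant type, quality-by-depth) and per-genotype sequencing depth.
Genotypes are stored as small integer codes so that every downstream
operation (filtering, clonal classification, diversity statistics, kinship)
is a vectorised numpy expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# genotype codes
HOMREF = 0
HET = 1
HOMALT = 2
MISSING = -1

GT_CODES = {"homref": HOMREF, "het": HET, "homalt": HOMALT, "missing": MISSING}

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "vtype", "qd"]


def variant_type(ref: str, alt: str) -> str:
    """SNP iff both alleles are single bases; otherwise INDEL.

    Multiallelic ALT strings (comma-separated) are labelled "MULTI"; they are
    only ever seen upstream of the biallelic filter.
    """
    if "," in alt:
        return "MULTI"
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    return "INDEL"


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for a sample panel over a set of variant sites.

    Attributes
    ----------
    samples : list of str
        Sample names, in column order.
    sites : pandas.DataFrame
        One row per site with columns chrom, pos (1-based), ref, alt, vtype
        (SNP/INDEL/MULTI) and qd (site-level quality by depth; NaN if the
        annotation is absent).
    gt : ndarray of int8, shape (n_sites, n_samples)
        Genotype codes: 0 homref, 1 het, 2 homalt, -1 missing.
    dp : ndarray of int32, shape (n_sites, n_samples)
        Per-genotype sequencing depth.
    """

    samples: list
    sites: pd.DataFrame
    gt: np.ndarray
    dp: np.ndarray

    def __post_init__(self):
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.dp = np.asarray(self.dp, dtype=np.int32)
        if self.gt.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"gt shape {self.gt.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if self.dp.shape != self.gt.shape:
            raise ValueError("dp shape does not match gt shape")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, names) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.samples)}
        return np.array([idx[n] for n in names], dtype=int)

    def select_sites(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.loc[mask].reset_index(drop=True)
            if mask.dtype == bool
            else self.sites.iloc[mask].reset_index(drop=True),
            gt=self.gt[mask],
            dp=self.dp[mask],
        )

    def select_samples(self, names) -> "GenotypeMatrix":
        cols = self.sample_index(names)
        return GenotypeMatrix(
            samples=list(names),
            sites=self.sites.copy().reset_index(drop=True),
            gt=self.gt[:, cols],
            dp=self.dp[:, cols],
        )

    def missing_mask(self) -> np.ndarray:
        return self.gt == MISSING

    def complete_mask(self) -> np.ndarray:
        """Boolean per-site mask: valid genotype in every sample."""
        return ~self.missing_mask().any(axis=1)

    def alt_allele_counts(self) -> np.ndarray:
        """Per-site count of ALT alleles over non-missing genotypes.

        het contributes 1, homalt contributes 2; missing contributes 0 (use
        :meth:`complete_mask` first when a constant haplotype count matters).
        """
        g = self.gt
        return ((g == HET).sum(axis=1) + 2 * (g == HOMALT).sum(axis=1)).astype(int)

    def sort(self) -> "GenotypeMatrix":
        order = np.lexsort((self.sites["pos"].to_numpy(), self.sites["chrom"].to_numpy()))
        if np.array_equal(order, np.arange(self.n_sites)):
            return self
        return self.select_sites(order)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and np.array_equal(self.gt, other.gt)
            and self.sites[["chrom", "pos", "ref", "alt"]].equals(
                other.sites[["chrom", "pos", "ref", "alt"]]
            )
        )


@dataclass
class CoverageMask:
    """Per-sample covered intervals (>= depth threshold), 0-based half-open.

    intervals: dict sample -> dict chrom -> ndarray of shape (k, 2).
    """

    chrom_lengths: dict
    intervals: dict = field(default_factory=dict)

    def bool_track(self, sample: str, chrom: str) -> np.ndarray:
        track = np.zeros(self.chrom_lengths[chrom], dtype=bool)
        for start, end in self.intervals.get(sample, {}).get(chrom, []):
            track[int(start) : int(end)] = True
        return track

    def all_samples_track(self, chrom: str, samples=None) -> np.ndarray:
        """bp where every (selected) sample is covered."""
        samples = samples if samples is not None else list(self.intervals)
        track = np.ones(self.chrom_lengths[chrom], dtype=bool)
        for s in samples:
            track &= self.bool_track(s, chrom)
        return track

    def any_sample_track(self, chrom: str, samples=None) -> np.ndarray:
        """bp covered (callable) in at least one selected sample."""
        samples = samples if samples is not None else list(self.intervals)
        track = np.zeros(self.chrom_lengths[chrom], dtype=bool)
        for s in samples:
            track |= self.bool_track(s, chrom)
        return track

    def coverage_count_track(self, chrom: str, samples=None) -> np.ndarray:
        """Per-bp count of covered samples."""
        samples = samples if samples is not None else list(self.intervals)
        track = np.zeros(self.chrom_lengths[chrom], dtype=np.int16)
        for s in samples:
            track += self.bool_track(s, chrom)
        return track


def intervals_from_bool(track: np.ndarray) -> np.ndarray:
    """Convert a boolean bp track to (k, 2) 0-based half-open intervals."""
    if track.size == 0:
        return np.empty((0, 2), dtype=int)
    padded = np.concatenate([[False], track, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return np.column_stack([starts, ends])


def write_bed(intervals_by_chrom: dict, path, name=None) -> None:
    """Write {chrom: (k,2) array} as 3- or 4-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in intervals_by_chrom:
            for start, end in intervals_by_chrom[chrom]:
                if name is None:
                    fh.write(f"{chrom}\t{int(start)}\t{int(end)}\n")
                else:
                    fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{name}\n")


def read_bed(path) -> dict:
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            out.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    return {c: np.array(v, dtype=int) for c, v in out.items()}
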