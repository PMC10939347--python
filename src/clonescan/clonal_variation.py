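"""Clone-level (intra-varietal) variant classification.

Separates variation of the panel against the reference ("varietal", shared by
all clones) from variation among the clones themselves: a site is polymorphic
when at least one clone carries a different unphased genotype call than the
rest, and clone-unique when exactly one clone diverges from the (identical)
genotype of all the others — e.g. one clone 0/1 against seven clones 1/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, HOMREF, MISSING
from .summaries import percent


def polymorphic_mask(matrix: GenotypeMatrix, require_complete: bool = True) -> np.ndarray:
    """Per-site boolean mask of polymorphic sites among the samples.

    A site is polymorphic when it shows >= 2 distinct non-missing genotype
    calls. With ``require_complete`` (the default) sites with any missing
    call are excluded first, matching a no-missing-data analysis set.
    """
    gt = matrix.gt
    valid = gt != MISSING
    if require_complete:
        complete = valid.all(axis=1)
    else:
        complete = valid.any(axis=1)
    lo = np.where(valid, gt, np.int8(127)).min(axis=1)
    hi = np.where(valid, gt, np.int8(-128)).max(axis=1)
    return complete & (hi > lo)


def polymorphic_sites(matrix: GenotypeMatrix, require_complete: bool = True) -> GenotypeMatrix:
    return matrix.select_sites(polymorphic_mask(matrix, require_complete))


def varietal_mask(matrix: GenotypeMatrix, require_complete: bool = True) -> np.ndarray:
    """Sites where every clone carries the same non-reference genotype."""
    gt = matrix.gt
    valid = gt != MISSING
    complete = valid.all(axis=1) if require_complete else valid.any(axis=1)
    lo = np.where(valid, gt, np.int8(127)).min(axis=1)
    hi = np.where(valid, gt, np.int8(-128)).max(axis=1)
    return complete & (hi == lo) & (hi > HOMREF)


@dataclass
class CloneUniqueSet:
    """Clone -> table of sites where only that clone's genotype diverges."""

    samples: list
    sites: dict = field(default_factory=dict)  # clone -> DataFrame(chrom, pos, vtype, ...)

    def counts(self) -> dict:
        return {c: len(df) for c, df in self.sites.items()}

    def total(self) -> int:
        return sum(self.counts().values())

    def all_sites(self) -> pd.DataFrame:
        frames = [df.assign(clone=c) for c, df in self.sites.items() if len(df)]
        if not frames:
            return pd.DataFrame(columns=["chrom", "pos", "vtype", "clone"])
        return pd.concat(frames, ignore_index=True)

    def write_beds(self, outdir) -> list:
        """One BED of single-bp intervals (0-based half-open) per clone."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for clone, df in self.sites.items():
            p = outdir / f"unique_{clone}.bed"
            with open(p, "w") as fh:
                for _, row in df.iterrows():
                    fh.write(f"{row['chrom']}\t{row['pos'] - 1}\t{row['pos']}\t{clone}\n")
            paths.append(p)
        return paths


def clone_unique_variants(matrix: GenotypeMatrix) -> CloneUniqueSet:
    """Assign complete-case polymorphic sites to the single divergent clone.

    A site belongs to clone c iff c's genotype differs from all other clones
    AND the other clones are mutually identical. Sites with two or more
    distinct minority genotypes are polymorphic but unique to nobody.
    """
    mask = polymorphic_mask(matrix, require_complete=True)
    sub = matrix.select_sites(mask)
    gt = sub.gt
    out = CloneUniqueSet(samples=list(matrix.samples))
    owner = np.full(sub.n_sites, -1, dtype=int)
    if sub.n_sites:
        counts = np.stack([(gt == v).sum(axis=1) for v in (0, 1, 2)], axis=1)
        n_distinct = (counts > 0).sum(axis=1)
        # exactly two genotype values, one carried by a single sample
        two_vals = n_distinct == 2
        minority_one = (counts == 1).any(axis=1) & two_vals
        idx = np.flatnonzero(minority_one)
        for i in idx:
            minority_value = int(np.flatnonzero(counts[i] == 1)[0])
            owner[i] = int(np.flatnonzero(gt[i] == minority_value)[0])
    for j, clone in enumerate(matrix.samples):
        sel = owner == j
        out.sites[clone] = sub.sites.loc[sel, ["chrom", "pos", "vtype"]].reset_index(drop=True)
    return out


@dataclass
class SharingSpectrum:
    """Non-reference sharing and missingness spectra over the site set."""

    n_samples: int
    sharing: dict  # k -> number of sites with non-ref genotype in exactly k samples
    missingness: dict  # m -> number of sites with a valid genotype in exactly m samples
    total_sites: int

    def sharing_percent(self, k: int) -> float:
        return percent(self.sharing.get(k, 0), self.total_sites)

    def complete_fraction_percent(self) -> float:
        return percent(self.missingness.get(self.n_samples, 0), self.total_sites)

    def at_least(self, m: int) -> int:
        return sum(v for mm, v in self.missingness.items() if mm >= m)

    def at_least_percent(self, m: int) -> float:
        return percent(self.at_least(m), self.total_sites)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(self.n_samples + 1):
            rows.append(
                {
                    "k": k,
                    "sites_nonref_in_k": self.sharing.get(k, 0),
                    "sites_valid_in_k": self.missingness.get(k, 0),
                }
            )
        return pd.DataFrame(rows)


def sharing_and_missingness(matrix: GenotypeMatrix) -> SharingSpectrum:
    """Exact per-k counts of non-reference carriers and valid genotypes."""
    gt = matrix.gt
    valid = gt != MISSING
    nonref = (gt > HOMREF) & valid
    k_nonref = nonref.sum(axis=1)
    m_valid = valid.sum(axis=1)
    sharing = {int(k): int(c) for k, c in zip(*np.unique(k_nonref, return_counts=True))}
    missing = {int(m): int(c) for m, c in zip(*np.unique(m_valid, return_counts=True))}
    spec = SharingSpectrum(
        n_samples=matrix.n_samples,
        sharing=sharing,
        missingness=missing,
        total_sites=matrix.n_sites,
    )
    assert sum(sharing.values()) == matrix.n_sites
    assert sum(missing.values()) == matrix.n_sites
    return spec


def per_window_unique_density(
    unique: CloneUniqueSet,
    chrom_lengths: dict,
    window: int = 1_000_000,
    stride: int | None = None,
) -> pd.DataFrame:
    """Per-clone unique-variant counts in genomic windows.

    Windows tumble by default (stride == window); pass a smaller stride for
    sliding windows. Returns a tidy frame: chrom, start, end, clone, count,
    per_mbp.
    """
    stride = stride or window
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, max(length, 1), stride)
        for clone, df in unique.sites.items():
            pos = df.loc[df["chrom"] == chrom, "pos"].to_numpy() - 1  # 0-based
            for s in starts:
                e = min(s + window, length)
                count = int(((pos >= s) & (pos < e)).sum())
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(s),
                        "end": int(e),
                        "clone": clone,
                        "count": count,
                        "per_mbp": count / ((e - s) / 1e6) if e > s else np.nan,
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "clone", "count", "per_mbp"])
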