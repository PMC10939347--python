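"""VCF 4.2 reading and writing for :class:`~clonescan.core.GenotypeMatrix`.

All parsing and serialisation is delegated to pysam; this module only maps
between VCF records and the integer-coded genotype matrix.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pysam

from .core import GenotypeMatrix, HET, HOMALT, HOMREF, MISSING, variant_type


def _code_genotype(gt_tuple) -> int:
    if gt_tuple is None or any(a is None for a in gt_tuple):
        return MISSING
    non_ref = sum(1 for a in gt_tuple if a != 0)
    if non_ref == 0:
        return HOMREF
    if non_ref == len(gt_tuple):
        return HOMALT
    return HET


def read_vcf(path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a GenotypeMatrix.

    Per-sample GT and DP are required; site QD is read from INFO (NaN when
    absent). Multiallelic records are kept with a comma-joined ALT string and
    vtype "MULTI" so the biallelic filter stage can count them.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, gts, dps = [], [], []
    for rec in vf:
        alts = rec.alts or ()
        alt = ",".join(alts) if alts else "."
        qd = rec.info.get("QD", None)
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": alt,
                "vtype": variant_type(rec.ref, alt),
                "qd": float(qd) if qd is not None else math.nan,
            }
        )
        gts.append([_code_genotype(rec.samples[s].get("GT")) for s in samples])
        dp_row = []
        for s in samples:
            dp = rec.samples[s].get("DP")
            dp_row.append(int(dp) if dp is not None else 0)
        dps.append(dp_row)
    vf.close()
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vtype", "qd"])
    n = len(samples)
    gt = np.array(gts, dtype=np.int8).reshape(len(rows), n)
    dp = np.array(dps, dtype=np.int32).reshape(len(rows), n)
    return GenotypeMatrix(samples=samples, sites=sites, gt=gt, dp=dp)


_GT_TUPLES = {
    HOMREF: (0, 0),
    HET: (0, 1),
    HOMALT: (1, 1),
    MISSING: (None, None),
}


def write_vcf(matrix: GenotypeMatrix, path, chrom_lengths: dict | None = None) -> None:
    """Write a GenotypeMatrix as a sorted VCF 4.2 file.

    Emits per-sample GT and DP and site-level QD in INFO. Positions are
    written 1-based and sorted within each chromosome (input is sorted first
    if needed). Missing genotypes become "./.".
    """
    if matrix.n_sites == 0 and not matrix.samples:
        raise ValueError("refusing to write an empty matrix with no samples")
    matrix = matrix.sort()
    header = pysam.VariantHeader()
    chroms = list(dict.fromkeys(matrix.sites["chrom"]))
    if chrom_lengths:
        for c, length in chrom_lengths.items():
            header.contigs.add(c, length=int(length))
        for c in chroms:
            if c not in chrom_lengths:
                header.contigs.add(c)
    else:
        maxpos = matrix.sites.groupby("chrom", sort=False)["pos"].max()
        for c in chroms:
            header.contigs.add(c, length=int(maxpos[c]) + 1000)
    header.info.add("QD", 1, "Float", "Variant call quality by depth")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Approximate read depth")
    for s in matrix.samples:
        header.add_sample(s)
    out = pysam.VariantFile(str(path), "w", header=header)
    sites = matrix.sites
    for i in range(matrix.n_sites):
        row = sites.iloc[i]
        alleles = (row["ref"],) + tuple(str(row["alt"]).split(","))
        rec = out.new_record(contig=row["chrom"], start=int(row["pos"]) - 1, alleles=alleles)
        if not math.isnan(row["qd"]):
            rec.info["QD"] = float(row["qd"])
        for j, s in enumerate(matrix.samples):
            rec.samples[s]["GT"] = _GT_TUPLES[int(matrix.gt[i, j])]
            rec.samples[s].phased = False
            rec.samples[s]["DP"] = int(matrix.dp[i, j])
        out.write(rec)
    out.close()
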