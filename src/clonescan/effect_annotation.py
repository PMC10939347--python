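"""Simplified high-impact variant-effect classification.

Given gene models (ordered CDS segments on a strand) and a reference
sequence, variants are classified into the loss-of-function categories
commonly labelled HIGH impact: stop_gained, stop_lost, start_lost,
frameshift_variant and splice_site_variant. Everything else — missense,
synonymous, intronic, intergenic, in-frame indels — is lumped as "none"
with impact "other". This is a deliberate reduction of a full effect
annotator to the categories a clonal loss-of-function screen reports.

Coordinates: GFF3 is 1-based inclusive on disk and converted to 0-based
half-open internally. Variants use VCF conventions (1-based POS; indels
carry an anchor base, so a deletion of k bases has ref length k+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

HIGH_EFFECTS = {
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift_variant",
    "splice_site_variant",
}

SPLICE_REGION = 2  # bp into the intron on each side of a CDS/intron boundary


@dataclass
class GeneModel:
    """A protein-coding gene: ordered, non-overlapping CDS segments.

    ``cds_segments`` are 0-based half-open intervals in ascending genomic
    order regardless of strand; for minus-strand genes the coding sequence is
    the reverse complement of their concatenation.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: list  # [(start, end), ...] ascending, 0-based half-open

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        segs = sorted((int(a), int(b)) for a, b in self.cds_segments)
        for (a1, b1), (a2, b2) in zip(segs, segs[1:]):
            if a2 < b1:
                raise ValueError(f"overlapping CDS segments in {self.gene_id}")
        if sum(b - a for a, b in segs) == 0:
            raise ValueError(f"empty CDS in {self.gene_id}")
        self.cds_segments = segs

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds_segments)

    @property
    def span(self) -> tuple:
        return self.cds_segments[0][0], self.cds_segments[-1][1]

    def phases(self) -> list:
        """GFF3 phase per segment, in translation order."""
        out, done = [], 0
        for a, b in self.cds_segments if self.strand == "+" else self.cds_segments[::-1]:
            out.append((3 - done % 3) % 3)
            done += b - a
        return out if self.strand == "+" else out[::-1]

    def coding_sequence(self, chrom_seq: str) -> str:
        spliced = "".join(chrom_seq[a:b] for a, b in self.cds_segments)
        if self.strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
        return spliced

    def genomic_to_cds(self, pos0: int) -> int | None:
        """Map a 0-based genomic position to a 0-based coding coordinate."""
        offset = 0
        for a, b in self.cds_segments:
            if a <= pos0 < b:
                idx = offset + (pos0 - a)
                if self.strand == "-":
                    idx = self.cds_length - 1 - idx
                return idx
            offset += b - a
        return None


@dataclass
class EffectCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    effect: str
    impact: str  # HIGH | other
    flagged: bool = False  # conservative call at a partially overlapped edge

    def as_row(self) -> dict:
        return {
            "chrom": self.chrom,
            "pos": self.pos,
            "ref": self.ref,
            "alt": self.alt,
            "gene_id": self.gene_id,
            "effect": self.effect,
            "impact": self.impact,
            "flagged": self.flagged,
        }


def read_gff3(path) -> list:
    """Load gene models (CDS features grouped by parent) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for gene in db.features_of_type(("gene",)):
        cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                cds_segments=[(c.start - 1, c.end) for c in cds],
            )
        )
    return genes


def write_gff3(genes: list, path, chrom_lengths: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for c, length in chrom_lengths.items():
                fh.write(f"##sequence-region {c} 1 {int(length)}\n")
        for g in genes:
            start, end = g.span
            fh.write(
                f"{g.chrom}\tclonescan\tgene\t{start + 1}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tclonescan\tmRNA\t{start + 1}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for (a, b), phase in zip(g.cds_segments, g.phases()):
                fh.write(
                    f"{g.chrom}\tclonescan\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t{phase}\t"
                    f"ID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
                )


STOPS = {"TAA", "TAG", "TGA"}


def _splice_distance(pos0_lo: int, pos0_hi: int, gene: GeneModel) -> bool:
    """True if [pos0_lo, pos0_hi] touches the first SPLICE_REGION intronic bp
    of an internal CDS boundary."""
    segs = gene.cds_segments
    for i, (a, b) in enumerate(segs):
        if i > 0:  # intron side upstream of this segment
            lo, hi = a - SPLICE_REGION, a - 1
            if pos0_lo <= hi and pos0_hi >= lo:
                return True
        if i < len(segs) - 1:  # intron side downstream
            lo, hi = b, b + SPLICE_REGION - 1
            if pos0_lo <= hi and pos0_hi >= lo:
                return True
    return False


def classify_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    genes: list,
    reference: dict,
) -> list:
    """Classify one normalized variant against every overlapping gene model.

    Returns a (possibly empty) list of :class:`EffectCall`, one per gene whose
    span (plus splice region) the variant touches. SNPs inside CDS are
    translated on the coding strand; indels fully inside a single CDS segment
    are frameshifts when their length is not a multiple of three. A deletion
    partially overlapping a CDS edge is conservatively called
    splice_site_variant with ``flagged=True``.
    """
    calls = []
    pos0 = pos - 1
    is_snp = len(ref) == 1 and len(alt) == 1
    # inclusive genomic footprint of the change
    if is_snp:
        lo, hi = pos0, pos0
    elif len(ref) > len(alt):  # deletion: removed bases follow the anchor
        lo, hi = pos0 + 1, pos0 + len(ref) - 1
    else:  # insertion lands between pos0 and pos0 + 1
        lo, hi = pos0, pos0 + 1
    for gene in genes:
        if gene.chrom != chrom:
            continue
        g_lo, g_hi = gene.span
        if hi < g_lo - SPLICE_REGION or lo > g_hi - 1 + SPLICE_REGION:
            continue
        call = _classify_for_gene(chrom, pos, ref, alt, gene, reference[chrom], is_snp)
        if call is not None:
            calls.append(call)
    return calls


def _classify_for_gene(chrom, pos, ref, alt, gene, chrom_seq, is_snp):
    pos0 = pos - 1
    if is_snp:
        cds_idx = gene.genomic_to_cds(pos0)
        if cds_idx is None:
            if _splice_distance(pos0, pos0, gene):
                return EffectCall(chrom, pos, ref, alt, gene.gene_id, "splice_site_variant", "HIGH")
            return EffectCall(chrom, pos, ref, alt, gene.gene_id, "none", "other")
        cds = gene.coding_sequence(chrom_seq)
        base = alt if gene.strand == "+" else str(Seq(alt).complement())
        codon_i = cds_idx // 3
        within = cds_idx % 3
        codon = cds[3 * codon_i : 3 * codon_i + 3]
        if len(codon) < 3:
            return EffectCall(chrom, pos, ref, alt, gene.gene_id, "none", "other")
        new_codon = codon[:within] + base + codon[within + 1 :]
        if codon_i == 0 and new_codon != "ATG":
            return EffectCall(chrom, pos, ref, alt, gene.gene_id, "start_lost", "HIGH")
        if codon in STOPS and new_codon not in STOPS:
            return EffectCall(chrom, pos, ref, alt, gene.gene_id, "stop_lost", "HIGH")
        if new_codon in STOPS and codon not in STOPS:
            return EffectCall(chrom, pos, ref, alt, gene.gene_id, "stop_gained", "HIGH")
        return EffectCall(chrom, pos, ref, alt, gene.gene_id, "none", "other")

    # indel
    indel_len = abs(len(alt) - len(ref))
    if len(ref) > len(alt):  # deletion: bases pos0+1 .. pos0+len(ref)-1 removed
        lo, hi = pos0 + 1, pos0 + len(ref) - 1
        in_segment = any(a <= lo and hi < b for a, b in gene.cds_segments)
        touches_cds = any(lo < b and hi >= a for a, b in gene.cds_segments)
        if touches_cds and not in_segment:
            return EffectCall(
                chrom, pos, ref, alt, gene.gene_id, "splice_site_variant", "HIGH", flagged=True
            )
        if in_segment:
            if indel_len % 3 != 0:
                return EffectCall(chrom, pos, ref, alt, gene.gene_id, "frameshift_variant", "HIGH")
            return EffectCall(chrom, pos, ref, alt, gene.gene_id, "none", "other")
        if _splice_distance(lo, hi, gene):
            return EffectCall(chrom, pos, ref, alt, gene.gene_id, "splice_site_variant", "HIGH")
        return EffectCall(chrom, pos, ref, alt, gene.gene_id, "none", "other")

    # insertion: lands between pos0 and pos0+1
    inside = any(a <= pos0 < b - 1 for a, b in gene.cds_segments)
    if inside:
        if indel_len % 3 != 0:
            return EffectCall(chrom, pos, ref, alt, gene.gene_id, "frameshift_variant", "HIGH")
        return EffectCall(chrom, pos, ref, alt, gene.gene_id, "none", "other")
    if _splice_distance(pos0, pos0 + 1, gene):
        return EffectCall(chrom, pos, ref, alt, gene.gene_id, "splice_site_variant", "HIGH")
    return EffectCall(chrom, pos, ref, alt, gene.gene_id, "none", "other")


def classify_matrix(matrix, genes: list, reference: dict) -> pd.DataFrame:
    """Classify every site in a GenotypeMatrix; returns a tidy table."""
    rows = []
    for i in range(matrix.n_sites):
        site = matrix.sites.iloc[i]
        for call in classify_variant(
            site["chrom"], int(site["pos"]), site["ref"], site["alt"], genes, reference
        ):
            rows.append(call.as_row())
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "gene_id", "effect", "impact", "flagged"],
    )


def summarize_high_impact(
    calls: pd.DataFrame,
    n_polymorphic_snps: int,
    n_polymorphic_indels: int,
    unique_sites: pd.DataFrame | None = None,
) -> dict:
    """Counts and percentages of HIGH-impact calls among polymorphic variants.

    Percentages are reported to two decimals on the 0-100 scale. If
    ``unique_sites`` (a table with chrom/pos of clone-unique variants) is
    given, HIGH calls restricted to those sites are counted as exclusive.
    """
    from .summaries import percent

    if len(calls) == 0:
        high = calls
    else:
        high = calls[calls["impact"] == "HIGH"]
    high_sites = high.drop_duplicates(subset=["chrom", "pos", "ref", "alt"]) if len(high) else high
    is_snp = (
        (high_sites["ref"].str.len() == 1) & (high_sites["alt"].str.len() == 1)
        if len(high_sites)
        else pd.Series(dtype=bool)
    )
    n_snp = int(is_snp.sum()) if len(high_sites) else 0
    n_indel = len(high_sites) - n_snp
    summary = {
        "high_snps": n_snp,
        "high_indels": n_indel,
        "pct_high_snps": percent(n_snp, n_polymorphic_snps),
        "pct_high_indels": percent(n_indel, n_polymorphic_indels),
        "by_effect": (
            high["effect"].value_counts().to_dict() if len(high) else {}
        ),
    }
    if unique_sites is not None and len(high_sites):
        key = set(zip(unique_sites["chrom"], unique_sites["pos"]))
        excl = high_sites[
            [
                (c, p) in key
                for c, p in zip(high_sites["chrom"], high_sites["pos"])
            ]
        ]
        is_snp_e = (excl["ref"].str.len() == 1) & (excl["alt"].str.len() == 1)
        summary["exclusive_high_snps"] = int(is_snp_e.sum())
        summary["exclusive_high_indels"] = int(len(excl) - is_snp_e.sum())
    return summary
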