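"""Effect classifier: handcrafted cases plus a whole-CDS re-translation oracle."""

import numpy as np
import pytest
from Bio.Seq import Seq

from clonescan.effect_annotation import (
    GeneModel,
    classify_variant,
    read_gff3,
    summarize_high_impact,
    write_gff3,
)

BASES = np.array(list("ACGT"))


def make_gene_reference(cds, strand="+", intron=None, pad=50, seed=0):
    """Assemble a chromosome holding one gene with the given coding sequence.

    With ``intron`` the CDS is split in two segments at the given coding
    offset (kept in frame only by the caller's choice).
    """
    rng = np.random.default_rng(seed)
    genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
    left = "".join(BASES[rng.integers(0, 4, pad)])
    right = "".join(BASES[rng.integers(0, 4, pad)])
    if intron is None:
        chrom_seq = left + genomic + right
        segs = [(pad, pad + len(genomic))]
    else:
        intron_seq = "".join(BASES[rng.integers(0, 4, 80)])
        cut = intron if strand == "+" else len(genomic) - intron
        chrom_seq = left + genomic[:cut] + intron_seq + genomic[cut:] + right
        segs = [(pad, pad + cut), (pad + cut + 80, pad + len(genomic) + 80)]
    gene = GeneModel(gene_id="g1", chrom="chr1", strand=strand, cds_segments=segs)
    return {"chr1": chrom_seq}, gene


CDS = "ATG" + "TGG" + "CCA" + "GAA" + "TTC" + "GGT" + "TAA"  # M W P E F G *


class TestSnpEffects:
    def test_tgg_to_tga_is_stop_gained(self):
        ref, gene = make_gene_reference(CDS)
        # codon 2 TGG, third base at genomic pos0 50+5
        pos = 50 + 5 + 1
        calls = classify_variant("chr1", pos, "G", "A", [gene], ref)
        assert calls[0].effect == "stop_gained"
        assert calls[0].impact == "HIGH"

    def test_terminal_stop_destroyed_is_stop_lost(self):
        ref, gene = make_gene_reference(CDS)
        pos = 50 + len(CDS) - 2  # middle base of TAA (1-based)
        calls = classify_variant("chr1", pos, "A", "C", [gene], ref)
        assert calls[0].effect == "stop_lost"

    def test_atg_disruption_is_start_lost(self):
        ref, gene = make_gene_reference(CDS)
        calls = classify_variant("chr1", 51, "A", "G", [gene], ref)
        assert calls[0].effect == "start_lost"

    def test_synonymous_or_missense_is_other(self):
        ref, gene = make_gene_reference(CDS)
        # GGT -> GGA (glycine, synonymous): codon 6, third base
        pos = 50 + 17 + 1
        calls = classify_variant("chr1", pos, "T", "A", [gene], ref)
        assert calls[0].impact == "other"

    def test_minus_strand_stop_gained(self):
        ref, gene = make_gene_reference(CDS, strand="-")
        # genomic: revcomp(CDS); coding TGG codon third base G is genomic
        # complement at position len-6 within the gene (0-based from right)
        cds_idx = 5  # third base of codon 2 in coding coordinates
        genomic_pos0 = 50 + (len(CDS) - 1 - cds_idx)
        ref_base = ref["chr1"][genomic_pos0]
        assert ref_base == "C"  # complement of G
        calls = classify_variant("chr1", genomic_pos0 + 1, "C", "T", [gene], ref)
        assert calls[0].effect == "stop_gained"


class TestIndelEffects:
    def test_two_bp_deletion_is_frameshift(self):
        ref, gene = make_gene_reference(CDS)
        anchor0 = 50 + 6  # inside CDS, deletion removes bases 8-9 (0-based 7,8)
        r = ref["chr1"][anchor0 : anchor0 + 3]
        calls = classify_variant("chr1", anchor0 + 1, r, r[0], [gene], ref)
        assert calls[0].effect == "frameshift_variant"

    def test_three_bp_inframe_deletion_not_high(self):
        ref, gene = make_gene_reference(CDS)
        anchor0 = 50 + 6
        r = ref["chr1"][anchor0 : anchor0 + 4]
        calls = classify_variant("chr1", anchor0 + 1, r, r[0], [gene], ref)
        assert calls[0].impact == "other"

    def test_insertion_frameshift(self):
        ref, gene = make_gene_reference(CDS)
        anchor0 = 50 + 6
        r = ref["chr1"][anchor0]
        calls = classify_variant("chr1", anchor0 + 1, r, r + "TT", [gene], ref)
        assert calls[0].effect == "frameshift_variant"

    def test_deletion_across_cds_edge_flagged_splice(self):
        ref, gene = make_gene_reference(CDS)
        start = gene.cds_segments[0][0]
        anchor0 = start - 2  # deletion spans the CDS boundary
        r = ref["chr1"][anchor0 : anchor0 + 5]
        calls = classify_variant("chr1", anchor0 + 1, r, r[0], [gene], ref)
        assert calls[0].effect == "splice_site_variant"
        assert calls[0].flagged


class TestSpliceSites:
    def test_intronic_snp_within_2bp_of_boundary(self):
        ref, gene = make_gene_reference(CDS + "GCTGCA" * 10, intron=9)
        seg1_end = gene.cds_segments[0][1]
        for offset in (0, 1):
            pos = seg1_end + offset + 1  # first/second intron base, 1-based
            calls = classify_variant("chr1", pos, ref["chr1"][pos - 1], "A" if ref["chr1"][pos - 1] != "A" else "C", [gene], ref)
            assert calls[0].effect == "splice_site_variant"

    def test_deep_intronic_snp_is_other(self):
        ref, gene = make_gene_reference(CDS + "GCTGCA" * 10, intron=9)
        seg1_end = gene.cds_segments[0][1]
        pos = seg1_end + 10
        calls = classify_variant("chr1", pos, ref["chr1"][pos - 1], "A" if ref["chr1"][pos - 1] != "A" else "C", [gene], ref)
        assert calls[0].impact == "other"


class TestStrandSymmetry:
    def test_reverse_complement_gene_gives_same_calls(self):
        """The same biological variant classified identically on both strands."""
        rng = np.random.default_rng(42)
        ref_f, gene_f = make_gene_reference(CDS, strand="+")
        ref_r, gene_r = make_gene_reference(CDS, strand="-")
        L = len(ref_f["chr1"])
        for _ in range(60):
            cds_idx = int(rng.integers(0, len(CDS)))
            base = "ACGT"[int(rng.integers(0, 4))]
            # + strand variant
            pos_f0 = 50 + cds_idx
            ref_base_f = ref_f["chr1"][pos_f0]
            if ref_base_f == base:
                continue
            calls_f = classify_variant("chr1", pos_f0 + 1, ref_base_f, base, [gene_f], ref_f)
            # equivalent - strand variant: complement base at mirrored position
            pos_r0 = 50 + (len(CDS) - 1 - cds_idx)
            ref_base_r = ref_r["chr1"][pos_r0]
            comp = str(Seq(base).complement())
            calls_r = classify_variant("chr1", pos_r0 + 1, ref_base_r, comp, [gene_r], ref_r)
            assert calls_f[0].effect == calls_r[0].effect


def retranslation_oracle(chrom_seq, gene, pos, ref_allele, alt_allele):
    """Independent protein-level oracle: apply the variant to the chromosome,
    re-extract the (possibly shifted) CDS, translate, and diff the proteins."""
    pos0 = pos - 1
    assert chrom_seq[pos0 : pos0 + len(ref_allele)] == ref_allele
    mutated = chrom_seq[:pos0] + alt_allele + chrom_seq[pos0 + len(ref_allele) :]
    shift = len(alt_allele) - len(ref_allele)
    segs = []
    for a, b in gene.cds_segments:
        # variants fully inside one segment only (guaranteed by the planter)
        if shift and a <= pos0 < b:
            segs.append((a, b + shift))
        elif shift and pos0 < a:
            segs.append((a + shift, b + shift))
        else:
            segs.append((a, b))
    spliced = "".join(mutated[a:b] for a, b in segs)
    if gene.strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
    orig = gene.coding_sequence(chrom_seq)
    prot_orig = str(Seq(orig).translate())
    if shift != 0:
        # indel categories are length-based: out-of-frame is a frameshift,
        # in-frame is not HIGH regardless of codon content
        return "frameshift_variant" if len(spliced) % 3 != 0 else "none_or_other"
    prot_new = str(Seq(spliced).translate())
    if not prot_new.startswith("M"):
        return "start_lost"
    if "*" in prot_new[:-1] and "*" not in prot_orig[:-1]:
        return "stop_gained"
    if prot_orig.endswith("*") and not prot_new.endswith("*"):
        return "stop_lost"
    return "none_or_other"


class TestRetranslationOracle:
    def test_classifier_agrees_on_planted_variants(self):
        """1,000 random planted CDS variants: classifier == protein-diff oracle."""
        from clonescan.clonesim import SimConfig, _random_reference, make_gene_models

        rng = np.random.default_rng(77)
        lengths = {"chr1": 120_000}
        reference = _random_reference(rng, lengths)
        genes = make_gene_models(rng, lengths, reference, spacing=4_000)
        chrom_seq = reference["chr1"]
        n_checked = 0
        agreements = 0
        while n_checked < 1000:
            gene = genes[int(rng.integers(0, len(genes)))]
            seg = gene.cds_segments[int(rng.integers(0, len(gene.cds_segments)))]
            if rng.random() < 0.6:  # SNP
                pos0 = int(rng.integers(seg[0], seg[1]))
                ref_a = chrom_seq[pos0]
                alt_a = "ACGT"[int(rng.integers(0, 4))]
                if alt_a == ref_a:
                    continue
            else:  # small indel fully inside the segment
                ln = int(rng.integers(1, 5))
                if rng.random() < 0.5:
                    pos0 = int(rng.integers(seg[0], seg[1] - ln - 1))
                    ref_a = chrom_seq[pos0 : pos0 + ln + 1]
                    alt_a = ref_a[0]
                else:
                    pos0 = int(rng.integers(seg[0], seg[1] - 1))
                    ref_a = chrom_seq[pos0]
                    alt_a = ref_a + "".join(
                        "ACGT"[int(rng.integers(0, 4))] for _ in range(ln)
                    )
            calls = classify_variant("chr1", pos0 + 1, ref_a, alt_a, [gene], reference)
            assert len(calls) == 1
            got = calls[0].effect
            expected = retranslation_oracle(chrom_seq, gene, pos0 + 1, ref_a, alt_a)
            n_checked += 1
            if expected == "none_or_other":
                agreements += got in ("none",)
            else:
                agreements += got == expected
        assert agreements == n_checked


class TestGff3AndSummary:
    def test_gff3_roundtrip(self, tmp_path):
        _, gene = make_gene_reference(CDS, intron=9)
        path = tmp_path / "g.gff3"
        write_gff3([gene], path, {"chr1": 1000})
        back = read_gff3(path)
        assert len(back) == 1
        assert back[0].strand == gene.strand
        assert back[0].cds_segments == gene.cds_segments

    def test_summary_percentages(self):
        import pandas as pd

        calls = pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 10, "ref": "A", "alt": "T",
                 "gene_id": "g1", "effect": "stop_gained", "impact": "HIGH", "flagged": False},
                {"chrom": "chr1", "pos": 50, "ref": "AT", "alt": "A",
                 "gene_id": "g1", "effect": "frameshift_variant", "impact": "HIGH", "flagged": False},
                {"chrom": "chr1", "pos": 99, "ref": "A", "alt": "G",
                 "gene_id": "g1", "effect": "none", "impact": "other", "flagged": False},
            ]
        )
        s = summarize_high_impact(calls, n_polymorphic_snps=1000, n_polymorphic_indels=200)
        assert s["high_snps"] == 1 and s["high_indels"] == 1
        assert s["pct_high_snps"] == 0.1
        assert s["pct_high_indels"] == 0.5
        assert s["by_effect"]["stop_gained"] == 1

    def test_empty_calls_zero_percent(self):
        import pandas as pd

        calls = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "gene_id", "effect", "impact", "flagged"])
        s = summarize_high_impact(calls, 100, 100)
        assert s["pct_high_snps"] == 0.0
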