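import hashlib
from pathlib import Path

import numpy as np
import pytest

from clonescan.clonesim import (
    SimConfig,
    read_fasta,
    read_te_table,
    simulate_population,
    write_dataset,
    write_te_tables,
)
from clonescan.vcfio import read_vcf


def file_hash(path):
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class TestConfig:
    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(varietal_snp_rate=-1)
        with pytest.raises(ValueError):
            SimConfig(ibd_fraction=1.5)
        with pytest.raises(ValueError):
            SimConfig(chrom_lengths={})

    def test_chrom_lengths_accepts_list(self):
        cfg = SimConfig(chrom_lengths=[1000, 2000])
        assert cfg.chrom_lengths == {"chr1": 1000, "chr2": 2000}


class TestSimulate:
    def test_zero_somatic_rates_no_polymorphism(self):
        from clonescan.clonal_variation import polymorphic_sites

        cfg = SimConfig(
            seed=2,
            chrom_lengths={"chr1": 200_000},
            somatic_rates=[0.0] * 8,
            missing_rate=0.0,
            dropout_fraction=0.0,
            te_counts_by_sharing={1: 3},
        )
        sim = simulate_population(cfg)
        assert polymorphic_sites(sim.matrix).n_sites == 0

    def test_varietal_count_tracks_configured_rate(self):
        """6 Mbp at 7.3 SNP/kbp -> ~43,800 varietal SNPs (Poisson-scale)."""
        cfg = SimConfig(seed=1, outgroup=False)
        sim = simulate_population(cfg)
        snps = sim.truth.varietal_variants.query("vtype == 'SNP'")
        expected = 7.3 * 6000
        assert abs(len(snps) - expected) < 5 * np.sqrt(expected)

    def test_divergent_clone_somatic_count_within_3_sigma(self):
        """Rate 282/Mbp on 6 Mbp -> truth count within 3 sigma of 1692."""
        cfg = SimConfig(seed=7, outgroup=False, te_counts_by_sharing={1: 5})
        sim = simulate_population(cfg)
        count = len(sim.truth.somatic_variants["C01"])
        mean = 282 * 6.0
        assert abs(count - mean) <= 3 * np.sqrt(mean)

    def test_somatic_variants_private_and_het(self):
        cfg = SimConfig(
            seed=4,
            chrom_lengths={"chr1": 200_000},
            missing_rate=0.0,
            dropout_fraction=0.0,
            te_counts_by_sharing={1: 3},
        )
        sim = simulate_population(cfg)
        m = sim.matrix
        key = {(c, p) for c, p in zip(m.sites["chrom"], m.sites["pos"])}
        seen = set()
        for clone, df in sim.truth.somatic_variants.items():
            ci = m.samples.index(clone)
            for chrom, pos in zip(df["chrom"], df["pos"]):
                assert (chrom, pos) in key
                assert (chrom, pos) not in seen  # in exactly one clone's list
                seen.add((chrom, pos))
                i = m.sites.index[(m.sites["chrom"] == chrom) & (m.sites["pos"] == pos)][0]
                assert m.gt[i, ci] == 1
                others = [j for j in range(m.n_samples) if j != ci]
                assert (m.gt[i, others] == 0).all()

    def test_no_duplicate_positions(self):
        cfg = SimConfig(seed=9, chrom_lengths={"chr1": 150_000}, te_counts_by_sharing={1: 3})
        sim = simulate_population(cfg)
        dup = sim.matrix.sites.duplicated(subset=["chrom", "pos"]).sum()
        assert dup == 0

    def test_ibd_tracts_have_reduced_rate(self):
        cfg = SimConfig(seed=13, outgroup=False, te_counts_by_sharing={1: 3})
        sim = simulate_population(cfg)
        v = sim.truth.varietal_variants.query("vtype == 'SNP'")
        in_tract = out_tract = 0
        tract_bp = total_bp = 0
        for chrom, length in cfg.chrom_lengths.items():
            tracks = np.zeros(length, bool)
            for a, b in sim.truth.ibd_tracts[chrom]:
                tracks[a:b] = True
            pos0 = v.loc[v["chrom"] == chrom, "pos"].to_numpy() - 1
            in_tract += int(tracks[pos0].sum())
            out_tract += int((~tracks[pos0]).sum())
            tract_bp += int(tracks.sum())
            total_bp += length
        in_rate = in_tract / (tract_bp / 1000)
        out_rate = out_tract / ((total_bp - tract_bp) / 1000)
        assert in_rate < 1.0  # low-variability definition
        assert out_rate > 5 * in_rate


class TestDeterminism:
    def test_identical_seed_identical_files(self, tmp_path):
        cfg = dict(
            seed=21, chrom_lengths={"chr1": 120_000}, te_counts_by_sharing={1: 4, 2: 2}
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(simulate_population(SimConfig(**cfg)), d1)
        write_dataset(simulate_population(SimConfig(**cfg)), d2)
        for rel in [p.relative_to(d1) for p in d1.rglob("*") if p.is_file()]:
            assert file_hash(d1 / rel) == file_hash(d2 / rel), rel

    def test_different_seed_different_data(self, tmp_path):
        cfg1 = SimConfig(seed=1, chrom_lengths={"chr1": 100_000}, te_counts_by_sharing={1: 3})
        cfg2 = SimConfig(seed=2, chrom_lengths={"chr1": 100_000}, te_counts_by_sharing={1: 3})
        s1, s2 = simulate_population(cfg1), simulate_population(cfg2)
        assert not s1.matrix.sites["pos"].equals(s2.matrix.sites["pos"])


class TestWriters:
    def test_written_vcf_roundtrips(self, tmp_path, small_sim):
        write_dataset(small_sim, tmp_path)
        back = read_vcf(tmp_path / "calls.vcf")
        assert back.equals(small_sim.matrix)

    def test_fasta_lengths_match_config(self, tmp_path, small_sim):
        write_dataset(small_sim, tmp_path)
        ref = read_fasta(tmp_path / "reference.fa")
        for chrom, length in small_sim.config.chrom_lengths.items():
            assert len(ref[chrom]) == length

    def test_te_tables_one_file_per_method(self, tmp_path, small_sim):
        paths = write_te_tables(small_sim.te_insertions, tmp_path)
        assert len(paths) == len(small_sim.config.te_methods)
        back = read_te_table(paths[0])
        assert len(back) == len(small_sim.te_insertions)

    def test_fully_shared_te_appears_for_all_clones_within_radius(self, small_sim):
        truth = small_sim.truth.te_events
        full = truth[truth["sharing"] == small_sim.config.n_clones]
        assert len(full) > 0
        for _, ev in full.iterrows():
            rows = small_sim.te_insertions[
                (small_sim.te_insertions["chrom"] == ev["chrom"])
                & (small_sim.te_insertions["family"] == ev["family"])
                & ((small_sim.te_insertions["pos"] - ev["pos"]).abs() <= 2000)
            ]
            assert set(rows["clone"]) == set(ev["clones"].split(","))
            assert rows["pos"].max() - rows["pos"].min() < 10_000

    def test_empty_truth_header_only_tables(self, tmp_path):
        import pandas as pd

        from clonescan.clonesim import TE_COLUMNS

        empty = pd.DataFrame(columns=TE_COLUMNS)
        paths = write_te_tables(empty, tmp_path)
        for p in paths:
            lines = open(p).read().strip().splitlines()
            assert len(lines) == 1  # header only


class TestTruthConsistency:
    def test_truth_counts_equal_matrix_contents(self, small_sim):
        m = small_sim.matrix
        n_varietal = len(small_sim.truth.varietal_variants)
        n_somatic = sum(len(df) for df in small_sim.truth.somatic_variants.values())
        # every truth variant exists in the written matrix
        key = {(c, p) for c, p in zip(m.sites["chrom"], m.sites["pos"])}
        for _, r in small_sim.truth.varietal_variants.iterrows():
            assert (r["chrom"], r["pos"]) in key
        assert n_varietal + n_somatic <= m.n_sites
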