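import itertools

import numpy as np
import pandas as pd
import pytest

from clonescan.te_sharing import (
    cluster_tei,
    exclusive_tei_per_clone,
    sharing_spectrum,
    tei_snp_correlation,
)


def tei_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "family", "te_class", "clone", "method"]
    )


def row(pos, clone="C1", family="Gypsy-12", chrom="chr1", method="retroseq"):
    return (chrom, pos, family, "LTR", clone, method)


class TestClustering:
    def test_boundary_9999_apart_merges(self):
        events = cluster_tei(tei_frame([row(5_000, "C1"), row(14_999, "C2")]))
        assert len(events) == 1
        assert events[0].sharing == 2

    def test_boundary_10000_apart_splits(self):
        events = cluster_tei(tei_frame([row(5_000, "C1"), row(15_000, "C2")]))
        assert len(events) == 2

    def test_different_families_never_merge(self):
        events = cluster_tei(
            tei_frame([row(5_000, "C1"), row(5_100, "C2", family="Copia-7")])
        )
        assert len(events) == 2

    def test_duplicate_clone_counted_once_and_flagged(self):
        events = cluster_tei(tei_frame([row(5_000, "C1"), row(5_050, "C1")]))
        assert len(events) == 1
        assert events[0].sharing == 1
        assert events[0].duplicates == 1

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(14)
        rows = [
            row(int(rng.integers(1, 200_000)), f"C{rng.integers(1, 9)}",
                family=["Gypsy-12", "Copia-7"][int(rng.integers(0, 2))])
            for _ in range(120)
        ]
        df = tei_frame(rows)
        events = cluster_tei(df, radius=10_000)
        # O(n^2) oracle: union-find over all pairs < radius, same chrom+family
        recs = list(df.itertuples(index=False))
        parent = list(range(len(recs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(recs)), 2):
            a, b = recs[i], recs[j]
            if (
                a.chrom == b.chrom
                and a.family == b.family
                and a.method == b.method
                and abs(a.pos - b.pos) < 10_000
            ):
                parent[find(i)] = find(j)
        oracle_clusters = {}
        for i in range(len(recs)):
            oracle_clusters.setdefault(find(i), []).append(i)
        # compare cluster structure: insertion conservation, cluster-size and
        # sharing-level multisets must coincide with the union-find oracle
        assert sum(e.n_insertions for e in events) == len(recs)
        oracle_sizes = sorted(len(m) for m in oracle_clusters.values())
        assert sorted(e.n_insertions for e in events) == oracle_sizes
        oracle_sharing = sorted(
            len({recs[i].clone for i in members}) for members in oracle_clusters.values()
        )
        assert sorted(e.sharing for e in events) == oracle_sharing

    def test_idempotent_and_radius_monotone(self):
        rng = np.random.default_rng(3)
        rows = [row(int(rng.integers(1, 300_000)), f"C{rng.integers(1, 5)}") for _ in range(80)]
        df = tei_frame(rows)
        n_small = len(cluster_tei(df, radius=5_000))
        n_mid = len(cluster_tei(df, radius=10_000))
        n_big = len(cluster_tei(df, radius=50_000))
        assert n_small >= n_mid >= n_big
        assert len(cluster_tei(df, radius=10_000)) == n_mid  # deterministic/idempotent

    def test_insertion_count_conserved(self):
        rng = np.random.default_rng(8)
        rows = [row(int(rng.integers(1, 100_000)), f"C{rng.integers(1, 4)}") for _ in range(50)]
        events = cluster_tei(tei_frame(rows))
        assert sum(e.n_insertions for e in events) == 50


class TestSpectrum:
    def test_percentages_to_two_decimals(self):
        events = cluster_tei(
            tei_frame(
                [row(5_000, "C1"), row(50_000, "C1"), row(90_000, "C2")]
                + [row(130_000, "C1"), row(131_000, "C2")]
            )
        )
        spec = sharing_spectrum(events, n_clones=8)
        assert spec.total == 4
        assert spec.percent_at(1) == 75.0
        assert spec.percent_at(2) == 25.0

    def test_all_exclusive(self):
        events = cluster_tei(tei_frame([row(5_000), row(50_000), row(95_000)]))
        spec = sharing_spectrum(events, n_clones=8)
        assert spec.percent_at(1) == 100.0

    def test_simulated_spectrum_recovered_exactly(self, small_sim):
        events = cluster_tei(small_sim.te_insertions)
        spec = sharing_spectrum(events, n_clones=small_sim.config.n_clones)
        planted = small_sim.truth.te_sharing_spectrum("retroseq")
        assert spec.counts == planted


class TestCorrelation:
    def test_perfectly_anti_monotone(self):
        tei = {f"C{i}": 10 - i for i in range(1, 9)}
        snp = {f"C{i}": i * 100 for i in range(1, 9)}
        out = tei_snp_correlation(tei, snp)
        assert out["rho"] == pytest.approx(-1.0)

    def test_identical_vectors_rho_one(self):
        v = {f"C{i}": i for i in range(1, 9)}
        assert tei_snp_correlation(v, v)["rho"] == pytest.approx(1.0)

    def test_constant_vector_warns_nan(self):
        tei = {f"C{i}": 5 for i in range(1, 9)}
        snp = {f"C{i}": i for i in range(1, 9)}
        with pytest.warns(UserWarning):
            out = tei_snp_correlation(tei, snp)
        assert np.isnan(out["rho"])

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        tei = {f"C{i}": int(rng.integers(0, 50)) for i in range(1, 9)}
        snp = {f"C{i}": int(rng.integers(0, 500)) for i in range(1, 9)}
        out = tei_snp_correlation(tei, snp)
        # independent oracle: scipy spearman per permutation
        from scipy import stats

        clones = sorted(tei)
        x = np.array([tei[c] for c in clones], float)
        y = np.array([snp[c] for c in clones], float)
        rho_obs = stats.spearmanr(x, y).statistic
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        hits = total = 0
        for perm in itertools.permutations(range(8)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]  # Pearson on ranks
            total += 1
            if abs(r) >= abs(rho_obs) - 1e-12:
                hits += 1
        assert out["rho"] == pytest.approx(rho_obs)
        assert out["p_value"] == pytest.approx(hits / total)

    def test_too_few_clones_rejected(self):
        with pytest.raises(ValueError):
            tei_snp_correlation({"a": 1, "b": 2}, {"a": 2, "b": 1})


def test_exclusive_counts_per_clone():
    events = cluster_tei(
        tei_frame([row(5_000, "C1"), row(50_000, "C1"), row(95_000, "C2"),
                   row(130_000, "C1"), row(131_000, "C2")])
    )
    excl = exclusive_tei_per_clone(events)
    assert excl == {"C1": 2, "C2": 1}
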