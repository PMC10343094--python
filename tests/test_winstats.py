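"""Filtering, windowed diversity, F_FM, LD and annotation statistics."""

import numpy as np
import pandas as pd
import pytest

from zwpar import winstats
from zwpar.recmap import GenomicTrack
from zwpar.winstats import (FilterConfig, IntervalSet, MISSING,
                            accessible_sites, apply_variant_filters,
                            annotation_tracks, diversity_window, fst_fm_window,
                            hwe_exact_p, ld_decay, ld_pairs, make_windows)

from conftest import toy_variant_table

SEXES5 = np.array(["F"] * 5 + ["M"] * 5)


class TestFilters:
    def failing_table(self):
        """Eight SNPs, each failing exactly one hard-filter rule."""
        n = 8
        ac = np.ones((n, 2), dtype=np.int8)
        vt = toy_variant_table(
            pos=np.arange(1, n + 1) * 100, alt_counts=ac, sexes=["F", "M"],
            QUAL=[10, 100, 100, 100, 100, 100, 100, 100],
            QD=[20, 1.0, 20, 20, 20, 20, 20, 20],
            MQ=[55, 55, 30.0, 55, 55, 55, 55, 55],
            MQRankSum=[0, 0, 0, -20.0, 0, 0, 0, 0],
            FS=[1, 1, 1, 1, 80.0, 1, 1, 1],
            ReadPosRankSum=[0, 0, 0, 0, 0, -10.0, 0, 0],
            SOR=[1, 1, 1, 1, 1, 1, 5.0, 1],
        )
        vt.depth[7] = (2, 1)  # total 3 < 5
        return vt

    def test_each_rule_fires_once(self):
        out, counts = apply_variant_filters(self.failing_table())
        assert out.n_sites == 0
        for rule in ("QUAL", "QD", "MQ", "MQRankSum", "FS", "ReadPosRankSum",
                     "SOR", "depth"):
            assert counts[rule] == 1, rule

    @pytest.mark.parametrize("total,kept", [(4, False), (5, True),
                                            (70, True), (71, False)])
    def test_depth_boundary_semantics(self, total, kept):
        vt = toy_variant_table([100], [[1, 1]], ["F", "M"])
        vt.depth[0] = (total, 0)
        out, _ = apply_variant_filters(vt)
        assert (out.n_sites == 1) is kept

    def test_order_independence_vs_set_intersection(self, rng):
        n = 200
        vt = toy_variant_table(
            pos=np.arange(1, n + 1) * 50,
            alt_counts=rng.integers(0, 3, size=(n, 4)).astype(np.int8),
            sexes=["F", "F", "M", "M"],
            QUAL=rng.uniform(0, 200, n), QD=rng.uniform(0, 30, n),
            MQ=rng.uniform(20, 60, n), FS=rng.uniform(0, 100, n),
        )
        vt.depth[:] = rng.integers(0, 30, size=vt.depth.shape)
        out, _ = apply_variant_filters(vt)
        cfg = FilterConfig()
        s = vt.sites
        total = vt.depth.sum(axis=1)
        survivors = (
            set(np.where(s["QUAL"] >= cfg.qual_min)[0])
            & set(np.where(s["QD"] >= cfg.qd_min)[0])
            & set(np.where(s["MQ"] >= cfg.mq_min)[0])
            & set(np.where(s["FS"] <= cfg.fs_max)[0])
            & set(np.where((total >= 5) & (total <= 70))[0])
        )
        assert set(out.sites["pos"]) == set(s["pos"].iloc[sorted(survivors)])

    def test_slr_haploidization(self):
        # three SLR sites: female hom-ref, hom-alt, het
        vt = toy_variant_table([1001, 1002, 1003],
                               [[0, 1], [2, 1], [1, 1]], ["F", "M"])
        slr = IntervalSet([("chrZ", 1000, 2000)])
        out, counts = apply_variant_filters(vt, slr=slr)
        assert counts["slr_female_haploidized"] == 2
        assert counts["slr_female_het_dropped"] == 1
        assert out.ploidy[:, 0].tolist() == [1, 1, 0]
        assert out.alt_counts[:, 0].tolist() == [0, 1, MISSING]
        # male calls untouched
        assert out.ploidy[:, 1].tolist() == [2, 2, 2]

    def test_missing_annotation_passes(self):
        vt = toy_variant_table([10], [[1, 1]], ["F", "M"], QD=np.nan)
        out, _ = apply_variant_filters(vt)
        assert out.n_sites == 1

    def test_repeat_removal(self):
        vt = toy_variant_table([100, 500], [[1, 1], [1, 1]], ["F", "M"])
        out, counts = apply_variant_filters(
            vt, repeats=IntervalSet([("chrZ", 400, 600)]))
        assert counts["repeat"] == 1
        assert out.sites["pos"].tolist() == [100]


class TestAccessibleSites:
    def test_uniform_depth(self):
        trk = {"s": GenomicTrack.from_arrays("chrZ", [0], [200_000], [30.0])}
        L = accessible_sites(trk, None, [("chrZ", 0, 200_000)])
        assert L[0] == 200_000

    def test_half_window_below_minimum(self):
        trk = {"s": GenomicTrack.from_arrays("chrZ", [0, 100_000],
                                             [100_000, 200_000], [2.0, 30.0])}
        L = accessible_sites(trk, None, [("chrZ", 0, 200_000)])
        assert L[0] == 100_000

    def test_random_profile_matches_bp_oracle(self, rng):
        edges = np.arange(0, 5001, 250)
        tracks = {}
        for s in ("a", "b"):
            vals = rng.integers(0, 40, size=len(edges) - 1).astype(float)
            tracks[s] = GenomicTrack.from_arrays("chrZ", edges[:-1], edges[1:], vals)
        repeats = IntervalSet([("chrZ", 100, 700), ("chrZ", 3000, 3300)])
        window = ("chrZ", 0, 5000)
        L = accessible_sites(tracks, repeats, [window], depth_min=5, depth_max=70)
        count = 0
        for bp in range(5000):
            tot = sum(t.df.loc[(t.df["start"] <= bp) & (t.df["end"] > bp),
                               "value"].iloc[0] for t in tracks.values())
            masked = (100 <= bp < 700) or (3000 <= bp < 3300)
            count += (5 <= tot <= 70) and not masked
        assert L[0] == count

    def test_window_beyond_track_raises(self):
        trk = {"s": GenomicTrack.from_arrays("chrZ", [0], [1000], [30.0])}
        with pytest.raises(ValueError, match="beyond"):
            accessible_sites(trk, None, [("chrZ", 0, 2000)])


class TestDiversity:
    def test_empty_window(self):
        vt = toy_variant_table([10], [[0, 0]], ["F", "M"])
        out = diversity_window(vt, 1000, "chrZ", 5000, 6000)
        assert out["S"] == 0 and out["pi"] == 0.0 and np.isnan(out["tajima_d"])

    def test_single_site_hand_value(self):
        # n=10 chromosomes (5 diploids), k=5, L=1000: pi = (2*5*5/90)/1000
        ac = np.array([[2, 1, 1, 1, 0]], dtype=np.int8)
        vt = toy_variant_table([500], ac, np.array(["F", "F", "M", "M", "M"]))
        out = diversity_window(vt, 1000, "chrZ", 0, 1000)
        assert out["pi"] == pytest.approx(5.5556e-4, rel=1e-4)
        assert out["S"] == 1
        a1 = sum(1.0 / i for i in range(1, 10))
        assert out["theta_w"] == pytest.approx(1 / a1 / 1000)

    def test_scales_inversely_with_L(self):
        ac = np.array([[1, 0, 1, 1, 0, 0, 1, 0, 0, 0]], dtype=np.int8)
        vt = toy_variant_table([500], ac, SEXES5)
        a = diversity_window(vt, 1000, "chrZ", 0, 1000)
        b = diversity_window(vt, 2000, "chrZ", 0, 1000)
        assert a["pi"] == pytest.approx(2 * b["pi"])
        assert a["theta_w"] == pytest.approx(2 * b["theta_w"])

    def test_against_tskit_oracle(self):
        """pi and Tajima's D agree with tskit's implementations on an
        msprime-simulated diploid sample."""
        import msprime

        ts = msprime.sim_ancestry(samples=5, population_size=1000,
                                  sequence_length=50_000, random_seed=9)
        ts = msprime.sim_mutations(ts, rate=5e-7, random_seed=9,
                                   model=msprime.BinaryMutationModel())
        G = ts.genotype_matrix()                 # sites x 10 haplotypes
        seg = (G.sum(axis=1) > 0) & (G.sum(axis=1) < G.shape[1])
        G = G[seg]
        pos = ts.tables.sites.position[seg].astype(int) + 1
        ac = (G[:, ::2] + G[:, 1::2]).astype(np.int8)  # pair haplotypes
        vt = toy_variant_table(pos, ac, np.array(["F", "M", "F", "M", "F"]))
        out = diversity_window(vt, int(ts.sequence_length), "chrZ",
                               0, int(ts.sequence_length))
        assert out["pi"] == pytest.approx(float(ts.diversity()), rel=1e-6)
        assert out["tajima_d"] == pytest.approx(float(ts.Tajimas_D()), rel=1e-6)


class TestFstFM:
    def test_equal_frequencies_near_zero(self):
        # same genotype configuration in both sexes at every site; the
        # estimator is unbiased around 0 up to its small-sample correction
        block = [0] * 8 + [1] * 8 + [2] * 4          # 20 individuals per sex
        ac = np.array([block + block], dtype=np.int8)
        sexes = np.array(["F"] * 20 + ["M"] * 20)
        vt = toy_variant_table([100], ac, sexes)
        assert fst_fm_window(vt, "chrZ", 0, 1000) == pytest.approx(0.0, abs=0.05)

    def test_fixed_difference_is_one(self):
        ac = np.array([[0] * 5 + [2] * 5], dtype=np.int8)
        vt = toy_variant_table([100], ac, SEXES5)
        assert fst_fm_window(vt, "chrZ", 0, 1000) == pytest.approx(1.0)

    def test_monomorphic_window_missing(self):
        vt = toy_variant_table([100], [[0] * 10], SEXES5)
        assert np.isnan(fst_fm_window(vt, "chrZ", 0, 1000))

    def test_three_site_toy_hand_value(self):
        """Ratio-of-sums W&C estimate, hand-computed from the variance
        components of the printed genotype matrix: 27/76."""
        females = [[0, 0, 1, 1, 1],   # k=3, 3 hets
                   [0, 0, 0, 0, 1],   # k=1, 1 het
                   [0, 0, 1, 2, 2]]   # k=5, 1 het
        males = [[1, 1, 1, 2, 2],     # k=7, 3 hets
                 [1, 2, 2, 2, 2],     # k=9, 1 het
                 [0, 1, 1, 1, 2]]     # k=5, 3 hets
        ac = np.hstack([np.array(females, dtype=np.int8),
                        np.array(males, dtype=np.int8)])
        vt = toy_variant_table([10, 20, 30], ac, SEXES5)
        assert fst_fm_window(vt, "chrZ", 0, 100) == pytest.approx(27 / 76, rel=1e-12)

    def test_sex_permutation_centered_on_zero(self, rng):
        n = 60
        ac = rng.integers(0, 3, size=(n, 10)).astype(np.int8)
        vals = []
        for _ in range(30):
            sexes = np.array(["F"] * 5 + ["M"] * 5)
            rng.shuffle(sexes)
            vt = toy_variant_table(np.arange(1, n + 1) * 10, ac, sexes)
            vals.append(fst_fm_window(vt, "chrZ", 0, 10_000))
        assert abs(np.nanmean(vals)) < 0.02


class TestHWE:
    def brute_force_p(self, het, hom1, hom2):
        """Enumerate P(het count) conditional on allele counts."""
        from math import comb
        n = het + hom1 + hom2
        n_a = het + 2 * min(hom1, hom2)
        probs = {}
        for h in range(n_a % 2, n_a + 1, 2):
            ra = (n_a - h) // 2
            ca = n - h - ra
            if ca < 0:
                continue
            # P ∝ n! / (h! ra! ca!) * 2^h  (conditional on allele counts)
            probs[h] = comb(n, h) * comb(n - h, ra) * 2 ** h
        tot = sum(probs.values())
        obs = probs[het]
        return sum(v for v in probs.values() if v <= obs) / tot

    @pytest.mark.parametrize("het,hom1,hom2", [
        (5, 2, 3), (0, 5, 5), (10, 0, 0), (3, 6, 1), (1, 1, 8)])
    def test_matches_enumeration(self, het, hom1, hom2):
        assert hwe_exact_p(het, hom1, hom2) == pytest.approx(
            self.brute_force_p(het, hom1, hom2), rel=1e-9)

    def test_monomorphic_is_one(self):
        assert hwe_exact_p(0, 10, 0) == 1.0


class TestLD:
    def test_cosegregating_pair(self):
        ac = np.array([[0, 1, 2, 1, 0], [0, 1, 2, 1, 0]], dtype=np.int8)
        vt = toy_variant_table([100, 200], ac, np.array(["F", "M", "F", "M", "F"]))
        pairs = ld_pairs(vt, "chrZ", 1000, hwe_p=0.0)
        assert len(pairs) == 1
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)
        assert pairs["distance"].iloc[0] == 100

    def test_matches_brute_force_correlation(self, rng):
        n = 12
        ac = rng.integers(0, 3, size=(n, 5)).astype(np.int8)
        vt = toy_variant_table(np.arange(1, n + 1) * 10, ac,
                               np.array(["F", "M", "F", "M", "F"]))
        pairs = ld_pairs(vt, "chrZ", 1000, hwe_p=0.0)
        for _, row in pairs.iterrows():
            i = np.where(vt.sites["pos"] - 1 == row["pos_i"])[0][0]
            j = np.where(vt.sites["pos"] - 1 == row["pos_j"])[0][0]
            r = np.corrcoef(ac[i].astype(float), ac[j].astype(float))[0, 1]
            assert row["r2"] == pytest.approx(r * r, rel=1e-9)

    def test_independent_sites_mean_r2(self, rng):
        """For independent sites the expected sample r^2 is ~1/(m-1) with m
        diploid individuals (dosage vectors of length m)."""
        m, n = 10, 400
        ac = rng.binomial(2, 0.5, size=(n, m)).astype(np.int8)
        vt = toy_variant_table(np.arange(1, n + 1), ac, SEXES5)
        pairs = ld_pairs(vt, "chrZ", 1000, hwe_p=0.0)
        assert pairs["r2"].mean() == pytest.approx(1 / (m - 1), rel=0.15)

    def test_hwe_filter_excludes_all_het_site(self):
        ac = np.array([[1] * 10, [0, 1, 2, 1, 0, 0, 1, 2, 1, 0]], dtype=np.int8)
        vt = toy_variant_table([100, 200], ac, SEXES5)
        assert hwe_exact_p(10, 0, 0) < 0.01
        pairs = ld_pairs(vt, "chrZ", 1000, hwe_p=0.01)
        assert len(pairs) == 0  # one site excluded -> no pair

    def test_haploid_sites_excluded(self):
        ac = np.array([[1, 0, 1, 1, 0], [1, 1, 0, 0, 1]], dtype=np.int8)
        pl = np.array([[1, 2, 2, 2, 2], [2] * 5], dtype=np.int8)
        vt = toy_variant_table([100, 200], ac, np.array(["F"] * 5), ploidy=pl)
        pairs = ld_pairs(vt, "chrZ", 1000, hwe_p=0.0)
        assert len(pairs) == 0

    def test_overlapping_windows_deduplicate(self, rng):
        n = 30
        ac = rng.integers(0, 3, size=(n, 10)).astype(np.int8)
        pos = rng.choice(np.arange(1, 500_000), size=n, replace=False)
        vt = toy_variant_table(np.sort(pos), ac, SEXES5)
        pairs = ld_pairs(vt, "chrZ", 500_000, window_size=200_000,
                         overlap=50_000, hwe_p=0.0)
        keys = list(zip(pairs["pos_i"], pairs["pos_j"]))
        assert len(keys) == len(set(keys))


class TestLDDecay:
    def test_all_background_first_bin(self):
        pairs = pd.DataFrame({"distance": np.arange(100, 5000, 100),
                              "r2": 0.15})
        curve, decay = ld_decay(pairs, background_r2=0.15)
        assert decay == curve["midpoint"].iloc[0]

    def test_exponential_decay_crossing(self):
        d = np.arange(100, 60_000, 50)
        r2 = 0.6 * np.exp(-d / 15_000.0)
        pairs = pd.DataFrame({"distance": d, "r2": r2})
        curve, decay = ld_decay(pairs, background_r2=0.15, smooth_bins=1)
        true_cross = -15_000 * np.log(0.15 / 0.6)   # ~20794 bp
        assert abs(decay - true_cross) <= 1000

    def test_never_reaching_background(self):
        pairs = pd.DataFrame({"distance": [100, 2000], "r2": [0.9, 0.8]})
        _, decay = ld_decay(pairs, background_r2=0.15)
        assert np.isnan(decay)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ld_decay(pd.DataFrame(columns=["distance", "r2"]))


class TestAnnotationTracks:
    def write_fasta(self, tmp_path, seqs):
        p = tmp_path / "ref.fa"
        with open(p, "w") as fh:
            for name, s in seqs.items():
                fh.write(f">{name}\n{s}\n")
        return p

    def write_gff(self, tmp_path, cds):
        p = tmp_path / "a.gff3"
        with open(p, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, (chrom, s, e) in enumerate(cds):
                fh.write(f"{chrom}\tt\tCDS\t{s}\t{e}\t.\t+\t0\tID=c{i}\n")
        return p

    def test_gc_and_cds_union(self, tmp_path):
        fa = self.write_fasta(tmp_path, {"chrZ": "GCGC" * 25 + "N" * 100 + "AT" * 50})
        # two overlapping CDS: union is 1..60 (60 bp), not 80
        gff = self.write_gff(tmp_path, [("chrZ", 1, 40), ("chrZ", 21, 60)])
        out = annotation_tracks(fa, gff, [("chrZ", 0, 100), ("chrZ", 100, 200),
                                          ("chrZ", 200, 300)])
        assert out["gc"].iloc[0] == pytest.approx(1.0)
        assert np.isnan(out["gc"].iloc[1])          # all-N window
        assert out["cds_frac"].iloc[1] == 0.0        # still computable
        assert out["gc"].iloc[2] == pytest.approx(0.0)
        assert out["cds_frac"].iloc[0] == pytest.approx(0.60)

    def test_window_beyond_sequence(self, tmp_path):
        fa = self.write_fasta(tmp_path, {"chrZ": "ACGT" * 10})
        gff = self.write_gff(tmp_path, [("chrZ", 1, 4)])
        with pytest.raises(ValueError, match="beyond"):
            annotation_tracks(fa, gff, [("chrZ", 0, 100)])


class TestWindows:
    def test_grid_anchored_at_zero(self):
        w = make_windows({"chrZ": 450_000}, 200_000)
        assert w == [("chrZ", 0, 200_000), ("chrZ", 200_000, 400_000),
                     ("chrZ", 400_000, 450_000)]

    def test_overlapping_grid(self):
        w = make_windows({"c": 500_000}, 200_000, 150_000)
        assert w[:3] == [("c", 0, 200_000), ("c", 150_000, 350_000),
                         ("c", 300_000, 500_000)]
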