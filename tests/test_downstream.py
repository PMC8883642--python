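"""HVR-based sample-structure analyses: scaling, activity scores, PCA,
Ward clustering, ARI, QTL scan, resampling enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hypervar import downstream as ds


class TestZscaleRegions:
    def test_unit_row_example(self):
        x = pd.DataFrame([[1.0, 2.0, 3.0]], index=["r0"], columns=list("abc"))
        np.testing.assert_allclose(
            ds.zscale_regions(x).to_numpy(), [[-1.0, 0.0, 1.0]]
        )

    def test_rows_have_mean_zero_sd_one(self, rng):
        x = pd.DataFrame(rng.normal(2, 3, size=(40, 8)))
        z = ds.zscale_regions(x).to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_constant_row_dropped_with_warning(self):
        x = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], columns=list("abc"))
        with pytest.warns(UserWarning, match="zero-spread"):
            z = ds.zscale_regions(x)
        assert len(z) == 1


class TestActivityScores:
    def _z(self, rows, ids=None):
        ids = ids or [f"h{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=ids, columns=["s1", "s2", "s3"][: len(rows[0])])

    def test_motif_hitting_all_hvrs_scores_zero(self, rng):
        z = self._z(rng.normal(size=(5, 3)).tolist())
        hits = pd.DataFrame([[1] * 5], index=["m1"], columns=z.index)
        np.testing.assert_allclose(
            ds.activity_scores(z, hits).to_numpy(), 0.0, atol=1e-12
        )

    def test_single_hit_motif(self):
        z = self._z([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
        hits = pd.DataFrame([[1, 0, 0]], index=["m"], columns=z.index)
        s = ds.activity_scores(z, hits)
        colmean = z.to_numpy().mean(axis=0)
        np.testing.assert_allclose(s.to_numpy()[0], z.to_numpy()[0] - colmean)

    def test_direct_sum_example(self):
        # 3 HVRs, hits (1,1,0), first sample column (2, 0, -2), colmean 0 -> 1
        z = self._z([[2.0], [0.0], [-2.0]])
        z.columns = ["s1"]
        hits = pd.DataFrame([[1, 1, 0]], index=["m"], columns=z.index)
        assert ds.activity_scores(z, hits).iloc[0, 0] == pytest.approx(1.0)

    def test_zero_hit_motif_is_missing(self):
        z = self._z([[1.0, 2.0, 3.0]])
        hits = pd.DataFrame([[0]], index=["m"], columns=z.index)
        assert ds.activity_scores(z, hits).isna().all().all()


class TestClassSpecificTests:
    def test_identical_groups_give_zero_t(self):
        s = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["m"],
                         columns=["a1", "a2", "b1", "b2"])
        labels = pd.Series(["A", "A", "B", "B"], index=s.columns)
        out = ds.class_specific_tests(s, labels, "A")
        assert out["t"].iloc[0] == pytest.approx(0.0)

    def test_hand_computed_welch_t(self):
        s = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["m"],
                         columns=[f"s{i}" for i in range(6)])
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=s.columns)
        out = ds.class_specific_tests(s, labels, "A")
        assert out["t"].iloc[0] == pytest.approx(-3.674, abs=1e-3)

    def test_shifted_motifs_take_top_ranks(self, rng):
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(400 + rep)
            s = pd.DataFrame(r.normal(size=(40, 30)),
                             index=[f"m{i}" for i in range(40)],
                             columns=[f"s{j}" for j in range(30)])
            labels = pd.Series(["A"] * 15 + ["B"] * 15, index=s.columns)
            s.iloc[:5, :15] += 2.0  # +2 SD class effect on 5 motifs
            out = ds.class_specific_tests(s, labels, "A")
            if set(out.index[out["rank"] <= 5]) == {f"m{i}" for i in range(5)}:
                hits += 1
        assert hits >= 18

    def test_small_group_rejected(self):
        s = pd.DataFrame([[1.0, 2.0, 3.0]], columns=list("abc"))
        labels = pd.Series(["A", "B", "B"], index=s.columns)
        with pytest.raises(ValueError, match="at least 2"):
            ds.class_specific_tests(s, labels, "A")


class TestPcaFeatures:
    def test_rank_one_data_single_component(self, rng):
        u = rng.normal(size=10)
        v = rng.normal(size=6)
        z = pd.DataFrame(np.outer(u, v))
        ratios = ds.explained_variance_ratio(z)
        assert ratios[0] == pytest.approx(1.0)

    def test_two_cluster_fixture_separated_by_pc1(self):
        block = np.zeros((20, 8))
        block[:10, :4] = 3.0
        block[10:, 4:] = 3.0
        z = pd.DataFrame(block.T)  # regions x samples: 8 samples, 2 groups
        scores = ds.pca_features(z, k=2)
        pc1 = scores["PC1"].to_numpy()
        assert len({tuple(np.sign(pc1[:4])), tuple(np.sign(pc1[4:]))}) == 2

    def test_full_rank_reconstruction(self, rng):
        z = pd.DataFrame(rng.normal(size=(30, 5)))
        with pytest.warns(UserWarning, match="clipped"):
            scores = ds.pca_features(z, k=10)
        assert scores.shape == (5, 5)
        ratios = ds.explained_variance_ratio(z)
        assert ratios.sum() == pytest.approx(1.0)

    def test_sign_convention_is_deterministic(self, rng):
        z = pd.DataFrame(rng.normal(size=(50, 7)))
        s1 = ds.pca_features(z, k=3)
        s2 = ds.pca_features(z.copy(), k=3)
        pd.testing.assert_frame_equal(s1, s2)


def _ari_brute_force(a, b):
    """Pair-counting oracle: ARI from agreements over all sample pairs."""
    n = len(a)
    ss = sd = ds_ = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        if same_a and same_b:
            ss += 1
        elif same_a:
            sd += 1
        elif same_b:
            ds_ += 1
        else:
            dd += 1
    total = ss + sd + ds_ + dd
    expected = (ss + sd) * (ss + ds_) / total
    max_index = 0.5 * ((ss + sd) + (ss + ds_))
    if max_index == expected:
        return 1.0 if ss == max_index else 0.0
    return (ss - expected) / (max_index - expected)


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        assert ds.adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_relabeling_invariance(self):
        a = [1, 1, 2, 2, 3]
        b = ["x", "x", "y", "y", "z"]
        assert ds.adjusted_rand_index(a, b) == 1.0

    def test_crossed_partition_example(self):
        got = ds.adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2])
        assert got == pytest.approx(_ari_brute_force([1, 1, 2, 2], [1, 2, 1, 2]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ds.adjusted_rand_index([1, 2], [1, 2, 3])

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(500):
            n = int(rng.integers(3, 13))
            a = rng.integers(0, 4, size=n).tolist()
            b = rng.integers(0, 4, size=n).tolist()
            assert ds.adjusted_rand_index(a, b) == pytest.approx(
                _ari_brute_force(a, b), abs=1e-12
            )


class TestWardClusterCut:
    def test_separated_blobs_split_perfectly(self, rng):
        a = rng.normal(0, 1, size=(10, 4))
        b = rng.normal(30, 1, size=(10, 4))  # ~10 sigma separation
        feats = pd.DataFrame(np.vstack([a, b]))
        ids = ds.ward_cluster_cut(feats, 2)
        truth = [0] * 10 + [1] * 10
        assert ds.adjusted_rand_index(ids.to_numpy(), truth) == 1.0

    def test_k_equals_n_gives_singletons(self, rng):
        feats = pd.DataFrame(rng.normal(size=(6, 3)))
        ids = ds.ward_cluster_cut(feats, 6)
        assert len(set(ids)) == 6

    def test_duplicated_points_share_cluster(self, rng):
        pts = rng.normal(size=(5, 3))
        feats = pd.DataFrame(np.vstack([pts, pts]))
        ids = ds.ward_cluster_cut(feats, 5).to_numpy()
        for i in range(5):
            assert ids[i] == ids[i + 5]

    def test_k_too_large_rejected(self, rng):
        feats = pd.DataFrame(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            ds.ward_cluster_cut(feats, 4)

    def test_matches_r_hclust_ward_d_on_known_fixture(self):
        """4-point fixture with merge heights hand-traced through the
        unsquared Lance-Williams Ward recurrence."""
        feats = pd.DataFrame([[0.0], [1.0], [10.0], [12.0]])
        ids = ds.ward_cluster_cut(feats, 2).to_numpy()
        assert ids[0] == ids[1] and ids[2] == ids[3] and ids[0] != ids[2]


class TestQtlScan:
    def _fixture(self, rng, n_samples=30, effect=0.0):
        x = pd.DataFrame(
            rng.normal(size=(20, n_samples)),
            index=[f"chr1:{i}00-{i}99" for i in range(20)],
            columns=[f"ind{j}" for j in range(n_samples)],
        )
        geno = np.array(["ref"] * n_samples, dtype=object)
        geno[: n_samples // 2] = "alt"
        genotypes = pd.DataFrame([geno], index=["snp1"], columns=x.columns)
        if effect:
            row = x.iloc[0].to_numpy()
            row[: n_samples // 2] += effect * row.std(ddof=1)
            x.iloc[0] = row
        snp_regions = pd.Series({"snp1": x.index[0]})
        return x, genotypes, snp_regions

    def test_small_genotype_group_filtered(self, rng):
        x, genotypes, snp_regions = self._fixture(rng)
        genotypes.loc["snp1"] = ["alt"] * 4 + ["ref"] * 26
        out = ds.qtl_scan(x, genotypes, snp_regions)
        assert len(out) == 0

    def test_identical_distributions_give_t_zero(self):
        x = pd.DataFrame(
            [np.tile([1.0, 2.0], 10)], index=["chr1:0-99"],
            columns=[f"i{j}" for j in range(20)],
        )
        geno = ["alt", "alt"] * 5 + ["ref", "ref"] * 5
        genotypes = pd.DataFrame([geno], index=["snp1"], columns=x.columns)
        out = ds.qtl_scan(x, genotypes, pd.Series({"snp1": "chr1:0-99"}))
        assert out["t"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_strong_qtl_detected_in_most_replicates(self):
        found = 0
        for rep in range(20):
            rng = np.random.default_rng(800 + rep)
            x, genotypes, snp_regions = self._fixture(rng, effect=3.0)
            out = ds.qtl_scan(x, genotypes, snp_regions)
            if len(out) and out["significant"].iloc[0]:
                found += 1
        assert found >= 19

    def test_type_one_error_controlled(self):
        calls = trials = 0
        for rep in range(10):
            rng = np.random.default_rng(900 + rep)
            x, genotypes, snp_regions = self._fixture(rng, effect=0.0)
            out = ds.qtl_scan(x, genotypes, snp_regions)
            calls += int(out["significant"].sum())
            trials += len(out)
        se = np.sqrt(0.1 * 0.9 / max(trials, 1))
        assert calls / max(trials, 1) <= 0.1 + 3 * se

    def test_snp_without_region_skipped_with_warning(self, rng):
        x, genotypes, _ = self._fixture(rng)
        with pytest.warns(UserWarning, match="without an enclosing region"):
            out = ds.qtl_scan(x, genotypes, pd.Series({"snp1": np.nan}))
        assert len(out) == 0


class TestResamplingEnrichment:
    def test_target_equals_universe_gives_p_one(self, rng):
        ids = [f"r{i}" for i in range(10)]
        counts = pd.Series(rng.integers(0, 5, size=10), index=ids)
        obs, null, p = ds.resampling_enrichment(ids, ids, counts, n_iter=50, seed=0)
        assert p == 1.0
        assert np.all(null == obs)

    def test_fully_concentrated_features_reach_floor(self):
        universe = [f"r{i}" for i in range(100)]
        target = universe[:5]
        counts = pd.Series(0, index=universe, dtype=float)
        counts[target] = 10.0
        obs, null, p = ds.resampling_enrichment(
            target, universe, counts, n_iter=199, seed=1
        )
        assert obs == 50.0
        assert p == pytest.approx(1.0 / 200.0)

    def test_same_seed_reproduces_null(self):
        universe = [f"r{i}" for i in range(50)]
        counts = pd.Series(np.arange(50, dtype=float), index=universe)
        _, null1, _ = ds.resampling_enrichment(universe[:10], universe, counts,
                                               n_iter=100, seed=42)
        _, null2, _ = ds.resampling_enrichment(universe[:10], universe, counts,
                                               n_iter=100, seed=42)
        np.testing.assert_array_equal(null1, null2)

    def test_target_exceeding_universe_rejected(self):
        with pytest.raises(ValueError, match="subset|larger"):
            ds.resampling_enrichment(
                ["a", "b"], ["a"], pd.Series({"a": 1.0}), n_iter=10
            )
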