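import logging

import numpy as np
import pandas as pd
import pytest

from dpanet.expression import PopulationProfile
from dpanet.lrnet import (
    LrnetConfig,
    bh_adjust,
    enumerate_candidate_paths,
    export_network,
    filter_paths,
    lrnet_test_from_profile,
    permutation_pvalue,
    summed_weight,
    validate_lr_map,
)


def make_profile(detection: dict, log2fc: dict) -> PopulationProfile:
    det = pd.DataFrame(detection)
    det.index.name = "gene"
    fc = pd.DataFrame(log2fc)
    fc.index = det.index
    return PopulationProfile(detection=det, log2fc=fc)


@pytest.fixture
def tiny_profile():
    genes = ["L1", "L2", "R1", "R2"]
    detection = {
        "src": pd.Series([0.5, 0.05, 0.2, 0.2], index=genes),
        "tgt": pd.Series([0.12, 0.3, 0.10, 0.09], index=genes),
    }
    log2fc = {
        "src": pd.Series([2.0, 1.0, 0.1, 0.2], index=genes),
        "tgt": pd.Series([-0.5, 0.3, 1.5, 2.5], index=genes),
    }
    return make_profile(detection, log2fc)


@pytest.fixture
def tiny_map():
    return pd.DataFrame(
        {
            "ligand": ["L1", "L2"],
            "receptor": ["R1", "R2"],
            "ppi_weight": [0.9, 0.8],
        }
    )


class TestEnumerateCandidatePaths:
    def test_detection_filter_and_weights(self, tiny_profile, tiny_map):
        paths = enumerate_candidate_paths(tiny_profile, tiny_map, ["src", "tgt"])
        # L2 is at 5% in src -> no src-sourced path for pair (L2, R2);
        # R1 is at exactly 0.10 in tgt -> boundary included
        keys = set(
            map(tuple, paths[["source", "ligand", "receptor", "target"]].to_numpy())
        )
        assert ("src", "L1", "R1", "tgt") in keys
        assert all(not (s == "src" and l == "L2") for s, l, _, _ in keys)
        row = paths.set_index(["source", "ligand", "receptor", "target"]).loc[
            ("src", "L1", "R1", "tgt")
        ]
        assert row["path_weight"] == pytest.approx(2.0 + 0.9 + 1.5)

    def test_receptor_below_detection_excluded(self, tiny_profile, tiny_map):
        paths = enumerate_candidate_paths(tiny_profile, tiny_map, ["src", "tgt"])
        # R2 at 9% in tgt -> no path terminating at (R2, tgt)
        assert not (
            (paths["receptor"] == "R2") & (paths["target"] == "tgt")
        ).any()

    def test_absent_genes_skipped_with_warning(self, tiny_profile, tiny_map, caplog):
        lr = pd.concat(
            [tiny_map, pd.DataFrame({"ligand": ["NOPE"], "receptor": ["R1"], "ppi_weight": [0.5]})],
            ignore_index=True,
        )
        with caplog.at_level(logging.WARNING, logger="dpanet.lrnet"):
            enumerate_candidate_paths(tiny_profile, lr, ["src", "tgt"])
        assert "skipping 1" in caplog.text

    def test_empty_map_is_an_error(self, tiny_profile):
        empty = pd.DataFrame(columns=["ligand", "receptor", "ppi_weight"])
        with pytest.raises(ValueError, match="empty"):
            enumerate_candidate_paths(tiny_profile, empty, ["src", "tgt"])

    def test_map_validation(self):
        bad = pd.DataFrame({"ligand": ["a"], "receptor": ["b"], "ppi_weight": [1.5]})
        with pytest.raises(ValueError, match="ppi_weight"):
            validate_lr_map(bad)
        dupes = pd.DataFrame(
            {"ligand": ["a", "a"], "receptor": ["b", "b"], "ppi_weight": [0.5, 0.6]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            validate_lr_map(dupes)


class TestFilterAndSum:
    def make_paths(self, weights):
        return pd.DataFrame(
            {
                "source": "s",
                "ligand": [f"L{i}" for i in range(len(weights))],
                "receptor": [f"R{i}" for i in range(len(weights))],
                "target": "t",
                "w_source_ligand": 0.0,
                "w_lr": 0.0,
                "w_receptor_target": 0.0,
                "path_weight": weights,
            }
        )

    def test_filter_boundary_inclusive(self):
        paths = self.make_paths([1.4, 1.5, 2.0])
        kept = filter_paths(paths, 1.5)
        assert kept["path_weight"].tolist() == [1.5, 2.0]

    def test_filter_empty_input(self):
        empty = self.make_paths([])
        assert len(filter_paths(empty, 1.5)) == 0

    def test_summed_weight(self):
        assert summed_weight(self.make_paths([4.4, 2.0])) == pytest.approx(6.4)
        assert summed_weight(self.make_paths([3.3])) == pytest.approx(3.3)
        assert summed_weight(self.make_paths([])) == 0.0

    def test_summed_weight_rejects_mixed_pairs(self):
        paths = self.make_paths([1.0, 2.0])
        paths.loc[1, "target"] = "other"
        with pytest.raises(ValueError, match="single"):
            summed_weight(paths)

    def test_raising_threshold_never_increases_sum(self):
        paths = self.make_paths([0.5, 1.5, 1.6, 2.5, 3.0])
        prev_n, prev_w = np.inf, np.inf
        for threshold in (0.0, 1.0, 1.5, 2.0, 5.0):
            kept = filter_paths(paths, threshold)
            assert len(kept) <= prev_n
            assert kept["path_weight"].sum() <= prev_w
            prev_n, prev_w = len(kept), kept["path_weight"].sum()


class TestPermutationPvalue:
    def test_no_candidate_paths_gives_p_one(self, rng):
        assert permutation_pvalue(0.0, np.array([]), np.array([1.0]), np.array([1.0]),
                                  m=10, min_path_weight=1.5, rng=rng) == 1.0

    def test_degenerate_pools_all_ties(self, rng):
        # every permutation reproduces the observed configuration exactly
        ppi = np.array([0.9, 0.9])
        lig = np.array([2.0])
        rec = np.array([1.0])
        obs = 2 * (2.0 + 0.9 + 1.0)
        p = permutation_pvalue(obs, ppi, lig, rec, m=100, min_path_weight=1.5, rng=rng)
        assert p == 1.0

    def test_unreachable_observed_gives_zero(self, rng):
        p = permutation_pvalue(
            1e6, np.array([0.5]), np.array([0.1]), np.array([0.1]),
            m=100, min_path_weight=0.0, rng=rng,
        )
        assert p == 0.0

    def test_matches_brute_force_oracle(self):
        """Chunked vectorized null equals a per-permutation python loop."""
        ppi = np.array([0.9, 0.7])
        lig_pool = np.array([0.5, 1.2, -0.3])
        rec_pool = np.array([0.2, 0.8, 1.5])
        m, mpw, w_obs, seed = 64, 1.5, 3.1, 99

        p_fast = permutation_pvalue(
            w_obs, ppi, lig_pool, rec_pool, m=m, min_path_weight=mpw,
            rng=np.random.default_rng(seed),
        )

        rng = np.random.default_rng(seed)
        li = rng.integers(0, 3, size=(m, 2))
        ri = rng.integers(0, 3, size=(m, 2))
        hits = 0
        for i in range(m):
            total = 0.0
            for j in range(2):
                w = lig_pool[li[i, j]] + ppi[j] + rec_pool[ri[i, j]]
                if w >= mpw:
                    total += w
            if total >= w_obs:
                hits += 1
        assert p_fast == hits / m

    def test_chunking_does_not_change_count_statistics(self, rng):
        # same m split into chunks still returns a valid p on the 1/m grid
        p = permutation_pvalue(
            2.0, np.array([0.9]), np.array([0.5, 1.5]), np.array([0.1, 0.9]),
            m=1000, min_path_weight=1.0, rng=rng, chunk=64,
        )
        assert 0.0 <= p <= 1.0
        assert float(p * 1000) == pytest.approx(round(p * 1000))


class TestBhAdjust:
    def test_textbook_example(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_identity_cases(self):
        assert bh_adjust(np.array([0.05])).tolist() == [0.05]
        assert bh_adjust(np.array([1.0, 1.0])).tolist() == [1.0, 1.0]

    def test_matches_step_up_formula(self, rng):
        p = rng.uniform(size=37)
        n = len(p)
        order = np.argsort(p)
        ranked = p[order] * n / np.arange(1, n + 1)
        stepped = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(stepped, 1.0)
        assert np.allclose(bh_adjust(p), expected)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError, match="0, 1"):
            bh_adjust(np.array([0.5, 1.2]))


class TestLrnetPipeline:
    def test_planted_channel_recovered(self, default_profile, default_dataset):
        _, _, _, lr_map, truth = default_dataset
        config = LrnetConfig(m=2000, seed=5)
        results, paths = lrnet_test_from_profile(default_profile, lr_map, config)
        sig = results.loc[results["significant"]]
        assert len(sig) == 1
        assert (sig.iloc[0]["source"], sig.iloc[0]["target"]) == ("P00", "P01")
        # the filtered path table is dominated by the planted channel
        planted = paths[
            (paths["source"] == "P00") & (paths["target"] == "P01")
        ]
        assert len(planted) >= 10

    def test_compositional_consistency(self, default_profile, default_dataset):
        _, _, _, lr_map, _ = default_dataset
        config = LrnetConfig(m=200, seed=5)
        results, _ = lrnet_test_from_profile(default_profile, lr_map, config)
        candidates = enumerate_candidate_paths(
            default_profile, lr_map, min_detection=config.min_detection
        )
        for _, row in results.sample(10, random_state=0).iterrows():
            sub = candidates[
                (candidates["source"] == row["source"])
                & (candidates["target"] == row["target"])
            ]
            assert len(sub) == row["T"]
            kept = filter_paths(sub, config.min_path_weight)
            assert summed_weight(kept) == pytest.approx(row["w_st"])

    def test_raising_min_detection_never_increases_T(self, default_profile, default_dataset):
        _, _, _, lr_map, _ = default_dataset
        prev = np.inf
        for md in (0.05, 0.10, 0.25, 0.5):
            paths = enumerate_candidate_paths(default_profile, lr_map, min_detection=md)
            assert len(paths) <= prev
            prev = len(paths)

    def test_path_weight_is_unnormalized_sum(self, default_profile, default_dataset):
        _, _, _, lr_map, _ = default_dataset
        paths = enumerate_candidate_paths(default_profile, lr_map)
        total = (
            paths["w_source_ligand"] + paths["w_lr"] + paths["w_receptor_target"]
        )
        assert np.array_equal(paths["path_weight"].to_numpy(), total.to_numpy())

    def test_pvalues_within_bounds_and_bh_monotone(self, default_profile, default_dataset):
        _, _, _, lr_map, _ = default_dataset
        results, _ = lrnet_test_from_profile(
            default_profile, lr_map, LrnetConfig(m=500, seed=2)
        )
        assert ((results["p_w"] >= 0) & (results["p_w"] <= 1)).all()
        assert (results["p_adj"] >= results["p_w"] - 1e-12).all()
        assert (results["p_adj"] <= 1.0).all()


class TestExportNetwork:
    def test_round_trip_is_bit_exact(self, tmp_path, default_profile, default_dataset):
        _, _, _, lr_map, _ = default_dataset
        results, paths = lrnet_test_from_profile(
            default_profile, lr_map, LrnetConfig(m=200, seed=3)
        )
        edges_file, paths_file = export_network(
            results, paths, str(tmp_path / "net")
        )
        edges = pd.read_csv(edges_file, sep="\t", float_precision="round_trip")
        assert np.array_equal(edges["w_st"].to_numpy(), results["w_st"].to_numpy())
        re_paths = pd.read_csv(paths_file, sep="\t")
        assert len(re_paths) == len(paths)

    def test_significant_only_can_be_header_only(self, tmp_path, tiny_profile, tiny_map):
        results, paths = lrnet_test_from_profile(
            tiny_profile, tiny_map, LrnetConfig(m=50, seed=1, alpha=1e-9)
        )
        edges_file, paths_file = export_network(
            results, paths, str(tmp_path / "net"), significant_only=True
        )
        edges = pd.read_csv(edges_file, sep="\t")
        assert len(edges) == 0
        assert list(edges.columns)[:2] == ["source", "target"]
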