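from io import StringIO

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode
from scipy.spatial.distance import pdist, squareform

from nichecase import diversity

from conftest import make_metadata, make_table


def euclidean_dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestAlpha:
    def test_shannon_closed_forms(self):
        table = make_table([[5, 5, 5, 5], [8, 0, 0, 0]])
        res = diversity.alpha_metrics(table)
        assert res["shannon"].iloc[0] == pytest.approx(2.0)
        assert res["shannon"].iloc[1] == pytest.approx(0.0)
        assert res["observed"].tolist() == [4, 1]

    def test_faith_pd_star_tree_counts_present_branches(self):
        # zero-length stem keeps the star geometry while giving skbio a root
        star = TreeNode.read(StringIO("((A:1,B:1,C:1,D:1,E:1):0);"))
        table = make_table([[1, 1, 1, 0, 0]], features=list("ABCDE"))
        res = diversity.alpha_metrics(table, star)
        assert res["faith_pd"].iloc[0] == pytest.approx(3.0)

    def test_missing_tip_is_error(self, paired_tree):
        table = make_table([[1, 1]], features=["A", "Z"])
        with pytest.raises(Exception, match="Z"):
            diversity.alpha_metrics(table, paired_tree)

    def test_z_normalize(self):
        alpha = pd.DataFrame({"observed": [8.0, 12.0, 14.0, 10.0]})
        z = diversity.z_normalize(alpha, [True, True, False, False])
        # control mean 10, sd ~2.828
        assert z["observed"].iloc[2] == pytest.approx((14 - 10) / np.sqrt(8))
        assert z["observed"].iloc[3] == pytest.approx(0.0)

    def test_z_normalize_constant_controls_error(self):
        alpha = pd.DataFrame({"observed": [10.0, 10.0, 14.0]})
        with pytest.raises(ValueError, match="variance"):
            diversity.z_normalize(alpha, [True, True, False])


class TestAlphaModel:
    def test_perfect_candidate_selected_with_full_contribution(self):
        rng = np.random.default_rng(0)
        n = 200
        meta = pd.DataFrame(
            {
                "age": rng.normal(50, 10, n),
                "sex": rng.choice(["m", "f"], n),
                "run": rng.choice(["r1", "r2"], n),
                "x": rng.normal(size=n),
            }
        )
        y = 2.0 * meta["x"]
        report = diversity.fit_alpha_model(y, meta, [], ["x"])
        assert report["terms"] == ["x"]
        assert report["contributions"]["x"] == pytest.approx(1.0, abs=1e-6)
        # with base covariates in the model, x still enters and dominates
        full = diversity.fit_alpha_model(y, meta, ["age", "sex", "run"], ["x"])
        assert "x" in full["terms"]
        assert full["contributions"]["x"] > 0.95

    def test_orthogonal_noise_candidate_rarely_selected(self):
        rng = np.random.default_rng(1)
        n, n_runs = 500, 20
        selected = 0
        for _ in range(n_runs):
            meta = pd.DataFrame(
                {
                    "age": rng.normal(50, 10, n),
                    "sex": rng.choice(["m", "f"], n),
                    "run": rng.choice(["r1", "r2"], n),
                }
            )
            y = rng.normal(size=n)
            noise = rng.normal(size=n)
            # orthogonalize against y and the base design: zero partial correlation
            from nichecase.design import build_design

            X = np.column_stack([build_design(meta, ["age", "sex", "run"]), y])
            noise = noise - X @ np.linalg.lstsq(X, noise, rcond=None)[0]
            meta["cand"] = noise
            report = diversity.fit_alpha_model(pd.Series(y), meta, ["age", "sex", "run"], ["cand"])
            selected += "cand" in report["terms"]
        assert selected <= 0.05 * n_runs

    def test_duplicated_candidate_columns_error(self):
        rng = np.random.default_rng(2)
        meta = pd.DataFrame(
            {
                "age": rng.normal(50, 10, 50),
                "sex": rng.choice(["m", "f"], 50),
                "run": rng.choice(["r1", "r2"], 50),
            }
        )
        meta["dup"] = meta["age"]
        with pytest.raises(ValueError, match="rank-deficient"):
            diversity.fit_alpha_model(
                pd.Series(rng.normal(size=50)), meta, ["age", "sex", "run", "dup"], []
            )


class TestBetaMetrics:
    def test_bray_curtis_closed_forms(self):
        table = make_table([[2, 2], [1, 3], [1, 0], [0, 1], [2, 2]])
        dm = diversity.bray_curtis(table)
        assert dm["s0", "s1"] == pytest.approx(0.25)
        assert dm["s2", "s3"] == pytest.approx(1.0)
        assert dm["s0", "s4"] == pytest.approx(0.0)

    def test_bray_curtis_zero_sum_error(self):
        with pytest.raises(Exception):
            diversity.bray_curtis(make_table([[0, 0], [1, 1]]))

    def test_unweighted_unifrac_oracle(self, paired_tree):
        # hand-enumerated branch sets on ((A:1,B:1):1,(C:1,D:1):1)
        table = make_table(
            [[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0], [1, 0, 0, 1]],
            features=list("ABCD"),
        )
        dm = diversity.unifrac(table, paired_tree, weighted=False)
        assert dm["s0", "s1"] == pytest.approx(1.0)  # disjoint clades
        assert dm["s2", "s3"] == pytest.approx(0.4)  # {A,C} vs {A,D}: 2/5
        assert dm["s0", "s0"] == 0.0

    def test_weighted_unifrac_oracle(self, paired_tree):
        # {A} vs {C}: all mass moves across 4 unit branches
        table = make_table([[4, 0, 0, 0], [0, 0, 4, 0]], features=list("ABCD"))
        dm = diversity.unifrac(table, paired_tree, weighted=True)
        assert dm["s0", "s1"] == pytest.approx(4.0)

    def test_unifrac_star_tree_equals_jaccard(self):
        rng = np.random.default_rng(4)
        star = TreeNode.read(
            StringIO("((" + ",".join(f"f{j}:1" for j in range(8)) + "):0);")
        )
        for _ in range(25):
            counts = rng.integers(0, 3, size=(5, 8))
            counts[counts.sum(axis=1) == 0, 0] = 1
            table = make_table(counts)
            dm = diversity.unifrac(table, star, weighted=False)
            presence = counts > 0
            for i in range(5):
                for j in range(i + 1, 5):
                    inter = (presence[i] & presence[j]).sum()
                    union = (presence[i] | presence[j]).sum()
                    assert dm.data[i, j] == pytest.approx(1 - inter / union)


class TestPcoa:
    def test_collinear_points_single_axis(self):
        dm = euclidean_dm([[0], [1], [3], [7]])
        res = diversity.pcoa(dm)
        pos = res.eigvals[res.eigvals > 1e-9]
        assert pos.iloc[0] / pos.sum() > 0.999

    def test_two_samples_axis_separation(self):
        dm = DistanceMatrix([[0, 3], [3, 0]], ids=["a", "b"])
        res = diversity.pcoa(dm)
        coords = res.samples.iloc[:, 0]
        assert abs(coords["a"] - coords["b"]) == pytest.approx(3.0)

    def test_identical_samples_zero_coordinates(self):
        dm = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        res = diversity.pcoa(dm)
        assert np.allclose(res.samples.to_numpy(), 0.0)

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        dm = euclidean_dm(pts)
        res = diversity.pcoa(dm)
        coords = res.samples.to_numpy()
        recon = squareform(pdist(coords))
        assert np.allclose(recon, dm.data, atol=1e-8)


class TestAdonis:
    def test_exhaustive_triplet_p(self):
        # two tight, well-separated triplets; enumerate all 20 assignments
        pts = np.array([[0, 0], [0.1, 0], [0, 0.1], [10, 10], [10.1, 10], [10, 10.1]])
        dm = euclidean_dm(pts)
        from itertools import combinations

        f_values = []
        for grp in combinations(range(6), 3):
            labels = ["b"] * 6
            for i in grp:
                labels[i] = "a"
            meta = pd.DataFrame({"g": labels}, index=dm.ids)
            res = diversity.adonis(dm, meta, ["g"], n_perm=1, seed=0)
            f_values.append(res.table.loc["g", "pseudo_F"])
        f_obs = f_values[0]  # assignment (0,1,2) is the true split
        p_exact = np.mean([f >= f_obs for f in f_values])
        assert p_exact == pytest.approx(2 / 20)

    def test_r2_matches_euclidean_brute_force(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(8, 2))
        labels = ["a"] * 4 + ["b"] * 4
        dm = euclidean_dm(pts)
        meta = pd.DataFrame({"g": labels}, index=dm.ids)
        res = diversity.adonis(dm, meta, ["g"], n_perm=1, seed=0)
        # brute force: SS_within from group centroids in coordinate space
        grand = pts.mean(axis=0)
        ss_total = ((pts - grand) ** 2).sum()
        ss_within = sum(
            ((pts[i] - pts[np.array(labels) == labels[i]].mean(axis=0)) ** 2).sum()
            for i in range(8)
        )
        r2 = 1 - ss_within / ss_total
        assert res.table.loc["g", "r_squared"] == pytest.approx(r2, abs=1e-8)
        assert res.table["r_squared"].drop("Total").sum() == pytest.approx(1.0, abs=1e-9)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 2))
        labels = rng.choice(["a", "b"], 10)
        dm = euclidean_dm(pts)
        meta = pd.DataFrame({"g": labels}, index=dm.ids)
        r2_ref = diversity.adonis(dm, meta, ["g"], n_perm=1, seed=0).table.loc["g", "r_squared"]
        order = rng.permutation(list(dm.ids))
        dm2 = dm.filter(order)
        r2_perm = diversity.adonis(dm2, meta, ["g"], n_perm=1, seed=0).table.loc["g", "r_squared"]
        assert r2_perm == pytest.approx(r2_ref, abs=1e-12)

    def test_single_level_term_error(self):
        dm = euclidean_dm(np.random.default_rng(8).normal(size=(6, 2)))
        meta = pd.DataFrame({"g": ["a"] * 6}, index=dm.ids)
        with pytest.raises(ValueError, match="single level"):
            diversity.adonis(dm, meta, ["g"], n_perm=9, seed=0)

    def test_matches_skbio_single_factor(self):
        from skbio.stats.distance import permanova

        rng = np.random.default_rng(9)
        pts = rng.normal(size=(12, 3))
        pts[:6] += 1.0
        labels = ["a"] * 6 + ["b"] * 6
        dm = euclidean_dm(pts)
        meta = pd.DataFrame({"g": labels}, index=dm.ids)
        ours = diversity.adonis(dm, meta, ["g"], n_perm=99, seed=0)
        ref = permanova(dm, np.array(labels), permutations=99)
        assert ours.table.loc["g", "pseudo_F"] == pytest.approx(ref["test statistic"], rel=1e-10)


class TestPermdispAndMantel:
    def test_permdisp_mirrored_groups_not_significant(self):
        rng = np.random.default_rng(10)
        cloud = rng.normal(size=(15, 2))
        pts = np.vstack([cloud, cloud + [50, 0]])  # identical dispersion
        dm = euclidean_dm(pts)
        res = diversity.permdisp(dm, ["a"] * 15 + ["b"] * 15, n_perm=199, seed=0)
        assert res["p-value"] > 0.5

    def test_permdisp_scaled_group_detected(self):
        rng = np.random.default_rng(11)
        hits = 0
        for rep in range(10):
            a = rng.normal(size=(30, 2))
            b = rng.normal(size=(30, 2)) * 3.0
            dm = euclidean_dm(np.vstack([a, b]))
            res = diversity.permdisp(dm, ["a"] * 30 + ["b"] * 30, n_perm=199, seed=rep)
            hits += res["p-value"] <= 0.05
        assert hits >= 9

    def test_permdisp_single_member_group_error(self):
        dm = euclidean_dm(np.random.default_rng(12).normal(size=(5, 2)))
        with pytest.raises(ValueError):
            diversity.permdisp(dm, ["a", "a", "a", "a", "b"])

    def test_mantel_identity_and_scale(self):
        dm = euclidean_dm(np.random.default_rng(13).normal(size=(10, 2)))
        r, r2, p = diversity.mantel(dm, dm, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)
        doubled = DistanceMatrix(dm.data * 2, ids=dm.ids)
        r, _, _ = diversity.mantel(dm, doubled, n_perm=9, seed=0)
        assert r == pytest.approx(1.0)

    def test_mantel_mismatched_ids_error(self):
        d1 = euclidean_dm(np.zeros((3, 2)), ids=list("abc"))
        d2 = euclidean_dm(np.zeros((3, 2)), ids=list("abd"))
        with pytest.raises(ValueError):
            diversity.mantel(d1, d2)


class TestGroupDistances:
    def test_identical_samples_all_zero(self):
        dm = DistanceMatrix(np.zeros((6, 6)), ids=[f"s{i}" for i in range(6)])
        rep = diversity.group_distance_summary(
            dm, ["a"] * 3 + ["b"] * 3, n_boot=50, n_perm=19, seed=0
        )
        assert rep["within"]["a"]["mean"] == 0.0
        assert rep["between"][("a", "b")]["mean"] == 0.0

    def test_heterogeneous_group_flagged(self):
        rng = np.random.default_rng(14)
        tight = rng.normal(0, 0.1, size=(10, 2))
        loose = rng.normal(0, 0.1, size=(10, 2)) * 60  # internal scatter >> separation
        dm = euclidean_dm(np.vstack([tight, loose]))
        rep = diversity.group_distance_summary(
            dm, ["tight"] * 10 + ["loose"] * 10, n_boot=50, n_perm=19, seed=0
        )
        assert "loose" in rep["heterogeneous"]
        assert rep["within"]["loose"]["mean"] > rep["between"][("tight", "loose")]["mean"]
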