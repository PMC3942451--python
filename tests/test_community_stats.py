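"""Distance-based tests vs exhaustive enumeration and independent oracles."""

import itertools
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

import fgakit as fk
from fgakit.community_stats import _multiset_permutations, _n_arrangements


def random_distance_matrix(rng, n):
    x = rng.random((n, 4))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.abs(x[i] - x[j]).sum()
    return d


# ---------------------------------------------------------------------------
# naive definitional oracles
# ---------------------------------------------------------------------------

def anosim_r_naive(d, labels):
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    from scipy.stats import rankdata

    ranks = rankdata([d[i, j] for i, j in pairs])
    within = [r for (i, j), r in zip(pairs, ranks) if labels[i] == labels[j]]
    between = [r for (i, j), r in zip(pairs, ranks) if labels[i] != labels[j]]
    m = n * (n - 1) / 2
    return (np.mean(between) - np.mean(within)) / (m / 2)


def adonis_f_naive(d, labels):
    n = len(labels)
    ss_t = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in set(labels):
        idx = [i for i, l in enumerate(labels) if l == g]
        ss_w += sum(
            d[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    a = len(set(labels))
    return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a)), (ss_t - ss_w) / ss_t


def mrpp_delta_naive(d, labels):
    n = len(labels)
    delta = 0.0
    for g in set(labels):
        idx = [i for i, l in enumerate(labels) if l == g]
        within = [d[i, j] for i in idx for j in idx if i < j]
        delta += (len(idx) / n) * np.mean(within)
    return delta


def exhaustive_p_naive(d, labels, stat_fn, larger_extreme):
    obs = stat_fn(d, labels)
    seen = set()
    count = total = 0
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        s = stat_fn(d, list(perm))
        total += 1
        if (s >= obs - 1e-12) if larger_extreme else (s <= obs + 1e-12):
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

class TestBrayCurtis:
    def test_arithmetic_example(self):
        prof = pd.DataFrame({"a": [1, 2, 3], "b": [3, 2, 1]})
        d = fk.bray_curtis(prof)
        assert d["a", "b"] == pytest.approx(1 / 3)

    def test_identical_samples_distance_zero(self):
        prof = pd.DataFrame({"a": [1, 2], "b": [1, 2]})
        assert fk.bray_curtis(prof)["a", "b"] == 0.0

    def test_disjoint_supports_distance_one(self):
        prof = pd.DataFrame({"a": [1, 0], "b": [0, 5]})
        assert fk.bray_curtis(prof)["a", "b"] == 1.0

    def test_negative_input_is_error(self):
        with pytest.raises(ValueError):
            fk.bray_curtis(pd.DataFrame({"a": [-1.0], "b": [1.0]}))

    def test_both_zero_pair_warns_and_is_zero(self):
        prof = pd.DataFrame({"a": [0.0, 0], "b": [0.0, 0], "c": [1.0, 1]})
        with pytest.warns(UserWarning):
            d = fk.bray_curtis(prof)
        assert d["a", "b"] == 0.0

    def test_agrees_with_scipy(self):
        from scipy.spatial.distance import braycurtis

        rng = np.random.default_rng(2)
        x = rng.random((5, 8))
        prof = pd.DataFrame(x.T, columns=[f"s{i}" for i in range(5)])
        d = fk.bray_curtis(prof)
        for i in range(5):
            for j in range(i + 1, 5):
                assert d[f"s{i}", f"s{j}"] == pytest.approx(braycurtis(x[i], x[j]))


# ---------------------------------------------------------------------------
# worked 4-sample case
# ---------------------------------------------------------------------------

class TestWorkedCase:
    def test_anosim(self, worked_distance_case):
        d, labels = worked_distance_case
        r = fk.anosim(d, labels)
        assert r.observed == pytest.approx(1.0)
        assert r.exhaustive and r.n_permutations == 6
        assert r.p_value == pytest.approx(2 / 6)

    def test_adonis(self, worked_distance_case):
        d, labels = worked_distance_case
        r = fk.adonis(d, labels)
        assert r.observed == pytest.approx(17.0)
        assert r.auxiliary["R2"] == pytest.approx(8.5 / 9.5)
        assert r.auxiliary["SS_total"] == pytest.approx(9.5)
        assert r.p_value == pytest.approx(1 / 3)

    def test_mrpp(self, worked_distance_case):
        d, labels = worked_distance_case
        r = fk.mrpp(d, labels)
        assert r.observed == pytest.approx(1.0)
        assert r.auxiliary["A"] == pytest.approx(4 / 7)
        assert r.p_value == pytest.approx(1 / 3)

    def test_all_equal_distances(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        labels = ["A", "A", "B", "B"]
        assert fk.anosim(d, labels).observed == pytest.approx(0.0)
        assert fk.mrpp(d, labels).auxiliary["A"] == pytest.approx(0.0)

    def test_single_group_is_error(self, worked_distance_case):
        d, _ = worked_distance_case
        for fn in (fk.anosim, fk.adonis, fk.mrpp):
            with pytest.raises(ValueError):
                fn(d, ["A", "A", "A", "A"])


# ---------------------------------------------------------------------------
# exhaustive enumeration agreement, N <= 6
# ---------------------------------------------------------------------------

class TestExhaustiveEnumeration:
    @pytest.mark.parametrize("n,sizes", [(4, (2, 2)), (5, (2, 3)), (6, (3, 3)), (6, (2, 2, 2))])
    def test_matches_naive_enumeration(self, n, sizes):
        rng = np.random.default_rng(n * 100 + len(sizes))
        d = random_distance_matrix(rng, n)
        labels = [chr(65 + gi) for gi, s in enumerate(sizes) for _ in range(s)]

        r = fk.anosim(d, labels)
        assert r.exhaustive
        assert r.observed == pytest.approx(anosim_r_naive(d, labels))
        assert r.p_value == pytest.approx(
            exhaustive_p_naive(d, labels, anosim_r_naive, True)
        )

        f = fk.adonis(d, labels)
        f_naive, r2_naive = adonis_f_naive(d, labels)
        assert f.observed == pytest.approx(f_naive)
        assert f.auxiliary["R2"] == pytest.approx(r2_naive)
        assert f.p_value == pytest.approx(
            exhaustive_p_naive(d, labels, lambda dd, ll: adonis_f_naive(dd, ll)[0], True)
        )

        m = fk.mrpp(d, labels)
        assert m.observed == pytest.approx(mrpp_delta_naive(d, labels))
        assert m.p_value == pytest.approx(
            exhaustive_p_naive(d, labels, mrpp_delta_naive, False)
        )
        # A uses the exact permutation expectation = mean pairwise distance
        iu = np.triu_indices(n, 1)
        assert m.auxiliary["A"] == pytest.approx(1 - m.observed / d[iu].mean())

    def test_multiset_permutation_generator(self):
        labels = ["A", "A", "B", "B", "B"]
        perms = [tuple(p) for p in _multiset_permutations(labels)]
        assert len(perms) == len(set(perms)) == _n_arrangements(np.array(labels)) == 10
        assert all(Counter(p) == Counter(labels) for p in perms)


# ---------------------------------------------------------------------------
# independent implementation cross-checks (scikit-bio)
# ---------------------------------------------------------------------------

class TestAgainstScikitBio:
    def test_anosim_r_matches_skbio(self):
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(5)
        d = fk.bray_curtis(pd.DataFrame(rng.random((12, 9)),
                                        columns=[f"s{i}" for i in range(9)]))
        labels = ["x"] * 4 + ["y"] * 5
        mine = fk.anosim(d, dict(zip(d.ids, labels)), n_perm=99, seed=0)
        ref = sk_anosim(d, grouping=list(labels), permutations=0)
        assert mine.observed == pytest.approx(ref["test statistic"])

    def test_permanova_f_matches_skbio(self):
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(6)
        d = fk.bray_curtis(pd.DataFrame(rng.random((12, 10)),
                                        columns=[f"s{i}" for i in range(10)]))
        labels = ["x"] * 5 + ["y"] * 5
        mine = fk.adonis(d, dict(zip(d.ids, labels)), n_perm=99, seed=0)
        ref = sk_permanova(d, grouping=list(labels), permutations=0)
        assert mine.observed == pytest.approx(ref["test statistic"])

    def test_anosim_rank_invariance(self):
        """R is invariant under strictly monotone distance transforms."""
        rng = np.random.default_rng(7)
        d = random_distance_matrix(rng, 8)
        labels = ["a"] * 4 + ["b"] * 4
        r1 = fk.anosim(d, labels).observed
        r2 = fk.anosim(np.sqrt(d), labels).observed
        assert r1 == pytest.approx(r2)

    def test_reordering_invariance_and_seed_reproducibility(self):
        rng = np.random.default_rng(8)
        d = random_distance_matrix(rng, 10)
        labels = ["a"] * 5 + ["b"] * 5
        perm = rng.permutation(10)
        d2 = d[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        assert fk.adonis(d, labels).observed == pytest.approx(
            fk.adonis(d2, labels2).observed
        )
        assert fk.mrpp(d, labels).observed == pytest.approx(
            fk.mrpp(d2, labels2).observed
        )
        a = fk.anosim(d, labels, n_perm=99, seed=13)
        b = fk.anosim(d, labels, n_perm=99, seed=13)
        assert a.p_value == b.p_value


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

class TestOrdination:
    def test_block_diagonal_groups_separate_on_axis_one(self):
        prof = pd.DataFrame(
            {"a1": [5, 3, 0, 0], "a2": [4, 4, 0, 0],
             "b1": [0, 0, 6, 2], "b2": [0, 0, 3, 5]},
        )
        scores = fk.ordinate(prof, method="ca")
        ax1 = scores["axis1"]
        assert np.sign(ax1["a1"]) == np.sign(ax1["a2"])
        assert np.sign(ax1["b1"]) == np.sign(ax1["b2"])
        assert np.sign(ax1["a1"]) != np.sign(ax1["b1"])

    def test_eigenvalues_between_zero_and_one(self):
        rng = np.random.default_rng(9)
        prof = pd.DataFrame(rng.random((6, 5)) * 10)
        scores = fk.ordinate(prof, method="ca")
        assert all(0 <= e <= 1 + 1e-12 for e in scores.attrs["eigenvalues"])

    def test_matches_reciprocal_averaging_fixed_point(self):
        """Axis-1 principal coordinates equal the reciprocal-averaging fixed
        point scaled by sqrt(eigenvalue)."""
        x = np.array([[5.0, 1, 0], [2, 4, 1], [0, 2, 6]])
        scores = fk.ordinate(pd.DataFrame(x, columns=["s1", "s2", "s3"]))
        r, c = x.sum(1), x.sum(0)
        v = np.array([1.0, 0.0, -1.0])
        for _ in range(3000):
            u = (x @ v) / r
            v = (x.T @ u) / c
            v = v - (c * v).sum() / c.sum()
            lam = math.sqrt((c * v**2).sum() / c.sum())
            v = v / lam
        # lam converges to the eigenvalue (two averaging steps per sweep);
        # principal coordinates are the standardized scores times sqrt(lam)
        expected = v * math.sqrt(lam)
        if np.sign(expected[0]) != np.sign(scores["axis1"].iloc[0]):
            expected = -expected
        assert scores["axis1"].values == pytest.approx(expected, abs=1e-8)
        assert scores.attrs["eigenvalues"][0] == pytest.approx(lam, abs=1e-10)

    def test_dca_detrending_centers_axis2_within_segments(self):
        rng = np.random.default_rng(10)
        prof = pd.DataFrame(rng.random((12, 10)) * 5)
        ca = fk.ordinate(prof, method="ca", segments=4)
        dca = fk.ordinate(prof, method="dca", segments=4)
        assert np.allclose(ca["axis1"], dca["axis1"])
        assert not np.allclose(ca["axis2"], dca["axis2"])

    def test_degenerate_matrix_is_error(self):
        with pytest.raises(ValueError):
            fk.ordinate(pd.DataFrame(np.zeros((3, 3))))


# ---------------------------------------------------------------------------
# response ratios
# ---------------------------------------------------------------------------

class TestResponseRatio:
    G = {"t1": "T", "t2": "T", "c1": "C", "c2": "C"}

    def test_hand_example(self):
        prof = pd.DataFrame({"t1": [4.0], "t2": [6.0], "c1": [1.0], "c2": [3.0]})
        rr = fk.response_ratio(prof, self.G, "T", "C")[0]
        assert rr.rr == pytest.approx(math.log(2.5), abs=1e-4)
        assert rr.se == pytest.approx(math.sqrt(0.29), abs=1e-4)
        assert rr.ci_low == pytest.approx(-0.139, abs=0.001)
        assert rr.ci_high == pytest.approx(1.972, abs=0.001)
        assert not rr.significant

    def test_equal_means_give_zero_rr(self):
        prof = pd.DataFrame({"t1": [2.0], "t2": [4.0], "c1": [4.0], "c2": [2.0]})
        rr = fk.response_ratio(prof, self.G, "T", "C")[0]
        assert rr.rr == pytest.approx(0.0)

    def test_zero_variance_degenerate_ci_is_significant(self):
        prof = pd.DataFrame({"t1": [4.0], "t2": [4.0], "c1": [2.0], "c2": [2.0]})
        rr = fk.response_ratio(prof, self.G, "T", "C")[0]
        assert rr.se == 0.0
        assert rr.ci_low == rr.ci_high == pytest.approx(math.log(2))
        assert rr.significant

    def test_zero_mean_reported_undefined(self):
        prof = pd.DataFrame({"t1": [0.0], "t2": [0.0], "c1": [2.0], "c2": [2.0]})
        rr = fk.response_ratio(prof, self.G, "T", "C")[0]
        assert not rr.defined
        assert not rr.significant

    def test_small_group_is_error(self):
        prof = pd.DataFrame({"t1": [1.0], "c1": [1.0], "c2": [2.0]})
        with pytest.raises(ValueError):
            fk.response_ratio(prof, {"t1": "T", "c1": "C", "c2": "C"}, "T", "C")


# ---------------------------------------------------------------------------
# array vs NGS comparison
# ---------------------------------------------------------------------------

class TestCompareToNGS:
    def _profiles(self, a_vals, g_vals):
        fams = [f"f{i}" for i in range(len(a_vals))]
        arr = fk.GeneFamilyProfile(
            pd.DataFrame({"s1": a_vals}, index=fams), provenance="array"
        )
        rel = np.asarray(g_vals, float)
        ngs = fk.GeneFamilyProfile(
            pd.DataFrame({"s1": rel / max(rel.sum(), 1.0)}, index=fams),
            provenance="ngs",
        )
        return arr, ngs

    def test_identical_orderings_give_r_one(self):
        arr, ngs = self._profiles([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        cmp = fk.compare_to_ngs(arr, ngs)
        assert cmp.pooled_r == pytest.approx(1.0)

    def test_anti_ordered_gives_r_minus_one(self):
        arr, ngs = self._profiles([4.0, 3, 2, 1], [1.0, 2, 3, 4])
        cmp = fk.compare_to_ngs(arr, ngs)
        assert cmp.pooled_r == pytest.approx(-1.0)

    def test_detection_floor_statistic(self):
        arr, ngs = self._profiles([5.0, 0.0, 2.0], [0.5, 0.3, 0.2])
        cmp = fk.compare_to_ngs(arr, ngs)
        assert cmp.detection_floor == pytest.approx(0.2)

    def test_too_few_shared_families_is_error(self):
        arr, ngs = self._profiles([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            fk.compare_to_ngs(arr, ngs)

    def test_correlation_recovery_on_simulated_pairs(self):
        """True correlation 0.8 at n = 139 estimated within ±0.1 in >=90%
        of seeds."""
        ok = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(1000 + seed)
            z = rng.standard_normal(139)
            e = rng.standard_normal(139)
            x = z
            y = 0.8 * z + math.sqrt(1 - 0.8**2) * e
            x = x - x.min() + 0.1
            y = y - y.min() + 0.1
            fams = [f"f{i}" for i in range(139)]
            arr = fk.GeneFamilyProfile(pd.DataFrame({"s": x}, index=fams))
            ngs = fk.GeneFamilyProfile(
                pd.DataFrame({"s": y / y.sum()}, index=fams), provenance="ngs"
            )
            r = fk.compare_to_ngs(arr, ngs).pooled_r
            ok += abs(r - 0.8) <= 0.1
        assert ok >= 90


class TestAgainstVegan:
    def test_mrpp_delta_and_a_match_vegan(self, tmp_path):
        """vegan::mrpp is the independent reference for delta and A."""
        import subprocess

        rng = np.random.default_rng(21)
        x = rng.random((6, 5)) + 0.05
        labels = ["a"] * 3 + ["b"] * 3
        d = fk.bray_curtis(pd.DataFrame(x.T, columns=[f"s{i}" for i in range(6)]))
        mine = fk.mrpp(d, dict(zip(d.ids, labels)))

        csv = tmp_path / "x.csv"
        pd.DataFrame(x).to_csv(csv, index=False)
        script = tmp_path / "mrpp.R"
        script.write_text(
            f"""
            suppressMessages(library(vegan))
            x <- as.matrix(read.csv("{csv}"))
            g <- factor(c("a","a","a","b","b","b"))
            m <- mrpp(vegdist(x, method="bray"), g, permutations=9)
            cat(sprintf("%.15g", m$delta), sprintf("%.15g", m$A), sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        delta_ref, a_ref = map(float, out.stdout.strip().split())
        assert mine.observed == pytest.approx(delta_ref, abs=1e-10)
        assert mine.auxiliary["A"] == pytest.approx(a_ref, abs=1e-10)
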