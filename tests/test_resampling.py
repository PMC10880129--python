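import itertools

import numpy as np
import pytest

from dayflower.datatypes import DistMatrix
from dayflower.resampling import (
    PairSet,
    build_pair_sets,
    ci_overlap_matrix,
    cross_group_correlation_ci,
    habitat_pair_resample,
    mantel,
    partial_mantel,
)


def _random_dist(rng, n, labels=None):
    pts = rng.normal(size=(n, 3))
    vals = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    labels = labels or [f"p{i}" for i in range(n)]
    return DistMatrix(labels, vals)


class TestMantel:
    def test_identity_gives_r_one_min_p(self, rng):
        x = _random_dist(rng, 6)
        res = mantel(x, x, n_perm=99, seed=1)
        assert res.observed == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_negated_entries_give_minus_one(self, rng):
        x = _random_dist(rng, 6)
        vals = x.values.max() - x.values
        np.fill_diagonal(vals, 0)
        # entries affinely negated off-diagonal -> r = -1
        y = DistMatrix(x.labels, vals)
        res = mantel(x, y, n_perm=49, seed=1)
        assert res.observed == pytest.approx(-1.0)

    def test_sampled_p_converges_to_exhaustive(self, rng):
        """On a 4x4 problem the sampled null converges to all 4! relabelings."""
        x = _random_dist(rng, 4)
        y = _random_dist(rng, 4)
        xu = x.condensed()

        def r_for(perm):
            yp = y.values[np.ix_(perm, perm)]
            iu = np.triu_indices(4, k=1)
            a, b = xu - xu.mean(), yp[iu] - yp[iu].mean()
            return (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())

        r_obs = r_for(np.arange(4))
        exhaustive = [r_for(np.array(p)) for p in itertools.permutations(range(4))]
        p_exact = np.mean([r >= r_obs - 1e-12 for r in exhaustive])
        res = mantel(x, y, n_perm=9999, seed=3)
        assert res.observed == pytest.approx(r_obs, abs=1e-12)
        assert res.p == pytest.approx(p_exact, abs=0.03)

    def test_matches_skbio_observed_statistic(self, rng):
        skbio = pytest.importorskip("skbio")
        x = _random_dist(rng, 7)
        y = _random_dist(rng, 7)
        r_ref, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(x.values, x.labels),
            skbio.DistanceMatrix(y.values, y.labels),
            method="pearson", permutations=0,
        )
        res = mantel(x, y, n_perm=9, seed=0)
        assert res.observed == pytest.approx(float(r_ref), abs=1e-12)

    def test_constant_matrix_rejected(self):
        x = DistMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        with pytest.raises(ValueError):
            mantel(x, x, n_perm=9, seed=0)

    def test_seed_reproducible_and_label_order_invariant(self, rng):
        x = _random_dist(rng, 6)
        y = _random_dist(rng, 6)
        res1 = mantel(x, y, n_perm=199, seed=42)
        res2 = mantel(x, y, n_perm=199, seed=42)
        assert res1.p == res2.p and res1.observed == res2.observed
        shuffled = [x.labels[i] for i in rng.permutation(6)]
        res3 = mantel(x.reorder(shuffled), y, n_perm=199, seed=42)
        assert res3.p == res1.p
        assert res3.observed == pytest.approx(res1.observed, abs=1e-12)


class TestPartialMantel:
    def test_perfect_association_partial_r_one(self, rng):
        x = _random_dist(rng, 6)
        z = _random_dist(rng, 6)
        res = partial_mantel(x, x, z, n_perm=49, seed=1)
        assert res.observed == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_covariate_rejected(self, rng):
        x = _random_dist(rng, 6)
        y = _random_dist(rng, 6)
        with pytest.raises(ValueError):
            partial_mantel(x, y, y, n_perm=9, seed=0)

    def test_uncorrelated_covariate_leaves_r_nearly_plain(self, rng):
        """With an independent covariate, partial r ~ plain Mantel r."""
        diffs = []
        for k in range(20):
            x = _random_dist(rng, 10)
            y = DistMatrix(x.labels, x.values + _random_dist(rng, 10).values / 2)
            z = _random_dist(rng, 10)
            plain = mantel(x, y, n_perm=9, seed=k).observed
            partial = partial_mantel(x, y, z, n_perm=9, seed=k).observed
            diffs.append(abs(plain - partial))
        assert np.median(diffs) < 0.12


class TestCrossGroup:
    def _groups(self, labels, n1):
        return {l: ("G1" if i < n1 else "G2") for i, l in enumerate(labels)}

    def test_monotone_relation_r_one(self, rng):
        x = _random_dist(rng, 8)
        y = DistMatrix(x.labels, x.values * 2.5)
        groups = {l: ("RA" if i < 4 else "UA") for i, l in enumerate(x.labels)}
        res = cross_group_correlation_ci(x, y, groups, "RA", "UA", 200, seed=0)
        assert res.observed == pytest.approx(1.0)

    def test_observed_equals_flat_pearson_oracle(self, rng):
        """Observed r equals an independent flat correlation over the pair list."""
        x = _random_dist(rng, 9)
        y = _random_dist(rng, 9, labels=x.labels)
        groups = {l: ("RA" if i < 4 else "UP") for i, l in enumerate(x.labels)}
        res = cross_group_correlation_ci(x, y, groups, "RA", "UP", 50, seed=0)
        order = sorted(x.labels)
        xs, ys = [], []
        for a in order:
            for b in order:
                if groups[a] == "RA" and groups[b] == "UP":
                    xs.append(x.pair_value(a, b))
                    ys.append(y.pair_value(a, b))
        assert res.observed == pytest.approx(np.corrcoef(xs, ys)[0, 1], abs=1e-12)

    def test_two_by_two_null_matches_enumeration(self, rng):
        """Groups of 2+2: every sampled null r appears in the exhaustive set."""
        x = _random_dist(rng, 4)
        y = _random_dist(rng, 4)
        labels = sorted(x.labels)
        groups = {l: ("RA" if i < 2 else "UA") for i, l in enumerate(labels)}
        res = cross_group_correlation_ci(x, y, groups, "RA", "UA", 500, seed=7)
        exhaustive = set()
        for combo in itertools.combinations(range(4), 2):
            g1 = list(combo)
            g2 = [i for i in range(4) if i not in combo]
            xs = [x.reorder(labels).values[a, b] for a in g1 for b in g2]
            ys = [y.reorder(labels).values[a, b] for a in g1 for b in g2]
            exhaustive.add(round(float(np.corrcoef(xs, ys)[0, 1]), 9))
        for r in res.replicates:
            assert round(float(r), 9) in exhaustive

    def test_too_few_pairs_rejected(self, rng):
        x = _random_dist(rng, 4)
        y = _random_dist(rng, 4)
        groups = {x.labels[0]: "RA", x.labels[1]: "RA",
                  x.labels[2]: "UA", x.labels[3]: "UP"}
        with pytest.raises(ValueError):
            cross_group_correlation_ci(x, y, groups, "RA", "UA", 10, seed=0)

    def test_bootstrap_ci_centres_on_observed(self, rng):
        x = _random_dist(rng, 10)
        y = DistMatrix(x.labels, x.values + 0.1 * _random_dist(rng, 10).values)
        groups = {l: ("RA" if i < 5 else "UR") for i, l in enumerate(x.labels)}
        res = cross_group_correlation_ci(
            x, y, groups, "RA", "UR", 500, seed=1, method="bootstrap"
        )
        assert res.ci_low <= res.observed <= res.ci_high


class TestPairSets:
    def test_study_size_combinatorics(self):
        groups = {}
        for hab, n in (("RA", 8), ("UA", 5), ("UP", 5), ("UR", 6)):
            for i in range(n):
                groups[f"{hab}{i}"] = hab
        cats = {c.label: c for c in build_pair_sets(groups)}
        assert len(cats["ALL"].pairs) == 276          # C(24, 2)
        assert len(cats["RA_UA"].pairs) == 40          # 8 * 5
        assert len(cats["UP"].pairs) == 10             # C(5, 2)
        assert len(cats["UA_UR"].pairs) == 30
        assert set(cats) == {"RA", "UA", "UP", "UR", "RA_UA", "RA_UP", "RA_UR",
                             "UA_UP", "UA_UR", "UP_UR", "ALL"}

    def test_unknown_habitat_rejected(self):
        with pytest.raises(ValueError):
            build_pair_sets({"a": "XX"})

    def test_self_and_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError):
            PairSet("bad", [("a", "a")])
        with pytest.raises(ValueError):
            PairSet("bad", [("a", "b"), ("b", "a")])


class TestHabitatPairResample:
    def test_single_pair_zero_width(self, rng):
        d = _random_dist(rng, 3)
        cat = PairSet("one", [(d.labels[0], d.labels[1])])
        res = habitat_pair_resample(d, [cat], n_reps=100, seed=0)["one"]
        v = d.pair_value(d.labels[0], d.labels[1])
        assert res.observed == pytest.approx(v)
        assert res.ci_low == res.ci_high == pytest.approx(v)

    def test_binary_category_mean_near_half(self):
        vals = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        d = DistMatrix(["a", "b", "c"], vals)
        cat = PairSet("mix", [("a", "b"), ("a", "c")])  # values {0, 1}
        res = habitat_pair_resample(d, [cat], n_reps=1000, seed=5)["mix"]
        assert 0.45 <= res.observed <= 0.55

    def test_infinite_pairs_excluded_with_warning(self):
        vals = np.array([[0.0, np.inf, 1.0], [np.inf, 0.0, 1.0], [1.0, 1.0, 0.0]])
        d = DistMatrix(["a", "b", "c"], vals)
        cat = PairSet("cat", [("a", "b"), ("a", "c")])
        with pytest.warns(RuntimeWarning):
            res = habitat_pair_resample(d, [cat], n_reps=50, seed=0)["cat"]
        assert res.observed == pytest.approx(1.0)

    def test_overlap_matrix_symmetric(self, rng):
        d = _random_dist(rng, 6)
        groups = {l: h for l, h in zip(d.labels, ["RA"] * 3 + ["UA"] * 3)}
        cats = [c for c in build_pair_sets(groups) if c.pairs]
        res = habitat_pair_resample(d, cats, n_reps=200, seed=2)
        overlap = ci_overlap_matrix(res)
        assert np.array_equal(overlap, overlap.T)
        assert overlap.diagonal().all()
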