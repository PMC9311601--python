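import itertools

import numpy as np
import pytest

from morphsym.io import ModulePartition
from morphsym.modularity import (
    CovariationModel,
    ModularSignalResult,
    compare_modular_signal,
    covariance_ratio,
    cr_effect_size,
    emmli_fit,
    enumerate_covariation_variants,
    landmark_congruence,
    modularity_test,
)
from morphsym.synthetic import generate_shape_matrix


@pytest.fixture(scope="module")
def two_module_partition():
    return ModulePartition("two", {i: ("A" if i <= 3 else "B") for i in range(1, 7)})


def brute_force_cr(shape, partition):
    """Double loop over coordinate-index pairs, straight from the formula.

    Squared between-module covariances (one term per cross pair of
    coordinates) over the geometric mean of the squared off-diagonal
    within-module covariances (both orders of each pair, matching the
    trace-of-squared-block convention).
    """
    cov = np.cov(shape, rowvar=False)
    labels = np.repeat(partition.labels_array(), 2)
    modules = partition.module_labels
    within = {m: 0.0 for m in modules}
    between = {frozenset(p): 0.0 for p in itertools.combinations(modules, 2)}
    p = cov.shape[0]
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            mi, mj = labels[i], labels[j]
            if mi == mj:
                within[mi] += cov[i, j] ** 2
            else:
                between[frozenset((mi, mj))] += cov[i, j] ** 2 / 2.0
    crs = []
    for a, b in itertools.combinations(modules, 2):
        crs.append(
            np.sqrt(between[frozenset((a, b))] / np.sqrt(within[a] * within[b]))
        )
    return float(np.mean(crs))


class TestCovarianceRatio:
    def test_orthogonal_modules_give_zero(self, two_module_partition):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((40, 6))
        b = rng.standard_normal((40, 6))
        a -= a.mean(axis=0)
        b -= b.mean(axis=0)
        # residualize module B on module A: exact zero cross-covariance
        b -= a @ np.linalg.lstsq(a, b, rcond=None)[0]
        shape = np.hstack([a, b])
        assert covariance_ratio(shape, two_module_partition) < 1e-10

    def test_equicorrelated_data_gives_count_ratio(self, two_module_partition):
        """When every off-diagonal covariance is equal, CR reduces to the
        ratio of between to within entry counts: sqrt(m1*m2 / sqrt(
        m1(m1-1) * m2(m2-1))) per coordinate-column block — approaching 1
        as the modules grow."""
        rho, p, n = 0.4, 12, 30
        c = np.full((p, p), rho) + (1 - rho) * np.eye(p)
        chol = np.linalg.cholesky(c)
        raw = np.random.default_rng(1).standard_normal((n, p))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        shape = np.sqrt(n - 1) * q @ chol.T  # sample covariance exactly c
        m1 = m2 = 6  # coordinate columns per module
        expected = np.sqrt(m1 * m2 / np.sqrt(m1 * (m1 - 1) * m2 * (m2 - 1)))
        assert covariance_ratio(shape, two_module_partition) == pytest.approx(
            expected, abs=1e-8
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed, two_module_partition):
        shape = np.random.default_rng(seed).standard_normal((25, 12))
        cr = covariance_ratio(shape, two_module_partition)
        assert cr == pytest.approx(brute_force_cr(shape, two_module_partition), abs=1e-10)

    def test_three_module_mean_of_pairwise(self):
        part = ModulePartition(
            "three", {1: "A", 2: "A", 3: "B", 4: "B", 5: "C", 6: "C"}
        )
        shape = np.random.default_rng(5).standard_normal((30, 12))
        assert covariance_ratio(shape, part) == pytest.approx(
            brute_force_cr(shape, part), abs=1e-10
        )

    def test_invariant_to_module_label_swap_and_within_shuffle(
        self, two_module_partition
    ):
        shape = np.random.default_rng(7).standard_normal((20, 12))
        cr = covariance_ratio(shape, two_module_partition)
        swapped = ModulePartition(
            "swap", {i: ("B" if i <= 3 else "A") for i in range(1, 7)}
        )
        assert covariance_ratio(shape, swapped) == pytest.approx(cr, abs=1e-14)
        # permute landmarks within module A (landmarks 1..3): reorder both
        # coordinate columns of landmarks 1 and 3
        perm = shape.copy()
        perm[:, [0, 1, 4, 5]] = shape[:, [4, 5, 0, 1]]
        assert covariance_ratio(perm, two_module_partition) == pytest.approx(
            cr, abs=1e-12
        )

    def test_decreases_with_weaker_between_correlation(self, two_module_partition):
        means = []
        for rho_b in (0.4, 0.2, 0.05):
            crs = [
                covariance_ratio(
                    generate_shape_matrix(
                        60, two_module_partition, 0.6, rho_b, seed=100 * s + 1
                    ),
                    two_module_partition,
                )
                for s in range(30)
            ]
            means.append(np.mean(crs))
        assert means[0] > means[1] > means[2]

    def test_degenerate_within_module_rejected(self, two_module_partition):
        shape = np.random.default_rng(2).standard_normal((20, 12))
        # constant columns: every within-module covariance of module A is
        # exactly zero, so the denominator is undefined
        shape[:, :6] = 1.0
        with pytest.raises(ValueError, match="within-module"):
            covariance_ratio(shape, two_module_partition)


class TestCrEffectSize:
    def test_modular_structure_gives_negative_z(self, two_module_partition):
        shape = generate_shape_matrix(100, two_module_partition, 0.7, 0.05, seed=3)
        res = cr_effect_size(shape, two_module_partition, permutations=199, seed=0)
        assert res.z_cr_mean < 0
        assert res.ci95[0] < res.ci95[1]
        assert len(res.z_cr_distribution) == 199

    def test_null_effect_sizes_are_calibrated(self, two_module_partition):
        """On exchangeable data ~95% of effect sizes stay within +-1.96."""
        inside = 0
        for s in range(100):
            shape = generate_shape_matrix(
                50, two_module_partition, 0.3, 0.3, seed=5000 + s
            )
            res = cr_effect_size(shape, two_module_partition, permutations=199, seed=s)
            if abs(res.z_cr_mean) <= 1.96:
                inside += 1
        assert inside >= 88

    def test_null_draws_are_fresh_cr_evaluations(self, two_module_partition):
        """The permutation null must equal covariance_ratio on a partition
        relabeled with the same size-preserving reassignment."""
        shape = generate_shape_matrix(40, two_module_partition, 0.5, 0.2, seed=9)
        labels = two_module_partition.labels_array()
        rng = np.random.default_rng(77)
        relabeled = two_module_partition.relabeled(
            labels[rng.permutation(len(labels))], "perm"
        )
        direct = covariance_ratio(shape, relabeled)
        # reproduce the first null draw of cr_effect_size with the same seed
        rng2 = np.random.default_rng(77)
        relabeled2 = two_module_partition.relabeled(
            labels[rng2.permutation(len(labels))], "perm2"
        )
        assert covariance_ratio(shape, relabeled2) == pytest.approx(direct, abs=1e-14)


def _fake_signal(name, center, spread, n=200, seed=0):
    rng = np.random.default_rng(seed)
    dist = rng.normal(center, spread, n)
    return ModularSignalResult(
        partition_name=name,
        cr=0.5,
        z_cr_mean=float(dist.mean()),
        z_cr_distribution=dist,
        ci95=(float(np.percentile(dist, 2.5)), float(np.percentile(dist, 97.5))),
        permutations=n,
        seed=seed,
    )


class TestCompareModularSignal:
    def test_self_comparison(self):
        r = _fake_signal("m1", -2.0, 0.5)
        out = compare_modular_signal([r, _fake_signal("m2", -2.0, 0.5)])
        row = out.pairwise.iloc[0]
        assert row["delta"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_overlap"] == pytest.approx(1.0, abs=0.2)

    def test_widely_separated_distributions(self):
        out = compare_modular_signal(
            [_fake_signal("a", 0.0, 0.5, seed=1), _fake_signal("b", -5.0, 0.5, seed=2)]
        )
        assert out.pairwise.iloc[0]["p_overlap"] < 0.001

    def test_letter_grouping_by_cliques(self):
        """Three models where only (1,2) and (2,3) overlap: groups a={1,2}
        and b={2,3}; 1 and 3 never share a letter."""
        res = [
            _fake_signal("m1", 0.0, 0.5, seed=1),
            _fake_signal("m2", -0.8, 0.5, seed=2),
            _fake_signal("m3", -1.6, 0.5, seed=3),
        ]
        out = compare_modular_signal(res)
        g = out.grouping
        assert set(g["m1"]) & set(g["m2"])
        assert set(g["m2"]) & set(g["m3"])
        assert not (set(g["m1"]) & set(g["m3"]))

    def test_mismatched_permutation_counts_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            compare_modular_signal(
                [_fake_signal("a", 0, 1, n=100), _fake_signal("b", 0, 1, n=200)]
            )


class TestModularityTest:
    def test_seed_stream_exchangeability(self, two_module_partition):
        shape = generate_shape_matrix(50, two_module_partition, 0.5, 0.3, seed=4)
        p1 = modularity_test(shape, two_module_partition, rounds=999, seed=1).p
        p2 = modularity_test(shape, two_module_partition, rounds=999, seed=2).p
        assert abs(p1 - p2) <= 2.0 / np.sqrt(999)

    def test_low_rounds_warn(self, two_module_partition):
        shape = generate_shape_matrix(30, two_module_partition, 0.5, 0.3, seed=4)
        with pytest.warns(UserWarning, match="unstable"):
            modularity_test(shape, two_module_partition, rounds=99, seed=0)

    def test_distribution_lengths(self, two_module_partition):
        shape = generate_shape_matrix(30, two_module_partition, 0.5, 0.3, seed=4)
        res = modularity_test(shape, two_module_partition, rounds=200, seed=0)
        assert len(res.cr_observed_distribution) == 200
        assert len(res.cr_arbitrary_distribution) == 200
        assert 0.0 < res.p <= 1.0


class TestEnumerateVariants:
    def test_uniform_partition_yields_single_flat_model(self):
        uni = ModulePartition("uniform", {i: "all" for i in range(1, 7)})
        models = enumerate_covariation_variants([uni])
        assert len(models) == 1
        assert models[0].k_params == 1

    def test_two_module_partition_yields_two_distinct(self, two_module_partition):
        models = enumerate_covariation_variants([two_module_partition])
        assert len(models) == 2
        assert sorted(m.k_params for m in models) == [2, 3]

    def test_three_module_partition_yields_four(self):
        part = ModulePartition(
            "three", {1: "A", 2: "A", 3: "B", 4: "B", 5: "C", 6: "C"}
        )
        models = enumerate_covariation_variants([part])
        assert len(models) == 4
        # {shared, per-module} within x {pooled, per-pair} between
        assert sorted(m.k_params for m in models) == [2, 4, 4, 6]

    def test_shipped_hypotheses_expand_to_nineteen(self, fixture_config):
        _, partitions = fixture_config
        assert len(enumerate_covariation_variants(partitions)) == 19


class TestEmmliFit:
    def test_loglik_matches_literal_summation(self, two_module_partition):
        """Pair-by-pair normal log-density summation on a 6-landmark
        instance must agree with the vectorized fit."""
        shape = generate_shape_matrix(40, two_module_partition, 0.5, 0.2, seed=6)
        model = CovariationModel(
            "m", two_module_partition, within_mode="per-module", between_mode="pooled"
        )
        fit = emmli_fit(shape, [model], n_eff=40)
        r = landmark_congruence(shape)
        groups = model.pair_groups()
        var = 1.0 / (40 - 3)
        zs = {}
        for (a, b), g in groups.items():
            zs.setdefault(g, []).append(np.arctanh(r[a - 1, b - 1]))
        expected = 0.0
        for g, vals in zs.items():
            mu = np.mean(vals)
            for z in vals:
                expected += -0.5 * np.log(2 * np.pi * var) - (z - mu) ** 2 / (2 * var)
        assert fit.table.loc[0, "logL"] == pytest.approx(expected, abs=1e-8)

    def test_saturated_grouping_dominates_nested(self, two_module_partition):
        class Saturated:
            name = "saturated"
            partition = two_module_partition

            def pair_groups(self):
                return {
                    (a, b): f"g{a}-{b}"
                    for a, b in itertools.combinations(range(1, 7), 2)
                }

        shape = generate_shape_matrix(40, two_module_partition, 0.5, 0.2, seed=8)
        nested = enumerate_covariation_variants([two_module_partition])
        fit = emmli_fit(
            shape, [*nested, Saturated()], n_eff=40, aicc_sample="n_eff"
        )
        sat = fit.table.set_index("name").loc["saturated", "logL"]
        assert (fit.table["logL"] <= sat + 1e-9).all()

    def test_weights_normalize_and_min_delta_zero(self, two_module_partition):
        shape = generate_shape_matrix(50, two_module_partition, 0.6, 0.1, seed=2)
        uni = ModulePartition("uniform", {i: "all" for i in range(1, 7)})
        fit = emmli_fit(
            shape,
            enumerate_covariation_variants([uni, two_module_partition]),
            n_eff=50,
        )
        assert fit.table["weight"].sum() == pytest.approx(1.0, abs=1e-8)
        assert fit.table["delta_aicc"].min() == 0.0
        assert all(-1 < r < 1 for m in fit.rho_estimates.values() for r in m.values())

    def test_flat_model_recovered_on_uniform_data(self, two_module_partition):
        """Data with one shared correlation everywhere: the 1-parameter
        flat model beats the modular expansions by AICc in >= 90% of 50
        seeds."""
        uni = ModulePartition("uniform", {i: "all" for i in range(1, 7)})
        registry = enumerate_covariation_variants([uni, two_module_partition])
        wins = 0
        for s in range(50):
            shape = generate_shape_matrix(100, two_module_partition, 0.4, 0.4, seed=700 + s)
            if emmli_fit(shape, registry, n_eff=100).best_model == "uniform":
                wins += 1
        assert wins >= 45

    def test_small_sample_rejected(self, two_module_partition):
        shape = generate_shape_matrix(10, two_module_partition, 0.5, 0.2, seed=1)
        with pytest.raises(ValueError, match="n_eff"):
            emmli_fit(
                shape,
                enumerate_covariation_variants([two_module_partition]),
                n_eff=3,
            )
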