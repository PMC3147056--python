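"""Growth yields: blank subtraction, date correction, mixture, calls, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phenodecouple.exceptions import (
    AmbiguousComponentsError,
    DegenerateMatrixError,
    InvalidParameterError,
    MissingBlankError,
)
from phenodecouple.growth import (
    GaussianMixtureFit,
    GrowthYieldMixture,
    anova_per_substrate,
    bh_fdr,
    call_growth,
    correct_date_effect,
    fit_mixture,
    growth_threshold,
    pca_scores,
    spline_growth_yield,
    subtract_blank,
)

STATED_MIXTURE = ((0.4, 0.02, 0.02), (0.2, 0.15, 0.08), (0.4, 1.00, 0.20))


def _plate_row(strain, substrate, od, date="d1", rep=1, blank=False):
    return dict(strain=strain, substrate=substrate, date=date, replicate=rep,
                od=od, is_blank=blank)


def _draw_mixture(rng, n, spec=STATED_MIXTURE):
    w = np.array([c[0] for c in spec])
    means = np.array([c[1] for c in spec])
    sds = np.array([c[2] for c in spec])
    comp = rng.choice(len(spec), p=w, size=n)
    return rng.normal(means[comp], sds[comp])


class TestSubtractBlank:
    def test_simple_subtraction(self):
        plate = pd.DataFrame([
            _plate_row("s1", "c1", 0.50),
            _plate_row("s1", "control", 0.10, blank=True),
        ])
        ym = subtract_blank(plate)
        assert ym.long["yield_od"].iloc[0] == pytest.approx(0.40)
        assert ym.blank_subtracted and not ym.date_corrected

    def test_negative_yield_preserved(self):
        plate = pd.DataFrame([
            _plate_row("s1", "c1", 0.05),
            _plate_row("s1", "control", 0.10, blank=True),
        ])
        assert subtract_blank(plate).long["yield_od"].iloc[0] == pytest.approx(-0.05)

    def test_full_synthetic_plate_shape(self, small_cohort):
        config, truth, plate = small_cohort
        ym = subtract_blank(plate)
        assert ym.data.shape == (config.n_strains, config.n_substrates)

    def test_missing_blank_names_the_plate(self):
        plate = pd.DataFrame([_plate_row("s7", "c1", 0.5, date="d2")])
        with pytest.raises(MissingBlankError, match="s7.*d2"):
            subtract_blank(plate)


def _balanced_two_date_yields(offset=0.1):
    rows = []
    base = {"s1": 0.2, "s2": 0.4, "s3": 0.6, "s4": 0.8}
    for i, (strain, y) in enumerate(base.items()):
        date = "d1" if i % 2 == 0 else "d2"
        shift = offset if date == "d1" else -offset
        rows.append(dict(strain=strain, substrate="c1", date=date, replicate=1,
                         yield_od=y + shift))
    from phenodecouple.growth import GrowthYieldMatrix

    return GrowthYieldMatrix(long=pd.DataFrame(rows))


METADATA_1FACTOR = pd.DataFrame(
    {
        "genetic_group": ["A/B1", "A/B1", "B2", "B2"],
        "pathogenic_group": ["commensal"] * 4,
        "anthropogenic_group": ["human"] * 4,
        "diet": ["omnivore"] * 4,
    },
    index=["s1", "s2", "s3", "s4"],
)


class TestDateCorrection:
    def test_single_date_is_identity(self):
        from phenodecouple.growth import GrowthYieldMatrix

        long = pd.DataFrame([
            dict(strain="s1", substrate="c1", date="d1", replicate=1, yield_od=0.3),
            dict(strain="s2", substrate="c1", date="d1", replicate=1, yield_od=0.7),
        ])
        meta = METADATA_1FACTOR.loc[["s1", "s2"]]
        out = correct_date_effect(GrowthYieldMatrix(long=long), meta)
        np.testing.assert_allclose(out.long["yield_od"], [0.3, 0.7])
        assert out.date_corrected

    def test_balanced_offsets_equalise_date_means(self):
        ym = _balanced_two_date_yields(offset=0.1)
        out = correct_date_effect(ym, METADATA_1FACTOR)
        means = out.long.groupby("date")["yield_od"].mean()
        assert abs(means["d1"] - means["d2"]) < 1e-9

    def test_idempotent(self):
        ym = _balanced_two_date_yields(offset=0.1)
        once = correct_date_effect(ym, METADATA_1FACTOR)
        twice = correct_date_effect(once, METADATA_1FACTOR)
        np.testing.assert_allclose(
            once.long["yield_od"], twice.long["yield_od"], atol=1e-9
        )

    def test_shrinks_between_date_variance_on_synthetic_plate(self, small_cohort):
        """With homogeneous strains, correction removes >= 90% of the
        between-date variance injected by date_effect_sd = 0.1."""
        import dataclasses

        from phenodecouple.synthetic import SyntheticConfig, gen_plate

        config, truth, _ = small_cohort
        cfg = SyntheticConfig(n_strains=config.n_strains, n_substrates=40,
                              n_pathways=config.n_pathways, n_dates=4,
                              date_effect_sd=0.1, seed=21)
        forced = truth.growth_states.iloc[:, :40].copy()
        forced.loc[:, :] = True
        t2 = dataclasses.replace(truth, growth_states=forced,
                                 date_of_strain=None, date_offsets=None)
        plate = gen_plate(t2, cfg, seed=21)
        raw = subtract_blank(plate)
        corrected = correct_date_effect(raw, truth.group_labels)

        def date_mean_var(ym):
            return ym.long.groupby("date")["yield_od"].mean().var()

        assert date_mean_var(corrected) < 0.1 * date_mean_var(raw) + 1e-6


class TestMixture:
    def test_single_component_recovers_standard_normal(self, rng):
        x = rng.normal(0.0, 1.0, size=2000)
        fit = fit_mixture(x, k_candidates=(1,), seed=0)
        assert fit.k == 1
        assert fit.weights[0] == pytest.approx(1.0)
        assert abs(fit.means[0]) < 3 / np.sqrt(2000)

    def test_bic_selects_three_components_on_stated_mixture(self, rng):
        x = _draw_mixture(rng, 5000)
        fit = fit_mixture(x, k_candidates=(1, 2, 3, 4, 5), seed=0)
        assert fit.k == 3
        np.testing.assert_allclose(
            np.sort(fit.means), [0.02, 0.15, 1.00], atol=0.03
        )

    def test_parsimony_preferred_on_single_population(self, rng):
        # with equal fit quality the smaller K wins through its BIC penalty
        x = rng.normal(0.5, 0.1, size=1500)
        assert fit_mixture(x, k_candidates=(1, 2, 3), seed=0).k == 1

    def test_loglik_trace_non_decreasing(self, rng):
        x = _draw_mixture(rng, 2000)
        fit = fit_mixture(x, k_candidates=(3,), seed=0)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-6)

    def test_agrees_with_sklearn_em(self, rng):
        """Independent EM implementation reaches the same likelihood basin."""
        from sklearn.mixture import GaussianMixture

        x = _draw_mixture(rng, 4000)
        fit = fit_mixture(x, k_candidates=(3,), seed=0)
        sk = GaussianMixture(3, n_init=5, random_state=0).fit(x.reshape(-1, 1))
        per_point = fit.log_likelihood / len(x)
        assert per_point == pytest.approx(sk.score(x.reshape(-1, 1)), abs=0.01)
        np.testing.assert_allclose(
            np.sort(fit.means), np.sort(sk.means_.ravel()), atol=0.02
        )

    def test_too_few_values_raise(self, rng):
        with pytest.raises(InvalidParameterError):
            fit_mixture(rng.normal(size=30), k_candidates=(5,))


def _two_component_fit(w_neg=0.5, neg=(0.0, 0.1), pos=(1.0, 0.2)):
    return GaussianMixtureFit(
        k=2,
        weights=np.array([w_neg, 1 - w_neg]),
        means=np.array([neg[0], pos[0]]),
        variances=np.array([neg[1] ** 2, pos[1] ** 2]),
        log_likelihood=0.0,
        bic=0.0,
        n=1000,
    )


class TestThreshold:
    def test_single_gaussian_nonpositive_part(self):
        # P(N(0, 0.1^2) > t) = 0.05  =>  t = 0.1 * z_0.95 = 0.16449
        t = growth_threshold(_two_component_fit(), fpr=0.05)
        assert t == pytest.approx(0.1 * stats.norm.ppf(0.95), abs=1e-5)
        assert t == pytest.approx(0.16449, abs=1e-4)

    def test_median_at_half(self):
        assert growth_threshold(_two_component_fit(), fpr=0.499999) == pytest.approx(
            0.0, abs=1e-4
        )

    def test_two_component_nonpositive_matches_grid_oracle(self):
        fit = GaussianMixtureFit(
            k=3,
            weights=np.array([0.3, 0.3, 0.4]),
            means=np.array([0.0, 0.2, 1.0]),
            variances=np.array([0.01, 0.01, 0.04]),
            log_likelihood=0.0,
            bic=0.0,
            n=1000,
        )
        t = growth_threshold(fit, fpr=0.05)
        grid = np.linspace(-1, 2, 3_000_001)
        sf = 0.5 * stats.norm.sf(grid, 0.0, 0.1) + 0.5 * stats.norm.sf(grid, 0.2, 0.1)
        t_grid = grid[np.argmin(np.abs(sf - 0.05))]
        assert t == pytest.approx(t_grid, abs=1e-6)

    def test_tied_largest_means_raise(self):
        fit = _two_component_fit(neg=(1.0, 0.1), pos=(1.0, 0.2))
        with pytest.raises(AmbiguousComponentsError):
            growth_threshold(fit)

    def test_empirical_fpr_small_sample(self, rng):
        fit = _two_component_fit()
        t = growth_threshold(fit, fpr=0.05)
        draws = rng.normal(0.0, 0.1, size=100_000)
        rate = np.mean(draws > t)
        se = np.sqrt(0.05 * 0.95 / 100_000)
        assert abs(rate - 0.05) < 3 * se

    def test_posterior_method_monotone_alternative(self):
        fit = _two_component_fit()
        t = growth_threshold(fit, fpr=0.05, method="posterior")
        post = fit.component_posteriors(t)[0, 1]
        assert post == pytest.approx(0.95, abs=1e-6)


class TestCalls:
    def test_positive_above_published_threshold(self):
        df = pd.DataFrame({"c1": [0.50]}, index=["s1"])
        assert call_growth(df, 0.3388).data.loc["s1", "c1"] == 1

    def test_boundary_is_strict(self):
        df = pd.DataFrame({"c1": [0.3388]}, index=["s1"])
        assert call_growth(df, 0.3388).data.loc["s1", "c1"] == 0

    def test_all_zero_matrix_is_all_nongrowing(self):
        df = pd.DataFrame(np.zeros((3, 4)), index=list("abc"),
                          columns=[f"c{i}" for i in range(4)])
        calls = call_growth(df, 0.3388)
        assert calls.substrate_summary() == {"nongrowing": 4, "common": 0, "selective": 0}


class TestAnova:
    def test_hand_computed_one_factor_f(self):
        # groups {0,1,2} vs {3,4,5}: two-sample t = 3.674, F = t^2 = 13.5
        yields = pd.DataFrame({"c1": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]},
                              index=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame(
            {
                "genetic_group": ["A/B1"] * 3 + ["B2"] * 3,
                "pathogenic_group": ["commensal"] * 6,
                "anthropogenic_group": ["human"] * 6,
                "diet": ["omnivore"] * 6,
            },
            index=yields.index,
        )
        table = anova_per_substrate(yields, meta)
        row = table.effects.query("effect == 'genetic_group'").iloc[0]
        assert row["F"] == pytest.approx(13.5)
        assert (row["df_num"], row["df_den"]) == (1.0, 4.0)
        assert row["p_value"] == pytest.approx(stats.f.sf(13.5, 1, 4))

    def test_type_iii_equals_sequential_on_orthogonal_design(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        y = rng.normal(size=16)
        a = np.repeat(["a1", "a2"], 8)
        b = np.tile(np.repeat(["b1", "b2"], 4), 2)
        yields = pd.DataFrame({"c1": y}, index=[f"s{i}" for i in range(16)])
        meta = pd.DataFrame(
            {"genetic_group": a, "pathogenic_group": b,
             "anthropogenic_group": ["human"] * 16, "diet": ["omnivore"] * 16},
            index=yields.index,
        )
        table = anova_per_substrate(yields, meta)
        df = pd.DataFrame({"y": y, "a": a, "b": b})
        seq = sm.stats.anova_lm(
            smf.ols("y ~ C(a, Sum) + C(b, Sum)", data=df).fit(), typ=1
        )
        got_a = table.effects.query("effect == 'genetic_group'")["F"].iloc[0]
        got_b = table.effects.query("effect == 'pathogenic_group'")["F"].iloc[0]
        assert got_a == pytest.approx(seq.loc["C(a, Sum)", "F"])
        assert got_b == pytest.approx(seq.loc["C(b, Sum)", "F"])

    def test_known_group_shift_detected_and_lsmeans_recovered(self, rng):
        n = 40
        groups = np.array(["A/B1"] * 20 + ["B2"] * 20)
        y = rng.normal(0.5, 0.05, size=n)
        y[groups == "B2"] += 0.5
        yields = pd.DataFrame({"c1": y, "c2": rng.normal(0.5, 0.05, size=n)},
                              index=[f"s{i}" for i in range(n)])
        meta = pd.DataFrame(
            {"genetic_group": groups,
             "pathogenic_group": rng.choice(["commensal", "ExPEC"], n),
             "anthropogenic_group": ["human"] * n, "diet": ["omnivore"] * n},
            index=yields.index,
        )
        table = anova_per_substrate(yields, meta)
        sig = table.significant(q=0.001)
        assert ("c1", "genetic_group") in set(zip(sig["substrate"], sig["effect"]))
        ls = table.lsmeans.query("substrate == 'c1' and effect == 'genetic_group'")
        diff = ls.set_index("level")["lsmean"].pipe(lambda s: s["B2"] - s["A/B1"])
        assert diff == pytest.approx(0.5, abs=0.1)
        assert (ls["se"] > 0).all()


class TestBH:
    def test_hand_computed_selection(self):
        p = np.array([1e-5, 4e-4, 2e-3, 0.6])
        np.testing.assert_array_equal(
            bh_fdr(p, 0.001), [True, True, False, False]
        )

    def test_all_zero_selected_all_one_none(self):
        assert bh_fdr(np.zeros(5), 0.01).all()
        assert not bh_fdr(np.ones(5), 0.01).any()

    def test_empty_input(self):
        assert bh_fdr([], 0.05).size == 0

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12),
        st.floats(min_value=0.001, max_value=0.3),
    )
    def test_matches_brute_force_step_up(self, pvals, q):
        """BH selection equals the definitional largest-i rule."""
        p = np.array(pvals)
        got = bh_fdr(p, q)
        m = len(p)
        order = np.argsort(p, kind="stable")
        k_star = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= rank * q / m:
                k_star = rank
        expected = np.zeros(m, dtype=bool)
        if k_star:
            expected[order[:k_star]] = True
        np.testing.assert_array_equal(got, expected)


class TestPCA:
    def test_single_varying_column_explains_everything(self):
        df = pd.DataFrame({"c1": [0.0, 1.0, 2.0], "c2": [1.0, 1.0, 1.0]},
                          index=list("abc"))
        _, evr = pca_scores(df)
        assert evr[0] == pytest.approx(1.0)

    def test_duplicated_strains_get_identical_scores(self, rng):
        x = rng.random((4, 5))
        df = pd.DataFrame(np.vstack([x, x[0]]), index=list("abcde"))
        scores, _ = pca_scores(df)
        np.testing.assert_allclose(scores.loc["a"], scores.loc["e"], atol=1e-9)

    def test_scores_reproduce_gram_matrix(self, rng):
        df = pd.DataFrame(rng.random((10, 5)), index=[f"s{i}" for i in range(10)])
        scores, _ = pca_scores(df)
        centered = df.to_numpy() - df.to_numpy().mean(axis=0)
        np.testing.assert_allclose(
            scores.to_numpy() @ scores.to_numpy().T, centered @ centered.T, atol=1e-9
        )

    def test_constant_matrix_raises(self):
        df = pd.DataFrame(np.ones((3, 4)), index=list("abc"))
        with pytest.raises(DegenerateMatrixError):
            pca_scores(df)


class TestSpline:
    def test_linear_curve_amplitude(self):
        t = np.arange(0, 18 * 60 + 1, 25, dtype=float)
        od = 0.1 + 0.05 * t / 60.0
        assert spline_growth_yield(t, od) == pytest.approx(0.9, abs=1e-9)

    def test_constant_series_zero_amplitude(self):
        t = np.linspace(0, 1080, 10)
        assert spline_growth_yield(t, np.full(10, 0.4)) == pytest.approx(0.0, abs=1e-12)

    def test_noisy_logistic_amplitude(self, rng):
        t = np.arange(0, 1081, 15, dtype=float)
        plateau, start, noise_sd = 1.1, 0.05, 0.01
        od = start + (plateau - start) / (1 + np.exp(-(t - 400) / 60.0))
        od += rng.normal(0, noise_sd, size=t.size)
        amp = spline_growth_yield(t, od)
        # amplitude error is the difference of two endpoint noise draws:
        # sd = sqrt(2) * noise_sd, tested at the suite-wide 3-sigma level
        assert abs(amp - (plateau - start)) < 3 * np.sqrt(2) * noise_sd

    def test_duplicate_times_raise(self):
        with pytest.raises(InvalidParameterError):
            spline_growth_yield([0, 100, 100, 1080], [0.1, 0.2, 0.2, 0.9])
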