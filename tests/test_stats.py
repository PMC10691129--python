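"""Statistical battery: Spearman/BH, Mann-Whitney, MVLR, ICC, power, OSI."""

import itertools

import numpy as np
import pandas as pd
import pytest

import lenszones.stats as st
from lenszones.errors import ValidationError
from lenszones.phantom import sample_cohort


class TestSpearman:
    def test_perfectly_monotone_pairs_give_rho_one(self):
        rho, p = st.spearman_test([1, 2, 3, 7, 9], [2, 4, 9, 11, 20])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)  # two perfectly monotone orders

    def test_exact_null_matches_brute_force_enumeration(self):
        """Independent oracle: full enumeration of all 6! rank permutations."""
        n = 6
        x = np.arange(1, n + 1, dtype=float)
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rho_obs, p_exact = st.spearman_test(x, y)
        count = 0
        for perm in itertools.permutations(range(1, n + 1)):
            d2 = sum((a - b) ** 2 for a, b in zip(range(1, n + 1), perm))
            rho = 1 - 6 * d2 / (n * (n**2 - 1))
            if abs(rho) >= abs(rho_obs) - 1e-12:
                count += 1
        assert p_exact == pytest.approx(count / 720, abs=1e-12)

    def test_constant_variable_is_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            st.spearman_test([1, 2, 3, 4, 5], [2, 2, 2, 2, 2])

    def test_type_one_error_under_independence(self):
        """Simulated size of the two-sided test at n = 49 stays near 5%."""
        rejection = st.simulate_spearman_power(0.0, 49, n_reps=2000, seed=7)
        assert 0.035 <= rejection <= 0.065


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        adj = st.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_corrected_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        adj = st.benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestMannWhitney:
    def test_three_vs_three_exact_enumeration(self):
        u, p = st.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 * (1 / 20))  # two-sided

    def test_identical_groups_give_central_u(self):
        u, _ = st.mann_whitney_u([5.0, 5.0, 5.0, 5.0], [5.0, 5.0, 5.0, 5.0])
        assert u == pytest.approx(8.0)  # n_a * n_b / 2

    def test_exact_and_normal_approximation_agree_at_20_vs_20(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=20)
        b = rng.normal(0.3, size=20)
        from scipy import stats as sps
        p_exact = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        p_norm = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert abs(p_exact - p_norm) < 0.01

    def test_rejection_rate_increases_with_shift(self):
        """Monte-Carlo monotonicity at the study's group sizes (21 vs 10)."""
        rng = np.random.default_rng(2)
        rates = []
        for shift in (0.0, 0.6, 1.2):
            hits = 0
            for _ in range(300):
                a = rng.normal(size=21)
                b = rng.normal(shift, size=10)
                _, p = st.mann_whitney_u(a, b)
                hits += p < 0.05
            rates.append(hits / 300)
        assert rates[0] < rates[1] < rates[2]


class TestMvlr:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 60
        t = np.arange(n)
        df = pd.DataFrame({
            "x1": np.cos(2 * np.pi * t / n), "x2": np.sin(2 * np.pi * t / n),
        })
        df["y"] = 2 * df.x1 - df.x2
        res = st.mvlr(df, "y", ["x1", "x2"])
        assert all(v == pytest.approx(1.0, abs=0.01) for v in res.vif.values())
        assert res.excluded == []

    def test_coefficient_recovery_within_three_se(self):
        rng = np.random.default_rng(3)
        n = 49
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = 0.27 * x1 + 0.38 * x2 + rng.normal(0, 0.2, size=n)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        res = st.mvlr(df, "y", ["x1", "x2"])
        se = 0.2 / np.sqrt(n)  # conservative scale for the check
        assert abs(res.coefficients["x1"] - 0.27) < 3 * 2 * se
        assert abs(res.coefficients["x2"] - 0.38) < 3 * 2 * se
        assert 0 <= res.breusch_pagan_p <= 1

    def test_duplicated_predictor_is_excluded(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        df = pd.DataFrame({"x1": x, "x2": x, "x3": rng.normal(size=40)})
        df["y"] = df.x1 + df.x3 + rng.normal(0, 0.1, size=40)
        res = st.mvlr(df, "y", ["x1", "x2", "x3"])
        assert len(res.excluded) == 1
        assert res.excluded[0] in ("x1", "x2")


class TestIcc:
    def test_identical_raters_give_one(self):
        r = np.tile(np.arange(1.0, 6.0)[:, None], (1, 3))
        assert st.icc(r) == pytest.approx(1.0)

    def test_constant_offset_hurts_absolute_agreement_only(self):
        r = np.arange(1.0, 6.0)[:, None] * [1.0, 1.0]
        r[:, 1] += 10.0
        assert st.icc(r, form="consistency") == pytest.approx(1.0)
        assert st.icc(r, form="absolute") < 0.2

    def test_matches_pingouin_on_random_data(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        r = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
        ours = st.icc(r)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 3),
            "rater": np.tile(np.arange(3), 12),
            "score": r.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        icc_a1 = ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0]
        assert ours == pytest.approx(icc_a1, abs=1e-9)
        icc_c1 = ref.loc[ref.Type == "ICC(C,1)", "ICC"].iloc[0]
        assert st.icc(r, form="consistency") == pytest.approx(icc_c1, abs=1e-9)

    def test_independent_raters_give_near_zero(self):
        rng = np.random.default_rng(6)
        r = rng.normal(size=(100, 2))
        assert abs(st.icc(r)) < 3 / np.sqrt(100)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            st.icc(np.ones((5, 2)))


class TestPower:
    def test_minimum_detectable_rho_at_study_size(self):
        assert st.spearman_min_detectable_rho(49) == pytest.approx(0.40, abs=0.02)

    def test_monotone_decreasing_in_n(self):
        vals = [st.spearman_min_detectable_rho(n) for n in (20, 49, 200, 10_000)]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.05

    def test_power_at_strong_correlation_is_essentially_one(self):
        assert st.spearman_power(0.86, 49) > 0.999

    def test_simulation_confirms_the_fisher_z_threshold(self):
        rho = st.spearman_min_detectable_rho(49)
        power = st.simulate_spearman_power(rho, 49, n_reps=2000, seed=11)
        assert power == pytest.approx(0.80, abs=0.05)


class TestOsi:
    def _ring_psf(self, ratio=0.0075, scale=0.25):
        n = 201
        yy, xx = np.mgrid[:n, :n]
        r = np.hypot(yy - 100, xx - 100) * scale
        psf = np.exp(-0.5 * (r / 0.3) ** 2)  # unique central peak
        psf += np.where((r >= 12) & (r <= 20), ratio, 0.0)
        return psf

    def test_delta_psf_gives_zero(self):
        psf = np.zeros((201, 201))
        psf[100, 100] = 1.0
        assert st.compute_osi(psf, 0.25) == 0.0

    def test_constructed_ratio_maps_to_reference_magnitude(self):
        # annulus at 0.0075 x the central peak, calibration 100 -> OSI 0.75
        assert st.compute_osi(self._ring_psf(), 0.25) == pytest.approx(0.75, abs=0.01)

    def test_intensity_scale_invariance(self):
        psf = self._ring_psf()
        assert st.compute_osi(2 * psf, 0.25) == pytest.approx(
            st.compute_osi(psf, 0.25), abs=1e-12
        )

    def test_annulus_outside_image_is_rejected(self):
        psf = np.zeros((41, 41))
        psf[20, 20] = 1.0
        with pytest.raises(ValidationError):
            st.compute_osi(psf, 0.25)


def test_default_cohort_shows_the_reported_age_trends():
    """Across 200 seeded replicates, lens thickness / C3 thickness / lens
    density correlate positively and the anterior-lens radius negatively
    with age (BH-significant) in at least 95% of cohorts."""
    hits = {"thickness_lens": 0, "thickness_c3": 0, "density_lens": 0,
            "radius_lens_ant": 0}
    n_rep = 200
    for seed in range(n_rep):
        t = sample_cohort(seed=seed)
        rep = st.spearman_with_bh(
            t, ("thickness_lens", "thickness_c3", "density_lens", "radius_lens_ant"))
        tab = rep.table.set_index("variable")
        for var in hits:
            sig = tab.loc[var, "significant"]
            sign_ok = (tab.loc[var, "r_s"] < 0) == (var == "radius_lens_ant")
            hits[var] += bool(sig and sign_ok)
    for var, n_hit in hits.items():
        assert n_hit >= 0.95 * n_rep, (var, n_hit)


def test_group_assignment_matches_the_study_bands():
    groups = st.assign_age_groups([9, 29, 30, 54, 55, 78])
    assert list(groups) == [1, 1, 2, 2, 3, 3]
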