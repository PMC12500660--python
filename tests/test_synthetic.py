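"""Copula cohort generator: determinism, supports, dependence, planted modes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circashift.synthetic import (
    ConfigurationError,
    DependenceSpec,
    MarginalSpec,
    PiecewiseSpec,
    ScheduleConfig,
    default_marginals,
    events_from_frame,
    generate_descriptive,
    generate_model_mode,
    generate_piecewise_mode,
    generate_shift_log,
    nearest_psd,
    refit_planted,
    spearman_to_latent,
)
from circashift.nonlinear import fit_piecewise, slope_contrast
from circashift.workload import ShiftClass, classify_shift, summarize_demand


class TestDeterminismAndSupport:
    def test_identical_seed_identical_table(self):
        t1, p1 = generate_descriptive(n=120, seed=9)
        t2, _ = generate_descriptive(n=120, seed=9)
        pd.testing.assert_frame_equal(t1, t2)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)
        t3, _ = generate_descriptive(n=120, seed=10)
        assert not t1.equals(t3)

    def test_all_values_within_declared_supports(self, cohort):
        for m in default_marginals():
            col = cohort[m.name]
            assert col.between(m.lo, m.hi).all(), m.name
            if m.discrete and m.kind != "bernoulli":
                assert (col == col.round()).all(), m.name

    def test_provenance_carries_full_config(self):
        _, prov = generate_descriptive(n=50, seed=1)
        assert prov["seed"] == 1 and prov["n"] == 50
        assert {m["name"] for m in prov["marginals"]} >= {"psqi", "phq9", "fr", "lv"}
        assert prov["dependence_repair"]

    def test_minimum_n_enforced(self):
        with pytest.raises(ConfigurationError):
            generate_descriptive(n=5, seed=0)

    def test_realized_medians_near_targets(self):
        """Each marginal's realized median stays within one score unit of its
        target at n=288, averaged over replicates."""
        targets = {m.name: m.median for m in default_marginals()
                   if m.kind == "beta" and m.median is not None}
        meds = {k: [] for k in targets}
        for seed in range(30):
            t, _ = generate_descriptive(n=288, seed=seed)
            for k in targets:
                meds[k].append(t[k].median())
        for k, target in targets.items():
            assert abs(np.mean(meds[k]) - target) <= 1.0, k


class TestDependence:
    def test_independence_when_all_rho_zero(self):
        marg = [MarginalSpec("u", 0, 30, median=15, iqr=8),
                MarginalSpec("v", 0, 30, median=15, iqr=8),
                MarginalSpec("w", 0, 30, median=15, iqr=8)]
        t, _ = generate_descriptive(marg, DependenceSpec(), n=10_000, seed=0)
        for a, b in (("u", "v"), ("u", "w"), ("v", "w")):
            rho = stats.spearmanr(t[a], t[b]).statistic
            assert abs(rho) < 0.05

    def test_copula_fidelity_against_sin_identity(self):
        """Realized Spearman matches the 2 sin(pi rho/6) latent conversion."""
        marg = [MarginalSpec("x", 0, 100, median=50, iqr=20, discrete=False),
                MarginalSpec("y", 0, 100, median=50, iqr=20, discrete=False)]
        dep = DependenceSpec(pairs=(("x", "y", 0.9),))
        t, _ = generate_descriptive(marg, dep, n=10_000, seed=4)
        realized = stats.spearmanr(t["x"], t["y"]).statistic
        assert realized == pytest.approx(0.9, abs=0.03)
        # independent oracle: simulate latent normals directly
        rng = np.random.default_rng(4)
        r = float(spearman_to_latent(0.9))
        z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=10_000)
        oracle = stats.spearmanr(z[:, 0], z[:, 1]).statistic
        assert realized == pytest.approx(oracle, abs=0.03)

    def test_impossible_triangle_raises_naming_pairs(self):
        marg = [MarginalSpec(k, 0, 30, median=15, iqr=8) for k in "abc"]
        dep = DependenceSpec(pairs=(("a", "b", 0.95), ("b", "c", 0.95),
                                    ("a", "c", -0.95)))
        with pytest.raises(ConfigurationError, match="offending pairs"):
            generate_descriptive(marg, dep, n=100, seed=0)

    def test_nearest_psd_repairs_and_preserves_unit_diagonal(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99],
                        [-0.99, 0.99, 1.0]])
        fixed = nearest_psd(bad)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        assert np.allclose(np.diag(fixed), 1.0)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ConfigurationError):
            DependenceSpec(pairs=(("a", "b", 1.5),))


class TestModelMode:
    def test_null_model_mean_is_inverse_link_of_intercept(self):
        from circashift.synthetic import GenerativeGLMSpec
        spec = GenerativeGLMSpec(outcome="psqi",
                                 coefficients={"intercept": 2.0},
                                 family="poisson", support=(0, 21))
        t, prov = generate_model_mode(spec, n=20_000, seed=1)
        assert t["psqi"].mean() == pytest.approx(np.exp(2.0), rel=0.03)
        assert prov["planted_coefficients"] == {"intercept": 2.0}

    def test_unknown_term_raises(self):
        from circashift.synthetic import GenerativeGLMSpec
        spec = GenerativeGLMSpec(outcome="psqi",
                                 coefficients={"intercept": 2.0, "nope": 0.5})
        with pytest.raises(ConfigurationError, match="unknown terms"):
            generate_model_mode(spec, n=100, seed=0)

    def test_outcome_excluded_from_copula_covariates(self):
        t, _ = generate_model_mode(outcome="phq9", n=100, seed=0)
        assert "phq9" in t.columns and "psqi" in t.columns

    def test_single_replicate_recovery_close(self):
        """One large cohort already recovers the planted headline terms."""
        t, _ = generate_model_mode(outcome="psqi", n=3_000, seed=2)
        fit = refit_planted(t, "psqi")
        assert fit.coef["phq9"] == pytest.approx(0.245, abs=0.03)

    def test_determinism(self):
        t1, _ = generate_model_mode(outcome="psqi", n=100, seed=3)
        t2, _ = generate_model_mode(outcome="psqi", n=100, seed=3)
        pd.testing.assert_frame_equal(t1, t2)


class TestPiecewiseMode:
    def test_noiseless_exact_recovery(self):
        spec = PiecewiseSpec(noise_sd=0.0, discretize=False)
        t, _ = generate_piecewise_mode(spec, n=400, seed=0)
        fit = fit_piecewise(t["shift_work_hours"], t["psqi"],
                            grid=np.unique(t["shift_work_hours"]))
        # x is continuous, so the true kink sits between observed candidates;
        # recovery is exact up to the local grid spacing
        assert fit.breakpoint == pytest.approx(spec.breakpoint, abs=0.5)
        assert fit.sse == pytest.approx(0.0, abs=1e-3)
        assert fit.slope_below == pytest.approx(spec.slope_below, abs=5e-3)
        assert fit.slope_above == pytest.approx(spec.slope_above, abs=5e-3)

    def test_breakpoint_mass_precondition(self):
        with pytest.raises(ConfigurationError, match="20%"):
            PiecewiseSpec(breakpoint=5.0, x_lo=0.0, x_hi=80.0)

    def test_equal_slopes_type_one_error_controlled(self):
        """With no slope change the structural test rejects at ~alpha."""
        spec = PiecewiseSpec(slope_below=0.02, slope_above=0.02, intercept=7.0,
                             noise_sd=2.0, discretize=False)
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            t, _ = generate_piecewise_mode(spec, n=200, seed=seed)
            # level is assessed at the true breakpoint; searching the grid
            # would add a selection effect on top of the Wald test itself
            fit = fit_piecewise(t["shift_work_hours"], t["psqi"],
                                grid=[spec.breakpoint])
            _, p = slope_contrast(fit)
            rejections += p < 0.05
        # nominal level 5%; the bound allows three binomial SDs of MC error
        assert rejections / n_rep <= 0.10


class TestShiftLog:
    def test_dn_roster_counts_and_hours(self):
        events, census, _ = generate_shift_log(n=2, seed=0)
        objs = [e for e in events_from_frame(events) if e.nurse_id == "N0001"]
        from datetime import datetime
        s = summarize_demand(objs, datetime(2024, 1, 1))
        assert s.night_count == 4
        assert s.shift_work_hours == pytest.approx(44.0)
        assert s.day_work_hours == pytest.approx(4 * 4 * 8.0)

    def test_zero_shift_config_all_zero(self):
        cfg = ScheduleConfig(long_nights_per_week=0, evenings_per_week=0,
                             day_shifts_per_week=0)
        events, _, _ = generate_shift_log(cfg, n=3, seed=0)
        assert events.empty

    def test_apn_style_roster_matches_brute_force_tally(self):
        cfg = ScheduleConfig(evenings_per_week=2, day_shifts_per_week=2)
        events, _, _ = generate_shift_log(cfg, n=1, seed=5)
        objs = events_from_frame(events)
        from datetime import datetime
        s = summarize_demand(objs, datetime(2024, 1, 1))
        tally = {"EVENING": 0, "NIGHT": 0, "shift_hours": 0.0}
        for e in objs:
            cls, net = classify_shift(e)
            if cls is not ShiftClass.DAY:
                tally[cls.value] += 1
                tally["shift_hours"] += net
        assert s.evening_count == tally["EVENING"] == 8
        assert s.night_count == tally["NIGHT"] == 4
        assert s.shift_work_hours == pytest.approx(tally["shift_hours"])
        assert s.shift_work_hours == pytest.approx(8 * 6 + 4 * 11)

    def test_events_non_overlapping_per_nurse(self):
        events, _, _ = generate_shift_log(
            ScheduleConfig(evenings_per_week=2, day_shifts_per_week=3),
            n=20, seed=1)
        for _, g in events.groupby("nurse_id"):
            g = g.sort_values("start")
            assert (g["start"].iloc[1:].to_numpy()
                    >= g["end"].iloc[:-1].to_numpy()).all()

    def test_census_covers_every_event_key(self):
        events, census, _ = generate_shift_log(n=10, seed=2)
        keys = set(zip(census["unit_id"], census["period"]))
        weeks = ((pd.to_datetime(events["start"])
                  - pd.Timestamp("2024-01-01")).dt.days // 7 + 1)
        for unit, w in zip(events["unit_id"], weeks):
            assert (unit, f"W{w}") in keys

    def test_overfull_week_rejected(self):
        with pytest.raises(ConfigurationError, match="distinct days"):
            ScheduleConfig(long_nights_per_week=3, evenings_per_week=3,
                           day_shifts_per_week=3)
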