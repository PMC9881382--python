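"""Synthetic cohort generator: determinism, planted-effect recovery, and
interval-construction invariants."""

import math

import numpy as np
import pytest
from scipy.stats import norm

import pressc as pc


class TestDiscoveryCohort:
    def test_same_seed_is_bit_identical(self):
        design = pc.DiscoveryDesign(n_proteins=40, seed=9)
        eff = [pc.EffectSpec("P0001", log2_fc=1.0, log_hr=1.5)]
        m1, meta1 = pc.generate_discovery_cohort(design, eff)
        m2, meta2 = pc.generate_discovery_cohort(design, eff)
        assert m1.equals(m2) and meta1.equals(meta2)

    def test_values_strictly_positive_and_shapes(self):
        design = pc.DiscoveryDesign(n_proteins=25, seed=1)
        m, meta = pc.generate_discovery_cohort(design)
        assert m.shape == (21, 25)
        assert (m.to_numpy() > 0).all()
        assert (meta["outcome"] == "progressor").sum() == 7
        assert ((meta["group"] == "control") == (meta["outcome"] == "not_applicable")).all()

    def test_planted_fold_change_recovered_at_large_n(self):
        # at n = 2000 per arm the empirical log2 FC pins the planted shift
        design = pc.DiscoveryDesign(n_cases=2000, n_controls=2000,
                                    n_proteins=5, n_progressors=1000, seed=4)
        m, meta = pc.generate_discovery_cohort(design, [pc.EffectSpec("P0001", log2_fc=1.0)])
        fc = pc.log_fold_change(m, meta)
        assert fc["P0001"] == pytest.approx(1.0, abs=0.06)
        assert abs(fc["P0002"]) < 0.06

    def test_null_fc_exceedance_matches_gaussian_theory(self):
        # |FC| >= 0.585 under the null: FC ~ N(0, sigma*sqrt(1/Nc + 1/Nhc))
        design_kw = dict(n_cases=13, n_controls=8, n_proteins=300, n_progressors=7)
        sd = 0.5 * math.sqrt(1 / 13 + 1 / 8)
        expected = 2 * norm.sf(0.585 / sd)
        hits = total = 0
        for seed in range(100):
            m, meta = pc.generate_discovery_cohort(pc.DiscoveryDesign(**design_kw, seed=seed))
            fc = pc.log_fold_change(m, meta)
            hits += int((np.abs(fc) >= 0.585).sum())
            total += len(fc)
        frac = hits / total
        se = math.sqrt(expected * (1 - expected) / total)
        assert abs(frac - expected) < 4 * se

    def test_progressor_shift_creates_point_biserial_association(self):
        design = pc.DiscoveryDesign(n_cases=4000, n_controls=8,
                                    n_progressors=2000, n_proteins=3, seed=2)
        m, meta = pc.generate_discovery_cohort(design, [pc.EffectSpec("P0001", log_hr=2.0)])
        log2 = np.log2(m["P0001"].to_numpy()[:4000])
        prog = (meta["outcome"] == "progressor").to_numpy()[:4000]
        gap = log2[prog].mean() - log2[~prog].mean()
        assert gap == pytest.approx(2.0 * design.sigma, abs=0.05)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            pc.DiscoveryDesign(n_cases=0)
        with pytest.raises(ValueError):
            pc.DiscoveryDesign(n_progressors=14)
        with pytest.raises(ValueError):
            pc.generate_discovery_cohort(
                pc.DiscoveryDesign(n_proteins=5),
                [pc.EffectSpec("P0001"), pc.EffectSpec("P0001")],
            )
        with pytest.raises(ValueError):
            pc.generate_discovery_cohort(
                pc.DiscoveryDesign(n_proteins=5), [pc.EffectSpec("absent")]
            )


class TestValidationCohort:
    def test_null_progression_fraction_matches_design(self):
        # baseline hazard calibrated for 40% cumulative 5-year risk
        design = pc.ValidationDesign(n_subjects=4000, n_proteins=2, seed=3)
        _, obs = pc.generate_validation_cohort(design)
        frac = np.mean([not o.right_censored for o in obs])
        assert frac == pytest.approx(0.40, abs=0.03)

    def test_interval_brackets_true_event_time(self):
        design = pc.ValidationDesign(n_subjects=300, seed=6)
        eff = pc.default_validation_effects(["P0001", "P0002"])
        _, obs, t_true = pc.generate_validation_cohort(design, eff, return_event_times=True)
        last = design.visit_times[-1]
        for o, t in zip(obs, t_true):
            if o.right_censored:
                assert t > last and o.L == last
            else:
                assert o.L < t <= o.R

    def test_interval_endpoints_lie_on_visit_grid(self):
        design = pc.ValidationDesign(n_subjects=200, seed=8)
        _, obs = pc.generate_validation_cohort(design)
        grid = set(design.visit_times) | {0.0}
        assert all(o.L in grid for o in obs)
        assert all(o.R in grid or o.right_censored for o in obs)

    def test_missing_rate(self):
        design = pc.ValidationDesign(n_subjects=400, n_proteins=10, missing_rate=0.0, seed=5)
        m, _ = pc.generate_validation_cohort(design)
        assert not m.isna().any().any()
        design = pc.ValidationDesign(n_subjects=400, n_proteins=10, missing_rate=0.1, seed=5)
        m, _ = pc.generate_validation_cohort(design)
        assert m.isna().to_numpy().mean() == pytest.approx(0.1, abs=0.02)

    def test_downstream_hazard_ratio_recovery(self):
        # one marker at log HR = log 2, n = 500, yearly visits
        design = pc.ValidationDesign(n_subjects=500, n_proteins=2, seed=21)
        m, obs = pc.generate_validation_cohort(design, [pc.EffectSpec("P0001", log_hr=math.log(2))])
        z = np.log2(m["P0001"].to_numpy())
        z = (z - z.mean()) / z.std(ddof=1)
        fit = pc.fit_ic_cox(z, obs)
        assert 1.5 < fit.hr < 2.6

    def test_bad_visit_schedules_rejected(self):
        with pytest.raises(ValueError):
            pc.ValidationDesign(visit_times=())
        with pytest.raises(ValueError):
            pc.ValidationDesign(visit_times=(1.0, 1.0, 2.0))
        with pytest.raises(ValueError):
            pc.ValidationDesign(visit_times=(1.0, 2.0), horizon=0.5)

    def test_hazard_calibration_closed_form(self):
        lam = pc.hazard_for_cumulative_risk(0.4, 5.0)
        assert 1 - math.exp(-lam * 5.0) == pytest.approx(0.4, abs=1e-12)
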