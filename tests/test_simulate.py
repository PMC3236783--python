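"""Simulator unit and property tests: cohorts, Ct model, PRT areas, degradation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnvassay.qpcr import predict_dct_drift
from cnvassay.simulate import (
    ConfigurationError,
    DegradationModel,
    InputModel,
    SimulationConfig,
    intact_fraction,
    make_cohort,
    simulate_ct,
    simulate_prt_run,
    simulate_qpcr_plate,
)

from conftest import make_sample


class TestMakeCohort:
    def test_degenerate_distribution_gives_constant_cohort(self):
        cfg = SimulationConfig(n_samples=10, cn_distribution={2: 1.0}, seed=3)
        cohort = make_cohort(cfg)
        assert len(cohort) == 10
        assert all(s.true_cn == 2 and s.input_mass == 5.0 for s in cohort)
        assert all(math.isinf(s.mean_fragment_length) for s in cohort)

    def test_same_seed_reproduces_cohort(self):
        cfg = SimulationConfig(
            n_samples=50,
            cn_distribution={1: 0.2, 2: 0.6, 3: 0.2},
            input_model=InputModel("lognormal", mean_ng=13.28, sigma_log=0.7),
            seed=11,
        )
        assert make_cohort(cfg) == make_cohort(cfg)

    def test_copy_number_frequencies_follow_distribution(self):
        cfg = SimulationConfig(
            n_samples=10_000, cn_distribution={1: 0.1, 2: 0.8, 3: 0.1}, seed=5
        )
        cns = np.array([s.true_cn for s in make_cohort(cfg)])
        for k, p in cfg.cn_distribution.items():
            assert abs((cns == k).mean() - p) < 0.02

    def test_lognormal_input_matches_mean(self):
        cfg = SimulationConfig(
            n_samples=20_000,
            cn_distribution={2: 1.0},
            input_model=InputModel("lognormal", mean_ng=13.28, sigma_log=0.7),
            seed=7,
        )
        mass = np.array([s.input_mass for s in make_cohort(cfg)])
        assert mass.mean() == pytest.approx(13.28, rel=0.03)
        assert (mass > 0).all()

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_samples=5, cn_distribution={2: 0.5, 3: 0.4})
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_samples=5, cn_distribution={-1: 1.0})


class TestIntactFraction:
    def test_closed_forms(self):
        assert intact_fraction(107, math.inf) == 1.0
        assert intact_fraction(300, 300) == pytest.approx(math.exp(-1), abs=1e-12)
        assert intact_fraction(299, 500) == pytest.approx(math.exp(-0.598), abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            intact_fraction(0, 300)
        with pytest.raises(ValueError):
            intact_fraction(107, 0)

    @given(
        length=st.floats(50, 2000),
        lam=st.floats(50, 5000),
        longer=st.floats(1, 500),
    )
    def test_monotone_in_length_and_fragment(self, length, lam, longer):
        f = intact_fraction(length, lam)
        assert 0 < f <= 1
        assert intact_fraction(length + longer, lam) <= f
        assert intact_fraction(length, lam + longer) >= f


class TestSimulateCt:
    def test_template_at_threshold_gives_ct_zero(self, target_assay, noiseless_config):
        sample = make_sample(cn=2, mass=1.0)  # 303 template copies
        cfg = noiseless_config.__class__(
            **{**noiseless_config.__dict__, "detection_threshold": 303.0}
        )
        assert simulate_ct(sample, target_assay, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_ten_perfect_doublings(self, noiseless_config):
        from cnvassay.simulate import ROLE_QPCR_TARGET, AssayProfile

        assay = AssayProfile("perfect", 1.0, 100, ROLE_QPCR_TARGET)
        sample = make_sample(cn=2, mass=1.0)  # 303 copies
        cfg = noiseless_config.__class__(
            **{**noiseless_config.__dict__, "detection_threshold": 303.0 * 2**10}
        )
        assert simulate_ct(sample, assay, cfg) == pytest.approx(10.0, abs=1e-9)

    def test_fully_degraded_template_is_missing(self, target_assay):
        cfg = SimulationConfig(n_samples=1, cn_distribution={2: 1.0}, seed=0)
        sample = make_sample(cn=2, mass=0.001, frag=1e-6)  # ~0 intact templates
        assert math.isnan(simulate_ct(sample, target_assay, cfg))

    def test_tenfold_input_shifts_ct_by_one_slope_unit(self, target_assay, noiseless_config):
        lo = simulate_ct(make_sample(mass=2.0), target_assay, noiseless_config)
        hi = simulate_ct(make_sample(mass=20.0), target_assay, noiseless_config)
        assert lo - hi == pytest.approx(1.0 / math.log10(2.0823), abs=1e-9)

    def test_prt_assay_role_rejected(self, prt_assay, noiseless_config):
        with pytest.raises(ConfigurationError):
            simulate_ct(make_sample(), prt_assay, noiseless_config)


class TestQpcrPlate:
    def test_shape_one_row_per_sample_replicate(self, target_assay, reference_assay):
        cfg = SimulationConfig(n_samples=10, cn_distribution={2: 1.0}, seed=1)
        cohort = make_cohort(cfg)
        table = simulate_qpcr_plate(cohort, target_assay, reference_assay, cfg)
        assert len(table) == 30
        assert set(table.replicate_index) == {1, 2, 3}
        assert table.ct_target.between(0, 40).all()

    def test_equal_efficiencies_make_dct_input_invariant(self, noiseless_config):
        from cnvassay.simulate import (
            ROLE_QPCR_REFERENCE,
            ROLE_QPCR_TARGET,
            AssayProfile,
        )

        t = AssayProfile("t", 0.9, 107, ROLE_QPCR_TARGET)
        r = AssayProfile("r", 0.9, 87, ROLE_QPCR_REFERENCE)
        cohort = [make_sample(mass=m, sid=f"S{i}") for i, m in enumerate([2, 5, 20, 120])]
        table = simulate_qpcr_plate(cohort, t, r, noiseless_config)
        dct = table.groupby("sample_id").ct_target.mean() - table.groupby(
            "sample_id"
        ).ct_reference.mean()
        assert np.ptp(dct.to_numpy()) < 1e-9

    def test_dct_shift_across_input_range_matches_slope_difference(self, noiseless_config):
        from cnvassay.simulate import (
            ROLE_QPCR_REFERENCE,
            ROLE_QPCR_TARGET,
            AssayProfile,
        )

        t = AssayProfile("t", 1.0823, 107, ROLE_QPCR_TARGET)
        r = AssayProfile("r", 1.0228, 87, ROLE_QPCR_REFERENCE)
        cohort = [make_sample(mass=2.0, sid="lo"), make_sample(mass=120.0, sid="hi")]
        table = simulate_qpcr_plate(cohort, t, r, noiseless_config)
        dct = (table.ct_target - table.ct_reference).groupby(table.sample_id).mean()
        measured = dct["hi"] - dct["lo"]
        expected = (-1 / math.log10(2.0823) + 1 / math.log10(2.0228)) * math.log10(60)
        assert measured == pytest.approx(expected, abs=1e-9)
        assert measured == pytest.approx(0.2297, abs=5e-4)
        # and it is what predict_dct_drift integrates over the range
        drift = predict_dct_drift(1.0823, 1.0228)
        assert measured == pytest.approx(drift.dct_per_decade * math.log10(60), abs=1e-9)

    def test_role_mismatch_rejected(self, target_assay, prt_assay, noiseless_config):
        with pytest.raises(ConfigurationError):
            simulate_qpcr_plate([make_sample()], target_assay, prt_assay, noiseless_config)

    def test_seed_determinism(self, target_assay, reference_assay):
        cfg = SimulationConfig(
            n_samples=25,
            cn_distribution={1: 0.1, 2: 0.8, 3: 0.1},
            input_model=InputModel("lognormal", mean_ng=13.28, sigma_log=0.7),
            seed=9,
        )
        a = simulate_qpcr_plate(make_cohort(cfg), target_assay, reference_assay, cfg)
        b = simulate_qpcr_plate(make_cohort(cfg), target_assay, reference_assay, cfg)
        assert a.equals(b)


class TestPrtRun:
    def test_balanced_loci_give_unit_ratio(self, prt_assay, noiseless_config):
        table = simulate_prt_run([make_sample(cn=2)], prt_assay, noiseless_config)
        assert (table.area_target / table.area_paralog).iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_duplication_doubles_ratio(self, prt_assay, noiseless_config):
        table = simulate_prt_run([make_sample(cn=4)], prt_assay, noiseless_config)
        assert (table.area_target / table.area_paralog).iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_degradation_widens_ratio_spread_without_bias(self, prt_assay):
        ratios = {}
        for frag in (math.inf, 300.0):
            cfg = SimulationConfig(
                n_samples=1000,
                cn_distribution={2: 1.0},
                degradation_model=(
                    DegradationModel("intact")
                    if math.isinf(frag)
                    else DegradationModel("degraded", frag, sigma_log=0.0)
                ),
                seed=21,
            )
            table = simulate_prt_run(make_cohort(cfg), prt_assay, cfg)
            ratios[frag] = (table.area_target / table.area_paralog).to_numpy()
        assert ratios[300.0].std() > ratios[math.inf].std()

    def test_area_ratio_unbiased_for_any_degradation(self, prt_assay):
        # E[area_target] / E[area_paralog] = true_cn / reference_copies exactly;
        # checked within 3 Monte-Carlo SE at three degradation levels.
        for frag in (math.inf, 300.0, 150.0):
            cfg = SimulationConfig(
                n_samples=10_000,
                cn_distribution={2: 1.0},
                degradation_model=(
                    DegradationModel("intact")
                    if math.isinf(frag)
                    else DegradationModel("degraded", frag, sigma_log=0.0)
                ),
                seed=22,
            )
            table = simulate_prt_run(make_cohort(cfg), prt_assay, cfg)
            at = table.area_target.to_numpy()
            ap = table.area_paralog.to_numpy()
            ratio_of_means = at.mean() / ap.mean()
            n = len(at)
            se = (
                ratio_of_means
                * math.sqrt(
                    (at.std() / at.mean()) ** 2 + (ap.std() / ap.mean()) ** 2
                )
                / math.sqrt(n)
            )
            assert abs(ratio_of_means - 1.0) < 3 * se

    def test_role_mismatch_rejected(self, target_assay, noiseless_config):
        with pytest.raises(ConfigurationError):
            simulate_prt_run([make_sample()], target_assay, noiseless_config)

    def test_seed_determinism(self, prt_assay):
        cfg = SimulationConfig(
            n_samples=30,
            cn_distribution={2: 1.0},
            degradation_model=DegradationModel("degraded", 300.0, 0.5),
            seed=4,
        )
        a = simulate_prt_run(make_cohort(cfg), prt_assay, cfg)
        b = simulate_prt_run(make_cohort(cfg), prt_assay, cfg)
        assert a.equals(b)


def test_degradation_hits_long_amplicons_harder(target_assay, reference_assay, prt_assay):
    """Call variance rises as fragment length falls, more for 299 bp PRT than 107 bp qPCR."""
    from cnvassay.prt import call_prt
    from cnvassay.qpcr import call_qpcr

    sds = {}
    for frag in (math.inf, 120.0):
        cfg = SimulationConfig(
            n_samples=2000,
            cn_distribution={2: 1.0},
            degradation_model=(
                DegradationModel("intact")
                if math.isinf(frag)
                else DegradationModel("degraded", frag, sigma_log=0.0)
            ),
            seed=31,
        )
        rng = np.random.default_rng(cfg.seed)
        cohort = make_cohort(cfg, rng)
        ct = simulate_qpcr_plate(cohort, target_assay, reference_assay, cfg, rng)
        pk = simulate_prt_run(cohort, prt_assay, cfg, rng)
        sds[frag] = (
            call_qpcr(ct, 2).continuous_cn.std(),
            call_prt(pk, 2, 2).continuous_cn.std(),
        )
    qpcr_inflation = sds[120.0][0] / sds[math.inf][0]
    prt_inflation = sds[120.0][1] / sds[math.inf][1]
    assert qpcr_inflation >= 1.0
    assert prt_inflation > qpcr_inflation
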