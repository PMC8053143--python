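"""Parameter defaults, distribution fitting, and the sensitivity registry."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from osteocea import (
    DistributionSpec,
    PARAM_REGISTRY,
    apply_overrides,
    default_parameters,
    fit_beta_from_ci,
    fit_gamma_from_ci,
    sample_parameter,
)


@pytest.mark.parametrize(
    "getter, expected",
    [
        (lambda p: p.drugs["teriparatide"].rr_hip, 0.35),
        (lambda p: p.drugs["teriparatide"].rr_vert, 0.23),
        (lambda p: p.drugs["alendronate"].rr_hip, 0.64),
        (lambda p: p.drugs["alendronate"].rr_vert, 0.50),
        (lambda p: p.drugs["teriparatide"].annual_drug_cost, 333_400),
        (lambda p: p.drugs["alendronate"].annual_drug_cost, 8_700),
        (lambda p: p.drugs["teriparatide"].prescription_charge, 1_100),
        (lambda p: p.drugs["alendronate"].prescription_charge, 1_700),
        (lambda p: p.drugs["teriparatide"].first_visit_cost, 18_300),
        (lambda p: p.drugs["teriparatide"].subsequent_visit_cost, 9_400),
        (lambda p: p.drugs["alendronate"].first_visit_cost, 3_600),
        (lambda p: p.drugs["alendronate"].subsequent_visit_cost, 1_900),
        (lambda p: p.costs.hip_medical_cost, 1_726_000),
        (lambda p: p.costs.vert_first_cost, 420_000),
        (lambda p: p.costs.vert_subsequent_cost, 842_000),
        (lambda p: p.costs.ltc_post_hip, 876_000),
        (lambda p: p.costs.ltc_post_vert, 213_000),
        (lambda p: p.costs.blood_test_cost, 2_900),
        (lambda p: p.costs.dxa_cost, 4_500),
        (lambda p: p.epidemiology.hip_rates.lookup(70), 158.1),
        (lambda p: p.epidemiology.hip_rates.lookup(82), 851.1),
        (lambda p: p.epidemiology.hip_rates.lookup(103), 2471.0),
        (lambda p: p.epidemiology.vert_rates.lookup(70), 514.0),
        (lambda p: p.epidemiology.vert_rates.lookup(96), 4369.0),
        (lambda p: p.epidemiology.rr_prior_vf_hip, 2.3),
        (lambda p: p.epidemiology.rr_prior_vf_vert, 4.4),
        (lambda p: p.mortality_extras.rh_hip_year1, 2.87),
        (lambda p: p.mortality_extras.rh_hip_later, 1.73),
        (lambda p: p.mortality_extras.attributable_hip, 0.25),
        (lambda p: p.mortality_extras.attributable_vert, 0.0),
        (lambda p: p.utilities.baseline.lookup(67), 0.862),
        (lambda p: p.utilities.baseline.lookup(72), 0.810),
        (lambda p: p.utilities.baseline.lookup(77), 0.771),
        (lambda p: p.utilities.baseline.lookup(83), 0.769),
        (lambda p: p.utilities.baseline.lookup(99), 0.684),
        (lambda p: p.utilities.hip_mult_year1, 0.776),
        (lambda p: p.utilities.vert_mult_later, 0.868),
        (lambda p: p.econ.discount_cost, 0.02),
        (lambda p: p.econ.yen_per_usd, 105),
        (lambda p: p.econ.horizon_age, 105),
        (lambda p: p.econ.wtp_thresholds, (5_000_000, 10_000_000)),
    ],
)
def test_default_values(params, getter, expected):
    assert getter(params) == expected


def test_default_parameters_pure_and_deterministic():
    a, b = default_parameters(), default_parameters()
    assert dataclasses.asdict(a) == dataclasses.asdict(b)


BETA_CIS = [
    (0.15, 0.73), (0.16, 0.32), (0.45, 0.88), (0.40, 0.64),
    (0.720, 0.844), (0.800, 0.909), (0.667, 0.779), (0.827, 0.922),
]
GAMMA_CIS = [(2.0, 2.8), (3.6, 5.4), (2.52, 3.27), (1.56, 1.90)]


@pytest.mark.parametrize("lo, hi", BETA_CIS)
def test_beta_ci_round_trip(lo, hi):
    a, b = fit_beta_from_ci(lo, hi)
    q = stats.beta.ppf([0.025, 0.975], a, b)
    assert q[0] == pytest.approx(lo, rel=1e-6)
    assert q[1] == pytest.approx(hi, rel=1e-6)


@pytest.mark.parametrize("lo, hi", GAMMA_CIS)
def test_gamma_ci_round_trip(lo, hi):
    k, scale = fit_gamma_from_ci(lo, hi)
    q = stats.gamma.ppf([0.025, 0.975], k, scale=scale)
    assert q[0] == pytest.approx(lo, rel=1e-6)
    assert q[1] == pytest.approx(hi, rel=1e-6)


def test_beta_fit_empirical_percentiles():
    a, b = fit_beta_from_ci(0.45, 0.88)
    draws = np.random.default_rng(7).beta(a, b, size=100_000)
    assert np.percentile(draws, 2.5) == pytest.approx(0.45, abs=0.01)
    assert np.percentile(draws, 97.5) == pytest.approx(0.88, abs=0.01)


def test_degenerate_ci_limits():
    a, b = fit_beta_from_ci(0.5 - 1e-7, 0.5 + 1e-7)
    assert a / (a + b) == pytest.approx(0.5, abs=1e-4)
    k, scale = fit_gamma_from_ci(1.73 - 1e-7, 1.73 + 1e-7)
    assert k * scale == pytest.approx(1.73, abs=1e-4)


@pytest.mark.parametrize("lo, hi", [(-0.1, 0.5), (0.0, 0.5), (0.5, 1.0), (0.6, 0.4)])
def test_beta_fit_rejects_bad_bounds(lo, hi):
    with pytest.raises(ValueError):
        fit_beta_from_ci(lo, hi)


def test_gamma_fit_rejects_nonpositive_bounds():
    with pytest.raises(ValueError):
        fit_gamma_from_ci(0.0, 2.8)
    with pytest.raises(ValueError):
        fit_gamma_from_ci(-1.0, 2.8)


def test_triangular_sampling_support_and_mean():
    spec = DistributionSpec("triangular", 0.7, 0.6, 0.8)
    rng = np.random.default_rng(11)
    draws = np.array([sample_parameter(spec, rng) for _ in range(100_000)])
    assert draws.min() >= 0.6 and draws.max() <= 0.8
    assert draws.mean() == pytest.approx((0.6 + 0.7 + 0.8) / 3, abs=0.001)


def test_fixed_distribution_is_constant():
    spec = DistributionSpec("fixed", 2.0)
    rng = np.random.default_rng(0)
    assert all(sample_parameter(spec, rng) == 2.0 for _ in range(10))


def test_distribution_spec_validates_bounds():
    with pytest.raises(ValueError):
        DistributionSpec("triangular", 0.9, 0.6, 0.8)   # base above hi
    with pytest.raises(ValueError):
        DistributionSpec("beta_from_ci", 0.5, 0.4, 1.2)


def test_registry_specs_are_consistent(params):
    for pid, spec in PARAM_REGISTRY.items():
        if spec.dsa_range is not None:
            lo, hi = spec.dsa_range
            assert lo <= spec.base <= hi, pid
        if spec.psa is not None and spec.psa.kind != "fixed":
            assert spec.psa.lo <= spec.psa.base <= spec.psa.hi, pid
        # applying the base value must leave a valid parameter set
        ps = params.copy()
        spec.apply(ps, spec.base)
        ps.validate()


def test_apply_overrides():
    ps = apply_overrides(default_parameters(), {"teriparatide.rr_vert": 0.16})
    assert ps.drugs["teriparatide"].rr_vert == 0.16
    # original untouched
    assert default_parameters().drugs["teriparatide"].rr_vert == 0.23


def test_apply_overrides_rejects_unknown_key():
    with pytest.raises(KeyError, match="unknown parameter identifier"):
        apply_overrides(default_parameters(), {"nonexistent.param": 1.0})
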