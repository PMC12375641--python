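import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from radioplan.dvh import DifferentialDVH
from radioplan.radiobiology import (
    DEFAULT_GAMMA50,
    FractionationScheme,
    MechanisticTCPParams,
    RadiobioModel,
    eqd2_transform,
    eud,
    evaluate_outcomes,
    load_default_registry,
    load_registry,
    ntcp_lkb,
    ntcp_poisson_lq,
    tcp_mechanistic,
    tcp_poisson_dvh,
    tcp_poisson_uniform,
)


def uniform_dvh(dose, volume=100.0, structure="s"):
    return DifferentialDVH([dose - 5.0, dose + 5.0], [volume], structure)


def two_bin(d1=4000.0, d2=6000.0, v1=0.5, v2=0.5):
    return DifferentialDVH(
        [d1 - 5, d1 + 5, d2 - 5, d2 + 5], [v1 * 100, 0.0, v2 * 100], "s"
    )


@pytest.fixture(scope="module")
def registry():
    return load_default_registry()


def by_endpoint(registry, fragment):
    matches = [m for m in registry if fragment.lower() in m.endpoint.lower()]
    assert len(matches) == 1, fragment
    return matches[0]


def ptv_model(registry):
    return next(m for m in registry if m.structure == "PTV")


# ---------------------------------------------------------------------------
# registry


class TestRegistry:
    def test_default_rows(self, registry):
        assert len(registry) == 5
        ptv = ptv_model(registry)
        assert ptv.d50 == 4920.0 and ptv.a == 9 and ptv.family == "poisson_lq"
        fib = by_endpoint(registry, "Fibrosis")
        assert (fib.d50, fib.m, fib.n) == (2880.0, 0.5, 0.34)
        pneu = by_endpoint(registry, "Pneumonitis")
        assert (pneu.d50, pneu.m, pneu.n) == (2190.0, 0.80, 0.37)
        eso = by_endpoint(registry, "Esophagitis")
        assert (eso.d50, eso.m, eso.n) == (5100.0, 0.32, 0.44)
        strict = by_endpoint(registry, "stricture")
        assert strict.d50 == 6800.0 and strict.family == "poisson_lq"

    def test_alpha_beta_converted_to_cgy(self, registry):
        assert ptv_model(registry).alpha_beta_cgy == 1000.0
        assert by_endpoint(registry, "Fibrosis").alpha_beta_cgy == 300.0

    def test_eud_exponent_is_inverse_n_for_lyman(self, registry):
        fib = by_endpoint(registry, "Fibrosis")
        assert fib.eud_exponent == pytest.approx(1 / 0.34)

    def test_eqd2_defaults(self, registry):
        assert ptv_model(registry).apply_eqd2 is True
        assert by_endpoint(registry, "stricture").apply_eqd2 is True
        assert by_endpoint(registry, "Fibrosis").apply_eqd2 is False

    def test_override_merge_by_key(self):
        models = load_registry(
            overrides=[
                {"structure": "PTV", "endpoint": "TCP Poisson-LQ", "gamma50": 2.0}
            ]
        )
        ptv = ptv_model(models)
        assert ptv.gamma50 == 2.0
        assert ptv.d50 == 4920.0  # untouched fields survive the merge

    def test_gamma50_required_when_no_default(self, registry):
        ptv = ptv_model(registry)
        with pytest.raises(ValueError, match="gamma50"):
            ptv.resolved_gamma50(default=None)

    def test_invalid_family(self):
        with pytest.raises(ValueError):
            RadiobioModel("X", "e", "probit", 100.0)

    def test_lyman_requires_m(self):
        with pytest.raises(ValueError, match="m > 0"):
            RadiobioModel("X", "e", "lyman", 100.0, n=0.5)


# ---------------------------------------------------------------------------
# EQD2


class TestEqd2:
    def test_two_gray_fixed_point(self):
        scheme = FractionationScheme(6000.0, 30)  # 2 Gy / fraction
        dvh = uniform_dvh(6000.0)
        out = eqd2_transform(dvh, 300.0, scheme)
        assert out.bin_centers[0] == pytest.approx(6000.0)

    def test_large_alpha_beta_limit(self):
        scheme = FractionationScheme(6000.0, 20)
        dvh = uniform_dvh(6000.0)
        out = eqd2_transform(dvh, 1e9, scheme)
        assert out.bin_centers[0] == pytest.approx(6000.0, rel=1e-6)

    def test_direct_lq_formula(self):
        # 6000 cGy in 20 fx at alpha/beta 3 Gy: 6000*(300+300)/(200+300) = 7200
        scheme = FractionationScheme(6000.0, 20)
        out = eqd2_transform(uniform_dvh(6000.0), 300.0, scheme)
        assert out.bin_centers[0] == pytest.approx(7200.0)

    def test_volumes_unchanged(self):
        scheme = FractionationScheme(5400.0, 30)
        dvh = two_bin()
        out = eqd2_transform(dvh, 300.0, scheme)
        assert out.total_volume == pytest.approx(dvh.total_volume)
        assert sorted(out.bin_volume) == sorted(dvh.bin_volume)


# ---------------------------------------------------------------------------
# EUD


class TestEud:
    def test_uniform_any_exponent(self):
        for a in (1.0, 9.0, 1 / 0.34, 1000.0, -5.0):
            assert eud(uniform_dvh(5000.0), a) == pytest.approx(5000.0)

    def test_a1_is_mean(self):
        dvh = two_bin()
        assert eud(dvh, 1.0) == pytest.approx(5000.0)

    def test_direct_sum_oracle_a9(self):
        # (0.5*4000^9 + 0.5*6000^9)^(1/9), evaluated independently
        assert eud(two_bin(), 9.0) == pytest.approx(5571.121717236471, rel=1e-12)

    def test_large_a_approaches_max(self):
        assert eud(two_bin(), 1000.0) == pytest.approx(6000.0, rel=1e-3)

    def test_scale_equivariance(self):
        dvh = two_bin()
        for c in (0.5, 2.0, 3.7):
            scaled = DifferentialDVH(dvh.bin_edges * c, dvh.bin_volume, "s")
            assert eud(scaled, 9.0) == pytest.approx(c * eud(dvh, 9.0), rel=1e-9)

    def test_a_zero_rejected(self):
        with pytest.raises(ValueError):
            eud(two_bin(), 0.0)

    def test_zero_volume_bins_ignored(self):
        dvh = DifferentialDVH([0, 10, 3995, 4005, 5995, 6005], [0, 0, 50, 0, 50], "s")
        assert eud(dvh, 9.0) == pytest.approx(eud(two_bin(), 9.0), rel=1e-9)


# ---------------------------------------------------------------------------
# mechanistic TCP


class TestMechanisticTCP:
    def test_zero_dose(self):
        p = MechanisticTCPParams(10.0, 1e-3)
        assert tcp_mechanistic(0.0, p) == pytest.approx(math.exp(-10.0))

    def test_high_dose_limit(self):
        p = MechanisticTCPParams(1e7, 1e-3)
        assert tcp_mechanistic(1e6, p) == pytest.approx(1.0)

    def test_half_control_dose(self):
        # choose alpha so N*exp(-alpha*D) = ln 2 at D = 5000 -> TCP = 0.5
        n, d = 1e7, 5000.0
        alpha = math.log(n / math.log(2)) / d
        assert tcp_mechanistic(d, MechanisticTCPParams(n, alpha)) == pytest.approx(0.5)

    def test_monotone_in_dose(self):
        p = MechanisticTCPParams(1e7, 2e-3)
        doses = np.linspace(0, 10000, 50)
        tcps = [tcp_mechanistic(d, p) for d in doses]
        assert np.all(np.diff(tcps) >= 0)


# ---------------------------------------------------------------------------
# phenomenological TCP


class TestPoissonTCP:
    def test_half_at_d50(self):
        assert tcp_poisson_uniform(4920.0, 4920.0, 1.5) == 0.5

    def test_limits(self):
        assert tcp_poisson_uniform(1e7, 4920.0, 1.5) == pytest.approx(1.0)
        g50 = 1.5
        expected_zero = 0.5 ** math.exp(2 * g50 / math.log(2))
        assert tcp_poisson_uniform(0.0, 4920.0, g50) == pytest.approx(expected_zero)

    def test_normalized_slope_at_d50(self):
        # gamma50 = D * dTCP/dD at D50 (normalised slope definition)
        d50, g50 = 4920.0, 1.5
        h = 0.01
        grad = (
            tcp_poisson_uniform(d50 + h, d50, g50) - tcp_poisson_uniform(d50 - h, d50, g50)
        ) / (2 * h)
        assert d50 * grad == pytest.approx(g50, rel=1e-3)

    def test_uniform_dvh_reduction(self):
        model = RadiobioModel("PTV", "tcp", "poisson_lq", 4920.0, gamma50=1.5, eqd2=False)
        dvh = uniform_dvh(5500.0)
        assert tcp_poisson_dvh(dvh, model) == pytest.approx(
            tcp_poisson_uniform(5500.0, 4920.0, 1.5), rel=1e-12
        )

    def test_per_bin_product_oracle(self, rng):
        model = RadiobioModel("PTV", "tcp", "poisson_lq", 4920.0, gamma50=1.5, eqd2=False)
        for _ in range(25):
            n = rng.integers(2, 30)
            edges = np.sort(rng.uniform(1000, 7000, size=n + 1))
            edges += np.arange(n + 1) * 1e-6
            vols = rng.uniform(0, 10, size=n)
            vols[rng.integers(0, n)] += 1.0
            dvh = DifferentialDVH(edges, vols, "s")
            v = dvh.relative_volume
            product = np.prod(
                [
                    tcp_poisson_uniform(d, 4920.0, 1.5) ** vi
                    for d, vi in zip(dvh.bin_centers, v)
                    if vi > 0
                ]
            )
            assert tcp_poisson_dvh(dvh, model) == pytest.approx(product, rel=1e-12)

    def test_zero_volume_bin_no_effect(self):
        model = RadiobioModel("PTV", "tcp", "poisson_lq", 4920.0, gamma50=1.5, eqd2=False)
        base = two_bin()
        padded = DifferentialDVH(
            np.concatenate([base.bin_edges, [9000.0]]),
            np.concatenate([base.bin_volume, [0.0]]),
            "s",
        )
        assert tcp_poisson_dvh(padded, model) == pytest.approx(
            tcp_poisson_dvh(base, model), rel=1e-12
        )

    def test_wrong_family_rejected(self):
        model = RadiobioModel("L", "x", "lyman", 2880.0, m=0.5, n=0.34)
        with pytest.raises(ValueError, match="poisson_lq"):
            tcp_poisson_dvh(uniform_dvh(5000.0), model)


# ---------------------------------------------------------------------------
# LKB NTCP


class TestLkbNtcp:
    @pytest.mark.parametrize("td50", [2190.0, 2880.0, 5100.0])
    def test_half_at_td50(self, registry, td50):
        model = [m for m in registry if m.family == "lyman" and m.d50 == td50][0]
        ntcp, eud_val = ntcp_lkb(uniform_dvh(td50), model)
        assert eud_val == pytest.approx(td50)
        assert ntcp == pytest.approx(0.5, abs=1e-12)

    def test_phi_one_at_td50_times_1_plus_m(self, registry):
        fib = by_endpoint(registry, "Fibrosis")
        dose = fib.d50 * (1 + fib.m)
        ntcp, _ = ntcp_lkb(uniform_dvh(dose), fib)
        assert ntcp == pytest.approx(0.8413447460685429, rel=1e-10)

    def test_quadrature_oracle_over_t_range(self, registry):
        fib = by_endpoint(registry, "Fibrosis")
        for t in np.linspace(-6, 6, 25):
            dose = fib.d50 * (1 + fib.m * t)
            if dose <= 0:
                continue
            ntcp, _ = ntcp_lkb(uniform_dvh(dose), fib)
            oracle, _ = integrate.quad(
                lambda x: math.exp(-x * x / 2) / math.sqrt(2 * math.pi), -np.inf, t
            )
            assert ntcp == pytest.approx(oracle, abs=1e-8)

    def test_zero_dose_equals_phi_at_minus_inverse_m(self, registry):
        # oracle: EUD = 0 -> t = -1/m -> NTCP = Phi(-1/m)
        from scipy.stats import norm

        for model in registry:
            if model.family != "lyman":
                continue
            ntcp, eud_val = ntcp_lkb(uniform_dvh(0.0 + 5.0, volume=1.0), model)
            # a true zero-dose DVH: one bin at dose 0
            zero = DifferentialDVH([0.0, 1.0], [10.0], "s")
            ntcp0, eud0 = ntcp_lkb(zero, model)
            assert eud0 == pytest.approx(0.5, abs=0.5)  # bin centre of [0, 1]
            assert ntcp0 == pytest.approx(norm.cdf(-1 / model.m), abs=1e-3)

    def test_monotone_in_dose(self, registry):
        fib = by_endpoint(registry, "Fibrosis")
        probs = [ntcp_lkb(uniform_dvh(d), fib)[0] for d in np.linspace(500, 6000, 30)]
        assert np.all(np.diff(probs) >= 0)

    def test_wrong_family_rejected(self, registry):
        ptv = ptv_model(registry)
        with pytest.raises(ValueError, match="lyman"):
            ntcp_lkb(uniform_dvh(5000.0), ptv)


# ---------------------------------------------------------------------------
# Poisson-LQ NTCP


class TestPoissonLqNtcp:
    def test_half_at_d50_physical(self):
        model = RadiobioModel("Esophagus", "stricture", "poisson_lq", 6800.0, eqd2=False)
        assert ntcp_poisson_lq(uniform_dvh(6800.0), model) == pytest.approx(0.5)

    def test_zero_dose_near_zero(self):
        model = RadiobioModel("Esophagus", "stricture", "poisson_lq", 6800.0, eqd2=False)
        zero = DifferentialDVH([0.0, 1.0], [10.0], "s")
        assert ntcp_poisson_lq(zero, model) < 1e-6

    def test_uniform_0p9_d50_scalar_oracle(self):
        g50 = 2.0
        model = RadiobioModel(
            "Esophagus", "stricture", "poisson_lq", 6800.0, gamma50=g50, eqd2=False
        )
        dose = 0.9 * 6800.0
        expected = 0.5 ** math.exp(2 * g50 * (1 - dose / 6800.0) / math.log(2))
        assert ntcp_poisson_lq(uniform_dvh(dose), model) == pytest.approx(expected, rel=1e-12)

    def test_missing_gamma50_instructs_config(self):
        model = RadiobioModel("Esophagus", "stricture", "poisson_lq", 6800.0, eqd2=False)
        with pytest.raises(ValueError, match="config"):
            ntcp_poisson_lq(uniform_dvh(6800.0), model, gamma50_default=None)


# ---------------------------------------------------------------------------
# cohort evaluation


class TestEvaluateOutcomes:
    def scheme(self):
        return FractionationScheme(5400.0, 30)

    def cohort(self, shift=0.0):
        dvhs = {}
        for p in ("P1", "P2"):
            for c in ("AAA", "AXB_Dm"):
                extra = shift if c == "AXB_Dm" else 0.0
                dvhs[(p, c)] = {
                    "PTV": uniform_dvh(5400.0 + extra, structure="PTV"),
                    "Lungs": two_bin(800.0, 2400.0, 0.7, 0.3),
                    "Esophagus": uniform_dvh(1500.0, structure="Esophagus"),
                }
        return dvhs

    def test_identical_conditions_zero_differences(self, registry):
        table = evaluate_outcomes(self.cohort(), registry, self.scheme())
        for (_, _), sub in table.groupby(["structure", "endpoint"]):
            assert sub["probability"].nunique() == 1

    def test_probabilities_in_unit_interval(self, registry):
        table = evaluate_outcomes(self.cohort(shift=300.0), registry, self.scheme())
        probs = table["probability"].dropna()
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_matches_scalar_calls(self, registry):
        table = evaluate_outcomes(self.cohort(), registry, self.scheme())
        fib = by_endpoint(registry, "Fibrosis")
        row = table[
            (table["patient"] == "P1") & (table["endpoint"] == fib.endpoint)
        ].iloc[0]
        expected, _ = ntcp_lkb(two_bin(800.0, 2400.0, 0.7, 0.3), fib, self.scheme())
        assert row["probability"] == pytest.approx(expected, rel=1e-12)

    def test_missing_structure_recorded_not_fatal(self, registry):
        dvhs = {("P1", "AAA"): {"PTV": uniform_dvh(5400.0)}}
        table = evaluate_outcomes(dvhs, registry, self.scheme())
        missing = table[table["structure"] == "Lungs"]
        assert (missing["error"] != "").all()
        assert missing["probability"].isna().all()
        ptv = table[table["structure"] == "PTV"]
        assert ptv["probability"].notna().all()


# ---------------------------------------------------------------------------
# properties


@settings(max_examples=40, deadline=None)
@given(
    dose=st.floats(100.0, 9000.0),
    bump=st.floats(1.0, 2000.0),
    g50=st.floats(0.5, 4.0),
)
def test_tcp_monotone_under_pointwise_increase(dose, bump, g50):
    assert tcp_poisson_uniform(dose + bump, 4920.0, g50) >= tcp_poisson_uniform(
        dose, 4920.0, g50
    )


@settings(max_examples=40, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_ntcp_monotone_under_pointwise_increase(seed):
    rng = np.random.default_rng(seed)
    model = RadiobioModel("L", "x", "lyman", 2880.0, m=0.5, n=0.34)
    n = int(rng.integers(2, 20))
    edges = np.sort(rng.uniform(100, 6000, size=n + 1))
    edges += np.arange(n + 1) * 1e-6
    vols = rng.uniform(0.1, 5, size=n)
    dvh = DifferentialDVH(edges, vols, "s")
    up = DifferentialDVH(edges + rng.uniform(10, 500), vols, "s")
    assert ntcp_lkb(up, model)[0] >= ntcp_lkb(dvh, model)[0]


@pytest.fixture
def rng():
    return np.random.default_rng(99)


def test_lyman_eud_limits():
    # n -> 0 (a -> inf): serial organ, EUD -> max dose; n = 1: EUD = mean
    dvh = two_bin()
    assert eud(dvh, 1000.0) == pytest.approx(6000.0, rel=1e-3)
    assert eud(dvh, 1.0) == pytest.approx(5000.0, rel=1e-12)
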