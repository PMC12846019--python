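"""Monte-Carlo propagation: degeneracy, convergence, sensitivity."""

import numpy as np
import pytest

from pte_risk.core_data import (
    CARCINOGENS,
    ELEMENTS,
    Category,
    DoseRegistry,
    Element,
    substitute_nd,
)
from pte_risk.health_risk import cancer_risk, material_risk, thq
from pte_risk.monte_carlo import (
    INPUT_KEYS,
    DistributionSpec,
    MCConfig,
    default_mc_config,
    prob_exceed,
    run_mc,
    sensitivity,
)
from .conftest import make_record


def point(v):
    return DistributionSpec("point", {"value": v})


def point_config(conc, ird=5.0, ef=90.0, bw=60.0, n_iter=100, seed=0, **over):
    inputs = {f"C_{e.value}": point(conc.get(e.value, 0.0)) for e in ELEMENTS}
    inputs["IRD"] = point(ird)
    inputs["EF"] = point(ef)
    inputs["BW"] = point(bw)
    inputs.update(over)
    return MCConfig(inputs=inputs, n_iter=n_iter, seed=seed)


class TestProbExceed:
    def test_strict_empirical_fraction(self):
        assert prob_exceed([1, 2, 3], 2) == pytest.approx(1 / 3)
        assert prob_exceed([1, 2, 3], 0) == 1.0
        assert prob_exceed([2, 2, 2], 2) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            prob_exceed([], 1.0)


class TestDegeneracy:
    def test_point_masses_reproduce_deterministic_model(self, exposure, toxicity):
        conc = {"As": 2.0, "Hg": 0.1, "Pb": 1.5, "Cd": 0.4, "Cu": 12.0}
        res = run_mc(point_config(conc, ird=5.0, n_iter=10_000))
        rec = make_record(conc=conc)
        det = material_risk([rec], DoseRegistry({"Pheretima": 5.0}), exposure, toxicity)
        assert np.all(res.hi_samples == res.hi_samples[0])
        assert res.hi_samples[0] == pytest.approx(det.hi, rel=1e-12)
        assert res.cr_samples[0] == pytest.approx(det.cr_total, rel=1e-12)
        assert res.p_hi_gt_1 in (0.0, 1.0)
        assert float(res.pct.loc["HI"].nunique()) == 1.0

    def test_zero_concentrations_give_zero_exceedance_probability(self):
        res = run_mc(point_config({}, n_iter=1000))
        assert res.p_hi_gt_1 == 0.0
        assert res.p_cr_gt_1e6 == 0.0


class TestClosedFormConvergence:
    def test_uniform_concentration_spanning_hi_threshold(self, exposure, toxicity):
        """HI is linear in a single varied concentration; uniform on
        (0, 2*c_star) with HI(c_star)=1 gives P(HI>1) = 0.5."""
        c_star = 1.0 / thq(Element.As, 1.0, 10.0, exposure, toxicity)
        cfg = point_config(
            {}, ird=10.0, n_iter=10_000, seed=42,
            C_As=DistributionSpec("uniform", {"lo": 0.0, "hi": 2.0 * c_star}),
        )
        res = run_mc(cfg)
        assert res.p_hi_gt_1 == pytest.approx(0.5, abs=0.02)

    def test_binomial_standard_error_across_seeds(self, exposure, toxicity):
        c_star = 1.0 / thq(Element.As, 1.0, 10.0, exposure, toxicity)
        ps = []
        for seed in range(5):
            cfg = point_config(
                {}, ird=10.0, n_iter=4000, seed=seed,
                C_As=DistributionSpec("uniform", {"lo": 0.0, "hi": 2.0 * c_star}),
            )
            ps.append(run_mc(cfg).p_hi_gt_1)
        se = np.sqrt(0.25 / 4000)
        assert abs(np.mean(ps) - 0.5) < 4 * se


class TestDeterminismAndScaling:
    def test_same_seed_identical_result(self):
        cfg = point_config({"As": 1.0}, n_iter=2000, seed=7,
                           C_Cu=DistributionSpec("uniform", {"lo": 1.0, "hi": 20.0}))
        a, b = run_mc(cfg), run_mc(cfg)
        assert np.array_equal(a.hi_samples, b.hi_samples)
        assert a.sensitivity.equals(b.sensitivity)

    def test_hi_percentiles_scale_with_concentration(self):
        base = {"lo": 1.0, "hi": 9.0}
        scale = 3.0
        cfg1 = point_config({}, n_iter=5000, seed=5,
                            C_As=DistributionSpec("uniform", base))
        cfg2 = point_config({}, n_iter=5000, seed=5,
                            C_As=DistributionSpec(
                                "uniform", {k: scale * v for k, v in base.items()}))
        p1 = run_mc(cfg1).pct.loc["HI"]
        p2 = run_mc(cfg2).pct.loc["HI"]
        assert np.allclose(p2.values, scale * p1.values, rtol=1e-10)


class TestSensitivity:
    def test_single_varied_input_gets_100_percent(self):
        cfg = point_config({"As": 1.0}, n_iter=2000, seed=3,
                           IRD=DistributionSpec("triangular", {"lo": 3, "mode": 9, "hi": 15}))
        res = run_mc(cfg)
        assert res.sensitivity.loc["IRD", "HI_contribution_pct"] == pytest.approx(100.0)
        assert res.sensitivity["HI_contribution_pct"].sum() == pytest.approx(100.0, abs=0.5)

    def test_symmetric_inputs_split_evenly(self):
        rng = np.random.default_rng(11)
        n = 10_000
        x1, x2 = rng.random(n), rng.random(n)
        contrib = sensitivity({"a": x1, "b": x2}, x1 + x2)
        assert contrib["a"] == pytest.approx(50.0, abs=3.0)
        assert contrib["b"] == pytest.approx(50.0, abs=3.0)

    def test_zero_coefficient_input_contributes_nothing(self):
        rng = np.random.default_rng(13)
        n = 10_000
        x1, x2 = rng.random(n), rng.random(n)
        contrib = sensitivity({"a": x1, "b": x2}, 3.0 * x1)
        assert contrib["b"] == pytest.approx(0.0, abs=1.0)
        assert contrib["a"] == pytest.approx(100.0, abs=1.0)

    def test_constant_output_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sensitivity({"a": np.arange(10.0)}, np.ones(10))

    def test_contributions_sum_to_100_in_full_model(self):
        records = substitute_nd([
            make_record(batch_id=f"B{i}", material="Pheretima",
                        conc={e: float(v) for e, v in zip(
                            ELEMENTS, np.random.default_rng(i).uniform(0.1, 5, 5))})
            for i in range(10)
        ])
        cfg = default_mc_config(records, Category.ANIMAL, (3.0, 15.0), n_iter=4000, seed=1)
        res = run_mc(cfg)
        for col in res.sensitivity.columns:
            assert res.sensitivity[col].sum() == pytest.approx(100.0, abs=0.5)
            assert (res.sensitivity[col] >= 0).all()


class TestValidation:
    def test_invalid_distribution_rejected_before_sampling(self):
        cfg = point_config({}, C_As=DistributionSpec("uniform", {"lo": 2.0, "hi": 1.0}))
        with pytest.raises(ValueError, match="C_As"):
            run_mc(cfg)

    def test_missing_input_rejected(self):
        cfg = point_config({})
        inputs = dict(cfg.inputs)
        del inputs["BW"]
        with pytest.raises(ValueError, match="BW"):
            run_mc(MCConfig(inputs=inputs, n_iter=10, seed=0))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            DistributionSpec("beta", {"a": 1, "b": 2}).validate()
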