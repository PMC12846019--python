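"""Single-factor and Nemerow pollution indices and their class bands."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pte_risk.core_data import ELEMENTS, Category, Element
from pte_risk.pollution import (
    PiResult,
    batch_pollution,
    classify_pi,
    classify_pn,
    material_pollution,
    nemerow_index,
    single_factor_index,
)
from .conftest import make_record


def pi_vector(values):
    return [
        PiResult(element=e, value=v, klass=classify_pi(v))
        for e, v in zip(ELEMENTS, values)
    ]


class TestSingleFactorIndex:
    def test_boundary_value_is_lower_class(self):
        assert single_factor_index(2.0, 2.0, Element.As).klass == "non"

    def test_printed_heavy_pollution_case(self):
        # an As concentration of 8.32 against the 2 mg/kg limit
        r = single_factor_index(8.32, 2.0, Element.As)
        assert r.value == pytest.approx(4.16)
        assert r.klass == "heavy"

    def test_zero_concentration(self):
        r = single_factor_index(0.0, 5.0, Element.Pb)
        assert (r.value, r.klass) == (0.0, "non")

    def test_nonpositive_limit_rejected(self):
        with pytest.raises(ValueError):
            single_factor_index(1.0, 0.0, Element.As)

    @given(st.floats(0.01, 100), st.floats(0.1, 50), st.floats(0.1, 10))
    def test_linearity_in_concentration(self, c, s, a):
        lhs = single_factor_index(a * c, s, Element.Cd).value
        rhs = a * single_factor_index(c, s, Element.Cd).value
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestNemerowIndex:
    def test_symmetric_unit_vector_is_alert(self):
        r = nemerow_index(pi_vector([1, 1, 1, 1, 1]))
        assert r.value == pytest.approx(1.0)
        assert r.klass == "alert"

    def test_hand_computed_single_spike(self):
        r = nemerow_index(pi_vector([2, 0, 0, 0, 0]))
        assert r.value == pytest.approx(math.sqrt((0.4**2 + 4) / 2), abs=1e-4)
        assert r.value == pytest.approx(1.4422, abs=1e-4)
        assert r.klass == "slight"

    def test_zero_vector_is_safe(self):
        r = nemerow_index(pi_vector([0, 0, 0, 0, 0]))
        assert (r.value, r.klass) == (0.0, "safe")

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            nemerow_index(pi_vector([1, 1, 1, 1, 1])[:4])

    @given(st.lists(st.floats(0, 10), min_size=5, max_size=5))
    @settings(max_examples=200)
    def test_algebraic_bounds(self, values):
        r = nemerow_index(pi_vector(values))
        mx = max(values)
        assert r.value <= mx + 1e-9
        assert r.value >= mx / math.sqrt(2) - 1e-9

    @given(
        st.lists(st.floats(0, 10), min_size=5, max_size=5),
        st.integers(0, 4),
        st.floats(0.01, 5),
    )
    def test_monotone_in_each_component(self, values, idx, bump):
        base = nemerow_index(pi_vector(values)).value
        values[idx] += bump
        assert nemerow_index(pi_vector(values)).value >= base - 1e-12


class TestClassBands:
    def test_bands_partition_dense_grid(self):
        grid = np.linspace(0.0, 6.0, 6001)
        for v in grid:
            assert classify_pi(float(v)) in ("non", "slight", "moderate", "heavy")
            assert classify_pn(float(v)) in ("safe", "alert", "slight", "moderate", "heavy")

    @pytest.mark.parametrize(
        "value, expected", [(1.0, "non"), (2.0, "slight"), (3.0, "moderate"), (3.0001, "heavy")]
    )
    def test_pi_boundaries_belong_to_lower_class(self, value, expected):
        assert classify_pi(value) == expected

    @pytest.mark.parametrize(
        "value, expected",
        [(0.7, "safe"), (1.0, "alert"), (2.0, "slight"), (3.0, "moderate"), (3.1, "heavy")],
    )
    def test_pn_boundaries_belong_to_lower_class(self, value, expected):
        assert classify_pn(value) == expected

    def test_pi_class_transitions_are_ordered(self):
        grid = np.linspace(0, 5, 2001)
        classes = [classify_pi(float(v)) for v in grid]
        order = {"non": 0, "slight": 1, "moderate": 2, "heavy": 3}
        ranks = [order[c] for c in classes]
        assert ranks == sorted(ranks)  # no gaps/overlaps: monotone class index


class TestBatchAndMaterialPollution:
    def test_half_limit_batch_is_safe(self):
        from pte_risk.core_data import limits_for
        limits = limits_for("Pheretima")
        rec = make_record(conc={e: limits[e] / 2 for e in ELEMENTS})
        pn = batch_pollution(rec)
        assert all(p.value == pytest.approx(0.5) for p in pn.pi_vector)
        assert pn.value == pytest.approx(0.5)
        assert pn.klass == "safe"

    def test_hirudo_override_changes_pi(self):
        rec = make_record(material="Hirudo",
                          conc={e: 0.5 if e is Element.Hg else 0.0 for e in ELEMENTS})
        pn = batch_pollution(rec)
        hg = next(p for p in pn.pi_vector if p.element is Element.Hg)
        assert hg.value == pytest.approx(0.5)  # limit 1 mg/kg, not the default 0.2

    def test_heavy_single_element_yields_moderate_composite(self):
        # one element at 3.11x its limit among a 0.2 background
        values = [3.11, 0.2, 0.2, 0.2, 0.2]
        pn = nemerow_index(pi_vector(values))
        assert pn.value == pytest.approx(2.267, abs=1e-3)
        assert pn.klass == "moderate"

    def test_single_batch_material_equals_batch_result(self):
        rec = make_record(conc={"As": 1.4, "Hg": 0.05, "Pb": 2.0, "Cd": 0.2, "Cu": 8.0})
        b = batch_pollution(rec)
        for mode in ("mean", "max"):
            m = material_pollution([rec], mode=mode)
            assert m.value == pytest.approx(b.value)

    def test_mean_and_max_modes(self):
        recs = [
            make_record(batch_id="B1", conc={"As": 1.0}),
            make_record(batch_id="B2", conc={"As": 3.0}),
        ]
        mean_pi = material_pollution(recs, mode="mean").pi_vector[0]
        max_pi = material_pollution(recs, mode="max").pi_vector[0]
        assert mean_pi.value == pytest.approx(1.0)  # mean 2.0 over limit 2
        assert max_pi.value == pytest.approx(1.5)

    def test_mixed_materials_rejected(self):
        recs = [make_record(material="Hirudo"), make_record(material="Pheretima")]
        with pytest.raises(ValueError, match="mixed"):
            material_pollution(recs)

    def test_unsubstituted_batch_rejected(self):
        with pytest.raises(ValueError, match="substitute"):
            batch_pollution(make_record(nd=("As",)))
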