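"""Life-cycle characterization engine and scenario operations."""

import numpy as np
import pandas as pd
import pytest

from cecburden.lca import (
    CharacterizationError,
    CharacterizationSet,
    ElectricityMix,
    Inventory,
    ScenarioSpec,
    apply_electricity_mix,
    apply_scenario,
    characterize,
    load_factors,
    load_inventory,
    load_mixes,
    percent_change,
    write_factors,
    write_inventory,
    write_mixes,
)


def identity_factors(flows, categories=None):
    cats = categories or list(flows)
    mat = pd.DataFrame(0.0, index=list(flows), columns=cats)
    for f, c in zip(flows, cats):
        mat.loc[f, c] = 1.0
    return CharacterizationSet(mat)


class TestCharacterize:
    def test_identity_matrix_returns_amounts(self):
        inv = Inventory({"a": 2.0, "b": 5.0})
        scores = characterize(inv, identity_factors(["a", "b"]))
        assert scores["a"] == 2.0 and scores["b"] == 5.0

    def test_zero_inventory_all_zero(self):
        inv = Inventory({"a": 0.0, "b": 0.0})
        cs = identity_factors(["a", "b"])
        assert (characterize(inv, cs) == 0.0).all()

    def test_toy_dot_products(self):
        inv = Inventory({"f1": 2.0, "f2": 3.0})
        cs = CharacterizationSet(
            pd.DataFrame([[1.0, 4.0], [2.0, 0.5]], index=["f1", "f2"], columns=["c1", "c2"])
        )
        scores = characterize(inv, cs)
        assert scores["c1"] == pytest.approx(2 * 1 + 3 * 2)
        assert scores["c2"] == pytest.approx(2 * 4 + 3 * 0.5)

    def test_missing_factor_listed(self):
        inv = Inventory({"a": 1.0, "zz": 1.0})
        with pytest.raises(CharacterizationError, match="zz"):
            characterize(inv, identity_factors(["a"]))

    def test_additive_in_inventories(self):
        cs = identity_factors(["a", "b"])
        i1, i2 = Inventory({"a": 1.0, "b": 2.0}), Inventory({"a": 0.5, "b": 4.0})
        combined = characterize(i1 + i2, cs)
        assert np.allclose(combined, characterize(i1, cs) + characterize(i2, cs))

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            Inventory({"a": -1.0})


def make_mix(shares, n_cat=3):
    sources = sorted(shares)
    factors = pd.DataFrame(
        [[float(i + 1)] * n_cat for i in range(len(sources))],
        index=sources,
        columns=[f"c{k}" for k in range(n_cat)],
    )
    return ElectricityMix(country_id="x", shares=shares, source_factors=factors)


class TestElectricityMix:
    def test_single_source_equals_source_factors(self):
        mix = make_mix({"coal": 1.0})
        inv, cs = apply_electricity_mix(Inventory({"electricity": 2.0}), mix)
        scores = characterize(inv, cs)
        expected = 2.0 * mix.source_factors.loc["coal"]
        assert np.allclose(scores, expected)

    def test_shares_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            make_mix({"coal": 0.6, "gas": 0.3})

    def test_total_kwh_preserved(self):
        mix = make_mix({"coal": 0.3, "gas": 0.7})
        inv, _ = apply_electricity_mix(Inventory({"electricity": 5.0, "other": 1.0}), mix)
        kwh = sum(a for f, a in inv.flows.items() if f.startswith("electricity"))
        assert kwh == pytest.approx(5.0)
        assert inv.flows["other"] == 1.0

    def test_fifty_fifty_mix_is_mean_of_single_sources(self):
        fifty = make_mix({"coal": 0.5, "hydro": 0.5})
        base = Inventory({"electricity": 3.0})
        inv, cs = apply_electricity_mix(base, fifty)
        mixed = characterize(inv, cs)
        singles = []
        for src in ("coal", "hydro"):
            mix1 = ElectricityMix(
                country_id="x", shares={src: 1.0}, source_factors=fifty.source_factors
            )
            inv1, cs1 = apply_electricity_mix(base, mix1)
            singles.append(characterize(inv1, cs1))
        assert np.allclose(mixed, (singles[0] + singles[1]) / 2.0)

    def test_label_permutation_symmetry(self):
        # swapping source labels together with matching factor rows is a no-op
        factors = pd.DataFrame(
            [[1.0], [2.0]], index=["s1", "s2"], columns=["c"]
        )
        m1 = ElectricityMix("x", {"s1": 0.3, "s2": 0.7}, factors)
        factors_swapped = factors.rename(index={"s1": "s2", "s2": "s1"})
        m2 = ElectricityMix("x", {"s2": 0.3, "s1": 0.7}, factors_swapped)
        base = Inventory({"electricity": 1.0})
        r1 = characterize(*apply_electricity_mix(base, m1))
        r2 = characterize(*apply_electricity_mix(base, m2))
        assert np.allclose(r1, r2)


class TestScenario:
    BASE = Inventory(
        {
            "electricity": 1.0,
            "membrane": 0.004,
            "transport_truck": 0.2,
            "transport_ship": 0.0,
        }
    )

    def test_identity_is_noop(self):
        out = apply_scenario(self.BASE, ScenarioSpec())
        assert out.flows == self.BASE.flows

    def test_double_membrane_life_halves_flow(self):
        out = apply_scenario(self.BASE, ScenarioSpec(membrane_life_multiplier=2.0))
        assert out.flows["membrane"] == pytest.approx(0.002)

    def test_zero_recovery_is_noop_on_electricity(self):
        out = apply_scenario(
            self.BASE, ScenarioSpec(energy_recovery_fraction=0.0, hp_pump_share=0.9)
        )
        assert out.flows["electricity"] == 1.0

    def test_half_share_thirty_pct_recovery(self):
        # recovering 30% of the ~50% high-pressure-pump share: x0.85
        out = apply_scenario(
            self.BASE, ScenarioSpec(energy_recovery_fraction=0.3, hp_pump_share=0.5)
        )
        assert out.flows["electricity"] == pytest.approx(0.85)

    def test_transport_mode_swap(self):
        out = apply_scenario(
            self.BASE, ScenarioSpec(transport_mode_swap={"truck": "ship"})
        )
        assert out.flows["transport_truck"] == 0.0
        assert out.flows["transport_ship"] == pytest.approx(0.2)

    def test_swap_to_unknown_mode(self):
        with pytest.raises(KeyError, match="rail"):
            apply_scenario(self.BASE, ScenarioSpec(transport_mode_swap={"truck": "rail"}))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(membrane_life_multiplier=0.5)
        with pytest.raises(ValueError):
            ScenarioSpec(energy_recovery_fraction=1.0)


class TestPercentChange:
    def test_no_change(self):
        s = pd.Series({"c1": 2.0, "c2": 3.0})
        assert (percent_change(s, s) == 0.0).all()

    def test_63_percent_reduction(self):
        base = pd.Series({"c": 10.0})
        assert percent_change(base, 0.37 * base)["c"] == pytest.approx(-63.0)

    def test_53_percent_increase(self):
        base = pd.Series({"c": 10.0})
        assert percent_change(base, 1.53 * base)["c"] == pytest.approx(53.0)

    def test_uniform_scaling_identity(self):
        base = pd.Series({"c1": 1.0, "c2": 2.0, "c3": 0.5})
        assert np.allclose(percent_change(base, 1.4 * base), 40.0)

    def test_zero_base_flagged(self):
        base = pd.Series({"c1": 0.0, "c2": 1.0})
        out = percent_change(base, pd.Series({"c1": 1.0, "c2": 2.0}))
        assert np.isnan(out["c1"]) and out["c2"] == 100.0


class TestFileRoundTrips:
    def test_inventory_and_factors(self, tmp_path):
        inv = Inventory({"a": 1.5, "b": 0.25})
        cs = identity_factors(["a", "b"])
        write_inventory(inv, tmp_path / "inv.csv")
        write_factors(cs, tmp_path / "fac.csv")
        assert load_inventory(tmp_path / "inv.csv").flows == inv.flows
        loaded = load_factors(tmp_path / "fac.csv")
        assert loaded.factors.sort_index().equals(cs.factors.sort_index())

    def test_mixes(self, tmp_path):
        mix = make_mix({"coal": 0.25, "gas": 0.75})
        write_mixes({"x": mix}, tmp_path / "mixes.csv", tmp_path / "src.csv")
        back = load_mixes(tmp_path / "mixes.csv", tmp_path / "src.csv")
        assert back["x"].shares == mix.shares
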