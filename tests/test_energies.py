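"""Binding/hydration energy arithmetic, aggregation and verdicts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nkaproton.energies import (HARTREE_TO_KCAL, EnergyLedger, LedgerError,
                                aggregate_strengths, binding_energy,
                                convert_energy, hydration_energy,
                                read_ledger_tsv, verdicts, write_ledger_tsv)
from nkaproton.synthetic import (make_study_energy_scenario,
                                 simulate_energy_ledger)


def _ledger(e_full=-5000.0, e_without=-4985.0, e_ion=-10.0, **kw):
    return EnergyLedger(state="3[EEE]", replica=0, e_full=e_full,
                        e_ion=e_ion, e_without={"I": e_without}, **kw)


class TestBindingEnergy:
    def test_signed_arithmetic(self):
        r = binding_energy(_ledger(), "I")
        assert r.delta_e == -5.0 and r.strength == 5.0

    def test_non_interacting_limit_is_zero(self):
        led = _ledger(e_full=-4995.0, e_without=-4985.0, e_ion=-10.0)
        assert binding_energy(led, "I").delta_e == 0.0

    def test_missing_site_rejected(self):
        with pytest.raises(LedgerError):
            binding_energy(_ledger(), "II")

    def test_missing_component_rejected(self):
        led = EnergyLedger(state="x", replica=0, e_without={"I": -1.0})
        with pytest.raises(LedgerError):
            binding_energy(led, "I")

    def test_reference_shift_invariance(self):
        """Adding a constant to E_full and E_without leaves dE unchanged."""
        base = binding_energy(_ledger(), "I").delta_e
        shift = 123.456
        led = _ledger(e_full=-5000.0 + shift, e_without=-4985.0 + shift)
        assert binding_energy(led, "I").delta_e == pytest.approx(base,
                                                                 abs=1e-9)

    def test_planted_strengths_recovered_exactly(self):
        strengths = {"3[EED]": {"I": 185.0, "II": 190.0, "III": 172.0}}
        ledgers, _ = simulate_energy_ledger(strengths, 170.0, noise_sd=0.0,
                                            n_replicas=1, seed=0)
        led = [l for l in ledgers if l.e_full is not None][0]
        for site, want in strengths["3[EED]"].items():
            assert binding_energy(led, site).strength == pytest.approx(want)

    def test_unit_conversion_round_trip(self):
        v = -0.293421
        there = convert_energy(v, "hartree", "kcal/mol")
        assert there == pytest.approx(v * HARTREE_TO_KCAL)
        assert convert_energy(there, "kcal/mol", "hartree") == pytest.approx(
            v, rel=1e-9)

    def test_hartree_ledger_converted_on_request(self):
        led = EnergyLedger(state="x", replica=0, unit="hartree",
                           e_full=-100.0, e_ion=-0.1,
                           e_without={"I": -99.6})
        r = binding_energy(led, "I", to_unit="kcal/mol")
        assert r.delta_e == pytest.approx(-0.3 * HARTREE_TO_KCAL)
        assert r.unit == "kcal/mol"


class TestHydrationEnergy:
    def test_arithmetic(self):
        led = EnergyLedger(state="shell", replica=0, e_shell=-900.0,
                           e_water=-870.0, e_ion=-10.0)
        r = hydration_energy(led)
        assert r.delta_e == -20.0 and r.strength == 20.0 and r.se is None

    def test_se_is_sd_over_sqrt_n(self):
        ledgers, _ = simulate_energy_ledger({}, 170.0, noise_sd=4.4,
                                            n_shell_replicas=10, seed=3)
        shells = [l for l in ledgers if l.e_shell is not None]
        r = hydration_energy(shells)
        des = np.array([l.e_shell - l.e_water - l.e_ion for l in shells])
        assert r.se == pytest.approx(des.std(ddof=1) / math.sqrt(10),
                                     rel=1e-12)

    def test_mixed_units_rejected(self):
        a = EnergyLedger(state="s", replica=0, e_shell=-1.0, e_water=-0.5,
                         e_ion=-0.1, unit="hartree")
        b = EnergyLedger(state="s", replica=1, e_shell=-900.0, e_water=-870.0,
                         e_ion=-10.0, unit="kcal/mol")
        with pytest.raises(LedgerError):
            hydration_energy([a, b])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=-300, max_value=-100), min_size=2,
                max_size=10))
def test_replica_stats_match_brute_force(values):
    """Mean/SE over replicas agree with a naive reference to 1e-12."""
    ledgers = [EnergyLedger(state="s", replica=i, e_full=-5000.0, e_ion=-10.0,
                            e_without={"I": -4990.0 - v})
               for i, v in enumerate(values)]
    df = aggregate_strengths(ledgers, sites=("I",))
    strengths = [binding_energy(l, "I").strength for l in ledgers]
    mean_ref = sum(strengths) / len(strengths)
    var_ref = sum((s - mean_ref) ** 2 for s in strengths) / (len(strengths) - 1)
    se_ref = math.sqrt(var_ref) / math.sqrt(len(strengths))
    assert df["strength"].iloc[0] == pytest.approx(mean_ref, abs=1e-12)
    assert df["se"].iloc[0] == pytest.approx(se_ref, abs=1e-12)


class TestVerdicts:
    def _strengths(self, per_state):
        ledgers = []
        for sym, sites in per_state.items():
            ledgers.append(EnergyLedger(
                state=sym, replica=0, e_full=-5000.0, e_ion=-10.0,
                e_without={s: -4990.0 + v for s, v in sites.items()}))
        return aggregate_strengths(ledgers)

    def _hydration(self, strength):
        led = EnergyLedger(state="shell", replica=0, e_ion=-10.0,
                           e_water=-870.0, e_shell=-880.0 - strength)
        return hydration_energy(led)

    def test_pocket_outcompeting_shell_is_bindable(self):
        df = self._strengths({"3[EEE]": {"I": 180.0, "II": 182.0,
                                         "III": 178.0}})
        rep = verdicts(df, self._hydration(170.0))
        assert rep.bindable["3[EEE]"]

    def test_thirty_kcal_shift_loses_bindability(self):
        df = self._strengths({"4[E2E]": {"I": 150.0, "II": 152.0,
                                         "III": 148.0}})
        rep = verdicts(df, self._hydration(170.0))
        assert not rep.bindable["4[E2E]"]

    def test_site_near_hydration_is_releasable(self):
        df = self._strengths({"3[EED]": {"I": 185.0, "II": 190.0,
                                         "III": 172.0}})
        rep = verdicts(df, self._hydration(170.0), tolerance=5.0)
        rel = rep.releasable.set_index("site")["releasable"]
        assert rel["III"] and not rel["I"] and not rel["II"]

    def test_weak_site_is_always_releasable(self):
        df = self._strengths({"x": {"I": 150.0, "II": 190.0, "III": 190.0}})
        rep = verdicts(df, self._hydration(170.0), tolerance=0.0)
        assert rep.releasable.set_index("site")["releasable"]["I"]


class TestLedgerIO:
    def test_tsv_round_trip(self, tmp_path):
        strengths, hyd, _ = make_study_energy_scenario()
        ledgers, _ = simulate_energy_ledger(strengths, hyd, noise_sd=4.4,
                                            n_replicas=3, seed=9)
        path = tmp_path / "energies.tsv"
        write_ledger_tsv(ledgers, path)
        back = read_ledger_tsv(path)
        assert len(back) == len(ledgers)
        for a, b in zip(sorted(ledgers, key=lambda l: (l.state, l.replica)),
                        back):
            assert (a.state, a.replica, a.unit) == (b.state, b.replica, b.unit)
            assert a.e_without.keys() == b.e_without.keys()
            for site in a.e_without:
                assert a.e_without[site] == pytest.approx(b.e_without[site],
                                                          rel=1e-9)

    def test_unknown_fragment_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("state\treplica\tfragment\tenergy\tunit\n"
                     "x\t0\tmystery\t-1.0\tkcal/mol\n")
        with pytest.raises(LedgerError):
            read_ledger_tsv(p)

    def test_mixed_units_within_ledger_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("state\treplica\tfragment\tenergy\tunit\n"
                     "x\t0\tfull\t-1.0\thartree\n"
                     "x\t0\tion\t-10.0\tkcal/mol\n")
        with pytest.raises(LedgerError):
            read_ledger_tsv(p)
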