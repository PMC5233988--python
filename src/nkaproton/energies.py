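"""Counterpoise binding-energy bookkeeping and binding/release verdicts.

The per-site Na+ binding energy of the cluster model is

    dE_bind(i) = E_full - E_without(i) - E_ion

where ``E_full`` is the energy of the pocket with all three ions,
``E_without(i)`` the same cluster with the site-*i* ion deleted, and
``E_ion`` the lone ion in vacuum.  The hydration reference is

    dE_hyd = E_shell - E_water - E_ion

for a single ion in a 9 Å water shell.  All component energies come from
external, counterpoise-corrected QM runs; this module only does the
bookkeeping.  Binding energies are stored signed (negative = stabilising)
and reported as a positive *strength* = -dE to match the conventional
presentation (~180 kcal/mol pocket vs ~170 kcal/mol shell).

Verdicts:

* a state is **bindable from water** when its mean site strength is at
  least the hydration strength (the pocket outcompetes the shell);
* a site is **releasable** when its strength is below the hydration
  strength or within a tolerance of it (default 5 kcal/mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HARTREE_TO_KCAL",
    "SITES",
    "FRAGMENTS",
    "LedgerError",
    "EnergyLedger",
    "BindingResult",
    "HydrationResult",
    "BindingEnergyReport",
    "convert_energy",
    "binding_energy",
    "hydration_energy",
    "aggregate_strengths",
    "verdicts",
    "read_ledger_tsv",
    "write_ledger_tsv",
]

#: 1 hartree in kcal/mol.
HARTREE_TO_KCAL = 627.509

SITES = ("I", "II", "III")
FRAGMENTS = ("full", "without_I", "without_II", "without_III",
             "ion", "shell", "shell_water")


class LedgerError(ValueError):
    """Missing fragment energies or inconsistent units."""


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    # size of each unit expressed in hartree
    units = {"hartree": 1.0, "kcal/mol": 1.0 / HARTREE_TO_KCAL}
    try:
        return value * units[from_unit.lower()] / units[to_unit.lower()]
    except KeyError as e:
        raise LedgerError(f"unknown energy unit {e.args[0]!r}") from None


@dataclass
class EnergyLedger:
    """Fragment energies for one (state, replica) pair, one unit."""

    state: str
    replica: int
    unit: str = "kcal/mol"
    e_full: Optional[float] = None
    e_without: dict[str, float] = field(default_factory=dict)
    e_ion: Optional[float] = None
    e_shell: Optional[float] = None
    e_water: Optional[float] = None

    def require(self, *names: str) -> None:
        missing = [n for n in names
                   if getattr(self, n, None) is None]
        if missing:
            raise LedgerError(
                f"ledger {self.state}/replica {self.replica}: missing {missing}")


@dataclass(frozen=True)
class BindingResult:
    site: str
    delta_e: float  # signed; negative stabilises
    strength: float  # = -delta_e
    unit: str


@dataclass(frozen=True)
class HydrationResult:
    delta_e: float
    strength: float
    se: Optional[float]
    n_replicas: int
    unit: str


def binding_energy(ledger: EnergyLedger, site: str,
                   to_unit: Optional[str] = None) -> BindingResult:
    """dE_bind(site) = E_full - E_without(site) - E_ion, plus strength."""
    ledger.require("e_full", "e_ion")
    if site not in ledger.e_without:
        raise LedgerError(
            f"ledger {ledger.state}/replica {ledger.replica}: "
            f"no ion-deleted energy for site {site}")
    de = ledger.e_full - ledger.e_without[site] - ledger.e_ion
    unit = ledger.unit
    if to_unit is not None and to_unit != unit:
        de = convert_energy(de, unit, to_unit)
        unit = to_unit
    return BindingResult(site=site, delta_e=de, strength=-de, unit=unit)


def hydration_energy(ledgers: Sequence[EnergyLedger] | EnergyLedger,
                     to_unit: Optional[str] = None) -> HydrationResult:
    """dE_hyd = E_shell - E_water - E_ion, averaged over shell replicas.

    The standard error (sample SD / sqrt(n)) is reported absent with a
    single replica.
    """
    if isinstance(ledgers, EnergyLedger):
        ledgers = [ledgers]
    if not ledgers:
        raise LedgerError("no shell ledgers supplied")
    units = {l.unit for l in ledgers}
    if len(units) != 1:
        raise LedgerError(f"mixed units in shell ledgers: {sorted(units)}")
    des = []
    for led in ledgers:
        led.require("e_shell", "e_water", "e_ion")
        des.append(led.e_shell - led.e_water - led.e_ion)
    des = np.asarray(des, dtype=float)
    unit = ledgers[0].unit
    if to_unit is not None and to_unit != unit:
        des = np.array([convert_energy(v, unit, to_unit) for v in des])
        unit = to_unit
    mean = float(des.mean())
    se = (float(des.std(ddof=1) / math.sqrt(len(des)))
          if len(des) >= 2 else None)
    return HydrationResult(delta_e=mean, strength=-mean, se=se,
                           n_replicas=len(des), unit=unit)


def aggregate_strengths(ledgers: Sequence[EnergyLedger],
                        sites: Sequence[str] = SITES) -> pd.DataFrame:
    """Per-state, per-site strength mean ± SE over replicas.

    Returns a tidy frame with columns
    (state, site, strength, se, n_replicas, unit).
    """
    if not ledgers:
        raise LedgerError("no ledgers supplied")
    rows = []
    by_state: dict[str, list[EnergyLedger]] = {}
    for led in ledgers:
        by_state.setdefault(led.state, []).append(led)
    for state in sorted(by_state):
        group = by_state[state]
        units = {l.unit for l in group}
        if len(units) != 1:
            raise LedgerError(f"state {state}: mixed units {sorted(units)}")
        for site in sites:
            vals = np.array([binding_energy(l, site).strength for l in group])
            se = (float(vals.std(ddof=1) / math.sqrt(len(vals)))
                  if len(vals) >= 2 else np.nan)
            rows.append({"state": state, "site": site,
                         "strength": float(vals.mean()), "se": se,
                         "n_replicas": len(vals), "unit": group[0].unit})
    return pd.DataFrame(rows)


@dataclass
class BindingEnergyReport:
    """Strengths, hydration reference and verdicts for a set of states."""

    strengths: pd.DataFrame  # from aggregate_strengths
    hydration: HydrationResult
    tolerance: float
    bindable: dict[str, bool]
    releasable: pd.DataFrame  # (state, site, strength, releasable)


def verdicts(strengths: pd.DataFrame, hydration: HydrationResult,
             tolerance: float = 5.0) -> BindingEnergyReport:
    """Binding/release calls against the hydration reference.

    * ``bindable_from_water``: mean strength over the three sites >= the
      hydration strength.
    * ``releasable`` per site: strength below the hydration strength, or
      within *tolerance* of it.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    href = hydration.strength
    bindable: dict[str, bool] = {}
    rel_rows = []
    for state, grp in strengths.groupby("state", sort=True):
        bindable[state] = bool(grp["strength"].mean() >= href)
        for _, row in grp.iterrows():
            s = row["strength"]
            rel_rows.append({"state": state, "site": row["site"],
                             "strength": s,
                             "releasable": bool(s < href or abs(s - href) <= tolerance)})
    return BindingEnergyReport(strengths=strengths, hydration=hydration,
                               tolerance=tolerance, bindable=bindable,
                               releasable=pd.DataFrame(rel_rows))


# ---------------------------------------------------------------------------
# TSV I/O — long format: state, replica, fragment, energy, unit

_FRAGMENT_FIELDS = {"full": "e_full", "ion": "e_ion",
                    "shell": "e_shell", "shell_water": "e_water"}


def read_ledger_tsv(path) -> list[EnergyLedger]:
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"state", "replica", "fragment", "energy", "unit"}
    if not needed.issubset(df.columns):
        raise LedgerError(f"ledger TSV needs columns {sorted(needed)}")
    ledgers: dict[tuple[str, int], EnergyLedger] = {}
    for _, row in df.iterrows():
        key = (str(row["state"]), int(row["replica"]))
        led = ledgers.get(key)
        if led is None:
            led = ledgers[key] = EnergyLedger(state=key[0], replica=key[1],
                                              unit=str(row["unit"]))
        if str(row["unit"]) != led.unit:
            raise LedgerError(f"ledger {key}: mixed units")
        frag = str(row["fragment"])
        e = float(row["energy"])
        if frag in _FRAGMENT_FIELDS:
            setattr(led, _FRAGMENT_FIELDS[frag], e)
        elif frag.startswith("without_"):
            led.e_without[frag.removeprefix("without_")] = e
        else:
            raise LedgerError(f"unknown fragment {frag!r}")
    return [ledgers[k] for k in sorted(ledgers)]


def write_ledger_tsv(ledgers: Sequence[EnergyLedger], path) -> pd.DataFrame:
    rows = []
    for led in ledgers:
        if led.e_full is not None:
            rows.append((led.state, led.replica, "full", led.e_full, led.unit))
        for site in sorted(led.e_without):
            rows.append((led.state, led.replica, f"without_{site}",
                         led.e_without[site], led.unit))
        if led.e_ion is not None:
            rows.append((led.state, led.replica, "ion", led.e_ion, led.unit))
        if led.e_shell is not None:
            rows.append((led.state, led.replica, "shell", led.e_shell, led.unit))
        if led.e_water is not None:
            rows.append((led.state, led.replica, "shell_water", led.e_water,
                         led.unit))
    df = pd.DataFrame(rows, columns=["state", "replica", "fragment",
                                     "energy", "unit"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return df
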