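"""Protonation states of the Na+,K+-ATPase binding pocket.

The transmembrane ion-binding pocket of the sodium pump contains three
sites (I, II, III), each coordinated by one glutamate and one aspartate.
A protonation state assigns a proton (or not) to each of the six acidic
side chains and is written as a compact symbol ``n[ijk]``:

* ``n`` — total number of protonated residues (0..6),
* ``i``, ``j``, ``k`` — one code per site, in site order I, II, III:
  ``0`` neither residue protonated, ``E`` the glutamate only,
  ``D`` the aspartate only, ``2`` both.

For example ``3[E20]`` carries three protons: Glu779 (site I) and both
Glu327 and Asp804 (site II); site III is fully deprotonated.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ResidueKey",
    "BindingSiteRegistry",
    "ProtonationState",
    "StateError",
    "RegistryMismatchError",
    "SymbolParseError",
    "SymbolConsistencyError",
    "SITE_CODES",
    "encode_state",
    "decode_symbol",
    "enumerate_states",
    "default_registry",
    "write_state_table",
    "read_state_table",
]

#: Per-site codes in canonical sort order (used for symbol enumeration).
SITE_CODES = ("0", "E", "D", "2")

_CODE_TO_FLAGS = {"0": (False, False), "E": (True, False),
                  "D": (False, True), "2": (True, True)}
_FLAGS_TO_CODE = {v: k for k, v in _CODE_TO_FLAGS.items()}
_CODE_ORDER = {c: i for i, c in enumerate(SITE_CODES)}

_SYMBOL_RE = re.compile(r"^(\d)\[([0ED2]*)\]$")


class StateError(ValueError):
    """Base class for protonation-state errors."""


class RegistryMismatchError(StateError):
    """Flags do not cover exactly the registry's residues."""


class SymbolParseError(StateError):
    """Symbol text does not match the n[ijk] grammar."""


class SymbolConsistencyError(StateError):
    """Symbol's leading digit disagrees with its site codes."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identifies one residue by chain, number and 3-letter name."""

    chain_id: str
    residue_number: int
    residue_name: str

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise StateError(f"residue_number must be >= 1, got {self.residue_number}")

    def __str__(self) -> str:  # e.g. "GLU779"
        return f"{self.residue_name}{self.residue_number}"


@dataclass(frozen=True)
class BindingSiteRegistry:
    """Ordered map of site label -> (glutamate, aspartate) residue keys.

    The registry fixes both the site order (I, II, III) and the
    within-site order (Glu first) used by the symbol grammar.
    """

    sites: tuple[tuple[str, ResidueKey, ResidueKey], ...]

    def __post_init__(self) -> None:
        for label, glu, asp in self.sites:
            if glu.residue_name != "GLU":
                raise StateError(f"site {label}: expected GLU, got {glu}")
            if asp.residue_name != "ASP":
                raise StateError(f"site {label}: expected ASP, got {asp}")
        residues = self.residues
        if len(set(residues)) != len(residues):
            raise StateError("registry residues must be distinct")

    @property
    def site_labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.sites)

    @property
    def residues(self) -> tuple[ResidueKey, ...]:
        """All residues in site order, Glu before Asp within a site."""
        out: list[ResidueKey] = []
        for _, glu, asp in self.sites:
            out.extend((glu, asp))
        return tuple(out)

    def site_residues(self, label: str) -> tuple[ResidueKey, ResidueKey]:
        for lab, glu, asp in self.sites:
            if lab == label:
                return glu, asp
        raise KeyError(label)


def default_registry(chain_id: str = "A") -> BindingSiteRegistry:
    """The pump's canonical binding-site registry.

    Site I: Glu779/Asp808, site II: Glu327/Asp804, site III: Glu954/Asp926
    (numbering follows the shark rectal-gland crystal structure).
    """
    rk = lambda num, name: ResidueKey(chain_id, num, name)
    return BindingSiteRegistry(sites=(
        ("I", rk(779, "GLU"), rk(808, "ASP")),
        ("II", rk(327, "GLU"), rk(804, "ASP")),
        ("III", rk(954, "GLU"), rk(926, "ASP")),
    ))


@dataclass(frozen=True)
class ProtonationState:
    """One assignment of protons to the registry's acidic residues."""

    flags: Mapping[ResidueKey, bool]
    symbol: str
    n_protons: int

    codes: tuple[str, ...] = field(default=())

    def protonated(self) -> tuple[ResidueKey, ...]:
        return tuple(r for r, f in sorted(self.flags.items()) if f)

    def site_code(self, index: int) -> str:
        return self.codes[index]


def _codes_from_flags(flags: Mapping[ResidueKey, bool],
                      registry: BindingSiteRegistry) -> tuple[str, ...]:
    expected = set(registry.residues)
    given = set(flags)
    if given != expected:
        missing = expected - given
        extra = given - expected
        raise RegistryMismatchError(
            f"flags do not match registry residues "
            f"(missing={sorted(map(str, missing))}, extra={sorted(map(str, extra))})")
    return tuple(_FLAGS_TO_CODE[(flags[glu], flags[asp])]
                 for _, glu, asp in registry.sites)


def encode_state(flags: Mapping[ResidueKey, bool],
                 registry: BindingSiteRegistry) -> ProtonationState:
    """Encode per-residue proton flags as an ``n[ijk]`` state.

    Raises :class:`RegistryMismatchError` if *flags* does not cover
    exactly the registry's six residues.
    """
    codes = _codes_from_flags(flags, registry)
    n = sum(flags.values())
    symbol = f"{n}[{''.join(codes)}]"
    return ProtonationState(flags=dict(flags), symbol=symbol,
                            n_protons=n, codes=codes)


def decode_symbol(symbol: str, registry: BindingSiteRegistry) -> ProtonationState:
    """Decode an ``n[ijk]`` symbol into per-residue flags.

    The leading digit is validated against the proton count implied by
    the site codes; the check is deliberate — a symbol such as ``2[EEE]``
    is rejected as inconsistent, not silently repaired.
    """
    m = _SYMBOL_RE.match(symbol.strip())
    if m is None:
        raise SymbolParseError(f"not a valid n[ijk] symbol: {symbol!r}")
    n_claimed = int(m.group(1))
    codes = tuple(m.group(2))
    if len(codes) != len(registry.sites):
        raise SymbolParseError(
            f"symbol {symbol!r} has {len(codes)} site codes; "
            f"registry defines {len(registry.sites)} sites")
    flags: dict[ResidueKey, bool] = {}
    for (label, glu, asp), code in zip(registry.sites, codes):
        glu_p, asp_p = _CODE_TO_FLAGS[code]
        flags[glu] = glu_p
        flags[asp] = asp_p
    n_actual = sum(flags.values())
    if n_actual != n_claimed:
        raise SymbolConsistencyError(
            f"symbol {symbol!r}: leading digit {n_claimed} but codes imply "
            f"{n_actual} protons")
    return ProtonationState(flags=flags, symbol=f"{n_actual}[{''.join(codes)}]",
                            n_protons=n_actual, codes=codes)


def enumerate_states(registry: BindingSiteRegistry) -> list[ProtonationState]:
    """All 4^n_sites protonation states, in a fixed reproducible order.

    States are sorted by proton count, then lexicographically by site
    codes with 0 < E < D < 2.  The default three-site registry yields 64
    states partitioned by proton count as binomial(6, n).
    """
    states = []
    for codes in itertools.product(SITE_CODES, repeat=len(registry.sites)):
        flags: dict[ResidueKey, bool] = {}
        for (label, glu, asp), code in zip(registry.sites, codes):
            flags[glu], flags[asp] = _CODE_TO_FLAGS[code]
        states.append(encode_state(flags, registry))
    states.sort(key=lambda s: (s.n_protons, tuple(_CODE_ORDER[c] for c in s.codes)))
    return states


# ---------------------------------------------------------------------------
# TSV state table (symbol + one +/- column per residue)

def _column_names(registry: BindingSiteRegistry) -> list[str]:
    return [str(r) for r in registry.residues]


def write_state_table(states: Iterable[ProtonationState],
                      registry: BindingSiteRegistry, path) -> pd.DataFrame:
    """Write states as a TSV table: symbol plus a +/- column per residue."""
    rows = []
    for s in states:
        row = {"symbol": s.symbol}
        for r in registry.residues:
            row[str(r)] = "+" if s.flags[r] else "-"
        rows.append(row)
    df = pd.DataFrame(rows, columns=["symbol", *_column_names(registry)])
    df.to_csv(path, sep="\t", index=False)
    return df


def read_state_table(path, registry: BindingSiteRegistry) -> list[ProtonationState]:
    """Read a TSV state table and validate each row against its symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    states = []
    for _, row in df.iterrows():
        flags = {r: row[str(r)].strip() == "+" for r in registry.residues}
        state = encode_state(flags, registry)
        if state.symbol != row["symbol"].strip():
            raise SymbolConsistencyError(
                f"table row {row['symbol']!r} disagrees with its +/- columns "
                f"(implied {state.symbol})")
        states.append(state)
    return states
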