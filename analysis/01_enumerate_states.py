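#!/usr/bin/env python
"""Enumerate the 64 protonation states of the binding pocket.

Writes the full state table (symbol + per-residue +/- flags) to
``results/states.tsv`` and prints the partition by proton count, which
follows binomial(6, n): 1, 6, 15, 20, 15, 6, 1.
"""

from collections import Counter
from pathlib import Path

from nkaproton.states import default_registry, enumerate_states, write_state_table

OUT = Path("results")


def main() -> None:
    registry = default_registry()
    states = enumerate_states(registry)
    OUT.mkdir(exist_ok=True)
    write_state_table(states, registry, OUT / "states.tsv")
    counts = Counter(s.n_protons for s in states)
    print(f"enumerated {len(states)} states -> {OUT / 'states.tsv'}")
    for n in sorted(counts):
        print(f"  {n} protons: {counts[n]} states")


if __name__ == "__main__":
    main()
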