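#!/usr/bin/env python
"""Carve the quantum-cluster pocket model and the water-shell reference.

Builds the synthetic pocket structure (three ions, the six acidic
residues with their sequence neighbours, near and far waters), selects
cluster residues by the 2.5 Å oxygen rule plus adjacency, carves the
model under the stable 3- and 4-proton states (capping severed peptide
bonds, freezing alpha carbons, accounting net charge), and emits the QM
decks.  Also extracts a 9 Å single-ion water shell from a bulk-water
snapshot.

Writes ``results/cluster_residues.tsv`` and per-state deck/XYZ pairs
under ``results/decks/``.
"""

import argparse
from pathlib import Path

import pandas as pd

from nkaproton.cluster import (carve_cluster, extract_water_shell,
                               select_cluster_residues, write_qm_deck)
from nkaproton.pipeline import symbol_to_filename
from nkaproton.states import decode_symbol, default_registry
from nkaproton.synthetic import (STABLE_SYMBOLS, make_pocket_structure,
                                 make_solvated_ion)

OUT = Path("results")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    registry = default_registry()
    pocket = make_pocket_structure(registry, seed=args.seed)
    residues = select_cluster_residues(pocket, hydration_radius=2.5)
    OUT.mkdir(exist_ok=True)
    pd.DataFrame([{"chain": r.chain_id, "residue": r.residue_number,
                   "name": r.residue_name} for r in residues]).to_csv(
        OUT / "cluster_residues.tsv", sep="\t", index=False)
    print(f"selected {len(residues)} cluster residues "
          f"(six acidics + neighbours)")

    for sym in (*STABLE_SYMBOLS, "3[EED]"):
        state = decode_symbol(sym, registry)
        model = carve_cluster(pocket, residues, state)
        write_qm_deck(model, name=symbol_to_filename(sym),
                      out_dir=OUT / "decks")
        print(f"  {sym}: {model.n_atoms} atoms, {model.cap_count} caps, "
              f"net charge {model.net_charge:+d}, "
              f"{len(model.frozen_atom_ids)} frozen CA")

    solvated = make_solvated_ion(radius=12.0, seed=args.seed)
    shell = extract_water_shell(solvated, radius=9.0)
    write_qm_deck(shell, name="water_shell", out_dir=OUT / "decks")
    print(f"water shell: {shell.n_waters} waters within 9 Å "
          f"(~same atom count as the pocket model)")
    print(f"decks -> {OUT}/decks/")


if __name__ == "__main__":
    main()
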