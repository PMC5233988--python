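#!/usr/bin/env python
"""Collect the analysis tables into the final text report (and plots).

Reads whatever tables steps 01-05 wrote under ``results/`` and renders
the deterministic summary to ``results/report.txt``; ``--plots`` adds
the stability scatter, flux bars and energy bars as PNGs.
"""

import argparse
from pathlib import Path

import pandas as pd

from nkaproton.pipeline import render_plots, render_report

OUT = Path("results")
TABLES = {"states": "states.tsv", "stability": "stability.tsv",
          "scatter": "scatter.tsv", "flux": "flux.tsv", "gates": "gates.tsv",
          "cluster_residues": "cluster_residues.tsv", "energy": "energy.tsv"}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--plots", action="store_true")
    args = ap.parse_args()

    tables = {key: pd.read_csv(OUT / name, sep="\t")
              for key, name in TABLES.items() if (OUT / name).is_file()}
    text = render_report(tables)
    (OUT / "report.txt").write_text(text)
    print(text)
    if args.plots:
        for p in render_plots(tables, OUT):
            print(f"wrote {p}")


if __name__ == "__main__":
    main()
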