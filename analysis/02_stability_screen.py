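#!/usr/bin/env python
"""Screen all 64 protonation states for stable Na+ binding.

Simulates the planted 64-state ensemble (3 replicas x 2000 frames at
50 ps sampling, i.e. 100 ns per replica), measures per-replica RMSF and
N_water over the last 10 ns, detects unbinding, and classifies each
state against the stability box N_water < 8, RMSF < 0.5 Å.

Writes ``results/metrics.tsv`` (per replica), ``results/scatter.tsv``
(the N_water vs RMSF plane) and ``results/stability.tsv`` (the stable
states in the published table layout), and prints the recovered stable
set next to the planted one.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from nkaproton.metrics import classify_stability, replica_metrics
from nkaproton.states import default_registry, write_state_table
from nkaproton.synthetic import make_study_scenario, simulate_trajectory

OUT = Path("results")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    registry = default_registry()
    specs, manifest = make_study_scenario(seed=args.seed)
    rows, verdicts = [], {}
    for spec in specs:
        trajs, _ = simulate_trajectory(spec)
        reps = [replica_metrics(t) for t in trajs]
        verdicts[spec.symbol] = classify_stability(spec.symbol, reps).verdict
        for k, r in enumerate(reps):
            rows.append({"state": spec.symbol, "replica": k,
                         "N_water": r.mean_nwater, "RMSF": r.mean_rmsf,
                         "unbound": bool(r.any_unbound)})
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "metrics.tsv", sep="\t", index=False, float_format="%.6g")
    df[~df["unbound"]].to_csv(OUT / "scatter.tsv", sep="\t", index=False,
                              float_format="%.6g")

    stable = sorted(s for s, v in verdicts.items() if v == "stable")
    from nkaproton.states import decode_symbol
    write_state_table([decode_symbol(s, registry) for s in stable],
                      registry, OUT / "stability.tsv")
    excluded = sorted(s for s, v in verdicts.items()
                      if v == "excluded_unbinding")
    print(f"stable states ({len(stable)}): {', '.join(stable)}")
    print(f"planted stable: {', '.join(sorted(manifest['planted_stable']))}")
    print(f"excluded by unbinding: {len(excluded)} states")
    print(f"tables -> {OUT}/metrics.tsv, scatter.tsv, stability.tsv")


if __name__ == "__main__":
    main()
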