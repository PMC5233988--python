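"""End-to-end orchestration: enumeration → stability → pathways → energies.

``run_pipeline`` consumes a :class:`~nkaproton.config.PipelineConfig` and
whatever inputs are available (multi-model PDB trajectories per state and
replica, a pocket structure, an energy-ledger TSV) and emits a bundle of
TSV report tables plus a deterministic text summary.  Stages whose inputs
are missing are skipped with an explicit log line; downstream stages
degrade gracefully.  All randomness is seeded from the config, and output
bytes are reproducible (timestamps live only in the log).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import cluster as qc
from . import energies as en
from . import metrics as mt
from . import pathways as pw
from .config import PipelineConfig
from .states import ProtonationState, decode_symbol, enumerate_states, write_state_table
from .trajectory import MetricWindow, Trajectory, read_multimodel_pdb

__all__ = ["PipelineResult", "run_pipeline", "render_report",
           "symbol_to_filename", "filename_to_symbol"]

logger = logging.getLogger(__name__)


def symbol_to_filename(symbol: str) -> str:
    """Filesystem-safe form of a state symbol: ``3[EEE]`` -> ``3_EEE``."""
    return symbol.replace("[", "_").replace("]", "")


def filename_to_symbol(stem: str) -> str:
    n, codes = stem.split("_", 1)
    return f"{n}[{codes}]"


@dataclass
class PipelineResult:
    """Report bundle: tidy tables keyed by name, plus the run log."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    stability: dict[str, mt.StabilityReport] = field(default_factory=dict)
    log_lines: list[str] = field(default_factory=list)

    def stable_symbols(self) -> list[str]:
        return [s for s, rep in self.stability.items()
                if rep.verdict == mt.STABLE]


def _log(result: PipelineResult, msg: str) -> None:
    logger.info(msg)
    result.log_lines.append(msg)


def _config_hash(config: PipelineConfig) -> str:
    blob = repr(sorted(config.to_dict().items())).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _load_trajectories(input_dir: Path) -> dict[str, list[Trajectory]]:
    """Read ``<symbol>_rep<k>.pdb`` files grouped by state symbol."""
    groups: dict[str, list[tuple[int, Trajectory]]] = {}
    for path in sorted(input_dir.glob("*_rep*.pdb")):
        stem, rep = path.stem.rsplit("_rep", 1)
        symbol = filename_to_symbol(stem)
        groups.setdefault(symbol, []).append(
            (int(rep), read_multimodel_pdb(path)))
    return {sym: [t for _, t in sorted(reps, key=lambda x: x[0])]
            for sym, reps in groups.items()}


def run_pipeline(config: PipelineConfig,
                 trajectories: Optional[Mapping[str, Sequence[Trajectory]]] = None,
                 ledgers: Optional[Sequence[en.EnergyLedger]] = None,
                 structure=None,
                 carve_state: Optional[str] = None) -> PipelineResult:
    """Run every stage whose inputs are available and write report TSVs.

    Inputs may be passed in memory; otherwise they are looked up under
    ``config.input_dir`` (trajectory PDBs, ``pocket.pdb``,
    ``energies.tsv``).
    """
    result = PipelineResult()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    window = (MetricWindow(*config.window) if config.window is not None
              else None)
    registry = config.registry
    _log(result, f"run config_hash={_config_hash(config)} seed={config.seed}")

    # ---- stage 1: enumeration (always possible) ----------------------------
    states = enumerate_states(registry)
    by_symbol = {s.symbol: s for s in states}
    result.tables["states"] = write_state_table(states, registry,
                                                out / "states.tsv")
    _log(result, f"enumerate: {len(states)} protonation states")

    # ---- locate inputs ------------------------------------------------------
    input_dir = Path(config.input_dir) if config.input_dir else None
    if trajectories is None and input_dir is not None and input_dir.is_dir():
        trajectories = _load_trajectories(input_dir)
        if trajectories:
            _log(result, f"inputs: {sum(map(len, trajectories.values()))} "
                         f"trajectories for {len(trajectories)} states")
    if ledgers is None and input_dir is not None:
        ledger_path = input_dir / "energies.tsv"
        if ledger_path.is_file():
            ledgers = en.read_ledger_tsv(ledger_path)
    if structure is None and input_dir is not None:
        pocket = input_dir / "pocket.pdb"
        if pocket.is_file():
            structure = qc.load_structure_pdb(pocket)

    # ---- stage 2: metrics + stability ---------------------------------------
    if trajectories:
        metric_rows, scatter_rows = [], []
        for symbol in sorted(trajectories, key=lambda s: (len(s), s)):
            reps = []
            for k, traj in enumerate(trajectories[symbol]):
                r = mt.replica_metrics(traj, cutoff=config.hydration_cutoff,
                                       window=window,
                                       escape_threshold=config.escape_threshold)
                reps.append(r)
                metric_rows.append({"state": symbol, "replica": k,
                                    "N_water": r.mean_nwater,
                                    "RMSF": r.mean_rmsf,
                                    "unbound": bool(r.any_unbound)})
                if not r.any_unbound:
                    scatter_rows.append({"state": symbol, "replica": k,
                                         "N_water": r.mean_nwater,
                                         "RMSF": r.mean_rmsf,
                                         "n_protons": by_symbol[symbol].n_protons
                                         if symbol in by_symbol else -1})
            result.stability[symbol] = mt.classify_stability(
                symbol, reps, config.thresholds)
        metrics_df = pd.DataFrame(metric_rows)
        scatter_df = pd.DataFrame(scatter_rows)
        verdict_df = pd.DataFrame(
            [{"state": s, "verdict": rep.verdict,
              "failures": "; ".join(rep.failures)}
             for s, rep in result.stability.items()])
        stable = [s for s in result.stability
                  if result.stability[s].verdict == mt.STABLE]
        stable_states = [by_symbol[s] for s in sorted(
            stable, key=lambda x: (by_symbol[x].n_protons, x))]
        stability_df = write_state_table(stable_states, registry,
                                         out / "stability.tsv")
        metrics_df.to_csv(out / "metrics.tsv", sep="\t", index=False,
                          float_format="%.6g")
        scatter_df.to_csv(out / "scatter.tsv", sep="\t", index=False,
                          float_format="%.6g")
        verdict_df.to_csv(out / "verdicts_stability.tsv", sep="\t", index=False)
        result.tables.update(metrics=metrics_df, scatter=scatter_df,
                             stability=stability_df,
                             stability_verdicts=verdict_df)
        _log(result, f"classify: {len(stable)} stable states "
                     f"of {len(result.stability)} analysed")
    else:
        _log(result, "classify: skipped (no trajectories)")

    # ---- stage 3: water pathways --------------------------------------------
    if trajectories and config.pathways:
        flux_rows = []
        flux_map: dict[tuple[str, str], pw.FluxSummary] = {}
        for symbol in sorted(trajectories, key=lambda s: (len(s), s)):
            for pathway in config.pathways:
                per_rep = [pw.count_transits(t, pathway)
                           for t in trajectories[symbol]]
                fs = pw.flux_summary(per_rep, pathway.name,
                                     config.open_baseline)
                flux_map[(symbol, pathway.name)] = fs
                flux_rows.append({"state": symbol, "pathway": pathway.name,
                                  "mean_inward": fs.mean,
                                  "se": np.nan if fs.se is None else fs.se,
                                  "gate": fs.gate_call})
        flux_df = pd.DataFrame(flux_rows)
        flux_df.to_csv(out / "flux.tsv", sep="\t", index=False,
                       float_format="%.6g")
        result.tables["flux"] = flux_df
        _log(result, f"pathways: {len(flux_rows)} (state, pathway) fluxes")
        try:
            syms = [s for s in trajectories if s in by_symbol]
            gates = pw.gate_association_test(
                flux_map, [by_symbol[s] for s in syms], registry,
                config.open_baseline)
            gates.to_csv(out / "gates.tsv", sep="\t", index=False,
                         float_format="%.6g")
            result.tables["gates"] = gates
            _log(result, "pathways: gate association table written")
        except pw.ContrastDesignError as e:
            _log(result, f"pathways: gate association skipped ({e})")
    else:
        _log(result, "pathways: skipped (no trajectories or no definitions)")

    # ---- stage 4: cluster carving -------------------------------------------
    if structure is not None:
        state = by_symbol.get(carve_state or "3[EEE]")
        if state is None:
            state = decode_symbol(carve_state, registry)
        residues = qc.select_cluster_residues(structure,
                                              config.hydration_radius)
        model = qc.carve_cluster(structure, residues, state,
                                 water_cutoff=config.carve_water_cutoff)
        qc.write_qm_deck(model, name="pocket", out_dir=out)
        sel_df = pd.DataFrame([{"chain": r.chain_id,
                                "residue": r.residue_number,
                                "name": r.residue_name} for r in residues])
        sel_df.to_csv(out / "cluster_residues.tsv", sep="\t", index=False)
        result.tables["cluster_residues"] = sel_df
        _log(result, f"carve: {len(residues)} residues, {model.n_atoms} atoms "
                     f"({model.cap_count} caps), charge {model.net_charge:+d} "
                     f"under {state.symbol}")
    else:
        _log(result, "carve: skipped (no structure)")

    # ---- stage 5: binding energies ------------------------------------------
    if ledgers:
        shell = [l for l in ledgers if l.e_shell is not None]
        site_ledgers = [l for l in ledgers if l.e_full is not None]
        if site_ledgers:
            strengths = en.aggregate_strengths(site_ledgers)
            if shell:
                hyd = en.hydration_energy(shell)
                report = en.verdicts(strengths, hyd, config.release_tolerance)
                energy_df = strengths.merge(
                    report.releasable[["state", "site", "releasable"]],
                    on=["state", "site"])
                energy_df["bindable_from_water"] = energy_df["state"].map(
                    report.bindable)
                energy_df["hydration_strength"] = hyd.strength
                energy_df["hydration_se"] = (np.nan if hyd.se is None
                                             else hyd.se)
                _log(result, f"energies: hydration {hyd.strength:.2f} "
                             f"± {0.0 if hyd.se is None else hyd.se:.2f} "
                             f"kcal/mol over {hyd.n_replicas} shells")
            else:
                energy_df = strengths
                _log(result, "energies: no shell replicas; verdicts skipped")
            energy_df.to_csv(out / "energy.tsv", sep="\t", index=False,
                             float_format="%.6g")
            result.tables["energy"] = energy_df
            _log(result, f"energies: {strengths['state'].nunique()} states")
    else:
        _log(result, "energies: skipped (no ledger)")

    (out / "run.log").write_text("\n".join(result.log_lines) + "\n")
    (out / "report.txt").write_text(render_report(result.tables))
    return result


def render_report(tables: Mapping[str, pd.DataFrame]) -> str:
    """Deterministic plain-text summary of the report bundle."""
    lines: list[str] = ["protonation-state pipeline report",
                        "=" * 34]
    if not any(len(t) for t in tables.values()):
        lines.append("no results")
        return "\n".join(lines) + "\n"
    if "states" in tables:
        lines.append(f"enumerated states: {len(tables['states'])}")
    if "stability" in tables:
        stable = tables["stability"]["symbol"].tolist()
        lines.append(f"stable states ({len(stable)}): " + ", ".join(stable))
    if "stability_verdicts" in tables:
        vc = tables["stability_verdicts"]["verdict"].value_counts()
        lines.append("verdicts: " + ", ".join(f"{k}={vc[k]}"
                                              for k in sorted(vc.index)))
    if "flux" in tables:
        for _, r in tables["flux"].iterrows():
            if r["gate"] == "open":
                lines.append(f"open gate: {r['state']} {r['pathway']} "
                             f"mean inward flux {r['mean_inward']:.2f}")
    if "gates" in tables:
        for _, r in tables["gates"].iterrows():
            if r["note"]:
                lines.append(f"gate: {r['note']}")
    if "cluster_residues" in tables:
        lines.append(f"cluster residues: {len(tables['cluster_residues'])}")
    if "energy" in tables:
        for _, r in tables["energy"].iterrows():
            se = r.get("se", float("nan"))
            se_txt = "" if pd.isna(se) else f" ± {se:.2f}"
            lines.append(f"energy: {r['state']} site {r['site']} "
                         f"strength {r['strength']:.2f}{se_txt} kcal/mol")
        if "bindable_from_water" in tables["energy"].columns:
            bind = tables["energy"].groupby("state")["bindable_from_water"].first()
            for state in sorted(bind.index):
                lines.append(f"verdict: {state} "
                             f"{'bindable' if bind[state] else 'not bindable'} "
                             f"from water")
    return "\n".join(lines) + "\n"


def render_plots(tables: Mapping[str, pd.DataFrame], out_dir) -> list[Path]:
    """Optional figures (stability scatter, flux bars, energy bars)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if "scatter" in tables and len(tables["scatter"]):
        df = tables["scatter"]
        fig, ax = plt.subplots(figsize=(5, 4))
        sc = ax.scatter(df["RMSF"], df["N_water"], c=df["n_protons"],
                        cmap="viridis", s=12)
        ax.axvline(0.5, ls="--", c="red", lw=0.8)
        ax.axhline(8.0, ls="--", c="red", lw=0.8)
        ax.set_xlabel("RMSF (Å)")
        ax.set_ylabel("N_water")
        fig.colorbar(sc, label="protons")
        fig.tight_layout()
        p = out_dir / "stability_scatter.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    if "flux" in tables and len(tables["flux"]):
        df = tables["flux"]
        fig, ax = plt.subplots(figsize=(6, 4))
        labels = df["state"] + "\n" + df["pathway"]
        ax.bar(range(len(df)), df["mean_inward"],
               yerr=df["se"].fillna(0.0), capsize=2)
        ax.set_xticks(range(len(df)), labels, fontsize=5, rotation=90)
        ax.set_ylabel("inward transits / replica")
        fig.tight_layout()
        p = out_dir / "pathway_flux.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    if "energy" in tables and len(tables["energy"]):
        df = tables["energy"]
        fig, ax = plt.subplots(figsize=(6, 4))
        labels = df["state"] + ":" + df["site"]
        ax.bar(range(len(df)), df["strength"],
               yerr=df.get("se", pd.Series(0, index=df.index)).fillna(0.0),
               capsize=2)
        if "hydration_strength" in df.columns:
            ax.axhline(df["hydration_strength"].iloc[0], ls="--", c="blue")
        ax.set_xticks(range(len(df)), labels, fontsize=6, rotation=90)
        ax.set_ylabel("binding strength (kcal/mol)")
        fig.tight_layout()
        p = out_dir / "binding_energies.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
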