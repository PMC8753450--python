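"""Orchestration: manifest validation, config handling, and the end-to-end
synthetic run that chains simulate -> differential abundance -> tracking ->
single-cell linkage -> emergence audit.

All stage outputs are TSV/JSON with fixed column orders, sorted rows and
fixed float formatting, so a rerun with the same seeds is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from clonodyn import __version__
from clonodyn.diff_abundance import BetaBinomNull, differential_abundance
from clonodyn.diversity import repertoire_clonality, subset_clonality
from clonodyn.errors import ConfigError
from clonodyn.overlap_resampling import audit_emergent_clones, overlap_curve
from clonodyn.repertoire_io import DEFAULT_TIMEPOINT_ORDER, write_repertoire
from clonodyn.clone_tracking import build_trajectories
from clonodyn.sc_link import gate_subsets, write_single_cell_inputs
from clonodyn.synthetic_data import (
    RepertoireGeneratorConfig,
    SCGeneratorConfig,
    Spike,
    generate_repertoire_series,
    generate_single_cell,
)

logger = logging.getLogger(__name__)

__all__ = ["Manifest", "validate_manifest", "default_config", "load_config", "run_all"]

MANIFEST_COLUMNS = ("subject", "timepoint", "compartment", "path", "datatype")
FLOAT_FORMAT = "%.10g"


@dataclass
class Manifest:
    rows: pd.DataFrame

    def paths(self, datatype: str | None = None) -> list[Path]:
        df = self.rows
        if datatype is not None:
            df = df[df["datatype"] == datatype]
        return [Path(p) for p in df["path"]]


def validate_manifest(path, timepoint_order=DEFAULT_TIMEPOINT_ORDER) -> Manifest:
    """Validate a sample manifest TSV and normalize its row order.

    Required columns: subject, timepoint, compartment, path, datatype.
    Rejects duplicate (subject, timepoint, compartment, datatype) keys,
    unknown timepoint labels, and missing files.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"manifest missing column(s): {', '.join(missing)}")
    key_cols = ["subject", "timepoint", "compartment", "datatype"]
    dupes = df[df.duplicated(key_cols, keep=False)]
    if not dupes.empty:
        first = dupes.index[0] + 2  # 1-based with header
        raise ConfigError(f"duplicate manifest key at file row {first}: "
                          f"{tuple(dupes.iloc[0][key_cols])}")
    order = list(timepoint_order)
    bad = sorted(set(df["timepoint"]) - set(order))
    if bad:
        raise ConfigError(f"unknown timepoint label(s) {bad}; allowed: {order}")
    for p in df["path"]:
        if not Path(p).exists():
            raise ConfigError(f"manifest path does not exist: {p}")
    df = df.assign(_tp=df["timepoint"].map(order.index)).sort_values(
        ["subject", "_tp", "compartment", "datatype"], kind="stable"
    ).drop(columns="_tp").reset_index(drop=True)
    return Manifest(rows=df)


def default_config() -> dict:
    """Default synthetic end-to-end run configuration."""
    return {
        "seed": 0,
        "repertoire": {
            "n_clones": 5000,
            "clone_frequency_law": "powerlaw",
            "alpha": 2.0,
            "n_templates": 20000,
            "phi": 1e-4,
            "timepoints": ["Day0", "EOC2", "EOC4"],
            "n_novel_spikes": 5,
            "spike_fold": 60.0,
            "spike_timepoint": "EOC4",
        },
        "test": {"phi": 1e-4, "fdr_threshold": 0.01, "novel_baseline_max": 0.001,
                 "min_total": 2},
        "single_cell": {"n_cells": 2000, "timepoints": ["Day0", "EOC2", "EOC4"]},
        "overlap": {"sizes": [100, 250, 500, 1000], "n_reps": 50},
    }


def load_config(path) -> dict:
    """Load a YAML config, layered over :func:`default_config`."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for section, values in user.items():
        if isinstance(values, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def run_all(config: dict, outdir) -> dict:
    """Run the full synthetic pipeline; returns a summary dict.

    Stages: repertoire simulation -> per-timepoint differential abundance
    vs baseline -> trajectory assembly -> coupled single-cell simulation,
    gating and subset clonality -> overlap curve -> emergence audit. Every
    artifact lands in ``outdir``; a run log records versions, seeds and
    parameters. Deterministic given the config seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    rcfg = config["repertoire"]
    tcfg = config["test"]
    spikes = tuple(
        Spike("new", float(rcfg["spike_fold"]), rcfg["spike_timepoint"])
        for _ in range(int(rcfg["n_novel_spikes"]))
    )
    gen = RepertoireGeneratorConfig(
        n_clones=int(rcfg["n_clones"]),
        clone_frequency_law=rcfg["clone_frequency_law"],
        alpha=float(rcfg["alpha"]),
        n_templates=int(rcfg["n_templates"]),
        phi=float(rcfg["phi"]),
        timepoints=tuple(rcfg["timepoints"]),
        spikes=spikes,
        seed=seed,
    )
    reps, truth = generate_repertoire_series(gen)
    baseline_tp = gen.timepoints[0]
    for tp, rep in reps.items():
        write_repertoire(rep, outdir / f"repertoire_{tp}.tsv")
    _write_tsv(truth.spiked, outdir / "truth_spiked.tsv")

    null = BetaBinomNull(phi=float(tcfg["phi"]), method="fixed")
    diff_results = []
    summary_rows = []
    for tp in gen.timepoints[1:]:
        res = differential_abundance(
            reps[baseline_tp],
            reps[tp],
            null,
            fdr_threshold=float(tcfg["fdr_threshold"]),
            novel_baseline_max=float(tcfg["novel_baseline_max"]),
            min_total=int(tcfg["min_total"]),
        )
        diff_results.append(res)
        out = res.records.sort_values(["q_value", "cdr3_nt"], kind="stable")
        _write_tsv(out, outdir / f"diffabund_{baseline_tp}_vs_{tp}.tsv")
        summary_rows.append(
            {"timepoint": tp, "n_tested": len(res.records),
             "n_expanded": res.n_expanded, "n_contracted": res.n_contracted,
             "n_novel": int(res.records["novel"].sum())}
        )
    _write_tsv(pd.DataFrame(summary_rows), outdir / "diffabund_summary.tsv")

    series = {(tp, gen.compartment): rep for tp, rep in reps.items()}
    trajectories = build_trajectories(
        series, diff_results, baseline=baseline_tp, timepoint_order=gen.timepoints
    )
    traj_rows = []
    for tr in trajectories:
        row = {
            "cdr3_nt": tr.key.cdr3_nt,
            "v_gene": tr.key.v_gene,
            "j_gene": tr.key.j_gene,
            "first_significant_timepoint": tr.first_significant_timepoint or "",
        }
        for (tp, comp), f in sorted(tr.frequencies.items()):
            row[f"freq_{tp}_{comp}"] = f
        traj_rows.append(row)
    _write_tsv(
        pd.DataFrame(traj_rows).sort_values("cdr3_nt", kind="stable")
        if traj_rows
        else pd.DataFrame(columns=["cdr3_nt"]),
        outdir / "trajectories.tsv",
    )

    sccfg = config["single_cell"]
    sc_series = {}
    clonality_rows = []
    for i, tp in enumerate(sccfg["timepoints"]):
        cells, _sc_truth = generate_single_cell(
            SCGeneratorConfig(n_cells=int(sccfg["n_cells"]), seed=seed + 1000 + i),
            bulk=reps[tp],
        )
        gate_subsets(cells, "auto")
        sc_series[tp] = cells
        write_single_cell_inputs(cells, outdir / f"sc_{tp}")
        bulk_clon = repertoire_clonality(reps[tp]).clonality
        for subset, d in subset_clonality(cells).items():
            clonality_rows.append(
                {"timepoint": tp, "subset": subset,
                 "clonality": d.clonality if d else float("nan"),
                 "n_cells": d.n_templates if d else 0,
                 "bulk_clonality": bulk_clon}
            )
    _write_tsv(pd.DataFrame(clonality_rows), outdir / "subset_clonality.tsv")

    ocfg = config["overlap"]
    last_tp = sccfg["timepoints"][-1]
    curve = overlap_curve(
        sc_series[last_tp], ocfg["sizes"], n_reps=int(ocfg["n_reps"]), seed=seed + 2000
    )
    _write_tsv(curve.table, outdir / "overlap_curve.tsv")

    audit = audit_emergent_clones(
        sc_series,
        last_tp,
        diff_results[-1],
        reps[baseline_tp],
        novelty_max=float(tcfg["novel_baseline_max"]),
        timepoint_order=gen.timepoints,
    )
    _write_tsv(audit, outdir / "emergence_audit.tsv")

    summary = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "n_expanded_by_timepoint": {r["timepoint"]: r["n_expanded"] for r in summary_rows},
        "n_trajectories": len(trajectories),
        "false_emergent_fraction": audit.attrs["false_emergent_fraction"],
    }
    (outdir / "run_log.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
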