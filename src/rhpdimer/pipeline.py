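"""Orchestration of the full analysis over one or many trajectories.

``run_single`` executes solvation → adsorption → contacts → interface
composition → RMSF on one (sequence, conformation, replicate) entry and
writes its per-simulation artifacts; ``run_batch`` maps over a manifest,
aggregates per-sequence means ± standard deviations, runs the
Kruskal-Wallis sequence-sensitivity tests on max/sum shared waters and the
percent of time adsorbed, and fits the per-monomer adsorption–composition
regression.  Identical inputs and configuration produce byte-identical
output tables; failed entries are recorded and skipped, and a batch fails
only if every entry fails.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts as ct
from . import dynamics as dyn
from . import solvation as sv
from .io import DEFAULT_RESIDUE_MAP, ResidueMap, load_topology, read_trajectory
from .model import MONOMER_CODES, AnalysisConfig, Trajectory
from .stats import METRIC_COLUMNS, SimulationMetrics, aggregate_metrics, kruskal_wallis

__all__ = ["ManifestEntry", "RunManifest", "BatchResult", "analyze_trajectory", "run_single", "run_batch"]

logger = logging.getLogger("rhpdimer")

KW_METRICS = ("max_shared", "percent_time_adsorbed", "sum_shared")


@dataclass(frozen=True)
class ManifestEntry:
    sequence: str
    conformation: str
    replicate: str
    topology: str
    trajectory: str

    @property
    def labels(self) -> tuple[str, str, str]:
        return (self.sequence, self.conformation, self.replicate)


@dataclass
class RunManifest:
    entries: list[ManifestEntry]
    config: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str = "rhpdimer_out"

    def __post_init__(self) -> None:
        triples = [e.labels for e in self.entries]
        if len(set(triples)) != len(triples):
            raise ValueError("manifest label triples must be unique")

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        entries = [ManifestEntry(**e) for e in d["entries"]]
        cfg = AnalysisConfig.from_dict(d.get("config", {}))
        return cls(entries=entries, config=cfg, output_dir=d.get("output_dir", "rhpdimer_out"))


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def analyze_trajectory(
    traj: Trajectory,
    cfg: AnalysisConfig,
    labels: tuple[str, str, str] = ("seq", "conf", "rep"),
    outdir: str | Path | None = None,
) -> SimulationMetrics:
    """All analyses for one trajectory; writes artifacts when ``outdir``."""
    topo = traj.topology
    c1, c2 = topo.require_dimer()

    series = sv.shared_water_series(traj, cfg)
    profile = sv.classify_adsorption(series, cfg.adsorption_threshold_waters)
    summary = sv.solvation_summary(series)

    report = ct.interacting_residues(traj, cfg.contact_cutoff_A, cfg)
    cts = ct.typepair_contact_timeseries(traj, cfg)
    iface = ct.interface_composition(traj, cfg.contact_cutoff_A, cfg)
    enrichment = (
        ct.composition_enrichment(iface, topo) if iface.fractions is not None else None
    )

    # pooled Table-2 style RMSF partition over both chains
    rmsf_reports = {}
    pooled_vals, pooled_flags = [], []
    for chain in (c1, c2):
        rep = dyn.backbone_rmsf(
            traj, chain, window_ns=cfg.rmsf_window_ns, superposition=True
        )
        rmsf_reports[chain] = rep
        inter = report.interacting[chain]
        pooled_vals.append(rep.rmsf)
        pooled_flags.append(np.asarray([int(r) in inter for r in rep.residues]))
    vals = np.concatenate(pooled_vals)
    flags = np.concatenate(pooled_flags)
    rmsf_i = float(vals[flags].mean()) if flags.any() else None
    rmsf_n = float(vals[~flags].mean()) if (~flags).any() else None

    metrics = SimulationMetrics(
        sequence=labels[0],
        conformation=labels[1],
        replicate=labels[2],
        percent_time_adsorbed=profile.percent_time_adsorbed,
        pct_residues_any_atom=report.mean_pct_any_atom,
        pct_residues_backbone=report.mean_pct_backbone,
        max_shared=summary.max_shared,
        sum_shared=summary.sum_shared,
        mean_shared=summary.mean_shared,
        mean_union_total=summary.mean_union_total,
        interface_composition=iface.fractions,
        rmsf_interacting=rmsf_i,
        rmsf_noninteracting=rmsf_n,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        solv = series.to_dataframe()
        solv["adsorbed"] = profile.adsorbed.astype(int)
        _write_tsv(solv, outdir / "solvation.tsv")
        _write_json(
            {**summary.to_dict(), "percent_time_adsorbed": profile.percent_time_adsorbed,
             "threshold_used": profile.threshold_used},
            outdir / "solvation_summary.json",
        )
        _write_tsv(cts.to_dataframe(), outdir / "contacts_typepair.tsv")
        _write_tsv(report.to_dataframe(), outdir / "interacting_residues.tsv")
        iface_doc = iface.to_dict()
        if enrichment is not None:
            iface_doc["enrichment"] = enrichment.to_dict()
        _write_json(iface_doc, outdir / "interface_composition.json")
        frames = []
        for chain, rep in rmsf_reports.items():
            frames.append(rep.to_dataframe(report.interacting[chain]))
        _write_tsv(pd.concat(frames, ignore_index=True), outdir / "rmsf.tsv")
        _write_json(
            {
                "rmsf_interacting": rmsf_i,
                "rmsf_noninteracting": rmsf_n,
                "window_ns": list(rmsf_reports[c1].window_ns),
            },
            outdir / "rmsf_groups.json",
        )
        _write_json(
            {k: (None if isinstance(v, float) and np.isnan(v) else v)
             for k, v in metrics.to_row().items()},
            outdir / "metrics.json",
        )
        _write_json({"config": cfg.to_dict(), "labels": list(labels)}, outdir / "provenance.json")
    return metrics


def run_single(
    entry: ManifestEntry,
    cfg: AnalysisConfig,
    outdir: str | Path | None = None,
    residue_map: ResidueMap | None = None,
) -> SimulationMetrics:
    """Load one manifest entry from disk and analyze it."""
    rmap = residue_map or DEFAULT_RESIDUE_MAP
    try:
        topo, _ = load_topology(entry.topology, rmap)
        traj = read_trajectory(entry.trajectory, topo)
        return analyze_trajectory(traj, cfg, entry.labels, outdir)
    except Exception as exc:
        raise RuntimeError(
            f"entry {entry.labels}: {type(exc).__name__}: {exc}"
        ) from exc


@dataclass
class BatchResult:
    master: pd.DataFrame
    aggregate: pd.DataFrame
    kw_tests: dict
    regression: dict
    failures: list[tuple[tuple[str, str, str], str]]


def _regression_points(master: pd.DataFrame) -> dict[str, list[tuple[float, float]]]:
    points: dict[str, list[tuple[float, float]]] = {c: [] for c in MONOMER_CODES}
    for _, row in master.iterrows():
        for c in MONOMER_CODES:
            x = row[f"iface_{c}"]
            if not np.isnan(x):
                points[c].append((100.0 * float(x), float(row["percent_time_adsorbed"]) / 100.0))
    return points


def run_batch(
    manifest: RunManifest, residue_map: ResidueMap | None = None
) -> BatchResult:
    """Analyze every manifest entry, then aggregate and test."""
    if not manifest.entries:
        raise ValueError("manifest has no entries")
    outroot = Path(manifest.output_dir)
    rows = []
    failures: list[tuple[tuple[str, str, str], str]] = []
    for entry in manifest.entries:  # manifest order, deterministic
        entry_dir = outroot / f"{entry.sequence}_{entry.conformation}_{entry.replicate}"
        try:
            metrics = run_single(entry, manifest.config, entry_dir, residue_map)
            rows.append(metrics.to_row())
        except Exception as exc:
            logger.error("entry %s failed: %s", entry.labels, exc)
            failures.append((entry.labels, str(exc)))
    if not rows:
        raise RuntimeError("all manifest entries failed")

    master = pd.DataFrame(rows).sort_values(
        ["sequence", "conformation", "replicate"]
    ).reset_index(drop=True)
    aggregate = aggregate_metrics(master)

    kw_tests: dict[str, dict] = {}
    groups_by_seq = master.groupby("sequence")
    for metric in KW_METRICS:
        groups = [g[metric].to_numpy(dtype=float) for _, g in groups_by_seq]
        try:
            kw_tests[metric] = kruskal_wallis(groups).to_dict()
        except ValueError as exc:
            kw_tests[metric] = {"error": str(exc)}

    fits = ct.adsorption_composition_regression(_regression_points(master))
    regression = {
        c: (fit.to_dict() if fit is not None else None) for c, fit in fits.items()
    }

    agg_dir = outroot / "aggregate"
    agg_dir.mkdir(parents=True, exist_ok=True)
    _write_tsv(master, agg_dir / "master_table.tsv")
    _write_tsv(aggregate, agg_dir / "aggregate_table.tsv")
    _write_json(kw_tests, agg_dir / "kw_tests.json")
    _write_json(regression, agg_dir / "regression.json")
    if failures:
        _write_json(
            [{"labels": list(l), "error": e} for l, e in failures],
            agg_dir / "failures.json",
        )
    return BatchResult(master, aggregate, kw_tests, regression, failures)
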