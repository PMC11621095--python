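"""End-to-end orchestration: simulate -> preprocess/QC -> connectomes ->
metrics + AUC -> group stats -> NBS, with one master seed, a serialized
config next to every run, and TSV outputs throughout."""

from __future__ import annotations

import hashlib
import json
import logging
import time

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import synth, preprocess, connectome, metrics, stats, nbs

log = logging.getLogger("fcnet")

_COHORT_KEYS = {
    "n_patients", "n_controls", "n_regions", "n_volumes", "tr_seconds",
    "n_modules", "within_module_coupling", "secondary_coupling_ratio",
    "between_module_coupling", "coupling_heterogeneity", "hub_coupling",
    "n_hub_pairs_per_link", "planted_node", "planted_node_retention",
    "clique_regions", "clique_coupling", "noise_sd", "motion_scale",
    "qc_violator_fraction",
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serializable)."""

    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    n_discard: int = 10
    band_hz: tuple[float, float] = (0.01, 0.08)
    use_global_signal: bool = True
    apply_qc: bool = True
    sparsity_min: float = 0.032
    sparsity_max: float = 0.492
    sparsity_step: float = 0.01
    rank: str = "signed"
    n_nulls: int = 1000
    swap_factor: int = 10
    include_nodal: bool = True
    nbs_p_threshold: float = 0.01
    nbs_primary_t: float | None = None
    n_permutations: int = 5000
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cohort_unknown = set(d.get("cohort", {})) - _COHORT_KEYS - {"planted_edges", "seed"}
        if cohort_unknown:
            raise ValueError(f"unknown cohort keys: {sorted(cohort_unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.band_hz, list):
            cfg.band_hz = tuple(cfg.band_hz)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["band_hz"] = list(self.band_hz)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def cohort_spec(self) -> synth.CohortSpec:
        kw = dict(self.cohort)
        kw.setdefault("seed", self.seed)
        pe = kw.get("planted_edges")
        if pe is not None:
            kw["planted_edges"] = [
                e if isinstance(e, synth.PlantedEdge) else synth.PlantedEdge(*e)
                for e in pe
            ]
        return synth.CohortSpec(**kw)

    def grid(self) -> connectome.SparsityGrid:
        return connectome.SparsityGrid(
            self.sparsity_min, self.sparsity_max, self.sparsity_step
        )


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class StageError(Exception):
    stage: str
    subject_id: str
    message: str

    def __str__(self) -> str:
        where = f" (subject {self.subject_id})" if self.subject_id else ""
        return f"stage {self.stage!r}{where}: {self.message}"


def preprocess_cohort(
    records: list[synth.SubjectRecord], config: RunConfig
) -> tuple[list[synth.SubjectRecord], pd.DataFrame]:
    """QC + denoising; returns retained subjects and the QC report."""
    kept = []
    qc_rows = []
    for rec in records:
        try:
            qc = preprocess.qc_exclude(rec.motion, rec.subject_id)
            qc_rows.append(
                {
                    "subject_id": rec.subject_id,
                    "max_translation_mm": qc.max_translation_mm,
                    "max_rotation_deg": qc.max_rotation_deg,
                    "mean_fd_mm": qc.mean_fd_mm,
                    "passed": qc.passed,
                    "reason": qc.reason,
                }
            )
            if config.apply_qc and not qc.passed:
                log.info("excluding %s: %s", rec.subject_id, qc.reason)
                continue
            clean = preprocess.preprocess_subject(
                rec.timeseries,
                motion=rec.motion,
                n_discard=config.n_discard,
                band_hz=config.band_hz,
                use_global_signal=config.use_global_signal,
            )
            kept.append(
                synth.SubjectRecord(
                    rec.subject_id, rec.group, rec.age, rec.sex, rec.education,
                    clean, rec.motion[config.n_discard:],
                )
            )
        except (ValueError, RuntimeError) as exc:
            raise StageError("preprocess", rec.subject_id, str(exc)) from exc
    return kept, pd.DataFrame(qc_rows)


def manifest_frame(records: list[synth.SubjectRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "age": rec.age,
                "sex": rec.sex,
                "education": rec.education,
                "mean_fd": float(preprocess.framewise_displacement(rec.motion).mean()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CohortAnalysis:
    """In-memory result of the simulate -> preprocess -> connectome ->
    metrics/AUC stages, shared by the disk-writing pipeline, the test
    suite and the acceptance script."""

    records: list
    manifest: pd.DataFrame
    connectomes: list
    metric_table: pd.DataFrame
    auc_table: pd.DataFrame
    design: "stats.DesignMatrix"
    grid: connectome.SparsityGrid


def analyze_cohort(
    config: RunConfig,
    include_nodal: bool | None = None,
    include_small_world: bool = True,
) -> CohortAnalysis:
    """Run the analysis stages up to the AUC table without touching disk."""
    spec = config.cohort_spec()
    records = synth.generate_cohort(spec)
    kept, _ = preprocess_cohort(records, config)
    manifest = manifest_frame(kept)
    connectomes_ = [
        connectome.connectome_from_timeseries(r.timeseries) for r in kept
    ]
    grid = config.grid()
    nodal = config.include_nodal if include_nodal is None else include_nodal
    tables = []
    for rec, w in zip(kept, connectomes_):
        nets = connectome.sweep(w, grid, rank=config.rank)
        tables.append(
            metrics.subject_metric_table(
                rec.subject_id, nets, grid,
                n_nulls=config.n_nulls,
                swap_factor=config.swap_factor,
                seed=derive_seed(config.seed, f"nulls:{rec.subject_id}"),
                include_nodal=nodal,
                include_small_world=include_small_world,
            )
        )
    metric_table = pd.concat(tables, ignore_index=True)
    auc_tab = metrics.auc_table(metric_table, grid)
    design = stats.build_design(manifest)
    return CohortAnalysis(kept, manifest, connectomes_, metric_table,
                          auc_tab, design, grid)


def group_mean_connectome(analysis: CohortAnalysis, group: str) -> connectome.WeightedConnectome:
    """Mean Fisher-z connectome of one group."""
    stack = [
        w.z_matrix
        for rec, w in zip(analysis.records, analysis.connectomes)
        if rec.group == group
    ]
    if not stack:
        raise ValueError(f"no subjects in group {group!r}")
    zbar = np.mean(stack, axis=0)
    zbar = (zbar + zbar.T) / 2.0
    np.fill_diagonal(zbar, 0.0)
    return connectome.WeightedConnectome(zbar, analysis.connectomes[0].region_labels)


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis; writes all tables under ``out_dir``."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config.config_hash()
    config.to_yaml(out / f"config_{tag}.yaml")
    run_log: dict = {
        "config_hash": tag,
        "seed": config.seed,
        "fcnet_version": __version__,
        "numpy_version": np.__version__,
    }

    # --- simulate -----------------------------------------------------
    spec = config.cohort_spec()
    try:
        records = synth.generate_cohort(spec)
    except ValueError as exc:
        raise StageError("simulate", "", str(exc)) from exc
    log.info("simulated %d subjects", len(records))

    # --- preprocess / QC ---------------------------------------------
    kept, qc_report = preprocess_cohort(records, config)
    qc_report.to_csv(out / f"qc_report_{tag}.tsv", sep="\t", index=False)
    manifest = manifest_frame(kept)
    manifest.to_csv(out / f"manifest_{tag}.tsv", sep="\t", index=False)
    run_log["n_subjects_after_qc"] = len(kept)
    if len(kept) < 4:
        raise StageError("preprocess", "", "fewer than 4 subjects after QC")

    # --- connectomes --------------------------------------------------
    conn_dir = out / "connectomes"
    conn_dir.mkdir(exist_ok=True)
    connectomes = []
    for rec in kept:
        try:
            w = connectome.connectome_from_timeseries(rec.timeseries)
        except ValueError as exc:
            raise StageError("connectome", rec.subject_id, str(exc)) from exc
        connectomes.append(w)
        connectome.write_connectome_tsv(w, conn_dir / f"{rec.subject_id}_z.tsv")

    # --- metrics + AUC -----------------------------------------------
    grid = config.grid()
    metric_tables = []
    for i, (rec, w) in enumerate(zip(kept, connectomes)):
        nets = connectome.sweep(w, grid, rank=config.rank)
        metric_tables.append(
            metrics.subject_metric_table(
                rec.subject_id, nets, grid,
                n_nulls=config.n_nulls,
                swap_factor=config.swap_factor,
                seed=derive_seed(config.seed, f"nulls:{rec.subject_id}"),
                include_nodal=config.include_nodal,
            )
        )
    metric_table = pd.concat(metric_tables, ignore_index=True)
    metric_table.to_csv(out / f"metrics_{tag}.tsv", sep="\t", index=False)
    aucs = metrics.auc_table(metric_table, grid)
    aucs.to_csv(out / f"auc_{tag}.tsv", sep="\t", index=False)

    # --- group statistics --------------------------------------------
    design = stats.build_design(manifest)
    global_res = stats.test_global(aucs, design, alpha=config.alpha)
    tables = [stats.results_table(global_res, "global")]
    if config.include_nodal:
        nodal_res = stats.test_nodal(aucs, design, alpha=config.alpha)
        tables.append(stats.results_table(nodal_res, "nodal"))
    stat_table = pd.concat(tables, ignore_index=True)
    stat_table.to_csv(out / f"group_tests_{tag}.tsv", sep="\t", index=False)

    # --- NBS ----------------------------------------------------------
    nbs_tables = []
    for tail in nbs.TAILS:
        res = nbs.permutation_test(
            connectomes, design,
            tail=tail,
            primary_threshold=config.nbs_primary_t,
            p_threshold=config.nbs_p_threshold,
            n_permutations=config.n_permutations,
            seed=derive_seed(config.seed, f"nbs:{tail}"),
            alpha=config.alpha,
        )
        nbs_tables.append(nbs.components_table(res, kept[0].timeseries.region_labels))
        nbs.write_significant_network(
            res, out / f"nbs_{tail}_{tag}", kept[0].timeseries.region_labels,
            alpha=config.alpha,
        )
    nbs_table = pd.concat(nbs_tables, ignore_index=True)
    nbs_table.to_csv(out / f"nbs_components_{tag}.tsv", sep="\t", index=False)

    # --- summary ------------------------------------------------------
    run_log["runtime_seconds"] = round(time.time() - t0, 1)
    sig_global = stat_table[(stat_table["family"] == "global") & stat_table["significant"]]
    run_log["significant_global_metrics"] = list(sig_global["metric"])
    sig_nbs = nbs_table[nbs_table["corrected_p"] < config.alpha] if len(nbs_table) else nbs_table
    run_log["n_significant_nbs_edges"] = int(len(sig_nbs))
    with open(out / f"run_log_{tag}.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    log.info("run complete in %.1fs -> %s", run_log["runtime_seconds"], out)
    return out
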