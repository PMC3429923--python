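"""End-to-end orchestration of the analysis.

One call runs the whole chain on a dataset (loaded from TSVs or freshly
simulated): optional structure adjustment, full-model forest, backward
purge, random baselines, top-k selection, the remove-one epistasis scan
with t-tests and q-values, genotypic LD annotation of the resulting
network, and export of every artifact as TSV/JSON/SIF under one output
directory. With ``adjust="both"`` the marker stages run twice, in parallel
``adjusted/`` and ``unadjusted/`` trees — the paired design used when
structure adjustment may over-correct a clinal trait.

Reruns with the same config and seed are bit-identical; a manifest records
the config hash, seed and artifact list.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .epistasis import export_network, interaction_scan, test_interactions
from .forest import RFConfig, derive_seed, fit_rf
from .io import Dataset, load_dataset, write_dataset
from .ld import annotate_ld
from .selection import backward_purge, random_baseline, select_top
from .simulate import SimParams, simulate_dataset
from .structure import adjust_phenotype

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "PipelineError", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Provide either input paths (``geno_path``/``pheno_path`` and optionally
    ``q_path``) or ``simulate`` params. Defaults follow the canonical
    workflow: 1500-tree forests, purge from the top 50 with 3 replicate
    fits per step, report the top 20, random baselines of sizes
    2/5/10/15/20 with 10 reps, 5 epistasis replicates, alpha 0.05.
    """

    out_dir: str | Path = "snpforest_run"
    geno_path: str | Path | None = None
    pheno_path: str | Path | None = None
    q_path: str | Path | None = None
    simulate: SimParams | None = None
    adjust: str = "both"  # "on" | "off" | "both"
    rf: RFConfig = field(default_factory=RFConfig)
    purge_start_k: int = 50
    purge_replicates: int = 3
    report_k: int = 20
    baseline_sizes: tuple = (2, 5, 10, 15, 20)
    baseline_reps: int = 10
    epistasis_replicates: int = 5
    epistasis_alpha: float = 0.05
    ld_n_perm: int = 10000
    ld_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.adjust not in ("on", "off", "both"):
            raise ValueError("adjust must be 'on', 'off' or 'both'")
        if self.report_k > self.purge_start_k:
            raise ValueError("report_k must not exceed purge_start_k")
        has_paths = self.geno_path is not None and self.pheno_path is not None
        if has_paths == (self.simulate is not None):
            raise ValueError("provide either input paths or a simulate block")
        if self.adjust != "off" and self.simulate is None and self.q_path is None:
            raise ValueError("structure adjustment requires a Q matrix input")

    def content_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (np.ndarray, tuple, list)):
                return [enc(v) for v in o]
            if isinstance(o, Path):
                return str(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return o

        body = enc(self)
        body.pop("out_dir", None)  # where outputs land is not part of the analysis
        payload = json.dumps(body, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    out_dir: Path
    manifest_path: Path
    artifacts: dict[str, str]
    summary: dict


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str, out: Path):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (out / "FAILED").write_text(f"stage {name}: {exc}\n")
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def _run_branch(dataset: Dataset, y: np.ndarray, cfg: PipelineConfig,
                branch_dir: Path, label: str) -> tuple[dict[str, str], dict]:
    """Marker stages (full RF, purge, baseline, epistasis, LD) on one trait
    version; returns (artifact paths, summary metrics)."""
    branch_dir.mkdir(parents=True, exist_ok=True)
    arts: dict[str, str] = {}
    summary: dict = {"branch": label}
    X = dataset.genotypes
    seed = derive_seed(cfg.seed, label)

    with _stage(f"{label}/full_rf", branch_dir):
        full_cfg = RFConfig(cfg.rf.n_trees, cfg.rf.mtry,
                            derive_seed(seed, "fullfit"), cfg.rf.min_node_size)
        full = fit_rf(X, y, full_cfg)
        imp = pd.DataFrame({"snp": X.snp_ids, "importance": full.importance})
        imp.to_csv(branch_dir / "full_model_importance.tsv", sep="\t", index=False)
        arts["full_model_importance"] = str(branch_dir / "full_model_importance.tsv")
        summary["full_model_pve"] = full.pve
        summary["n_negative_importance"] = int(np.sum(full.importance < 0))

    with _stage(f"{label}/purge", branch_dir):
        start_k = min(cfg.purge_start_k, X.p)
        purge_cfg = RFConfig(cfg.rf.n_trees, cfg.rf.mtry,
                             derive_seed(seed, "purge"), cfg.rf.min_node_size)
        traj = backward_purge(X, y, start_k=start_k,
                              replicates=cfg.purge_replicates, config=purge_cfg)
        traj.to_frame().to_csv(branch_dir / "purge_trajectory.tsv", sep="\t", index=False)
        arts["purge_trajectory"] = str(branch_dir / "purge_trajectory.tsv")
        report_k = min(cfg.report_k, start_k)
        top = select_top(traj, report_k)
        (branch_dir / "top_snps.txt").write_text("\n".join(top) + "\n")
        arts["top_snps"] = str(branch_dir / "top_snps.txt")
        summary["purged_pve_at_report_k"] = float(traj.pve_by_size()[report_k])
        summary["report_k"] = report_k

    with _stage(f"{label}/baseline", branch_dir):
        base_cfg = RFConfig(cfg.rf.n_trees, cfg.rf.mtry,
                            derive_seed(seed, "baseline"), cfg.rf.min_node_size)
        sizes = [s for s in cfg.baseline_sizes if s <= X.p]
        baseline = random_baseline(X, y, sizes=sizes, reps=cfg.baseline_reps,
                                   config=base_cfg)
        baseline.table.to_csv(branch_dir / "baseline.tsv", sep="\t", index=False)
        arts["baseline"] = str(branch_dir / "baseline.tsv")
        summary["baseline_mean_pve"] = {
            int(k): float(v) for k, v in baseline.summary().items()
        }

    with _stage(f"{label}/epistasis", branch_dir):
        epi_cfg = RFConfig(cfg.rf.n_trees, cfg.rf.mtry,
                           derive_seed(seed, "epistasis"), cfg.rf.min_node_size)
        edges = interaction_scan(X.subset(top), y,
                                 replicates=cfg.epistasis_replicates, config=epi_cfg)
        net = test_interactions(edges, alpha=cfg.epistasis_alpha)
        summary["n_interactions"] = net.graph.number_of_edges()

    with _stage(f"{label}/ld", branch_dir):
        net = annotate_ld(net, X, n_perm=cfg.ld_n_perm, alpha=cfg.ld_alpha,
                          seed=derive_seed(seed, "ld"))
        paths = export_network(net, branch_dir)
        arts["epistasis_edges"] = str(paths["edges"])
        arts["epistasis_ordered_pairs"] = str(paths["ordered_pairs"])
        arts["network_sif"] = str(paths["sif"])
        summary["n_ld_significant"] = int(
            sum(1 for *_, d in net.graph.edges(data=True) if d.get("ld_significant"))
        )

    return arts, summary


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full analysis; returns a report with artifact paths and metrics."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    summary: dict = {}

    with _stage("load", out):
        if config.simulate is not None:
            dataset, truth = simulate_dataset(config.simulate)
            truth.to_json(out / "truth.json")
            artifacts["truth"] = str(out / "truth.json")
        else:
            dataset = load_dataset(config.geno_path, config.pheno_path, config.q_path)
        paths = write_dataset(dataset, out / "input")
        for key, pth in paths.items():
            artifacts[key] = str(pth)
        summary["n_individuals"] = dataset.n
        summary["n_snps"] = dataset.p

    branches: list[tuple[str, np.ndarray]] = []
    if config.adjust in ("off", "both"):
        branches.append(("unadjusted", dataset.phenotype.values))
    if config.adjust in ("on", "both"):
        with _stage("adjust", out):
            if dataset.ancestry is None:
                raise ValueError("structure adjustment requested without a Q matrix")
            adj = adjust_phenotype(dataset.phenotype, dataset.ancestry)
            adf = pd.DataFrame({"individual": adj.individual_ids, adj.name: adj.values})
            adf.to_csv(out / "phenotype_adjusted.tsv", sep="\t", index=False)
            artifacts["phenotype_adjusted"] = str(out / "phenotype_adjusted.tsv")
            summary["r_squared_structure"] = adj.r_squared_structure
            branches.append(("adjusted", adj.values))

    summary["branches"] = {}
    for label, y in branches:
        arts, bsum = _run_branch(dataset, y, config, out / label, label)
        for key, pth in arts.items():
            artifacts[f"{label}/{key}"] = pth
        summary["branches"][label] = bsum

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "snpforest_version": __version__,
        "artifacts": {k: str(Path(v).relative_to(out)) for k, v in artifacts.items()},
        "summary": summary,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return RunReport(out_dir=out, manifest_path=manifest_path,
                     artifacts=artifacts, summary=summary)
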