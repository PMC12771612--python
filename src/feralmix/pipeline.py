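"""End-to-end orchestration: panel assembly and QC, per-sample supervised
ancestry with bootstrap standard errors, unsupervised two-lineage partition,
PCA projection, ROH profiling, and island-level reporting.

The pipeline mirrors the study design it implements: reference panels are
merged on shared markers and pruned of close relatives (pi-hat >= 0.70);
each query is then run *individually* through a supervised admixture fit
with 100 locus-bootstrap replicates (one query per iteration, so a single
query never perturbs the reference cluster frequencies seen by another);
an unsupervised K = 2 fit over declared Asian/European super-groups
partitions each query between the two lineages; PCA axes are fitted on a
declared reference subset and queries projected through them; and a
ROH scan with its own call-rate filters yields per-sample fROH.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from feralmix.ancestry_engine import (
    AncestryEstimate,
    ReferencePanel,
    bootstrap_standard_errors,
    estimate_cluster_frequencies,
    unsupervised_fit,
)
from feralmix.genotype_io import (
    GenotypeMatrix,
    apply_callrate_filters,
    merge_on_shared_markers,
    read_genotypes,
)
from feralmix.panel_qc import estimate_pairwise_ibd, prune_duplicates_and_relatives
from feralmix.pca_projection import fit_reference_pca, project_queries
from feralmix.roh_scan import ROHParams, compare_groups, scan_panel, segments_to_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of a full pipeline run."""

    # inputs: file-based ...
    query_path: str | None = None
    query_format: str = "plink_binary"
    reference_paths: list[tuple[str, str]] = field(default_factory=list)
    cluster_table: str | None = None  # TSV: sample_id <tab> cluster
    metadata: str | None = None  # TSV: sample_id <tab> island
    # ... or simulated (synthetic demonstration run)
    simulate: dict | None = None

    # QC thresholds
    ibd_threshold: float = 0.70
    run_reference_ibd: bool = True
    max_individual_missing: float = 0.05
    marker_callrate: float = 0.95
    roh_individual_callrate: float = 0.90

    # engine settings
    n_boot: int = 100
    tol: float = 1e-6
    max_iter: int = 2000
    mode: str = "joint"
    significance_multiplier: float = 1.0
    seed: int = 0

    # unsupervised two-lineage stage
    k2_asian_clusters: list[str] = field(default_factory=list)
    k2_european_clusters: list[str] = field(default_factory=list)
    k2_per_query: bool = True

    # PCA stage
    pca_reference_clusters: list[str] | None = None
    pca_components: int = 2
    pca_scale: bool = False

    # ROH stage
    roh: ROHParams = field(default_factory=ROHParams)
    autosome_kb: float = 2_265_775.0

    # reporting
    exclusions: list[str] = field(default_factory=list)
    outlier_threshold: float = 0.90
    out_dir: str = "feralmix_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "roh" in raw and isinstance(raw["roh"], dict):
            raw["roh"] = ROHParams(**raw["roh"])
        if "reference_paths" in raw:
            raw["reference_paths"] = [tuple(x) for x in raw["reference_paths"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class AncestryReport:
    """Per-sample and per-island ancestry summaries."""

    estimates: list[AncestryEstimate]
    cluster_ids: list[str]
    island_of: dict[str, str]
    island_table: pd.DataFrame
    significance_counts: pd.DataFrame

    def q_matrix(self) -> pd.DataFrame:
        rows = {}
        for e in self.estimates:
            row = {f"q_{c}": v for c, v in zip(e.cluster_ids, e.q)}
            if e.se is not None:
                row.update({f"se_{c}": v for c, v in zip(e.cluster_ids, e.se)})
            if e.significant is not None:
                row.update({
                    f"sig_{c}": bool(v)
                    for c, v in zip(e.cluster_ids, e.significant)
                })
            row["island"] = self.island_of.get(e.sample_id, "unassigned")
            row["converged"] = e.converged
            rows[e.sample_id] = row
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "sample_id"
        return df


@dataclass
class PipelineResult:
    config: PipelineConfig
    report: AncestryReport
    k2_table: pd.DataFrame | None
    pca_reference_scores: np.ndarray | None
    pca_query_scores: np.ndarray | None
    roh_summary: pd.DataFrame
    roh_segments: pd.DataFrame
    manifest: dict


# ---------------------------------------------------------------------------
# reporting helpers
# ---------------------------------------------------------------------------

def summarize_by_island(
    estimates: list[AncestryEstimate],
    metadata: dict[str, str],
    exclusions: list[str] | None = None,
    outlier_threshold: float = 0.90,
) -> pd.DataFrame:
    """Per-island mean ancestry with min-max ranges per cluster.

    Samples without island metadata fall into an ``unassigned`` row.  Ranges
    are computed twice: over all island members and after removing the
    declared ``exclusions``.  Samples with more than ``outlier_threshold``
    association to any single cluster are flagged (count per island).
    """
    exclusions = set(exclusions or [])
    if not estimates:
        return pd.DataFrame()
    clusters = estimates[0].cluster_ids
    rows = []
    islands: dict[str, list[AncestryEstimate]] = {}
    for e in estimates:
        islands.setdefault(metadata.get(e.sample_id, "unassigned"), []).append(e)
    for island in sorted(islands):
        members = islands[island]
        Q = np.vstack([e.q for e in members])
        kept = [e for e in members if e.sample_id not in exclusions]
        Qk = np.vstack([e.q for e in kept]) if kept else None
        row: dict[str, object] = {"island": island, "n": len(members)}
        for k, c in enumerate(clusters):
            row[f"mean_{c}"] = Q[:, k].mean()
            row[f"min_{c}"] = Q[:, k].min()
            row[f"max_{c}"] = Q[:, k].max()
            if Qk is not None:
                row[f"min_excl_{c}"] = Qk[:, k].min()
                row[f"max_excl_{c}"] = Qk[:, k].max()
        row["n_outliers"] = int((Q.max(axis=1) > outlier_threshold).sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("island")


def significance_counts(estimates: list[AncestryEstimate]) -> pd.DataFrame:
    """Per-cluster count of samples with a significant association (x/N)."""
    if not estimates:
        return pd.DataFrame()
    clusters = estimates[0].cluster_ids
    N = len(estimates)
    counts = np.zeros(len(clusters), dtype=int)
    for e in estimates:
        if e.significant is not None:
            counts += e.significant.astype(int)
    return pd.DataFrame({
        "cluster": clusters,
        "n_significant": counts,
        "n_total": N,
        "fraction": counts / N,
        "label": [f"{c}/{N}" for c in counts],
    }).set_index("cluster")


def export_report(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write Q-matrix/island/significance CSVs, a JSON manifest and a
    markdown summary; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    qdf = result.report.q_matrix()
    paths["q_matrix"] = out / "q_matrix.csv"
    qdf.to_csv(paths["q_matrix"])

    paths["island_summary"] = out / "island_summary.csv"
    result.report.island_table.to_csv(paths["island_summary"])

    paths["significance"] = out / "significance_counts.csv"
    result.report.significance_counts.to_csv(paths["significance"])

    if result.k2_table is not None:
        paths["k2"] = out / "k2_lineages.csv"
        result.k2_table.to_csv(paths["k2"])

    paths["roh_summary"] = out / "roh_summary.csv"
    result.roh_summary.to_csv(paths["roh_summary"])
    paths["roh_segments"] = out / "roh_segments.tsv"
    result.roh_segments.to_csv(paths["roh_segments"], sep="\t", index=False)

    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str, sort_keys=True)

    lines = ["# feralmix run summary", ""]
    lines += [f"- samples queried: {len(result.report.estimates)}"]
    lines += [f"- reference clusters: {len(result.report.cluster_ids)}", ""]
    lines += ["## Island summary", "", result.report.island_table.to_markdown(), ""]
    lines += ["## Significance counts", "",
              result.report.significance_counts.to_markdown(), ""]
    lines += ["## ROH summary", "", result.roh_summary.to_markdown(), ""]
    paths["markdown"] = out / "report.md"
    paths["markdown"].write_text("\n".join(lines))
    return paths


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _load_inputs(
    cfg: PipelineConfig,
) -> tuple[GenotypeMatrix, dict[str, str], dict[str, str], list]:
    """Returns (merged matrix, cluster_of for reference samples, island_of
    for queries, truth records if simulated)."""
    if cfg.simulate is not None:
        from feralmix.synthetic_panel import (
            SimulationConfig, simulate_admixed_queries, simulate_reference_panel,
        )

        sim = dict(cfg.simulate)
        n_queries = int(sim.pop("n_queries", 30))
        islands = sim.pop("islands", ["island_1", "island_2"])
        alpha = float(sim.pop("dirichlet_alpha", 1.0))
        missing_rate = float(sim.pop("missing_rate", 0.0))
        scfg = SimulationConfig(seed=cfg.seed, **sim)
        panel, freqs = simulate_reference_panel(scfg)
        rng = np.random.default_rng(cfg.seed + 1)
        q_list = [rng.dirichlet(np.full(scfg.n_clusters, alpha))
                  for _ in range(n_queries)]
        queries, truths = simulate_admixed_queries(
            freqs, q_list, seed=cfg.seed + 2, layout=scfg.layout(),
            missing_rate=missing_rate,
        )
        island_of = {
            t.sample_id: islands[i % len(islands)] for i, t in enumerate(truths)
        }
        merged = merge_on_shared_markers([panel.genotypes, queries])
        return merged, dict(panel.cluster_of), island_of, truths

    if cfg.query_path is None or not cfg.reference_paths or cfg.cluster_table is None:
        raise ValueError("config needs query_path, reference_paths and "
                         "cluster_table (or a simulate block)")
    panels = [read_genotypes(p, f) for p, f in cfg.reference_paths]
    query = read_genotypes(cfg.query_path, cfg.query_format)
    merged = merge_on_shared_markers(panels + [query])
    cluster_of = {}
    for line in Path(cfg.cluster_table).read_text().splitlines():
        if not line.strip() or line.startswith("sample_id"):
            continue
        sid, cl = line.split("\t")[:2]
        cluster_of[sid] = cl
    island_of = {}
    if cfg.metadata:
        for line in Path(cfg.metadata).read_text().splitlines():
            if not line.strip() or line.startswith("sample_id"):
                continue
            sid, isl = line.split("\t")[:2]
            island_of[sid] = isl
    return merged, cluster_of, island_of, []


def _k2_lineage_stage(
    cfg: PipelineConfig,
    reference: ReferencePanel,
    queries: GenotypeMatrix,
    rng: np.random.Generator,
) -> pd.DataFrame | None:
    """Unsupervised K = 2 partition of each query between two declared
    lineage super-groups (e.g. Asian vs European reference clusters)."""
    asian = set(cfg.k2_asian_clusters)
    euro = set(cfg.k2_european_clusters)
    if not asian or not euro:
        return None
    ref_idx = [
        i for i, sid in enumerate(reference.genotypes.sample_ids)
        if reference.cluster_of[sid] in (asian | euro)
    ]
    ref_sub = reference.genotypes.subset(sample_idx=ref_idx)
    asian_mask = np.array([
        reference.cluster_of[sid] in asian for sid in ref_sub.sample_ids
    ])
    rows = []
    seed = int(rng.integers(2**31))
    if cfg.k2_per_query:
        for qi in range(queries.n_samples):
            stacked = np.vstack([ref_sub.dosage, queries.dosage[qi:qi + 1]])
            Q, _, _, _ = unsupervised_fit(
                stacked, K=2, seed=seed, tol=cfg.tol,
                max_iter=cfg.max_iter, n_restarts=1,
            )
            # align: the cluster with higher mean membership among declared
            # Asian references is the Asian lineage
            asian_k = int(np.argmax(Q[:-1][asian_mask].mean(axis=0)))
            rows.append({
                "sample_id": queries.sample_ids[qi],
                "q_asian": Q[-1, asian_k],
                "q_european": Q[-1, 1 - asian_k],
            })
    else:
        stacked = np.vstack([ref_sub.dosage, queries.dosage])
        Q, _, _, _ = unsupervised_fit(
            stacked, K=2, seed=seed, tol=cfg.tol,
            max_iter=cfg.max_iter, n_restarts=1,
        )
        n_ref = ref_sub.n_samples
        asian_k = int(np.argmax(Q[:n_ref][asian_mask].mean(axis=0)))
        for qi in range(queries.n_samples):
            rows.append({
                "sample_id": queries.sample_ids[qi],
                "q_asian": Q[n_ref + qi, asian_k],
                "q_european": Q[n_ref + qi, 1 - asian_k],
            })
    return pd.DataFrame(rows).set_index("sample_id")


def run_full_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage in order and return the collected results.

    Stage order: input assembly/merge -> call-rate QC -> reference IBD
    pruning -> cluster frequency model -> per-sample supervised query with
    bootstrap SEs -> unsupervised K = 2 lineage partition -> PCA fit +
    projection -> ROH scan -> island report.  A failed query is recorded and
    does not abort the batch.  Fixed seeds give identical reports.
    """
    rng = np.random.default_rng(cfg.seed)
    manifest: dict = {"config": cfg.to_dict(), "stages": {}}

    merged, cluster_of, island_of, truths = _load_inputs(cfg)
    manifest["stages"]["merge"] = {
        "n_samples": merged.n_samples, "n_markers": merged.n_markers,
    }

    filtered, filt_report = apply_callrate_filters(
        merged,
        max_individual_missing=cfg.max_individual_missing,
        min_marker_callrate=0.0,  # global stage filters individuals only;
    )                             # the marker filter is applied in the ROH stage
    manifest["stages"]["callrate_qc"] = {
        "removed_samples": filt_report.removed_samples,
        "removed_markers": len(filt_report.removed_markers),
    }

    is_ref = np.array([s.sample_id in cluster_of for s in filtered.samples])
    ref_g = filtered.subset(sample_idx=np.flatnonzero(is_ref))
    query_g = filtered.subset(sample_idx=np.flatnonzero(~is_ref))
    if query_g.n_samples == 0:
        raise ValueError("no query samples after QC")

    if cfg.run_reference_ibd:
        estimates = estimate_pairwise_ibd(ref_g)
        missingness = dict(zip(ref_g.sample_ids, ref_g.missing_fraction_per_sample()))
        retained, removal_log = prune_duplicates_and_relatives(
            estimates, threshold=cfg.ibd_threshold, missingness=missingness,
        )
        keep_idx = [i for i, sid in enumerate(ref_g.sample_ids) if sid in set(retained)]
        ref_g = ref_g.subset(sample_idx=keep_idx)
        manifest["stages"]["ibd_pruning"] = {
            "removed": removal_log["removed"].tolist() if len(removal_log) else [],
        }

    reference = ReferencePanel(
        genotypes=ref_g,
        cluster_of={sid: cluster_of[sid] for sid in ref_g.sample_ids},
    )
    freq_model = estimate_cluster_frequencies(reference)
    manifest["stages"]["frequencies"] = {
        "n_clusters": freq_model.n_clusters, "n_markers": freq_model.n_markers,
    }

    estimates: list[AncestryEstimate] = []
    failures: list[str] = []
    for qi in range(query_g.n_samples):
        sid = query_g.sample_ids[qi]
        try:
            est = bootstrap_standard_errors(
                query_g.dosage[qi], reference,
                n_boot=cfg.n_boot, seed=int(rng.integers(2**31)),
                significance_multiplier=cfg.significance_multiplier,
                mode=cfg.mode, tol=cfg.tol, max_iter=cfg.max_iter,
                sample_id=sid,
            )
            estimates.append(est)
        except ValueError as exc:
            logger.warning("query %s failed: %s", sid, exc)
            failures.append(sid)
    manifest["stages"]["supervised"] = {
        "n_queries": len(estimates), "failures": failures,
    }

    k2_table = _k2_lineage_stage(cfg, reference, query_g, rng)

    pca_ref_scores = pca_query_scores = None
    pca_clusters = cfg.pca_reference_clusters or reference.cluster_ids
    pca_idx = [
        i for i, sid in enumerate(ref_g.sample_ids)
        if reference.cluster_of[sid] in set(pca_clusters)
    ]
    if len(pca_idx) > cfg.pca_components:
        pca_panel = ref_g.subset(sample_idx=pca_idx)
        model = fit_reference_pca(pca_panel, cfg.pca_components, scale=cfg.pca_scale)
        pca_ref_scores = model.reference_scores
        pca_query_scores = project_queries(model, query_g)
        manifest["stages"]["pca"] = {
            "n_reference": len(pca_idx),
            "explained_variance": model.explained_variance.tolist(),
        }

    # ROH stage: its own call-rate filters (marker then individual)
    roh_input, _ = apply_callrate_filters(
        filtered,
        max_individual_missing=1.0 - cfg.roh_individual_callrate,
        min_marker_callrate=cfg.marker_callrate,
    )
    profiles = scan_panel(roh_input, cfg.roh, autosome_kb=cfg.autosome_kb)
    by_group: dict[str, list] = {}
    for p in profiles:
        if p.sample_id in cluster_of:
            key = f"reference:{cluster_of[p.sample_id]}"
        else:
            key = island_of.get(p.sample_id, "query")
        by_group.setdefault(key, []).append(p)
    roh_summary = compare_groups(by_group)
    all_segments = [s for p in profiles for s in p.segments]
    manifest["stages"]["roh"] = {
        "n_profiles": len(profiles), "n_segments": len(all_segments),
    }

    island_table = summarize_by_island(
        estimates, island_of, exclusions=cfg.exclusions,
        outlier_threshold=cfg.outlier_threshold,
    )
    report = AncestryReport(
        estimates=estimates,
        cluster_ids=reference.cluster_ids,
        island_of=island_of,
        island_table=island_table,
        significance_counts=significance_counts(estimates),
    )
    manifest["seed"] = cfg.seed
    if truths:
        truth_q = {t.sample_id: t.true_q for t in truths}
        errs = [
            float(np.abs(e.q - truth_q[e.sample_id]).sum() / 2.0)
            for e in estimates if e.sample_id in truth_q
        ]
        if errs:
            manifest["stages"]["truth"] = {
                "mean_total_variation_error": float(np.mean(errs)),
            }
    return PipelineResult(
        config=cfg,
        report=report,
        k2_table=k2_table,
        pca_reference_scores=pca_ref_scores,
        pca_query_scores=pca_query_scores,
        roh_summary=roh_summary,
        roh_segments=segments_to_table(all_segments),
        manifest=manifest,
    )
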