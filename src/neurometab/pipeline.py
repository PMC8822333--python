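"""End-to-end orchestration of the imaging-metabolomics integration.

Stages run in the fixed order: simulate (or load) -> metabolomics
preprocessing -> gray-matter mask + PLS-DA voxel selection -> voxel x
metabolite network with automatic cutoff -> community detection +
centrality -> atlas annotation -> per-community pathway enrichment ->
train/validation replication. Each stage leaves a machine-readable report;
when ground truth is available (synthetic runs) recovery metrics are
attached.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import network as net_mod
from .annotate import AtlasVolume, annotate_communities
from .enrichment import enrich_cluster
from .errors import ConfigurationError
from .plsda import PLSDAVoxelSelector
from .preprocess import MetabolomicsPreprocessor
from .replication import fit_r2, replicate_network, stratified_split
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset
from .volumes import build_gm_mask, extract_voxel_matrix


@dataclass
class PipelineConfig:
    """All stage thresholds with the reference pipeline's values as defaults."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    mask_threshold: float = 0.3
    cv_max: float = 0.75
    r_min: float = 0.7
    miss_max: float = 0.20
    vip_min: float = 2.0
    pct_min: float = 2.0
    k_folds: int = 3
    max_components: int = 5
    alpha: float = 0.05
    cutoff: float | None = None          # None = automatic weakest-link rule
    association_mode: str = "pearson"
    tol_ppm: float = 10.0
    n_perm: int = 100
    train_frac: float = 0.67
    contig_min: float = 0.5
    majority_min: float = 0.5
    seed: int = 0

    REQUIRED = (
        "mask_threshold", "cv_max", "r_min", "miss_max", "vip_min", "pct_min",
        "alpha", "tol_ppm", "train_frac",
    )

    def validate(self) -> None:
        for name in self.REQUIRED:
            v = getattr(self, name, None)
            if v is None:
                raise ConfigurationError(f"missing required threshold: {name}")
        if not (0 <= self.mask_threshold <= 1):
            raise ConfigurationError("mask_threshold must lie in [0, 1]")
        if self.cutoff is not None and not (0 < self.cutoff <= 1):
            raise ConfigurationError("cutoff must lie in (0, 1]")
        if not (0 < self.train_frac < 1):
            raise ConfigurationError("train_frac must lie in (0, 1)")
        self.synthetic.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", {})
        if "grid_dims" in syn:
            syn["grid_dims"] = tuple(syn["grid_dims"])
        known = {f.name for f in dataclasses.fields(cls) if f.name != "synthetic"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(synthetic=SyntheticConfig(**syn), **raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: SyntheticDataset
    clean: object
    mask: object
    selector: PLSDAVoxelSelector
    assoc: object | None
    network: object | None
    communities: object | None
    centrality: pd.Series | None
    cluster_summary: pd.DataFrame | None
    annotations: pd.DataFrame | None
    enrichments: dict[int, pd.DataFrame]
    enrichment_status: dict[int, str]
    replication: object | None
    metrics: dict
    stage_reports: list[dict]
    status: str = "ok"


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def run_all(config: PipelineConfig, dataset: SyntheticDataset | None = None,
            outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage on a (possibly pre-generated) dataset."""
    config.validate()
    reports: list[dict] = []

    def report(stage: str, t0: float, **info) -> None:
        reports.append({"stage": stage, "runtime_s": round(time.time() - t0, 3), **info})

    t0 = time.time()
    if dataset is None:
        dataset = generate_dataset(config.synthetic)
    truth, cohort = dataset.truth, dataset.cohort
    report("simulate", t0, n_subjects=len(cohort), seed=config.synthetic.seed)

    # --- metabolomics preprocessing
    t0 = time.time()
    prep = MetabolomicsPreprocessor(
        cv_max=config.cv_max, r_min=config.r_min, miss_max=config.miss_max
    )
    clean = prep.fit_transform(dataset.raw, cohort)
    report(
        "preprocess", t0,
        features_in=dataset.raw.n_features,
        features_out=int(clean.intensities.shape[0]),
        samples_dropped=len(clean.dropped_samples),
    )

    # --- voxel selection
    t0 = time.time()
    samples = list(clean.intensities.columns)
    gm = dataset.gm.subset(samples)
    mask = build_gm_mask(gm, threshold=config.mask_threshold)
    X = extract_voxel_matrix(gm, mask)
    y = cohort.loc[samples, "diagnosis"].to_numpy()
    selector = PLSDAVoxelSelector(
        vip_min=config.vip_min, pct_min=config.pct_min,
        k_folds=config.k_folds, max_components=config.max_components,
        random_state=config.seed,
    ).fit(X, y)
    report(
        "select_voxels", t0,
        mask_voxels=mask.n_voxels,
        selected=int(selector.selected_ids_.size),
        artifacts=int(selector.artifact_ids_.size),
        n_components=selector.model_.n_components,
    )

    metrics: dict = {}
    if truth.region_voxel_ids:
        sel_grid = set(mask.to_grid_ids(selector.selected_ids_).tolist())
        planted = set(truth.all_region_voxels.tolist())
        metrics["voxel_jaccard"] = _jaccard(sel_grid, planted)

    if selector.selected_ids_.size == 0:
        return PipelineResult(
            config=config, dataset=dataset, clean=clean, mask=mask,
            selector=selector, assoc=None, network=None, communities=None,
            centrality=None, cluster_summary=None, annotations=None,
            enrichments={}, enrichment_status={}, replication=None,
            metrics=metrics, stage_reports=reports, status="no voxels selected",
        )

    # --- network integration
    t0 = time.time()
    Xsel = X[:, selector.selected_ids_]
    voxel_names = [f"V{int(j)}" for j in selector.selected_ids_]
    M = clean.intensities.to_numpy().T          # samples x features
    feat_names = list(clean.intensities.index)
    assoc = net_mod.compute_association_matrix(
        Xsel, M, mode=config.association_mode,
        voxel_ids=voxel_names, metabolite_ids=feat_names,
    )
    cutoff = config.cutoff or net_mod.select_cutoff(assoc, alpha=config.alpha)
    network = net_mod.build_network(assoc, cutoff=cutoff, alpha=config.alpha)
    communities = net_mod.detect_communities(network, seed=config.seed)
    centrality = net_mod.compute_centrality(network)
    summary = net_mod.summarize_clusters(communities)
    report(
        "integrate", t0,
        cutoff=float(cutoff),
        n_edges=len(network.edges),
        n_communities=len(communities.communities),
        modularity=communities.modularity,
    )

    # --- annotation
    t0 = time.time()
    atlas = AtlasVolume(labels=dataset.atlas, names=dataset.atlas_names)
    name_to_id = {f"V{int(j)}": int(j) for j in selector.selected_ids_}
    annotations = annotate_communities(
        communities, mask, atlas, name_to_id,
        contig_min=config.contig_min, majority_min=config.majority_min,
    )
    report("annotate", t0, communities=len(annotations))

    # --- recovery bookkeeping for community structure
    if truth.region_voxel_ids:
        region_of_grid = {}
        for r, vox in enumerate(truth.region_voxel_ids):
            for v in vox:
                region_of_grid[int(v)] = r
        sel_grid_ids = mask.to_grid_ids(selector.selected_ids_)
        truth_labels, pred_labels = [], []
        for name, j in zip(voxel_names, sel_grid_ids):
            if int(j) in region_of_grid and name in communities.membership.index:
                truth_labels.append(region_of_grid[int(j)])
                pred_labels.append(int(communities.membership[name]))
        feat_region = {}
        for r, feats in enumerate(truth.signal_feature_ids):
            for f in feats:
                feat_region[f"F{int(f) + 1:06d}"] = r
        for name, r in feat_region.items():
            if name in communities.membership.index:
                truth_labels.append(r)
                pred_labels.append(int(communities.membership[name]))
        if truth_labels:
            metrics["community_ari"] = float(
                adjusted_rand_score(truth_labels, pred_labels)
            )

    # --- pathway enrichment per community
    t0 = time.time()
    enrichments: dict[int, pd.DataFrame] = {}
    status: dict[int, str] = {}
    mz = clean.mz
    for c in communities.communities:
        feats = [
            v for v in communities.nodes_in(c)
            if communities.node_types[v] == "metabolite"
        ]
        if not feats:
            continue
        table, st = enrich_cluster(
            feats, feat_names, dataset.db, mz,
            tol_ppm=config.tol_ppm, n_perm=config.n_perm, seed=config.seed + c,
        )
        enrichments[c] = table
        status[c] = st
    report("enrich", t0, communities_enriched=len(enrichments))

    if truth.enriched_pathway_id is not None and truth.region_voxel_ids:
        # the community holding the plurality of the enriched region's voxels
        region = truth.enriched_region
        target_grid = set(truth.region_voxel_ids[region].tolist())
        votes: dict[int, int] = {}
        for name, j in zip(voxel_names, mask.to_grid_ids(selector.selected_ids_)):
            if int(j) in target_grid and name in communities.membership.index:
                c = int(communities.membership[name])
                votes[c] = votes.get(c, 0) + 1
        if votes:
            target_comm = max(votes, key=votes.get)
            metrics["enriched_community"] = target_comm
            table = enrichments.get(target_comm)
            if table is not None and len(table):
                ranked = table.sort_values(
                    ["permutation_p", "fisher_p"], kind="stable"
                ).reset_index(drop=True)
                where = ranked.index[ranked["pathway"] == truth.enriched_pathway_id]
                if len(where):
                    metrics["planted_pathway_rank"] = int(where[0]) + 1
                    metrics["planted_pathway_permutation_p"] = float(
                        ranked.loc[where[0], "permutation_p"]
                    )
                    metrics["planted_pathway_fisher_p"] = float(
                        ranked.loc[where[0], "fisher_p"]
                    )

    # --- replication
    t0 = time.time()
    split = stratified_split(
        cohort.loc[samples], train_frac=config.train_frac, seed=config.seed
    )
    replication = replicate_network(
        X=Xsel, M=M, subjects=samples, split=split, cutoff=cutoff,
        alpha=config.alpha, voxel_ids=voxel_names, metabolite_ids=feat_names,
    )
    report(
        "replicate", t0,
        n_pairs=len(replication.pairs),
        r2_pairs=replication.fit_pairs.r2,
        r2_averages=replication.fit_averages.r2,
    )

    if truth.region_voxel_ids and truth.signal_feature_ids:
        grid_of_name = {f"V{int(j)}": int(g) for j, g in
                        zip(selector.selected_ids_, mask.to_grid_ids(selector.selected_ids_))}
        pair_region_v = replication.pairs["voxel"].map(
            lambda v: region_of_grid.get(grid_of_name.get(v, -1), -1)
        )
        pair_region_m = replication.pairs["metabolite"].map(
            lambda m: feat_region.get(m, -2)
        )
        is_signal = (pair_region_v == pair_region_m) & (pair_region_v >= 0)
        metrics["n_signal_pairs"] = int(is_signal.sum())
        if is_signal.sum() >= 3:
            sub = replication.pairs[is_signal]
            metrics["replication_r2_signal"] = fit_r2(
                sub["r_train"].to_numpy(), sub["r_valid"].to_numpy()
            ).r2
        metrics["replication_r2_all"] = replication.fit_pairs.r2
        metrics["replication_r2_averages"] = replication.fit_averages.r2

    result = PipelineResult(
        config=config, dataset=dataset, clean=clean, mask=mask,
        selector=selector, assoc=assoc, network=network,
        communities=communities, centrality=centrality,
        cluster_summary=summary, annotations=annotations,
        enrichments=enrichments, enrichment_status=status,
        replication=replication, metrics=metrics, stage_reports=reports,
    )
    if outdir is not None:
        write_results(result, outdir)
    return result


def write_results(result: PipelineResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(result.config.to_dict()))
    (out / "stage_reports.json").write_text(json.dumps(result.stage_reports, indent=1))
    (out / "metrics.json").write_text(json.dumps(result.metrics, indent=1))
    sel = result.selector
    mask = result.mask
    sel_table = pd.DataFrame(
        {
            "voxel_id": np.arange(sel.vip_.size),
            "x": mask.coords[:, 0],
            "y": mask.coords[:, 1],
            "z": mask.coords[:, 2],
            "vip": sel.vip_,
            "pct_diff": sel.pct_diff_,
        }
    )
    bucket = np.full(sel.vip_.size, "none", dtype=object)
    bucket[sel.selected_ids_] = "selected"
    bucket[sel.artifact_ids_] = "artifact"
    sel_table["bucket"] = bucket
    sel_table.to_csv(out / "voxel_selection.tsv", sep="\t", index=False)
    result.clean.qc_log.to_csv(out / "qc_log.tsv", sep="\t")
    if result.network is not None:
        result.network.edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        net_mod.export_graphml(
            result.network, result.communities, result.centrality,
            path=str(out / "network.graphml"),
        )
        result.cluster_summary.to_csv(out / "cluster_summary.tsv", sep="\t", index=False)
        result.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
        for c, table in result.enrichments.items():
            table.to_csv(out / f"enrichment_community_{c}.tsv", sep="\t", index=False)
    if result.replication is not None:
        result.replication.pairs.to_csv(out / "replication_pairs.tsv", sep="\t", index=False)
        result.replication.metabolite_averages.to_csv(
            out / "replication_metabolite_averages.tsv", sep="\t", index=False
        )
        fits = {
            "pairs": dataclasses.asdict(result.replication.fit_pairs),
            "metabolite_averages": dataclasses.asdict(result.replication.fit_averages),
            "cutoff": result.replication.cutoff,
        }
        (out / "replication_fits.json").write_text(json.dumps(fits, indent=1))
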