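"""End-to-end experiment runner.

Pipeline order: generate phantoms -> preprocess into the eight
configurations -> propensity match + grouped splits -> train the session
schedule on every requested configuration -> evaluate -> LRP heatmaps ->
similarity vs the reference configuration -> paired exact McNemar family ->
spectral clustering -> shortcut (boundary relevance) summary.

Everything is driven by one :class:`ExperimentConfig` and a global seed;
reports are plain TSV/JSON. When an output directory is given, reports are
written there together with a config hash, and a rerun with the identical
config reuses the stored reports instead of retraining.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .cnn import (
    Network,
    NetworkSpec,
    PerformanceRecord,
    RunResult,
    TrainingSpec,
    build_network,
    evaluate,
    train_session,
)
from .cohort import (
    SamplingSchedule,
    SessionPlan,
    SplitSpec,
    grouped_split,
    make_schedule,
    propensity_logit_match,
)
from .lrp import LRPParams, RelevanceMap, WindowingSpec, lrp_alpha_beta, mean_heatmap
from .phantom import PhantomCohort, PhantomConfig, generate_cohort, STRUCTURE_LABELS
from .preprocess import BinarizationSpec, HistogramSpec, build_configurations
from .similarity import SimilarityRow, aggregate_similarity, compare_maps
from .stats import ComparisonReport, ComparisonSpec, run_family
from .cluster import ClusterConfig, build_affinity, embed_2d, spectral_cluster

__all__ = [
    "ExperimentConfig",
    "ShortcutSummary",
    "ExperimentBundle",
    "run_experiment",
    "shortcut_summary",
    "boundary_shell",
]

ALL_CONFIG_IDS = ("A1", "B1", "C1", "D1", "A2", "B2", "C2", "D2")


@dataclass(frozen=True)
class ExperimentConfig:
    phantom: PhantomConfig = PhantomConfig()
    split: SplitSpec = SplitSpec()
    schedule: SamplingSchedule = SamplingSchedule(n_samplings=2, n_inits=2)
    training: TrainingSpec = TrainingSpec(epochs=10)
    hist_spec: HistogramSpec = HistogramSpec()
    bin_spec: BinarizationSpec = BinarizationSpec()
    comparison: ComparisonSpec = ComparisonSpec()
    cluster: ClusterConfig = ClusterConfig(k_neighbors=5)
    windowing: WindowingSpec = WindowingSpec()
    configurations: tuple[str, ...] = ALL_CONFIG_IDS
    reference: str = "A2"
    shell_width: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.configurations) - set(ALL_CONFIG_IDS)
        if unknown:
            raise ValueError(f"unknown configuration ids {sorted(unknown)}")
        if self.reference not in self.configurations:
            raise ValueError("reference configuration must be in the trained set")

    def network_spec(self) -> NetworkSpec:
        return NetworkSpec(input_shape=self.phantom.grid_shape)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ShortcutSummary:
    """Where does the model look? Shares of top-relevance voxels by
    compartment, averaged over test images of one configuration."""

    boundary_share: float
    interior_share: float
    exterior_share: float
    ventricle_share: Optional[float] = None
    hippocampus_share: Optional[float] = None


@dataclass
class ExperimentBundle:
    config: ExperimentConfig
    cohort: PhantomCohort
    sessions: dict[str, list[RunResult]]
    networks: dict[tuple[str, int, int], Network]
    performance: pd.DataFrame
    mean_heatmaps: dict[str, RelevanceMap]
    similarity: pd.DataFrame
    comparison: ComparisonReport
    shortcut: dict[str, ShortcutSummary]
    cluster_table: Optional[pd.DataFrame] = None


def boundary_shell(mask: np.ndarray, width: int = 2) -> np.ndarray:
    """Voxels within ``width`` voxels of the brain-mask boundary surface."""
    boundary = mask & ~ndimage.binary_erosion(mask)
    return ndimage.binary_dilation(boundary, iterations=width)


def shortcut_summary(
    maps: Sequence[RelevanceMap],
    masks: Sequence[np.ndarray],
    labels: Optional[Sequence[np.ndarray]] = None,
    fraction: float = 0.10,
    shell_width: int = 2,
    n_bins: int = 196,
) -> ShortcutSummary:
    """Compartment shares of the top-``fraction`` relevance voxels.

    The boundary shell, mask interior and exterior partition the grid, so
    the three shares sum to 1. Structure shares (ventricle, hippocampus)
    are reported when structure-label fields are available. A constant
    relevance map selects every voxel (no windowing threshold exists).
    """
    from .lrp import binarize_top_fraction, WindowingSpec as _WSpec

    spec = _WSpec(relevance_fraction=fraction, n_bins=n_bins)
    b_sh, i_sh, e_sh, v_sh, h_sh = [], [], [], [], []
    for idx, (m, mask) in enumerate(zip(maps, masks)):
        if np.ptp(m.R) == 0:
            top = np.ones(m.shape, dtype=bool)
        elif m.R.sum() <= 0:
            continue  # degenerate map (non-positive explained logit)
        else:
            top = binarize_top_fraction(m, spec)
        n_top = top.sum()
        if n_top == 0:
            continue
        shell = boundary_shell(mask, shell_width)
        interior = mask & ~shell
        exterior = ~mask & ~shell
        b_sh.append((top & shell).sum() / n_top)
        i_sh.append((top & interior).sum() / n_top)
        e_sh.append((top & exterior).sum() / n_top)
        if labels is not None:
            lab = labels[idx]
            if lab.any():
                v_sh.append((top & (lab == STRUCTURE_LABELS["ventricle"])).sum() / n_top)
                h_sh.append((top & (lab == STRUCTURE_LABELS["hippocampus"])).sum() / n_top)
    if not b_sh:
        raise ValueError("no usable relevance maps for the shortcut summary")
    return ShortcutSummary(
        boundary_share=float(np.mean(b_sh)),
        interior_share=float(np.mean(i_sh)),
        exterior_share=float(np.mean(e_sh)),
        ventricle_share=float(np.mean(v_sh)) if v_sh else None,
        hippocampus_share=float(np.mean(h_sh)) if h_sh else None,
    )


# ---------------------------------------------------------------------------
# stages


def stage_preprocess(cohort: PhantomCohort, cfg: ExperimentConfig) -> dict[str, np.ndarray]:
    """Stack the eight preprocessed variants of every image: config id ->
    float32 array (n_images, D, H, W), in cohort image order."""
    stacks: dict[str, list[np.ndarray]] = {c: [] for c in ALL_CONFIG_IDS}
    for im in cohort.images:
        variants = build_configurations(im.volume, im.mask, cfg.hist_spec, cfg.bin_spec)
        for cid, vol in variants.items():
            stacks[cid].append(vol.intensities.astype(np.float32))
    return {cid: np.stack(v) for cid, v in stacks.items()}


def stage_match(cohort: PhantomCohort) -> list[str]:
    """Propensity-matched analysis set: matched patients and controls."""
    cases = [s for s in cohort.subjects if s.class_label == "patient"]
    controls = [s for s in cohort.subjects if s.class_label == "control"]
    pairs = propensity_logit_match(cases, controls)
    keep = sorted({sid for pair in pairs for sid in pair})
    return keep


def _split_indices(
    cohort: PhantomCohort, keep_subjects: list[str], sampling_seed: int,
    ratios: tuple[float, float, float],
) -> dict[str, np.ndarray]:
    subjects = [s for s in cohort.subjects if s.subject_id in set(keep_subjects)]
    counts: dict[str, int] = {}
    for im in cohort.images:
        counts[im.subject.subject_id] = counts.get(im.subject.subject_id, 0) + 1
    assignment = grouped_split(
        subjects, SplitSpec(ratios=ratios, seed=sampling_seed), counts
    )
    out = {}
    for subset in ("train", "val", "test"):
        out[subset] = np.array(
            [
                i
                for i, im in enumerate(cohort.images)
                if assignment.get(im.subject.subject_id) == subset
            ],
            dtype=int,
        )
    return out


def stage_train(
    cohort: PhantomCohort,
    stacks: dict[str, np.ndarray],
    cfg: ExperimentConfig,
    keep_subjects: Optional[list[str]] = None,
) -> tuple[dict[str, list[RunResult]], dict[tuple[str, int, int], Network]]:
    """Train schedule x configurations; identical (sampling, init) seed
    pairs across configurations keep sessions comparable."""
    keep = keep_subjects if keep_subjects is not None else [s.subject_id for s in cohort.subjects]
    plans = make_schedule(cfg.schedule, cfg.split)
    y = np.array(
        [1 if im.subject.class_label == "patient" else 0 for im in cohort.images]
    )
    ids = [im.image_id for im in cohort.images]
    net_spec = cfg.network_spec()
    sessions: dict[str, list[RunResult]] = {c: [] for c in cfg.configurations}
    networks: dict[tuple[str, int, int], Network] = {}
    split_cache: dict[int, dict[str, np.ndarray]] = {}
    for plan in plans:
        if plan.sampling_seed not in split_cache:
            split_cache[plan.sampling_seed] = _split_indices(
                cohort, keep, plan.sampling_seed, cfg.split.ratios
            )
        sp = split_cache[plan.sampling_seed]
        for cid in cfg.configurations:
            x = stacks[cid]
            rng = np.random.default_rng(
                np.random.SeedSequence(plan.init_seed, spawn_key=(0x1417,))
            )
            network = build_network(net_spec, rng)
            tspec = dataclasses.replace(cfg.training, init_seed=plan.init_seed)
            result = train_session(
                network,
                x[sp["train"]], y[sp["train"]],
                x[sp["val"]], y[sp["val"]],
                tspec,
                test_x=x[sp["test"]], test_y=y[sp["test"]],
                test_ids=[ids[i] for i in sp["test"]],
                config_id=cid,
                sampling_index=plan.sampling_index,
                init_index=plan.init_index,
                sampling_seed=plan.sampling_seed,
            )
            sessions[cid].append(result)
            networks[(cid, plan.sampling_index, plan.init_index)] = network
    return sessions, networks


def performance_table(sessions: dict[str, list[RunResult]]) -> pd.DataFrame:
    rows = []
    for cid in sorted(sessions):
        try:
            perf = evaluate(sessions[cid])
        except ValueError:
            continue
        row = {"configuration": cid, "n_sessions": perf.n_sessions}
        for metric in ("accuracy", "sensitivity", "specificity", "auc"):
            s = getattr(perf, metric)
            row.update(
                {
                    f"{metric}_mean": round(s.mean, 4),
                    f"{metric}_sd": round(s.sd, 4),
                    f"{metric}_ci_low": round(s.ci_low, 4),
                    f"{metric}_ci_high": round(s.ci_high, 4),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _session_mean_map(
    network: Network,
    x: np.ndarray,
    ids: Sequence[str],
    session_id: str,
    params: LRPParams,
) -> tuple[RelevanceMap, list[RelevanceMap]]:
    maps = [
        lrp_alpha_beta(network, x[i], params, image_id=ids[i], session_id=session_id)
        for i in range(len(x))
    ]
    return mean_heatmap(maps), maps


def stage_explain(
    cohort: PhantomCohort,
    stacks: dict[str, np.ndarray],
    sessions: dict[str, list[RunResult]],
    networks: dict[tuple[str, int, int], Network],
    cfg: ExperimentConfig,
    params: LRPParams = LRPParams(),
) -> tuple[dict[str, RelevanceMap], dict[str, list[RelevanceMap]], pd.DataFrame]:
    """Mean heatmap per configuration from its best converged session, plus
    per-pair similarity of session mean heatmaps against the reference."""
    id_to_idx = {im.image_id: i for i, im in enumerate(cohort.images)}

    def maps_for(cid: str, run: RunResult) -> tuple[RelevanceMap, list[RelevanceMap]]:
        net = networks[(cid, run.sampling_index, run.init_index)]
        idx = [id_to_idx[i] for i in run.image_ids]
        x = stacks[cid][idx]
        sid = f"{cid}_s{run.sampling_index}_i{run.init_index}"
        return _session_mean_map(net, x, run.image_ids, sid, params)

    best_mean: dict[str, RelevanceMap] = {}
    best_individual: dict[str, list[RelevanceMap]] = {}
    session_means: dict[tuple[str, int, int], RelevanceMap] = {}
    for cid in cfg.configurations:
        converged = [r for r in sessions[cid] if r.converged]
        if not converged:
            continue
        for run in converged:
            mmap, imaps = maps_for(cid, run)
            session_means[(cid, run.sampling_index, run.init_index)] = mmap
            best = max(converged, key=lambda r: r.validation_accuracy)
            if (run.sampling_index, run.init_index) == (best.sampling_index, best.init_index):
                best_mean[cid] = mmap
                best_individual[cid] = imaps

    # similarity across aligned session pairs vs the reference configuration
    sim_rows = []
    agg_rows: dict[str, list[SimilarityRow]] = {}
    for (cid, s_idx, i_idx), alt_map in session_means.items():
        ref_map = session_means.get((cfg.reference, s_idx, i_idx))
        if ref_map is None:
            continue
        if np.ptp(ref_map.R) == 0 or np.ptp(alt_map.R) == 0:
            continue  # constant maps carry no comparable structure
        row = compare_maps(ref_map, alt_map)
        agg_rows.setdefault(cid, []).append(row)
        sim_rows.append(
            {"configuration": cid, "sampling": s_idx, "init": i_idx, **row.as_dict()}
        )
    summary_rows = []
    for cid in sorted(agg_rows):
        agg = aggregate_similarity(agg_rows[cid])
        row = {"configuration": cid, "n_pairs": len(agg_rows[cid])}
        for metric, a in agg.items():
            row.update(
                {
                    f"{metric}_mean": round(a.mean, 4),
                    f"{metric}_sd": round(a.sd, 4),
                    f"{metric}_ci_low": round(a.ci_low, 4),
                    f"{metric}_ci_high": round(a.ci_high, 4),
                }
            )
        summary_rows.append(row)
    return best_mean, best_individual, pd.DataFrame(summary_rows)


def stage_shortcut(
    cohort: PhantomCohort,
    best_individual: dict[str, list[RelevanceMap]],
    cfg: ExperimentConfig,
) -> dict[str, ShortcutSummary]:
    id_to_im = {im.image_id: im for im in cohort.images}
    out = {}
    for cid, maps in best_individual.items():
        masks = [id_to_im[m.image_id].mask.mask for m in maps]
        labels = [id_to_im[m.image_id].labels for m in maps]
        if not any(lab.any() for lab in labels):
            labels = None
        try:
            out[cid] = shortcut_summary(
                maps, masks, labels, fraction=0.10, shell_width=cfg.shell_width
            )
        except ValueError:
            continue  # all maps of this configuration were degenerate
    return out


def stage_cluster(
    best_individual: dict[str, list[RelevanceMap]], cfg: ExperimentConfig
) -> Optional[pd.DataFrame]:
    """Cluster the reference configuration's per-image relevance maps."""
    maps = best_individual.get(cfg.reference)
    if not maps or len(maps) < max(3, cfg.cluster.k_neighbors + 1):
        return None
    affinity = build_affinity(maps, cfg.cluster)
    result = spectral_cluster(affinity, cfg.cluster)
    coords = embed_2d(maps, cfg.cluster)
    return pd.DataFrame(
        {
            "map_id": [m.image_id for m in maps],
            "cluster": result.labels,
            "x": np.round(coords[:, 0], 4),
            "y": np.round(coords[:, 1], 4),
        }
    )


def run_experiment(
    cfg: ExperimentConfig, out_dir: Optional[Path | str] = None
) -> ExperimentBundle:
    """Execute the full audit pipeline under one config and global seed."""
    out_path = Path(out_dir) if out_dir is not None else None
    phantom_cfg = dataclasses.replace(cfg.phantom, seed=cfg.seed)
    split_spec = dataclasses.replace(cfg.split, seed=cfg.seed + 1)
    cfg = dataclasses.replace(cfg, phantom=phantom_cfg, split=split_spec)

    if out_path is not None:
        hash_file = out_path / "config_hash.json"
        if hash_file.exists():
            stored = json.loads(hash_file.read_text())
            if stored.get("hash") == cfg.hash() and (out_path / "performance.tsv").exists():
                return _load_bundle(cfg, out_path)

    cohort = generate_cohort(cfg.phantom)
    stacks = stage_preprocess(cohort, cfg)
    keep = stage_match(cohort)
    sessions, networks = stage_train(cohort, stacks, cfg, keep)
    perf = performance_table(sessions)
    best_mean, best_individual, similarity = stage_explain(
        cohort, stacks, sessions, networks, cfg
    )
    comparison = run_family(sessions, cfg.reference, cfg.comparison)
    shortcut = stage_shortcut(cohort, best_individual, cfg)
    cluster_table = stage_cluster(best_individual, cfg)

    bundle = ExperimentBundle(
        config=cfg,
        cohort=cohort,
        sessions=sessions,
        networks=networks,
        performance=perf,
        mean_heatmaps=best_mean,
        similarity=similarity,
        comparison=comparison,
        shortcut=shortcut,
        cluster_table=cluster_table,
    )
    if out_path is not None:
        _write_bundle(bundle, out_path)
    return bundle


def _comparison_table(report: ComparisonReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "configuration": t.config_id,
                "sampling": t.sampling_index,
                "init": t.init_index,
                "metric": t.metric,
                "n01": t.n01,
                "n10": t.n10,
                "p_value": round(t.p_value, 6),
                "min_attainable_p": round(t.min_attainable_p, 6),
                "significant": t.rejected,
            }
            for t in report.tests
        ]
    )


def _write_bundle(bundle: ExperimentBundle, out_path: Path) -> None:
    import nibabel as nib

    out_path.mkdir(parents=True, exist_ok=True)
    heatmap_dir = out_path / "heatmaps"
    heatmap_dir.mkdir(exist_ok=True)
    aff = np.diag([bundle.config.phantom.voxel_size_mm] * 3 + [1.0])
    for cid, m in bundle.mean_heatmaps.items():
        nib.save(
            nib.Nifti1Image(m.R.astype(np.float32), aff),
            heatmap_dir / f"mean_heatmap_{cid}.nii.gz",
        )
    bundle.performance.to_csv(out_path / "performance.tsv", sep="\t", index=False)
    bundle.similarity.to_csv(out_path / "similarity.tsv", sep="\t", index=False)
    _comparison_table(bundle.comparison).to_csv(
        out_path / "comparisons.tsv", sep="\t", index=False
    )
    if bundle.cluster_table is not None:
        bundle.cluster_table.to_csv(out_path / "clusters.tsv", sep="\t", index=False)
    shortcut = {
        cid: {k: v for k, v in dataclasses.asdict(s).items() if v is not None}
        for cid, s in bundle.shortcut.items()
    }
    summary = {
        "significant_comparisons": bundle.comparison.n_significant,
        "total_comparisons": len(bundle.comparison.tests),
        "significant_by_configuration": bundle.comparison.significant_by_config(),
        "shortcut": shortcut,
    }
    (out_path / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out_path / "config_hash.json").write_text(
        json.dumps({"hash": bundle.config.hash()})
    )


def _load_bundle(cfg: ExperimentConfig, out_path: Path) -> ExperimentBundle:
    summary = json.loads((out_path / "summary.json").read_text())
    shortcut = {
        cid: ShortcutSummary(**vals) for cid, vals in summary["shortcut"].items()
    }
    cluster_file = out_path / "clusters.tsv"
    return ExperimentBundle(
        config=cfg,
        cohort=None,  # type: ignore[arg-type]
        sessions={},
        networks={},
        performance=pd.read_csv(out_path / "performance.tsv", sep="\t"),
        mean_heatmaps={},
        similarity=pd.read_csv(out_path / "similarity.tsv", sep="\t"),
        comparison=ComparisonReport([], 0.05),
        shortcut=shortcut,
        cluster_table=pd.read_csv(cluster_file, sep="\t") if cluster_file.exists() else None,
    )
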