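"""End-to-end pipeline: simulate/read → virtual array → normalize →
filter → beta → embed → cluster → match → CNV → group summaries → stats.

``run_pipeline`` executes every stage from a single :class:`PipelineConfig`,
writes all artifacts (delimited text plus figures) under the output
directory and returns a structured, versioned report.  The report body
is deterministic for a fixed seed: it contains no timestamps and all
keys are sorted on serialization.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import array_io
from .containers import NOISE_LABEL, NEUTRAL
from .simulate import (
    SimulationConfig,
    ClassSpec,
    CNVEvent,
    generate_manifest,
    simulate_cohort,
    split_by_design,
    write_fixture,
    demo_config,
)
from .preprocess import (
    combine_arrays,
    stratified_quantile_normalize,
    filter_probes,
    compute_beta,
)
from .cluster import (
    UMAPParams,
    HDBSCANParams,
    embed_umap,
    cluster_hdbscan,
    match_clusters_to_reference,
    adjusted_rand_index,
    NOVEL,
)
from .cnv import CNVParams, total_log_intensity, bin_genome, call_cnv
from .summary import summarize_group
from .stats import chi_square_2x2, outcome_table

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Everything needed for one pipeline run.

    Exactly one of ``simulation`` (generate a synthetic cohort) or
    ``input_dir`` (read manifest/intensities/sample sheet written by
    :func:`methclass.write_fixture`) must be set.  ``seed`` drives UMAP
    and CBS permutation randomness and is mandatory.
    """

    seed: int
    outdir: Path
    simulation: SimulationConfig | None = None
    input_dir: Path | None = None
    umap: UMAPParams | None = None
    hdbscan: HDBSCANParams = field(default_factory=HDBSCANParams)
    cnv: CNVParams = field(default_factory=CNVParams)
    beta_offset: float = 100.0
    purity_threshold: float = 0.5
    # sensitivity switches: cluster the UMAP embedding (default) or the
    # beta matrix directly; optionally restrict UMAP to the most
    # variable probes (None = all retained probes)
    cluster_on: str = "embedding"
    top_variance_probes: int | None = None

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_dir is None):
            raise ValueError("exactly one of simulation / input_dir must be given")
        if self.cluster_on not in ("embedding", "betas"):
            raise ValueError("cluster_on must be 'embedding' or 'betas'")
        self.outdir = Path(self.outdir)
        if self.input_dir is not None:
            self.input_dir = Path(self.input_dir)
        if self.umap is None:
            self.umap = UMAPParams(seed=_derive_seed(self.seed, "umap"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        seed = raw["seed"]
        sim = None
        if "simulation" in raw and raw["simulation"] is not None:
            simraw = raw["simulation"]
            if simraw.get("demo"):
                sim = demo_config(seed=simraw.get("seed", seed))
            else:
                sim = simulation_config_from_dict(simraw)
        umap_params = None
        if "umap" in raw and raw["umap"] is not None:
            u = dict(raw["umap"])
            u.setdefault("seed", _derive_seed(seed, "umap"))
            umap_params = UMAPParams(**u)
        return cls(
            seed=seed,
            outdir=Path(raw.get("outdir", "methclass_out")),
            simulation=sim,
            input_dir=Path(raw["input_dir"]) if raw.get("input_dir") else None,
            umap=umap_params,
            hdbscan=HDBSCANParams(**raw.get("hdbscan", {})),
            cnv=CNVParams(**raw.get("cnv", {})),
            beta_offset=raw.get("beta_offset", 100.0),
            purity_threshold=raw.get("purity_threshold", 0.5),
            cluster_on=raw.get("cluster_on", "embedding"),
            top_variance_probes=raw.get("top_variance_probes"),
        )


def simulation_config_from_dict(raw: dict) -> SimulationConfig:
    raw = dict(raw)
    classes = []
    for c in raw.pop("classes", []):
        c = dict(c)
        events = tuple(CNVEvent(**e) for e in c.pop("cnv_events", []))
        classes.append(ClassSpec(cnv_events=events, **c))
    return SimulationConfig(classes=tuple(classes), **raw)


def _derive_seed(seed: int, label: str) -> int:
    """A stable sub-seed per pipeline stage, kept below 2**31."""
    token = sum(ord(ch) for ch in label)
    return int(np.random.SeedSequence([seed, token]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the structured report (also written to disk)."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_file_log(outdir / "pipeline.log")
    stages: list[dict] = []

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return result

    # ------------------------------------------------------------------ data
    def _load():
        if config.simulation is not None:
            manifest = generate_manifest(config.simulation)
            matrix, sheet, truth = simulate_cohort(config.simulation, manifest)
            write_fixture(outdir / "data", matrix, manifest, sheet, truth)
            matrices = split_by_design(matrix, sheet, manifest)
            return manifest, matrices, sheet, truth
        d = config.input_dir
        manifest = array_io.read_manifest(d / array_io.MANIFEST_FILE)
        matrix = array_io.read_intensities(d)
        sheet = array_io.read_sample_sheet(d / array_io.SAMPLE_SHEET_FILE)
        truth_path = d / array_io.TRUTH_FILE
        truth = array_io.read_truth(truth_path) if truth_path.exists() else None
        matrices = split_by_design(matrix, sheet, manifest)
        return manifest, matrices, sheet, truth

    manifest, matrices, sheet, truth = stage("load", _load)
    stages.append({"stage": "load", "n_probes_manifest": len(manifest),
                   "n_samples": int(len(sheet)), "n_matrices": len(matrices)})

    # ------------------------------------------------------------ preprocess
    virtual = stage("combine_arrays", lambda: combine_arrays(matrices, manifest))
    stages.append({"stage": "combine_arrays", "n_probes": virtual.n_probes,
                   "n_samples": virtual.n_samples})
    normalized = stage(
        "stratified_quantile_normalize",
        lambda: stratified_quantile_normalize(virtual, manifest),
    )
    filtered = stage("filter_probes", lambda: filter_probes(normalized, manifest))
    stages.append({"stage": "filter_probes", "n_probes": filtered.n_probes})
    betas = stage("compute_beta", lambda: compute_beta(filtered, config.beta_offset))

    # ---------------------------------------------------- embedding/clusters
    # copy-neutral CNV controls are not part of the methylation cohort;
    # only tumor samples are embedded and clustered
    sheet_idx = sheet.set_index("sample_id")
    cohort_ids = [
        s for s in betas.columns if not bool(sheet_idx.loc[s, "is_reference"])
    ]
    embedding = stage(
        "embed_umap",
        lambda: embed_umap(betas[cohort_ids], config.umap,
                           top_variance=config.top_variance_probes),
    )
    # flag members of the labeled (published) reference cohort in the plot
    labeled_flag = sheet_idx.loc[embedding.index, "known_class"].notna().to_numpy()

    def _cluster():
        coords = embedding if config.cluster_on == "embedding" else betas[cohort_ids].T
        raw = cluster_hdbscan(coords, config.hdbscan)
        from .containers import ClusterAssignment

        return ClusterAssignment(embedding.index, embedding.to_numpy(),
                                 raw.labels, labeled_flag)

    assignment = stage("cluster_hdbscan", _cluster)
    known = sheet_idx["known_class"].dropna().to_dict()
    mapping, match_report = stage(
        "match_clusters",
        lambda: match_clusters_to_reference(assignment, known, config.purity_threshold),
    )
    clusters_frame = assignment.to_frame()
    clusters_frame["mapped_label"] = [
        mapping.get(lab, "noise") for lab in assignment.labels
    ]
    clusters_frame.insert(0, "sample_id", clusters_frame.index)
    clusters_frame.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    sizes = {str(cid): int((assignment.labels == cid).sum()) for cid in assignment.cluster_ids}
    stages.append({"stage": "cluster", "n_clusters": len(sizes),
                   "n_noise": int((assignment.labels == NOISE_LABEL).sum())})

    ari = None
    truth_classes = sheet_idx["true_class"]
    has_truth = truth_classes.notna()
    if has_truth.any():
        ids = truth_classes.index[has_truth]
        pos = embedding.index.get_indexer(ids)
        ari = adjusted_rand_index(
            truth_classes.loc[ids].to_numpy(), assignment.labels[pos]
        )

    # ------------------------------------------------------------------- cnv
    def _cnv():
        log_int = total_log_intensity(filtered)
        fm = manifest[manifest["probe_id"].isin(filtered.probe_ids)]
        bins = bin_genome(fm, config.cnv)
        ref_ids = sheet.loc[sheet["is_reference"], "sample_id"].tolist()
        if len(ref_ids) < 2:
            raise ValueError("need at least 2 copy-neutral reference samples")
        query_ids = [s for s in filtered.sample_ids if s not in ref_ids]
        refs = log_int[ref_ids]
        ss = np.random.SeedSequence([config.seed, 9])
        profiles = []
        for sid, child in zip(query_ids, ss.spawn(len(query_ids))):
            profiles.append(
                call_cnv(sid, log_int[sid], refs, bins, config.cnv,
                         np.random.default_rng(child))
            )
        # neutrality check: each reference as query vs the remaining refs
        ref_nonneutral = []
        if len(ref_ids) >= 3:
            for sid, child in zip(ref_ids, ss.spawn(len(ref_ids))):
                others = [r for r in ref_ids if r != sid]
                p = call_cnv(sid, log_int[sid], refs[others], bins, config.cnv,
                             np.random.default_rng(child))
                ref_nonneutral.append(float(np.mean(p.calls != NEUTRAL) * 100.0))
        return bins, profiles, ref_nonneutral

    bins, profiles, ref_nonneutral = stage("cnv_calling", _cnv)
    array_io.write_seg(profiles, outdir / "segments.seg")
    array_io.write_calls(profiles, outdir / "calls.tsv")
    stages.append({"stage": "cnv_calling", "n_bins": len(bins),
                   "n_profiles": len(profiles)})

    # --------------------------------------------------------------- summary
    def _tracks():
        tracks = {}
        profile_ids = {p.sample_id for p in profiles}
        for cid in assignment.cluster_ids:
            members = [
                s for s in assignment.sample_ids[assignment.labels == cid]
                if s in profile_ids
            ]
            if not members:
                continue
            name = mapping.get(cid, NOVEL)
            group = f"{name}_{cid}" if list(mapping.values()).count(name) > 1 else name
            tracks[group] = summarize_group(profiles, members, group=group)
        return tracks

    tracks = stage("summarize_groups", _tracks)
    for group, track in tracks.items():
        array_io.write_track(track, outdir / f"track_{group}.tsv")

    # ----------------------------------------------------------------- stats
    def _stats():
        novel_ids = {
            s
            for cid, lab in mapping.items()
            if lab == NOVEL
            for s in assignment.sample_ids[assignment.labels == cid]
        }
        in_group = sheet["sample_id"].isin(novel_ids).to_numpy()
        if not in_group.any():
            return {"note": "no NOVEL cluster; outcome comparison skipped"}
        table = outcome_table(sheet, in_group)
        try:
            stat, p = chi_square_2x2(table, yates=False)
            stat_y, p_y = chi_square_2x2(table, yates=True)
        except ValueError as exc:
            return {"table": table.tolist(), "note": f"chi-square not computable: {exc}"}
        return {
            "table": table.tolist(),
            "chi2": stat, "p": p,
            "chi2_yates": stat_y, "p_yates": p_y,
            "seizure_free_pct_novel": _sf_pct(table[0]),
            "seizure_free_pct_rest": _sf_pct(table[1]),
        }

    outcome = stage("outcome_stats", _stats)

    # --------------------------------------------------------------- figures
    def _figures():
        from .plotting import plot_embedding, plot_cnv_profile, plot_summary_track

        plot_embedding(assignment, mapping, outdir / "umap.png")
        if profiles:
            plot_cnv_profile(profiles[0], outdir / f"profile_{profiles[0].sample_id}.png")
        for group, track in tracks.items():
            plot_summary_track(track, outdir / f"summary_{group}.png")

    stage("figures", _figures)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "stages": stages,
        "clusters": {
            "sizes": sizes,
            "mapping": {str(k): v for k, v in mapping.items()},
            "match_report": _jsonable_report(match_report),
        },
        "ari_vs_truth": ari,
        "cnv": {
            "n_bins": len(bins),
            "n_profiles": len(profiles),
            "reference_nonneutral_pct": (
                float(np.mean(ref_nonneutral)) if ref_nonneutral else None
            ),
        },
        "tracks": {
            group: {
                "n_samples": t.n_samples,
                "max_pct_gain": float(t.pct_gain.max()),
                "max_pct_loss": float(t.pct_loss.max()),
                "mean_pct_altered": float(np.mean(t.pct_gain + t.pct_loss)),
            }
            for group, t in tracks.items()
        },
        "outcome": outcome,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def _sf_pct(row) -> float:
    return float(100.0 * row[0] / (row[0] + row[1]))


def _jsonable_report(report: dict) -> dict:
    return json.loads(json.dumps(report, default=str))


def _setup_file_log(path: Path) -> None:
    root = logging.getLogger("methclass")
    root.setLevel(logging.INFO)
    for h in list(root.handlers):
        if isinstance(h, logging.FileHandler):
            root.removeHandler(h)
    root.addHandler(logging.FileHandler(path, mode="w"))
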