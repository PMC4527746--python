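"""End-to-end pipeline: simulate (optional) -> LOH -> CNA -> landscape ->
survival screen -> clustering, with a reproducibility manifest.

Each stage writes its artifacts under the configured output directory; any
stage failure is re-raised as :class:`PipelineStageError` carrying the stage
name.  Given identical inputs and seed the outputs (including the manifest)
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from pathlib import Path

import pandas as pd

from . import __version__, cluster, cna, io, landscape, loh, survival, synthetic
from .errors import LohcnaError, PipelineStageError

logger = logging.getLogger(__name__)


def build_callset(blood_genotypes, tumor_genotypes, blood_signal, tumor_signal,
                  annotation, params: cna.SegmentationParams | None = None,
                  cutoff_grid=None, target_fdr: float = cna.DEFAULT_TARGET_FDR,
                  per_subject: bool = False):
    """Run LOH calling and FDR-controlled CNA calling on in-memory matrices.

    Convenience composition of the calling stages; returns
    ``(CallSet, CutoffSelection-or-Series)``.
    """
    params = params or cna.SegmentationParams()
    loh_matrix = loh.call_loh(blood_genotypes, tumor_genotypes)
    retained, _ = loh.filter_uninformative_snps(loh_matrix)
    segmented = cna.segment_cohort(tumor_signal, blood_signal, annotation, params)
    grid = cna.DEFAULT_CUTOFF_GRID if cutoff_grid is None else cutoff_grid
    curve = cna.estimate_fdr_curve(segmented, grid)
    if per_subject:
        selection = cna.select_cutoff_per_subject(curve, target_fdr)
        cutoff = selection
    else:
        selection = cna.select_cutoff(curve, target_fdr)
        cutoff = selection.cutoff
    calls = cna.call_cna(segmented, cutoff)
    loh_aligned = loh_matrix.loc[retained].reindex(calls.classes.index,
                                                   fill_value="N")
    joint = cna.classify_joint(loh_aligned, calls.classes)
    callset = cna.CallSet(loh=loh_aligned, cna=calls, joint=joint,
                          annotation=annotation)
    return callset, selection


def call_cohort(cohort: synthetic.Cohort, **kwargs):
    """``build_callset`` on a synthetic :class:`~lohcna.synthetic.Cohort`."""
    return build_callset(cohort.blood_genotypes, cohort.tumor_genotypes,
                         cohort.blood_signal, cohort.tumor_signal,
                         cohort.annotation, **kwargs)


@contextmanager
def _stage(name: str):
    logger.info("stage %s", name)
    try:
        yield
    except LohcnaError as exc:
        raise PipelineStageError(name, exc) from exc


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: io.PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict = {}
    input_paths: dict = {}

    if config.simulate:
        with _stage("simulate"):
            if config.sim_scenario == "interaction":
                from .scenarios import opposite_sign_interaction_config
                sim_cfg = opposite_sign_interaction_config(
                    config.seed, n_samples=config.sim_n_samples)
            else:
                sim_cfg = synthetic.CohortConfig(
                    n_samples=config.sim_n_samples, seed=config.seed)
            cohort = synthetic.generate_cohort(sim_cfg)
            simdir = outdir / "inputs"
            input_paths = io.write_cohort(cohort, simdir)
    else:
        input_paths = {k: getattr(config, k) for k in (
            "blood_genotypes", "tumor_genotypes", "blood_signal",
            "tumor_signal", "annotation", "clinical")}

    with _stage("read-inputs"):
        bundle = io.read_inputs(
            input_paths["blood_genotypes"], input_paths["tumor_genotypes"],
            input_paths["blood_signal"], input_paths["tumor_signal"],
            input_paths["annotation"], input_paths["clinical"])

    with _stage("call-loh"):
        loh_matrix = loh.call_loh(bundle.blood_genotypes, bundle.tumor_genotypes)
        if config.exclude_probes:
            keep = loh_matrix.index.difference(pd.Index(config.exclude_probes))
            keep = loh_matrix.index[loh_matrix.index.isin(keep)]
            loh_matrix = loh_matrix.loc[keep]
        retained, exclusion_log = loh.filter_uninformative_snps(loh_matrix)
        loh_matrix = loh_matrix.loc[retained]
        io.write_matrix(loh_matrix, outdir / "loh_matrix.tsv")
        exclusion_log.to_csv(outdir / "loh_exclusions.tsv", sep="\t", index=False)
        written["loh_matrix"] = "loh_matrix.tsv"

    with _stage("call-cna"):
        params = cna.SegmentationParams(config.t_threshold, config.min_seg_len)
        segmented = cna.segment_cohort(bundle.tumor_signal, bundle.blood_signal,
                                       bundle.annotation, params)
        curve = cna.estimate_fdr_curve(segmented, config.cutoff_grid())
        if config.per_subject_cutoff:
            cutoff = cna.select_cutoff_per_subject(curve, config.target_fdr)
            chosen = {"mode": "per_subject",
                      "cutoffs": {k: float(v) for k, v in cutoff.items()}}
        else:
            sel = cna.select_cutoff(curve, config.target_fdr)
            cutoff = sel.cutoff
            chosen = {"mode": "global", "cutoff": sel.cutoff,
                      "mean_fdr": sel.mean_fdr,
                      "subject_fdr_median": float(sel.subject_fdr.median()),
                      "subject_fdr_max": float(sel.subject_fdr.max())}
        calls = cna.call_cna(segmented, cutoff)
        joint = cna.classify_joint(loh_matrix.reindex(calls.classes.index,
                                                      fill_value="N"),
                                   calls.classes)
        callset = cna.CallSet(loh=loh_matrix.reindex(calls.classes.index,
                                                     fill_value="N"),
                              cna=calls, joint=joint,
                              annotation=bundle.annotation)
        io.write_seg(segmented.segments, outdir / "segments.seg")
        curve.mean_fdr.to_csv(outdir / "fdr_curve.tsv", sep="\t")
        io.write_matrix(calls.classes, outdir / "cna_calls.tsv")
        io.write_matrix(joint, outdir / "joint_classes.tsv")
        (outdir / "cutoff.json").write_text(json.dumps(chosen, indent=2, sort_keys=True))
        written.update({"segments": "segments.seg", "cna_calls": "cna_calls.tsv",
                        "joint_classes": "joint_classes.tsv", "cutoff": "cutoff.json"})

    with _stage("landscape"):
        consensus = landscape.consensus_frequencies(callset, config.loh_denominator)
        consensus.to_csv(outdir / "consensus.tsv", sep="\t", index_label="probe")
        arms = landscape.arm_events(callset)
        arms.arm_percentages.to_csv(outdir / "arm_percentages.tsv", sep="\t",
                                    index_label="arm")
        per_sample, summary = landscape.burden(callset)
        per_sample.to_csv(outdir / "burden.tsv", sep="\t")
        summary.to_csv(outdir / "burden_summary.tsv", sep="\t")
        for ev, tbl in landscape.top_k_tables(consensus, bundle.annotation,
                                              config.top_k).items():
            tbl.to_csv(outdir / f"top_{ev}.tsv", sep="\t", index_label="probe")
        io.write_bed_track(consensus, bundle.annotation, "loh_fraction",
                           outdir / "consensus_loh.bed")
        written["consensus"] = "consensus.tsv"

    with _stage("screen"):
        result = survival.screen(callset, bundle.clinical,
                                 min_loh_samples=config.min_loh_samples,
                                 cna_coding=config.cna_coding)
        result.to_csv(outdir / "screen.tsv", sep="\t", index_label="probe")
        if not result.empty:
            survival.manhattan_table(result, bundle.annotation).to_csv(
                outdir / "manhattan.tsv", sep="\t", index_label="probe")
        written["screen"] = "screen.tsv"

    with _stage("cluster"):
        cres = cluster.cluster_samples(callset, config.cluster_event_type,
                                       linkage_method=config.linkage_method)
        cres.labels.to_csv(outdir / "clusters.tsv", sep="\t")
        assoc = {"degenerate": cres.degenerate, "event_type": cres.event_type}
        if not cres.degenerate:
            comp = cluster.compare_mortality(cres.labels, bundle.clinical)
            assoc["logrank_p"] = comp.p_value
            assoc["logrank_statistic"] = comp.statistic
            assoc["events_per_cluster"] = {str(k): int(v)
                                           for k, v in comp.n_events.items()}
            for cov in ("smoking", "stage", "site"):
                p, _ = cluster.fisher_exact(cres.labels, bundle.clinical[cov])
                assoc[f"fisher_p_{cov}"] = p
        (outdir / "cluster_association.json").write_text(
            json.dumps(assoc, indent=2, sort_keys=True))
        written["clusters"] = "clusters.tsv"

    manifest = {
        "package": "lohcna",
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(config).items()},
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)}
                   for k, v in input_paths.items()},
        "outputs": {k: {"path": v, "sha256": _sha256(outdir / v)}
                    for k, v in written.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
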