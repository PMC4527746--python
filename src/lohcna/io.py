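"""Readers and writers for the pipeline's interchange formats.

All tables are plain text: genotype and signal matrices as TSV (probe rows,
sample columns), probe annotation as TSV (probe, chrom, arm, position,
cytoband, gene; 1-based positions), the clinical table as CSV, segments in
IGV SEG layout (1-based inclusive), consensus tracks as BED (0-based
half-open at the boundary), and summaries as JSON.  Matrices are
index-aligned on read: probes sorted by chromosome then position, samples
by identifier.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (AnnotationError, ClinicalTableError, ConfigError,
                     PairingError)
from .synthetic import GENOTYPES, Cohort

CLINICAL_COLUMNS = ("sex", "age", "smoking", "alcohol", "stage", "site",
                    "nodal", "time_months", "event")
EVENT_LEVELS = ("OSCC_death", "other_death", "censored")
SMOKING_LEVELS = ("never", "former", "current")


# ---------------------------------------------------------------- matrices

def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="probe")


def read_genotype_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="probe", dtype=str)
    bad = ~df.isin(GENOTYPES)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ConfigError(
            f"invalid genotype code {df.iat[r, c]!r} at probe {df.index[r]}, "
            f"sample {df.columns[c]} in {path}")
    return df


def read_signal_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe").astype(float)


def read_loh_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe", dtype=str)


# -------------------------------------------------------------- annotation

def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index_label="probe")


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="probe",
                      dtype={"chrom": str, "arm": str, "cytoband": str},
                      keep_default_na=False, na_values=[])
    for col in ("chrom", "arm", "position"):
        if col not in ann.columns:
            raise AnnotationError(f"annotation file missing column '{col}': {path}")
    bad_arm = ~ann["arm"].isin(["p", "q"])
    if bad_arm.any():
        raise AnnotationError(
            f"unknown arm labels for probes {list(ann.index[bad_arm][:10])} in {path}")
    ann["position"] = ann["position"].astype(int)
    if "cytoband" not in ann.columns:
        ann["cytoband"] = ""
    if "gene" not in ann.columns:
        ann["gene"] = ""
    return ann


# ---------------------------------------------------------------- clinical

def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index_label="sample")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample")
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ClinicalTableError(f"clinical table missing columns: {sorted(missing)}")
    for i, (sample, row) in enumerate(df.iterrows(), start=2):  # line 1 = header
        if row["event"] not in EVENT_LEVELS:
            raise ClinicalTableError(
                f"line {i} (sample {sample}): bad event {row['event']!r}")
        if row["smoking"] not in SMOKING_LEVELS:
            raise ClinicalTableError(
                f"line {i} (sample {sample}): bad smoking {row['smoking']!r}")
        if not row["time_months"] > 0:
            raise ClinicalTableError(
                f"line {i} (sample {sample}): time_months must be > 0, "
                f"got {row['time_months']}")
    return df


# ------------------------------------------------------------ seg and bed

def write_seg(segments: pd.DataFrame, path) -> None:
    """IGV SEG: sample, chrom, 1-based inclusive start/end, probe count, mean."""
    out = segments.rename(columns={
        "sample": "ID", "chrom": "chrom", "start": "loc.start",
        "end": "loc.end", "num_probes": "num.mark", "seg_mean": "seg.mean"})
    out.to_csv(path, sep="\t", index=False)


def write_bed_track(consensus: pd.DataFrame, annotation: pd.DataFrame,
                    column: str, path, probe_span: int = 1) -> None:
    """Consensus fractions as BED: probe intervals scored by the fraction.

    Converts the 1-based annotation positions to BED's 0-based half-open
    coordinates at the boundary.
    """
    ann = annotation.loc[consensus.index]
    bed = pd.DataFrame({
        "chrom": ann["chrom"],
        "start": ann["position"] - 1,
        "end": ann["position"] - 1 + probe_span,
        "name": consensus.index,
        "score": consensus[column],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


# ------------------------------------------------------------ ground truth

def write_ground_truth(truth, path) -> None:
    """Long-format TSV: probe, sample, true LOH indicator, true tumor CN."""
    loh = truth.loh.stack()
    cn = truth.cn_tumor.stack()
    long = pd.DataFrame({"true_loh": loh.astype(int), "true_cn": cn})
    long.index.names = ["probe", "sample"]
    long.reset_index().to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    long = pd.read_csv(path, sep="\t")
    loh = long.pivot(index="probe", columns="sample", values="true_loh").astype(bool)
    cn = long.pivot(index="probe", columns="sample", values="true_cn").astype(int)
    loh.columns.name = None
    cn.columns.name = None
    return loh, cn


# ------------------------------------------------------------ input bundle

@dataclass
class InputBundle:
    blood_genotypes: pd.DataFrame
    tumor_genotypes: pd.DataFrame
    blood_signal: pd.DataFrame
    tumor_signal: pd.DataFrame
    annotation: pd.DataFrame
    clinical: pd.DataFrame
    validation: dict


def _align(df: pd.DataFrame, probes: pd.Index, samples: list, name: str) -> pd.DataFrame:
    missing_s = [s for s in samples if s not in df.columns]
    if missing_s:
        raise PairingError(f"{name}: missing sample columns {missing_s[:10]}")
    missing_p = probes.difference(df.index)
    if len(missing_p):
        raise AnnotationError(f"{name}: probes missing {list(missing_p[:10])}")
    return df.loc[probes, samples]


def read_inputs(blood_genotype_path, tumor_genotype_path, blood_signal_path,
                tumor_signal_path, annotation_path, clinical_path) -> InputBundle:
    """Read and index-align the six input files.

    Probes are ordered by chromosome then position (annotation order);
    samples by identifier.  Every sample must appear in all four matrices
    and the clinical table; every matrix probe must be annotated.
    """
    ann = read_annotation(annotation_path).sort_values(["chrom", "position"])
    bg = read_genotype_matrix(blood_genotype_path)
    tg = read_genotype_matrix(tumor_genotype_path)
    bs = read_signal_matrix(blood_signal_path)
    ts = read_signal_matrix(tumor_signal_path)
    clinical = read_clinical(clinical_path)

    unknown = bg.index.difference(ann.index)
    if len(unknown):
        raise AnnotationError(
            f"probes in matrices but not in annotation: {list(unknown[:10])}")
    samples = sorted(bg.columns)
    for name, df in (("tumor genotypes", tg), ("blood signal", bs),
                     ("tumor signal", ts)):
        extra = set(df.columns) ^ set(samples)
        if extra:
            raise PairingError(f"{name}: unpaired samples {sorted(extra)[:10]}")
    missing_clin = [s for s in samples if s not in clinical.index]
    if missing_clin:
        raise PairingError(f"clinical table missing samples {missing_clin[:10]}")

    probes = ann.index.intersection(bg.index)
    probes = ann.loc[probes].index  # annotation (genomic) order
    bundle = InputBundle(
        blood_genotypes=_align(bg, probes, samples, "blood genotypes"),
        tumor_genotypes=_align(tg, probes, samples, "tumor genotypes"),
        blood_signal=_align(bs, probes, samples, "blood signal"),
        tumor_signal=_align(ts, probes, samples, "tumor signal"),
        annotation=ann.loc[probes],
        clinical=clinical.loc[samples],
        validation={
            "n_probes": int(len(probes)),
            "n_samples": int(len(samples)),
            "n_events_oscc": int((clinical.loc[samples, "event"] == "OSCC_death").sum()),
            "missing_rate_genotypes": float((bg.loc[probes, samples] == "NC")
                                            .to_numpy().mean()),
        },
    )
    return bundle


def write_cohort(cohort: Cohort, outdir) -> dict:
    """Write the six standard inputs plus the ground-truth TSV; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "blood_genotypes": outdir / "blood_genotypes.tsv",
        "tumor_genotypes": outdir / "tumor_genotypes.tsv",
        "blood_signal": outdir / "blood_signal.tsv",
        "tumor_signal": outdir / "tumor_signal.tsv",
        "annotation": outdir / "annotation.tsv",
        "clinical": outdir / "clinical.csv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    write_matrix(cohort.blood_genotypes, paths["blood_genotypes"])
    write_matrix(cohort.tumor_genotypes, paths["tumor_genotypes"])
    write_matrix(cohort.blood_signal, paths["blood_signal"])
    write_matrix(cohort.tumor_signal, paths["tumor_signal"])
    write_annotation(cohort.annotation, paths["annotation"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_ground_truth(cohort.truth, paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}


# ----------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    """Run configuration: input paths, stage parameters, seed, output dir."""

    outdir: str = "lohcna_out"
    seed: int = 0
    simulate: bool = True
    sim_n_samples: int = 75
    sim_scenario: str = "default"
    blood_genotypes: str | None = None
    tumor_genotypes: str | None = None
    blood_signal: str | None = None
    tumor_signal: str | None = None
    annotation: str | None = None
    clinical: str | None = None
    t_threshold: float = 4.0
    min_seg_len: int = 10
    cutoff_grid_start: float = 0.05
    cutoff_grid_stop: float = 2.0
    cutoff_grid_step: float = 0.05
    target_fdr: float = 0.10
    per_subject_cutoff: bool = False
    loh_denominator: str = "informative"
    min_loh_samples: int = 5
    cna_coding: str = "ternary"
    top_k: int = 100
    cluster_event_type: str = "loh"
    linkage_method: str = "complete"
    exclude_probes: tuple = ()

    def __post_init__(self):
        if not 0 <= self.target_fdr <= 1:
            raise ConfigError(f"target_fdr must be in [0,1]: got {self.target_fdr}")
        if self.loh_denominator not in ("informative", "all"):
            raise ConfigError(f"loh_denominator invalid: {self.loh_denominator!r}")
        if self.cna_coding not in ("ternary", "delta"):
            raise ConfigError(f"cna_coding invalid: {self.cna_coding!r}")
        if self.cluster_event_type not in ("loh", "cna"):
            raise ConfigError(f"cluster_event_type invalid: {self.cluster_event_type!r}")
        if self.min_loh_samples < 0:
            raise ConfigError(f"min_loh_samples must be >= 0: got {self.min_loh_samples}")
        if self.sim_scenario not in ("default", "interaction"):
            raise ConfigError(f"sim_scenario invalid: {self.sim_scenario!r}")

    def cutoff_grid(self) -> np.ndarray:
        return np.round(np.arange(self.cutoff_grid_start,
                                  self.cutoff_grid_stop + 1e-9,
                                  self.cutoff_grid_step), 10)


def load_config(path) -> PipelineConfig:
    """Load a YAML (or JSON) config file, rejecting unknown keys."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config must be a mapping: {path}")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "exclude_probes" in data:
        data["exclude_probes"] = tuple(data["exclude_probes"])
    return PipelineConfig(**data)
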