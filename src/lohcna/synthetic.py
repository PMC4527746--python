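"""Synthetic paired tumor/blood cohorts with known aberration ground truth.

Emulates a paired-sample SNP-array study of HPV-negative oral squamous cell
carcinoma: germline genotype calls from blood, tumor genotype calls carrying
implanted loss-of-heterozygosity (LOH) segments, real-valued copy-number (CN)
signal for both tissues, a clinical covariate table, and proportional-hazards
survival outcomes optionally tied to designated effect probes.  Every
implanted event is recorded in a :class:`GroundTruth` object so downstream
calling, landscape and screening stages can be validated against truth.

Generation starts at genotype calls and normalized CN signal; raw allele
intensities and genotype-caller behaviour are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, GenerationError

# Aberration template types and the tumor copy numbers they imply.
LOH_TYPES = frozenset({"LOH_loss", "LOH_neutral", "LOH_gain"})
CNA_TYPES = frozenset({"gain_only", "loss_only", "high_amp"})
ABERRATION_TYPES = LOH_TYPES | CNA_TYPES

GENOTYPES = ("AA", "AB", "BB", "NC")

# Independent RNG streams, all derived from the single config seed.
_STREAM_GERMLINE = 1
_STREAM_CARRIERS = 2
_STREAM_CN = 3
_STREAM_NOISE = 4
_STREAM_ERRORS = 5
_STREAM_CLINICAL = 6


@dataclass(frozen=True)
class SegmentTemplate:
    """An aberration to implant: a contiguous probe run on one chromosome.

    ``start``/``end`` are 0-based inclusive probe offsets within the
    chromosome; ``carrier_fraction`` is the fraction of samples carrying the
    event.
    """

    chrom: str
    start: int
    end: int
    kind: str
    carrier_fraction: float

    @property
    def is_loh(self) -> bool:
        return self.kind in LOH_TYPES


@dataclass(frozen=True)
class SurvivalSpec:
    """Proportional-hazards outcome model.

    Times are in months.  The linear predictor sums genomic effects at the
    designated ``effect_probes`` (ternary CNA code {-1,0,+1} from true copy
    number, binary true LOH, and their product) with sex/age/smoking effects;
    OSCC-death times are exponential with rate
    ``baseline_rate * exp(linear predictor)``.  Deaths from other causes are
    an independent exponential; administrative censoring at ``censor_time``
    (``inf`` disables it).
    """

    baseline_rate: float = 0.0023
    beta_cna: float = 0.0
    beta_loh: float = 0.0
    beta_interaction: float = 0.0
    effect_probes: tuple = ()
    beta_sex: float = 0.2
    beta_age: float = 0.02
    beta_smoking_former: float = 0.3
    beta_smoking_current: float = 0.6
    beta_cluster: float = 0.0
    censor_time: float = 120.0
    other_death_rate: float = 0.0025


#: Desk-scale default layout: 4 chromosomes with p/q arms, 5,000 probes.
DEFAULT_CHROM_LAYOUT = (
    ("chr1", "p", 700), ("chr1", "q", 800),
    ("chr2", "p", 600), ("chr2", "q", 700),
    ("chr3", "p", 550), ("chr3", "q", 650),
    ("chr4", "p", 400), ("chr4", "q", 600),
)

#: Default implanted events: every LOH class (loss/neutral/gain), plain gain
#: and loss, and one focal high-level amplification, at mixed carrier
#: fractions, including one whole-arm loss-LOH (chr4q).
DEFAULT_ABERRATIONS = (
    SegmentTemplate("chr1", 100, 349, "LOH_loss", 0.45),
    SegmentTemplate("chr1", 900, 1099, "gain_only", 0.35),
    SegmentTemplate("chr2", 150, 329, "loss_only", 0.30),
    SegmentTemplate("chr2", 800, 979, "LOH_neutral", 0.25),
    SegmentTemplate("chr3", 80, 259, "LOH_gain", 0.25),
    SegmentTemplate("chr3", 700, 759, "high_amp", 0.15),
    SegmentTemplate("chr4", 420, 899, "LOH_loss", 0.40),
)


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort; a pure function of itself
    and ``seed`` downstream."""

    n_samples: int = 75
    chrom_layout: tuple = DEFAULT_CHROM_LAYOUT
    het_rate: float = 0.3
    genotype_error_rate: float = 0.01
    cn_noise_sd: float = 0.3
    purity: float = 1.0
    aberration_spec: tuple = DEFAULT_ABERRATIONS
    survival_spec: SurvivalSpec = field(default_factory=SurvivalSpec)
    cluster_template: int | None = None
    seed: int = 0

    @property
    def n_probes(self) -> int:
        return sum(n for _, _, n in self.chrom_layout)

    def __post_init__(self):
        if self.n_samples < 1:
            raise ConfigError(f"n_samples must be >= 1: got {self.n_samples}")
        if not self.chrom_layout:
            raise ConfigError("chrom_layout must be non-empty")
        for chrom, arm, n in self.chrom_layout:
            if n < 1:
                raise ConfigError(
                    f"chrom_layout probe count must be >= 1: got {n} for {chrom}{arm}")
        if not 0.0 <= self.het_rate < 1.0:
            raise ConfigError(f"het_rate must be in [0,1): got {self.het_rate}")
        if not 0.0 <= self.genotype_error_rate < 0.2:
            raise ConfigError(
                f"genotype_error_rate must be in [0,0.2): got {self.genotype_error_rate}")
        if self.cn_noise_sd < 0:
            raise ConfigError(f"cn_noise_sd must be >= 0: got {self.cn_noise_sd}")
        if not 0.0 < self.purity <= 1.0:
            raise ConfigError(f"purity must be in (0,1]: got {self.purity}")
        sizes = {c: 0 for c, _, _ in self.chrom_layout}
        for chrom, _, n in self.chrom_layout:
            sizes[chrom] += n
        for i, tpl in enumerate(self.aberration_spec):
            if tpl.kind not in ABERRATION_TYPES:
                raise ConfigError(f"aberration_spec[{i}].kind unknown: {tpl.kind}")
            if tpl.chrom not in sizes:
                raise ConfigError(f"aberration_spec[{i}].chrom unknown: {tpl.chrom}")
            if not 0 <= tpl.start <= tpl.end < sizes[tpl.chrom]:
                raise ConfigError(
                    f"aberration_spec[{i}] segment [{tpl.start},{tpl.end}] outside "
                    f"{tpl.chrom} (length {sizes[tpl.chrom]})")
            if not 0.0 < tpl.carrier_fraction <= 1.0:
                raise ConfigError(
                    f"aberration_spec[{i}].carrier_fraction must be in (0,1]: "
                    f"got {tpl.carrier_fraction}")
        sv = self.survival_spec
        for name in ("baseline_rate", "other_death_rate"):
            if getattr(sv, name) < 0:
                raise ConfigError(f"survival_spec.{name} must be >= 0: got {getattr(sv, name)}")
        if not sv.censor_time > 0:
            raise ConfigError(f"survival_spec.censor_time must be > 0: got {sv.censor_time}")
        if self.cluster_template is not None and not (
                0 <= self.cluster_template < len(self.aberration_spec)):
            raise ConfigError(
                f"cluster_template index out of range: {self.cluster_template}")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Everything implanted, recorded for downstream validation."""

    loh: pd.DataFrame            # probes x samples, bool: true LOH
    cn_tumor: pd.DataFrame       # probes x samples, int: true tumor CN (blood is 2)
    carriers: dict               # template index -> list of sample ids
    cluster: pd.Series | None    # per sample: 1/2 label if a cluster scenario was requested
    linear_predictor: pd.Series | None = None  # filled by generate_clinical

    def cna_code(self) -> pd.DataFrame:
        """True ternary CNA code per probe/sample: sign(CN - 2) in {-1,0,+1}."""
        return pd.DataFrame(
            np.sign(self.cn_tumor.to_numpy() - 2).astype(int),
            index=self.cn_tumor.index, columns=self.cn_tumor.columns)


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([abs(int(config.seed)), stream])


def probe_ids(config: CohortConfig) -> pd.Index:
    return pd.Index([f"SNP{i:05d}" for i in range(config.n_probes)], name="probe")


def sample_ids(config: CohortConfig) -> list:
    return [f"S{i:03d}" for i in range(config.n_samples)]


def build_annotation(config: CohortConfig) -> pd.DataFrame:
    """Probe annotation: chromosome, arm, 1-based position, cytoband, gene.

    Probes are spaced 5 kb apart within each chromosome; cytobands are
    200-probe blocks within an arm; alternating 40-probe blocks carry a
    synthetic gene symbol, the rest are intergenic.
    """
    rows = []
    offset_in_chrom: dict = {}
    for chrom, arm, n in config.chrom_layout:
        start = offset_in_chrom.get(chrom, 0)
        for j in range(n):
            idx_in_chrom = start + j
            band = j // 200 + 1
            block = j // 40
            gene = f"G{chrom[3:]}{arm.upper()}{block}" if block % 2 == 0 else ""
            rows.append((chrom, arm, (idx_in_chrom + 1) * 5000,
                         f"{chrom[3:]}{arm}{band}", gene))
        offset_in_chrom[chrom] = start + n
    ann = pd.DataFrame(rows, columns=["chrom", "arm", "position", "cytoband", "gene"],
                       index=probe_ids(config))
    return ann


def _global_probe_slice(config: CohortConfig, tpl: SegmentTemplate) -> np.ndarray:
    """Global probe row indices covered by a template (chromosome-local offsets)."""
    offset = 0
    chrom_start = None
    for chrom, _, n in config.chrom_layout:
        if chrom == tpl.chrom and chrom_start is None:
            chrom_start = offset
        offset += n
    return np.arange(chrom_start + tpl.start, chrom_start + tpl.end + 1)


def generate_germline(config: CohortConfig) -> pd.DataFrame:
    """Blood genotype-call matrix (probes x samples).

    Each call is independent: AB with probability ``het_rate``, otherwise AA
    or BB equiprobably.  Deterministic given the config seed.
    """
    rng = _rng(config, _STREAM_GERMLINE)
    shape = (config.n_probes, config.n_samples)
    u = rng.random(shape)
    hom = rng.random(shape) < 0.5
    calls = np.where(u < config.het_rate, "AB", np.where(hom, "AA", "BB"))
    return pd.DataFrame(calls, index=probe_ids(config), columns=sample_ids(config))


def _assign_carriers(config: CohortConfig, rng: np.random.Generator) -> tuple[dict, np.ndarray]:
    """Pick carrier samples per template, refusing contradictory overlaps.

    Returns ``(carriers, kind_map)`` where ``kind_map`` is a probes x samples
    int matrix of template indices (-1 = unaffected).  Carriers for each
    template are drawn among samples whose overlapping probes are not already
    assigned a different aberration type; if too few samples remain eligible
    the conflict is reported.
    """
    samples = sample_ids(config)
    kind_map = np.full((config.n_probes, config.n_samples), -1, dtype=int)
    carriers: dict = {}
    for ti, tpl in enumerate(config.aberration_spec):
        rows = _global_probe_slice(config, tpl)
        n_carriers = int(round(tpl.carrier_fraction * config.n_samples))
        n_carriers = max(n_carriers, 1)
        eligible = []
        for si in range(config.n_samples):
            assigned = kind_map[rows, si]
            prior = {config.aberration_spec[k].kind for k in np.unique(assigned) if k >= 0}
            if all(k == tpl.kind for k in prior):
                eligible.append(si)
        if len(eligible) < n_carriers:
            raise GenerationError(
                f"template {ti} ({tpl.kind} {tpl.chrom}:{tpl.start}-{tpl.end}) needs "
                f"{n_carriers} carriers but only {len(eligible)} samples are free of "
                f"contradictory overlapping aberrations")
        chosen = rng.choice(np.array(eligible), size=n_carriers, replace=False)
        chosen = np.sort(chosen)
        carriers[ti] = [samples[i] for i in chosen]
        kind_map[np.ix_(rows, chosen)] = ti
    return carriers, kind_map


def implant_aberrations(
    germline: pd.DataFrame, config: CohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Implant the configured aberration segments into a germline cohort.

    Returns ``(tumor_genotypes, blood_signal, tumor_signal, ground_truth)``.
    For LOH-type segments, tumor calls at blood-heterozygous probes become
    homozygous (allele chosen at random).  True tumor copy number is 1 for
    losses, 2 for copy-neutral LOH, 3-4 for gains and 7-8 (delta >= 5) for
    high-level amplification; the observed signal adds Gaussian noise, with
    optional purity shrinkage of the tumor signal toward 2.  Genotype
    het<->hom errors are injected into the tumor calls after implantation.
    """
    if germline.shape != (config.n_probes, config.n_samples):
        raise GenerationError(
            f"germline shape {germline.shape} does not match config "
            f"({config.n_probes}, {config.n_samples})")
    rng_car = _rng(config, _STREAM_CARRIERS)
    rng_cn = _rng(config, _STREAM_CN)
    rng_noise = _rng(config, _STREAM_NOISE)
    rng_err = _rng(config, _STREAM_ERRORS)

    carriers, kind_map = _assign_carriers(config, rng_car)
    samples = sample_ids(config)
    sample_pos = {s: i for i, s in enumerate(samples)}

    geno = germline.to_numpy().copy()
    cn = np.full(geno.shape, 2, dtype=int)
    loh_true = np.zeros(geno.shape, dtype=bool)

    for ti, tpl in enumerate(config.aberration_spec):
        rows = _global_probe_slice(config, tpl)
        for s in carriers[ti]:
            si = sample_pos[s]
            if tpl.kind in ("LOH_loss", "loss_only"):
                cn[rows, si] = 1
            elif tpl.kind == "LOH_neutral":
                cn[rows, si] = 2
            elif tpl.kind in ("LOH_gain", "gain_only"):
                cn[rows, si] = rng_cn.integers(3, 5)
            elif tpl.kind == "high_amp":
                cn[rows, si] = rng_cn.integers(7, 9)
            if tpl.is_loh:
                het = geno[rows, si] == "AB"
                loh_rows = rows[het]
                loh_true[loh_rows, si] = True
                alleles = np.where(rng_cn.random(loh_rows.size) < 0.5, "AA", "BB")
                geno[loh_rows, si] = alleles

    # het<->hom flip errors, tumor calls only
    if config.genotype_error_rate > 0:
        flip = rng_err.random(geno.shape) < config.genotype_error_rate
        is_het = geno == "AB"
        to_hom = flip & is_het
        to_het = flip & ~is_het
        hom_choice = np.where(rng_err.random(geno.shape) < 0.5, "AA", "BB")
        geno = np.where(to_hom, hom_choice, geno)
        geno = np.where(to_het, "AB", geno)

    tumor_mean = 2.0 + config.purity * (cn - 2.0)
    tumor_signal = tumor_mean + rng_noise.normal(0.0, config.cn_noise_sd, geno.shape)
    blood_signal = 2.0 + rng_noise.normal(0.0, config.cn_noise_sd, geno.shape)

    idx, cols = probe_ids(config), samples
    cluster = None
    if config.cluster_template is not None:
        members = set(carriers[config.cluster_template])
        cluster = pd.Series([1 if s in members else 2 for s in cols],
                            index=pd.Index(cols, name="sample"), name="cluster")
    truth = GroundTruth(
        loh=pd.DataFrame(loh_true, index=idx, columns=cols),
        cn_tumor=pd.DataFrame(cn, index=idx, columns=cols),
        carriers=carriers,
        cluster=cluster,
    )
    return (
        pd.DataFrame(geno, index=idx, columns=cols),
        pd.DataFrame(blood_signal, index=idx, columns=cols),
        pd.DataFrame(tumor_signal, index=idx, columns=cols),
        truth,
    )


def generate_clinical(config: CohortConfig, truth: GroundTruth) -> pd.DataFrame:
    """Clinical table with covariates and cause-specific survival outcomes.

    Columns: sex (1=male), age (years), smoking (never/former/current),
    alcohol, stage (I-IV), site, nodal, time_months, event
    (OSCC_death/other_death/censored).  OSCC-death times are exponential with
    rate ``baseline_rate * exp(lp)`` where ``lp`` combines the genomic
    effects at the designated effect probes with sex/age/smoking (age
    centered at 60) and an optional planted-cluster effect; other-cause death
    and administrative censoring compete.  The realized linear predictor is
    recorded on the ground truth.
    """
    sv = config.survival_spec
    rng = _rng(config, _STREAM_CLINICAL)
    n = config.n_samples
    samples = sample_ids(config)

    sex = (rng.random(n) < 0.7).astype(int)
    age = np.clip(rng.normal(60.0, 10.0, n), 30.0, 90.0)
    smoking = rng.choice(["never", "former", "current"], size=n, p=[0.25, 0.40, 0.35])
    alcohol = np.where(rng.random(n) < 0.7, "yes", "no")
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.15, 0.20, 0.25, 0.40])
    site = rng.choice(["oral_cavity", "oropharynx"], size=n, p=[0.8, 0.2])
    nodal = (rng.random(n) < 0.55).astype(int)

    lp = (sv.beta_sex * sex
          + sv.beta_age * (age - 60.0)
          + sv.beta_smoking_former * (smoking == "former")
          + sv.beta_smoking_current * (smoking == "current")).astype(float)
    if sv.effect_probes:
        cna_code = truth.cna_code()
        for p in sv.effect_probes:
            if p not in truth.loh.index:
                raise ConfigError(f"survival_spec.effect_probes: unknown probe {p}")
            c = cna_code.loc[p].to_numpy(dtype=float)
            l = truth.loh.loc[p].to_numpy(dtype=float)
            lp += sv.beta_cna * c + sv.beta_loh * l + sv.beta_interaction * c * l
    if sv.beta_cluster != 0.0:
        if truth.cluster is None:
            raise ConfigError(
                "survival_spec.beta_cluster set but cluster_template is None")
        lp += sv.beta_cluster * (truth.cluster.to_numpy() == 1)

    if sv.baseline_rate > 0:
        t_oscc = rng.exponential(1.0, n) / (sv.baseline_rate * np.exp(lp))
    else:
        t_oscc = np.full(n, np.inf)
    if sv.other_death_rate > 0:
        t_other = rng.exponential(1.0 / sv.other_death_rate, n)
    else:
        t_other = np.full(n, np.inf)
    t_cens = sv.censor_time

    time = np.minimum(np.minimum(t_oscc, t_other), t_cens)
    event = np.where(t_oscc <= time, "OSCC_death",
                     np.where(t_other <= time, "other_death", "censored"))
    time = np.maximum(time, 1e-6)  # follow-up time must be > 0

    truth.linear_predictor = pd.Series(lp, index=pd.Index(samples, name="sample"),
                                       name="linear_predictor")
    return pd.DataFrame(
        {
            "sex": sex, "age": np.round(age, 1), "smoking": smoking,
            "alcohol": alcohol, "stage": stage, "site": site, "nodal": nodal,
            "time_months": np.round(time, 4), "event": event,
        },
        index=pd.Index(samples, name="sample"),
    )


@dataclass
class Cohort:
    """A fully generated cohort with its ground truth."""

    config: CohortConfig
    annotation: pd.DataFrame
    blood_genotypes: pd.DataFrame
    tumor_genotypes: pd.DataFrame
    blood_signal: pd.DataFrame
    tumor_signal: pd.DataFrame
    clinical: pd.DataFrame
    truth: GroundTruth


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a complete cohort: germline, implanted tumor, clinical table."""
    germline = generate_germline(config)
    tumor_geno, blood_sig, tumor_sig, truth = implant_aberrations(germline, config)
    clinical = generate_clinical(config, truth)
    return Cohort(config, build_annotation(config), germline, tumor_geno,
                  blood_sig, tumor_sig, clinical, truth)
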