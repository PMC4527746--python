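"""Copy-number segmentation, blood-null empirical FDR cutoff, and CNA calls.

The paired copy-number analysis works on difference series: tumor minus
blood for the tumor tissue, blood minus the diploid reference (2) for the
blood tissue.  Each series is segmented per chromosome per sample by
recursive binary segmentation: the candidate split maximizing the pooled
two-sample t-statistic between the flanks is accepted when |t| exceeds a
threshold and both children meet the minimum segment length.

The gain/loss magnitude cutoff is then chosen empirically: blood is assumed
to carry no true somatic copy-number change, so for a cutoff ``c`` the
per-subject false discovery rate is estimated as the number of blood probes
with |segmented value| >= c divided by the number of tumor probes exceeding
the same cutoff.  The smallest cutoff whose cross-subject mean estimated FDR
meets the target (10% by default) produces the final calls.  A probe whose
segmented tumor-blood difference is >= 5 is flagged as high-level
amplification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, CutoffError
from .loh import LOH, NON_INFORMATIVE

logger = logging.getLogger(__name__)

GAIN, LOSS, NEUTRAL = "GAIN", "LOSS", "NEUTRAL"
HIGH_AMP_DELTA = 5.0

#: Default cutoff grid on the CN scale: 0.05 to 2.0 in steps of 0.05.
DEFAULT_CUTOFF_GRID = np.round(np.arange(0.05, 2.0 + 1e-9, 0.05), 10)
DEFAULT_TARGET_FDR = 0.10

JOINT_CLASSES = (
    "CN_GAIN_LOH", "CN_LOSS_LOH", "CN_NEUTRAL_LOH",
    "GAIN_NO_LOH", "LOSS_NO_LOH", "NEUTRAL_NO_LOH", "UNINFORMATIVE",
)


@dataclass(frozen=True)
class SegmentationParams:
    t_threshold: float = 4.0
    min_seg_len: int = 10

    def __post_init__(self):
        if self.t_threshold <= 0:
            raise ConfigError(f"t_threshold must be > 0: got {self.t_threshold}")
        if self.min_seg_len < 1:
            raise ConfigError(f"min_seg_len must be >= 1: got {self.min_seg_len}")


@dataclass(frozen=True)
class Segment:
    """One constant-level run of probes (0-based inclusive local indices)."""

    chrom: str
    start: int
    end: int
    mean: float

    @property
    def n_probes(self) -> int:
        return self.end - self.start + 1


def best_split(x: np.ndarray, min_seg_len: int) -> tuple[int, float]:
    """Best single change-point of a series by the pooled two-sample t-statistic.

    Returns ``(k, t)`` where the split puts ``x[:k]`` against ``x[k:]`` and
    ``t`` is the largest |t| over admissible splits (both sides of length >=
    ``min_seg_len``); ``(-1, 0.0)`` when no split is admissible.  A split of
    zero pooled variance but unequal means scores infinite.
    """
    n = x.size
    if n < 2 * min_seg_len:
        return -1, 0.0
    ks = np.arange(min_seg_len, n - min_seg_len + 1)
    cs = np.cumsum(x)
    css = np.cumsum(x * x)
    n1 = ks.astype(float)
    n2 = n - n1
    s1 = cs[ks - 1]
    s2 = cs[-1] - s1
    ss1 = css[ks - 1]
    ss2 = css[-1] - ss1
    m1 = s1 / n1
    m2 = s2 / n2
    rss = (ss1 - n1 * m1 * m1) + (ss2 - n2 * m2 * m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = np.maximum(rss, 0.0) / (n - 2)
        diff = np.abs(m1 - m2)
        t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t[np.isnan(t)] = 0.0
    # zero-variance flanks (noise-free steps): infinite t iff the means
    # genuinely differ; tolerances relative to the series scale absorb
    # cumulative-sum rounding on constant series
    scale = max(float(np.abs(x).max()), 1e-300)
    degenerate = sp2 <= (1e-9 * scale) ** 2
    t[degenerate & (diff <= 1e-7 * scale)] = 0.0
    t[degenerate & (diff > 1e-7 * scale)] = np.inf
    i = int(np.argmax(t))
    return int(ks[i]), float(t[i])


def segment_series(x: np.ndarray, params: SegmentationParams = SegmentationParams(),
                   chrom: str = "") -> list[Segment]:
    """Recursive binary segmentation of one difference series.

    Splits are accepted while |t| > ``t_threshold`` and both children have at
    least ``min_seg_len`` probes; segments are contiguous, non-overlapping
    and cover every probe.  Series shorter than ``min_seg_len`` yield a
    single segment with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size < params.min_seg_len:
        logger.warning("series of %d probes is shorter than min_seg_len=%d; "
                       "returning a single segment", x.size, params.min_seg_len)
        return [Segment(chrom, 0, x.size - 1, float(x.mean()))]
    out: list[Segment] = []
    stack = [(0, x.size)]  # half-open [lo, hi)
    while stack:
        lo, hi = stack.pop()
        k, t = best_split(x[lo:hi], params.min_seg_len)
        if k > 0 and t > params.t_threshold:
            stack.append((lo + k, hi))
            stack.append((lo, lo + k))
        else:
            out.append(Segment(chrom, lo, hi - 1, float(x[lo:hi].mean())))
    out.sort(key=lambda s: s.start)
    return out


def segments_to_values(segments: list[Segment], n: int) -> np.ndarray:
    """Per-probe fitted values: each probe gets its segment mean."""
    v = np.empty(n, dtype=float)
    for s in segments:
        v[s.start:s.end + 1] = s.mean
    return v


def segment_paired(tumor: np.ndarray, blood: np.ndarray,
                   params: SegmentationParams = SegmentationParams(),
                   chrom: str = "") -> list[Segment]:
    """Segment the tumor-minus-blood difference series of one chromosome."""
    return segment_series(np.asarray(tumor, float) - np.asarray(blood, float),
                          params, chrom)


@dataclass
class SegmentedCohort:
    """Per-probe segmented difference values for both tissues.

    ``tumor_delta`` holds the segmented tumor-blood difference, ``blood_delta``
    the segmented blood-2 difference (probes x samples).  ``segments`` is a
    long table (sample, chrom, start/end position, n probes, segment mean on
    the CN scale) suitable for SEG export.
    """

    tumor_delta: pd.DataFrame
    blood_delta: pd.DataFrame
    segments: pd.DataFrame
    params: SegmentationParams = field(default_factory=SegmentationParams)


def segment_cohort(tumor_signal: pd.DataFrame, blood_signal: pd.DataFrame,
                   annotation: pd.DataFrame,
                   params: SegmentationParams = SegmentationParams()) -> SegmentedCohort:
    """Segment every sample's tumor and blood signal chromosome by chromosome."""
    probes = tumor_signal.index
    tumor_delta = np.empty(tumor_signal.shape)
    blood_delta = np.empty(tumor_signal.shape)
    seg_rows = []
    chrom_groups = [(c, np.flatnonzero((annotation["chrom"] == c).to_numpy()))
                    for c in annotation["chrom"].unique()]
    pos = annotation["position"].to_numpy()
    t_all = tumor_signal.to_numpy()
    b_all = blood_signal.to_numpy()
    for si, sample in enumerate(tumor_signal.columns):
        for chrom, rows in chrom_groups:
            d_t = t_all[rows, si] - b_all[rows, si]
            d_b = b_all[rows, si] - 2.0
            segs_t = segment_series(d_t, params, chrom)
            segs_b = segment_series(d_b, params, chrom)
            tumor_delta[rows, si] = segments_to_values(segs_t, rows.size)
            blood_delta[rows, si] = segments_to_values(segs_b, rows.size)
            for s in segs_t:
                seg_rows.append((sample, chrom, int(pos[rows[s.start]]),
                                 int(pos[rows[s.end]]), s.n_probes,
                                 round(2.0 + s.mean, 6)))
    segments = pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "start", "end", "num_probes", "seg_mean"])
    return SegmentedCohort(
        tumor_delta=pd.DataFrame(tumor_delta, index=probes, columns=tumor_signal.columns),
        blood_delta=pd.DataFrame(blood_delta, index=probes, columns=tumor_signal.columns),
        segments=segments, params=params)


@dataclass
class FDRCurve:
    """Blood-null empirical FDR as a function of the magnitude cutoff."""

    grid: np.ndarray                 # strictly increasing cutoffs
    blood_counts: pd.DataFrame       # cutoffs x samples: probes surviving in blood
    tumor_counts: pd.DataFrame       # cutoffs x samples: probes surviving in tumor
    subject_fdr: pd.DataFrame        # cutoffs x samples: blood/tumor ratio (raw, 0 if tumor=0)
    mean_fdr: pd.Series              # per cutoff: mean over subjects of min(fdr, 1)


def estimate_fdr_curve(segmented: SegmentedCohort,
                       grid: np.ndarray = DEFAULT_CUTOFF_GRID) -> FDRCurve:
    """Estimate the per-subject and mean FDR at each cutoff on the grid.

    Blood is assumed free of true somatic copy-number change, so for subject
    ``s`` and cutoff ``c`` the FDR estimate is ``#{|blood_delta| >= c} /
    #{|tumor_delta| >= c}``, defined as 0 when the tumor count is 0 (no
    calls, nothing false).  The mean curve caps subject ratios at 1.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ConfigError("cutoff grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ConfigError("cutoff grid must be strictly increasing")
    t_abs = np.abs(segmented.tumor_delta.to_numpy())
    b_abs = np.abs(segmented.blood_delta.to_numpy())
    samples = segmented.tumor_delta.columns
    bc = (b_abs[None, :, :] >= grid[:, None, None]).sum(axis=1)
    tc = (t_abs[None, :, :] >= grid[:, None, None]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(tc > 0, bc / np.where(tc > 0, tc, 1), 0.0)
    mean = np.minimum(fdr, 1.0).mean(axis=1)
    idx = pd.Index(grid, name="cutoff")
    return FDRCurve(
        grid=grid,
        blood_counts=pd.DataFrame(bc, index=idx, columns=samples),
        tumor_counts=pd.DataFrame(tc, index=idx, columns=samples),
        subject_fdr=pd.DataFrame(fdr, index=idx, columns=samples),
        mean_fdr=pd.Series(mean, index=idx, name="mean_fdr"),
    )


@dataclass
class CutoffSelection:
    cutoff: float
    mean_fdr: float
    subject_fdr: pd.Series   # per subject at the chosen cutoff


def select_cutoff(curve: FDRCurve, target: float = DEFAULT_TARGET_FDR) -> CutoffSelection:
    """Smallest grid cutoff whose cross-subject mean FDR meets the target."""
    ok = np.flatnonzero(curve.mean_fdr.to_numpy() <= target)
    if ok.size == 0:
        raise CutoffError(
            f"no cutoff on the grid attains mean FDR <= {target}; "
            "extend the grid upward or raise the target")
    i = int(ok[0])
    return CutoffSelection(
        cutoff=float(curve.grid[i]),
        mean_fdr=float(curve.mean_fdr.iloc[i]),
        subject_fdr=curve.subject_fdr.iloc[i].rename("subject_fdr"),
    )


def select_cutoff_per_subject(curve: FDRCurve,
                              target: float = DEFAULT_TARGET_FDR) -> pd.Series:
    """Non-default mode: per-subject smallest cutoff with subject FDR <= target."""
    fdr = np.minimum(curve.subject_fdr.to_numpy(), 1.0)
    out = {}
    for j, s in enumerate(curve.subject_fdr.columns):
        ok = np.flatnonzero(fdr[:, j] <= target)
        if ok.size == 0:
            raise CutoffError(f"no cutoff attains FDR <= {target} for subject {s}")
        out[s] = float(curve.grid[int(ok[0])])
    return pd.Series(out, name="cutoff")


@dataclass
class CNACalls:
    """Final per-probe, per-sample CNA calls."""

    classes: pd.DataFrame    # GAIN / LOSS / NEUTRAL
    delta: pd.DataFrame      # segmented tumor - blood difference
    high_amp: pd.DataFrame   # bool: delta >= 5
    cutoff: float


def call_cna(segmented: SegmentedCohort, cutoff) -> CNACalls:
    """Threshold the segmented tumor-blood difference into gain/loss calls.

    ``cutoff`` may be a scalar (global mode, default) or a per-sample Series
    (per-subject mode).  ``delta >= 5`` flags high-level amplification.
    """
    delta = segmented.tumor_delta
    if isinstance(cutoff, pd.Series):
        cut = cutoff.reindex(delta.columns).to_numpy()[None, :]
        scalar_cut = float("nan")
    else:
        cut = float(cutoff)
        scalar_cut = float(cutoff)
    d = delta.to_numpy()
    cls = np.where(d >= cut, GAIN, np.where(d <= -cut, LOSS, NEUTRAL))
    return CNACalls(
        classes=pd.DataFrame(cls, index=delta.index, columns=delta.columns),
        delta=delta.copy(),
        high_amp=pd.DataFrame(d >= HIGH_AMP_DELTA, index=delta.index,
                              columns=delta.columns),
        cutoff=scalar_cut,
    )


_JOINT_MAP = {
    (LOH, GAIN): "CN_GAIN_LOH",
    (LOH, LOSS): "CN_LOSS_LOH",
    (LOH, NEUTRAL): "CN_NEUTRAL_LOH",
    ("R", GAIN): "GAIN_NO_LOH",
    ("R", LOSS): "LOSS_NO_LOH",
    ("R", NEUTRAL): "NEUTRAL_NO_LOH",
    (NON_INFORMATIVE, GAIN): "UNINFORMATIVE",
    (NON_INFORMATIVE, LOSS): "UNINFORMATIVE",
    (NON_INFORMATIVE, NEUTRAL): "UNINFORMATIVE",
}


def classify_joint(loh: pd.DataFrame, cna_classes: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate LOH status with the CNA class at every probe/sample.

    LOH-positive loci split into copy-loss, copy-neutral and copy-gain LOH;
    retained loci into the corresponding no-LOH classes; non-informative LOH
    maps to UNINFORMATIVE regardless of copy number.  Total on all
    (status, class) pairs.
    """
    if not loh.index.equals(cna_classes.index) or list(loh.columns) != list(cna_classes.columns):
        raise ConfigError("LOH and CNA matrices are not aligned")
    l = loh.to_numpy()
    c = cna_classes.to_numpy()
    out = np.empty(l.shape, dtype=object)
    for (ls, cs), name in _JOINT_MAP.items():
        out[(l == ls) & (c == cs)] = name
    return pd.DataFrame(out, index=loh.index, columns=loh.columns)


@dataclass
class CallSet:
    """Aligned per-probe x per-sample call matrices for one cohort."""

    loh: pd.DataFrame          # L / R / N
    cna: CNACalls
    joint: pd.DataFrame        # JointClass labels
    annotation: pd.DataFrame   # probe -> chrom, arm, position, cytoband, gene

    @property
    def samples(self) -> list:
        return list(self.loh.columns)

    @property
    def probes(self) -> pd.Index:
        return self.loh.index
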