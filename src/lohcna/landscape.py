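"""Genomic landscape summaries of a cohort's LOH/CNA call set.

Consensus (cross-sample) event frequencies with the frequent (>20%) and
extremely frequent (>80%) tiers, per-sample aberration burden, large-region
chromosome-arm events (>50% of an arm's probes aberrant in one sample), and
annotated top-k event tables.  All tier thresholds are strict inequalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cna import GAIN, LOSS, CallSet
from .errors import AnnotationError
from .loh import LOH, NON_INFORMATIVE, loh_frequency

logger = logging.getLogger(__name__)

FREQUENT_THRESHOLD = 0.20
EXTREME_THRESHOLD = 0.80
LARGE_REGION_THRESHOLD = 0.50

EVENT_TYPES = ("loh", "gain", "loss")


def consensus_frequencies(callset: CallSet,
                          denominator: str = "informative") -> pd.DataFrame:
    """Per-probe event fractions with frequency tiers.

    LOH fractions use the informative-sample denominator by default (a
    germline-homozygous patient cannot evidence LOH); gain/loss fractions
    divide by all samples.  ``*_frequent`` is strict >20%, ``*_extreme``
    strict >80% (extreme implies frequent).
    """
    n = len(callset.samples)
    cls = callset.cna.classes.to_numpy()
    out = pd.DataFrame(index=callset.probes)
    out["loh_fraction"] = loh_frequency(callset.loh, denominator)
    out["gain_fraction"] = (cls == GAIN).sum(axis=1) / n
    out["loss_fraction"] = (cls == LOSS).sum(axis=1) / n
    for ev in EVENT_TYPES:
        f = out[f"{ev}_fraction"]
        out[f"{ev}_frequent"] = f > FREQUENT_THRESHOLD
        out[f"{ev}_extreme"] = f > EXTREME_THRESHOLD
    return out


@dataclass
class ArmEventProfile:
    """Per-sample, per-arm aberrant-probe fractions and large-region flags."""

    fractions: dict          # event type -> DataFrame (arms x samples)
    large_region: dict       # event type -> bool DataFrame (arms x samples)
    arm_percentages: pd.DataFrame  # arms x event types: % samples flagged


def arm_events(callset: CallSet, annotation: pd.DataFrame | None = None) -> ArmEventProfile:
    """Arm-level event fractions and large-region (>50% of arm probes) flags.

    Also reports, per arm and event type, the percentage of samples carrying
    a large-region event (the cross-sample summary).  LOH fractions here use
    all probes of the arm as denominator (the event either covers the arm or
    it does not).
    """
    ann = callset.annotation if annotation is None else annotation
    missing = callset.probes.difference(ann.index)
    if len(missing):
        raise AnnotationError(f"probes missing from annotation: {list(missing[:10])}")
    ann = ann.loc[callset.probes]
    if ann["arm"].isna().any():
        bad = ann.index[ann["arm"].isna()]
        raise AnnotationError(f"probes with missing arm label: {list(bad[:10])}")
    arm_key = ann["chrom"].astype(str) + ann["arm"].astype(str)

    indicators = {
        "loh": (callset.loh.to_numpy() == LOH),
        "gain": (callset.cna.classes.to_numpy() == GAIN),
        "loss": (callset.cna.classes.to_numpy() == LOSS),
    }
    arms = pd.Index(arm_key.unique(), name="arm")
    fractions, large, pct_rows = {}, {}, {}
    for ev, ind in indicators.items():
        df = pd.DataFrame(ind, index=callset.probes, columns=callset.samples)
        frac = df.groupby(arm_key.to_numpy()).mean().reindex(arms)
        flag = frac > LARGE_REGION_THRESHOLD
        fractions[ev] = frac
        large[ev] = flag
        pct_rows[ev] = flag.mean(axis=1) * 100.0
    return ArmEventProfile(
        fractions=fractions, large_region=large,
        arm_percentages=pd.DataFrame(pct_rows).reindex(arms))


def burden(callset: CallSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample aberration burden as percentages of all probes.

    Returns ``(per_sample, summary)``: per sample the % of probes with LOH,
    with any CNA, with gain, with loss (so %CNA = %gain + %loss), and the
    cross-sample mean/sd of each.
    """
    n_probes = len(callset.probes)
    cls = callset.cna.classes.to_numpy()
    per = pd.DataFrame(index=pd.Index(callset.samples, name="sample"))
    per["pct_loh"] = 100.0 * (callset.loh.to_numpy() == LOH).sum(axis=0) / n_probes
    per["pct_gain"] = 100.0 * (cls == GAIN).sum(axis=0) / n_probes
    per["pct_loss"] = 100.0 * (cls == LOSS).sum(axis=0) / n_probes
    per["pct_cna"] = per["pct_gain"] + per["pct_loss"]
    summary = per.agg(["mean", "std"]).T
    return per, summary


def top_k_tables(consensus: pd.DataFrame, annotation: pd.DataFrame,
                 k: int = 100) -> dict:
    """Top-k probes by event frequency, annotated, one table per event type.

    Ties are broken by genomic order (annotation row order: chromosome then
    position).  If ``k`` exceeds the probe count the full sorted table is
    returned with a warning.
    """
    if k > len(consensus):
        logger.warning("top_k_tables: k=%d exceeds probe count %d; returning all",
                       k, len(consensus))
        k = len(consensus)
    ann = annotation.loc[consensus.index]
    genome_order = pd.Series(np.arange(len(ann)), index=ann.index)
    out = {}
    for ev in EVENT_TYPES:
        df = pd.DataFrame({
            "fraction": consensus[f"{ev}_fraction"],
            "_order": genome_order,
        }).sort_values(["fraction", "_order"], ascending=[False, True]).head(k)
        tbl = ann.loc[df.index, ["chrom", "arm", "position", "cytoband", "gene"]].copy()
        tbl.insert(0, "rank", np.arange(1, len(df) + 1))
        tbl["fraction"] = df["fraction"]
        out[ev] = tbl
    return out
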