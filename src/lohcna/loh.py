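"""Per-probe LOH calling from paired blood/tumor genotype calls.

A locus is informative for LOH only when the blood (germline) call is
heterozygous and both calls are present: a germline-homozygous patient
cannot lose heterozygosity at that probe.  Status codes in the LOH matrix
are ``L`` (LOH), ``R`` (retained heterozygosity) and ``N`` (non-informative).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError

logger = logging.getLogger(__name__)

LOH, RETAINED, NON_INFORMATIVE = "L", "R", "N"


def _check_aligned(blood: pd.DataFrame, tumor: pd.DataFrame) -> None:
    if not blood.index.equals(tumor.index):
        diff = blood.index.symmetric_difference(tumor.index)
        raise AlignmentError(f"probe indices differ between tissues: {list(diff[:10])}")
    if list(blood.columns) != list(tumor.columns):
        diff = set(blood.columns) ^ set(tumor.columns)
        raise AlignmentError(f"sample columns differ between tissues: {sorted(diff)[:10]}")


def call_loh(blood: pd.DataFrame, tumor: pd.DataFrame) -> pd.DataFrame:
    """Call LOH status per probe and sample from paired genotype matrices.

    blood AB & tumor homozygous -> ``L``; blood AB & tumor AB -> ``R``;
    blood homozygous, or a no-call (NC) in either tissue -> ``N``.
    """
    _check_aligned(blood, tumor)
    b = blood.to_numpy()
    t = tumor.to_numpy()
    out = np.full(b.shape, NON_INFORMATIVE, dtype="<U1")
    informative = (b == "AB") & (t != "NC")
    out[informative & ((t == "AA") | (t == "BB"))] = LOH
    out[informative & (t == "AB")] = RETAINED
    return pd.DataFrame(out, index=blood.index, columns=blood.columns)


def filter_uninformative_snps(loh: pd.DataFrame) -> tuple[pd.Index, pd.DataFrame]:
    """Drop probes that are non-informative in every sample.

    Returns ``(retained_probes, exclusion_log)``; the log has one row per
    excluded probe with the reason.  Idempotent: re-filtering the retained
    set excludes nothing.
    """
    if loh.empty:
        logger.warning("filter_uninformative_snps: empty LOH matrix")
        return loh.index, pd.DataFrame(columns=["probe", "reason"])
    all_n = (loh.to_numpy() == NON_INFORMATIVE).all(axis=1)
    excluded = loh.index[all_n]
    log = pd.DataFrame({"probe": excluded,
                        "reason": "non-informative in all samples"})
    return loh.index[~all_n], log


def loh_frequency(loh: pd.DataFrame, denominator: str = "informative") -> pd.Series:
    """Per-probe LOH fraction.

    ``denominator='informative'`` divides by the number of samples with an
    informative call at the probe (the default: only germline-heterozygous
    patients can show LOH); ``'all'`` divides by the total sample count.
    Probes with a zero denominator are reported as NaN, not zero.
    """
    m = loh.to_numpy()
    n_loh = (m == LOH).sum(axis=1).astype(float)
    if denominator == "informative":
        denom = (m != NON_INFORMATIVE).sum(axis=1).astype(float)
    elif denominator == "all":
        denom = float(loh.shape[1]) * np.ones(loh.shape[0])
    else:
        raise ConfigError(f"denominator must be 'informative' or 'all': got {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, n_loh / denom, np.nan)
    return pd.Series(frac, index=loh.index, name="loh_fraction")
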