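"""Ground-truth comparison utilities for synthetic cohorts.

Used to validate the calling pipeline against the recorded truth of a
synthetic cohort: realized false-discovery proportions of CNA calls, LOH
recovery, and planted-partition agreement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cna import CNACalls, GAIN, LOSS
from .loh import LOH
from .synthetic import GroundTruth


def realized_cna_fdp(calls: CNACalls, truth: GroundTruth) -> pd.Series:
    """Per-subject realized false-discovery proportion of gain/loss calls.

    A call is false when the probe's true tumor copy number is exactly 2
    (no implanted aberration).  Subjects with no calls score 0.
    """
    called = np.isin(calls.classes.to_numpy(), (GAIN, LOSS))
    false = called & (truth.cn_tumor.to_numpy() == 2)
    n_called = called.sum(axis=0)
    n_false = false.sum(axis=0)
    fdp = np.where(n_called > 0, n_false / np.maximum(n_called, 1), 0.0)
    return pd.Series(fdp, index=calls.classes.columns, name="realized_fdp")


def loh_call_agreement(loh_calls: pd.DataFrame, truth: GroundTruth) -> float:
    """Fraction of informative probe/sample cells whose LOH call matches truth."""
    informative = loh_calls.to_numpy() != "N"
    called = loh_calls.to_numpy() == LOH
    return float((called == truth.loh.to_numpy())[informative].mean())


def mean_realized_fdp_study(base_seed: int = 0, n_cohorts: int = 20,
                            n_samples: int = 75) -> dict:
    """Replicated FDR-control study on the study-scale synthetic design.

    Generates ``n_cohorts`` cohorts (75 samples, 5,000 probes by default;
    cohort seeds ``base_seed + 1 .. base_seed + n_cohorts``), runs paired
    segmentation and blood-null cutoff selection at the default 10% target,
    and measures each cohort's cross-subject mean realized false-discovery
    proportion against ground truth.  Returns the overall mean (as a
    fraction), its Monte-Carlo standard error over cohorts, and the
    per-cohort means.
    """
    from .pipeline import call_cohort
    from .synthetic import CohortConfig, generate_cohort

    per_cohort = []
    for i in range(1, n_cohorts + 1):
        cohort = generate_cohort(CohortConfig(n_samples=n_samples,
                                              seed=base_seed + i))
        callset, _ = call_cohort(cohort)
        per_cohort.append(float(realized_cna_fdp(callset.cna, cohort.truth).mean()))
    per_cohort = np.asarray(per_cohort)
    se = per_cohort.std(ddof=1) / np.sqrt(n_cohorts) if n_cohorts > 1 else 0.0
    return {"mean_fdp": float(per_cohort.mean()), "mc_se": float(se),
            "per_cohort": per_cohort}


def interaction_type1_study(base_seed: int = 0, n_cohorts: int = 20,
                            probes_per_cohort: int = 150) -> dict:
    """Null calibration of the interaction LRT over replicated cohorts.

    Generates global-null cohorts with identifiable CNA x LOH designs,
    screens the overlap probes, and pools the interaction p-values of the
    regular (converged) fits; monotone-likelihood fits are flagged by the
    screen and excluded, since their likelihood-ratio statistic has no
    chi-square reference.  Returns the pooled rejection rate at 0.05 and
    the number of tests.
    """
    from .pipeline import call_cohort
    from .scenarios import interaction_null_config
    from .survival import screen
    from .synthetic import generate_cohort

    overlap = [f"SNP{i:05d}" for i in
               list(range(100, 250)) + list(range(400, 550))]
    ps = []
    for i in range(1, n_cohorts + 1):
        cohort = generate_cohort(interaction_null_config(base_seed + i))
        callset, _ = call_cohort(cohort)
        res = screen(callset, cohort.clinical,
                     probes=overlap[:probes_per_cohort])
        ps.extend(res.loc[res["converged"], "p_interaction"].tolist())
    ps = np.asarray(ps)
    return {"rejection_rate": float((ps < 0.05).mean()), "n_tests": int(ps.size)}


def sign_recovery_study(base_seed: int = 0, n_replicates: int = 50,
                        n_samples: int = 300) -> dict:
    """Opposite-sign interaction recovery rate across replicates.

    Each replicate plants a copy-number effect that raises the hazard in
    LOH carriers and lowers it otherwise at one probe; success means the
    screen reports stratum signs (+ with LOH, - without) at that probe.
    """
    from .pipeline import call_cohort
    from .scenarios import EFFECT_PROBE, opposite_sign_interaction_config
    from .survival import screen
    from .synthetic import generate_cohort

    hits = 0
    for i in range(1, n_replicates + 1):
        cohort = generate_cohort(
            opposite_sign_interaction_config(base_seed + i, n_samples=n_samples))
        callset, _ = call_cohort(cohort)
        res = screen(callset, cohort.clinical, probes=[EFFECT_PROBE])
        if (not res.empty
                and res.iloc[0]["sign_no_loh"] == "-"
                and res.iloc[0]["sign_loh"] == "+"):
            hits += 1
    return {"recovery_rate": hits / n_replicates, "n_replicates": n_replicates}


def partition_agreement(labels: pd.Series, truth_labels: pd.Series) -> float:
    """Fraction of samples on which two 2-cluster labelings agree (up to swap)."""
    a = labels.loc[truth_labels.index].to_numpy()
    b = truth_labels.to_numpy()
    direct = (a == b).mean()
    swapped = (a == (3 - b)).mean()
    return float(max(direct, swapped))
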