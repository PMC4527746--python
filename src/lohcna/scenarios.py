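"""Predefined synthetic study designs for validation experiments.

The default cohort (:data:`lohcna.synthetic.DEFAULT_ABERRATIONS`) implants
each aberration type in its own region, which makes the CNA and LOH
covariates at a probe nearly collinear (every LOH carrier at a loss-LOH
probe also has the loss).  The designs here overlay gain-LOH, gain-only and
copy-neutral-LOH templates on the same probe run with disjoint carrier
sets, so that at each probe in the overlap all four (CNA, LOH) cells are
populated and the CNA x LOH interaction in a Cox model is identifiable.
Used for null-calibration and effect-recovery studies of the survival
screen.
"""

from __future__ import annotations

from lohcna.synthetic import CohortConfig, SegmentTemplate, SurvivalSpec

#: 600 probes over 2 chromosomes with p/q arms; small enough for replicated runs.
SMALL_LAYOUT = (
    ("chr1", "p", 150), ("chr1", "q", 150),
    ("chr2", "p", 150), ("chr2", "q", 150),
)

#: Overlapping templates (disjoint carriers) covering chr1:100-249 and
#: chr2:100-249: gain with LOH, gain without LOH, LOH without copy change.
_OVERLAY = tuple(
    SegmentTemplate(chrom, 100, 249, kind, frac)
    for chrom in ("chr1", "chr2")
    for kind, frac in (("LOH_gain", 0.30), ("gain_only", 0.30),
                       ("LOH_neutral", 0.20))
)

#: A probe in the middle of the chr1 overlap (chr1 spans global probes 0-299).
EFFECT_PROBE = "SNP00175"


def interaction_null_config(seed: int, n_samples: int = 150) -> CohortConfig:
    """Global-null cohort: identifiable interactions, all survival betas 0."""
    return CohortConfig(
        n_samples=n_samples, chrom_layout=SMALL_LAYOUT,
        aberration_spec=_OVERLAY,
        survival_spec=SurvivalSpec(beta_sex=0.0, beta_age=0.0,
                                   beta_smoking_former=0.0,
                                   beta_smoking_current=0.0),
        seed=seed)


def opposite_sign_interaction_config(seed: int, n_samples: int = 300,
                                     beta_cna: float = -1.0,
                                     beta_loh: float = 0.3,
                                     beta_interaction: float = 2.0) -> CohortConfig:
    """Cohort with a planted opposite-sign CNA x LOH effect at one probe.

    With the defaults the copy-number effect on the hazard is negative
    without LOH (``beta_cna``) and positive with LOH
    (``beta_cna + beta_interaction``) at :data:`EFFECT_PROBE`.
    """
    return CohortConfig(
        n_samples=n_samples, chrom_layout=SMALL_LAYOUT,
        aberration_spec=_OVERLAY,
        survival_spec=SurvivalSpec(
            beta_cna=beta_cna, beta_loh=beta_loh,
            beta_interaction=beta_interaction,
            effect_probes=(EFFECT_PROBE,)),
        seed=seed)


def planted_cluster_config(seed: int, n_samples: int = 75,
                           carrier_fraction: float = 23 / 75,
                           cn_noise_sd: float = 0.3,
                           beta_cluster: float = 0.0) -> CohortConfig:
    """Two-block cohort: one shared amplified region in a carrier subgroup.

    With the defaults 23 of 75 samples carry a high-level amplification of
    chr1:100-249; clustering the copy-number matrix separates carriers from
    non-carriers.  ``beta_cluster`` optionally links the hazard to carrier
    status.
    """
    return CohortConfig(
        n_samples=n_samples, chrom_layout=SMALL_LAYOUT,
        cn_noise_sd=cn_noise_sd,
        aberration_spec=(SegmentTemplate("chr1", 100, 249, "high_amp",
                                         carrier_fraction),),
        cluster_template=0,
        survival_spec=SurvivalSpec(beta_cluster=beta_cluster),
        seed=seed)
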