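"""Genome-wide Cox proportional-hazards screen for OSCC-specific mortality.

For every probe retained after the minimum-LOH-sample filter, nested Cox
models adjusted for sex, age and smoking history are compared by
log-likelihood-ratio tests:

* covariates only;
* covariates + CNA + LOH;
* the full model: covariates + CNA + LOH + CNA*LOH.

``p_all`` tests the three genomic terms jointly (3 df, full vs covariates
only); ``p_interaction`` tests the multiplicative interaction (1 df, full vs
CNA+LOH).  CNA enters as a ternary code (-1 loss, 0 neutral, +1 gain; a
continuous segmented-delta coding is available), LOH as a binary indicator
with non-informative probes coded 0.  The CNA effect is reported separately
in the two LOH strata: ``beta_cna`` without LOH and ``beta_cna +
beta_interaction`` with LOH, each as a sign (+/-/undetermined, the latter
for non-converged or monotone-likelihood fits).  Multiplicity is controlled
both by Bonferroni at family-wise 0.05 over the tested probes and by Storey
q-values, computed separately for the two p-value families.

Deaths from causes other than OSCC are censored at the death time
(cause-specific hazard analysis).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cna import GAIN, LOSS, CallSet
from .errors import ConfigError, DegenerateDesignError, UsageError
from .loh import LOH

logger = logging.getLogger(__name__)

COVARIATES = ("sex", "age", "smoking_former", "smoking_current")
DEFAULT_MIN_LOH_SAMPLES = 5
MONOTONE_BETA = 10.0  # |beta| beyond this on coded covariates flags a runaway fit


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test p-value threshold at family-wise error level ``alpha``."""
    if n_tests < 1:
        raise ConfigError(f"n_tests must be >= 1: got {n_tests}")
    return alpha / n_tests


def encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Covariate/outcome frame from the clinical table.

    Smoking is one-hot with never as reference; age continuous; non-OSCC
    deaths are censored at their death time (event=1 only for OSCC death).
    """
    needed = {"sex", "age", "smoking", "time_months", "event"}
    missing = needed - set(clinical.columns)
    if missing:
        raise ConfigError(f"clinical table missing columns: {sorted(missing)}")
    df = pd.DataFrame(index=clinical.index)
    df["sex"] = clinical["sex"].astype(float)
    df["age"] = clinical["age"].astype(float)
    df["smoking_former"] = (clinical["smoking"] == "former").astype(float)
    df["smoking_current"] = (clinical["smoking"] == "current").astype(float)
    df["time"] = clinical["time_months"].astype(float)
    df["event"] = (clinical["event"] == "OSCC_death").astype(int)
    return df


def encode_design(callset: CallSet, clinical: pd.DataFrame, probe: str,
                  cna_coding: str = "ternary") -> pd.DataFrame:
    """Per-probe Cox design: genomic covariates + clinical covariates + outcome.

    CNA coding ``'ternary'`` maps GAIN->+1, NEUTRAL->0, LOSS->-1;
    ``'delta'`` uses the segmented tumor-blood difference.  LOH maps L->1,
    R->0 and N->0 (non-informative treated as no evidence of LOH so the risk
    set does not change probe by probe).
    """
    missing = [s for s in callset.samples if s not in clinical.index]
    if missing:
        raise ConfigError(f"samples in callset missing from clinical table: {missing[:10]}")
    base = encode_clinical(clinical.loc[callset.samples])
    if cna_coding == "ternary":
        cls = callset.cna.classes.loc[probe]
        cna = cls.map({GAIN: 1.0, LOSS: -1.0}).fillna(0.0)
    elif cna_coding == "delta":
        cna = callset.cna.delta.loc[probe].astype(float)
    else:
        raise ConfigError(f"cna_coding must be 'ternary' or 'delta': got {cna_coding!r}")
    loh = (callset.loh.loc[probe] == LOH).astype(float)
    df = base.copy()
    df.insert(0, "cna", cna.to_numpy(dtype=float))
    df.insert(1, "loh", loh.to_numpy(dtype=float))
    df.insert(2, "cna_loh", df["cna"] * df["loh"])
    return df


@dataclass
class CoxFit:
    """A fitted Cox model: coefficients, covariance, log partial likelihood."""

    terms: tuple
    params: pd.Series
    cov: pd.DataFrame
    log_likelihood: float
    n_events: int
    converged: bool


def null_log_partial_likelihood(time: np.ndarray, event: np.ndarray) -> float:
    """Efron log partial likelihood of the no-covariate model (all betas 0).

    With all risk scores equal to 1, at an event time with ``d`` events and a
    risk set of size ``r`` the Efron denominators are ``r - l`` for
    ``l = 0..d-1``; the numerator vanishes.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        d = int(((time == t) & (event == 1)).sum())
        r = int((time >= t).sum())
        ll -= sum(np.log(r - l) for l in range(d))
    return ll


def fit_cox(design: pd.DataFrame, terms) -> CoxFit:
    """Maximum partial likelihood fit (Efron ties) of the given covariates.

    ``design`` must carry ``time`` and ``event`` columns plus the covariates
    named in ``terms``.  An empty ``terms`` returns the null model (log
    partial likelihood at beta=0).  Constant covariates raise
    :class:`DegenerateDesignError`; non-convergence or a monotone likelihood
    is returned as a flagged (``converged=False``) fit, not an exception.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError, ConvergenceWarning

    terms = tuple(terms)
    n_events = int(design["event"].sum())
    if n_events < 1:
        raise DegenerateDesignError("no events in the design; cannot fit")
    if not terms:
        ll = null_log_partial_likelihood(design["time"].to_numpy(),
                                         design["event"].to_numpy())
        return CoxFit((), pd.Series(dtype=float), pd.DataFrame(), ll, n_events, True)
    for t in terms:
        if design[t].nunique() <= 1:
            raise DegenerateDesignError(f"covariate '{t}' is constant")
    xmat = design[list(terms)].to_numpy(dtype=float)
    if len(terms) > 1:
        centered = xmat - xmat.mean(axis=0)
        if np.linalg.matrix_rank(centered) < len(terms):
            raise DegenerateDesignError(
                f"collinear covariates among {terms}")
    df = design[list(terms) + ["time", "event"]]
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError as exc:
            raise DegenerateDesignError(f"Cox fit failed to converge: {exc}") from exc
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    params = cph.params_.reindex(list(terms))
    if np.abs(params.to_numpy()).max() > MONOTONE_BETA:
        converged = False
    return CoxFit(terms, params, cph.variance_matrix_,
                  float(cph.log_likelihood_), n_events, converged)


def lrt(full: CoxFit, nested: CoxFit, df: int | None = None) -> tuple[float, float]:
    """Log-likelihood-ratio test of nested Cox models.

    Returns ``(statistic, p)``: twice the log partial likelihood difference
    (floored at 0) referred to the chi-square upper tail with ``df`` degrees
    of freedom (default: difference in parameter counts).
    """
    if not set(nested.terms) <= set(full.terms):
        raise UsageError(
            f"models are not nested: {nested.terms} is not a subset of {full.terms}")
    if df is None:
        df = len(full.terms) - len(nested.terms)
    if df < 1:
        raise UsageError(f"df must be >= 1: got {df}")
    stat = max(0.0, 2.0 * (full.log_likelihood - nested.log_likelihood))
    return stat, float(chi2.sf(stat, df))


def qvalues(pvalues, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values.

    ``pi0`` is estimated at a single ``lambda`` (default 0.5) as
    ``#{p > lambda} / ((1 - lambda) m)``, clipped into ``[1/m, 1]``; then
    ``q(p_(i)) = min_{j >= i} pi0 * m * p_(j) / j`` over the sorted
    p-values, which makes q monotone non-decreasing in p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ConfigError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = (p > lambda_).sum() / ((1.0 - lambda_) * m)
    pi0 = min(1.0, max(pi0, 1.0 / m))
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate((pi0 * m * p[order] / ranks)[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _sign(value: float, determined: bool) -> str:
    if not determined:
        return "undetermined"
    return "+" if value > 0 else "-" if value < 0 else "undetermined"


def screen(callset: CallSet, clinical: pd.DataFrame,
           min_loh_samples: int = DEFAULT_MIN_LOH_SAMPLES,
           probes=None, cna_coding: str = "ternary",
           alpha: float = 0.05) -> pd.DataFrame:
    """Per-probe Cox screen with nested LRTs and multiplicity control.

    Probes with LOH in fewer than ``min_loh_samples`` samples are excluded
    before testing (strict "fewer than": a probe with exactly
    ``min_loh_samples`` LOH samples is retained).  Probes whose genomic
    covariates are constant after encoding are skipped and logged.  Returns
    one row per tested probe with betas and 95% CIs for the three genomic
    terms, ``p_all`` (3 df), ``p_interaction`` (1 df), stratum-specific CNA
    effect signs, the Bonferroni flag at family-wise ``alpha``, and q-values
    per p-value family.
    """
    loh_counts = (callset.loh.to_numpy() == LOH).sum(axis=1)
    retained = callset.probes[loh_counts >= min_loh_samples]
    if probes is not None:
        retained = retained.intersection(pd.Index(probes)).sort_values()
        retained = pd.Index([p for p in callset.probes if p in set(retained)])
    if len(retained) == 0:
        logger.warning("screen: no probes retained after the LOH-sample filter")
        return pd.DataFrame()

    base_design = None
    rows = []
    z = 1.959963984540054
    for probe in retained:
        design = encode_design(callset, clinical, probe, cna_coding)
        if base_design is None:
            base_design = design
            fit0 = fit_cox(design, COVARIATES)
        try:
            fit2 = fit_cox(design, ("cna", "loh") + COVARIATES)
            fit3 = fit_cox(design, ("cna", "loh", "cna_loh") + COVARIATES)
        except DegenerateDesignError as exc:
            logger.info("screen: probe %s skipped (%s)", probe, exc)
            continue
        _, p_all = lrt(fit3, fit0, df=3)
        _, p_int = lrt(fit3, fit2, df=1)
        b = fit3.params
        se = np.sqrt(np.diag(fit3.cov.loc[list(fit3.terms), list(fit3.terms)]))
        se = pd.Series(se, index=list(fit3.terms))
        ok = fit3.converged
        b_cna, b_loh, b_int = b["cna"], b["loh"], b["cna_loh"]
        var_sum = (fit3.cov.loc["cna", "cna"] + fit3.cov.loc["cna_loh", "cna_loh"]
                   + 2.0 * fit3.cov.loc["cna", "cna_loh"])
        rows.append({
            "probe": probe,
            "beta_cna": b_cna, "ci_cna_lo": b_cna - z * se["cna"],
            "ci_cna_hi": b_cna + z * se["cna"],
            "beta_loh": b_loh, "ci_loh_lo": b_loh - z * se["loh"],
            "ci_loh_hi": b_loh + z * se["loh"],
            "beta_interaction": b_int,
            "ci_interaction_lo": b_int - z * se["cna_loh"],
            "ci_interaction_hi": b_int + z * se["cna_loh"],
            "beta_cna_loh_stratum": b_cna + b_int,
            "se_cna_loh_stratum": float(np.sqrt(max(var_sum, 0.0))),
            "p_all": p_all, "p_interaction": p_int,
            "sign_no_loh": _sign(b_cna, ok),
            "sign_loh": _sign(b_cna + b_int, ok),
            "converged": ok,
        })
    out = pd.DataFrame(rows).set_index("probe")
    if out.empty:
        return out
    m = len(out)
    thr = bonferroni_threshold(m, alpha)
    out["n_tested"] = m
    out["bonferroni_threshold"] = thr
    out["bonferroni_significant_all"] = out["p_all"] < thr
    out["bonferroni_significant_interaction"] = out["p_interaction"] < thr
    out["q_all"] = qvalues(out["p_all"].to_numpy())
    out["q_interaction"] = qvalues(out["p_interaction"].to_numpy())
    return out


def manhattan_table(screen_result: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Genome-ordered table of -log10 p-values for Manhattan plots."""
    ann = annotation.loc[screen_result.index]
    out = pd.DataFrame({
        "chrom": ann["chrom"], "position": ann["position"],
        "cytoband": ann["cytoband"], "gene": ann["gene"],
        "neglog10_p_all": -np.log10(screen_result["p_all"]),
        "neglog10_p_interaction": -np.log10(screen_result["p_interaction"]),
    })
    return out.sort_values(["chrom", "position"])
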