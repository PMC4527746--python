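"""Independent oracles and small builders shared across the test suite.

The oracles deliberately avoid the library code paths they check: exhaustive
change-point search, direct Newton/BFGS maximization of the written-out Cox
partial likelihood, hypergeometric enumeration, and a double-loop q-value
computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from lohcna.cna import CNACalls, CallSet, classify_joint


def exhaustive_best_split(x: np.ndarray, min_len: int) -> tuple[int, float]:
    """Best single change-point by looping over every admissible split."""
    best_k, best_t = -1, -np.inf
    for k in range(min_len, len(x) - min_len + 1):
        t = stats.ttest_ind(x[:k], x[k:], equal_var=True).statistic
        if np.isnan(t):
            t = 0.0
        if abs(t) > best_t:
            best_k, best_t = k, abs(t)
    return best_k, best_t


def cox_partial_loglik_no_ties(beta, X, time, event):
    """Written-out Cox partial likelihood (valid when event times are unique)."""
    beta = np.asarray(beta, float)
    eta = X @ beta
    ll = 0.0
    for i in np.flatnonzero(event):
        at_risk = time >= time[i]
        ll += eta[i] - np.log(np.exp(eta[at_risk]).sum())
    return ll


def newton_cox_beta(X, time, event):
    """Independent maximization of the partial likelihood via BFGS."""
    res = optimize.minimize(
        lambda b: -cox_partial_loglik_no_ties(b, X, time, event),
        x0=np.zeros(X.shape[1]), method="BFGS")
    return res.x


def qvalues_stepwise(p, lambda_=0.5):
    """Double-loop re-computation of Storey q-values (same pi0 convention)."""
    p = np.asarray(p, float)
    m = p.size
    pi0 = min(1.0, max((p > lambda_).sum() / ((1 - lambda_) * m), 1.0 / m))
    ranks = stats.rankdata(p, method="max")
    q = np.empty(m)
    for i in range(m):
        candidates = [pi0 * m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]]
        q[i] = min(1.0, min(candidates))
    return q


def fisher_2x2_enumeration(table) -> float:
    """Two-sided Fisher p for a 2x2 table by direct hypergeometric enumeration."""
    t = np.asarray(table, int)
    n = t.sum()
    r1 = t[0].sum()
    c1 = t[:, 0].sum()
    rv = stats.hypergeom(n, r1, c1)
    p_obs = rv.pmf(t[0, 0])
    total = 0.0
    for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pa = rv.pmf(a)
        if pa <= p_obs * (1 + 1e-7):
            total += pa
    return min(1.0, total)


def make_callset(loh_df: pd.DataFrame, classes_df: pd.DataFrame,
                 delta_df: pd.DataFrame | None = None,
                 annotation: pd.DataFrame | None = None,
                 cutoff: float = 0.5) -> CallSet:
    """Assemble a CallSet from hand-built matrices."""
    if delta_df is None:
        mapping = {"GAIN": 1.0, "LOSS": -1.0, "NEUTRAL": 0.0}
        delta_df = classes_df.apply(lambda col: col.map(mapping)).astype(float)
    if annotation is None:
        n = len(loh_df)
        annotation = pd.DataFrame({
            "chrom": "chr1", "arm": ["p"] * (n // 2) + ["q"] * (n - n // 2),
            "position": (np.arange(n) + 1) * 1000,
            "cytoband": "1p1", "gene": "",
        }, index=loh_df.index)
    calls = CNACalls(classes=classes_df, delta=delta_df,
                     high_amp=delta_df >= 5.0, cutoff=cutoff)
    joint = classify_joint(loh_df, classes_df)
    return CallSet(loh=loh_df, cna=calls, joint=joint, annotation=annotation)
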