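"""Sample clustering on aberration matrices and cluster/outcome association.

Samples are clustered hierarchically (complete linkage, two groups) on
either the binary LOH matrix (Jaccard distance) or on the segmented
copy-number differences (Euclidean distance), genome wide or restricted to
a probe subset.  Cluster labels are then related to categorical covariates
by the Fisher exact test (full enumeration for 2 x k tables) and to
OSCC-specific mortality by cumulative incidence (one minus Kaplan-Meier,
competing deaths censored) with the two-group log-rank test, or by a Cox
model with additional adjusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import chi2

from .cna import CallSet
from .errors import ConfigError, UsageError
from .loh import LOH
from .survival import encode_clinical, fit_cox, lrt

logger = logging.getLogger(__name__)

ENUMERATION_LIMIT = 2_000_000


@dataclass
class ClusterResult:
    labels: pd.Series        # per sample: 1 or 2
    linkage_matrix: np.ndarray
    event_type: str
    n_probes: int
    degenerate: bool = False


def cluster_samples(callset: CallSet, event_type: str = "loh",
                    probe_subset=None, linkage_method: str = "complete") -> ClusterResult:
    """Cut a complete-linkage dendrogram of the samples into two groups.

    ``event_type='loh'`` clusters the binary LOH indicator with Jaccard
    distance; ``'cna'`` clusters the segmented tumor-blood differences with
    Euclidean distance.  Deterministic for a given input.  If every sample
    is identical the single-cluster result is returned flagged degenerate.
    """
    if event_type == "loh":
        feats = (callset.loh == LOH).astype(float)
        metric = "jaccard"
    elif event_type == "cna":
        feats = callset.cna.delta
        metric = "euclidean"
    else:
        raise ConfigError(f"event_type must be 'loh' or 'cna': got {event_type!r}")
    if probe_subset is not None:
        probe_subset = pd.Index(probe_subset)
        missing = probe_subset.difference(feats.index)
        if len(missing):
            raise ConfigError(f"probe_subset has unknown probes: {list(missing[:10])}")
        feats = feats.loc[probe_subset]
    if feats.shape[1] < 4:
        raise ConfigError(f"need >= 4 samples to cluster: got {feats.shape[1]}")
    if feats.shape[0] == 0:
        raise ConfigError("probe subset is empty")

    x = feats.to_numpy().T  # samples x probes
    with np.errstate(invalid="ignore"):
        d = pdist(x, metric=metric)
    d = np.nan_to_num(d, nan=0.0)  # jaccard of two all-zero samples: identical
    z = linkage(d, method=linkage_method)
    raw = fcluster(z, t=2, criterion="maxclust")
    degenerate = len(np.unique(raw)) < 2
    if degenerate:
        logger.warning("cluster_samples: all samples identical; single cluster")
    # stable labeling: cluster containing the first sample is 1
    labels = np.where(raw == raw[0], 1, 2)
    return ClusterResult(
        labels=pd.Series(labels, index=feats.columns, name="cluster"),
        linkage_matrix=z, event_type=event_type, n_probes=feats.shape[0],
        degenerate=degenerate)


def _log_table_prob(col_sums: np.ndarray, row1: np.ndarray, n: int, r1: int) -> float:
    """log P(table) under the hypergeometric null with fixed margins."""
    lc = lambda a, b: lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)
    return sum(lc(c, a) for c, a in zip(col_sums, row1)) - lc(n, r1)


def fisher_exact_table(table, monte_carlo: bool = False, n_draws: int = 100_000,
                       seed: int = 0) -> float:
    """Exact conditional p for a 2 x k contingency table.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one.  Tables
    whose enumeration would exceed ~2e6 states raise an error advising the
    Monte-Carlo mode (``monte_carlo=True``), which samples tables from the
    fixed-margin null via random permutation of the column labels.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise UsageError(f"expected a 2 x k table: got shape {t.shape}")
    if (t < 0).any():
        raise UsageError("table entries must be non-negative")
    col = t.sum(axis=0)
    r1 = int(t[0].sum())
    n = int(t.sum())
    if n == 0:
        return 1.0
    log_obs = _log_table_prob(col, t[0], n, r1)
    size_bound = np.prod([min(c, r1) + 1 for c in col], dtype=float)
    if size_bound > ENUMERATION_LIMIT:
        if not monte_carlo:
            raise UsageError(
                f"enumeration bound {size_bound:.2g} exceeds {ENUMERATION_LIMIT}; "
                "use monte_carlo=True")
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(col.size), col)
        hits = 0
        for _ in range(n_draws):
            rng.shuffle(labels)
            a = np.bincount(labels[:r1], minlength=col.size)
            if _log_table_prob(col, a, n, r1) <= log_obs + 1e-7:
                hits += 1
        return (hits + 1) / (n_draws + 1)

    k = col.size
    total = 0.0
    # depth-first over row-1 entries with margin pruning
    def recurse(j: int, remaining: int, acc: float):
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= col[j]:
                lp = acc + (lgamma(col[j] + 1) - lgamma(remaining + 1)
                            - lgamma(col[j] - remaining + 1))
                lp -= lgamma(n + 1) - lgamma(r1 + 1) - lgamma(n - r1 + 1)
                if lp <= log_obs + 1e-7:
                    total += np.exp(lp)
            return
        tail_capacity = int(col[j + 1:].sum())
        lo = max(0, remaining - tail_capacity)
        hi = min(col[j], remaining)
        for a in range(lo, hi + 1):
            recurse(j + 1, remaining - a,
                    acc + lgamma(col[j] + 1) - lgamma(a + 1) - lgamma(col[j] - a + 1))

    recurse(0, r1, 0.0)
    return min(1.0, total)


def fisher_exact(labels: pd.Series, covariate: pd.Series, **kwargs) -> tuple[float, pd.DataFrame]:
    """Fisher exact association of two-cluster labels with a categorical covariate.

    Returns ``(p, contingency_table)`` where the table has clusters as rows.
    """
    cov = covariate.loc[labels.index]
    table = pd.crosstab(labels, cov)
    if table.shape[0] != 2:
        raise UsageError(f"need exactly 2 clusters: got {table.shape[0]}")
    if table.shape[1] > 6:
        raise UsageError(f"covariate has {table.shape[1]} levels; at most 6 supported")
    return fisher_exact_table(table.to_numpy(), **kwargs), table


@dataclass
class MortalityComparison:
    observed: float           # events observed in group 1
    expected: float           # events expected in group 1 under the null
    variance: float
    statistic: float
    p_value: float
    curves: dict              # group label -> DataFrame(time, cumulative_incidence)
    n_events: pd.Series       # events per group


def logrank_two_group(time: np.ndarray, event: np.ndarray,
                      group: np.ndarray) -> tuple[float, float, float, float, float]:
    """Two-group log-rank: ``(O1, E1, V, statistic, p)``.

    At each distinct event time, group 1's observed events are compared with
    the expectation ``d * n1 / n`` under the null and the hypergeometric
    variance ``d * (n1/n) * (n2/n) * (n-d)/(n-1)``; the statistic is
    ``(O1-E1)^2 / V`` on one chi-square degree of freedom.  Invariant to
    swapping the two group labels.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    g1 = np.asarray(group) == np.unique(np.asarray(group))[0]
    o1 = e1 = v = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * ((n - n1) / n) * (n - d) / (n - 1)
    if v <= 0:
        return o1, e1, v, 0.0, 1.0
    stat = (o1 - e1) ** 2 / v
    return o1, e1, v, stat, float(chi2.sf(stat, 1))


def compare_mortality(labels: pd.Series, clinical: pd.DataFrame) -> MortalityComparison:
    """Cumulative incidence of OSCC-specific death by cluster, with log-rank p.

    Non-OSCC deaths are censored at the death time; the cumulative incidence
    curve per cluster is one minus the Kaplan-Meier estimate of
    OSCC-death-free survival.
    """
    from lifelines import KaplanMeierFitter

    enc = encode_clinical(clinical.loc[labels.index])
    time = enc["time"].to_numpy()
    event = enc["event"].to_numpy()
    group = labels.to_numpy()
    groups = np.unique(group)
    if groups.size != 2:
        raise UsageError(f"need exactly 2 clusters: got {groups.size}")
    n_events = pd.Series({g: int(event[group == g].sum()) for g in groups})
    if n_events.sum() == 0:
        logger.warning("compare_mortality: no OSCC deaths in either cluster")
        o1 = e1 = v = stat = 0.0
        p = 1.0
    else:
        o1, e1, v, stat, p = logrank_two_group(time, event, group)
    curves = {}
    for g in groups:
        m = group == g
        km = KaplanMeierFitter()
        km.fit(time[m], event[m])
        sf = km.survival_function_
        curves[int(g)] = pd.DataFrame({
            "time": sf.index.to_numpy(),
            "cumulative_incidence": 1.0 - sf.iloc[:, 0].to_numpy(),
        })
    return MortalityComparison(o1, e1, v, stat, p, curves, n_events)


def cluster_covariate_cox(labels: pd.Series, clinical: pd.DataFrame,
                          adjusters=()) -> tuple[float, float]:
    """LRT p for the cluster term in a Cox model with optional adjusters.

    ``adjusters`` are clinical column names; categorical columns are one-hot
    encoded with the first level as reference.  Returns ``(statistic, p)``
    with 1 degree of freedom.
    """
    enc = encode_clinical(clinical.loc[labels.index])
    df = enc[["time", "event"]].copy()
    df["cluster"] = (labels == labels.iloc[0]).astype(float).to_numpy()
    adj_cols = []
    for name in adjusters:
        col = clinical.loc[labels.index, name]
        if pd.api.types.is_numeric_dtype(col):
            df[name] = col.astype(float).to_numpy()
            adj_cols.append(name)
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True).astype(float)
            for c in dummies.columns:
                df[c] = dummies[c].to_numpy()
                adj_cols.append(c)
    full = fit_cox(df, ["cluster"] + adj_cols)
    nested = fit_cox(df, adj_cols)
    return lrt(full, nested, df=1)
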