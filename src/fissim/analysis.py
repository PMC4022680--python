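"""Statistical treatment of days-to-fission from batch sweeps.

Per-condition summaries, the linear regression of mean days on the
transfer percentage, the Kruskal-Wallis + Dunn comparison of
Nutrition/Sociality ratio levels (with homogeneity groupings), a Poisson
generalised linear model of days on the three design covariates, and
right-censored survival curves.

Censoring policy: replicates that reach the day cap without fissioning
can either be excluded ("exclude") or entered at the cap value
("cap_at_max"); every routine that touches days takes the policy
explicitly so both readings of the original analyses are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import BatchResult
from .errors import ConfigurationError, InsufficientDataError

CENSOR_POLICIES = ("exclude", "cap_at_max")

#: condition key columns of the tidy batch table
CONDITION_KEY = ["n", "C", "lambda1", "lambda2", "transfer", "ratio"]

#: Nutrition/Sociality band boundaries: below the low bound (group-size
#: dependent) fission essentially never happens; above the high bound it is
#: slow; in between it is fastest
LOW_BAND_BOUND = {10: 0.43, 20: 0.25}
HIGH_BAND_BOUND = 2.33


def _policy_days(table: pd.DataFrame, censor_policy: str) -> pd.DataFrame:
    if censor_policy not in CENSOR_POLICIES:
        raise ConfigurationError(
            f"censor_policy must be one of {CENSOR_POLICIES}, got {censor_policy!r}"
        )
    if censor_policy == "exclude":
        return table.loc[~table["censored"]]
    return table


def summarize(batch: BatchResult, censor_policy: str = "exclude") -> pd.DataFrame:
    """Per-condition mean/min/max days and fission fraction.

    Under ``censor_policy="exclude"`` the day statistics cover only the
    replicates with an event; a condition where every replicate was
    censored gets NaN statistics and ``all_censored=True`` rather than an
    error.  Under ``"cap_at_max"`` censored replicates enter at the cap.
    """
    table = batch.table
    if table.empty:
        raise ConfigurationError("empty batch")
    rows = []
    for key, grp in table.groupby(CONDITION_KEY, sort=True):
        days = _policy_days(grp, censor_policy)["days"]
        rec = dict(zip(CONDITION_KEY, key))
        rec.update(
            mean_days=days.mean() if len(days) else float("nan"),
            min_days=float(days.min()) if len(days) else float("nan"),
            max_days=float(days.max()) if len(days) else float("nan"),
            fission_fraction=float((~grp["censored"]).mean()),
            n_replicates=int(len(grp)),
            all_censored=bool(grp["censored"].all()),
            censor_policy=censor_policy,
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def mean_days_by_transfer(
    batch: BatchResult,
    n: int,
    censor_policy: str = "cap_at_max",
    include_transfers: list[float] | None = None,
) -> pd.Series:
    """Mean days per transfer level for group size ``n``, pooled over the
    ratio conditions (censored runs capped by default, as on the day-cap
    surface plots)."""
    table = batch.table[batch.table["n"] == n]
    if include_transfers is not None:
        table = table[table["transfer"].isin(include_transfers)]
    if table.empty:
        raise InsufficientDataError(f"no replicates for n={n}")
    days = _policy_days(table, censor_policy)
    return days.groupby(days["transfer"])["days"].mean()


@dataclass(frozen=True)
class LinearFit:
    """OLS of mean days on transfer percentage."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int


def transfer_linearity(mean_days: pd.Series | dict[float, float]) -> LinearFit:
    """Ordinary least squares of per-transfer mean days on the transfer
    percentage; the slope is expected negative (faster fission at higher
    transfer).  The F statistic tests the regression on 1 and
    ``levels - 2`` degrees of freedom; a perfectly flat response returns
    F = 0 rather than NaN.
    """
    s = pd.Series(mean_days).sort_index()
    if len(s) < 3:
        raise InsufficientDataError(
            f"need >= 3 transfer levels for a regression, got {len(s)}"
        )
    x = s.index.to_numpy(dtype=float)
    y = s.to_numpy(dtype=float)
    df_den = len(s) - 2
    if np.ptp(y) == 0.0:  # flat response: define the fit as null
        return LinearFit(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                         f_statistic=0.0, p_value=1.0, df_num=1, df_den=df_den)
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2
    if np.isclose(r2, 1.0):
        f = float("inf")
    else:
        f = r2 / (1.0 - r2) * df_den
    p = 1.0 if f == 0 else float(stats.f.sf(f, 1, df_den))
    return LinearFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(r2), f_statistic=float(f), p_value=p,
        df_num=1, df_den=df_den,
    )


def _dunn_zmatrix(samples: list[np.ndarray]) -> np.ndarray:
    """Pairwise Dunn z statistics from pooled mid-ranks with tie correction."""
    pooled = np.concatenate(samples)
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    # tie correction term sum(t^3 - t) over tie groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    var_factor = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    mean_ranks = []
    sizes = []
    start = 0
    for s in samples:
        stop = start + len(s)
        mean_ranks.append(ranks[start:stop].mean())
        sizes.append(len(s))
        start = stop
    k = len(samples)
    z = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
            zij = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            z[i, j] = zij
            z[j, i] = -zij
    return z


def _adjust_pvalues(p: np.ndarray, method: str) -> np.ndarray:
    m = len(p)
    if method == "none":
        return p
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ConfigurationError(f"unknown adjustment {method!r}")


@dataclass(frozen=True)
class RatioGroupsResult:
    """Kruskal-Wallis across ratio levels plus Dunn pairwise comparisons."""

    kruskal_statistic: float
    kruskal_pvalue: float
    dunn_z: pd.DataFrame
    dunn_p: pd.DataFrame
    groups: tuple[tuple[float, ...], ...]
    dropped: tuple[float, ...]
    adjust: str
    alpha: float


def ratio_groups(
    batch: BatchResult,
    n: int,
    *,
    exclude_transfers: tuple[float, ...] = (10.0,),
    censor_policy: str = "cap_at_max",
    alpha: float = 0.05,
    adjust: str = "none",
) -> RatioGroupsResult:
    """Rank-based comparison of days-to-fission across the ratio levels.

    Runs at 10% transfer are excluded by default (they are uniformly
    censored and would only flatten the ranks).  Homogeneity groups are
    the connected components of the "not significantly different" relation
    at level ``alpha``, ordered by mean days; with well-separated levels
    this recovers the low / middle / high ratio bands.
    """
    table = batch.table[
        (batch.table["n"] == n) & ~batch.table["transfer"].isin(exclude_transfers)
    ]
    table = _policy_days(table, censor_policy)
    dropped = []
    samples: dict[float, np.ndarray] = {}
    for ratio, grp in table.groupby("ratio", sort=True):
        samples[float(ratio)] = grp["days"].to_numpy(dtype=float)
    all_ratios = sorted(batch.table.loc[batch.table["n"] == n, "ratio"].unique())
    for r in all_ratios:
        if float(r) not in samples:
            dropped.append(float(r))
    if dropped:
        warnings.warn(
            f"ratio levels without usable replicates dropped: {dropped}",
            stacklevel=2,
        )
    levels = sorted(samples)
    if len(levels) < 2:
        raise InsufficientDataError("need >= 2 ratio levels with data")
    arrays = [samples[r] for r in levels]
    K, kp = stats.kruskal(*arrays)
    z = _dunn_zmatrix(arrays)
    iu = np.triu_indices(len(levels), 1)
    p_flat = 2.0 * stats.norm.sf(np.abs(z[iu]))
    p_flat = _adjust_pvalues(p_flat, adjust)
    pmat = np.ones((len(levels), len(levels)))
    pmat[iu] = p_flat
    pmat[(iu[1], iu[0])] = p_flat

    # homogeneity groups: transitive closure of non-significance
    parent = list(range(len(levels)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            if pmat[i, j] >= alpha:
                parent[find(i)] = find(j)
    comps: dict[int, list[float]] = {}
    for idx, r in enumerate(levels):
        comps.setdefault(find(idx), []).append(r)
    mean_days = {r: samples[r].mean() for r in levels}
    groups = sorted(
        (tuple(sorted(g)) for g in comps.values()),
        key=lambda g: np.mean([mean_days[r] for r in g]),
    )
    idx = pd.Index(levels, name="ratio")
    return RatioGroupsResult(
        kruskal_statistic=float(K), kruskal_pvalue=float(kp),
        dunn_z=pd.DataFrame(z, index=idx, columns=idx),
        dunn_p=pd.DataFrame(pmat, index=idx, columns=idx),
        groups=tuple(groups), dropped=tuple(dropped),
        adjust=adjust, alpha=alpha,
    )


def ratio_band(ratio: float, n: int) -> str:
    """Classify a Nutrition/Sociality ratio into the low / mid / high band
    for group size ``n`` (low bound 0.43 at n=10, 0.25 at n=20)."""
    low = LOW_BAND_BOUND.get(int(n), LOW_BAND_BOUND[10])
    if ratio < low:
        return "low"
    if ratio <= HIGH_BAND_BOUND:
        return "mid"
    return "high"


def band_summary(
    batch: BatchResult,
    n: int,
    *,
    exclude_transfers: tuple[float, ...] = (10.0,),
    censor_policy: str = "exclude",
) -> pd.DataFrame:
    """Mean days and fission fraction per ratio band (low / mid / high)."""
    table = batch.table[
        (batch.table["n"] == n) & ~batch.table["transfer"].isin(exclude_transfers)
    ].copy()
    if table.empty:
        raise InsufficientDataError(f"no replicates for n={n}")
    table["band"] = [ratio_band(r, n) for r in table["ratio"]]
    rows = []
    for band in ("low", "mid", "high"):
        grp = table[table["band"] == band]
        if grp.empty:
            continue
        days = _policy_days(grp, censor_policy)["days"]
        rows.append(dict(
            band=band,
            mean_days=days.mean() if len(days) else float("nan"),
            fission_fraction=float((~grp["censored"]).mean()),
            n_replicates=int(len(grp)),
        ))
    return pd.DataFrame(rows).set_index("band")


def poisson_covariate_model(
    batch: BatchResult, censor_policy: str = "cap_at_max"
) -> pd.DataFrame:
    """Poisson regression of days on group size, transfer and ratio.

    Returns a coefficient table (coef, std err, z, p) indexed by term.
    Covariates that do not vary in the batch are dropped with a warning.
    """
    import statsmodels.api as sm

    table = _policy_days(batch.table, censor_policy)
    if table.empty:
        raise InsufficientDataError("no usable replicates")
    covs = []
    for c in ("n", "transfer", "ratio"):
        if table[c].nunique() > 1:
            covs.append(c)
        else:
            warnings.warn(f"covariate {c!r} does not vary; dropped", stacklevel=2)
    if not covs:
        raise InsufficientDataError("no varying covariates")
    X = sm.add_constant(table[covs].astype(float))
    model = sm.GLM(table["days"].astype(float), X, family=sm.families.Poisson())
    fit = model.fit()
    return pd.DataFrame({
        "coef": fit.params,
        "std_err": fit.bse,
        "z": fit.tvalues,
        "p_value": fit.pvalues,
    })


def survival_curve(batch: BatchResult, **key: float) -> pd.DataFrame:
    """Right-censored empirical survival function of days-to-fission.

    ``key`` filters the batch table by column values (e.g. ``n=10,
    transfer=50``).  Returns a tidy frame with columns ``day`` and
    ``survival`` (fraction of replicates not yet fissioned), monotone
    non-increasing from 1.
    """
    from lifelines import KaplanMeierFitter

    table = batch.table
    for col, val in key.items():
        if col not in table.columns:
            raise ConfigurationError(f"unknown batch column {col!r}")
        table = table[np.isclose(table[col].astype(float), float(val))]
    if table.empty:
        raise InsufficientDataError(f"no replicates match {key!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(table["days"], event_observed=~table["censored"])
    sf = kmf.survival_function_
    return pd.DataFrame({
        "day": sf.index.to_numpy(dtype=float),
        "survival": sf.iloc[:, 0].to_numpy(dtype=float),
    })
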