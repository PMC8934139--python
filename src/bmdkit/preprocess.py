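"""Probe-level screening for dose–response analysis.

Probes are filtered on two axes before any curve fitting:

* **Effect size** — the signed fold change between each dose group and control,
  computed on the anti-logged scale and folded so that down-regulation maps to
  values ≤ −1 (a probe with no change has fold change 1).
* **Statistical significance** — one-way ANOVA, and/or monotone-trend tests of
  the Williams type built on the isotonic (monotone-constrained) MLE of the
  group means, with permutation (Williams) or bootstrap (Oriogen-style) null
  distributions and Benjamini–Hochberg adjustment across probes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import ExpressionDataset, summarize_dataset

__all__ = [
    "FilterSettings",
    "TrendFit",
    "compute_fold_change",
    "anova_pvalue",
    "isotonic_group_means",
    "williams_statistic",
    "trend_fit",
    "resampling_pvalue",
    "bh_adjust",
    "screen_probes",
    "filter_probes",
]

TREND_TESTS = ("anova", "williams", "oriogen")


@dataclass
class FilterSettings:
    """Screening thresholds.

    ``fold_change_cutoff`` is inclusive on |f| (default 2);
    ``p_cutoff`` is strict (default 0.05). ``which_test`` selects the p-value
    used by :func:`filter_probes`; ``use_adjusted`` switches to BH-adjusted
    p-values. ``resampling_count`` is the number of permutation/bootstrap
    replicates B for the trend tests.
    """

    fold_change_cutoff: float = 2.0
    p_cutoff: float = 0.05
    which_test: str = "williams"
    use_adjusted: bool = False
    resampling_count: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.fold_change_cutoff <= 0 or self.p_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.which_test not in TREND_TESTS:
            raise ValueError(f"unknown test {self.which_test!r}; choose from {TREND_TESTS}")
        if self.resampling_count < 100:
            raise ValueError("resampling_count must be at least 100")


@dataclass
class TrendFit:
    """Isotonic trend fit for one probe: observed and monotone-constrained group
    means, pooled within-group SD, and the standardized trend statistic."""

    group_means: np.ndarray
    group_sizes: np.ndarray
    isotonic_means: np.ndarray
    pooled_sd: float
    statistic: float
    direction: str  # 'increasing' or 'decreasing'


def compute_fold_change(group_means: Sequence[float], control_mean: float,
                        log_base: float) -> float:
    """Signed fold change across dose levels relative to control.

    For each non-control level the anti-logged ratio ``r = base**(mean - control)``
    is folded into a signed magnitude: ``r`` when ``r >= 1``, ``-1/r`` otherwise,
    and the candidate with the largest absolute value wins. |f| >= 1 always.
    """
    means = np.asarray(group_means, dtype=float)
    if means.size == 0:
        raise ValueError("no non-control dose level")
    if not (np.all(np.isfinite(means)) and np.isfinite(control_mean)):
        raise ValueError("non-finite group means")
    # work on |log diff| so extreme responders cannot overflow the anti-log
    diff = (means - control_mean) * math.log(float(log_base))
    best = diff[np.argmax(np.abs(diff))]
    mag = math.exp(min(abs(best), 700.0))
    return float(mag if best >= 0 else -mag)


def anova_pvalue(ds: ExpressionDataset, probe_id: str) -> float:
    """Classical one-way ANOVA F-test p-value across dose groups."""
    y = ds.probe_values(probe_id)
    groups = [y[idx] for idx in ds.group_indices()]
    f, p = stats.f_oneway(*groups)
    if not np.isfinite(p):
        raise ValueError(f"ANOVA undefined for probe {probe_id!r} "
                         "(zero within-group variance)")
    return float(p)


def _maxmin_isotonic(means: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Increasing isotonic MLE via the max-min formula, vectorized over leading
    batch axes of ``means`` (shape ``(..., K)``)."""
    means = np.asarray(means, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    K = means.shape[-1]
    w = sizes * means  # (..., K)
    cw = np.concatenate([np.zeros(means.shape[:-1] + (1,)), np.cumsum(w, axis=-1)], axis=-1)
    cn = np.concatenate([[0.0], np.cumsum(sizes)])
    # pooled[..., u, v] = weighted mean of groups u..v (0-based, u <= v)
    u = np.arange(K)[:, None]
    v = np.arange(K)[None, :]
    num = cw[..., v + 1] - cw[..., u]          # (..., K, K)
    den = (cn[v + 1] - cn[u])                  # (K, K)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = num / den
    pooled = np.where(u <= v, pooled, np.nan)
    # suffix-min over v, so inner[..., u, u] = min over v in u..K-1
    inner = np.fmin.accumulate(pooled[..., ::-1], axis=-1)[..., ::-1]
    diag = np.diagonal(inner, axis1=-2, axis2=-1)
    # mu_i = max over u <= i of inner[u]
    mu = np.maximum.accumulate(diag, axis=-1)
    return mu


def isotonic_group_means(group_means: Sequence[float], group_sizes: Sequence[int],
                         direction: str = "increasing") -> np.ndarray:
    """Monotone-constrained MLE of the group means (max-min formula).

    For the increasing case, ``mu_i = max_{u<=i} min_{v in u..K} `` of the
    size-weighted mean of groups u..v; the decreasing case swaps max and min,
    equivalently fits the negated responses. The result is the isotonic
    regression of the group means with the group sizes as weights.
    """
    means = np.asarray(group_means, dtype=float)
    sizes = np.asarray(group_sizes, dtype=float)
    if means.ndim != 1 or means.size < 2:
        raise ValueError("need at least 2 dose groups")
    if np.any(sizes < 1):
        raise ValueError("group sizes must be >= 1")
    if direction == "increasing":
        return _maxmin_isotonic(means, sizes)
    if direction == "decreasing":
        return -_maxmin_isotonic(-means, sizes)
    raise ValueError(f"direction must be 'increasing' or 'decreasing', got {direction!r}")


def pooled_within_sd(y: np.ndarray, group_idx: Sequence[np.ndarray]) -> float:
    """Unbiased pooled within-group SD over all groups including control."""
    y = np.asarray(y, dtype=float)
    ss = 0.0
    n = 0
    for idx in group_idx:
        g = y[..., idx]
        ss += ((g - g.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
        n += idx.size
    dof = n - len(group_idx)
    return np.sqrt(ss / dof)


def williams_statistic(isotonic_means: np.ndarray, control_mean: float,
                       pooled_sd: float, group_sizes: Sequence[int]) -> float:
    """Williams-type standardized trend statistic.

    ``T = max_i |mu_i - control_mean| / (s * sqrt(1/n_i + 1/n_0))`` over the
    treated levels (i >= 1), where ``mu`` is the isotonic fit, ``s`` the pooled
    within-group SD and ``n_0`` the control group size.
    """
    mu = np.asarray(isotonic_means, dtype=float)
    n = np.asarray(group_sizes, dtype=float)
    if np.any(pooled_sd <= 0):
        raise ValueError("pooled within-group SD must be positive")
    se = np.sqrt(1.0 / n[1:] + 1.0 / n[0])
    t = np.abs(mu[..., 1:] - np.asarray(control_mean)[..., None]) / (
        np.asarray(pooled_sd)[..., None] * se)
    return np.max(t, axis=-1)


def _batch_trend_statistic(group_means: np.ndarray, sizes: np.ndarray,
                           control_mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Direction-maximized trend statistic, batched over leading axes."""
    t_inc = williams_statistic(_maxmin_isotonic(group_means, sizes),
                               control_mean, sd, sizes)
    t_dec = williams_statistic(-_maxmin_isotonic(-group_means, sizes),
                               control_mean, sd, sizes)
    return np.maximum(t_inc, t_dec)


def trend_fit(ds: ExpressionDataset, probe_id: str) -> TrendFit:
    """Fit the monotone trend for one probe, choosing the direction
    (increasing/decreasing) that maximizes the standardized statistic."""
    y = ds.probe_values(probe_id)
    idx = ds.group_indices()
    sizes = ds.group_sizes()
    means = np.array([y[i].mean() for i in idx])
    sd = float(pooled_within_sd(y, idx))
    if sd <= 0:
        raise ValueError(f"probe {probe_id!r} has zero within-group variance")
    best = None
    for direction in ("increasing", "decreasing"):
        mu = isotonic_group_means(means, sizes, direction)
        t = float(williams_statistic(mu, means[0], sd, sizes))
        if best is None or t > best.statistic:
            best = TrendFit(means, sizes, mu, sd, t, direction)
    return best


def resampling_pvalue(ds: ExpressionDataset, probe_id: str,
                      method: str = "permutation", B: int = 1000,
                      seed: int = 0) -> float:
    """Resampling p-value for the direction-maximized trend statistic.

    ``permutation`` shuffles dose labels across all samples; ``bootstrap``
    resamples with replacement from the pooled (null) sample. The +1-corrected
    estimator ``p = (1 + #{T_b >= T_obs}) / (B + 1)`` keeps p in
    ``[1/(B+1), 1]``.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if method not in ("permutation", "bootstrap"):
        raise ValueError(f"unknown resampling method {method!r}")
    # canonicalize: sort values within each dose group so the resampling
    # stream (and hence p) is exactly invariant to input column order
    raw = ds.probe_values(probe_id)
    y = np.concatenate([np.sort(raw[i]) for i in ds.group_indices()])
    sizes = ds.group_sizes()
    stops = np.cumsum(sizes)
    idx = [np.arange(start, stop) for start, stop in
           zip(np.concatenate([[0], stops[:-1]]), stops)]
    n = y.size
    sd = float(pooled_within_sd(y, idx))
    if sd <= 0:
        raise ValueError(f"probe {probe_id!r} has zero within-group variance")
    means = np.array([y[i].mean() for i in idx])
    t_obs = float(_batch_trend_statistic(means, sizes.astype(float),
                                         np.asarray(means[0]), np.asarray(sd)))

    rng = np.random.default_rng(seed)
    if method == "permutation":
        draws = np.argsort(rng.random((B, n)), axis=1)
        resampled = y[draws]
    else:
        resampled = y[rng.integers(0, n, size=(B, n))]
    # group structure follows the canonical (dose-sorted) column layout
    gm = np.stack([resampled[:, i].mean(axis=1) for i in idx], axis=1)  # (B, K)
    sd_b = pooled_within_sd(resampled, idx)
    ok = sd_b > 0
    t_b = np.zeros(B)
    t_b[ok] = _batch_trend_statistic(gm[ok], sizes.astype(float), gm[ok, 0], sd_b[ok])
    return float((1 + np.count_nonzero(t_b >= t_obs - 1e-12)) / (B + 1))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def screen_probes(ds: ExpressionDataset, settings: FilterSettings | None = None,
                  tests: Iterable[str] | None = None) -> pd.DataFrame:
    """Run the probe screen and return the per-probe summary table.

    Columns: ``probe_id, fold_change, direction, p_anova, p_williams, p_oriogen,
    adj_p_anova, adj_p_williams, adj_p_oriogen, valid, passed``. Tests that are
    not requested are NaN. Invalid probes (non-finite or zero-variance) carry
    NaN statistics and never pass.
    """
    settings = settings or FilterSettings()
    if tests is None:
        tests = {"anova", settings.which_test}
    tests = set(tests)
    unknown = tests - set(TREND_TESTS)
    if unknown:
        raise ValueError(f"unknown tests: {sorted(unknown)}")

    summary = summarize_dataset(ds)
    valid = summary.valid_probe_mask
    seeds = np.random.SeedSequence(settings.seed).spawn(ds.n_probes)

    rows = []
    for i, probe in enumerate(ds.probe_ids):
        row = {"probe_id": probe, "valid": bool(valid[i]),
               "fold_change": np.nan, "direction": "",
               "p_anova": np.nan, "p_williams": np.nan, "p_oriogen": np.nan}
        if valid[i]:
            means = ds.group_means(probe)
            row["fold_change"] = compute_fold_change(means[1:], means[0], ds.log_base)
            fit = trend_fit(ds, probe)
            row["direction"] = fit.direction
            child = seeds[i].generate_state(1)[0] % (2 ** 31)
            if "anova" in tests:
                row["p_anova"] = anova_pvalue(ds, probe)
            if "williams" in tests:
                row["p_williams"] = resampling_pvalue(
                    ds, probe, "permutation", settings.resampling_count, child)
            if "oriogen" in tests:
                row["p_oriogen"] = resampling_pvalue(
                    ds, probe, "bootstrap", settings.resampling_count, child)
        rows.append(row)
    df = pd.DataFrame(rows)
    for t in TREND_TESTS:
        col = f"p_{t}"
        adj = np.full(len(df), np.nan)
        mask = df[col].notna().to_numpy()
        if mask.any():
            adj[mask] = bh_adjust(df.loc[mask, col].to_numpy())
        df[f"adj_p_{t}"] = adj
    df["passed"] = filter_probes(df, settings, as_mask=True)
    return df


def filter_probes(results: pd.DataFrame, settings: FilterSettings,
                  as_mask: bool = False):
    """Apply the AND of the fold-change and p-value criteria.

    |fold change| >= cutoff is inclusive; p < cutoff is strict. Returns the kept
    probe ids (or a boolean mask with ``as_mask=True``).
    """
    col = ("adj_" if settings.use_adjusted else "") + "p_" + settings.which_test
    if col not in results.columns:
        raise ValueError(f"screen results lack column {col!r}")
    fc_ok = results["fold_change"].abs() >= settings.fold_change_cutoff
    p_ok = results[col] < settings.p_cutoff
    mask = (fc_ok & p_ok & results["valid"]).fillna(False).to_numpy(dtype=bool)
    if as_mask:
        return mask
    return results.loc[mask, "probe_id"].tolist()
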