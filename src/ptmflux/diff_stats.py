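"""Per-feature differential statistics on log2 abundance matrices.

The workhorses are empirical-Bayes moderated two-group t-tests (limma-style
variance shrinkage toward a scaled inverse-chi-square prior fitted by
trigamma-inversion method of moments) and a factorial linear model
``~ Nitrogen + Time + Nitrogen:Time`` fitted per feature by ordinary least
squares with the same moderation of coefficient standard errors.  Raw
p-values are Benjamini-Hochberg adjusted within each result set.

Two entry styles are provided: the functional operations
(:func:`moderated_two_group`, :func:`fit_factorial`, ...) and thin model
classes (:class:`ModeratedTTest`, :class:`FactorialModel`) whose ``fit()``
returns a :class:`DiffResults` carrying the estimate table and a
``summary()`` view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix

__all__ = [
    "ModerationPrior",
    "DiffResults",
    "ModeratedTTest",
    "FactorialModel",
    "filter_min_reps",
    "estimate_prior",
    "moderated_two_group",
    "fit_factorial",
    "bh_adjust",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Replicate filtering
# ---------------------------------------------------------------------------

def filter_min_reps(
    m: AbundanceMatrix, k: int = 2, conditions: list[str] | None = None
) -> AbundanceMatrix:
    """Keep features observed in >= k biological replicates of at least one
    condition (of the tested contrast when ``conditions`` is given).

    Technical-replicate bridge channels of the same biological sample count
    once: observation is per distinct sample_id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    conds = conditions if conditions is not None else m.conditions
    keep = pd.Series(False, index=m.data.index)
    for cond in conds:
        cols = m.condition_columns(cond)
        if len(cols) == 0:
            continue
        samples = m.channels.loc[cols, "sample_id"]
        observed = m.data[cols].notna()
        # a biological replicate is observed if any of its channels is
        by_sample = observed.T.groupby(samples.to_numpy()).any().T
        keep |= by_sample.sum(axis=1) >= k
    return m.subset_features(m.data.index[keep])


# ---------------------------------------------------------------------------
# Empirical-Bayes variance prior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModerationPrior:
    """Scaled inverse-chi-square prior on residual variances.

    ``d0`` (prior degrees of freedom) may be ``inf``, which collapses every
    moderated variance to ``s0_sq``; ``d0 = 0`` leaves variances untouched
    (ordinary t-test).
    """

    d0: float
    s0_sq: float

    def squeeze(self, s_sq: np.ndarray, df: np.ndarray) -> np.ndarray:
        if np.isinf(self.d0):
            return np.full_like(np.asarray(s_sq, dtype=float), self.s0_sq)
        return (self.d0 * self.s0_sq + df * s_sq) / (self.d0 + df)


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x by monotone Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def estimate_prior(residual_vars: list[tuple[float, float]] | None = None,
                   s_sq: np.ndarray | None = None, df: np.ndarray | None = None) -> ModerationPrior:
    """Method-of-moments fit of the variance prior from observed residual
    variances ``(s_sq, df)``.

    Works on the log scale with digamma/trigamma bias corrections; when the
    spread of log variances does not exceed its theoretical sampling
    variance the prior degrees of freedom are infinite.
    """
    if residual_vars is not None:
        arr = np.asarray(residual_vars, dtype=float)
        s_sq, df = arr[:, 0], arr[:, 1]
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s_sq) & (df >= 1)
    s_sq, df = s_sq[ok], df[ok]
    if s_sq.size < 10:
        raise ValueError("need >= 10 features with df >= 1 to estimate the prior")
    if np.all(s_sq == 0):
        raise ValueError("all residual variances are zero; nothing to moderate")
    positive = s_sq > 0
    if not positive.all():
        log.warning("estimate_prior: dropping %d zero variances", int((~positive).sum()))
        s_sq, df = s_sq[positive], df[positive]
    if np.allclose(s_sq, s_sq[0], rtol=1e-12, atol=0):
        return ModerationPrior(d0=np.inf, s0_sq=float(s_sq[0]))
    z = np.log(s_sq)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return ModerationPrior(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    half_d0 = _trigamma_inverse(e_var)
    s0_sq = np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0))
    return ModerationPrior(d0=2.0 * half_d0, s0_sq=float(s0_sq))


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------

class DiffResults:
    """Differential-test results for one contrast or model fit.

    ``table`` has one row per (feature, contrast) with columns
    ``feature_id, contrast, log2FC, t, df, p, adj_p, n_a, n_b``.
    """

    def __init__(self, table: pd.DataFrame, prior: ModerationPrior | None = None,
                 skipped: list[str] | None = None):
        self.table = table.reset_index(drop=True)
        self.prior = prior
        self.skipped = skipped or []
        if len(self.table):
            bad = ~((self.table["p"] > 0) & (self.table["p"] <= 1))
            if bad.any():
                raise ValueError("p-values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.table)

    def significant(self, adj_p_max: float = 0.05, lfc_min: float = 0.0) -> pd.DataFrame:
        t = self.table
        return t[(t["adj_p"] <= adj_p_max) & (t["log2FC"].abs() >= lfc_min)]

    def counts(self, adj_p_max: float = 0.05, lfc_min: float = 0.0) -> tuple[int, int]:
        """(n_upregulated, n_downregulated) at the given thresholds."""
        sig = self.significant(adj_p_max, lfc_min)
        return int((sig["log2FC"] > 0).sum()), int((sig["log2FC"] < 0).sum())

    def summary(self, adj_p_max: float = 0.05, lfc_min: float = 0.0) -> str:
        up, down = self.counts(adj_p_max, lfc_min)
        lines = [
            "Differential results",
            "=" * 60,
            f"features tested : {len(self.table)}",
            f"contrasts       : {sorted(self.table['contrast'].unique())}",
            f"prior           : d0={getattr(self.prior, 'd0', None)}, "
            f"s0_sq={getattr(self.prior, 's0_sq', None)}",
            f"significant     : {up} up / {down} down "
            f"(adj p <= {adj_p_max}, |log2FC| >= {lfc_min})",
            f"skipped features: {len(self.skipped)}",
            "=" * 60,
        ]
        top = self.table.nsmallest(min(10, len(self.table)), "p")
        lines.append(top.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Moderated two-group test
# ---------------------------------------------------------------------------

def _group_stats(block: np.ndarray):
    n = np.sum(~np.isnan(block), axis=1)
    sums = np.nansum(block, axis=1)
    mean = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    ss = np.nansum((block - mean[:, None]) ** 2, axis=1)
    return n, mean, ss


def moderated_two_group(
    m: AbundanceMatrix,
    group_a: str,
    group_b: str,
    prior: ModerationPrior | None = None,
) -> DiffResults:
    """Two-group (moderated) t-test of condition ``group_a`` vs ``group_b``.

    log2FC = mean(A) - mean(B) on log2 data; with a prior, the pooled
    variance is squeezed toward ``s0_sq`` and the t statistic gains ``d0``
    degrees of freedom.  ``prior=None`` gives the ordinary Student test.
    Features with fewer than two observations in either group are skipped.
    """
    cols_a, cols_b = m.condition_columns(group_a), m.condition_columns(group_b)
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError(f"no channels for contrast {group_a} vs {group_b}")
    A = m.data[cols_a].to_numpy(dtype=float)
    B = m.data[cols_b].to_numpy(dtype=float)
    n_a, mean_a, ss_a = _group_stats(A)
    n_b, mean_b, ss_b = _group_stats(B)
    ok = (n_a >= 2) & (n_b >= 2)
    skipped = [f for f, o in zip(m.data.index, ok) if not o]
    if skipped:
        log.info("moderated_two_group: %d features skipped (<2 per group)", len(skipped))
    idx = np.where(ok)[0]
    n_a, mean_a, ss_a = n_a[idx], mean_a[idx], ss_a[idx]
    n_b, mean_b, ss_b = n_b[idx], mean_b[idx], ss_b[idx]
    df = (n_a + n_b - 2).astype(float)
    s_sq = (ss_a + ss_b) / df
    lfc = mean_a - mean_b
    if prior is None:
        s_tilde_sq, total_df = s_sq, df
    else:
        s_tilde_sq = prior.squeeze(s_sq, df)
        total_df = df + prior.d0
    se = np.sqrt(s_tilde_sq * (1.0 / n_a + 1.0 / n_b))
    t = np.zeros_like(lfc)
    p = np.ones_like(lfc)
    nz = se > 0
    t[nz] = lfc[nz] / se[nz]
    p[nz] = 2.0 * stats.t.sf(np.abs(t[nz]), total_df[nz])
    exact = (~nz) & (lfc != 0)
    t[exact] = np.sign(lfc[exact]) * np.inf
    p[exact] = np.nextafter(0, 1)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    table = pd.DataFrame(
        {
            "feature_id": np.asarray(m.data.index)[idx],
            "contrast": f"{group_a} vs {group_b}",
            "log2FC": lfc,
            "t": t,
            "df": total_df,
            "p": p,
            "adj_p": bh_adjust(p) if len(p) else p,
            "n_a": n_a,
            "n_b": n_b,
        }
    )
    return DiffResults(table, prior=prior, skipped=skipped)


# ---------------------------------------------------------------------------
# Factorial model  ~ Nitrogen + Time + Nitrogen:Time
# ---------------------------------------------------------------------------

def _factorial_design(channels: pd.DataFrame, time_coding: str) -> tuple[np.ndarray, list[str], pd.Index]:
    bio = channels.index[
        channels["channel_class"].isin(("sample", "bridge")) & channels["condition"].notna()
    ]
    sub = channels.loc[bio]
    nitrogen = (sub["nitrogen"] == "low").astype(float).to_numpy()
    hours = sub["timepoint_h"].astype(float).to_numpy()
    if time_coding == "numeric":
        time = hours - 24.0
        X = np.column_stack([np.ones_like(time), nitrogen, time, nitrogen * time])
        names = ["Intercept", "Nitrogen", "Time", "Nitrogen:Time"]
    elif time_coding == "categorical":
        cols = [np.ones(len(sub)), nitrogen]
        names = ["Intercept", "Nitrogen"]
        for t in (48, 72):
            ind = (hours == t).astype(float)
            cols += [ind, nitrogen * ind]
            names += [f"Time{t}", f"Nitrogen:Time{t}"]
        X = np.column_stack(cols)
    else:
        raise ValueError(f"unknown time_coding {time_coding!r}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_columns(X, names)
        raise ValueError(f"rank-deficient factorial design; aliased columns: {aliased}")
    return X, names, bio


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    aliased, kept = [], np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            aliased.append(name)
        else:
            kept = cand
    return aliased


def fit_factorial(
    m: AbundanceMatrix,
    prior: ModerationPrior | None | str = "auto",
    time_coding: str = "numeric",
) -> DiffResults:
    """Per-feature OLS fit of ``~ Nitrogen + Time + Nitrogen:Time``.

    Nitrogen is coded 0 = high, 1 = low; time numeric in hours centered at
    24 h (a categorical coding is available).  Coefficient standard errors
    are moderated with a prior shared across features; ``prior="auto"``
    estimates it from this fit's residual variances, ``prior=None`` disables
    moderation.  One result row per non-intercept coefficient.
    """
    X_full, names, bio_cols = _factorial_design(m.channels, time_coding)
    Y = m.data[bio_cols].to_numpy(dtype=float)
    p_cols = X_full.shape[1]
    feats, betas, ses, s_sqs, dfs = [], [], [], [], []
    for i, feat in enumerate(m.data.index):
        y = Y[i]
        obs = ~np.isnan(y)
        X = X_full[obs]
        if obs.sum() < p_cols or np.linalg.matrix_rank(X) < p_cols:
            continue
        beta, rss, _, _ = np.linalg.lstsq(X, y[obs], rcond=None)
        resid = y[obs] - X @ beta
        rss = float(resid @ resid)
        if rss < 1e-16 * max(1.0, float(y[obs] @ y[obs])):
            rss = 0.0  # numerically exact fit
        df = int(obs.sum()) - p_cols
        s_sq = rss / df if df > 0 else np.nan
        xtx_inv = np.linalg.inv(X.T @ X)
        se_unit = np.sqrt(np.diag(xtx_inv))
        feats.append(feat)
        betas.append(beta)
        s_sqs.append(s_sq)
        dfs.append(df)
        ses.append(se_unit)
    if not feats:
        raise ValueError("no feature has enough observations for the factorial fit")
    betas = np.asarray(betas)
    se_unit = np.asarray(ses)
    s_sq = np.asarray(s_sqs)
    df = np.asarray(dfs, dtype=float)
    if prior == "auto":
        try:
            prior = estimate_prior(s_sq=s_sq, df=df)
        except ValueError:
            prior = None
    if prior is None:
        s_tilde_sq, total_df = s_sq, df
    else:
        s_tilde_sq = prior.squeeze(s_sq, df)
        total_df = df + prior.d0
    rows = []
    for j, name in enumerate(names):
        if name == "Intercept":
            continue
        beta_j = betas[:, j]
        se_j = se_unit[:, j] * np.sqrt(s_tilde_sq)
        t = np.zeros_like(beta_j)
        p = np.ones_like(beta_j)
        nz = se_j > 0
        t[nz] = beta_j[nz] / se_j[nz]
        p[nz] = 2.0 * stats.t.sf(np.abs(t[nz]), total_df[nz])
        exact = (~nz) & (np.abs(beta_j) > 1e-12)
        t[exact] = np.sign(beta_j[exact]) * np.inf
        p[exact] = np.nextafter(0, 1)
        p = np.clip(p, np.nextafter(0, 1), 1.0)
        rows.append(
            pd.DataFrame(
                {
                    "feature_id": feats,
                    "contrast": name,
                    "log2FC": beta_j,
                    "t": t,
                    "df": total_df,
                    "p": p,
                    "adj_p": bh_adjust(p),
                    "n_a": df.astype(int) + p_cols,
                    "n_b": 0,
                }
            )
        )
    return DiffResults(pd.concat(rows, ignore_index=True), prior=prior)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order of input preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Model classes
# ---------------------------------------------------------------------------

class ModeratedTTest:
    """Two-group differential model on a log2 abundance matrix.

    Parameters
    ----------
    m : AbundanceMatrix (log2)
    group_a, group_b : condition labels (e.g. ``"low_72h"``, ``"high_72h"``)
    moderate : bool
        Empirical-Bayes variance moderation (default True); the prior is
        estimated from the pooled within-group variances of the tested
        features.
    min_reps : replicate filter applied to the contrast's conditions.
    """

    def __init__(self, m: AbundanceMatrix, group_a: str, group_b: str,
                 moderate: bool = True, min_reps: int = 2):
        if m.scale != "log2":
            raise ValueError("differential tests run on log2 data")
        self.m = filter_min_reps(m, k=min_reps, conditions=[group_a, group_b])
        self.group_a, self.group_b = group_a, group_b
        self.moderate = moderate

    def _pooled_variances(self):
        A = self.m.data[self.m.condition_columns(self.group_a)].to_numpy(dtype=float)
        B = self.m.data[self.m.condition_columns(self.group_b)].to_numpy(dtype=float)
        n_a, _, ss_a = _group_stats(A)
        n_b, _, ss_b = _group_stats(B)
        ok = (n_a >= 2) & (n_b >= 2)
        df = (n_a + n_b - 2.0)[ok]
        return (ss_a + ss_b)[ok] / df, df

    def fit(self) -> DiffResults:
        prior = None
        if self.moderate:
            s_sq, df = self._pooled_variances()
            try:
                prior = estimate_prior(s_sq=s_sq, df=df)
            except ValueError as e:
                log.warning("falling back to ordinary t-test: %s", e)
        return moderated_two_group(self.m, self.group_a, self.group_b, prior)


class FactorialModel:
    """Factorial differential model ``~ Nitrogen + Time + Nitrogen:Time``."""

    def __init__(self, m: AbundanceMatrix, moderate: bool = True,
                 time_coding: str = "numeric", min_reps: int = 2):
        if m.scale != "log2":
            raise ValueError("differential tests run on log2 data")
        self.m = filter_min_reps(m, k=min_reps)
        self.moderate = moderate
        self.time_coding = time_coding

    def fit(self) -> DiffResults:
        return fit_factorial(self.m, prior="auto" if self.moderate else None,
                             time_coding=self.time_coding)
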