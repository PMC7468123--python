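"""Group-level inference on MST metrics.

Covariate-adjusted group comparisons (ANCOVA with age, sex and education),
Benjamini-Hochberg FDR control across the family of global measures,
Fisher-LSD-style pairwise post-hoc contrasts, medication-stratum contrasts,
and permutation-based max-statistic family-wise-error-corrected nodal tests.

The ANCOVA is an ordinary least-squares linear model with group indicator
columns plus covariates; effect F statistics use the drop-the-effect
(Type III) convention — SS_effect is the increase in residual sum of squares
when the effect's columns are removed from the full model — and effect sizes
are partial eta squared, SS_effect / (SS_effect + SS_error).  Adjusted group
means are model predictions at the sample covariate means.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GLOBAL_MEASURES = ("strength", "diameter_norm", "kappa", "leaf_fraction")

__all__ = [
    "GLOBAL_MEASURES",
    "AncovaResult",
    "PermutationResult",
    "fit_ancova",
    "posthoc_pairwise",
    "bh_fdr",
    "nodal_permutation_test",
    "medication_contrast",
    "run_group_analysis",
]


@dataclass
class AncovaResult:
    measure: str
    effect: str
    df_effect: int
    df_error: int
    F: float
    p: float
    partial_eta_sq: float
    adjusted_means: dict[str, tuple[float, float]] | None = None
    fdr_significant: bool | None = None


@dataclass(frozen=True)
class PermutationResult:
    node_id: str
    observed_stat: float
    p_fwe: float
    direction: int  # sign of (group A mean - group B mean)


def _encode_column(col: pd.Series, name: str) -> np.ndarray:
    """Numeric passthrough; dichotomous strings/bools become 0/1 indicators
    (levels sorted, the later level coded 1)."""
    if pd.api.types.is_bool_dtype(col):
        return col.to_numpy(dtype=float)
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    levels = sorted(col.astype(str).unique())
    if len(levels) > 2:
        raise ValueError(f"covariate {name!r} must be numeric or dichotomous")
    return (col.astype(str) == levels[-1]).to_numpy(dtype=float)


class _FittedModel:
    """OLS fit of measure ~ intercept + group dummies + covariates."""

    def __init__(self, table: pd.DataFrame, measure: str, group_factor: str,
                 covariates: Sequence[str]):
        if table[measure].isna().any():
            raise ValueError("missing values in outcome")
        self.levels = sorted(table[group_factor].astype(str).unique())
        if len(self.levels) < 2:
            raise ValueError("need at least 2 groups")
        counts = table[group_factor].astype(str).value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(f"groups with <2 subjects: {list(small.index)}")
        self.measure, self.group_factor = measure, group_factor
        self.covariates = list(covariates)
        self.y = table[measure].to_numpy(dtype=float)
        n = len(self.y)
        g = table[group_factor].astype(str).to_numpy()
        # group dummies, first level as reference
        self.dummies = np.column_stack(
            [(g == lev).astype(float) for lev in self.levels[1:]]
        ) if len(self.levels) > 1 else np.empty((n, 0))
        self.cov_cols = {
            c: _encode_column(table[c], c) for c in self.covariates
        }
        for c, v in self.cov_cols.items():
            if np.any(~np.isfinite(v)):
                raise ValueError(f"missing values in covariate {c!r}")
        blocks = [np.ones((n, 1)), self.dummies] + [
            v[:, None] for v in self.cov_cols.values()
        ]
        self.X = np.hstack(blocks)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("rank-deficient design matrix")
        self.n, self.p = self.X.shape
        self.df_error = self.n - self.p
        if self.df_error <= 0:
            raise ValueError("no residual degrees of freedom")
        self.beta, _, _, _ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ self.beta
        self.sse = float(resid @ resid)
        self.mse = self.sse / self.df_error
        self.xtx_inv = np.linalg.inv(self.X.T @ self.X)
        # column index ranges per effect
        k = 1 + self.dummies.shape[1]
        self.effect_cols: dict[str, list[int]] = {
            group_factor: list(range(1, k))
        }
        for i, c in enumerate(self.covariates):
            self.effect_cols[c] = [k + i]

    def drop_effect_ss(self, effect: str) -> tuple[float, int]:
        cols = self.effect_cols[effect]
        keep = [i for i in range(self.p) if i not in cols]
        xr = self.X[:, keep]
        beta_r, _, _, _ = np.linalg.lstsq(xr, self.y, rcond=None)
        resid = self.y - xr @ beta_r
        ss = float(resid @ resid) - self.sse
        return max(ss, 0.0), len(cols)

    def effect_f(self, effect: str) -> tuple[int, float, float, float]:
        ss, df_eff = self.drop_effect_ss(effect)
        f = (ss / df_eff) / self.mse if self.mse > 0 else np.inf
        p = float(stats.f.sf(f, df_eff, self.df_error))
        eta = ss / (ss + self.sse) if (ss + self.sse) > 0 else 0.0
        return df_eff, float(f), p, float(eta)

    def _group_row(self, level: str) -> np.ndarray:
        x = np.zeros(self.p)
        x[0] = 1.0
        if level != self.levels[0]:
            x[1 + self.levels[1:].index(level)] = 1.0
        k = 1 + self.dummies.shape[1]
        for i, c in enumerate(self.covariates):
            x[k + i] = self.cov_cols[c].mean()
        return x

    def adjusted_means(self) -> dict[str, tuple[float, float]]:
        out = {}
        for lev in self.levels:
            x = self._group_row(lev)
            mean = float(x @ self.beta)
            se = float(np.sqrt(x @ self.xtx_inv @ x * self.mse))
            out[lev] = (mean, se)
        return out

    def contrast(self, level_a: str, level_b: str) -> tuple[float, float, float, float]:
        """Adjusted-mean difference a-b, its SE, t and two-sided p."""
        c = self._group_row(level_a) - self._group_row(level_b)
        diff = float(c @ self.beta)
        se = float(np.sqrt(c @ self.xtx_inv @ c * self.mse))
        if se == 0:
            return diff, se, 0.0, 1.0
        t = diff / se
        p = float(2.0 * stats.t.sf(abs(t), self.df_error))
        return diff, se, t, p


def fit_ancova(
    table: pd.DataFrame,
    measure: str,
    group_factor: str = "group",
    covariates: Sequence[str] = ("age", "sex", "education"),
) -> list[AncovaResult]:
    """ANCOVA of one measure: F, p and partial eta squared for the group
    factor and each covariate, plus covariate-adjusted group means.

    Returns one :class:`AncovaResult` per effect, the group effect first
    (it carries the adjusted means)."""
    model = _FittedModel(table, measure, group_factor, covariates)
    results = []
    for effect in [group_factor] + list(covariates):
        df_eff, f, p, eta = model.effect_f(effect)
        results.append(
            AncovaResult(
                measure=measure,
                effect=effect,
                df_effect=df_eff,
                df_error=model.df_error,
                F=f,
                p=p,
                partial_eta_sq=eta,
                adjusted_means=model.adjusted_means()
                if effect == group_factor
                else None,
            )
        )
    return results


def posthoc_pairwise(
    table: pd.DataFrame,
    measure: str,
    group_factor: str = "group",
    covariates: Sequence[str] = ("age", "sex", "education"),
    method: str = "lsd",
) -> pd.DataFrame:
    """Model-based pairwise group contrasts.

    ``method="lsd"`` (Fisher's least significant difference) reports
    unadjusted t-test p values from the fitted ANCOVA model; ``"hsd"``
    applies the Tukey studentized-range correction instead.
    """
    if method not in ("lsd", "hsd"):
        raise ValueError("method must be 'lsd' or 'hsd'")
    model = _FittedModel(table, measure, group_factor, covariates)
    rows = []
    k = len(model.levels)
    for a, b in combinations(model.levels, 2):
        diff, se, t, p = model.contrast(a, b)
        if method == "hsd" and se > 0:
            p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k,
                                                 model.df_error))
        rows.append(
            {"measure": measure, "group_a": a, "group_b": b,
             "difference": diff, "se": se, "t": t, "p": p}
        )
    return pd.DataFrame(rows)


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags, in input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def nodal_permutation_test(
    nodal_values: pd.DataFrame | np.ndarray,
    labels: Sequence[str],
    n_perm: int = 10000,
    seed: int | np.random.SeedSequence = 0,
    node_ids: Sequence[str] | None = None,
) -> list[PermutationResult]:
    """Two-group nodal test with max-statistic family-wise error control.

    The observed statistic per node is the absolute difference of group
    means (two-sided).  The null is built by permuting group labels
    ``n_perm`` times; p_fwe(node) = (1 + #{permutations whose maximum
    null statistic across nodes >= observed(node)}) / (n_perm + 1).
    """
    if isinstance(nodal_values, pd.DataFrame):
        node_ids = list(nodal_values.columns) if node_ids is None else list(node_ids)
        x = nodal_values.to_numpy(dtype=float)
    else:
        x = np.asarray(nodal_values, dtype=float)
        if node_ids is None:
            node_ids = [f"n{i}" for i in range(x.shape[1])]
    labels = np.asarray([str(v) for v in labels])
    if len(labels) != x.shape[0]:
        raise ValueError("labels length must match number of subjects")
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    mask_a = labels == uniq[0]
    na, nb = int(mask_a.sum()), int((~mask_a).sum())
    if min(na, nb) < 2:
        raise ValueError("each group needs at least 2 subjects")
    signed_obs = x[mask_a].mean(axis=0) - x[~mask_a].mean(axis=0)
    obs = np.abs(signed_obs)

    rng = np.random.default_rng(seed)
    n = na + nb
    total = x.sum(axis=0)
    # permuted group-A membership as 0/1 matrix (n_perm, n)
    ranks = np.argsort(rng.random((n_perm, n)), axis=1)
    sel = np.zeros((n_perm, n))
    rows = np.repeat(np.arange(n_perm), na)
    sel[rows, ranks[:, :na].ravel()] = 1.0
    sum_a = sel @ x
    null = np.abs(sum_a / na - (total - sum_a) / nb)
    max_null = null.max(axis=1)
    exceed = (max_null[:, None] >= obs[None, :]).sum(axis=0)
    p_fwe = (1.0 + exceed) / (n_perm + 1.0)
    return [
        PermutationResult(
            node_id=str(node_ids[i]),
            observed_stat=float(obs[i]),
            p_fwe=float(p_fwe[i]),
            direction=int(np.sign(signed_obs[i])) if signed_obs[i] != 0 else 0,
        )
        for i in range(x.shape[1])
    ]


def medication_contrast(
    table: pd.DataFrame,
    measure: str,
    stratum_flag: str,
    covariates: Sequence[str] = ("age", "sex", "education"),
) -> AncovaResult:
    """ANCOVA contrasting two medication strata within one diagnostic group
    (e.g., BD with vs without lithium): the same model machinery as
    :func:`fit_ancova` with the stratum flag as the factor."""
    strata = table[stratum_flag].astype(str).unique()
    if len(strata) != 2:
        raise ValueError(
            f"stratum flag {stratum_flag!r} must have exactly 2 levels, "
            f"got {sorted(strata)}"
        )
    results = fit_ancova(table, measure, group_factor=stratum_flag,
                         covariates=covariates)
    return results[0]


def run_group_analysis(
    cohort_table: pd.DataFrame,
    measures: Sequence[str] = GLOBAL_MEASURES,
    group_factor: str = "group",
    covariates: Sequence[str] = ("age", "sex", "education"),
    q: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full global-measure analysis: per-measure ANCOVAs, BH-FDR across the
    measures' group-effect p values, and LSD post-hoc contrasts.

    Returns (effects table, post-hoc contrasts table)."""
    all_results: list[AncovaResult] = []
    group_results: list[AncovaResult] = []
    posthoc_frames = []
    for m in measures:
        res = fit_ancova(cohort_table, m, group_factor, covariates)
        group_results.append(res[0])
        all_results.extend(res)
        posthoc_frames.append(
            posthoc_pairwise(cohort_table, m, group_factor, covariates)
        )
    flags = bh_fdr([r.p for r in group_results], q=q)
    for r, flag in zip(group_results, flags):
        r.fdr_significant = bool(flag)

    rows = []
    for r in all_results:
        row = {
            "measure": r.measure, "effect": r.effect,
            "df_effect": r.df_effect, "df_error": r.df_error,
            "F": r.F, "p": r.p, "partial_eta_sq": r.partial_eta_sq,
            "fdr_significant": r.fdr_significant,
        }
        if r.adjusted_means:
            for lev, (mean, se) in r.adjusted_means.items():
                row[f"adj_mean_{lev}"] = mean
                row[f"adj_se_{lev}"] = se
        rows.append(row)
    return pd.DataFrame(rows), pd.concat(posthoc_frames, ignore_index=True)
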