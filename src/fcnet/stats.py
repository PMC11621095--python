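"""Covariate-adjusted two-sample inference on AUC network metrics.

Each per-subject metric AUC is regressed on a group indicator
(patient = 1, control = 0) plus the covariates age, sex, education and
mean framewise displacement; the reported statistic is the t of the group
coefficient (two-tailed). Global metrics are tested uncorrected at
p < 0.05; nodal metrics are Bonferroni-corrected over the 90 nodes within
each metric family.

Covariates are mean-centred before fitting; this improves conditioning and
leaves the group coefficient and its t unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import GLOBAL_METRICS, NODAL_METRICS

DEFAULT_COVARIATES = ("age", "sex", "education", "mean_fd")
N_NODES_DEFAULT = 90


@dataclass
class DesignMatrix:
    """Group-comparison design: intercept, group indicator, covariates."""

    matrix: np.ndarray
    column_names: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        X = np.asarray(self.matrix, dtype=float)
        if X.ndim != 2:
            raise ValueError("design must be 2-D")
        if len(self.column_names) != X.shape[1]:
            raise ValueError("column name count must match design width")
        if len(self.subject_ids) != X.shape[0]:
            raise ValueError("subject id count must match design rows")
        if "group" not in self.column_names:
            raise ValueError("design must contain a 'group' column")
        g = X[:, self.column_names.index("group")]
        if not np.isin(g, (0.0, 1.0)).all():
            raise ValueError("group column must be binary 0/1 (patient = 1)")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        self.matrix = X

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def df_resid(self) -> int:
        return self.matrix.shape[0] - self.matrix.shape[1]

    @property
    def group_index(self) -> int:
        return self.column_names.index("group")


def build_design(
    manifest: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> DesignMatrix:
    """Design from a subject manifest with ``group`` plus covariate columns.

    ``group`` may be the strings patient/control or 0/1. Covariate columns
    are mean-centred.
    """
    g = manifest["group"]
    if g.dtype == object:
        group = (g == "patient").astype(float).values
    else:
        group = g.astype(float).values
    cols = [np.ones(len(manifest)), group]
    names = ["intercept", "group"]
    for c in covariates:
        if c not in manifest.columns:
            raise ValueError(f"covariate column {c!r} missing from manifest")
        x = manifest[c].astype(float).values
        cols.append(x - x.mean())
        names.append(c)
    return DesignMatrix(
        np.column_stack(cols), names, [str(s) for s in manifest["subject_id"]]
    )


@dataclass
class GroupTestResult:
    metric_name: str
    node: str
    t_value: float
    p_value: float
    df: int
    significant: bool
    correction: str = "none"


def ols_t(
    y: np.ndarray, X: np.ndarray, coef_index: int
) -> tuple[float, float, int]:
    """(t, two-tailed p, df) for one coefficient of an OLS fit.

    Degenerate outcomes (zero residual variance or zero coefficient
    variance) return t = 0, p = 1 with a warning rather than NaN.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValueError("not enough subjects for the requested design")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    rss = float(resid @ resid)
    denom = rss / df * xtx_inv[coef_index, coef_index]
    if denom <= 0 or not np.isfinite(denom):
        warnings.warn(
            "degenerate outcome (zero residual variance); reporting t=0, p=1",
            stacklevel=2,
        )
        return 0.0, 1.0, df
    t = float(beta[coef_index] / np.sqrt(denom))
    pval = float(2.0 * sps.t.sf(abs(t), df))
    return t, pval, df


def glm_group_t(
    auc_vector: np.ndarray,
    design: DesignMatrix,
    metric_name: str = "",
    node: str = "global",
    alpha: float = 0.05,
) -> GroupTestResult:
    """Group-difference t-test on one AUC vector, adjusting for covariates."""
    y = np.asarray(auc_vector, dtype=float)
    if y.shape[0] != design.n_subjects:
        raise ValueError("AUC vector length does not match design rows")
    if np.any(~np.isfinite(y)):
        raise ValueError("AUC vector contains missing values")
    if np.ptp(y) == 0:
        warnings.warn(
            f"constant AUC for {metric_name}/{node}; test degenerate (p = 1)",
            stacklevel=2,
        )
        return GroupTestResult(metric_name, node, 0.0, 1.0, design.df_resid, False)
    t, p, df = ols_t(y, design.matrix, design.group_index)
    return GroupTestResult(metric_name, node, t, p, df, p < alpha)


def _auc_vector(
    auc_table: pd.DataFrame, design: DesignMatrix, metric: str, node: str
) -> np.ndarray:
    sub = auc_table[
        (auc_table["metric_name"] == metric) & (auc_table["node"] == node)
    ].set_index("subject_id")["auc"]
    try:
        return sub.loc[design.subject_ids].values
    except KeyError as exc:
        raise ValueError(
            f"AUC table is missing subjects for metric {metric!r}, node {node!r}"
        ) from exc


def test_global(
    auc_table: pd.DataFrame,
    design: DesignMatrix,
    alpha: float = 0.05,
) -> list[GroupTestResult]:
    """Uncorrected group tests of the seven global metric AUCs."""
    present = set(
        auc_table.loc[auc_table["node"] == "global", "metric_name"]
    )
    missing = [m for m in GLOBAL_METRICS if m not in present]
    if missing:
        raise ValueError(f"global metrics missing from AUC table: {missing}")
    return [
        glm_group_t(
            _auc_vector(auc_table, design, m, "global"), design, m, "global", alpha
        )
        for m in GLOBAL_METRICS
    ]


def test_nodal(
    auc_table: pd.DataFrame,
    design: DesignMatrix,
    alpha: float = 0.05,
    metrics: tuple[str, ...] = NODAL_METRICS,
    family_size: int | None = None,
) -> list[GroupTestResult]:
    """Per-node group tests, Bonferroni-corrected within each metric.

    The correction family defaults to the number of nodes tested for that
    metric (90), i.e. nodes within one metric form one family.
    """
    results: list[GroupTestResult] = []
    for metric in metrics:
        nodes = list(
            auc_table.loc[auc_table["metric_name"] == metric, "node"].unique()
        )
        if not nodes:
            raise ValueError(f"no nodal AUCs for metric {metric!r}")
        m = family_size or len(nodes)
        for node in nodes:
            res = glm_group_t(
                _auc_vector(auc_table, design, metric, node),
                design,
                metric,
                node,
                alpha,
            )
            res.significant = res.p_value < alpha / m
            res.correction = "bonferroni"
            results.append(res)
    return results


def results_table(results: list[GroupTestResult], family: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": family,
                "metric": r.metric_name,
                "node": r.node,
                "t": r.t_value,
                "p": r.p_value,
                "df": r.df,
                "significant": r.significant,
                "correction": r.correction,
            }
            for r in results
        ]
    )
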