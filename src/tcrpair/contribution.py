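"""Feature-contribution analysis: OLS of task AUC on configuration indicators.

Each evaluated feature configuration is represented as a one-hot indicator
vector over the optional features -- TCRalpha, V&J genes (a single
variable, since V and J toggle together), MHC, and T-cell type -- and the
observed AUCs are regressed on those indicators by ordinary least squares.
The always-present TCRbeta chain has no indicator: its contribution is the
fitted intercept minus 0.5, the AUC of a random predictor. For regressions
pooling the TPP tasks, task-type indicators are added with TPP-I as the
reference level absorbed into the intercept.

Uncertainty is reported as empirical 10/25/75/90 percentiles of the
coefficients over independent learning realizations (no significance
testing beyond that).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

FEATURE_VARS = ("alpha", "vj", "mhc", "t_cell_type")
TASK_VARS = ("TPP-II", "TPP-III")  # TPP-I is the reference level
PERCENTILES = (10, 25, 75, 90)


class SingularDesignError(ValueError):
    """The configuration design matrix is rank deficient."""


@dataclass
class ContributionReport:
    """Per-feature OLS coefficients, the derived beta-chain contribution,
    and (after summarization) per-variable percentiles over realizations."""

    coefficients: dict[str, float]
    beta_chain_contribution: float
    intercept: float
    reference_task: str = "TPP-I"
    percentiles: dict[str, dict[int, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variable": "beta_chain", "coefficient": self.beta_chain_contribution}]
        rows += [{"variable": k, "coefficient": v} for k, v in self.coefficients.items()]
        df = pd.DataFrame(rows)
        for p in PERCENTILES:
            df[f"p{p}"] = [self.percentiles.get(r["variable"], {}).get(p, np.nan)
                           for r in rows]
        return df


def _config_indicators(config) -> dict[str, float]:
    return {"alpha": float(config.use_alpha), "vj": float(config.use_vj),
            "mhc": float(config.use_mhc), "t_cell_type": float(config.use_t_cell_type)}


def build_design_matrix(results, include_task_indicators: bool = False
                        ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """One-hot design over feature (and optionally task) indicators.

    Columns are ``[alpha, vj, mhc, t_cell_type, (TPP-II, TPP-III,) const]``;
    the response is the AUC of each defined :class:`TaskResult`. Raises
    :class:`SingularDesignError` when the resulting design is rank
    deficient, naming the offending columns.
    """
    rows, y = [], []
    for r in results:
        if not r.defined:
            continue
        ind = _config_indicators(r.config)
        row = [ind[v] for v in FEATURE_VARS]
        if include_task_indicators:
            row += [1.0 if r.task.kind == t else 0.0 for t in TASK_VARS]
        row.append(1.0)
        rows.append(row)
        y.append(r.auc)
    if len({tuple(r) for r in rows}) < 2:
        raise SingularDesignError("need at least 2 distinct configurations")
    X = np.array(rows)
    y = np.array(y)
    names = list(FEATURE_VARS) + (list(TASK_VARS) if include_task_indicators else [])
    names.append("const")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by testing each column's removal
        collinear = [names[j] for j in range(X.shape[1])
                     if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {collinear}")
    return X, y, names


def fit_contribution(X: np.ndarray, y: np.ndarray, names: list[str]
                     ) -> ContributionReport:
    """OLS fit; the beta-chain contribution is the intercept minus 0.5."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    fit = sm.OLS(y, X).fit()
    coef = dict(zip(names, fit.params))
    intercept = coef.pop("const")
    return ContributionReport(coefficients=coef,
                              beta_chain_contribution=intercept - 0.5,
                              intercept=intercept)


def fit_contribution_from_results(results, include_task_indicators: bool = False
                                  ) -> ContributionReport:
    X, y, names = build_design_matrix(results, include_task_indicators)
    return fit_contribution(X, y, names)


def average_reports(a: ContributionReport, b: ContributionReport
                    ) -> ContributionReport:
    """Average two fitted reports variable-by-variable.

    Used to combine acceptor-based and autoencoder-based model results into
    a single reported contribution per feature.
    """
    if set(a.coefficients) != set(b.coefficients):
        raise ValueError("reports cover different variables")
    coef = {k: (a.coefficients[k] + b.coefficients[k]) / 2.0 for k in a.coefficients}
    return ContributionReport(
        coefficients=coef,
        beta_chain_contribution=(a.beta_chain_contribution
                                 + b.beta_chain_contribution) / 2.0,
        intercept=(a.intercept + b.intercept) / 2.0)


def summarize_percentiles(reports: list[ContributionReport]) -> ContributionReport:
    """Empirical 10/25/75/90 percentiles per variable over realizations.

    Quantiles use linear interpolation between order statistics. The central
    coefficients of the returned report are the per-variable means.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 realizations to summarize")
    variables = {"beta_chain": [r.beta_chain_contribution for r in reports]}
    for k in reports[0].coefficients:
        variables[k] = [r.coefficients[k] for r in reports]
    percentiles = {
        v: {p: float(np.percentile(vals, p)) for p in PERCENTILES}
        for v, vals in variables.items()
    }
    mean_coef = {k: float(np.mean(v)) for k, v in variables.items() if k != "beta_chain"}
    return ContributionReport(
        coefficients=mean_coef,
        beta_chain_contribution=float(np.mean(variables["beta_chain"])),
        intercept=float(np.mean(variables["beta_chain"])) + 0.5,
        percentiles=percentiles)


def contribution_boxplot(summary: ContributionReport, path) -> None:
    """Box-style figure of per-variable coefficient distributions.

    Boxes span the 25th-75th percentiles, whiskers the 10th-90th.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    variables = ["beta_chain"] + [k for k in summary.coefficients]
    fig, ax = plt.subplots(figsize=(1.2 * len(variables) + 2, 4))
    for i, v in enumerate(variables):
        p = summary.percentiles.get(v, {})
        center = (summary.beta_chain_contribution if v == "beta_chain"
                  else summary.coefficients[v])
        if p:
            ax.add_patch(plt.Rectangle((i - 0.25, p[25]), 0.5, p[75] - p[25],
                                       fill=False))
            ax.plot([i, i], [p[10], p[90]], "k-", lw=1)
        ax.plot([i - 0.25, i + 0.25], [center, center], "r-", lw=2)
    ax.set_xticks(range(len(variables)))
    ax.set_xticklabels(variables, rotation=30, ha="right")
    ax.set_ylabel("contribution to AUC")
    ax.axhline(0.0, color="grey", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
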