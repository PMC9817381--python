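"""OLS regression of questionnaire scores on the 8 SARIMA weight features.

Each of the five scales (BDI-II and the four BADS subscales) is regressed
separately on the same zero-substituted feature matrix with an intercept.
Features are deliberately not standardized: the published weights are only
interpretable on the raw coefficient scale.  Reported per scale: slopes with
two-sided t p-values, R², the overall F-test with (8, n-9) degrees of
freedom, variance inflation factors for the 8 predictors, and centered
partial residuals for plotting.

No multiple-testing correction is applied across scales by default (this
mirrors the analysis design); Bonferroni or Holm adjustment of the five
overall F p-values can be requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .selection import FEATURE_NAMES

__all__ = [
    "RegressionReport",
    "AssociationResults",
    "FeatureRegression",
    "fit_ols",
    "compute_vif",
    "partial_residuals",
    "RankDeficiencyError",
]

SIGNIFICANCE_LEVEL = 0.05

_DISPLAY = {
    "ar1": "AR(1)", "ar2": "AR(2)", "ar3": "AR(3)",
    "ma1": "MA(1)", "ma2": "MA(2)", "ma3": "MA(3)",
    "sar1": "sAR(1)", "sma1": "sMA(1)",
}


class RankDeficiencyError(ValueError):
    """Raised when the design matrix (with intercept) is not full rank."""


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    """Full-rank check that names the offending columns."""
    Xc = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(Xc)
    if rank == Xc.shape[1]:
        return
    bad = []
    # a column is implicated if dropping it restores full rank relative to size
    for j in range(X.shape[1]):
        sub = np.delete(Xc, j + 1, axis=1)
        if np.linalg.matrix_rank(sub) == rank:
            bad.append(names[j])
    raise RankDeficiencyError(
        f"design matrix is rank deficient (rank {rank} < {Xc.shape[1]}); "
        f"collinear or constant columns: {bad or names}"
    )


@dataclass
class RegressionReport:
    """OLS fit of one questionnaire scale on the 8 weight features."""

    scale_name: str
    names: list[str]
    coefficients: np.ndarray       # intercept first, then the 8 slopes
    standard_errors: np.ndarray
    coefficient_p_values: np.ndarray
    r2: float
    f_stat: float
    f_df: tuple[int, int]
    f_p_value: float
    vifs: np.ndarray
    n: int
    residuals: np.ndarray
    X: np.ndarray = field(repr=False)

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.coefficients[1:]

    @property
    def significant(self) -> bool:
        return self.f_p_value < SIGNIFICANCE_LEVEL

    def partial_residuals(self, predictor) -> np.ndarray:
        """Centered partial-residual pairs for one predictor (index or name)."""
        return partial_residuals(self, predictor)

    def summary(self) -> str:
        lines = [
            f"{self.scale_name}: R^2 = {self.r2:.2f}, "
            f"F({self.f_df[0]},{self.f_df[1]}) = {self.f_stat:.2f}, "
            f"p = {self.f_p_value:.3f}{' *' if self.significant else ''}",
        ]
        for j, name in enumerate(self.names):
            star = " *" if self.coefficient_p_values[j + 1] < SIGNIFICANCE_LEVEL else ""
            lines.append(
                f"  {_DISPLAY.get(name, name):>7s} = {self.coefficients[j + 1]: .2f} "
                f"(se {self.standard_errors[j + 1]:.2f}, "
                f"p {self.coefficient_p_values[j + 1]:.3f}){star}"
            )
        return "\n".join(lines)


def fit_ols(features, scores, scale_name: str = "", names=None) -> RegressionReport:
    """Least-squares fit of one score vector on the n x 8 feature matrix."""
    X = np.asarray(getattr(features, "values", features), dtype=float)
    y = np.asarray(getattr(scores, "values", scores), dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("features must be a 2-d matrix")
    n, k = X.shape
    names = list(names) if names is not None else list(FEATURE_NAMES[:k])
    if len(y) != n:
        raise ValueError("scores length does not match features")
    if n <= k + 1:
        raise ValueError(f"need n > {k + 1} participants, got {n}")
    _check_rank(X, names)
    Xc = np.column_stack([np.ones(n), X])
    beta, _, _, _ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    df_resid = n - k - 1
    sigma2 = float(resid @ resid) / df_resid
    XtX_inv = np.linalg.inv(Xc.T @ Xc)
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(resid @ resid)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    f_stat = (r2 / k) / ((1.0 - r2) / df_resid) if r2 < 1.0 else np.inf
    f_p = float(stats.f.sf(f_stat, k, df_resid)) if np.isfinite(f_stat) else 0.0
    vifs = compute_vif(X, names)
    return RegressionReport(
        scale_name=scale_name,
        names=names,
        coefficients=beta,
        standard_errors=se,
        coefficient_p_values=pvals,
        r2=r2,
        f_stat=float(f_stat),
        f_df=(k, df_resid),
        f_p_value=f_p,
        vifs=vifs,
        n=n,
        residuals=resid,
        X=X,
    )


def compute_vif(features, names=None) -> np.ndarray:
    """VIF_j = 1 / (1 - R²_j), regressing column j on the others + intercept."""
    X = np.asarray(getattr(features, "values", features), dtype=float)
    n, k = X.shape
    names = list(names) if names is not None else list(FEATURE_NAMES[:k])
    vifs = np.empty(k)
    for j in range(k):
        xj = X[:, j]
        if np.allclose(xj, xj[0]):
            raise ValueError(f"predictor {names[j]!r} is constant; VIF undefined")
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ beta
        ss_tot = float(((xj - xj.mean()) ** 2).sum())
        r2j = 1.0 - float(resid @ resid) / ss_tot
        vifs[j] = np.inf if r2j >= 1.0 else 1.0 / (1.0 - r2j)
    return vifs


def partial_residuals(report: RegressionReport, predictor) -> np.ndarray:
    """Centered partial-residual pairs (x_ij - x̄_j, e_i + β_j (x_ij - x̄_j)).

    The OLS slope through the returned pairs equals the fitted β_j, so the
    plot shows the predictor's adjusted effect at the raw coefficient scale.
    """
    if isinstance(predictor, str):
        try:
            j = report.names.index(predictor)
        except ValueError:
            raise ValueError(f"unknown predictor {predictor!r}") from None
    else:
        j = int(predictor)
        if not 0 <= j < len(report.names):
            raise ValueError(f"predictor index {j} out of range")
    x = report.X[:, j]
    xc = x - x.mean()
    pr = report.residuals + report.slopes[j] * xc
    return np.column_stack([xc, pr])


@dataclass
class AssociationResults:
    """Per-scale regression reports plus the combined summary table."""

    reports: dict[str, RegressionReport]

    def __getitem__(self, scale: str) -> RegressionReport:
        return self.reports[scale]

    def adjusted_f_p_values(self, method: str = "bonferroni") -> dict[str, float]:
        """Optional multiple-testing adjustment of the five overall F tests."""
        scales = list(self.reports)
        p = np.array([self.reports[s].f_p_value for s in scales])
        k = len(p)
        if method == "bonferroni":
            adj = np.minimum(p * k, 1.0)
        elif method == "holm":
            order = np.argsort(p)
            adj = np.empty(k)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (k - rank) * p[idx])
                adj[idx] = min(running, 1.0)
        else:
            raise ValueError("method must be 'bonferroni' or 'holm'")
        return dict(zip(scales, map(float, adj)))

    def summary_table(self) -> pd.DataFrame:
        """Rows AR(1)..sMA(1), R², F; one column per scale (report style)."""
        scales = list(self.reports)
        names = self.reports[scales[0]].names
        index = [_DISPLAY.get(n, n) for n in names] + ["R2", "F"]
        data = {}
        for s in scales:
            rep = self.reports[s]
            col = [round(float(b), 2) for b in rep.slopes]
            col += [round(rep.r2, 2), round(rep.f_stat, 2)]
            data[s] = col
        return pd.DataFrame(data, index=index)

    def summary(self) -> str:
        return "\n\n".join(rep.summary() for rep in self.reports.values())


class FeatureRegression:
    """Model object tying the feature matrix to the questionnaire scores.

    Parameters
    ----------
    features : DataFrame
        One row per participant with the 8 feature columns (ar1..sma1);
        a participant_id column, if present, is used for alignment.
    scores : DataFrame
        One row per participant with one column per scale.
    """

    def __init__(self, features: pd.DataFrame, scores: pd.DataFrame,
                 drop_constant: bool = False):
        features = features.copy()
        scores = scores.copy()
        if "participant_id" in features.columns and "participant_id" in scores.columns:
            features = features.set_index("participant_id")
            scores = scores.set_index("participant_id")
            scores = scores.loc[features.index]
        missing = [c for c in FEATURE_NAMES if c not in features.columns]
        if missing:
            raise ValueError(f"features frame is missing columns {missing}")
        names = list(FEATURE_NAMES)
        self.dropped: list[str] = []
        if drop_constant:
            for c in FEATURE_NAMES:
                col = features[c].to_numpy(dtype=float)
                if np.allclose(col, col[0]):
                    self.dropped.append(c)
            names = [c for c in names if c not in self.dropped]
            if not names:
                raise ValueError("all feature columns are constant")
        self.names = names
        self.features = features[names]
        self.scale_names = [c for c in scores.columns if c != "participant_id"]
        if not self.scale_names:
            raise ValueError("scores frame has no scale columns")
        self.scores = scores[self.scale_names]

    @classmethod
    def from_csv(cls, features_csv, scores_csv) -> "FeatureRegression":
        return cls(pd.read_csv(features_csv), pd.read_csv(scores_csv))

    def fit(self) -> AssociationResults:
        X = self.features.to_numpy(dtype=float)
        reports = {
            scale: fit_ols(X, self.scores[scale].to_numpy(dtype=float),
                           scale_name=scale, names=self.names)
            for scale in self.scale_names
        }
        return AssociationResults(reports)
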