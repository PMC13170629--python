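"""ROI-wise white-matter volume models, group comparisons, and FDR.

The volume model regresses each WM ROI's volume on log NF-L with age and
estimated total intracranial volume (eTIV) as covariates, within one
diagnostic group, and corrects the 73 Wald p-values with the
Benjamini-Hochberg step-up procedure. Group comparisons use Wilcoxon
rank-sum tests with continuity correction (effect size r = |z| / sqrt(n))
for demographic and clinical variables and a Welch t-test for log NF-L.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["VolumeModel", "VolumeResults", "fit_volume_models",
           "GroupComparisonResult", "compare_groups",
           "partial_correlation", "bh_fdr"]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _ols_with_stats(y: np.ndarray, X: np.ndarray):
    """QR-based OLS: coefficients, standard errors, two-sided p-values.

    QR keeps the fit stable when columns differ in scale by orders of
    magnitude (eTIV in mm^3 next to an intercept).
    """
    n, k = X.shape
    Q, R = np.linalg.qr(X)
    beta = scipy.linalg.solve_triangular(R, Q.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2 = resid @ resid / df
    r_inv = scipy.linalg.solve_triangular(R, np.eye(k))
    xtx_inv_diag = (r_inv**2).sum(axis=1)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv_diag, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    return beta, se, t, p, df


@dataclass
class VolumeResults:
    """Per-ROI association of volume with log NF-L."""
    table: pd.DataFrame       # index ROI; beta, std_beta, p, q
    group: str
    n: int
    covariates: list[str]
    params: dict = field(default_factory=dict)

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        out = self.table.copy()
        out["significant"] = np.where(out["q"] < 0.01, "**",
                                      np.where(out["q"] < alpha, "*", ""))
        return out

    @property
    def significant_rois(self) -> list[str]:
        return list(self.table.index[self.table["q"] < 0.05])


class VolumeModel:
    """ROI-wise OLS of WM volume on log NF-L + age + eTIV within a group.

    Parameters
    ----------
    volumes : DataFrame (participants x 73 ROI columns, mm^3)
    cohort : participant table with group, nfl/log_nfl, age, etiv
    group : {"AN", "HC"}
    log_nfl : bool
        Model NF-L on the log scale (default); raw scale available.
    """

    def __init__(self, volumes: pd.DataFrame, cohort: pd.DataFrame,
                 group: str = "AN", log_nfl: bool = True,
                 expected_rois: list[str] | None = None):
        if expected_rois is not None:
            missing = [r for r in expected_rois if r not in volumes.columns]
            if missing:
                raise ValueError(f"missing ROI columns: {missing}")
        sub = cohort[cohort["group"] == group]
        if len(sub) < 6:
            raise ValueError(f"need >= 6 participants in group {group!r}")
        self.group = group
        self.log_nfl = log_nfl
        self.cohort = sub.set_index("id")
        self.volumes = volumes.loc[self.cohort.index]

    def fit(self) -> VolumeResults:
        c = self.cohort
        x = np.log(c["nfl"].to_numpy()) if self.log_nfl \
            else c["nfl"].to_numpy()
        X = np.column_stack([np.ones(len(c)), x,
                             c["age"].to_numpy(), c["etiv"].to_numpy()])
        rows = {}
        for roi in self.volumes.columns:
            y = self.volumes[roi].to_numpy(float)
            beta, se, t, p, df = _ols_with_stats(y, X)
            sd_y = y.std(ddof=1)
            std_beta = beta[1] * x.std(ddof=1) / sd_y if sd_y > 0 else 0.0
            rows[roi] = dict(beta=beta[1], std_beta=std_beta, t=t[1],
                             p=p[1])
        table = pd.DataFrame(rows).T
        table["q"] = bh_fdr(table["p"].to_numpy())
        logger.info("volume models: group=%s n=%d tests=%d (BH-FDR)",
                    self.group, len(c), len(table))
        return VolumeResults(table, self.group, len(c),
                             ["age", "etiv"],
                             params=dict(log_nfl=self.log_nfl,
                                         n_tests=len(table)))


def fit_volume_models(volumes, cohort, group="AN", log_nfl=True,
                      expected_rois=None) -> VolumeResults:
    """Functional wrapper over :class:`VolumeModel` (spec surface)."""
    return VolumeModel(volumes, cohort, group, log_nfl, expected_rois).fit()


@dataclass
class GroupComparisonResult:
    table: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        return self.table


def _wilcoxon_ranksum(x, y, alternative: str):
    """Rank-sum W (first sample's U, the R convention), z, p with
    continuity correction and tie correction."""
    res = scipy.stats.mannwhitneyu(x, y, alternative=alternative,
                                   method="asymptotic")
    w = float(res.statistic)
    # recover |z| from the reported p
    p = float(res.pvalue)
    tail = p / 2 if alternative == "two-sided" else p
    z = scipy.stats.norm.isf(min(max(tail, 1e-300), 1.0))
    return w, abs(z), p


def compare_groups(cohort: pd.DataFrame,
                   variables: list[str] | None = None,
                   sidedness: dict[str, str] | None = None,
                   welch_vars: tuple[str, ...] = ("log_nfl",),
                   ) -> GroupComparisonResult:
    """AN vs HC group comparisons mirroring the demographics table.

    Wilcoxon rank-sum tests (continuity-corrected) for demographic and
    clinical variables, Welch t-tests for variables in ``welch_vars``
    (log NF-L by default). ``sidedness`` maps variable name to
    {"two-sided", "less", "greater"} (AN relative to HC); the default is
    one-sided per prior hypothesis except age, which is two-sided.
    Medians and IQRs are reported on the raw scale; q is BH-FDR over the
    comparisons run.
    """
    an = cohort[cohort["group"] == "AN"]
    hc = cohort[cohort["group"] == "HC"]
    if len(an) == 0 or len(hc) == 0:
        raise ValueError("both groups must be non-empty")
    if variables is None:
        variables = ["age", "bmi", "bmi_sds", "edi_dt", "edi_bd", "bdi2",
                     "log_nfl", "leptin"]
        variables = [v for v in variables if v in cohort.columns]
    default_sides = {"age": "two-sided", "bmi": "less", "bmi_sds": "less",
                     "edi_dt": "greater", "edi_bd": "greater",
                     "bdi2": "greater", "log_nfl": "greater",
                     "leptin": "less"}
    sidedness = {**default_sides, **(sidedness or {})}

    rows = []
    for var in variables:
        xa = an[var].dropna().to_numpy(float)
        xh = hc[var].dropna().to_numpy(float)
        alt = sidedness.get(var, "two-sided")
        n = xa.size + xh.size
        if np.ptp(np.concatenate([xa, xh])) == 0:
            warnings.warn(f"variable {var!r} has no variation; p set to 1")
            rows.append(dict(variable=var, test="wilcoxon", statistic=np.nan,
                             p=1.0, r=0.0,
                             an_median=np.median(xa), hc_median=np.median(xh),
                             an_iqr_lo=np.percentile(xa, 25),
                             an_iqr_hi=np.percentile(xa, 75),
                             hc_iqr_lo=np.percentile(xh, 25),
                             hc_iqr_hi=np.percentile(xh, 75)))
            continue
        if var in welch_vars:
            res = scipy.stats.ttest_ind(xa, xh, equal_var=False,
                                        alternative=alt)
            t, p = float(res.statistic), float(res.pvalue)
            nu = float(getattr(res, "df", n - 2))
            r = float(np.sqrt(t * t / (t * t + nu)))
            stat, test = t, "welch_t"
        else:
            stat, z, p = _wilcoxon_ranksum(xa, xh, alt)
            r = float(z / np.sqrt(n))
            test = "wilcoxon"
        rows.append(dict(variable=var, test=test, statistic=stat, p=float(p),
                         r=r,
                         an_median=np.median(xa), hc_median=np.median(xh),
                         an_iqr_lo=np.percentile(xa, 25),
                         an_iqr_hi=np.percentile(xa, 75),
                         hc_iqr_lo=np.percentile(xh, 25),
                         hc_iqr_hi=np.percentile(xh, 75)))
    table = pd.DataFrame(rows).set_index("variable")
    table["q"] = bh_fdr(table["p"].to_numpy())
    return GroupComparisonResult(table)


def partial_correlation(x, y, control) -> tuple[float, float]:
    """Correlation of x and y after removing a control variable.

    Both x and y are residualized on (intercept + control); the p-value
    uses the t transform with df = n - 3.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    control = np.asarray(control, float)
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(control))
    x, y, control = x[ok], y[ok], control[ok]
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 complete triples")
    Z = np.column_stack([np.ones(n), control])
    Q, _ = np.linalg.qr(Z)
    rx = x - Q @ (Q.T @ x)
    ry = y - Q @ (Q.T @ y)
    rx2, ry2 = rx @ rx, ry @ ry
    if rx2 <= 1e-20 * max(x @ x, 1.0) or ry2 <= 1e-20 * max(y @ y, 1.0):
        raise ValueError("zero residual variance; partial correlation "
                         "undefined")
    denom = np.sqrt(rx2 * ry2)
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - 3
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * scipy.stats.t.sf(abs(t), df))
    return r, p
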