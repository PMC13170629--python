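"""Component-level clinical statistics.

Once the NBS has identified components whose FA tracks NF-L, each
participant is summarized by the mean connectivity over a component's edge
set. This module relates those summaries to clinical variables with
robust (Huber M-estimated) linear models and Wald tests, FDR-corrected
across components, and decomposes the leptin-NF-L association into direct
and connectivity-mediated paths with a nonparametric case-resampling
bootstrap. Utilities cover single-pass outlier exclusion, left-censored
leptin imputation at the assay's limit of detection, and subgroup
deviation scores for sensitivity analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.integrate
import scipy.stats
import statsmodels.api as sm

from .connectome import ConnectivityMatrix
from .nbs import Component
from .volumes import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "mean_component_connectivity", "exclude_outliers", "impute_lod",
    "RobustComponentModel", "RobustFitResults",
    "robust_component_regression",
    "Mediation", "MediationResults", "mediation_bootstrap",
    "subgroup_deviation",
]


def mean_component_connectivity(matrix: ConnectivityMatrix,
                                component: Component) -> float:
    """Mean of the participant's edge weights over the component's edges."""
    n = matrix.n_nodes
    for a, b in component.edges:
        if not (0 <= a < n and 0 <= b < n):
            raise ValueError(f"component edge ({a}, {b}) outside the "
                             f"{n}-node matrix")
    return float(np.mean([matrix.values[a, b] for a, b in component.edges]))


def exclude_outliers(values, groups, k: float = 3.0) -> np.ndarray:
    """Single-pass exclusion mask: keep values within k group SDs.

    Group mean and SD are computed on the full group including the
    candidate (one pass, no iteration). Returns a boolean inclusion mask;
    NaN values are kept (they carry their own missingness).
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    include = np.ones(values.size, dtype=bool)
    for g in pd.unique(groups):
        sel = groups == g
        v = values[sel]
        obs = v[~np.isnan(v)]
        if obs.size < 3:
            raise ValueError(f"group {g!r} needs >= 3 observations")
        mu, sd = obs.mean(), obs.std(ddof=1)
        if sd == 0:
            warnings.warn(f"group {g!r} has zero SD; nothing excluded")
            continue
        with np.errstate(invalid="ignore"):
            out = np.abs(values - mu) > k * sd
        include[sel & np.nan_to_num(out, nan=False).astype(bool)] = False
    return include


def impute_lod(values, censored, lod: float, method: str = "lod_sqrt2",
               seed: int | None = None, group=None) -> np.ndarray:
    """Replace left-censored assay values.

    ``lod_sqrt2`` (default) substitutes LOD/sqrt(2) deterministically.
    ``truncated_lognormal`` fits a log-normal to the uncensored values
    (per group when ``group`` is given) and draws each censored entry from
    that distribution truncated above at the LOD (seeded). Uncensored and
    missing entries pass through unchanged.
    """
    if not lod > 0:
        raise ValueError("lod must be > 0")
    values = np.asarray(values, float).copy()
    censored = np.asarray(censored, bool)
    if method == "lod_sqrt2":
        values[censored] = lod / np.sqrt(2.0)
        return values
    if method != "truncated_lognormal":
        raise ValueError(f"unknown imputation method {method!r}")
    rng = np.random.default_rng(seed)
    groups = np.zeros(values.size) if group is None else np.asarray(group)
    for g in pd.unique(groups):
        sel = groups == g
        cen = sel & censored
        if not cen.any():
            continue
        donors = values[sel & ~censored]
        donors = donors[~np.isnan(donors) & (donors > 0)]
        if donors.size < 3:
            raise ValueError("too few uncensored values to fit the "
                             "imputation distribution")
        mu, sd = np.log(donors).mean(), np.log(donors).std(ddof=1)
        # inverse-CDF sampling of the log-normal truncated above at LOD
        p_lod = scipy.stats.norm.cdf((np.log(lod) - mu) / sd)
        u = rng.uniform(0.0, p_lod, cen.sum())
        values[cen] = np.exp(mu + sd * scipy.stats.norm.ppf(u))
    return values


@dataclass
class RobustFitResults:
    """Standardized robust-regression slopes per (component, predictor)."""
    table: pd.DataFrame          # columns: predictor, component, std_beta, p, q
    nuisances: list[str]
    estimator: dict = field(default_factory=dict)

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        out = self.table.copy()
        out["significant"] = np.where(out["q"] < 0.01, "**",
                                      np.where(out["q"] < alpha, "*", ""))
        return out


class RobustComponentModel:
    """Robust regression of mean component connectivity on clinical variables.

    For each (component, clinical predictor) pair, fits a Huber
    M-estimated linear model of the participant's mean component
    connectivity on the z-scored predictor plus nuisance variables (age,
    WM volume, motion by default), with MAD scale and tuning constant
    1.345. Outcome and predictor are z-scored so the slope is a
    standardized beta; p-values are Wald tests on the robust covariance,
    and q is BH-FDR across components within each predictor (7 tests in
    the reference design).
    """

    def __init__(self, mean_conn: pd.DataFrame, cohort: pd.DataFrame,
                 predictors: list[str],
                 nuisances: tuple[str, ...] = ("age", "wm_volume", "motion"),
                 max_iter: int = 200, tol: float = 1e-8):
        self.mean_conn = mean_conn
        self.cohort = cohort.set_index("id") if "id" in cohort.columns \
            else cohort
        self.predictors = list(predictors)
        self.nuisances = list(nuisances)
        self.max_iter = max_iter
        self.tol = tol
        missing = [c for c in self.predictors + self.nuisances
                   if c not in self.cohort.columns]
        if missing:
            raise ValueError(f"cohort lacks columns {missing}")

    def _fit_one(self, y: np.ndarray, x: np.ndarray, Z: np.ndarray):
        if x.std(ddof=0) == 0:
            raise ValueError("predictor has zero variance")
        ys = (y - y.mean()) / y.std(ddof=1)
        xs = (x - x.mean()) / x.std(ddof=1)
        X = np.column_stack([np.ones(y.size), xs, Z])
        model = sm.RLM(ys, X, M=sm.robust.norms.HuberT(t=1.345))
        res = model.fit(maxiter=self.max_iter, tol=self.tol,
                        scale_est="mad")
        if res.fit_history["iteration"] >= self.max_iter:
            raise RuntimeError(
                "robust fit did not converge in "
                f"{self.max_iter} iterations "
                f"(|dev| trace tail: {res.fit_history['deviance'][-3:]})")
        beta = float(res.params[1])
        p = float(2.0 * scipy.stats.norm.sf(abs(res.tvalues[1])))
        return beta, p

    def fit(self) -> RobustFitResults:
        comps = list(self.mean_conn.columns)
        need = len(self.nuisances) + 3
        rows = []
        for pred in self.predictors:
            for comp in comps:
                frame = pd.concat(
                    [self.mean_conn[comp].rename("y"),
                     self.cohort[[pred] + self.nuisances]], axis=1,
                    join="inner").dropna()
                if len(frame) < need:
                    raise ValueError(
                        f"need >= {need} participants for {pred}/{comp}, "
                        f"got {len(frame)}")
                Z = frame[self.nuisances].to_numpy(float)
                beta, p = self._fit_one(frame["y"].to_numpy(float),
                                        frame[pred].to_numpy(float), Z)
                rows.append(dict(predictor=pred, component=comp,
                                 std_beta=beta, p=p))
        table = pd.DataFrame(rows)
        table["q"] = np.nan
        for pred in self.predictors:
            sel = table["predictor"] == pred
            table.loc[sel, "q"] = bh_fdr(table.loc[sel, "p"].to_numpy())
        logger.info("robust component models: %d predictors x %d components "
                    "(FDR over %d tests per predictor)",
                    len(self.predictors), len(comps), len(comps))
        return RobustFitResults(
            table, self.nuisances,
            estimator=dict(loss="huber", tuning=1.345, scale="mad",
                           max_iter=self.max_iter, tol=self.tol))


def robust_component_regression(mean_conn, cohort, predictors,
                                nuisances=("age", "wm_volume", "motion"),
                                ) -> RobustFitResults:
    """Functional wrapper over :class:`RobustComponentModel`."""
    return RobustComponentModel(mean_conn, cohort, predictors,
                                nuisances).fit()


@dataclass
class MediationResults:
    """Direct / indirect / total effect decomposition with bootstrap CIs.

    Effects are on standardized scales when the model standardizes;
    ``total = direct + indirect`` holds by construction (the separately
    fitted total-only model is kept in ``total_refit`` for comparison).
    """
    direct: float
    indirect: float
    total: float
    paths: dict
    ci: dict            # effect -> (lower, upper)
    z: dict             # direct/total -> z-value (estimate / bootstrap SE)
    p: dict             # effect -> p-value
    total_refit: float
    n_boot: int
    seed: int | None
    n: int
    params: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, est in (("direct", self.direct),
                          ("indirect", self.indirect),
                          ("total", self.total)):
            lo, hi = self.ci[name]
            rows.append(dict(effect=name, estimate=est,
                             z=self.z.get(name, np.nan),
                             p=self.p[name], ci_lower=lo, ci_upper=hi))
        return pd.DataFrame(rows).set_index("effect")


def _path_fits(x, m, y, robust: bool):
    """Path a from m ~ x; paths b, c' from y ~ m + x."""
    n = x.size
    Xa = np.column_stack([np.ones(n), x])
    Xb = np.column_stack([np.ones(n), m, x])
    if robust:
        ra = sm.RLM(m, Xa, M=sm.robust.norms.HuberT(t=1.345)).fit(
            scale_est="mad")
        rb = sm.RLM(y, Xb, M=sm.robust.norms.HuberT(t=1.345)).fit(
            scale_est="mad")
        a = float(ra.params[1])
        b, c = float(rb.params[1]), float(rb.params[2])
    else:
        a = float(np.linalg.lstsq(Xa, m, rcond=None)[0][1])
        cb = np.linalg.lstsq(Xb, y, rcond=None)[0]
        b, c = float(cb[1]), float(cb[2])
    return a, b, c


class Mediation:
    """Single-mediator decomposition x -> m -> y with bootstrap inference.

    Intended use: x = (imputed) leptin, m = mean component connectivity,
    y = log NF-L. Path a is the slope of m on x; b and c' (direct) come
    from the model of y on m and x jointly; indirect = a*b and
    total = c' + a*b. Percentile confidence intervals and the two-sided
    indirect-effect p-value come from a nonparametric case-resampling
    bootstrap, deterministic for a fixed seed. Variables are z-scored
    before fitting by default, so all effects are standardized.
    """

    def __init__(self, x, m, y, estimator: str = "ols",
                 standardize: bool = True):
        if estimator not in ("ols", "robust"):
            raise ValueError("estimator must be 'ols' or 'robust'")
        arrs = [np.asarray(v, float) for v in (x, m, y)]
        ok = ~np.any([np.isnan(v) for v in arrs], axis=0)
        self.x, self.m, self.y = (v[ok] for v in arrs)
        if self.x.size < 20:
            raise ValueError("need >= 20 complete (x, m, y) triples")
        for name, v in zip("xmy", (self.x, self.m, self.y)):
            if v.std(ddof=0) == 0:
                raise ValueError(f"variable {name} has zero variance")
        if standardize:
            self.x, self.m, self.y = (
                (v - v.mean()) / v.std(ddof=1)
                for v in (self.x, self.m, self.y))
        self.estimator = estimator
        self.standardize = standardize

    def fit(self, n_boot: int = 5000, seed: int | None = None,
            ci_level: float = 0.95) -> MediationResults:
        if n_boot < 1000:
            raise ValueError("n_boot must be >= 1000 for stable percentile "
                             "intervals")
        robust = self.estimator == "robust"
        x, m, y = self.x, self.m, self.y
        n = x.size
        a, b, c = _path_fits(x, m, y, robust)
        direct, indirect = c, a * b
        total = direct + indirect
        total_refit = float(np.linalg.lstsq(
            np.column_stack([np.ones(n), x]), y, rcond=None)[0][1])

        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, 3))  # direct, indirect, total
        for i in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                ab, bb, cb = _path_fits(x[idx], m[idx], y[idx], robust)
            except np.linalg.LinAlgError:   # degenerate resample
                ab, bb, cb = a, b, c
            boots[i] = (cb, ab * bb, cb + ab * bb)

        alpha = 1.0 - ci_level
        lo = np.percentile(boots, 100 * alpha / 2, axis=0)
        hi = np.percentile(boots, 100 * (1 - alpha / 2), axis=0)
        ci = {k: (float(lo[i]), float(hi[i]))
              for i, k in enumerate(("direct", "indirect", "total"))}
        se = boots.std(axis=0, ddof=1)
        z = {"direct": float(direct / se[0]) if se[0] > 0 else np.nan,
             "total": float(total / se[2]) if se[2] > 0 else np.nan}
        p = {}
        for i, (k, est) in enumerate(zip(("direct", "indirect", "total"),
                                         (direct, indirect, total))):
            neg = float(np.mean(boots[:, i] < 0))
            pos = float(np.mean(boots[:, i] > 0))
            p[k] = min(1.0, 2.0 * min(neg, pos) + float(
                np.mean(boots[:, i] == 0)))
        return MediationResults(direct, indirect, total,
                                dict(a=a, b=b, c_prime=c), ci, z, p,
                                total_refit, n_boot, seed, n,
                                params=dict(estimator=self.estimator,
                                            standardize=self.standardize,
                                            ci_level=ci_level))


def mediation_bootstrap(x, m, y, n_boot: int = 5000,
                        seed: int | None = None, estimator: str = "ols",
                        standardize: bool = True) -> MediationResults:
    """Functional wrapper over :class:`Mediation` (spec surface)."""
    return Mediation(x, m, y, estimator, standardize).fit(n_boot, seed)


def subgroup_deviation(values, subgroup_mask, group_mask
                       ) -> tuple[float, float]:
    """Mean subgroup distance from the group mean, in group-SD units.

    Returns the signed mean distance and its absolute-value variant
    (sensitivity statistic for medication / diagnostic-subtype subgroups).
    """
    values = np.asarray(values, float)
    sub = np.asarray(subgroup_mask, bool)
    grp = np.asarray(group_mask, bool)
    if np.any(sub & ~grp):
        raise ValueError("subgroup must be contained in the group")
    if not sub.any():
        raise ValueError("subgroup is empty")
    gv = values[grp]
    gv = gv[~np.isnan(gv)]
    sd = gv.std(ddof=1)
    if sd == 0:
        raise ValueError("group SD is zero; deviation undefined")
    zscores = (values[sub] - gv.mean()) / sd
    return float(np.nanmean(zscores)), float(np.nanmean(np.abs(zscores)))
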