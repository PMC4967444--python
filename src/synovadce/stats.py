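"""Responsiveness and association statistics.

To compare the treatment response of measurements on different scales, each
parameter is converted to a z-score over the pooled baseline + follow-up
sample and the standardized change is estimated as the visit-interaction
coefficient of a random-effects linear panel model

    y_it = X_it1 beta + X_it2 beta + W_i + U_it

where i indexes subjects, t the visit (0 baseline / 1 follow-up), X_it1 are
parameter-type dummies, X_it2 the type-by-visit interactions, W_i a
subject random effect and U_it the idiosyncratic error.  Estimation is
feasible GLS with Swamy-Arora variance components; in a balanced two-visit
panel each interaction coefficient equals the mean within-subject z-score
change of its parameter, while the random effect propagates into the
confidence intervals.

Associations between change in each MRI measure and change in the KOOS
pain subscale are quantified by bivariate ordinary least squares (slope b
with 95% CI and two-sided p) and by Pearson's r with a Fisher-z 95% CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizedChangeResult",
    "AssociationResult",
    "pooled_zscore",
    "standardized_change_panel",
    "mean_change",
    "association",
    "pearson_fisher_ci",
    "responsiveness_table",
    "association_table",
]


@dataclass(frozen=True)
class StandardizedChangeResult:
    """Standardized change for one parameter with its raw-scale companion.

    ``orientation`` records the sign convention: ``"raw"`` for the model
    coefficient as estimated, ``"improvement-negative"`` when the sign has
    been flipped so that clinical improvement is negative (applied to KOOS,
    whose scale runs from 100 = no pain down to 0 = extreme pain).
    """

    parameter_type: str
    estimate: float
    ci_low: float
    ci_high: float
    raw_mean_change: float
    raw_ci_low: float
    raw_ci_high: float
    orientation: str = "raw"


@dataclass(frozen=True)
class AssociationResult:
    parameter_type: str
    b: float
    b_ci_low: float
    b_ci_high: float
    p: float
    r: float
    r_ci_low: float
    r_ci_high: float
    n: int


def pooled_zscore(baseline: np.ndarray, followup: np.ndarray, name: str = "parameter"):
    """Standardize paired visit values over the pooled two-visit sample.

    Mean and SD (ddof=1) are computed on the stacked 2n observations, so the
    resulting z-scores have pooled mean 0 and SD 1; the within-subject
    z-change is then the raw change in pooled-SD units.  Affine-invariant:
    a*x + b (a > 0) yields identical z-scores.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if baseline.shape != followup.shape or baseline.ndim != 1:
        raise ValueError("baseline and followup must be 1-D arrays of equal length")
    if baseline.size < 2:
        raise ValueError("need at least 2 subjects")
    pooled = np.concatenate([baseline, followup])
    mu = pooled.mean()
    sd = pooled.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"zero pooled variance for {name!r}; cannot standardize")
    return (baseline - mu) / sd, (followup - mu) / sd


def _swamy_arora_gls(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """Random-effects feasible GLS with Swamy-Arora variance components.

    Balanced panels only (T observations per group).  Returns
    (beta, se, sigma2_u, sigma2_w, theta).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    uniq, inv = np.unique(groups, return_inverse=True)
    n_groups = uniq.size
    counts = np.bincount(inv)
    if not np.all(counts == counts[0]):
        raise ValueError("unbalanced panel; complete cases must be enforced upstream")
    T = int(counts[0])
    n_obs = y.size

    # group means per column
    def gmean(a: np.ndarray) -> np.ndarray:
        sums = np.zeros((n_groups,) + a.shape[1:])
        np.add.at(sums, inv, a)
        return sums / counts.reshape((-1,) + (1,) * (a.ndim - 1))

    ybar = gmean(y)
    Xbar = gmean(X)

    # within (fixed-effects) residual variance -> sigma2_u
    yw = y - ybar[inv]
    Xw = X - Xbar[inv]
    rank_w = np.linalg.matrix_rank(Xw) if Xw.size else 0
    beta_w, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta_w
    df_w = n_obs - n_groups - rank_w
    if df_w <= 0:
        raise ValueError("not enough degrees of freedom for the within variance")
    sigma2_u = float(resid_w @ resid_w) / df_w

    # between regression on group means -> sigma2_1 = sigma2_u/T + sigma2_w
    rank_b = np.linalg.matrix_rank(Xbar)
    beta_b, *_ = np.linalg.lstsq(Xbar, ybar, rcond=None)
    resid_b = ybar - Xbar @ beta_b
    df_b = n_groups - rank_b
    if df_b <= 0:
        raise ValueError("not enough groups for the between variance")
    sigma2_1 = float(resid_b @ resid_b) / df_b
    sigma2_w = max(0.0, sigma2_1 - sigma2_u / T)

    theta = 1.0 - np.sqrt(sigma2_u / (sigma2_u + T * sigma2_w))
    ystar = y - theta * ybar[inv]
    Xstar = X - theta * Xbar[inv]
    XtX = Xstar.T @ Xstar
    beta = np.linalg.solve(XtX, Xstar.T @ ystar)
    cov = sigma2_u * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    return beta, se, sigma2_u, sigma2_w, theta


def standardized_change_panel(panel: pd.DataFrame, mode: str = "pooled") -> pd.DataFrame:
    """Visit-interaction coefficients of the random-effects panel model.

    ``panel`` is long format with columns ``subject_id``, ``visit`` (0/1),
    ``parameter_type`` and standardized score ``y``; every subject must
    contribute both visits of every parameter type.

    ``mode="pooled"`` fits all parameter types in one model (intercept +
    type dummies + one type-by-visit interaction per type, a single subject
    random effect); ``mode="per_parameter"`` fits each type separately.
    The balanced-panel identity makes the point estimates identical in both
    modes; the CIs may differ slightly.  Normal-theory 95% CIs.
    """
    req = {"subject_id", "visit", "parameter_type", "y"}
    if not req <= set(panel.columns):
        raise ValueError(f"panel must have columns {sorted(req)}")
    if not set(panel["visit"].unique()) <= {0, 1}:
        raise ValueError("visit must be coded 0 (baseline) / 1 (follow-up)")
    ptypes = list(pd.unique(panel["parameter_type"]))

    def _fit(df: pd.DataFrame, types: list[str]) -> dict[str, tuple[float, float]]:
        df = df.sort_values(["subject_id", "parameter_type", "visit"])
        n_cells = df.groupby(["subject_id", "parameter_type", "visit"]).size()
        if (n_cells != 1).any():
            raise ValueError("panel is not balanced: expect exactly one observation per subject/type/visit")
        y = df["y"].to_numpy(dtype=float)
        visit = df["visit"].to_numpy(dtype=float)
        cols = [np.ones(len(df))]
        for t in types[1:]:  # type dummies, first type as reference
            cols.append((df["parameter_type"] == t).to_numpy(dtype=float))
        for t in types:      # type-by-visit interactions, one per type
            cols.append(visit * (df["parameter_type"] == t).to_numpy(dtype=float))
        X = np.column_stack(cols)
        beta, se, *_ = _swamy_arora_gls(y, X, df["subject_id"].to_numpy())
        k0 = len(types)  # first interaction column index
        return {t: (float(beta[k0 + j]), float(se[k0 + j])) for j, t in enumerate(types)}

    if mode == "pooled":
        est = _fit(panel, ptypes)
    elif mode == "per_parameter":
        est = {}
        for t in ptypes:
            est.update(_fit(panel[panel["parameter_type"] == t], [t]))
    else:
        raise ValueError("mode must be 'pooled' or 'per_parameter'")

    zcrit = sps.norm.ppf(0.975)
    rows = [{"parameter_type": t, "estimate": b, "ci_low": b - zcrit * s, "ci_high": b + zcrit * s}
            for t, (b, s) in est.items()]
    return pd.DataFrame(rows)


def mean_change(baseline: np.ndarray, followup: np.ndarray) -> tuple[float, float, float]:
    """Raw-scale mean within-subject change with a t-distribution 95% CI."""
    d = np.asarray(followup, dtype=float) - np.asarray(baseline, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired observations")
    m = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(d.size))
    tcrit = sps.t.ppf(0.975, d.size - 1)
    return m, m - tcrit * se, m + tcrit * se


def pearson_fisher_ci(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """Pearson correlation with a Fisher z-transform (1-alpha) CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs for a Fisher-z interval")
    r = float(np.corrcoef(x, y)[0, 1])
    with np.errstate(divide="ignore"):  # r = +/-1: z = inf, interval degenerates to {r}
        z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = sps.norm.ppf(1 - alpha / 2)
    return r, float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))


def association(delta_param: np.ndarray, delta_koos: np.ndarray,
                parameter_type: str = "parameter") -> AssociationResult:
    """Bivariate OLS of KOOS change on parameter change plus Pearson r with CI."""
    dx = np.asarray(delta_param, dtype=float)
    dy = np.asarray(delta_koos, dtype=float)
    if dx.shape != dy.shape or dx.ndim != 1:
        raise ValueError("delta arrays must be 1-D and of equal length")
    if dx.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(dx) == 0:
        raise ValueError(f"constant predictor for {parameter_type!r}")
    model = sm.OLS(dy, sm.add_constant(dx)).fit()
    ci = model.conf_int(alpha=0.05)
    r, rlo, rhi = pearson_fisher_ci(dx, dy)
    return AssociationResult(
        parameter_type=parameter_type,
        b=float(model.params[1]), b_ci_low=float(ci[1][0]), b_ci_high=float(ci[1][1]),
        p=float(model.pvalues[1]), r=r, r_ci_low=rlo, r_ci_high=rhi, n=dx.size,
    )


# ---------------------------------------------------------------------------
# cohort-table front ends

def _paired(cohort: pd.DataFrame, column: str) -> tuple[np.ndarray, np.ndarray]:
    wide = cohort.pivot(index="subject_id", columns="visit", values=column)
    if wide.isna().any().any():
        raise ValueError(f"incomplete pairs for {column!r}")
    return wide["baseline"].to_numpy(), wide["followup"].to_numpy()


def responsiveness_table(cohort: pd.DataFrame, parameters: list[str] | None = None,
                         koos_column: str = "koos_pain", mode: str = "pooled") -> pd.DataFrame:
    """Standardized change (panel model) and raw mean change for every parameter.

    ``cohort`` is the long-format cohort table.  The KOOS pain subscale is
    included as a parameter type and reported with the improvement-negative
    orientation (its estimate is sign-flipped, marked in ``orientation``).
    """
    from .roi import MRI_PARAMETERS

    parameters = list(parameters) if parameters is not None else list(MRI_PARAMETERS)
    all_params = parameters + [koos_column]

    obs = []
    raw = {}
    for p in all_params:
        b, f = _paired(cohort, p)
        raw[p] = mean_change(b, f)
        zb, zf = pooled_zscore(b, f, name=p)
        subjects = cohort.pivot(index="subject_id", columns="visit", values=p).index
        for vals, visit in ((zb, 0), (zf, 1)):
            obs.append(pd.DataFrame({"subject_id": subjects, "visit": visit,
                                     "parameter_type": p, "y": vals}))
    panel = pd.concat(obs, ignore_index=True)
    fit = standardized_change_panel(panel, mode=mode).set_index("parameter_type")

    rows = []
    for p in all_params:
        est, lo, hi = fit.loc[p, ["estimate", "ci_low", "ci_high"]]
        orientation = "raw"
        if p == koos_column:
            # KOOS runs 100 (no pain) .. 0 (extreme pain): flip so that
            # improvement is negative, comparable with the MRI parameters.
            est, lo, hi = -est, -hi, -lo
            orientation = "improvement-negative"
        m, mlo, mhi = raw[p]
        rows.append(StandardizedChangeResult(
            parameter_type=p, estimate=float(est), ci_low=float(lo), ci_high=float(hi),
            raw_mean_change=m, raw_ci_low=mlo, raw_ci_high=mhi, orientation=orientation))
    return pd.DataFrame([r.__dict__ for r in rows])


def association_table(cohort: pd.DataFrame, parameters: list[str] | None = None,
                      koos_column: str = "koos_pain") -> pd.DataFrame:
    """Bivariate association of each parameter's change with KOOS pain change.

    Synovial volume is converted from mm^3 to cm^3 before regression so the
    b coefficient is on the conventional reporting scale.
    """
    from .roi import MRI_PARAMETERS

    parameters = list(parameters) if parameters is not None else list(MRI_PARAMETERS)
    kb, kf = _paired(cohort, koos_column)
    dkoos = kf - kb
    rows = []
    for p in parameters:
        b, f = _paired(cohort, p)
        d = f - b
        if p == "volume_mm3":
            d = d / 1000.0  # report volume slope per cm^3
        rows.append(association(d, dkoos, parameter_type=p).__dict__)
    return pd.DataFrame(rows)
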