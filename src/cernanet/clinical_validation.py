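"""Clinical validation of network members: Kaplan-Meier, Cox, and ROC.

Each candidate biomarker is dichotomized at its median tumor expression
(high = strictly above the median; patients tied at the median go to the
low group, which makes splits reproducible).  The two groups are compared
with the product-limit (Kaplan-Meier) estimator and the two-group log-rank
test; hazard ratios come from Cox proportional-hazards fits (Efron tie
handling), with the multivariate model entering the covariates that were
univariate-significant (p < 0.05 by default).  Discrimination is summarized
by the ROC AUC — the Mann-Whitney U statistic divided by n1*n2 — with the
event-at-end-of-follow-up status as the binary label, and a Hanley-McNeil
standard-error confidence interval (a conservative exact-binomial option is
available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Median split
# ---------------------------------------------------------------------------


def median_split(values: pd.Series | np.ndarray) -> pd.Series:
    """Dichotomize an expression vector at its median.

    ``high`` = strictly above the median; ties at the median are assigned to
    ``low``.  Raises for constant vectors (no split exists) and for n < 4.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 4:
        raise ValueError(f"need n >= 4 to split, got {len(s)}")
    if s.nunique() == 1:
        raise ValueError("constant expression vector cannot be median-split")
    med = s.median()
    return pd.Series(np.where(s > med, "high", "low"), index=s.index)


# ---------------------------------------------------------------------------
# Kaplan-Meier + log-rank
# ---------------------------------------------------------------------------


@dataclass
class SurvivalSplit:
    """KM curves and log-rank comparison of a high/low expression split."""

    feature_id: str
    endpoint: str
    groups: pd.Series  # patient -> {high, low}
    km_curves: dict[str, pd.DataFrame]  # group -> (timeline, survival)
    logrank_chi2: float
    logrank_p: float
    zero_event_groups: list[str] = field(default_factory=list)


def km_logrank(
    clinical: pd.DataFrame,
    groups: pd.Series,
    feature_id: str = "",
    endpoint: str = "OS",
) -> SurvivalSplit:
    """Product-limit estimate per group and the two-group log-rank test.

    ``clinical`` needs columns patient_id, time, event (one endpoint);
    ``groups`` maps patient_id to 'high'/'low'.  A group with zero events is
    flagged but the test still runs.
    """
    df = clinical.set_index("patient_id")
    missing = [p for p in groups.index if p not in df.index]
    if missing:
        raise KeyError(f"group patients absent from clinical table: {missing[:5]}")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two nonempty groups, got {labels}")

    curves: dict[str, pd.DataFrame] = {}
    zero_event = []
    arms = {}
    for g in labels:
        patients = groups.index[groups == g]
        t = df.loc[patients, "time"].to_numpy(dtype=float)
        e = df.loc[patients, "event"].to_numpy(dtype=int)
        arms[g] = (t, e)
        if e.sum() == 0:
            zero_event.append(g)
            logger.warning("group %s has zero events", g)
        kmf = KaplanMeierFitter()
        kmf.fit(t, e, label=g)
        curves[g] = pd.DataFrame(
            {"time": kmf.survival_function_.index.to_numpy(), "survival": kmf.survival_function_[g].to_numpy()}
        )
    res = logrank_test(arms[labels[0]][0], arms[labels[1]][0], arms[labels[0]][1], arms[labels[1]][1])
    return SurvivalSplit(
        feature_id=feature_id,
        endpoint=endpoint,
        groups=groups,
        km_curves=curves,
        logrank_chi2=float(res.test_statistic),
        logrank_p=float(res.p_value),
        zero_event_groups=zero_event,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

COX_COLUMNS = ["variable", "beta", "hr", "ci_lo", "ci_hi", "p", "model"]


def cox_fit(
    clinical: pd.DataFrame,
    covariates: list[str],
    mode: str = "univariate",
    entry_p: float = 0.05,
) -> pd.DataFrame:
    """Cox proportional-hazards fits (partial likelihood, Efron ties).

    ``mode='univariate'`` fits one single-covariate model per covariate;
    ``mode='multivariate'`` first screens univariately and jointly fits the
    covariates with univariate p < ``entry_p`` (the forward-entry rule).
    Returns one row per (variable, model) with beta, HR = exp(beta), 95% CI
    and p.  Non-convergence or separation is reported as an error.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"mode must be 'univariate' or 'multivariate', got {mode!r}")
    missing = [c for c in covariates if c not in clinical.columns]
    if missing:
        raise KeyError(f"covariate(s) absent from clinical table: {missing}")
    if clinical[covariates].isna().any().any():
        raise ValueError("covariates must be complete (no missing values)")

    def _fit(cols: list[str], label: str) -> pd.DataFrame:
        cph = CoxPHFitter()
        cph.fit(clinical[["time", "event", *cols]], duration_col="time", event_col="event")
        summ = cph.summary
        return pd.DataFrame(
            {
                "variable": summ.index,
                "beta": summ["coef"].to_numpy(),
                "hr": np.exp(summ["coef"].to_numpy()),
                "ci_lo": np.exp(summ["coef lower 95%"].to_numpy()),
                "ci_hi": np.exp(summ["coef upper 95%"].to_numpy()),
                "p": summ["p"].to_numpy(),
                "model": label,
            }
        )

    uni = pd.concat([_fit([c], "univariate") for c in covariates], ignore_index=True)
    if mode == "univariate":
        return uni
    selected = uni.loc[uni["p"] < entry_p, "variable"].tolist()
    if not selected:
        logger.warning("no covariate passed univariate p < %g; multivariate model empty", entry_p)
        return uni
    multi = _fit(selected, "multivariate")
    return pd.concat([uni, multi], ignore_index=True)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    feature_id: str
    endpoint: str
    auc: float
    ci_lo: float
    ci_hi: float
    curve: pd.DataFrame  # columns fpr, tpr


def _hanley_se(auc: float, n1: int, n0: int) -> float:
    # Hanley & McNeil (1982) standard error of the empirical AUC
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    return float(np.sqrt(max(var, 0.0)))


def roc_auc(
    scores,
    labels,
    feature_id: str = "",
    endpoint: str = "OS",
    ci_method: str = "hanley",
    alpha: float = 0.05,
) -> ROCResult:
    """Empirical ROC curve and AUC via the rank (Mann-Whitney U) statistic.

    AUC = U / (n1*n0) with half-credit for score ties, which equals the
    trapezoidal area under the empirical curve.  ``ci_method='hanley'`` gives
    the Hanley-McNeil normal interval; ``'exact-binomial'`` treats the number
    of concordant pairs as binomial for a conservative Clopper-Pearson
    interval.  Both are clipped to [0, 1].
    """
    y = np.asarray(labels, dtype=int)
    x = np.asarray(scores, dtype=float)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    ranks = stats.rankdata(x)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))

    # empirical curve: thresholds descending over unique scores
    order = np.argsort(-x, kind="mergesort")
    ys = y[order]
    xs = x[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    # keep the last point of each tied-score run
    last = np.r_[xs[1:] != xs[:-1], True]
    tpr = np.r_[0.0, tps[last] / n1]
    fpr = np.r_[0.0, fps[last] / n0]
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})

    if ci_method == "hanley":
        se = _hanley_se(auc, n1, n0)
        z = stats.norm.ppf(1 - alpha / 2)
        lo, hi = auc - z * se, auc + z * se
    elif ci_method == "exact-binomial":
        n_pairs = n1 * n0
        k = int(round(auc * n_pairs))
        lo = stats.beta.ppf(alpha / 2, k, n_pairs - k + 1) if k > 0 else 0.0
        hi = stats.beta.ppf(1 - alpha / 2, k + 1, n_pairs - k) if k < n_pairs else 1.0
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ROCResult(
        feature_id=feature_id,
        endpoint=endpoint,
        auc=auc,
        ci_lo=float(np.clip(lo, 0.0, 1.0)),
        ci_hi=float(np.clip(hi, 0.0, 1.0)),
        curve=curve,
    )


# ---------------------------------------------------------------------------
# Per-feature validation driver
# ---------------------------------------------------------------------------


def validate_features(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    features: list[str],
    endpoint: str = "OS",
) -> pd.DataFrame:
    """Median-split KM log-rank, univariate Cox HR, and AUC per feature.

    ``expr`` is features x patients (tumor samples named by patient_id);
    ``clinical`` holds one endpoint's rows.  Returns one row per feature.
    """
    rows = []
    clin = clinical.set_index("patient_id")
    shared = [p for p in expr.columns if p in clin.index]
    if len(shared) < 4:
        raise ValueError("fewer than 4 patients shared between expression and clinical tables")
    clin = clin.loc[shared]
    for fid in features:
        vec = expr.loc[fid, shared]
        groups = median_split(vec)
        split = km_logrank(clin.reset_index(), groups, feature_id=fid, endpoint=endpoint)
        ctab = clin.reset_index()[["patient_id", "time", "event"]].copy()
        ctab[fid] = vec.to_numpy()
        cox = cox_fit(ctab, [fid], mode="univariate")
        roc = roc_auc(vec.to_numpy(), clin["event"].to_numpy(), feature_id=fid, endpoint=endpoint)
        rows.append(
            {
                "feature_id": fid,
                "endpoint": endpoint,
                "logrank_p": split.logrank_p,
                "hr": float(cox["hr"].iloc[0]),
                "hr_p": float(cox["p"].iloc[0]),
                "auc": roc.auc,
                "auc_lo": roc.ci_lo,
                "auc_hi": roc.ci_hi,
            }
        )
    return pd.DataFrame(rows)
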