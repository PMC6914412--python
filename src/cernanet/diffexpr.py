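"""Moderated differential expression and cross-cohort intersection.

The tumor-vs-normal screen uses a random variance model (RVM) t-test:
per-feature variances are modelled as draws from an inverse-gamma prior, so
that for a feature with pooled variance ``s2`` on ``d`` degrees of freedom,
``s2 * a * b ~ F(d, 2a)``.  The hyperparameters ``(a, b)`` are fitted by
maximum likelihood across all features of a cohort, and each feature's
variance is shrunk toward the prior::

    s2_mod = (d * s2 + 2 / b) / (d + 2 * a),    df_mod = d + 2 * a

which stabilizes the denominator of the t statistic when per-group sample
sizes are small, as in microarray cohorts.  With ``prior=None`` the
statistic reduces exactly to the classical pooled two-sample t.

Fold changes follow the signed display convention used in microarray
reports: ``fc_signed = 2**log2fc`` for up-regulated features and
``-2**(-log2fc)`` for down-regulated ones, so a feature repressed 4-fold
appears as -4.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from cernanet.io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Default per-class significance rules.  mRNA/lncRNA: |FC| > 2 and p < 0.05;
#: miRNA additionally requires FDR < 0.05 at the looser |FC| > 1.5 cut.
DEFAULT_CLASS_RULES: dict[str, dict[str, float]] = {
    "mRNA": {"min_abs_fc": 2.0, "max_p": 0.05, "max_fdr": None},
    "lncRNA": {"min_abs_fc": 2.0, "max_p": 0.05, "max_fdr": None},
    "miRNA": {"min_abs_fc": 1.5, "max_p": 0.05, "max_fdr": 0.05},
}

DE_COLUMNS = [
    "feature_id",
    "feature_class",
    "cohort",
    "log2fc",
    "fc_signed",
    "t_stat",
    "p",
    "fdr",
    "direction",
]


@dataclass(frozen=True)
class RVMPrior:
    """Inverse-gamma variance hyperparameters fitted on one cohort."""

    a: float
    b: float
    fitted_on: str = ""

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"RVM hyperparameters must be positive, got a={self.a}, b={self.b}")


def _group_arrays(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    x = matrix.values.to_numpy(dtype=float)
    tmask = matrix.condition_mask("tumor")
    nmask = matrix.condition_mask("normal")
    return x[:, tmask], x[:, nmask]


def _pooled_variances(tumor: np.ndarray, normal: np.ndarray) -> tuple[np.ndarray, int]:
    n1, n2 = tumor.shape[1], normal.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >=2 samples per condition, got tumor={n1}, normal={n2}")
    d = n1 + n2 - 2
    ss = tumor.var(axis=1, ddof=1) * (n1 - 1) + normal.var(axis=1, ddof=1) * (n2 - 1)
    return ss / d, d


def fit_rvm_prior(matrix: ExpressionMatrix, cohort: str = "") -> RVMPrior:
    """Fit the variance-prior hyperparameters (a, b) by maximum likelihood.

    Under the model, observed pooled variances satisfy ``s2*a*b ~ F(d, 2a)``;
    the likelihood is maximized over ``log a, log b`` (box-bounded: with
    near-constant observed variances the likelihood is flat in the
    ``a -> inf`` direction, whose limit is a degenerate, maximally tight
    prior — the boundary solution reproduces that limit).  Raises if every
    variance is zero; on optimizer failure the caller should fall back to
    the unmoderated test (``prior=None``).
    """
    tumor, normal = _group_arrays(matrix)
    s2, d = _pooled_variances(tumor, normal)
    s2 = s2[s2 > 0]
    if s2.size == 0:
        raise ValueError("all per-feature variances are zero; cannot fit variance prior")

    def nll(theta: np.ndarray) -> float:
        a, b = np.exp(theta)
        ab = a * b
        # density of s2: f(x) = a*b * f_F(a*b*x; d, 2a)
        ll = np.log(ab) + stats.f.logpdf(ab * s2, d, 2.0 * a)
        return -float(np.sum(ll))

    # moment-flavored start: prior mean of 1/sigma^2 is a*b ~ 1/mean(s2)
    start = np.log([1.0, 1.0 / float(np.mean(s2))])
    bounds = [(np.log(1e-4), np.log(1e5)), (None, None)]
    res = optimize.minimize(nll, start, method="L-BFGS-B", bounds=bounds)
    if not res.success:
        # line searches can fail in the flat a -> inf direction; polish the
        # best iterate with a derivative-free pass before giving up
        polish = optimize.minimize(
            nll,
            res.x if np.all(np.isfinite(res.x)) else start,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 5000, "maxfev": 5000},
        )
        if polish.fun <= res.fun or polish.success:
            res = polish
        else:
            logger.warning(
                "variance-prior fit did not converge (%s); falling back to classical t", res.message
            )
            raise RuntimeError(f"variance-prior optimizer failed: {res.message}")
    a, b = np.exp(np.clip(res.x, [np.log(1e-4), -700.0], [np.log(1e5), 700.0]))
    return RVMPrior(a=float(a), b=float(b), fitted_on=cohort)


def moderated_t(matrix: ExpressionMatrix, prior: RVMPrior | None) -> pd.DataFrame:
    """Per-feature moderated (or classical, if ``prior`` is None) two-sample t.

    Returns a DataFrame indexed by feature_id with columns t, p, df.
    Two-sided p-values from the t distribution with the augmented degrees of
    freedom ``d + 2a``.
    """
    tumor, normal = _group_arrays(matrix)
    n1, n2 = tumor.shape[1], normal.shape[1]
    s2, d = _pooled_variances(tumor, normal)
    diff = tumor.mean(axis=1) - normal.mean(axis=1)
    if prior is None:
        s2_mod, df = s2, float(d)
    else:
        s2_mod = (d * s2 + 2.0 / prior.b) / (d + 2.0 * prior.a)
        df = float(d + 2.0 * prior.a)
    denom = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame({"t": t, "p": p, "df": df}, index=matrix.values.index)


def fold_change(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-feature log2 fold change (tumor - normal) and signed fold change."""
    tumor, normal = _group_arrays(matrix)
    lfc = tumor.mean(axis=1) - normal.mean(axis=1)
    fc_signed = np.where(lfc >= 0, 2.0**lfc, -(2.0 ** (-lfc)))
    return pd.DataFrame({"log2fc": lfc, "fc_signed": fc_signed}, index=matrix.values.index)


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (the default FDR used for gating)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def legacy_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """The literal ``FDR = 1 - Nk/T`` quantity, reported alongside BH.

    For the k-th smallest of T p-values, Nk is the number of p-values
    strictly below it, so the smallest p maps to 1 and a p larger than all
    others maps to 1 - (T-1)/T.  This reading is documented, not canonical;
    it is never used for significance gating unless explicitly configured.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    T = p.size
    # Nk via rank: count of strictly smaller p-values
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    nk_sorted = np.searchsorted(sorted_p, sorted_p, side="left")
    nk = np.empty(T, dtype=float)
    nk[order] = nk_sorted
    return 1.0 - nk / T


def run_de(
    matrix: ExpressionMatrix,
    cohort: str | None = None,
    prior: RVMPrior | None | str = "fit",
) -> pd.DataFrame:
    """Full differential screen for one cohort: moderated t, FC, BH FDR.

    ``prior='fit'`` fits the RVM prior on this cohort (falling back to the
    classical t if the fit fails); pass ``None`` to force the classical test.
    Returns a DataFrame with :data:`DE_COLUMNS`.
    """
    if cohort is not None:
        matrix = matrix.subset_cohort(cohort)
        cohort_label = cohort
    else:
        cohorts = matrix.cohorts
        cohort_label = cohorts[0] if len(cohorts) == 1 else "+".join(cohorts)
    if prior == "fit":
        try:
            prior = fit_rvm_prior(matrix, cohort=cohort_label)
        except (RuntimeError, ValueError) as exc:
            logger.warning("cohort %s: %s; using classical t", cohort_label, exc)
            prior = None
    tp = moderated_t(matrix, prior)
    fc = fold_change(matrix)
    out = pd.DataFrame(
        {
            "feature_id": matrix.values.index,
            "feature_class": matrix.feature_class.to_numpy(),
            "cohort": cohort_label,
            "log2fc": fc["log2fc"].to_numpy(),
            "fc_signed": fc["fc_signed"].to_numpy(),
            "t_stat": tp["t"].to_numpy(),
            "p": tp["p"].to_numpy(),
            "fdr": bh_fdr(tp["p"].to_numpy()),
            "direction": np.where(fc["log2fc"].to_numpy() > 0, "up", "down"),
        }
    )
    # deterministic order: by t magnitude desc, feature_id tie-break
    out = out.sort_values(["p", "feature_id"], kind="mergesort").reset_index(drop=True)
    return out


def select_de(
    records: pd.DataFrame,
    class_rules: Mapping[str, Mapping[str, float | None]] | None = None,
) -> pd.DataFrame:
    """Apply the per-class significance thresholds to a DE table.

    Defaults: mRNA/lncRNA pass with ``|fc_signed| > 2`` and ``p < 0.05``;
    miRNA passes with ``|fc_signed| > 1.5``, ``p < 0.05`` and ``fdr < 0.05``.
    """
    rules = dict(DEFAULT_CLASS_RULES)
    if class_rules:
        rules.update({k: dict(v) for k, v in class_rules.items()})
    if records.empty:
        return records.copy()
    unknown = set(records["feature_class"].unique()) - set(rules)
    if unknown:
        raise ValueError(f"no selection rule for feature class(es): {sorted(unknown)}")
    keep = np.zeros(len(records), dtype=bool)
    for cls, rule in rules.items():
        mask = (records["feature_class"] == cls).to_numpy()
        if not mask.any():
            continue
        ok = mask & (records["fc_signed"].abs() > rule["min_abs_fc"]).to_numpy()
        ok &= (records["p"] < rule["max_p"]).to_numpy()
        if rule.get("max_fdr") is not None:
            ok &= (records["fdr"] < rule["max_fdr"]).to_numpy()
        keep |= ok
    return records[keep].reset_index(drop=True)


def intersect_de(
    per_cohort: Mapping[str, pd.DataFrame],
    min_cohorts: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Direction-consistent intersection of per-cohort DE tables.

    A feature is kept iff it is present (i.e. significant) with the SAME
    direction in all cohorts (default) or in at least ``min_cohorts``.
    Features significant with conflicting directions are dropped and logged.
    Returns (intersected table, Venn-style counts keyed by cohort-membership
    pattern such as ``"A&B"``).
    """
    if not per_cohort:
        raise ValueError("need at least one cohort DE table")
    names = list(per_cohort)
    need = len(names) if min_cohorts is None else min_cohorts
    membership: dict[str, dict[str, str]] = {}
    for name, df in per_cohort.items():
        for _, row in df.iterrows():
            membership.setdefault(row["feature_id"], {})[name] = row["direction"]

    venn: dict[str, int] = {}
    rows = []
    for fid in sorted(membership):
        present = membership[fid]
        key = "&".join(n for n in names if n in present)
        venn[key] = venn.get(key, 0) + 1
        dirs = set(present.values())
        if len(present) >= need:
            if len(dirs) > 1:
                logger.warning("feature %s: conflicting DE directions across cohorts %s; dropped", fid, present)
                continue
            rows.append({"feature_id": fid, "direction": dirs.pop(), "n_cohorts": len(present)})
    first = next(iter(per_cohort.values()))
    class_map = dict(zip(first["feature_id"], first["feature_class"]))
    out = pd.DataFrame(rows, columns=["feature_id", "direction", "n_cohorts"])
    out["feature_class"] = out["feature_id"].map(class_map)
    return out, venn


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    features: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of features on 1 - Pearson distance.

    Constant (zero-variance) features get distance 1 to everything.  Input
    features are sorted by id first so the linkage and leaf order are
    deterministic.  Returns (scipy linkage matrix, leaf-ordered feature ids).
    """
    if features is None:
        features = matrix.feature_ids
    features = sorted(features)
    if len(features) < 2:
        raise ValueError("need >=2 features to cluster")
    x = matrix.values.loc[features].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    const = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    dist = 1.0 - corr
    dist[const, :] = 1.0
    dist[:, const] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    z = linkage(squareform(dist, checks=False), method="average")
    order = [features[i] for i in leaves_list(z)]
    return z, order


def screen_summary(n_up: int, n_down: int) -> dict[str, float]:
    """Totals and up/down percentages of a differential screen, with the
    percentages rounded to one decimal as reported in screen tables."""
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be non-negative")
    total = n_up + n_down
    if total == 0:
        raise ValueError("empty screen")
    return {
        "total": total,
        "pct_up": round(100.0 * n_up / total, 1),
        "pct_down": round(100.0 * n_down / total, 1),
    }
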