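"""Statistical layer: mixed-effects ratio models, LRT, ROC, ICC, group tests.

AA-ratios from one subject are correlated (many branches per CT) and lobes
differ systematically, so ratio contrasts are estimated with linear
mixed-effects models carrying a subject random intercept and a lobe variance
component, fitted by REML (ML refits for likelihood-ratio comparisons).
Diagnostic cut-offs come from ROC analysis with Youden's index; observer
agreement is summarised by an intraclass correlation from a hierarchical
variance-components model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec", "LMMResult", "ROCResult", "ICCResult",
    "fit_lmm", "lrt_select", "roc_threshold", "compute_icc", "group_tests",
    "auc_mann_whitney",
]


class SpecificationError(ValueError):
    """Model specification incompatible with the data."""


RESPONSES = ("AinA", "AoutA", "AWTA", "AWTratio")


@dataclass
class ModelSpec:
    """Specification of one mixed-effects AA-ratio model."""

    response: str
    fixed: Sequence[str] = ("disease_status", "volume_state")
    interactions: Sequence[Tuple[str, str]] = ()
    subject_col: str = "subject_id"
    lobe_col: Optional[str] = "lobe"     # None drops the lobe component

    def formula(self) -> str:
        terms = list(self.fixed) or ["1"]
        terms += [f"{a}:{b}" for a, b in self.interactions]
        return f"{self.response} ~ " + " + ".join(terms)


@dataclass
class LMMResult:
    """Fitted mixed-model summary: fixed effects and variance components."""

    response: str
    formula: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    var_subject: float
    var_lobe: float
    var_residual: float
    llf: float
    n_obs: int
    n_fixed_params: int
    method: str = "reml"
    converged: bool = True
    singular: bool = False

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.bse,
                             "p": self.pvalues})


def fit_lmm(data: pd.DataFrame, spec: ModelSpec, reml: bool = True) -> LMMResult:
    """Fit a linear mixed model with subject random intercept (+ lobe).

    The lobe effect enters as a variance component within subject (lobe
    nested in subject), capturing per-subject lobe heterogeneity. A variance
    component estimated at (near) zero flags the result as singular rather
    than failing. Wald p-values are reported for fixed effects.
    """
    cols = {spec.response, spec.subject_col} | set(spec.fixed)
    if spec.lobe_col:
        cols.add(spec.lobe_col)
    missing = cols - set(data.columns)
    if missing:
        raise SpecificationError(f"model columns missing from data: {missing}")
    df = data.dropna(subset=list(cols)).copy()
    if df[spec.subject_col].nunique() < 2:
        raise SpecificationError("need >= 2 subjects to fit a subject intercept")

    vc = {}
    if spec.lobe_col and df[spec.lobe_col].nunique() > 1:
        vc["lobe"] = f"0 + C({spec.lobe_col})"
    model = smf.mixedlm(spec.formula(), df, groups=df[spec.subject_col],
                        re_formula="1", vc_formula=vc or None)

    exog_rank = np.linalg.matrix_rank(model.exog)
    if exog_rank < model.exog.shape[1]:
        raise SpecificationError(
            f"rank-deficient fixed-effect design ({exog_rank} < "
            f"{model.exog.shape[1]}): collinear or constant covariates")

    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=reml, method=["powell", "cg"], maxiter=500)

    k_fe = model.exog.shape[1]
    fe = fit.fe_params
    bse_fe = pd.Series(np.asarray(fit.bse_fe), index=fe.index)
    z = np.asarray(fe) / np.asarray(bse_fe)
    pvals = pd.Series(2 * sps.norm.sf(np.abs(z)), index=fe.index)
    var_subject = float(np.asarray(fit.cov_re)[0, 0]) if fit.cov_re.size else 0.0
    var_lobe = float(fit.vcomp[0]) if len(getattr(fit, "vcomp", [])) else 0.0
    var_resid = float(fit.scale)
    singular = min(var_subject, var_resid) < 1e-8 or (bool(vc) and var_lobe < 1e-8)
    return LMMResult(
        response=spec.response,
        formula=spec.formula(),
        params=fe,
        bse=bse_fe,
        pvalues=pvals,
        var_subject=var_subject,
        var_lobe=var_lobe,
        var_residual=var_resid,
        llf=float(fit.llf),
        n_obs=int(model.nobs),
        n_fixed_params=k_fe,
        method="reml" if reml else "ml",
        converged=bool(fit.converged),
        singular=singular,
    )


def lrt_select(full: LMMResult, reduced: LMMResult) -> Tuple[float, int, float]:
    """Likelihood-ratio test between nested ML fits.

    Returns (statistic, df, p) with statistic = 2(llf_full - llf_reduced)
    and a chi-square reference on the fixed-parameter difference.
    """
    if full.method != "ml" or reduced.method != "ml":
        raise SpecificationError("LRT requires ML fits (reml=False), not REML")
    full_terms = set(full.params.index)
    if not set(reduced.params.index) <= full_terms:
        raise SpecificationError(
            "models are not nested: reduced model has terms absent from the "
            f"full model: {set(reduced.params.index) - full_terms}")
    df = full.n_fixed_params - reduced.n_fixed_params
    if df < 0:
        raise SpecificationError("reduced model has more parameters than full")
    stat = max(2.0 * (full.llf - reduced.llf), 0.0)
    p = 1.0 if df == 0 else float(sps.chi2.sf(stat, df))
    return stat, df, p


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    auc_ci: Tuple[float, float]
    threshold: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int


def auc_mann_whitney(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney U) formulation, ties at half credit."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise SpecificationError("AUC needs both classes present")
    ranks = sps.rankdata(values)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _youden_threshold(values: np.ndarray,
                      labels: np.ndarray) -> Tuple[float, float, float]:
    """Best cut over midpoints of adjacent sorted unique values; the
    positive call is ``value > threshold``. Ties resolve toward the higher
    (more specific) threshold."""
    uniq = np.unique(values)
    if len(uniq) == 1:
        cuts = np.array([uniq[0]])
    else:
        cuts = (uniq[:-1] + uniq[1:]) / 2
    pos, neg = labels, ~labels
    best = None
    for t in cuts:
        called = values > t
        sens = (called & pos).sum() / pos.sum()
        spec = (~called & neg).sum() / neg.sum()
        j = sens + spec
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12
                                                   and t > best[1]):
            best = (j, float(t), float(sens), float(spec))
    return best[1], best[2], best[3]


def roc_threshold(values: Sequence[float], labels: Sequence[bool],
                  subjects: Optional[Sequence] = None, n_boot: int = 500,
                  rng: Optional[np.random.Generator] = None) -> ROCResult:
    """ROC analysis: rank-based AUC, Youden-optimal threshold, bootstrap CI.

    The 95% CI resamples subjects (not rows) when subject ids are given, so
    within-subject correlation of branches does not shrink the interval.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    subjects = np.asarray(subjects)[keep] if subjects is not None else None
    if labels.all() or not labels.any():
        raise SpecificationError("ROC needs observations from both classes")
    auc = auc_mann_whitney(values, labels)
    thr, sens, spec = _youden_threshold(values, labels)

    rng = rng or np.random.default_rng(0)
    boots = []
    if subjects is not None:
        uniq = np.unique(subjects)
        groups = {s: np.flatnonzero(subjects == s) for s in uniq}
        for _ in range(n_boot):
            pick = rng.choice(uniq, size=len(uniq), replace=True)
            idx = np.concatenate([groups[s] for s in pick])
            if labels[idx].all() or not labels[idx].any():
                continue
            boots.append(auc_mann_whitney(values[idx], labels[idx]))
    else:
        n = len(values)
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            if labels[idx].all() or not labels[idx].any():
                continue
            boots.append(auc_mann_whitney(values[idx], labels[idx]))
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        lo, hi = min(lo, auc), max(hi, auc)
    else:
        lo = hi = auc
    return ROCResult(auc=auc, auc_ci=(float(lo), float(hi)), threshold=thr,
                     sensitivity=sens, specificity=spec,
                     n_pos=int(labels.sum()), n_neg=int((~labels).sum()))


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    icc: float
    var_components: Dict[str, float] = field(default_factory=dict)
    band: str = ""


def icc_band(icc: float) -> str:
    """Agreement bands: <0.4 below-moderate, 0.4-0.6 moderate, 0.6-0.8 good,
    >=0.8 very good."""
    if icc >= 0.8:
        return "very good"
    if icc >= 0.6:
        return "good"
    if icc >= 0.4:
        return "moderate"
    return "below-moderate"


def compute_icc(data: pd.DataFrame, value_col: str = "value",
                target_col: str = "branch_id",
                subject_col: Optional[str] = None,
                generation_col: Optional[str] = None) -> ICCResult:
    """Agreement ICC from a hierarchical variance-components model.

    Repeated measurements (>= 2 per target) are decomposed into
    between-target and within-target (replication) variance; when subject
    and generation columns are given the nesting branch-within-generation-
    within-subject is respected and all between-target strata count toward
    agreement:

        ICC = (var_subject + var_generation + var_branch) / total variance
    """
    counts = data.groupby(target_col)[value_col].count()
    if (counts < 2).all():
        raise SpecificationError(
            "ICC needs >= 2 measurements per target (no replication found)")

    within = data.groupby(target_col)[value_col].var(ddof=1)
    if np.allclose(within.fillna(0.0), 0.0):
        # perfect agreement: replicates identical for every target
        return ICCResult(icc=1.0, var_components={"residual": 0.0},
                         band=icc_band(1.0))

    df = data.rename(columns={value_col: "y"}).copy()
    if subject_col and generation_col and df[subject_col].nunique() > 1:
        vc = {"generation": f"0 + C({generation_col})",
              "branch": f"0 + C({target_col})"}
        model = smf.mixedlm("y ~ 1", df, groups=df[subject_col],
                            re_formula="1", vc_formula=vc)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True, method=["powell", "cg"], maxiter=500)
        var_subject = float(np.asarray(fit.cov_re)[0, 0])
        try:
            names = list(model.exog_vc.names)
        except AttributeError:
            names = list(vc.keys())
        vcomp = dict(zip(names, np.asarray(fit.vcomp, dtype=float)))
        var_gen = float(vcomp.get("generation", 0.0))
        var_branch = float(vcomp.get("branch", 0.0))
        var_resid = float(fit.scale)
        between = var_subject + var_gen + var_branch
        comps = {"subject": var_subject, "generation": var_gen,
                 "branch": var_branch, "residual": var_resid}
    else:
        model = smf.mixedlm("y ~ 1", df, groups=df[target_col], re_formula="1")
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True, method=["powell", "cg"], maxiter=500)
        between = float(np.asarray(fit.cov_re)[0, 0])
        var_resid = float(fit.scale)
        comps = {"target": between, "residual": var_resid}
    icc = between / (between + var_resid) if between + var_resid > 0 else 0.0
    icc = float(np.clip(icc, 0.0, 1.0))
    return ICCResult(icc=icc, var_components=comps, band=icc_band(icc))


# ---------------------------------------------------------------------------
# nonparametric group tests + regression
# ---------------------------------------------------------------------------

def mann_whitney(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Unpaired two-sample Mann-Whitney U test (cohort comparisons)."""
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


def wilcoxon_signed_rank(paired_a: Sequence[float],
                         paired_b: Sequence[float]) -> Dict[str, float]:
    """Paired Wilcoxon signed-rank test (e.g. inspiration vs expiration
    counts per subject). Identical pairs give p = 1."""
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise SpecificationError(
            f"signed-rank needs paired samples of equal length "
            f"({len(a)} vs {len(b)})")
    if np.all(a == b):
        return {"statistic": 0.0, "p": 1.0}
    res = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


def linear_regression(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Simple linear regression (e.g. AA-pair count vs height or age)."""
    res = sps.linregress(np.asarray(x, float), np.asarray(y, float))
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "p": float(res.pvalue), "r": float(res.rvalue)}


def group_tests(counts: pd.DataFrame,
                count_col: str = "n_ok") -> Dict[str, Dict[str, float]]:
    """The study's nonparametric battery on a per-subject count table.

    Expects one row per (subject_id, volume_state) with ``disease_status``,
    ``age_years``, ``height_cm`` and the count column. Returns Wilcoxon
    signed-rank inspiration-vs-expiration tests per cohort, Mann-Whitney
    CF-vs-control tests per volume state, and count~age / count~height
    regressions.
    """
    needed = {"subject_id", "volume_state", "disease_status", count_col}
    if not needed <= set(counts.columns):
        raise SpecificationError(f"count table missing {needed - set(counts.columns)}")
    wide = counts.pivot_table(index=["subject_id", "disease_status"],
                              columns="volume_state", values=count_col,
                              aggfunc="sum").reset_index()
    if not {"inspiration", "expiration"} <= set(wide.columns):
        raise SpecificationError("need both volume states for paired testing")
    out: Dict[str, Dict[str, float]] = {}
    for status, grp in wide.groupby("disease_status"):
        out[f"wilcoxon_insp_vs_exp_{status}"] = wilcoxon_signed_rank(
            grp["inspiration"], grp["expiration"])
    for state in ("inspiration", "expiration"):
        cf = wide.loc[wide["disease_status"] == "CF", state]
        ctrl = wide.loc[wide["disease_status"] != "CF", state]
        if len(cf) and len(ctrl):
            out[f"mannwhitney_cf_vs_control_{state}"] = mann_whitney(cf, ctrl)
    if {"age_years", "height_cm"} <= set(counts.columns):
        insp = counts[counts["volume_state"] == "inspiration"]
        per = insp.groupby("subject_id").agg(
            n=(count_col, "sum"), age=("age_years", "first"),
            height=("height_cm", "first"))
        if len(per) >= 3:
            out["regression_count_vs_age"] = linear_regression(per["age"], per["n"])
            out["regression_count_vs_height"] = linear_regression(per["height"],
                                                                  per["n"])
    return out
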