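"""Inferential layer of the clinical trial.

Implements the analyses reported for the randomized add-on trial:
ANCOVA on the post score controlling for the pre score (immediate
effect), an intention-to-treat linear mixed model with REML and a
compound-symmetry covariance (subject random intercept) for the
follow-up trajectories, classical repeated-measures ANOVAs (the
within-subject condition x session analysis of the NF signal and the
split-plot group x time analysis of the completers cohort), the
first-five vs last-five session learning contrast, Benjamini-Hochberg
FDR, and loss-of-diagnosis ARR / number-needed-to-treat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .published import TIMEPOINTS

TIME_CODES = {tp: float(i) for i, tp in enumerate(TIMEPOINTS)}


# --------------------------------------------------------------------------
# printed arithmetic


def reduction_delta(pre_mean: float, post_mean: float) -> float:
    """Symptom reduction in scale points: pre minus post."""
    if not (math.isfinite(pre_mean) and math.isfinite(post_mean)):
        raise ValueError("means must be finite")
    return pre_mean - post_mean


def nnt_from_arr(arr: float) -> float:
    """Number needed to treat, the reciprocal absolute risk reduction."""
    if arr <= 0:
        raise ValueError("NNT is defined only for a positive risk reduction")
    return 1.0 / arr


# --------------------------------------------------------------------------
# ANCOVA (immediate effect)


@dataclass
class AncovaResult:
    F: float
    df: tuple
    p: float
    partial_eta_sq: float
    adjusted_group_means: dict
    n: int
    group_effect: float = float("nan")  # adjusted test - control difference


def _wide_scores(table: pd.DataFrame, instrument: str) -> pd.DataFrame:
    sub = table[table["instrument"] == instrument]
    wide = sub.pivot_table(index=["subject_id", "group"], columns="timepoint",
                           values="score", aggfunc="first").reset_index()
    return wide


def ancova_immediate(table: pd.DataFrame, instrument: str = "CAPS5") -> AncovaResult:
    """post ~ pre + group, with the group F-test (listwise deletion).

    partial eta^2 = SS_group / (SS_group + SS_residual).
    """
    wide = _wide_scores(table, instrument)
    if "post" not in wide or "pre" not in wide:
        raise ValueError("table lacks pre/post assessments")
    data = wide.dropna(subset=["pre", "post"]).copy()
    counts = data["group"].value_counts()
    for g in ("test", "control"):
        if counts.get(g, 0) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 complete cases")
    data["grp"] = (data["group"] == "test").astype(float)
    fit = smf.ols("post ~ pre + grp", data=data).fit()
    t_grp = fit.tvalues["grp"]
    n = int(len(data))
    df = (1, n - 3)
    ssr_floor = 1e-12 * float(np.var(data["post"])) * n
    if not math.isfinite(t_grp) or float(fit.ssr) <= ssr_floor:
        # perfect fit (e.g. post identical to pre): the covariate absorbs
        # everything and there is no group effect to test
        F, p = 0.0, 1.0
    else:
        F = float(t_grp**2)
        p = float(fit.pvalues["grp"])
    ss_res = float(fit.ssr)
    ss_group = F * ss_res / df[1]
    eta = ss_group / (ss_group + ss_res) if (ss_group + ss_res) > 0 else 0.0
    pre_bar = float(data["pre"].mean())
    b = fit.params
    adj = {
        "control": float(b["Intercept"] + b["pre"] * pre_bar),
        "test": float(b["Intercept"] + b["grp"] + b["pre"] * pre_bar),
    }
    return AncovaResult(F=F, df=df, p=p, partial_eta_sq=float(eta),
                        adjusted_group_means=adj, n=n,
                        group_effect=float(b["grp"]))


# --------------------------------------------------------------------------
# linear mixed model (intention-to-treat follow-up)


@dataclass
class MixedResult:
    fixed_effects: dict          # term -> {coef, se, F, p}
    sigma2_between: float
    sigma2_within: float
    loglik_reml: float
    converged: bool
    n_subjects: int
    n_obs: int
    time_coding: str


def mixed_model_followup(table: pd.DataFrame, instrument: str = "PCL5",
                         time_coding: str = "numeric") -> MixedResult:
    """REML mixed model: score ~ group + time + group x time.

    The compound-symmetry covariance is fit as a subject random
    intercept (the two parameterizations are equivalent for
    non-negative intraclass correlation).  Missing assessments are
    handled by the likelihood, not imputed.  Time enters as a numeric
    covariate 0..4 over the five assessments by default; ``"categorical"``
    is available as a sensitivity analysis.
    """
    sub = table[table["instrument"] == instrument].copy()
    if sub.empty:
        raise ValueError(f"no rows for instrument {instrument!r}")
    sub["time"] = sub["timepoint"].map(TIME_CODES)
    sub["grp"] = (sub["group"] == "test").astype(float)
    per_subj = sub.groupby("subject_id")["timepoint"].nunique()
    if (per_subj >= 2).mean() < 0.8:
        raise ValueError("fewer than 80% of subjects have >= 2 timepoints")
    if time_coding == "numeric":
        formula = "score ~ grp * time"
        terms = {"group": "grp", "time": "time", "group_x_time": "grp:time"}
    elif time_coding == "categorical":
        formula = "score ~ grp * C(timepoint)"
        terms = None
    else:
        raise ValueError("time_coding must be 'numeric' or 'categorical'")
    model = smf.mixedlm(formula, data=sub, groups=sub["subject_id"])
    res = None
    # boundary fits (random-effect variance -> 0) can break a given
    # optimizer; fall through a chain before flagging non-convergence
    for method in ("lbfgs", "bfgs", "powell", "nm"):
        try:
            import warnings

            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=True, method=method)
            break
        except (np.linalg.LinAlgError, ValueError):
            continue
    if res is None:
        raise RuntimeError("mixed model failed to converge under any optimizer")
    fixed = {}
    if terms is not None:
        for name, key in terms.items():
            coef = float(res.params[key])
            se = float(res.bse[key])
            F = (coef / se) ** 2 if se > 0 else float("nan")
            p = 2 * stats.norm.sf(abs(coef / se)) if se > 0 else float("nan")
            fixed[name] = {"coef": coef, "se": se, "F": float(F), "p": float(p)}
    else:
        wt = res.wald_test_terms(scalar=True)
        for name in wt.table.index:
            fixed[name] = {
                "coef": float("nan"), "se": float("nan"),
                "F": float(wt.table.loc[name, "statistic"]),
                "p": float(wt.table.loc[name, "pvalue"]),
            }
    return MixedResult(
        fixed_effects=fixed,
        sigma2_between=float(res.cov_re.iloc[0, 0]),
        sigma2_within=float(res.scale),
        loglik_reml=float(res.llf),
        converged=bool(res.converged),
        n_subjects=int(sub["subject_id"].nunique()),
        n_obs=int(len(sub)),
        time_coding=time_coding)


# --------------------------------------------------------------------------
# repeated-measures ANOVAs


@dataclass
class RmAnovaResult:
    effects: dict          # name -> {F, df, p, partial_eta_sq}
    n_subjects: int
    n_dropped: int = 0

    def __getitem__(self, key):
        return self.effects[key]


def rm_anova_condition_session(data) -> RmAnovaResult:
    """Two-way fully-within ANOVA: condition (2) x session, classical
    sums-of-squares partition.

    ``data`` is an array (n_subjects, 2, n_sessions) of per-subject
    per-session condition means (row order Watch, Regulate), or a tidy
    DataFrame with columns subject_id, condition, session, value.
    Subjects with incomplete tables are dropped and counted.
    """
    if isinstance(data, pd.DataFrame):
        piv = data.pivot_table(index="subject_id", columns=["condition", "session"],
                               values="value", aggfunc="first")
        sessions = sorted(data["session"].unique())
        conditions = ["Watch", "Regulate"]
        full = len(conditions) * len(sessions)
        complete = piv.dropna()
        n_dropped = len(piv) - len(complete)
        if complete.shape[1] != full:
            raise ValueError("incomplete condition x session grid")
        cube = np.stack([
            complete[c].loc[:, sessions].to_numpy() for c in conditions], axis=1)
    else:
        cube = np.asarray(data, dtype=float)
        n_dropped = int(np.sum(np.isnan(cube).any(axis=(1, 2))))
        cube = cube[~np.isnan(cube).any(axis=(1, 2))]
    n, a, b = cube.shape
    if n < 2:
        raise ValueError("need at least 2 complete subjects")
    grand = cube.mean()
    A = cube.mean(axis=(0, 2))          # condition means
    B = cube.mean(axis=(0, 1))          # session means
    S = cube.mean(axis=(1, 2))          # subject means
    AS = cube.mean(axis=2)              # n x a
    BS = cube.mean(axis=1)              # n x b
    AB = cube.mean(axis=0)              # a x b
    ss_a = n * b * np.sum((A - grand) ** 2)
    ss_b = n * a * np.sum((B - grand) ** 2)
    ss_as = b * np.sum((AS - A[None, :] - S[:, None] + grand) ** 2)
    ss_bs = a * np.sum((BS - B[None, :] - S[:, None] + grand) ** 2)
    ss_ab = n * np.sum((AB - A[:, None] - B[None, :] + grand) ** 2)
    resid = (cube - AS[:, :, None] - BS[:, None, :] - AB[None, :, :]
             + A[None, :, None] + B[None, None, :] + S[:, None, None] - grand)
    ss_abs = np.sum(resid**2)

    def eff(ss_eff, df_eff, ss_err, df_err):
        if df_eff <= 0 or df_err <= 0:
            return {"F": float("nan"), "df": (df_eff, df_err), "p": float("nan"),
                    "partial_eta_sq": float("nan")}
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else float("nan")
        p = float(stats.f.sf(F, df_eff, df_err)) if math.isfinite(F) else float("nan")
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else float("nan")
        return {"F": float(F), "df": (df_eff, df_err), "p": p,
                "partial_eta_sq": float(eta)}

    effects = {
        "condition": eff(ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        "session": eff(ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        "condition_x_session": eff(ss_ab, (a - 1) * (b - 1), ss_abs,
                                   (a - 1) * (b - 1) * (n - 1)),
    }
    return RmAnovaResult(effects=effects, n_subjects=n, n_dropped=n_dropped)


def rm_anova_group_time(table: pd.DataFrame, instrument: str,
                        timepoints=TIMEPOINTS) -> RmAnovaResult:
    """Split-plot ANOVA (group between, time within) on completers.

    Only subjects observed at every requested timepoint enter (the
    per-protocol cohort); the count of dropped subjects is reported.
    """
    wide = _wide_scores(table, instrument)
    cols = [tp for tp in timepoints if tp in wide.columns]
    complete = wide.dropna(subset=cols)
    n_dropped = len(wide) - len(complete)
    groups = complete["group"].to_numpy()
    X = complete[cols].to_numpy(dtype=float)
    n, b = X.shape
    labels = np.unique(groups)
    if n < 2 or labels.size < 2:
        raise ValueError("need completers in both groups")
    grand = X.mean()
    subj_means = X.mean(axis=1)
    time_means = X.mean(axis=0)
    ss_between_subj = b * np.sum((subj_means - grand) ** 2)
    ss_group = 0.0
    ss_gt = 0.0
    for g in labels:
        sel = groups == g
        gmean = X[sel].mean()
        ss_group += b * sel.sum() * (gmean - grand) ** 2
        gt = X[sel].mean(axis=0)
        ss_gt += sel.sum() * np.sum((gt - gmean - time_means + grand) ** 2)
    ss_subj_within = ss_between_subj - ss_group
    ss_time = n * np.sum((time_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err_within = ss_total - ss_between_subj - ss_time - ss_gt
    g = labels.size
    dfs = {
        "group": (g - 1, n - g),
        "time": (b - 1, (n - g) * (b - 1)),
        "group_x_time": ((g - 1) * (b - 1), (n - g) * (b - 1)),
    }
    ss = {"group": (ss_group, ss_subj_within),
          "time": (ss_time, ss_err_within),
          "group_x_time": (ss_gt, ss_err_within)}
    effects = {}
    for name, (ss_eff, ss_err) in ss.items():
        df_eff, df_err = dfs[name]
        ms_eff, ms_err = ss_eff / df_eff, ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else float("nan")
        effects[name] = {
            "F": float(F), "df": (df_eff, df_err),
            "p": float(stats.f.sf(F, df_eff, df_err)) if math.isfinite(F) else float("nan"),
            "partial_eta_sq": float(ss_eff / (ss_eff + ss_err)) if ss_eff + ss_err > 0
            else float("nan"),
        }
    return RmAnovaResult(effects=effects, n_subjects=n, n_dropped=n_dropped)


# --------------------------------------------------------------------------
# learning contrast


@dataclass
class LearningTestResult:
    t: float
    df: int
    p: float
    mean_first5: float
    mean_last5: float
    n: int
    n_excluded: int = 0
    degenerate: bool = False


def paired_learning_test(session_success: np.ndarray) -> LearningTestResult:
    """Paired t-test of mean success over sessions 1-5 vs 6-10.

    ``session_success`` is (n_subjects, 10) with NaN for missing
    sessions; each half is averaged over the available sessions, and
    subjects missing an entire half are excluded (and counted).
    """
    arr = np.asarray(session_success, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 10:
        raise ValueError("expected an (n_subjects, 10) session-success array")
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        first = np.nanmean(arr[:, :5], axis=1)
        last = np.nanmean(arr[:, 5:], axis=1)
    ok = ~(np.isnan(first) | np.isnan(last))
    first, last = first[ok], last[ok]
    n = int(ok.sum())
    if n < 2:
        raise ValueError("need at least 2 subjects with sessions in both halves")
    diff = first - last
    sd = diff.std(ddof=1)
    if sd == 0:
        # identical halves are a well-defined null (t = 0); a constant
        # non-zero difference has no admissible t and is flagged
        if np.all(diff == 0):
            return LearningTestResult(
                t=0.0, df=n - 1, p=1.0,
                mean_first5=float(first.mean()), mean_last5=float(last.mean()),
                n=n, n_excluded=int((~ok).sum()))
        return LearningTestResult(
            t=float("nan"), df=n - 1, p=float("nan"),
            mean_first5=float(first.mean()), mean_last5=float(last.mean()),
            n=n, n_excluded=int((~ok).sum()), degenerate=True)
    t = float(diff.mean() / (sd / math.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return LearningTestResult(
        t=t, df=n - 1, p=p,
        mean_first5=float(first.mean()), mean_last5=float(last.mean()),
        n=n, n_excluded=int((~ok).sum()))


# --------------------------------------------------------------------------
# multiplicity and loss-of-diagnosis effect sizes


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class NNTResult:
    p_test: float
    p_control: float
    arr: float
    nnt: float
    ci_arr: tuple
    ci_nnt: tuple | None
    beneficial: bool


def arr_and_nnt(loss_test: int, n_test: int, loss_control: int, n_control: int,
                alpha: float = 0.05) -> NNTResult:
    """Absolute risk reduction for loss of diagnosis, and its NNT.

    The ARR confidence interval uses the Newcombe hybrid score method
    (Wilson limits per group); the NNT interval is the reciprocal of the
    ARR interval when the reduction is beneficial throughout.
    """
    if not (0 <= loss_test <= n_test and 0 <= loss_control <= n_control):
        raise ValueError("counts must lie within group sizes")
    p1 = loss_test / n_test
    p2 = loss_control / n_control
    arr = p1 - p2
    l1, u1 = proportion_confint(loss_test, n_test, alpha=alpha, method="wilson")
    l2, u2 = proportion_confint(loss_control, n_control, alpha=alpha, method="wilson")
    lower = arr - math.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
    upper = arr + math.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    beneficial = arr > 0
    nnt = 1.0 / arr if beneficial else float("nan")
    ci_nnt = (1.0 / upper, 1.0 / lower) if (beneficial and lower > 0) else None
    return NNTResult(p_test=p1, p_control=p2, arr=arr, nnt=nnt,
                     ci_arr=(lower, upper), ci_nnt=ci_nnt, beneficial=beneficial)


# --------------------------------------------------------------------------
# power utility (not a primary endpoint)


def required_sample_size(partial_eta_sq: float = 0.16, alpha: float = 0.05,
                         power: float = 0.8, df1: int = 1,
                         n_model_params: int = 3, n_max: int = 1000) -> int:
    """Smallest total N achieving the target power for an F-test of the
    given partial eta^2 (noncentral-F computation)."""
    f2 = partial_eta_sq / (1.0 - partial_eta_sq)
    for n in range(n_model_params + 2, n_max):
        df2 = n - n_model_params
        crit = stats.f.isf(alpha, df1, df2)
        lam = f2 * n
        if stats.ncf.sf(crit, df1, df2, lam) >= power:
            return n
    raise ValueError("no sample size below n_max achieves the target power")


# --------------------------------------------------------------------------
# full trial bundle


def diagnosis_loss_counts(table: pd.DataFrame) -> dict:
    """Per-group loss-of-diagnosis counts at the post assessment."""
    post = table[(table["timepoint"] == "post") & (table["instrument"] == "CAPS5")]
    post = post.dropna(subset=["diagnosis"])
    out = {}
    for g in ("test", "control"):
        sel = post[post["group"] == g]
        out[g] = {"lost": int((~sel["diagnosis"].astype(bool)).sum()),
                  "n": int(len(sel))}
    return out


def analyze_trial(table: pd.DataFrame, session_success: np.ndarray | None = None,
                  session_condition_means=None) -> dict:
    """Run the full inferential bundle on a clinical table.

    Returns a JSON-serializable dict with five blocks: ancova (CAPS-5
    immediate effect), nnt (loss of diagnosis), mixed_model (PCL-5 and
    DES-II intention-to-treat), per_protocol (completers split-plot
    ANOVA), and learning (NF session analyses, present when session
    data are supplied).
    """
    from dataclasses import asdict

    anc = ancova_immediate(table, "CAPS5")
    counts = diagnosis_loss_counts(table)
    nnt = arr_and_nnt(counts["test"]["lost"], counts["test"]["n"],
                      counts["control"]["lost"], counts["control"]["n"])
    mixed = {inst: asdict(mixed_model_followup(table, inst))
             for inst in ("PCL5", "DES2")}
    per_protocol = {inst: asdict(rm_anova_group_time(table, inst))
                    for inst in ("PCL5", "DES2")}
    result = {
        "ancova": asdict(anc),
        "nnt": asdict(nnt),
        "mixed_model": mixed,
        "per_protocol": per_protocol,
        "learning": None,
    }
    if session_success is not None:
        learning = {"paired_test": asdict(paired_learning_test(session_success))}
        if session_condition_means is not None:
            learning["rm_anova"] = asdict(
                rm_anova_condition_session(session_condition_means))
        result["learning"] = learning
    return result


__all__ = [
    "reduction_delta", "nnt_from_arr", "AncovaResult", "ancova_immediate",
    "MixedResult", "mixed_model_followup", "RmAnovaResult",
    "rm_anova_condition_session", "rm_anova_group_time",
    "LearningTestResult", "paired_learning_test", "bh_fdr",
    "NNTResult", "arr_and_nnt", "required_sample_size",
    "diagnosis_loss_counts", "analyze_trial", "TIME_CODES",
]
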