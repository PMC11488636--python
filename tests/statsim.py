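"""Shared simulation helpers for the statistics tests.

Small, fast generators of null / effect datasets in the shapes the
trial-statistics layer consumes, plus a directly-coded compound-symmetry
REML log-likelihood used as an independent oracle for the mixed model.
"""

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from efpnf.trial import TIME_CODES, TIMEPOINTS


def ancova_frame(n1=20, n2=20, gap=0.0, sd=8.0, slope=0.6, rng=None,
                 pre=None):
    """Pre/post long table; ``gap`` is the true adjusted group difference."""
    rng = rng or np.random.default_rng()
    if pre is None:
        pre = 40.0 + 9.0 * rng.standard_normal(n1 + n2)
    groups = ["test"] * n1 + ["control"] * n2
    post = (slope * pre + gap * (np.arange(n1 + n2) < n1)
            + sd * rng.standard_normal(n1 + n2))
    rows = []
    for i, (g, a, b) in enumerate(zip(groups, pre, post)):
        rows.append({"subject_id": f"S{i}", "group": g, "timepoint": "pre",
                     "instrument": "CAPS5", "score": a, "diagnosis": True})
        rows.append({"subject_id": f"S{i}", "group": g, "timepoint": "post",
                     "instrument": "CAPS5", "score": b, "diagnosis": None})
    return pd.DataFrame(rows)


def longitudinal_frame(n1=25, n2=15, interaction=0.0, s_b=2.0, s_w=3.0,
                       rng=None, instrument="PCL5"):
    """Five-timepoint long table with a subject random intercept.

    ``interaction`` is the true per-unit-time slope difference
    (test minus control).
    """
    rng = rng or np.random.default_rng()
    rows = []
    for i in range(n1 + n2):
        g = "test" if i < n1 else "control"
        u = s_b * rng.standard_normal()
        for tp in TIMEPOINTS:
            t = TIME_CODES[tp]
            mu = 40.0 + u + (interaction * t if g == "test" else 0.0)
            rows.append({"subject_id": f"S{i}", "group": g, "timepoint": tp,
                         "instrument": instrument,
                         "score": mu + s_w * rng.standard_normal(),
                         "diagnosis": None})
    return pd.DataFrame(rows)


def cs_reml_loglik(table, instrument="PCL5"):
    """Directly maximized compound-symmetry REML log-likelihood.

    Builds the marginal covariance V_i = s2w I + s2b J per subject and
    evaluates the standard REML criterion
    -0.5 [log|V| + log|X' V^-1 X| + r' V^-1 r + (n-p) log 2 pi],
    maximized over (s2b, s2w) by Nelder-Mead.  Independent of the
    statsmodels route used by the implementation.
    """
    sub = table[table["instrument"] == instrument].copy()
    sub["time"] = sub["timepoint"].map(TIME_CODES)
    sub["grp"] = (sub["group"] == "test").astype(float)
    X = np.column_stack([np.ones(len(sub)), sub["grp"], sub["time"],
                         sub["grp"] * sub["time"]])
    y = sub["score"].to_numpy()
    subjects = sub["subject_id"].to_numpy()
    uniq = pd.unique(subjects)
    p = X.shape[1]

    def loglik(params):
        s2b, s2w = params
        if s2b < 0 or s2w <= 1e-10:
            return -1e12
        logdet = quad = 0.0
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        blocks = []
        for s in uniq:
            idx = subjects == s
            ni = int(idx.sum())
            V = s2w * np.eye(ni) + s2b * np.ones((ni, ni))
            Vi = np.linalg.inv(V)
            logdet += np.linalg.slogdet(V)[1]
            XtVX += X[idx].T @ Vi @ X[idx]
            XtVy += X[idx].T @ Vi @ y[idx]
            blocks.append((idx, Vi))
        beta = np.linalg.solve(XtVX, XtVy)
        for idx, Vi in blocks:
            r = y[idx] - X[idx] @ beta
            quad += r @ Vi @ r
        n = y.size
        return -0.5 * (logdet + np.linalg.slogdet(XtVX)[1] + quad
                       + (n - p) * np.log(2 * np.pi))

    res = minimize(lambda th: -loglik(th), x0=[2.0, 5.0], method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 8000})
    return -res.fun


def session_success_cohort(agent, n_subjects, seed):
    """Per-subject 10-session success matrix from the agent-level course."""
    from efpnf.nf import simulate_session_successes

    ss = np.random.SeedSequence(seed)
    return np.stack([simulate_session_successes(agent, seed=s)
                     for s in ss.spawn(n_subjects)])
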