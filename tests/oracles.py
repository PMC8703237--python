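"""Independent brute-force oracles used to check the package's operations.

Each oracle is a direct transcription of the defining formula, kept free of
any code path it is used to verify.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def brute_force_auc(scores, labels) -> float:
    """AUC by exhaustive pairwise counting with ties scored 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def bh_stepup(pvals) -> np.ndarray:
    """Textbook Benjamini-Hochberg adjusted p-values.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, mapped back to the
    input order.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = running
    return q


def efron_negloglik(beta, X, time, event) -> float:
    """Negative Efron partial log-likelihood."""
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    for ut in np.unique(time[event == 1]):
        D = (time == ut) & (event == 1)
        R = time >= ut
        d = int(D.sum())
        ll += eta[D].sum()
        s_risk, s_dead = w[R].sum(), w[D].sum()
        for l in range(d):
            ll -= np.log(s_risk - (l / d) * s_dead)
    return -ll


def fit_cox_brute_force(X, time, event) -> np.ndarray:
    """Newton-type optimization of the Efron partial likelihood."""
    X = np.asarray(X, dtype=float)
    res = minimize(efron_negloglik, np.zeros(X.shape[1]),
                   args=(X, np.asarray(time, dtype=float),
                         np.asarray(event, dtype=int)),
                   method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
    return res.x


def ols_effect(D, y_col) -> tuple[float, float]:
    """(beta, se) of the second design column by the normal equations."""
    D = np.asarray(D, dtype=float)
    y = np.asarray(y_col, dtype=float)
    xtx_inv = np.linalg.inv(D.T @ D)
    beta = xtx_inv @ D.T @ y
    resid = y - D @ beta
    dof = len(y) - D.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    return float(beta[1]), float(se)
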