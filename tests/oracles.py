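"""Independent reference computations used only by the test suite.

These deliberately avoid the code paths they check: the group-L1
oracle minimizes a smoothed objective over the null-space
parametrization of the constraint with BFGS (no ADMM, no shrinkage,
no polish), and the ANOVA oracle computes textbook sums of squares
longhand.
"""

import numpy as np
from scipy import linalg as sla
from scipy.optimize import minimize


def group_l1_oracle(A, b, weights, group_size=4, mus=(1e-2, 1e-4, 1e-6, 1e-9)):
    """Minimum of sum w_i ||x_i|| s.t. Ax = b via smoothing + BFGS.

    Feasible set parametrized as x0 + N t with x0 the least-squares
    particular solution and N an orthonormal null-space basis; the
    nonsmooth objective is replaced by sum w_i sqrt(||x_i||^2 + mu^2)
    with mu-continuation, warm-starting each stage.
    Returns (objective, x).
    """
    A = np.asarray(A, float)
    b = np.asarray(b, float).ravel()
    w = np.asarray(weights, float).ravel()
    x0, *_ = np.linalg.lstsq(A, b, rcond=None)
    N = sla.null_space(A)

    def fun_grad(t, mu):
        x = x0 + N @ t
        blocks = x.reshape(-1, group_size)
        norms = np.sqrt(np.sum(blocks**2, axis=1) + mu**2)
        f = float(w @ norms)
        gx = (blocks * (w / norms)[:, None]).ravel()
        return f, N.T @ gx

    t = np.zeros(N.shape[1])
    for mu in mus:
        res = minimize(
            fun_grad, t, args=(mu,), jac=True, method="BFGS",
            options={"gtol": 1e-12, "maxiter": 2000},
        )
        t = res.x
    x = x0 + N @ t
    blocks = x.reshape(-1, group_size)
    obj = float(w @ np.linalg.norm(blocks, axis=1))
    return obj, x


def single_source_enumeration(A, b, weights, group_size=4, tol=1e-9):
    """All groups whose columns alone fit b exactly (least squares)."""
    n = A.shape[1] // group_size
    hits = []
    for i in range(n):
        Ai = A[:, group_size * i : group_size * (i + 1)]
        xi, *_ = np.linalg.lstsq(Ai, b, rcond=None)
        if np.linalg.norm(Ai @ xi - b) <= tol * max(1.0, np.linalg.norm(b)):
            hits.append((i, float(weights[i] * np.linalg.norm(xi))))
    return hits


def rm_anova_longhand(values):
    """Two-way within-subject ANOVA sums of squares, textbook formulas.

    values: (subjects, a_levels, b_levels).  Returns dict of
    (F, df1, df2) per effect.
    """
    y = np.asarray(values, float)
    s, a, b = y.shape
    grand = y.mean()
    # means
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = s * b * np.sum((m_a - grand) ** 2)
    ss_b = s * a * np.sum((m_b - grand) ** 2)
    ss_ab = s * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_sab = np.sum(
        (
            y
            - m_sa[:, :, None]
            - m_sb[:, None, :]
            - m_ab[None, :, :]
            + m_s[:, None, None]
            + m_a[None, :, None]
            + m_b[None, None, :]
            - grand
        )
        ** 2
    )
    out = {}
    df_a, df_b = a - 1, b - 1
    out["A"] = (
        (ss_a / df_a) / (ss_sa / ((s - 1) * df_a)),
        df_a,
        (s - 1) * df_a,
    )
    if b > 1:
        out["B"] = (
            (ss_b / df_b) / (ss_sb / ((s - 1) * df_b)),
            df_b,
            (s - 1) * df_b,
        )
        out["A*B"] = (
            (ss_ab / (df_a * df_b)) / (ss_sab / ((s - 1) * df_a * df_b)),
            df_a * df_b,
            (s - 1) * df_a * df_b,
        )
    return out
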