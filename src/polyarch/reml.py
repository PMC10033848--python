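"""Restricted maximum likelihood for linear variance-component models.

The engine fits models ``y = X b + sum_k u_k`` where the covariance of y is
``V(theta) = sum_k theta_k V_k`` with known symmetric structure matrices
``V_k`` (e.g. ``Z K Z'`` for an additive genetic term with a genomic or
pedigree relationship matrix ``K``, identity or per-site diagonal blocks for
residuals, and cross-trait blocks for bivariate models). Updates are
average-information (AI) steps with step-halving on the restricted
log-likelihood and non-negativity projection for variance components;
convergence is declared when the restricted log-likelihood changes by less
than ``tol``.

Two computational paths share the same update algebra: a dense path for
arbitrary structures, and a fast diagonal path used when every structure
matrix is diagonal (after an eigen-rotation of a single relationship matrix,
the common univariate case).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

_JITTER = 1e-8


@dataclass
class Component:
    """One variance component: a name, a structure matrix, and whether the
    coefficient is a variance (constrained >= 0) or a free covariance."""

    name: str
    matrix: np.ndarray  # dense (n, n) or 1-D diagonal
    is_variance: bool = True

    @property
    def diag_only(self) -> bool:
        return self.matrix.ndim == 1


@dataclass
class REMLResult:
    theta: dict
    loglik: float
    beta: np.ndarray
    beta_cov: np.ndarray
    component_cov: np.ndarray
    component_names: list[str]
    converged: bool
    n_iter: int
    py: np.ndarray  # P y at the optimum (original coordinates)
    vinv_diag_path: bool = False
    extra: dict = field(default_factory=dict)


def _build_v(components: list[Component], theta: np.ndarray, n: int):
    if all(c.diag_only for c in components):
        d = np.zeros(n)
        for c, t in zip(components, theta):
            d = d + t * c.matrix
        return ("diag", d)
    V = np.zeros((n, n))
    for c, t in zip(components, theta):
        if c.diag_only:
            V[np.diag_indices(n)] += t * c.matrix
        else:
            V = V + t * c.matrix
    return ("dense", V)


def _reml_quantities(kind, V, X, y):
    """Return loglik, P-action closures, and pieces needed for scores."""
    n, p = X.shape
    if kind == "diag":
        d = np.maximum(V, _JITTER * max(float(V.max()), 1.0))
        vinv_y = y / d
        vinv_X = X / d[:, None]
        logdet_v = float(np.sum(np.log(d)))
        xtvx = X.T @ vinv_X
        B = linalg.inv(xtvx)
        beta = B @ (vinv_X.T @ y)
        py = vinv_y - vinv_X @ (B @ (vinv_X.T @ y))

        def p_dot(v):
            return v / d - vinv_X @ (B @ (vinv_X.T @ v))

        def p_diag_weighted(w):
            # tr(P diag(w)) = sum_i w_i P_ii
            pii = 1.0 / d - np.einsum("ij,jk,ik->i", vinv_X, B, vinv_X)
            return float(np.dot(w, pii))

        trace_fn = ("diag", p_diag_weighted)
    else:
        Vm = V + _JITTER * np.trace(V) / n * np.eye(n)
        cf = linalg.cho_factor(Vm, lower=True)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        vinv = linalg.cho_solve(cf, np.eye(n))
        vinv_X = vinv @ X
        xtvx = X.T @ vinv_X
        B = linalg.inv(xtvx)
        P = vinv - vinv_X @ B @ vinv_X.T
        beta = B @ (vinv_X.T @ y)
        py = P @ y

        def p_dot(v):
            return P @ v

        trace_fn = ("dense", P)

    sign, logdet_x = np.linalg.slogdet(xtvx)
    loglik = -0.5 * (logdet_v + logdet_x + float(y @ py))
    return loglik, beta, B, py, p_dot, trace_fn


def _score_and_ai(components, theta, X, y, kind, V):
    n = len(y)
    loglik, beta, B, py, p_dot, trace = _reml_quantities(kind, V, X, y)
    k = len(components)
    t_vecs = []
    tr_pv = np.empty(k)
    for i, c in enumerate(components):
        if c.diag_only:
            t_vecs.append(c.matrix * py)
            if trace[0] == "diag":
                tr_pv[i] = trace[1](c.matrix)
            else:
                tr_pv[i] = float(np.dot(np.diag(trace[1]), c.matrix))
        else:
            t_vecs.append(c.matrix @ py)
            tr_pv[i] = float(np.sum(trace[1] * c.matrix))
    score = np.empty(k)
    ai = np.empty((k, k))
    p_t = [p_dot(t) for t in t_vecs]
    # score_i = -0.5 (tr(P V_i) - y' P V_i P y), and y' P V_i P y = py . t_i
    for i in range(k):
        score[i] = -0.5 * (tr_pv[i] - float(py @ t_vecs[i]))
    for i in range(k):
        for j in range(i, k):
            ai[i, j] = ai[j, i] = 0.5 * float(t_vecs[i] @ p_t[j])
    return loglik, beta, B, py, score, ai


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    components: list[Component],
    theta0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 200,
    psd_pairs: list[tuple[int, int, int]] | None = None,
) -> REMLResult:
    """AI-REML with EM-style safeguarding.

    ``psd_pairs`` lists (var_i, var_j, cov_ij) index triples whose implied
    2x2 covariance blocks are projected to (near-)PSD after each update,
    used by bivariate models.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    vary = float(np.var(y)) or 1.0
    floor = 1e-8 * vary
    k = len(components)
    if theta0 is None:
        n_var = sum(c.is_variance for c in components)
        theta = np.array(
            [vary / max(n_var, 1) if c.is_variance else 0.0 for c in components]
        )
    else:
        theta = np.asarray(theta0, dtype=float).copy()

    def project(th):
        th = th.copy()
        for i, c in enumerate(components):
            if c.is_variance and th[i] < floor:
                th[i] = floor
        if psd_pairs:
            for (i, j, c_ij) in psd_pairs:
                lim = 0.999 * np.sqrt(th[i] * th[j])
                th[c_ij] = float(np.clip(th[c_ij], -lim, lim))
        return th

    theta = project(theta)
    kind, V = _build_v(components, theta, n)
    loglik, beta, B, py, score, ai = _score_and_ai(components, theta, X, y, kind, V)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ai_reg = ai + np.eye(k) * (1e-10 + 1e-8 * np.trace(ai) / k)
        try:
            delta = linalg.solve(ai_reg, score, assume_a="pos")
        except linalg.LinAlgError:
            delta = score / np.maximum(np.diag(ai_reg), 1e-12)
        step = 1.0
        accepted = False
        for _ in range(25):
            cand = project(theta + step * delta)
            kind_c, V_c = _build_v(components, cand, n)
            try:
                ll_c, beta_c, B_c, py_c, score_c, ai_c = _score_and_ai(
                    components, cand, X, y, kind_c, V_c
                )
            except (linalg.LinAlgError, np.linalg.LinAlgError):
                step *= 0.5
                continue
            if np.isfinite(ll_c) and ll_c >= loglik - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        dl = ll_c - loglik
        theta, loglik, beta, B, py, score, ai = cand, ll_c, beta_c, B_c, py_c, score_c, ai_c
        if abs(dl) < tol:
            converged = True
            break

    ai_reg = ai + np.eye(k) * (1e-12 + 1e-10 * np.trace(ai) / k)
    try:
        comp_cov = linalg.inv(ai_reg)
    except linalg.LinAlgError:
        comp_cov = np.full((k, k), np.nan)
    names = [c.name for c in components]
    theta_out = {nm: (0.0 if (c.is_variance and t <= 2 * floor) else float(t))
                 for nm, c, t in zip(names, components, theta)}
    return REMLResult(
        theta=theta_out,
        loglik=float(loglik),
        beta=beta,
        beta_cov=B,
        component_cov=comp_cov,
        component_names=names,
        converged=converged,
        n_iter=it,
        py=py,
    )
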