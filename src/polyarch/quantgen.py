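"""Mixed-model quantitative genetics: heritability, correlations, breeding
values, adjusted phenotypes, Wald tests, and inbreeding-depression models.

The central model is ``y = X b + Z a + e`` with ``a ~ N(0, K s2_g)`` for a
genomic (GBLUP) or pedigree (ABLUP) relationship matrix ``K``, and residuals
either homogeneous or split by site. Narrow-sense heritability is
``h2 = s2_g / (s2_g + mean site residual variance)`` with a first-order
delta-method standard error from the average-information matrix. Genetic and
phenotypic correlations come from bivariate fits with an unstructured 2x2
genetic and residual covariance.

Fixed-effect terms are named by data columns; object/categorical/integer
columns enter as treatment-coded factors, float columns as covariates, and
``"a:b"`` denotes an interaction. Wald F-tests use the numerator rank of the
term and residual denominator degrees of freedom ``n - rank(X)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .containers import DosageMatrix
from .relatedness import RelationshipMatrix, compute_grrm
from .reml import Component, fit_reml


# ---------------------------------------------------------------------------
# design matrices


def _is_categorical(col: pd.Series) -> bool:
    return not pd.api.types.is_float_dtype(col)


def _term_columns(data: pd.DataFrame, term: str):
    """Columns and names for one term (main effect or ':' interaction)."""
    parts = term.split(":")
    mats = []
    for p in parts:
        col = data[p]
        if _is_categorical(col):
            levels = pd.unique(col.astype(str))
            levels = sorted(levels)
            dummies = np.column_stack(
                [(col.astype(str) == lv).to_numpy(float) for lv in levels[1:]]
            ) if len(levels) > 1 else np.empty((len(col), 0))
            mats.append((dummies, [f"{p}[{lv}]" for lv in levels[1:]]))
        else:
            mats.append((col.to_numpy(float)[:, None], [p]))
    X, names = mats[0]
    for M, nms in mats[1:]:
        X = np.einsum("ni,nj->nij", X, M).reshape(len(X), -1)
        names = [f"{a}:{b}" for a in names for b in nms]
    return X, names


def build_design(data: pd.DataFrame, fixed_terms: list[str]):
    """Build a fixed-effects design matrix with an intercept.

    Returns ``(X, term_slices, names)``; ``term_slices`` maps each term to
    its column indices. Aliased (exactly collinear) columns are dropped,
    keeping the earliest.
    """
    blocks = [np.ones((len(data), 1))]
    names = ["(Intercept)"]
    term_slices: dict[str, list[int]] = {"(Intercept)": [0]}
    col = 1
    for term in fixed_terms:
        M, nms = _term_columns(data, term)
        idx = list(range(col, col + M.shape[1]))
        term_slices[term] = idx
        blocks.append(M)
        names.extend(nms)
        col += M.shape[1]
    X = np.hstack(blocks)
    # drop aliased columns (keep earliest)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        kept_idx = np.where(keep)[0]
        remap = {int(old): new for new, old in enumerate(kept_idx)}
        X = X[:, kept_idx]
        names = [names[i] for i in kept_idx]
        term_slices = {
            t: [remap[i] for i in idx if i in remap] for t, idx in term_slices.items()
        }
    return X, term_slices, names


@dataclass
class ModelSpec:
    """Declarative model description bound to phenotype-table columns."""

    response: str
    fixed: list[str] = field(default_factory=lambda: ["site"])
    random_kind: str = "additive"  # bound to the supplied K
    residual: str = "homogeneous"  # or "by_site"
    site_col: str = "site"
    id_col: str = "id"


@dataclass
class REMLFit:
    """Fitted univariate mixed model."""

    spec: ModelSpec
    varcomp: dict
    component_cov: np.ndarray
    component_names: list[str]
    beta: np.ndarray
    beta_cov: np.ndarray
    beta_names: list[str]
    term_slices: dict
    blup: pd.Series
    blup_se: pd.Series | None  # prediction-error SE, sqrt(PEV)
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    rank_x: int

    @property
    def sigma_g2(self) -> float:
        return self.varcomp["genetic"]

    def residual_components(self) -> list[float]:
        return [v for k, v in self.varcomp.items() if k.startswith("residual")]


def _z_matrix(ids: list[str], k_ids: list[str]) -> np.ndarray:
    pos = {s: i for i, s in enumerate(k_ids)}
    Z = np.zeros((len(ids), len(k_ids)))
    for r, s in enumerate(ids):
        if s not in pos:
            raise ValueError(f"individual {s!r} missing from relationship matrix")
        Z[r, pos[s]] = 1.0
    return Z


def fit_univariate_reml(
    spec: ModelSpec,
    data: pd.DataFrame,
    K: RelationshipMatrix,
    tol: float = 1e-9,
    max_iter: int = 200,
    compute_pev: bool = True,
) -> REMLFit:
    """REML fit of ``y = X b + Z a + e`` with ``a ~ N(0, K s2_g)``.

    Uses an eigen-rotated O(n) path when each observation maps to a distinct
    relationship-matrix entry and residuals are homogeneous; otherwise the
    dense path. BLUPs of all K individuals are returned with prediction
    error SEs (``compute_pev=False`` skips the O(n^3) PEV pass).
    """
    y = data[spec.response].to_numpy(float)
    if np.var(y) == 0:
        raise ValueError("response has zero variance")
    X, term_slices, names = build_design(data, spec.fixed)
    ids = list(data[spec.id_col].astype(str))
    Z = _z_matrix(ids, K.ids)
    n = len(y)
    identity_map = (
        n == len(K.ids) and np.array_equal(Z.sum(axis=0), np.ones(len(K.ids)))
    )
    if spec.residual == "homogeneous" and identity_map:
        ZKZ = Z @ K.values @ Z.T
        w, U = linalg.eigh(ZKZ)
        w = np.maximum(w, 0.0)
        y_r = U.T @ y
        X_r = U.T @ X
        comps = [
            Component("genetic", w, True),
            Component("residual", np.ones(n), True),
        ]
        res = fit_reml(y_r, X_r, comps, tol=tol, max_iter=max_iter)
        py = U @ res.py
    else:
        comps = [Component("genetic", Z @ K.values @ Z.T, True)]
        if spec.residual == "by_site":
            sites = data[spec.site_col].to_numpy()
            for s in sorted(pd.unique(sites), key=str):
                comps.append(
                    Component(f"residual[{s}]", (sites == s).astype(float), True)
                )
        else:
            comps.append(Component("residual", np.ones(n), True))
        res = fit_reml(y, X, comps, tol=tol, max_iter=max_iter)
        py = res.py

    sg = res.theta["genetic"]
    a_hat = sg * (K.values @ (Z.T @ py))
    blup = pd.Series(a_hat, index=list(K.ids))
    blup_se = None
    if compute_pev:
        # PEV diag: Var(a - a_hat) = sg K - sg^2 K Z' P Z K
        V = sg * (Z @ K.values @ Z.T)
        if spec.residual == "by_site":
            sites = data[spec.site_col].to_numpy()
            rv = np.array([res.theta[f"residual[{s}]"] for s in sites])
            V[np.diag_indices(n)] += rv
        else:
            V[np.diag_indices(n)] += res.theta["residual"]
        V += 1e-8 * np.trace(V) / n * np.eye(n)
        vinv = linalg.inv(V)
        vinv_X = vinv @ X
        P = vinv - vinv_X @ linalg.inv(X.T @ vinv_X) @ vinv_X.T
        ZK = Z @ K.values
        pev = sg * np.diag(K.values) - sg**2 * np.einsum("ij,ij->j", ZK, P @ ZK)
        blup_se = pd.Series(np.sqrt(np.clip(pev, 0.0, None)), index=list(K.ids))
    rank_x = np.linalg.matrix_rank(X)
    return REMLFit(
        spec=spec,
        varcomp=res.theta,
        component_cov=res.component_cov,
        component_names=res.component_names,
        beta=res.beta,
        beta_cov=res.beta_cov,
        beta_names=names,
        term_slices=term_slices,
        blup=blup,
        blup_se=blup_se,
        loglik=res.loglik,
        converged=res.converged,
        n_iter=res.n_iter,
        n_obs=n,
        rank_x=rank_x,
    )


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float


def estimate_h2(fit: REMLFit) -> HeritabilityEstimate:
    """``h2 = s2_g / (s2_g + mean(site residual variances))`` with a
    first-order delta-method SE from the AI-matrix inverse."""
    sg = fit.varcomp["genetic"]
    resid = fit.residual_components()
    if not resid:
        raise ValueError("no residual components in fit")
    ebar = float(np.mean(resid))
    tot = sg + ebar
    if tot <= 0:
        raise ValueError("total variance is zero; h2 undefined")
    h2 = sg / tot
    # gradient in component order
    grad = np.zeros(len(fit.component_names))
    s = len(resid)
    for i, nm in enumerate(fit.component_names):
        if nm == "genetic":
            grad[i] = ebar / tot**2
        elif nm.startswith("residual"):
            grad[i] = -sg / (s * tot**2)
    se = float(np.sqrt(max(0.0, grad @ fit.component_cov @ grad)))
    return HeritabilityEstimate(h2=float(np.clip(h2, 0.0, 1.0)), se=se)


@dataclass
class CorrelationEstimate:
    r_g: float
    r_g_se: float
    r_p: float
    r_p_se: float
    components: dict
    boundary: bool


def fit_bivariate_reml(
    spec1: ModelSpec,
    spec2: ModelSpec,
    data: pd.DataFrame,
    K: RelationshipMatrix,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> CorrelationEstimate:
    """Bivariate REML with unstructured 2x2 genetic and residual covariance.

    Genetic correlation ``r_g = cov_g / sqrt(Vg1 Vg2)``; phenotypic
    correlation ``r_p = (cov_g + cov_e) / sqrt((Vg1+Ve1)(Vg2+Ve2))``. SEs by
    the delta method on the component covariance matrix. If either genetic
    variance sits at the zero boundary, ``r_g`` is NaN and flagged.
    """
    y1 = data[spec1.response].to_numpy(float)
    y2 = data[spec2.response].to_numpy(float)
    X1, _, _ = build_design(data, spec1.fixed)
    X2, _, _ = build_design(data, spec2.fixed)
    ids = list(data[spec1.id_col].astype(str))
    Z = _z_matrix(ids, K.ids)
    ZKZ = Z @ K.values @ Z.T
    n = len(y1)
    zero = np.zeros((n, n))
    eye = np.eye(n)

    def block(m11, m12, m22):
        return np.block([[m11, m12], [m12.T, m22]])

    comps = [
        Component("Vg1", block(ZKZ, zero, zero), True),
        Component("Vg2", block(zero, zero, ZKZ), True),
        Component("cov_g", block(zero, ZKZ, zero), False),
        Component("Ve1", block(eye, zero, zero), True),
        Component("Ve2", block(zero, zero, eye), True),
        Component("cov_e", block(zero, eye, zero), False),
    ]
    yy = np.concatenate([y1, y2])
    XX = linalg.block_diag(X1, X2)
    res = fit_reml(
        yy, XX, comps, tol=tol, max_iter=max_iter,
        psd_pairs=[(0, 1, 2), (3, 4, 5)],
    )
    th = res.theta
    vg1, vg2, cg = th["Vg1"], th["Vg2"], th["cov_g"]
    ve1, ve2, ce = th["Ve1"], th["Ve2"], th["cov_e"]
    boundary = vg1 <= 0 or vg2 <= 0
    names = res.component_names
    C = res.component_cov

    def delta_se(grad: dict) -> float:
        g = np.array([grad.get(nm, 0.0) for nm in names])
        return float(np.sqrt(max(0.0, g @ C @ g)))

    if boundary:
        r_g, r_g_se = float("nan"), float("nan")
    else:
        den = np.sqrt(vg1 * vg2)
        r_g = cg / den
        r_g_se = delta_se({
            "cov_g": 1.0 / den,
            "Vg1": -cg / (2.0 * vg1 * den),
            "Vg2": -cg / (2.0 * vg2 * den),
        })
        r_g = float(np.clip(r_g, -1.0, 1.0))
    p1, p2 = vg1 + ve1, vg2 + ve2
    denp = np.sqrt(p1 * p2)
    r_p = (cg + ce) / denp
    dp = -(cg + ce) / (2.0 * denp)
    r_p_se = delta_se({
        "cov_g": 1.0 / denp,
        "cov_e": 1.0 / denp,
        "Vg1": dp / p1,
        "Ve1": dp / p1,
        "Vg2": dp / p2,
        "Ve2": dp / p2,
    })
    return CorrelationEstimate(
        r_g=r_g,
        r_g_se=r_g_se,
        r_p=float(np.clip(r_p, -1.0, 1.0)),
        r_p_se=r_p_se,
        components=dict(th),
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# fixed-effects-only fits, adjusted phenotypes and Wald tests


@dataclass
class OLSFit:
    beta: np.ndarray
    beta_cov: np.ndarray
    beta_names: list[str]
    term_slices: dict
    residuals: np.ndarray
    fitted: np.ndarray
    sigma2: float
    n_obs: int
    rank_x: int
    diagnostics: dict = field(default_factory=dict)

    def coef(self, name: str) -> float:
        return float(self.beta[self.beta_names.index(name)])

    def se(self, name: str) -> float:
        i = self.beta_names.index(name)
        return float(np.sqrt(self.beta_cov[i, i]))


def fit_ols(data: pd.DataFrame, response: str, fixed: list[str]) -> OLSFit:
    """Ordinary least squares on the named terms (intercept always included)."""
    y = data[response].to_numpy(float)
    X, term_slices, names = build_design(data, fixed)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rank_x = np.linalg.matrix_rank(X)
    dof = len(y) - rank_x
    sigma2 = float(resid @ resid) / max(dof, 1)
    xtx_inv = np.linalg.pinv(X.T @ X)
    diag = {
        "resid_skew": float(stats.skew(resid)),
        "resid_kurtosis": float(stats.kurtosis(resid)),
        "abs_resid_fitted_corr": float(
            np.corrcoef(np.abs(resid), fitted)[0, 1]
        ) if np.std(fitted) > 0 else 0.0,
    }
    return OLSFit(
        beta=beta,
        beta_cov=sigma2 * xtx_inv,
        beta_names=names,
        term_slices=term_slices,
        residuals=resid,
        fitted=fitted,
        sigma2=sigma2,
        n_obs=len(y),
        rank_x=rank_x,
        diagnostics=diag,
    )


@dataclass
class WaldResult:
    term: str
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


def wald_test(fit, term: str) -> WaldResult:
    """Wald F-test of all coefficients belonging to ``term``.

    ``F = (L b)' (L C L')^{-1} (L b) / rank(L)`` with residual denominator
    degrees of freedom ``n - rank(X)``.
    """
    if term not in fit.term_slices:
        raise KeyError(f"term {term!r} not in model")
    idx = fit.term_slices[term]
    if not idx:
        raise ValueError(f"term {term!r} has no estimable coefficients")
    b = fit.beta[idx]
    C = fit.beta_cov[np.ix_(idx, idx)]
    q = len(idx)
    try:
        sol = linalg.solve(C, b, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise ValueError("singular contrast covariance") from exc
    f_stat = float(b @ sol) / q
    df_den = fit.n_obs - fit.rank_x
    p = float(stats.f.sf(f_stat, q, df_den))
    return WaldResult(term=term, f_stat=f_stat, df_num=q, df_den=df_den, p_value=p)


@dataclass
class AdjustedPhenotypes:
    """Fixed-effects-only residuals (the Bayesian model's response)."""

    residuals: pd.Series
    wald: dict
    fit: OLSFit


def adjust_phenotypes(spec: ModelSpec, data: pd.DataFrame) -> AdjustedPhenotypes:
    """Residuals of the fixed-effects-only model (no additive random term),
    with a Wald test per fixed term."""
    fit = fit_ols(data, spec.response, spec.fixed)
    wald = {t: wald_test(fit, t) for t in spec.fixed if fit.term_slices.get(t)}
    return AdjustedPhenotypes(
        residuals=pd.Series(fit.residuals, index=data[spec.id_col].astype(str)),
        wald=wald,
        fit=fit,
    )


# ---------------------------------------------------------------------------
# inbreeding depression


@dataclass
class InbreedingDepressionRow:
    """One report row: the regression of a trait on genomic inbreeding."""

    trait: str
    estimate: float
    se: float
    f_stat: float
    p_value: float


def estimate_inbreeding_depression(
    trait: str,
    data: pd.DataFrame,
    K: RelationshipMatrix,
    f_col: str = "f_uni",
    fixed: list[str] | None = None,
    residual: str = "homogeneous",
) -> InbreedingDepressionRow:
    """Mixed model with the genomic inbreeding coefficient as a fixed
    covariate; reports its coefficient (trait units per unit F), SE, Wald F
    and p-value."""
    if data[f_col].std() == 0:
        raise ValueError("no variance in the inbreeding covariate")
    fixed = list(fixed or [])
    if f_col not in fixed:
        fixed = fixed + [f_col]
    spec = ModelSpec(response=trait, fixed=fixed, residual=residual)
    fit = fit_univariate_reml(spec, data, K)
    w = wald_test(fit, f_col)
    i = fit.term_slices[f_col][0]
    return InbreedingDepressionRow(
        trait=trait,
        estimate=float(fit.beta[i]),
        se=float(np.sqrt(fit.beta_cov[i, i])),
        f_stat=w.f_stat,
        p_value=w.p_value,
    )


def fit_selfing_ols(bv_table: pd.DataFrame, model: str = "simple") -> OLSFit:
    """OLS models for breeding values against inbreeding in selfing lines.

    ``model="simple"``: ``y = u + F + e`` (inbreeding-depression slope).
    ``model="selection"``: ``y = u + F + line_type + F:line_type + family + e``
    — the interaction measures how selection changes the slope. Expects
    columns ``bv``, ``F``, ``line_type``, ``family``.
    """
    df = bv_table.copy()
    df["family"] = df["family"].astype(str)
    if model == "simple":
        return fit_ols(df, "bv", ["F"])
    if model == "selection":
        return fit_ols(df, "bv", ["F", "line_type", "F:line_type", "family"])
    raise ValueError(f"unknown selfing OLS model {model!r}")


class GBLUPRegressor:
    """Genomic BLUP as a scikit-learn-style estimator.

    ``fit(X, y)`` accepts an (n, m) dosage array or :class:`DosageMatrix`,
    builds the VanRaden relationship matrix, and estimates variance
    components by REML. Fitted attributes: ``h2_`` / ``h2_se_``,
    ``sigma_g2_``, ``sigma_e2_``, ``blup_`` (training breeding values).
    ``predict(X)`` returns breeding-value predictions for new genotype rows
    via the cross-relationship with the training panel.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def get_params(self, deep: bool = True) -> dict:
        return {"ridge": self.ridge}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _dosage(self, X) -> DosageMatrix:
        if isinstance(X, DosageMatrix):
            return X
        X = np.asarray(X)
        return DosageMatrix(X.astype(np.int8), [str(i) for i in range(len(X))])

    def fit(self, X, y):
        D = self._dosage(X)
        y = np.asarray(y, dtype=float)
        G = compute_grrm(D)
        data = pd.DataFrame({"id": D.ids, "y": y})
        fit = fit_univariate_reml(ModelSpec(response="y", fixed=[]), data, G)
        h2 = estimate_h2(fit)
        dos = D.imputed()
        self._p = dos.mean(axis=0) / 2.0
        self._denom = 2.0 * float(np.sum(self._p * (1.0 - self._p)))
        self._W_train = dos - 2.0 * self._p
        self._py = None
        self.fit_ = fit
        self.h2_ = h2.h2
        self.h2_se_ = h2.se
        self.sigma_g2_ = fit.varcomp["genetic"]
        self.sigma_e2_ = fit.varcomp["residual"]
        self.blup_ = fit.blup
        self.intercept_ = float(fit.beta[0])
        # V^{-1}(y - Xb) for cross predictions: a_new = sg * G_cross V^{-1} r
        n = len(y)
        V = self.sigma_g2_ * G.values + self.sigma_e2_ * np.eye(n)
        V += self.ridge * np.eye(n)
        self._vinv_r = np.linalg.solve(V, y - self.intercept_)
        self.n_features_in_ = D.n_snps
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "blup_"):
            raise RuntimeError("estimator is not fitted")
        D = self._dosage(X)
        W_new = D.imputed() - 2.0 * self._p
        G_cross = (W_new @ self._W_train.T) / self._denom
        return self.intercept_ + self.sigma_g2_ * (G_cross @ self._vinv_r)

    def score(self, X, y) -> float:
        y = np.asarray(y, dtype=float)
        pred = self.predict(X)
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
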