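"""Four-component normal-mixture model of SNP effects (BayesR-style Gibbs).

The model: adjusted phenotype ``y = mu + D beta + e`` with every SNP effect
drawn from a mixture of four normals with variances
``(0, 1e-4, 1e-3, 1e-2) x sigma_g2`` (no effect, polygenic, small, large),
mixture proportions ``pi ~ Dirichlet(1,1,1,1)``, and scaled inverse
chi-square priors on ``sigma_g2`` and ``sigma_e2``. Each Gibbs sweep visits
SNPs (optionally in random order), samples the component indicator from its
conditional categorical with the effect integrated out analytically, then
the effect from its conditional normal, maintaining a running residual.

Multiple independent chains are run and combined: convergence is checked on
``h2`` and the per-class variance shares via the Gelman-Rubin potential
scale reduction factor, and per-SNP summaries (posterior component
probabilities, mean effects and effect sizes ``ES = 2 beta^2 f (1-f)``) are
averaged across chains. SNPs are assigned to classes by ranking on ES and
taking the posterior-mean expected number of SNPs per class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .containers import DosageMatrix

GAMMA_DEFAULT = (0.0, 1e-4, 1e-3, 1e-2)
CLASS_LABELS = ("no_effect", "polygenic", "small", "large")


@dataclass
class BayesRConfig:
    """Sampler settings. Defaults follow the reference run profile
    (300k iterations, 100k burn-in, thin 10, 5 chains, permuted order);
    :func:`desk_profile` gives a small-problem profile for routine use."""

    n_iterations: int = 300_000
    burn_in: int = 100_000
    thinning: int = 10
    n_chains: int = 5
    permute: bool = True
    gamma: tuple = GAMMA_DEFAULT
    dirichlet_alpha: tuple = (1.0, 1.0, 1.0, 1.0)
    df_e: float = 4.0
    df_g: float = 4.0
    scale_e: float | None = None  # default: half the phenotypic variance
    scale_g: float | None = None
    sample_mu: bool = True
    sample_pi: bool = True
    sample_sigma_e: bool = True
    sample_sigma_g: bool = True
    sigma_e2_init: float | None = None
    sigma_g2_init: float | None = None
    pi_init: tuple | None = None
    store_effect_draws: bool = False

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn-in must be smaller than the iteration count")
        g = tuple(self.gamma)
        if g[0] != 0.0 or any(g[i] > g[i + 1] for i in range(3)):
            raise ValueError("gamma must be non-decreasing with gamma[0] == 0")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thinning


def desk_profile(**overrides) -> BayesRConfig:
    """Settings sized for panels of a few hundred SNPs."""
    base = dict(n_iterations=20_000, burn_in=5_000, thinning=10, n_chains=2)
    base.update(overrides)
    return BayesRConfig(**base)


@dataclass
class ChainSamples:
    """Thinned post-burn-in draws and per-SNP accumulations for one chain."""

    mu: np.ndarray
    sigma_e2: np.ndarray
    sigma_g2: np.ndarray
    pi: np.ndarray  # (T, 4)
    h2: np.ndarray
    class_counts: np.ndarray  # (T, 4) SNPs per class per draw
    class_var: np.ndarray  # (T, 4) ES-weighted genetic variance per class
    beta_mean: np.ndarray  # (m,) posterior-mean effect
    comp_prob: np.ndarray  # (m, 4) posterior component probabilities
    seed: int
    beta_draws: np.ndarray | None = None  # (T, m) when requested
    resid_drift: float = 0.0  # max |running residual - recomputed| (hygiene check)

    @property
    def n_retained(self) -> int:
        return len(self.mu)


@dataclass
class PosteriorSummary:
    """Across-chain averaged posterior summaries."""

    beta_mean: np.ndarray
    comp_prob: np.ndarray  # (m, 4), rows sum to 1
    effect_size: np.ndarray  # ES = 2 beta^2 f(1-f), trait-variance units
    maf: np.ndarray
    class_counts: np.ndarray  # (4,) posterior-mean SNPs per class
    h2_mean: float
    h2_interval: tuple
    class_var_share: np.ndarray  # (4,) posterior-mean variance share
    snp_ids: list[str]
    n_chains: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "beta_mean": self.beta_mean,
                "es": self.effect_size,
                "maf": self.maf,
            }
        )
        for k, lab in enumerate(CLASS_LABELS):
            df[f"p_{lab}"] = self.comp_prob[:, k]
        return df


@dataclass
class ConvergenceReport:
    psrf: dict
    threshold: float
    passed: bool


@njit(cache=True)
def _gibbs_chain(
    Dt, y, w_het, gamma, alpha,
    n_iter, burn_in, thin, permute, fixed_order, use_fixed_order, seed,
    df_e, scale_e, df_g, scale_g,
    sample_mu, sample_pi, sample_sigma_e, sample_sigma_g,
    sigma_e2_init, sigma_g2_init, pi_init, store_draws,
):
    np.random.seed(seed)
    m, n = Dt.shape
    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Dt[j, i] * Dt[j, i]
        xtx[j] = s
    beta = np.zeros(m)
    comp = np.zeros(m, dtype=np.int64)
    mu = 0.0
    if sample_mu:
        mu = y.mean()
    e = y - mu
    sigma_e2 = sigma_e2_init
    sigma_g2 = sigma_g2_init
    pi = pi_init.copy()
    T = (n_iter - burn_in) // thin
    out_mu = np.empty(T)
    out_se = np.empty(T)
    out_sg = np.empty(T)
    out_pi = np.empty((T, 4))
    out_h2 = np.empty(T)
    out_counts = np.empty((T, 4))
    out_cvar = np.empty((T, 4))
    beta_sum = np.zeros(m)
    comp_count = np.zeros((m, 4))
    if store_draws:
        draws = np.empty((T, m))
    else:
        draws = np.empty((0, m))
    logl = np.empty(4)
    probs = np.empty(4)
    drift = 0.0
    t_out = 0
    for it in range(1, n_iter + 1):
        if use_fixed_order:
            order = fixed_order
        elif permute:
            order = np.random.permutation(m)
        else:
            order = np.arange(m)
        for jj in range(m):
            j = order[jj]
            bj = beta[j]
            rhs = 0.0
            for i in range(n):
                rhs += Dt[j, i] * e[i]
            rhs += xtx[j] * bj
            logl[0] = np.log(pi[0]) if pi[0] > 0 else -1e300
            for k in range(1, 4):
                if pi[k] <= 0 or gamma[k] * sigma_g2 <= 0 or xtx[j] == 0:
                    logl[k] = -1e300
                    continue
                v = gamma[k] * sigma_g2
                c = xtx[j] + sigma_e2 / v
                logl[k] = (
                    np.log(pi[k])
                    - 0.5 * np.log(v * xtx[j] / sigma_e2 + 1.0)
                    + 0.5 * rhs * rhs / (sigma_e2 * c)
                )
            mx = logl[0]
            for k in range(1, 4):
                if logl[k] > mx:
                    mx = logl[k]
            tot = 0.0
            for k in range(4):
                probs[k] = np.exp(logl[k] - mx)
                tot += probs[k]
            u = np.random.random() * tot
            k_new = 3
            acc = 0.0
            for k in range(4):
                acc += probs[k]
                if u <= acc:
                    k_new = k
                    break
            if k_new == 0:
                b_new = 0.0
            else:
                v = gamma[k_new] * sigma_g2
                c = xtx[j] + sigma_e2 / v
                b_new = rhs / c + np.sqrt(sigma_e2 / c) * np.random.standard_normal()
            if b_new != bj:
                diff = bj - b_new
                for i in range(n):
                    e[i] += Dt[j, i] * diff
                beta[j] = b_new
            comp[j] = k_new
        if sample_mu:
            e_mean = e.mean()
            mu_new = mu + e_mean + np.sqrt(sigma_e2 / n) * np.random.standard_normal()
            d_mu = mu_new - mu
            for i in range(n):
                e[i] -= d_mu
            mu = mu_new
        counts = np.zeros(4)
        for j in range(m):
            counts[comp[j]] += 1.0
        if sample_pi:
            tot = 0.0
            for k in range(4):
                pi[k] = np.random.gamma(alpha[k] + counts[k], 1.0)
                tot += pi[k]
            for k in range(4):
                pi[k] /= tot
        if sample_sigma_e:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            sigma_e2 = (sse + df_e * scale_e) / np.random.chisquare(n + df_e)
        if sample_sigma_g:
            ssb = 0.0
            m_nz = 0.0
            for j in range(m):
                if comp[j] > 0:
                    ssb += beta[j] * beta[j] / gamma[comp[j]]
                    m_nz += 1.0
            sigma_g2 = (ssb + df_g * scale_g) / np.random.chisquare(m_nz + df_g)
        if it % 1000 == 0:
            # bookkeeping check: running residual vs recomputation from scratch
            for i in range(n):
                ei = y[i] - mu
                for j in range(m):
                    ei -= Dt[j, i] * beta[j]
                d = ei - e[i]
                if d < 0.0:
                    d = -d
                if d > drift:
                    drift = d
        if it > burn_in and (it - burn_in) % thin == 0:
            out_mu[t_out] = mu
            out_se[t_out] = sigma_e2
            out_sg[t_out] = sigma_g2
            for k in range(4):
                out_pi[t_out, k] = pi[k]
                out_counts[t_out, k] = counts[k]
            # genetic values g = y - mu - e; h2 from their empirical variance
            gm = 0.0
            for i in range(n):
                gm += y[i] - mu - e[i]
            gm /= n
            vg = 0.0
            for i in range(n):
                d = y[i] - mu - e[i] - gm
                vg += d * d
            vg /= n
            out_h2[t_out] = vg / (vg + sigma_e2) if vg + sigma_e2 > 0 else 0.0
            for k in range(4):
                out_cvar[t_out, k] = 0.0
            for j in range(m):
                if comp[j] > 0:
                    out_cvar[t_out, comp[j]] += w_het[j] * beta[j] * beta[j]
            for j in range(m):
                beta_sum[j] += beta[j]
                comp_count[j, comp[j]] += 1.0
            if store_draws:
                for j in range(m):
                    draws[t_out, j] = beta[j]
            t_out += 1
    return (
        out_mu, out_se, out_sg, out_pi, out_h2, out_counts, out_cvar,
        beta_sum, comp_count, draws, drift,
    )


def run_chain(
    y_adj: np.ndarray, D: DosageMatrix, cfg: BayesRConfig, seed: int,
    scan_order: np.ndarray | None = None,
) -> ChainSamples:
    """One Gibbs chain on centred adjusted phenotypes; missing dosages are
    mean-imputed. With a fixed seed the output is bit-reproducible.
    ``scan_order`` fixes the within-iteration SNP visit order (overrides the
    permute flag), which makes per-SNP outputs exactly equivariant under a
    matched column/scan permutation."""
    y = np.asarray(y_adj, dtype=float)
    if np.var(y) == 0:
        raise ValueError("zero-variance phenotype")
    dos = np.ascontiguousarray(D.imputed().T)  # (m, n), SNP-major
    p = dos.mean(axis=1) / 2.0
    w_het = 2.0 * p * (1.0 - p)
    vary = float(np.var(y))
    scale_e = cfg.scale_e if cfg.scale_e is not None else vary / 2.0
    scale_g = cfg.scale_g if cfg.scale_g is not None else vary / 2.0
    se0 = cfg.sigma_e2_init if cfg.sigma_e2_init is not None else vary / 2.0
    sg0 = cfg.sigma_g2_init if cfg.sigma_g2_init is not None else vary / 2.0
    alpha = np.asarray(cfg.dirichlet_alpha, dtype=float)
    pi0 = (
        np.asarray(cfg.pi_init, dtype=float)
        if cfg.pi_init is not None
        else alpha / alpha.sum()
    )
    if scan_order is None:
        fixed_order = np.zeros(0, dtype=np.int64)
        use_fixed = False
    else:
        fixed_order = np.asarray(scan_order, dtype=np.int64)
        use_fixed = True
    out = _gibbs_chain(
        dos, y, w_het, np.asarray(cfg.gamma, dtype=float), alpha,
        cfg.n_iterations, cfg.burn_in, cfg.thinning, cfg.permute,
        fixed_order, use_fixed, int(seed) % (2**31),
        cfg.df_e, scale_e, cfg.df_g, scale_g,
        cfg.sample_mu, cfg.sample_pi, cfg.sample_sigma_e, cfg.sample_sigma_g,
        se0, sg0, pi0, cfg.store_effect_draws,
    )
    (mu, se, sg, pi, h2, counts, cvar, beta_sum, comp_count, draws, drift) = out
    T = cfg.n_retained
    return ChainSamples(
        mu=mu, sigma_e2=se, sigma_g2=sg, pi=pi, h2=h2,
        class_counts=counts, class_var=cvar,
        beta_mean=beta_sum / T,
        comp_prob=comp_count / T,
        seed=int(seed),
        beta_draws=draws if cfg.store_effect_draws else None,
        resid_drift=float(drift),
    )


def compute_effect_size(beta, f):
    """Variance explained by a SNP: ``ES = 2 beta^2 f (1 - f)``."""
    beta = np.asarray(beta, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    return 2.0 * beta * beta * f * (1.0 - f)


def gelman_rubin(sequences: np.ndarray, split: bool = False) -> float:
    """Potential scale reduction factor across chains (rows = chains).

    The classic between/within comparison: identical chains give exactly 1.0
    (values below 1 from sampling noise are clamped). ``split=True`` halves
    each chain first.
    """
    seqs = np.asarray(sequences, dtype=float)
    if seqs.ndim != 2 or seqs.shape[0] < 2:
        raise ValueError("need >= 2 equal-length chains")
    if split:
        half = seqs.shape[1] // 2
        seqs = np.vstack([seqs[:, :half], seqs[:, half : 2 * half]])
    c, n = seqs.shape
    if n < 10:
        raise ValueError("need at least 10 retained draws per chain")
    means = seqs.mean(axis=1)
    w = seqs.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0 if b <= 0 else np.inf
    var_hat = (n - 1) / n * w + b / n
    return float(max(1.0, np.sqrt(var_hat / w)))


def check_convergence(
    chains: list[ChainSamples], threshold: float = 1.1, split: bool = False
) -> ConvergenceReport:
    """PSRF for h2 and each nonzero-class variance share; pass iff all are
    below the threshold."""
    if len(chains) < 2:
        raise ValueError("need >= 2 chains for convergence checking")
    T = chains[0].n_retained
    if any(c.n_retained != T for c in chains):
        raise ValueError("chains have unequal lengths")
    psrf = {"h2": gelman_rubin(np.vstack([c.h2 for c in chains]), split=split)}
    for k, lab in enumerate(CLASS_LABELS):
        if k == 0:
            continue
        tot = np.vstack([c.class_var[:, 1:].sum(axis=1) for c in chains])
        share = np.vstack([c.class_var[:, k] for c in chains]) / np.where(tot > 0, tot, 1.0)
        psrf[f"share_{lab}"] = gelman_rubin(share, split=split)
    passed = all(np.isfinite(v) and v < threshold for v in psrf.values())
    return ConvergenceReport(psrf=psrf, threshold=threshold, passed=passed)


def summarize_chains(chains: list[ChainSamples], D: DosageMatrix) -> PosteriorSummary:
    """Average per-SNP and global summaries across chains (ES computed per
    chain from that chain's posterior-mean effects, then averaged)."""
    f = D.minor_allele_frequencies()
    f = np.where(np.isfinite(f), f, 0.0)
    es = np.mean([compute_effect_size(c.beta_mean, f) for c in chains], axis=0)
    beta_mean = np.mean([c.beta_mean for c in chains], axis=0)
    comp_prob = np.mean([c.comp_prob for c in chains], axis=0)
    class_counts = np.mean([c.class_counts.mean(axis=0) for c in chains], axis=0)
    h2_all = np.concatenate([c.h2 for c in chains])
    cvar = np.mean([c.class_var.mean(axis=0) for c in chains], axis=0)
    nz = cvar[1:].sum()
    share = np.zeros(4)
    if nz > 0:
        share[1:] = cvar[1:] / nz
    return PosteriorSummary(
        beta_mean=beta_mean,
        comp_prob=comp_prob,
        effect_size=es,
        maf=f,
        class_counts=class_counts,
        h2_mean=float(h2_all.mean()),
        h2_interval=(float(np.quantile(h2_all, 0.025)), float(np.quantile(h2_all, 0.975))),
        class_var_share=share,
        snp_ids=list(D.snp_map["snp_id"].astype(str)),
        n_chains=len(chains),
    )


def run_bayesr(
    y_adj: np.ndarray, D: DosageMatrix, cfg: BayesRConfig, seed: int = 0
) -> tuple[PosteriorSummary, ConvergenceReport]:
    """Run all chains, check convergence, and average the summaries."""
    if cfg.n_chains < 2:
        raise ValueError("need >= 2 chains")
    chains = []
    for c in range(cfg.n_chains):
        chain_seed = (int(seed) * 1_000_003 + 7919 * c + 1) % (2**31)
        try:
            chains.append(run_chain(y_adj, D, cfg, chain_seed))
        except Exception as exc:
            raise RuntimeError(f"chain {c} failed: {exc}") from exc
    report = check_convergence(chains)
    return summarize_chains(chains, D), report


def assign_snps_to_classes(summary: PosteriorSummary) -> np.ndarray:
    """Assign SNPs to mixture classes from posterior counts and ES ranks.

    The rounded (half-up) posterior-mean SNP count per nonzero class sets how
    many SNPs each class receives; SNPs ranked by descending ES fill the
    large, then small, then polygenic class; the rest have no effect. Ties
    break by map order. Returns integer labels 0..3.
    """
    m = len(summary.effect_size)
    n_k = [int(np.floor(c + 0.5)) for c in summary.class_counts]
    if n_k[1] + n_k[2] + n_k[3] > m:
        raise ValueError("posterior class counts exceed the panel size")
    order = np.lexsort((np.arange(m), -summary.effect_size))
    labels = np.zeros(m, dtype=int)
    pos = 0
    for k in (3, 2, 1):
        labels[order[pos : pos + n_k[k]]] = k
        pos += n_k[k]
    return labels


def variance_by_class(summary: PosteriorSummary, labels: np.ndarray) -> np.ndarray:
    """Share of associated-SNP variance per nonzero class:
    ``share_k = sum_{j in k} ES_j / sum_{j associated} ES_j``."""
    labels = np.asarray(labels)
    assoc = labels > 0
    total = summary.effect_size[assoc].sum()
    if total <= 0:
        raise ValueError("no associated SNPs; shares undefined")
    shares = np.zeros(4)
    for k in (1, 2, 3):
        shares[k] = summary.effect_size[labels == k].sum() / total
    return shares


class BayesRRegressor:
    """Whole-genome regression with the four-class mixture prior,
    scikit-learn estimator conventions.

    ``fit(X, y)`` takes an (n, m) dosage array (or :class:`DosageMatrix`)
    and a centred adjusted phenotype; fitted attributes carry the averaged
    posterior summary. ``predict(X)`` returns genetic values from the
    posterior-mean effects.
    """

    def __init__(
        self,
        n_iterations: int = 20_000,
        burn_in: int = 5_000,
        thinning: int = 10,
        n_chains: int = 2,
        permute: bool = True,
        gamma: tuple = GAMMA_DEFAULT,
        random_state: int = 0,
    ):
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thinning = thinning
        self.n_chains = n_chains
        self.permute = permute
        self.gamma = gamma
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "burn_in": self.burn_in,
            "thinning": self.thinning,
            "n_chains": self.n_chains,
            "permute": self.permute,
            "gamma": self.gamma,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _as_dosage(self, X) -> DosageMatrix:
        if isinstance(X, DosageMatrix):
            return X
        X = np.asarray(X)
        return DosageMatrix(X.astype(np.int8), [str(i) for i in range(len(X))])

    def fit(self, X, y):
        D = self._as_dosage(X)
        y = np.asarray(y, dtype=float)
        if len(y) != D.n_individuals:
            raise ValueError("X and y have different lengths")
        cfg = BayesRConfig(
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            thinning=self.thinning,
            n_chains=self.n_chains,
            permute=self.permute,
            gamma=self.gamma,
        )
        self._y_mean = float(np.mean(y))
        self._col_mean = D.imputed().mean(axis=0)
        summary, report = run_bayesr(y - self._y_mean, D, cfg, seed=self.random_state)
        self.summary_ = summary
        self.convergence_ = report
        self.beta_mean_ = summary.beta_mean
        self.h2_ = summary.h2_mean
        self.labels_ = assign_snps_to_classes(summary)
        self.n_features_in_ = D.n_snps
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "beta_mean_"):
            raise RuntimeError("estimator is not fitted")
        D = self._as_dosage(X)
        return self._y_mean + (D.imputed() - self._col_mean) @ self.beta_mean_

    def score(self, X, y) -> float:
        y = np.asarray(y, dtype=float)
        pred = self.predict(X)
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
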