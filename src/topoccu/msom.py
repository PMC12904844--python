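"""Bayesian hierarchical multispecies occupancy model (MSOM).

The model is the standard single-season detection/occupancy decomposition.
For species s at site i with occasions j:

    z_is  ~ Bernoulli(psi_is)            latent occupancy (habitat use)
    y_ijs ~ Bernoulli(z_is * p_ijs)      detection given presence

    logit(psi_is) = x_i' beta_s          occupancy: intercept + topographic terms
    logit(p_ijs)  = w_ij' alpha_s        detection: same terms + log(effort)

All regression coefficients carry independent weakly informative
Normal(0, variance 1000) priors (precision 0.001).  An optional community
layer pools species coefficients through Normal hyperpriors; it is off by
default because the base model treats species independently.

Inference is Metropolis-within-Gibbs: each z_is is drawn exactly from its
full conditional, and each coefficient is updated by a Gaussian
random-walk Metropolis step whose proposal scale adapts toward ~30%
acceptance during burn-in only (adaptation is frozen afterwards so the
retained chain satisfies detailed balance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import SiteCovariates
from .detections import DetectionHistory

__all__ = [
    "MSOMSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "build_design",
    "site_marginal_loglik",
    "conditional_z_probability",
    "run_mcmc",
    "gelman_rubin",
    "summarize_posterior",
    "summarize_all",
    "psi_by_category",
    "psi_draws_for_category",
]

PRIOR_VARIANCE = 1000.0  # precision 0.001

#: covariate-table column holding each categorical variable's class label
CLASS_COLUMNS = {
    "aspect": "aspect_class",
    "slope": "slope_class",
    "ruggedness": "ruggedness_class",
    "solar": "solar_class",
    "landscape_unit": "landscape_unit",
}
CONTINUOUS_COLUMNS = {"slope": "slope_z", "ruggedness": "tri_z", "solar": "solar_z"}


# ---------------------------------------------------------------------------
# model specification


@dataclass
class MSOMSpec:
    """Design matrices and prior settings for one model fit.

    ``X`` is the occupancy design (sites x P), ``W`` the detection design
    (sites x occasions x Q).  ``classes`` lists the levels of the
    categorical variable in the design; the first (alphabetical) level is
    the reference and has no indicator column.
    """

    X: np.ndarray
    W: np.ndarray
    occ_names: list[str]
    det_names: list[str]
    species: list[str]
    variable: str | None = None
    classes: list[str] = field(default_factory=list)
    prior_variance: float = PRIOR_VARIANCE

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("occupancy design matrix is rank deficient")
        Wflat = self.W.reshape(-1, self.W.shape[2])
        if np.linalg.matrix_rank(Wflat) < Wflat.shape[1]:
            raise ValueError("detection design matrix is rank deficient")

    @property
    def reference(self) -> str | None:
        return self.classes[0] if self.classes else None


def build_design(
    covariates: SiteCovariates,
    history: DetectionHistory,
    variable: str | None = None,
    *,
    continuous: tuple[str, ...] = (),
    effort_in_detection: bool = True,
    prior_variance: float = PRIOR_VARIANCE,
) -> MSOMSpec:
    """Build the per-variable model design (one topographic variable at a time).

    Occupancy gets an intercept, indicator columns for the non-reference
    classes of ``variable`` (reference = first class alphabetically), and
    any requested z-standardized ``continuous`` covariates.  Detection gets
    the same terms plus standardized log(effort) per occasion.
    """
    tab = covariates.table.set_index("site_id").loc[history.site_ids]
    N, J = history.n_sites, history.n_occasions

    occ_cols: list[np.ndarray] = [np.ones(N)]
    occ_names = ["intercept"]
    classes: list[str] = []
    if variable is not None:
        col = CLASS_COLUMNS[variable]
        labels = tab[col].astype(str)
        if labels.isna().any() or (labels == "nan").any():
            raise ValueError(f"sites missing a {variable} class")
        classes = sorted(labels.unique())
        if len(classes) < 2:
            raise ValueError(f"{variable} has a single observed class; nothing to contrast")
        for cls in classes[1:]:
            occ_cols.append((labels == cls).to_numpy(dtype=float))
            occ_names.append(f"{variable}[{cls}]")
    for cont in continuous:
        occ_cols.append(tab[CONTINUOUS_COLUMNS[cont]].to_numpy(dtype=float))
        occ_names.append(f"{cont}_z")
    X = np.column_stack(occ_cols)

    det_names = list(occ_names)
    W = np.repeat(X[:, None, :], J, axis=1)  # (N, J, P): site terms per occasion
    if effort_in_detection:
        eff = history.effort.astype(float)
        logeff = np.where(history.mask, np.log(np.maximum(eff, 1e-12)), 0.0)
        vals = logeff[history.mask]
        sd = vals.std(ddof=0)
        if sd > 0:  # perfectly uniform effort carries no information
            z = np.where(history.mask, (logeff - vals.mean()) / sd, 0.0)
            W = np.concatenate([W, z[:, :, None]], axis=2)
            det_names.append("log_effort_z")

    return MSOMSpec(
        X=X,
        W=W,
        occ_names=occ_names,
        det_names=det_names,
        species=list(history.species),
        variable=variable,
        classes=classes,
        prior_variance=prior_variance,
    )


# ---------------------------------------------------------------------------
# likelihood pieces


def _check_prob(name: str, value: np.ndarray) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


def site_marginal_loglik(psi: float, p: np.ndarray, y: np.ndarray, mask=None) -> float:
    """Log-likelihood of one site history with the latent z marginalized out.

    With at least one detection, z = 1 is certain:
        log psi + sum_j [y_j log p_j + (1-y_j) log(1-p_j)]
    With an all-zero history, both states contribute:
        log( psi * prod_j (1-p_j) + (1-psi) )
    Masked occasions are excluded.
    """
    psi = float(_check_prob("psi", psi))
    p = _check_prob("p", np.atleast_1d(p))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if mask is not None:
        keep = np.asarray(mask, dtype=bool)
        p, y = p[keep], y[keep]
    with np.errstate(divide="ignore"):
        if np.any(y > 0):
            # select per occasion to avoid 0 * log(0) at the boundaries
            ll = np.log(psi) + np.sum(np.where(y > 0, np.log(p), np.log(1 - p)))
            return float(ll)
        return float(np.log(psi * np.prod(1 - p) + (1 - psi)))


def conditional_z_probability(psi: float, p: np.ndarray, mask=None) -> float:
    """P(z = 1 | all-zero history): Bayes rule on the marginal likelihood."""
    psi = float(_check_prob("psi", psi))
    p = _check_prob("p", np.atleast_1d(p))
    if mask is not None:
        p = p[np.asarray(mask, dtype=bool)]
    q = psi * np.prod(1 - p)
    return float(q / (q + (1 - psi)))


# ---------------------------------------------------------------------------
# sampler


@dataclass
class MCMCConfig:
    """Chain layout and proposal-adaptation settings.

    Retained draws total ``n_chains * floor((n_iter - n_burnin) / thin)``.
    """

    n_chains: int = 3
    n_iter: int = 100_000
    n_burnin: int = 50_000
    thin: int = 10
    seed: int = 0
    target_accept: float = 0.3
    adapt_interval: int = 50
    initial_scale: float = 0.5
    refresh_interval: int = 10

    def __post_init__(self) -> None:
        if not self.n_burnin < self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin

    @property
    def n_retained(self) -> int:
        return self.n_chains * self.n_retained_per_chain


@dataclass
class PosteriorDraws:
    """Retained MCMC draws for every regression coefficient.

    ``beta`` has shape (chains, kept, species, P) and ``alpha``
    (chains, kept, species, Q), aligned with ``spec.occ_names`` /
    ``spec.det_names`` and ``spec.species``.
    """

    beta: np.ndarray
    alpha: np.ndarray
    spec: MSOMSpec
    config: MCMCConfig
    accept_beta: np.ndarray | None = None
    accept_alpha: np.ndarray | None = None

    @property
    def n_retained(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def parameter_names(self) -> list[str]:
        names = []
        for s in self.spec.species:
            names += [f"beta[{s}|{t}]" for t in self.spec.occ_names]
            names += [f"alpha[{s}|{t}]" for t in self.spec.det_names]
        return names

    def parameter_chains(self):
        """Yield (name, (chains, kept) array) for every coefficient."""
        for si, s in enumerate(self.spec.species):
            for ti, t in enumerate(self.spec.occ_names):
                yield f"beta[{s}|{t}]", self.beta[:, :, si, ti]
            for ti, t in enumerate(self.spec.det_names):
                yield f"alpha[{s}|{t}]", self.alpha[:, :, si, ti]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.parameter_chains():
            C, K = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(C), K),
                        "iteration": np.tile(np.arange(K), C),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def max_rhat(self) -> float:
        worst = -np.inf
        for _, arr in self.parameter_chains():
            r = gelman_rubin(arr)
            if np.isfinite(r):
                worst = max(worst, r)
        return float(worst)


def _log_expit(x: np.ndarray) -> np.ndarray:
    """log(sigmoid(x)), numerically stable."""
    return -np.logaddexp(0.0, -x)


def _expit(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _det_caches(M: np.ndarray, y: np.ndarray, mask3: np.ndarray) -> np.ndarray:
    """Per-site detection log-likelihood given presence: (S, N).

    For an all-zero site history this equals ``sum_j log(1 - p_j)`` over
    unmasked occasions, which is exactly the term the collapsed site
    likelihood needs.
    """
    return np.sum(mask3 * (y * _log_expit(M) + (1 - y) * _log_expit(-M)), axis=2)


def _collapsed_loglik(L: np.ndarray, det_part: np.ndarray, detected: np.ndarray) -> np.ndarray:
    """Per-species marginal log-likelihood with z integrated out analytically.

    Detected sites force z = 1: ``log psi + log P(y | z=1)``.  All-zero
    sites mix both states: ``log(psi * prod(1-p) + (1-psi))``.
    """
    logpsi = _log_expit(L)
    log1mpsi = _log_expit(-L)
    site = np.where(detected, logpsi + det_part, np.logaddexp(logpsi + det_part, log1mpsi))
    return site.sum(axis=1)


class _BlockProposal:
    """Per-species adaptive multivariate random-walk proposal.

    During burn-in the proposal covariance tracks the empirical covariance
    of the chain so far (Haario-style adaptive Metropolis) and a per-species
    scalar scale is tuned toward the target acceptance rate; both freeze at
    the end of burn-in so the retained chain is a valid Markov chain.
    """

    COV_WARMUP = 200  # iterations before the empirical covariance is trusted

    def __init__(self, S: int, D: int, config: "MCMCConfig", rng: np.random.Generator):
        self.S, self.D = S, D
        self.config = config
        self.rng = rng
        self.scale = np.full(S, config.initial_scale * 2.38 / np.sqrt(D))
        self.chol = np.tile(np.eye(D), (S, 1, 1))
        self.mean = np.zeros((S, D))
        self.m2 = np.zeros((S, D, D))
        self.count = 0
        self.acc = np.zeros(S)
        self.tot = 0
        self.post_acc = np.zeros(S)
        self.post_tot = 0

    def draw(self) -> np.ndarray:
        eps = self.rng.standard_normal((self.S, self.D))
        return self.scale[:, None] * np.einsum("sij,sj->si", self.chol, eps)

    def record(self, accept: np.ndarray, value: np.ndarray, in_burnin: bool) -> None:
        if not in_burnin:
            self.post_acc += accept
            self.post_tot += 1
            return
        self.acc += accept
        self.tot += 1
        # Welford update of the running chain covariance
        self.count += 1
        delta = value - self.mean
        self.mean += delta / self.count
        self.m2 += np.einsum("si,sj->sij", delta, value - self.mean)
        if self.tot >= self.config.adapt_interval:
            rate = self.acc / self.tot
            self.scale = np.clip(
                self.scale * np.exp(rate - self.config.target_accept), 1e-4, 100.0
            )
            self.acc[:] = 0
            self.tot = 0
            if self.count > self.COV_WARMUP:
                cov = self.m2 / (self.count - 1) + 1e-6 * np.eye(self.D)
                self.chol = np.linalg.cholesky(cov)

    def post_burnin_rate(self) -> np.ndarray:
        return self.post_acc / max(self.post_tot, 1)


def run_mcmc(
    spec: MSOMSpec,
    history: DetectionHistory,
    config: MCMCConfig,
    community_layer: bool = False,
) -> PosteriorDraws:
    """Fit the MSOM by Metropolis-within-Gibbs.

    Latent occupancy states are drawn exactly from their conditionals each
    sweep; coefficients take coefficient-wise Gaussian random-walk steps,
    vectorized across species (species are conditionally independent).
    With ``community_layer=True`` the species coefficients additionally
    share Normal(mu_t, sigma_t^2) hyperpriors per term, with conjugate
    Gibbs updates for (mu_t, sigma_t^2).
    """
    if list(history.species) != list(spec.species):
        raise ValueError("history species do not match the model spec")
    y = history.y.astype(float)
    mask = history.mask.astype(float)  # (N, J)
    S, N, J = y.shape
    P, Q = spec.X.shape[1], spec.W.shape[2]
    detected = history.y.any(axis=2)  # (S, N)

    # class-indicator columns sit right after the intercept in both designs
    n_class_terms = (
        sum(1 for t in spec.occ_names if t.startswith(f"{spec.variable}["))
        if spec.variable
        else 0
    )

    kept = config.n_retained_per_chain
    beta_draws = np.empty((config.n_chains, kept, S, P))
    alpha_draws = np.empty((config.n_chains, kept, S, Q))
    acc_b_all = np.zeros((config.n_chains, S, P))
    acc_a_all = np.zeros((config.n_chains, S, Q))

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for chain in range(config.n_chains):
        rng = np.random.default_rng(seeds[chain])
        beta = rng.normal(0.0, 1.0, (S, P))
        alpha = rng.normal(0.0, 1.0, (S, Q))
        prop_b = _BlockProposal(S, P, config, rng)
        prop_a = _BlockProposal(S, Q, config, rng)

        # community hyperparameters (used only when community_layer=True)
        mu_b = np.zeros(P)
        tau2_b = np.full(P, spec.prior_variance)
        mu_a = np.zeros(Q)
        tau2_a = np.full(Q, spec.prior_variance)

        mask3 = mask[None]
        L = beta @ spec.X.T  # (S, N) occupancy logits
        M = np.einsum("sq,njq->snj", alpha, spec.W)  # (S, N, J)
        det_part = _det_caches(M, y, mask3)  # (S, N)
        z = detected.astype(float)

        ki = 0
        for it in range(config.n_iter):
            in_burnin = it < config.n_burnin

            # Coefficients are updated against the collapsed likelihood
            # (z integrated out in closed form per site).  Conditioning on a
            # sampled z instead makes chains stick whenever a species/class
            # cell is separated (all or none of its sites detected): the
            # "absent" (psi -> 0) and "present but undetected" (p -> 0)
            # posterior arms are then unreachable from each other.

            # ---- beta: per-species block random-walk Metropolis
            step = prop_b.draw()
            beta_new = beta + step
            Lnew = beta_new @ spec.X.T
            dll = _collapsed_loglik(Lnew, det_part, detected) - _collapsed_loglik(
                L, det_part, detected
            )
            dprior = np.sum(
                ((beta - mu_b) ** 2 - (beta_new - mu_b) ** 2) / (2 * tau2_b), axis=1
            )
            accept = np.log(rng.random(S)) < dll + dprior
            beta[accept] = beta_new[accept]
            L[accept] = Lnew[accept]
            prop_b.record(accept, beta, in_burnin)

            # ---- alpha: per-species block random-walk Metropolis
            step = prop_a.draw()
            alpha_new = alpha + step
            Mnew = np.einsum("sq,njq->snj", alpha_new, spec.W)
            det_new = _det_caches(Mnew, y, mask3)
            dll = _collapsed_loglik(L, det_new, detected) - _collapsed_loglik(
                L, det_part, detected
            )
            dprior = np.sum(
                ((alpha - mu_a) ** 2 - (alpha_new - mu_a) ** 2) / (2 * tau2_a), axis=1
            )
            accept = np.log(rng.random(S)) < dll + dprior
            alpha[accept] = alpha_new[accept]
            M[accept] = Mnew[accept]
            det_part[accept] = det_new[accept]
            prop_a.record(accept, alpha, in_burnin)

            # ---- periodic prior-independence refresh, coefficient-wise.
            # Under a vague prior a separated coefficient sits on a likelihood
            # plateau stretching far into the prior tail; random-walk steps
            # cross it slowly, but an independence proposal from the prior
            # jumps anywhere on it (prior and proposal densities cancel in
            # the acceptance ratio).
            if config.refresh_interval and (it + 1) % config.refresh_interval == 0:
                cur = _collapsed_loglik(L, det_part, detected)
                for c in range(P):
                    prop = mu_b[c] + np.sqrt(tau2_b[c]) * rng.standard_normal(S)
                    Lnew = L + spec.X[:, c][None, :] * (prop - beta[:, c])[:, None]
                    new = _collapsed_loglik(Lnew, det_part, detected)
                    accept = np.log(rng.random(S)) < new - cur
                    beta[accept, c] = prop[accept]
                    L[accept] = Lnew[accept]
                    cur[accept] = new[accept]
                for c in range(Q):
                    prop = mu_a[c] + np.sqrt(tau2_a[c]) * rng.standard_normal(S)
                    Mnew = M + spec.W[:, :, c][None] * (prop - alpha[:, c])[:, None, None]
                    det_new = _det_caches(Mnew, y, mask3)
                    new = _collapsed_loglik(L, det_new, detected)
                    accept = np.log(rng.random(S)) < new - cur
                    alpha[accept, c] = prop[accept]
                    M[accept] = Mnew[accept]
                    det_part[accept] = det_new[accept]
                    cur[accept] = new[accept]

                # translation move along the reference-class ridge: shifting
                # the intercept while counter-shifting every class indicator
                # leaves all non-reference cells' logits unchanged, so when
                # the *reference* cell is separated this is the flat direction
                # no coefficient-wise move can follow
                if n_class_terms and P >= 2:
                    delta = 0.5 * np.sqrt(tau2_b[0]) * rng.standard_normal(S)
                    beta_new = beta.copy()
                    beta_new[:, 0] += delta
                    beta_new[:, 1 : 1 + n_class_terms] -= delta[:, None]
                    Lnew = beta_new @ spec.X.T
                    new = _collapsed_loglik(Lnew, det_part, detected)
                    curL = _collapsed_loglik(L, det_part, detected)
                    dprior = np.sum(
                        ((beta - mu_b) ** 2 - (beta_new - mu_b) ** 2) / (2 * tau2_b),
                        axis=1,
                    )
                    accept = np.log(rng.random(S)) < new - curL + dprior
                    beta[accept] = beta_new[accept]
                    L[accept] = Lnew[accept]

                    delta = 0.5 * np.sqrt(tau2_a[0]) * rng.standard_normal(S)
                    alpha_new = alpha.copy()
                    alpha_new[:, 0] += delta
                    alpha_new[:, 1 : 1 + n_class_terms] -= delta[:, None]
                    Mnew = np.einsum("sq,njq->snj", alpha_new, spec.W)
                    det_new = _det_caches(Mnew, y, mask3)
                    new = _collapsed_loglik(L, det_new, detected)
                    curM = _collapsed_loglik(L, det_part, detected)
                    dprior = np.sum(
                        ((alpha - mu_a) ** 2 - (alpha_new - mu_a) ** 2) / (2 * tau2_a),
                        axis=1,
                    )
                    accept = np.log(rng.random(S)) < new - curM + dprior
                    alpha[accept] = alpha_new[accept]
                    M[accept] = Mnew[accept]
                    det_part[accept] = det_new[accept]

            # ---- z | coefficients, y: exact conditional draw
            # (detection forces z = 1; for all-zero sites det_part is
            # sum_j log(1-p_j), so the conditional is Bayes' rule)
            logpsi = _log_expit(L)
            log1mpsi = _log_expit(-L)
            lognum = logpsi + det_part
            cond = np.exp(lognum - np.logaddexp(lognum, log1mpsi))
            z = np.where(detected, 1.0, (rng.random((S, N)) < cond).astype(float))

            # ---- optional community layer: conjugate updates per term
            if community_layer and S > 1:
                for arrs, mu, tau2 in ((beta, mu_b, tau2_b), (alpha, mu_a, tau2_a)):
                    for c in range(arrs.shape[1]):
                        # mu | rest with N(0, prior_var) hyperprior
                        prec = S / tau2[c] + 1.0 / spec.prior_variance
                        mean = (arrs[:, c].sum() / tau2[c]) / prec
                        mu[c] = rng.normal(mean, np.sqrt(1.0 / prec))
                        # sigma^2 | rest, inverse-gamma(2, 1) hyperprior
                        a_post = 2.0 + S / 2.0
                        b_post = 1.0 + 0.5 * np.sum((arrs[:, c] - mu[c]) ** 2)
                        tau2[c] = b_post / rng.gamma(a_post)

            if not in_burnin and (it - config.n_burnin + 1) % config.thin == 0:
                beta_draws[chain, ki] = beta
                alpha_draws[chain, ki] = alpha
                ki += 1

        acc_b_all[chain] = prop_b.post_burnin_rate()[:, None]
        acc_a_all[chain] = prop_a.post_burnin_rate()[:, None]
        pinned = (acc_b_all[chain, :, 0] < 0.01).any() or (acc_a_all[chain, :, 0] < 0.01).any()
        if pinned and config.n_iter - config.n_burnin >= 100:
            warnings.warn(
                f"chain {chain}: some proposal acceptance rates are pinned near 0 "
                "after burn-in; adaptation may not have converged",
                RuntimeWarning,
                stacklevel=2,
            )

    return PosteriorDraws(
        beta=beta_draws,
        alpha=alpha_draws,
        spec=spec,
        config=config,
        accept_beta=acc_b_all,
        accept_alpha=acc_a_all,
    )


# ---------------------------------------------------------------------------
# diagnostics and summaries


def gelman_rubin(chains: np.ndarray, split: bool = False) -> float:
    """Potential scale reduction factor (R-hat) from >= 2 equal-length chains.

    ``chains`` is (n_chains, n_draws).  With ``split=True`` each chain is
    halved first (the split-chain variant).  Returns NaN (with a warning)
    when every chain has zero within-chain variance.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a (n_chains >= 2, n_draws) array")
    if split:
        half = arr.shape[1] // 2
        arr = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
    m, n = arr.shape
    if n < 10:
        raise ValueError("chains too short for a meaningful R-hat")
    W = arr.var(axis=1, ddof=1).mean()
    B_over_n = arr.mean(axis=1).var(ddof=1)
    if W == 0:
        warnings.warn("degenerate chains: zero within-chain variance", RuntimeWarning)
        return float("nan")
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


SUPPORT_LEVELS = ("strong", "moderate", "none")


def summarize_posterior(draws: np.ndarray) -> dict:
    """Posterior mean, equal-tailed 95%/75% BCIs, R-hat, and support class.

    Support is classified against zero: "strong" when the 95% BCI excludes
    zero, "moderate" when only the 75% BCI excludes it, otherwise "none".
    R-hat is computed when the draws come as (chains >= 2, kept) and NaN
    otherwise.
    """
    arr = np.asarray(draws, dtype=float)
    flat = arr.reshape(-1)
    if flat.size < 100:
        raise ValueError("need at least 100 draws to summarize")
    q025, q125, q875, q975 = np.quantile(flat, [0.025, 0.125, 0.875, 0.975])
    rhat = gelman_rubin(arr) if (arr.ndim == 2 and arr.shape[0] >= 2) else float("nan")
    if q025 > 0 or q975 < 0:
        support = "strong"
    elif q125 > 0 or q875 < 0:
        support = "moderate"
    else:
        support = "none"
    return {
        "mean": float(flat.mean()),
        "q2.5": float(q025),
        "q12.5": float(q125),
        "q87.5": float(q875),
        "q97.5": float(q975),
        "rhat": rhat,
        "support": support,
    }


def summarize_all(draws: PosteriorDraws) -> pd.DataFrame:
    """One summary row per monitored coefficient."""
    rows = []
    for name, arr in draws.parameter_chains():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            row = summarize_posterior(arr)
        row["parameter"] = name
        rows.append(row)
    df = pd.DataFrame(rows)
    return df[["parameter", "mean", "q2.5", "q12.5", "q87.5", "q97.5", "rhat", "support"]]


def psi_draws_for_category(
    draws: PosteriorDraws, species: str, category: str
) -> np.ndarray:
    """Per-draw occupancy probability for one species in one class.

    psi = expit(intercept + class effect), continuous covariates held at
    their mean (0 after z-standardization); the reference class has no
    indicator so its effect is zero.  Returns a (chains, kept) array on
    the probability scale.
    """
    spec = draws.spec
    if category not in spec.classes:
        raise ValueError(f"unknown category {category!r}; have {spec.classes}")
    si = spec.species.index(species)
    logit = draws.beta[:, :, si, spec.occ_names.index("intercept")].copy()
    term = f"{spec.variable}[{category}]"
    if term in spec.occ_names:
        logit = logit + draws.beta[:, :, si, spec.occ_names.index(term)]
    return _expit(logit)


def psi_by_category(draws: PosteriorDraws, species: str, category: str) -> dict:
    """Posterior summary of category-specific occupancy for one species."""
    psi = psi_draws_for_category(draws, species, category)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return summarize_posterior(psi)
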