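"""Variational-Bayes inference for latent Dirichlet allocation on count tables.

The model: sample i draws an assemblage mixture theta_i ~ Dirichlet(alpha);
each of its reads draws a latent assemblage z ~ Categorical(theta_i) and then
a feature (genus or KO) ~ Categorical(phi_z), with phi_k ~ Dirichlet(beta)
rows over the D features. alpha is asymmetric (one concentration per
assemblage); beta is a single scalar tied across features.

Inference is mean-field coordinate ascent maximizing the evidence lower
bound (the variational lower bound, VLB) on the log marginal likelihood of
the token sequence. Responsibilities are stored per (sample, feature) pair
weighted by the pair's count, which is equivalent to per-read storage for
exchangeable reads. Hyperparameters are re-estimated every outer iteration
by Minka-style fixed-point updates (empirical Bayes), which are MM steps on
the VLB and therefore preserve its monotonicity.

Estimates reported to users are posterior expectations:
theta[i,k] = (n_ik + alpha_k) / (n_i + sum(alpha)),
phi[k,j] = (n_kj + beta) / (n_k + D beta),
where n are count-weighted responsibility sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import digamma, gammaln, logsumexp, polygamma, xlogy

from .datatypes import CountTable

HYPER_FLOOR = 1e-10


class LDAConvergenceError(RuntimeError):
    """Raised when every restart of a fit fails numerically."""


@dataclass
class LDAHyperparams:
    """Dirichlet hyperparameters: asymmetric alpha (length K), tied scalar beta."""

    alpha: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.ndim != 1 or (self.alpha <= 0).any():
            raise ValueError("alpha must be a 1-D vector of positive reals")
        self.beta = float(self.beta)
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def K(self) -> int:
        return self.alpha.shape[0]


@dataclass
class VariationalState:
    """Mean-field state: responsibilities and their count-weighted sums.

    resp[i, j, :] is the posterior assemblage distribution shared by all
    reads of feature j in sample i (meaningful only where counts[i, j] > 0).
    expected_sample_counts[i, k] = sum_j counts[i, j] * resp[i, j, k];
    expected_feature_counts[k, j] = sum_i counts[i, j] * resp[i, j, k].
    """

    resp: np.ndarray
    expected_sample_counts: np.ndarray
    expected_feature_counts: np.ndarray
    hyperparams: LDAHyperparams


@dataclass
class LDAFit:
    """Best-restart LDA estimate with provenance."""

    theta: np.ndarray
    phi: np.ndarray
    hyperparams: LDAHyperparams
    vlb_trace: np.ndarray
    best_trial_seed: int
    K: int
    n_iterations: int
    trial_vlbs: dict[int, float]
    sample_ids: list[str] | None = None
    feature_ids: list[str] | None = None

    @property
    def final_vlb(self) -> float:
        return float(self.vlb_trace[-1])


def _recompute_expected_counts(resp: np.ndarray, counts: np.ndarray):
    weighted = counts[:, :, None] * resp
    return weighted.sum(axis=1), weighted.sum(axis=0).T


def init_variational_state(
    table: CountTable, K: int, hyperparams: LDAHyperparams, rng: np.random.Generator
) -> VariationalState:
    """Random start: one symmetric-Dirichlet(1) responsibility draw per sample.

    The draw is shared by all features of the sample (a random theta start);
    keeping the initialization feature-independent makes the whole fit
    exactly equivariant under permutations of the feature columns.
    """
    N, D = table.counts.shape
    raw = rng.standard_gamma(1.0, size=(N, 1, K))
    resp = np.broadcast_to(raw / raw.sum(axis=2, keepdims=True), (N, D, K)).copy()
    esc, efc = _recompute_expected_counts(resp, table.counts.astype(float))
    return VariationalState(resp, esc, efc, hyperparams)


def vb_e_step(state: VariationalState, table: CountTable) -> VariationalState:
    """One mean-field responsibility update followed by count re-aggregation.

    resp(i,j,k) is proportional to
    exp(psi(n_ik + alpha_k)) * exp(psi(n_kj + beta)) / exp(psi(n_k + D beta)),
    normalized over k; this is the exact coordinate-ascent optimum of q(z)
    given the current Dirichlet variational posteriors over theta and phi.
    """
    alpha = state.hyperparams.alpha
    beta = state.hyperparams.beta
    K = alpha.shape[0]
    counts = table.counts.astype(float)
    D = counts.shape[1]

    gamma = state.expected_sample_counts + alpha           # (N, K)
    lam = state.expected_feature_counts + beta             # (K, D)
    if (gamma <= 0).any() or (lam <= 0).any():
        raise FloatingPointError("non-positive digamma argument in e-step")
    e_log_theta = digamma(gamma)                           # per-sample term; row psi(sum) cancels
    e_log_phi = digamma(lam) - digamma(lam.sum(axis=1))[:, None]

    log_r = e_log_theta[:, None, :] + e_log_phi.T[None, :, :]   # (N, D, K)
    log_r -= logsumexp(log_r, axis=2, keepdims=True)
    resp = np.exp(log_r)
    if K == 1:
        resp = np.ones_like(resp)

    esc, efc = _recompute_expected_counts(resp, counts)
    return VariationalState(resp, esc, efc, state.hyperparams)


def _vlb_parts(state: VariationalState, table: CountTable) -> tuple[float, float]:
    """(sample part, phi part) of the VLB; their sum is the full bound.

    The sample part collects the token likelihood, the q(z) entropy, and the
    theta prior-minus-posterior terms (additive over samples for a fixed phi
    posterior); the phi part is -KL(q(phi) || p(phi)), shared by all samples.
    """
    alpha = state.hyperparams.alpha
    beta = state.hyperparams.beta
    counts = table.counts.astype(float)
    D = counts.shape[1]

    gamma = state.expected_sample_counts + alpha
    lam = state.expected_feature_counts + beta
    e_log_theta = digamma(gamma) - digamma(gamma.sum(axis=1))[:, None]
    e_log_phi = digamma(lam) - digamma(lam.sum(axis=1))[:, None]

    resp = state.resp
    # token term + q(z) entropy, weighted by counts; 0 log 0 = 0 via xlogy
    per_pair = resp * (e_log_theta[:, None, :] + e_log_phi.T[None, :, :]) - xlogy(resp, resp)
    token_part = float(np.sum(counts * per_pair.sum(axis=2)))

    theta_part = float(
        np.sum(
            gammaln(alpha.sum())
            - gammaln(alpha).sum()
            + ((alpha - gamma) * e_log_theta).sum(axis=1)
            + gammaln(gamma).sum(axis=1)
            - gammaln(gamma.sum(axis=1))
        )
    )
    phi_part = float(
        np.sum(
            gammaln(D * beta)
            - D * gammaln(beta)
            + ((beta - lam) * e_log_phi).sum(axis=1)
            + gammaln(lam).sum(axis=1)
            - gammaln(lam.sum(axis=1))
        )
    )
    return token_part + theta_part, phi_part


def compute_vlb(state: VariationalState, table: CountTable) -> float:
    """Evidence lower bound on the log marginal likelihood of the corpus.

    Valid for any variational state (not only coordinate-ascent fixed
    points), so it always lower-bounds the exact log marginal likelihood of
    the token sequence under the current hyperparameters.
    """
    sample_part, phi_part = _vlb_parts(state, table)
    vlb = sample_part + phi_part
    if not np.isfinite(vlb):
        raise FloatingPointError("non-finite VLB")
    return vlb


def posterior_expectations(state: VariationalState) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-mean point estimates (theta, phi) from the variational counts."""
    alpha = state.hyperparams.alpha
    beta = state.hyperparams.beta
    esc = state.expected_sample_counts
    efc = state.expected_feature_counts
    D = efc.shape[1]
    theta = (esc + alpha) / (esc.sum(axis=1) + alpha.sum())[:, None]
    phi = (efc + beta) / (efc.sum(axis=1) + D * beta)[:, None]
    return theta, phi


def _inverse_digamma(y: np.ndarray) -> np.ndarray:
    """Newton inversion of the digamma function (Minka's initialization)."""
    y = np.asarray(y, dtype=float)
    x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y - digamma(1.0)))
    for _ in range(5):
        x = x - (digamma(x) - y) / polygamma(1, x)
    return x


def fit_dirichlet_fixed_point(
    mean_log_p: np.ndarray,
    init: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """Maximum-likelihood Dirichlet concentration by fixed-point iteration.

    ``mean_log_p[k]`` is the average of log p_k (or E[log p_k]) over the
    observed probability vectors. Each step solves
    psi(a_k_new) = psi(sum a_old) + mean_log_p[k]; this is an MM update, so
    the Dirichlet log likelihood never decreases.
    """
    a = np.asarray(init, dtype=float).copy()
    if (a <= 0).any():
        raise ValueError("initial concentrations must be positive")
    for _ in range(max_iter):
        a_new = _inverse_digamma(digamma(a.sum()) + mean_log_p)
        if (a_new <= 0).any() or not np.isfinite(a_new).all():
            warnings.warn("Dirichlet fixed point produced non-positive value; clamping")
            a_new = np.clip(np.nan_to_num(a_new, nan=HYPER_FLOOR), HYPER_FLOOR, None)
        if np.max(np.abs(a_new - a)) < tol:
            return a_new
        a = a_new
    return a


def fit_symmetric_dirichlet_fixed_point(
    mean_log_p: float,
    dim: int,
    init: float,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> float:
    """Tied-scalar variant: all ``dim`` components share one concentration.

    ``mean_log_p`` is the average of log p over all components of all
    observed rows. Fixed point: psi(b_new) = psi(dim * b_old) + mean_log_p.
    """
    b = float(init)
    if b <= 0:
        raise ValueError("initial concentration must be positive")
    for _ in range(max_iter):
        b_new = float(_inverse_digamma(digamma(dim * b) + mean_log_p))
        if b_new <= 0 or not np.isfinite(b_new):
            warnings.warn("tied Dirichlet fixed point produced non-positive value; clamping")
            b_new = HYPER_FLOOR
        if abs(b_new - b) < tol:
            return b_new
        b = b_new
    return b


def update_hyperparameters(
    state: VariationalState, max_inner: int = 100, tol: float = 1e-8
) -> LDAHyperparams:
    """Empirical-Bayes re-estimation of (alpha, beta) from the current state.

    Sufficient statistics are the variational expectations E[log theta_ik]
    and E[log phi_kj]; the inner fixed-point loop (capped at ``max_inner``)
    maximizes the corresponding VLB terms, so the VLB cannot decrease.
    """
    alpha = state.hyperparams.alpha
    beta = state.hyperparams.beta
    gamma = state.expected_sample_counts + alpha
    lam = state.expected_feature_counts + beta
    D = lam.shape[1]

    s_alpha = np.mean(digamma(gamma) - digamma(gamma.sum(axis=1))[:, None], axis=0)
    alpha_new = fit_dirichlet_fixed_point(s_alpha, init=alpha, max_iter=max_inner, tol=tol)

    s_beta = float(np.mean(digamma(lam) - digamma(lam.sum(axis=1))[:, None]))
    beta_new = fit_symmetric_dirichlet_fixed_point(
        s_beta, dim=D, init=beta, max_iter=max_inner, tol=tol
    )
    return LDAHyperparams(np.clip(alpha_new, HYPER_FLOOR, None), max(beta_new, HYPER_FLOOR))


def _run_trial(
    table: CountTable,
    K: int,
    init_alpha: float,
    init_beta: float,
    tol: float,
    seed: int,
    max_iter: int,
    tol_mode: str,
    estimate_hyperparams: bool,
) -> tuple[VariationalState, np.ndarray]:
    rng = np.random.default_rng(seed)
    hyper = LDAHyperparams(np.full(K, init_alpha), init_beta)
    state = init_variational_state(table, K, hyper, rng)
    trace: list[float] = []
    for _ in range(max_iter):
        state = vb_e_step(state, table)
        if estimate_hyperparams:
            state = replace(state, hyperparams=update_hyperparameters(state))
        vlb = compute_vlb(state, table)
        trace.append(vlb)
        if len(trace) >= 2:
            delta = abs(trace[-1] - trace[-2])
            if tol_mode == "rel":
                delta /= max(abs(trace[-2]), 1.0)
            if delta < tol:
                break
    return state, np.asarray(trace)


def fit_lda(
    table: CountTable,
    K: int,
    init_alpha: float = 0.1,
    init_beta: float = 0.05,
    tol: float = 1e-6,
    n_trials: int = 10,
    base_seed: int = 0,
    max_iter: int = 1000,
    tol_mode: str = "abs",
    estimate_hyperparams: bool = True,
    sort_by_mean_theta: bool = True,
) -> LDAFit:
    """Fit a K-assemblage LDA model with multi-restart VB and pick the best VLB.

    Runs ``n_trials`` independently initialized restarts (seeds
    ``base_seed .. base_seed + n_trials - 1``); each iterates e-step,
    hyperparameter fixed-point update, and VLB evaluation until the change
    in VLB is below ``tol`` (absolute by default; ``tol_mode='rel'`` for
    relative). The restart with the highest final VLB wins; exact ties go to
    the lowest seed. Restarts that fail numerically are recorded and
    skipped; if all fail, ``LDAConvergenceError`` is raised.

    Assemblage indices are arbitrary under the model; for stable reporting
    the returned assemblages are ordered by descending mean theta column.
    """
    if K < 1:
        raise ValueError("K must be a positive integer")
    if table.n_samples == 0 or table.n_features == 0:
        raise ValueError("count table is empty")
    if (table.row_totals() == 0).any():
        raise ValueError("every sample must have positive total count")
    if tol_mode not in ("abs", "rel"):
        raise ValueError("tol_mode must be 'abs' or 'rel'")

    best: tuple[float, int, VariationalState, np.ndarray] | None = None
    trial_vlbs: dict[int, float] = {}
    for seed in range(base_seed, base_seed + n_trials):
        try:
            state, trace = _run_trial(
                table, K, init_alpha, init_beta, tol, seed, max_iter, tol_mode,
                estimate_hyperparams,
            )
        except FloatingPointError as exc:
            warnings.warn(f"trial with seed {seed} failed: {exc}")
            trial_vlbs[seed] = float("nan")
            continue
        final = float(trace[-1])
        trial_vlbs[seed] = final
        if best is None or final > best[0]:
            best = (final, seed, state, trace)
    if best is None:
        raise LDAConvergenceError("all restarts failed numerically")

    _, best_seed, state, trace = best
    theta, phi = posterior_expectations(state)
    hyper = state.hyperparams
    if sort_by_mean_theta and K > 1:
        order = np.argsort(-theta.mean(axis=0), kind="stable")
        theta = theta[:, order]
        phi = phi[order, :]
        hyper = LDAHyperparams(hyper.alpha[order], hyper.beta)
    return LDAFit(
        theta=theta,
        phi=phi,
        hyperparams=hyper,
        vlb_trace=trace,
        best_trial_seed=best_seed,
        K=K,
        n_iterations=len(trace),
        trial_vlbs=trial_vlbs,
        sample_ids=list(table.sample_ids),
        feature_ids=list(table.feature_ids),
    )


def exact_log_marginal_likelihood(
    table: CountTable, K: int, alpha: np.ndarray, beta: float
) -> float:
    """Exact log marginal likelihood of a tiny corpus by exhaustive enumeration.

    Sums the collapsed Dirichlet-multinomial joint p(w, z) over every
    assignment of each read to one of K assemblages. Cost is K^(total
    reads); intended only as an oracle for corpora with a handful of reads.
    """
    import itertools

    alpha = np.asarray(alpha, dtype=float)
    counts = table.counts
    N, D = counts.shape
    # expand counts to a token list [(sample, feature), ...]
    tokens = [(i, j) for i in range(N) for j in range(D) for _ in range(counts[i, j])]
    T = len(tokens)
    if K**T > 2_000_000:
        raise ValueError("corpus too large for exhaustive enumeration")
    log_terms = []
    for assign in itertools.product(range(K), repeat=T):
        n_ik = np.zeros((N, K))
        n_kj = np.zeros((K, D))
        for (i, j), k in zip(tokens, assign):
            n_ik[i, k] += 1
            n_kj[k, j] += 1
        lp = 0.0
        for i in range(N):
            lp += (
                gammaln(alpha.sum())
                - gammaln(alpha.sum() + n_ik[i].sum())
                + (gammaln(alpha + n_ik[i]) - gammaln(alpha)).sum()
            )
        for k in range(K):
            lp += (
                gammaln(D * beta)
                - gammaln(D * beta + n_kj[k].sum())
                + (gammaln(beta + n_kj[k]) - gammaln(beta)).sum()
            )
        log_terms.append(lp)
    return float(logsumexp(log_terms))
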