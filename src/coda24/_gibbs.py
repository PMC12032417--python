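"""Blocked Gibbs sampler for the Gaussian multilevel linear model.

Model
-----
    y_ij = x_ij' beta + z_ij' b_i + eps_ij,    eps_ij ~ N(0, sigma^2)
    b_i ~ N(0, Sigma_b)                        (random intercept + slopes)

Priors (all conditionally conjugate):
    beta_k ~ N(m_k, s_k^2)                     independent, weakly informative
    sigma  ~ half-t(nu_s, A_s)                 via inverse-gamma scale mixture
    Sigma_b = diag(alpha) Sigma_c diag(alpha)  scaled inverse-Wishart:
        Sigma_c ~ InvWishart(q + 1, I_q)       (marginally uniform correlations)
        alpha_k ~ N(0, A_k^2)                  so each random-effect SD is
                                               |alpha_k| * sqrt(Sigma_c[kk]),
                                               a heavy-tailed half-normal-like
                                               margin of scale ~A_k

Two mixing devices matter here.  First, beta is drawn *collapsed*: the
random effects are marginalised out via the Woodbury identity, so beta is
sampled from N(y; X beta, sigma^2 I + Z Sigma_b Z') exactly, removing the
beta--b autocorrelation of naive Gibbs.  Second, the random-effect
covariance uses a redundant multiplicative parameterisation
(b_i = diag(alpha) eta_i): the scale parameters alpha have Gaussian full
conditionals that pass freely through zero, which eliminates the familiar
stuck-near-zero behaviour of centered samplers when a variance component is
small.  All per-person quantities are precomputed as stacked (m, ., .)
arrays, so each sweep is a handful of batched linear-algebra calls with no
Python-level loop over persons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GibbsPriors", "GibbsResult", "run_chain"]


@dataclass(frozen=True)
class GibbsPriors:
    beta_mean: np.ndarray  # (p,)
    beta_sd: np.ndarray  # (p,)
    sigma_df: float = 3.0
    sigma_scale: float = 1.0  # A_s
    ranef_scale: np.ndarray | float = 1.0  # A_k, scalar or (q,)


@dataclass
class GibbsResult:
    beta: np.ndarray  # (draws, p)
    sigma: np.ndarray  # (draws,)
    sd_ranef: np.ndarray  # (draws, q)
    corr_ranef: np.ndarray  # (draws, q, q)
    ranef: np.ndarray  # (draws, m, q)


def _invwishart_bartlett(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw from InverseWishart(df, scale) via Bartlett decomposition."""
    q = scale.shape[0]
    # W ~ Wishart(df, scale^{-1});  draw = W^{-1}
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((q, q))
    A[np.diag_indices(q)] = np.sqrt(rng.chisquare(df - np.arange(q)))
    A[np.tril_indices(q, -1)] = rng.standard_normal(q * (q - 1) // 2)
    LA = L @ A
    return np.linalg.inv(LA @ LA.T)


def run_chain(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    person_index: np.ndarray,
    priors: GibbsPriors,
    iterations: int,
    warmup: int,
    seed: int,
) -> GibbsResult:
    """Run one chain; returns the ``iterations - warmup`` post-warmup draws."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    person_index = np.asarray(person_index, int)
    n, p = X.shape
    q = Z.shape[1]
    m = person_index.max() + 1

    # --- per-person sufficient statistics, stacked ---
    ZtZ = np.zeros((m, q, q))
    XtZ = np.zeros((m, p, q))
    Zty = np.zeros((m, q))
    np.add.at(ZtZ, person_index, Z[:, :, None] * Z[:, None, :])
    np.add.at(XtZ, person_index, X[:, :, None] * Z[:, None, :])
    np.add.at(Zty, person_index, Z * y[:, None])
    XtX = X.T @ X
    Xty = X.T @ y

    prior_prec = 1.0 / priors.beta_sd**2
    prior_mean_term = prior_prec * priors.beta_mean
    nu_s, A_s = priors.sigma_df, priors.sigma_scale
    A_r = np.broadcast_to(np.asarray(priors.ranef_scale, float), (q,)).copy()

    # --- initial state: ridge beta, residual sd, modest random effects ---
    beta = np.linalg.solve(XtX + np.eye(p), Xty)
    resid = y - X @ beta
    sigma2 = max(float(resid @ resid) / max(n - p, 1), 1e-8)
    alpha = np.full(q, 0.25 * np.sqrt(sigma2))
    Sigma_c = np.eye(q)
    Sigma = np.diag(alpha) @ Sigma_c @ np.diag(alpha)
    a_sigma = 1.0
    eye_q = np.eye(q)

    keep = iterations - warmup
    out_beta = np.empty((keep, p))
    out_sigma = np.empty(keep)
    out_sd = np.empty((keep, q))
    out_corr = np.empty((keep, q, q))
    out_b = np.empty((keep, m, q))

    for it in range(iterations):
        # --- beta | Sigma, sigma2 (b marginalised out; Woodbury) ---
        Sigma_inv = np.linalg.inv(Sigma + 1e-12 * eye_q)
        W = np.linalg.inv(sigma2 * Sigma_inv[None, :, :] + ZtZ)  # (m,q,q)
        XtVX = (XtX - np.einsum("mpq,mqr,msr->ps", XtZ, W, XtZ)) / sigma2
        XtVy = (Xty - np.einsum("mpq,mqr,mr->p", XtZ, W, Zty)) / sigma2
        A = XtVX + np.diag(prior_prec)
        L = np.linalg.cholesky(A)
        mu = np.linalg.solve(A, XtVy + prior_mean_term)
        beta = mu + np.linalg.solve(L.T, rng.standard_normal(p))

        # --- random-effect block, refreshed a few times per sweep to cut
        #     the autocorrelation of the variance components ---
        r0 = y - X @ beta
        XtZ_beta = np.einsum("mpq,p->mq", XtZ, beta)
        for _ in range(5):
            # b_i | beta: N(W_i (Zty_i - Z'X_i beta), sigma2 W_i), batched
            mean_b = np.einsum("mqr,mr->mq", W, Zty - XtZ_beta)
            Lb = np.linalg.cholesky(sigma2 * W + 1e-14 * eye_q)
            b = mean_b + np.einsum("mqr,mr->mq", Lb, rng.standard_normal((m, q)))

            # redundant scales alpha | eta, beta, sigma2 (Gaussian)
            denom = np.where(np.abs(alpha) > 1e-12, alpha, 1e-12)
            eta = b / denom  # (m, q)
            C = Z * eta[person_index]  # column k: Z[:,k] * eta[person,k]
            prec_a = C.T @ C / sigma2 + np.diag(1.0 / A_r**2)
            La = np.linalg.cholesky(prec_a)
            mu_a = np.linalg.solve(prec_a, C.T @ r0 / sigma2)
            alpha = mu_a + np.linalg.solve(La.T, rng.standard_normal(q))

            # Sigma_c | eta: conjugate inverse-Wishart
            Sigma_c = _invwishart_bartlett(q + 1 + m, eye_q + eta.T @ eta, rng)
            Sigma = (alpha[:, None] * alpha[None, :]) * Sigma_c
            b = alpha * eta

            # sigma2 | rest with half-t auxiliary (coupled with tau0, so it
            # refreshes inside the block as well)
            r = r0 - np.einsum("nq,nq->n", Z, b[person_index])
            rate_as = nu_s / sigma2 + 1.0 / A_s**2
            a_sigma = 1.0 / rng.gamma(0.5 * (nu_s + 1.0), 1.0 / rate_as)
            rate_s = nu_s / a_sigma + 0.5 * float(r @ r)
            sigma2 = 1.0 / rng.gamma(0.5 * (n + nu_s), 1.0 / rate_s)

            Sigma_inv = np.linalg.inv(Sigma + 1e-12 * eye_q)
            W = np.linalg.inv(sigma2 * Sigma_inv[None, :, :] + ZtZ)

        if it >= warmup:
            k = it - warmup
            out_beta[k] = beta
            out_sigma[k] = np.sqrt(sigma2)
            sd = np.sqrt(np.diag(Sigma))
            out_sd[k] = sd
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = Sigma / np.outer(sd, sd)
            corr[~np.isfinite(corr)] = 0.0
            np.fill_diagonal(corr, 1.0)
            out_corr[k] = corr
            out_b[k] = b

    return GibbsResult(out_beta, out_sigma, out_sd, out_corr, out_b)
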