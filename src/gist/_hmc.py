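"""Hamiltonian Monte Carlo for the per-spot robust decomposition posterior.

Every spot j has its own parameter block: a simplex column H^(j) of cell
type proportions, a Student-t degrees-of-freedom nu_j > 3, an intercept
beta0_j and a scale sigma_j.  Spots share no parameters, so n independent
posteriors are sampled simultaneously with all heavy operations batched as
(genes x spots) array arithmetic.  Gradients of the log posterior are
analytic.

Unconstrained parameterization per spot (D = p + 2 dimensions):

* ``x`` (p-1 values): additive-logistic (softmax with a fixed last
  coordinate) coordinates of the simplex; the Dirichlet(1, ..., 1) prior
  plus the transform Jacobian contributes sum_k log h_k to the target.
* ``b``: intercept, flat prior.
* ``u = log(nu - 3)``: shifted Gamma(2, 0.1) prior on nu - 3 keeps the
  degrees of freedom above 3.
* ``v``: sigma = sigma_floor + exp(v).  Default prior is half-Cauchy on
  sigma with a wide Normal containment on v as a numerical guard against
  the scale collapsing on exactly-noiseless data.

Warmup follows the usual two-window scheme: dual-averaging step-size
adaptation (target acceptance 0.8), a diagonal mass matrix estimated from
the first window's iterates, then a second dual-averaging window under the
new metric.  Each spot draws all of its randomness from its own seeded
stream, so a joint fit and a single-spot fit with the same per-spot seed
produce bit-identical chains.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.special import digamma, gammaln

__all__ = ["sample_posterior", "derive_spot_seeds"]

# dual-averaging constants (Hoffman & Gelman 2014)
_DA_GAMMA = 0.05
_DA_T0 = 10.0
_DA_KAPPA = 0.75
_DA_TARGET = 0.8

_N_LEAPFROG = 12
_DIVERGENCE_THRESHOLD = 1000.0
_CONTAINMENT_SD = 5.0  # wide Normal on v = log(sigma - floor), numerical guard


def derive_spot_seeds(seed: int, n_spots: int, chain: int = 0) -> np.ndarray:
    """Deterministic per-spot seeds for a given global seed and chain."""
    return np.random.SeedSequence([int(seed), int(chain)]).generate_state(n_spots)


class _Posterior:
    """Batched log density and gradient for n independent spot posteriors."""

    def __init__(
        self,
        Y: np.ndarray,
        W: np.ndarray,
        prior_idx: Optional[np.ndarray] = None,
        prior_tau: Optional[np.ndarray] = None,
        prior_lam: float = 0.0,
        sigma_prior: str = "half_cauchy",
    ) -> None:
        self.m, self.n = Y.shape
        self.p = W.shape[1]
        self.W = W  # (m, p)
        self.prior_idx = prior_idx
        self.prior_tau = prior_tau
        self.prior_lam = float(prior_lam)
        if sigma_prior not in ("half_cauchy", "flat"):
            raise ValueError(f"unknown sigma prior {sigma_prior!r}")
        self.sigma_prior = sigma_prior

        # spot-major storage: each spot's data is a contiguous row, so all
        # per-spot reductions are bit-identical whether the spot is fitted
        # alone or inside a batch.  Per-spot rescaling conditions the
        # sampler without changing the posterior over h (beta0/sigma are
        # reported back on the input scale).
        Yt = np.ascontiguousarray(Y.T)  # (n, m)
        self.col_scale = np.maximum(np.mean(np.abs(Yt), axis=1), 1e-300)
        self.Y = Yt / self.col_scale[:, None]  # (n, m), scaled

        self.sigma_floor = 1e-6
        sd_y = np.std(self.Y, axis=1)
        self.cauchy_scale = np.maximum(5.0 * sd_y, 1e-6)

        # deterministic symmetric start: uniform simplex, intercept 0
        wh0 = np.zeros(self.m)
        for k in range(self.p):
            wh0 += self.W[:, k] * (1.0 / self.p)
        resid = self.Y - wh0[None, :] / self.col_scale[:, None]
        s0 = np.maximum(np.std(resid, axis=1), 1e-3)
        self.v0 = np.log(np.maximum(s0 - self.sigma_floor, 1e-12))

    @property
    def dim(self) -> int:
        return self.p + 2

    def initial_position(self) -> np.ndarray:
        theta = np.zeros((self.n, self.dim))
        theta[:, self.p] = np.log(10.0)  # nu = 13
        theta[:, self.p + 1] = self.v0
        return theta

    def logp_grad(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m, n, p = self.m, self.n, self.p
        # layout: [x (p-1), b, u, v]
        x = theta[:, : p - 1]
        b = theta[:, p - 1]
        u = theta[:, p]
        v = theta[:, p + 1]

        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            z = np.concatenate([x, np.zeros((n, 1))], axis=1)  # (n, p)
            z = z - z.max(axis=1, keepdims=True)
            log_h = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
            h = np.exp(log_h)  # (n, p)

            nu = 3.0 + np.exp(u)  # (n,)
            sig = self.sigma_floor + np.exp(v)  # (n,)

            # accumulate over types explicitly (p is small); spot-major
            # layout keeps every reduction within one contiguous row
            wh = np.zeros((n, m))
            for k in range(p):
                wh += h[:, k][:, None] * self.W[:, k][None, :]
            mu = wh / self.col_scale[:, None] + b[:, None]  # (n, m)
            r = (self.Y - mu) / sig[:, None]
            a = r * r
            l1p = np.log1p(a / nu[:, None])
            ratio = a / (nu[:, None] + a)
            S_l1p = l1p.sum(axis=1)
            S_ratio = ratio.sum(axis=1)

            c_nu = (
                gammaln((nu + 1.0) / 2.0)
                - gammaln(nu / 2.0)
                - 0.5 * np.log(nu * np.pi)
            )
            L = m * c_nu - m * np.log(sig) - 0.5 * (nu + 1.0) * S_l1p
            L = L + log_h.sum(axis=1)  # flat Dirichlet + simplex Jacobian
            L = L + 2.0 * u - 0.1 * np.exp(u)  # Gamma(2, 0.1) on nu - 3
            L = L + v  # Jacobian of sigma = floor + exp(v)
            if self.sigma_prior == "half_cauchy":
                L = L - np.log1p((sig / self.cauchy_scale) ** 2)
            L = L - 0.5 * ((v - self.v0) / _CONTAINMENT_SD) ** 2

            # gradients
            G = (nu + 1.0)[:, None] * r / (sig[:, None] * (nu[:, None] + a))
            db = G.sum(axis=1)
            Gs = G / self.col_scale[:, None]
            dh = np.empty((n, p))
            for k in range(p):
                dh[:, k] = (Gs * self.W[:, k][None, :]).sum(axis=1)

            if self.prior_idx is not None and self.prior_lam > 0:
                g = h[:, self.prior_idx].sum(axis=1)
                g = np.clip(g, 1e-300, 1.0 - 1e-16)
                tau = self.prior_tau
                lam = self.prior_lam
                L = L + lam * (tau * np.log(g) + (1.0 - tau) * np.log1p(-g))
                dh[:, self.prior_idx] += (
                    lam * (tau / g - (1.0 - tau) / (1.0 - g))
                )[:, None]

            inner = (h * dh).sum(axis=1)
            dx_full = h * (dh - inner[:, None]) + (1.0 - p * h)
            dx = dx_full[:, : p - 1]

            dL_dsig = (-m + (nu + 1.0) * S_ratio) / sig
            if self.sigma_prior == "half_cauchy":
                dL_dsig = dL_dsig - 2.0 * sig / (self.cauchy_scale**2 + sig**2)
            dv = (
                (sig - self.sigma_floor) * dL_dsig
                + 1.0
                - (v - self.v0) / _CONTAINMENT_SD**2
            )

            c_prime = (
                0.5 * digamma((nu + 1.0) / 2.0)
                - 0.5 * digamma(nu / 2.0)
                - 0.5 / nu
            )
            dL_dnu = m * c_prime - 0.5 * S_l1p + 0.5 * (nu + 1.0) / nu * S_ratio
            du = (nu - 3.0) * dL_dnu + 2.0 - 0.1 * (nu - 3.0)

            grad = np.concatenate(
                [dx, db[:, None], du[:, None], dv[:, None]], axis=1
            )

        bad = ~np.isfinite(L)
        if bad.any():
            L = np.where(bad, -np.inf, L)
            grad = np.where(np.isfinite(grad), grad, 0.0)
        return L, grad

    def decode(self, theta: np.ndarray):
        """Map unconstrained positions to (h, nu, beta0, sigma), input scale."""
        p = self.p
        z = np.concatenate([theta[:, : p - 1], np.zeros((theta.shape[0], 1))], axis=1)
        z = z - z.max(axis=1, keepdims=True)
        h = np.exp(z)
        h = h / h.sum(axis=1, keepdims=True)
        nu = 3.0 + np.exp(theta[:, p])
        sig = (self.sigma_floor + np.exp(theta[:, p + 1])) * self.col_scale
        beta0 = theta[:, p - 1] * self.col_scale
        return h, nu, beta0, sig


def _pregenerate(spot_seeds: np.ndarray, iterations: int, dim: int):
    """Per-spot random streams: momenta, log-uniforms, step-size jitter."""
    n = len(spot_seeds)
    momenta = np.empty((n, iterations, dim))
    log_u = np.empty((n, iterations))
    jitter = np.empty((n, iterations))
    for j, sj in enumerate(spot_seeds):
        rng = np.random.Generator(np.random.PCG64(int(sj)))
        momenta[j] = rng.standard_normal((iterations, dim))
        log_u[j] = np.log(rng.random(iterations))
        jitter[j] = rng.uniform(0.8, 1.2, iterations)
    return momenta, log_u, jitter


def sample_posterior(
    Y: np.ndarray,
    W: np.ndarray,
    iterations: int = 2000,
    burn_in: int = 1000,
    spot_seeds: Optional[np.ndarray] = None,
    seed: int = 0,
    prior_idx: Optional[np.ndarray] = None,
    prior_tau: Optional[np.ndarray] = None,
    prior_lam: float = 0.0,
    sigma_prior: str = "half_cauchy",
    n_leapfrog: int = _N_LEAPFROG,
    initial_step_size: float = 0.1,
) -> dict:
    """Draw posterior samples for all spots; return samples and diagnostics.

    Returns a dict with ``h`` (draws, p, n) post-burn-in simplex samples,
    posterior-mean arrays ``nu``, ``beta0``, ``sigma`` and a ``diagnostics``
    dict (per-spot acceptance rate, divergence fraction, step sizes).
    """
    Y = np.asarray(Y, dtype=float)
    W = np.asarray(W, dtype=float)
    if not 0 <= burn_in < iterations:
        raise ValueError("need 0 <= burn_in < iterations")
    m, n = Y.shape
    post = _Posterior(Y, W, prior_idx, prior_tau, prior_lam, sigma_prior)
    D = post.dim
    if spot_seeds is None:
        spot_seeds = derive_spot_seeds(seed, n)
    spot_seeds = np.asarray(spot_seeds)
    if len(spot_seeds) != n:
        raise ValueError("spot_seeds length must equal the number of spots")

    momenta, log_u, jitter = _pregenerate(spot_seeds, iterations, D)

    theta = post.initial_position()
    logp, grad = post.logp_grad(theta)

    mass_inv = np.ones((n, D))
    sqrt_mass = np.ones((n, D))
    eps = np.full(n, float(initial_step_size))

    # dual averaging state
    da_mu = np.log(10.0 * eps)
    da_hbar = np.zeros(n)
    da_logeps_bar = np.log(eps)
    da_t = 0

    # windowed mass estimation (Welford)
    b1 = burn_in // 2
    var_start = b1 // 2
    welford_n = 0
    welford_mean = np.zeros((n, D))
    welford_m2 = np.zeros((n, D))

    keep = iterations - burn_in
    h_samples = np.empty((keep, post.p, n))
    nu_sum = np.zeros(n)
    b_sum = np.zeros(n)
    sig_sum = np.zeros(n)
    accept_count = np.zeros(n)
    divergences = np.zeros(n)

    def _da_reset(current_eps):
        nonlocal da_mu, da_hbar, da_logeps_bar, da_t
        da_mu = np.log(10.0 * current_eps)
        da_hbar = np.zeros(n)
        da_logeps_bar = np.log(current_eps)
        da_t = 0

    for t in range(iterations):
        warming = t < burn_in
        eps_t = eps * jitter[:, t]
        phi = momenta[:, t, :] * sqrt_mass
        ke0 = 0.5 * ((phi * phi) * mass_inv).sum(axis=1)

        theta_new = theta.copy()
        with np.errstate(over="ignore", invalid="ignore"):
            phi_new = phi + 0.5 * eps_t[:, None] * grad
            grad_new = grad
            for step in range(n_leapfrog):
                theta_new = theta_new + eps_t[:, None] * (phi_new * mass_inv)
                logp_new, grad_new = post.logp_grad(theta_new)
                if step < n_leapfrog - 1:
                    phi_new = phi_new + eps_t[:, None] * grad_new
            phi_new = phi_new + 0.5 * eps_t[:, None] * grad_new
            ke1 = 0.5 * ((phi_new * phi_new) * mass_inv).sum(axis=1)
            d_energy = (logp_new - ke1) - (logp - ke0)
        d_energy = np.where(np.isfinite(d_energy), d_energy, -np.inf)
        diverged = d_energy < -_DIVERGENCE_THRESHOLD
        alpha = np.exp(np.minimum(d_energy, 0.0))
        accept = log_u[:, t] < d_energy

        theta[accept] = theta_new[accept]
        logp = np.where(accept, logp_new, logp)
        grad[accept] = grad_new[accept]

        if warming:
            da_t += 1
            w = 1.0 / (da_t + _DA_T0)
            da_hbar = (1.0 - w) * da_hbar + w * (_DA_TARGET - alpha)
            log_eps = da_mu - np.sqrt(da_t) / _DA_GAMMA * da_hbar
            eta = da_t ** (-_DA_KAPPA)
            da_logeps_bar = eta * log_eps + (1.0 - eta) * da_logeps_bar
            eps = np.exp(log_eps)

            if var_start <= t < b1:
                welford_n += 1
                delta = theta - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (theta - welford_mean)
            if t == b1 - 1 and welford_n >= 5:
                var = welford_m2 / max(welford_n - 1, 1)
                # regularized diagonal metric, Stan style
                shrink = welford_n / (welford_n + 5.0)
                mass_inv = shrink * var + (1.0 - shrink) * 1e-3
                mass_inv = np.clip(mass_inv, 1e-10, 1e10)
                sqrt_mass = 1.0 / np.sqrt(mass_inv)
                eps = np.exp(da_logeps_bar)
                _da_reset(eps)
            if t == burn_in - 1:
                eps = np.exp(da_logeps_bar)
        else:
            accept_count += accept
            divergences += diverged
            h, nu, b0, sig = post.decode(theta)
            h_samples[t - burn_in] = h.T
            nu_sum += nu
            b_sum += b0
            sig_sum += sig

    diagnostics = {
        "accept_rate": accept_count / max(keep, 1),
        "divergence_fraction": divergences / max(keep, 1),
        "step_size": eps.copy(),
        "n_leapfrog": n_leapfrog,
        "spot_seeds": spot_seeds.copy(),
    }
    return {
        "h": h_samples,
        "nu": nu_sum / max(keep, 1),
        "beta0": b_sum / max(keep, 1),
        "sigma": sig_sum / max(keep, 1),
        "diagnostics": diagnostics,
    }
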