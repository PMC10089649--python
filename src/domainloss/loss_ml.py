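"""Maximum-likelihood estimation of the per-domain total loss rate.

The likelihood of a Dollo reconstruction given a loss rate ``lam`` (per My)
is the product over retention branches k of exp(-t_k*lam) and over loss
branches j of (1 - exp(-t_j*lam)): losses are a Poisson process along each
branch, so the probability of at least one total loss on a branch of
length t is 1 - exp(-t*lam).

The maximizer is found by Newton's method on log(lam) — which enforces
positivity — initialized at the parsimony rate (losses per My of retention
branch length), with step-halving and a bounded-minimization fallback when
the curvature is unusable.  Estimates above 1 loss/My are treated as
runaway fits driven by unmodelled false positives and reset to the
parsimony initialization (guard path).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .dollo import DolloReconstruction, parsimony_init_rate

__all__ = ["LossFit", "branch_loss_prob", "loglik", "mle_loss_rate"]

RATE_GUARD = 1.0  # losses/My above which the ML estimate is deemed runaway
_TOL = 1e-10
_MAX_ITER = 100


@dataclass(frozen=True)
class LossFit:
    pfam_id: str
    lambda_hat: float      # losses/My
    loglik: float          # natural log likelihood at lambda_hat
    n_iter: int
    guard_triggered: bool
    init_rate: float


def branch_loss_prob(t: float, lam: float) -> float:
    """Probability of at least one total loss on a branch of length t My."""
    if t < 0 or lam < 0:
        raise ValueError("branch length and loss rate must be non-negative")
    return -math.expm1(-t * lam)


def loglik(recon: DolloReconstruction, lam: float) -> float:
    """Log likelihood of the reconstruction at loss rate ``lam``.

    Evaluates sum_k(-t_k*lam) + sum_j log(1 - exp(-t_j*lam)) with
    expm1-based stability for small t*lam.  ``lam = 0`` with losses
    present gives -inf.  Zero-length loss branches (possible under
    polytomy-derived trees) carry no rate information and are dropped
    from the product.
    """
    if lam < 0:
        raise ValueError("loss rate must be non-negative")
    ll = -recon.retention_length * lam
    for t in recon.loss_lengths:
        if t == 0:
            continue
        p = -math.expm1(-t * lam)
        if p <= 0.0:
            return -math.inf
        ll += math.log(p)
    return ll


def _derivatives(recon: DolloReconstruction, lam: float) -> tuple[float, float]:
    """First and second derivatives of the log likelihood w.r.t. lam."""
    d1 = -recon.retention_length
    d2 = 0.0
    for t in recon.loss_lengths:
        x = t * lam
        if x == 0 or x > 700:  # zero-length branch, or exp overflow
            continue
        em1 = math.expm1(x)
        d1 += t / em1
        d2 -= t * t * math.exp(x) / (em1 * em1)
    return d1, d2


def mle_loss_rate(
    recon: DolloReconstruction, init_denominator: str = "retention"
) -> LossFit:
    """Fit the total loss rate for one reconstruction.

    Returns exactly 0 for zero-loss domains.  Otherwise Newton iteration on
    log(lam) until the log-likelihood changes by less than 1e-10 (or 100
    iterations), falling back to bounded minimization on
    [init/100, 100*init] if Newton cannot make progress.  A maximizer above
    1/My triggers the guard: the parsimony initialization is returned with
    its own likelihood.
    """
    if recon.n_losses == 0:
        return LossFit(recon.pfam_id, 0.0, 0.0, 0, False, 0.0)

    if recon.retention_length <= 0:
        # likelihood strictly increasing in lam: unbounded, always guarded
        init = parsimony_init_rate(recon, denominator="total")
        return LossFit(recon.pfam_id, init, loglik(recon, init), 0, True, init)

    init = parsimony_init_rate(recon, denominator=init_denominator)
    u = math.log(init)
    ll = loglik(recon, math.exp(u))
    n_iter = 0
    converged = False
    for n_iter in range(1, _MAX_ITER + 1):
        lam = math.exp(u)
        d1, d2 = _derivatives(recon, lam)
        g = lam * d1                       # d loglik / d log(lam)
        h = lam * d1 + lam * lam * d2      # second derivative in log(lam)
        if h >= 0 or not math.isfinite(h):
            converged = False
            break
        step = -g / h
        # safeguarded step-halving
        new_ll = -math.inf
        for _ in range(60):
            cand = u + step
            new_ll = loglik(recon, math.exp(cand))
            if new_ll >= ll - 1e-15:
                break
            step *= 0.5
        if new_ll < ll - 1e-15:
            converged = False
            break
        u += step
        if abs(new_ll - ll) < _TOL:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    lam_hat = math.exp(u)

    if not converged:
        lo, hi = math.log(init / 100.0), math.log(init * 100.0)
        res = minimize_scalar(
            lambda v: -loglik(recon, math.exp(v)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        if not res.success:
            raise RuntimeError(
                f"{recon.pfam_id or 'reconstruction'}: loss-rate optimization "
                f"failed after Newton and bounded fallback ({res.message})"
            )
        lam_hat, ll = math.exp(res.x), -res.fun
        n_iter += int(res.nfev)

    if lam_hat > RATE_GUARD:
        return LossFit(recon.pfam_id, init, loglik(recon, init), n_iter, True, init)
    return LossFit(recon.pfam_id, lam_hat, ll, n_iter, False, init)


def fit_all(recons, init_denominator: str = "retention") -> "np.ndarray":
    """Vector of lambda_hat over an iterable of reconstructions."""
    return np.array(
        [mle_loss_rate(r, init_denominator).lambda_hat for r in recons]
    )
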