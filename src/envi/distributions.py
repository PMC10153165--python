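"""Count and Gaussian likelihoods for the variational model.

Negative binomial convention: ``r`` failures and success probability ``p``
with pmf C(k+r-1, r-1) (1-p)^k p^r, hence mean r(1-p)/p. This matches both
numpy's and scipy's (n, p) parameterization; the convention is stated
explicitly because libraries differ on which outcome ``p`` refers to.

All log-probabilities use log-gamma forms and accept either plain numpy
arrays or autodiff Tensors (the latter propagate gradients).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln as _gammaln

from .autodiff import Tensor

FAMILIES = ("poisson", "negative_binomial", "zinb", "normal")

_P_MIN, _P_MAX = 1e-6, 1.0 - 1e-6


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _val(x):
    return x.data if _is_tensor(x) else np.asarray(x, dtype=np.float64)


def poisson_logpmf(k, lam):
    """log Pois(k | lambda) = k log lambda - lambda - log k!"""
    k_arr = _val(k)
    if np.any(k_arr < 0):
        raise ValueError("counts must be non-negative")
    const = -_gammaln(k_arr + 1.0)
    if _is_tensor(lam):
        return lam.log() * k_arr - lam + const
    lam = np.asarray(lam, dtype=np.float64)
    if np.any(lam <= 0):
        raise ValueError("Poisson rate must be positive")
    return k_arr * np.log(lam) - lam + const


def nb_logpmf(k, r, p):
    """log NB(k | r, p) with pmf C(k+r-1, r-1) (1-p)^k p^r."""
    k_arr = _val(k)
    if np.any(k_arr < 0):
        raise ValueError("counts must be non-negative")
    if _is_tensor(r) or _is_tensor(p):
        r_t = r if _is_tensor(r) else Tensor(np.asarray(r, dtype=np.float64))
        p_t = p if _is_tensor(p) else Tensor(np.asarray(p, dtype=np.float64))
        comb = (r_t + k_arr).gammaln() - r_t.gammaln() - _gammaln(k_arr + 1.0)
        return comb + (1.0 - p_t).log() * k_arr + p_t.log() * r_t
    r = np.asarray(r, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if np.any(r <= 0) or np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("need r > 0 and p in (0, 1)")
    return (
        _gammaln(k_arr + r) - _gammaln(r) - _gammaln(k_arr + 1.0)
        + k_arr * np.log1p(-p) + r * np.log(p)
    )


def zinb_logpmf(k, r, p, dropout):
    """Zero-inflated NB: point mass ``dropout`` at 0 mixed with NB(r, p)."""
    k_arr = _val(k)
    zero_mask = (k_arr == 0).astype(np.float64)
    base = nb_logpmf(k, r, p)
    if _is_tensor(base) or _is_tensor(dropout):
        d = dropout if _is_tensor(dropout) else Tensor(np.asarray(dropout, dtype=np.float64))
        nb_prob = base.exp()
        at_zero = (d + (1.0 - d) * nb_prob + 1e-300).log()
        elsewhere = (1.0 - d + 1e-300).log() + base
        return at_zero * zero_mask + elsewhere * (1.0 - zero_mask)
    d = np.asarray(dropout, dtype=np.float64)
    if np.any(d < 0) or np.any(d > 1):
        raise ValueError("dropout weight must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        at_zero = np.log(d + (1.0 - d) * np.exp(base) + 1e-300)
        elsewhere = np.log(1.0 - d + 1e-300) + base
    return np.where(k_arr == 0, at_zero, elsewhere)


def normal_logpdf(x, mu, scale=1.0):
    """Diagonal Gaussian log-density."""
    x_arr = _val(x)
    if _is_tensor(mu):
        s = scale if _is_tensor(scale) else np.asarray(scale, dtype=np.float64)
        log_s = s.log() if _is_tensor(s) else np.log(s)
        z = (mu - x_arr) / s
        return -(0.5 * np.log(2.0 * np.pi)) - log_s - 0.5 * z * z
    mu = np.asarray(mu, dtype=np.float64)
    scale = np.asarray(scale, dtype=np.float64)
    z = (x_arr - mu) / scale
    return -0.5 * np.log(2.0 * np.pi) - np.log(scale) - 0.5 * z * z


def log_prob(family: str, params: dict, counts):
    """Per-element log-likelihood for one of the supported families.

    ``params`` keys: ``lam`` (poisson); ``r``, ``p`` (negative_binomial);
    plus ``dropout`` (zinb); ``mu`` and optional ``scale`` (normal).
    """
    if family == "poisson":
        return poisson_logpmf(counts, params["lam"])
    if family == "negative_binomial":
        return nb_logpmf(counts, params["r"], params["p"])
    if family == "zinb":
        return zinb_logpmf(counts, params["r"], params["p"], params["dropout"])
    if family == "normal":
        return normal_logpdf(counts, params["mu"], params.get("scale", 1.0))
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


def family_mean(family: str, params: dict):
    """Expected value of each family (used for imputation)."""
    if family == "poisson":
        return _val(params["lam"])
    if family == "negative_binomial":
        r, p = _val(params["r"]), _val(params["p"])
        return r * (1.0 - p) / p
    if family == "zinb":
        r, p, d = _val(params["r"]), _val(params["p"]), _val(params["dropout"])
        return (1.0 - d) * r * (1.0 - p) / p
    if family == "normal":
        return _val(params["mu"])
    raise ValueError(f"unknown family {family!r}")


def kl_diag_gaussian(mu, sigma):
    """KL( N(mu, diag sigma^2) || N(0, I) ), summed over dimensions.

    Closed form 0.5 * sum(mu^2 + sigma^2 - 1 - 2 log sigma).
    """
    if _is_tensor(mu) or _is_tensor(sigma):
        mu_t = mu if _is_tensor(mu) else Tensor(mu)
        sg = sigma if _is_tensor(sigma) else Tensor(sigma)
        return (mu_t * mu_t + sg * sg - 1.0 - sg.log() * 2.0).sum(axis=-1) * 0.5
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    return 0.5 * np.sum(mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma), axis=-1)


def clamp_probability(p):
    """Keep success probabilities strictly inside (0, 1) for log safety."""
    if _is_tensor(p):
        return p * (_P_MAX - _P_MIN) + _P_MIN
    return np.clip(p, _P_MIN, _P_MAX)
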