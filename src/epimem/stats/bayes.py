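"""JZS (Jeffreys–Zellner–Siow) Bayes factors.

The JZS setup places a Jeffreys prior on the grand mean and error variance
and a Cauchy(0, r) prior on the standardized effect, implemented through a
scaled inverse-chi-square mixing variable ``g`` (g ~ Inv-Gamma(1/2, r^2/2)).
``BF10`` is the marginal-likelihood ratio of the effect model over the
null, obtained by one-dimensional numerical integration over ``g``.

* ``one_sample``: the classic t-test Bayes factor of Rouder et al.'s
  default approach — the integrand depends on the data only through the
  t statistic and sample size.
* ``one_way``: the g-prior generalization for a single categorical factor;
  the k-group effect vector is given an i.i.d. ``N(0, g*sigma^2)`` prior on
  k-1 orthonormalized sum-to-zero contrasts, and the marginal ratio is
  integrated over the same Inv-Gamma prior on g.

Default prior scale ``r = sqrt(2)/2`` ("medium").  BF10 < 1 means the data
favor the null; both BF10 and BF01 = 1/BF10 are reported.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, special

from ..types import BayesFactorResult, DegenerateDataError

__all__ = ["jzs_bayes_factor"]

DEFAULT_SCALE = np.sqrt(2.0) / 2.0


def _log_invgamma_pdf(g: np.ndarray, r: float) -> np.ndarray:
    # Inv-Gamma(shape 1/2, scale r^2/2)
    a, b = 0.5, r * r / 2.0
    return a * np.log(b) - special.gammaln(a) - (a + 1.0) * np.log(g) - b / g


def _log_bf_g_one_sample(g: np.ndarray, t: float, n: int) -> np.ndarray:
    nu = n - 1.0
    ng1 = 1.0 + n * g
    num = -0.5 * np.log(ng1) - (nu + 1.0) / 2.0 * np.log1p(t * t / (ng1 * nu))
    den = -(nu + 1.0) / 2.0 * np.log1p(t * t / nu)
    return num - den


def _integrate_bf(log_bf_g, r: float, rtol: float = 1e-6) -> float:
    """Integrate exp(log_bf_g(g)) * pi_r(g) over g in (0, inf)."""

    def f(g):
        g = np.asarray(g, dtype=float)
        return np.exp(log_bf_g(g) + _log_invgamma_pdf(g, r))

    v1, e1 = integrate.quad(f, 0.0, 1.0, limit=200)
    v2, e2 = integrate.quad(lambda h: f(1.0 / h) / (h * h), 1e-12, 1.0, limit=200)
    val, err = v1 + v2, e1 + e2
    if not np.isfinite(val) or val <= 0 or err > max(rtol * val, 1e-10):
        raise DegenerateDataError(
            f"Bayes-factor quadrature did not converge: value={val}, abserr={err}"
        )
    return float(val)


def _one_way_log_bf_g(groups: dict[str, np.ndarray]):
    names = list(groups)
    k = len(names)
    if k < 2:
        raise DegenerateDataError("one-way design needs >= 2 groups")
    y = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    N = y.size
    labels = np.concatenate([np.full(len(groups[g]), i) for i, g in enumerate(names)])
    C = np.zeros((N, k))
    C[np.arange(N), labels.astype(int)] = 1.0
    # orthonormal basis of the sum-to-zero contrast space
    Q, _ = np.linalg.qr(np.eye(k) - np.ones((k, k)) / k)
    Q = Q[:, : k - 1]
    Z = C @ Q
    Z = Z - Z.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    yty = float(yc @ yc)
    if yty <= 0:
        raise DegenerateDataError("zero variance")
    G = Z.T @ Z
    lam, V = np.linalg.eigh(G)
    w = V.T @ (Z.T @ yc)

    def log_bf(g: np.ndarray) -> np.ndarray:
        g = np.atleast_1d(np.asarray(g, dtype=float))
        one_pg = 1.0 + np.outer(g, lam)  # (m, k-1)
        logdet = -0.5 * np.sum(np.log(one_pg), axis=1)
        R = yty - np.sum((g[:, None] * w[None, :] ** 2) / one_pg, axis=1)
        out = logdet - (N - 1.0) / 2.0 * (np.log(R) - np.log(yty))
        return out if out.size > 1 else out[0]

    return log_bf, N


def jzs_bayes_factor(
    data,
    design: str = "one_sample",
    mu0: float = 0.0,
    r: float = DEFAULT_SCALE,
) -> BayesFactorResult:
    """JZS Bayes factor for a one-sample mean or a one-way group effect.

    Parameters
    ----------
    data : array of values (``one_sample``) or mapping group -> values
        (``one_way``).
    mu0 : null mean for the one-sample design.
    r : Cauchy prior scale on the standardized effect (default sqrt(2)/2).

    Returns a :class:`BayesFactorResult` with ``bf10`` (evidence for the
    effect model) and the prior descriptor.
    """
    if design == "one_sample":
        x = np.asarray(data, dtype=float)
        x = x[~np.isnan(x)]
        if x.size < 2 or x.std(ddof=1) == 0:
            raise DegenerateDataError("one-sample BF needs >= 2 values with variance")
        n = x.size
        t = (x.mean() - mu0) / (x.std(ddof=1) / np.sqrt(n))
        bf10 = _integrate_bf(lambda g: _log_bf_g_one_sample(g, t, n), r)
        return BayesFactorResult(bf10=bf10, prior=f"JZS (Cauchy scale r={r:g})", design="one_sample")
    if design == "one_way":
        log_bf, _ = _one_way_log_bf_g(dict(data))
        bf10 = _integrate_bf(log_bf, r)
        return BayesFactorResult(
            bf10=bf10, prior=f"JZS (g-prior, scale r={r:g})", design="one_way"
        )
    raise ValueError(f"unknown design {design!r}; expected one_sample or one_way")
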