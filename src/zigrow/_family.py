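"""Per-observation derivatives of the zero-inflated Gaussian log-density.

The observation model on the log-growth scale: with mortality probability
``p = logistic(eta)`` and conditional mean ``mu``,

* ``y = 0``:  ``f = p + (1 - p) * phi(0; mu, sigma^2)``
* ``y > 0``:  ``f = (1 - p) * phi(y; mu, sigma^2)``

i.e. the zero-inflation mixes a point mass at zero with the Gaussian
*density value* at zero (the numerical convention of the reference
mixed-model machinery for continuous zero-inflation).

The Laplace marginal likelihood and its exact gradient need ``log f`` and
its partial derivatives with respect to ``(mu, eta, log sigma)`` up to
third order.  All formulas are written in terms of the posterior weight of
the sampling-zero branch ``A = (1-p) * phi0 / f`` (and ``B = 1 - A``),
which keeps them bounded and stable for extreme ``eta`` or ``mu``.

Derivative naming: ``d.mu_eta_ls`` style keys, e.g. ``mu2`` is
``d^2 log f / d mu^2`` and ``mu2ls`` is ``d^3 log f / d mu^2 d log sigma``.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
from scipy.special import expit

LOG_2PI = float(np.log(2.0 * np.pi))

# keys of the derivative bundle, in a fixed order
DERIV_KEYS = (
    "ll",
    "mu1", "eta1", "ls1",
    "mu2", "mueta", "eta2", "muls", "etals",
    "mu3", "mu2eta", "mueta2", "eta3",
    "mu2ls", "muetals", "eta2ls",
)


def gaussian_derivs(y, mu, log_sigma):
    """Derivative bundle for a plain Gaussian observation model (no zi).

    All ``eta``-derivatives are absent (set to None).
    """
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    sigma2 = np.exp(2.0 * log_sigma)
    c2 = 1.0 / sigma2
    r = y - mu
    d = SimpleNamespace(**{k: None for k in DERIV_KEYS})
    d.ll = -0.5 * LOG_2PI - log_sigma - 0.5 * r**2 * c2
    d.mu1 = r * c2
    d.ls1 = r**2 * c2 - 1.0
    d.mu2 = np.full_like(mu, -c2)
    d.muls = -2.0 * r * c2
    d.mu3 = np.zeros_like(mu)
    d.mu2ls = np.full_like(mu, 2.0 * c2)
    return d


def zi_gaussian_derivs(y, mu, eta, log_sigma):
    """Derivative bundle for the zero-inflated Gaussian log-density.

    Vectorized over observations; ``y == 0`` selects the mixture branch.
    """
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    eta = np.asarray(eta, float)
    n = y.shape[0]
    sigma2 = np.exp(2.0 * log_sigma)
    c2 = 1.0 / sigma2

    p = expit(eta)
    q = expit(-eta)
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    pq = p * q

    zero = y == 0.0
    d = SimpleNamespace(**{k: np.empty(n) for k in DERIV_KEYS})

    # --- positive branch: log f = log q + log phi(y; mu, sigma) ----------
    pos = ~zero
    r = y[pos] - mu[pos]
    d.ll[pos] = log_q[pos] - 0.5 * LOG_2PI - log_sigma - 0.5 * r**2 * c2
    d.mu1[pos] = r * c2
    d.eta1[pos] = -p[pos]
    d.ls1[pos] = r**2 * c2 - 1.0
    d.mu2[pos] = -c2
    d.mueta[pos] = 0.0
    d.eta2[pos] = -pq[pos]
    d.muls[pos] = -2.0 * r * c2
    d.etals[pos] = 0.0
    d.mu3[pos] = 0.0
    d.mu2eta[pos] = 0.0
    d.mueta2[pos] = 0.0
    d.eta3[pos] = -pq[pos] * (q[pos] - p[pos])
    d.mu2ls[pos] = 2.0 * c2
    d.muetals[pos] = 0.0
    d.eta2ls[pos] = 0.0

    # --- zero branch: log f = logaddexp(log p, log q + log phi0) ---------
    mz, ez = mu[zero], eta[zero]
    log_g = -0.5 * LOG_2PI - log_sigma - 0.5 * mz**2 * c2
    lf = np.logaddexp(log_p[zero], log_q[zero] + log_g)
    A = np.exp(log_q[zero] + log_g - lf)  # sampling-zero branch weight
    B = np.exp(log_p[zero] - lf)  # structural-zero branch weight
    AB = A * B
    pz, qz = p[zero], q[zero]
    pqz = pz * qz
    m = mz * c2  # d(-log g)/d mu
    k = mz**2 * c2 - 1.0  # d log g / d log sigma

    d.ll[zero] = lf
    d.mu1[zero] = -A * m
    d.eta1[zero] = B - pz
    d.ls1[zero] = A * k
    d.mu2[zero] = AB * m**2 - A * c2
    d.mueta[zero] = AB * m
    d.eta2[zero] = AB - pqz
    d.muls[zero] = A * m * 2.0 - AB * m * k
    d.etals[zero] = -AB * k
    AmB = A - B
    d.mu3[zero] = AB * AmB * m**3 + 3.0 * AB * m * c2
    d.mu2eta[zero] = AB * AmB * m**2 + AB * c2
    d.mueta2[zero] = AB * m * AmB
    d.eta3[zero] = AB * AmB - pqz * (qz - pz)
    d.mu2ls[zero] = 2.0 * A * c2 - 4.0 * AB * m**2 - AB * m**2 * k * AmB - AB * k * c2
    d.muetals[zero] = -AB * m * (2.0 + k * AmB)
    d.eta2ls[zero] = -k * AB * AmB
    return d
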