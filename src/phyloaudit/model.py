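"""The GTR+Gamma substitution model shared by the simulator and the ML engine.

The rate matrix Q is normalized to one expected substitution per site per
unit branch length, so branch lengths (and the campaign's alpha scale factor)
are interpretable directly as expected substitutions per site.

Among-site rate variation uses the discrete-Gamma approximation: equal
probability categories whose rates are the conditional means of a
Gamma(shape, shape) distribution on the category intervals (the convention of
the common simulators and ML programs); a median-based discretization is
available behind a flag. An optional proportion of invariant sites adds a
zero-rate category, with the Gamma rates rescaled so the overall mean rate
stays 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc, gammaincinv

__all__ = ["GTRModel", "discrete_gamma_rates", "gtr_transition_matrix", "JC"]

# exchangeability order: AC, AG, AT, CG, CT, GT
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def discrete_gamma_rates(
    shape: float, n_categories: int, *, median: bool = False
) -> np.ndarray:
    """Rate multipliers of the discrete-Gamma model (mean exactly 1).

    Categories have equal probability 1/k. By default each category's rate is
    the conditional mean of Gamma(shape, rate=shape) over the category
    interval; with ``median=True``, the interval median is used instead
    (renormalized to mean 1).
    """
    if shape <= 0:
        raise ValueError(f"gamma shape must be positive, got {shape}")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    k = n_categories
    if k == 1:
        return np.ones(1)
    if median:
        quantiles = (2 * np.arange(k) + 1) / (2 * k)
        rates = gammaincinv(shape, quantiles) / shape
    else:
        # interval boundaries of Gamma(shape, rate=shape); F_a(x) = gammainc(a, a*x)
        bounds = np.concatenate(
            [[0.0], gammaincinv(shape, np.arange(1, k) / k) / shape, [np.inf]]
        )
        upper = gammainc(shape + 1, shape * bounds[1:])
        lower = gammainc(shape + 1, shape * bounds[:-1])
        rates = k * (upper - lower)
    return rates / rates.mean()


@dataclass
class GTRModel:
    """General time-reversible model with discrete-Gamma rate variation.

    Parameters
    ----------
    exchangeabilities : six symmetric rates in the order AC, AG, AT, CG, CT, GT.
    freqs : equilibrium base frequencies (A, C, G, T), summing to 1.
    gamma_shape : shape of the Gamma rate distribution.
    n_categories : number of discrete Gamma categories.
    p_invariant : proportion of invariant (zero-rate) sites.
    """

    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float = 1.0
    n_categories: int = 4
    p_invariant: float = 0.0
    median_rates: bool = field(default=False, repr=False)

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.shape != (4,) or np.any(freqs <= 0):
            raise ValueError("freqs must be 4 positive numbers")
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError(f"freqs sum to {freqs.sum()}, not 1")
        rates = np.asarray(self.exchangeabilities, dtype=float)
        if rates.shape != (6,) or np.any(rates <= 0):
            raise ValueError("exchangeabilities must be 6 positive numbers")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if not 0 <= self.p_invariant < 1:
            raise ValueError("p_invariant must lie in [0, 1)")
        self._freqs = freqs
        self._exch = rates
        self._eig = None

    # -- rate matrix -----------------------------------------------------

    @property
    def pi(self) -> np.ndarray:
        return self._freqs

    @property
    def Q(self) -> np.ndarray:
        """Rate matrix normalized to mean rate 1 (-sum_i pi_i q_ii = 1)."""
        Q = np.zeros((4, 4))
        for s, (i, j) in zip(self._exch, _PAIRS):
            Q[i, j] = s * self._freqs[j]
            Q[j, i] = s * self._freqs[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(self._freqs * np.diag(Q)).sum()
        return Q / mu

    def _eigen(self):
        if self._eig is None:
            sqrt_pi = np.sqrt(self._freqs)
            B = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
            lam, V = np.linalg.eigh((B + B.T) / 2.0)
            left = V.T * sqrt_pi[None, :]  # V^T D^{1/2}
            right = V / sqrt_pi[:, None]  # D^{-1/2} V
            self._eig = (lam, right, left)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), rows summing to 1; requires t >= 0."""
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        lam, right, left = self._eigen()
        P = (right * np.exp(lam * t)) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, t: float, rates: np.ndarray) -> np.ndarray:
        """Stacked P(rate_k * t) for each rate category, shape (k, 4, 4)."""
        return np.stack([self.transition_matrix(r * t) for r in rates])

    # -- site-rate mixture ------------------------------------------------

    def category_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the site-rate mixture, mean rate exactly 1."""
        gamma = discrete_gamma_rates(
            self.gamma_shape, self.n_categories, median=self.median_rates
        )
        if self.p_invariant > 0:
            rates = np.concatenate([[0.0], gamma / (1.0 - self.p_invariant)])
            weights = np.concatenate(
                [
                    [self.p_invariant],
                    np.full(self.n_categories, (1 - self.p_invariant) / self.n_categories),
                ]
            )
        else:
            rates = gamma
            weights = np.full(self.n_categories, 1.0 / self.n_categories)
        return rates, weights

    def with_empirical_freqs(self, alignment) -> "GTRModel":
        """Return a copy using base frequencies counted from an alignment
        (the +F convention); gaps and ambiguities are ignored."""
        mat = alignment.matrix()
        counts = np.array([(mat == base.encode()).sum() for base in "ACGT"], float)
        if counts.sum() == 0:
            raise ValueError("alignment contains no unambiguous nucleotides")
        freqs = counts / counts.sum()
        # keep frequencies strictly positive for the eigendecomposition
        freqs = np.clip(freqs, 1e-6, None)
        freqs = freqs / freqs.sum()
        return GTRModel(
            exchangeabilities=tuple(self._exch),
            freqs=tuple(freqs),
            gamma_shape=self.gamma_shape,
            n_categories=self.n_categories,
            p_invariant=self.p_invariant,
            median_rates=self.median_rates,
        )


def gtr_transition_matrix(model: GTRModel, t: float) -> np.ndarray:
    """Functional alias for :meth:`GTRModel.transition_matrix`."""
    return model.transition_matrix(t)


def JC(gamma_shape: float = 1.0, n_categories: int = 4) -> GTRModel:
    """Jukes-Cantor special case (equal exchangeabilities and frequencies)."""
    return GTRModel(gamma_shape=gamma_shape, n_categories=n_categories)
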