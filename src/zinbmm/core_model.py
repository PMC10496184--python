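"""Probability kernels and objective functions for the ZINB mixture model.

The observation model for a raw count ``X_ij`` (cell i, gene j) in cluster k is
a zero-inflated negative binomial (ZINB),

    f_ZINB(x; pi_jk, mu_ijk, phi_j)
        = pi_jk * I(x == 0) + (1 - pi_jk) * f_NB(x; mu_ijk, phi_j),

with the NB parameterized by mean ``mu`` and dispersion ``phi``
(Var = mu + mu^2 / phi) and a log-linear mean with an additive batch shift,

    log mu_ijk = beta_jk + B_i' gamma.

All arithmetic is carried out in log space (log-gamma functions, log-sum-exp):
with ~1000 genes the per-cluster likelihood products underflow catastrophically
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

logger = logging.getLogger("zinbmm")

# exp(beta + B'gamma) is clamped to this range before use: quasi-Newton line
# searches can transiently propose extreme values.
MU_MIN = 1e-10
MU_MAX = 1e12


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """A cells x genes matrix of non-negative integer counts."""

    values: np.ndarray
    cell_ids: list[str] = field(default=None)  # type: ignore[assignment]
    gene_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("count matrix must be 2-D and non-empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("count matrix contains non-finite entries")
        if np.any(self.values < 0) or np.any(self.values != np.floor(self.values)):
            raise ValueError("count matrix must contain non-negative integers")
        self.values = self.values.astype(np.int64)
        n, J = self.values.shape
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i + 1}" for i in range(n)]
        if self.gene_ids is None:
            self.gene_ids = [f"gene{j + 1}" for j in range(J)]
        if len(self.cell_ids) != n or len(self.gene_ids) != J:
            raise ValueError("id lists must match matrix dimensions")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def J(self) -> int:
        return self.values.shape[1]

    # cached derived arrays (the matrix is immutable once constructed)
    @property
    def float_values(self) -> np.ndarray:
        cached = self.__dict__.get("_float_values")
        if cached is None:
            cached = self.values.astype(float)
            self.__dict__["_float_values"] = cached
        return cached

    @property
    def zero_mask(self) -> np.ndarray:
        cached = self.__dict__.get("_zero_mask")
        if cached is None:
            cached = self.values == 0
            self.__dict__["_zero_mask"] = cached
        return cached

    @property
    def gammaln_x1(self) -> np.ndarray:
        cached = self.__dict__.get("_gammaln_x1")
        if cached is None:
            cached = gammaln(self.float_values + 1.0)
            self.__dict__["_gammaln_x1"] = cached
        return cached


@dataclass
class BatchDesign:
    """One-hot batch membership for n cells over S known batches."""

    indicators: np.ndarray

    def __post_init__(self) -> None:
        self.indicators = np.asarray(self.indicators, dtype=float)
        if self.indicators.ndim != 2:
            raise ValueError("batch indicators must be an n x S matrix")
        if not np.all(np.isin(self.indicators, (0.0, 1.0))):
            raise ValueError("batch indicators must be binary")
        if not np.all(self.indicators.sum(axis=1) == 1):
            raise ValueError("each cell must belong to exactly one batch")
        if np.any(self.indicators.sum(axis=0) == 0):
            raise ValueError("every batch must contain at least one cell")

    @classmethod
    def from_labels(cls, labels) -> "BatchDesign":
        """Build a one-hot design with batches ordered by first appearance."""
        labels = list(labels)
        order: list = []
        for lab in labels:
            if lab not in order:
                order.append(lab)
        idx = {lab: s for s, lab in enumerate(order)}
        ind = np.zeros((len(labels), len(order)))
        for i, lab in enumerate(labels):
            ind[i, idx[lab]] = 1.0
        return cls(ind)

    @property
    def n(self) -> int:
        return self.indicators.shape[0]

    @property
    def S(self) -> int:
        return self.indicators.shape[1]

    def batch_index(self) -> np.ndarray:
        """Integer batch index per cell (0-based)."""
        return self.indicators.argmax(axis=1)


@dataclass
class ZinbmmParams:
    """Full parameter vector theta for a K-component ZINB mixture.

    ``p``      : (K,) mixing proportions
    ``pi``     : (J, K) dropout probabilities
    ``beta``   : (J, K) cluster log-means (batch-adjusted)
    ``phi``    : (J,) NB dispersions, shared across clusters
    ``gamma``  : (S,) batch coefficients, shared across clusters and genes
    ``beta_star``: (J,) pre-estimated global log-means (shrinkage targets)
    """

    p: np.ndarray
    pi: np.ndarray
    beta: np.ndarray
    phi: np.ndarray
    gamma: np.ndarray
    beta_star: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.beta_star = np.asarray(self.beta_star, dtype=float)

    @property
    def K(self) -> int:
        return self.p.shape[0]

    @property
    def J(self) -> int:
        return self.beta.shape[0]

    @property
    def S(self) -> int:
        return self.gamma.shape[0]

    def validate(self) -> None:
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("mixing proportions must be non-negative and sum to 1")
        if np.any(self.pi < 0) or np.any(self.pi > 1):
            raise ValueError("dropout probabilities must lie in [0, 1]")
        if np.any(self.phi <= 0):
            raise ValueError("dispersions must be positive")
        for arr in (self.p, self.pi, self.beta, self.phi, self.gamma, self.beta_star):
            if not np.all(np.isfinite(arr)):
                raise ValueError("parameters contain non-finite values")
        if self.pi.shape != self.beta.shape or self.beta.shape != (self.J, self.K):
            raise ValueError("pi and beta must both be J x K")

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.p, self.pi.ravel(), self.beta.ravel(), self.phi, self.gamma]
        )

    def copy(self) -> "ZinbmmParams":
        return ZinbmmParams(
            self.p.copy(), self.pi.copy(), self.beta.copy(),
            self.phi.copy(), self.gamma.copy(), self.beta_star.copy(),
        )


# ---------------------------------------------------------------------------
# Probability kernels
# ---------------------------------------------------------------------------

def _check_domain(x, mu, phi) -> None:
    x = np.asarray(x)
    mu = np.asarray(mu)
    phi = np.asarray(phi)
    if np.any(~np.isfinite(mu)) or np.any(~np.isfinite(phi)):
        raise ValueError("mu and phi must be finite")
    if np.any(mu <= 0) or np.any(phi <= 0):
        raise ValueError("mu and phi must be positive")
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("counts must be non-negative integers")


def nb_logpmf(x, mu, phi, *, validate: bool = True):
    """Log-pmf of the negative binomial with mean ``mu`` and dispersion ``phi``.

    f_NB(x; mu, phi) = Gamma(x+phi) / (x! Gamma(phi))
                       * (mu/(mu+phi))^x * (phi/(mu+phi))^phi
    """
    if validate:
        _check_domain(x, mu, phi)
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    log_denom = np.log(mu + phi)
    return (
        gammaln(x + phi) - gammaln(phi) - gammaln(x + 1.0)
        + x * (np.log(mu) - log_denom)
        + phi * (np.log(phi) - log_denom)
    )


def zinb_logpmf(x, pi, mu, phi, *, validate: bool = True):
    """Log-pmf of the zero-inflated negative binomial.

    log( pi * I(x == 0) + (1 - pi) * f_NB(x; mu, phi) ), combining the two
    branches at x = 0 with a stable log-sum-exp.
    """
    if validate:
        _check_domain(x, mu, phi)
        if np.any(np.asarray(pi) < 0) or np.any(np.asarray(pi) > 1):
            raise ValueError("pi must lie in [0, 1]")
    x, pi, mu, phi = np.broadcast_arrays(
        np.asarray(x, dtype=float), np.asarray(pi, dtype=float),
        np.asarray(mu, dtype=float), np.asarray(phi, dtype=float),
    )
    nb = nb_logpmf(x, mu, phi, validate=False)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1mpi = np.log1p(-pi)
    out = log_1mpi + nb  # x > 0 branch (and the NB part at x == 0)
    zero = x == 0
    if np.any(zero):
        out = np.where(
            zero,
            np.logaddexp(log_pi, log_1mpi + nb),
            out,
        )
    return out[()] if out.ndim == 0 else out


def _mu_matrix(beta_k, offset):
    """exp(beta + offset) with overflow clamping; logs when the clamp fires."""
    with np.errstate(over="ignore"):
        mu = np.exp(np.add.outer(offset, beta_k) if np.ndim(offset) else beta_k + offset)
    clipped = (mu < MU_MIN) | (mu > MU_MAX)
    if np.any(clipped):
        logger.warning("clamped %d extreme NB means into [%g, %g]",
                       int(clipped.sum()), MU_MIN, MU_MAX)
        mu = np.clip(mu, MU_MIN, MU_MAX)
    return mu


def cell_cluster_loglik(x_row, params: ZinbmmParams, b_row, k: int) -> float:
    """Log-likelihood of one cell's gene profile under cluster k.

    sum_j log f_ZINB(x_j; pi_jk, exp(beta_jk + B_i' gamma), phi_j)
    """
    x_row = np.asarray(x_row, dtype=float)
    offset = float(np.dot(np.asarray(b_row, dtype=float), params.gamma))
    mu = _mu_matrix(params.beta[:, k], offset)
    return float(np.sum(zinb_logpmf(x_row, params.pi[:, k], mu, params.phi,
                                    validate=False)))


def loglik_matrix(X: CountMatrix, B: BatchDesign, params: ZinbmmParams) -> np.ndarray:
    """(n, K) matrix of per-cell per-cluster ZINB log-likelihoods.

    Exploits the structure of the model: the batch offset takes only S
    distinct values, so for each (batch, cluster) pair the gene-level NB
    terms are shared by all cells of that batch, and the cell sums reduce to
    matrix-vector products. The only O(n x J) special-function work is the
    count-dependent log-Gamma term, which is cluster-independent.
    """
    x = X.float_values
    phi = params.phi
    K, S = params.K, params.S
    log_phi = np.log(phi)
    # cluster-independent: sum_j [lgamma(x+phi) - lgamma(phi) - lgamma(x+1)]
    lg_row = (gammaln(x + phi[None, :]) - gammaln(phi)[None, :]
              - X.gammaln_x1).sum(axis=1)
    zero_f = X.zero_mask.astype(float)
    batch_idx = B.indicators.argmax(axis=1)
    rows_by_batch = [np.flatnonzero(batch_idx == s) for s in range(S)]
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)        # (J, K)
        log_1mpi = np.log1p(-params.pi)
    out = np.empty((X.n, K))
    for k in range(K):
        beta_k = params.beta[:, k]
        for s, rows in enumerate(rows_by_batch):
            if rows.size == 0:
                continue
            with np.errstate(over="ignore"):
                mu = np.clip(np.exp(beta_k + params.gamma[s]), MU_MIN, MU_MAX)
            log_mp = np.log(mu + phi)
            log_nb0 = phi * (log_phi - log_mp)       # NB mass at zero, (J,)
            vals = lg_row[rows] + x[rows] @ (np.log(mu) - log_mp) \
                + log_nb0.sum() + log_1mpi[:, k].sum()
            # zero entries: replace (1-pi) NB(0) by pi + (1-pi) NB(0)
            corr = np.logaddexp(log_pi[:, k], log_1mpi[:, k] + log_nb0) \
                - (log_1mpi[:, k] + log_nb0)
            out[rows, k] = vals + zero_f[rows] @ corr
    return out


def observed_loglik(X: CountMatrix, B: BatchDesign, params: ZinbmmParams) -> float:
    """Observed-data mixture log-likelihood l(theta).

    sum_i log sum_k p_k * prod_j f_ZINB(X_ij; ...)
    """
    if params.K == 0 or X.n == 0:
        raise ValueError("need at least one cluster and one cell")
    with np.errstate(divide="ignore"):
        log_p = np.log(params.p)
    return float(logsumexp(log_p[None, :] + loglik_matrix(X, B, params), axis=1).sum())


def penalized_objective(X: CountMatrix, B: BatchDesign, params: ZinbmmParams,
                        lam: float) -> float:
    """l(theta) - lambda * sum_{j,k} |beta_jk - beta*_j|."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    penalty = np.abs(params.beta - params.beta_star[:, None]).sum()
    return observed_loglik(X, B, params) - lam * penalty
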