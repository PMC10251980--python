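"""Bayesian multivariate animal model estimated by Gibbs sampling.

The model, for a pair of traits (k = 2; any k is supported):

    y = X beta + Z u + e,
    u ~ N(0, G0 (x) A),   e ~ N(0, R0 (x) I),

with ``A`` the numerator relationship matrix over all pedigreed animals
(parents without records included in ``u``), a flat prior on the fixed
effects ``beta`` (default intercept + sex) and conjugate inverse-Wishart
priors on the additive and residual covariance blocks:

    G0 ~ IW(nu_A, V_A),   R0 ~ IW(nu_E, V_E).

A systematic-scan Gibbs sampler draws in turn

1. ``beta`` from its multivariate-normal full conditional;
2. each animal's k-variate breeding-value block from its normal full
   conditional — single-site updates exploiting the sparsity of
   ``A^{-1}`` (each animal's conditional involves only its parents,
   progeny and mates), so no dense system is ever factorized;
3. ``G0`` from IW(nu_A + q, V_A + U' A^{-1} U);
4. ``R0`` from IW(nu_E + n, V_E + E'E).

Chains are fully reproducible given the seed.  Passing
``a_inverse=None`` drops the genetic effect entirely, leaving ordinary
Bayesian multivariate regression — the reduction used by the
closed-form conjugate checks in the test-suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit

from .pedigree import Pedigree

__all__ = [
    "ModelSpec",
    "ChainConfig",
    "DesignMatrices",
    "PosteriorChain",
    "build_design",
    "gibbs_sample",
    "retained_sample_count",
]


@dataclass(frozen=True)
class ModelSpec:
    """Trait pair, fixed effects and priors for one bivariate run.

    ``prior_g`` / ``prior_r`` are ``(nu, V)`` tuples; when omitted the
    default is weakly informative: ``nu = k + 1`` and scale equal to
    half the sample phenotypic covariance of the traits, split evenly
    between the genetic and residual blocks.
    """

    traits: tuple
    fixed_effects: tuple = ("intercept", "sex")
    prior_g: tuple | None = None
    prior_r: tuple | None = None

    def __post_init__(self):
        if not self.traits:
            raise ValueError("at least one trait required")
        for pr, name in ((self.prior_g, "prior_g"), (self.prior_r, "prior_r")):
            if pr is None:
                continue
            nu, V = pr
            V = np.atleast_2d(np.asarray(V, dtype=float))
            k = len(self.traits)
            if V.shape != (k, k) or not np.allclose(V, V.T):
                raise ValueError(f"{name} scale must be symmetric {k}x{k}")
            if np.any(np.linalg.eigvalsh(V) <= 0):
                raise ValueError(f"{name} scale must be positive definite")
            if nu <= k - 1:
                raise ValueError(f"{name} degrees of freedom must exceed k-1")


@dataclass(frozen=True)
class ChainConfig:
    """MCMC bookkeeping: total iterations, burn-in, thinning, seed.

    The reference configuration (110 000 iterations, 10 000 burn-in,
    thinning 50) retains exactly 2000 samples.
    """

    n_iterations: int = 110_000
    burn_in: int = 10_000
    thin: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")


def retained_sample_count(chain: ChainConfig) -> int:
    """Number of post-burn-in, thinned samples the chain retains.

    ``floor((n_iterations - burn_in)/thin)``; warns when the division is
    not exact.
    """
    span = chain.n_iterations - chain.burn_in
    if span % chain.thin:
        warnings.warn(
            f"(n_iterations - burn_in) = {span} not divisible by "
            f"thin = {chain.thin}; retaining floor({span}/{chain.thin})",
            stacklevel=2,
        )
    return span // chain.thin


@dataclass
class DesignMatrices:
    """Stacked data for one multi-trait run (one record per animal)."""

    y: np.ndarray  # n x k trait records
    X: np.ndarray  # n x p fixed-effect design
    animal_index: np.ndarray  # n, position of each record's animal in the pedigree
    trait_names: tuple
    fixed_names: tuple
    n_pedigree: int


def build_design(
    phenotypes: pd.DataFrame, pedigree: Pedigree, spec: ModelSpec
) -> DesignMatrices:
    """Assemble (y, X, Z) for the trait pair.

    Records missing any trait of the pair are dropped listwise.  ``Z``
    is represented by ``animal_index``: record i maps to breeding-value
    slot ``animal_index[i]``; animals without records (e.g. base
    parents) simply have no row pointing at them but keep their slot in
    ``u``.
    """
    traits = list(spec.traits)
    missing_cols = [t for t in traits if t not in phenotypes.columns]
    if missing_cols:
        raise KeyError(f"phenotype table lacks trait column(s) {missing_cols}")
    sub = phenotypes.dropna(subset=traits)
    if sub.empty and not phenotypes.empty:
        raise ValueError(f"all records missing for traits {traits}")
    try:
        aidx = np.array([pedigree.position(a) for a in sub["id"]], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"phenotyped animal absent from pedigree: {exc}") from exc

    cols, names = [], []
    for eff in spec.fixed_effects:
        if eff == "intercept":
            cols.append(np.ones(len(sub)))
            names.append("intercept")
        elif eff == "sex":
            sex = sub["sex"].to_numpy()
            if len(np.unique(sex)) < 2:
                warnings.warn(
                    "sex has a single level; dropping it from the design",
                    stacklevel=2,
                )
                continue
            cols.append((sex == "F").astype(float))
            names.append("sex_F")
        else:
            raise ValueError(f"unknown fixed effect {eff!r}")
    if not cols:
        cols, names = [np.ones(len(sub))], ["intercept"]
    X = np.column_stack(cols) if len(sub) else np.empty((0, len(cols)))
    y = sub[traits].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite trait values after listwise deletion")
    return DesignMatrices(
        y=y,
        X=X,
        animal_index=aidx,
        trait_names=tuple(traits),
        fixed_names=tuple(names),
        n_pedigree=pedigree.n_animals,
    )


@dataclass
class PosteriorChain:
    """Thinned post-burn-in samples from one Gibbs run."""

    g0: np.ndarray  # m x k x k
    r0: np.ndarray  # m x k x k
    beta: np.ndarray  # m x p x k
    u: np.ndarray | None  # m x q x k when stored
    trait_names: tuple
    fixed_names: tuple
    spec: ModelSpec = field(repr=False, default=None)
    chain: ChainConfig = field(repr=False, default=None)

    @property
    def n_samples(self) -> int:
        return self.g0.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Columnar view: one row per retained sample (G0/R0 elements
        and fixed effects; breeding values omitted)."""
        k = len(self.trait_names)
        data = {}
        for a in range(k):
            for b in range(a, k):
                ta, tb = self.trait_names[a], self.trait_names[b]
                data[f"g_{ta}_{tb}"] = self.g0[:, a, b]
                data[f"r_{ta}_{tb}"] = self.r0[:, a, b]
        for j, name in enumerate(self.fixed_names):
            for a, t in enumerate(self.trait_names):
                data[f"beta_{name}_{t}"] = self.beta[:, j, a]
        return pd.DataFrame(data)

    def save_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, index=False)


@njit(cache=True)
def _update_u(u, resid, rec_of_animal, indptr, indices, data, G0inv, R0inv, z):
    """Single-site Gibbs scan over animals (k-variate blocks).

    ``resid`` holds y - X beta per record; ``z`` supplies one standard
    normal per (animal, trait) so all randomness stays with the caller's
    generator.  Updates ``u`` in place (Gauss-Seidel style, which is the
    exact single-site sampler).
    """
    q, k = u.shape
    P = np.empty((k, k))
    L = np.empty((k, k))
    s = np.empty(k)
    b = np.empty(k)
    m = np.empty(k)
    w = np.empty(k)
    for i in range(q):
        aii = 1.0
        for t in range(k):
            s[t] = 0.0
        for ptr in range(indptr[i], indptr[i + 1]):
            j = indices[ptr]
            if j == i:
                aii = data[ptr]
            else:
                aij = data[ptr]
                for t in range(k):
                    s[t] += aij * u[j, t]
        for a in range(k):
            acc = 0.0
            for t in range(k):
                acc += G0inv[a, t] * s[t]
            b[a] = -acc
            for c in range(k):
                P[a, c] = aii * G0inv[a, c]
        r = rec_of_animal[i]
        if r >= 0:
            for a in range(k):
                acc = 0.0
                for t in range(k):
                    acc += R0inv[a, t] * resid[r, t]
                b[a] += acc
                for c in range(k):
                    P[a, c] += R0inv[a, c]
        # Cholesky P = L L'
        for a in range(k):
            acc = P[a, a]
            for t in range(a):
                acc -= L[a, t] * L[a, t]
            L[a, a] = np.sqrt(acc)
            for c in range(a + 1, k):
                acc = P[c, a]
                for t in range(a):
                    acc -= L[c, t] * L[a, t]
                L[c, a] = acc / L[a, a]
        # mean: solve L w = b, then L' m = w
        for a in range(k):
            acc = b[a]
            for t in range(a):
                acc -= L[a, t] * w[t]
            w[a] = acc / L[a, a]
        for a in range(k - 1, -1, -1):
            acc = w[a]
            for t in range(a + 1, k):
                acc -= L[t, a] * m[t]
            m[a] = acc / L[a, a]
        # noise: solve L' s = z_i  (covariance P^{-1})
        for a in range(k - 1, -1, -1):
            acc = z[i, a]
            for t in range(a + 1, k):
                acc -= L[t, a] * s[t]
            s[a] = acc / L[a, a]
        for t in range(k):
            u[i, t] = m[t] + s[t]


def _inv_wishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Draw from IW(df, scale) via the Bartlett decomposition.

    Density convention: p(S) proportional to
    |S|^{-(df+k+1)/2} exp(-tr(S^{-1} scale)/2), mean scale/(df-k-1).
    """
    k = scale.shape[0]
    if df <= k - 1:
        raise ValueError("inverse-Wishart needs df > k - 1")
    Sigma = np.linalg.inv(scale)
    L = np.linalg.cholesky((Sigma + Sigma.T) / 2.0)
    Abar = np.zeros((k, k))
    for i in range(k):
        Abar[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            Abar[i, j] = rng.standard_normal()
    W = L @ Abar
    W = W @ W.T
    out = np.linalg.inv(W)
    return (out + out.T) / 2.0


def _default_priors(y: np.ndarray, k: int):
    """nu = k+1; scale = sample phenotypic covariance / 2 for each block."""
    if len(y) > 1:
        Sp = np.atleast_2d(np.cov(y, rowvar=False))
    else:
        Sp = np.eye(k)
    # guard degenerate sample covariances
    if np.any(np.linalg.eigvalsh(Sp) <= 0):
        Sp = Sp + 1e-6 * np.trace(Sp) / max(k, 1) * np.eye(k) + 1e-12 * np.eye(k)
    return (k + 1.0, Sp / 2.0)


def gibbs_sample(
    design: DesignMatrices,
    a_inverse,
    spec: ModelSpec,
    chain: ChainConfig,
    store_u: bool = False,
) -> PosteriorChain:
    """Run the systematic-scan Gibbs sampler.

    Parameters
    ----------
    design
        Output of :func:`build_design`.
    a_inverse
        Sparse ``A^{-1}`` covering every breeding-value slot, or ``None``
        to fit the fixed-effects-only reduction (no ``u``, no ``G0``).
    spec, chain
        Model and chain configuration.
    store_u
        Keep the retained breeding-value samples (m x q x k array);
        off by default to bound memory.

    Raises
    ------
    numpy.linalg.LinAlgError
        If a full-conditional covariance loses positive definiteness;
        the failing iteration is named in the message.
    """
    rng = np.random.default_rng(chain.seed)
    y, X, aidx = design.y, design.X, design.animal_index
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in y")
    n, k = y.shape
    p = X.shape[1]
    has_u = a_inverse is not None
    if has_u:
        Ainv = sp.csr_matrix(a_inverse)
        q = Ainv.shape[0]
        if q < design.n_pedigree:
            raise ValueError("A-inverse smaller than the pedigree")
        rec_of_animal = np.full(q, -1, dtype=np.int64)
        rec_of_animal[aidx] = np.arange(n)
        indptr = Ainv.indptr
        indices = Ainv.indices
        adata = Ainv.data.astype(np.float64)
    else:
        q = 0

    nu_a, V_a = spec.prior_g or _default_priors(y, k)
    nu_e, V_e = spec.prior_r or _default_priors(y, k)
    V_a = np.atleast_2d(np.asarray(V_a, dtype=float))
    V_e = np.atleast_2d(np.asarray(V_e, dtype=float))

    m = retained_sample_count(chain)
    out_g = np.empty((m, k, k))
    out_r = np.empty((m, k, k))
    out_b = np.empty((m, p, k))
    out_u = np.empty((m, q, k)) if (store_u and has_u) else None

    G0 = V_a.copy()
    R0 = V_e.copy()
    u = np.zeros((q, k))
    beta = np.zeros((p, k))
    XtX = X.T @ X if n else np.zeros((p, p))

    stored = 0
    for it in range(chain.n_iterations):
        try:
            R0inv = np.linalg.inv(R0)
            if has_u:
                G0inv = np.linalg.inv(G0)

            if n:
                # (1) fixed effects: flat prior, normal full conditional
                ytil = y - (u[aidx] if has_u else 0.0)
                prec = np.kron(R0inv, XtX)
                rhs = (X.T @ ytil @ R0inv).reshape(-1, order="F")
                Lb = np.linalg.cholesky(prec)
                mean = np.linalg.solve(prec, rhs)
                zb = rng.standard_normal(p * k)
                vecb = mean + np.linalg.solve(Lb.T, zb)
                beta = vecb.reshape((p, k), order="F")

            if has_u:
                # (2) breeding values, animal by animal
                resid = y - X @ beta if n else np.zeros((0, k))
                z = rng.standard_normal((q, k))
                _update_u(
                    u, resid, rec_of_animal, indptr, indices, adata,
                    G0inv, R0inv, z,
                )
                # (3) additive covariance
                Su = u.T @ (Ainv @ u)
                G0 = _inv_wishart(rng, nu_a + q, V_a + Su)

            # (4) residual covariance
            if n:
                E = y - X @ beta - (u[aidx] if has_u else 0.0)
                Se = E.T @ E
            else:
                Se = np.zeros((k, k))
            R0 = _inv_wishart(rng, nu_e + n, V_e + Se)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"full conditional not positive definite at iteration {it}: {exc}"
            ) from exc

        if it + 1 > chain.burn_in and (it + 1 - chain.burn_in) % chain.thin == 0:
            if stored < m:
                out_g[stored] = G0
                out_r[stored] = R0
                out_b[stored] = beta
                if out_u is not None:
                    out_u[stored] = u
                stored += 1

    return PosteriorChain(
        g0=out_g,
        r0=out_r,
        beta=out_b,
        u=out_u,
        trait_names=design.trait_names,
        fixed_names=design.fixed_names,
        spec=spec,
        chain=chain,
    )
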