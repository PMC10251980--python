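"""Default trait parameterization for the simulated quail flock.

Eleven traits are modelled: body weights at 5 and 6 weeks (BW5, BW6, g),
cumulative feed intakes (FI5, FI6, g), cumulative feed conversion
efficiencies (FCE5, FCE6, gain/feed), the Gompertz parameters (beta0 g,
beta1 dimensionless, beta2 per day) and the inflection-point coordinates
(IPT days, IPW g).

The numbers below — trait means, phenotypic SDs, heritabilities, sex
contrasts (female minus male) and the genetic/phenotypic correlation
structure — are the generator's study conditions: values characteristic
of an unselected growing Japanese quail flock.  They define the ground
truth against which parameter-recovery tests are run.
"""

from __future__ import annotations

import warnings

import numpy as np

TRAITS = (
    "BW5", "BW6", "FI5", "FI6", "FCE5", "FCE6",
    "beta0", "beta1", "beta2", "IPT", "IPW",
)

MEAN = {
    "BW5": 185.84, "BW6": 204.54, "FI5": 449.77, "FI6": 621.48,
    "FCE5": 0.409, "FCE6": 0.328, "beta0": 249.91, "beta1": 3.31,
    "beta2": 0.069, "IPT": 17.60, "IPW": 91.94,
}

SD = {
    "BW5": 19.23, "BW6": 20.48, "FI5": 51.89, "FI6": 77.74,
    "FCE5": 0.0576, "FCE6": 0.0507, "beta0": 36.64, "beta1": 0.23,
    "beta2": 0.010, "IPT": 2.58, "IPW": 13.48,
}

HERITABILITY = {
    "BW5": 0.59, "BW6": 0.61, "FI5": 0.36, "FI6": 0.23,
    "FCE5": 0.37, "FCE6": 0.26, "beta0": 0.37, "beta1": 0.43,
    "beta2": 0.47, "IPT": 0.37, "IPW": 0.38,
}

# Additive sex contrast, female minus male, in trait units.
SEX_CONTRAST = {
    "BW5": 9.90, "BW6": 9.59, "FI5": 39.53, "FI6": 56.86,
    "FCE5": 0.005, "FCE6": -0.0075, "beta0": 24.07, "beta1": 0.03,
    "beta2": 0.003, "IPT": -1.61, "IPW": 8.84,
}

# Genetic correlations, lower triangle (row trait, column trait follow
# TRAITS order); matrix symmetrized below.
_RG_LOWER = [
    [1.00],
    [0.92, 1.00],
    [0.49, 0.34, 1.00],
    [0.35, 0.48, 0.75, 1.00],
    [0.71, 0.61, -0.53, -0.32, 1.00],
    [0.52, 0.83, -0.45, -0.58, 0.83, 1.00],
    [0.58, 0.82, 0.16, 0.12, 0.34, 0.28, 1.00],
    [-0.17, -0.17, 0.06, 0.21, 0.20, 0.12, -0.37, 1.00],
    [-0.16, -0.19, 0.13, 0.11, 0.12, 0.14, -0.70, 0.66, 1.00],
    [0.22, 0.20, 0.12, 0.14, 0.17, 0.12, 0.69, 0.79, -0.95, 1.00],
    [0.58, 0.82, 0.15, 0.22, 0.34, 0.29, 0.99, -0.36, -0.71, 0.70, 1.00],
]

# Phenotypic correlations, lower triangle in the same order.
_RP_LOWER = [
    [1.00],
    [0.90, 1.00],
    [0.40, 0.28, 1.00],
    [0.33, 0.43, 0.68, 1.00],
    [0.67, 0.59, -0.49, -0.29, 1.00],
    [0.49, 0.75, -0.29, -0.44, 0.78, 1.00],
    [0.52, 0.76, 0.08, 0.09, 0.29, 0.27, 1.00],
    [-0.11, -0.09, -0.02, -0.01, 0.19, 0.06, -0.34, 1.00],
    [-0.13, -0.18, -0.02, -0.01, -0.09, -0.23, -0.64, 0.51, 1.00],
    [0.18, 0.12, 0.08, 0.10, 0.15, 0.11, 0.66, 0.71, -0.89, 1.00],
    [0.53, 0.75, 0.09, 0.08, 0.29, 0.28, 0.99, -0.34, -0.64, 0.66, 1.00],
]


def _symmetrize(lower: list[list[float]]) -> np.ndarray:
    n = len(lower)
    M = np.zeros((n, n))
    for i, row in enumerate(lower):
        M[i, : i + 1] = row
    return M + M.T - np.diag(np.diag(M))


GENETIC_CORRELATION = _symmetrize(_RG_LOWER)
PHENOTYPIC_CORRELATION = _symmetrize(_RP_LOWER)


def _indices(traits) -> list[int]:
    missing = [t for t in traits if t not in TRAITS]
    if missing:
        raise KeyError(f"unknown trait(s): {missing}; choose from {TRAITS}")
    return [TRAITS.index(t) for t in traits]


def nearest_positive_definite(M: np.ndarray, floor_frac: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues up to a small positive floor (fraction of mean
    eigenvalue).  Correlation submatrices assembled from independently
    rounded pairwise values need not be PD; this is the standard repair."""
    w, V = np.linalg.eigh((M + M.T) / 2.0)
    floor = floor_frac * max(np.mean(np.abs(w)), np.finfo(float).tiny)
    if np.all(w >= floor):
        return M
    warnings.warn(
        "covariance preset not positive definite; eigenvalues clipped",
        stacklevel=2,
    )
    return (V * np.maximum(w, floor)) @ V.T


def trait_covariances(traits, h2=None, rg=None, rp=None):
    """Additive (G0) and residual (R0) covariance blocks for a trait set.

    Phenotypic variance per trait is SD², split into additive and
    residual parts by the trait's heritability; off-diagonals follow the
    genetic and phenotypic correlation tables (residual covariance is the
    phenotypic minus the additive part).  Individual entries can be
    overridden through ``h2``, ``rg``, ``rp`` dicts keyed by trait /
    trait pair.

    Returns
    -------
    (G0, R0) : ndarray, ndarray
        k x k covariance matrices in squared trait units, repaired to
        positive definite if pairwise rounding made them indefinite.
    """
    idx = _indices(traits)
    k = len(idx)
    h2 = dict(h2 or {})
    rg = {frozenset(p): v for p, v in (rg or {}).items()}
    rp = {frozenset(p): v for p, v in (rp or {}).items()}

    vp = np.array([SD[t] ** 2 for t in traits])
    va = np.array([h2.get(t, HERITABILITY[t]) for t in traits]) * vp
    ve = vp - va
    if np.any(va <= 0) or np.any(ve <= 0):
        raise ValueError("heritabilities must lie strictly inside (0, 1)")

    G0 = np.diag(va)
    R0 = np.diag(ve)
    for a in range(k):
        for b in range(a + 1, k):
            key = frozenset((traits[a], traits[b]))
            rg_ab = rg.get(key, GENETIC_CORRELATION[idx[a], idx[b]])
            rp_ab = rp.get(key, PHENOTYPIC_CORRELATION[idx[a], idx[b]])
            cov_a = rg_ab * np.sqrt(va[a] * va[b])
            cov_p = rp_ab * np.sqrt(vp[a] * vp[b])
            G0[a, b] = G0[b, a] = cov_a
            R0[a, b] = R0[b, a] = cov_p - cov_a
    return nearest_positive_definite(G0), nearest_positive_definite(R0)


def trait_means(traits) -> np.ndarray:
    _indices(traits)
    return np.array([MEAN[t] for t in traits])


def sex_contrasts(traits) -> np.ndarray:
    _indices(traits)
    return np.array([SEX_CONTRAST[t] for t in traits])
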