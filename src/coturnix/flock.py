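"""Synthetic quail flock generator.

Simulates pedigrees, multivariate breeding values, Gompertz growth
trajectories and feed-efficiency phenotypes with exactly the statistical
structure the animal model assumes, so every downstream stage is
testable without real records:

* base population of ``n_sires`` sires and ``n_dams`` dams (dams nested
  within sires), producing ``n_offspring`` phenotyped chicks — defaults
  40/120/700, i.e. 860 pedigreed animals in total;
* breeding values with covariance ``A (x) G0`` generated by the
  Mendelian-sampling recursion (never by factorizing the Kronecker
  product);
* residuals with covariance ``I (x) R0``, plus an optional shared
  feeder-group deviation on the feed-intake traits (feed is consumed
  from group feeders of 4-8 birds);
* an additive sex effect (females heavier);
* per-bird Gompertz weight trajectories with measurement noise.

Two generation modes are exposed: ``direct`` draws the configured traits
jointly from (G0, R0) — the clean generative model used for parameter
recovery — while the mechanistic helpers derive growth traits from
simulated curves (weights, and the inflection-weight identity
``IPW = beta0/e``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import presets
from .growth import GompertzParams, gompertz_value
from .pedigree import (
    Pedigree,
    inbreeding_coefficients,
    mendelian_variance_scale,
    validate_and_sort,
)

__all__ = [
    "FlockConfig",
    "FlockData",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_growth_records",
    "simulate_feed_traits",
    "simulate_flock",
    "assign_feeder_groups",
    "split_group_intake",
    "derive_inflection_weight",
]

_WEIGHT_FLOOR = 0.5  # g; recorded weights truncated below at this


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class FlockConfig:
    """Study-design configuration for the simulated flock.

    Defaults mirror the reference design: 40 sires x 3 dams each = 120
    dams, 700 phenotyped offspring (860 pedigreed animals), weekly
    weighings at 0-42 days, feeder groups of 4-8 birds.
    """

    n_sires: int = 40
    n_dams: int = 120
    n_offspring: int = 700
    seed: int = 20230526
    trait_names: tuple = ("BW5", "BW6")
    G0_true: np.ndarray | None = None
    R0_true: np.ndarray | None = None
    sex_effect: np.ndarray | None = None  # female minus male, per trait
    trait_mean: np.ndarray | None = None
    weigh_ages: tuple = (0, 7, 14, 21, 28, 35, 42)
    feeder_group_size: tuple = (4, 8)
    weight_noise_sd: float = 2.0  # g, scale repeatability of the balance + handling
    feeder_group_var_frac: float = 0.2  # share of FI residual variance at cage level
    fi_split: str = "latent"  # latent | equal | weight
    # Condition founder breeding values and residual pools to hit their
    # target covariances exactly (recovery-study variance reduction: the
    # simulated truth is then the nominal parameter, not a realized draw).
    exact_variance: bool = False

    def __post_init__(self):
        for name in ("n_sires", "n_dams", "n_offspring"):
            v = getattr(self, name)
            if v < 0 or (name != "n_offspring" and v <= 0):
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_dams % self.n_sires:
            raise ValueError(
                f"n_dams={self.n_dams} not partitionable across "
                f"n_sires={self.n_sires} mating groups"
            )
        lo, hi = self.feeder_group_size
        if not (1 <= lo <= hi):
            raise ValueError("feeder_group_size must be an increasing range >= 1")
        if self.fi_split not in ("latent", "equal", "weight"):
            raise ValueError("fi_split must be latent, equal or weight")
        k = len(self.trait_names)
        G0, R0, mu, sx = self.G0_true, self.R0_true, self.trait_mean, self.sex_effect
        if G0 is None:
            G0, R0_default = presets.trait_covariances(self.trait_names)
            R0 = R0_default if R0 is None else R0
        elif R0 is None:
            _, R0 = presets.trait_covariances(self.trait_names)
        if mu is None:
            mu = presets.trait_means(self.trait_names)
        if sx is None:
            sx = presets.sex_contrasts(self.trait_names)
        G0 = np.atleast_2d(np.asarray(G0, dtype=float))
        R0 = np.atleast_2d(np.asarray(R0, dtype=float))
        for name, M in (("G0_true", G0), ("R0_true", R0)):
            if M.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k} for {k} trait(s)")
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.linalg.eigvalsh(M) <= 0):
                raise ValueError(f"{name} must be positive definite")
        object.__setattr__(self, "G0_true", G0)
        object.__setattr__(self, "R0_true", R0)
        object.__setattr__(self, "trait_mean", np.asarray(mu, dtype=float))
        object.__setattr__(self, "sex_effect", np.asarray(sx, dtype=float))

    @property
    def dams_per_sire(self) -> int:
        return self.n_dams // self.n_sires

    @property
    def n_animals(self) -> int:
        return self.n_sires + self.n_dams + self.n_offspring

    def with_traits(self, trait_names, **overrides) -> "FlockConfig":
        """Copy of the config re-targeted at another trait set."""
        return replace(
            self,
            trait_names=tuple(trait_names),
            G0_true=overrides.pop("G0_true", None),
            R0_true=overrides.pop("R0_true", None),
            sex_effect=overrides.pop("sex_effect", None),
            trait_mean=overrides.pop("trait_mean", None),
            **overrides,
        )


@dataclass
class FlockData:
    """Everything the generator knows about one simulated flock.

    ``phenotypes`` has one row per phenotyped offspring (id, sex, one
    column per trait); the exact decomposition
    ``phenotype = fixed + breeding value + residual`` holds row by row.
    """

    config: FlockConfig
    pedigree: Pedigree
    breeding_values: pd.DataFrame  # all pedigreed animals x traits
    phenotypes: pd.DataFrame
    fixed_part: pd.DataFrame
    residuals: pd.DataFrame
    feeder_group: pd.Series | None = None
    weights: pd.DataFrame | None = None  # long format, mechanistic runs
    true_params: pd.DataFrame | None = None


def simulate_pedigree(config: FlockConfig, rng=None) -> Pedigree:
    """Simulate the base-plus-offspring pedigree.

    Sires get ids 1..n_sires (male), dams follow (female), then the
    offspring.  Dams are nested within sires (each dam mated to exactly
    one sire); each offspring picks a dam uniformly at random and
    inherits that dam's assigned sire.  Offspring sexes are a random
    half/half split.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    ns, nd, no = config.n_sires, config.n_dams, config.n_offspring
    sire_ids = np.arange(1, ns + 1)
    dam_ids = np.arange(ns + 1, ns + nd + 1)
    off_ids = np.arange(ns + nd + 1, ns + nd + no + 1)

    # random nesting of dams within sires
    dam_order = rng.permutation(nd)
    sire_of_dam = np.empty(nd, dtype=np.int64)
    sire_of_dam[dam_order] = np.repeat(sire_ids, config.dams_per_sire)

    recs = [(int(i), 0, 0, "M") for i in sire_ids]
    recs += [(int(i), 0, 0, "F") for i in dam_ids]
    if no:
        # near-balanced clutches: eggs are collected from every dam over a
        # fixed window, so family sizes differ by at most one
        base_rounds = np.repeat(np.arange(nd), no // nd)
        extras = rng.choice(nd, size=no - len(base_rounds), replace=False)
        dam_of_off = rng.permutation(np.concatenate([base_rounds, extras]))
        sexes = np.array(["M", "F"])[
            rng.permutation(np.arange(no) % 2)
        ]
        for j in range(no):
            d = dam_of_off[j]
            recs.append(
                (int(off_ids[j]), int(sire_of_dam[d]), int(dam_ids[d]), sexes[j])
            )
    return validate_and_sort(recs)


def _standardize(z: np.ndarray) -> np.ndarray:
    """Center a draw matrix and whiten it to exact identity sample
    covariance (ddof=1).  No-op for degenerate shapes."""
    n, k = z.shape
    if n < k + 2:
        return z
    zc = z - z.mean(axis=0)
    S = zc.T @ zc / (n - 1)
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        return z
    return zc @ np.linalg.inv(L).T


def simulate_breeding_values(pedigree: Pedigree, G0, rng, exact: bool = False) -> np.ndarray:
    """Multivariate breeding values by the Mendelian-sampling recursion.

    Base animals are drawn from N(0, G0); every other animal is the mean
    of its known parents' values plus a Mendelian deviation with
    covariance ``d_i * G0`` where ``d_i`` accounts for the parents'
    inbreeding.  The resulting vector has covariance ``A (x) G0``
    exactly, without ever forming A.

    With ``exact=True`` the founder and Mendelian standard-normal pools
    are whitened to identity sample covariance before scaling, so the
    realized base-population additive covariance equals G0 exactly
    (conditioned simulation for parameter-recovery studies).
    """
    rng = _as_rng(rng)
    G0 = np.atleast_2d(np.asarray(G0, dtype=float))
    k = G0.shape[0]
    if G0.shape != (k, k):
        raise ValueError("G0 must be square")
    L = _psd_factor(G0)
    F = inbreeding_coefficients(pedigree)
    dscale = mendelian_variance_scale(pedigree, F)
    q = pedigree.n_animals
    z = rng.standard_normal((q, k))
    if exact:
        base = pedigree.is_base
        if base.any():
            z[base] = _standardize(z[base])
        if (~base).any():
            z[~base] = _standardize(z[~base])
    z = z @ L.T
    u = np.zeros((q, k))
    s, d = pedigree.sire_idx, pedigree.dam_idx
    for i in range(q):
        pa = 0.0
        if s[i] >= 0:
            pa = pa + 0.5 * u[s[i]]
        if d[i] >= 0:
            pa = pa + 0.5 * u[d[i]]
        u[i] = pa + np.sqrt(dscale[i]) * z[i]
    return u


def _psd_factor(M: np.ndarray) -> np.ndarray:
    """Cholesky-like factor valid for semi-definite matrices."""
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(M)
        if np.any(w < -1e-10 * max(w.max(), 1.0)):
            raise ValueError("covariance matrix is not positive semi-definite")
        return V @ np.diag(np.sqrt(np.clip(w, 0, None)))


def simulate_growth_records(
    pedigree: Pedigree,
    params: pd.DataFrame,
    weigh_ages,
    weight_noise_sd: float,
    rng,
) -> pd.DataFrame:
    """Weekly weight records from per-bird Gompertz parameters.

    ``params`` is indexed by animal id with columns beta0, beta1, beta2.
    Weight at age t is the curve value plus independent N(0, sd²) noise,
    truncated below at a small positive floor.
    """
    rng = _as_rng(rng)
    if np.any(params[["beta0", "beta1", "beta2"]].to_numpy() <= 0):
        raise ValueError("all Gompertz parameters must be positive")
    ages = np.asarray(weigh_ages, dtype=float)
    if np.any(ages < 0):
        raise ValueError("weigh ages must be non-negative")
    rows = []
    for bird, row in params.iterrows():
        p = GompertzParams(row["beta0"], row["beta1"], row["beta2"])
        mu = gompertz_value(p, ages)
        noise = (
            rng.standard_normal(len(ages)) * weight_noise_sd
            if weight_noise_sd > 0
            else 0.0
        )
        w = np.maximum(mu + noise, _WEIGHT_FLOOR)
        for t, wt in zip(ages, w):
            rows.append({"id": bird, "age_days": t, "weight_g": wt})
    return pd.DataFrame(rows)


def assign_feeder_groups(offspring_ids, size_range, rng) -> pd.Series:
    """Random partition of the offspring into feeder groups.

    Group sizes are uniform on ``[lo, hi]``; the trailing remainder
    forms one smaller group if fewer than ``lo`` birds are left over.
    """
    rng = _as_rng(rng)
    ids = np.asarray(offspring_ids)
    order = rng.permutation(len(ids))
    lo, hi = size_range
    groups = np.empty(len(ids), dtype=np.int64)
    g, pos = 0, 0
    while pos < len(ids):
        size = int(rng.integers(lo, hi + 1))
        groups[order[pos : pos + size]] = g
        pos += size
        g += 1
    return pd.Series(groups, index=ids, name="feeder_group")


def split_group_intake(
    fi: pd.Series, groups: pd.Series, rule: str = "equal", weights: pd.Series | None = None
) -> pd.Series:
    """Impute individual feed intake from feeder-group totals.

    The measured quantity in practice is the group total; ``rule``
    chooses how it is redistributed: ``equal`` shares it uniformly,
    ``weight`` proportionally to body weight.  (``latent`` in the
    generator keeps the true individual values and bypasses this.)
    """
    totals = fi.groupby(groups).transform("sum")
    if rule == "equal":
        share = 1.0 / groups.groupby(groups).transform("size")
    elif rule == "weight":
        if weights is None:
            raise ValueError("weight-proportional split needs body weights")
        share = weights / weights.groupby(groups).transform("sum")
    else:
        raise ValueError(f"unknown split rule {rule!r}")
    return totals * share


def simulate_feed_traits(
    pedigree: Pedigree,
    breeding_values: np.ndarray,
    config: FlockConfig,
    rng,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Offspring phenotypes for the configured trait block.

    Residuals are N(0, R0) per bird; for feed-intake traits (names
    starting ``FI``) a fraction ``feeder_group_var_frac`` of the
    residual variance is moved to a deviation shared by all birds on the
    same feeder, leaving each bird's total residual variance at R0.
    Feed-conversion traits (``FCE``) are truncated away from zero and an
    error is raised if truncation would be needed for more than it can
    absorb (FCE must stay positive).

    Returns (phenotypes, fixed_part, residuals, feeder_group).
    """
    rng = _as_rng(rng)
    cfg = config
    traits = list(cfg.trait_names)
    k = len(traits)
    off_mask = ~pedigree.is_base if cfg.n_offspring else np.zeros(
        pedigree.n_animals, dtype=bool
    )
    off_pos = np.flatnonzero(off_mask)
    ids = pedigree.ids[off_pos]
    n = len(ids)

    fi_cols = [j for j, t in enumerate(traits) if t.startswith("FI")]
    R0 = cfg.R0_true.copy()
    group_var = np.zeros(k)
    for j in fi_cols:
        group_var[j] = cfg.feeder_group_var_frac * R0[j, j]
    R_ind = R0 - np.diag(group_var)
    if np.any(np.linalg.eigvalsh(R_ind) < -1e-10):
        raise ValueError(
            "feeder_group_var_frac too large: individual residual "
            "covariance is no longer positive semi-definite"
        )

    e = rng.standard_normal((n, k))
    if cfg.exact_variance:
        e = _standardize(e)
    e = e @ _psd_factor(R_ind).T
    groups = assign_feeder_groups(ids, cfg.feeder_group_size, rng)
    if fi_cols and n:
        n_groups = int(groups.max()) + 1
        gdev = rng.standard_normal((n_groups, len(fi_cols))) * np.sqrt(
            group_var[fi_cols]
        )
        e[:, fi_cols] += gdev[groups.to_numpy()]

    female = (pedigree.sex[off_pos] == "F").astype(float)
    fixed = cfg.trait_mean[None, :] + female[:, None] * cfg.sex_effect[None, :]
    y = fixed + breeding_values[off_pos] + e

    for j, t in enumerate(traits):
        if t.startswith("FCE") and n and np.any(y[:, j] <= 0):
            raise ValueError(
                f"simulated {t} non-positive for some birds; "
                "check means/variances"
            )

    sex = pedigree.sex[off_pos]
    phen = pd.DataFrame(y, columns=traits)
    phen.insert(0, "sex", sex)
    phen.insert(0, "id", ids)
    fixed_df = pd.DataFrame(fixed, columns=traits, index=ids)
    resid_df = pd.DataFrame(e, columns=traits, index=ids)
    return phen, fixed_df, resid_df, groups


def feed_conversion_ratio(fce) -> np.ndarray:
    """FCR = 1/FCE (feed per unit gain); FCE must be positive."""
    fce = np.asarray(fce, dtype=float)
    if np.any(fce <= 0):
        raise ValueError("FCE must be positive")
    return 1.0 / fce


def derive_inflection_weight(beta0_values: pd.Series, noise_cv: float, rng) -> pd.Series:
    """Mechanistic inflection-point weight: ``IPW = beta0/e`` per bird,
    plus independent noise with the given coefficient of variation
    (emulating growth-curve fitting error)."""
    rng = _as_rng(rng)
    ipw = beta0_values / np.e
    if noise_cv > 0:
        ipw = ipw + rng.standard_normal(len(ipw)) * (noise_cv * ipw.mean())
    return ipw.rename("IPW")


def simulate_flock(config: FlockConfig | None = None, mode: str = "direct") -> FlockData:
    """End-to-end flock simulation.

    ``direct`` draws the configured traits jointly from (G0, R0): the
    clean generative model matching the animal model's assumptions,
    used for parameter-recovery testing.  ``mechanistic`` additionally
    simulates per-bird Gompertz curves (parameters beta0/beta1/beta2 as
    a direct 3-trait block) and weekly weight records with measurement
    noise, from which growth traits can be re-derived by curve fitting.
    """
    cfg = config or FlockConfig()
    if mode not in ("direct", "mechanistic"):
        raise ValueError("mode must be 'direct' or 'mechanistic'")
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    u = simulate_breeding_values(ped, cfg.G0_true, rng, exact=cfg.exact_variance)
    phen, fixed, resid, groups = simulate_feed_traits(ped, u, cfg, rng)
    bv = pd.DataFrame(u, columns=list(cfg.trait_names), index=ped.ids)

    weights = None
    true_params = None
    if mode == "mechanistic":
        gcfg = cfg.with_traits(("beta0", "beta1", "beta2"))
        gu = simulate_breeding_values(ped, gcfg.G0_true, rng)
        gphen, _, _, _ = simulate_feed_traits(ped, gu, gcfg, rng)
        true_params = gphen.set_index("id")[["beta0", "beta1", "beta2"]]
        # guard against non-physical draws in the far tails
        true_params = true_params.clip(
            lower=pd.Series({"beta0": 50.0, "beta1": 1.5, "beta2": 0.02}),
            axis=1,
        )
        weights = simulate_growth_records(
            ped, true_params, cfg.weigh_ages, cfg.weight_noise_sd, rng
        )
    return FlockData(
        config=cfg,
        pedigree=ped,
        breeding_values=bv,
        phenotypes=phen,
        fixed_part=fixed,
        residuals=resid,
        feeder_group=groups,
        weights=weights,
        true_params=true_params,
    )


def write_phenotypes_csv(data: FlockData, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={data.config.seed}")
        if header_comment:
            fh.write(f" {header_comment}")
        fh.write("\n")
        data.phenotypes.to_csv(fh, index=False)
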