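"""Descriptive statistics, sex contrasts and pipeline orchestration.

`run_pipeline` wires the stages end to end on a synthetic flock:
simulate -> fit growth curves -> describe -> estimate variance
components per trait pair -> summarize, writing a CSV/Markdown report
bundle and a JSON run log.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import yaml

from . import __version__
from .animal_model import ChainConfig, ModelSpec, build_design, gibbs_sample
from .flock import FlockConfig, FlockData, simulate_flock
from .growth import fit_gompertz_batch
from .pedigree import a_inverse, write_pedigree_csv
from .posterior import (
    genetic_correlation,
    heritability,
    phenotypic_correlation,
    summarize_chain,
)

__all__ = [
    "DescriptiveRow",
    "describe",
    "sex_ttest",
    "ks_normality",
    "descriptive_table",
    "estimate_pair",
    "PipelineConfig",
    "run_pipeline",
]


@dataclass(frozen=True)
class DescriptiveRow:
    trait: str
    n: int
    mean: float
    sd: float
    cv_percent: float | None
    minimum: float
    maximum: float
    sex_p_value: float | None = None

    def as_dict(self) -> dict:
        return {
            "trait": self.trait,
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "cv_percent": self.cv_percent,
            "min": self.minimum,
            "max": self.maximum,
            "sex_p": self.sex_p_value,
        }


def describe(values, trait: str = "") -> DescriptiveRow:
    """Mean, SD (n-1), CV% = 100*SD/mean, min, max.

    CV is flagged undefined (None, with a warning) for a zero mean.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("need at least 2 finite values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if mean == 0:
        warnings.warn(f"CV undefined for zero-mean trait {trait!r}", stacklevel=2)
        cv = None
    else:
        cv = 100.0 * sd / mean
    return DescriptiveRow(
        trait=trait, n=len(x), mean=mean, sd=sd, cv_percent=cv,
        minimum=float(np.min(x)), maximum=float(np.max(x)),
    )


def sex_ttest(values, sex_labels, welch: bool = False) -> tuple[float, float]:
    """Two-sided independent-samples t-test between the sexes.

    Pooled-variance by default; set ``welch=True`` for the unequal
    variance form.  Returns (t statistic, p value).
    """
    x = np.asarray(values, dtype=float)
    sex = np.asarray(sex_labels)
    levels = np.unique(sex)
    if len(levels) != 2:
        raise ValueError(f"need exactly two sexes, got {levels.tolist()}")
    a, b = (x[sex == lv] for lv in levels)
    if min(len(a), len(b)) < 2:
        raise ValueError("each sex needs at least 2 values")
    res = st.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def ks_normality(values) -> tuple[float, float]:
    """One-sample KS test against a normal with estimated mean/SD.

    Estimating the parameters from the same sample makes the test
    conservative (the Lilliefors caveat); the p value is reported with
    that caveat understood.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 values")
    mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("constant input; normality test undefined")
    res = st.kstest(x, "norm", args=(mu, sd))
    return float(res.statistic), float(res.pvalue)


def descriptive_table(phenotypes: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Per-trait descriptives plus the sex-contrast p value."""
    traits = traits or [
        c for c in phenotypes.columns if c not in ("id", "sex")
    ]
    rows = []
    for t in traits:
        row = describe(phenotypes[t], t)
        p = None
        if "sex" in phenotypes.columns:
            try:
                _, p = sex_ttest(phenotypes[t], phenotypes["sex"])
            except ValueError:
                p = None
        rows.append({**row.as_dict(), "sex_p": p})
    return pd.DataFrame(rows)


def estimate_pair(
    data: FlockData,
    traits,
    chain: ChainConfig,
    spec: ModelSpec | None = None,
    phenotypes: pd.DataFrame | None = None,
):
    """Design + A-inverse + Gibbs for one trait pair of a flock.

    Returns (PosteriorChain, summaries dict) where the summaries cover
    each trait's heritability and, for pairs, the genetic and
    phenotypic correlations.
    """
    spec = spec or ModelSpec(traits=tuple(traits))
    phen = phenotypes if phenotypes is not None else data.phenotypes
    design = build_design(phen, data.pedigree, spec)
    Ainv = a_inverse(data.pedigree)
    post = gibbs_sample(design, Ainv, spec, chain)
    summaries = {}
    for i, t in enumerate(spec.traits):
        summaries[f"h2_{t}"] = summarize_chain(
            heritability(post.g0, post.r0, i), name=f"h2_{t}"
        )
    if len(spec.traits) >= 2:
        for i in range(len(spec.traits)):
            for j in range(i + 1, len(spec.traits)):
                ta, tb = spec.traits[i], spec.traits[j]
                summaries[f"rg_{ta}_{tb}"] = summarize_chain(
                    genetic_correlation(post.g0, i, j), name=f"rg_{ta}_{tb}"
                )
                summaries[f"rp_{ta}_{tb}"] = summarize_chain(
                    phenotypic_correlation(post.g0, post.r0, i, j),
                    name=f"rp_{ta}_{tb}",
                )
    return post, summaries


@dataclass
class PipelineConfig:
    """YAML-loadable configuration for `run_pipeline`."""

    seed: int = 20230526
    mode: str = "mechanistic"
    trait_pairs: list = field(
        default_factory=lambda: [["BW5", "BW6"], ["beta0", "IPW"]]
    )
    n_iterations: int = 11_000
    burn_in: int = 1_000
    thin: int = 5
    flock: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def run_pipeline(config: PipelineConfig | None = None, outdir="coturnix_run"):
    """Simulate, fit, describe, estimate and report.

    Writes pedigree/phenotypes/weights CSVs, per-pair chain CSVs, a
    heritability table (mean, median, SD, MCSE, BCI, HPDI columns), a
    correlation table, a Markdown report and a JSON run log under
    ``outdir``.  Any stage failure aborts with the stage name; files
    already written are left in place.
    """
    from pathlib import Path

    cfg = config or PipelineConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = {"seed": cfg.seed, "version": __version__, "stages": []}
    stage = "simulate"
    try:
        all_traits = sorted({t for pair in cfg.trait_pairs for t in pair})
        direct_traits = [t for t in all_traits if t not in ("IPW", "IPT")]
        fcfg = FlockConfig(
            seed=cfg.seed, trait_names=tuple(direct_traits), **cfg.flock
        )
        data = simulate_flock(fcfg, mode=cfg.mode)
        phen = data.phenotypes.copy()
        if "IPW" in all_traits:
            from .flock import derive_inflection_weight

            if "beta0" not in phen.columns:
                raise ValueError("IPW requires beta0 among the simulated traits")
            rng = np.random.default_rng(cfg.seed + 1)
            phen["IPW"] = derive_inflection_weight(
                phen["beta0"], noise_cv=0.01, rng=rng
            ).to_numpy()
        write_pedigree_csv(
            data.pedigree, out / "pedigree.csv", f"seed={cfg.seed}"
        )
        with open(out / "phenotypes.csv", "w") as fh:
            fh.write(f"# seed={cfg.seed}\n")
            phen.to_csv(fh, index=False)
        log["stages"].append(stage)

        stage = "fit-growth"
        fits = None
        if data.weights is not None:
            data.weights.to_csv(out / "weights.csv", index=False)
            fits = fit_gompertz_batch(data.weights)
            fits.to_csv(out / "growth_fits.csv")
        log["stages"].append(stage)

        stage = "describe"
        table1 = descriptive_table(phen)
        table1.to_csv(out / "table_descriptives.csv", index=False)
        log["stages"].append(stage)

        stage = "estimate"
        chain = ChainConfig(
            n_iterations=cfg.n_iterations,
            burn_in=cfg.burn_in,
            thin=cfg.thin,
            seed=cfg.seed,
        )
        h2_rows, corr_rows = {}, []
        for pair in cfg.trait_pairs:
            post, summ = estimate_pair(data, pair, chain, phenotypes=phen)
            post.save_csv(
                out / f"chain_{'_'.join(pair)}.csv",
                f"seed={cfg.seed} iterations={cfg.n_iterations}",
            )
            for t in pair:
                if t not in h2_rows:  # first pair containing the trait wins
                    h2_rows[t] = summ[f"h2_{t}"].as_dict()
            ta, tb = pair[0], pair[1]
            corr_rows.append(
                {
                    "trait_i": ta,
                    "trait_j": tb,
                    "r_g": summ[f"rg_{ta}_{tb}"].mean,
                    "r_g_sd": summ[f"rg_{ta}_{tb}"].sd,
                    "r_p": summ[f"rp_{ta}_{tb}"].mean,
                    "r_p_bci_excludes_zero": not (
                        summ[f"rp_{ta}_{tb}"].bci_lower
                        <= 0.0
                        <= summ[f"rp_{ta}_{tb}"].bci_upper
                    ),
                }
            )
        table2 = pd.DataFrame(list(h2_rows.values()))
        table2.to_csv(out / "table_heritability.csv", index=False)
        table3 = pd.DataFrame(corr_rows)
        table3.to_csv(out / "table_correlations.csv", index=False)
        log["stages"].append(stage)

        stage = "report"
        lines = [
            "# Synthetic quail flock — genetic parameter report",
            "",
            f"Seed: {cfg.seed}; flock: {fcfg.n_sires} sires, "
            f"{fcfg.n_dams} dams, {fcfg.n_offspring} offspring "
            f"({data.pedigree.n_animals} pedigreed).",
            "",
            "## Descriptive statistics",
            "",
            table1.round(4).to_string(index=False),
            "",
            "## Heritability (posterior summaries)",
            "",
            table2.round(4).to_string(index=False),
            "",
            "## Correlations (posterior means)",
            "",
            table3.round(4).to_string(index=False),
            "",
        ]
        if fits is not None:
            lines.insert(
                5,
                f"Growth fits: {int(fits['converged'].sum())}/{len(fits)} "
                f"converged, median R² = {fits['r_squared'].median():.5f}.\n",
            )
        (out / "report.md").write_text("\n".join(lines))
        log["stages"].append(stage)
    except Exception as exc:
        log["failed_stage"] = stage
        log["error"] = str(exc)
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return {
        "outdir": str(out),
        "descriptives": table1,
        "heritability": table2,
        "correlations": table3,
        "log": log,
    }
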