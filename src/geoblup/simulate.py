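"""Synthetic populations with the cross-design, repeated-measures structure.

Emulates a biparental-cross breeding population: a small set of fathers
and mothers, each father x mother pair producing a full-sib family of
offspring; biallelic markers segregate by Mendelian sampling (independent
markers, or Haldane recombination along a linear map when a spacing is
given).  A subset of QTL among the markers carries additive effects; the
true breeding value (TBV) of an individual is the sum of its QTL codes
times the effects.  Each phenotyped individual is observed at a handful
of times on a logistic growth curve whose asymptote is shifted by its
TBV, with i.i.d. Gaussian measurement error; breeding values are to be
predicted at a target time beyond the last measurement.

Defaults mirror the motivating design: ~2000 offspring from 2 fathers x
10 mothers, 450 markers with 30 QTL, five measurement times
(0, 132, 265, 397, 530), about half the offspring phenotyped, and
prediction at time 600.  Everything is reproducible from the mandatory
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .growth import logistic_mean
from .markers import GenotypeMatrix
from .pedigree import Pedigree

__all__ = ["SimConfig", "SimOutput", "simulate_population", "simulate_growth_phenotypes"]


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_fathers: int = 2
    n_mothers: int = 10
    offspring_per_cross: int = 100
    n_markers: int = 450
    n_qtl: int = 30
    qtl_effect_scale: float = 1.0
    allele_freq_range: tuple[float, float] = (0.2, 0.8)
    marker_spacing_cm: float | None = None  # None = unlinked markers
    alpha_base: float = 60.0
    beta_base: float = 9.0
    gamma_base: float = 0.01
    beta_sd: float = 0.0
    gamma_sd: float = 0.0
    measurement_error_sd: float = 1.0
    times: tuple[float, ...] = (0.0, 132.0, 265.0, 397.0, 530.0)
    phenotyped_fraction: float = 1000.0 / 2025.0
    target_time: float = 600.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.n_qtl <= self.n_markers:
            raise ValueError("need 0 <= n_qtl <= n_markers")
        if not 0 < self.phenotyped_fraction <= 1:
            raise ValueError("phenotyped_fraction must be in (0, 1]")
        lo, hi = self.allele_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("allele_freq_range must satisfy 0 < lo <= hi < 1")
        if self.n_fathers < 1 or self.n_mothers < 1 or self.offspring_per_cross < 1:
            raise ValueError("population dimensions must be positive")
        if len(self.times) < 4:
            raise ValueError("need >= 4 measurement times for stage 1")


@dataclass(frozen=True)
class SimOutput:
    genotypes: GenotypeMatrix          # parents + offspring
    pedigree: Pedigree
    phenotypes: pd.DataFrame           # long format: individual, time, value
    tbv: pd.Series                     # all individuals
    true_target: pd.Series             # noise-free curve value at target_time, all offspring
    phenotyped_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]    # unphenotyped offspring
    params: dict                       # generating record

    @property
    def offspring_ids(self) -> tuple[str, ...]:
        return tuple(self.true_target.index)


def _gamete(haplos: np.ndarray, rng: np.random.Generator,
            recomb: np.ndarray | None) -> np.ndarray:
    """One gamete from a parent's two haplotypes (rows of ``haplos``)."""
    m = haplos.shape[1]
    if recomb is None:
        choice = rng.integers(0, 2, size=m)
    else:
        # Haldane: switch haplotype between adjacent markers with prob r
        switches = rng.random(m - 1) < recomb
        choice = np.empty(m, dtype=int)
        choice[0] = rng.integers(0, 2)
        for k in range(1, m):
            choice[k] = choice[k - 1] ^ int(switches[k - 1])
    return haplos[choice, np.arange(m)]


def simulate_population(config: SimConfig) -> SimOutput:
    """Draw founders, cross them, and phenotype a subset of the offspring."""
    rng = np.random.default_rng(config.seed)
    m = config.n_markers
    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, size=m)

    fathers = [f"F{j+1}" for j in range(config.n_fathers)]
    mothers = [f"M{j+1}" for j in range(config.n_mothers)]
    haplos = {
        p: rng.binomial(1, freqs, size=(2, m)).astype(np.int8)
        for p in fathers + mothers
    }

    recomb = None
    if config.marker_spacing_cm is not None:
        d = config.marker_spacing_cm
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        recomb = np.full(m - 1, r)

    ped_rows = [
        {"individual": p, "father": "", "mother": ""} for p in fathers + mothers
    ]
    ids: list[str] = list(fathers) + list(mothers)
    geno_rows: list[np.ndarray] = [haplos[p].sum(axis=0) - 1 for p in fathers + mothers]
    offspring: list[str] = []
    for f in fathers:
        for mo in mothers:
            for k in range(config.offspring_per_cross):
                ind = f"{f}{mo}_{k+1}"
                g = _gamete(haplos[f], rng, recomb) + _gamete(haplos[mo], rng, recomb)
                ids.append(ind)
                geno_rows.append(g.astype(np.int16) - 1)
                offspring.append(ind)
                ped_rows.append({"individual": ind, "father": f, "mother": mo})

    Z = np.vstack(geno_rows).astype(float)
    marker_ids = tuple(f"m{k+1}" for k in range(m))
    genotypes = GenotypeMatrix(Z, tuple(ids), marker_ids)
    pedigree = Pedigree.from_frame(pd.DataFrame(ped_rows))

    qtl_idx = np.sort(rng.choice(m, size=config.n_qtl, replace=False)) if config.n_qtl else np.array([], dtype=int)
    effects = rng.normal(0.0, config.qtl_effect_scale, size=config.n_qtl)
    tbv = pd.Series(Z[:, qtl_idx] @ effects if config.n_qtl else np.zeros(len(ids)),
                    index=list(ids), name="tbv")

    n_pheno = int(round(config.phenotyped_fraction * len(offspring)))
    n_pheno = max(1, min(n_pheno, len(offspring)))
    phenotyped = tuple(sorted(rng.choice(offspring, size=n_pheno, replace=False)))
    validation = tuple(i for i in offspring if i not in set(phenotyped))

    phenotypes, true_target = simulate_growth_phenotypes(
        tbv, config, rng, phenotyped_ids=phenotyped, all_offspring=tuple(offspring)
    )

    params = {
        **asdict(config),
        "qtl_indices": qtl_idx.tolist(),
        "qtl_effects": effects.tolist(),
        "allele_freqs": freqs.tolist(),
        "var_tbv_offspring": float(np.var(tbv.loc[list(offspring)], ddof=1)) if len(offspring) > 1 else 0.0,
        "n_offspring": len(offspring),
        "n_phenotyped": len(phenotyped),
    }
    return SimOutput(
        genotypes=genotypes,
        pedigree=pedigree,
        phenotypes=phenotypes,
        tbv=tbv,
        true_target=true_target,
        phenotyped_ids=phenotyped,
        validation_ids=validation,
        params=params,
    )


def simulate_growth_phenotypes(
    tbv: pd.Series,
    config: SimConfig,
    rng: np.random.Generator,
    *,
    phenotyped_ids,
    all_offspring,
) -> tuple[pd.DataFrame, pd.Series]:
    """Logistic repeated measures for the phenotyped subset.

    Each individual grows toward the asymptote alpha_i = alpha_base + tbv_i
    (beta and gamma optionally perturbed per individual); observations at
    ``config.times`` carry i.i.d. N(0, measurement_error_sd^2) error.  The
    noise-free curve value at ``config.target_time`` is returned for every
    offspring (the simulation's ground truth for coverage checks).
    """
    times = np.asarray(config.times, dtype=float)
    records = []
    truth = {}
    betas = {}
    gammas = {}
    for ind in all_offspring:
        b = config.beta_base
        g = config.gamma_base
        if config.beta_sd > 0:
            b = max(config.beta_base + rng.normal(0, config.beta_sd), 1e-3)
        if config.gamma_sd > 0:
            g = max(config.gamma_base + rng.normal(0, config.gamma_sd), 1e-6)
        betas[ind], gammas[ind] = b, g
        alpha_i = config.alpha_base + float(tbv[ind])
        truth[ind] = float(logistic_mean(config.target_time, alpha_i, b, g))
    for ind in phenotyped_ids:
        alpha_i = config.alpha_base + float(tbv[ind])
        mean = logistic_mean(times, alpha_i, betas[ind], gammas[ind])
        noise = (
            rng.normal(0.0, config.measurement_error_sd, size=len(times))
            if config.measurement_error_sd > 0
            else np.zeros(len(times))
        )
        for t, v in zip(times, mean + noise):
            records.append({"individual": ind, "time": t, "value": v})
    phenotypes = pd.DataFrame(records, columns=["individual", "time", "value"])
    true_target = pd.Series({i: truth[i] for i in all_offspring}, name="true_target")
    return phenotypes, true_target
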