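"""Synthetic half-sib populations with known additive/dominance architecture.

The generator emulates a single-generation sheep breeding design: a small set
of sires each mated to many unrelated dams, producing mostly paternal
half-sib offspring with a small fraction of full-sib pairs, distributed over
a handful of herds with both sexes represented.  Defaults mirror the study
population this package analyses: 498 offspring of 26 sires across 7 herds
(59% rams), under 12% full-sibs, with a desk-scale marker panel.

Marker loci are unlinked; founder genotypes are drawn from Hardy-Weinberg
proportions at frequencies from a uniform MAF law, and offspring receive one
allele per parent by independent Mendelian transmission.  Phenotypes are
generated from the same additive and dominance marker codings used to build
the relationship matrices, with per-marker effect variances scaled by the
matrix denominators so the simulated variance components are the ones the
fitted GBLUP models estimate:

    a_i ~ N(0, sigma2_a / (2 sum p q)),   u = W1 a
    d_i ~ N(0, sigma2_d / (4 sum p^2 q^2)),   v = W2 d
    y = intercept + sex + herd + u + v + e,   e ~ N(0, sigma2_e I)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, estimate_frequencies, write_plink
from .relationship import build_additive_design, build_dominance_design

__all__ = [
    "SimScenario",
    "SimTruth",
    "simulate_founders_and_gametes",
    "simulate_phenotypes",
    "simulate_population",
    "inject_missing",
    "export_fixture",
]


@dataclass
class SimScenario:
    """Generative parameters for one synthetic population.

    Variance defaults give a staple-length-like trait (h2 = 0.5, no
    dominance); herd and sex effects are a modest fraction of the phenotypic
    standard deviation.
    """

    n_offspring: int = 498
    n_sires: int = 26
    n_herds: int = 7
    male_fraction: float = 295 / 498
    full_sib_fraction: float = 0.10
    n_markers: int = 5000
    maf_min: float = 0.05
    sigma2_a: float = 40.0
    sigma2_d: float = 0.0
    sigma2_e: float = 40.0
    intercept: float = 83.5
    sex_effect: float = 4.0
    herd_effect_sd: float = 4.0
    trait_name: str = "trait"
    seed: int = 0

    def validate(self) -> None:
        if min(self.sigma2_a, self.sigma2_d, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")
        if not 0.0 <= self.full_sib_fraction < 1.0:
            raise ValueError("full-sib fraction must lie in [0, 1)")
        if not 0.0 < self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in (0, 0.5]")
        if self.n_sires < 1 or self.n_offspring < self.n_sires:
            raise ValueError("need at least one offspring per sire")


@dataclass
class SimTruth:
    """Ground truth saved alongside a simulated phenotype."""

    u: np.ndarray
    v: np.ndarray
    additive_effects: np.ndarray
    dominance_effects: np.ndarray
    fixed_part: np.ndarray
    residual: np.ndarray
    realized: dict[str, float] = field(default_factory=dict)


def _gamete(parent_doses: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One allele per marker: transmitted A1 with probability dose/2."""
    return (rng.random(parent_doses.shape) < parent_doses / 2.0).astype(np.int8)


def simulate_founders_and_gametes(
    scenario: SimScenario, rng: np.random.Generator | None = None
):
    """Draw founders and offspring genotypes plus the sample table.

    Returns ``(GenotypeMatrix, markers, samples)`` for the offspring
    generation only (founders are not genotyped, as in the study).  Full-sib
    pairs are created by letting some dams produce two offspring of the same
    sire; everyone else is a singleton, so offspring of one sire are paternal
    half-sibs.
    """
    scenario.validate()
    rng = rng or np.random.default_rng(scenario.seed)
    n, m = scenario.n_offspring, scenario.n_markers

    p = rng.uniform(scenario.maf_min, 0.5, size=m)
    sires = rng.binomial(2, p, size=(scenario.n_sires, m)).astype(np.int8)

    # offspring -> sire, balanced families
    sire_of = np.repeat(
        np.arange(scenario.n_sires),
        np.diff(np.linspace(0, n, scenario.n_sires + 1).astype(int)),
    )
    # full-sib pairs: two consecutive offspring of a family share a dam
    n_pairs = int(round(scenario.full_sib_fraction * n / 2))
    dam_of = np.arange(n)
    pair_count = 0
    fam_starts = np.flatnonzero(np.r_[True, np.diff(sire_of) != 0])
    fam_sizes = np.diff(np.r_[fam_starts, n])
    offset = 0  # rotate through families, converting singleton slots to pairs
    while pair_count < n_pairs:
        made = False
        for start, size in zip(fam_starts, fam_sizes):
            if pair_count >= n_pairs:
                break
            i = start + 2 * offset
            if i + 1 < start + size:
                dam_of[i + 1] = dam_of[i]
                pair_count += 1
                made = True
        if not made:
            break
        offset += 1
    dam_ids, dam_index = np.unique(dam_of, return_inverse=True)
    dams = rng.binomial(2, p, size=(len(dam_ids), m)).astype(np.int8)

    doses = _gamete(sires[sire_of], rng) + _gamete(dams[dam_index], rng)
    ids = np.array([f"O{i + 1:04d}" for i in range(n)], dtype=object)
    genos = GenotypeMatrix(doses, np.zeros_like(doses, dtype=bool), ids)

    markers = pd.DataFrame(
        {
            "marker_id": [f"SNP{i + 1:06d}" for i in range(m)],
            "chrom": [str(i % 26 + 1) for i in range(m)],
            "pos": np.arange(1, m + 1) * 1000,
            "a1": "A",
            "a2": "B",
        }
    )
    samples = pd.DataFrame(
        {
            "individual_id": ids,
            "sex": np.where(rng.random(n) < scenario.male_fraction, "M", "F"),
            "herd": [f"H{h + 1}" for h in rng.integers(0, scenario.n_herds, n)],
            "sire_id": [f"S{s + 1:02d}" for s in sire_of],
            "dam_id": [f"D{d + 1:04d}" for d in dam_index],
        }
    )
    return genos, markers, samples


def simulate_phenotypes(
    genos: GenotypeMatrix,
    samples: pd.DataFrame,
    scenario: SimScenario,
    rng: np.random.Generator | None = None,
):
    """Phenotypes from the generative mixed model; returns (table, truth).

    Marker effects use the same codings and denominators as the relationship
    matrices, so ``Var(u) ~ sigma2_a G`` and the scenario variances are the
    estimands of the REML fit.  Monomorphic markers (possible in small
    samples) carry no effect.
    """
    scenario.validate()
    rng = rng or np.random.default_rng(scenario.seed + 1)
    n = genos.n_individuals
    freqs = estimate_frequencies(genos)
    poly = (freqs > 0.0) & (freqs < 1.0)
    sub = genos.subset(cols=np.flatnonzero(poly))
    p = freqs[poly]
    pq = p * (1 - p)

    u = np.zeros(n)
    a = np.zeros(poly.sum())
    if scenario.sigma2_a > 0:
        a = rng.normal(0.0, np.sqrt(scenario.sigma2_a / (2.0 * pq.sum())), poly.sum())
        u = build_additive_design(sub.doses, p, sub.missing).values @ a
    v = np.zeros(n)
    d = np.zeros(poly.sum())
    if scenario.sigma2_d > 0:
        d = rng.normal(
            0.0, np.sqrt(scenario.sigma2_d / (4.0 * (pq * pq).sum())), poly.sum()
        )
        v = build_dominance_design(sub.doses, p, sub.missing).values @ d

    herd_levels = sorted(samples["herd"].unique())
    herd_effects = dict(
        zip(herd_levels, rng.normal(0.0, scenario.herd_effect_sd, len(herd_levels)))
    )
    fixed = (
        scenario.intercept
        + np.where(samples["sex"].to_numpy() == "M", scenario.sex_effect, 0.0)
        + samples["herd"].map(herd_effects).to_numpy()
    )
    e = rng.normal(0.0, np.sqrt(scenario.sigma2_e), n)
    y = fixed + u + v + e

    pheno = samples[["individual_id", "sex", "herd"]].copy()
    pheno[scenario.trait_name] = y
    truth = SimTruth(
        u=u,
        v=v,
        additive_effects=a,
        dominance_effects=d,
        fixed_part=fixed,
        residual=e,
        realized={
            "var_u": float(np.var(u, ddof=1)),
            "var_v": float(np.var(v, ddof=1)),
            "var_e": float(np.var(e, ddof=1)),
        },
    )
    return pheno, truth


def simulate_population(scenario: SimScenario):
    """Full deterministic simulation from ``scenario.seed``.

    Returns ``(genos, markers, samples, pheno, truth)``.
    """
    rng = np.random.default_rng(scenario.seed)
    genos, markers, samples = simulate_founders_and_gametes(scenario, rng)
    pheno, truth = simulate_phenotypes(genos, samples, scenario, rng)
    return genos, markers, samples, pheno, truth


def inject_missing(
    genos: GenotypeMatrix, rate: float, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Set a random ``rate`` fraction of calls to missing (for QC testing)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must lie in [0, 1)")
    rng = rng or np.random.default_rng(0)
    mask = genos.missing | (rng.random(genos.doses.shape) < rate)
    doses = genos.doses.copy()
    doses[mask] = -1
    return GenotypeMatrix(doses, mask, genos.ids.copy())


def export_fixture(
    prefix: str | Path,
    genos: GenotypeMatrix,
    markers: pd.DataFrame,
    samples: pd.DataFrame,
    pheno: pd.DataFrame | None = None,
    truth: SimTruth | None = None,
) -> None:
    """Write the population as a PLINK triplet plus delimited phenotype file
    (and, when given, the simulation truth) so it round-trips through the
    genotype reader."""
    prefix = Path(prefix)
    write_plink(prefix, genos, markers, samples)
    if pheno is not None:
        pheno.to_csv(f"{prefix}.pheno.tsv", sep="\t", index=False)
    if truth is not None:
        pd.DataFrame(
            {"individual_id": genos.ids, "u": truth.u, "v": truth.v}
        ).to_csv(f"{prefix}.truth.tsv", sep="\t", index=False)
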