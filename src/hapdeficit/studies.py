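"""Replicated simulation studies: detection power, type-I error, risk contrast.

These compose the generator, the scan and the phenotype module into the
standard validation experiments for a homozygosity-deficit analysis: how
often a planted fully penetrant lethal is recovered at a given sample size,
how often a neutral genome yields any significant haplotype, and how closely
the risk1 insemination-success contrast approaches the theoretical 25% loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenotypes import build_category_table
from .scan import merge_significant_windows, scan
from .simulate import SimulationConfig, simulate_mating_cohort, simulate_population

#: study conditions for the N ~= 5,000 power experiment: a shallow
#: three-generation pedigree keeps the realized haplotype frequency close to
#: the founder frequency instead of eroding it by deep-pedigree drift
POWER_CONFIG = dict(n_founders=1_700, n_generations=3,
                    n_offspring_per_generation=1_700, q_lethal=0.07,
                    causal_ld_breakage=0.0)  # complete LD: O = 0 expected

#: study conditions for the neutral type-I-error experiment
NULL_CONFIG = dict(penetrance_stage="none", n_founders=500, n_generations=3,
                   n_offspring_per_generation=500, n_markers=200,
                   genome_length_bp=10_000_000)


@dataclass
class DetectionResult:
    hits: int
    n_seeds: int
    obs_hom_at_region: list[int]
    n_animals: list[int]

    @property
    def rate(self) -> float:
        return self.hits / self.n_seeds


def planted_region_detection(n_seeds: int = 20, seed0: int = 0,
                             **config_kwargs) -> DetectionResult:
    """Fraction of replicate populations whose planted region is recovered.

    A hit requires a merged significant region overlapping the planted
    interval.  Also records the observed homozygote count of the planted
    (all-alternate) haplotype in overlapping significant windows.
    """
    kwargs = {**POWER_CONFIG, **config_kwargs}
    hits = 0
    obs_hom: list[int] = []
    sizes: list[int] = []
    for i in range(n_seeds):
        cfg = SimulationConfig(rng_seed=seed0 + i, **kwargs)
        res = simulate_population(cfg)
        truth = res.true_state
        records = scan(res.phased)
        regions = merge_significant_windows(records)
        hit = any(r.chrom == truth.chrom and r.start < truth.region_end
                  and truth.region_start < r.end for r in regions)
        hits += hit
        planted = [r for r in records if r.significant
                   and set(r.alleles) == {"1"}
                   and r.window.start < truth.region_end
                   and truth.region_start < r.window.end]
        if planted:
            obs_hom.append(min(r.obs_hom for r in planted))
        sizes.append(res.phased.n_animals)
    return DetectionResult(hits, n_seeds, obs_hom, sizes)


def neutral_false_positives(n_seeds: int = 100, seed0: int = 0,
                            alpha: float = 0.05, **config_kwargs) -> tuple[int, int]:
    """Replicates of a neutral simulation with any significant haplotype.

    Under the null the family-wise false-positive rate should not exceed
    ``alpha`` (Bonferroni is conservative, so typically far below it).
    """
    kwargs = {**NULL_CONFIG, **config_kwargs}
    fp = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(rng_seed=seed0 + i, **kwargs)
        res = simulate_population(cfg)
        records = scan(res.phased, alpha=alpha)
        fp += any(r.significant for r in records)
    return fp, n_seeds


@dataclass
class RiskContrast:
    """Risk1 vs non-risk insemination-success contrast on cohort data."""

    risk_success: int
    risk_n: int
    nonrisk_success: int
    nonrisk_n: int
    rel_diff_pct: float
    p: float

    @property
    def rel_diff_se_pct(self) -> float:
        """Delta-method standard error of the relative difference (in %)."""
        p1 = self.nonrisk_success / self.nonrisk_n
        p2 = self.risk_success / self.risk_n
        v1 = p1 * (1 - p1) / self.nonrisk_n
        v2 = p2 * (1 - p2) / self.risk_n
        return 100 * math.sqrt(v2 / p1 ** 2 + (p2 ** 2) * v1 / p1 ** 4)


def risk_mating_contrast(n_pairs: int = 10_000, seed: int = 0,
                         **config_kwargs) -> RiskContrast:
    """Simulate carrier x carrier vs non-carrier x carrier matings and
    measure the relative insemination-success reduction through the full
    record-level phenotype machinery."""
    cfg = SimulationConfig(rng_seed=seed, **config_kwargs)
    rng = np.random.default_rng([5, seed])
    m1, f1, s1 = simulate_mating_cohort(cfg, n_pairs, True, True, rng, "R")
    m0, f0, s0 = simulate_mating_cohort(cfg, n_pairs, False, True, rng, "N")
    matings = pd.concat([m1, m0], ignore_index=True)
    foals = pd.concat([f1, f0], ignore_index=True)
    status = pd.concat([s1, s0], ignore_index=True)
    tab = build_category_table(matings, foals, status).set_index("category")
    risk, ref = tab.loc["risk1"], tab.loc["non-risk"]
    return RiskContrast(
        risk_success=int(risk["successes"]), risk_n=int(risk["n_matings"]),
        nonrisk_success=int(ref["successes"]), nonrisk_n=int(ref["n_matings"]),
        rel_diff_pct=float(risk["rel_diff_pct"]), p=float(risk["p"]))
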