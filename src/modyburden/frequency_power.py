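"""Allele-frequency arithmetic, maximum credible frequency screening, and
burden-test power analysis.

The credibility screen follows the maximum-credible-allele-frequency
framework for dominant (monoallelic) disease: a causal variant's population
frequency cannot exceed

    AF_max = prevalence x max allelic contribution x max genetic
             contribution / (2 x penetrance)

For MODY (prevalence 248 per million, penetrance >= 50%) this caps the most
common credible pathogenic variant at a handful of occurrences in a
141,456-individual reference database.

Power analysis targets the carrier-collapsing Fisher exact design: given
cohort sizes, a control carrier frequency (2 x MAF under the heterozygote
approximation) and a gene-level odds ratio, power is estimated either by
Monte-Carlo simulation of binomial carrier counts or by a normal (Wald)
approximation on the log odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.stats import chi2, fisher_exact, norm

#: individuals in the gnomAD v2.1.1 reference used for credibility screening
GNOMAD_V2_INDIVIDUALS = 141456

#: MODY prevalence: 248 cases per million
MODY_PREVALENCE = 248e-6


@dataclass
class FrequencyRecord:
    """Per-population allele counts for one variant."""

    counts: dict  # population label -> (ac, an)

    def __post_init__(self):
        for pop, (ac, an) in self.counts.items():
            if ac < 0 or an < 0 or ac > an:
                raise ValueError(f"bad counts for population {pop}")

    def af(self, pop: str) -> float:
        ac, an = self.counts[pop]
        return allele_frequency(ac, an)


def allele_frequency(ac: int, an: int) -> float:
    """Exact allele frequency ac/an; an must be positive."""
    if an <= 0:
        raise ValueError("allele frequency undefined for an <= 0")
    if not (0 <= ac <= an):
        raise ValueError("need 0 <= ac <= an")
    return ac / an


def popmax(r: FrequencyRecord) -> tuple:
    """Population with the maximum allele frequency (ties alphabetical).

    Populations with an == 0 are skipped; at least one population must have
    observed alleles.
    """
    best = None
    for pop in sorted(r.counts):
        ac, an = r.counts[pop]
        if an == 0:
            continue
        f = ac / an
        if best is None or f > best[1]:
            best = (pop, f)
    if best is None:
        raise ValueError("no population with an > 0")
    return best


@dataclass(frozen=True)
class CredibilityConfig:
    """Parameters of the maximum-credible-frequency formula (monoallelic).

    The allelic and genetic contributions (the share of disease attributable
    to the most common variant and to the gene) have no safe defaults and
    must be supplied explicitly.
    """

    prevalence: float = MODY_PREVALENCE
    penetrance: float = 0.5
    max_allelic_contribution: float = 1.0
    max_genetic_contribution: float = 1.0
    inheritance: str = "monoallelic"

    def __post_init__(self):
        for name in ("prevalence", "penetrance",
                     "max_allelic_contribution", "max_genetic_contribution"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.inheritance != "monoallelic":
            raise ValueError("only monoallelic inheritance is supported")


def max_credible_af(cfg: CredibilityConfig) -> float:
    """Maximum credible population allele frequency for a causal variant."""
    return (
        cfg.prevalence
        * cfg.max_allelic_contribution
        * cfg.max_genetic_contribution
        / (2.0 * cfg.penetrance)
    )


def max_tolerated_ac(
    af_max: float, n_individuals: int, mode: str = "point"
) -> int:
    """Maximum tolerated allele count in a reference of ``n_individuals``.

    ``point``: the expected count rounded to the nearest integer.
    ``poisson95``: the largest count whose one-sided 95% lower confidence
    bound (Garwood/exact Poisson) does not exceed the expected count.
    """
    if af_max < 0:
        raise ValueError("af_max must be non-negative")
    expected = af_max * n_individuals
    if mode == "point":
        return int(round(expected))
    if mode == "poisson95":
        c = 0
        while True:
            nxt = c + 1
            lower = 0.5 * chi2.ppf(0.05, 2 * nxt)  # exact lower 95% bound
            if lower > expected:
                return c
            c = nxt
            if c > 10_000_000:  # pragma: no cover - safety stop
                raise RuntimeError("max_tolerated_ac did not converge")
    raise ValueError("mode must be 'point' or 'poisson95'")


@dataclass(frozen=True)
class PowerConfig:
    """Configuration of the carrier Fisher-test power calculation."""

    n_case: int = 2571
    n_control: int = 155501
    maf: float = 1e-4
    carrier_model: str = "2maf"  # heterozygote approximation, or "maf"
    odds_ratio: float = 9.8
    alpha: float = 0.05
    method: str = "simulation"  # or "wald"
    n_reps: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.maf < 0.5):
            raise ValueError("maf must be in (0, 0.5)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if self.carrier_model not in ("2maf", "maf"):
            raise ValueError("carrier_model must be '2maf' or 'maf'")
        if self.method not in ("simulation", "wald"):
            raise ValueError("method must be 'simulation' or 'wald'")

    @property
    def control_carrier_prob(self) -> float:
        return 2.0 * self.maf if self.carrier_model == "2maf" else self.maf

    @property
    def case_carrier_prob(self) -> float:
        q = self.control_carrier_prob
        odds = self.odds_ratio * q / (1.0 - q)
        return odds / (1.0 + odds)


def burden_power(cfg: PowerConfig) -> float:
    """Power of the two-sided carrier Fisher exact test.

    Simulation: binomially sampled carrier counts per cohort over
    ``n_reps`` replicates (Fisher p-values cached over distinct count
    pairs); power is the rejection fraction at ``alpha``.  Wald: normal
    approximation Phi(|ln OR| / SE - z_{1-alpha/2}) with the log-OR
    standard error evaluated at the expected cell counts.
    """
    q, pc = cfg.control_carrier_prob, cfg.case_carrier_prob
    if cfg.method == "wald":
        a = cfg.n_case * pc
        b = cfg.n_case - a
        c = cfg.n_control * q
        d = cfg.n_control - c
        if min(a, b, c, d) <= 0:
            raise ValueError("expected cell count not positive")
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = norm.ppf(1.0 - cfg.alpha / 2.0)
        return float(norm.cdf(abs(math.log(cfg.odds_ratio)) / se - z))
    rng = np.random.default_rng(cfg.seed)
    a = rng.binomial(cfg.n_case, pc, cfg.n_reps)
    c = rng.binomial(cfg.n_control, q, cfg.n_reps)
    cache: dict = {}
    hits = 0
    for ai, ci in zip(a.tolist(), c.tolist()):
        key = (ai, ci)
        p = cache.get(key)
        if p is None:
            p = fisher_exact(
                [[ai, cfg.n_case - ai], [ci, cfg.n_control - ci]]
            )[1]
            cache[key] = p
        hits += p < cfg.alpha
    return hits / cfg.n_reps


def detectable_or(
    cfg: PowerConfig,
    power_target: float = 0.80,
    or_max: float = 1000.0,
    tol: float = 0.05,
) -> float:
    """Smallest odds ratio reaching ``power_target``, by bisection.

    Power is monotone non-decreasing in the odds ratio; the search brackets
    [1, or_max] and stops at an OR resolution of ``tol``.
    """
    if not (0.0 < power_target < 1.0):
        raise ValueError("power_target must be in (0, 1)")

    def power_at(or_):
        return burden_power(replace(cfg, odds_ratio=or_))

    if power_at(or_max) < power_target:
        raise ValueError(f"no odds ratio <= {or_max} reaches the target power")
    lo, hi = 1.0, or_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if power_at(mid) >= power_target:
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# Catalog of the first-reported MODY-associated variants (input data: allele
# counts in the gnomAD v2.1.1 reference plus the ancestry with the maximum
# frequency), used by the frequency-screening stage.
# ---------------------------------------------------------------------------

FIRST_REPORTED_VARIANTS = [
    # (gene, variant, overall (ac, an), popmax population, popmax (ac, an))
    ("HNF1A", "p.P447L", (3, 249186), "Finnish", (1, 20812)),
    ("HNF1A", "p.V380Sfs*4", (0, 249186), None, (0, 0)),
    ("HNF1A", "p.E548Rfs*112", (0, 249186), None, (0, 0)),
    ("HNF1A", "p.R131Q", (1, 251390), "non-Finnish European", (1, 113698)),
    ("HNF1A", "c.1768+1G>A", (0, 249186), None, (0, 0)),
    ("HNF1A", "c.1108-2A>G", (0, 249186), None, (0, 0)),
    ("RFX6", "p.Q25*", (1, 31362), "non-Finnish European", (1, 15422)),
    ("RFX6", "p.L292*", (0, 31362), None, (0, 0)),
    ("RFX6", "p.H293Lfs", (52, 282332), "Finnish", (51, 25096)),
    ("RFX6", "p.K351*", (0, 31362), None, (0, 0)),
    ("RFX6", "p.R377*", (1, 250964), "African", (1, 16252)),
    ("RFX6", "p.R652*", (4, 251320), "African", (1, 16254)),
    ("NEUROD1", "p.H206Pfs*38", (0, 249186), None, (0, 0)),
    ("PDX1", "p.P63Rfs*60", (2, 138298), "non-Finnish European", (1, 49632)),
    ("WFS1", "p.W314R", (0, 249186), None, (0, 0)),
    ("APPL1", "p.L552*", (0, 249186), None, (0, 0)),
    ("APPL1", "p.D94N", (1, 248002), "non-Finnish European", (1, 112840)),
]


def frequency_screen(
    variants=FIRST_REPORTED_VARIANTS,
    credibility: Optional[CredibilityConfig] = None,
    n_individuals: int = GNOMAD_V2_INDIVIDUALS,
):
    """Tabulate frequencies and credibility verdicts for a variant catalog.

    Each row reports the overall allele frequency, the popmax frequency,
    and — when a credibility configuration is given — whether the popmax
    frequency exceeds the maximum credible allele frequency.
    """
    import pandas as pd

    af_cap = max_credible_af(credibility) if credibility is not None else None
    rows = []
    for gene, name, (ac, an), pop, (pac, pan) in variants:
        af = allele_frequency(ac, an) if an > 0 else 0.0
        paf = allele_frequency(pac, pan) if pan > 0 else 0.0
        row = {
            "gene": gene,
            "variant": name,
            "ac": ac,
            "an": an,
            "af": af,
            "popmax_population": pop if pop is not None else "",
            "popmax_ac": pac,
            "popmax_an": pan,
            "popmax_af": paf,
        }
        if af_cap is not None:
            row["max_credible_af"] = af_cap
            row["exceeds_credible"] = paf > af_cap
        rows.append(row)
    return pd.DataFrame(rows)
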