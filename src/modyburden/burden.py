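"""Ultra-rare qualifying-variant selection and carrier burden testing.

The burden (collapsing) test compares, per gene and variant class, the
proportion of individuals carrying at least one qualifying variant between a
case cohort and a population-control cohort, with a two-sided Fisher exact
test.  Effect sizes are sample odds ratios with Woolf (log-OR) 95% CIs; the
Haldane–Anscombe correction (0.5 added to every cell) is applied when any
cell of the 2x2 table is zero.

Qualifying variants are ultra-rare (control-population MAF below a
configurable threshold, 1e-4 in the primary analysis), of one analysis
class, and — for PTVs in the primary analysis — predicted subject to NMD;
single-exon genes keep all their PTVs because NMD never engages.  The
sensitivity grid varies the MAF tier (5e-5, 2e-4, no threshold for PTVs,
MAC=1) and the region scope (functional domains in/out, NMD-escape-only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import fisher_exact, norm

from .gene_annotation import (
    GeneModel,
    VariantClass,
    VariantRecord,
    classify_variant,
    in_functional_domain,
    is_nmd_escape,
)

#: Bonferroni-corrected significance threshold: 0.05 / (6 genes x 3 classes)
DEFAULT_ALPHA = 0.002

REGION_SCOPES = ("all", "in_domain", "out_domain", "nmd_escape_only")


@dataclass(frozen=True)
class BurdenConfig:
    """One cell of the analysis grid.

    ``maf_threshold=None`` disables the frequency filter (used as a PTV-only
    sensitivity tier); ``mac1_only`` restricts to singleton alleles.
    """

    variant_class: VariantClass = VariantClass.PTV
    maf_threshold: Optional[float] = 1e-4
    mac1_only: bool = False
    region_scope: str = "all"
    exclude_nmd_escape_ptv: bool = True
    revel_cutoff: float = 0.7
    alpha: float = DEFAULT_ALPHA
    tier: str = "primary"

    def __post_init__(self):
        if self.region_scope not in REGION_SCOPES:
            raise ValueError(f"region_scope must be one of {REGION_SCOPES}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.maf_threshold is not None and self.maf_threshold <= 0:
            raise ValueError("maf_threshold must be positive or None")


@dataclass
class BurdenResult:
    gene: str
    config: BurdenConfig
    case_carriers: int
    case_n: int
    control_carriers: int
    control_n: int
    odds_ratio: Optional[float]
    ci95: Optional[tuple]
    p: float
    significant: bool

    def __post_init__(self):
        if not (0 <= self.case_carriers <= self.case_n):
            raise ValueError("case carrier count outside [0, n]")
        if not (0 <= self.control_carriers <= self.control_n):
            raise ValueError("control carrier count outside [0, n]")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p outside [0, 1]")


@dataclass
class CohortGenotypes:
    """Sparse per-cohort carrier matrix over variant keys.

    ``carriers`` maps a variant key to the array of carrier sample indices;
    ``missing`` maps a key to indices with missing calls; ``metrics`` maps a
    key to per-carrier ``(index, dp, gq, ad_ref, ad_alt)`` tuples.
    """

    n: int
    carriers: dict = field(default_factory=dict)
    missing: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    sample_ids: Optional[list] = None

    def carrier_count(self, keys: Iterable) -> int:
        """Individuals carrying ≥1 alternate allele at ≥1 of ``keys``; an
        individual with several qualifying variants counts once."""
        seen = set()
        for k in keys:
            if k in self.carriers:
                seen.update(int(i) for i in self.carriers[k])
        return len(seen)

    def allele_frequency(self, key) -> float:
        """Allele frequency assuming heterozygous carriers (AC = carriers,
        AN = 2n)."""
        return len(self.carriers.get(key, ())) / (2 * self.n)


@dataclass
class StudyData:
    """Harmonized case/control data ready for the burden suite."""

    case: CohortGenotypes
    control: CohortGenotypes
    variants: list  # of VariantRecord
    gene_models: dict  # gene name -> GeneModel

    def variants_of(self, gene: str) -> list:
        return [v for v in self.variants if v.gene == gene]


def count_carriers(genotypes: CohortGenotypes, qualifying: Iterable) -> int:
    return genotypes.carrier_count(qualifying)


def control_allele_frequencies(study: StudyData) -> dict:
    """Per-variant allele frequency in the control cohort (the default
    frequency source for the ultra-rare filter; absent variant => 0)."""
    return {v.key: study.control.allele_frequency(v.key) for v in study.variants}


def reference_allele_frequencies(study: StudyData) -> dict:
    """Per-variant frequency from the external reference populations carried
    on each record (summed AC / summed AN; no data => 0).

    Preferred when the control cohort is too small to resolve frequencies
    near the ultra-rare threshold (its minimum nonzero AF is 1/(2n))."""
    out = {}
    for v in study.variants:
        an = sum(v.pop_an.values())
        out[v.key] = (sum(v.pop_ac.values()) / an) if an > 0 else 0.0
    return out


def select_qualifying(
    variants: Sequence[VariantRecord],
    gene_model: GeneModel,
    cfg: BurdenConfig,
    control_af: Mapping,
    mac: Optional[Mapping] = None,
) -> set:
    """Select the qualifying variant keys for one gene under one config.

    Filters, in order: analysis class; control-population MAF strictly below
    the threshold (absent => frequency 0); MAC=1 restriction when requested
    (``mac`` supplies the combined minor allele count per key); region scope;
    NMD policy for PTVs.  Variants whose class is ``NONE`` never qualify;
    a variant that cannot be classified at all is an input error upstream.
    """
    if cfg.mac1_only and mac is None:
        raise ValueError("mac1_only requires a MAC mapping")
    kept = set()
    for v in variants:
        vclass = classify_variant(v, cfg.revel_cutoff)
        if vclass is not cfg.variant_class:
            continue
        af = control_af.get(v.key, 0.0)
        if cfg.maf_threshold is not None and not (af < cfg.maf_threshold):
            continue
        if cfg.mac1_only and mac.get(v.key, 0) != 1:
            continue
        if cfg.region_scope == "in_domain":
            if v.protein_pos is None or not in_functional_domain(v, gene_model):
                continue
        elif cfg.region_scope == "out_domain":
            # complement of in_domain: includes variants without a protein
            # position so the two scopes partition every qualifying set
            if v.protein_pos is not None and in_functional_domain(v, gene_model):
                continue
        if vclass is VariantClass.PTV:
            escape = is_nmd_escape(v, gene_model)
            if cfg.region_scope == "nmd_escape_only":
                if not escape:
                    continue
            elif (
                cfg.exclude_nmd_escape_ptv
                and escape
                and not gene_model.single_exon
            ):
                continue
        elif cfg.region_scope == "nmd_escape_only":
            continue
        kept.add(v.key)
    return kept


@lru_cache(maxsize=500_000)
def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_burden(
    case_carriers: int,
    case_n: int,
    control_carriers: int,
    control_n: int,
    alpha: float = DEFAULT_ALPHA,
) -> tuple:
    """Two-sided Fisher exact test with sample OR and Woolf 95% CI.

    Returns ``(p, odds_ratio, ci95)``.  The Haldane–Anscombe correction
    (+0.5 to all cells) is applied for the OR/CI whenever any cell is zero;
    a table with no carriers in either cohort is degenerate: p = 1 and the
    OR is undefined (None).
    """
    a, c = case_carriers, control_carriers
    b, d = case_n - case_carriers, control_n - control_carriers
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if a == 0 and c == 0:
        return 1.0, None, None
    p = _fisher_p(a, b, c, d)
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    or_ = (a2 * d2) / (b2 * c2)
    se = math.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    z = norm.ppf(0.975)
    lo = math.exp(math.log(or_) - z * se)
    hi = math.exp(math.log(or_) + z * se)
    return p, or_, (lo, hi)


def primary_grid(
    genes: Iterable[str],
    classes: Iterable[VariantClass] = (
        VariantClass.PTV,
        VariantClass.DAMAGING_MISSENSE,
        VariantClass.SYNONYMOUS,
    ),
    **kwargs,
) -> list:
    """The primary analysis grid: one config per gene-independent class."""
    return [BurdenConfig(variant_class=c, **kwargs) for c in classes]


def sensitivity_grid(base: BurdenConfig = BurdenConfig()) -> list:
    """Sensitivity tiers for one variant class: stricter/looser MAF,
    MAC=1, domain split, NMD-escape-only, and (PTV) no frequency filter."""
    tiers = [
        replace(base, maf_threshold=5e-5, tier="maf_5e-05"),
        replace(base, maf_threshold=2e-4, tier="maf_0.0002"),
        replace(base, mac1_only=True, tier="mac1"),
        replace(base, region_scope="in_domain", tier="in_domain"),
        replace(base, region_scope="out_domain", tier="out_domain"),
    ]
    if base.variant_class is VariantClass.PTV:
        tiers.append(replace(base, maf_threshold=None, tier="no_maf"))
        tiers.append(
            replace(base, region_scope="nmd_escape_only", tier="nmd_escape")
        )
    return tiers


def run_suite(
    study: StudyData,
    configs: Sequence[BurdenConfig],
    control_af: Optional[Mapping] = None,
    mac: Optional[Mapping] = None,
) -> list:
    """Run every config against every gene; one BurdenResult per cell.

    ``control_af`` defaults to control-cohort frequencies.  ``mac`` (needed
    for MAC=1 tiers) defaults to combined case+control allele counts.
    """
    if control_af is None:
        control_af = control_allele_frequencies(study)
    needs_mac = any(c.mac1_only for c in configs)
    if mac is None and needs_mac:
        mac = {
            v.key: len(study.case.carriers.get(v.key, ()))
            + len(study.control.carriers.get(v.key, ()))
            for v in study.variants
        }
    results = []
    genes = sorted({v.gene for v in study.variants if v.gene is not None})
    for gene in genes:
        if gene not in study.gene_models:
            raise ValueError(f"no gene model for {gene}")
        gvars = study.variants_of(gene)
        model = study.gene_models[gene]
        for cfg in configs:
            keys = select_qualifying(gvars, model, cfg, control_af, mac)
            a = study.case.carrier_count(keys)
            c = study.control.carrier_count(keys)
            p, or_, ci = fisher_burden(a, study.case.n, c, study.control.n)
            results.append(
                BurdenResult(
                    gene=gene,
                    config=cfg,
                    case_carriers=a,
                    case_n=study.case.n,
                    control_carriers=c,
                    control_n=study.control.n,
                    odds_ratio=or_,
                    ci95=ci,
                    p=p,
                    significant=p < cfg.alpha,
                )
            )
    return results


def results_to_frame(results: Sequence[BurdenResult]):
    """Tabulate suite results (one row per gene x class x tier x scope)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene,
                "class": r.config.variant_class.value,
                "tier": r.config.tier,
                "scope": r.config.region_scope,
                "case_carriers": r.case_carriers,
                "case_n": r.case_n,
                "control_carriers": r.control_carriers,
                "control_n": r.control_n,
                "OR": float("nan") if r.odds_ratio is None else r.odds_ratio,
                "CI_low": float("nan") if r.ci95 is None else r.ci95[0],
                "CI_high": float("nan") if r.ci95 is None else r.ci95[1],
                "p": r.p,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
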