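"""Site-, genotype- and sample-level quality control with cross-cohort
harmonization.

Three threshold profiles mirror the three data sources of a panel-vs-biobank
case-control design:

* ``panel``   — targeted panel cases (read-depth minimum 20);
* ``wgs``     — genome-sequenced controls (read-depth minimum 15, Graphtyper
  AAscore and low-complexity-region filters apply);
* ``gnomad``  — aggregate reference data (low-complexity and coverage-based
  region filters; caller internals unavailable).

Site metrics that are absent from a record are treated as non-evaluable
(the rule is skipped with a warning), never as failures.  A variant that
fails QC in either cohort is removed from both ("harmonization").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import binomtest

from .gene_annotation import VariantRecord

logger = logging.getLogger("modyburden")

#: region with known high false-positive rates on panel data
HNF1A_C_INSERTION_REGION = ("12", 120994310, 120994335)


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults reproduce the framework's QC rules."""

    fs_max: float = 60.0
    qd_min: float = 2.0
    read_pos_rank_sum_min: float = -8.0
    mq_rank_sum_min: float = -12.5
    mq_min: float = 40.0
    dp_min_panel: int = 20
    dp_min_wgs: int = 15
    gq_min: int = 20
    ab_binomial_p_min: float = 0.001
    genotype_missingness_max: float = 0.02
    sample_missingness_max: float = 0.02
    aascore_min: float = 0.5          # wgs mode only
    coverage_fraction_min: float = 0.80  # gnomad mode: ≤10x in ≤80% of samples
    coverage_depth: int = 10
    excluded_regions: tuple = (HNF1A_C_INSERTION_REGION,)

    def __post_init__(self):
        for chrom, s, e in self.excluded_regions:
            if s > e or s < 0:
                raise ValueError(f"malformed excluded region {chrom}:{s}-{e}")

    def dp_min(self, mode: str) -> int:
        return self.dp_min_panel if mode == "panel" else self.dp_min_wgs


@dataclass
class QCResult:
    status: str  # pass | fail
    reasons: list = field(default_factory=list)

    def __post_init__(self):
        if (self.status == "pass") != (not self.reasons):
            raise ValueError("status must be 'pass' iff reasons is empty")

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def _result(reasons: list) -> QCResult:
    return QCResult("fail", sorted(reasons)) if reasons else QCResult("pass")


_MODES = ("panel", "wgs", "gnomad")


def site_qc(v: VariantRecord, t: QCThresholds, mode: str = "panel") -> QCResult:
    """Variant-level QC.

    Evaluates strand-bias FS, quality-by-depth QD, the two rank-sum
    statistics, mapping quality, the Graphtyper AAscore (wgs mode),
    low-complexity flags (wgs and gnomad modes), the coverage rule (gnomad
    mode) and excluded-region overlap.  The reason list is order-independent
    (sorted) and the operation is idempotent.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    m = v.site_metrics
    reasons = []

    def check(name, predicate, modes=_MODES):
        if mode not in modes:
            return
        if name not in m or m[name] is None:
            logger.warning("site metric %s absent for %s:%d; rule skipped",
                           name, v.chrom, v.pos)
            return
        if predicate(m[name]):
            reasons.append(name)

    check("FS", lambda x: x > t.fs_max)
    check("QD", lambda x: x < t.qd_min)
    check("ReadPosRankSum", lambda x: x < t.read_pos_rank_sum_min)
    check("MQRankSum", lambda x: x < t.mq_rank_sum_min)
    check("MQ", lambda x: x < t.mq_min)
    check("AAscore", lambda x: x < t.aascore_min, modes=("wgs",))
    if mode in ("wgs", "gnomad") and v.flags.get("low_complexity"):
        reasons.append("low_complexity")
    if mode == "gnomad" and v.flags.get("low_coverage_region"):
        reasons.append("low_coverage_region")
    for chrom, s, e in t.excluded_regions:
        if v.chrom == chrom and s <= v.pos <= e:
            reasons.append("excluded_region")
            break
    return _result(reasons)


from functools import lru_cache


@lru_cache(maxsize=200_000)
def _binom_two_sided(k: int, n: int) -> float:
    return binomtest(k, n, 0.5).pvalue


def allele_balance_test(ad_ref: int, ad_alt: int) -> float:
    """Two-sided binomial test of allelic balance for a heterozygous call.

    Tests ``ad_alt`` alternate reads out of ``ad_ref + ad_alt`` total against
    an expected proportion of 0.5, under the minimum-likelihood two-sided
    convention (sum of outcome probabilities no larger than the observed
    outcome's).
    """
    if ad_ref < 0 or ad_alt < 0:
        raise ValueError("allele depths must be non-negative")
    n = ad_ref + ad_alt
    if n == 0:
        raise ValueError("zero total allele depth")
    return _binom_two_sided(ad_alt, n)


def genotype_qc(
    dp: int,
    gq: int,
    ad_ref: int,
    ad_alt: int,
    t: QCThresholds,
    mode: str = "panel",
    het: bool = True,
) -> QCResult:
    """Per-genotype QC: read depth, genotype quality and, for heterozygous
    calls, the allelic-balance binomial test."""
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    if min(dp, gq, ad_ref, ad_alt) < 0:
        raise ValueError("negative depth or quality")
    reasons = []
    if dp < t.dp_min(mode):
        reasons.append("DP")
    if gq < t.gq_min:
        reasons.append("GQ")
    if het and (ad_ref + ad_alt) > 0:
        if allele_balance_test(ad_ref, ad_alt) < t.ab_binomial_p_min:
            reasons.append("allele_balance")
    return _result(reasons)


def harmonize(
    case_set: Iterable[tuple[VariantRecord, QCResult]],
    control_set: Iterable[tuple[VariantRecord, QCResult]],
) -> tuple[list, list]:
    """Cross-cohort harmonization of QC outcomes.

    A variant key is retained only if it passes QC in every cohort where it
    is present; failure in either cohort removes it from both.  Absence from
    a cohort is not failure.  Returns the kept keys per cohort.
    """
    def index(pairs, label):
        d = {}
        for v, r in pairs:
            if v.key in d:
                raise ValueError(f"duplicate variant key {v.key} in {label}")
            d[v.key] = r
        return d

    case_qc = index(case_set, "case cohort")
    control_qc = index(control_set, "control cohort")
    failed = {k for k, r in case_qc.items() if not r.passed}
    failed |= {k for k, r in control_qc.items() if not r.passed}
    case_kept = [k for k in case_qc if k not in failed]
    control_kept = [k for k in control_qc if k not in failed]
    return case_kept, control_kept


def sample_missingness_filter(
    genotype_matrix, max_missing: float = 0.02
) -> list:
    """Remove samples whose fraction of missing genotype calls exceeds
    ``max_missing`` (strict).

    ``genotype_matrix`` is a samples x variants array-like (or DataFrame)
    where NaN marks a missing call.  Returns retained sample labels (the
    DataFrame index, or row positions for plain arrays) in input order.
    """
    import pandas as pd

    df = pd.DataFrame(genotype_matrix)
    if df.size == 0:
        raise ValueError("empty genotype matrix")
    frac = df.isna().mean(axis=1)
    return [s for s, f in frac.items() if f <= max_missing]


def variant_call_rate_filter(
    missing_fraction: Mapping, max_missing: float = 0.02
) -> list:
    """Per-variant analogue of the missingness rule: keep variant keys whose
    fraction of missing genotypes is ≤ ``max_missing`` (strict removal)."""
    return [k for k, f in missing_fraction.items() if f <= max_missing]
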