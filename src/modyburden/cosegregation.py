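"""Pedigree co-segregation evidence: eligibility, LOD scores, and the
binomial co-segregation / non-penetrance tests.

A pedigree is eligible when the candidate variant is rare enough in the
population (frequency below 1/1500 by default) and the family shows at
least four informative co-segregations.  Evidence is summarized as

* a LOD score — log10 likelihood ratio of linked versus independent
  segregation over the informative meioses, additive across families;
* a binomial test of the proportion of affected, genotyped members who
  carry the variant against an expected 0.5;
* a binomial test of non-penetrance — the proportion of unaffected,
  genotyped members aged >= 25 who carry the variant — against a 10%
  tolerance threshold.

LOD counting rule.  An informative meiosis is a parent-to-child
transmission where the parent is an observed carrier and the child has both
an observed genotype and a known affection status (meioses where both
parents carry the variant are uninformative and skipped; ungenotyped
connector individuals are never imputed as obligate carriers).  The meiosis
is *consistent* when genotype matches phenotype (affected carrier or
unaffected non-carrier).  With R consistent and X inconsistent meioses the
score is the maximized two-point LOD with the phenotype treated as a fully
penetrant marker locus:

    LOD = max(0, R*log10(2*(1-t)) + X*log10(2*t)),   t = X/(R+X)

which reduces to M*log10(2) when all M informative meioses co-segregate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from scipy.stats import binomtest

logger = logging.getLogger("modyburden")

AFFECTED_VALUES = ("yes", "no", "unknown")
GENOTYPE_VALUES = ("carrier", "non_carrier", "unknown")


@dataclass
class Individual:
    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"  # male | female | unknown
    affected: str = "unknown"
    age: Optional[float] = None
    genotype: str = "unknown"

    def __post_init__(self):
        if self.affected not in AFFECTED_VALUES:
            raise ValueError(f"affected must be one of {AFFECTED_VALUES}")
        if self.genotype not in GENOTYPE_VALUES:
            raise ValueError(f"genotype must be one of {GENOTYPE_VALUES}")


@dataclass
class Pedigree:
    family_id: str
    individuals: list

    def __post_init__(self):
        self._by_id = {}
        for ind in self.individuals:
            if ind.id in self._by_id:
                raise ValueError(f"duplicate individual id {ind.id}")
            self._by_id[ind.id] = ind
        for ind in self.individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self._by_id:
                    raise ValueError(f"unknown parent id {pid} for {ind.id}")
        self._check_acyclic()

    def _check_acyclic(self):
        state = {}  # 0 visiting, 1 done

        def visit(iid):
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise ValueError("cyclic parent links in pedigree")
            state[iid] = 0
            ind = self._by_id[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    visit(pid)
            state[iid] = 1

        for iid in self._by_id:
            visit(iid)

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    @property
    def founders(self) -> list:
        return [
            i for i in self.individuals
            if i.father_id is None and i.mother_id is None
        ]

    def parents(self, ind: Individual) -> list:
        return [
            self._by_id[pid]
            for pid in (ind.father_id, ind.mother_id)
            if pid is not None
        ]


@dataclass(frozen=True)
class CosegConfig:
    min_cosegregations: int = 4
    pedigree_variant_af_max: float = 1.0 / 1500.0
    coseg_null_proportion: float = 0.5
    nonpenetrance_null_proportion: float = 0.1
    nonpenetrance_min_age: float = 25.0

    def __post_init__(self):
        for p in (self.coseg_null_proportion, self.nonpenetrance_null_proportion):
            if not (0.0 < p < 1.0):
                raise ValueError("null proportions must be in (0, 1)")


@dataclass
class CosegResult:
    lod: float
    n_affected_genotyped: int
    n_affected_carriers: int
    coseg_p: Optional[float]
    n_unaffected_genotyped_age_ok: int
    n_unaffected_carriers_age_ok: int
    nonpenetrance_p: Optional[float]


def informative_meioses(p: Pedigree) -> list:
    """List of (parent_id, child_id, consistent) for informative meioses.

    Informative: one observed-carrier parent, child with observed genotype
    and known affection.  Consistent: child genotype matches affection.
    """
    out = []
    for child in p.individuals:
        parents = p.parents(child)
        carrier_parents = [q for q in parents if q.genotype == "carrier"]
        if len(carrier_parents) != 1:
            continue  # no carrier parent, or phase-ambiguous double carrier
        if child.genotype == "unknown" or child.affected == "unknown":
            continue
        consistent = (child.genotype == "carrier") == (child.affected == "yes")
        out.append((carrier_parents[0].id, child.id, consistent))
    return out


def lod_score(p: Pedigree) -> float:
    """Co-segregation LOD by the informative-meiosis counting rule.

    With all meioses consistent this is M*log10(2); discordant meioses are
    penalized through the maximized two-point likelihood ratio (see module
    docstring).  No informative meioses => 0.
    """
    meioses = informative_meioses(p)
    m = len(meioses)
    if m == 0:
        return 0.0
    x = sum(1 for _, _, ok in meioses if not ok)
    r = m - x
    if x == 0:
        return r * math.log10(2.0)
    theta = x / m
    if theta >= 0.5:
        return 0.0
    return max(
        0.0, r * math.log10(2.0 * (1.0 - theta)) + x * math.log10(2.0 * theta)
    )


def combined_lod(lods: Iterable[float]) -> float:
    """LOD scores from independent families add."""
    return float(sum(lods))


def cosegregation_count(p: Pedigree) -> int:
    """Number of informative meioses consistent with co-segregation."""
    return sum(1 for _, _, ok in informative_meioses(p) if ok)


def pedigree_eligible(
    p: Pedigree, variant_af: float, cfg: CosegConfig = CosegConfig()
) -> bool:
    """Inclusion rule: >= min_cosegregations informative co-segregations and
    population variant frequency strictly below the cap (1/1500 default)."""
    if variant_af < 0:
        raise ValueError("variant_af must be non-negative")
    if not (variant_af < cfg.pedigree_variant_af_max):
        return False
    return cosegregation_count(p) >= cfg.min_cosegregations


def two_sided_binomial(k: int, n: int, p0: float) -> float:
    """Minimum-likelihood two-sided binomial test.

    The p-value sums the probabilities of all outcomes whose point
    probability under Binomial(n, p0) does not exceed that of the observed
    k; capped at 1.
    """
    if not (0 <= k <= n) or n <= 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    return binomtest(k, n, p0).pvalue


def coseg_tests(p: Pedigree, cfg: CosegConfig = CosegConfig()) -> CosegResult:
    """Co-segregation and non-penetrance binomial tests for one family.

    Co-segregation: carriers among affected, genotyped members vs 0.5.
    Non-penetrance: carriers among unaffected, genotyped members aged
    >= cfg.nonpenetrance_min_age vs cfg.nonpenetrance_null_proportion;
    individuals of unknown age are excluded (the age gate cannot be
    certified).  Zero denominators yield a None p-value with a warning.
    """
    affected = [
        i for i in p.individuals
        if i.affected == "yes" and i.genotype != "unknown"
    ]
    n_aff = len(affected)
    k_aff = sum(1 for i in affected if i.genotype == "carrier")

    unaffected_age_ok = [
        i for i in p.individuals
        if i.affected == "no"
        and i.genotype != "unknown"
        and i.age is not None
        and i.age >= cfg.nonpenetrance_min_age
    ]
    n_un = len(unaffected_age_ok)
    k_un = sum(1 for i in unaffected_age_ok if i.genotype == "carrier")

    if n_aff > 0:
        coseg_p = two_sided_binomial(k_aff, n_aff, cfg.coseg_null_proportion)
    else:
        logger.warning("family %s: no affected genotyped members", p.family_id)
        coseg_p = None
    if n_un > 0:
        nonpen_p = two_sided_binomial(
            k_un, n_un, cfg.nonpenetrance_null_proportion
        )
    else:
        logger.warning(
            "family %s: no unaffected genotyped members aged >= %g",
            p.family_id, cfg.nonpenetrance_min_age,
        )
        nonpen_p = None

    return CosegResult(
        lod=lod_score(p),
        n_affected_genotyped=n_aff,
        n_affected_carriers=k_aff,
        coseg_p=coseg_p,
        n_unaffected_genotyped_age_ok=n_un,
        n_unaffected_carriers_age_ok=k_un,
        nonpenetrance_p=nonpen_p,
    )
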