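"""Shared fixtures: small hand-built gene models, pedigrees, and the
independent brute-force oracles used to validate the statistical engines."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import binom, hypergeom

from modyburden import GeneModel, Individual, Pedigree


# -- oracles ----------------------------------------------------------------

def binomial_minlike_oracle(k: int, n: int, p0: float) -> float:
    """Two-sided binomial p by direct enumeration of the pmf: sum the
    probabilities of all outcomes no more likely than the observed one."""
    pmf = binom.pmf(np.arange(n + 1), n, p0)
    return float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-9)].sum()))


def fisher_minlike_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration with fixed
    margins: sum probabilities of all tables no more likely than observed."""
    row1, col1, total = a + b, a + c, a + b + c + d
    lo, hi = max(0, col1 - (total - row1)), min(row1, col1)
    xs = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(xs, total, row1, col1)
    obs = hypergeom.pmf(a, total, row1, col1)
    return float(min(1.0, pmf[pmf <= obs * (1 + 1e-9)].sum()))


def lod_enumeration_oracle(ped: Pedigree, grid: int = 20001) -> float:
    """LOD by explicit enumeration of carrier-state transmission patterns.

    The phenotype is treated as a fully penetrant marker of the disease
    locus; a child of one carrier parent inherits the variant with
    probability (1-theta) when affected and theta when unaffected (0.5 when
    affection is unknown).  Founders other than observed carriers are
    non-carriers.  The likelihood sums, over every carrier-state assignment
    of the unknown-genotype members, the product of per-meiosis transmission
    probabilities; the LOD is the log10 ratio of the theta-maximized
    likelihood to the likelihood at theta = 0.5.
    """
    people = ped.individuals
    idx = {p.id: i for i, p in enumerate(people)}
    free = [
        i for i, p in enumerate(people)
        if p.genotype == "unknown"
        and not (p.father_id is None and p.mother_id is None)
    ]  # unknown-genotype founders are assumed non-carriers

    terms = []  # (exp_1mt, exp_t, exp_half) per surviving assignment
    for code in range(1 << len(free)):
        states = []
        for i, p in enumerate(people):
            if i in free:
                states.append((code >> free.index(i)) & 1)
            else:
                states.append(1 if p.genotype == "carrier" else 0)
        a = b = c = 0  # exponents of (1-theta), theta, 0.5
        ok = True
        for p, s in zip(people, states):
            if p.father_id is None and p.mother_id is None:
                continue
            parents = [states[idx[q]] for q in (p.father_id, p.mother_id)
                       if q is not None]
            ncp = sum(parents)
            if ncp == 0:
                if s:
                    ok = False
                    break
                continue
            if ncp > 1:
                raise ValueError("fixture has a double-carrier mating")
            if p.affected == "unknown":
                c += 1
            elif (p.affected == "yes") == bool(s):
                a += 1
            else:
                b += 1
        if ok:
            terms.append((a, b, c))
    if not terms:
        return 0.0

    def likelihood(theta: float) -> float:
        return sum(
            (1.0 - theta) ** a * theta ** b * 0.5 ** c for a, b, c in terms
        )

    l_half = likelihood(0.5)
    best = max(likelihood(t) for t in np.linspace(0.0, 0.5, grid))
    if l_half == 0.0 or best == 0.0:
        return 0.0
    return max(0.0, math.log10(best / l_half))


def power_enumeration_oracle(n_case, n_control, p_case, p_control, alpha):
    """Exact power of the two-sided Fisher test by enumerating every
    possible pair of carrier counts with its binomial probability."""
    from modyburden.burden import fisher_burden

    power = 0.0
    pa = binom.pmf(np.arange(n_case + 1), n_case, p_case)
    pc = binom.pmf(np.arange(n_control + 1), n_control, p_control)
    for a in range(n_case + 1):
        for c in range(n_control + 1):
            p, _, _ = fisher_burden(a, n_case, c, n_control)
            if p < alpha:
                power += pa[a] * pc[c]
    return power


# -- fixtures ---------------------------------------------------------------

@pytest.fixture
def three_exon_gene() -> GeneModel:
    """Plus-strand, 3 coding exons of 120/90/60 bp; domain aa 10-40."""
    return GeneModel(
        gene_id="G3",
        transcript_id="TX_G3",
        chrom="1",
        strand="+",
        exons=((1000, 1119), (1620, 1709), (2210, 2269)),
        cds_start=1000,
        cds_end=2269,
        domains=(("dom", 10, 40),),
    )


@pytest.fixture
def three_exon_gene_minus() -> GeneModel:
    """Minus-strand mirror of the 3-exon gene (same exon sizes)."""
    return GeneModel(
        gene_id="G3M",
        transcript_id="TX_G3M",
        chrom="1",
        strand="-",
        exons=((2210, 2269), (1620, 1709), (1000, 1119)),
        cds_start=1000,
        cds_end=2269,
        domains=(("dom", 10, 40),),
    )


@pytest.fixture
def single_exon_gene() -> GeneModel:
    return GeneModel(
        gene_id="G1",
        transcript_id="TX_G1",
        chrom="2",
        strand="+",
        exons=((500, 1570),),
        cds_start=500,
        cds_end=1570,
        domains=(("dom", 92, 265),),
    )


def _ind(iid, father=None, mother=None, affected="unknown",
         genotype="unknown", age=None, sex="unknown"):
    return Individual(id=iid, father_id=father, mother_id=mother, sex=sex,
                      affected=affected, age=age, genotype=genotype)


@pytest.fixture
def nuclear_coseg_pedigree() -> Pedigree:
    """Founder carrier with 4 genotyped children, all co-segregating."""
    members = [
        _ind("F", affected="yes", genotype="carrier", age=60, sex="male"),
        _ind("M", affected="no", genotype="non_carrier", age=58, sex="female"),
        _ind("C1", "F", "M", affected="yes", genotype="carrier", age=35),
        _ind("C2", "F", "M", affected="yes", genotype="carrier", age=33),
        _ind("C3", "F", "M", affected="no", genotype="non_carrier", age=30),
        _ind("C4", "F", "M", affected="no", genotype="non_carrier", age=28),
    ]
    return Pedigree(family_id="NUC", individuals=members)


@pytest.fixture
def three_generation_pedigree() -> Pedigree:
    """10 informative meioses, one recombinant-like inconsistency (C5).

    Generation 1: founder couple with 5 genotyped children; generation 2:
    two carrier children each marry in and have genotyped children.
    """
    members = [
        _ind("F", affected="yes", genotype="carrier", age=80, sex="male"),
        _ind("M", affected="no", genotype="non_carrier", age=78, sex="female"),
        _ind("C1", "F", "M", affected="yes", genotype="carrier", age=55),
        _ind("C2", "F", "M", affected="yes", genotype="carrier", age=53),
        _ind("C3", "F", "M", affected="no", genotype="non_carrier", age=50),
        _ind("C4", "F", "M", affected="no", genotype="non_carrier", age=48),
        _ind("C5", "F", "M", affected="yes", genotype="non_carrier", age=45),
        _ind("S1", affected="no", genotype="non_carrier", age=56, sex="female"),
        _ind("S2", affected="no", genotype="non_carrier", age=52, sex="female"),
        _ind("G1", "C1", "S1", affected="yes", genotype="carrier", age=30),
        _ind("G2", "C1", "S1", affected="no", genotype="non_carrier", age=28),
        _ind("G3", "C2", "S2", affected="yes", genotype="carrier", age=27),
        _ind("G4", "C2", "S2", affected="no", genotype="non_carrier", age=25),
        _ind("G5", "C2", "S2", affected="yes", genotype="carrier", age=26),
    ]
    return Pedigree(family_id="3GEN", individuals=members)
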