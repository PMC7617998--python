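"""Synthetic study generator: gene models, two-cohort case/control variant
data with known class-specific odds ratios and injected QC artifacts, and
autosomal-dominant pedigrees with configurable penetrance.

The generator emulates the design of a panel-sequenced disease cohort
compared against a biobank-scale control cohort.  Carrier counts are drawn
binomially: a variant with control carrier frequency f has case carrier
probability odds/(1+odds) with odds = OR x f/(1-f), so the configured class
odds ratio is the generating truth that downstream burden tests should
recover.  Site and genotype metrics are drawn from benign distributions
except where QC artifacts are injected at configured rates; only
threshold-crossing matters to QC.

All randomness flows from a single integer seed; identical configuration
and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .burden import CohortGenotypes, StudyData
from .cosegregation import Individual, Pedigree
from .gene_annotation import GeneModel, VariantRecord

# failing values injected per artifact key (site level)
_SITE_ARTIFACTS = {
    "FS": ("FS", 75.0),
    "QD": ("QD", 1.0),
    "ReadPosRankSum": ("ReadPosRankSum", -9.0),
    "MQRankSum": ("MQRankSum", -13.0),
    "MQ": ("MQ", 30.0),
    "AAscore": ("AAscore", 0.3),
}


@dataclass(frozen=True)
class ClassParams:
    """Per-gene, per-class generating truth.

    ``baseline_carrier_freq`` is the aggregate control carrier frequency of
    the class (split evenly across ``n_variants`` ultra-rare variants).
    """

    baseline_carrier_freq: float
    odds_ratio: float = 1.0
    n_variants: int = 6

    def __post_init__(self):
        if not (0.0 < self.baseline_carrier_freq < 1.0):
            raise ValueError("baseline_carrier_freq must be in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")


@dataclass(frozen=True)
class GeneSpec:
    name: str
    n_exons: int
    cds_length: int  # coding bases
    domain_fraction: float = 0.5
    domain_placement: str = "central"  # or "three_prime"
    strand: str = "+"
    classes: dict = field(default_factory=dict)  # class value -> ClassParams

    def __post_init__(self):
        if self.n_exons < 1:
            raise ValueError("n_exons must be >= 1")
        if not (0.0 < self.domain_fraction < 1.0):
            raise ValueError("domain_fraction must be in (0, 1)")


@dataclass(frozen=True)
class PedigreeConfig:
    n_generations: int = 3
    mean_offspring: float = 3.0
    penetrance: float = 0.9
    phenocopy_rate: float = 0.02
    age_min: int = 1
    age_max: int = 80

    def __post_init__(self):
        if not (0.0 <= self.phenocopy_rate < 1.0):
            raise ValueError("phenocopy_rate must be in [0, 1)")
        if not (0.0 < self.penetrance <= 1.0):
            raise ValueError("penetrance must be in (0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    genes: tuple
    n_case: int = 2571
    n_control: int = 155501
    qc_artifact_rates: dict = field(
        default_factory=lambda: {"FS": 0.01, "QD": 0.01, "low_complexity": 0.01}
    )
    genotype_artifact_rates: dict = field(
        default_factory=lambda: {"DP": 0.01, "GQ": 0.01, "AB": 0.005}
    )
    genotype_missing_rate: float = 0.002
    pedigree: PedigreeConfig = PedigreeConfig()
    seed: int = 0


def default_study_config(
    n_case: int = 2571, n_control: int = 155501, seed: int = 0, **kwargs
) -> SimulationConfig:
    """The default six-gene study: a high-penetrance and a low-penetrance
    positive-control gene, a single-exon enriched gene, a multi-exon gene
    with a 3'-situated domain covering 22% of the protein, and two null
    genes.  Synonymous classes are null (OR = 1) everywhere.

    The single-exon gene's PTV truth (control carrier frequency 1.2e-4,
    OR 21) is the parameter-recovery benchmark used in the tests.
    """
    g = [
        GeneSpec(
            "HNF1A_like", n_exons=10, cds_length=1896, domain_fraction=0.5,
            classes={
                "PTV": ClassParams(3e-5, 80.0),
                "DAMAGING_MISSENSE": ClassParams(1e-4, 30.0),
                "SYNONYMOUS": ClassParams(3e-4, 1.0),
            },
        ),
        GeneSpec(
            "RFX6_like", n_exons=19, cds_length=2790, domain_fraction=0.4,
            strand="-",
            classes={
                "PTV": ClassParams(2e-4, 6.0),
                "DAMAGING_MISSENSE": ClassParams(1e-4, 2.0),
                "SYNONYMOUS": ClassParams(3e-4, 1.0),
            },
        ),
        GeneSpec(
            "NEUROD1_like", n_exons=1, cds_length=1071, domain_fraction=0.489,
            strand="-",
            classes={
                "PTV": ClassParams(1.2e-4, 21.0),
                "DAMAGING_MISSENSE": ClassParams(1.5e-4, 6.0),
                "SYNONYMOUS": ClassParams(1.5e-4, 1.0),
            },
        ),
        GeneSpec(
            "PDX1_like", n_exons=2, cds_length=852, domain_fraction=0.22,
            domain_placement="three_prime",
            classes={
                "PTV": ClassParams(1e-4, 2.0),
                "DAMAGING_MISSENSE": ClassParams(6e-5, 5.0),
                "SYNONYMOUS": ClassParams(2e-4, 1.0),
            },
        ),
        GeneSpec(
            "APPL1_like", n_exons=22, cds_length=2130,
            domain_fraction=0.3, domain_placement="three_prime",
            classes={
                "PTV": ClassParams(2e-4, 1.0),
                "DAMAGING_MISSENSE": ClassParams(2e-4, 1.0),
                "SYNONYMOUS": ClassParams(4e-4, 1.0),
            },
        ),
        GeneSpec(
            "WFS1_like", n_exons=8, cds_length=2673, domain_fraction=0.5,
            classes={
                "PTV": ClassParams(1.5e-4, 1.0),
                "DAMAGING_MISSENSE": ClassParams(3e-4, 1.0),
                "SYNONYMOUS": ClassParams(4e-4, 1.0),
            },
        ),
    ]
    return SimulationConfig(
        genes=tuple(g), n_case=n_case, n_control=n_control, seed=seed, **kwargs
    )


def simulate_gene_models(cfg: SimulationConfig) -> dict:
    """Deterministic transcript models from the gene specifications."""
    models = {}
    for i, spec in enumerate(cfg.genes):
        chrom = str(i + 1)
        start = 1_000_000
        base = spec.cds_length // spec.n_exons
        sizes = [base] * spec.n_exons
        sizes[-1] += spec.cds_length - base * spec.n_exons
        exons_genomic = []
        pos = start
        for sz in sizes:
            exons_genomic.append((pos, pos + sz - 1))
            pos += sz + 500  # fixed intron length
        exons = (
            tuple(exons_genomic)
            if spec.strand == "+"
            else tuple(exons_genomic[::-1])
        )
        cds_start = exons_genomic[0][0]
        cds_end = exons_genomic[-1][1]
        plen = max(1, spec.cds_length // 3 - 1)
        dlen = max(1, round(spec.domain_fraction * plen))
        if spec.domain_placement == "three_prime":
            dom = ("functional", plen - dlen + 1, plen)
        else:
            a = max(1, (plen - dlen) // 2 + 1)
            dom = ("functional", a, a + dlen - 1)
        models[spec.name] = GeneModel(
            gene_id=spec.name,
            transcript_id=f"TX_{spec.name}",
            chrom=chrom,
            strand=spec.strand,
            exons=exons,
            cds_start=cds_start,
            cds_end=cds_end,
            domains=(dom,),
        )
    return models


def _case_carrier_prob(f: float, odds_ratio: float) -> float:
    odds = odds_ratio * f / (1.0 - f)
    return odds / (1.0 + odds)


def _sample_new_carriers(rng, n, count, used: set) -> np.ndarray:
    """Sample ``count`` distinct indices in [0, n) avoiding ``used`` (one
    qualifying variant per carrier within a gene)."""
    out = []
    while len(out) < count:
        draw = rng.integers(0, n, size=max(4, 2 * (count - len(out))))
        for idx in draw.tolist():
            if idx not in used:
                used.add(idx)
                out.append(idx)
                if len(out) == count:
                    break
    return np.array(sorted(out), dtype=np.int64)


def _genomic_position(model: GeneModel, cds_pos: int) -> int:
    """Genomic coordinate of a 1-based coding position."""
    off = cds_pos - 1
    for s, e in model.coding_exons:
        ln = e - s + 1
        if off < ln:
            return (s + off) if model.strand == "+" else (e - off)
        off -= ln
    raise ValueError("coding position beyond CDS")


_CLASS_CONSEQUENCES = {
    "PTV": ("stop_gain", "frameshift"),
    "DAMAGING_MISSENSE": ("missense",),
    "SYNONYMOUS": ("synonymous",),
}


def _draw_site_metrics(rng, artifact_rates: dict) -> tuple:
    """Benign metric draws, then artifact injection; returns (metrics, flags)."""
    m = {
        "FS": float(abs(rng.normal(5.0, 3.0))),
        "QD": float(max(5.0, rng.normal(20.0, 4.0))),
        "ReadPosRankSum": float(rng.normal(0.0, 0.8)),
        "MQRankSum": float(rng.normal(0.0, 1.0)),
        "MQ": float(max(55.0, rng.normal(60.0, 1.0))),
        "AAscore": float(rng.uniform(0.85, 1.0)),
    }
    flags = {"low_complexity": False, "low_coverage_region": False}
    for key, rate in artifact_rates.items():
        if rng.random() >= rate:
            continue
        if key in _SITE_ARTIFACTS:
            name, value = _SITE_ARTIFACTS[key]
            m[name] = value
        elif key in ("low_complexity", "low_coverage_region"):
            flags[key] = True
        else:
            raise ValueError(f"unknown QC artifact key {key!r}")
    return m, flags


def _carrier_metrics(rng, indices, artifact_rates: dict) -> list:
    """Per-carrier (idx, dp, gq, ad_ref, ad_alt), with genotype artifacts."""
    out = []
    for idx in indices.tolist():
        dp = int(rng.integers(30, 60))
        ad_alt = int(rng.binomial(dp, 0.5))
        gq = int(rng.integers(40, 100))
        if rng.random() < artifact_rates.get("DP", 0.0):
            dp = 10
            ad_alt = min(ad_alt, dp)
        if rng.random() < artifact_rates.get("GQ", 0.0):
            gq = 10
        if rng.random() < artifact_rates.get("AB", 0.0):
            ad_alt = min(2, dp)
        out.append((idx, dp, gq, dp - ad_alt, ad_alt))
    return out


def simulate_cohorts(
    models: dict, cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> StudyData:
    """Simulate the two-cohort study for the configured genes.

    Carrier counts per variant are Binomial(n, f) in controls and
    Binomial(n, f') in cases with the class odds ratio applied on the odds
    scale.  Within a gene each individual carries at most one variant.
    Population AC/AN fields are made consistent with the generating
    frequency (one reference population, 'nfe').
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ref_an = 2 * 34_029  # reference population allele number
    variants: list = []
    case = CohortGenotypes(n=cfg.n_case)
    control = CohortGenotypes(n=cfg.n_control)
    for spec in cfg.genes:
        model = models[spec.name]
        plen = model.protein_length
        used_case: set = set()
        used_control: set = set()
        allele_serial = 0
        for cls in ("PTV", "DAMAGING_MISSENSE", "SYNONYMOUS"):
            if cls not in spec.classes:
                continue
            params = spec.classes[cls]
            k = params.n_variants
            f = params.baseline_carrier_freq / k
            p_case = _case_carrier_prob(f, params.odds_ratio)
            for j in range(k):
                # spread variants across the CDS, codon-aligned
                cds_pos = 3 * (
                    1 + int(rng.integers(0, max(1, model.cds_length // 3 - 2)))
                )
                pos = _genomic_position(model, cds_pos)
                consequence = _CLASS_CONSEQUENCES[cls][j % len(_CLASS_CONSEQUENCES[cls])]
                protein_pos = min(plen, (cds_pos - 1) // 3 + 1)
                revel = (
                    float(rng.uniform(0.75, 0.99)) if cls == "DAMAGING_MISSENSE"
                    else None
                )
                ref, alt = ("AT", "A") if consequence == "frameshift" else ("A", "T")
                metrics, flags = _draw_site_metrics(rng, cfg.qc_artifact_rates)
                ac = int(round(f * ref_an))
                v = VariantRecord(
                    chrom=model.chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt + "ACGT"[allele_serial % 4],  # keep keys unique
                    consequence=consequence,
                    gene=spec.name,
                    revel=revel if consequence == "missense" else None,
                    protein_pos=protein_pos,
                    site_metrics=metrics,
                    flags=flags,
                    pop_ac={"nfe": ac},
                    pop_an={"nfe": ref_an},
                )
                allele_serial += 1
                variants.append(v)
                n_ctl = int(rng.binomial(cfg.n_control, f))
                n_cas = int(rng.binomial(cfg.n_case, p_case))
                ctl_idx = _sample_new_carriers(rng, cfg.n_control, n_ctl, used_control)
                cas_idx = _sample_new_carriers(rng, cfg.n_case, n_cas, used_case)
                control.carriers[v.key] = ctl_idx
                case.carriers[v.key] = cas_idx
                control.metrics[v.key] = _carrier_metrics(
                    rng, ctl_idx, cfg.genotype_artifact_rates
                )
                case.metrics[v.key] = _carrier_metrics(
                    rng, cas_idx, cfg.genotype_artifact_rates
                )
                if cfg.genotype_missing_rate > 0:
                    for coh in (case, control):
                        n_miss = int(rng.binomial(coh.n, cfg.genotype_missing_rate))
                        coh.missing[v.key] = np.sort(
                            rng.choice(coh.n, size=n_miss, replace=False)
                        )
    variants.sort(key=lambda v: (int(v.chrom), v.pos, v.ref, v.alt))
    return StudyData(case=case, control=control, variants=variants,
                     gene_models=dict(models))


def simulate_pedigree(
    cfg: PedigreeConfig,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    family_id: str = "FAM1",
) -> Pedigree:
    """One autosomal-dominant family segregating a founder variant.

    The variant enters through one founder; each meiosis transmits it with
    probability 0.5.  Affection is penetrance for carriers and the
    phenocopy rate for non-carriers; ages are uniform integers on
    [age_min, age_max] so the adult (>= 25 y) gate is exercised.  All
    members are genotyped and phenotyped.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    people: list = []
    counter = [0]

    def affected_for(carrier: bool) -> str:
        p = cfg.penetrance if carrier else cfg.phenocopy_rate
        return "yes" if rng.random() < p else "no"

    def new_person(father, mother, carrier, sex=None) -> Individual:
        counter[0] += 1
        ind = Individual(
            id=f"{family_id}_{counter[0]}",
            father_id=father,
            mother_id=mother,
            sex=sex or ("male" if rng.random() < 0.5 else "female"),
            affected=affected_for(carrier),
            age=int(rng.integers(cfg.age_min, cfg.age_max + 1)),
            genotype="carrier" if carrier else "non_carrier",
        )
        people.append(ind)
        return ind

    founder = new_person(None, None, carrier=True, sex="male")
    spouse = new_person(None, None, carrier=False, sex="female")
    current = [(founder, spouse)]
    for _ in range(cfg.n_generations - 1):
        nxt = []
        for father, mother in current:
            carrier_parent = father if father.genotype == "carrier" else mother
            n_children = max(1, int(rng.poisson(cfg.mean_offspring)))
            for _ in range(n_children):
                inherits = (
                    carrier_parent.genotype == "carrier" and rng.random() < 0.5
                )
                child = new_person(father.id, mother.id, carrier=inherits)
                partner_sex = "female" if child.sex == "male" else "male"
                partner = new_person(None, None, carrier=False, sex=partner_sex)
                couple = (
                    (child, partner) if child.sex == "male" else (partner, child)
                )
                nxt.append(couple)
        current = nxt
    return Pedigree(family_id=family_id, individuals=people)


def simulate_pedigrees(cfg: PedigreeConfig, n: int, seed: int = 0) -> list:
    """Independent families (LOD scores add across them)."""
    rng = np.random.default_rng(seed)
    return [
        simulate_pedigree(cfg, rng=rng, family_id=f"FAM{i + 1}")
        for i in range(n)
    ]
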