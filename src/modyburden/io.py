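"""Readers and writers for the framework's on-disk formats.

* Gene models: one JSON document per study (exons genomic 1-based closed in
  transcription order; domains in amino-acid coordinates; domains may
  alternatively be supplied as BED, 0-based half-open, converted on read).
* Cohorts: VCF with the INFO keys below and per-sample GT/DP/GQ/AD.
* Pedigrees: 6-column PED plus a phenotype sidecar TSV with columns
  ``id``, ``affected`` (yes/no/unknown), ``age`` and ``genotype``
  (carrier/non_carrier/unknown).

INFO keys written and understood: ``GENE``, ``CSQ`` (consequence term),
``REVEL``, ``PROTEIN_POS``, ``FS``, ``QD``, ``ReadPosRankSum``,
``MQRankSum``, ``MQ``, ``AAscore``, flags ``LCR`` (low-complexity region)
and ``LOWCOV`` (low-coverage region), and gnomAD-style per-population
``AC_<pop>`` / ``AN_<pop>`` pairs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from .burden import CohortGenotypes
from .cosegregation import Individual, Pedigree
from .gene_annotation import GeneModel, VariantRecord

_SITE_METRIC_KEYS = ("FS", "QD", "ReadPosRankSum", "MQRankSum", "MQ", "AAscore")


# -- gene models ------------------------------------------------------------

def write_gene_models_json(models: dict, path) -> None:
    doc = []
    for m in models.values():
        doc.append(
            {
                "gene_id": m.gene_id,
                "transcript_id": m.transcript_id,
                "chrom": m.chrom,
                "strand": m.strand,
                "exons": [list(e) for e in m.exons],
                "cds_start": m.cds_start,
                "cds_end": m.cds_end,
                "domains": [list(d) for d in m.domains],
            }
        )
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_gene_models_json(path) -> dict:
    doc = json.loads(Path(path).read_text())
    models = {}
    for g in doc:
        models[g["gene_id"]] = GeneModel(
            gene_id=g["gene_id"],
            transcript_id=g["transcript_id"],
            chrom=g["chrom"],
            strand=g["strand"],
            exons=tuple(tuple(e) for e in g["exons"]),
            cds_start=g["cds_start"],
            cds_end=g["cds_end"],
            domains=tuple(tuple(d) for d in g.get("domains", [])),
        )
    return models


def read_domains_bed(path) -> list:
    """Domains from BED (0-based half-open) to 1-based closed aa intervals."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        start, end = int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else "domain"
        out.append((name, start + 1, end))
    return out


# -- cohort VCF -------------------------------------------------------------

def _vcf_header(variants, n_samples: int, sample_prefix: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in sorted({v.chrom for v in variants}, key=str):
        header.contigs.add(chrom, length=2_000_000_000)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("CSQ", 1, "String", "Consequence term")
    header.info.add("REVEL", 1, "Float", "REVEL ensemble missense score")
    header.info.add("PROTEIN_POS", 1, "Integer", "1-based amino-acid position")
    header.info.add("FS", 1, "Float", "Phred-scaled strand-bias Fisher p")
    header.info.add("QD", 1, "Float", "Variant confidence / depth")
    header.info.add("ReadPosRankSum", 1, "Float", "Read position rank-sum Z")
    header.info.add("MQRankSum", 1, "Float", "Mapping quality rank-sum Z")
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.info.add("AAscore", 1, "Float", "Graphtyper true-positive probability")
    header.info.add("LCR", 0, "Flag", "Low-complexity region")
    header.info.add("LOWCOV", 0, "Flag", "Low-coverage region")
    pops = sorted({p for v in variants for p in v.pop_ac})
    for pop in pops:
        header.info.add(f"AC_{pop}", 1, "Integer", f"Allele count, {pop}")
        header.info.add(f"AN_{pop}", 1, "Integer", f"Allele number, {pop}")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    for i in range(n_samples):
        header.add_sample(f"{sample_prefix}{i:06d}")
    return header


def write_cohort_vcf(
    variants, genotypes: CohortGenotypes, path, sample_prefix: str = "S"
) -> None:
    """Write one cohort to an uncompressed VCF (all samples, sparse alt
    genotypes; only carrier genotypes receive DP/GQ/AD)."""
    header = _vcf_header(variants, genotypes.n, sample_prefix)
    sample_names = list(header.samples)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in variants:
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            if v.gene is not None:
                rec.info["GENE"] = v.gene
            rec.info["CSQ"] = v.consequence
            if v.revel is not None:
                rec.info["REVEL"] = v.revel
            if v.protein_pos is not None:
                rec.info["PROTEIN_POS"] = v.protein_pos
            for k in _SITE_METRIC_KEYS:
                if k in v.site_metrics and v.site_metrics[k] is not None:
                    rec.info[k] = v.site_metrics[k]
            if v.flags.get("low_complexity"):
                rec.info["LCR"] = True
            if v.flags.get("low_coverage_region"):
                rec.info["LOWCOV"] = True
            for pop, ac in v.pop_ac.items():
                rec.info[f"AC_{pop}"] = ac
                rec.info[f"AN_{pop}"] = v.pop_an[pop]
            metrics = {
                idx: (dp, gq, adr, ada)
                for idx, dp, gq, adr, ada in genotypes.metrics.get(v.key, [])
            }
            carriers = set(int(i) for i in genotypes.carriers.get(v.key, ()))
            missing = set(int(i) for i in genotypes.missing.get(v.key, ()))
            for i, name in enumerate(sample_names):
                s = rec.samples[name]
                if i in missing:
                    s["GT"] = (None, None)
                elif i in carriers:
                    s["GT"] = (0, 1)
                    if i in metrics:
                        dp, gq, adr, ada = metrics[i]
                        s["DP"] = dp
                        s["GQ"] = gq
                        s["AD"] = (adr, ada)
                else:
                    s["GT"] = (0, 0)
            vcf.write(rec)


def read_cohort_vcf(path) -> tuple:
    """Read a cohort VCF back into ``(variants, CohortGenotypes)``."""
    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        genotypes = CohortGenotypes(n=len(samples), sample_ids=samples)
        for rec in vcf:
            info = rec.info
            pop_ac, pop_an = {}, {}
            for k in info.keys():
                if k.startswith("AC_"):
                    pop = k[3:]
                    pop_ac[pop] = int(info[k])
                    pop_an[pop] = int(info.get(f"AN_{pop}", 0))
            consequence = info.get("CSQ", "other")
            revel = info.get("REVEL")
            v = VariantRecord(
                chrom=rec.contig,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alts[0],
                consequence=consequence,
                gene=info.get("GENE"),
                revel=(
                    float(revel)
                    if revel is not None and consequence == "missense"
                    else None
                ),
                protein_pos=(
                    int(info["PROTEIN_POS"]) if "PROTEIN_POS" in info else None
                ),
                site_metrics={
                    k: float(info[k]) for k in _SITE_METRIC_KEYS if k in info
                },
                flags={
                    "low_complexity": "LCR" in info,
                    "low_coverage_region": "LOWCOV" in info,
                },
                pop_ac=pop_ac,
                pop_an=pop_an,
            )
            variants.append(v)
            carriers, missing, metrics = [], [], []
            for i, name in enumerate(samples):
                s = rec.samples[name]
                gt = s.get("GT")
                if gt is None or gt[0] is None:
                    missing.append(i)
                elif any(a == 1 for a in gt if a is not None):
                    carriers.append(i)
                    dp, gq, ad = s.get("DP"), s.get("GQ"), s.get("AD")
                    if dp is not None and gq is not None and ad is not None:
                        metrics.append((i, int(dp), int(gq), int(ad[0]), int(ad[1])))
            genotypes.carriers[v.key] = np.array(carriers, dtype=np.int64)
            genotypes.missing[v.key] = np.array(missing, dtype=np.int64)
            genotypes.metrics[v.key] = metrics
    return variants, genotypes


# -- pedigrees --------------------------------------------------------------

_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}
_PED_TO_SEX = {"1": "male", "2": "female"}


def write_ped(pedigrees, ped_path, pheno_path) -> None:
    """6-column PED plus phenotype sidecar TSV (id, affected, age, genotype)."""
    ped_lines, pheno_lines = [], ["id\taffected\tage\tgenotype"]
    for ped in pedigrees:
        for ind in ped.individuals:
            aff = {"yes": "2", "no": "1", "unknown": "0"}[ind.affected]
            ped_lines.append(
                "\t".join(
                    [
                        ped.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_TO_PED[ind.sex],
                        aff,
                    ]
                )
            )
            age = "" if ind.age is None else str(int(ind.age))
            pheno_lines.append(f"{ind.id}\t{ind.affected}\t{age}\t{ind.genotype}")
    Path(ped_path).write_text("\n".join(ped_lines) + "\n")
    Path(pheno_path).write_text("\n".join(pheno_lines) + "\n")


def read_ped(ped_path, pheno_path: Optional[str] = None) -> list:
    """Read PED (+ optional phenotype sidecar) into Pedigree objects.

    The sidecar's affection column overrides the PED phenotype column, and
    supplies age and carrier genotype.
    """
    pheno = {}
    if pheno_path is not None:
        lines = Path(pheno_path).read_text().splitlines()
        header = lines[0].rstrip("\n").split("\t")
        for line in lines[1:]:
            if not line.strip():
                continue
            row = dict(zip(header, line.split("\t")))
            pheno[row["id"]] = row
    families: dict = {}
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fam, iid, fid, mid, sex, aff = line.split("\t")[:6]
        side = pheno.get(iid, {})
        affected = side.get(
            "affected", {"2": "yes", "1": "no"}.get(aff, "unknown")
        )
        age_s = side.get("age", "")
        ind = Individual(
            id=iid,
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
            sex=_PED_TO_SEX.get(sex, "unknown"),
            affected=affected,
            age=float(age_s) if age_s not in ("", None) else None,
            genotype=side.get("genotype", "unknown"),
        )
        families.setdefault(fam, []).append(ind)
    return [Pedigree(family_id=f, individuals=m) for f, m in families.items()]
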