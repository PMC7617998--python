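"""End-to-end orchestration: simulate -> QC -> burden -> co-segregation ->
frequency screen -> power grid, with a run manifest.

``qc_study`` applies the full QC cascade to an in-memory study:

1. sample-level missingness filter per cohort (strict > 2% removed);
2. site-level QC per cohort under its mode profile;
3. genotype-level QC on carrier genotypes (failing carriers are dropped and
   counted as missing calls);
4. per-variant call-rate filter (strict > 2% missing removed);
5. cross-cohort harmonization: a variant failing in either cohort is
   removed from both.

``run_pipeline`` drives all stages from a plain-text YAML configuration and
writes TSV outputs plus a JSON manifest (resolved configuration, seed,
per-stage row counts, input digests).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden import (
    BurdenConfig,
    CohortGenotypes,
    StudyData,
    VariantClass,
    primary_grid,
    results_to_frame,
    run_suite,
    sensitivity_grid,
)
from .cosegregation import CosegConfig, coseg_tests, lod_score, pedigree_eligible
from .frequency_power import (
    CredibilityConfig,
    PowerConfig,
    burden_power,
    frequency_screen,
)
from . import io as mio
from .synthetic_data import (
    PedigreeConfig,
    SimulationConfig,
    default_study_config,
    simulate_cohorts,
    simulate_gene_models,
    simulate_pedigrees,
)
from .variant_qc import QCThresholds, genotype_qc, site_qc

logger = logging.getLogger("modyburden")


# -- QC cascade -------------------------------------------------------------

def _sample_missing_fractions(g: CohortGenotypes, n_variants: int) -> np.ndarray:
    counts = np.zeros(g.n, dtype=np.int64)
    for idx in g.missing.values():
        counts[np.asarray(idx, dtype=np.int64)] += 1
    return counts / max(1, n_variants)


def qc_study(
    study: StudyData,
    thresholds: QCThresholds = QCThresholds(),
    case_mode: str = "panel",
    control_mode: str = "wgs",
) -> tuple:
    """Apply the QC cascade; returns ``(filtered_study, report, removal_counts)``.

    ``report`` is a per-variant DataFrame with the QC status and reasons in
    each cohort and the harmonized verdict; ``removal_counts`` logs how many
    variants/samples each filter removed (mirrored to the logger).
    """
    removal = {}
    cohorts = {"case": (study.case, case_mode), "control": (study.control, control_mode)}
    n_variants = len(study.variants)

    # 1. sample missingness (per cohort)
    retained = {}
    for label, (g, _) in cohorts.items():
        frac = _sample_missing_fractions(g, n_variants)
        keep = frac <= thresholds.sample_missingness_max
        retained[label] = keep
        removal[f"samples_removed_{label}"] = int((~keep).sum())

    # 2-3. site and genotype QC
    site_results = {}
    dropped_genotypes = {"case": 0, "control": 0}
    missing_extra = {"case": {}, "control": {}}
    for label, (g, mode) in cohorts.items():
        keep_mask = retained[label]
        for v in study.variants:
            site_results[(label, v.key)] = site_qc(v, thresholds, mode)
            kept_carriers = []
            failed = 0
            metrics = {
                idx: (dp, gq, adr, ada)
                for idx, dp, gq, adr, ada in g.metrics.get(v.key, [])
            }
            for idx in np.asarray(g.carriers.get(v.key, ()), dtype=np.int64):
                idx = int(idx)
                if not keep_mask[idx]:
                    continue
                m = metrics.get(idx)
                if m is not None:
                    r = genotype_qc(m[0], m[1], m[2], m[3], thresholds, mode)
                    if not r.passed:
                        failed += 1
                        continue
                kept_carriers.append(idx)
            dropped_genotypes[label] += failed
            g.carriers[v.key] = np.array(kept_carriers, dtype=np.int64)
            missing_extra[label][v.key] = failed
    removal["genotypes_removed_case"] = dropped_genotypes["case"]
    removal["genotypes_removed_control"] = dropped_genotypes["control"]

    # rebuild cohorts restricted to retained samples
    filtered = {}
    for label, (g, _) in cohorts.items():
        keep_mask = retained[label]
        n_keep = int(keep_mask.sum())
        g2 = CohortGenotypes(n=n_keep, sample_ids=None)
        for v in study.variants:
            g2.carriers[v.key] = g.carriers.get(v.key, np.array([], dtype=np.int64))
            miss = np.asarray(g.missing.get(v.key, ()), dtype=np.int64)
            g2.missing[v.key] = miss[keep_mask[miss]] if miss.size else miss
            g2.metrics[v.key] = g.metrics.get(v.key, [])
        filtered[label] = g2

    # 4. per-variant call-rate filter
    callrate_fail = {"case": set(), "control": set()}
    for label, g2 in filtered.items():
        for v in study.variants:
            n_missing = len(g2.missing.get(v.key, ())) + missing_extra[label][v.key]
            if n_missing / g2.n > thresholds.genotype_missingness_max:
                callrate_fail[label].add(v.key)
    removal["variants_failing_call_rate"] = len(
        callrate_fail["case"] | callrate_fail["control"]
    )

    # 5. harmonization
    rows = []
    kept_keys = []
    for v in study.variants:
        reasons = {}
        for label in ("case", "control"):
            r = site_results[(label, v.key)]
            rs = list(r.reasons)
            if v.key in callrate_fail[label]:
                rs.append("call_rate")
            reasons[label] = rs
        ok = not reasons["case"] and not reasons["control"]
        if ok:
            kept_keys.append(v.key)
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "case_status": "pass" if not reasons["case"] else "fail",
                "case_reasons": ";".join(sorted(reasons["case"])),
                "control_status": "pass" if not reasons["control"] else "fail",
                "control_reasons": ";".join(sorted(reasons["control"])),
                "harmonized": "kept" if ok else "removed",
            }
        )
    removal["variants_removed_harmonized"] = n_variants - len(kept_keys)
    for k, n in sorted(removal.items()):
        logger.info("qc: %s = %d", k, n)

    kept = set(kept_keys)
    variants = [v for v in study.variants if v.key in kept]
    for g2 in filtered.values():
        for drop in set(g2.carriers) - kept:
            g2.carriers.pop(drop, None)
            g2.missing.pop(drop, None)
            g2.metrics.pop(drop, None)
    out = StudyData(
        case=filtered["case"],
        control=filtered["control"],
        variants=variants,
        gene_models=study.gene_models,
    )
    return out, pd.DataFrame(rows), removal


# -- pipeline ---------------------------------------------------------------

DEFAULT_PIPELINE_CONFIG = {
    "n_case": 600,
    "n_control": 4000,
    "seed": 1,
    "case_mode": "panel",
    "control_mode": "wgs",
    "grid": "full",  # primary | full
    "freq_source": "reference",  # reference | control
    "pedigrees": {"n_families": 3, "penetrance": 0.9, "phenocopy_rate": 0.02},
    "credibility": {
        "prevalence": 248e-6,
        "penetrance": 0.5,
        "max_allelic_contribution": 1.0,
        "max_genetic_contribution": 1.0,
    },
    "power": {
        "mafs": [5e-5, 1e-4, 2e-4],
        "odds_ratios": [5.0, 9.8, 14.5, 21.0],
        "n_reps": 2000,
        "alpha": 0.05,
    },
}


class PipelineError(RuntimeError):
    def __init__(self, message, exit_code=4):
        super().__init__(message)
        self.exit_code = exit_code


def load_config(path: Optional[str]) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_PIPELINE_CONFIG))  # deep copy
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise PipelineError(f"config file not found: {path}", exit_code=3)
        try:
            user = yaml.safe_load(p.read_text()) or {}
        except yaml.YAMLError as e:
            raise PipelineError(f"config does not parse: {e}", exit_code=2)
        if not isinstance(user, dict):
            raise PipelineError("config must be a mapping", exit_code=2)
        for k, v in user.items():
            if k not in cfg:
                raise PipelineError(f"unknown config key {k!r}", exit_code=2)
            if isinstance(cfg[k], dict) and isinstance(v, dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def build_grid(which: str) -> list:
    configs = primary_grid(genes=())
    if which == "full":
        for base in list(configs):
            configs.extend(sensitivity_grid(base))
    return configs


def run_pipeline(
    config_path: Optional[str] = None,
    out_dir: str = "pipeline_out",
    seed: Optional[int] = None,
) -> Path:
    """Run every stage; returns the output directory.

    Outputs: ``gene_models.json``, ``cases.vcf``, ``controls.vcf``,
    ``families.ped``/``families_pheno.tsv``, ``qc_report.tsv``,
    ``burden.tsv``, ``coseg.tsv``, ``frequency_screen.tsv``,
    ``power_grid.tsv`` and ``manifest.json``.
    """
    t0 = time.time()
    cfg = load_config(config_path)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = {}

    # simulate
    sim_cfg = default_study_config(
        n_case=int(cfg["n_case"]), n_control=int(cfg["n_control"]),
        seed=int(cfg["seed"]),
    )
    models = simulate_gene_models(sim_cfg)
    study = simulate_cohorts(models, sim_cfg)
    mio.write_gene_models_json(models, out / "gene_models.json")
    mio.write_cohort_vcf(study.variants, study.case, out / "cases.vcf", "CASE")
    mio.write_cohort_vcf(
        study.variants, study.control, out / "controls.vcf", "CTRL"
    )
    ped_cfg = PedigreeConfig(
        penetrance=float(cfg["pedigrees"].get("penetrance", 0.9)),
        phenocopy_rate=float(cfg["pedigrees"].get("phenocopy_rate", 0.02)),
    )
    peds = simulate_pedigrees(
        ped_cfg, int(cfg["pedigrees"].get("n_families", 3)),
        seed=int(cfg["seed"]) + 1,
    )
    mio.write_ped(peds, out / "families.ped", out / "families_pheno.tsv")
    counts["variants_simulated"] = len(study.variants)

    # qc (round-trip through the VCFs so the readers are on the real path)
    case_variants, case_gt = mio.read_cohort_vcf(out / "cases.vcf")
    ctrl_variants, ctrl_gt = mio.read_cohort_vcf(out / "controls.vcf")
    study2 = StudyData(
        case=case_gt, control=ctrl_gt, variants=case_variants,
        gene_models=models,
    )
    study_qc, report, removal = qc_study(
        study2,
        case_mode=cfg["case_mode"],
        control_mode=cfg["control_mode"],
    )
    report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    counts["variants_after_qc"] = len(study_qc.variants)
    counts.update(removal)

    # burden
    from .burden import control_allele_frequencies, reference_allele_frequencies
    af_fn = (
        reference_allele_frequencies
        if cfg.get("freq_source", "reference") == "reference"
        else control_allele_frequencies
    )
    results = run_suite(study_qc, build_grid(cfg["grid"]), control_af=af_fn(study_qc))
    bdf = results_to_frame(results)
    bdf.to_csv(out / "burden.tsv", sep="\t", index=False)
    counts["burden_rows"] = len(bdf)

    # co-segregation
    ped_in = mio.read_ped(out / "families.ped", out / "families_pheno.tsv")
    coseg_cfg = CosegConfig()
    rows = []
    for ped in ped_in:
        res = coseg_tests(ped, coseg_cfg)
        rows.append(
            {
                "family": ped.family_id,
                "eligible": pedigree_eligible(ped, 0.0, coseg_cfg),
                "lod": res.lod,
                "coseg_proportion": (
                    res.n_affected_carriers / res.n_affected_genotyped
                    if res.n_affected_genotyped else float("nan")
                ),
                "coseg_k": res.n_affected_carriers,
                "coseg_n": res.n_affected_genotyped,
                "coseg_p": res.coseg_p,
                "nonpenetrance_proportion": (
                    res.n_unaffected_carriers_age_ok
                    / res.n_unaffected_genotyped_age_ok
                    if res.n_unaffected_genotyped_age_ok else float("nan")
                ),
                "nonpenetrance_k": res.n_unaffected_carriers_age_ok,
                "nonpenetrance_n": res.n_unaffected_genotyped_age_ok,
                "nonpenetrance_p": res.nonpenetrance_p,
            }
        )
    cdf = pd.DataFrame(rows)
    cdf.to_csv(out / "coseg.tsv", sep="\t", index=False)
    counts["coseg_rows"] = len(cdf)

    # frequency screen
    cred = CredibilityConfig(**cfg["credibility"])
    fdf = frequency_screen(credibility=cred)
    fdf.to_csv(out / "frequency_screen.tsv", sep="\t", index=False)
    counts["frequency_rows"] = len(fdf)

    # power grid
    prows = []
    pw = cfg["power"]
    for maf in pw["mafs"]:
        for orr in pw["odds_ratios"]:
            pc = PowerConfig(
                n_case=int(cfg["n_case"]) if cfg.get("power_at_pipeline_n") else 2571,
                n_control=(
                    int(cfg["n_control"]) if cfg.get("power_at_pipeline_n")
                    else 155501
                ),
                maf=float(maf),
                odds_ratio=float(orr),
                alpha=float(pw.get("alpha", 0.05)),
                n_reps=int(pw.get("n_reps", 2000)),
                seed=int(cfg["seed"]) + 2,
            )
            prows.append(
                {
                    "maf": maf,
                    "odds_ratio": orr,
                    "n_case": pc.n_case,
                    "n_control": pc.n_control,
                    "alpha": pc.alpha,
                    "power": burden_power(pc),
                }
            )
    pdf = pd.DataFrame(prows)
    pdf.to_csv(out / "power_grid.tsv", sep="\t", index=False)
    counts["power_rows"] = len(pdf)

    manifest = {
        "tool": "modyburden",
        "version": __version__,
        "config": cfg,
        "seed": cfg["seed"],
        "inputs": {
            name: _digest(out / name)
            for name in ("gene_models.json", "cases.vcf", "controls.vcf",
                         "families.ped", "families_pheno.tsv")
        },
        "row_counts": counts,
        "started": t0,
        "finished": time.time(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return out
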