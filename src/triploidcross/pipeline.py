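"""End-to-end orchestration: load/simulate -> kinships -> fits -> reports.

A single run configuration (YAML/JSON-able dict) drives the whole study:
either a simulation block or input paths (VCF + pedigree/phenotype CSVs),
the traits and model variants to fit, and the evaluation stages to run.
Every output CSV carries the configuration hash so runs are content
addressed; a failure in one trait is isolated and recorded in the manifest
without aborting the remaining traits.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .crosses import (cross_summaries, estimate_values,
                      genotypic_correlations, min_progeny_table,
                      pca_cross_means)
from .genotypes import read_parent_vcf
from .kinship import KinshipSet, build_kinship_set
from .models import build_model, heritability
from .prediction import loo_cross_validation
from .simulate import SimulationConfig, simulate_dataset
from .tables import StudyTables, load_study_tables
from .traits import trait_direction

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one input source)."""

    output_dir: str
    seed: int = 0
    simulation: dict | None = None
    vcf_path: str | None = None
    pedigree_path: str | None = None
    phenotype_path: str | None = None
    traits: list[str] | None = None
    variants: list[str] = field(default_factory=lambda: ["PHENO"])
    cv_scenarios: list[str] = field(default_factory=list)
    cv_refit: bool = False
    min_progeny: int = 16
    probability: float = 0.9
    check_control: str = "Cavendish"
    column_map: dict | None = None

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_files = self.pedigree_path is not None
        if has_sim == has_files:
            raise ValueError(
                "exactly one of a simulation block or input paths is required"
            )
        genomic = any(v != "PHENO" for v in self.variants)
        if genomic and not has_sim and self.vcf_path is None:
            raise ValueError(
                f"variants {self.variants} need genomic information but no "
                "vcf_path was given"
            )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sim = SimulationConfig(**{**config.simulation, "seed": config.seed})
        data = simulate_dataset(sim)
        return data.genotypes, data.tables, data
    tables = load_study_tables(config.pedigree_path, config.phenotype_path,
                               column_map=config.column_map)
    geno = None
    if config.vcf_path:
        parents = sorted(set(tables.pedigree["parent2x_id"])
                         | set(tables.pedigree["parent4x_id"]))
        geno = read_parent_vcf(config.vcf_path, keep_parents=parents)
    return geno, tables, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute all requested stages; return the run manifest."""
    os.makedirs(config.output_dir, exist_ok=True)
    chash = config.hash()
    manifest: dict = {"config_hash": chash, "seed": config.seed,
                      "stages": {}, "artifacts": {}, "errors": {}}

    def save(name: str, df: pd.DataFrame) -> str:
        path = os.path.join(config.output_dir, f"{name}.csv")
        with open(path, "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            df.to_csv(fh)
        manifest["artifacts"][name] = path
        return path

    geno, tables, _sim = _load_inputs(config)
    traits = config.traits or tables.traits
    genomic = any(v != "PHENO" for v in config.variants)

    kin: KinshipSet | None = None
    if genomic or config.cv_scenarios and any(
            v != "PHENO" for v in config.variants):
        crosses = list(zip(tables.pedigree["parent2x_id"],
                           tables.pedigree["parent4x_id"]))
        kin = build_kinship_set(geno, sorted(set(crosses)))
        manifest["stages"]["kinship"] = "done"
    else:
        manifest["stages"]["kinship"] = "skipped"

    h2_rows, values_by_trait, yref = [], {}, {}
    for trait in traits:
        try:
            fits = {}
            for variant in config.variants:
                bundle = build_model(variant, tables, trait, kin)
                fit = bundle.fit()
                fits[variant] = (bundle, fit)
                h2_rows.append(heritability(fit, bundle).as_series())
            bundle, fit = fits.get("PHENO", next(iter(fits.values())))
            vals = estimate_values(fit, bundle)
            values_by_trait[trait] = vals
            ctl = vals.table[vals.table["type"] == "control"]
            if config.check_control in ctl.index:
                yref[trait] = float(ctl.loc[config.check_control, "ytilde"])
            cs_bundle = build_model(bundle.variant, tables, trait, kin,
                                    cross_specific_variance=True,
                                    min_progeny=config.min_progeny)
            cs_fit = cs_bundle.fit()
            summ = cross_summaries(vals, cs_fit, cs_bundle,
                                   min_progeny=config.min_progeny)
            save(f"cross_summary_{trait}", summ.table)
            try:
                direction = trait_direction(trait)
            except KeyError:  # trait outside the catalog: no ideotype
                direction = "none"
            if trait in yref and direction != "none":
                save(f"nmin_{trait}",
                     min_progeny_table(summ, yref[trait],
                                       p=config.probability))
            manifest["stages"][f"fit:{trait}"] = "done"
        except Exception as exc:  # per-trait isolation
            log.exception("trait %s failed", trait)
            manifest["stages"][f"fit:{trait}"] = "failed"
            manifest["errors"][trait] = str(exc)

    if h2_rows:
        save("heritability", pd.DataFrame(h2_rows))
    if values_by_trait:
        yhat = pd.DataFrame({
            t: v.breed()["yhat"] for t, v in values_by_trait.items()})
        save("clonal_values", yhat)
        if len(values_by_trait) >= 2:
            r, p, kept = genotypic_correlations(yhat)
            save("genotypic_correlations", r)
            save("genotypic_correlations_retained", kept)
        means = pd.DataFrame({
            t: pd.concat([
                v.breed().groupby(["parent2x_id", "parent4x_id"])["yhat"]
                 .mean(),
            ]) for t, v in values_by_trait.items()})
        if means.notna().all().all() and len(means) >= 3:
            pca = pca_cross_means(means.dropna())
            save("pca_scores", pca.scores)
            save("pca_explained", pca.explained.to_frame("percent"))

    for scenario in config.cv_scenarios:
        for variant in config.variants:
            for trait in traits:
                key = f"cv:{scenario}:{variant}:{trait}"
                try:
                    rep = loo_cross_validation(
                        tables, trait, variant=variant, scenario=scenario,
                        kinships=kin, refit=config.cv_refit)
                    save(f"cv_{scenario}_{variant}_{trait}", rep.folds)
                    manifest["stages"][key] = (
                        f"r={rep.predictive_ability:.3f}")
                except Exception as exc:
                    manifest["stages"][key] = "failed"
                    manifest["errors"][key] = str(exc)

    manifest_path = os.path.join(config.output_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    manifest["artifacts"]["manifest"] = manifest_path
    return manifest
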