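"""End-to-end analysis pipeline and run configuration.

Mirrors the flow of the underlying study: survey-wave selection and
imputation -> subscale scoring -> inverse normal transform -> familial
correlation table -> univariate A/D/H/E fits with nested likelihood-ratio
tests -> bivariate fit of the two subscales.  Every table is written both
as TSV (human) and inside a results JSON (machine); the log records the
number of individuals retained at each stage, and the seed and config are
echoed into the results so each number is reproducible from inputs + config
alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bivariate, correlations, scales, varcomp
from .pedigree import PedigreeGraph, load_pedigree

logger = logging.getLogger(__name__)

RESULTS_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    pedigree_path: str = ""
    phenotype_path: str = ""          # wide phenotype CSV
    items_path: str = ""              # optional long item CSV (scored if given)
    output_dir: str = "pedvar_out"
    traits: tuple = ("na", "si", "naxsi")
    model: str = "ADHE"
    reduced_models: tuple = ("ADE", "AHE", "AE")
    transform: bool = True
    cutoff: int = 3
    n_boot: int = 500
    bivariate_traits: tuple = ("na", "si")
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for key in ("traits", "reduced_models", "bivariate_traits"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def score_items_table(items: pd.DataFrame, cutoff: int = 3) -> pd.DataFrame:
    """Wave selection + cross-wave imputation + scoring for a long item table."""
    by_person = scales.waves_from_long(items)
    records = [
        scales.score_individual(waves, cutoff=cutoff)
        for waves in by_person.values()
    ]
    return scales.phenotypes_to_frame(records)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the result bundle."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "seed": config.seed,
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in asdict(config).items()},
        "stage_counts": {},
    }

    stage = "load_pedigree"
    try:
        peds = load_pedigree(config.pedigree_path)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    n_members = sum(len(p) for p in peds.values())
    results["stage_counts"]["pedigree_members"] = n_members
    logger.info("loaded %d families, %d members", len(peds), n_members)

    stage = "phenotypes"
    try:
        if config.items_path:
            items = pd.read_csv(config.items_path)
            phenos = score_items_table(items, cutoff=config.cutoff)
            ages = pd.read_csv(config.phenotype_path) if config.phenotype_path else None
            if ages is not None and "age" in ages.columns:
                phenos = phenos.drop(columns=["age", "sex"]).merge(
                    ages[["individual_id", "age", "sex"]], on="individual_id",
                    how="left",
                )
        else:
            phenos = pd.read_csv(config.phenotype_path)
        phenos["individual_id"] = phenos["individual_id"].astype(str)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    ped_ids = {iid for p in peds.values() for iid in p.members}
    phenos = phenos[phenos["individual_id"].isin(ped_ids)]
    if phenos.empty:
        raise PipelineError(
            stage, "no phenotyped individuals overlap the pedigree ids"
        )
    for t in config.traits:
        if t in phenos.columns:
            results["stage_counts"][f"n_{t}"] = int(phenos[t].notna().sum())
    phenos.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    logger.info("phenotypes retained: %d rows", len(phenos))

    stage = "correlations"
    try:
        corr = correlations.correlation_table(
            peds, phenos,
            measures=tuple(t for t in config.traits if t in phenos.columns),
            n_boot=config.n_boot, seed=config.seed,
        )
        corr.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
        results["correlations"] = corr.to_dict(orient="records")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "univariate_fits"
    full_spec = varcomp.ComponentSpec.parse(config.model)
    results["univariate"] = {}
    lrt_rows = []
    try:
        for trait in config.traits:
            if trait not in phenos.columns:
                continue
            ds = varcomp.build_dataset(
                peds, phenos, trait, transform=config.transform, spec=full_spec
            )
            full = varcomp.fit_univariate(ds, full_spec)
            entry = {"full": full.summary(), "reduced": {}}
            for red in config.reduced_models:
                rspec = varcomp.ComponentSpec.parse(red)
                rfit = varcomp.fit_univariate(ds.restrict(rspec), rspec)
                lrt = varcomp.compare_fits(full, rfit, mixture=True)
                entry["reduced"][red] = rfit.summary()
                lrt_rows.append(
                    {
                        "trait": trait, "full": config.model, "reduced": red,
                        "loglik_full": full.loglik, "loglik_reduced": rfit.loglik,
                        "chi2": lrt.chi2, "delta_df": lrt.delta_df,
                        "p_value": lrt.p_value,
                        "p_value_mixture": lrt.p_value_mixture,
                    }
                )
            results["univariate"][trait] = entry
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    pd.DataFrame(lrt_rows).to_csv(outdir / "lrt.tsv", sep="\t", index=False)
    results["lrt"] = lrt_rows
    _univariate_tsv(results["univariate"]).to_csv(
        outdir / "univariate.tsv", sep="\t", index=False
    )

    stage = "bivariate_fit"
    t1, t2 = config.bivariate_traits
    if t1 in phenos.columns and t2 in phenos.columns:
        try:
            blocks = bivariate.blocks_from_phenotypes(
                peds, phenos, (t1, t2), transform=config.transform
            )
            bds = bivariate.BivariateDataset(blocks, tuple(full_spec))
            bfit = bivariate.fit_bivariate(bds, full_spec)
            results["bivariate"] = bfit.summary()
            results["bivariate"]["r_se"] = bfit.r_se()
            pd.DataFrame(
                [
                    {
                        "component": c,
                        "var_trait1": bfit.C[c][0, 0],
                        "var_trait2": bfit.C[c][1, 1],
                        "covariance": bfit.C[c][0, 1],
                        "correlation": bfit.r[c],
                        "cov_share": bfit.cov_share[c],
                    }
                    for c in full_spec
                ]
            ).to_csv(outdir / "bivariate.tsv", sep="\t", index=False)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, default=_jsonable)
    logger.info("results written to %s", outdir)
    return results


def _univariate_tsv(uni: dict) -> pd.DataFrame:
    rows = []
    for trait, entry in uni.items():
        for model_name, summ in [("full", entry["full"])] + [
            (k, v) for k, v in entry["reduced"].items()
        ]:
            row = {"trait": trait, "model": summ["model"], "which": model_name,
                   "loglik": summ["loglik"],
                   "total_variance": summ["total_variance"],
                   "broad_h2": summ["broad_h2"], "broad_h2_se": summ["broad_h2_se"]}
            for c in "ADHE":
                row[f"sigma2_{c}"] = summ["sigma2"].get(c)
                row[f"se_{c}"] = summ["se"].get(c)
            rows.append(row)
    return pd.DataFrame(rows)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
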