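"""End-to-end analysis pipeline: QC -> relationship matrices -> per-trait
variance components (additive-only and additive+dominance) -> cross-validated
prediction accuracy, with delimited report tables and a run manifest.

The pipeline is the library counterpart of the numbered driver scripts under
``analysis/``: every step here is importable and deterministic given the
configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cv import cross_validate
from .genotype_io import (
    GenotypeMatrix,
    QCThresholds,
    apply_qc,
    read_plink,
)
from .relationship import build_grm_from_genotypes, stabilize
from .reml import build_fixed_design, fit_reml, variance_ratios

logger = logging.getLogger("merinogp")

__all__ = [
    "PipelineConfig",
    "descriptive_stats",
    "harmonize",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run (YAML-loadable)."""

    genotype_prefix: str
    phenotype_file: str
    traits: list[str]
    models: list[str] = field(default_factory=lambda: ["MAG", "MADG"])
    fixed_factors: list[str] = field(default_factory=lambda: ["sex", "herd"])
    qc: QCThresholds = field(default_factory=QCThresholds)
    ridge: float = 1e-6
    cv_k: int = 5
    cv_repeats: int = 2
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        qc = QCThresholds(**raw.pop("qc", {}))
        return cls(qc=qc, **raw)

    def digest(self) -> str:
        d = asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]


def descriptive_stats(pheno: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Per-trait n, mean, sample SD, CV(%) and SE of the mean.

    CV is reported uniformly as ``100 * SD / mean`` and SE as ``SD / sqrt(n)``
    over non-missing records.  Traits with fewer than 2 values are omitted
    with a warning.
    """
    rows = []
    for trait in traits:
        vals = pd.to_numeric(pheno[trait], errors="coerce").dropna()
        if len(vals) < 2:
            warnings.warn(f"trait {trait!r} has <2 values; omitted", stacklevel=2)
            continue
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        rows.append(
            {
                "trait": trait,
                "n": int(len(vals)),
                "mean": mean,
                "sd": sd,
                "cv_pct": 100.0 * sd / mean if mean != 0 else np.nan,
                "se": sd / np.sqrt(len(vals)),
            }
        )
    return pd.DataFrame(rows)


def harmonize(genos: GenotypeMatrix, pheno: pd.DataFrame):
    """Intersect genotyped and phenotyped individuals, ordering the phenotype
    table to the genotype rows.  Returns ``(genos, pheno, dropped_ids)``."""
    geno_ids = list(genos.ids)
    pheno_ids = set(pheno["individual_id"].astype(str))
    keep = [i for i, iid in enumerate(geno_ids) if str(iid) in pheno_ids]
    if not keep:
        raise ValueError("no overlap between genotyped and phenotyped individuals")
    dropped = sorted(
        set(map(str, geno_ids)).symmetric_difference(pheno_ids)
    )
    genos = genos.subset(rows=keep)
    pheno = (
        pheno.assign(individual_id=pheno["individual_id"].astype(str))
        .set_index("individual_id")
        .loc[[str(i) for i in genos.ids]]
        .reset_index()
    )
    if dropped:
        logger.info("harmonize: dropped %d unmatched ids", len(dropped))
    return genos, pheno, dropped


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write report tables under ``config.out_dir``.

    Outputs: ``qc_report.tsv``, ``descriptive_stats.tsv``,
    ``variance_components.tsv`` (per trait x model, with ratios),
    ``cv_accuracy.tsv`` and ``cv_cells.tsv``, plus ``manifest.json`` carrying
    the seed and a configuration hash.  A trait whose fit fails is logged and
    skipped; other traits are unaffected.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genos, markers, samples = read_plink(config.genotype_prefix)
    logger.info("read %d individuals x %d markers", genos.n_individuals, genos.n_markers)
    genos, markers, samples, qc_report = apply_qc(genos, markers, samples, config.qc)
    logger.info(
        "QC: %d markers, %d individuals retained",
        qc_report.n_markers_out, qc_report.n_individuals_out,
    )
    qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)

    pheno = pd.read_csv(config.phenotype_file, sep="\t", dtype={"individual_id": str})
    genos, pheno, _ = harmonize(genos, pheno)
    stats = descriptive_stats(pheno, config.traits)
    stats.to_csv(out / "descriptive_stats.tsv", sep="\t", index=False,
                 float_format="%.6g")

    freqs = markers["freq"].to_numpy()
    kin = {"additive": stabilize(build_grm_from_genotypes(genos, freqs, "additive"),
                                 config.ridge)}
    if any(m == "MADG" for m in config.models):
        kin["dominance"] = stabilize(
            build_grm_from_genotypes(genos, freqs, "dominance"), config.ridge
        )

    design = build_fixed_design(pheno, config.fixed_factors)
    vc_rows, cv_rows, cv_cells = [], [], []
    for trait in config.traits:
        y = pd.to_numeric(pheno[trait], errors="coerce").to_numpy()
        ok = np.isfinite(y)
        for model in config.models:
            terms = ("additive",) if model == "MAG" else ("additive", "dominance")
            sub_kin = {t: kin[t].values[np.ix_(ok, ok)] for t in terms}
            try:
                fit = fit_reml(y[ok], design.X[ok], sub_kin)
            except np.linalg.LinAlgError as exc:
                logger.error("%s/%s fit failed: %s", trait, model, exc)
                continue
            ratios = variance_ratios(fit)
            row = {
                "trait": trait, "model": model, "n": int(ok.sum()),
                "sigma2_a": fit.components["additive"],
                "se_a": fit.component_se["additive"],
                "sigma2_d": fit.components.get("dominance", np.nan),
                "se_d": fit.component_se.get("dominance", np.nan),
                "sigma2_e": fit.components["residual"],
                "se_e": fit.component_se["residual"],
                "h2": ratios.h2, "h2_se": ratios.h2_se,
                "d2": ratios.d2 if ratios.d2 is not None else np.nan,
                "converged": fit.converged, "iterations": fit.iterations,
            }
            vc_rows.append(row)

            res = cross_validate(
                y, design.X, kin, model=model, k=config.cv_k,
                repeats=config.cv_repeats, seed=config.seed,
            )
            cv_rows.append(
                {"trait": trait, "model": model,
                 "mean_accuracy": res.mean_accuracy, "se": res.se,
                 "n_cells": res.n_cells}
            )
            cells = res.cells.assign(trait=trait, model=model)
            cv_cells.append(cells)

    vc = pd.DataFrame(vc_rows)
    vc.to_csv(out / "variance_components.tsv", sep="\t", index=False,
              float_format="%.6g")
    cv_summary = pd.DataFrame(cv_rows)
    cv_summary.to_csv(out / "cv_accuracy.tsv", sep="\t", index=False,
                      float_format="%.6g")
    if cv_cells:
        pd.concat(cv_cells, ignore_index=True).to_csv(
            out / "cv_cells.tsv", sep="\t", index=False, float_format="%.6g"
        )

    manifest = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "n_individuals": int(genos.n_individuals),
        "n_markers": int(genos.n_markers),
        "ridge": config.ridge,
        "traits": config.traits,
        "models": config.models,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "qc_report": qc_report,
        "descriptive_stats": stats,
        "variance_components": vc,
        "cv_accuracy": cv_summary,
        "manifest": manifest,
    }
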