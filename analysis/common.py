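"""Shared paths and loaders for the numbered analysis drivers.

The drivers emulate the study workflow on a synthetic population with the
study's structure (498 half-sib offspring of 26 sires, 7 herds, two sexes)
and two traits of known architecture: a staple-length-like trait
(sigma2_a = 40, sigma2_e = 40; h2 = 0.5) and a fleece-extension-like trait
(sigma2_a = 0, sigma2_d = 22.29, sigma2_e = 8.07; dominance proportion 0.73).
"""

from pathlib import Path

import numpy as np
import pandas as pd

import merinogp as mg

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
FIXTURE = RESULTS / "sim" / "population"
SEED = 20201111

SL_LIKE = dict(sigma2_a=40.0, sigma2_d=0.0, sigma2_e=40.0,
               intercept=83.5, trait_name="SL_like")
FER_LIKE = dict(sigma2_a=0.0, sigma2_d=22.29, sigma2_e=8.07,
                intercept=19.5, trait_name="FER_like")

QC = mg.QCThresholds()  # call rate >= 95%, HWE p >= 1e-6, MAF >= 1%, mind <= 10%


def load_qc_data():
    """Fixture -> QC -> harmonised genotypes, phenotypes, marker frequencies."""
    genos, markers, samples = mg.read_plink(FIXTURE)
    genos, markers, samples, report = mg.apply_qc(genos, markers, samples, QC)
    pheno = pd.read_csv(f"{FIXTURE}.pheno.tsv", sep="\t",
                        dtype={"individual_id": str})
    genos, pheno, _ = mg.harmonize(genos, pheno)
    return genos, markers, samples, pheno, report


def kinships(genos, markers, ridge=1e-6):
    freqs = markers["freq"].to_numpy()
    G = mg.stabilize(mg.build_grm_from_genotypes(genos, freqs, "additive"), ridge)
    D = mg.stabilize(mg.build_grm_from_genotypes(genos, freqs, "dominance"), ridge)
    return G, D
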