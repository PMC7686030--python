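"""Simulate the study-structured population and write it as analysis input.

Generates 498 offspring of 26 sires over 7 herds (59% rams, ~10% full-sibs)
with 5,000 unlinked SNPs, plus two phenotypes: a staple-length-like additive
trait (h2 = 0.5) and a fleece-extension-like dominance trait (d2 = 0.73).
A little missingness is injected so the QC step has work to do.  Output is a
PLINK 1 triplet plus a delimited phenotype table under results/sim/.
"""

import numpy as np

import merinogp as mg
from common import FER_LIKE, FIXTURE, SEED, SL_LIKE


def main():
    rng = np.random.default_rng(SEED)
    sc = mg.SimScenario(seed=SEED, **SL_LIKE)
    genos, markers, samples = mg.simulate_founders_and_gametes(sc, rng)

    pheno, truth_sl = mg.simulate_phenotypes(genos, samples, sc, rng)
    fer, truth_fer = mg.simulate_phenotypes(
        genos, samples, mg.SimScenario(seed=SEED, **FER_LIKE), rng
    )
    pheno["FER_like"] = fer["FER_like"]

    genos_obs = mg.inject_missing(genos, 0.01, rng)
    # degrade a slice of the panel so the QC step has real work:
    # 50 markers drop below the 95% call-rate threshold and the last 20
    # are relabelled to the X chromosome
    doses = genos_obs.doses.copy()
    bad = rng.choice(genos.n_markers - 20, 50, replace=False)
    drop = rng.random((genos.n_individuals, 50)) < 0.08
    doses[:, bad] = np.where(drop, -1, doses[:, bad])
    genos_obs = mg.GenotypeMatrix(doses, doses == -1, genos_obs.ids)
    markers.loc[genos.n_markers - 20:, "chrom"] = "X"
    FIXTURE.parent.mkdir(parents=True, exist_ok=True)
    mg.export_fixture(FIXTURE, genos_obs, markers, samples, pheno)
    np.savetxt(f"{FIXTURE}.true_u_sl.txt", truth_sl.u)
    np.savetxt(f"{FIXTURE}.true_v_fer.txt", truth_fer.v)

    print(f"wrote {FIXTURE}.bed/.bim/.fam and {FIXTURE}.pheno.tsv")
    print(f"  {genos.n_individuals} individuals x {genos.n_markers} markers, "
          f"{samples['sire_id'].nunique()} sires, "
          f"{samples['herd'].nunique()} herds, "
          f"missing rate {genos_obs.missing.mean():.3%}")
    fam = samples.groupby(["sire_id", "dam_id"]).size()
    print(f"  full-sib individuals: {fam[fam > 1].sum() / len(samples):.1%}")
    print(f"  realized var(u) SL-like {truth_sl.realized['var_u']:.1f} "
          f"(target 40), var(v) FER-like {truth_fer.realized['var_v']:.1f} "
          f"(target 22.3)")


if __name__ == "__main__":
    main()
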