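import numpy as np
import pytest

import merinogp as mg


def polymorphic_grms(genos, ridge=1e-6):
    """G and D from the polymorphic markers of a simulated population."""
    freqs = mg.estimate_frequencies(genos)
    poly = (freqs > 0.0) & (freqs < 1.0)
    sub = genos.subset(cols=np.flatnonzero(poly))
    f = freqs[poly]
    G = mg.stabilize(mg.build_grm_from_genotypes(sub, f, "additive"), ridge)
    D = mg.stabilize(mg.build_grm_from_genotypes(sub, f, "dominance"), ridge)
    return G, D


@pytest.fixture(scope="session")
def small_population():
    """120 half-sib offspring of 8 sires, 400 markers, additive-only trait."""
    scenario = mg.SimScenario(
        n_offspring=120, n_sires=8, n_herds=4, n_markers=400,
        sigma2_a=40.0, sigma2_d=0.0, sigma2_e=40.0, seed=42,
    )
    genos, markers, samples, pheno, truth = mg.simulate_population(scenario)
    return {
        "scenario": scenario, "genos": genos, "markers": markers,
        "samples": samples, "pheno": pheno, "truth": truth,
    }


@pytest.fixture(scope="session")
def small_fit_inputs(small_population):
    pop = small_population
    G, D = polymorphic_grms(pop["genos"])
    X = mg.build_fixed_design(pop["pheno"]).X
    y = pop["pheno"]["trait"].to_numpy()
    return {"y": y, "X": X, "G": G, "D": D, **pop}
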