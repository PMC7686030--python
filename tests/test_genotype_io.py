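"""Genotype I/O, frequency estimation, HWE exact test and QC filters."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import merinogp as mg
from merinogp.genotype_io import PlinkFormatError, is_autosomal


def _random_genotypes(rng, n, m, missing_rate=0.05):
    doses = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    mask = rng.random((n, m)) < missing_rate
    doses[mask] = -1
    ids = np.array([f"I{i}" for i in range(n)], dtype=object)
    return mg.GenotypeMatrix(doses, mask, ids)


def _marker_table(m):
    return pd.DataFrame(
        {
            "marker_id": [f"SNP{i}" for i in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1),
            "a1": "A",
            "a2": "B",
        }
    )


# ---------------------------------------------------------------------------
# PLINK round trips and format errors


def test_plink_round_trip_identity(tmp_path):
    rng = np.random.default_rng(1)
    genos = _random_genotypes(rng, 17, 23)  # n not divisible by 4: pad bits
    mg.write_plink(tmp_path / "pop", genos, _marker_table(23))
    back, markers, samples = mg.read_plink(tmp_path / "pop")
    np.testing.assert_array_equal(back.doses, genos.doses)
    np.testing.assert_array_equal(back.missing, genos.missing)
    assert list(markers["marker_id"]) == [f"SNP{i}" for i in range(23)]


def test_bed_decoding_matches_manual_bits(tmp_path):
    # n=3 individuals, m=2 markers -> 1 byte per marker, low bits first.
    # marker 1: ind1=hom A1 (00), ind2=het (10), ind3=missing (01)
    # marker 2: ind1=hom A2 (11), ind2=hom A1 (00), ind3=het (10)
    payload = bytes([0b00_01_10_00, 0b00_10_00_11])
    (tmp_path / "toy.bed").write_bytes(bytes([0x6C, 0x1B, 0x01]) + payload)
    (tmp_path / "toy.bim").write_text("1\ts1\t0\t1\tA\tB\n1\ts2\t0\t2\tA\tB\n")
    (tmp_path / "toy.fam").write_text(
        "0 a 0 0 1 -9\n0 b 0 0 1 -9\n0 c 0 0 2 -9\n"
    )
    genos, _, _ = mg.read_plink(tmp_path / "toy")
    np.testing.assert_array_equal(genos.doses, [[2, 0], [1, 2], [-1, 1]])
    np.testing.assert_array_equal(genos.missing, [[0, 0], [0, 0], [1, 0]])


@pytest.mark.parametrize(
    "corruption, match",
    [
        (lambda raw: b"XX" + raw[2:], "magic"),
        (lambda raw: raw[:2] + b"\x00" + raw[3:], "individual-major"),
        (lambda raw: raw[:-1], "expected"),
    ],
)
def test_bad_bed_rejected(tmp_path, corruption, match):
    rng = np.random.default_rng(2)
    genos = _random_genotypes(rng, 5, 4)
    mg.write_plink(tmp_path / "pop", genos, _marker_table(4))
    bed = tmp_path / "pop.bed"
    bed.write_bytes(corruption(bed.read_bytes()))
    with pytest.raises(PlinkFormatError, match=match):
        mg.read_plink(tmp_path / "pop")


def test_missing_member_names_file(tmp_path):
    rng = np.random.default_rng(3)
    genos = _random_genotypes(rng, 4, 3)
    mg.write_plink(tmp_path / "pop", genos, _marker_table(3))
    (tmp_path / "pop.fam").unlink()
    with pytest.raises(FileNotFoundError, match="pop.fam"):
        mg.read_plink(tmp_path / "pop")


# ---------------------------------------------------------------------------
# allele frequencies


@pytest.mark.parametrize(
    "doses, expected",
    [([0, 1, 2], 0.5), ([2, 2, 2], 1.0), ([0, 1, -1, 2, 1], 0.5)],
)
def test_estimate_frequencies_hand_counts(doses, expected):
    doses = np.array(doses, dtype=np.int8).reshape(-1, 1)
    genos = mg.GenotypeMatrix(
        doses, doses == -1, np.array([f"I{i}" for i in range(len(doses))], object)
    )
    assert mg.estimate_frequencies(genos)[0] == pytest.approx(expected)


def test_all_missing_marker_flagged_nan():
    doses = np.array([[-1], [-1]], dtype=np.int8)
    genos = mg.GenotypeMatrix(doses, doses == -1, np.array(["a", "b"], object))
    assert np.isnan(mg.estimate_frequencies(genos)[0])


@given(st.permutations(list(range(8))))
@settings(deadline=None, max_examples=25)
def test_frequencies_invariant_to_individual_order(perm):
    rng = np.random.default_rng(11)
    genos = _random_genotypes(rng, 8, 5)
    shuffled = genos.subset(rows=np.array(perm))
    np.testing.assert_allclose(
        mg.estimate_frequencies(shuffled), mg.estimate_frequencies(genos)
    )


# ---------------------------------------------------------------------------
# HWE exact test


def _hwe_brute_force(n_aa, n_ab, n_bb):
    """Exact-integer enumeration of the conditional heterozygote distribution."""
    n = n_aa + n_ab + n_bb
    rare = 2 * min(n_aa, n_bb) + n_ab
    if rare == 0:
        return 1.0
    common = 2 * n - rare
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        a, b = (rare - h) // 2, (common - h) // 2
        weights[h] = (
            2**h * math.factorial(n)
            // (math.factorial(a) * math.factorial(h) * math.factorial(b))
        )
    w_obs = weights[n_ab]
    num = sum(w for w in weights.values() if w <= w_obs)
    return num / sum(weights.values())


@pytest.mark.parametrize(
    "counts, expected",
    [((25, 50, 25), 1.0), ((5, 0, 0), 1.0)],
)
def test_hwe_exact_conventions(counts, expected):
    assert mg.hwe_exact_test(*counts) == pytest.approx(expected)


def test_hwe_extreme_disequilibrium_tiny_p():
    # no heterozygotes among 100 individuals with both alleles at 0.5
    assert mg.hwe_exact_test(50, 0, 50) < 1e-6
    assert mg.hwe_exact_test(50, 0, 50) == pytest.approx(
        _hwe_brute_force(50, 0, 50), rel=1e-9
    )


def test_hwe_matches_enumeration_exhaustively():
    for n in range(1, 41):
        for n_aa in range(n + 1):
            for n_ab in range(n - n_aa + 1):
                n_bb = n - n_aa - n_ab
                got = mg.hwe_exact_test(n_aa, n_ab, n_bb)
                want = _hwe_brute_force(n_aa, n_ab, n_bb)
                assert got == pytest.approx(want, rel=1e-9, abs=1e-12), (
                    n_aa, n_ab, n_bb,
                )


def test_hwe_rejects_bad_counts():
    with pytest.raises(ValueError):
        mg.hwe_exact_test(-1, 2, 3)
    with pytest.raises(ValueError):
        mg.hwe_exact_test(0, 0, 0)


# ---------------------------------------------------------------------------
# QC


def _toy_panel():
    """200 individuals x 10 markers: chrX, rare, low call rate, seven clean.

    Ten markers keep a single missing call (10% of an individual's genotype)
    below the individual-missingness threshold, so the marker filters act in
    isolation.
    """
    rng = np.random.default_rng(7)
    n = 200
    cols, chroms = [], []

    def hwe_col(p):
        return rng.binomial(2, p, n).astype(np.int8)

    cols.append(hwe_col(0.4)); chroms.append("X")        # non-autosomal
    rare = np.zeros(n, dtype=np.int8); rare[0] = 1       # MAF = 1/400 < 0.01
    cols.append(rare); chroms.append("1")
    low = hwe_col(0.3); low[:20] = -1                    # call rate 0.90
    cols.append(low); chroms.append("2")
    for c in ("3", "4", "5", "6", "7", "8", "9"):
        cols.append(hwe_col(0.35)); chroms.append(c)     # clean

    doses = np.column_stack(cols)
    genos = mg.GenotypeMatrix(
        doses, doses == -1, np.array([f"I{i}" for i in range(n)], object)
    )
    markers = _marker_table(10)
    markers["chrom"] = chroms
    samples = pd.DataFrame(
        {"individual_id": genos.ids, "sex": "M", "herd": "H1"}
    )
    return genos, markers, samples


def test_apply_qc_toy_panel_retains_only_clean_markers():
    genos, markers, samples = _toy_panel()
    out, out_markers, out_samples, report = mg.apply_qc(genos, markers, samples)
    assert out.n_markers == 7
    assert set(out_markers["chrom"]) == set("3456789")
    assert report.n_markers_out == 7
    assert report.marker_removals["snp_call_rate"] == 1
    assert report.marker_removals["maf"] == 1
    assert report.marker_removals["autosome"] == 1
    assert report.n_markers_in == sum(report.marker_removals.values()) + 7
    assert "freq" in out_markers


def test_apply_qc_relaxed_thresholds_is_identity():
    genos, markers, samples = _toy_panel()
    thr = mg.QCThresholds(
        snp_call_rate_min=0.0, hwe_p_min=0.0, maf_min=0.0,
        sample_missing_max=1.0, autosomes_only=False,
    )
    out, out_markers, _, report = mg.apply_qc(genos, markers, samples, thr)
    assert out.n_markers == genos.n_markers
    assert out.n_individuals == genos.n_individuals
    np.testing.assert_array_equal(out.doses, genos.doses)


def test_apply_qc_idempotent():
    genos, markers, samples = _toy_panel()
    once = mg.apply_qc(genos, markers, samples)
    twice = mg.apply_qc(once[0], once[1], once[2])
    np.testing.assert_array_equal(twice[0].doses, once[0].doses)
    assert sum(twice[3].marker_removals.values()) == 0
    assert sum(twice[3].individual_removals.values()) == 0


def test_apply_qc_removes_high_missingness_individuals():
    genos, markers, samples = _toy_panel()
    doses = genos.doses.copy()
    doses[5, :] = -1  # individual missing everywhere
    genos = mg.GenotypeMatrix(doses, doses == -1, genos.ids)
    _, _, out_samples, report = mg.apply_qc(genos, markers, samples)
    assert report.individual_removals["sample_missing"] == 1
    assert "I5" not in set(out_samples["individual_id"])


def test_apply_qc_threshold_validation_and_empty_output():
    genos, markers, samples = _toy_panel()
    with pytest.raises(ValueError):
        mg.apply_qc(genos, markers, samples, mg.QCThresholds(maf_min=1.5))
    with pytest.raises(ValueError, match="no markers survive"):
        mg.apply_qc(genos, markers, samples, mg.QCThresholds(maf_min=0.49999))


@pytest.mark.parametrize(
    "label, expected",
    [("1", True), ("26", True), ("X", False), ("Y", False), ("MT", False),
     ("0", False), ("contig_7", False)],
)
def test_autosome_labels(label, expected):
    assert is_autosomal(label) is expected


# ---------------------------------------------------------------------------
# imputation


def test_impute_no_missing_is_identity():
    doses = np.array([[0, 1], [2, 1]], dtype=np.int8)
    genos = mg.GenotypeMatrix(doses, np.zeros_like(doses, bool),
                              np.array(["a", "b"], object))
    out = mg.impute_missing(genos, mg.estimate_frequencies(genos))
    np.testing.assert_array_equal(out, doses.astype(float))


def test_impute_fills_marker_mean():
    doses = np.array([[0], [1], [-1], [0]], dtype=np.int8)
    genos = mg.GenotypeMatrix(doses, doses == -1,
                              np.array(list("abcd"), object))
    out = mg.impute_missing(genos, np.array([0.25]))
    assert out[2, 0] == pytest.approx(0.5)  # 2p with p=0.25
    np.testing.assert_array_equal(out[[0, 1, 3], 0], [0, 1, 0])


def test_impute_column_means_match_2p_on_random_fixture():
    rng = np.random.default_rng(9)
    genos = _random_genotypes(rng, 300, 40, missing_rate=0.1)
    freqs = mg.estimate_frequencies(genos)
    out = mg.impute_missing(genos, freqs)
    np.testing.assert_allclose(out.mean(axis=0), 2 * freqs, atol=1e-12)


def test_impute_undefined_frequency_errors():
    doses = np.array([[-1], [-1]], dtype=np.int8)
    genos = mg.GenotypeMatrix(doses, doses == -1, np.array(["a", "b"], object))
    with pytest.raises(ValueError, match="undefined frequency"):
        mg.impute_missing(genos, mg.estimate_frequencies(genos))
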