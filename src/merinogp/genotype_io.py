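"""PLINK 1 binary genotype I/O, allele-frequency estimation and marker/sample QC.

Genotypes are held as allele-dose codes in {0, 1, 2} counting copies of the A1
allele, with an explicit missing mask.  The reader and writer implement the
PLINK 1 .bed/.bim/.fam triplet (SNP-major .bed only); QC applies the usual
marker filters (call rate, MAF, Hardy-Weinberg exact test, autosome
restriction) and an individual missingness filter, in a documented and
configurable order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "GenotypeMatrix",
    "QCThresholds",
    "QCReport",
    "PlinkFormatError",
    "read_plink",
    "write_plink",
    "estimate_frequencies",
    "hwe_exact_test",
    "apply_qc",
    "impute_missing",
]

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

#: 2-bit PLINK codes -> A1 dose; 1 marks a missing call (mapped to -1 here).
_CODE_TO_DOSE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSE_TO_CODE = {2: 0, 1: 2, 0: 3, -1: 1}

#: chromosome labels that are never autosomal
_NON_AUTOSOMAL = {"X", "Y", "XY", "MT", "M", "0"}


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam member violates the PLINK 1 format."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers A1-allele dose codes with a missing mask.

    ``doses`` is an ``(n, m)`` int8 array; missing entries hold ``-1`` and are
    flagged in ``missing``.  ``ids`` orders the individuals (rows).
    """

    doses: np.ndarray
    missing: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.doses.shape != self.missing.shape:
            raise ValueError("doses and missing mask shapes differ")
        if self.doses.shape[0] != len(self.ids):
            raise ValueError("row count does not match number of individual ids")
        valid = self.missing | np.isin(self.doses, (0, 1, 2))
        if not valid.all():
            raise ValueError("non-missing doses must be 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return self.doses.shape[0]

    @property
    def n_markers(self) -> int:
        return self.doses.shape[1]

    def subset(self, rows=None, cols=None) -> "GenotypeMatrix":
        rows = slice(None) if rows is None else np.asarray(rows)
        cols = slice(None) if cols is None else np.asarray(cols)
        return GenotypeMatrix(
            self.doses[rows][:, cols], self.missing[rows][:, cols], self.ids[rows]
        )


@dataclass
class QCThresholds:
    """Filter thresholds; fractions live in [0, 1].

    ``filter_order`` lists the stages to run, by name, and is applied left to
    right; markers/individuals are counted against the first stage that
    removes them.
    """

    snp_call_rate_min: float = 0.95
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    sample_missing_max: float = 0.10
    autosomes_only: bool = True
    filter_order: tuple[str, ...] = (
        "sample_missing",
        "snp_call_rate",
        "maf",
        "hwe",
        "autosome",
    )

    def validate(self) -> None:
        for name in ("snp_call_rate_min", "hwe_p_min", "maf_min", "sample_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        known = {"sample_missing", "snp_call_rate", "maf", "hwe", "autosome"}
        unknown = set(self.filter_order) - known
        if unknown:
            raise ValueError(f"unknown filter stage(s): {sorted(unknown)}")


@dataclass
class QCReport:
    n_markers_in: int
    n_individuals_in: int
    thresholds: QCThresholds
    marker_removals: dict[str, int] = field(default_factory=dict)
    individual_removals: dict[str, int] = field(default_factory=dict)

    @property
    def n_markers_out(self) -> int:
        return self.n_markers_in - sum(self.marker_removals.values())

    @property
    def n_individuals_out(self) -> int:
        return self.n_individuals_in - sum(self.individual_removals.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("markers", "in", self.n_markers_in)]
        rows += [("markers", k, v) for k, v in self.marker_removals.items()]
        rows.append(("markers", "out", self.n_markers_out))
        rows.append(("individuals", "in", self.n_individuals_in))
        rows += [("individuals", k, v) for k, v in self.individual_removals.items()]
        rows.append(("individuals", "out", self.n_individuals_out))
        return pd.DataFrame(rows, columns=["axis", "stage", "count"])


# ---------------------------------------------------------------------------
# PLINK 1 binary triplet


def read_plink(prefix: str | Path):
    """Read a PLINK 1 ``.bed/.bim/.fam`` triplet.

    Returns ``(GenotypeMatrix, markers, samples)`` where ``markers`` has
    columns ``marker_id, chrom, pos, a1, a2`` and ``samples`` has
    ``individual_id, sex, herd, sire_id`` (herd taken from the family ID
    column, sire from the paternal ID column).
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        member = prefix.with_suffix(prefix.suffix + ext)
        if not member.exists():
            raise FileNotFoundError(f"missing PLINK member: {member}")

    fam = pd.read_csv(
        _member(prefix, ".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex_code", "pheno"],
        dtype={"fid": str, "iid": str, "pat": str, "mat": str},
    )
    bim = pd.read_csv(
        _member(prefix, ".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "marker_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "marker_id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)

    raw = _member(prefix, ".bed").read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes {raw[:2]!r}")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{prefix}.bed: individual-major mode byte 0x{raw[2]:02X} is unsupported"
        )
    bytes_per_marker = (n + 3) // 4
    expected = 3 + bytes_per_marker * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{prefix}.bed: expected {expected} bytes for {n} individuals x "
            f"{m} markers, found {len(raw)}"
        )

    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_marker)
    codes = np.stack([(data >> s) & 0b11 for s in (0, 2, 4, 6)], axis=-1)
    codes = codes.reshape(m, bytes_per_marker * 4)[:, :n]
    doses = _CODE_TO_DOSE[codes].T  # (n, m)
    genos = GenotypeMatrix(doses, doses == -1, fam["iid"].to_numpy(dtype=object))

    markers = bim[["marker_id", "chrom", "pos", "a1", "a2"]].copy()
    samples = pd.DataFrame(
        {
            "individual_id": fam["iid"],
            "sex": fam["sex_code"].map({1: "M", 2: "F"}),
            "herd": fam["fid"],
            "sire_id": fam["pat"].where(fam["pat"] != "0"),
            "dam_id": fam["mat"].where(fam["mat"] != "0"),
        }
    )
    return genos, markers, samples


def write_plink(
    prefix: str | Path,
    genos: GenotypeMatrix,
    markers: pd.DataFrame,
    samples: pd.DataFrame | None = None,
) -> None:
    """Write a SNP-major PLINK 1 triplet; inverse of :func:`read_plink`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = genos.doses.shape
    if len(markers) != m:
        raise ValueError("marker table length does not match genotype columns")

    doses = genos.doses.copy()
    doses[genos.missing] = -1
    # lookup indexed by dose + 1 so the missing code (-1) lands at 0
    lut = np.empty(4, dtype=np.uint8)
    for dose, code in _DOSE_TO_CODE.items():
        lut[dose + 1] = code
    codes = lut[(doses.T + 1)]  # (m, n)

    bytes_per_marker = (n + 3) // 4
    padded = np.zeros((m, bytes_per_marker * 4), dtype=np.uint8)  # pad bits are 0
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    ).astype(np.uint8)

    with open(_member(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": markers["chrom"],
            "marker_id": markers["marker_id"],
            "cm": 0,
            "pos": markers["pos"],
            "a1": markers["a1"],
            "a2": markers["a2"],
        }
    )
    bim.to_csv(_member(prefix, ".bim"), sep="\t", header=False, index=False)

    if samples is None:
        samples = pd.DataFrame({"individual_id": genos.ids})
    sex_code = samples.get("sex", pd.Series(index=samples.index, dtype=object))
    fam = pd.DataFrame(
        {
            "fid": samples.get("herd", pd.Series("0", index=samples.index)).fillna("0"),
            "iid": samples["individual_id"],
            "pat": samples.get("sire_id", pd.Series(index=samples.index, dtype=object)).fillna("0"),
            "mat": samples.get("dam_id", pd.Series(index=samples.index, dtype=object)).fillna("0"),
            "sex_code": sex_code.map({"M": 1, "F": 2}).fillna(0).astype(int),
            "pheno": -9,
        }
    )
    fam.to_csv(_member(prefix, ".fam"), sep="\t", header=False, index=False)


def _member(prefix: Path, ext: str) -> Path:
    return prefix.with_suffix(prefix.suffix + ext)


# ---------------------------------------------------------------------------
# frequencies, HWE, QC


def estimate_frequencies(genos: GenotypeMatrix) -> np.ndarray:
    """Per-marker frequency of the counted (A1) allele among non-missing calls.

    Markers with no non-missing call get ``nan`` (they cannot survive the
    call-rate filter).
    """
    ok = ~genos.missing
    n_called = ok.sum(axis=0)
    allele_sum = np.where(ok, genos.doses, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = allele_sum / (2.0 * n_called)
    freq[n_called == 0] = np.nan
    return freq


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic marker.

    Conditions on the observed allele counts; the p-value sums the
    probabilities of all heterozygote counts whose conditional probability
    does not exceed that of the observed count (the standard SNP-QC exact
    test).  Monomorphic markers return 1.0 by convention.
    """
    counts = (n_aa, n_ab, n_bb)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers: {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotype call required")
    rare = 2 * min(n_aa, n_bb) + n_ab
    if rare == 0:
        return 1.0
    common = 2 * n - rare

    hets = np.arange(rare % 2, rare + 1, 2)
    logw = (
        hets * np.log(2.0)
        - gammaln(hets + 1.0)
        - gammaln((rare - hets) / 2.0 + 1.0)
        - gammaln((common - hets) / 2.0 + 1.0)
    )
    logp = logw - logsumexp(logw)
    probs = np.exp(logp)
    p_obs = probs[hets == n_ab][0]
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(1.0, p)


def apply_qc(
    genos: GenotypeMatrix,
    markers: pd.DataFrame,
    samples: pd.DataFrame,
    thresholds: QCThresholds | None = None,
):
    """Apply marker and individual QC filters.

    Default stage order: individual missingness, SNP call rate, MAF, HWE
    exact test, autosome restriction.  Each marker/individual is counted in
    the report against the first stage that removes it.  Returns the filtered
    ``(GenotypeMatrix, markers, samples, QCReport)``; ``markers`` gains a
    ``freq`` column estimated from the retained individuals.
    """
    thr = thresholds or QCThresholds()
    thr.validate()
    if len(markers) != genos.n_markers or len(samples) != genos.n_individuals:
        raise ValueError("genotypes, markers and samples have inconsistent sizes")

    report = QCReport(genos.n_markers, genos.n_individuals, thr)
    keep_rows = np.ones(genos.n_individuals, dtype=bool)
    keep_cols = np.ones(genos.n_markers, dtype=bool)

    for stage in thr.filter_order:
        g = genos.doses[keep_rows][:, keep_cols]
        miss = genos.missing[keep_rows][:, keep_cols]
        if stage == "sample_missing":
            frac = miss.mean(axis=1) if miss.shape[1] else np.zeros(miss.shape[0])
            bad = frac > thr.sample_missing_max
            report.individual_removals["sample_missing"] = int(bad.sum())
            idx = np.flatnonzero(keep_rows)
            keep_rows[idx[bad]] = False
        else:
            bad = _marker_stage_fail(stage, g, miss, markers.loc[keep_cols], thr)
            report.marker_removals[stage] = int(bad.sum())
            idx = np.flatnonzero(keep_cols)
            keep_cols[idx[bad]] = False

    if not keep_cols.any():
        raise ValueError("no markers survive QC with the given thresholds")
    if not keep_rows.any():
        raise ValueError("no individuals survive QC with the given thresholds")

    out = genos.subset(keep_rows, keep_cols)
    out_markers = markers.loc[keep_cols].reset_index(drop=True).copy()
    out_markers["freq"] = estimate_frequencies(out)
    out_samples = samples.loc[keep_rows].reset_index(drop=True)
    return out, out_markers, out_samples, report


def _marker_stage_fail(stage, doses, miss, markers, thr: QCThresholds) -> np.ndarray:
    n = doses.shape[0]
    if stage == "snp_call_rate":
        call_rate = 1.0 - miss.mean(axis=0)
        return call_rate < thr.snp_call_rate_min
    if stage == "maf":
        sub = GenotypeMatrix(doses, miss, np.arange(n).astype(object))
        p = estimate_frequencies(sub)
        with np.errstate(invalid="ignore"):
            maf = np.minimum(p, 1.0 - p)
        return np.isnan(maf) | (maf < thr.maf_min)
    if stage == "hwe":
        ok = ~miss
        n_bb = ((doses == 0) & ok).sum(axis=0)
        n_ab = ((doses == 1) & ok).sum(axis=0)
        n_aa = ((doses == 2) & ok).sum(axis=0)
        fail = np.zeros(doses.shape[1], dtype=bool)
        for j in range(doses.shape[1]):
            if n_aa[j] + n_ab[j] + n_bb[j] == 0:
                fail[j] = True
                continue
            fail[j] = hwe_exact_test(int(n_aa[j]), int(n_ab[j]), int(n_bb[j])) < thr.hwe_p_min
        return fail
    if stage == "autosome":
        if not thr.autosomes_only:
            return np.zeros(len(markers), dtype=bool)
        return ~markers["chrom"].map(is_autosomal).to_numpy(dtype=bool)
    raise ValueError(f"unknown stage {stage!r}")


def is_autosomal(chrom: str) -> bool:
    """Positive-integer chromosome labels are autosomes; X/Y/MT/0 are not."""
    label = str(chrom).strip().upper()
    if label in _NON_AUTOSOMAL:
        return False
    try:
        return int(label) > 0
    except ValueError:
        return False


def impute_missing(genos: GenotypeMatrix, freqs: np.ndarray) -> np.ndarray:
    """Replace missing doses by the marker mean ``2 p_i`` (float output).

    Mean imputation keeps the centred additive design at zero for imputed
    cells and is unbiased for allele content in expectation.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (genos.n_markers,):
        raise ValueError("one frequency per marker required")
    if np.isnan(freqs[genos.missing.any(axis=0)]).any():
        raise ValueError("cannot impute markers with undefined frequency")
    out = genos.doses.astype(np.float64)
    fill = np.broadcast_to(2.0 * freqs, out.shape)
    out[genos.missing] = fill[genos.missing]
    return out
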