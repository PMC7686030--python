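"""Additive (G) and dominance (D) genomic relationship matrices.

The additive matrix follows the classical marker-based construction
``G = W1 W1' / (2 * sum_i p_i (1 - p_i))`` with ``W1`` the dose matrix centred
at ``2 p_i`` per marker.  The dominance matrix uses the dominance-deviation
coding ``{A1A1, A1A2, A2A2} -> {-2q^2, 2pq, -2p^2}`` (p the A1 frequency,
q = 1 - p) with denominator ``4 * sum_i p_i^2 (1 - p_i)^2 = sum_i (2 p_i q_i)^2``.
Both codings have zero mean under Hardy-Weinberg genotype frequencies, so the
expected diagonal of either matrix is 1 in an unrelated HWE population.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

__all__ = [
    "MarkerDesignMatrix",
    "KinshipMatrix",
    "build_additive_design",
    "build_dominance_design",
    "build_grm",
    "build_grm_from_genotypes",
    "stabilize",
    "write_kinship_text",
    "read_kinship_text",
    "write_grm_gcta",
    "read_grm_gcta",
]

Kind = Literal["additive", "dominance"]


@dataclass
class MarkerDesignMatrix:
    """n x m real design; ``kind`` says which coding produced it."""

    values: np.ndarray
    kind: Kind
    freqs: np.ndarray


@dataclass
class KinshipMatrix:
    """Symmetric n x n genomic relationship matrix with provenance."""

    values: np.ndarray
    kind: Kind
    denominator: float
    ids: np.ndarray
    ridge: float = 0.0

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _check_freqs(freqs: np.ndarray, m: int) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (m,):
        raise ValueError("one frequency per marker required")
    if np.any(~np.isfinite(freqs)) or np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
        raise ValueError("frequencies must lie strictly in (0, 1); fixed markers "
                         "should have been removed by the MAF filter")
    return freqs


def build_additive_design(
    doses: np.ndarray,
    freqs: np.ndarray,
    missing: np.ndarray | None = None,
) -> MarkerDesignMatrix:
    """Centred allele-content design: entry (j, i) = dose(j, i) - 2 p_i.

    ``doses`` may be integer codes or mean-imputed reals.  If a missing mask
    is given, missing cells are set to 0 (the value mean imputation would
    produce after centring).
    """
    doses = np.asarray(doses, dtype=float)
    freqs = _check_freqs(freqs, doses.shape[1])
    w = doses - 2.0 * freqs
    if missing is not None:
        w = np.where(missing, 0.0, w)
    return MarkerDesignMatrix(w, "additive", freqs)


def build_dominance_design(
    doses: np.ndarray,
    freqs: np.ndarray,
    missing: np.ndarray | None = None,
) -> MarkerDesignMatrix:
    """Dominance-deviation design.

    Per marker with A1 frequency p and q = 1 - p the genotype codes are
    ``A1A1 (dose 2) -> -2 q**2``, ``A1A2 (dose 1) -> 2 p q`` and
    ``A2A2 (dose 0) -> -2 p**2``; the coding is symmetric under allele-label
    swap and has zero HWE expectation.  Missing (or imputed, non-integer)
    cells receive 0, their HWE expectation.
    """
    doses = np.asarray(doses, dtype=float)
    p = _check_freqs(freqs, doses.shape[1])
    q = 1.0 - p
    w = np.select(
        [doses == 2.0, doses == 1.0, doses == 0.0],
        [np.broadcast_to(-2.0 * q * q, doses.shape),
         np.broadcast_to(2.0 * p * q, doses.shape),
         np.broadcast_to(-2.0 * p * p, doses.shape)],
        default=0.0,
    )
    if missing is not None:
        w = np.where(missing, 0.0, w)
    return MarkerDesignMatrix(w, "dominance", p)


def _denominator(kind: Kind, freqs: np.ndarray) -> float:
    pq = freqs * (1.0 - freqs)
    if kind == "additive":
        den = 2.0 * float(pq.sum())
    else:
        den = 4.0 * float((pq * pq).sum())
    if den <= 0.0:
        raise ValueError("zero denominator: no polymorphic markers")
    return den


def build_grm(design: MarkerDesignMatrix, ids=None) -> KinshipMatrix:
    """Cross-product relationship matrix ``W W' / denominator``."""
    w = design.values
    if w.size == 0:
        raise ValueError("empty design matrix")
    den = _denominator(design.kind, design.freqs)
    values = (w @ w.T) / den
    values = 0.5 * (values + values.T)
    if ids is None:
        ids = np.arange(w.shape[0]).astype(object)
    return KinshipMatrix(values, design.kind, den, np.asarray(ids, dtype=object))


def build_grm_from_genotypes(
    genos: GenotypeMatrix,
    freqs: np.ndarray,
    kind: Kind,
    block_size: int = 4096,
) -> KinshipMatrix:
    """Build G or D streaming over marker blocks (never materialising n x m
    beyond one block); results match :func:`build_grm` to float reassociation
    tolerance."""
    n, m = genos.doses.shape
    freqs = _check_freqs(freqs, m)
    builder = build_additive_design if kind == "additive" else build_dominance_design
    acc = np.zeros((n, n))
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        w = builder(
            genos.doses[:, start:stop],
            freqs[start:stop],
            genos.missing[:, start:stop],
        ).values
        acc += w @ w.T
    values = acc / _denominator(kind, freqs)
    values = 0.5 * (values + values.T)
    return KinshipMatrix(values, kind, _denominator(kind, freqs), genos.ids.copy())


def stabilize(k: KinshipMatrix, ridge: float = 1e-6) -> KinshipMatrix:
    """Add ``ridge * I`` to the diagonal so the mixed-model covariance is
    invertible even when n exceeds the effective marker rank; the applied
    ridge accumulates in the metadata."""
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    if ridge == 0:
        return k
    return replace(k, values=k.values + ridge * np.eye(k.n), ridge=k.ridge + ridge)


# ---------------------------------------------------------------------------
# kinship import/export


def write_kinship_text(path: str | Path, k: KinshipMatrix) -> None:
    """Dense tab-delimited matrix with a header row of individual IDs."""
    df = pd.DataFrame(k.values, columns=[str(i) for i in k.ids])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_kinship_text(path: str | Path, kind: Kind = "additive") -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t")
    values = df.to_numpy(dtype=float)
    return KinshipMatrix(values, kind, np.nan, np.asarray(df.columns, dtype=object))


def write_grm_gcta(prefix: str | Path, k: KinshipMatrix, n_markers: int) -> None:
    """GCTA GRM triplet: ``.grm.bin`` float32 lower triangle (row-major, i>=j),
    ``.grm.N.bin`` float32 marker counts per pair, ``.grm.id`` FID/IID text."""
    prefix = Path(prefix)
    n = k.n
    tri = k.values[np.tril_indices(n)].astype("<f4")
    Path(f"{prefix}.grm.bin").write_bytes(tri.tobytes())
    Path(f"{prefix}.grm.N.bin").write_bytes(
        np.full(tri.shape, n_markers, dtype="<f4").tobytes()
    )
    with open(f"{prefix}.grm.id", "w") as fh:
        for iid in k.ids:
            fh.write(f"0\t{iid}\n")


def read_grm_gcta(prefix: str | Path, kind: Kind = "additive") -> KinshipMatrix:
    prefix = Path(prefix)
    ids = [line.split()[1] for line in Path(f"{prefix}.grm.id").read_text().splitlines()]
    n = len(ids)
    tri = np.frombuffer(Path(f"{prefix}.grm.bin").read_bytes(), dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise ValueError(
            f"GRM payload holds {tri.size} values, expected {n * (n + 1) // 2}"
        )
    values = np.zeros((n, n))
    values[np.tril_indices(n)] = tri
    values = values + np.tril(values, -1).T
    return KinshipMatrix(values, kind, np.nan, np.asarray(ids, dtype=object))
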