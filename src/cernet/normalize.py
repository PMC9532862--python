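"""Per-layer abundance measures: RPM (circRNA), TPM (miRNA), FPKM (mRNA).

All three scale by the per-sample total of assigned reads (the column
sum); TPM and FPKM additionally divide by feature length, with TPM
renormalized so each column sums to one million.  No fragment-length
correction is applied: the effective length is the given length.
"""

from __future__ import annotations

import numpy as np

from .containers import ExpressionMatrix, FeatureLengths

SCALE = 1e6


def _require_raw(matrix: ExpressionMatrix) -> None:
    if matrix.unit != "raw-count":
        raise ValueError(f"expected raw counts, got unit {matrix.unit!r}")


def _colsums(matrix: ExpressionMatrix) -> np.ndarray:
    cs = matrix.values.sum(axis=0).to_numpy(dtype=float)
    if (cs <= 0).any():
        bad = list(matrix.samples[cs <= 0])
        raise ValueError(f"zero column sum in samples {bad}")
    return cs


def _lengths_vector(matrix: ExpressionMatrix,
                    lengths: FeatureLengths) -> np.ndarray:
    missing = [f for f in matrix.features if f not in lengths]
    if missing:
        raise ValueError(f"missing lengths for {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    return np.array([lengths[f] for f in matrix.features], dtype=float)


def rpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Reads per million mapped reads: count * 1e6 / column sum."""
    _require_raw(counts)
    cs = _colsums(counts)
    vals = counts.values.astype(float) * SCALE / cs
    return ExpressionMatrix(vals, unit="RPM", layer=counts.layer)


def tpm(counts: ExpressionMatrix, lengths: FeatureLengths) -> ExpressionMatrix:
    """Transcripts per million: length-normalized rates rescaled to 1e6 per column."""
    _require_raw(counts)
    lens = _lengths_vector(counts, lengths)
    rates = counts.values.astype(float).div(lens, axis=0)
    rate_sums = rates.sum(axis=0).to_numpy()
    if (rate_sums <= 0).any():
        bad = list(counts.samples[rate_sums <= 0])
        raise ValueError(f"zero rate sum in samples {bad}")
    vals = rates * SCALE / rate_sums
    return ExpressionMatrix(vals, unit="TPM", layer=counts.layer)


def fpkm(counts: ExpressionMatrix, lengths: FeatureLengths) -> ExpressionMatrix:
    """Fragments per kilobase per million mapped reads: count * 1e9 / (len * colsum)."""
    _require_raw(counts)
    cs = _colsums(counts)
    lens = _lengths_vector(counts, lengths)
    vals = counts.values.astype(float).div(lens, axis=0) * 1e9 / cs
    return ExpressionMatrix(vals, unit="FPKM", layer=counts.layer)


def filter_low_expression(matrix: ExpressionMatrix, min_value: float = 0.0,
                          min_samples: int = 0) -> ExpressionMatrix:
    """Keep features with value >= min_value in >= min_samples samples."""
    if min_value < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    if min_samples > len(matrix.samples):
        raise ValueError("min_samples exceeds the number of samples")
    keep = (matrix.values >= min_value).sum(axis=1) >= min_samples
    return ExpressionMatrix(matrix.values.loc[keep].copy(), matrix.unit,
                            matrix.layer)


def log2p1(matrix: ExpressionMatrix) -> "np.ndarray | object":
    """log2(value + 1) DataFrame view used by the correlation stage."""
    return np.log2(matrix.values + 1.0)
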