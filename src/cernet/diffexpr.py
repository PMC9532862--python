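"""Differential expression between two sample groups.

The caller applies the decision rules of the study pipeline — circRNA and
miRNA significant at fold change >= 2 and raw p < 0.05; mRNA significant
at |FC| >= 2 and Benjamini-Hochberg FDR < 0.05 — on top of one exact
conditional negative-binomial test.

The test conditions on the total count t of the two groups: given t, the
split (a, t - a) between groups follows the conditional law induced by
the group totals being NB(n_g * mu, phi / n_g).  The two-sided p-value
sums the probabilities of all splits no more likely than the observed one
(ties included).  At phi = 0 this reduces exactly to a conditional
binomial(t, n_A / (n_A + n_B)) double-tail test.

Counts are first equalized to a common library size (the geometric mean
of the column sums) and rounded half-to-even.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, SampleDesign

#: tie slack in log-probability space for the two-sided tail
_TIE_EPS = 1e-9

LAYER_RULES = {
    "circRNA": "p",   # FC >= 2 and raw p < 0.05
    "miRNA": "p",
    "mRNA": "fdr",    # |FC| >= 2 and FDR < 0.05
}


@dataclasses.dataclass
class DispersionEstimate:
    per_feature: pd.Series
    common: float
    method: str = "moments-pooled"

    def __post_init__(self):
        if not np.isfinite(self.common) or self.common < 0:
            raise ValueError("common dispersion must be finite and >= 0")


def equalize_library_sizes(counts: pd.DataFrame) -> pd.DataFrame:
    """Rescale each column to the geometric-mean library size; round half-to-even."""
    cs = counts.sum(axis=0).to_numpy(dtype=float)
    if (cs <= 0).any():
        raise ValueError("zero library size")
    target = np.exp(np.mean(np.log(cs)))
    scaled = counts.to_numpy(dtype=float) * (target / cs)
    return pd.DataFrame(np.rint(scaled).astype(np.int64),
                        index=counts.index, columns=counts.columns)


def estimate_dispersion(counts: pd.DataFrame,
                        groups: pd.Series) -> DispersionEstimate:
    """Method-of-moments dispersion on library-size-equalized counts.

    Per feature: phi_i = max(0, (s^2 - m) / m^2) with m the grand mean and
    s^2 the pooled within-group variance.  The common dispersion is the
    median of the finite per-feature values.
    """
    labels = groups.loc[counts.columns]
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise ValueError("need >= 2 replicates in every group")
    eq = equalize_library_sizes(counts).to_numpy(dtype=float)
    m = eq.mean(axis=1)

    ss = np.zeros(len(counts))
    for g in sizes.index:
        block = eq[:, (labels == g).to_numpy()]
        ss += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / (eq.shape[1] - len(sizes))

    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(m > 0, np.maximum(0.0, (s2 - m) / m ** 2), np.nan)
    finite = phi[np.isfinite(phi)]
    common = float(np.median(finite)) if finite.size else 0.0
    return DispersionEstimate(pd.Series(phi, index=counts.index),
                              common=common)


def _conditional_logpmf(t: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """log P(a | t) for a = 0..t under the conditional NB split law."""
    a = np.arange(t + 1, dtype=float)
    b = t - a
    if phi == 0.0:
        # binomial(t, n_a / (n_a + n_b))
        lp = (gammaln(t + 1) - gammaln(a + 1) - gammaln(b + 1)
              + a * np.log(n_a / (n_a + n_b)) + b * np.log(n_b / (n_a + n_b)))
    else:
        r_a, r_b = n_a / phi, n_b / phi
        lp = (gammaln(a + r_a) - gammaln(a + 1) - gammaln(r_a)
              + gammaln(b + r_b) - gammaln(b + 1) - gammaln(r_b))
        lp -= logsumexp(lp)
    return lp


def exact_nb_test(counts_a, counts_b, phi: float) -> float:
    """Two-sided exact conditional NB test on two count vectors.

    Probability mass of all splits of t = sum(A) + sum(B) whose
    conditional probability does not exceed the observed split's.
    """
    a_arr = np.asarray(counts_a)
    b_arr = np.asarray(counts_b)
    if (a_arr < 0).any() or (b_arr < 0).any():
        raise ValueError("negative counts")
    if not np.isfinite(phi) or phi < 0:
        raise ValueError("dispersion must be finite and >= 0")
    a_obs = int(round(float(a_arr.sum())))
    t = a_obs + int(round(float(b_arr.sum())))
    if t == 0:
        return 1.0
    lp = _conditional_logpmf(t, len(a_arr), len(b_arr), phi)
    keep = lp <= lp[a_obs] + _TIE_EPS
    p = float(np.exp(logsumexp(lp[keep]) - logsumexp(lp)))
    return min(1.0, max(p, np.finfo(float).tiny))


def log2_fold_change(mean_a: float, mean_b: float,
                     pseudocount: float = 1.0) -> float:
    """log2((mean_b + c) / (mean_a + c)); antisymmetric under group swap."""
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be >= 0")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return float(np.log2((mean_b + pseudocount) / (mean_a + pseudocount)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(results: pd.DataFrame, layer: str,
            lfc_threshold: float = 1.0, p_threshold: float = 0.05,
            fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Add the up/down/ns call column under the layer-specific rule."""
    if layer not in LAYER_RULES:
        raise ValueError(f"unknown layer {layer!r}")
    out = results.copy()
    crit = out["p"] if LAYER_RULES[layer] == "p" else out["fdr"]
    thr = p_threshold if LAYER_RULES[layer] == "p" else fdr_threshold
    sig = (out["log2fc"].abs() >= lfc_threshold) & (crit < thr)
    out["call"] = np.where(~sig, "ns",
                           np.where(out["log2fc"] > 0, "up", "down"))
    return out


def de_table(matrix: ExpressionMatrix, design: SampleDesign,
             group_a: str, group_b: str,
             dispersion: float | None = None,
             pseudocount: float = 1.0) -> pd.DataFrame:
    """Full DE table (log2fc, p, fdr, call) for one two-group comparison.

    ``group_b`` over ``group_a``; dispersion defaults to the common
    method-of-moments estimate from the two groups' samples.
    """
    if matrix.unit != "raw-count":
        raise ValueError("differential expression runs on raw counts")
    samples_a = design.samples_in_group(group_a)
    samples_b = design.samples_in_group(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    sub = matrix.values.loc[:, samples_a + samples_b]
    eq = equalize_library_sizes(sub)
    if dispersion is None:
        dispersion = estimate_dispersion(sub, design.groups).common

    arr_a = eq.loc[:, samples_a].to_numpy()
    arr_b = eq.loc[:, samples_b].to_numpy()
    pvals = np.array([exact_nb_test(arr_a[i], arr_b[i], dispersion)
                      for i in range(eq.shape[0])])
    lfc = np.array([log2_fold_change(arr_a[i].mean(), arr_b[i].mean(),
                                     pseudocount)
                    for i in range(eq.shape[0])])
    out = pd.DataFrame({
        "feature": eq.index, "layer": matrix.layer,
        "comparison": f"{group_a}_vs_{group_b}",
        "log2fc": lfc, "p": pvals, "fdr": bh_adjust(pvals),
    }).set_index("feature")
    return call_de(out, matrix.layer)


def de_features(table: pd.DataFrame) -> list[str]:
    """Feature ids called up or down."""
    return list(table.index[table["call"] != "ns"])
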