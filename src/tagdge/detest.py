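"""Pairwise differential expression for replicate-free tag libraries.

With a single library per stage, the only sampling model available is the
tag-counting process itself. The Audic-Claverie test treats the count of
a gene in library 2 given its count x in library 1 as the posterior
predictive

    P(Y = k | x) = (N2/N1)^k * (x+k)! / (x! k!) / (1 + N2/N1)^(x+k+1)

(N1, N2 the library totals), i.e. Y | x ~ NegativeBinomial(x+1,
N1/(N1+N2)).  The lower tail P(Y <= y) is evaluated exactly through the
regularized incomplete beta function and the two-sided p-value is twice
the smaller of P(Y <= y) and P(Y > y), capped at 1.  With these
complementary tails the p-value is exactly invariant under exchanging
the two libraries, p(x, y, N1, N2) = p(y, x, N2, N1), a property the
point-inclusive upper-tail convention only holds approximately.

A gene is called differentially expressed when it clears the four-part
filter: TPM >= 20 in at least one stage, p <= 0.001, |log2 ratio| >= 1,
and Benjamini-Hochberg q < 0.05 (BH applied within the comparison, over
the genes passing the TPM filter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc

from .quantify import ExpressionMatrix, TPM_SCALE

TPM_MIN = 20.0
P_MAX = 0.001
LFC_MIN = 1.0
FDR_MAX = 0.05

UP = "up"
DOWN = "down"


def count_test_p(x, y, n1, n2):
    """Two-sided Audic-Claverie p-value; accepts scalars or arrays.

    ``x`` is the count in the library of total ``n1``, ``y`` in the
    library of total ``n2``.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if not (np.issubdtype(x.dtype, np.integer) or np.allclose(x, np.round(x))):
        raise ValueError("counts must be integers")
    if not (np.issubdtype(y.dtype, np.integer) or np.allclose(y, np.round(y))):
        raise ValueError("counts must be integers")
    if np.any(np.asarray(n1) <= 0) or np.any(np.asarray(n2) <= 0):
        raise ValueError("library totals must be positive")
    x = x.astype(np.int64)
    y = y.astype(np.int64)
    p_succ = np.asarray(n1 / (n1 + n2), dtype=float)
    # P(Y <= y) for NB(x+1, p) is I_p(x+1, y+1); its exact complement
    # P(Y > y) = I_{1-p}(y+1, x+1) is evaluated directly rather than as
    # 1 - lower, which would lose all precision for extreme counts.
    lower = betainc(x + 1, y + 1, np.broadcast_to(p_succ, x.shape))
    upper = betainc(y + 1, x + 1, np.broadcast_to(1.0 - p_succ, x.shape))
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return p if p.ndim else float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values: q_i = min_{p_j >= p_i} m * p_j / rank_j."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class DEThresholds:
    tpm_min: float = TPM_MIN
    p_max: float = P_MAX
    lfc_min: float = LFC_MIN
    fdr_max: float = FDR_MAX


def call_de(
    matrix: ExpressionMatrix,
    stage_a: str,
    stage_b: str,
    thresholds: DEThresholds = DEThresholds(),
    use_distributed: bool = True,
) -> pd.DataFrame:
    """Differential expression of stage_b over stage_a for every gene.

    The log2 ratio is computed from TPM with a detection-limit floor:
    a zero TPM is replaced by the TPM equivalent of a single tag
    (10^6 / clean_tag_total of that library) so ratios stay finite.
    The count test uses distributed counts rounded to the nearest
    integer (or raw unambiguous counts with ``use_distributed=False``).
    """
    for stage in (stage_a, stage_b):
        if stage not in matrix.tpm.columns:
            raise KeyError(f"unknown stage label: {stage!r}")
    tpm_a = matrix.tpm[stage_a].to_numpy()
    tpm_b = matrix.tpm[stage_b].to_numpy()
    n1 = int(matrix.clean_totals[stage_a])
    n2 = int(matrix.clean_totals[stage_b])
    floor_a = TPM_SCALE / n1
    floor_b = TPM_SCALE / n2
    log2_ratio = np.log2(
        np.where(tpm_b == 0, floor_b, tpm_b) / np.where(tpm_a == 0, floor_a, tpm_a)
    )
    source = matrix.distributed if use_distributed else matrix.counts
    x = np.rint(source[stage_a].to_numpy()).astype(np.int64)
    y = np.rint(source[stage_b].to_numpy()).astype(np.int64)
    p = np.asarray(count_test_p(x, y, n1, n2))
    passes_tpm = (tpm_a >= thresholds.tpm_min) | (tpm_b >= thresholds.tpm_min)
    q = np.full(p.shape, np.nan)
    if passes_tpm.any():
        q[passes_tpm] = bh_fdr(p[passes_tpm])
    passes_p = p <= thresholds.p_max
    passes_fc = np.abs(log2_ratio) >= thresholds.lfc_min
    passes_fdr = np.where(np.isnan(q), False, q < thresholds.fdr_max)
    is_de = passes_tpm & passes_p & passes_fc & passes_fdr
    result = pd.DataFrame(
        {
            "count_a": x,
            "count_b": y,
            "tpm_a": tpm_a,
            "tpm_b": tpm_b,
            "log2_ratio": log2_ratio,
            "p_value": p,
            "fdr_q": q,
            "passes_tpm_filter": passes_tpm,
            "passes_p": passes_p,
            "passes_fc": passes_fc,
            "passes_fdr": passes_fdr,
            "is_de": is_de,
            "direction": np.where(log2_ratio > 0, UP, DOWN),
        },
        index=matrix.genes,
    )
    result.index.name = "gene"
    result.attrs["comparison"] = (stage_a, stage_b)
    return result


def call_all(
    matrix: ExpressionMatrix,
    comparisons,
    thresholds: DEThresholds = DEThresholds(),
    use_distributed: bool = True,
) -> dict[tuple[str, str], pd.DataFrame]:
    """call_de over a list of (stage_a, stage_b) pairs."""
    return {
        (a, b): call_de(matrix, a, b, thresholds, use_distributed)
        for a, b in comparisons
    }
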