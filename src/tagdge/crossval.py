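"""qRT-PCR relative quantification and cross-platform concordance.

qRT-PCR expression is quantified by the 2^-ddCt method against an
internal reference transcript (polyubiquitin in this assay) with a
baseline stage: dCt = Ct_target - Ct_reference (replicate-averaged),
ddCt = dCt(stage) - dCt(baseline), ratio = 2^-ddCt (amplification
efficiency fixed at 2). Concordance with the sequencing platform is the
Pearson correlation of paired log2 ratios, reported overall and per
stage as r and R^2.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ExpressionMatrix, TPM_SCALE

CT_COLUMNS = ["gene", "stage", "replicate", "target_ct", "reference_ct"]


def read_ct_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return table


def relative_expression(ct: pd.DataFrame, baseline: str) -> pd.DataFrame:
    """Gene x stage table of 2^-ddCt ratios relative to ``baseline``."""
    for col in ("gene", "stage", "target_ct", "reference_ct"):
        if col not in ct.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    values = ct[["target_ct", "reference_ct"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValueError("Ct values must be positive and finite")
    work = ct.assign(dct=ct["target_ct"] - ct["reference_ct"])
    dct = work.groupby(["gene", "stage"])["dct"].mean().unstack("stage")
    if baseline not in dct.columns:
        raise ValueError(f"baseline stage {baseline!r} missing from Ct table")
    if dct[baseline].isna().any():
        bad = dct.index[dct[baseline].isna()].tolist()
        raise ValueError(f"baseline stage missing for genes: {bad}")
    ddct = dct.sub(dct[baseline], axis=0)
    return np.power(2.0, -ddct)


def rnaseq_log2_ratio(matrix: ExpressionMatrix, baseline: str) -> pd.DataFrame:
    """log2 TPM ratio of each stage over the baseline stage, with the
    single-tag TPM floor substituted for zeros (mirrors the DE ratio)."""
    tpm = matrix.tpm
    floors = TPM_SCALE / matrix.clean_totals
    floored = tpm.where(tpm > 0, floors, axis=1)
    return np.log2(floored.div(floored[baseline], axis=0))


def platform_correlation(
    rnaseq_log2: pd.DataFrame,
    qpcr_log2: pd.DataFrame,
    grouping: str = "overall",
) -> pd.DataFrame:
    """Pearson r and R^2 between paired log2 values.

    Both inputs are gene x stage tables of log2 ratios; pairs are formed
    by inner join on (gene, stage). ``grouping`` is "overall" or
    "per-stage". Groups with fewer than 3 pairs are skipped with a
    warning.
    """
    a = rnaseq_log2.stack().rename("rnaseq")
    b = qpcr_log2.stack().rename("qpcr")
    paired = pd.concat([a, b], axis=1, join="inner").dropna()
    paired.index.names = ["gene", "stage"]
    if grouping == "overall":
        groups = [("overall", paired)]
    elif grouping == "per-stage":
        groups = list(paired.groupby(level="stage"))
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    rows = []
    for name, sub in groups:
        if len(sub) < 3:
            warnings.warn(f"group {name!r} skipped: only {len(sub)} pairs")
            continue
        r, _ = stats.pearsonr(sub["rnaseq"], sub["qpcr"])
        rows.append({"group": name, "n": len(sub), "r": r, "r2": r * r})
    return pd.DataFrame(rows, columns=["group", "n", "r", "r2"])
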