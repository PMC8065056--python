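"""Diagnostics and figure-data generation: genomic inflation, Manhattan/QQ.

Figures are emitted as plain data files regenerable from the
summary-statistics table alone; rendering is optional and separate, so the
testable artifact is the data, not the image.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import MODELS

#: median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.45493642311957283


def lambda_gc(p_values) -> float:
    """Genomic inflation factor: median implied 1-df chi-square over the
    null 1-df chi-square median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def manhattan_data(summary: pd.DataFrame, model: str) -> pd.DataFrame:
    """chrom / pos / p / -log10 p for one model, ready to plot."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    col = f"{model}_p"
    df = summary[["chrom", "pos", col]].dropna().rename(columns={col: "p"})
    df["neg_log10_p"] = -np.log10(df["p"].clip(lower=1e-300))
    return df.reset_index(drop=True)


def qq_data(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p under the uniform null."""
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[np.isfinite(p)]
    n = len(p)
    if n == 0:
        raise ValueError("no p-values supplied")
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({
        "expected_neg_log10_p": -np.log10(expected),
        "observed_neg_log10_p": -np.log10(np.clip(p, 1e-300, None)),
    })


def model_inflation_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-model variant counts and lambda-GC from a summary-stats frame."""
    rows = []
    for model in MODELS:
        col = f"{model}_p"
        if col not in summary.columns:
            continue
        p = summary[col].dropna()
        rows.append({"model": model, "n_variants": len(p),
                     "lambda_gc": lambda_gc(p) if len(p) else np.nan})
    return pd.DataFrame(rows)
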