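"""Fixed-effect meta-analysis of GWAS summary statistics.

Two schemes are provided, mirroring standard METAL usage: the
inverse-variance-weighted (IVW) fixed-effect model pooling betas by
``w_i = 1/SE_i^2``, and the sample-size-based scheme that converts each
study's p-value and effect direction into a z-score and pools with
``w_i = sqrt(n_i)``.  Cochran's Q and the I-squared statistic quantify
between-study heterogeneity of the IVW inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import NA


@dataclass
class StudyStat:
    """One study's summary statistic for one variant."""

    study: str
    beta: float | None = None
    se: float | None = None
    p: float | None = None
    direction: int | None = None  # +1 / -1
    n: float | None = None

    def __post_init__(self):
        if self.beta is not None and self.se is not None and self.se <= 0:
            raise ValueError(f"study {self.study}: se must be positive")
        if self.direction is None and self.beta is not None:
            self.direction = 1 if self.beta >= 0 else -1
        if self.direction not in (None, 1, -1):
            raise ValueError("direction must be +1 or -1")


@dataclass
class MetaResult:
    method: str
    beta: float | None = None
    se: float | None = None
    z: float | None = None
    p: float | None = None
    k: int = 0
    q: float | None = None
    q_p: float | None = None
    i2: float | None = None


def effective_n(n_cases: float, n_controls: float) -> float:
    """Effective sample size ``4 / (1/n_cases + 1/n_controls)`` for
    case-control studies with unbalanced allocation."""
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def ivw_meta(studies: Sequence[StudyStat], with_heterogeneity: bool = True) -> MetaResult:
    """Inverse-variance-weighted fixed-effect pooling of betas."""
    usable = [s for s in studies if s.beta is not None and s.se is not None]
    if not usable:
        raise ValueError("no study with usable beta and se")
    betas = np.array([s.beta for s in usable])
    w = np.array([1.0 / s.se**2 for s in usable])
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    res = MetaResult(method="ivw", beta=beta, se=se, z=float(z), p=p, k=len(usable))
    if with_heterogeneity and len(usable) >= 2:
        res.q, res.q_p, res.i2 = heterogeneity(usable)
    return res


def samplesize_meta(studies: Sequence[StudyStat]) -> MetaResult:
    """Sample-size-weighted z-score pooling (direction + p-value per study)."""
    usable = [s for s in studies
              if s.p is not None and s.direction is not None and s.n is not None]
    if not usable:
        raise ValueError("no study with usable p, direction and n")
    for s in usable:
        if s.p <= 0:
            raise ValueError(
                f"study {s.study}: p = 0 is unrepresentable as a z-score; "
                "supply beta/se and use the IVW method instead")
    z_i = np.array([stats.norm.isf(s.p / 2.0) * s.direction for s in usable])
    w = np.array([np.sqrt(s.n) for s in usable])
    z = float(np.sum(w * z_i) / np.sqrt(np.sum(w**2)))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(method="samplesize", z=z, p=p, k=len(usable))


def heterogeneity(studies: Sequence[StudyStat]):
    """Cochran's Q, its chi-square p-value, and I-squared (0-100)."""
    usable = [s for s in studies if s.beta is not None and s.se is not None]
    if len(usable) < 2:
        return None, None, None
    betas = np.array([s.beta for s in usable])
    w = np.array([1.0 / s.se**2 for s in usable])
    pooled = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - pooled) ** 2))
    df = len(usable) - 1
    q_p = float(stats.chi2.sf(q, df))
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    return q, q_p, i2


# ---------------------------------------------------------------------------
# table-level meta-analysis with allele alignment
# ---------------------------------------------------------------------------

_KEY = ["chrom", "pos"]


def align_effect_alleles(reference: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Align a study table's effect alleles to a reference table.

    Rows whose (ref, eff) pair is swapped relative to the reference get
    their beta sign and direction flipped; rows with incompatible allele
    pairs are dropped.
    """
    ref = reference.set_index(_KEY)
    out = []
    for _, row in other.iterrows():
        key = (row["chrom"], row["pos"])
        if key not in ref.index:
            continue
        r = ref.loc[key]
        row = row.copy()
        if (row["ref_allele"], row["eff_allele"]) == (r["ref_allele"], r["eff_allele"]):
            pass
        elif (row["ref_allele"], row["eff_allele"]) == (r["eff_allele"], r["ref_allele"]):
            if "beta" in row and pd.notna(row["beta"]):
                row["beta"] = -row["beta"]
            if "direction" in row and pd.notna(row["direction"]):
                row["direction"] = -row["direction"]
            row["ref_allele"], row["eff_allele"] = r["ref_allele"], r["eff_allele"]
        else:
            continue
        out.append(row)
    return pd.DataFrame(out).reset_index(drop=True)


def meta_analyze_tables(tables: dict, method: str = "ivw",
                        use_effective_n: bool = False) -> pd.DataFrame:
    """Meta-analyze per-study summary tables keyed by (chrom, pos, alleles).

    Each table needs columns chrom, pos, ref_allele, eff_allele plus
    beta/se (IVW) or p/beta-or-direction/n (sample-size).  Only variants
    present in every study are pooled.
    """
    names = list(tables)
    if not names:
        raise ValueError("no study tables")
    ref_name = names[0]
    aligned = {ref_name: tables[ref_name]}
    for name in names[1:]:
        aligned[name] = align_effect_alleles(tables[ref_name], tables[name])

    keyed = {name: t.set_index(_KEY) for name, t in aligned.items()}
    common = set(keyed[ref_name].index)
    for name in names[1:]:
        common &= set(keyed[name].index)

    rows = []
    for key in sorted(common):
        studies = []
        for name in names:
            r = keyed[name].loc[key]
            n = r.get("n")
            if use_effective_n and "n_cases" in r and pd.notna(r.get("n_cases")):
                n = effective_n(float(r["n_cases"]), float(r["n_controls"]))
            elif n is None and "n_cases" in r and pd.notna(r.get("n_cases")):
                n = float(r["n_cases"]) + float(r["n_controls"])
            studies.append(StudyStat(
                study=name,
                beta=None if pd.isna(r.get("beta")) else float(r["beta"]),
                se=None if pd.isna(r.get("se")) else float(r["se"]),
                p=None if pd.isna(r.get("p")) else float(r["p"]),
                direction=None if pd.isna(r.get("direction", np.nan)) else int(r["direction"]),
                n=None if n is None or pd.isna(n) else float(n),
            ))
        res = ivw_meta(studies) if method == "ivw" else samplesize_meta(studies)
        ref_row = keyed[ref_name].loc[key]
        rows.append({
            "chrom": key[0], "pos": key[1],
            "ref_allele": ref_row["ref_allele"], "eff_allele": ref_row["eff_allele"],
            "beta": res.beta, "se": res.se, "z": res.z, "p": res.p,
            "k": res.k, "q": res.q, "q_p": res.q_p, "i2": res.i2,
        })
    return pd.DataFrame(rows)
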