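"""Marker quality control: info scores, Hardy-Weinberg testing, filters.

Two filter stages are implemented.  Pre-association marker QC removes
variants by missingness, all-cohort HWE and MAF.  Post-association
filtering removes results with control-HWE violations (all models) and,
for the recessive and genotypic models only, variants with fewer than
three hard-called effect-allele homozygote cases — both guard against
imputation artifacts that inflate or deflate those models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeProbabilityMatrix, PhenotypeTable


@dataclass
class QcThresholds:
    """Default marker-QC thresholds."""

    max_missingness: float = 0.05
    hwe_all_p_floor: float = 1e-20
    min_maf: float = 0.001
    min_info: float = 0.7
    hwe_controls_p_floor: float = 1e-6
    min_alt_hom_cases: int = 3
    hard_call_threshold: float = 0.9

    def __post_init__(self):
        for name in ("max_missingness", "min_maf", "min_info"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} out of [0, 1]: {v}")
        for name in ("hwe_all_p_floor", "hwe_controls_p_floor"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} out of (0, 1): {v}")
        if self.min_alt_hom_cases < 0:
            raise ValueError("min_alt_hom_cases must be >= 0")
        if not 1 / 3 < self.hard_call_threshold <= 1:
            raise ValueError("hard_call_threshold must be in (1/3, 1]")


def impute_info_score(triples: np.ndarray, missing: np.ndarray | None = None) -> float:
    """IMPUTE2-style info score for one variant.

    With per-sample expected dosage ``e_i = p1 + 2 p2`` and second moment
    ``f_i = p1 + 4 p2``, and allele frequency ``theta = sum(e_i) / 2N``::

        info = 1 - sum(f_i - e_i^2) / (2 N theta (1 - theta))

    i.e. one minus the ratio of the mean posterior genotype variance to the
    binomial variance expected at the estimated allele frequency.  ``info``
    is 1 for fully certain genotypes, can be negative for anti-informative
    triples, and is defined as 1 when ``theta`` is 0 or 1 (monomorphic).
    Returns NaN when every triple is missing.
    """
    triples = np.asarray(triples, dtype=float)
    if missing is not None:
        triples = triples[~np.asarray(missing, dtype=bool)]
    if triples.size == 0:
        return float("nan")
    e = triples[:, 1] + 2.0 * triples[:, 2]
    f = triples[:, 1] + 4.0 * triples[:, 2]
    n = len(e)
    theta = e.sum() / (2.0 * n)
    if theta <= 0.0 or theta >= 1.0:
        return 1.0
    return float(1.0 - (f - e**2).sum() / (2.0 * n * theta * (1.0 - theta)))


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities that do not exceed the observed
    configuration's probability (Wigginton-style exact test, as in PLINK).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    n_rare = 2 * min(n_aa, n_bb) + n_ab  # minor allele count
    obs_het = n_ab

    # probabilities over het counts of the same parity as n_rare, built by the
    # ratio recurrence from the mode to avoid overflow
    het_vals = np.arange(n_rare % 2, n_rare + 1, 2)
    if len(het_vals) == 1:
        return 1.0
    mid = int(round(n_rare * (2.0 * n - n_rare) / (2.0 * n - 1.0)))
    if mid % 2 != n_rare % 2:
        mid += 1
    mid = min(max(mid, het_vals[0]), het_vals[-1])

    probs = {mid: 1.0}
    # going down: P(h-2)/P(h) = h (h-1) / ((rare-h+2)/2 * (n - (rare+h)/2 + 1)) / 4
    h = mid
    while h - 2 >= het_vals[0]:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
        h -= 2
    h = mid
    while h + 2 <= het_vals[-1]:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
    total = sum(probs.values())
    p_obs = probs[obs_het] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return float(min(1.0, p))


def variant_qc_table(matrix: GenotypeProbabilityMatrix,
                     thresholds: QcThresholds | None = None) -> pd.DataFrame:
    """Per-variant missingness, MAF, info and all-sample HWE p."""
    thresholds = thresholds or QcThresholds()
    calls = matrix.hard_calls(thresholds.hard_call_threshold)
    maf = matrix.maf()
    rows = []
    for j, variant in enumerate(matrix.variants):
        missingness = float(matrix.missing[:, j].mean())
        info = impute_info_score(matrix.probs[:, j, :], matrix.missing[:, j])
        cj = calls[:, j]
        counts = [int((cj == g).sum()) for g in (0, 1, 2)]
        hwe_p = hwe_exact_test(*counts) if sum(counts) >= 1 else float("nan")
        rows.append({
            "chrom": variant.chrom, "pos": variant.pos, "id": variant.id,
            "missingness": missingness, "maf": float(maf[j]),
            "info": info, "hwe_p": hwe_p,
        })
    return pd.DataFrame(rows)


def marker_qc(matrix: GenotypeProbabilityMatrix,
              phenotypes: PhenotypeTable | None = None,
              thresholds: QcThresholds | None = None):
    """Apply pre-association marker filters.

    Removes variants with missingness >= ``max_missingness``, all-cohort
    HWE p <= ``hwe_all_p_floor`` (hard calls), or MAF < ``min_maf``.
    Returns ``(kept_matrix, report)`` where the report records a decision
    and failure reason per variant.
    """
    thresholds = thresholds or QcThresholds()
    if phenotypes is not None and phenotypes.samples != matrix.samples:
        raise ValueError("matrix and phenotype table are not aligned")
    table = variant_qc_table(matrix, thresholds)
    reasons = []
    for _, row in table.iterrows():
        why = []
        if row["missingness"] >= thresholds.max_missingness:
            why.append("missingness")
        if row["hwe_p"] <= thresholds.hwe_all_p_floor:
            why.append("hwe_all")
        if row["maf"] < thresholds.min_maf:
            why.append("maf")
        reasons.append(",".join(why))
    table["decision"] = ["remove" if r else "keep" for r in reasons]
    table["reason"] = reasons
    kept = [j for j, r in enumerate(reasons) if not r]
    return matrix.subset_variants(kept), table


def post_association_filter(records: Sequence, thresholds: QcThresholds | None = None) -> list:
    """Drop association records failing the post-association filters.

    Any model: control-HWE p < ``hwe_controls_p_floor``.  Recessive and
    genotypic models additionally require at least ``min_alt_hom_cases``
    hard-called effect-allele homozygote cases.
    """
    thresholds = thresholds or QcThresholds()
    kept = []
    for rec in records:
        if rec.hwe_controls_p is None:
            raise ValueError(f"record {rec.variant.id}/{rec.model} lacks hwe_controls_p")
        if rec.hwe_controls_p < thresholds.hwe_controls_p_floor:
            continue
        if rec.model in ("recessive", "genotypic"):
            if rec.alt_hom_cases is None:
                raise ValueError(f"record {rec.variant.id}/{rec.model} lacks alt_hom_cases")
            if rec.alt_hom_cases < thresholds.min_alt_hom_cases:
                continue
        kept.append(rec)
    return kept


def write_qc_report(report: pd.DataFrame, path):
    report.to_csv(path, sep="\t", index=False, na_rep="NA")
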