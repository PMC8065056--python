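"""Combining per-panel imputation results and evaluating imputation quality.

Different reference panels cover different variants and impute the shared
ones with different certainty.  The combination rule is simple and
deterministic: take the union of variant keys and, per variant, the
genotypes from the covering panel with the highest info score (ties broken
by a configured panel priority).  Quality against held-out truth genotypes
is summarized by the allelic dosage R-squared, binned by MAF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenotypeProbabilityMatrix, VariantKey, chrom_sort_key

#: MAF bin edges used for quality summaries (left-open intervals)
DEFAULT_MAF_BINS = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5)


@dataclass
class PanelResultSet:
    """One imputation run: panel name, probabilities and per-variant info."""

    name: str
    matrix: GenotypeProbabilityMatrix
    info: Mapping[tuple, float]

    def __post_init__(self):
        keys = [v.match_key() for v in self.matrix.variants]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate variant within panel {self.name}")
        for k in keys:
            if k not in self.info:
                raise ValueError(f"panel {self.name} lacks info for {k}")


@dataclass
class CombinedSet:
    """Best-info union of several panels' results."""

    matrix: GenotypeProbabilityMatrix
    info: Mapping[tuple, float]
    source_panel: Mapping[tuple, str]

    def provenance_frame(self) -> pd.DataFrame:
        rows = [{"chrom": v.chrom, "pos": v.pos, "id": v.id,
                 "info": self.info[v.match_key()],
                 "best_panel": self.source_panel[v.match_key()]}
                for v in self.matrix.variants]
        return pd.DataFrame(rows)


def combine_panels(sets: Sequence[PanelResultSet],
                   panel_priority: Sequence[str] | None = None) -> CombinedSet:
    """Merge panel result sets by the best-info-score rule.

    Variants are matched across panels on (chrom, pos, unordered allele
    pair); panels are assumed strand-harmonized.  The output contains every
    variant covered by at least one panel, each taken wholesale (genotypes
    and info) from its best panel.
    """
    if not sets:
        raise ValueError("need at least one panel result set")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("panel names must be unique")
    samples = sets[0].matrix.samples
    for s in sets[1:]:
        if s.matrix.samples != samples:
            raise ValueError(f"panel {s.name} has a different sample ordering")
    priority = list(panel_priority) if panel_priority else names
    rank = {name: i for i, name in enumerate(priority)}

    best: dict = {}
    for s in sets:
        for j, v in enumerate(s.matrix.variants):
            key = v.match_key()
            cand = (s.info[key], s, j, v)
            if key not in best:
                best[key] = cand
                continue
            cur_info, cur_s, _, _ = best[key]
            if (cand[0] > cur_info
                    or (cand[0] == cur_info
                        and rank.get(s.name, len(rank)) < rank.get(cur_s.name, len(rank)))):
                best[key] = cand

    chosen = sorted(best.values(),
                    key=lambda c: (chrom_sort_key(c[3].chrom), c[3].pos, c[3].id))
    variants = [c[3] for c in chosen]
    probs = np.stack([c[1].matrix.probs[:, c[2], :] for c in chosen], axis=1) \
        if chosen else np.empty((len(samples), 0, 3))
    missing = np.stack([c[1].matrix.missing[:, c[2]] for c in chosen], axis=1) \
        if chosen else np.empty((len(samples), 0), dtype=bool)
    matrix = GenotypeProbabilityMatrix(variants, samples, probs, missing)
    info = {v.match_key(): c[0] for v, c in zip(variants, chosen)}
    source = {v.match_key(): c[1].name for v, c in zip(variants, chosen)}
    return CombinedSet(matrix=matrix, info=info, source_panel=source)


def make_insilico_array(truth: GenotypeProbabilityMatrix,
                        array_variant_ids: Sequence[str]):
    """Mask a truth matrix down to a genotyped-array backbone.

    Returns ``(masked, withheld)``: the array variants as one-hot copies of
    truth (the genotyped backbone an imputation run would start from) and
    the withheld remainder kept as evaluation truth.
    """
    ids = {v.id: j for j, v in enumerate(truth.variants)}
    unknown = [i for i in array_variant_ids if i not in ids]
    if unknown:
        raise ValueError(f"array ids absent from truth: {unknown}")
    array_idx = [ids[i] for i in array_variant_ids]
    withheld_idx = [j for j in range(truth.n_variants) if j not in set(array_idx)]
    masked = truth.subset_variants(array_idx)
    onehot = np.zeros_like(masked.probs)
    calls = np.argmax(masked.probs, axis=2)
    s, v = np.meshgrid(np.arange(masked.n_samples), np.arange(masked.n_variants),
                       indexing="ij")
    onehot[s, v, calls] = 1.0
    masked = GenotypeProbabilityMatrix(masked.variants, masked.samples, onehot)
    return masked, truth.subset_variants(withheld_idx)


def allelic_dosage_r2(imputed_triples: np.ndarray, truth_genotypes: np.ndarray,
                      missing: np.ndarray | None = None) -> float:
    """Squared Pearson correlation of imputed expected dosage vs true dosage.

    NaN when fewer than two paired samples remain or either vector is
    constant.  Invariant to reflecting which allele is counted.
    """
    trips = np.asarray(imputed_triples, dtype=float)
    g = np.asarray(truth_genotypes, dtype=float)
    keep = np.isfinite(g)
    if missing is not None:
        keep &= ~np.asarray(missing, dtype=bool)
    e = (trips[:, 1] + 2.0 * trips[:, 2])[keep]
    g = g[keep]
    if len(g) < 2 or np.ptp(e) == 0 or np.ptp(g) == 0:
        return float("nan")
    r = np.corrcoef(e, g)[0, 1]
    return float(r * r)


def panel_r2_table(panel: PanelResultSet, truth: GenotypeProbabilityMatrix) -> pd.DataFrame:
    """Per-variant allelic dosage R2 of a panel against truth hard calls."""
    truth_by_key = {v.match_key(): j for j, v in enumerate(truth.variants)}
    truth_dosage = truth.expected_dosage()
    rows = []
    for j, v in enumerate(panel.matrix.variants):
        tj = truth_by_key.get(v.match_key())
        if tj is None:
            continue
        g = truth_dosage[:, tj]
        if truth.variants[tj].eff_allele != v.eff_allele:
            g = 2.0 - g  # opposite allele counted: reflect the dosage
        r2 = allelic_dosage_r2(panel.matrix.probs[:, j, :], g,
                               panel.matrix.missing[:, j])
        rows.append({"chrom": v.chrom, "pos": v.pos, "id": v.id,
                     "maf": min(np.nanmean(g) / 2, 1 - np.nanmean(g) / 2),
                     "info": panel.info[v.match_key()], "r2": r2})
    return pd.DataFrame(rows)


def maf_binned_quality(r2: np.ndarray, maf: np.ndarray, info: np.ndarray,
                       bins: Sequence[float] = DEFAULT_MAF_BINS,
                       r2_floor: float = 0.5, info_floor: float = 0.7) -> pd.DataFrame:
    """Percent of variants per MAF bin that are both well imputed and high-info.

    A variant counts as high quality when ``r2 >= r2_floor`` and
    ``info >= info_floor``.  Bins are left-open intervals over ``bins``;
    an empty bin reports count 0 and a missing percentage.  The returned
    frame ends with an ``overall`` row.
    """
    r2 = np.asarray(r2, dtype=float)
    maf = np.asarray(maf, dtype=float)
    info = np.asarray(info, dtype=float)
    ok = np.isfinite(r2) & np.isfinite(maf) & np.isfinite(info)
    high = ok & (r2 >= r2_floor) & (info >= info_floor)
    rows = []
    edges = list(bins)
    for lo, hi in zip(edges[:-1], edges[1:]):
        inbin = ok & (maf > lo) & (maf <= hi)
        n = int(inbin.sum())
        pct = float(100.0 * high[inbin].sum() / n) if n else float("nan")
        rows.append({"maf_bin": f"({lo},{hi}]", "n": n, "pct_high_quality": pct})
    n_all = int(ok.sum())
    rows.append({"maf_bin": "overall", "n": n_all,
                 "pct_high_quality": float(100.0 * high.sum() / n_all) if n_all
                 else float("nan")})
    return pd.DataFrame(rows)
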