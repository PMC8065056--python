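"""Locus collapsing, experiment-wide threshold and inheritance classification.

Genome-wide significant variants on a chromosome are merged transitively
whenever they fall within a window (500 kb by default) of a variant already
in the locus — the reduce-with-window idiom.  Each locus carries its lead
variant (global minimum p over models), per-model minimum p-values, and an
inheritance classification that combines the per-model significance pattern
with the dominance-deviation test:

* significant only under additive -> ``additive``
* additive + a non-additive model -> non-additive only when the deviation
  test rejects additivity (p < 0.05), else ``additive``
* only non-additive model(s) -> non-additive when the deviation test
  rejects, else ``undetermined``

The non-additive subtype is the model with the smallest p-value.
X-chromosome loci are left out of deviation-based classification (the
deviation test is a diploid autosomal construct).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MODELS, AssociationRecord, chrom_sort_key
from .assoc import GENOME_WIDE_ALPHA

DEFAULT_WINDOW = 500_000
NON_ADDITIVE = ("dominant", "recessive", "heterodominant", "genotypic")


def experimentwide_threshold(alpha_gw: float = GENOME_WIDE_ALPHA,
                             effective_tests: float = 2.5) -> float:
    """Bonferroni correction of the genome-wide alpha for the effective
    number of inheritance-model tests (2.5 for the standard model set)."""
    if not 0 < alpha_gw < 1:
        raise ValueError(f"alpha out of (0, 1): {alpha_gw}")
    if effective_tests < 1:
        raise ValueError("effective_tests must be >= 1")
    return alpha_gw / effective_tests


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    lead: AssociationRecord
    phenotype: str | None = None
    best_model: str = ""
    model_min_p: Mapping[str, float] = field(default_factory=dict)
    members: list = field(default_factory=list)
    classification: str = "unclassified"
    dominance_deviation_p: float | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("locus start must be <= end")
        if not self.start <= self.lead.variant.pos <= self.end:
            raise ValueError("lead variant outside locus range")


def collapse_loci(records: Sequence[AssociationRecord],
                  window: int = DEFAULT_WINDOW,
                  threshold: float = GENOME_WIDE_ALPHA,
                  phenotype: str | None = None) -> list[Locus]:
    """Collapse significant records into loci by transitive window merging.

    Only records with ``p < threshold`` under at least one model seed loci.
    Variants whose position is within ``window`` of any variant already in
    a locus are merged into it (single linkage on member distance), so loci
    on a chromosome end up pairwise more than ``window`` apart.
    """
    sig = [r for r in records if r.p is not None and r.p < threshold]
    by_chrom: dict = {}
    for r in sig:
        by_chrom.setdefault(r.variant.chrom, []).append(r)

    loci = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.variant.pos, r.model))
        groups: list[list[AssociationRecord]] = []
        for r in recs:
            if groups and r.variant.pos - groups[-1][-1].variant.pos <= window:
                groups[-1].append(r)
            else:
                groups.append([r])
        for grp in groups:
            model_min_p: dict = {}
            for r in grp:
                cur = model_min_p.get(r.model)
                if cur is None or r.p < cur:
                    model_min_p[r.model] = r.p
            lead = min(grp, key=lambda r: r.p)
            loci.append(Locus(
                chrom=chrom,
                start=min(r.variant.pos for r in grp),
                end=max(r.variant.pos for r in grp),
                lead=lead, phenotype=phenotype,
                best_model=lead.model, model_min_p=model_min_p,
                members=grp,
            ))
    return loci


def classify_inheritance(locus: Locus, dominance_deviation_p: float | None,
                         alpha_dev: float = 0.05,
                         threshold: float = GENOME_WIDE_ALPHA) -> str:
    """Classify a locus as additive / non-additive:<model> / undetermined."""
    sig_models = {m for m, p in locus.model_min_p.items() if p < threshold}
    if not sig_models:
        raise ValueError("locus without a significant model is not a locus")
    additive_sig = "additive" in sig_models
    non_add_sig = sig_models & set(NON_ADDITIVE)
    if str(locus.chrom) == "X":
        return "additive" if additive_sig and not non_add_sig else "undetermined"

    def subtype():
        best = min(non_add_sig, key=lambda m: locus.model_min_p[m])
        return f"non-additive:{best}"

    deviates = dominance_deviation_p is not None and dominance_deviation_p < alpha_dev
    if additive_sig and not non_add_sig:
        result = "additive"
    elif additive_sig and non_add_sig:
        result = subtype() if deviates else "additive"
    else:
        result = subtype() if deviates else "undetermined"
    locus.classification = result
    locus.dominance_deviation_p = dominance_deviation_p
    return result


def loci_table(loci: Sequence[Locus]) -> pd.DataFrame:
    rows = []
    for loc in loci:
        row = {"chrom": loc.chrom, "start": loc.start, "end": loc.end,
               "lead_id": loc.lead.variant.id, "lead_p": loc.lead.p,
               "phenotype": loc.phenotype, "best_model": loc.best_model,
               "classification": loc.classification,
               "dominance_deviation_p": loc.dominance_deviation_p}
        for m in MODELS:
            row[f"{m}_min_p"] = loc.model_min_p.get(m)
        rows.append(row)
    return pd.DataFrame(rows)


def cross_phenotype_matrix(loci_by_phenotype: Mapping[str, Sequence[Locus]],
                           window: int = DEFAULT_WINDOW,
                           threshold: float = GENOME_WIDE_ALPHA) -> pd.DataFrame:
    """Locus-by-phenotype matrix of minimum p-values and significance flags.

    Loci from all phenotypes are merged by the same window rule; each cell
    holds the phenotype's minimum member p in the merged range (NaN where
    the phenotype has no variant there) and a ``<phenotype>_sig`` flag at
    the genome-wide threshold.
    """
    phenos = list(loci_by_phenotype)
    all_loci = [(ph, loc) for ph in phenos for loc in loci_by_phenotype[ph]]
    if not all_loci:
        return pd.DataFrame()
    merged: list[dict] = []
    for ph, loc in sorted(all_loci,
                          key=lambda t: (chrom_sort_key(t[1].chrom), t[1].start)):
        home = None
        for grp in merged:
            if grp["chrom"] == loc.chrom and (
                    loc.start <= grp["end"] + window and loc.end >= grp["start"] - window):
                home = grp
                break
        if home is None:
            home = {"chrom": loc.chrom, "start": loc.start, "end": loc.end,
                    "members": []}
            merged.append(home)
        home["start"] = min(home["start"], loc.start)
        home["end"] = max(home["end"], loc.end)
        home["members"].append((ph, loc))
    rows = []
    for grp in merged:
        row = {"chrom": grp["chrom"], "start": grp["start"], "end": grp["end"]}
        for ph in phenos:
            ps = [loc.lead.p for p, loc in grp["members"] if p == ph]
            row[ph] = min(ps) if ps else np.nan
            row[f"{ph}_sig"] = bool(ps and min(ps) < threshold)
        rows.append(row)
    return pd.DataFrame(rows)
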