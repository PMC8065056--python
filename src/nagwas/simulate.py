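"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: HWE
hard-call genotypes at declared allele frequencies, a binary phenotype from
a population logistic risk model on a declared inheritance-model encoding,
and per-panel imputation noise that turns hard calls into probability
triples with controllable certainty and panel-specific variant coverage.

Case-control data arise by population simulation plus logistic risk (not
retrospective sampling), so one mechanism serves association testing,
power checks and calibration tests alike.  Variants are simulated
independently: no linkage disequilibrium, no population structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from .io import GenotypeProbabilityMatrix, PhenotypeTable, VariantKey
from .qc import impute_info_score

import pandas as pd

SIM_MODELS = ("additive", "dominant", "recessive", "heterodominant", "genotypic", "null")

#: kappa at or above this produces exact one-hot triples
KAPPA_HARD_CAP = 1e6


@dataclass
class SimVariant:
    """One simulated variant: allele frequency, risk model and effect size."""

    maf: float
    model: str = "null"
    or_: float | tuple = 1.0
    chrom: str = "1"
    pos: int = 0
    id: str = ""
    ref_allele: str = "A"
    eff_allele: str = "G"

    def __post_init__(self):
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.model not in SIM_MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        ors = self.or_ if isinstance(self.or_, (tuple, list)) else (self.or_,)
        if any(o <= 0 for o in ors):
            raise ValueError("odds ratios must be positive")
        if self.model == "genotypic" and not isinstance(self.or_, (tuple, list)):
            raise ValueError("genotypic variants need (or_het, or_hom)")

    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.id, self.ref_allele,
                          self.eff_allele)

    @property
    def is_indel(self) -> bool:
        return self.key().is_indel


@dataclass
class PanelSpec:
    """One imputation panel: certainty parameter and variant coverage."""

    name: str
    kappa: float = 10.0
    covers: Callable[[SimVariant], bool] = field(default=lambda v: True)

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass
class SimulationSpec:
    n_samples: int = 2000
    case_fraction: float = 0.2
    variants: Sequence[SimVariant] = field(default_factory=list)
    sex_effect: float = 0.0
    age_effect: float = 0.0
    pc_effects: Sequence[float] = field(default_factory=list)
    panels: Sequence[PanelSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        self.variants = list(self.variants)
        for i, v in enumerate(self.variants):
            if v.pos == 0:
                v.pos = (i + 1) * 10_000
            if not v.id:
                v.id = f"sim{i + 1}"

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        variants = [SimVariant(
            maf=float(v["maf"]), model=v.get("model", "null"),
            or_=tuple(v["or"]) if isinstance(v.get("or", 1.0), list) else float(v.get("or", 1.0)),
            chrom=str(v.get("chrom", "1")), pos=int(v.get("pos", 0)),
            id=str(v.get("id", "")),
            ref_allele=str(v.get("ref_allele", "A")),
            eff_allele=str(v.get("eff_allele", "G")),
        ) for v in cfg.get("variants", [])]
        panels = []
        for p in cfg.get("panels", []):
            no_indels = bool(p.get("exclude_indels", False))
            panels.append(PanelSpec(
                name=str(p["name"]), kappa=float(p.get("kappa", 10.0)),
                covers=(lambda v, _ni=no_indels: not (_ni and v.is_indel)),
            ))
        return cls(
            n_samples=int(cfg.get("n_samples", 2000)),
            case_fraction=float(cfg.get("case_fraction", 0.2)),
            variants=variants,
            sex_effect=float(cfg.get("sex_effect", 0.0)),
            age_effect=float(cfg.get("age_effect", 0.0)),
            pc_effects=[float(x) for x in cfg.get("pc_effects", [])],
            panels=panels, seed=int(cfg.get("seed", 0)),
        )


def simulate_genotypes(spec: SimulationSpec, rng: np.random.Generator | None = None):
    """Draw true hard-call genotypes.

    Autosomal genotypes are Binomial(2, q) (HWE); X-chromosome males are
    0/1 hemizygotes.  Returns ``(genotypes, sex)`` with genotypes of shape
    ``(n_samples, n_variants)``.
    """
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n_samples
    sex = rng.integers(1, 3, size=n)  # 1 male / 2 female
    geno = np.empty((n, len(spec.variants)), dtype=np.int8)
    for j, v in enumerate(spec.variants):
        q = v.maf
        if str(v.chrom) == "X":
            male = sex == 1
            g = rng.binomial(2, q, size=n)
            g[male] = rng.binomial(1, q, size=int(male.sum()))
            geno[:, j] = g
        else:
            geno[:, j] = rng.binomial(2, q, size=n)
    return geno, sex


def _risk_encoding(g: np.ndarray, v: SimVariant, sex: np.ndarray) -> np.ndarray:
    """Linear-predictor contribution of one variant (log-odds units)."""
    if v.model == "null":
        return np.zeros(len(g), dtype=float)
    if v.model == "genotypic":
        b_het, b_hom = np.log(v.or_[0]), np.log(v.or_[1])
        x = np.where(g == 1, b_het, 0.0) + np.where(g == 2, b_hom, 0.0)
        if str(v.chrom) == "X":
            x = np.where((sex == 1) & (g == 1), b_hom, x)  # hemizygote = hom scale
        return x
    beta = np.log(float(v.or_))
    gg = g.astype(float)
    if str(v.chrom) == "X":
        gg = np.where(sex == 1, 2.0 * gg, gg)  # full inactivation
    if v.model == "additive":
        enc = gg
    elif v.model == "dominant":
        enc = (gg >= 1).astype(float)
    elif v.model == "recessive":
        enc = (gg == 2).astype(float)
    else:  # heterodominant
        enc = (gg == 1).astype(float)
    return beta * enc


def simulate_phenotype(genotypes: np.ndarray, spec: SimulationSpec,
                       sex: np.ndarray | None = None,
                       rng: np.random.Generator | None = None) -> PhenotypeTable:
    """Binary disease status from a population logistic risk model.

    ``P(case) = logistic(alpha + sum_v beta_v x_v + covariate terms)`` with
    ``beta_v = ln(OR_v)`` on each variant's declared encoding; the intercept
    is solved by bisection so the expected case fraction hits the target.
    Age ~ Uniform(40, 90), sex ~ Bernoulli(1/2), PCs ~ N(0, 1).
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    n = genotypes.shape[0]
    if sex is None:
        sex = rng.integers(1, 3, size=n)
    age = rng.uniform(40, 90, size=n)
    n_pc = len(spec.pc_effects)
    pcs = rng.standard_normal((n, n_pc)) if n_pc else np.empty((n, 0))

    lin = np.zeros(n)
    for j, v in enumerate(spec.variants):
        lin += _risk_encoding(genotypes[:, j], v, sex)
    lin += spec.sex_effect * (sex == 2)
    lin += spec.age_effect * (age - 65.0) / 10.0
    for k, b in enumerate(spec.pc_effects):
        lin += b * pcs[:, k]

    def mean_risk(alpha):
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + lin))))) - spec.case_fraction

    lo, hi = -40.0, 40.0
    if mean_risk(lo) > 0 or mean_risk(hi) < 0:
        raise ValueError("target case fraction unattainable under these effects")
    alpha = brentq(mean_risk, lo, hi, xtol=1e-12)
    status = rng.binomial(1, 1.0 / (1.0 + np.exp(-(alpha + lin)))).astype(int)

    df = pd.DataFrame({"status": status, "sex": sex, "age": age},
                      index=[f"sample_{i + 1}" for i in range(n)])
    for k in range(n_pc):
        df[f"PC{k + 1}"] = pcs[:, k]
    return PhenotypeTable(df)


def _dirichlet_triples(g: np.ndarray, kappa: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Noisy probability triples centered on the true genotypes.

    Concentration ``alpha_j = 1 + kappa`` on the true genotype and 0.5 on
    the two others: uninformative at kappa 0, hard calls as kappa grows.
    """
    n = len(g)
    onehot = np.zeros((n, 3))
    onehot[np.arange(n), g] = 1.0
    if kappa >= KAPPA_HARD_CAP:
        return onehot
    alpha = 0.5 + onehot * (0.5 + kappa)
    draws = rng.standard_gamma(alpha)
    return draws / draws.sum(axis=1, keepdims=True)


def simulate_imputation(genotypes: np.ndarray, spec: SimulationSpec,
                        sex: np.ndarray | None = None,
                        rng: np.random.Generator | None = None):
    """Per-panel imputed probability triples for the true genotypes.

    Each panel covers the variants its coverage predicate admits; covered
    variants get Dirichlet-noise triples whose concentration grows with the
    panel's kappa, and the IMPUTE2-style info score is attached per variant.
    X-chromosome male triples put their single-allele probability on the
    (p0, p1) components.  Returns a list of
    :class:`~nagwas.panels.PanelResultSet`.
    """
    from .panels import PanelResultSet

    rng = rng or np.random.default_rng(spec.seed + 2)
    n = genotypes.shape[0]
    samples = [f"sample_{i + 1}" for i in range(n)]
    results = []
    for panel in spec.panels:
        cols, variants = [], []
        for j, v in enumerate(spec.variants):
            if not panel.covers(v):
                continue
            g = genotypes[:, j].astype(int)
            trips = _dirichlet_triples(g, panel.kappa, rng)
            if str(v.chrom) == "X" and sex is not None:
                male = sex == 1
                two = _dirichlet_triples(g[male], panel.kappa, rng)[:, :2]
                hemi = np.zeros((int(male.sum()), 3))
                denom = two.sum(axis=1, keepdims=True)
                hemi[:, :2] = two / denom
                trips[male] = hemi
            variants.append(v.key())
            cols.append(trips)
        probs = (np.stack(cols, axis=1) if cols
                 else np.empty((n, 0, 3)))
        matrix = GenotypeProbabilityMatrix(variants, samples, probs)
        info = {vk.match_key(): impute_info_score(matrix.probs[:, j, :],
                                                  matrix.missing[:, j])
                for j, vk in enumerate(matrix.variants)}
        results.append(PanelResultSet(name=panel.name, matrix=matrix, info=info))
    return results


def simulate_cohort(spec: SimulationSpec):
    """Convenience end-to-end draw: genotypes, phenotypes and panel sets."""
    rng = np.random.default_rng(spec.seed)
    genotypes, sex = simulate_genotypes(spec, rng)
    phenotypes = simulate_phenotype(genotypes, spec, sex=sex, rng=rng)
    panels = simulate_imputation(genotypes, spec, sex=sex, rng=rng)
    return genotypes, phenotypes, panels
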