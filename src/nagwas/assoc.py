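"""Five-inheritance-model logistic association testing.

Genotype uncertainty enters through expected encodings of the probability
triple (the deterministic "expected" method): each inheritance model maps a
triple ``(p0, p1, p2)`` to one or two design columns,

========== ======================
additive   ``p1 + 2 p2`` (dosage)
dominant   ``p1 + p2``
recessive  ``p2``
heterodom. ``p1``
genotypic  ``[p1, p2]``
========== ======================

and a maximum-likelihood logistic regression with covariates is fitted per
variant.  Single-column models are tested with a 1-df Wald test, the
genotypic model with a 2-df likelihood-ratio test against the
covariate-only fit.  X-chromosome variants use a full-inactivation
encoding: females are scored as autosomes while a male's single-allele
probability is mapped onto the homozygote scale, so hemizygote carriers
behave like female homozygotes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import MODELS, AssociationRecord, GenotypeProbabilityMatrix, PhenotypeTable
from .qc import QcThresholds, hwe_exact_test, impute_info_score, post_association_filter

GENOME_WIDE_ALPHA = 5e-8
#: hg19 pseudoautosomal boundaries; only non-PAR X is analysed
PAR1_END = 2_699_520
PAR2_START = 154_931_044
#: |beta| beyond this marks quasi-complete separation / non-convergence
SEPARATION_BETA = 15.0


def is_par(chrom: str, pos: int) -> bool:
    return str(chrom) == "X" and (pos <= PAR1_END or pos >= PAR2_START)


def encode_model(triples: np.ndarray, model: str, sex: np.ndarray | None = None,
                 chrom: str = "1") -> tuple[np.ndarray, np.ndarray]:
    """Design column(s) for one variant; returns ``(columns, valid_mask)``.

    ``triples`` is ``(n, 3)``.  For X variants ``sex`` (1 male / 2 female)
    is required; samples with missing sex are dropped via the mask.  Male X
    probabilities are collapsed to a single-allele probability
    ``p(B) = p1 + p2`` and mapped to the homozygote scale.
    """
    triples = np.asarray(triples, dtype=float)
    n = len(triples)
    p1, p2 = triples[:, 1], triples[:, 2]
    valid = np.ones(n, dtype=bool)
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")

    if str(chrom) != "X":
        cols = _autosomal_columns(p1, p2, model)
        return cols, valid

    if sex is None:
        raise ValueError("sex is required for X-chromosome encoding")
    sex = np.asarray(sex, dtype=float)
    valid = np.isfinite(sex) & np.isin(sex, (1.0, 2.0))
    male = sex == 1.0
    cols = _autosomal_columns(p1, p2, model)
    p_b = p1 + p2  # male single-allele probability
    if model == "additive":
        cols[male, 0] = 2.0 * p_b[male]
    elif model in ("dominant", "recessive"):
        cols[male, 0] = p_b[male]
    elif model == "heterodominant":
        cols[male, 0] = 0.0
    else:  # genotypic: [het, hom]; males load only the homozygote column
        cols[male, 0] = 0.0
        cols[male, 1] = p_b[male]
    return cols, valid


def _autosomal_columns(p1, p2, model):
    if model == "additive":
        return (p1 + 2.0 * p2)[:, None].copy()
    if model == "dominant":
        return (p1 + p2)[:, None].copy()
    if model == "recessive":
        return p2[:, None].copy()
    if model == "heterodominant":
        return p1[:, None].copy()
    return np.column_stack([p1, p2])


@dataclass
class LogisticFit:
    """Result of one IRLS logistic fit."""

    coef: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    iterations: int
    term_names: list = field(default_factory=list)
    joint_p: float | None = None  # 2-df LRT p for multi-column genotype terms

    def wald_z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coef / self.se

    def wald_p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.wald_z()))


def _irls(y, design, weights=None, tol=1e-8, max_iter=25):
    n, k = design.shape
    w_obs = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    beta = np.zeros(k)
    ybar = np.clip(np.average(y, weights=w_obs), 1e-9, 1 - 1e-9)
    beta[0] = np.log(ybar / (1 - ybar))  # intercept warm start
    converged = False
    it = 0
    singular = False
    for it in range(1, max_iter + 1):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = w_obs * mu * (1.0 - mu)
        xtw = design.T * w
        hess = xtw @ design
        grad = design.T @ (w_obs * (y - mu))
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            singular = True
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = design @ beta
    # log-likelihood via the numerically stable log1p(exp) form
    ll = float(np.sum(w_obs * (y * eta - np.logaddexp(0.0, eta))))
    se = np.full(k, np.nan)
    if not singular:
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = w_obs * mu * (1.0 - mu)
        hess = (design.T * w) @ design
        try:
            cov = np.linalg.inv(hess)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            converged = False
    return beta, se, ll, converged, it


def fit_logistic(status, genotype_cols, covariates=None, weights=None,
                 tol: float = 1e-8, max_iter: int = 25) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    The design is ``[intercept, genotype column(s), covariates]``; covariates
    are standardized internally for conditioning (genotype effects are
    unaffected, covariate effects are not reported on the original scale).
    Quasi-complete separation — any genotype |beta| > 15 or non-convergence —
    sets ``converged=False`` and callers must treat the statistics as
    missing rather than report fabricated estimates.

    For a two-column genotype term the joint test is a 2-df likelihood-ratio
    test against the covariate-only model.
    """
    y = np.asarray(status, dtype=float)
    if weights is None:
        n_case = float((y == 1).sum())
        n_ctrl = float((y == 0).sum())
    else:
        w = np.asarray(weights, dtype=float)
        n_case = float(w[y == 1].sum())
        n_ctrl = float(w[y == 0].sum())
    if n_case < 1 or n_ctrl < 1:
        raise ValueError("need at least one case and one control")
    geno = np.atleast_2d(np.asarray(genotype_cols, dtype=float))
    if geno.shape[0] != len(y):
        geno = geno.T
    n_geno = geno.shape[1]
    parts = [np.ones((len(y), 1)), geno]
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(y):
            cov = cov.T
        mean = cov.mean(axis=0)
        sd = cov.std(axis=0)
        sd[sd == 0] = 1.0
        parts.append((cov - mean) / sd)
    design = np.column_stack(parts)

    # drop constant genotype columns: the model is unidentifiable there
    keep = np.ones(design.shape[1], dtype=bool)
    for j in range(1, 1 + n_geno):
        if np.ptp(design[:, j]) == 0:
            keep[j] = False
    if not keep[1:1 + n_geno].any():
        raise ValueError("genotype column is constant (monomorphic variant)")
    dropped = ~keep
    design = design[:, keep]

    n_geno_kept = int(keep[1:1 + n_geno].sum())
    beta, se, ll, conv, it = _irls(y, design, weights, tol, max_iter)
    if conv and np.any(np.abs(beta[1:1 + n_geno_kept]) > SEPARATION_BETA):
        conv = False

    # re-expand dropped genotype columns as NaN
    full_k = len(keep)
    coef = np.full(full_k, np.nan)
    se_full = np.full(full_k, np.nan)
    coef[keep] = beta
    se_full[keep] = se

    joint_p = None
    if n_geno > 1 and conv:
        red_cols = np.ones(full_k, dtype=bool)
        red_cols[1:1 + n_geno] = False
        red_design = np.column_stack(parts)[:, red_cols]
        _, _, ll0, conv0, _ = _irls(y, red_design, weights, tol, max_iter)
        if conv0:
            lrt = max(0.0, 2.0 * (ll - ll0))
            joint_p = float(stats.chi2.sf(lrt, df=n_geno_kept))
    names = (["intercept"] + [f"geno{j}" for j in range(n_geno)]
             + [f"covar{j}" for j in range(full_k - 1 - n_geno)])
    return LogisticFit(coef=coef, se=se_full, loglik=ll, converged=conv,
                       iterations=it, term_names=names, joint_p=joint_p)


def _model_record(variant, model, fit: LogisticFit, n_geno: int) -> dict:
    """Effect/SE/p block for one fitted model; NaNs if not converged."""
    out = {}
    if not fit.converged:
        out.update(beta=None, se=None, p=None, converged=False)
        return out
    if n_geno == 1:
        out["beta"] = float(fit.coef[1])
        out["se"] = float(fit.se[1])
        out["p"] = float(fit.wald_p()[1])
    else:
        out["beta_het"] = float(fit.coef[1])
        out["se_het"] = float(fit.se[1])
        out["beta_hom"] = float(fit.coef[2])
        out["se_hom"] = float(fit.se[2])
        out["p"] = fit.joint_p
    out["converged"] = True
    return out


def association_for_variant(triples, missing, variant, phenotypes: PhenotypeTable,
                            covariate_names=(), models=MODELS,
                            hard_call_threshold: float = 0.9):
    """Fit the requested inheritance models for one variant.

    Returns a list of :class:`AssociationRecord`; monomorphic or separated
    fits yield ``converged=False`` records with missing statistics.
    """
    y = phenotypes.status
    sex = phenotypes.sex
    covars = phenotypes.covariates(covariate_names)
    use = ~np.asarray(missing, dtype=bool) & np.isfinite(y)
    triples = np.asarray(triples, dtype=float)

    calls = np.where(np.max(triples, axis=1) >= hard_call_threshold,
                     np.argmax(triples, axis=1), -1)
    calls = np.where(use, calls, -1)
    is_x = str(variant.chrom) == "X"
    if is_x:
        # hemizygote carrier males count as effect-allele homozygotes
        male = sex == 1.0
        carrier = np.isin(calls, (1, 2))
        eff_hom = np.where(male, carrier, calls == 2)
    else:
        eff_hom = calls == 2
    alt_hom_cases = int(np.sum(eff_hom & (y == 1) & use))
    ctrl = (y == 0) & use & (calls >= 0)
    if is_x:
        ctrl = ctrl & (sex == 2.0)  # control HWE is a diploid notion
    counts = [int(np.sum(ctrl & (calls == g))) for g in (0, 1, 2)]
    hwe_p = hwe_exact_test(*counts) if sum(counts) >= 1 else float("nan")

    dose = triples[:, 1] + 2.0 * triples[:, 2]
    theta = float(np.mean(dose[use]) / 2.0) if use.any() else float("nan")
    maf = min(theta, 1.0 - theta)
    info = impute_info_score(triples, ~use)

    records = []
    for model in models:
        cols, valid = encode_model(triples, model, sex=sex if is_x else None,
                                   chrom=variant.chrom)
        mask = use & valid
        common = dict(
            variant=variant, model=model, maf=maf, info=info,
            n_cases=int((y[mask] == 1).sum()), n_controls=int((y[mask] == 0).sum()),
            alt_hom_cases=alt_hom_cases, hwe_controls_p=hwe_p,
        )
        try:
            fit = fit_logistic(y[mask], cols[mask],
                               covars[mask] if covars.size else None)
        except ValueError:
            records.append(AssociationRecord(converged=False, **common))
            continue
        block = _model_record(variant, model, fit, cols.shape[1])
        records.append(AssociationRecord(**common, **{k: v for k, v in block.items()}))
    return records


def run_association(combined, phenotypes: PhenotypeTable, covariate_names=(),
                    models=MODELS, thresholds: QcThresholds | None = None,
                    gw_threshold: float = GENOME_WIDE_ALPHA,
                    apply_filter: bool = True):
    """Association testing over a combined (or single-panel) variant set.

    ``combined`` may be a :class:`~nagwas.panels.CombinedSet` or a bare
    :class:`GenotypeProbabilityMatrix`.  PAR X variants are excluded with a
    warning.  The post-association filter is applied unless disabled.
    """
    thresholds = thresholds or QcThresholds()
    matrix = getattr(combined, "matrix", combined)
    info = getattr(combined, "info", None)
    source = getattr(combined, "source_panel", None)
    phenotypes = phenotypes.aligned_to(matrix.samples)

    records = []
    for j, variant in enumerate(matrix.variants):
        if is_par(variant.chrom, variant.pos):
            warnings.warn(f"excluding pseudoautosomal variant {variant.id}")
            continue
        recs = association_for_variant(
            matrix.probs[:, j, :], matrix.missing[:, j], variant, phenotypes,
            covariate_names, models, thresholds.hard_call_threshold)
        for rec in recs:
            if info is not None:
                rec.info = float(info[variant.match_key()])
            if source is not None:
                rec.panel = source[variant.match_key()]
        records.extend(recs)
    records = [r for r in records if r.converged]
    if apply_filter:
        records = post_association_filter(records, thresholds)
    return records


def stratified_x_association(matrix: GenotypeProbabilityMatrix,
                             phenotypes: PhenotypeTable, models=MODELS,
                             covariate_names=()):
    """Sex-stratified X-chromosome association.

    Fits a sex-specific baseline (sex main effect) with a shared genotype
    effect on the full-inactivation encoding — equivalent to pooling the
    sex-stratified scores.  Falls back to the unstratified fit with a
    warning when only one sex is present.  Each record's ``panel`` field
    carries the method tag used.
    """
    phenotypes = phenotypes.aligned_to(matrix.samples)
    sex = phenotypes.sex
    sexes = set(np.unique(sex[np.isfinite(sex)]))
    stratify = sexes >= {1.0, 2.0}
    if not stratify:
        warnings.warn("single-sex data: falling back to unstratified X fit")
    y = phenotypes.status
    covars = phenotypes.covariates(covariate_names)
    records = []
    for j, variant in enumerate(matrix.variants):
        if is_par(variant.chrom, variant.pos):
            warnings.warn(f"excluding pseudoautosomal variant {variant.id}")
            continue
        triples = matrix.probs[:, j, :]
        for model in models:
            cols, valid = encode_model(triples, model, sex=sex, chrom=variant.chrom)
            mask = valid & ~matrix.missing[:, j] & np.isfinite(y)
            parts = [covars[mask]] if covars.size else []
            if stratify:
                parts.insert(0, (sex[mask] == 1.0).astype(float)[:, None])
            cov = np.column_stack(parts) if parts else None
            common = dict(variant=variant, model=model,
                          panel="x:stratified" if stratify else "x:pooled",
                          n_cases=int((y[mask] == 1).sum()),
                          n_controls=int((y[mask] == 0).sum()))
            try:
                fit = fit_logistic(y[mask], cols[mask], cov)
            except ValueError:
                records.append(AssociationRecord(converged=False, hwe_controls_p=1.0,
                                                 alt_hom_cases=0, **common))
                continue
            block = _model_record(variant, model, fit, cols.shape[1])
            records.append(AssociationRecord(hwe_controls_p=1.0, alt_hom_cases=0,
                                             **common, **block))
    return records


def dominance_deviation_test(triples, phenotypes: PhenotypeTable,
                             covariate_names=("sex", "age"),
                             missing=None):
    """Test departure from additivity at one variant.

    Adds an expected-heterozygosity column (``p1``) to the additive dosage
    and returns the Wald p-value of that deviation coefficient, or
    ``(None, reason)`` when there are no heterozygote carriers or the fit
    separates.
    """
    triples = np.asarray(triples, dtype=float)
    use = np.isfinite(phenotypes.status)
    if missing is not None:
        use &= ~np.asarray(missing, dtype=bool)
    covars = phenotypes.covariates([c for c in covariate_names
                                    if c == "sex" or c in phenotypes.df.columns])
    sex_ok = np.ones(len(use), dtype=bool)
    if "sex" in covariate_names:
        sex_ok = np.isfinite(phenotypes.sex)
    use &= sex_ok
    p1 = triples[use, 1]
    if np.sum(p1) < 1e-9:
        return None, "no heterozygote carriers"
    dose = triples[use, 1] + 2.0 * triples[use, 2]
    cols = np.column_stack([dose, p1])
    try:
        fit = fit_logistic(phenotypes.status[use], cols,
                           covars[use] if covars.size else None)
    except ValueError as exc:
        return None, str(exc)
    if not fit.converged:
        return None, "non-convergence / separation"
    return float(fit.wald_p()[2]), None
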