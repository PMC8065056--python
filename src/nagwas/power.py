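"""Power and required sample size per inheritance model.

For carrier-style models the variant is a binary exposure — effect-allele
homozygosity (recessive, population frequency ``q^2`` under HWE) or
carriage of at least one copy (dominant, ``1 - (1-q)^2``) — and power is
the classical two-proportion normal approximation with unequal case-control
allocation: the control exposure frequency equals the population frequency
(rare-disease approximation) and the case exposure frequency is obtained by
applying the odds ratio to the exposure odds.

For the additive model the per-allele odds ratio is treated as a
multiplicative genotype relative risk in a population with disease
prevalence equal to the study case fraction (the convention of the classic
genetic power calculators): baseline risk is solved so genotype-averaged
risk matches the prevalence, case and control allele frequencies follow by
Bayes' rule, and power comes from the 1-df allelic/trend-test
noncentrality on 2N alleles.

"Population sample size" means the total cohort size at the study's
observed case fraction.  A Monte-Carlo oracle that simulates cohorts and
pushes them through the logistic Wald test of the association engine
serves as the correctness check for the analytic approximations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GENOME_WIDE_ALPHA = 5e-8
N_CAP = 1_000_000_000
POWER_MODELS = ("additive", "dominant", "recessive")


@dataclass
class PowerSpec:
    model: str
    maf: float
    or_: float
    alpha: float = GENOME_WIDE_ALPHA
    target_power: float = 0.80
    n_cases: int | None = None
    n_controls: int | None = None
    case_fraction: float | None = None

    def __post_init__(self):
        if self.model not in POWER_MODELS:
            raise ValueError(f"model must be one of {POWER_MODELS}")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if self.or_ <= 0:
            raise ValueError("odds ratio must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target power must be in (0, 1)")
        if self.case_fraction is None:
            if self.n_cases is None or self.n_controls is None:
                raise ValueError("need case_fraction or (n_cases, n_controls)")
            self.case_fraction = self.n_cases / (self.n_cases + self.n_controls)
        if not 0 < self.case_fraction < 1:
            raise ValueError("case fraction must be in (0, 1)")


def genotype_frequencies(maf: float):
    """HWE genotype frequencies ``((1-q)^2, 2q(1-q), q^2)``."""
    if not 0 < maf < 1:
        raise ValueError("allele frequency must be in (0, 1)")
    q = maf
    return ((1 - q) ** 2, 2 * q * (1 - q), q * q)


def exposure_frequencies(spec: PowerSpec):
    """Control and case exposure frequencies for carrier-style models."""
    q = spec.maf
    f = q * q if spec.model == "recessive" else 1 - (1 - q) ** 2
    if f <= 0 or f >= 1:
        raise ValueError("degenerate exposure frequency")
    odds_case = spec.or_ * f / (1 - f)
    if not np.isfinite(odds_case):
        raise ValueError("exposure odds overflow")
    p1 = odds_case / (1 + odds_case)
    return f, p1


def _case_control_allele_freqs(spec: PowerSpec):
    """Case/control effect-allele frequencies under the multiplicative
    genotype-relative-risk model at prevalence = case fraction."""
    q = spec.maf
    k = spec.case_fraction
    f = np.array(genotype_frequencies(q))
    rr = np.array([1.0, spec.or_, spec.or_**2])
    r0 = k / float(np.sum(f * rr))
    risks = r0 * rr
    if np.any(risks >= 1.0):
        raise ValueError(
            "genotype risk exceeds 1 under this prevalence/odds-ratio pair")
    g_case = f * risks / k
    g_ctrl = f * (1.0 - risks) / (1.0 - k)
    q_case = g_case[1] / 2 + g_case[2]
    q_ctrl = g_ctrl[1] / 2 + g_ctrl[2]
    return q_case, q_ctrl, g_case, g_ctrl


def _two_sided_power(mean_z: float, z_alpha: float) -> float:
    return float(stats.norm.sf(z_alpha - mean_z) + stats.norm.sf(z_alpha + mean_z))


def power_case_control(spec: PowerSpec, total_n: int) -> float:
    """Analytic power at a total cohort size ``total_n``."""
    if total_n < 10:
        raise ValueError("total_n must be >= 10")
    phi = spec.case_fraction
    n1, n2 = phi * total_n, (1 - phi) * total_n
    z_a = stats.norm.isf(spec.alpha / 2.0)

    if spec.model in ("recessive", "dominant"):
        p0, p1 = exposure_frequencies(spec)
        d = p1 - p0
        pbar = (n1 * p1 + n2 * p0) / (n1 + n2)
        se0 = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
        se1 = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n2)
        return float(stats.norm.sf((z_a * se0 - d) / se1)
                     + stats.norm.sf((z_a * se0 + d) / se1))

    q_case, q_ctrl, _, _ = _case_control_allele_freqs(spec)
    d = q_case - q_ctrl
    pbar = phi * q_case + (1 - phi) * q_ctrl
    se = np.sqrt(pbar * (1 - pbar) * (1 / (2 * n1) + 1 / (2 * n2)))
    return _two_sided_power(d / se, z_a)


def sample_size_for_power(spec: PowerSpec, n_cap: int = N_CAP) -> int:
    """Smallest total cohort size reaching the target power.

    Bisection on the (monotone) analytic power over total N at the fixed
    case fraction; returns the crossing N rounded up.
    """
    lo, hi = 10, 20
    while power_case_control(spec, hi) < spec.target_power:
        lo = hi
        hi *= 2
        if hi > n_cap:
            raise ValueError(f"target power unreachable below N = {n_cap}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_case_control(spec, mid) >= spec.target_power:
            hi = mid
        else:
            lo = mid
    return hi


def power_curve(spec: PowerSpec, maf_grid) -> pd.DataFrame:
    """Required total N across a MAF grid; unreachable points are flagged."""
    rows = []
    for maf in maf_grid:
        row = {"maf": float(maf), "model": spec.model, "or": spec.or_}
        try:
            point = PowerSpec(model=spec.model, maf=float(maf), or_=spec.or_,
                              alpha=spec.alpha, target_power=spec.target_power,
                              case_fraction=spec.case_fraction)
            row["required_n"] = sample_size_for_power(point)
            row["reachable"] = True
        except ValueError:
            row["required_n"] = np.nan
            row["reachable"] = False
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------


def monte_carlo_power(spec: PowerSpec, total_n: int, n_reps: int = 2000,
                      seed: int = 0, statistic: str = "wald") -> float:
    """Simulation power estimate through the association engine.

    Each replicate draws case/control exposure (or genotype) counts from
    the same population model the analytic formulas assume, expands them to
    a frequency-weighted design, and applies the logistic test of
    :func:`nagwas.assoc.fit_logistic` (1-df, two-sided).  Non-convergent
    (separated) fits count as non-rejections, mirroring how such variants
    are excluded downstream.

    ``statistic`` selects the test applied per replicate: ``"wald"`` is the
    engine's reported test; ``"score"`` is the logistic score test (the
    pooled-variance 2x2 chi-square for a binary exposure), which is the
    statistic the analytic approximation tracks.  The two agree at moderate
    exposed counts; with very few expected carriers the Wald test is
    conservative and its power falls below the score test's.
    """
    from .assoc import fit_logistic

    if statistic not in ("wald", "score"):
        raise ValueError("statistic must be 'wald' or 'score'")
    rng = np.random.default_rng(seed)
    phi = spec.case_fraction
    n1 = int(round(total_n * phi))
    n2 = total_n - n1
    rejections = 0

    if spec.model in ("recessive", "dominant"):
        p0, p1 = exposure_frequencies(spec)
        a = rng.binomial(n1, p1, size=n_reps)   # exposed cases
        c = rng.binomial(n2, p0, size=n_reps)   # exposed controls
        if statistic == "score":
            z_a = stats.norm.isf(spec.alpha / 2.0)
            pp = (a + c) / (n1 + n2)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.abs(a / n1 - c / n2) / np.sqrt(
                    pp * (1 - pp) * (1 / n1 + 1 / n2))
            return float(np.mean(np.nan_to_num(z) > z_a))
        for i in range(n_reps):
            y = np.array([1.0, 1.0, 0.0, 0.0])
            x = np.array([1.0, 0.0, 1.0, 0.0])
            w = np.array([a[i], n1 - a[i], c[i], n2 - c[i]], dtype=float)
            keep = w > 0
            if len(np.unique(x[keep])) < 2 or len(np.unique(y[keep])) < 2:
                continue
            fit = fit_logistic(y[keep], x[keep][:, None], weights=w[keep])
            if fit.converged and fit.wald_p()[1] < spec.alpha:
                rejections += 1
        return rejections / n_reps

    _, _, g_case, g_ctrl = _case_control_allele_freqs(spec)
    cases = rng.multinomial(n1, g_case, size=n_reps)
    ctrls = rng.multinomial(n2, g_ctrl, size=n_reps)
    if statistic == "score":
        z_a = stats.norm.isf(spec.alpha / 2.0)
        qc_hat = (cases[:, 1] + 2 * cases[:, 2]) / (2 * n1)
        q0_hat = (ctrls[:, 1] + 2 * ctrls[:, 2]) / (2 * n2)
        pp = (phi * qc_hat + (1 - phi) * q0_hat)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(qc_hat - q0_hat) / np.sqrt(
                pp * (1 - pp) * (1 / (2 * n1) + 1 / (2 * n2)))
        return float(np.mean(np.nan_to_num(z) > z_a))
    for i in range(n_reps):
        y = np.repeat([1.0, 0.0], 3)
        x = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        w = np.concatenate([cases[i], ctrls[i]]).astype(float)
        keep = w > 0
        if len(np.unique(x[keep])) < 2 or len(np.unique(y[keep])) < 2:
            continue
        fit = fit_logistic(y[keep], x[keep][:, None], weights=w[keep])
        if fit.converged and fit.wald_p()[1] < spec.alpha:
            rejections += 1
    return rejections / n_reps
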