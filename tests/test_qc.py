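"""Info score, exact HWE test and the two filter stages."""

import numpy as np
import pytest
from scipy.special import gammaln

from nagwas.io import AssociationRecord, VariantKey
from nagwas.qc import (QcThresholds, hwe_exact_test, impute_info_score,
                       marker_qc, post_association_filter)
from conftest import random_matrix


# ---------------------------------------------------------------------------
# info score
# ---------------------------------------------------------------------------

def test_info_is_one_for_hard_calls():
    trips = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 1, 0]], dtype=float)
    assert impute_info_score(trips) == pytest.approx(1.0)


def test_info_hand_value_for_uninformative_triples():
    trips = np.full((2, 3), 1 / 3)
    assert impute_info_score(trips) == pytest.approx(-1 / 3)


def test_info_monomorphic_convention():
    trips = np.tile([1.0, 0, 0], (5, 1))
    assert impute_info_score(trips) == 1.0


def test_info_missing_handling():
    trips = np.array([[1, 0, 0], [0.2, 0.2, 0.2]])
    missing = np.array([False, True])
    assert impute_info_score(trips, missing) == 1.0
    assert np.isnan(impute_info_score(trips, np.array([True, True])))


def test_info_never_exceeds_one(rng):
    for _ in range(50):
        trips = rng.dirichlet([0.4, 0.4, 0.4], size=20)
        assert impute_info_score(trips) <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# HWE exact test, against an exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def hwe_oracle(n_aa, n_ab, n_bb):
    """Exhaustive log-gamma enumeration of the conditional het distribution."""
    n = n_aa + n_ab + n_bb
    rare = 2 * min(n_aa, n_bb) + n_ab

    def logp(het):
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        return (gammaln(n + 1) - gammaln(hom_r + 1) - gammaln(het + 1)
                - gammaln(hom_c + 1) + het * np.log(2)
                + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1))

    hets = range(rare % 2, rare + 1, 2)
    logs = np.array([logp(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[list(hets).index(n_ab)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def test_hwe_single_configuration_is_one():
    assert hwe_exact_test(7, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 11) == 1.0


def test_hwe_matches_enumeration_oracle_at_hand_example():
    assert hwe_exact_test(25, 50, 25) == pytest.approx(hwe_oracle(25, 50, 25),
                                                       abs=1e-12)


def test_hwe_extreme_disequilibrium_below_cohort_floor():
    p = hwe_exact_test(100, 0, 100)
    assert p < 1e-20
    assert p == pytest.approx(hwe_oracle(100, 0, 100), rel=1e-9)


@pytest.mark.parametrize("counts", [
    (5, 5, 5), (50, 20, 30), (0, 10, 0), (3, 0, 97), (40, 40, 20), (1, 2, 1),
])
def test_hwe_agrees_with_oracle(counts):
    assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts),
                                                    abs=1e-12)


def test_hwe_agrees_with_oracle_on_random_tables(rng):
    for _ in range(40):
        n = int(rng.integers(2, 100))  # up to 200 chromosomes
        aa = int(rng.integers(0, n + 1))
        ab = int(rng.integers(0, n - aa + 1))
        counts = (aa, ab, n - aa - ab)
        assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts),
                                                        abs=1e-12)


def test_hwe_rejects_negative_counts():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


# ---------------------------------------------------------------------------
# marker QC
# ---------------------------------------------------------------------------

def _matrix_from_dosages(dosages, chrom="1"):
    """One-hot matrix from integer genotypes (samples x variants)."""
    from nagwas.io import GenotypeProbabilityMatrix
    g = np.asarray(dosages)
    probs = np.zeros(g.shape + (3,))
    s, v = np.meshgrid(*map(np.arange, g.shape), indexing="ij")
    probs[s, v, g] = 1.0
    variants = [VariantKey(chrom, 1000 * (j + 1), f"rs{j + 1}", "A", "G")
                for j in range(g.shape[1])]
    samples = [f"sample_{i + 1}" for i in range(g.shape[0])]
    return GenotypeProbabilityMatrix(variants, samples, probs)


def test_marker_qc_flags_missingness(rng):
    g = rng.binomial(2, 0.3, size=(100, 1))
    matrix = _matrix_from_dosages(g)
    matrix.probs[:6, 0, :] = 0.2  # 6% deflated triples -> missing
    matrix.missing[:6, 0] = True
    kept, report = marker_qc(matrix)
    assert kept.n_variants == 0
    assert report.loc[0, "reason"] == "missingness"


def test_marker_qc_maf_boundary():
    # two variants: MAF 0.0009 (removed) and exactly 0.001 (kept)
    n = 10000
    g = np.zeros((n, 2), dtype=int)
    g[:9, 0] = 1    # 9 / 20000 alleles = 0.00045... scaled to expected dosage
    g[:20, 1] = 1   # 20 / 20000 = 0.001
    g[:18, 0] = 0
    g[:9, 0] = 1
    matrix = _matrix_from_dosages(g)
    maf = matrix.maf()
    assert maf[0] < 0.001 <= maf[1] + 1e-12
    kept, report = marker_qc(matrix)
    assert [v.id for v in kept.variants] == ["rs2"]
    assert "maf" in report.loc[0, "reason"]


def test_marker_qc_all_pass(rng):
    g = rng.binomial(2, 0.3, size=(200, 4))
    matrix = _matrix_from_dosages(g)
    kept, report = marker_qc(matrix)
    assert kept.n_variants == 4
    assert (report["decision"] == "keep").all()


def test_marker_qc_is_idempotent(rng):
    g = rng.binomial(2, 0.05, size=(300, 6))
    matrix = _matrix_from_dosages(g)
    once, _ = marker_qc(matrix)
    twice, _ = marker_qc(once)
    assert [v.id for v in twice.variants] == [v.id for v in once.variants]


# ---------------------------------------------------------------------------
# post-association filter
# ---------------------------------------------------------------------------

def _record(model, hwe_p, alt_hom, vid="rs1"):
    return AssociationRecord(
        variant=VariantKey("1", 1000, vid, "A", "G"), model=model,
        beta=0.1, se=0.05, p=0.01, hwe_controls_p=hwe_p, alt_hom_cases=alt_hom)


def test_post_association_filter_rules():
    records = [
        _record("recessive", 0.5, 2),        # dropped: alt-hom count
        _record("recessive", 0.5, 3),        # kept: boundary is "below three"
        _record("genotypic", 0.5, 0),        # dropped: alt-hom count
        _record("additive", 0.5, 0),         # kept: count rule scoped
        _record("heterodominant", 0.5, 1),   # kept
        _record("dominant", 1e-7, 50),       # dropped: controls HWE
        _record("dominant", 1e-6, 50),       # kept: boundary is strict <
        _record("additive", 1e-9, 50),       # dropped: controls HWE, any model
        _record("recessive", 1e-7, 10),      # dropped: controls HWE
        _record("genotypic", 0.2, 7),        # kept
        _record("additive", 0.9, 100),       # kept
        _record("recessive", 0.9, 100),      # kept
    ]
    kept = post_association_filter(records)
    assert len(kept) == 7
    assert all(r.hwe_controls_p >= 1e-6 for r in kept)
    assert all(r.alt_hom_cases >= 3 for r in kept
               if r.model in ("recessive", "genotypic"))


def test_post_association_filter_is_idempotent():
    records = [_record("recessive", 0.5, 5), _record("additive", 1e-9, 5)]
    once = post_association_filter(records)
    assert post_association_filter(once) == once


def test_post_association_filter_requires_fields():
    rec = AssociationRecord(variant=VariantKey("1", 1, "rs1", "A", "G"),
                            model="recessive", hwe_controls_p=None)
    with pytest.raises(ValueError, match="hwe_controls_p"):
        post_association_filter([rec])


def test_thresholds_defaults_match_protocol():
    t = QcThresholds()
    assert (t.max_missingness, t.hwe_all_p_floor, t.min_maf) == (0.05, 1e-20, 0.001)
    assert (t.min_info, t.hwe_controls_p_floor, t.min_alt_hom_cases) == (0.7, 1e-6, 3)
    assert t.hard_call_threshold == 0.9
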