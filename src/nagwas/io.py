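"""Readers and writers for genotype-probability data and summary statistics.

The native dialect is Oxford GEN/SAMPLE: one GEN row per variant with five
leading fields (chrom, id, pos, allele A, allele B) followed by a probability
triple ``(p0, p1, p2)`` per sample, giving the probabilities of carrying
0, 1 or 2 copies of allele B.  Allele B is the *effect* allele throughout:
betas and odds ratios always refer to it, while MAF is reported for the
minor allele.  VCF input is supported through the GP/DS FORMAT fields.

Probability triples that sum to less than ``MIN_TRIPLE_SUM`` (0.98) are
treated as missing genotypes: imputation engines emit deflated triples for
uncertain calls, and keeping them would bias expected dosages.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: triples whose probabilities sum below this are treated as missing
MIN_TRIPLE_SUM = 0.98
#: tolerance on the sum of a well-formed probability triple
TRIPLE_SUM_TOL = 1e-3
#: missing-value token used in every text output
NA = "NA"

MODELS = ("additive", "dominant", "recessive", "heterodominant", "genotypic")

_CHROM_ORDER = {str(i): i for i in range(1, 23)}
_CHROM_ORDER["X"] = 23


def chrom_sort_key(chrom: str) -> int:
    """Numeric ordering for chromosome labels 1-22, X."""
    try:
        return _CHROM_ORDER[str(chrom)]
    except KeyError as exc:
        raise ValueError(f"unsupported chromosome label: {chrom!r}") from exc


@dataclass(frozen=True)
class VariantKey:
    """Identity of one biallelic variant; indels use multi-base allele strings."""

    chrom: str
    pos: int
    id: str
    ref_allele: str
    eff_allele: str

    def __post_init__(self):
        chrom_sort_key(self.chrom)
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref_allele or not self.eff_allele:
            raise ValueError(f"alleles must be non-empty for {self.id}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != 1 or len(self.eff_allele) != 1

    @property
    def allele_pair(self) -> frozenset:
        return frozenset((self.ref_allele, self.eff_allele))

    def match_key(self) -> tuple:
        """Cross-panel matching key: position plus unordered allele pair."""
        return (self.chrom, self.pos, self.allele_pair)


class GenotypeProbabilityMatrix:
    """Per-sample, per-variant genotype probability triples.

    Parameters
    ----------
    variants : ordered list of :class:`VariantKey`
    samples : ordered list of sample ids
    probs : array of shape ``(n_samples, n_variants, 3)``
    missing : optional boolean mask ``(n_samples, n_variants)``; triples whose
        sum falls below :data:`MIN_TRIPLE_SUM` are added to it automatically.
    """

    def __init__(self, variants, samples, probs, missing=None):
        self.variants = list(variants)
        self.samples = list(samples)
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (len(self.samples), len(self.variants), 3):
            raise ValueError(
                f"probs shape {probs.shape} does not match "
                f"({len(self.samples)}, {len(self.variants)}, 3)"
            )
        if np.any(probs < -1e-12):
            raise ValueError("negative genotype probability")
        self.probs = probs
        sums = probs.sum(axis=2)
        auto_missing = sums < MIN_TRIPLE_SUM
        if missing is None:
            missing = auto_missing
        else:
            missing = np.asarray(missing, dtype=bool) | auto_missing
        self.missing = missing
        bad = ~missing & (sums > 1 + TRIPLE_SUM_TOL)
        if np.any(bad):
            raise ValueError("probability triple sums exceed 1 + 1e-3")
        keys = [v.match_key() + (v.ref_allele,) for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variants in matrix")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def expected_dosage(self) -> np.ndarray:
        """Expected effect-allele count ``p1 + 2 p2``; NaN where missing."""
        d = self.probs[:, :, 1] + 2.0 * self.probs[:, :, 2]
        return np.where(self.missing, np.nan, d)

    def hard_calls(self, threshold: float = 0.9) -> np.ndarray:
        """Best-guess genotypes; -1 where the top probability < threshold or missing."""
        calls = np.argmax(self.probs, axis=2)
        top = np.max(self.probs, axis=2)
        calls = np.where((top >= threshold) & ~self.missing, calls, -1)
        return calls.astype(int)

    def eff_allele_freq(self) -> np.ndarray:
        """Expected effect-allele frequency per variant over non-missing samples."""
        d = self.expected_dosage()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        theta = self.eff_allele_freq()
        return np.minimum(theta, 1.0 - theta)

    def subset_variants(self, indices: Sequence[int]) -> "GenotypeProbabilityMatrix":
        idx = list(indices)
        return GenotypeProbabilityMatrix(
            [self.variants[i] for i in idx],
            self.samples,
            self.probs[:, idx, :],
            self.missing[:, idx],
        )


@dataclass
class PhenotypeTable:
    """Case-control status plus covariates, indexed by sample id.

    ``status`` is 0 control / 1 case, ``sex`` 1 male / 2 female (NaN missing),
    ``age`` in years; every other numeric column is a covariate.
    """

    df: pd.DataFrame

    def __post_init__(self):
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if "status" not in self.df.columns:
            raise ValueError("phenotype table must have a 'status' column")
        status = self.df["status"].dropna()
        if not status.isin([0, 1]).all():
            raise ValueError("status must be binary 0/1")
        for col in self.covariate_names:
            if not np.isfinite(self.df[col].to_numpy(dtype=float)).all():
                raise ValueError(f"covariate {col!r} has non-finite values")

    @property
    def samples(self) -> list:
        return list(self.df.index)

    @property
    def status(self) -> np.ndarray:
        return self.df["status"].to_numpy(dtype=float)

    @property
    def sex(self) -> np.ndarray:
        if "sex" in self.df.columns:
            return self.df["sex"].to_numpy(dtype=float)
        return np.full(len(self.df), np.nan)

    @property
    def covariate_names(self) -> list:
        return [c for c in self.df.columns if c not in ("status", "sex")]

    def covariates(self, names: Iterable[str]) -> np.ndarray:
        names = list(names)
        cols = []
        for name in names:
            if name == "sex":
                cols.append(self.sex)
            else:
                cols.append(self.df[name].to_numpy(dtype=float))
        if not cols:
            return np.empty((len(self.df), 0))
        return np.column_stack(cols)

    def aligned_to(self, samples: Sequence[str]) -> "PhenotypeTable":
        """Reindex to the matrix sample order; mismatched sets raise."""
        have = set(self.df.index)
        want = set(samples)
        missing = [s for s in samples if s not in have]
        extra = [s for s in self.df.index if s not in want]
        if missing or extra:
            raise ValueError(
                f"sample sets differ: missing from phenotypes {missing[:5]}, "
                f"absent from genotypes {extra[:5]}"
            )
        return PhenotypeTable(self.df.loc[list(samples)])


@dataclass
class AssociationRecord:
    """One variant x inheritance-model association result."""

    variant: VariantKey
    model: str
    beta: float | None = None
    se: float | None = None
    p: float | None = None
    beta_het: float | None = None
    se_het: float | None = None
    beta_hom: float | None = None
    se_hom: float | None = None
    maf: float | None = None
    info: float | None = None
    panel: str | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    alt_hom_cases: int | None = None
    hwe_controls_p: float | None = None
    converged: bool = True

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.p is not None and not 0 <= self.p <= 1:
            raise ValueError(f"p-value out of range: {self.p}")
        if self.alt_hom_cases is not None and self.alt_hom_cases < 0:
            raise ValueError("alt_hom_cases must be >= 0")

    def odds_ratio(self) -> tuple[float, float, float] | None:
        """OR and 95% CI ``exp(beta +/- 1.96 se)`` for 1-df models."""
        if self.beta is None or self.se is None:
            return None
        return (
            float(np.exp(self.beta)),
            float(np.exp(self.beta - 1.959963984540054 * self.se)),
            float(np.exp(self.beta + 1.959963984540054 * self.se)),
        )


# ---------------------------------------------------------------------------
# GEN / SAMPLE
# ---------------------------------------------------------------------------


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_gen(gen_path, sample_path=None):
    """Read an Oxford GEN file (and optionally its SAMPLE file).

    Returns ``matrix`` or ``(matrix, phenotypes)`` when ``sample_path`` is
    given.  GEN allele B is taken as the effect allele and triples are parsed
    in ``(p0, p1, p2)`` order of allele-B copies.
    """
    variants, rows = [], []
    n_samples = None
    with _open_text(gen_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if (len(fields) - 5) % 3 != 0 or len(fields) <= 5:
                raise ValueError(
                    f"{gen_path}:{lineno}: row length {len(fields)} is not 5 + 3N"
                )
            n = (len(fields) - 5) // 3
            if n_samples is None:
                n_samples = n
            elif n != n_samples:
                raise ValueError(
                    f"{gen_path}:{lineno}: {n} samples, expected {n_samples}"
                )
            chrom, vid, pos, a_allele, b_allele = fields[:5]
            try:
                probs = np.array(fields[5:], dtype=float).reshape(n, 3)
            except ValueError as exc:
                raise ValueError(f"{gen_path}:{lineno}: bad probability") from exc
            if np.any(probs < 0):
                raise ValueError(f"{gen_path}:{lineno}: negative probability")
            variants.append(VariantKey(chrom, int(pos), vid, a_allele, b_allele))
            rows.append(probs)
    probs = np.stack(rows, axis=1) if rows else np.empty((n_samples or 0, 0, 3))
    if sample_path is None:
        samples = [f"sample_{i + 1}" for i in range(n_samples or 0)]
        return GenotypeProbabilityMatrix(variants, samples, probs)
    phenotypes = read_sample(sample_path)
    if len(phenotypes.df) != (n_samples or 0):
        raise ValueError(
            f"GEN has {n_samples} samples but SAMPLE file has {len(phenotypes.df)}"
        )
    matrix = GenotypeProbabilityMatrix(variants, phenotypes.samples, probs)
    return matrix, phenotypes


def read_sample(sample_path) -> PhenotypeTable:
    """Read an Oxford SAMPLE file (two-row header convention)."""
    with _open_text(sample_path) as fh:
        header = fh.readline().split()
        types = fh.readline().split()
        if len(header) != len(types):
            raise ValueError("SAMPLE header and type rows differ in length")
        records = [line.split() for line in fh if line.strip()]
    df = pd.DataFrame(records, columns=header)
    df = df.set_index(header[0])
    drop = [c for c, t in zip(header[1:], types[1:]) if t == "0"]
    df = df.drop(columns=drop)
    for col in df.columns:
        df[col] = pd.to_numeric(df[col].replace(NA, np.nan))
    return PhenotypeTable(df)


def write_gen(matrix: GenotypeProbabilityMatrix, gen_path, precision: int = 6):
    with _open_text(gen_path, "wt") as fh:
        for j, v in enumerate(matrix.variants):
            head = f"{v.chrom} {v.id} {v.pos} {v.ref_allele} {v.eff_allele}"
            trips = matrix.probs[:, j, :].copy()
            trips[matrix.missing[:, j]] = 0.0  # deflated triple encodes missing
            body = " ".join(f"{p:.{precision}f}" for p in trips.ravel())
            fh.write(f"{head} {body}\n")


def write_sample(phenotypes: PhenotypeTable, sample_path):
    df = phenotypes.df
    cols = list(df.columns)
    types = []
    for col in cols:
        if col == "status":
            types.append("B")
        elif col == "sex":
            types.append("D")
        else:
            types.append("C")
    with _open_text(sample_path, "wt") as fh:
        fh.write("ID_1 " + " ".join(cols) + "\n")
        fh.write("0 " + " ".join(types) + "\n")
        for sid, row in df.iterrows():
            vals = []
            for col, t in zip(cols, types):
                x = row[col]
                if pd.isna(x):
                    vals.append(NA)
                elif t in ("B", "D"):
                    vals.append(str(int(x)))
                else:
                    vals.append(f"{x:.6g}")
            fh.write(f"{sid} " + " ".join(vals) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf_dosage(vcf_path) -> GenotypeProbabilityMatrix:
    """Read genotype probabilities from a VCF with GP or DS FORMAT fields.

    GP triples map directly.  A dosage ``d`` maps to the minimal-variance
    triple consistent with it: ``(1-d, d, 0)`` for ``d <= 1`` and
    ``(0, 2-d, d-1)`` above.  Multiallelic records are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    variants, cols = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(
                f"skipping multiallelic record {rec.ID or rec.POS} at "
                f"{rec.CHROM}:{rec.POS}"
            )
            continue
        gp = rec.format("GP")
        if gp is not None:
            trip = np.asarray(gp, dtype=float)
        else:
            ds = rec.format("DS")
            if ds is None:
                warnings.warn(
                    f"skipping record without GP or DS at {rec.CHROM}:{rec.POS}"
                )
                continue
            trip = dosage_to_triple(np.asarray(ds, dtype=float).ravel())
        chrom = rec.CHROM.removeprefix("chr")
        variants.append(
            VariantKey(chrom, rec.POS, rec.ID or f"{chrom}:{rec.POS}", rec.REF, rec.ALT[0])
        )
        cols.append(trip)
    probs = np.stack(cols, axis=1) if cols else np.empty((len(samples), 0, 3))
    probs = np.nan_to_num(probs, nan=0.0)  # missing GP/DS -> deflated triple
    return GenotypeProbabilityMatrix(variants, samples, probs)


def dosage_to_triple(dosage: np.ndarray) -> np.ndarray:
    """Minimal-variance probability triple consistent with a dosage in [0, 2]."""
    d = np.asarray(dosage, dtype=float)
    trip = np.zeros(d.shape + (3,))
    lo = d <= 1
    trip[..., 0] = np.where(lo, 1 - d, 0.0)
    trip[..., 1] = np.where(lo, d, 2 - d)
    trip[..., 2] = np.where(lo, 0.0, d - 1)
    trip[np.isnan(d)] = 0.0
    return np.clip(trip, 0.0, 1.0)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

_FIXED_COLS = ["chrom", "pos", "id", "ref_allele", "eff_allele", "maf", "info", "panel"]
_MODEL_COLS = ["beta", "se", "or", "ci_low", "ci_high", "p"]
_GENOTYPIC_EXTRA = ["beta_het", "se_het", "beta_hom", "se_hom"]
_TAIL_COLS = ["n_cases", "n_controls", "hwe_controls_p", "alt_hom_cases"]


def summary_stats_columns() -> list:
    cols = list(_FIXED_COLS)
    for model in MODELS:
        for c in _MODEL_COLS:
            cols.append(f"{model}_{c}")
    cols += [f"genotypic_{c}" for c in _GENOTYPIC_EXTRA]
    cols += _TAIL_COLS
    return cols


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Wide per-variant table with one column block per inheritance model."""
    if not records:
        raise ValueError("no association records to write")
    by_variant: dict = {}
    for rec in records:
        key = (rec.variant.chrom, rec.variant.pos, rec.variant.ref_allele,
               rec.variant.eff_allele)
        row = by_variant.setdefault(key, {
            "chrom": rec.variant.chrom,
            "pos": rec.variant.pos,
            "id": rec.variant.id,
            "ref_allele": rec.variant.ref_allele,
            "eff_allele": rec.variant.eff_allele,
        })
        for shared in ("maf", "info", "panel", "n_cases", "n_controls",
                       "hwe_controls_p", "alt_hom_cases"):
            val = getattr(rec, shared)
            if val is not None:
                row[shared] = val
        m = rec.model
        row[f"{m}_beta"] = rec.beta
        row[f"{m}_se"] = rec.se
        row[f"{m}_p"] = rec.p
        orci = rec.odds_ratio()
        if orci is not None:
            row[f"{m}_or"], row[f"{m}_ci_low"], row[f"{m}_ci_high"] = orci
        if m == "genotypic":
            for c in _GENOTYPIC_EXTRA:
                row[f"genotypic_{c}"] = getattr(rec, c)
    df = pd.DataFrame(list(by_variant.values()))
    df = df.reindex(columns=summary_stats_columns())
    df["_ck"] = df["chrom"].map(chrom_sort_key)
    df = df.sort_values(["_ck", "pos"]).drop(columns="_ck").reset_index(drop=True)
    return df


def write_summary_stats(records: Sequence[AssociationRecord], path):
    df = records_to_frame(records)
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.10g")


def read_summary_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=NA, dtype={"chrom": str})


def frame_to_records(df: pd.DataFrame) -> list[AssociationRecord]:
    """Inverse of :func:`records_to_frame` (one record per non-NA model block)."""
    records = []

    def _get(row, col):
        val = row.get(col)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            return None
        return val

    for _, row in df.iterrows():
        variant = VariantKey(str(row["chrom"]), int(row["pos"]), str(row["id"]),
                             str(row["ref_allele"]), str(row["eff_allele"]))
        for model in MODELS:
            p = _get(row, f"{model}_p")
            beta = _get(row, f"{model}_beta")
            if p is None and beta is None:
                continue
            ahc = _get(row, "alt_hom_cases")
            records.append(AssociationRecord(
                variant=variant, model=model,
                beta=beta, se=_get(row, f"{model}_se"), p=p,
                beta_het=_get(row, "genotypic_beta_het") if model == "genotypic" else None,
                se_het=_get(row, "genotypic_se_het") if model == "genotypic" else None,
                beta_hom=_get(row, "genotypic_beta_hom") if model == "genotypic" else None,
                se_hom=_get(row, "genotypic_se_hom") if model == "genotypic" else None,
                maf=_get(row, "maf"), info=_get(row, "info"),
                panel=_get(row, "panel"),
                n_cases=None if _get(row, "n_cases") is None else int(row["n_cases"]),
                n_controls=None if _get(row, "n_controls") is None else int(row["n_controls"]),
                alt_hom_cases=None if ahc is None else int(ahc),
                hwe_controls_p=_get(row, "hwe_controls_p"),
            ))
    return records
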