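"""Pipeline orchestration: configuration, staging and re-entrancy.

The pipeline chains the library stages — simulate (optional), marker QC,
panel combination, association, locus collapsing/classification, report —
writing each stage's outputs under the configured directory.  A stage that
already ran with unchanged inputs is skipped via a checksum guard, so
individual stages can be re-executed after deleting their outputs without
recomputing upstream results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import assoc, loci, panels, qc, report, simulate
from .io import (MODELS, PhenotypeTable, read_gen, read_sample,
                 records_to_frame, write_gen, write_sample, write_summary_stats)

log = logging.getLogger("nagwas.pipeline")

STAGES = ("simulate", "qc", "combine", "assoc", "loci", "report")


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    output_dir: Path
    seed: int = 0
    models: tuple = MODELS
    covariates: tuple = ()
    panel_priority: tuple = ()
    phenotype: str = "disease"
    gw_threshold: float = assoc.GENOME_WIDE_ALPHA
    effective_tests: float = 2.5
    thresholds: qc.QcThresholds = field(default_factory=qc.QcThresholds)
    simulation: simulate.SimulationSpec | None = None
    panel_gens: tuple = ()      # (name, gen_path) pairs when not simulating
    sample_file: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        unknown_models = set(cfg.get("models", [])) - set(MODELS)
        if unknown_models:
            raise ValueError(f"unsupported models: {sorted(unknown_models)}")
        thr = qc.QcThresholds(**cfg.get("thresholds", {}))
        sim = None
        if "simulation" in cfg:
            sim_path = path.parent / cfg["simulation"]
            sim = simulate.SimulationSpec.from_yaml(sim_path)
        panel_gens = tuple((p["name"], str(path.parent / p["gen"]))
                           for p in cfg.get("panels", []))
        for _, gen in panel_gens:
            if not Path(gen).exists():
                raise FileNotFoundError(gen)
        return cls(
            output_dir=path.parent / cfg.get("output_dir", "out"),
            seed=int(cfg.get("seed", 0)),
            models=tuple(cfg.get("models", MODELS)),
            covariates=tuple(cfg.get("covariates", [])),
            panel_priority=tuple(cfg.get("panel_priority", [])),
            phenotype=str(cfg.get("phenotype", "disease")),
            gw_threshold=float(cfg.get("gw_threshold", assoc.GENOME_WIDE_ALPHA)),
            effective_tests=float(cfg.get("effective_tests", 2.5)),
            thresholds=thr, simulation=sim, panel_gens=panel_gens,
            sample_file=None if "sample_file" not in cfg
            else str(path.parent / cfg["sample_file"]),
        )


def _checksum(paths) -> str:
    h = hashlib.sha256()
    for p in sorted(str(p) for p in paths):
        h.update(p.encode())
        fp = Path(p)
        if fp.exists():
            h.update(fp.read_bytes())
    return h.hexdigest()


def _stage_done(outdir: Path, stage: str, inputs) -> bool:
    guard = outdir / f".{stage}.done"
    if not guard.exists():
        return False
    try:
        return json.loads(guard.read_text())["checksum"] == _checksum(inputs)
    except (json.JSONDecodeError, KeyError):
        return False


def _sim_fingerprint(spec) -> str:
    """Stable digest of a simulation spec (panel coverage is summarized by
    the names of the variants each panel covers)."""
    payload = {
        "n_samples": spec.n_samples, "case_fraction": spec.case_fraction,
        "seed": spec.seed, "sex_effect": spec.sex_effect,
        "age_effect": spec.age_effect, "pc_effects": list(spec.pc_effects),
        "variants": [(v.chrom, v.pos, v.id, v.maf, v.model, v.or_,
                      v.ref_allele, v.eff_allele) for v in spec.variants],
        "panels": [(p.name, p.kappa,
                    [v.id for v in spec.variants if p.covers(v)])
                   for p in spec.panels],
    }
    return hashlib.sha256(json.dumps(payload, default=list).encode()).hexdigest()


def _mark_done(outdir: Path, stage: str, inputs, counts: dict):
    guard = outdir / f".{stage}.done"
    guard.write_text(json.dumps({"checksum": _checksum(inputs), "counts": counts}))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory.

    Deterministic for a fixed config seed.  Stage failures raise
    :class:`StageError` naming the stage; completed stages' outputs are
    preserved.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # --- simulate ---------------------------------------------------------
    panel_gens = list(config.panel_gens)
    sample_file = config.sample_file
    if config.simulation is not None:
        try:
            spec = config.simulation
            spec.seed = config.seed if spec.seed == 0 else spec.seed
            fp = outdir / ".simulate.fp"
            fresh = not (fp.exists() and fp.read_text() == _sim_fingerprint(spec))
            if fresh or not _stage_done(outdir, "simulate", [fp]):
                genotypes, phenotypes, panel_sets = simulate.simulate_cohort(spec)
                write_sample(phenotypes, outdir / "cohort.sample")
                for pset in panel_sets:
                    write_gen(pset.matrix, outdir / f"panel_{pset.name}.gen")
                fp.write_text(_sim_fingerprint(spec))
                _mark_done(outdir, "simulate", [fp], {
                    "n_samples": spec.n_samples,
                    "n_variants": len(spec.variants),
                    "n_panels": len(panel_sets)})
            panel_gens = [(p.name, str(outdir / f"panel_{p.name}.gen"))
                          for p in config.simulation.panels]
            sample_file = str(outdir / "cohort.sample")
            log.info("stage simulate done (%.1fs)", time.time() - t0)
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError("simulate", exc) from exc

    if not panel_gens or sample_file is None:
        raise StageError("qc", "no panel GEN files or sample file configured")

    # --- qc + combine -----------------------------------------------------
    try:
        phenotypes = read_sample(sample_file)
        panel_sets = []
        for name, gen in panel_gens:
            matrix = read_gen(gen)
            matrix.samples = phenotypes.samples  # GEN carries no sample ids
            kept, qc_report = qc.marker_qc(matrix, phenotypes, config.thresholds)
            qc.write_qc_report(qc_report, outdir / f"qc_{name}.tsv")
            info = {v.match_key(): qc.impute_info_score(kept.probs[:, j, :],
                                                        kept.missing[:, j])
                    for j, v in enumerate(kept.variants)}
            keep = [j for j, v in enumerate(kept.variants)
                    if info[v.match_key()] >= config.thresholds.min_info]
            kept = kept.subset_variants(keep)
            info = {v.match_key(): info[v.match_key()] for v in kept.variants}
            panel_sets.append(panels.PanelResultSet(name=name, matrix=kept, info=info))
            log.info("stage qc: panel %s kept %d variants", name, kept.n_variants)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("qc", exc) from exc

    try:
        combined = panels.combine_panels(panel_sets, config.panel_priority or None)
        combined.provenance_frame().to_csv(outdir / "combined_provenance.tsv",
                                           sep="\t", index=False)
        log.info("stage combine: %d variants", combined.matrix.n_variants)
    except Exception as exc:  # noqa: BLE001
        raise StageError("combine", exc) from exc

    # --- association ------------------------------------------------------
    summary_path = outdir / "summary_stats.tsv"
    try:
        if not _stage_done(outdir, "assoc", [sample_file] + [g for _, g in panel_gens]):
            records = assoc.run_association(
                combined, phenotypes, config.covariates, config.models,
                config.thresholds, config.gw_threshold)
            if records:
                write_summary_stats(records, summary_path)
            _mark_done(outdir, "assoc",
                       [sample_file] + [g for _, g in panel_gens],
                       {"n_records": len(records)})
        else:
            from .io import frame_to_records, read_summary_stats
            records = frame_to_records(read_summary_stats(summary_path))
        log.info("stage assoc: %d records", len(records))
    except Exception as exc:  # noqa: BLE001
        raise StageError("assoc", exc) from exc

    # --- loci -------------------------------------------------------------
    try:
        found = loci.collapse_loci(records, threshold=config.gw_threshold,
                                   phenotype=config.phenotype)
        ew = loci.experimentwide_threshold(config.gw_threshold,
                                           config.effective_tests)
        key_of = {v.match_key(): j for j, v in enumerate(combined.matrix.variants)}
        for loc in found:
            dev_p = None
            j = key_of.get(loc.lead.variant.match_key())
            if j is not None and str(loc.chrom) != "X":
                dev_p, _ = assoc.dominance_deviation_test(
                    combined.matrix.probs[:, j, :], phenotypes,
                    covariate_names=("sex", *config.covariates),
                    missing=combined.matrix.missing[:, j])
            loci.classify_inheritance(loc, dev_p, threshold=config.gw_threshold)
        table = loci.loci_table(found) if found else None
        if table is not None:
            table["experimentwide_sig"] = table["lead_p"] < ew
            table.to_csv(outdir / "loci.tsv", sep="\t", index=False, na_rep="NA")
        log.info("stage loci: %d loci", len(found))
    except Exception as exc:  # noqa: BLE001
        raise StageError("loci", exc) from exc

    # --- report -----------------------------------------------------------
    try:
        if records:
            summary = records_to_frame(records)
            report.model_inflation_table(summary).to_csv(
                outdir / "lambda_gc.tsv", sep="\t", index=False)
            for model in config.models:
                report.manhattan_data(summary, model).to_csv(
                    outdir / f"manhattan_{model}.tsv", sep="\t", index=False)
                p = summary[f"{model}_p"].dropna()
                if len(p):
                    report.qq_data(p).to_csv(outdir / f"qq_{model}.tsv",
                                             sep="\t", index=False)
        log.info("pipeline complete in %.1fs", time.time() - t0)
    except Exception as exc:  # noqa: BLE001
        raise StageError("report", exc) from exc
    return outdir
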