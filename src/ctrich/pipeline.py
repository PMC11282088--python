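"""End-to-end driver: simulate -> preprocess -> genotype -> classify -> assoc -> qtl.

Every stage writes its tables under a numbered subdirectory of the output
directory, stamped with the config hash, and appends record counts to a
machine-readable run log. One master seed derives per-stage substreams so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import genotype as _genotype
from . import io as _io
from . import primers as _primers
from . import qtl as _qtl
from . import simulate as _sim
from . import stats as _stats


@dataclass
class PipelineConfig:
    simulation: _sim.SimulationConfig = field(default_factory=_sim.SimulationConfig)
    primer_spec: _primers.PrimerSpec = field(default_factory=_primers.PrimerSpec)
    flank_spec: _genotype.FlankSpec = field(default_factory=_genotype.FlankSpec)
    thresholds: _genotype.Thresholds = field(default_factory=_genotype.Thresholds)
    qtl_filters: _qtl.QtlFilterConfig = field(default_factory=_qtl.QtlFilterConfig)
    expression: _sim.ExpressionSpec = field(default_factory=_sim.ExpressionSpec)
    max_edit_distance: int = 1
    umap_components: int = 2
    cis_window: int = 1_000_000
    seed: int = 0
    outdir: str = "ctrich_run"

    def echo(self) -> str:
        return yaml.safe_dump({"config": repr(self), "seed": self.seed}, sort_keys=False)

    def hash(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        import dataclasses

        return _io.config_hash(dataclasses.replace(self, outdir=""))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_all(config: PipelineConfig) -> Path:
    """Run the whole pipeline and return the output directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    note = f"config={chash}"
    (out / "config_echo.yaml").write_text(config.echo())
    log: list[dict] = []
    rngs = np.random.SeedSequence(config.seed).spawn(4)
    rng_cohort, rng_reads, rng_ctss, rng_tpm = (np.random.default_rng(s) for s in rngs)

    # --- simulate -----------------------------------------------------------
    stage_dir = out / "01_simulate"
    stage_dir.mkdir(exist_ok=True)
    try:
        refs = _sim.make_reference_haplotypes(config.simulation)
        cohort = _sim.simulate_cohort(config.simulation, rng_cohort)
        reads = _sim.simulate_reads(cohort, refs, config.simulation, rng_reads)
    except _sim.ConfigError as exc:
        raise StageError("simulate", str(exc)) from exc
    _io.write_reference_fasta(refs, stage_dir / "references.fasta", note)
    _io.write_fastq(reads, stage_dir / "reads.fastq")
    _io.write_truth_table(reads, stage_dir / "truth.tsv", note)
    _io.write_table(cohort, stage_dir / "cohort.tsv", note)
    log.append({"stage": "simulate", "n_samples": len(cohort), "n_reads": len(reads)})

    # --- preprocess ---------------------------------------------------------
    stage_dir = out / "02_preprocess"
    stage_dir.mkdir(exist_ok=True)
    kept, rejections = _primers.orient_and_filter(reads, config.primer_spec)
    _io.write_fastq(kept, stage_dir / "oriented.fastq")
    _io.write_table(rejections, stage_dir / "read_classes.tsv", note)
    log.append(
        {"stage": "preprocess", "n_in": len(reads), "n_kept": len(kept),
         "class_counts": rejections["class"].value_counts().to_dict()}
    )

    # --- genotype -----------------------------------------------------------
    stage_dir = out / "03_genotype"
    stage_dir.mkdir(exist_ok=True)
    genotypes = _genotype.genotype_cohort(kept, config.flank_spec, config.thresholds)
    _io.write_table(_genotype.genotypes_to_table(genotypes), stage_dir / "genotypes.tsv", note)
    _io.write_repeat_vcf(genotypes, stage_dir / "repeat.vcf", chash)
    log.append({"stage": "genotype", "n_samples": len(genotypes),
                "n_qc_pass": sum(g.qc_pass for g in genotypes)})

    # --- classify -----------------------------------------------------------
    stage_dir = out / "04_classify"
    stage_dir.mkdir(exist_ok=True)
    bins = _classify.LengthBins.from_references(refs)
    try:
        assignments, freqs = _classify.cohort_dosages(genotypes, bins, refs, config.max_edit_distance)
    except ValueError as exc:
        raise StageError("classify", str(exc)) from exc
    _io.write_table(assignments, stage_dir / "assignments.tsv", note)
    _io.write_table(freqs, stage_dir / "frequencies.tsv", note)
    log.append({"stage": "classify", "n_assigned": int((~assignments["excluded"]).sum()),
                "n_excluded": int(assignments["excluded"].sum())})

    # --- association --------------------------------------------------------
    stage_dir = out / "05_assoc"
    stage_dir.mkdir(exist_ok=True)
    snv_ids = [s.id for s in config.simulation.snv_specs]
    # analysis uses the *called* dosages merged with simulated SNVs/covariates
    called = assignments[["sample_id"] + [f"dosage_{h}" for h in _sim.HAPLOTYPE_NAMES]]
    analysis = called.merge(
        cohort.drop(columns=[f"dosage_{h}" for h in _sim.HAPLOTYPE_NAMES]), on="sample_id"
    )
    try:
        table1 = _stats.haplotype_snv_table(analysis, snv_ids)
        table2 = _stats.phenotype_table(analysis, snv_ids)
        carriers = _stats.homozygote_carrier_table(assignments, cohort[["sample_id"] + snv_ids])
    except ValueError as exc:
        raise StageError("assoc", str(exc)) from exc
    _io.write_table(table1, stage_dir / "haplotype_snv_assoc.tsv", note)
    _io.write_table(table2, stage_dir / "phenotype_assoc.tsv", note)
    _io.write_table(carriers, stage_dir / "homozygote_carriers.tsv", note)
    log.append({"stage": "assoc", "n_table1": len(table1), "n_table2": len(table2)})

    # --- qtl ----------------------------------------------------------------
    stage_dir = out / "06_qtl"
    stage_dir.mkdir(exist_ok=True)
    counts, coords = _sim.simulate_expression(cohort, config.expression, rng_ctss, kind="CTSS-count")
    filtered, audit = _qtl.filter_features(counts, "CTSS-count", config.qtl_filters,
                                           ages=cohort.set_index("sample_id")["age"])
    normalized, _constant = _qtl.quantile_normalize(filtered)
    umap_cov = _qtl.umap_covariates(normalized, config.umap_components, seed=config.seed)
    covs = cohort.set_index("sample_id")[list(_stats.DEFAULT_COVARIATES)].loc[normalized.columns]
    if not umap_cov.empty:
        covs = pd.concat([covs, umap_cov], axis=1)
    variants = analysis.set_index("sample_id")[[f"dosage_{h}" for h in _sim.HAPLOTYPE_NAMES] + snv_ids]
    variants.columns = list(_sim.HAPLOTYPE_NAMES) + snv_ids
    positions = pd.DataFrame(
        {"variant": variants.columns,
         "chrom": _sim.REPEAT_CHROM,
         "pos": [_sim.REPEAT_POS] * 4 + [s.position for s in config.simulation.snv_specs]}
    )
    variants = variants.reindex(normalized.columns).dropna()
    qtl_res = _qtl.cis_scan(variants, positions, normalized[variants.index], coords,
                            covs.loc[variants.index], window=config.cis_window)
    _io.write_table(audit, stage_dir / "filter_audit.tsv", note)
    _io.write_bed(coords, stage_dir / "features.bed", note)
    _io.write_table(qtl_res, stage_dir / "qtl_ctss.tsv", note)
    # per-dosage box-plot data for the top hit (plot table, not a figure)
    if not qtl_res.empty:
        top = qtl_res.sort_values("p_nominal").iloc[0]
        plot_df = pd.DataFrame(
            {"sample_id": variants.index,
             "dosage": variants[top["variant"]].to_numpy(),
             "normalized_expression": normalized.loc[top["feature"], variants.index].to_numpy()}
        )
        _io.write_table(plot_df, stage_dir / "top_hit_boxplot_data.tsv", note)
    log.append({"stage": "qtl", "n_features_kept": len(filtered), "n_pairs": len(qtl_res)})

    with open(out / "run_log.json", "w") as fh:
        json.dump({"config_hash": chash, "stages": log}, fh, indent=2)
    return out
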