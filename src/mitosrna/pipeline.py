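"""End-to-end orchestration: simulate -> preprocess -> catalog -> DE -> tRF.

A single config (YAML file or dict) drives the whole analysis and every
stage writes plain TSV tables into the output directory, so each step can be
rerun or inspected independently.  A JSON run summary records the counts at
every stage plus every parameter needed to reproduce the run; identical
config and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog import Catalog, build_catalog, feature_enrichment, summarize_catalog
from .de import relative_log2fc_matrix, run_stage_de
from .genome import read_genome
from .preprocess import (CountMatrix, filter_low_abundance, normalize,
                         preprocess_libraries)
from .simulate import (SimDesign, default_fragments, make_toy_genome,
                       plant_fragments, simulate_libraries)
from .trf import (classify_catalog_ends, cluster_expression, coverage_profile,
                  find_conserved_core, mitos_fraction, trait_correlation)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Input paths, parameters and the output directory for one run."""

    genome: str = ""
    annotation: str = ""
    samples: str = ""
    reads_dir: str = ""
    traits: str = ""  # optional stage-traits TSV
    output_dir: str = "mitosrna_out"

    adapter: str = "TGGAATTCTCGG"
    min_overlap: int = 6
    min_len: int = 15
    max_len: int = 27
    min_total: int = 10
    mean_threshold: float = 25.0
    lfc_threshold: float = 2.0
    padj_threshold: float = 0.01
    pseudocount: float = 0.5
    tau: int = 2
    k: int = 3
    restarts: int = 20
    flank: int = 5
    seed: int = 0

    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate_inputs(self) -> None:
        for label, p in (("genome", self.genome), ("annotation", self.annotation),
                         ("samples", self.samples)):
            if not p or not Path(p).exists():
                raise StageError("inputs", f"missing {label} file: {p!r}")


def simulate(config: PipelineConfig) -> dict[str, Path]:
    """Generate a synthetic input set (and truth table) per the config.

    Fills in the config's input paths so ``run`` can consume them directly.
    """
    sim = dict(config.sim)
    outdir = Path(sim.pop("outdir", Path(config.output_dir) / "sim"))
    genome = make_toy_genome(seed=sim.pop("genome_seed", config.seed),
                             length=sim.pop("genome_length", 2000))
    design = SimDesign(seed=sim.pop("seed", config.seed), **sim)
    truth = plant_fragments(genome, default_fragments(genome),
                            seed=design.seed, stages=design.stages,
                            treatments=design.treatments)
    paths = simulate_libraries(genome, truth, design, outdir)
    config.genome = str(paths["genome"])
    config.annotation = str(paths["annotation"])
    config.samples = str(paths["samples"])
    config.reads_dir = str(outdir)
    return paths


def run(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run summary dict.

    Outputs are assembled in a staging directory and moved into place only
    on success, so a failed run leaves no partial output bundle.
    """
    out_final = Path(config.output_dir)
    out = out_final.with_name(out_final.name + ".partial")
    if out.exists():
        shutil.rmtree(out)
    out.mkdir(parents=True)
    summary: dict = {"version": __version__, "parameters": {
        k: v for k, v in asdict(config).items() if k != "sim"}}
    try:
        _run_stages(config, out, summary)
    except StageError:
        shutil.rmtree(out, ignore_errors=True)
        raise
    except Exception as exc:  # tag unexpected failures with their stage
        shutil.rmtree(out, ignore_errors=True)
        raise StageError(summary.get("_stage", "unknown"), str(exc)) from exc
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    if out_final.exists():
        shutil.rmtree(out_final)
    out.rename(out_final)
    return summary


def _run_stages(config: PipelineConfig, out: Path, summary: dict) -> None:
    summary["_stage"] = "inputs"
    config.validate_inputs()
    genome, decoys = read_genome(config.genome, config.annotation)
    sheet = pd.read_csv(config.samples, sep="\t")

    # --- preprocess -------------------------------------------------------
    summary["_stage"] = "preprocess"
    reads_dir = Path(config.reads_dir or Path(config.samples).parent)
    fastqs = {row["library"]: reads_dir / row["fastq"]
              for _, row in sheet.iterrows()}
    matrix = preprocess_libraries(fastqs, config.adapter, config.min_overlap,
                                  config.min_len, config.max_len)
    summary["n_unique_sequences"] = int(len(matrix.raw))
    summary["reads_retained_per_library"] = matrix.raw.sum().to_dict()

    # --- alignment retention + catalog -----------------------------------
    summary["_stage"] = "catalog"
    cat_all = build_catalog(matrix.raw.index, genome, decoys)
    aligned = cat_all.flags[cat_all.flags != "unaligned"].index
    matrix = CountMatrix(raw=matrix.raw.loc[matrix.raw.index.isin(aligned)])
    matrix = filter_low_abundance(matrix, config.min_total)
    matrix = normalize(matrix)
    norm = matrix.normalized
    catalog = Catalog(
        table=cat_all.table.loc[cat_all.table.index.isin(matrix.raw.index)],
        flags=cat_all.flags.loc[cat_all.flags.index.isin(matrix.raw.index)],
        all_hits=cat_all.all_hits)
    summary["n_aligned"] = int(len(aligned))
    summary["n_after_abundance_filter"] = int(len(matrix.raw))
    summary["n_mitosrna"] = int(len(catalog.table))

    _write_catalog(catalog, out)
    matrix.raw.to_csv(out / "counts_raw.tsv", sep="\t")
    norm.round(4).to_csv(out / "counts_normalized.tsv", sep="\t")
    matrix.size_factors.round(6).to_csv(out / "size_factors.tsv", sep="\t")
    summarize_catalog(catalog).table.to_csv(out / "catalog_summary.tsv", sep="\t")
    if len(catalog.table):
        feature_enrichment(catalog, genome).to_csv(out / "enrichment.tsv", sep="\t")

    # --- differential expression ------------------------------------------
    summary["_stage"] = "diff_expression"
    mito_norm = norm.loc[norm.index.isin(catalog.table.index)]
    th = {"mean": config.mean_threshold, "lfc": config.lfc_threshold,
          "padj": config.padj_threshold}
    de_any = pd.Series(False, index=mito_norm.index)
    for stage in sheet["stage"].unique():
        res = run_stage_de(mito_norm, sheet, stage,
                           pseudocount=config.pseudocount, thresholds=th)
        res.to_csv(out / f"de_{stage}.tsv", sep="\t")
        de_any |= res["de_flag"].reindex(de_any.index).fillna(False)
    de_seqs = de_any[de_any].index
    summary["n_de"] = int(len(de_seqs))
    summarize_catalog(catalog, subset=de_seqs).table.to_csv(
        out / "catalog_summary_de.tsv", sep="\t")

    heatmap = relative_log2fc_matrix(mito_norm.loc[de_seqs], config.pseudocount)
    heatmap.round(4).to_csv(out / "heatmap_relative_log2fc.tsv", sep="\t")

    # --- tRF profiling -----------------------------------------------------
    summary["_stage"] = "trf_profile"
    ends = classify_catalog_ends(catalog, genome, "tRNA", tau=config.tau)
    ends.to_csv(out / "end_classes.tsv", sep="\t", index=False)

    if len(heatmap) >= config.k:
        model = cluster_expression(heatmap, k=config.k, seed=config.seed,
                                   restarts=config.restarts)
        model.assignments.to_csv(out / "clusters.tsv", sep="\t")
        summary["cluster_wcss"] = model.wcss

    probe_rows = []
    de_ends = ends[ends["sequence"].isin(de_seqs)]
    for fid, grp in de_ends[de_ends["end_class"] == "three_prime"].groupby("feature_id"):
        core = find_conserved_core(sorted(grp["sequence"].unique()))
        probe_rows.append({"feature_id": fid,
                           "feature_name": grp["feature_name"].iloc[0],
                           "n_variants": grp["sequence"].nunique(),
                           "core": core.core, "core_length": core.core_length,
                           "probe": core.probe})
    pd.DataFrame(probe_rows, columns=["feature_id", "feature_name", "n_variants",
                                      "core", "core_length", "probe"]
                 ).to_csv(out / "probes.tsv", sep="\t", index=False)
    summary["n_probe_groups"] = len(probe_rows)

    cov_rows = []
    for fid in de_ends["feature_id"].unique():
        for treatment in ("t0", "LA"):
            cols = sheet.loc[sheet["treatment"] == treatment, "library"].tolist()
            prof = coverage_profile(catalog, norm, genome, fid,
                                    [c for c in cols if c in norm.columns],
                                    flank=config.flank)
            for pos, v in prof.items():
                cov_rows.append({"feature_id": fid, "treatment": treatment,
                                 "position": pos, "value": round(float(v), 4)})
    pd.DataFrame(cov_rows, columns=["feature_id", "treatment", "position",
                                    "value"]).to_csv(
        out / "coverage_profiles.tsv", sep="\t", index=False)

    # --- mitosRNA fraction / traits ----------------------------------------
    fracs = {}
    for stage in sheet["stage"].unique():
        cols = sheet.loc[(sheet["stage"] == stage) & (sheet["treatment"] == "t0"),
                         "library"].tolist()
        cols = [c for c in cols if c in norm.columns]
        if cols:
            fracs[stage] = mitos_fraction(norm, catalog.flags, cols)
    frac_series = pd.Series(fracs, name="mitos_fraction")
    frac_series.round(6).to_csv(out / "mitos_fraction.tsv", sep="\t")
    summary["mitos_fraction"] = {k: round(v, 6) for k, v in fracs.items()}

    if config.traits:
        traits = pd.read_csv(config.traits, sep="\t", index_col="stage")
        corr_rows = []
        for trait in traits.columns:
            try:
                r, p = trait_correlation(frac_series, traits, trait)
                corr_rows.append({"trait": trait, "pearson_r": round(r, 4),
                                  "pvalue": round(p, 4)})
            except ValueError as exc:
                log.warning("trait %s skipped: %s", trait, exc)
        pd.DataFrame(corr_rows).to_csv(out / "trait_correlation.tsv",
                                       sep="\t", index=False)
    summary.pop("_stage", None)


def _write_catalog(catalog: Catalog, out: Path) -> None:
    tab = catalog.table.copy()
    tab["feature_types"] = tab["feature_types"].map(",".join)
    tab.to_csv(out / "catalog.tsv", sep="\t")
    catalog.flags.rename_axis("sequence").to_csv(out / "alignment_flags.tsv", sep="\t")
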