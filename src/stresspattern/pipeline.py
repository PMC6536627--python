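"""End-to-end pipeline runner and run manifest.

``run_pipeline`` ties the stages together: expression calls, direction
bias, Venn partition, concordance, clustering, phenotype and fecal-CORT
ANOVA tables, and enrichment, all written to an output directory with a
machine-readable manifest (config, package version, seed, file list).
Inputs are either loaded from the configured paths or, when no expression
path is given, generated by the synthetic-data module from the configured
seed — in which case a small synthetic gene-set collection built from the
planted transcripts is used so the enrichment stage is exercised too.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, enrichment, fileio, overlap, patterns, phenotypes, simulate

log = logging.getLogger("stresspattern")


@dataclass
class RunConfig:
    """Paths, thresholds and seed for an end-to-end run."""

    out_dir: str = "stresspattern_out"
    expression_path: str | None = None
    samples_path: str | None = None
    phenotypes_path: str | None = None
    fcort_path: str | None = None
    gmt_path: str | None = None
    target_region: str | None = None  # Venn region used as enrichment target
    alpha: float = 0.05
    fc_threshold: float = 0.10
    outlier_k: float = 2.0
    min_category: int = 5
    seed: int = 0
    log_level: str = "INFO"
    sim_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("alpha", "fc_threshold", "outlier_k"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.min_category < 1:
            raise ValueError("min_category must be >= 1")
        if (self.expression_path is None) != (self.samples_path is None):
            raise ValueError("expression_path and samples_path must be given together")


def _synthetic_gene_sets(truth: simulate.PlantedTruth, universe, seed: int,
                         n_sets: int = 8, set_size: int = 50) -> enrichment.GeneSetCollection:
    """Synthetic gene-set collection for pipeline smoke runs.

    Half the sets are enriched in planted transcripts, half drawn
    uniformly from the universe, so the enrichment stage has signal.
    """
    import numpy as np

    rng = np.random.default_rng(seed + 17)
    universe = sorted(universe)
    planted = sorted(truth.planted_transcripts)
    sets = {}
    for i in range(n_sets):
        if planted and i % 2 == 0:
            n_planted = min(set_size // 2, len(planted))
            members = list(rng.choice(planted, size=n_planted, replace=False))
            members += list(rng.choice(universe, size=set_size - n_planted, replace=False))
        else:
            members = list(rng.choice(universe, size=set_size, replace=False))
        sets[f"SYNSET_{i:02d}"] = set(members)
    return enrichment.GeneSetCollection(
        sets=sets, descriptions={k: "synthetic set" for k in sets}
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dictionary.

    Outputs written to ``config.out_dir``: calls.tsv,
    direction_counts.tsv, partition.tsv, concordance.tsv, dendrogram.nwk,
    phenotype_anova.tsv, fcort_anova.tsv, enrichment.tsv, plus
    manifest.json.  Stage failures mark the manifest's ``complete`` flag
    false before re-raising.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "outputs": [],
        "complete": False,
    }
    gene_sets = None
    truth = None
    try:
        if config.expression_path is None:
            sim_cfg = simulate.SimulationConfig(seed=config.seed, **config.sim_overrides)
            log.info("simulating expression (%d transcripts)", sim_cfg.n_transcripts)
            matrix, samples, truth = simulate.simulate_expression(sim_cfg)
            pheno_cfg = simulate.PhenoSimConfig(seed=config.seed)
            pheno = simulate.simulate_phenotypes(pheno_cfg)
            fcort = simulate.simulate_fcort_timecourse(pheno_cfg)
            gene_sets = _synthetic_gene_sets(truth, matrix.index, config.seed)
        else:
            matrix = fileio.read_expression(config.expression_path)
            samples = fileio.read_samples(config.samples_path)
            pheno = fileio.read_table(config.phenotypes_path) if config.phenotypes_path else None
            fcort = fileio.read_table(config.fcort_path) if config.fcort_path else None
            if config.gmt_path:
                gene_sets = enrichment.GeneSetCollection.from_gmt(config.gmt_path)

        def emit(name: str, writer) -> None:
            path = out / name
            writer(path)
            manifest["outputs"].append(name)

        calls = patterns.call_stress_transcripts(
            matrix, samples, alpha=config.alpha, fc_threshold=config.fc_threshold
        )
        emit("calls.tsv", lambda p: fileio.write_calls(calls, p))

        counts = patterns.direction_counts_table(calls)
        emit("direction_counts.tsv", lambda p: counts.to_csv(p, sep="\t", index=False))

        part = overlap.partition_calls(calls, strains=pd.unique(samples["strain"]))
        emit("partition.tsv", lambda p: part.to_frame().to_csv(p, sep="\t", index=False))

        conc = overlap.concordance_table(part)
        emit("concordance.tsv", lambda p: conc.to_csv(p, sep="\t", index=False))

        if len(part.multi_strain_transcripts) >= 2:
            _, _, newick = overlap.cluster_overlap(matrix, samples, part)
            emit("dendrogram.nwk", lambda p: fileio.atomic_write_text(newick + "\n", p))

        if pheno is not None:
            anova = phenotypes.phenotype_anova_table(pheno)
            emit("phenotype_anova.tsv", lambda p: anova.to_csv(p, sep="\t", index=False))
        if fcort is not None:
            fc_anova = phenotypes.fcort_analysis(fcort).reset_index(names="term")
            emit("fcort_anova.tsv", lambda p: fc_anova.to_csv(p, sep="\t", index=False))

        if gene_sets is not None:
            passing = calls[calls["passes"]]
            if config.target_region:
                target = set(part.regions.get(config.target_region, []))
            else:
                target = set(passing["transcript"])
            if target:
                result = enrichment.ora(
                    target, set(matrix.index), gene_sets,
                    min_size=config.min_category, alpha=config.alpha,
                )
                emit("enrichment.tsv", lambda p: result.to_csv(p, sep="\t", index=False))

        manifest["complete"] = True
    finally:
        fileio.atomic_write_text(json.dumps(manifest, indent=2, default=str),
                                 out / "manifest.json")
    return manifest
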