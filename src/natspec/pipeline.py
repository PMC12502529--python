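"""End-to-end delineation runs: ingest -> common genes -> core -> degeneracy
-> metrics -> tree -> boundary, driven by one structured config.

Outputs in the run directory (all plain text, deterministic given the seed):

* ``common_gene_percent.tsv`` — pairwise percent of the smaller gene set
* ``degeneracy_{counts,denominators,ratios}.tsv``
* ``boundary.json`` — clusters, threshold, evidence ratios
* ``metrics.tsv`` — ANI / dDDH / 16S per pair (as toggled)
* ``distances.tsv``, ``distances.phylip``, ``tree.nwk``
* ``provenance.json`` — config echo + hash, package versions, stage timings
  (timings are wall-clock and vary between reruns; everything else is
  byte-reproducible)
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .degeneracy_boundary import (THRESHOLD_PRESETS, call_boundaries,
                                  degeneracy_matrix)
from .errors import ArgumentError
from .genome_io import GenomeRecord, read_genome
from .genome_metrics import ani_details, best_s16_identity, ddh_formula2
from .ortholog_table import Thresholds, common_genes, core_genes
from .phylogeny import bootstrap, pdistance, write_newick
from .synthetic_data import SimulationConfig, simulate_panel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one delineation run depends on."""

    genomes: list[dict] = field(default_factory=list)  # {fasta, gff?, id?}
    simulate: dict | None = None                       # SimulationConfig fields
    identity_threshold: float = 70.0
    coverage_threshold: float = 70.0
    denominator_mode: str = "core_of_set"
    boundary_threshold: float = THRESHOLD_PRESETS["default"]
    bootstrap_replicates: int = 1000
    seed: int = 42
    metrics: list[str] = field(default_factory=lambda: ["ani", "ddh", "16s"])
    outgroup: str | None = None
    strategy: str = "screened"

    def validate(self) -> None:
        for name, v in (("identity_threshold", self.identity_threshold),
                        ("coverage_threshold", self.coverage_threshold),
                        ("boundary_threshold", self.boundary_threshold)):
            if not 0.0 < v < 100.0:
                raise ArgumentError(f"{name} must be in (0, 100), got {v}")
        if self.bootstrap_replicates < 1:
            raise ArgumentError("bootstrap_replicates must be >= 1")
        if not self.genomes and self.simulate is None:
            raise ArgumentError("config needs genome inputs or a simulate block")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def thresholds(self) -> Thresholds:
        return Thresholds(identity=self.identity_threshold,
                          coverage=self.coverage_threshold)


def _load_genomes(config: RunConfig) -> list[GenomeRecord]:
    genomes: list[GenomeRecord] = []
    if config.simulate is not None:
        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        if "gene_length" in sim:
            sim["gene_length"] = tuple(sim["gene_length"])
        panel, _ = simulate_panel(SimulationConfig(**sim))
        genomes.extend(panel)
    for entry in config.genomes:
        genomes.append(read_genome(entry["fasta"], entry.get("gff"),
                                   genome_id=entry.get("id"),
                                   accession=entry.get("accession")))
    if len(genomes) < 2:
        raise ArgumentError("run_pipeline needs at least 2 genomes")
    return genomes


def _write_matrix(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", float_format="%.6f")


def run_pipeline(config: RunConfig, out_dir: str) -> dict:
    """Run the full analysis; returns the result objects keyed by stage."""
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    timings: dict[str, float] = {}
    results: dict = {}

    def stage(name):
        logger.info("stage: %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    s = stage("ingest")
    genomes = _load_genomes(config)
    ids = [g.genome_id for g in genomes]
    results["genomes"] = genomes
    done(s)

    thresholds = config.thresholds()
    n = len(ids)

    s = stage("common_genes")
    pct = np.full((n, n), 100.0)
    tables = {}
    for i in range(n):
        for j in range(i + 1, n):
            t = common_genes(genomes[i], genomes[j], thresholds,
                             strategy=config.strategy)
            tables[(ids[i], ids[j])] = t
            pct[i, j] = pct[j, i] = t.percents()["of_smaller"]
    results["common_gene_percent"] = pd.DataFrame(pct, index=ids, columns=ids)
    _write_matrix(results["common_gene_percent"],
                  os.path.join(out_dir, "common_gene_percent.tsv"))
    rows = []
    for (ga, gb), t in tables.items():
        for p in t.pairs:
            rows.append((ga, gb, p.gene_a, p.gene_b, p.identity,
                         p.coverage_a, p.coverage_b, int(p.zero_degeneracy)))
    pd.DataFrame(rows, columns=["genome_a", "genome_b", "gene_a", "gene_b",
                                "identity", "cov_a", "cov_b",
                                "zero_degeneracy"]).to_csv(
        os.path.join(out_dir, "common_gene_pairs.tsv"), sep="\t",
        index=False, float_format="%.4f")
    done(s)

    s = stage("core_genes")
    core = core_genes(genomes, thresholds, strategy=config.strategy)
    results["core"] = core
    with open(os.path.join(out_dir, "core_families.json"), "w") as fh:
        json.dump({"genome_ids": core.genome_ids, "reference": core.reference,
                   "families": core.families}, fh, indent=1, sort_keys=True)
    done(s)

    s = stage("degeneracy")
    dmat = degeneracy_matrix(genomes, core=core, mode=config.denominator_mode,
                             thresholds=thresholds, strategy=config.strategy)
    results["degeneracy"] = dmat
    for which in ("counts", "denominators", "ratios"):
        _write_matrix(dmat.to_dataframe(which),
                      os.path.join(out_dir, f"degeneracy_{which}.tsv"))
    done(s)

    s = stage("boundary")
    call = call_boundaries(dmat, config.boundary_threshold)
    results["boundary"] = call
    with open(os.path.join(out_dir, "boundary.json"), "w") as fh:
        json.dump(call.to_json(), fh, indent=1, sort_keys=True)
    done(s)

    if config.metrics:
        s = stage("metrics")
        rows = []
        for i in range(n):
            for j in range(i + 1, n):
                row = {"genome_a": ids[i], "genome_b": ids[j]}
                if "ani" in config.metrics:
                    row["ani"], row["fragments_used"] = ani_details(
                        genomes[i], genomes[j])
                if "ddh" in config.metrics:
                    row["ddh"] = ddh_formula2(genomes[i], genomes[j])
                if "16s" in config.metrics:
                    try:
                        row["s16_identity"] = best_s16_identity(
                            genomes[i], genomes[j])[0]
                    except Exception:
                        row["s16_identity"] = float("nan")
                rows.append(row)
        results["metrics"] = pd.DataFrame(rows)
        results["metrics"].to_csv(os.path.join(out_dir, "metrics.tsv"),
                                  sep="\t", index=False, float_format="%.4f")
        done(s)

    s = stage("tree")
    dm = pdistance(core, genomes)
    results["distances"] = dm
    _write_matrix(dm.to_dataframe(), os.path.join(out_dir, "distances.tsv"))
    with open(os.path.join(out_dir, "distances.phylip"), "w") as fh:
        fh.write(dm.to_phylip())
    if n >= 3:
        tree = bootstrap(core, genomes, replicates=config.bootstrap_replicates,
                         seed=config.seed)
        results["tree"] = tree
        with open(os.path.join(out_dir, "tree.nwk"), "w") as fh:
            fh.write(write_newick(tree, outgroup=config.outgroup))
    else:
        logger.info("fewer than 3 genomes; skipping tree construction")
    done(s)

    cfg_json = json.dumps(asdict(config), sort_keys=True)
    provenance = {
        "natspec_version": __version__,
        "numpy_version": np.__version__,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        "n_genomes": n,
        "n_core_families": len(core.families),
    }
    with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    return results


#: Files whose bytes must be identical across reruns of the same config.
DETERMINISTIC_OUTPUTS = (
    "common_gene_percent.tsv", "common_gene_pairs.tsv", "core_families.json",
    "degeneracy_counts.tsv", "degeneracy_denominators.tsv",
    "degeneracy_ratios.tsv", "boundary.json", "metrics.tsv",
    "distances.tsv", "distances.phylip", "tree.nwk",
)
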