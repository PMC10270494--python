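"""Run configuration, input validation, and the staged pipeline driver.

A :class:`RunConfig` captures every input path, stage toggle, threshold and
seed of a run and round-trips losslessly through YAML. :func:`run_pipeline`
executes the requested stages in dependency order (load -> relative ->
diversity / translocation / differential abundance -> association), writes
one TSV per result table plus a JSON manifest with full parameter provenance,
and logs stage timing to standard error. The manifest is deterministic, so a
rerun under the same config and seed is bitwise identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import io as gio
from .assoc import differential_expression, gene_genus_grid
from .diversity import alpha_diversity_report, beta_diversity_report
from .lefse import DEFAULT_PAIRS, DEFAULT_THRESHOLD, lefse_screen
from .simulate import SimConfig, simulate_cohort, simulate_transcriptome
from .tables import COMPARTMENTS, CompartmentTable, SchemaError
from .translocation import DEFAULT_TAU_ABUND, DEFAULT_TAU_PREV, translocation_report

logger = logging.getLogger("gutliver")

ALL_STAGES = ("diversity", "beta", "translocate", "da", "associate")


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    outdir: str = "gutliver_out"
    feature_table: str | None = None
    metadata: str | None = None
    taxonomy: str | None = None
    gene_counts: str | None = None
    simulate: dict | None = None          # SimConfig fields; replaces file inputs
    stages: tuple[str, ...] = ALL_STAGES
    # stage parameters (defaults are the analysis' reporting thresholds)
    tau_abund: float = DEFAULT_TAU_ABUND
    tau_prev: float = DEFAULT_TAU_PREV
    reference_group: str = "NAFLD"
    pooled_signature: bool = False
    n_perm: int = 999
    lda_threshold: float = DEFAULT_THRESHOLD
    n_boot: int = 30
    contrast: tuple[str, str] = ("NAFLD", "HCC")
    min_nonzero: int = 5
    q_threshold: float = 0.05
    de_genes_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}; choose from {ALL_STAGES}")
        self.stages = tuple(self.stages)
        self.contrast = tuple(self.contrast)

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["contrast"] = list(self.contrast)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


def validate_inputs(feature_table: str, metadata: str,
                    gene_counts: str | None = None,
                    strict: bool = False) -> pd.DataFrame:
    """Cross-check sample ids across the input files.

    Returns one record per issue (kind, detail). Orphans and duplicates are
    reported without failing unless ``strict``, in which case duplicates
    raise. Schema violations in individual files always raise, naming the
    offender.
    """
    issues: list[dict] = []
    counts = gio.read_feature_table(feature_table)
    meta = gio.read_metadata(metadata)
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()].unique().tolist()
        if strict:
            raise SchemaError(f"duplicate sample_id(s) in metadata: {dup}")
        issues.append(dict(kind="duplicate_sample_id", detail=str(dup)))
    for sid in counts.index.difference(meta.index):
        issues.append(dict(kind="orphan_sample_in_feature_table", detail=sid))
    for sid in meta.index.difference(counts.index):
        issues.append(dict(kind="orphan_sample_in_metadata", detail=sid))
    if gene_counts is not None:
        genes = gio.read_gene_counts(gene_counts)
        if genes.index.has_duplicates:
            dup = genes.index[genes.index.duplicated()].unique().tolist()
            if strict:
                raise SchemaError(f"duplicate gene id(s): {dup}")
            issues.append(dict(kind="duplicate_gene_id", detail=str(dup)))
        for sid in genes.columns.difference(meta.index):
            issues.append(dict(kind="orphan_sample_in_gene_counts", detail=sid))
    return pd.DataFrame(issues, columns=["kind", "detail"])


def _write(df: pd.DataFrame, outdir: str, name: str, manifest: dict, index=True) -> None:
    path = os.path.join(outdir, name)
    df.to_csv(path, sep="\t", na_rep=gio.NA_TOKEN, index=index)
    manifest["outputs"].append(name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "config": {**dataclasses.asdict(config),
                   "stages": list(config.stages), "contrast": list(config.contrast)},
        "outputs": [],
    }
    t0 = time.perf_counter()

    gene_counts = None
    if config.simulate is not None:
        sim = SimConfig(**config.simulate)
        logger.info("simulating cohort (seed=%d)", sim.seed)
        table, truth = simulate_cohort(sim)
        gene_counts, truth = simulate_transcriptome(sim, truth, table)
        indir = os.path.join(config.outdir, "inputs")
        os.makedirs(indir, exist_ok=True)
        gio.write_feature_table(table.counts, os.path.join(indir, "feature_table.tsv"))
        gio.write_metadata(table.meta, os.path.join(indir, "metadata.tsv"))
        gio.write_taxonomy(table.lineage, os.path.join(indir, "taxonomy.tsv"))
        gio.write_gene_counts(gene_counts, os.path.join(indir, "gene_counts.tsv"))
        sim.to_yaml(os.path.join(indir, "sim_config.yaml"))
        truth.write(indir)
        manifest["outputs"].extend(
            f"inputs/{f}" for f in sorted(os.listdir(indir)))
    else:
        if config.feature_table is None or config.metadata is None:
            raise ValueError("need feature_table and metadata paths (or simulate:)")
        table = gio.load_compartment_table(config.feature_table, config.metadata,
                                           config.taxonomy)
        if config.gene_counts is not None:
            gene_counts = gio.read_gene_counts(config.gene_counts)

    if "diversity" in config.stages:
        t = time.perf_counter()
        alpha = alpha_diversity_report(table)
        _write(alpha.per_sample, config.outdir, "alpha_diversity.tsv", manifest)
        _write(alpha.tests, config.outdir, "alpha_tests.tsv", manifest, index=False)
        logger.info("diversity stage: %.1fs", time.perf_counter() - t)

    if "beta" in config.stages:
        t = time.perf_counter()
        rows = []
        for comp in COMPARTMENTS:
            if comp not in set(table.meta["compartment"]):
                continue
            res = beta_diversity_report(table, comp, n_perm=config.n_perm,
                                        seed=config.seed)
            gio.write_distance_matrix(
                res.distances, os.path.join(config.outdir, f"beta_{comp}_distances.tsv"))
            manifest["outputs"].append(f"beta_{comp}_distances.tsv")
            g = res.global_test
            rows.append(dict(compartment=comp, scope="global", group1=gio.NA_TOKEN,
                             group2=gio.NA_TOKEN, f=g.f, r2=g.r2, p=g.p, q=math.nan,
                             n_permutations=g.n_permutations))
            for _, r in res.pairwise.iterrows():
                rows.append(dict(compartment=comp, scope="pairwise",
                                 group1=r["group1"], group2=r["group2"], f=r["f"],
                                 r2=r["r2"], p=r["p"], q=r["q"],
                                 n_permutations=r["n_permutations"]))
        _write(pd.DataFrame(rows), config.outdir, "beta_permanova.tsv",
               manifest, index=False)
        logger.info("beta stage: %.1fs", time.perf_counter() - t)

    if "translocate" in config.stages:
        t = time.perf_counter()
        rep = translocation_report(
            table, reference_group=config.reference_group,
            tau_abund=config.tau_abund, tau_prev=config.tau_prev,
            pooled_signature=config.pooled_signature)
        _write(rep.samples, config.outdir, "translocation.tsv", manifest)
        _write(rep.contrasts, config.outdir, "translocation_contrasts.tsv",
               manifest, index=False)
        summary = {
            "tau_abund": config.tau_abund, "tau_prev": config.tau_prev,
            "reference_group": config.reference_group,
            "pooled_signature": config.pooled_signature,
            "signature_sizes": {g: len(s.genera) for g, s in rep.signatures.items()},
            "n_fecal_samples": {g: s.n_fecal_samples for g, s in rep.signatures.items()},
            "median_proportion": {
                f"{c}/{g}": float(v) for (c, g), v in
                rep.samples.groupby(["compartment", "group"])["proportion"]
                .median().items()},
        }
        with open(os.path.join(config.outdir, "translocation_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        manifest["outputs"].append("translocation_summary.json")
        logger.info("translocation stage: %.1fs", time.perf_counter() - t)

    if "da" in config.stages:
        t = time.perf_counter()
        screen = lefse_screen(table, pairs=DEFAULT_PAIRS,
                              threshold=config.lda_threshold,
                              n_boot=config.n_boot, seed=config.seed)
        _write(screen.records, config.outdir, "lefse_records.tsv", manifest,
               index=False)
        _write(screen.reported, config.outdir, "lefse_reported.tsv", manifest,
               index=False)
        logger.info("differential-abundance stage: %.1fs", time.perf_counter() - t)

    if "associate" in config.stages:
        if gene_counts is None:
            raise ValueError("associate stage needs gene_counts (or simulate:)")
        t = time.perf_counter()
        de = differential_expression(gene_counts, table.meta["group"],
                                     contrast=config.contrast)
        _write(de, config.outdir, "de_table.tsv", manifest)
        genes = de.index[de["de"].fillna(False)] if config.de_genes_only else None
        grid = gene_genus_grid(gene_counts, table, genes=genes,
                               min_nonzero=config.min_nonzero,
                               q_threshold=config.q_threshold, de_table=de)
        _write(grid.records, config.outdir, "association_grid.tsv", manifest,
               index=False)
        _write(grid.pruned, config.outdir, "association_pruned.tsv", manifest,
               index=False)
        summary = {
            "n_pairs_tested": int(grid.records["p"].notna().sum()),
            "n_significant": int(grid.records["significant"].sum()),
            "n_genera_tested": len(grid.genera_tested),
            "min_nonzero": config.min_nonzero,
            "q_threshold": config.q_threshold,
            "joint_fdr": grid.joint_fdr,
            "n_de_genes": int(de["de"].fillna(False).sum()),
        }
        with open(os.path.join(config.outdir, "association_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        manifest["outputs"].append("association_summary.json")
        logger.info("association stage: %.1fs", time.perf_counter() - t)

    manifest["outputs"] = sorted(manifest["outputs"])
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline done in %.1fs", time.perf_counter() - t0)
    return manifest
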