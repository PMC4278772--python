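"""End-to-end pipeline orchestration.

Chains the stages demultiplex -> trim -> reference build -> map -> profile ->
pairwise comparison -> expression analysis, either on user-supplied files or
on a freshly simulated dataset, and writes every intermediate table to the
run directory.  All stages are deterministic given the configuration seed.
"""

from __future__ import annotations

import hashlib
import itertools
import sys
from collections import Counter
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import apacomp, expr, mapper, refdb, simulate, tagproc
from .errors import ConfigurationError, InputError


@dataclass
class PipelineConfig:
    """Everything needed for one run.

    In synthetic mode the genome/annotation/reads come from the generator
    (``sim``); in real-data mode the four file paths must exist.  The numeric
    defaults are the workflow's canonical constants: 500-nt UTR extension, >5 tpm expression
    filter, pseudocount 1, fold-change cutoff 2.
    """

    output_dir: Path = Path("patseq_run")
    synthetic: bool = True
    sim: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    reads_fastq: Path | None = None
    genome_fasta: Path | None = None
    annotation: Path | None = None
    barcode_tsv: Path | None = None
    bin_tsv: Path | None = None
    adapter_5p: str = ""
    adapter_3p: str = ""
    extension: int = 500
    cluster_window: int = 24
    min_tags: int = 10
    tpm_threshold: float = 5.0
    pseudocount: float = 1.0
    fold_cutoff: float = 2.0
    screen_low: float = 0.2
    screen_high: float = 0.5
    max_mismatch: int = 2
    demux_max_mismatch: int = 0
    min_tag_len: int = 20
    mask_internal_priming: bool = False
    seed: int = 0
    render_plots: bool = False

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.synthetic:
            self.sim.seed = self.seed
            self.sim.extension = self.extension
            if not self.adapter_5p:
                self.adapter_5p = self.sim.adapter_5p
            if not self.adapter_3p:
                self.adapter_3p = self.sim.adapter_3p
        else:
            for name in ("reads_fastq", "genome_fasta", "annotation", "barcode_tsv"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ConfigurationError(f"real-data mode requires existing {name}")
            if not self.adapter_5p or not self.adapter_3p:
                raise ConfigurationError("real-data mode requires both adapters")
        if self.screen_low >= self.screen_high:
            raise ConfigurationError("screen_low must be < screen_high")
        for positive in ("extension", "cluster_window", "min_tags", "min_tag_len"):
            if getattr(self, positive) <= 0:
                raise ConfigurationError(f"{positive} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if sim_raw:
            sim_known = {f.name for f in fields(simulate.SimulationConfig)}
            bad = set(sim_raw) - sim_known
            if bad:
                raise ConfigurationError(f"unknown sim key(s): {sorted(bad)}")
            for key in ("utr_length_range", "n_sites_range", "polyA_remnant_length_range"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            cfg.sim = simulate.SimulationConfig(**sim_raw)
            cfg.sim.seed = cfg.seed
            cfg.sim.extension = cfg.extension
        return cfg


@dataclass
class PipelineResult:
    """In-memory view of a finished run (everything is also on disk)."""

    output_dir: Path
    samples: dict[str, str]  # sample -> genotype
    n_reads: int
    demux_counts: dict[str, int]
    n_unassigned: int
    discarded: dict[str, int]
    map_stats: dict[str, Counter]
    profiles: dict[str, dict[str, mapper.SiteProfile]]
    counts: pd.DataFrame
    d_maps: dict[str, dict[str, float]]
    expression: expr.ExpressionMatrix | None
    cam_pass: pd.DataFrame | None
    screen_genes: list[str]
    truth: simulate.SyntheticTruth | None


class _RunLog:
    """Deterministic run log (file + stderr), no timestamps."""

    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def log(self, message: str) -> None:
        self.lines.append(message)
        print(message, file=sys.stderr)

    def write(self) -> None:
        self.path.write_text("".join(line + "\n" for line in self.lines))


def _read_barcode_tsv(path: Path) -> tuple[dict[str, str], dict[str, str]]:
    """Barcode TSV: sample, barcode[, genotype]."""
    barcodes: dict[str, str] = {}
    genotypes: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.startswith("sample\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            barcodes[parts[0]] = parts[1]
            genotypes[parts[0]] = parts[2] if len(parts) > 2 else parts[0]
    return barcodes, genotypes


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = config.output_dir
    for sub in ("demux", "db", "map", "compare", "expression"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run_log.txt")
    truth = None

    # -- stage: inputs ------------------------------------------------------
    if config.synthetic:
        genome, annotation, truth = simulate.generate_reference(config.sim)
        reads = simulate.simulate_tag_reads(genome, annotation, truth, config.sim)
        refdb.write_genome_fasta(genome, out / "genome.fasta")
        refdb.write_gff3(annotation, out / "utrs.gff3")
        refdb.write_bed(annotation, out / "utrs.bed")
        simulate.write_truth_tables(
            truth,
            out / "truth_sites.tsv",
            out / "truth_expression.tsv",
            out / "truth_bins.tsv",
        )
        tagproc.write_fastq(reads, out / "reads.fastq")
        barcodes = {s: config.sim.barcodes[s] for s in config.sim.samples}
        sample_genotypes = dict(config.sim.samples)
        bin_map = truth.bin_map
        log.log(f"stage=simulate genes={len(annotation)} reads={len(reads)}")
    else:
        genome = refdb.read_genome_fasta(config.genome_fasta)
        annotation = refdb.read_utr_annotation(config.annotation, config.extension)
        reads = list(tagproc.read_fastq(config.reads_fastq))
        barcodes, sample_genotypes = _read_barcode_tsv(Path(config.barcode_tsv))
        bin_map = expr.read_bin_map(config.bin_tsv) if config.bin_tsv else None
        log.log(f"stage=load genes={len(annotation)} reads={len(reads)}")
    n_reads = len(reads)

    # -- stage: demultiplex -------------------------------------------------
    assigned, unassigned = tagproc.demultiplex(
        reads, barcodes, max_mismatch=config.demux_max_mismatch
    )
    del reads
    demux_counts = {s: len(v) for s, v in assigned.items()}
    if sum(demux_counts.values()) + len(unassigned) != n_reads:
        raise InputError("demultiplex lost reads")  # pragma: no cover
    for sample in sorted(assigned):
        tagproc.write_fastq(assigned[sample], out / "demux" / f"{sample}.fastq")
        log.log(f"stage=demux sample={sample} reads={demux_counts[sample]}")
    log.log(f"stage=demux sample=unassigned reads={len(unassigned)}")
    tagproc.write_demux_report(demux_counts, len(unassigned), out / "demux" / "report.tsv")

    # -- stage: trim --------------------------------------------------------
    trimmed: dict[str, list[tagproc.TagRead]] = {}
    discarded: dict[str, int] = {}
    for sample in sorted(assigned):
        kept, n_disc = tagproc.trim_reads(
            assigned[sample],
            config.adapter_5p,
            config.adapter_3p,
            min_len=config.min_tag_len,
        )
        trimmed[sample] = kept
        discarded[sample] = n_disc
        log.log(f"stage=trim sample={sample} kept={len(kept)} discarded={n_disc}")
    del assigned

    # -- stage: reference database -----------------------------------------
    records = refdb.build_extended_utr_db(annotation, genome, config.extension)
    refdb.write_db_fasta(records, out / "db" / "utrdb.fasta", out / "db" / "utrdb.map.tsv")
    index = mapper.TagIndex(records)
    log.log(f"stage=makedb records={len(records)}")

    # -- stage: map + profile ----------------------------------------------
    profiles: dict[str, dict[str, mapper.SiteProfile]] = {}
    map_stats: dict[str, Counter] = {}
    gene_ids = [g.gene_id for g in annotation]
    count_cols = {}
    for sample in sorted(trimmed):
        tag_seqs = {r.read_id: r.sequence for r in trimmed[sample]}
        hits, stats = index.map_tags(
            ((r.read_id, r.sequence) for r in trimmed[sample]),
            max_mismatch=config.max_mismatch,
        )
        map_stats[sample] = stats
        mapper.write_sam(
            out / "map" / f"{sample}.sam",
            records,
            ((h, tag_seqs[h.read_id]) for h in hits),
        )
        prof = mapper.build_site_profiles(hits, sample, window=config.cluster_window)
        if config.mask_internal_priming:
            prof = mapper.mask_internal_priming(
                prof, records, cluster_window=config.cluster_window
            )
        profiles[sample] = prof
        mapper.write_site_counts(prof, out / "map" / f"{sample}.sites.tsv")
        count_cols[sample] = pd.Series(
            {g: prof[g].total if g in prof else 0 for g in gene_ids}, dtype=int
        )
        log.log(
            f"stage=map sample={sample} mapped={stats[mapper.MAPPED]} "
            f"unmapped={stats[mapper.UNMAPPED]} multimapped={stats[mapper.MULTIMAPPED]}"
        )
    counts = pd.DataFrame(count_cols, index=pd.Index(gene_ids, name="gene_id"))
    expr.write_counts_tsv(counts, out / "expression" / "counts.tsv")

    # -- stage: pairwise profile comparisons --------------------------------
    d_maps: dict[str, dict[str, float]] = {}
    curves = []
    for a, b in itertools.combinations(sorted(profiles), 2):
        key = apacomp.pair_key(a, b)
        diffs = apacomp.genomewide_comparison(
            profiles[a], profiles[b], min_tags=config.min_tags, window=config.cluster_window
        )
        d_maps[key] = {g: d.d for g, d in diffs.items()}
        apacomp.write_comparison_tsv(diffs, out / "compare" / f"D_{key}.tsv")
        if diffs:
            curve = apacomp.cumulative_curve(d_maps[key].values(), label=key)
            apacomp.write_ecdf_tsv(curve, out / "compare" / f"ecdf_{key}.tsv")
            curves.append(curve)
        log.log(f"stage=apacompare pair={key} genes={len(diffs)}")
    if config.render_plots and curves:
        apacomp.plot_curves(curves, out / "compare" / "curves.png")

    # -- stage: APA pattern screen -----------------------------------------
    genotype_rep: dict[str, str] = {}
    for sample in sorted(sample_genotypes):
        genotype_rep.setdefault(sample_genotypes[sample], sample)
    screen_genes: list[str] = []
    if set(simulate.GENOTYPES) <= set(genotype_rep):
        rep = genotype_rep
        screen_genes = apacomp.screen_pattern_genes(
            d_maps,
            low_thr=config.screen_low,
            high_thr=config.screen_high,
            wt=rep["wt"],
            oxt6=rep["oxt6"],
            c30g=rep["c30g"],
            c30gm=rep["c30gm"],
        )
        (out / "compare" / "apa_screen_genes.tsv").write_text(
            "gene_id\n" + "".join(g + "\n" for g in screen_genes)
        )
        log.log(f"stage=apascreen genes={len(screen_genes)}")

    # -- stage: expression --------------------------------------------------
    expression = None
    cam_pass = None
    if set(simulate.GENOTYPES) <= set(genotype_rep):
        genotype_counts = counts[[genotype_rep[g] for g in simulate.GENOTYPES]]
        genotype_counts.columns = list(simulate.GENOTYPES)
        expression = expr.ExpressionMatrix.from_counts(
            genotype_counts,
            tpm_threshold=config.tpm_threshold,
            pseudocount=config.pseudocount,
        )
        expression.tpm.to_csv(out / "expression" / "tpm.tsv", sep="\t")
        expression.adjusted.to_csv(out / "expression" / "adjusted.tsv", sep="\t")
        expression.ratios.to_csv(out / "expression" / "ratios.tsv", sep="\t")
        expression.log2_ratios.to_csv(out / "expression" / "log2_ratios.tsv", sep="\t")
        cam_pass = expr.cam_dependent_filter(expression.ratios, cutoff=config.fold_cutoff)
        cam_pass.to_csv(out / "expression" / "cam_filter.tsv", sep="\t")
        (out / "expression" / "cam_pass_genes.tsv").write_text(
            "gene_id\n" + "".join(g + "\n" for g in cam_pass.index[cam_pass["pass"]])
        )
        log.log(
            f"stage=express filtered_genes={len(expression.ratios)} "
            f"cam_pass={int(cam_pass['pass'].sum())}"
        )
        if bin_map is not None:
            label = expr.comparison_label("wt", "oxt6")
            enrich = expr.wilcoxon_bin_test(expression.log2_ratios[label], bin_map)
            enrich.to_csv(out / "expression" / "bin_enrichment.tsv", sep="\t", index=False)
            log.log(f"stage=bins tested={len(enrich)}")
        groups: dict[str, list[str]] = {}
        for sample, gt in sample_genotypes.items():
            groups.setdefault(gt, []).append(sample)
        bag = expr.baggerly_table(counts, sorted(groups["wt"]), sorted(groups["oxt6"]))
        bag.to_csv(out / "expression" / "baggerly_wt_vs_oxt6.tsv", sep="\t")
        log.log(f"stage=baggerly genes={len(bag)}")

    log.write()
    return PipelineResult(
        output_dir=out,
        samples=sample_genotypes,
        n_reads=n_reads,
        demux_counts=demux_counts,
        n_unassigned=len(unassigned),
        discarded=discarded,
        map_stats=map_stats,
        profiles=profiles,
        counts=counts,
        d_maps=d_maps,
        expression=expression,
        cam_pass=cam_pass,
        screen_genes=screen_genes,
        truth=truth,
    )


def checksum_run(output_dir: str | Path) -> dict[str, str]:
    """MD5 of every regular file in a run directory (for determinism checks)."""
    out = {}
    for path in sorted(Path(output_dir).rglob("*")):
        if path.is_file():
            out[str(path.relative_to(output_dir))] = hashlib.md5(
                path.read_bytes()
            ).hexdigest()
    return out
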