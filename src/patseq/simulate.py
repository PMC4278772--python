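"""Synthetic PAT-seq data generator with ground truth.

Emulates a four-genotype poly(A)-tag sequencing experiment: a wild type
(``wt``), a CPSF30-deficient mutant (``oxt6``), and two complemented lines
(``c30g`` carrying the wild-type transgene, ``c30gm`` carrying a
calmodulin-binding-deficient one).  The generator produces a random genome,
a 3'-UTR annotation, multiplexed single-end tag reads, and truth tables, so
that the downstream pipeline (demultiplex -> trim -> map -> profile ->
compare) can be validated end to end.

Study structure encoded in the truth:

* every gene has 1-3 true poly(A) sites inside its 3'-UTR or up to the
  extension distance downstream (products of inefficient termination);
* a planted minority of genes (default 10%) is *APA-shifted*: the ``oxt6``
  usage vector moves its dominant site, while ``c30g`` and ``c30gm`` are
  identical to ``wt`` (site choice restored by either transgene — the headline
  restoration effect).  An optional sub-fraction can be left unrestored in
  ``c30gm`` to exercise the pattern screen;
* a planted minority (default 2%) is *calmodulin-dependent* in expression:
  mean tag counts follow wt ~ C30G >> oxt6 ~ C30GM (or the inverse) at a
  configurable fold (default 5); all other genes are expressed identically
  across genotypes.

Reads are laid out barcode + 5' adapter + tag + poly(A) remnant + 3'
adapter, where the tag is a slice of the reverse-complemented extended-UTR
database ending at the (Gaussian-jittered) cleavage site, so tags align
sense to the database.  Per-gene read counts are Poisson around the genotype
expression means; substitution errors are applied uniformly at
``error_rate``.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .refdb import ExtendedUtrRecord, GeneModel, build_extended_utr_db

GENOTYPES = ("wt", "oxt6", "c30g", "c30gm")

DEFAULT_SAMPLES: dict[str, str] = {g: g for g in GENOTYPES}

DEFAULT_BARCODES: dict[str, str] = {
    "wt": "ACGTAC",
    "oxt6": "TGCAGT",
    "c30g": "GATCTG",
    "c30gm": "CTAGCA",
    "wt2": "GTTGCA",
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment (defaults are the reference
    conditions used throughout the test suite)."""

    n_chromosomes: int = 2
    genes_per_chromosome: int = 250
    utr_length_range: tuple[int, int] = (150, 350)
    n_sites_range: tuple[int, int] = (1, 3)
    cluster_sigma: float = 3.0
    depth_per_sample: int = 200_000
    samples: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SAMPLES))
    barcodes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_BARCODES))
    adapter_5p: str = "TACACGACGCTC"
    adapter_3p: str = "AGATCGGAAGAGC"
    tag_length: int = 50
    polyA_remnant_length_range: tuple[int, int] = (6, 14)
    error_rate: float = 0.001
    seed: int = 0
    planted_cam_fraction: float = 0.02
    planted_apa_fraction: float = 0.10
    cam_fold: float = 5.0
    c30gm_apa_unrestored_fraction: float = 0.0
    extension: int = 500
    n_bins: int = 20
    chromosome_length: int | None = None  # None: sized automatically
    min_site_separation: int = 60
    min_expected_tpm: float = 400.0

    def validate(self) -> None:
        counts = [
            self.n_chromosomes,
            self.genes_per_chromosome,
            self.depth_per_sample,
            self.tag_length,
            self.extension,
            self.n_bins,
        ]
        if any(c <= 0 for c in counts):
            raise ConfigurationError("all counts must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigurationError("error_rate must be in [0, 1)")
        for frac in (
            self.planted_cam_fraction,
            self.planted_apa_fraction,
            self.c30gm_apa_unrestored_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("planted fractions must be in [0, 1]")
        lo, hi = self.utr_length_range
        if not 0 < lo <= hi:
            raise ConfigurationError("invalid utr_length_range")
        slo, shi = self.n_sites_range
        if not 0 < slo <= shi:
            raise ConfigurationError("invalid n_sites_range")
        missing = set(self.samples) - set(self.barcodes)
        if missing:
            raise ConfigurationError(f"samples without barcode: {sorted(missing)}")
        used = [self.barcodes[s] for s in self.samples]
        if len({len(b) for b in used}) != 1:
            raise ConfigurationError("barcodes must be equal length")
        if len(set(used)) != len(used):
            raise ConfigurationError("barcodes must be pairwise distinct")
        bad = set(self.samples.values()) - set(GENOTYPES)
        if bad:
            raise ConfigurationError(f"unknown genotype(s): {sorted(bad)}")
        if self.chromosome_length is not None:
            if self.utr_length_range[1] > self.chromosome_length:
                raise ConfigurationError("UTR longer than chromosome")

    def auto_chromosome_length(self) -> int:
        slot = self.utr_length_range[1] + self.extension + 200
        return 100 + self.genes_per_chromosome * slot + 2 * self.extension


@dataclass
class GeneTruth:
    """Ground truth for one gene."""

    gene_id: str
    chromosome: str
    strand: str
    site_db_positions: list[int]
    site_genomic_positions: list[int]
    usage: dict[str, np.ndarray]  # genotype -> proportions over sites
    expression: dict[str, float]  # genotype -> mean tag count per sample
    planted_cam_dependent: bool = False
    cam_pattern: str = ""  # "high_wt" | "high_oxt6" | ""
    planted_apa_shifted: bool = False
    apa_unrestored_in_c30gm: bool = False


@dataclass
class SyntheticTruth:
    genes: dict[str, GeneTruth]
    bin_map: pd.DataFrame  # columns gene_id, bin_id

    def usage_matrix(self, genotype: str) -> dict[str, np.ndarray]:
        return {g: t.usage[genotype] for g, t in self.genes.items()}


def _random_genome(rng: np.random.Generator, lengths: dict[str, int]) -> dict[str, str]:
    genome = {}
    for chrom, length in lengths.items():
        arr = _BASES[rng.integers(0, 4, size=length)]
        genome[chrom] = _cap_homopolymers(arr.tobytes().decode("ascii"))
    return genome


def _cap_homopolymers(seq: str, max_run: int = 4) -> str:
    """Break homopolymer runs longer than ``max_run``.

    Keeps oligo-dT-remnant trimming from eating genuine junction-adjacent
    sequence by more than the cleavage-jitter tolerance.
    """
    out = list(seq)
    run = 1
    for i in range(1, len(out)):
        if out[i] == out[i - 1]:
            run += 1
            if run > max_run:
                out[i] = "ACGT"[("ACGT".index(out[i]) + 1) % 4]
                run = 1
        else:
            run = 1
    return "".join(out)


def _draw_sites(
    rng: np.random.Generator, n: int, low: int, high: int, min_sep: int
) -> list[int]:
    """Distinct db positions in [low, high) with pairwise separation."""
    span = high - low
    max_fit = max(1, span // min_sep)
    n = min(n, max_fit)
    for _ in range(200):
        pos = np.sort(rng.integers(low, high, size=n))
        if n == 1 or np.diff(pos).min() >= min_sep:
            return [int(p) for p in pos]
    # fall back to an evenly spaced layout
    return [int(low + i * span // n + span // (2 * n)) for i in range(n)]


def _shifted_usage(rng: np.random.Generator, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(wt, oxt6) usage for an APA-shifted gene: dominant site moves."""
    def dominant(at: int) -> np.ndarray:
        m = rng.uniform(0.7, 0.9)
        rest = rng.dirichlet(np.ones(k - 1)) * (1.0 - m)
        u = np.insert(rest, at, m)
        return u / u.sum()

    return dominant(0), dominant(k - 1)


def generate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], SyntheticTruth]:
    """Generate genome, 3'-UTR annotation and ground truth (deterministic)."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    chrom_len = config.chromosome_length or config.auto_chromosome_length()
    slot = config.utr_length_range[1] + config.extension + 200
    lengths = {f"chr{c + 1}": chrom_len for c in range(config.n_chromosomes)}
    genome = _random_genome(rng, lengths)

    genes: list[GeneModel] = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for i in range(config.genes_per_chromosome):
            utr_len = int(rng.integers(*config.utr_length_range, endpoint=True))
            start = 100 + i * slot + config.extension
            if start + utr_len + config.extension > chrom_len:
                raise ConfigurationError(
                    f"gene does not fit on {chrom} (length {chrom_len})"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene_{c + 1}_{i + 1:04d}",
                    chromosome=chrom,
                    strand=strand,
                    utr_start=start,
                    utr_end=start + utr_len,
                    extension=config.extension,
                )
            )

    records = build_extended_utr_db(genes, genome, config.extension)
    rec_by_gene = {r.gene_id: r for r in records}

    n_genes = len(genes)
    # relative abundance: lognormal over genes with a floor.  The synthetic
    # gene set stands for the post-expression-filter gene universe of a real
    # tag experiment, where the >5 tpm filter at multi-million-tag library
    # depth guarantees tens of tags per analyzed gene; the floor (default
    # 400 tpm) keeps every synthetic gene in that shot-noise regime.
    rel = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    rel /= rel.sum()
    floor = config.min_expected_tpm / 1e6
    if n_genes * floor >= 1.0:
        raise ConfigurationError("min_expected_tpm too high for this many genes")
    rel = floor + (1.0 - n_genes * floor) * rel
    base_mean = rel * config.depth_per_sample
    expected_tpm = rel * 1e6

    # planted classes, drawn only among adequately expressed genes so the
    # minority classes are detectable spike-ins
    n_cam = int(round(config.planted_cam_fraction * n_genes))
    n_apa = int(round(config.planted_apa_fraction * n_genes))
    cam_eligible = np.flatnonzero(expected_tpm >= 1000.0)
    apa_eligible = np.flatnonzero(expected_tpm >= 150.0)
    cam_idx = set(
        rng.choice(cam_eligible, size=min(n_cam, cam_eligible.size), replace=False).tolist()
    )
    apa_idx = set(
        rng.choice(apa_eligible, size=min(n_apa, apa_eligible.size), replace=False).tolist()
    )

    sqrt_fold = float(np.sqrt(config.cam_fold))
    truth_genes: dict[str, GeneTruth] = {}
    for gi, gene in enumerate(genes):
        rec = rec_by_gene[gene.gene_id]
        is_apa = gi in apa_idx
        low = config.tag_length + 5
        high = rec.db_length - 20
        k = int(rng.integers(*config.n_sites_range, endpoint=True))
        if is_apa:
            k = max(k, 2)
        sites = _draw_sites(rng, k, low, high, config.min_site_separation)
        k = len(sites)
        if is_apa and k < 2:
            is_apa = False

        if is_apa:
            wt_u, oxt6_u = _shifted_usage(rng, k)
        else:
            wt_u = rng.dirichlet(np.full(k, 2.0))
            oxt6_u = wt_u
        unrestored = bool(
            is_apa and rng.random() < config.c30gm_apa_unrestored_fraction
        )
        usage = {
            "wt": wt_u,
            "oxt6": oxt6_u,
            "c30g": wt_u.copy(),
            "c30gm": oxt6_u.copy() if unrestored else wt_u.copy(),
        }

        is_cam = gi in cam_idx
        if is_cam:
            pattern = "high_wt" if rng.random() < 0.5 else "high_oxt6"
            hi_mean = base_mean[gi] * sqrt_fold
            lo_mean = base_mean[gi] / sqrt_fold
            if pattern == "high_wt":
                expr = {"wt": hi_mean, "c30g": hi_mean, "oxt6": lo_mean, "c30gm": lo_mean}
            else:
                expr = {"wt": lo_mean, "c30g": lo_mean, "oxt6": hi_mean, "c30gm": hi_mean}
        else:
            pattern = ""
            expr = {g: float(base_mean[gi]) for g in GENOTYPES}

        truth_genes[gene.gene_id] = GeneTruth(
            gene_id=gene.gene_id,
            chromosome=gene.chromosome,
            strand=gene.strand,
            site_db_positions=sites,
            site_genomic_positions=[rec.db_to_genome(s)[1] for s in sites],
            usage=usage,
            expression={g: float(v) for g, v in expr.items()},
            planted_cam_dependent=is_cam,
            cam_pattern=pattern,
            planted_apa_shifted=bool(is_apa and not unrestored),
            apa_unrestored_in_c30gm=unrestored,
        )

    bin_ids = rng.integers(1, config.n_bins + 1, size=n_genes)
    bin_map = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "bin_id": [f"bin{b:02d}" for b in bin_ids]}
    )
    return genome, genes, SyntheticTruth(truth_genes, bin_map)


# ---------------------------------------------------------------------------
# Read simulation


def sample_counts(
    truth: SyntheticTruth, samples: Mapping[str, str], seed: int
) -> pd.DataFrame:
    """Poisson tag counts per gene x sample around the truth means."""
    rng = np.random.default_rng([seed, 2])
    gene_ids = sorted(truth.genes)
    data = {}
    for sample in samples:
        genotype = samples[sample]
        means = np.array([truth.genes[g].expression[genotype] for g in gene_ids])
        data[sample] = rng.poisson(means)
    return pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))


def simulate_tag_reads(
    genome: Mapping[str, str],
    annotation: Iterable[GeneModel],
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> list[tuple[str, str, str]]:
    """Emit multiplexed (read_id, sequence, qualities) tuples.

    Read ids carry the source sample and gene (``sample:gene:serial``) so
    tests can trace every read back to its origin; the pipeline itself never
    consults them.
    """
    config.validate()
    annotation = list(annotation)
    missing = {g.gene_id for g in annotation} - set(truth.genes)
    if missing:
        raise ConfigurationError(f"truth does not cover genes: {sorted(missing)[:5]}")
    rng = np.random.default_rng([config.seed, 1])
    records = build_extended_utr_db(annotation, genome, config.extension)
    rec_by_gene = {r.gene_id: r for r in records}
    rem_lo, rem_hi = config.polyA_remnant_length_range
    a5, a3 = config.adapter_5p, config.adapter_3p
    tag_len = config.tag_length

    reads: list[tuple[str, str, str]] = []
    for sample in sorted(config.samples):
        genotype = config.samples[sample]
        barcode = config.barcodes[sample]
        for gene in annotation:
            t = truth.genes[gene.gene_id]
            n = int(rng.poisson(t.expression[genotype]))
            if n == 0:
                continue
            rec = rec_by_gene[gene.gene_id]
            seq = rec.db_sequence
            sites = np.asarray(t.site_db_positions)
            idx = rng.choice(len(sites), size=n, p=t.usage[genotype])
            jitter = np.rint(
                rng.normal(0.0, config.cluster_sigma, size=n)
            ).astype(int)
            junctions = np.clip(sites[idx] + jitter, 0, rec.db_length - 1)
            remnants = rng.integers(rem_lo, rem_hi, size=n, endpoint=True)
            for serial in range(n):
                j = int(junctions[serial])
                tag = seq[max(0, j - tag_len + 1): j + 1]
                read = barcode + a5 + tag + "A" * int(remnants[serial]) + a3
                if config.error_rate > 0.0:
                    read = _inject_errors(rng, read, config.error_rate)
                reads.append(
                    (
                        f"{sample}:{gene.gene_id}:{serial}",
                        read,
                        "I" * len(read),
                    )
                )
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def _inject_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for pos in positions:
        current = chars[pos]
        options = [b for b in "ACGT" if b != current]
        chars[pos] = options[int(rng.integers(0, len(options)))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Truth table output


def write_truth_tables(
    truth: SyntheticTruth,
    sites_path: str | Path,
    expression_path: str | Path,
    bins_path: str | Path,
) -> None:
    with open(sites_path, "w") as fh:
        fh.write(
            "gene_id\tchromosome\tstrand\tsite_index\tdb_position\tgenomic_position\t"
            + "\t".join(f"usage_{g}" for g in GENOTYPES)
            + "\tplanted_apa_shifted\tapa_unrestored_in_c30gm\n"
        )
        for gene_id in sorted(truth.genes):
            t = truth.genes[gene_id]
            for si in range(len(t.site_db_positions)):
                usages = "\t".join(f"{t.usage[g][si]:.6f}" for g in GENOTYPES)
                fh.write(
                    f"{gene_id}\t{t.chromosome}\t{t.strand}\t{si}\t"
                    f"{t.site_db_positions[si]}\t{t.site_genomic_positions[si]}\t"
                    f"{usages}\t{int(t.planted_apa_shifted)}\t"
                    f"{int(t.apa_unrestored_in_c30gm)}\n"
                )
    with open(expression_path, "w") as fh:
        fh.write(
            "gene_id\t"
            + "\t".join(f"mean_{g}" for g in GENOTYPES)
            + "\tplanted_cam_dependent\tcam_pattern\n"
        )
        for gene_id in sorted(truth.genes):
            t = truth.genes[gene_id]
            means = "\t".join(f"{t.expression[g]:.4f}" for g in GENOTYPES)
            fh.write(
                f"{gene_id}\t{means}\t{int(t.planted_cam_dependent)}\t{t.cam_pattern}\n"
            )
    truth.bin_map.to_csv(bins_path, sep="\t", index=False)
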