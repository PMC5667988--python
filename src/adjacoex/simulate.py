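"""Synthetic chromosome-arm fixtures with planted ground truth.

The generator lays non-overlapping genes along one arm and emits the
full input bundle the pipeline consumes: annotation + cytobands, a
copy-number matrix with focal amplification segments, an expression
matrix produced by a latent-factor linear-Gaussian model, a miRNA
abundance matrix, regulator target sets, and intergenic spacer
sequences for planted divergent pairs.

Expression model, per gene g and sample s::

    expr(g,s) = mu + beta_g * (cna(g,s) - 2)
              + sum_blocks  tau_b * f_b(s) * [g in block b]
              - sum_miRNAs  gamma_m * m(s) * [g targeted by m]
              + eps,   eps ~ N(0, sigma^2)

with f_b and m standard-normal latent sample factors. A linear-Gaussian
model (rather than count noise) is used because every downstream
statistic is a Pearson correlation on continuous normalised values;
shared miRNA repression then induces the marginal positive covariance
between co-targets that the ceRNA caller looks for.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .model import (
    CytobandMap,
    GeneAnnotation,
    GeneRecord,
    GenomicInterval,
    OmicsMatrix,
    RegulatorSetCollection,
    ValidationError,
)

__all__ = [
    "ConfigError",
    "AmpSegment",
    "CoexprBlock",
    "DivergentPair",
    "MirnaLink",
    "SimConfig",
    "SyntheticTruth",
    "default_config",
    "simulate_genome",
    "simulate_cna",
    "simulate_expression",
    "simulate_bundle",
    "write_fixture_bundle",
]


class ConfigError(ValidationError):
    pass


@dataclass(frozen=True)
class AmpSegment:
    """A focal amplification segment spanning a contiguous gene range
    (indices inclusive); each sample gains ``gain`` extra copies with
    probability ``p_amp``, and all genes inside share the event."""

    first_gene: int
    last_gene: int
    p_amp: float = 0.5
    gain: float = 2.0


@dataclass(frozen=True)
class CoexprBlock:
    """Consecutive gene indices wired to one shared latent factor with
    effect size ``tau``."""

    members: tuple[int, ...]
    tau: float = 1.5


@dataclass(frozen=True)
class DivergentPair:
    """Genes ``left_gene`` and ``left_gene + 1`` placed head-to-head with
    the given intergenic spacer length."""

    left_gene: int
    spacer: int = 89
    cpg_rich: bool = True


@dataclass(frozen=True)
class MirnaLink:
    mirna_id: str
    targets: tuple[int, ...]
    gamma: float = 1.0


@dataclass
class SimConfig:
    n_genes: int = 60
    n_samples: int = 200
    n_bands: int = 8
    amp_segments: list[AmpSegment] = field(default_factory=list)
    beta_cna: dict[int, float] = field(default_factory=dict)
    coexpr_blocks: list[CoexprBlock] = field(default_factory=list)
    divergent_pairs: list[DivergentPair] = field(default_factory=list)
    mirna_links: list[MirnaLink] = field(default_factory=list)
    noise_sd: float = 1.0
    baseline_expr: float = 8.0
    chrom: str = "chr20"
    arm_length: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1 or self.n_bands < 1:
            raise ConfigError("n_genes, n_samples and n_bands must be positive")
        if self.n_bands > self.n_genes:
            raise ConfigError("more bands than genes")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for seg in self.amp_segments:
            if not 0 <= seg.first_gene <= seg.last_gene < self.n_genes:
                raise ConfigError(f"segment {seg} outside gene range")
            if not 0.0 <= seg.p_amp <= 1.0:
                raise ConfigError(f"p_amp {seg.p_amp} outside [0, 1]")
        for blk in self.coexpr_blocks:
            m = blk.members
            if not m or list(m) != list(range(m[0], m[-1] + 1)):
                raise ConfigError(f"block members {m} not consecutive indices")
            if m[0] < 0 or m[-1] >= self.n_genes:
                raise ConfigError(f"block {m} outside gene range")
        for dp in self.divergent_pairs:
            if dp.spacer < 1:
                raise ConfigError("spacer length must be >= 1")
            if not 0 <= dp.left_gene < self.n_genes - 1:
                raise ConfigError(f"divergent pair at {dp.left_gene} out of range")
        for link in self.mirna_links:
            if any(not 0 <= t < self.n_genes for t in link.targets):
                raise ConfigError(f"miRNA link {link.mirna_id} targets out of range")


# Real names of the distal 20q bands, used when the default band count fits.
_ARM_BAND_NAMES = [
    "20q11.21", "20q11.22", "20q11.23", "20q12",
    "20q13.11", "20q13.12", "20q13.13", "20q13.2",
]


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The default planted world: 60 genes on one arm, 8 bands, two focal
    amplification segments, two co-expression blocks (5 and 3 genes), one
    divergent CpG-rich pair at an 89 bp spacer which is also a ceRNA pair
    coupled through 6 shared miRNAs."""
    segments = [AmpSegment(14, 26), AmpSegment(38, 46)]
    beta = {}
    for seg in segments:
        for g in range(seg.first_gene, seg.last_gene + 1):
            beta[g] = 0.5
    # one cis-null gene inside each segment, for specificity checks
    beta[15] = 0.0
    beta[44] = 0.0
    cfg = SimConfig(
        amp_segments=segments,
        beta_cna=beta,
        coexpr_blocks=[
            CoexprBlock(members=tuple(range(17, 22))),
            CoexprBlock(members=tuple(range(40, 43))),
        ],
        divergent_pairs=[DivergentPair(left_gene=30)],
        mirna_links=[
            MirnaLink(f"mir-sim-{i + 1}", targets=(30, 31)) for i in range(6)
        ],
        seed=seed,
        **overrides,
    )
    cfg.validate()
    return cfg


@dataclass
class SyntheticTruth:
    """Registry of everything that was planted, for recovery checks."""

    gene_ids: list[str]
    annotation: GeneAnnotation
    bands: CytobandMap
    band_labels: dict[str, str]
    beta_cna: dict[str, float]
    amp_segment_genes: list[list[str]]
    blocks: list[list[str]]
    divergent_pairs: list[tuple[str, str, int, bool]]
    mirna_targets: dict[str, list[str]]
    spacer_seqs: dict[str, str]
    cna: OmicsMatrix | None = None


def _gene_id(i: int) -> str:
    return f"G{i:03d}"


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


_BASES = np.array(list("ACGT"))


def _spacer_sequence(rng: np.random.Generator, length: int, cpg_rich: bool) -> str:
    """Generate a spacer; CpG-rich spacers satisfy GC >= 0.5 and
    observed/expected CpG >= 0.6 by construction and carry no TATAWAW
    consensus (rejection-sampled, deterministic under the rng)."""
    from .promoters import _cpg_stats, tata_scan  # local import avoids a cycle

    for _ in range(100):
        if cpg_rich:
            parts: list[str] = []
            n = 0
            while n < length:
                if rng.random() < 0.45:
                    parts.append("CG")
                    n += 2
                else:
                    parts.append(str(rng.choice(_BASES)))
                    n += 1
            seq = "".join(parts)[:length]
            gc, oe = _cpg_stats(seq)
            if gc < 0.5 or oe < 0.6:
                continue
        else:
            seq = "".join(rng.choice(_BASES, p=[0.3, 0.2, 0.2, 0.3], size=length))
        if not tata_scan(seq)[0]:
            return seq
    raise RuntimeError("could not generate a qualifying spacer sequence")


def simulate_genome(config: SimConfig) -> tuple[GeneAnnotation, CytobandMap, SyntheticTruth]:
    """Lay out genes, bands and divergent pairs on one chromosome arm.

    Non-planted intergenic gaps are drawn above 1 kb so the planted
    divergent pairs are the only candidates a < 1 kb bidirectional
    screen can flag.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_genes
    lengths = rng.integers(2000, 8001, size=n)
    gaps = rng.integers(1001, 5001, size=n)  # gap before each gene
    strands = rng.choice(np.array(["+", "-"]), size=n)
    spacer_for: dict[int, DivergentPair] = {}
    for dp in config.divergent_pairs:
        spacer_for[dp.left_gene] = dp
        strands[dp.left_gene] = "-"
        strands[dp.left_gene + 1] = "+"

    starts = np.zeros(n, dtype=int)
    pos = 100_000
    for i in range(n):
        if i - 1 in spacer_for:
            pos += spacer_for[i - 1].spacer
        else:
            pos += int(gaps[i])
        starts[i] = pos
        pos += int(lengths[i])
    arm_end = pos + 10_000
    if config.arm_length is not None and arm_end > config.arm_length:
        raise ConfigError(
            f"layout needs {arm_end} bp but arm_length is {config.arm_length}"
        )

    records = [
        GeneRecord(
            gene_id=_gene_id(i),
            symbol=_gene_id(i),
            interval=GenomicInterval(
                config.chrom, int(starts[i]), int(starts[i] + lengths[i]), str(strands[i])
            ),
        )
        for i in range(n)
    ]

    # contiguous gene-index chunks -> bands partitioning [0, arm_end)
    chunk_sizes = [n // config.n_bands] * config.n_bands
    for i in range(n % config.n_bands):
        chunk_sizes[i] += 1
    if config.n_bands == len(_ARM_BAND_NAMES):
        names = list(_ARM_BAND_NAMES)
    else:
        names = [f"{config.chrom.removeprefix('chr')}q{i + 1:02d}" for i in range(config.n_bands)]
    bands = []
    first = 0
    lo = 0
    for bi, size in enumerate(chunk_sizes):
        nxt = first + size
        hi = int(starts[nxt]) if nxt < n else arm_end
        bands.append((names[bi], GenomicInterval(config.chrom, lo, hi)))
        lo = hi
        first = nxt
    band_map = CytobandMap(bands)

    annotation = io_formats.assign_cytobands(GeneAnnotation(records), band_map)
    band_labels = {r.gene_id: r.cytoband for r in annotation}

    spacers = {}
    for dp in config.divergent_pairs:
        pair_name = f"{_gene_id(dp.left_gene)}|{_gene_id(dp.left_gene + 1)}"
        spacers[pair_name] = _spacer_sequence(rng, dp.spacer, dp.cpg_rich)

    truth = SyntheticTruth(
        gene_ids=[_gene_id(i) for i in range(n)],
        annotation=annotation,
        bands=band_map,
        band_labels=band_labels,
        beta_cna={_gene_id(i): float(config.beta_cna.get(i, 0.0)) for i in range(n)},
        amp_segment_genes=[
            [_gene_id(i) for i in range(seg.first_gene, seg.last_gene + 1)]
            for seg in config.amp_segments
        ],
        blocks=[[_gene_id(i) for i in blk.members] for blk in config.coexpr_blocks],
        divergent_pairs=[
            (_gene_id(dp.left_gene), _gene_id(dp.left_gene + 1), dp.spacer, dp.cpg_rich)
            for dp in config.divergent_pairs
        ],
        mirna_targets={
            link.mirna_id: [_gene_id(t) for t in link.targets]
            for link in config.mirna_links
        },
        spacer_seqs=spacers,
    )
    return annotation, band_map, truth


def _sample_ids(config: SimConfig) -> list[str]:
    return [f"S{j:03d}" for j in range(config.n_samples)]


def simulate_cna(truth: SyntheticTruth, config: SimConfig) -> OmicsMatrix:
    """Copy-number matrix: baseline 2, focal gains shared by all genes of a
    segment within each gained sample."""
    rng = _rng(config, 1)
    samples = _sample_ids(config)
    data = np.full((config.n_genes, config.n_samples), 2.0)
    for seg in config.amp_segments:
        gained = rng.random(config.n_samples) < seg.p_amp
        rows = slice(seg.first_gene, seg.last_gene + 1)
        data[rows, gained] += seg.gain
    cna = OmicsMatrix(pd.DataFrame(data, index=truth.gene_ids, columns=samples))
    truth.cna = cna
    return cna


def simulate_expression(
    truth: SyntheticTruth, config: SimConfig
) -> tuple[OmicsMatrix, OmicsMatrix]:
    """mRNA and miRNA matrices from the latent-factor linear model."""
    if truth.cna is None:
        raise ValidationError("simulate_cna must run before simulate_expression")
    rng = _rng(config, 2)
    samples = _sample_ids(config)
    n, m = config.n_genes, config.n_samples
    cna = truth.cna.data.to_numpy()
    beta = np.array([truth.beta_cna[g] for g in truth.gene_ids])

    expr = config.baseline_expr + beta[:, None] * (cna - 2.0)
    for blk in config.coexpr_blocks:
        f = rng.standard_normal(m)
        for g in blk.members:
            expr[g] += blk.tau * f
    mirna_rows = []
    for link in config.mirna_links:
        mvec = rng.standard_normal(m)
        mirna_rows.append(mvec)
        for g in link.targets:
            expr[g] -= link.gamma * mvec
    expr += rng.standard_normal((n, m)) * config.noise_sd

    expr_m = OmicsMatrix(pd.DataFrame(expr, index=truth.gene_ids, columns=samples))
    mirna_index = [link.mirna_id for link in config.mirna_links]
    mirna_m = OmicsMatrix(
        pd.DataFrame(
            np.array(mirna_rows).reshape(len(mirna_rows), m) if mirna_rows else
            np.empty((0, m)),
            index=mirna_index,
            columns=samples,
        )
    )
    return expr_m, mirna_m


MIRNA_SOURCES = ["TarBase", "miRTarBase", "starBase"]
TF_SOURCE = "ChIP"


def simulate_bundle(config: SimConfig):
    """Run the full generator: genome, CNA, expression, regulator sets."""
    annotation, bands, truth = simulate_genome(config)
    cna = simulate_cna(truth, config)
    expr, mirna = simulate_expression(truth, config)

    reg_sets = RegulatorSetCollection()
    for bi, members in enumerate(truth.blocks):
        reg_sets.add(f"TF-block-{bi + 1}", TF_SOURCE, members)
    for mirna_id, targets in truth.mirna_targets.items():
        for src in MIRNA_SOURCES:
            reg_sets.add(mirna_id, src, targets)
    return annotation, bands, truth, cna, expr, mirna, reg_sets


def write_fixture_bundle(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the complete fixture bundle to ``out_dir``.

    Files: genes.bed, cytoBand.txt, mrna.tsv, cna.tsv, mirna.tsv,
    tf_sets.gmt, mirna_sets_<source>.gmt, spacers.fasta and truth.json.
    Identical configs produce byte-identical bundles.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation, bands, truth, cna, expr, mirna, reg_sets = simulate_bundle(config)

    paths: dict[str, Path] = {}

    def _p(name: str) -> Path:
        paths[name] = out / name
        return paths[name]

    io_formats.write_gene_annotation(annotation, _p("genes.bed"), format="bed")
    io_formats.write_cytoband_map(bands, _p("cytoBand.txt"))
    io_formats.write_matrix(expr, _p("mrna.tsv"), id_label="gene_id")
    io_formats.write_matrix(cna, _p("cna.tsv"), id_label="gene_id")
    io_formats.write_matrix(mirna, _p("mirna.tsv"), id_label="mirna_id")
    io_formats.write_regulator_sets_gmt(reg_sets, _p("tf_sets.gmt"), source=TF_SOURCE)
    for src in MIRNA_SOURCES:
        io_formats.write_regulator_sets_gmt(
            reg_sets, _p(f"mirna_sets_{src}.gmt"), source=src
        )
    if truth.spacer_seqs:
        io_formats.write_fasta(truth.spacer_seqs, _p("spacers.fasta"))

    manifest = {
        "seed": config.seed,
        "n_genes": config.n_genes,
        "n_samples": config.n_samples,
        "n_bands": config.n_bands,
        "band_labels": truth.band_labels,
        "beta_cna": truth.beta_cna,
        "amp_segment_genes": truth.amp_segment_genes,
        "blocks": truth.blocks,
        "divergent_pairs": [list(t) for t in truth.divergent_pairs],
        "mirna_targets": truth.mirna_targets,
    }
    with open(_p("truth.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
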