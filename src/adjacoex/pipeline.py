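"""Configuration-driven end-to-end orchestration.

Stages run in dependency order: io -> correlate -> neighborhood ->
promoters -> regulators -> cerna -> report. A stage failure halts the
run but leaves completed stages' outputs on disk; with ``resume=True`` a
stage whose output files already exist is reloaded instead of
recomputed. For a fixed config the output directory is byte-identical
across runs (timers go to the log, never into output files).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, correlation, io_formats, neighborhood, promoters, regulators
from .model import OmicsMatrix, RegulatorSetCollection, ValidationError

log = logging.getLogger("adjacoex")

STAGES = ["correlate", "neighborhood", "promoters", "regulators", "cerna"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All inputs and knobs of an end-to-end run.

    Threshold defaults: cis screen r > 0.65 at p < 1e-4; co-expression
    r >= 0.6; adjacency max_gap 0 / min_size 2; bidirectional spacer
    < 1000 bp; Gardiner-Garden/Frommer CpG-island parameters; ceRNA
    min_shared 5 / pair r >= 0.6 / min_support 3.
    """

    annotation: str = ""
    annotation_format: str = "bed"
    cytoband: str | None = None
    expression: str = ""
    cna: str | None = None
    mirna_expression: str | None = None
    tf_sets: str | None = None
    mirna_sets: dict[str, str] = field(default_factory=dict)  # source -> GMT path
    spacer_fasta: str | None = None
    pwm_file: str | None = None

    seed_gene: str | None = None
    r_min_cis: float = 0.65
    alpha_cis: float = 1e-4
    cis_use_bh: bool = False
    r_min_coexpr: float = 0.6
    max_gap: int = 0
    min_size: int = 2
    max_dist: int = 1000
    cpg_min_len: int = 200
    cpg_gc_min: float = 0.5
    cpg_oe_min: float = 0.6
    pwm_threshold: float = 8.0
    cerna_min_shared: int = 5
    cerna_r_pair_min: float = 0.6
    cerna_min_support: int = 3
    cerna_alpha: float = 0.05

    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Finding:
    level: str  # "error" | "warning"
    message: str


def validate_config(config: PipelineConfig) -> list[Finding]:
    """Blocking errors and non-blocking warnings; nothing is thrown."""
    findings: list[Finding] = []

    def err(msg: str) -> None:
        findings.append(Finding("error", msg))

    def warn(msg: str) -> None:
        findings.append(Finding("warning", msg))

    required = {"annotation": config.annotation, "expression": config.expression}
    for label, path in required.items():
        if not path:
            err(f"{label} path not set")
        elif not Path(path).exists():
            err(f"{label} file not found: {path}")
    optional = {
        "cytoband": config.cytoband,
        "cna": config.cna,
        "mirna_expression": config.mirna_expression,
        "tf_sets": config.tf_sets,
        "spacer_fasta": config.spacer_fasta,
        "pwm_file": config.pwm_file,
        **{f"mirna_sets[{s}]": p for s, p in config.mirna_sets.items()},
    }
    for label, path in optional.items():
        if path and not Path(path).exists():
            err(f"{label} file not found: {path}")

    for name, val in (("r_min_cis", config.r_min_cis), ("r_min_coexpr", config.r_min_coexpr),
                      ("cerna_r_pair_min", config.cerna_r_pair_min)):
        if not -1.0 <= val <= 1.0:
            err(f"{name}={val} outside [-1, 1]")
    for name, val in (("alpha_cis", config.alpha_cis), ("cerna_alpha", config.cerna_alpha),
                      ("cpg_gc_min", config.cpg_gc_min), ("cpg_oe_min", config.cpg_oe_min)):
        if not 0.0 <= val <= 1.0:
            err(f"{name}={val} outside [0, 1]")
    if config.max_gap < 0:
        err("max_gap must be >= 0")
    if config.min_size < 1:
        err("min_size must be >= 1")
    if config.max_dist < 1:
        err("max_dist must be >= 1")
    if config.cpg_min_len < 1:
        err("cpg_min_len must be >= 1")
    elif config.cpg_min_len < 200:
        warn(
            f"cpg_min_len={config.cpg_min_len} is below the standard 200 bp "
            f"island length; short islands will be reported"
        )
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        err(f"unknown stages: {sorted(unknown)}")
    if config.annotation_format.lower() not in ("bed", "gff3"):
        err(f"unknown annotation format {config.annotation_format!r}")
    return findings


@dataclass
class RunReport:
    version: str
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


class _Pipeline:
    def __init__(self, config: PipelineConfig, resume: bool = False):
        self.cfg = config
        self.resume = resume
        self.out = Path(config.out_dir)
        self.report = RunReport(version=__version__, config=config.to_dict())

    # ------------------------------------------------------------------ io

    def load_inputs(self) -> None:
        cfg = self.cfg
        self.annotation = io_formats.read_gene_annotation(
            cfg.annotation, format=cfg.annotation_format
        )
        if cfg.cytoband:
            bands = io_formats.read_cytoband_map(cfg.cytoband)
            self.annotation = io_formats.assign_cytobands(self.annotation, bands)
        self.expr = io_formats.read_matrix(cfg.expression)
        self.cna = io_formats.read_matrix(cfg.cna) if cfg.cna else None
        self.mirna_expr = (
            io_formats.read_matrix(cfg.mirna_expression)
            if cfg.mirna_expression
            else None
        )
        self.tf_sets = (
            io_formats.read_regulator_sets(cfg.tf_sets, "gmt", source="ChIP")
            if cfg.tf_sets
            else None
        )
        self.mirna_sets = RegulatorSetCollection()
        for src, path in cfg.mirna_sets.items():
            for (reg, _s), members in io_formats.read_regulator_sets(
                path, "gmt", source=src
            ):
                self.mirna_sets.add(reg, src, members)
        self.spacers = (
            io_formats.read_fasta(cfg.spacer_fasta) if cfg.spacer_fasta else {}
        )
        self.pwms = (
            promoters.read_jaspar_pwms(cfg.pwm_file) if cfg.pwm_file else []
        )
        self.report.stages["io"] = {
            "status": "ok",
            "n_genes_annotated": len(self.annotation),
            "expression_shape": list(self.expr.shape),
        }

    # ----------------------------------------------------------- correlate

    def stage_correlate(self) -> None:
        if self.cna is None:
            self.report.stages["correlate"] = {"status": "skipped", "reason": "no CNA input"}
            self.cis = None
            return
        out_res = self.out / "cis_screen.tsv"
        out_exc = self.out / "cis_exclusions.tsv"
        if self.resume and out_res.exists() and out_exc.exists():
            results = pd.read_csv(out_res, sep="\t")
            excl = pd.read_csv(out_exc, sep="\t")
            self.cis = correlation.CisScreenReport(
                results=results, exclusions=excl,
                r_min=self.cfg.r_min_cis, alpha=self.cfg.alpha_cis,
                use_bh=self.cfg.cis_use_bh,
            )
            self.report.stages["correlate"] = {"status": "resumed"}
            return
        self.cis = correlation.cna_mrna_screen(
            self.cna, self.expr,
            r_min=self.cfg.r_min_cis, alpha=self.cfg.alpha_cis,
            use_bh=self.cfg.cis_use_bh,
        )
        _write_tsv(self.cis.results, out_res)
        _write_tsv(self.cis.exclusions, out_exc)
        self.report.stages["correlate"] = {
            "status": "ok",
            "n_tested": int(len(self.cis.results)),
            "n_cis_driven": int(self.cis.results["cis_driven"].sum()),
            "n_excluded": int(len(self.cis.exclusions)),
        }

    # -------------------------------------------------------- neighborhood

    def _seed_gene(self) -> str:
        if self.cfg.seed_gene:
            return self.cfg.seed_gene
        if self.cis is not None and len(self.cis.results):
            return str(self.cis.results.iloc[0]["gene_id"])
        return self.expr.row_ids[0]

    def stage_neighborhood(self) -> None:
        seed = self._seed_gene()
        profile = neighborhood.seed_profile(self.expr, seed)
        significant = neighborhood.threshold_profile(profile, self.cfg.r_min_coexpr)
        band_table, skipped = neighborhood.band_fractions(significant, self.annotation)
        clusters = neighborhood.adjacency_clusters(
            significant | {seed},
            self.annotation,
            max_gap=self.cfg.max_gap,
            min_size=self.cfg.min_size,
            profile=profile,
        )
        self.significant = significant
        self.clusters = clusters
        _write_tsv(profile.entries, self.out / "coexpression_profile.tsv")
        _write_tsv(band_table, self.out / "band_fractions.tsv")
        cl_df = pd.DataFrame(
            [
                (i + 1, ";".join(c.members), c.band_span, c.size, c.min_r, c.max_r)
                for i, c in enumerate(clusters)
            ],
            columns=["cluster_id", "members", "band_span", "size", "min_r", "max_r"],
        )
        _write_tsv(cl_df, self.out / "clusters.tsv")
        self.report.stages["neighborhood"] = {
            "status": "ok",
            "seed_gene": seed,
            "n_significant": len(significant),
            "n_clusters": len(clusters),
            "n_unbanded_skipped": len(skipped),
        }

    # ----------------------------------------------------------- promoters

    def stage_promoters(self) -> None:
        pairs = promoters.find_bidirectional_pairs(
            self.annotation, max_dist=self.cfg.max_dist
        )
        rows = []
        for p in pairs:
            key = f"{p.gene_left}|{p.gene_right}"
            seq = self.spacers.get(key)
            cpg = tata = motif_ids = ""
            if p.bidirectional_flag and seq:
                islands = promoters.cpg_island_scan(
                    seq,
                    len_min=self.cfg.cpg_min_len,
                    gc_min=self.cfg.cpg_gc_min,
                    oe_min=self.cfg.cpg_oe_min,
                    window=min(100, len(seq)),
                )
                cpg = "yes" if islands else "no"
                tata = "yes" if promoters.tata_scan(seq)[0] else "no"
                hits = []
                for pwm in self.pwms:
                    hits += promoters.pwm_scan(seq, pwm, self.cfg.pwm_threshold)
                motif_ids = ";".join(sorted({h.motif_id for h in hits}))
            rows.append(
                (
                    p.gene_left, p.gene_right, p.orientation, p.distance_bp,
                    p.bidirectional_flag, cpg, tata, motif_ids,
                )
            )
        df = pd.DataFrame(
            rows,
            columns=[
                "gene_left", "gene_right", "orientation", "distance_bp",
                "bidirectional", "cpg_island", "tata", "motif_hits",
            ],
        )
        _write_tsv(df, self.out / "promoter_pairs.tsv")
        self.bidirectional = [p for p in pairs if p.bidirectional_flag]
        self.report.stages["promoters"] = {
            "status": "ok",
            "n_pairs": len(pairs),
            "n_bidirectional": len(self.bidirectional),
        }

    # ---------------------------------------------------------- regulators

    def stage_regulators(self) -> None:
        if self.tf_sets is None:
            self.report.stages["regulators"] = {
                "status": "skipped", "reason": "no TF sets input"
            }
            return
        universe = set(self.expr.row_ids)
        query = (
            set(self.clusters[0].members)
            if getattr(self, "clusters", None)
            else self.significant
        )
        query &= universe
        table = regulators.shared_regulator_enrichment(self.tf_sets, query, universe)
        _write_tsv(table, self.out / "regulator_enrichment.tsv")

        # per-gene TF lists of the query genes, Venn-partitioned
        gene_tf: dict[str, set[str]] = {g: set() for g in sorted(query)[:8]}
        for (reg, _src), targets in self.tf_sets:
            for g in gene_tf:
                if g in targets:
                    gene_tf[g].add(reg)
        gene_tf = {g: s for g, s in gene_tf.items() if s}
        venn_summary = {}
        if gene_tf:
            venn = regulators.venn_partition(gene_tf)
            (self.out / "tf_venn.json").write_text(
                json.dumps(
                    {sig: sorted(m) for sig, m in venn.cells.items()},
                    indent=2, sort_keys=True,
                ) + "\n"
            )
            venn_summary = {
                "n_genes": len(venn.set_names),
                "full_intersection": len(venn.full_intersection),
            }
        self.report.stages["regulators"] = {
            "status": "ok",
            "n_regulators_tested": int(len(table)),
            "tf_venn": venn_summary,
        }

    # --------------------------------------------------------------- cerna

    def stage_cerna(self) -> None:
        if self.mirna_expr is None or not len(self.mirna_sets):
            self.report.stages["cerna"] = {
                "status": "skipped", "reason": "no miRNA inputs"
            }
            return
        pairs = [
            (p.gene_left, p.gene_right)
            for p in getattr(self, "bidirectional", [])
            if p.gene_left in self.expr and p.gene_right in self.expr
        ]
        cands = regulators.cerna_candidates(
            pairs,
            self.mirna_sets,
            self.expr,
            self.mirna_expr,
            min_shared=self.cfg.cerna_min_shared,
            r_pair_min=self.cfg.cerna_r_pair_min,
            min_support=self.cfg.cerna_min_support,
            alpha=self.cfg.cerna_alpha,
        )
        df = pd.DataFrame(
            [
                (
                    c.gene_a, c.gene_b, c.union_count, round(c.pair_r, 6),
                    c.anticorr_support, c.verdict,
                    ";".join(sorted(c.shared_union)),
                )
                for c in cands
            ],
            columns=[
                "gene_a", "gene_b", "shared_mirnas", "pair_r",
                "anticorr_support", "verdict", "mirna_union",
            ],
        )
        _write_tsv(df, self.out / "cerna_candidates.tsv")
        self.report.stages["cerna"] = {
            "status": "ok",
            "n_pairs_tested": len(cands),
            "n_candidates": int(sum(c.verdict for c in cands)),
        }

    # ----------------------------------------------------------------- run

    def run(self) -> RunReport:
        self.out.mkdir(parents=True, exist_ok=True)
        stage_fns = {
            "correlate": self.stage_correlate,
            "neighborhood": self.stage_neighborhood,
            "promoters": self.stage_promoters,
            "regulators": self.stage_regulators,
            "cerna": self.stage_cerna,
        }
        ordered = [s for s in STAGES if s in self.cfg.stages]
        try:
            t0 = time.perf_counter()
            self.load_inputs()
            log.info("stage io: ok (%.2fs)", time.perf_counter() - t0)
            for stage in ordered:
                t0 = time.perf_counter()
                stage_fns[stage]()
                log.info("stage %s: %s (%.2fs)", stage,
                         self.report.stages[stage]["status"],
                         time.perf_counter() - t0)
        except StageError:
            raise
        except Exception as exc:
            stage = next(
                (s for s in ["io"] + ordered if s not in self.report.stages), "io"
            )
            self.report.stages[stage] = {"status": "failed", "error": str(exc)}
            (self.out / "report.json").write_text(self.report.to_json())
            raise StageError(stage, exc) from exc
        (self.out / "report.json").write_text(self.report.to_json())
        return self.report


def run_pipeline(config: PipelineConfig, resume: bool = False) -> RunReport:
    """Validate, then execute the configured stages in dependency order."""
    findings = validate_config(config)
    errors = [f for f in findings if f.level == "error"]
    if errors:
        raise ValidationError("; ".join(f.message for f in errors))
    for f in findings:
        log.warning(f.message)
    return _Pipeline(config, resume=resume).run()
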