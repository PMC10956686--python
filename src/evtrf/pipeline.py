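"""Stage orchestration: config validation, stage runners, run report.

A run is driven by a YAML config naming either a synthetic cohort to
generate or real inputs (reference FASTAs, FASTQ directory, sample sheet).
Stages execute in order simulate -> preprocess -> annotate -> diffexp ->
variants -> targets (-> qpcr), each leaving a plain-text TSV in the output
directory plus a JSON manifest recording the seed and a parameter hash;
identical config + seed reproduces byte-identical stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import assign_classes, class_read_fractions, coverage_profile, write_annotation_tsv
from .diffstats import cumulative_share, differential_expression, rpm_normalize
from .preprocess import FragmentTable, collapse, length_histogram, preprocess_fastq
from .qpcr import pfaffl_relative_expression, select_targets
from .refdb import RNA_CLASSES, ReferenceSet, five_prime_prefixes, read_fasta, write_fasta
from .simulate import (
    SimulationConfig,
    simulate_background_rpm,
    simulate_cohort,
    simulate_references,
    simulate_validation_plate,
)
from .variants import annotate_variants

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


class ConfigError(ValueError):
    """Raised when a run config fails validation; message lists all violations."""


@dataclass
class RunConfig:
    """Fully-defaulted parameters of one pipeline run."""

    seed: int = 0
    outdir: str = "evtrf_out"
    # synthetic cohort (used when no external reads are given)
    simulate: dict = field(default_factory=dict)
    # external inputs (all three required together)
    references: dict = field(default_factory=dict)  # class -> FASTA path
    fastq_dir: str | None = None
    sample_sheet: str | None = None
    # stage parameters
    adapter: str | None = None  # None: use the simulated adapter
    min_mean_q: float = 20.0
    max_n: int = 0
    min_len: int = 15
    max_len: int = 50
    max_mm: int = 2
    end_tol: int = 3
    priority: list = field(default_factory=lambda: list(RNA_CLASSES))
    coverage_mode: str = "max"
    de_threshold: float = 100.0
    alpha: float = 0.05
    eps: float = 1.0
    filter_scope: str = "all"  # "all" or "case"
    prefix_min: int = 28
    prefix_max: int = 36
    variant_max_d: int = 2
    variant_substitutions: bool = True
    target_percentile: float = 90.0
    bg_threshold: float = 100.0
    qpcr: dict = field(default_factory=dict)
    top_k: int = 12


_SIM_KEYS = {
    "profile", "compartment", "n_case", "n_control", "n_refs", "n_fragments",
    "n_de", "de_fold", "de_min_rpm", "variant_fraction",
    "substitution_error_rate", "library_size", "dispersion", "adapter",
    "read_length", "lognormal_sigma",
}
_QPCR_KEYS = {"enabled", "fold", "n_case", "n_control", "efficiency",
              "noise_sd", "loading_sd"}


def validate_config(source: str | Path | Mapping[str, Any]) -> RunConfig:
    """Parse and validate a YAML config (or dict), filling defaults.

    Unknown keys, out-of-range parameters and missing input paths are all
    collected and reported in a single error.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")

    known = {f.name for f in dataclasses.fields(RunConfig)}
    problems: list[str] = []
    for key in raw:
        if key not in known:
            problems.append(f"unknown key {key!r}")
    for key in raw.get("simulate", {}) or {}:
        if key not in _SIM_KEYS:
            problems.append(f"unknown key simulate.{key!r}")
    for key in raw.get("qpcr", {}) or {}:
        if key not in _QPCR_KEYS:
            problems.append(f"unknown key qpcr.{key!r}")

    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})

    for name in ("de_threshold", "bg_threshold", "min_mean_q", "alpha", "eps"):
        if getattr(cfg, name) < 0:
            problems.append(f"{name} must be non-negative")
    if not 0 < cfg.alpha < 1 and cfg.alpha != 0:
        problems.append("alpha must lie in (0, 1)")
    if cfg.min_len > cfg.max_len:
        problems.append("min_len must not exceed max_len")
    if cfg.max_mm < 0:
        problems.append("max_mm must be non-negative")
    if cfg.coverage_mode not in ("max", "reads"):
        problems.append(f"unknown coverage_mode {cfg.coverage_mode!r}")
    if cfg.filter_scope not in ("all", "case"):
        problems.append(f"unknown filter_scope {cfg.filter_scope!r}")
    if sorted(cfg.priority) != sorted(RNA_CLASSES):
        problems.append("priority must be a permutation of the five RNA classes")
    external = bool(cfg.references or cfg.fastq_dir or cfg.sample_sheet)
    if external:
        for label, p in [("fastq_dir", cfg.fastq_dir), ("sample_sheet", cfg.sample_sheet)]:
            if p is None:
                problems.append(f"{label} required when external inputs are used")
            elif not Path(p).exists():
                problems.append(f"{label} path {p!r} does not exist")
        for cls, p in (cfg.references or {}).items():
            if cls not in RNA_CLASSES:
                problems.append(f"unknown reference class {cls!r}")
            elif not Path(p).exists():
                problems.append(f"reference FASTA {p!r} does not exist")
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    return cfg


def _param_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class PipelineRun:
    """Holds the in-memory state threaded through the stages of one run."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.refs: dict[str, ReferenceSet] = {}
        self.truth: pd.DataFrame | None = None
        self.sheet: pd.DataFrame | None = None
        self.fastq: dict[str, Path] = {}
        self.adapter: str = cfg.adapter or ""
        self.table: FragmentTable | None = None
        self.assignment: pd.DataFrame | None = None
        self.rpm: pd.DataFrame | None = None
        self.de: pd.DataFrame | None = None
        self.variants: pd.DataFrame | None = None
        self.targets: pd.DataFrame | None = None
        self.background: pd.DataFrame | None = None
        self.relative_expression: pd.DataFrame | None = None

    # -- stages ------------------------------------------------------------

    def stage_simulate(self) -> None:
        sim_raw = dict(self.cfg.simulate)
        sim_raw.setdefault("seed", self.cfg.seed)
        sim = SimulationConfig(**sim_raw)
        self.refs = simulate_references(sim)
        refdir = self.outdir / "references"
        refdir.mkdir(exist_ok=True)
        for cls, refset in self.refs.items():
            write_fasta(refset, refdir / f"{cls}.fasta")
        self.fastq, self.truth, self.sheet = simulate_cohort(
            sim, self.refs, self.outdir / "reads"
        )
        self.adapter = self.cfg.adapter if self.cfg.adapter is not None else sim.adapter
        self.background = simulate_background_rpm(self.truth, seed=self.cfg.seed)
        self.truth.to_csv(self.outdir / "truth.tsv", sep="\t", float_format=_FLOAT_FMT)
        self.sheet.to_csv(self.outdir / "samples.tsv", sep="\t", index=False)
        self.background.to_csv(
            self.outdir / "background_rpm.tsv", sep="\t", float_format=_FLOAT_FMT
        )

    def stage_load_inputs(self) -> None:
        cfg = self.cfg
        self.sheet = pd.read_csv(cfg.sample_sheet, sep="\t")
        for cls in RNA_CLASSES:
            path = (cfg.references or {}).get(cls)
            if path is None:
                raise FileNotFoundError(
                    f"reference FASTA for class {cls!r} missing from config"
                )
            self.refs[cls] = read_fasta(path, cls)
        for sample in self.sheet["sample_id"]:
            p = Path(cfg.fastq_dir) / f"{sample}.fastq"
            if not p.exists():
                raise FileNotFoundError(f"FASTQ for sample {sample!r} not found: {p}")
            self.fastq[sample] = p
        bg = self.outdir / "background_rpm.tsv"
        self.background = (
            pd.read_csv(bg, sep="\t", index_col=0) if bg.exists() else None
        )

    def stage_preprocess(self) -> None:
        cfg = self.cfg
        reads = {
            sample: preprocess_fastq(
                path,
                adapter=self.adapter,
                min_mean_q=cfg.min_mean_q,
                max_n=cfg.max_n,
                min_len=cfg.min_len,
                max_len=cfg.max_len,
            )
            for sample, path in self.fastq.items()
        }
        self.table = collapse(reads)
        self.table.to_tsv(self.outdir / "fragments.tsv")
        hists = {
            s: length_histogram(self.table, s) for s in self.table.samples
        }
        pd.DataFrame(hists).fillna(0).astype(int).rename_axis("length").to_csv(
            self.outdir / "length_histograms.tsv", sep="\t"
        )

    def stage_annotate(self) -> None:
        cfg = self.cfg
        self.assignment = assign_classes(
            list(self.table.fragments),
            self.refs,
            priority=cfg.priority,
            max_mm=cfg.max_mm,
            end_tol=cfg.end_tol,
        )
        write_annotation_tsv(self.assignment, self.outdir / "annotation.tsv")
        ref_lengths = {
            rec.ref_id: len(rec.sequence)
            for refset in self.refs.values()
            for rec in refset
        }
        profiles = {
            s: coverage_profile(
                self.assignment, self.table.counts[s], ref_lengths, cfg.coverage_mode
            )
            for s in self.table.samples
        }
        cov = pd.DataFrame(profiles)
        cov.index.name = "bin"
        cov["aggregate"] = coverage_profile(
            self.assignment, self.table.counts.sum(axis=1), ref_lengths,
            cfg.coverage_mode,
        )
        cov.to_csv(self.outdir / "coverage.tsv", sep="\t", float_format=_FLOAT_FMT)

    def stage_diffexp(self) -> None:
        cfg = self.cfg
        classes = self.assignment["rna_class"]
        self.rpm = rpm_normalize(self.table, classes)
        groups = self.sheet.set_index("sample_id")["group"]
        if cfg.filter_scope == "case":
            filter_samples = groups.index[groups == "case"].tolist()
        else:
            filter_samples = groups.index.tolist()
        self.de = differential_expression(
            self.rpm,
            groups,
            classes=classes,
            filter_samples=filter_samples,
            threshold=cfg.de_threshold,
            alpha=cfg.alpha,
            eps=cfg.eps,
        )
        self.rpm.rename_axis("fragment").to_csv(
            self.outdir / "rpm.tsv", sep="\t", float_format=_FLOAT_FMT
        )
        self.de.to_csv(self.outdir / "de.tsv", sep="\t", float_format=_FLOAT_FMT)
        case_samples = groups.index[groups == "case"].tolist()
        n_sig = int(self.de["significant"].sum())
        k = min(self.cfg.top_k, n_sig)
        summary = {
            "n_fragments": int(len(self.table.fragments)),
            "n_filtered": int(len(self.de)),
            "n_significant": n_sig,
            "top_k": k,
            "top_k_share": (
                cumulative_share(self.de, self.rpm, case_samples, k) if k else None
            ),
        }
        with open(self.outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def stage_variants(self) -> None:
        cfg = self.cfg
        index = five_prime_prefixes(
            self.refs["tRNA"], range(cfg.prefix_min, cfg.prefix_max + 1)
        )
        index.to_tsv(self.outdir / "prefix_index.tsv")
        unmapped_sig = self.de.index[
            (self.de["rna_class"] == "unmapped") & self.de["significant"]
        ]
        self.variants = annotate_variants(
            unmapped_sig, index, cfg.variant_max_d, cfg.variant_substitutions
        )
        self.variants.to_csv(self.outdir / "variants.tsv", sep="\t")

    def stage_targets(self) -> None:
        cfg = self.cfg
        bg = (
            self.background
            if self.background is not None
            else pd.DataFrame(index=self.de.index)
        )
        if len(self.de):
            self.targets = select_targets(
                self.de, bg, cfg.target_percentile, cfg.bg_threshold
            )
        else:
            self.targets = self.de.copy()
        self.targets.to_csv(
            self.outdir / "targets.tsv", sep="\t", float_format=_FLOAT_FMT
        )

    def stage_qpcr(self) -> None:
        q = dict(self.cfg.qpcr)
        if not q.pop("enabled", False):
            return
        records = simulate_validation_plate(seed=self.cfg.seed, **q)
        records.to_csv(
            self.outdir / "qpcr_records.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )
        self.relative_expression = pfaffl_relative_expression(
            records, "target", "reference"
        )
        self.relative_expression.to_csv(
            self.outdir / "relative_expression.tsv", sep="\t",
            float_format=_FLOAT_FMT,
        )

    def write_manifest(self) -> None:
        manifest = {
            "package": "evtrf",
            "version": __version__,
            "seed": self.cfg.seed,
            "parameter_hash": _param_hash(self.cfg),
            "outputs": sorted(
                p.name for p in self.outdir.iterdir() if p.is_file()
            ),
        }
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(cfg: RunConfig) -> PipelineRun:
    """Execute all stages in order; returns the populated run state."""
    run = PipelineRun(cfg)
    stages = [
        ("simulate" if not cfg.fastq_dir else "load_inputs",
         run.stage_simulate if not cfg.fastq_dir else run.stage_load_inputs),
        ("preprocess", run.stage_preprocess),
        ("annotate", run.stage_annotate),
        ("diffexp", run.stage_diffexp),
        ("variants", run.stage_variants),
        ("targets", run.stage_targets),
        ("qpcr", run.stage_qpcr),
    ]
    for name, fn in stages:
        logger.info("stage %s", name)
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    run.write_manifest()
    write_report(run)
    return run


def write_report(run: PipelineRun) -> Path:
    """Render a human-readable run report (markdown) from the stage outputs."""
    lines = ["# evtrf run report", ""]
    cfg = run.cfg
    lines.append(f"- seed: {cfg.seed}")
    lines.append(f"- parameter hash: {_param_hash(cfg)}")
    lines.append("")

    if run.table is not None:
        lines.append("## Library summaries")
        lines.append("")
        lines.append("| sample | retained reads | modal length |")
        lines.append("|---|---|---|")
        for s in run.table.samples:
            hist = length_histogram(run.table, s)
            mode = int(hist.idxmax()) if hist.sum() else "-"
            lines.append(f"| {s} | {int(hist.sum())} | {mode} |")
        lines.append("")
    else:
        lines.append("_preprocessing output missing_")

    if run.assignment is not None and run.table is not None:
        lines.append("## Class mapping (read-weighted)")
        lines.append("")
        frac = class_read_fractions(
            run.assignment, run.table.counts.sum(axis=1)
        )
        for cls, f in frac.sort_values(ascending=False).items():
            lines.append(f"- {cls}: {100 * f:.1f}%")
        trna = run.assignment[run.assignment["rna_class"] == "tRNA"]
        if len(trna):
            five = (trna["trf_type"] == "five_prime").mean()
            lines.append(f"- tRNA fragments typed 5': {100 * five:.1f}%")
        lines.append("")
    else:
        lines.append("_annotation output missing_")

    if run.de is not None:
        lines.append("## Differential expression")
        lines.append("")
        n_sig = int(run.de["significant"].sum())
        lines.append(f"- fragments tested (abundance-filtered): {len(run.de)}")
        lines.append(f"- significant (q < {cfg.alpha}): {n_sig}")
        if n_sig == 0:
            lines.append("- no significant fragments")
        else:
            groups = run.sheet.set_index("sample_id")["group"]
            case_samples = groups.index[groups == "case"].tolist()
            k = min(cfg.top_k, n_sig)
            share = cumulative_share(run.de, run.rpm, case_samples, k)
            lines.append(
                f"- top-{k} share of DE case counts: {100 * share:.1f}%"
            )
        lines.append("")
    else:
        lines.append("_differential-expression output missing_")

    if run.variants is not None:
        lines.append("## Variant re-annotation of unmapped DE fragments")
        lines.append("")
        counts = run.variants["status"].value_counts().to_dict() if len(run.variants) else {}
        lines.append(
            f"- resolved as 5'-tRF variants: {counts.get('variant', 0)}; "
            f"exact: {counts.get('exact', 0)}; unresolved: {counts.get('unresolved', 0)}"
        )
        lines.append("")

    if run.targets is not None and len(run.targets):
        n_sel = int(run.targets["selected"].sum())
        lines.append(f"## qPCR target selection: {n_sel} candidate(s)")
        lines.append("")
    if run.relative_expression is not None:
        med = run.relative_expression.groupby("group")["relative_expression"].median()
        lines.append("## Pfaffl relative expression (median per group)")
        lines.append("")
        for g, v in med.items():
            lines.append(f"- {g}: {v:.2f}")
        lines.append("")

    path = run.outdir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
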