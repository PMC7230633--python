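"""End-to-end drivers: simulate -> demux -> align -> call -> report.

The in-memory helpers (:func:`simulate_sample`, :func:`genotype_sample`)
are the programmatic interface; the disk-writing ``run_*`` functions back
the command-line tool and write a provenance record (config + seed +
version) with every run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .align import assign_batch
from .calling import GenotypeCall, LocusCountTable, call_single_source, count_table, score_against_truth
from .demux import DemuxResult, categorize_batch
from .diagnostics import feature_report
from .panel import (
    AlleleRecord, LocusDefinition, build_reference_db, fixture_genotype_alleles,
    fixture_panel, load_panel, write_fasta,
)
from .report import RunSummary, build_summary, render
from .simulate import (
    ErrorModel, Genotype, MixtureSpec, SimRead, StutterModel,
    build_amplicon_pool, get_preset, sequence_reads, write_fastq,
)

__all__ = [
    "PipelineConfig", "GenotypeOutcome", "truth_alleles_for",
    "simulate_sample", "genotype_sample",
    "run_simulate", "run_genotype", "run_diagnose", "run_all",
]


@dataclass
class PipelineConfig:
    """Knobs of the analysis, with the pipeline's standard defaults:
    fuzzy primer matching with at most 2 mismatches per primer, the >50%
    second-allele calling rule, and a 0.4 complication fraction."""

    panel_path: str | None = None      # None = built-in fixture panel
    mode: str = "fuzzy"                # "exact" | "fuzzy"
    max_mismatch: int = 2
    allow_indels: bool = True
    min_score_frac: float = 0.4
    threshold: float = 0.5
    complication_frac: float = 0.4
    preset: str = "long-noisy"
    rho_minus: float = 0.10
    rho_plus: float = 0.02
    depth_per_locus: int = 500
    rc_fraction: float = 0.5
    seed: int = 0
    outdir: str = "strnano-out"

    def load_panel(self) -> list[LocusDefinition]:
        return fixture_panel() if self.panel_path is None else load_panel(self.panel_path)


@dataclass(frozen=True)
class GenotypeOutcome:
    """Everything one sample's analysis produced, stage by stage."""

    demux: DemuxResult
    breakdown: pd.DataFrame
    tables: dict[str, LocusCountTable]
    calls: dict[str, GenotypeCall]
    scores: pd.DataFrame | None
    summary: RunSummary


def truth_alleles_for(mixture: MixtureSpec) -> dict[str, set]:
    """Per-locus union of true alleles over the mixture's contributors."""
    truth: dict[str, set] = {}
    for geno, _ in mixture.contributors:
        for locus, labels in geno.alleles.items():
            truth.setdefault(locus, set()).update(labels)
    return truth


def simulate_sample(
    panel: Sequence[LocusDefinition],
    mixture: MixtureSpec,
    error: ErrorModel,
    stutter: StutterModel | None = None,
    depth_per_locus: int = 500,
    seed: int = 0,
    rc_fraction: float = 0.5,
    representation_bias: Mapping[str, float] | None = None,
    db: Sequence[AlleleRecord] | None = None,
) -> tuple[list[SimRead], pd.DataFrame]:
    """Simulate one sample's FASTQ-ready reads plus the truth table."""
    db = list(db) if db is not None else build_reference_db(list(panel))
    rng = np.random.default_rng(seed)
    pool = build_amplicon_pool(
        mixture, db, stutter=stutter, depth_per_locus=depth_per_locus,
        representation_bias=dict(representation_bias) if representation_bias else None,
        seed=rng,
    )
    return sequence_reads(pool, error, seed=rng, rc_fraction=rc_fraction)


def genotype_sample(
    reads,
    panel: Sequence[LocusDefinition],
    db: Sequence[AlleleRecord] | None = None,
    config: PipelineConfig | None = None,
    truth: Mapping[str, Sequence[str]] | None = None,
    mixture: bool = False,
) -> GenotypeOutcome:
    """Run demux, alignment, counting, calling and reporting on reads.

    ``reads`` is a FASTQ path or an iterable of (id, sequence).  With a
    truth profile the alignment breakdown gains true/non-true states and
    genotype statuses are scored.
    """
    cfg = config or PipelineConfig()
    panel = list(panel)
    db = list(db) if db is not None else build_reference_db(panel)
    demux = categorize_batch(
        reads, panel, max_mismatch=cfg.max_mismatch, mode=cfg.mode,
        allow_indels=cfg.allow_indels,
    )
    truth_sets = {k: set(v) for k, v in truth.items()} if truth is not None else None
    assignments, breakdown = assign_batch(
        demux.per_locus, db, min_score_frac=cfg.min_score_frac,
        truth_alleles=truth_sets,
    )
    tables = {loc.name: count_table(assignments, loc.name) for loc in panel}
    calls = {name: call_single_source(t, cfg.threshold) for name, t in tables.items()}
    scores = None
    if truth_sets is not None:
        scores = score_against_truth(
            calls, truth_sets, tables, mixture=mixture,
            complication_frac=cfg.complication_frac,
        )
    genotypes = scores if scores is not None else pd.DataFrame(
        [{"locus": n, "called": ",".join(c.alleles), "truth": "", "status": ""}
         for n, c in calls.items()]
    )
    summary = build_summary(demux, breakdown, tables, genotypes)
    return GenotypeOutcome(demux, breakdown, tables, calls, scores, summary)


# --- disk-level drivers ------------------------------------------------------

def _provenance(cfg: PipelineConfig, outdir: Path) -> None:
    rec = {"config": asdict(cfg), "version": __version__}
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(rec, fh, indent=1)


def _fixture_samples(seed: int):
    """The study design: two single contributors and their 50:50 mixture."""
    genos = fixture_genotype_alleles()
    ga = Genotype("A", genos["A"])
    gb = Genotype("B", genos["B"])
    return {
        "sampleA": MixtureSpec.single(ga),
        "sampleB": MixtureSpec.single(gb),
        "sampleC": MixtureSpec.balanced(ga, gb),
    }


def run_simulate(cfg: PipelineConfig) -> dict[str, Path]:
    """Simulate the three fixture samples to FASTQ + truth TSVs."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = cfg.load_panel()
    db = build_reference_db(panel)
    write_fasta(db, outdir / "reference_alleles.fasta")
    error = get_preset(cfg.preset)
    stutter = StutterModel(cfg.rho_minus, cfg.rho_plus)
    paths: dict[str, Path] = {}
    for i, (name, mix) in enumerate(_fixture_samples(cfg.seed).items()):
        reads, truth = simulate_sample(
            panel, mix, error, stutter, cfg.depth_per_locus,
            seed=cfg.seed + i, rc_fraction=cfg.rc_fraction, db=db,
        )
        fq = outdir / f"{name}.fastq"
        write_fastq(reads, fq)
        truth.to_csv(outdir / f"{name}.truth.tsv", sep="\t", index=False)
        paths[name] = fq
    _provenance(cfg, outdir)
    return paths


def run_genotype(cfg: PipelineConfig, fastq: str, truth_profile: Mapping[str, Sequence[str]] | None = None,
                 mixture: bool = False, sample: str = "sample") -> GenotypeOutcome:
    """Genotype one FASTQ file; writes all stage TSVs under outdir/sample."""
    outdir = Path(cfg.outdir) / sample
    outdir.mkdir(parents=True, exist_ok=True)
    panel = cfg.load_panel()
    outcome = genotype_sample(fastq, panel, config=cfg, truth=truth_profile, mixture=mixture)
    render(outcome.summary, outdir)
    _provenance(cfg, outdir)
    return outcome


def run_diagnose(cfg: PipelineConfig) -> pd.DataFrame:
    """Write the locus-suitability feature report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = cfg.load_panel()
    report = feature_report(panel)
    report.to_csv(outdir / "locus_features.tsv", sep="\t", index=False)
    _provenance(cfg, outdir)
    return report


def run_all(cfg: PipelineConfig) -> dict[str, GenotypeOutcome]:
    """Simulate the three fixture samples, genotype each, and diagnose."""
    genos = fixture_genotype_alleles()
    samples = _fixture_samples(cfg.seed)
    loci = {loc.name for loc in cfg.load_panel()}
    truths = {
        "sampleA": {k: set(v) for k, v in genos["A"].items() if k in loci},
        "sampleB": {k: set(v) for k, v in genos["B"].items() if k in loci},
        "sampleC": {k: v for k, v in truth_alleles_for(samples["sampleC"]).items() if k in loci},
    }
    fastqs = run_simulate(cfg)
    outcomes = {}
    for name, fq in fastqs.items():
        outcomes[name] = run_genotype(
            cfg, str(fq), truth_profile=truths[name],
            mixture=(name == "sampleC"), sample=name,
        )
    run_diagnose(cfg)
    return outcomes
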