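"""Aggregation of pipeline stage outputs into run-level result tables.

The summary is a pure function of the stage outputs — locus
representation (demux), four-way alignment breakdown, per-allele
histograms of uniquely aligned reads, and genotype statuses — and
re-rendering it never changes a number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .calling import GenotypeCall, LocusCountTable
from .demux import DemuxResult

__all__ = ["RunSummary", "build_summary", "average_representation", "render", "plot_representation"]


@dataclass(frozen=True)
class RunSummary:
    totals: dict
    representation: pd.DataFrame   # locus, count, fraction
    breakdown: pd.DataFrame        # locus, n, state counts + fractions
    histograms: pd.DataFrame       # locus, allele, count, fraction
    genotypes: pd.DataFrame        # locus, called, truth, status, ...


def build_summary(
    demux: DemuxResult,
    breakdown: pd.DataFrame,
    tables: Mapping[str, LocusCountTable],
    genotypes: pd.DataFrame,
) -> RunSummary:
    """Assemble one sample's stage outputs; validates locus consistency."""
    loci = set(demux.summary["locus"])
    for other, what in ((set(breakdown["locus"]), "alignment breakdown"),
                        (set(tables), "count tables")):
        if not other <= loci:
            raise ValueError(f"{what} has loci absent from demux: {sorted(other - loci)}")
    hist = pd.concat(
        [t.to_frame() for t in tables.values()], ignore_index=True
    ) if tables else pd.DataFrame(columns=["locus", "allele", "count", "fraction"])
    totals = {
        "reads": demux.total,
        "categorized": demux.categorized,
        "categorized_fraction": demux.categorized / demux.total if demux.total else 0.0,
        "malformed": demux.malformed,
    }
    return RunSummary(
        totals=totals,
        representation=demux.summary.copy(),
        breakdown=breakdown.copy(),
        histograms=hist,
        genotypes=genotypes.copy(),
    )


def average_representation(representations: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean per-locus representation fraction over samples."""
    cat = pd.concat(representations, ignore_index=True)
    out = cat.groupby("locus", as_index=False)["fraction"].mean()
    return out.sort_values("fraction", ascending=False).reset_index(drop=True)


def render(summary: RunSummary, outdir) -> dict[str, Path]:
    """Write the summary as stable-column-order TSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    sections = {
        "representation": summary.representation,
        "breakdown": summary.breakdown,
        "allele_histograms": summary.histograms,
        "genotypes": summary.genotypes,
    }
    for name, df in sections.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    totals = pd.DataFrame([summary.totals])
    p = outdir / "totals.tsv"
    totals.to_csv(p, sep="\t", index=False)
    paths["totals"] = p
    return paths


def plot_representation(summary: RunSummary, path) -> None:
    """Optional cosmetic bar chart of locus representation."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = summary.representation.sort_values("fraction", ascending=False)
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.bar(df["locus"], df["fraction"], color="#c23b22")
    ax.set_ylabel("fraction of categorized reads")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
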