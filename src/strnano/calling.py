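"""Allele-count tables and genotype calling.

Counting uses uniquely assigned reads only.  The single-contributor
calling rule: the allele with the most reads is always called, and the
second-ranked allele joins it only when its count strictly exceeds
``threshold`` (default 50%) of the maximum — a strict reading of
"exceeds".  For mixtures the contribution ratio is unknown, so no such
rule applies; instead alleles are ranked by fraction and a profile is
correct when the top-m alleles equal the m-allele union of the
contributors' genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .align import AssignmentResult
from .panel import label_key

__all__ = [
    "LocusCountTable",
    "GenotypeCall",
    "RankedAllele",
    "count_table",
    "call_single_source",
    "rank_mixture",
    "score_against_truth",
]


@dataclass(frozen=True)
class LocusCountTable:
    """Unique-read counts and fractions per allele for one locus."""

    locus: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        return {a: c / t for a, c in self.counts.items()} if t else {}

    def to_frame(self) -> pd.DataFrame:
        fr = self.fractions
        rows = sorted(self.counts, key=lambda a: (-self.counts[a], label_key(a)))
        return pd.DataFrame(
            {"locus": self.locus, "allele": rows,
             "count": [self.counts[a] for a in rows],
             "fraction": [fr[a] for a in rows]}
        )


@dataclass(frozen=True)
class GenotypeCall:
    locus: str
    alleles: tuple[str, ...]          # () = no-call; size 1 or 2 otherwise
    supporting: dict[str, float] = field(default_factory=dict)

    @property
    def is_no_call(self) -> bool:
        return not self.alleles


class RankedAllele(NamedTuple):
    label: str
    count: int
    fraction: float
    tied: bool


def count_table(assignments: Iterable[AssignmentResult], locus: str) -> LocusCountTable:
    """Tally uniquely assigned reads of one locus into a count table."""
    counts: dict[str, int] = {}
    for res in assignments:
        if res.locus == locus and res.status == "unique":
            counts[res.allele] = counts.get(res.allele, 0) + 1
    return LocusCountTable(locus, counts)


def call_single_source(table: LocusCountTable, threshold: float = 0.5) -> GenotypeCall:
    """Call 1 or 2 alleles from a single-contributor count table.

    The top allele is always called; the runner-up only if its count
    strictly exceeds ``threshold * max_count``.  A count tie at the top
    calls both tied alleles (each exceeds the threshold relative to the
    other); a runner-up exactly at the boundary is excluded.  Empty table
    -> no-call.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if table.total == 0:
        return GenotypeCall(table.locus, ())
    ranked = sorted(table.counts, key=lambda a: (-table.counts[a], label_key(a)))
    top = ranked[0]
    called = [top]
    if len(ranked) > 1:
        second = ranked[1]
        if table.counts[second] > threshold * table.counts[top]:
            called.append(second)
    fr = table.fractions
    called = sorted(called, key=label_key)
    return GenotypeCall(table.locus, tuple(called), {a: fr[a] for a in called})


def rank_mixture(table: LocusCountTable) -> list[RankedAllele]:
    """Alleles in descending count order; count ties broken by numeric
    label and flagged."""
    fr = table.fractions
    ordered = sorted(table.counts, key=lambda a: (-table.counts[a], label_key(a)))
    out = []
    for a in ordered:
        tied = sum(1 for b in table.counts if table.counts[b] == table.counts[a]) > 1
        out.append(RankedAllele(a, table.counts[a], fr[a], tied))
    return out


def _complicated(table: LocusCountTable, truth: set, complication_frac: float) -> bool:
    if not table.counts:
        return False
    cmax = max(table.counts.values())
    return any(
        a not in truth and c > complication_frac * cmax
        for a, c in table.counts.items()
    )


def score_against_truth(
    calls: Mapping[str, GenotypeCall],
    truth: Mapping[str, Iterable[str]],
    tables: Mapping[str, LocusCountTable],
    mixture: bool = False,
    complication_frac: float = 0.4,
) -> pd.DataFrame:
    """Per-locus genotype status against a truth profile.

    Single source: correct iff called set == truth set.  Mixture: correct
    iff the top-m ranked alleles equal the m-allele truth union.  A
    correct locus becomes ``correct-complicated`` when some allele outside
    the truth set still collects more than ``complication_frac`` of the
    maximum count.  Missing true alleles are drop-outs, called non-true
    alleles drop-ins.
    """
    loci = set(calls) if not mixture else set(tables)
    if set(truth) < loci:
        raise ValueError(f"truth is missing loci: {sorted(loci - set(truth))}")
    rows = []
    for locus in loci:
        truth_set = set(truth[locus])
        table = tables[locus]
        if mixture:
            ranked = rank_mixture(table)
            called = {r.label for r in ranked[: len(truth_set)]}
        else:
            called = set(calls[locus].alleles)
        if not called:
            status = "no-call"
        elif called == truth_set:
            status = ("correct-complicated"
                      if _complicated(table, truth_set, complication_frac) else "correct")
        else:
            status = "incorrect"
        rows.append({
            "locus": locus,
            "called": ",".join(sorted(called, key=label_key)),
            "truth": ",".join(sorted(truth_set, key=label_key)),
            "status": status,
            "dropouts": len(truth_set - called),
            "dropins": len(called - truth_set),
        })
    return pd.DataFrame(rows).sort_values("locus").reset_index(drop=True)
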