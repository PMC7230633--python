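"""Best-allele assignment of locus-categorized reads.

Each read is scored by full global alignment (unit-cost edit distance,
negated so higher is better) against every reference allele of its locus —
allele databases are tiny, so exhaustive scoring is exact and
reproducible.  A read is:

* ``unique``     — a single allele achieves the best score;
* ``ambiguous``  — two or more alleles tie at the best score; discarded
  downstream, the analogue of a multi-mapping (XA-tagged) read;
* ``unaligned``  — even the best allele is further than
  ``min_score_frac`` x read length edits away.

With a truth table the per-locus breakdown splits unique assignments into
true (assigned allele is in the sample's genotype) and non-true; reads
from stutter molecules assigned to their stutter allele are non-true —
stutter alignment does not count as true alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from .panel import AlleleRecord, label_key
from .demux import CategorizedRead

__all__ = ["AssignmentResult", "pairwise_score", "assign_read", "assign_batch", "BREAKDOWN_STATES"]

BREAKDOWN_STATES = ("unaligned", "ambiguous", "nontrue", "true")


@dataclass(frozen=True)
class AssignmentResult:
    read_id: str
    locus: str
    status: str                 # "unique" | "ambiguous" | "unaligned"
    allele: str | None = None   # set iff unique
    score: float | None = None  # negated edit distance of the best allele
    margin: float | None = None  # best minus second-best distance, > 0 iff unique


def pairwise_score(read: str, allele_sequence: str) -> int:
    """Global-alignment score: negated unit-cost edit distance."""
    if not read or not allele_sequence:
        raise ValueError("pairwise_score requires non-empty sequences")
    return -edlib.align(read, allele_sequence, mode="NW", task="distance")["editDistance"]


def assign_read(
    read_id: str,
    sequence: str,
    candidates: Sequence[AlleleRecord],
    min_score_frac: float = 0.4,
) -> AssignmentResult:
    """Score one read against all candidate alleles of its locus."""
    if not candidates:
        raise ValueError("assign_read needs at least one candidate allele")
    locus = candidates[0].locus
    ordered = sorted(candidates, key=lambda r: label_key(r.label))
    dists = [
        edlib.align(sequence, rec.sequence, mode="NW", task="distance")["editDistance"]
        for rec in ordered
    ]
    best = min(dists)
    if best > min_score_frac * len(sequence):
        return AssignmentResult(read_id, locus, "unaligned")
    ties = [rec for rec, d in zip(ordered, dists) if d == best]
    if len(ties) > 1:
        return AssignmentResult(read_id, locus, "ambiguous", score=-best)
    second = min((d for d in dists if d > best), default=None)
    margin = float(second - best) if second is not None else float("inf")
    return AssignmentResult(read_id, locus, "unique", allele=ties[0].label,
                            score=-best, margin=margin)


def assign_batch(
    categorized: Mapping[str, Iterable[CategorizedRead]],
    db: Sequence[AlleleRecord],
    min_score_frac: float = 0.4,
    truth_alleles: Mapping[str, set] | None = None,
) -> tuple[list[AssignmentResult], pd.DataFrame]:
    """Assign every categorized read; tabulate the per-locus breakdown.

    ``truth_alleles`` maps locus -> set of true allele labels for the
    sample (for a mixture, the union over contributors).  With truth the
    breakdown fractions are {unaligned, ambiguous, nontrue, true}; without
    it, {unaligned, ambiguous, unique}.  Fractions are over each locus's
    categorized read count and sum to 1.
    """
    by_locus: dict[str, list[AlleleRecord]] = {}
    for rec in db:
        by_locus.setdefault(rec.locus, []).append(rec)
    if truth_alleles is not None:
        for locus, labels in truth_alleles.items():
            known = {r.label for r in by_locus.get(locus, [])}
            bad = set(labels) - known
            if bad:
                raise ValueError(f"truth for {locus} references unknown alleles {sorted(bad)}")

    results: list[AssignmentResult] = []
    rows = []
    for locus, reads in categorized.items():
        cands = by_locus.get(locus)
        if cands is None:
            raise ValueError(f"no reference alleles for categorized locus {locus!r}")
        tally = {"unaligned": 0, "ambiguous": 0, "unique": 0, "true": 0, "nontrue": 0}
        n = 0
        for cat in reads:
            res = assign_read(cat.read_id, cat.sequence, cands, min_score_frac)
            results.append(res)
            n += 1
            tally[res.status] += 1
            if res.status == "unique" and truth_alleles is not None:
                truth = truth_alleles.get(locus, set())
                tally["true" if res.allele in truth else "nontrue"] += 1
        row = {"locus": locus, "n": n, **{k: tally[k] for k in ("unaligned", "ambiguous", "unique")}}
        if truth_alleles is not None:
            row["true"] = tally["true"]
            row["nontrue"] = tally["nontrue"]
            for state in BREAKDOWN_STATES:
                row[f"frac_{state}"] = tally[state] / n if n else 0.0
        else:
            for state in ("unaligned", "ambiguous", "unique"):
                row[f"frac_{state}"] = tally[state] / n if n else 0.0
        rows.append(row)
    breakdown = pd.DataFrame(rows)
    return results, breakdown
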