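"""Locus categorization of amplicon reads by primer matching.

A read belongs to a locus when BOTH its primers are found: the forward
primer near the 5' end and the reverse-complemented reverse primer near
the 3' end, in either read orientation.  ``exact`` mode requires perfect
primer matches (the short-read convention); ``fuzzy`` mode allows up to
``max_mismatch`` errors per primer (default 2), counted as edit distance
so indels — the dominant long-read error — are tolerated.  A
substitution-only Hamming mode is available behind ``allow_indels=False``.

Reads matching more than one locus are left uncategorized: with no
defined tiebreak, discarding is the conservative choice, matching the
ambiguity-discard philosophy applied downstream at the allele level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import edlib
import pandas as pd

from .panel import LocusDefinition, revcomp

__all__ = ["CategorizedRead", "DemuxResult", "categorize_read", "categorize_batch", "iter_fastq"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CategorizedRead:
    read_id: str
    locus: str
    orientation: str            # "forward" | "reverse-complement"
    mismatches_fwd: int
    mismatches_rev: int
    sequence: str               # always forward-oriented


def _edit_within(primer: str, window: str, k: int) -> int:
    """Best edit distance of primer anywhere inside window, or -1 if > k."""
    if not window:
        return -1
    return edlib.align(primer, window, mode="HW", task="distance", k=k)["editDistance"]


def _hamming_within(primer: str, window: str, k: int) -> int:
    """Best substitution-only distance over full-length placements, -1 if > k."""
    best = -1
    for off in range(len(window) - len(primer) + 1):
        d = sum(a != b for a, b in zip(primer, window[off:off + len(primer)]))
        if d <= k and (best < 0 or d < best):
            best = d
    return best


def _match_primers(seq: str, locus: LocusDefinition, k: int, allow_indels: bool):
    pf = locus.primer_fwd
    pr_rc = revcomp(locus.primer_rev)
    head = seq[: len(pf) + k]
    tail = seq[max(0, len(seq) - len(pr_rc) - k):]
    dist = _edit_within if allow_indels else _hamming_within
    df = dist(pf, head, k)
    if df < 0:
        return None
    dr = dist(pr_rc, tail, k)
    if dr < 0:
        return None
    return df, dr


def categorize_read(
    read_id: str,
    sequence: str,
    panel: list[LocusDefinition],
    max_mismatch: int = 2,
    mode: str = "fuzzy",
    allow_indels: bool = True,
) -> CategorizedRead | None:
    """Assign one read to a locus, or return None (uncategorized).

    Uncategorized covers both no-match and ambiguous (>1 locus) reads.
    The returned sequence is orientation-normalised to the forward strand.
    """
    if mode not in ("exact", "fuzzy"):
        raise ValueError(f"mode must be 'exact' or 'fuzzy', got {mode!r}")
    k = 0 if mode == "exact" else max_mismatch
    if k < 0:
        raise ValueError("max_mismatch must be >= 0")
    hits = []  # (total mismatches, orientation rank, locus, orient, df, dr, oriented seq)
    for rank, (orient, seq) in enumerate(
        (("forward", sequence), ("reverse-complement", revcomp(sequence)))
    ):
        for locus in panel:
            m = _match_primers(seq, locus, k, allow_indels)
            if m is not None:
                hits.append((m[0] + m[1], rank, locus.name, orient, m[0], m[1], seq))
    if not hits:
        return None
    if len({h[2] for h in hits}) > 1:
        return None  # matches multiple loci: ambiguous, dropped
    _, _, name, orient, df, dr, seq = min(hits)
    return CategorizedRead(read_id, name, orient, df, dr, seq)


@dataclass
class DemuxResult:
    per_locus: dict[str, list[CategorizedRead]]
    total: int
    categorized: int
    uncategorized: int
    malformed: int
    summary: pd.DataFrame  # locus, count, fraction (of categorized reads)


def categorize_batch(
    reads: Iterable[tuple[str, str]] | str,
    panel: list[LocusDefinition],
    max_mismatch: int = 2,
    mode: str = "fuzzy",
    allow_indels: bool = True,
) -> DemuxResult:
    """Categorize a stream of (read id, sequence) pairs or a FASTQ path.

    The summary table gives each locus's read count and its fraction of
    the categorized total — the locus-representation (amplification bias)
    read-out.
    """
    malformed = 0
    if isinstance(reads, str):
        source = iter_fastq(reads)
    else:
        source = ((rid, seq, True) for rid, seq in reads)
    per_locus: dict[str, list[CategorizedRead]] = {loc.name: [] for loc in panel}
    total = categorized = 0
    for rid, seq, ok in source:
        if not ok:
            malformed += 1
            continue
        total += 1
        cat = categorize_read(rid, seq, panel, max_mismatch=max_mismatch,
                              mode=mode, allow_indels=allow_indels)
        if cat is None:
            continue
        per_locus[cat.locus].append(cat)
        categorized += 1
    rows = [
        (name, len(lst), len(lst) / categorized if categorized else 0.0)
        for name, lst in per_locus.items()
    ]
    summary = pd.DataFrame(rows, columns=["locus", "count", "fraction"])
    return DemuxResult(
        per_locus=per_locus,
        total=total + malformed,
        categorized=categorized,
        uncategorized=total + malformed - categorized,
        malformed=malformed,
        summary=summary,
    )


def iter_fastq(path: str) -> Iterator[tuple[str, str, bool]]:
    """Lenient FASTQ iteration yielding (id, sequence, well_formed).

    Structurally broken 4-line groups are reported with ``well_formed``
    False (and a logged warning) instead of aborting the stream, so one
    corrupt record cannot void a whole run.
    """
    with open(path) as fh:
        while True:
            chunk = [fh.readline() for _ in range(4)]
            if not chunk[0]:
                return
            header, seq, plus, qual = (line.rstrip("\n") for line in chunk)
            ok = (
                header.startswith("@")
                and plus.startswith("+")
                and len(seq) == len(qual)
                and len(seq) > 0
            )
            if not ok:
                logger.warning("skipping malformed FASTQ record near %r", header[:40])
                yield header[1:].split()[0] if header else "", "", False
                continue
            yield header[1:].split()[0], seq.upper(), True
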