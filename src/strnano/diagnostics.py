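"""Locus-suitability diagnostics for long-read STR genotyping.

Four sequence characteristics make an STR locus hard to genotype on an
indel-prone platform, and each has a computable read-out here:

* homopolymer content of the repeat array — constant-signal stretches
  that defeat base callers; measured as the longest run of identical
  bases in a two-copy tandem array of the repeat unit, so runs spanning
  the unit junction are counted (AGAA|AGAA carries an AAA run of 3);
* run-length-encoding collisions — allele pairs whose repeat regions
  become identical once every homopolymer run is collapsed to one base
  (TH01 9.3 vs 10), ruling out RLE as an error-correction strategy;
* flank-repeat similarity — flanking sequence resembling the repeat unit
  blurs the repeat-array boundary and lowers mapping accuracy (D18S51,
  D21S11);
* allele-range width — more reference alleles means more near neighbours
  one indel apart.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations, groupby

import edlib
import pandas as pd

from .panel import LocusDefinition, repeat_region

__all__ = [
    "LocusFeatures",
    "max_homopolymer_run",
    "repeat_homopolymer_length",
    "run_length_encode",
    "rle_collision_scan",
    "flank_repeat_identity",
    "feature_report",
]

_DNA_OR_EMPTY = re.compile(r"^[ACGT]*$")


@dataclass(frozen=True)
class LocusFeatures:
    locus: str
    repeat_homopolymer_len: int | None   # None for sequence loci (N/A)
    flank_homopolymer_len: int
    flank_repeat_identity: float | None
    allele_range_width: int
    complexity_class: str
    rle_collisions: tuple[tuple[str, str], ...]


def max_homopolymer_run(sequence: str) -> int:
    """Length of the longest run of identical consecutive bases (0 if empty)."""
    if not _DNA_OR_EMPTY.match(sequence):
        raise ValueError(f"sequence contains characters outside A/C/G/T: {sequence!r}")
    return max((len(list(g)) for _, g in groupby(sequence)), default=0)


def repeat_homopolymer_length(locus: LocusDefinition) -> int | None:
    """Longest homopolymer in the idealized repeat array, per block.

    Computed on a two-copy tandem array of each block motif so that runs
    spanning the copy junction count, then maximized over blocks.  None
    (N/A) for sequence loci.
    """
    if locus.is_sequence_locus:
        return None
    return max(max_homopolymer_run(b.motif * 2) for b in locus.repeat_blocks)


def run_length_encode(sequence: str) -> str:
    """Collapse every maximal homopolymer run to a single base (idempotent)."""
    if not _DNA_OR_EMPTY.match(sequence):
        raise ValueError(f"sequence contains characters outside A/C/G/T: {sequence!r}")
    return "".join(ch for ch, _ in groupby(sequence))


def rle_collision_scan(panel: list[LocusDefinition]) -> dict[str, list[tuple[str, str]]]:
    """Allele pairs per locus whose repeat regions are RLE-identical.

    Collisions are computed on the repeat-region insert only: flanks are
    locus-constant, so they cannot disambiguate alleles.
    """
    out: dict[str, list[tuple[str, str]]] = {}
    for locus in panel:
        encoded = {lab: run_length_encode(repeat_region(locus, lab))
                   for lab in locus.allele_labels}
        pairs = [
            (a, b)
            for a, b in combinations(locus.allele_labels, 2)
            if encoded[a] == encoded[b]
        ]
        out[locus.name] = pairs
    return out


def _identity(a: str, b: str) -> float:
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _tile(motif: str, length: int) -> str:
    reps = -(-length // len(motif))
    return (motif * reps)[:length]


def flank_repeat_identity(locus: LocusDefinition) -> float | None:
    """How much the flanks look like the repeat array, in [0, 1].

    Each non-empty flank is globally aligned (unit costs) against an
    idealized tandem array of the variable motif tiled to the flank's
    length; identity = 1 - edit distance / length.  The tiling considers
    every rotation of the motif — a flank that IS a perfect tandem array
    scores exactly 1.0 whatever phase it starts in — and the maximum over
    flanks and rotations is returned.  None when the locus has no flanks
    or no variable motif.
    """
    if locus.is_sequence_locus:
        return None
    motif = locus.variable_block.motif
    rotations = {motif[i:] + motif[:i] for i in range(len(motif))}
    best = None
    for flank in (locus.flank5, locus.flank3):
        if not flank:
            continue
        score = max(_identity(flank, _tile(rot, len(flank))) for rot in rotations)
        best = score if best is None else max(best, score)
    return best


def feature_report(panel: list[LocusDefinition]) -> pd.DataFrame:
    """One diagnostics row per locus, mirroring a locus-characteristics table."""
    collisions = rle_collision_scan(panel)
    rows = []
    for locus in panel:
        flank_hp = max(
            max_homopolymer_run(locus.flank5), max_homopolymer_run(locus.flank3)
        )
        feats = LocusFeatures(
            locus=locus.name,
            repeat_homopolymer_len=repeat_homopolymer_length(locus),
            flank_homopolymer_len=flank_hp,
            flank_repeat_identity=flank_repeat_identity(locus),
            allele_range_width=len(locus.allele_labels),
            complexity_class=locus.complexity_class,
            rle_collisions=tuple(collisions[locus.name]),
        )
        rows.append({
            "locus": feats.locus,
            "repeat_homopolymer_len": feats.repeat_homopolymer_len,
            "flank_homopolymer_len": feats.flank_homopolymer_len,
            "flank_repeat_identity": (
                None if feats.flank_repeat_identity is None
                else round(feats.flank_repeat_identity, 4)
            ),
            "allele_range_width": feats.allele_range_width,
            "complexity_class": feats.complexity_class,
            "rle_collisions": ";".join(f"{a}~{b}" for a, b in feats.rle_collisions),
        })
    return pd.DataFrame(rows)
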