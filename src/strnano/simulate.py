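"""Synthetic amplicon-sequencing reads with PCR stutter and platform errors.

The generator follows the noise structure the downstream analysis assumes:

1. genotypes (single contributors or weighted mixtures) define the parent
   alleles per locus;
2. PCR stutter converts a fraction of each parent's molecules into the
   one-repeat-shorter (n-1, dominant) and one-repeat-longer (n+1, minor)
   products;
3. a platform error model corrupts each molecule base by base —
   substitutions, insertions, and deletions whose probability grows with
   the length of the homopolymer run the base sits in, emulating the
   constant-signal weakness of nanopore base calling.

Reads are emitted as FASTQ; ground truth (source allele, contributor) is
kept in a side table keyed by read id, never in the read name itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .panel import AlleleRecord, parse_label, revcomp

__all__ = [
    "Genotype",
    "MixtureSpec",
    "StutterModel",
    "ErrorModel",
    "Molecule",
    "SimRead",
    "presets",
    "build_amplicon_pool",
    "sequence_reads",
    "expected_deletions",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Genotype:
    """Per-locus allele labels (1 = homozygous, 2 = heterozygous) for one
    contributor."""

    contributor: str
    alleles: dict[str, tuple[str, ...]]

    def __post_init__(self):
        for locus, labels in self.alleles.items():
            if not 1 <= len(labels) <= 2:
                raise ValueError(f"{self.contributor}/{locus}: need 1 or 2 alleles, got {labels}")

    def allele_pair(self, locus: str) -> tuple[str, str]:
        labs = self.alleles[locus]
        return (labs[0], labs[0]) if len(labs) == 1 else (labs[0], labs[1])


@dataclass(frozen=True)
class MixtureSpec:
    """Weighted set of contributors; weights must be positive and sum to 1."""

    contributors: tuple[tuple[Genotype, float], ...]

    def __post_init__(self):
        if not self.contributors:
            raise ValueError("mixture needs at least one contributor")
        weights = [w for _, w in self.contributors]
        if any(w <= 0 for w in weights):
            raise ValueError("contributor weights must be positive")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"contributor weights must sum to 1, got {sum(weights)}")

    @classmethod
    def single(cls, genotype: Genotype) -> "MixtureSpec":
        return cls(((genotype, 1.0),))

    @classmethod
    def balanced(cls, *genotypes: Genotype) -> "MixtureSpec":
        w = 1.0 / len(genotypes)
        return cls(tuple((g, w) for g in genotypes))


@dataclass(frozen=True)
class StutterModel:
    """Fraction of a parent allele's molecules emitted as stutter products.

    ``rho_minus``/``rho_plus`` are the n-1 / n+1 fractions.  With
    ``repeat_scaling`` s > 0 the fractions grow linearly with repeat number
    above ``pivot``: rho * (1 + s * max(0, n - pivot)) — longer repeats
    stutter more.
    """

    rho_minus: float = 0.0
    rho_plus: float = 0.0
    repeat_scaling: float = 0.0
    pivot: int = 10

    def __post_init__(self):
        if self.rho_minus < 0 or self.rho_plus < 0 or self.repeat_scaling < 0:
            raise ValueError("stutter fractions must be non-negative")
        if self.rho_minus + self.rho_plus >= 1:
            raise ValueError("rho_minus + rho_plus must be < 1")

    def rates_for(self, n_repeats: int) -> tuple[float, float]:
        scale = 1.0 + self.repeat_scaling * max(0, n_repeats - self.pivot)
        rm, rp = self.rho_minus * scale, self.rho_plus * scale
        total = rm + rp
        if total >= 1.0:  # keep a valid categorical distribution
            rm, rp = rm / (total + 1e-9), rp / (total + 1e-9)
        return rm, rp


@dataclass(frozen=True)
class ErrorModel:
    """Per-base corruption probabilities for one sequencing platform.

    Deletion probability inside a homopolymer run of length L is
    ``p_del * (1 + homopolymer_factor * (min(L, homopolymer_cap) - 1))``,
    so isolated bases are deleted at the base rate and long runs at up to
    ``1 + h*(cap-1)`` times that rate.  Quality strings are a constant
    placeholder; the pipeline never uses them.
    """

    p_sub: float = 0.0
    p_ins: float = 0.0
    p_del: float = 0.0
    homopolymer_factor: float = 1.0
    homopolymer_cap: int = 8
    name: str = "custom"

    def __post_init__(self):
        for p in (self.p_sub, self.p_ins, self.p_del):
            if not 0 <= p < 1:
                raise ValueError("per-base probabilities must be in [0, 1)")
        if self.homopolymer_factor < 0 or self.homopolymer_cap < 1:
            raise ValueError("homopolymer_factor >= 0 and homopolymer_cap >= 1 required")
        if self.p_del * (1 + self.homopolymer_factor * (self.homopolymer_cap - 1)) >= 1:
            raise ValueError("effective deletion probability reaches 1 inside long runs")

    @property
    def total_error(self) -> float:
        return self.p_sub + self.p_ins + self.p_del

    def to_config(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_config(cls, path) -> "ErrorModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def presets() -> dict[str, ErrorModel]:
    """Named platform error profiles.

    ``short-accurate`` mimics a low-error short-read instrument (base
    substitutions dominate, indels negligible); ``long-noisy`` mimics a
    long-read nanopore-style instrument (indel-dominant with
    homopolymer-length-dependent deletions).  Magnitudes are typical
    published platform error rates, not fits to any particular run.
    """
    return {
        "short-accurate": ErrorModel(
            p_sub=0.002, p_ins=1e-4, p_del=1e-4,
            homopolymer_factor=1.0, homopolymer_cap=8, name="short-accurate",
        ),
        "long-noisy": ErrorModel(
            p_sub=0.03, p_ins=0.02, p_del=0.025,
            homopolymer_factor=1.5, homopolymer_cap=8, name="long-noisy",
        ),
    }


def get_preset(name: str) -> ErrorModel:
    try:
        return presets()[name]
    except KeyError:
        raise KeyError(f"unknown error-model preset {name!r}; have {sorted(presets())}") from None


class Molecule(NamedTuple):
    locus: str
    label: str          # the allele this molecule actually carries
    parent_label: str   # the genotype allele it descends from
    contributor: str
    sequence: str


class SimRead(NamedTuple):
    read_id: str
    sequence: str


def _stutter_target(label: str, shift: int) -> str:
    n, y = parse_label(label)
    return f"{n + shift}.{y}" if y else str(n + shift)


def build_amplicon_pool(
    mixture: MixtureSpec,
    db: list[AlleleRecord],
    stutter: StutterModel | None = None,
    depth_per_locus: int = 1000,
    representation_bias: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> list[Molecule]:
    """Draw the PCR product pool for one sample.

    Each locus receives ``depth_per_locus * bias`` molecules.  A molecule's
    contributor is drawn by mixture weight, its parent allele uniformly
    from that contributor's (1 or 2) alleles, and its product category
    multinomially over {parent, n-1, n+1}.  Stutter products falling
    outside the locus's allele range are clamped out (the molecule stays a
    parent copy).  Reproducible for a fixed seed.
    """
    if depth_per_locus < 1:
        raise ValueError("depth_per_locus must be >= 1")
    stutter = stutter or StutterModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    index: dict[tuple[str, str], str] = {(r.locus, r.label): r.sequence for r in db}
    loci = list(dict.fromkeys(r.locus for r in db))
    bias = representation_bias or {}
    if representation_bias is not None and all(v == 0 for v in representation_bias.values()):
        raise ValueError("representation bias is zero for every locus")
    genotypes = [g for g, _ in mixture.contributors]
    weights = np.array([w for _, w in mixture.contributors])

    pool: list[Molecule] = []
    for locus in loci:
        n_mol = int(round(depth_per_locus * bias.get(locus, 1.0)))
        if n_mol == 0:
            continue
        contrib_idx = rng.choice(len(genotypes), size=n_mol, p=weights)
        hap_idx = rng.integers(0, 2, size=n_mol)
        u = rng.random(n_mol)
        for ci, hi, ui in zip(contrib_idx, hap_idx, u):
            geno = genotypes[ci]
            if locus not in geno.alleles:
                raise KeyError(f"contributor {geno.contributor} has no genotype for locus {locus}")
            parent = geno.allele_pair(locus)[hi]
            label = parent
            try:
                n_units, _ = parse_label(parent)
                rm, rp = stutter.rates_for(n_units)
                if ui < rm:
                    label = _stutter_target(parent, -1)
                elif ui < rm + rp:
                    label = _stutter_target(parent, +1)
            except ValueError:
                pass  # sequence locus (X/Y): no stutter ladder
            if (locus, label) not in index:
                label = parent  # clamped out at the range edge
            pool.append(Molecule(locus, label, parent, geno.contributor, index[(locus, label)]))
    return pool


def _run_lengths(seq_u8: np.ndarray) -> np.ndarray:
    """Length of the homopolymer run containing each position."""
    n = seq_u8.size
    boundaries = np.flatnonzero(np.diff(seq_u8) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    lengths = ends - starts
    return np.repeat(lengths, lengths)


def _deletion_profile(seq: str, error: ErrorModel) -> np.ndarray:
    u8 = np.frombuffer(seq.encode(), dtype=np.uint8)
    runs = np.minimum(_run_lengths(u8), error.homopolymer_cap)
    return error.p_del * (1.0 + error.homopolymer_factor * (runs - 1.0))


def expected_deletions(seq: str, error: ErrorModel) -> float:
    """Closed-form expected number of deleted bases for one molecule."""
    return float(_deletion_profile(seq, error).sum())


def _corrupt(seq_u8: np.ndarray, del_p: np.ndarray, error: ErrorModel,
             rng: np.random.Generator) -> str:
    n = seq_u8.size
    u = rng.random((3, n))
    out = seq_u8.copy()
    sub_mask = u[0] < error.p_sub
    if sub_mask.any():
        # substitute with one of the three other bases, uniformly
        orig = np.searchsorted(_BASES, out[sub_mask])
        alt = (orig + rng.integers(1, 4, size=orig.size)) % 4
        out[sub_mask] = _BASES[alt]
    keep = u[2] >= del_p
    ins_mask = u[1] < error.p_ins
    if not ins_mask.any():
        return out[keep].tobytes().decode()
    # insertions sit before their anchor position
    pieces: list[bytes] = []
    last = 0
    for pos in np.flatnonzero(ins_mask):
        pieces.append(out[last:pos][keep[last:pos]].tobytes())
        pieces.append(bytes([_BASES[rng.integers(0, 4)]]))
        last = pos
    pieces.append(out[last:][keep[last:]].tobytes())
    return b"".join(pieces).decode()


def sequence_reads(
    pool: Iterable[Molecule],
    error: ErrorModel,
    seed: int | np.random.Generator = 0,
    rc_fraction: float = 0.0,
    id_prefix: str = "read",
) -> tuple[list[SimRead], pd.DataFrame]:
    """Corrupt each pool molecule into one read; return reads plus truth.

    Each molecule is processed left to right: substitution, then insertion
    before the position, then (homopolymer-scaled) deletion.  A fraction
    ``rc_fraction`` of reads is emitted reverse-complemented, as both
    strands of an amplicon are sequenced.  The truth table (read id, locus,
    source allele, parent allele, contributor, strand) is the side channel
    for scoring; read names carry no ground truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not 0 <= rc_fraction <= 1:
        raise ValueError("rc_fraction must be in [0, 1]")
    profile_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    reads: list[SimRead] = []
    truth_rows = []
    for i, mol in enumerate(pool):
        cached = profile_cache.get(mol.sequence)
        if cached is None:
            u8 = np.frombuffer(mol.sequence.encode(), dtype=np.uint8).copy()
            cached = (u8, _deletion_profile(mol.sequence, error))
            profile_cache[mol.sequence] = cached
        u8, del_p = cached
        if error.total_error == 0:
            seq = mol.sequence
        else:
            seq = _corrupt(u8, del_p, error, rng)
        is_rc = rc_fraction > 0 and rng.random() < rc_fraction
        if is_rc:
            seq = revcomp(seq)
        rid = f"{id_prefix}{i:07d}"
        reads.append(SimRead(rid, seq))
        truth_rows.append((rid, mol.locus, mol.label, mol.parent_label,
                           mol.contributor, "-" if is_rc else "+"))
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "locus", "allele", "parent_allele", "contributor", "strand"],
    )
    return reads, truth


def write_fastq(reads: Iterable[SimRead], path, quality: str = "I") -> None:
    """Write reads as FASTQ with a constant placeholder quality character."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality * len(seq)}\n")
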