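"""Locus models and reference-allele databases for a forensic STR multiplex.

An STR locus is amplified by a primer pair.  Between the primers sit a 5'
flanking sequence, an array of tandem-repeat blocks, and a 3' flanking
sequence.  Alleles are named by repeat count using standard forensic
nomenclature: ``"9"`` is nine full repeat units, ``"9.3"`` is nine full
units plus a 3-base partial unit (e.g. TH01).  The amelogenin sex locus is
not an STR — its X and Y alleles are literal sequences — and is modelled as
a *sequence locus*.

The reference database expands every allele label of every locus into a
full amplicon sequence (forward primer .. reverse-complemented reverse
primer), the object reads are later aligned against.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "RepeatBlock",
    "LocusDefinition",
    "AlleleRecord",
    "revcomp",
    "parse_label",
    "label_key",
    "expand_allele",
    "repeat_region",
    "build_reference_db",
    "write_fasta",
    "read_fasta",
    "save_panel",
    "load_panel",
    "classify_complexity",
    "fixture_panel",
    "fixture_genotype_alleles",
]

_DNA = re.compile(r"^[ACGT]+$")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_LABEL = re.compile(r"^(\d+)(?:\.(\d+))?$")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(value: str, what: str, allow_empty: bool = False) -> None:
    if value == "":
        if allow_empty:
            return
        raise ValueError(f"{what} must be non-empty")
    if not _DNA.match(value):
        raise ValueError(f"{what} contains characters outside A/C/G/T: {value!r}")


def parse_label(label: str) -> tuple[int, int]:
    """Split an allele label into (full units, partial bases).

    ``"9" -> (9, 0)``; ``"9.3" -> (9, 3)``.  Raises ValueError for anything
    that is not ``n`` or ``n.y`` with integer parts.
    """
    m = _LABEL.match(label)
    if not m:
        raise ValueError(f"allele label {label!r} is not of the form 'n' or 'n.y'")
    return int(m.group(1)), int(m.group(2) or 0)


def label_key(label: str):
    """Sort key giving numeric order for STR labels, lexical for others (X, Y)."""
    try:
        n, y = parse_label(label)
        return (0, n, y)
    except ValueError:
        return (1, label)


@dataclass(frozen=True)
class RepeatBlock:
    """One block of the repeat array: a motif repeated a variable or fixed
    number of times.  Exactly one block per STR locus is ``variable``; its
    copy number is what the allele label counts."""

    motif: str
    kind: str = "variable"  # "variable" | "fixed"
    fixed_count: int = 1

    def __post_init__(self):
        _check_dna(self.motif, "repeat motif")
        if self.kind not in ("variable", "fixed"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.kind == "fixed" and self.fixed_count < 1:
            raise ValueError("fixed block needs fixed_count >= 1")


@dataclass(frozen=True)
class LocusDefinition:
    """Everything needed to expand the alleles of one locus.

    ``primer_rev`` is stored 5'->3' on its own strand, as primers are
    ordered; the amplicon ends with its reverse complement.  For an ``n.y``
    allele the partial unit is ``motif[:y]`` (``partial_side="prefix"``) or
    ``motif[-y:]`` (``"suffix"``), placed after ``partial_after`` full units
    (``None`` = after all of them).  ``sequence_alleles`` maps labels to
    literal insert sequences for non-STR loci (amelogenin).
    """

    name: str
    primer_fwd: str
    primer_rev: str
    flank5: str = ""
    flank3: str = ""
    repeat_blocks: tuple[RepeatBlock, ...] = ()
    allele_labels: tuple[str, ...] = ()
    complexity_class: str = "Low"
    is_sequence_locus: bool = False
    sequence_alleles: dict[str, str] = field(default_factory=dict)
    partial_side: str = "prefix"
    partial_after: int | None = None

    def __post_init__(self):
        if not self.name:
            raise ValueError("locus name must be non-empty")
        _check_dna(self.primer_fwd, f"{self.name} primer_fwd")
        _check_dna(self.primer_rev, f"{self.name} primer_rev")
        _check_dna(self.flank5, f"{self.name} flank5", allow_empty=True)
        _check_dna(self.flank3, f"{self.name} flank3", allow_empty=True)
        if self.complexity_class not in ("Low", "Medium", "High"):
            raise ValueError(f"complexity_class must be Low/Medium/High, got {self.complexity_class!r}")
        if self.partial_side not in ("prefix", "suffix"):
            raise ValueError("partial_side must be 'prefix' or 'suffix'")
        if self.is_sequence_locus:
            if not self.sequence_alleles:
                raise ValueError(f"{self.name}: sequence locus needs sequence_alleles")
            for lab, seq in self.sequence_alleles.items():
                _check_dna(seq, f"{self.name} allele {lab}")
            object.__setattr__(self, "allele_labels", tuple(self.sequence_alleles))
            return
        variable = [b for b in self.repeat_blocks if b.kind == "variable"]
        if len(variable) != 1:
            raise ValueError(f"{self.name}: STR locus needs exactly one variable block, got {len(variable)}")
        motif_len = len(variable[0].motif)
        for lab in self.allele_labels:
            n, y = parse_label(lab)
            if y and not (1 <= y < motif_len):
                raise ValueError(
                    f"{self.name} allele {lab}: partial length {y} must satisfy 1 <= y < {motif_len}"
                )

    @property
    def variable_block(self) -> RepeatBlock:
        if self.is_sequence_locus:
            raise ValueError(f"{self.name} is a sequence locus; it has no variable block")
        return next(b for b in self.repeat_blocks if b.kind == "variable")


@dataclass(frozen=True)
class AlleleRecord:
    """One reference allele: full amplicon sequence from primer to primer."""

    locus: str
    label: str
    sequence: str


def _expand_variable(block: RepeatBlock, label: str, side: str, after: int | None) -> str:
    n, y = parse_label(label)
    motif = block.motif
    full = [motif] * n
    if y == 0:
        return "".join(full)
    part = motif[:y] if side == "prefix" else motif[-y:]
    cut = n if after is None else min(after, n)
    return "".join(full[:cut]) + part + "".join(full[cut:])


def repeat_region(locus: LocusDefinition, label: str) -> str:
    """The repeat-array insert for one allele: all blocks, no flanks/primers."""
    if locus.is_sequence_locus:
        return locus.sequence_alleles[label]
    if label not in locus.allele_labels:
        raise KeyError(f"unknown allele {label!r} for locus {locus.name}")
    parts = []
    for block in locus.repeat_blocks:
        if block.kind == "fixed":
            parts.append(block.motif * block.fixed_count)
        else:
            parts.append(_expand_variable(block, label, locus.partial_side, locus.partial_after))
    return "".join(parts)


def expand_allele(locus: LocusDefinition, label: str) -> AlleleRecord:
    """Expand one allele label into its full amplicon sequence.

    The amplicon is ``primer_fwd + flank5 + repeat array + flank3 +
    revcomp(primer_rev)``; deterministic in all inputs.
    """
    if locus.is_sequence_locus:
        raise ValueError(f"{locus.name} is a sequence locus; expand_allele applies to STR loci only")
    insert = repeat_region(locus, label)
    seq = locus.primer_fwd + locus.flank5 + insert + locus.flank3 + revcomp(locus.primer_rev)
    return AlleleRecord(locus=locus.name, label=label, sequence=seq)


def build_reference_db(panel: list[LocusDefinition]) -> list[AlleleRecord]:
    """One AlleleRecord per (locus, label), in locus order then numeric label order."""
    if not panel:
        raise ValueError("panel is empty")
    names = [loc.name for loc in panel]
    if len(set(names)) != len(names):
        raise ValueError("duplicate locus names in panel")
    records: list[AlleleRecord] = []
    for locus in panel:
        if not locus.allele_labels:
            raise ValueError(f"{locus.name}: empty allele label list")
        for label in sorted(locus.allele_labels, key=label_key):
            if locus.is_sequence_locus:
                seq = (
                    locus.primer_fwd + locus.flank5 + locus.sequence_alleles[label]
                    + locus.flank3 + revcomp(locus.primer_rev)
                )
                records.append(AlleleRecord(locus.name, label, seq))
            else:
                records.append(expand_allele(locus, label))
        seqs = [r.sequence for r in records if r.locus == locus.name]
        if len(set(seqs)) != len(seqs):
            raise ValueError(f"{locus.name}: allele sequences are not unique")
    return records


def write_fasta(db: list[AlleleRecord], path) -> None:
    """Write the reference database as FASTA with ``locus|label`` headers."""
    recs = [
        SeqRecord(Seq(r.sequence), id=f"{r.locus}|{r.label}", description="")
        for r in db
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> list[AlleleRecord]:
    """Read a reference database written by :func:`write_fasta`.

    Sequences are normalised to uppercase; a header without ``|`` is a
    parse error.
    """
    db = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"malformed reference header {rec.id!r}: expected 'locus|label'")
        locus, label = rec.id.split("|", 1)
        seq = str(rec.seq).upper()
        _check_dna(seq, f"{rec.id} sequence")
        db.append(AlleleRecord(locus, label, seq))
    return db


def save_panel(panel: list[LocusDefinition], path) -> None:
    """Serialise a panel definition to JSON."""
    payload = []
    for loc in panel:
        d = asdict(loc)
        d["repeat_blocks"] = [asdict(b) for b in loc.repeat_blocks]
        payload.append(d)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_panel(path) -> list[LocusDefinition]:
    with open(path) as fh:
        payload = json.load(fh)
    panel = []
    for d in payload:
        blocks = tuple(RepeatBlock(**b) for b in d.pop("repeat_blocks", []))
        d["repeat_blocks"] = blocks
        d["allele_labels"] = tuple(d.get("allele_labels", ()))
        panel.append(LocusDefinition(**d))
    return panel


def classify_complexity(locus: LocusDefinition) -> str:
    """Heuristic complexity class from structure alone (block count, partial
    repeats, range width).  Provided for exploration; the pipeline always
    uses the declared ``complexity_class``, never this."""
    if locus.is_sequence_locus:
        return "Low"
    has_partial = any(parse_label(l)[1] for l in locus.allele_labels)
    blocks = len(locus.repeat_blocks)
    width = len(locus.allele_labels)
    score = (blocks - 1) + (1 if has_partial else 0) + (1 if width > 10 else 0)
    return "High" if score >= 2 else ("Medium" if score == 1 else "Low")


# --- fixture panel -----------------------------------------------------------
#
# A 15-plex (14 STRs + amelogenin) mirroring a commonly used forensic
# multiplex: real repeat motifs and population allele ranges, synthetic
# primers and (mostly) synthetic flanks.  The D18S51 5' flank and the
# D21S11 repeat-adjacent sequence are the published flanking sequences that
# resemble the repeat motif.  TH01 carries the 9.3 allele with its partial
# unit between the 6th and 7th full repeat, so that alleles 9.3 and 10
# collapse to the same string under run-length encoding.

_PRIMERS = {
    "AMEL": ("CCCTGGGCTCTGTAAAGAA", "ATCAGAGCTTAAACTGGGAAGCTG"),
    "TPOX": ("ACTGGCACAGAACAGGCACT", "GGAGGAACTGGGAACCACAC"),
    "TH01": ("GTGGGCTGAAAAGCTCCCGATTAT", "GTGATTCCCATTGGCCTGTTC"),
    "D7S820": ("ATGTTGGTCAGGCTGACTATG", "GATTCCACATTTATCCTCATTGAC"),
    "D13S317": ("ACAGAAGTCTGGGATGTGGA", "GCCCAAAAAGACAGACAGAA"),
    "D8S1179": ("TTTTTGTATTTCATGTGTACATTCG", "CGTAGCTATAATTAGTTCATTTTCA"),
    "D16S539": ("GATCCCAAGCTCTTCCTCTT", "ACGTTTGTGTGTGCATCTGT"),
    "D5S818": ("GGTGATTTTCCTCTTTGGTATCC", "AGCCACAGTTTACAACATTTGTATCT"),
    "D3S1358": ("ACTGCAGTCCAATCTGGGT", "ATGAAATCAACAGAGGCTTGC"),
    "D18S51": ("CAAACCCGACTACCAGCAAC", "GAGCCATGTTCATGCCACTG"),
    "FGA": ("GCCCCATAGGTTTTGAACTCA", "TGATTTGTCTGTAATTGCCAGC"),
    "vWA": ("GGACAGATGATAAATACATAGGATGGATGG", "GCCCTAGTGGATGATAAGAATAATCAGTATGTG"),
    "CD4": ("TTGGAGTCGCAAGCTGAACTAGC", "CCAGGAAGTTGAGGTTGCAGTG"),
    "D21S11": ("ATATGTGAGTCAATTCCCCAAG", "TGTATTAGTCAATGTTCTCCAG"),
    "SE33": ("AATCTGGGCGACAAGAGTGA", "ACATCTCCCCTACCGCTATA"),
}

_FLANKS = {
    "AMEL": ("GATCACTT", "TGAACCAT"),
    "TPOX": ("TGGGAACC", "CTTAGGGA"),
    "TH01": ("CCCTGTAC", "CAGGGAAC"),
    "D7S820": ("TAGAACAC", "GTTAGTTC"),
    "D13S317": ("CCCATCTA", "ACAGTGGA"),
    "D8S1179": ("TTGTATTT", "ACCTATCC"),
    "D16S539": ("AAAGGGAACAGAAATAAAAGAAAG", "TTCCCAAT"),
    "D5S818": ("CTCTTTGG", "ACCTCTAT"),
    "D3S1358": ("CCTGTGGT", "TGAGACAG"),
    # published D18S51 flanking sequence, very similar to the AGAA repeat
    "D18S51": ("AAAGAGAGAGGAAAGAAAGAGAAAAAGAAAAGAAATAGTA", "GGTGGCAC"),
    "FGA": ("GGCTGCAG", "TCATTGAC"),
    "vWA": ("CTAGTGGA", "CCATCCAT"),
    "CD4": ("CTTGAGCC", "GGAGTCAG"),
    # published D21S11 repeat-adjacent sequence, similar to the TCTA unit
    "D21S11": ("TCGTCTATCTATCCAGTCTATCTA", "TCGTCTCA"),
    "SE33": ("CTTTCTCT", "TGAGCACA"),
}


def _labels(lo: int, hi: int, extra: tuple[str, ...] = ()) -> tuple[str, ...]:
    return tuple(str(n) for n in range(lo, hi + 1)) + extra


def fixture_panel() -> list[LocusDefinition]:
    """The built-in 15-locus panel (14 STRs + amelogenin)."""

    def mk(name, blocks, labels, cls, **kw):
        f5, f3 = _FLANKS[name]
        pf, pr = _PRIMERS[name]
        return LocusDefinition(
            name=name, primer_fwd=pf, primer_rev=pr, flank5=f5, flank3=f3,
            repeat_blocks=tuple(blocks), allele_labels=labels,
            complexity_class=cls, **kw,
        )

    v = RepeatBlock  # shorthand
    panel = [
        LocusDefinition(
            name="AMEL",
            primer_fwd=_PRIMERS["AMEL"][0], primer_rev=_PRIMERS["AMEL"][1],
            flank5=_FLANKS["AMEL"][0], flank3=_FLANKS["AMEL"][1],
            is_sequence_locus=True,
            sequence_alleles={
                "X": "CCCTTTGAAGTGGTACCAGAGCA",
                "Y": "CCCTTTGAAGTGATACCAGTTTA",
            },
        ),
        mk("TPOX", [v("AATG")], _labels(8, 12), "Low"),
        # TH01: 9.3 = six full AATG units, the 3-base partial ATG, three more
        # full units; run-length-encodes identically to allele 10.
        mk("TH01", [v("AATG")], _labels(6, 10, ("9.3",)), "Low",
           partial_side="suffix", partial_after=6),
        mk("D7S820", [v("GATA")], _labels(7, 14), "Low"),
        mk("D13S317", [v("TATC")], _labels(8, 15), "Low"),
        mk("D8S1179", [v("TCTA", "fixed", 1), v("TCTG", "fixed", 1), v("TCTA")],
           _labels(8, 17), "Medium"),
        mk("D16S539", [v("GATA")], _labels(8, 14), "Low"),
        mk("D5S818", [v("AGAT")], _labels(8, 14), "Low"),
        mk("D3S1358", [v("TCTG", "fixed", 1), v("TCTA")], _labels(13, 19), "Medium"),
        mk("D18S51", [v("AGAA")], _labels(10, 22), "Low"),
        mk("FGA", [v("TTTC", "fixed", 3), v("TTCC", "fixed", 1), v("TTTC")],
           _labels(18, 28), "High"),
        mk("vWA", [v("TCTA", "fixed", 1), v("TCTG", "fixed", 3), v("TCTA")],
           _labels(14, 20), "High"),
        mk("CD4", [v("AAAAG")], _labels(4, 11), "Low"),
        mk("D21S11", [v("TCTA", "fixed", 4), v("TCTG", "fixed", 6), v("TCTA")],
           _labels(27, 36), "High"),
        mk("SE33", [v("AAAG")], _labels(12, 34), "High"),
    ]
    return panel


def fixture_genotype_alleles() -> dict[str, dict[str, tuple[str, ...]]]:
    """Two synthetic single-contributor profiles over the fixture panel.

    Stand-ins for laboratory reference samples; every allele lies inside
    the panel's population range for its locus.
    """
    a = {
        "AMEL": ("X", "X"), "TPOX": ("8", "11"), "TH01": ("7", "9.3"),
        "D7S820": ("10", "12"), "D13S317": ("9", "11"), "D8S1179": ("12", "14"),
        "D16S539": ("9", "12"), "D5S818": ("10", "11"), "D3S1358": ("14", "16"),
        "D18S51": ("13", "15"), "FGA": ("21", "24"), "vWA": ("16", "18"),
        "CD4": ("6", "9"), "D21S11": ("29", "31"), "SE33": ("18", "26"),
    }
    b = {
        "AMEL": ("X", "Y"), "TPOX": ("9", "9"), "TH01": ("6", "9"),
        "D7S820": ("8", "11"), "D13S317": ("8", "8"), "D8S1179": ("10", "13"),
        "D16S539": ("11", "13"), "D5S818": ("9", "12"), "D3S1358": ("15", "17"),
        "D18S51": ("12", "17"), "FGA": ("19", "23"), "vWA": ("15", "17"),
        "CD4": ("5", "10"), "D21S11": ("28", "30"), "SE33": ("14", "22"),
    }
    return {"A": a, "B": b}
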