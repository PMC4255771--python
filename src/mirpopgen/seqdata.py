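"""Data model and IO for per-locus haplotype alignments, hairpin annotations,
and reference secondary structures.

Coordinates are 0-based half-open everywhere in memory; reports convert to
1-based inclusive. Alignments are multi-FASTA, one file per locus, with headers
following a ``strain|population`` convention (delimiter configurable). A record
whose strain id matches the designated outgroup id is stored separately as the
outgroup sequence rather than as an ingroup haplotype.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    AlphabetError,
    CoordinateError,
    InputError,
    SampleSizeError,
    StructureError,
)

ALPHABET = frozenset("ACGT-")

#: complement map; gaps map to themselves
_COMPLEMENT = str.maketrans("ACGT-", "TGCA-")

Interval = tuple[int, int]


def reverse_complement(seq: str) -> str:
    """Reverse-complement an aligned sequence, preserving gap characters."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Haplotype:
    strain_id: str
    population_id: str
    sequence: str


@dataclass(frozen=True)
class LocusAlignment:
    """Phased haplotypes (plus optional single outgroup) for one miRNA locus."""

    locus_id: str
    haplotypes: tuple[Haplotype, ...]
    outgroup_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.haplotypes) < 2:
            raise SampleSizeError(
                f"{self.locus_id}: need >= 2 ingroup haplotypes, "
                f"got {len(self.haplotypes)}"
            )
        lengths = {len(h.sequence) for h in self.haplotypes}
        if self.outgroup_sequence is not None:
            lengths.add(len(self.outgroup_sequence))
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.locus_id}: unequal sequence lengths {sorted(lengths)}"
            )
        for name, seq in self._iter_named_sequences():
            bad = set(seq) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"{self.locus_id}/{name}: illegal characters {sorted(bad)}"
                )
            if set(seq) == {"-"}:
                raise AlignmentError(f"{self.locus_id}/{name}: all-gap sequence")

    def _iter_named_sequences(self) -> Iterable[tuple[str, str]]:
        for h in self.haplotypes:
            yield h.strain_id, h.sequence
        if self.outgroup_sequence is not None:
            yield "<outgroup>", self.outgroup_sequence

    @property
    def n(self) -> int:
        """Ingroup sample size."""
        return len(self.haplotypes)

    @property
    def num_columns(self) -> int:
        return len(self.haplotypes[0].sequence)

    @property
    def populations(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for h in self.haplotypes:
            seen.setdefault(h.population_id, None)
        return tuple(seen)

    def sequences(self, population: Optional[str] = None) -> list[str]:
        """Ingroup sequences, optionally restricted to one population."""
        return [
            h.sequence
            for h in self.haplotypes
            if population is None or h.population_id == population
        ]

    def subset(self, population: str) -> "LocusAlignment":
        """Alignment restricted to one population (outgroup retained)."""
        haps = tuple(h for h in self.haplotypes if h.population_id == population)
        return LocusAlignment(self.locus_id, haps, self.outgroup_sequence)


def _validate_interval(name: str, iv: Interval, outer: Optional[Interval] = None) -> None:
    s, e = iv
    if not (0 <= s < e):
        raise CoordinateError(f"{name}: bad interval [{s},{e})")
    if outer is not None and not (outer[0] <= s and e <= outer[1]):
        raise CoordinateError(f"{name}: [{s},{e}) not within [{outer[0]},{outer[1]})")


def _disjoint(a: Optional[Interval], b: Optional[Interval]) -> bool:
    if a is None or b is None:
        return True
    return a[1] <= b[0] or b[1] <= a[0]


# offsets of the seed within the mature miR: positions 2-8, i.e. [1, 8)
SEED_OFFSETS = (1, 8)


@dataclass(frozen=True)
class HairpinAnnotation:
    """Coordinates of hairpin/miR/miR*/loop plus conservation and expression
    metadata, all in locus coordinates (0-based half-open)."""

    locus_id: str
    hairpin: Interval
    mir: Interval
    mir_star: Optional[Interval] = None
    loop: Optional[Interval] = None
    strand: str = "+"
    seed: Optional[Interval] = None
    seed_family_presence: frozenset[str] = field(default_factory=frozenset)
    expression_reads: int = 0
    nearest_mirna_distance_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise CoordinateError(f"{self.locus_id}: strand must be + or -")
        _validate_interval(f"{self.locus_id}.hairpin", self.hairpin)
        _validate_interval(f"{self.locus_id}.mir", self.mir, self.hairpin)
        if self.mir_star is not None:
            _validate_interval(f"{self.locus_id}.mir_star", self.mir_star, self.hairpin)
            if not _disjoint(self.mir_star, self.mir):
                raise CoordinateError(f"{self.locus_id}: mir_star overlaps mir")
        if self.loop is not None:
            _validate_interval(f"{self.locus_id}.loop", self.loop, self.hairpin)
            if not (_disjoint(self.loop, self.mir) and _disjoint(self.loop, self.mir_star)):
                raise CoordinateError(f"{self.locus_id}: loop overlaps mir/mir_star")
        if self.seed is None:
            # default convention: miR positions 2-8 (7 nt), counted from the
            # miR 5' end -- the right edge in stored coordinates on '-' strand
            if self.strand == "+":
                seed = (self.mir[0] + SEED_OFFSETS[0], self.mir[0] + SEED_OFFSETS[1])
            else:
                seed = (self.mir[1] - SEED_OFFSETS[1], self.mir[1] - SEED_OFFSETS[0])
            object.__setattr__(self, "seed", seed)
        _validate_interval(f"{self.locus_id}.seed", self.seed, self.mir)
        if self.expression_reads < 0:
            raise InputError(f"{self.locus_id}: negative expression_reads")
        if not isinstance(self.seed_family_presence, frozenset):
            object.__setattr__(
                self, "seed_family_presence", frozenset(self.seed_family_presence)
            )

    @property
    def hairpin_length(self) -> int:
        return self.hairpin[1] - self.hairpin[0]


@dataclass(frozen=True)
class StructureMap:
    """Dot-bracket pairing of the reference hairpin allele.

    ``partner[i]`` is the 0-based hairpin-local index paired with position
    ``i``, or None for unpaired positions.
    """

    locus_id: str
    dot_bracket: str
    partner: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        if len(self.partner) != len(self.dot_bracket):
            raise StructureError(f"{self.locus_id}: partner/dot-bracket length mismatch")
        for i, j in enumerate(self.partner):
            if j is None:
                continue
            if j == i or self.partner[j] != i:
                raise StructureError(f"{self.locus_id}: partner relation not involutive")

    def is_paired(self, i: int) -> bool:
        return self.partner[i] is not None


def parse_dot_bracket(text: str, locus_id: str = "") -> StructureMap:
    """Build a StructureMap from a dot-bracket string with a bracket stack."""
    partner: list[Optional[int]] = [None] * len(text)
    stack: list[int] = []
    for i, ch in enumerate(text):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"{locus_id}: unbalanced ')' at position {i}")
            j = stack.pop()
            partner[i] = j
            partner[j] = i
        elif ch != ".":
            raise StructureError(f"{locus_id}: illegal character {ch!r}")
    if stack:
        raise StructureError(f"{locus_id}: {len(stack)} unclosed '('")
    return StructureMap(locus_id, text, tuple(partner))


def reverse_structure(sm: StructureMap) -> StructureMap:
    """Structure of the reverse-complemented hairpin: string reversed with
    bracket sense swapped."""
    swapped = sm.dot_bracket.translate(str.maketrans("()", ")("))[::-1]
    return parse_dot_bracket(swapped, sm.locus_id)


# ---------------------------------------------------------------------------
# readers / writers


def read_locus_alignment(
    path: str | Path,
    outgroup_id: Optional[str] = None,
    delimiter: str = "|",
) -> LocusAlignment:
    """Read a per-locus multi-FASTA into a LocusAlignment.

    Headers follow ``strain<delimiter>population``; a record whose strain part
    equals ``outgroup_id`` becomes the outgroup sequence. Lowercase bases are
    normalized to uppercase.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: no FASTA records")
    locus_id = path.stem
    haps: list[Haplotype] = []
    outgroup: Optional[str] = None
    for rec in records:
        strain, _, pop = rec.id.partition(delimiter)
        seq = str(rec.seq).upper()
        if outgroup_id is not None and strain == outgroup_id:
            if outgroup is not None:
                raise InputError(f"{path}: multiple records match outgroup {outgroup_id}")
            outgroup = seq
        else:
            haps.append(Haplotype(strain, pop, seq))
    return LocusAlignment(locus_id, tuple(haps), outgroup)


def write_locus_alignment(
    aln: LocusAlignment,
    path: str | Path,
    outgroup_id: str = "outgroup",
    delimiter: str = "|",
) -> None:
    records = [
        SeqRecord(Seq(h.sequence), id=f"{h.strain_id}{delimiter}{h.population_id}", description="")
        for h in aln.haplotypes
    ]
    if aln.outgroup_sequence is not None:
        records.append(
            SeqRecord(Seq(aln.outgroup_sequence), id=f"{outgroup_id}{delimiter}outgroup", description="")
        )
    SeqIO.write(records, str(path), "fasta")


_ANNOTATION_COLUMNS = [
    "locus_id", "hairpin_start", "hairpin_end", "mir_start", "mir_end",
    "mirstar_start", "mirstar_end", "loop_start", "loop_end", "strand",
    "expression_reads", "seed_family_presence", "nearest_mirna_distance_bp",
]


def _opt_interval(row: dict, a: str, b: str) -> Optional[Interval]:
    sa, sb = row.get(a, ""), row.get(b, "")
    if sa == "" or sb == "":
        return None
    return (int(sa), int(sb))


def read_annotations(path: str | Path) -> dict[str, HairpinAnnotation]:
    """Read the hairpin annotation TSV into a map locus_id -> annotation."""
    import csv

    out: dict[str, HairpinAnnotation] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_ANNOTATION_COLUMNS[:5]) - set(reader.fieldnames or [])
        if missing:
            raise InputError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            row = {k: (v or "").strip() for k, v in row.items() if k is not None}
            locus = row["locus_id"]
            if locus in out:
                raise InputError(f"{path}: duplicate locus_id {locus}")
            presence = frozenset(
                s for s in row.get("seed_family_presence", "").split(",") if s
            )
            dist = row.get("nearest_mirna_distance_bp", "")
            out[locus] = HairpinAnnotation(
                locus_id=locus,
                hairpin=(int(row["hairpin_start"]), int(row["hairpin_end"])),
                mir=(int(row["mir_start"]), int(row["mir_end"])),
                mir_star=_opt_interval(row, "mirstar_start", "mirstar_end"),
                loop=_opt_interval(row, "loop_start", "loop_end"),
                strand=row.get("strand", "+") or "+",
                seed_family_presence=presence,
                expression_reads=int(row.get("expression_reads", "0") or 0),
                nearest_mirna_distance_bp=int(dist) if dist != "" else None,
            )
    return out


def write_annotations(anns: Iterable[HairpinAnnotation], path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_ANNOTATION_COLUMNS)
        for a in anns:
            def iv(x: Optional[Interval]) -> tuple:
                return ("", "") if x is None else x

            w.writerow(
                [a.locus_id, *a.hairpin, *a.mir, *iv(a.mir_star), *iv(a.loop),
                 a.strand, a.expression_reads,
                 ",".join(sorted(a.seed_family_presence)),
                 "" if a.nearest_mirna_distance_bp is None else a.nearest_mirna_distance_bp]
            )


def read_structures(path: str | Path) -> dict[str, StructureMap]:
    """Read two-line records (locus_id, dot-bracket) from a plain text file."""
    out: dict[str, StructureMap] = {}
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) % 2:
        raise InputError(f"{path}: odd number of non-empty lines")
    for i in range(0, len(lines), 2):
        locus = lines[i].lstrip(">")
        if locus in out:
            raise InputError(f"{path}: duplicate structure for {locus}")
        out[locus] = parse_dot_bracket(lines[i + 1], locus)
    return out


def write_structures(structs: Iterable[StructureMap], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sm in structs:
            fh.write(f">{sm.locus_id}\n{sm.dot_bracket}\n")


# ---------------------------------------------------------------------------
# orientation


def _flip_interval(iv: Optional[Interval], length: int) -> Optional[Interval]:
    if iv is None:
        return None
    return (length - iv[1], length - iv[0])


def orient_locus(
    aln: LocusAlignment, ann: HairpinAnnotation
) -> tuple[LocusAlignment, HairpinAnnotation]:
    """Return the alignment/annotation with the miRNA reading 5'->3' left to
    right. Identity on '+' strand; reverse-complement with coordinate flip
    (new_start = L - old_end) on '-'. The strand field records the genomic
    strand and is left unchanged, which makes the operation an involution on
    '-' loci; callers apply it exactly once before analysis."""
    if ann.strand == "+":
        return aln, ann
    L = aln.num_columns
    haps = tuple(
        Haplotype(h.strain_id, h.population_id, reverse_complement(h.sequence))
        for h in aln.haplotypes
    )
    out = None if aln.outgroup_sequence is None else reverse_complement(aln.outgroup_sequence)
    new_aln = LocusAlignment(aln.locus_id, haps, out)
    new_ann = dataclasses.replace(
        ann,
        hairpin=_flip_interval(ann.hairpin, L),
        mir=_flip_interval(ann.mir, L),
        mir_star=_flip_interval(ann.mir_star, L),
        loop=_flip_interval(ann.loop, L),
        seed=_flip_interval(ann.seed, L),
    )
    return new_aln, new_ann
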