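"""Column scanning of haplotype alignments into SNPs and indel events,
outgroup polarization, and site-frequency spectra.

Gap handling follows complete deletion: any alignment column containing a gap
in any ingroup haplotype is excluded from SNP calling and from the surveyed
length; gap runs are scored separately as indel events keyed by their carrier
set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import PolarizationError
from .seqdata import HairpinAnnotation, LocusAlignment

BASES = ("A", "C", "G", "T")


@dataclass
class SiteVariant:
    """One segregating alignment column.

    ``counts`` holds pooled ingroup base counts, ``pop_counts`` the same split
    by population. Context fields (domain, pairing, in_seed) are attached
    later by the domains module.
    """

    column: int
    counts: dict[str, int]
    pop_counts: dict[str, dict[str, int]]
    n_effective: int
    ancestral: Optional[str] = None
    derived_count: Optional[int] = None
    polarized: bool = False
    # structural / functional context, filled by domains.annotate_variant_context
    domain: Optional[str] = None
    pairing: Optional[str] = None
    in_seed: Optional[bool] = None

    @property
    def num_alleles(self) -> int:
        return len(self.counts)

    @property
    def is_biallelic(self) -> bool:
        return len(self.counts) == 2

    @property
    def minor_count(self) -> int:
        return self.n_effective - max(self.counts.values())

    @property
    def major_allele(self) -> str:
        # deterministic tie-break: higher count first, then base order
        return max(self.counts, key=lambda b: (self.counts[b], b))


@dataclass(frozen=True)
class IndelEvent:
    """A maximal run of consecutive gap columns shared by one carrier set."""

    start: int
    length: int
    carriers: frozenset[str]
    frequency: float
    overlaps: dict[str, bool] = field(hash=False, default_factory=dict)
    hairpin_fraction_removed: float = 0.0


@dataclass(frozen=True)
class SFSpectrum:
    """Site frequency spectrum over biallelic segregating sites.

    ``counts[i-1]`` is the number of sites with derived (unfolded) or minor
    (folded) allele count i; the unfolded spectrum runs 1..n-1, the folded
    1..floor(n/2).
    """

    mode: str  # "folded" | "unfolded"
    counts: tuple[int, ...]
    n: int

    @property
    def num_sites(self) -> int:
        return int(sum(self.counts))


def _seq_matrix(aln: LocusAlignment) -> np.ndarray:
    return np.array([list(h.sequence) for h in aln.haplotypes], dtype="U1")


def gap_free_columns(aln: LocusAlignment) -> np.ndarray:
    """Boolean mask of columns with no gap in any ingroup haplotype."""
    return ~(_seq_matrix(aln) == "-").any(axis=0)


def scan_sites(aln: LocusAlignment) -> tuple[list[SiteVariant], int]:
    """Scan alignment columns into SiteVariants.

    Returns (variants, surveyed_sites) where surveyed_sites counts the
    gap-free columns; a column is a variant iff >= 2 distinct bases are
    observed among ingroup haplotypes. Multiallelic columns yield a single
    variant.
    """
    mat = _seq_matrix(aln)
    mask = ~(mat == "-").any(axis=0)
    surveyed = int(mask.sum())
    pops = [h.population_id for h in aln.haplotypes]
    variants: list[SiteVariant] = []
    for col in np.nonzero(mask)[0]:
        column = mat[:, col]
        bases, cnts = np.unique(column, return_counts=True)
        if len(bases) < 2:
            continue
        counts = {str(b): int(c) for b, c in zip(bases, cnts)}
        pop_counts: dict[str, dict[str, int]] = {}
        for p, b in zip(pops, column):
            pop_counts.setdefault(p, {}).setdefault(str(b), 0)
            pop_counts[p][str(b)] += 1
        variants.append(
            SiteVariant(
                column=int(col),
                counts=counts,
                pop_counts=pop_counts,
                n_effective=aln.n,
            )
        )
    return variants, surveyed


def call_indel_events(
    aln: LocusAlignment, ann: Optional[HairpinAnnotation] = None
) -> list[IndelEvent]:
    """Group gap columns into events: one event per maximal run of consecutive
    gap columns sharing an identical carrier set. Overlap flags and the
    fraction of the hairpin removed are computed against the annotation when
    provided."""
    mat = _seq_matrix(aln)
    strains = [h.strain_id for h in aln.haplotypes]
    gap = mat == "-"
    events: list[IndelEvent] = []
    run_start = None
    run_carriers: Optional[frozenset[str]] = None
    for col in range(aln.num_columns + 1):
        carriers = (
            frozenset(s for s, g in zip(strains, gap[:, col]) if g)
            if col < aln.num_columns
            else frozenset()
        )
        if carriers != run_carriers or not carriers:
            if run_carriers:
                events.append(
                    _finish_event(run_start, col - run_start, run_carriers, aln.n, ann)
                )
            run_start = col if carriers else None
            run_carriers = carriers if carriers else None
    return events


def _interval_overlap(start: int, end: int, iv: Optional[tuple[int, int]]) -> int:
    if iv is None:
        return 0
    return max(0, min(end, iv[1]) - max(start, iv[0]))


def _finish_event(
    start: int,
    length: int,
    carriers: frozenset[str],
    n: int,
    ann: Optional[HairpinAnnotation],
) -> IndelEvent:
    end = start + length
    overlaps = {}
    frac = 0.0
    if ann is not None:
        overlaps = {
            "seed": _interval_overlap(start, end, ann.seed) > 0,
            "mir": _interval_overlap(start, end, ann.mir) > 0,
            "mir_star": _interval_overlap(start, end, ann.mir_star) > 0,
            "hairpin": _interval_overlap(start, end, ann.hairpin) > 0,
        }
        frac = _interval_overlap(start, end, ann.hairpin) / ann.hairpin_length
    return IndelEvent(
        start=start,
        length=length,
        carriers=carriers,
        frequency=len(carriers) / n,
        overlaps=overlaps,
        hairpin_fraction_removed=frac,
    )


def polarize_variants(
    variants: list[SiteVariant], aln: LocusAlignment
) -> list[SiteVariant]:
    """Assign ancestral/derived states from the outgroup base, in place.

    A variant polarizes iff the outgroup base at its column is a non-gap base
    equal to one of the observed ingroup alleles; otherwise (third allele,
    outgroup gap) the variant stays unpolarized and is excluded from unfolded
    analyses downstream.
    """
    if aln.outgroup_sequence is None:
        raise PolarizationError(f"{aln.locus_id}: no outgroup sequence")
    for v in variants:
        base = aln.outgroup_sequence[v.column]
        if base in v.counts:
            v.ancestral = base
            v.derived_count = v.n_effective - v.counts[base]
            v.polarized = True
        else:
            v.ancestral = None
            v.derived_count = None
            v.polarized = False
    return variants


def compute_sfs(variants: list[SiteVariant], n: int, mode: str) -> SFSpectrum:
    """Tally the site frequency spectrum over biallelic sites.

    Unfolded mode uses polarized biallelic variants only (counts indexed by
    derived allele count); folded mode uses all biallelic variants (minor
    allele count). Multiallelic sites never enter the spectrum.
    """
    if mode not in {"folded", "unfolded"}:
        raise ValueError(f"mode must be folded|unfolded, got {mode!r}")
    biallelic = [v for v in variants if v.is_biallelic]
    if mode == "unfolded":
        usable = [v for v in biallelic if v.polarized]
        if not usable and biallelic:
            warnings.warn(
                "unfolded SFS requested but no variant is polarized; "
                "returning an empty spectrum",
                stacklevel=2,
            )
        counts = np.zeros(n - 1, dtype=int)
        for v in usable:
            if 1 <= v.derived_count <= n - 1:
                counts[v.derived_count - 1] += 1
    else:
        counts = np.zeros(n // 2, dtype=int)
        for v in biallelic:
            mc = v.minor_count
            if 1 <= mc <= n // 2:
                counts[mc - 1] += 1
    return SFSpectrum(mode=mode, counts=tuple(int(c) for c in counts), n=n)
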