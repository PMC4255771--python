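"""Functional-domain partitioning of miRNA loci, variant context annotation,
per-domain and sliding-window statistics, the misannotation filter, and
seed-family conservation classification.

Domain vocabulary: per-column fine labels are flank_up / backbone / mir /
loop / mir_star / flank_down. Summary views add composites: "hairpin" (all
hairpin columns), "backbone" in the field's reporting sense (hairpin minus
the mature miR, i.e. including miR* and loop), the finer residual
"backbone_strict", "flank" (both flanks pooled), paired/unpaired (from the
reference structure), and "locus" (everything).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np
import pandas as pd

from .errors import StructureError
from .popstats import (
    DomainSummary,
    jc_divergence,
    nucleotide_diversity,
    snp_density,
    tajimas_d,
    watterson_theta,
)
from .seqdata import HairpinAnnotation, LocusAlignment, StructureMap
from .variants import SiteVariant, compute_sfs, scan_sites

FINE_LABELS = ("flank_up", "backbone", "mir", "loop", "mir_star", "flank_down")

SUMMARY_DOMAINS = (
    "mir", "mir_star", "loop", "backbone", "backbone_strict", "hairpin",
    "paired", "unpaired", "flank_up", "flank_down", "flank", "locus",
)


@dataclass(frozen=True)
class DomainPartition:
    """Per-column fine labels plus pairing status on hairpin columns."""

    locus_id: str
    labels: tuple[str, ...]
    hairpin: tuple[int, int]
    pairing: tuple[Optional[str], ...]  # per locus column; None outside hairpin

    @property
    def num_columns(self) -> int:
        return len(self.labels)

    def columns(self, domain: str) -> np.ndarray:
        """Locus-coordinate column indices belonging to a summary domain."""
        lab = np.array(self.labels)
        hp = np.zeros(len(lab), dtype=bool)
        hp[self.hairpin[0]: self.hairpin[1]] = True
        if domain == "locus":
            mask = np.ones(len(lab), dtype=bool)
        elif domain == "hairpin":
            mask = hp
        elif domain == "backbone":
            mask = hp & (lab != "mir")
        elif domain == "backbone_strict":
            mask = lab == "backbone"
        elif domain == "flank":
            mask = (lab == "flank_up") | (lab == "flank_down")
        elif domain in {"paired", "unpaired"}:
            pairing = np.array([p if p else "" for p in self.pairing])
            mask = pairing == domain
        elif domain in FINE_LABELS:
            mask = lab == domain
        else:
            raise ValueError(f"unknown domain {domain!r}")
        return np.nonzero(mask)[0]


def partition_domains(
    ann: HairpinAnnotation, struct: Optional[StructureMap], num_columns: int
) -> DomainPartition:
    """Assign each locus column its fine domain label, and each hairpin
    column its paired/unpaired status from the reference structure."""
    hs, he = ann.hairpin
    if he > num_columns:
        raise StructureError(f"{ann.locus_id}: hairpin extends past the alignment")
    if struct is not None and len(struct.dot_bracket) != he - hs:
        raise StructureError(
            f"{ann.locus_id}: structure length {len(struct.dot_bracket)} != "
            f"hairpin length {he - hs}"
        )
    labels = []
    for col in range(num_columns):
        if col < hs:
            labels.append("flank_up")
        elif col >= he:
            labels.append("flank_down")
        elif ann.mir[0] <= col < ann.mir[1]:
            labels.append("mir")
        elif ann.mir_star is not None and ann.mir_star[0] <= col < ann.mir_star[1]:
            labels.append("mir_star")
        elif ann.loop is not None and ann.loop[0] <= col < ann.loop[1]:
            labels.append("loop")
        else:
            labels.append("backbone")
    pairing: list[Optional[str]] = [None] * num_columns
    if struct is not None:
        for i in range(hs, he):
            pairing[i] = "paired" if struct.is_paired(i - hs) else "unpaired"
    return DomainPartition(
        locus_id=ann.locus_id,
        labels=tuple(labels),
        hairpin=ann.hairpin,
        pairing=tuple(pairing),
    )


def annotate_variant_context(
    variants: list[SiteVariant],
    partition: DomainPartition,
    ann: HairpinAnnotation,
) -> list[SiteVariant]:
    """Tag each variant with its column's domain label, pairing status
    (hairpin columns only), and seed membership, in place."""
    for v in variants:
        v.domain = partition.labels[v.column]
        v.pairing = partition.pairing[v.column]
        v.in_seed = ann.seed[0] <= v.column < ann.seed[1]
    return variants


def _restrict(sequences: Sequence[str], cols: np.ndarray) -> list[str]:
    return ["".join(s[c] for c in cols) for s in sequences]


def domain_summary_all(
    aln: LocusAlignment,
    partition: DomainPartition,
    reference_strain: Optional[str] = None,
    domains: Sequence[str] = SUMMARY_DOMAINS,
) -> list[DomainSummary]:
    """Per-domain S, pi, theta_W, SNP density for one locus; Tajima's D on
    the hairpin and whole-locus views (the SFS tests target the entire
    hairpin); Jukes-Cantor K to the outgroup when present.

    K uses a designated representative ingroup allele (``reference_strain``,
    defaulting to the first haplotype) against the outgroup, with pairwise
    deletion.
    """
    out: list[DomainSummary] = []
    ref_seq = aln.haplotypes[0].sequence
    if reference_strain is not None:
        match = [h for h in aln.haplotypes if h.strain_id == reference_strain]
        if match:
            ref_seq = match[0].sequence
    for domain in domains:
        cols = partition.columns(domain)
        if cols.size == 0:
            continue
        seqs = _restrict(aln.sequences(), cols)
        sub = LocusAlignment(aln.locus_id, tuple(
            type(aln.haplotypes[0])(h.strain_id, h.population_id, s)
            for h, s in zip(aln.haplotypes, seqs)
        ))
        variants, L = scan_sites(sub)
        S = len(variants)
        pi, pi_total = nucleotide_diversity(seqs)
        summary = DomainSummary(
            locus_id=aln.locus_id, domain=domain, n=aln.n, L=L, S=S, pi=pi
        )
        if L >= 1:
            summary.theta_w = watterson_theta(S, aln.n, L)
            summary.snp_density = snp_density(S, aln.n, L)
        if domain in {"hairpin", "locus"}:
            summary.tajima_D = tajimas_d(S, pi_total, aln.n)
        if aln.outgroup_sequence is not None:
            og = "".join(aln.outgroup_sequence[c] for c in cols)
            ref = "".join(ref_seq[c] for c in cols)
            try:
                summary.K_jc = jc_divergence(ref, og)
            except Exception:
                summary.K_jc = None
        out.append(summary)
    return out


# ---------------------------------------------------------------------------
# sliding windows


@dataclass(frozen=True)
class SlidingProfile:
    """Cross-locus average of windowed per-site values, indexed by window
    start relative to the first position of the mature miR."""

    value: str  # "pi" | "K"
    window: int
    step: int
    rows: pd.DataFrame  # columns: relative_start, mean_value, loci_count


def _locus_windows(
    aln: LocusAlignment,
    ann: HairpinAnnotation,
    value: str,
    window: int,
    step: int,
) -> list[tuple[int, float]]:
    """(relative_start, value) for every full window of one oriented locus,
    on a step grid anchored at the miR first position."""
    L = aln.num_columns
    mir_start = ann.mir[0]
    first = -(mir_start // step)  # smallest k with mir_start + k*step >= 0
    rows = []
    seqs = aln.sequences()
    for k in range(first, 10**9):
        start = mir_start + k * step
        if start + window > L:
            break
        cols = np.arange(start, start + window)
        if value == "pi":
            pi, _ = nucleotide_diversity(_restrict(seqs, cols))
            if pi is not None:
                rows.append((start - mir_start, pi))
        elif value == "K":
            if aln.outgroup_sequence is None:
                continue
            ref = "".join(aln.haplotypes[0].sequence[c] for c in cols)
            og = "".join(aln.outgroup_sequence[c] for c in cols)
            try:
                k_jc = jc_divergence(ref, og)
            except Exception:
                k_jc = None
            if k_jc is not None:
                rows.append((start - mir_start, k_jc))
        else:
            raise ValueError(f"value must be pi|K, got {value!r}")
    return rows


def sliding_profile(
    loci: Sequence[tuple[LocusAlignment, HairpinAnnotation]],
    value: str = "pi",
    window: int = 15,
    step: int = 5,
    min_loci: int = 10,
    min_neighbor_distance: int = 200,
) -> SlidingProfile:
    """Average windowed diversity (or divergence) across loci.

    Windows of ``window`` bp advance by ``step`` bp on a grid aligned to the
    first position of the mature miR; per relative start, the mean across
    contributing loci is retained only when at least ``min_loci`` loci
    contribute. Loci closer than ``min_neighbor_distance`` bp to their
    nearest miRNA neighbour are excluded so flanks are miRNA-free.
    """
    usable = [
        (aln, ann)
        for aln, ann in loci
        if ann.nearest_mirna_distance_bp is not None
        and ann.nearest_mirna_distance_bp > min_neighbor_distance
    ]
    acc: dict[int, list[float]] = {}
    for aln, ann in usable:
        for rel, val in _locus_windows(aln, ann, value, window, step):
            acc.setdefault(rel, []).append(val)
    if not usable:
        warnings.warn("no locus passes the neighbour-distance filter", stacklevel=2)
    rows = [
        (rel, float(np.mean(vals)), len(vals))
        for rel, vals in sorted(acc.items())
        if len(vals) >= min_loci
    ]
    df = pd.DataFrame(rows, columns=["relative_start", "mean_value", "loci_count"])
    return SlidingProfile(value=value, window=window, step=step, rows=df)


# ---------------------------------------------------------------------------
# filters and classification


def misannotation_flags(summaries: Sequence[DomainSummary]) -> dict[str, str]:
    """Flag loci whose hairpin diversity strictly exceeds flank diversity
    (candidate misannotations); loci without a usable flank are marked
    not-evaluable. Input is the pooled summary list across loci."""
    by_locus: dict[str, dict[str, DomainSummary]] = {}
    for s in summaries:
        by_locus.setdefault(s.locus_id, {})[s.domain] = s
    out: dict[str, str] = {}
    for locus, doms in by_locus.items():
        hp = doms.get("hairpin")
        fl = doms.get("flank")
        if hp is None or fl is None or hp.pi is None or fl.pi is None or fl.L == 0:
            out[locus] = "not_evaluable"
        elif hp.pi > fl.pi:
            out[locus] = "flagged"
        else:
            out[locus] = "ok"
    return out


def classify_conservation(ann: HairpinAnnotation, scheme: str = "strict") -> str:
    """Seed-family conservation class.

    strict: "unique" iff no other species shares the seed family, else
    "conserved". relaxed: "low" iff shared with at most one other species,
    else "high".
    """
    k = len(ann.seed_family_presence)
    if scheme == "strict":
        return "unique" if k == 0 else "conserved"
    if scheme == "relaxed":
        return "low" if k <= 1 else "high"
    raise ValueError(f"unknown scheme {scheme!r}")
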