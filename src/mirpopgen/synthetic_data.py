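"""Desk-scale synthetic datasets with the selective architecture the analysis
expects: multi-population haplotype samples at miRNA-like loci, strong
diversity suppression inside the hairpin (strongest in the mature miR), an
outgroup at a few percent divergence, and optional injected seed SNPs or
domain-ablating deletions.

The generator is coalescent-based: one genealogy per locus spans all
populations (no recombination within a locus, no migration after population
splits), and purifying selection is emulated by thinning the mutation rate
per functional domain (multipliers on a neutral flank rate) rather than by
explicit fitness - enough to reproduce the diversity-suppression signature
while staying analytically checkable. Every dataset ships a truth table with
the realized per-domain mutation counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigError
from .seqdata import (
    Haplotype,
    HairpinAnnotation,
    LocusAlignment,
    StructureMap,
    parse_dot_bracket,
    write_annotations,
    write_locus_alignment,
    write_structures,
)

_BASES = np.array(list("ACGT"))

OUTGROUP_ID = "OUTG"

DOMAIN_NAMES = ("flank_up", "backbone5", "mir", "loop", "mir_star", "backbone3", "flank_down")


@dataclass(frozen=True)
class HairpinGeometry:
    """Segment lengths (bp) of the simulated locus, 5' to 3'. The hairpin is
    backbone5 + mir + loop + mir_star + backbone3."""

    flank_up: int = 200
    backbone5: int = 10
    mir: int = 22
    loop: int = 15
    mir_star: int = 22
    backbone3: int = 10
    flank_down: int = 200

    def __post_init__(self) -> None:
        for name in DOMAIN_NAMES:
            if getattr(self, name) < 1:
                raise ConfigError(f"geometry segment {name} must be >= 1 bp")

    @property
    def locus_length(self) -> int:
        return sum(getattr(self, n) for n in DOMAIN_NAMES)

    @property
    def hairpin_length(self) -> int:
        return self.backbone5 + self.mir + self.loop + self.mir_star + self.backbone3

    def segments(self) -> dict[str, tuple[int, int]]:
        """Locus-coordinate interval of each segment."""
        out = {}
        pos = 0
        for name in DOMAIN_NAMES:
            ln = getattr(self, name)
            out[name] = (pos, pos + ln)
            pos += ln
        return out


@dataclass(frozen=True)
class EventSpec:
    """An injected variant: a seed SNP or a deletion, carried at a target
    frequency within one population."""

    locus: int
    kind: str  # "seed_snp" | "deletion"
    population: str
    frequency: float
    position: Optional[int] = None  # seed_snp: offset within the seed (default 2)
    start: Optional[int] = None  # deletion: locus-coordinate start
    length: int = 14  # deletion length

    def __post_init__(self) -> None:
        if self.kind not in {"seed_snp", "deletion"}:
            raise ConfigError(f"unknown event kind {self.kind!r}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ConfigError("event frequency must be in [0, 1]")


def _default_multipliers() -> dict[str, float]:
    return {"mir": 0.05, "mir_star": 0.1, "backbone": 0.3, "loop": 0.6, "flank": 1.0}


def _default_pops() -> dict[str, int]:
    return {"OH": 10, "ON": 9, "DE": 10}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for dataset generation.

    Defaults emulate the sampling design the pipeline is built for: 129 loci
    of ~480 bp (79 bp hairpin with ~200 bp flanks), three populations of
    10/9/10 haplotypes, a neutral flank diversity of 4% per site, domain
    mutation multipliers producing ~20x suppression in the mature miR, and an
    outgroup branch at 4% per-site divergence (also domain-thinned).
    """

    num_loci: int = 129
    n_per_population: dict[str, int] = field(default_factory=_default_pops)
    # population i (ordered, i >= 1) joins the ancestral pool at split_times[i-1]
    split_times: tuple[float, ...] = (0.2, 0.4)
    theta_flank: float = 0.04
    domain_multipliers: dict[str, float] = field(default_factory=_default_multipliers)
    outgroup_divergence: float = 0.04
    geometry: HairpinGeometry = field(default_factory=HairpinGeometry)
    injected_events: tuple[EventSpec, ...] = ()
    # locus index -> weight multiplier on external branches during mutation
    # placement; a caricature used to produce skewed-SFS loci, not a model
    branch_bias: dict[int, float] = field(default_factory=dict)
    conserved_fraction: float = 105 / 129
    distant_fraction: float = 95 / 129
    seed: int = 0
    locus_prefix: str = "synmir"

    def __post_init__(self) -> None:
        if self.num_loci < 0:
            raise ConfigError("num_loci must be >= 0")
        if not self.n_per_population or any(v < 2 for v in self.n_per_population.values()):
            raise ConfigError("each population needs >= 2 haplotypes")
        if len(self.split_times) != len(self.n_per_population) - 1:
            raise ConfigError("need one split time per population after the first")
        if any(t < 0 for t in self.split_times) or list(self.split_times) != sorted(
            self.split_times
        ):
            raise ConfigError("split_times must be non-negative and non-decreasing")
        if self.theta_flank <= 0:
            raise ConfigError("theta_flank must be > 0")
        if any(m <= 0 for m in self.domain_multipliers.values()):
            raise ConfigError("domain multipliers must be > 0")
        if self.outgroup_divergence < 0:
            raise ConfigError("outgroup_divergence must be >= 0")

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(self.n_per_population)

    @property
    def n_total(self) -> int:
        return sum(self.n_per_population.values())

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (frozenset, set, tuple)):
                return list(o)
            raise TypeError(type(o))

        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=enc)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def locus_id(self, index: int) -> str:
        return f"{self.locus_prefix}-{index + 1:03d}"


# ---------------------------------------------------------------------------
# genealogy across populations


@dataclass(frozen=True)
class _SimBranch:
    mask: np.ndarray  # boolean carriers, length n_total
    birth: float
    death: float

    @property
    def length(self) -> float:
        return self.death - self.birth

    @property
    def is_external(self) -> bool:
        return int(self.mask.sum()) == 1


def _structured_genealogy(
    ns: list[int], split_times: tuple[float, ...], rng: np.random.Generator
) -> list[_SimBranch]:
    """Coalescent genealogy over populations that merge (backward in time)
    into the first population's ancestral pool at the given split times."""
    n_tot = sum(ns)
    groups: list[list[tuple[np.ndarray, float]]] = []
    leaf = 0
    for n in ns:
        group = []
        for _ in range(n):
            mask = np.zeros(n_tot, dtype=bool)
            mask[leaf] = True
            group.append((mask, 0.0))
            leaf += 1
        groups.append(group)
    schedule = [(t, i + 1) for i, t in enumerate(split_times)]
    branches: list[_SimBranch] = []
    t = 0.0

    def coalesce(group: list, when: float) -> None:
        k = len(group)
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        (m_i, b_i), (m_j, b_j) = group[i], group[j]
        branches.append(_SimBranch(m_i, b_i, when))
        branches.append(_SimBranch(m_j, b_j, when))
        for idx in sorted((i, j), reverse=True):
            group.pop(idx)
        group.append((m_i | m_j, when))

    for epoch_end, merge_pop in schedule + [(math.inf, None)]:
        while True:
            waits = []
            for gi, group in enumerate(groups):
                k = len(group)
                if k >= 2:
                    waits.append((rng.exponential(2.0 / (k * (k - 1))), gi))
            if not waits:
                t = epoch_end if math.isfinite(epoch_end) else t
                break
            wait, gi = min(waits)
            if t + wait >= epoch_end:
                t = epoch_end
                break
            t += wait
            coalesce(groups[gi], t)
        if merge_pop is not None:
            groups[0].extend(groups[merge_pop])
            groups[merge_pop] = []
    # root lineage remains in groups[0]; its (absent) parent branch is dropped
    return branches


# ---------------------------------------------------------------------------
# per-locus generation


def _column_multipliers(cfg: SyntheticConfig) -> np.ndarray:
    seg = cfg.geometry.segments()
    mult = np.empty(cfg.geometry.locus_length)
    m = cfg.domain_multipliers
    per_segment = {
        "flank_up": m["flank"],
        "backbone5": m["backbone"],
        "mir": m["mir"],
        "loop": m["loop"],
        "mir_star": m["mir_star"],
        "backbone3": m["backbone"],
        "flank_down": m["flank"],
    }
    for name, (s, e) in seg.items():
        mult[s:e] = per_segment[name]
    return mult


def _build_structure(geom: HairpinGeometry, locus_id: str) -> StructureMap:
    """Dot-bracket for the simulated hairpin: the two stems (backbone5+mir vs
    mir_star+backbone3) pair position-wise outside-in, the loop and any
    stem-length excess stay unpaired."""
    L5 = geom.backbone5 + geom.mir
    L3 = geom.mir_star + geom.backbone3
    k = min(L5, L3)
    db = "(" * k + "." * (L5 - k) + "." * geom.loop + "." * (L3 - k) + ")" * k
    return parse_dot_bracket(db, locus_id)


def _apply_mutations(
    seqs: np.ndarray,
    branches: list[_SimBranch],
    lam_per_column: np.ndarray,
    bias: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Drop Poisson mutations column by column onto the genealogy, oldest
    first so that nested branch overwrites resolve correctly. Returns the
    per-column mutation counts (realized)."""
    lengths = np.array([b.length for b in branches])
    total = lengths.sum()
    weights = lengths.copy()
    if bias != 1.0:
        ext = np.array([b.is_external for b in branches])
        weights[ext] *= bias
    cum = np.cumsum(weights)
    counts = rng.poisson(lam_per_column * total / 2.0)
    for col in np.nonzero(counts)[0]:
        k = int(counts[col])
        picks = np.searchsorted(cum, rng.random(k) * cum[-1], side="right")
        picks = np.minimum(picks, len(branches) - 1)
        times = [
            branches[b].birth + rng.random() * branches[b].length for b in picks
        ]
        for b_idx in [p for _, p in sorted(zip(times, picks), reverse=True)]:
            br = branches[int(b_idx)]
            carrier = int(np.nonzero(br.mask)[0][0])
            cur = seqs[carrier, col]
            new = int((cur + 1 + rng.integers(3)) % 4)
            seqs[br.mask, col] = new
    return counts


def generate_locus(
    cfg: SyntheticConfig,
    locus_index: int,
    rng: Optional[np.random.Generator] = None,
) -> tuple[LocusAlignment, HairpinAnnotation, StructureMap, dict]:
    """Simulate one locus: genealogy, domain-thinned mutations, outgroup,
    structure, annotation metadata, and injected events. Returns the truth
    record alongside the data objects."""
    if rng is None:
        rng = np.random.default_rng([cfg.seed, locus_index])
    geom = cfg.geometry
    L = geom.locus_length
    pops = list(cfg.n_per_population)
    ns = [cfg.n_per_population[p] for p in pops]
    n_tot = sum(ns)
    branches = _structured_genealogy(ns, cfg.split_times, rng)

    anc = rng.integers(4, size=L)
    seqs = np.tile(anc, (n_tot, 1))
    mult = _column_multipliers(cfg)
    bias = cfg.branch_bias.get(locus_index, 1.0)
    mut_counts = _apply_mutations(seqs, branches, cfg.theta_flank * mult, bias, rng)

    # outgroup: substitutions on its own branch from the ancestral sequence,
    # thinned by the same domain multipliers (constraint acts there too)
    og = anc.copy()
    og_counts = rng.poisson(cfg.outgroup_divergence * mult)
    for col in np.nonzero(og_counts)[0]:
        for _ in range(int(og_counts[col])):
            og[col] = (og[col] + 1 + rng.integers(3)) % 4

    seg = geom.segments()
    locus_id = cfg.locus_id(locus_index)
    hairpin = (seg["backbone5"][0], seg["backbone3"][1])

    conserved = rng.random() < cfg.conserved_fraction
    presence = (
        frozenset(
            rng.choice(["elegans", "briggsae", "brenneri"], size=int(rng.integers(1, 4)), replace=False)
        )
        if conserved
        else frozenset()
    )
    # conserved miRNAs are more highly expressed (lognormal read counts)
    expression = int(rng.lognormal(7.0 if conserved else 5.0, 1.5))
    distant = rng.random() < cfg.distant_fraction
    neighbor = int(rng.integers(250, 5000)) if distant else int(rng.integers(0, 200))

    ann = HairpinAnnotation(
        locus_id=locus_id,
        hairpin=hairpin,
        mir=seg["mir"],
        mir_star=seg["mir_star"],
        loop=seg["loop"],
        strand="+",
        seed_family_presence=presence,
        expression_reads=expression,
        nearest_mirna_distance_bp=neighbor,
    )
    struct = _build_structure(geom, locus_id)

    base_seqs = ["".join(_BASES[row]) for row in seqs]
    haps = []
    idx = 0
    for p, n in zip(pops, ns):
        for i in range(n):
            haps.append(Haplotype(f"{p}{i + 1:02d}", p, base_seqs[idx]))
            idx += 1
    aln = LocusAlignment(locus_id, tuple(haps), "".join(_BASES[og]))

    events_applied = []
    for ev in cfg.injected_events:
        if ev.locus == locus_index:
            aln = inject_event(aln, ann, ev, rng)
            events_applied.append(ev)

    per_domain = {
        name: int(mut_counts[s:e].sum()) for name, (s, e) in seg.items()
    }
    truth = {
        "locus_id": locus_id,
        "mutations_total": int(mut_counts.sum()),
        "outgroup_substitutions": int(og_counts.sum()),
        "per_domain_mutations": per_domain,
        "branch_total_length": float(sum(b.length for b in branches)),
        "events": [dataclasses.asdict(e) for e in events_applied],
        "conserved": bool(conserved),
    }
    return aln, ann, struct, truth


def inject_event(
    aln: LocusAlignment,
    ann: HairpinAnnotation,
    spec: EventSpec,
    rng: Optional[np.random.Generator] = None,
) -> LocusAlignment:
    """Apply a seed SNP or deletion to ceil(frequency * n_pop) haplotypes of
    the named population."""
    if rng is None:
        rng = np.random.default_rng(0)
    pop_members = [i for i, h in enumerate(aln.haplotypes) if h.population_id == spec.population]
    if not pop_members:
        raise ConfigError(f"population {spec.population!r} absent from {aln.locus_id}")
    k = math.ceil(spec.frequency * len(pop_members))
    if k == 0:
        return aln
    carriers = pop_members[:k]
    seqs = [list(h.sequence) for h in aln.haplotypes]
    if spec.kind == "seed_snp":
        offset = 2 if spec.position is None else spec.position
        col = ann.seed[0] + offset
        if not (ann.hairpin[0] <= col < ann.hairpin[1]):
            raise ConfigError(f"seed_snp column {col} outside hairpin")
        current = seqs[carriers[0]][col]
        alternatives = [b for b in "ACGT" if b != current]
        new = alternatives[int(rng.integers(3))]
        for c in carriers:
            seqs[c][col] = new
    else:  # deletion
        start = spec.start if spec.start is not None else ann.seed[0] - 3
        end = start + spec.length
        if start < 0 or end > aln.num_columns:
            raise ConfigError(f"deletion [{start},{end}) outside locus")
        if end <= ann.hairpin[0] or start >= ann.hairpin[1]:
            raise ConfigError("deletion target outside hairpin")
        for c in carriers:
            for col in range(start, end):
                seqs[c][col] = "-"
    haps = tuple(
        Haplotype(h.strain_id, h.population_id, "".join(s))
        for h, s in zip(aln.haplotypes, seqs)
    )
    return LocusAlignment(aln.locus_id, haps, aln.outgroup_sequence)


# ---------------------------------------------------------------------------
# dataset output


def generate_dataset(
    cfg: SyntheticConfig, out_dir: str | Path, overwrite: bool = False
) -> dict:
    """Generate the full dataset under ``out_dir``: per-locus FASTA files, an
    annotation TSV, a structure file, a truth table, and a manifest. Returns
    the manifest dict."""
    import csv

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise ConfigError(f"{out} exists and is not empty; pass overwrite=True")
    (out / "alignments").mkdir(parents=True, exist_ok=True)

    anns, structs, truths = [], [], []
    files = []
    for i in range(cfg.num_loci):
        aln, ann, struct, truth = generate_locus(cfg, i)
        fa = out / "alignments" / f"{aln.locus_id}.fa"
        write_locus_alignment(aln, fa, outgroup_id=OUTGROUP_ID)
        files.append(str(fa.relative_to(out)))
        anns.append(ann)
        structs.append(struct)
        truths.append(truth)

    write_annotations(anns, out / "annotations.tsv")
    write_structures(structs, out / "structures.txt")

    with open(out / "truth.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["locus_id", "mutations_total", "outgroup_substitutions",
             "branch_total_length", "conserved", "per_domain_mutations", "events"]
        )
        for t in truths:
            w.writerow(
                [t["locus_id"], t["mutations_total"], t["outgroup_substitutions"],
                 f"{t['branch_total_length']:.6f}", int(t["conserved"]),
                 json.dumps(t["per_domain_mutations"]), json.dumps(t["events"])]
            )

    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "num_loci": cfg.num_loci,
        "populations": dict(cfg.n_per_population),
        "outgroup_id": OUTGROUP_ID,
        "alignments": files,
        "annotations": "annotations.tsv",
        "structures": "structures.txt",
        "truth": "truth.tsv",
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
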