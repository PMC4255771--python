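"""End-to-end orchestration: read a dataset directory, orient loci, call and
polarize variants, partition domains, compute per-domain statistics,
neutrality tests against coalescent nulls with FDR adjustment, F_ST,
sliding-window profiles, conservation classes, the misannotation filter, and
group contrasts - emitted as a bundle of TSV tables.

Neutrality nulls are conditioned on the observed segregating-site count and
cached by (statistic, n, S, replicates) within a run, so loci sharing a
configuration share one null distribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .coalsim import null_pvalue, sample_null_statistics
from .domains import (
    SUMMARY_DOMAINS,
    annotate_variant_context,
    classify_conservation,
    domain_summary_all,
    misannotation_flags,
    partition_domains,
    sliding_profile,
)
from .errors import InputError
from .popstats import (
    bh_adjust,
    faywu_h_normalized,
    hudson_fst,
    nucleotide_diversity,
    tajimas_d,
)
from .seqdata import (
    Haplotype,
    LocusAlignment,
    orient_locus,
    read_annotations,
    read_locus_alignment,
    read_structures,
)
from .variants import compute_sfs, call_indel_events, polarize_variants, scan_sites

logger = logging.getLogger("mirpopgen")


@dataclass
class PipelineConfig:
    dataset_dir: Path
    seed: int = 0
    q: float = 0.05
    replicates_D: int = 50_000
    replicates_H: int = 10_000
    neutrality_population: Optional[str] = "OH"
    window: int = 15
    step: int = 5
    min_loci: int = 10
    min_neighbor_distance: int = 200
    conservation_scheme: str = "strict"


@dataclass
class ReportBundle:
    """All output tables of one pipeline run plus run metadata."""

    domain_stats: pd.DataFrame
    variant_context: pd.DataFrame
    indel_events: pd.DataFrame
    neutrality: pd.DataFrame
    fst: pd.DataFrame
    profiles: dict[str, pd.DataFrame]
    conservation: pd.DataFrame
    misannotation: pd.DataFrame
    contrasts: pd.DataFrame
    exclusions: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = "# " + json.dumps(self.metadata, sort_keys=True) + "\n"
        tables = {
            "domain_stats.tsv": self.domain_stats,
            "variant_context.tsv": self.variant_context,
            "indel_events.tsv": self.indel_events,
            "neutrality.tsv": self.neutrality,
            "fst.tsv": self.fst,
            "conservation.tsv": self.conservation,
            "misannotation.tsv": self.misannotation,
            "contrasts.tsv": self.contrasts,
            "exclusions.tsv": self.exclusions,
        }
        for name, df in self.profiles.items():
            tables[f"profile_{name}.tsv"] = df
        for name, df in tables.items():
            with open(out / name, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _load_dataset(cfg: PipelineConfig):
    root = Path(cfg.dataset_dir)
    manifest_path = root / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        aln_files = [root / f for f in manifest["alignments"]]
        outgroup_id = manifest.get("outgroup_id")
        ann_file = root / manifest.get("annotations", "annotations.tsv")
        struct_file = root / manifest.get("structures", "structures.txt")
    else:
        aln_dir = root / "alignments" if (root / "alignments").is_dir() else root
        aln_files = sorted(aln_dir.glob("*.fa"))
        outgroup_id = None
        ann_file = root / "annotations.tsv"
        struct_file = root / "structures.txt"
        manifest = None
    if not aln_files:
        raise InputError(f"{root}: no alignments found (empty dataset?)")
    if not ann_file.exists():
        raise InputError(f"{root}: missing annotation table {ann_file.name}")
    anns = read_annotations(ann_file)
    structs = read_structures(struct_file) if struct_file.exists() else {}
    return aln_files, outgroup_id, anns, structs, manifest


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    rng = np.random.default_rng(cfg.seed)
    aln_files, outgroup_id, anns, structs, manifest = _load_dataset(cfg)

    domain_rows, variant_rows, indel_rows, neut_rows, fst_rows = [], [], [], [], []
    cons_rows, excl_rows = [], []
    all_summaries = []
    profile_loci = []
    per_locus_stats: dict[str, dict] = {}
    null_cache: dict[tuple, np.ndarray] = {}

    def cached_null(stat: str, n: int, S: int, reps: int) -> np.ndarray:
        key = (stat, n, S, reps)
        if key not in null_cache:
            null_cache[key] = sample_null_statistics(stat, n, S, reps, rng)
        return null_cache[key]

    for path in aln_files:
        locus = Path(path).stem
        try:
            aln = read_locus_alignment(path, outgroup_id=outgroup_id)
        except Exception as exc:  # malformed file: log and move on
            excl_rows.append({"locus_id": locus, "stage": "read", "reason": str(exc)})
            continue
        ann = anns.get(locus)
        if ann is None:
            excl_rows.append({"locus_id": locus, "stage": "annotate", "reason": "no annotation"})
            continue
        aln, ann = orient_locus(aln, ann)
        struct = structs.get(locus)
        if struct is None:
            logger.info("%s: no structure; pairing analyses skipped", locus)
            excl_rows.append({"locus_id": locus, "stage": "structure",
                              "reason": "no structure (pairing views skipped)"})
        partition = partition_domains(ann, struct, aln.num_columns)

        variants, surveyed = scan_sites(aln)
        if aln.outgroup_sequence is not None:
            polarize_variants(variants, aln)
        annotate_variant_context(variants, partition, ann)
        for v in variants:
            row = {
                "locus_id": locus, "column": v.column + 1, "n_effective": v.n_effective,
                "alleles": "/".join(sorted(v.counts)),
                "counts": "/".join(str(v.counts[b]) for b in sorted(v.counts)),
                "ancestral": v.ancestral or "", "polarized": v.polarized,
                "derived_count": "" if v.derived_count is None else v.derived_count,
                "minor_count": v.minor_count, "domain": v.domain,
                "pairing": v.pairing or "", "in_seed": bool(v.in_seed),
            }
            for pop in aln.populations:
                pc = v.pop_counts.get(pop, {})
                npop = sum(pc.values())
                minor = v.major_allele  # pooled major; report its complement freq
                row[f"freq_nonmajor_{pop}"] = (
                    round(1 - pc.get(minor, 0) / npop, 4) if npop else ""
                )
            variant_rows.append(row)

        events = call_indel_events(aln, ann)
        for ev in events:
            indel_rows.append({
                "locus_id": locus, "start": ev.start + 1, "length": ev.length,
                "num_carriers": len(ev.carriers), "frequency": round(ev.frequency, 4),
                "carriers": ",".join(sorted(ev.carriers)),
                "overlaps_seed": ev.overlaps.get("seed", False),
                "overlaps_mir": ev.overlaps.get("mir", False),
                "overlaps_mir_star": ev.overlaps.get("mir_star", False),
                "overlaps_hairpin": ev.overlaps.get("hairpin", False),
                "hairpin_fraction_removed": round(ev.hairpin_fraction_removed, 4),
            })

        summaries = domain_summary_all(aln, partition)
        all_summaries.extend(summaries)
        for s in summaries:
            domain_rows.append(vars(s).copy())
        per_locus_stats[locus] = {s.domain: s for s in summaries}

        # neutrality on the entire hairpin, in the reference population sample
        test_aln = aln
        if cfg.neutrality_population and cfg.neutrality_population in aln.populations:
            test_aln = aln.subset(cfg.neutrality_population)
        hp_cols = partition.columns("hairpin")
        hp_aln = LocusAlignment(locus, tuple(
            Haplotype(h.strain_id, h.population_id, "".join(h.sequence[c] for c in hp_cols))
            for h in test_aln.haplotypes
        ), None if test_aln.outgroup_sequence is None else
            "".join(test_aln.outgroup_sequence[c] for c in hp_cols))
        hp_variants, hp_L = scan_sites(hp_aln)
        S_hp = len(hp_variants)
        neut_row = {"locus_id": locus, "n": hp_aln.n, "L": hp_L, "S": S_hp,
                    "D": "", "p_D": "", "H": "", "p_H": ""}
        if S_hp >= 1 and hp_aln.n >= 4:
            _, pi_total = nucleotide_diversity(hp_aln.sequences())
            D = tajimas_d(S_hp, pi_total, hp_aln.n)
            res = null_pvalue("D", D, hp_aln.n, S_hp, cfg.replicates_D, rng,
                              null_sample=cached_null("D", hp_aln.n, S_hp, cfg.replicates_D))
            neut_row["D"] = D
            neut_row["p_D"] = res.p
            if hp_aln.outgroup_sequence is not None:
                polarize_variants(hp_variants, hp_aln)
                sfs = compute_sfs(hp_variants, hp_aln.n, "unfolded")
                S_pol = sfs.num_sites
                if S_pol >= 1:
                    h = faywu_h_normalized(sfs)
                    if h is not None:
                        resH = null_pvalue(
                            "H", h[0], hp_aln.n, S_pol, cfg.replicates_H, rng,
                            null_sample=cached_null("H", hp_aln.n, S_pol, cfg.replicates_H))
                        neut_row["H"] = h[0]
                        neut_row["p_H"] = resH.p
        neut_rows.append(neut_row)

        # F_ST over the entire hairpin
        if len(aln.populations) >= 2:
            groups = {
                p: ["".join(h.sequence[c] for c in hp_cols)
                    for h in aln.haplotypes if h.population_id == p]
                for p in aln.populations
            }
            groups = {p: seqs for p, seqs in groups.items() if len(seqs) >= 2}
            if len(groups) >= 2:
                f = hudson_fst(groups)
                fst_rows.append({"locus_id": locus,
                                 "fst": "" if f is None else f,
                                 "populations": ",".join(groups)})

        cons_rows.append({
            "locus_id": locus,
            "class_strict": classify_conservation(ann, "strict"),
            "class_relaxed": classify_conservation(ann, "relaxed"),
            "expression_reads": ann.expression_reads,
        })
        profile_loci.append((aln, ann))

    # BH adjustment across loci, D and H families separately
    neut = pd.DataFrame(neut_rows)
    for col in ("p_D", "p_H"):
        pvals = pd.to_numeric(neut[col], errors="coerce") if len(neut) else pd.Series(dtype=float)
        mask = pvals.notna()
        adj = pd.Series([""] * len(neut), dtype=object)
        rej = pd.Series([""] * len(neut), dtype=object)
        if mask.any():
            r, a = bh_adjust(pvals[mask].to_numpy(), cfg.q)
            adj[mask.to_numpy()] = a
            rej[mask.to_numpy()] = r
        neut[col + "_bh"] = adj
        neut[col.replace("p_", "reject_")] = rej

    profiles = {}
    prof_pi = sliding_profile(profile_loci, "pi", cfg.window, cfg.step,
                              cfg.min_loci, cfg.min_neighbor_distance)
    profiles["pi"] = prof_pi.rows
    has_outgroup = any(a.outgroup_sequence is not None for a, _ in profile_loci)
    if has_outgroup:
        profiles["K"] = sliding_profile(profile_loci, "K", cfg.window, cfg.step,
                                        cfg.min_loci, cfg.min_neighbor_distance).rows

    flags = misannotation_flags(all_summaries)
    mis = pd.DataFrame(
        [{"locus_id": k, "flag": v} for k, v in sorted(flags.items())]
    )

    cons = pd.DataFrame(cons_rows)
    contrasts = _group_contrasts(cons, per_locus_stats)

    domain_stats = pd.DataFrame(domain_rows)
    metadata = {
        "seed": cfg.seed,
        "version": __version__,
        "replicates_D": cfg.replicates_D,
        "replicates_H": cfg.replicates_H,
        "q": cfg.q,
        "num_loci": len(aln_files),
        "config_hash": (manifest or {}).get("config_hash", ""),
    }
    return ReportBundle(
        domain_stats=domain_stats,
        variant_context=pd.DataFrame(variant_rows),
        indel_events=pd.DataFrame(indel_rows),
        neutrality=neut,
        fst=pd.DataFrame(fst_rows),
        profiles=profiles,
        conservation=cons,
        misannotation=mis,
        contrasts=contrasts,
        exclusions=pd.DataFrame(excl_rows, columns=["locus_id", "stage", "reason"]),
        metadata=metadata,
    )


def _group_contrasts(cons: pd.DataFrame, per_locus: dict[str, dict]) -> pd.DataFrame:
    """Rank-based group contrasts: hairpin diversity and expression between
    conservation classes, and the expression-diversity rank correlation."""
    rows = []
    if cons.empty:
        return pd.DataFrame(columns=["contrast", "statistic", "p_value", "n1", "n2"])
    pi_hairpin = {
        k: d["hairpin"].pi for k, d in per_locus.items()
        if "hairpin" in d and d["hairpin"].pi is not None
    }
    cons = cons.set_index("locus_id")
    for scheme, (lo, hi) in {"class_strict": ("unique", "conserved"),
                             "class_relaxed": ("low", "high")}.items():
        a = [pi_hairpin[k] for k in pi_hairpin if cons.loc[k, scheme] == lo]
        b = [pi_hairpin[k] for k in pi_hairpin if cons.loc[k, scheme] == hi]
        if len(a) >= 2 and len(b) >= 2:
            st = sps.mannwhitneyu(a, b, alternative="two-sided")
            rows.append({"contrast": f"pi_hairpin:{lo}_vs_{hi}",
                         "statistic": st.statistic, "p_value": st.pvalue,
                         "n1": len(a), "n2": len(b)})
        ea = cons.loc[cons[scheme] == lo, "expression_reads"].to_numpy()
        eb = cons.loc[cons[scheme] == hi, "expression_reads"].to_numpy()
        if len(ea) >= 2 and len(eb) >= 2:
            st = sps.mannwhitneyu(ea, eb, alternative="two-sided")
            rows.append({"contrast": f"expression:{lo}_vs_{hi}",
                         "statistic": st.statistic, "p_value": st.pvalue,
                         "n1": len(ea), "n2": len(eb)})
    common = [k for k in pi_hairpin if k in cons.index]
    if len(common) >= 3:
        rho, p = sps.spearmanr(
            [cons.loc[k, "expression_reads"] for k in common],
            [pi_hairpin[k] for k in common],
        )
        rows.append({"contrast": "spearman_expression_vs_pi_hairpin",
                     "statistic": rho, "p_value": p,
                     "n1": len(common), "n2": len(common)})
    return pd.DataFrame(rows, columns=["contrast", "statistic", "p_value", "n1", "n2"])
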