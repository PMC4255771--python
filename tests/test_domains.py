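import numpy as np
import pytest

from conftest import make_alignment
from mirpopgen.domains import (
    annotate_variant_context,
    classify_conservation,
    domain_summary_all,
    misannotation_flags,
    partition_domains,
    sliding_profile,
)
from mirpopgen.popstats import DomainSummary, nucleotide_diversity
from mirpopgen.seqdata import HairpinAnnotation, parse_dot_bracket
from mirpopgen.synthetic_data import SyntheticConfig, generate_locus
from mirpopgen.variants import scan_sites


def full_annotation(L=120):
    return HairpinAnnotation(
        "m", hairpin=(10, 110), mir=(20, 42), mir_star=(70, 92), loop=(50, 65),
    )


class TestPartition:
    def test_backbone_is_interval_complement(self):
        ann = HairpinAnnotation("m", hairpin=(0, 100), mir=(10, 32),
                                mir_star=(60, 82), loop=(40, 55))
        part = partition_domains(ann, None, 100)
        backbone = part.columns("backbone_strict")
        expected = sorted(
            set(range(0, 10)) | set(range(32, 40)) | set(range(55, 60))
            | set(range(82, 100))
        )
        assert list(backbone) == expected
        assert len(backbone) == 41

    def test_labels_partition_all_columns(self):
        ann = full_annotation()
        part = partition_domains(ann, None, 120)
        fine = ["flank_up", "backbone_strict", "mir", "loop", "mir_star", "flank_down"]
        total = sum(len(part.columns(d)) for d in fine)
        assert total == 120

    def test_pairing_from_structure(self):
        ann = HairpinAnnotation("m", hairpin=(2, 8), mir=(2, 4), seed=(2, 4))
        struct = parse_dot_bracket("((..))")
        part = partition_domains(ann, struct, 10)
        assert part.pairing[2] == "paired"
        assert part.pairing[4] == "unpaired"
        assert part.pairing[0] is None
        assert len(part.columns("paired")) + len(part.columns("unpaired")) == 6

    def test_backbone_view_is_hairpin_minus_mir(self):
        ann = full_annotation()
        part = partition_domains(ann, None, 120)
        assert len(part.columns("backbone")) == 100 - 22
        assert len(part.columns("hairpin")) == 100

    def test_structure_length_mismatch_rejected(self):
        ann = HairpinAnnotation("m", hairpin=(0, 10), mir=(1, 9))
        with pytest.raises(Exception):
            partition_domains(ann, parse_dot_bracket("(((...)))"), 10)


class TestVariantContext:
    def test_seed_membership_uses_mir_positions_2_to_8(self):
        ann = HairpinAnnotation("m", hairpin=(5, 60), mir=(10, 32))
        part = partition_domains(ann, None, 60)
        seqs = ["A" * 60, "A" * 60]
        # SNPs at miR position 3 (in seed) and position 1 (not in seed)
        s1 = list(seqs[1])
        s1[12] = "G"  # miR position 3
        s1[10] = "G"  # miR position 1
        s1[2] = "G"  # flank
        aln = make_alignment([seqs[0], "".join(s1)])
        variants, _ = scan_sites(aln)
        annotate_variant_context(variants, part, ann)
        by_col = {v.column: v for v in variants}
        assert by_col[12].in_seed is True
        assert by_col[10].in_seed is False
        assert by_col[12].domain == "mir"
        assert by_col[2].domain == "flank_up"
        assert by_col[2].pairing is None


class TestDomainSummaries:
    def test_monomorphic_domain(self):
        ann = HairpinAnnotation("m", hairpin=(2, 10), mir=(2, 10), seed=(3, 9))
        part = partition_domains(ann, None, 12)
        aln = make_alignment(["ACGTACGTACGT"] * 4)
        summaries = {s.domain: s for s in domain_summary_all(aln, part)}
        assert summaries["mir"].S == 0
        assert summaries["mir"].pi == 0.0
        assert summaries["hairpin"].tajima_D is None

    def test_length_weighted_fine_partition_recovers_hairpin_pi(self):
        """Sum of pi_d * L_d over the fine hairpin partition equals
        pi_hairpin * L_hairpin exactly (same gap exclusion per column)."""
        cfg = SyntheticConfig(seed=17, num_loci=6)
        for i in range(cfg.num_loci):
            aln, ann, struct, _ = generate_locus(cfg, i)
            part = partition_domains(ann, struct, aln.num_columns)
            summaries = {s.domain: s for s in domain_summary_all(aln, part)}
            total = 0.0
            length = 0
            for d in ("mir", "mir_star", "loop", "backbone_strict"):
                s = summaries[d]
                total += s.pi * s.L
                length += s.L
            hp = summaries["hairpin"]
            assert length == hp.L
            assert total == pytest.approx(hp.pi * hp.L, abs=1e-12)

    def test_paired_unpaired_cover_hairpin(self):
        cfg = SyntheticConfig(seed=18, num_loci=1)
        aln, ann, struct, _ = generate_locus(cfg, 0)
        part = partition_domains(ann, struct, aln.num_columns)
        summaries = {s.domain: s for s in domain_summary_all(aln, part)}
        # gap-free locus: surveyed lengths add up to the hairpin length
        assert summaries["paired"].L + summaries["unpaired"].L == ann.hairpin_length

    def test_k_to_outgroup_reported(self):
        cfg = SyntheticConfig(seed=19, num_loci=1)
        aln, ann, struct, _ = generate_locus(cfg, 0)
        part = partition_domains(ann, struct, aln.num_columns)
        summaries = {s.domain: s for s in domain_summary_all(aln, part)}
        assert summaries["flank"].K_jc is not None
        assert summaries["flank"].K_jc >= 0


class TestSlidingProfile:
    @staticmethod
    def constant_pi_locus(locus_id="flat", n=20, L=200, mir_start=90):
        """Every column has exactly one variant carrier: per-site pi is
        2*1*(n-1)/(n*(n-1)) = 2/n everywhere; n=20 gives 0.1."""
        base = ["A"] * L
        alt = ["C"] * L
        seqs = ["".join(base)] * (n - 1) + ["".join(alt)]
        aln = make_alignment(seqs, locus_id=locus_id)
        ann = HairpinAnnotation(locus_id, hairpin=(mir_start - 10, mir_start + 60),
                                mir=(mir_start, mir_start + 22),
                                nearest_mirna_distance_bp=1000)
        return aln, ann

    def test_flat_profile_exact(self):
        aln, ann = self.constant_pi_locus()
        prof = sliding_profile([(aln, ann)] * 10, "pi", min_loci=10)
        assert not prof.rows.empty
        assert np.allclose(prof.rows["mean_value"], 0.1)
        # rows sit on the 5-bp grid relative to the miR start
        assert (prof.rows["relative_start"] % 5 == 0).all()

    def test_min_loci_threshold_drops_all_rows(self):
        aln, ann = self.constant_pi_locus()
        prof = sliding_profile([(aln, ann)] * 9, "pi", min_loci=10)
        assert prof.rows.empty

    def test_neighbor_distance_filter(self):
        aln, ann = self.constant_pi_locus()
        near = HairpinAnnotation(ann.locus_id, hairpin=ann.hairpin, mir=ann.mir,
                                 nearest_mirna_distance_bp=50)
        with pytest.warns(UserWarning):
            prof = sliding_profile([(aln, near)] * 10, "pi", min_loci=1)
        assert prof.rows.empty

    def test_single_window_equals_region_pi(self):
        rng = np.random.default_rng(44)
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(6)]
        aln = make_alignment(seqs)
        ann = HairpinAnnotation("m", hairpin=(0, 35), mir=(0, 22),
                                nearest_mirna_distance_bp=1000)
        prof = sliding_profile([(aln, ann)], "pi", window=40, step=40, min_loci=1)
        row = prof.rows[prof.rows.relative_start == 0]
        pi, _ = nucleotide_diversity(seqs)
        assert row["mean_value"].iloc[0] == pytest.approx(pi)


class TestFlagsAndClasses:
    @staticmethod
    def summary(locus, domain, pi, L=100):
        return DomainSummary(locus_id=locus, domain=domain, n=10, L=L, S=0, pi=pi)

    def test_misannotation_rule(self):
        summaries = [
            self.summary("a", "hairpin", 0.02), self.summary("a", "flank", 0.01),
            self.summary("b", "hairpin", 0.01), self.summary("b", "flank", 0.01),
            self.summary("c", "hairpin", 0.02),
        ]
        flags = misannotation_flags(summaries)
        assert flags == {"a": "flagged", "b": "ok", "c": "not_evaluable"}

    def test_mostly_unflagged_on_suppressed_synthetic_data(self):
        cfg = SyntheticConfig(seed=23, num_loci=40)
        summaries = []
        for i in range(cfg.num_loci):
            aln, ann, struct, _ = generate_locus(cfg, i)
            part = partition_domains(ann, struct, aln.num_columns)
            summaries.extend(domain_summary_all(aln, part))
        flags = misannotation_flags(summaries)
        flagged = sum(1 for v in flags.values() if v == "flagged")
        assert flagged / len(flags) < 0.10

    @pytest.mark.parametrize(
        "presence,strict,relaxed",
        [
            (frozenset(), "unique", "low"),
            (frozenset({"elegans"}), "conserved", "low"),
            (frozenset({"elegans", "briggsae"}), "conserved", "high"),
        ],
    )
    def test_conservation_schemes(self, presence, strict, relaxed):
        ann = HairpinAnnotation("m", hairpin=(0, 60), mir=(10, 32),
                                seed_family_presence=presence)
        assert classify_conservation(ann, "strict") == strict
        assert classify_conservation(ann, "relaxed") == relaxed
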