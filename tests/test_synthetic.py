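import json

import numpy as np
import pytest
from scipy import stats as sps

from mirpopgen.errors import ConfigError
from mirpopgen.popstats import hudson_fst, nucleotide_diversity
from mirpopgen.seqdata import read_annotations, read_locus_alignment, read_structures
from mirpopgen.synthetic_data import (
    EventSpec,
    HairpinGeometry,
    SyntheticConfig,
    generate_dataset,
    generate_locus,
    inject_event,
)
from mirpopgen.variants import call_indel_events


class TestConfigValidation:
    def test_bad_multiplier(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(domain_multipliers={"mir": 0.0, "mir_star": 0.1,
                                                "backbone": 0.3, "loop": 0.6,
                                                "flank": 1.0})

    def test_split_times_must_match_populations(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(n_per_population={"A": 5, "B": 5}, split_times=())

    def test_geometry_rejects_empty_segment(self):
        with pytest.raises(ConfigError):
            HairpinGeometry(loop=0)

    def test_tiny_population_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(n_per_population={"A": 1, "B": 5}, split_times=(0.1,))


class TestGenerateLocus:
    def test_deterministic_under_seed(self):
        cfg = SyntheticConfig(seed=9)
        a1, n1, s1, t1 = generate_locus(cfg, 4)
        a2, n2, s2, t2 = generate_locus(cfg, 4)
        assert a1 == a2 and n1 == n2 and s1 == s2 and t1 == t2

    def test_shapes_and_sample_sizes(self):
        cfg = SyntheticConfig(seed=1)
        aln, ann, struct, truth = generate_locus(cfg, 0)
        assert aln.n == 29
        assert aln.num_columns == cfg.geometry.locus_length
        assert aln.outgroup_sequence is not None
        assert ann.hairpin_length == cfg.geometry.hairpin_length
        assert len(struct.dot_bracket) == ann.hairpin_length
        assert set(aln.populations) == {"OH", "ON", "DE"}

    def test_structure_pairs_mir_with_mir_star(self):
        cfg = SyntheticConfig(seed=1)
        _, ann, struct, _ = generate_locus(cfg, 0)
        hs = ann.hairpin[0]
        mir_local = range(ann.mir[0] - hs, ann.mir[1] - hs)
        star_local = set(range(ann.mir_star[0] - hs, ann.mir_star[1] - hs))
        for i in mir_local:
            assert struct.partner[i] in star_local
        loop_local = range(ann.loop[0] - hs, ann.loop[1] - hs)
        assert all(struct.partner[i] is None for i in loop_local)

    def test_truth_mutation_counts_poisson_consistent(self):
        """Aggregated realized per-domain mutation counts match the
        configured rates (chi-square goodness of fit at the 1% level),
        using each locus's realized total branch length."""
        cfg = SyntheticConfig(seed=21, num_loci=80)
        m = cfg.domain_multipliers
        seg_mult = {"flank_up": m["flank"], "backbone5": m["backbone"],
                    "mir": m["mir"], "loop": m["loop"], "mir_star": m["mir_star"],
                    "backbone3": m["backbone"], "flank_down": m["flank"]}
        observed = dict.fromkeys(seg_mult, 0.0)
        expected = dict.fromkeys(seg_mult, 0.0)
        for i in range(cfg.num_loci):
            _, _, _, truth = generate_locus(cfg, i)
            T = truth["branch_total_length"]
            for name, (s, e) in cfg.geometry.segments().items():
                observed[name] += truth["per_domain_mutations"][name]
                expected[name] += cfg.theta_flank * seg_mult[name] * (e - s) * T / 2
        obs = np.array([observed[k] for k in seg_mult])
        exp = np.array([expected[k] for k in seg_mult])
        chi2 = sps.chisquare(obs, exp * obs.sum() / exp.sum())
        assert chi2.pvalue > 0.01

    def test_outgroup_divergence_matches_model_expectation(self):
        """Flank Jukes-Cantor divergence to the outgroup approximates the
        outgroup-branch rate plus the ingroup root-to-leaf contribution."""
        from mirpopgen.popstats import jc_divergence

        cfg = SyntheticConfig(seed=2, num_loci=120)
        ks, depths = [], []
        for i in range(cfg.num_loci):
            aln, ann, _, truth = generate_locus(cfg, i)
            fl = list(range(0, 200)) + list(range(ann.hairpin[1], aln.num_columns))
            ref = "".join(aln.haplotypes[0].sequence[c] for c in fl)
            og = "".join(aln.outgroup_sequence[c] for c in fl)
            k = jc_divergence(ref, og)
            if k is not None:
                ks.append(k)
        mean_k = float(np.mean(ks))
        # ingroup lineage adds ~ (theta/2) * E[root-to-leaf time]; with three
        # populations and the default splits that time is a little over 1
        lower = cfg.outgroup_divergence
        upper = cfg.outgroup_divergence + cfg.theta_flank * 1.6
        assert lower < mean_k < upper


class TestInjectEvents:
    def test_zero_frequency_is_identity(self):
        cfg = SyntheticConfig(seed=3)
        aln, ann, _, _ = generate_locus(cfg, 0)
        out = inject_event(aln, ann, EventSpec(0, "seed_snp", "OH", 0.0))
        assert out == aln

    def test_seed_deletion_recovered_at_population_frequency(self):
        # the classic scenario: a 14-bp deletion at 2/9 in one population
        # removes the seed motif
        cfg = SyntheticConfig(
            seed=4,
            injected_events=(EventSpec(1, "deletion", "ON", 2 / 9, length=14),),
        )
        aln, ann, _, _ = generate_locus(cfg, 1)
        events = call_indel_events(aln.subset("ON"), ann)
        seed_events = [e for e in events if e.overlaps.get("seed")]
        assert len(seed_events) == 1
        ev = seed_events[0]
        assert ev.length == 14
        assert ev.frequency == pytest.approx(2 / 9, abs=5e-4)

    def test_large_deletion_fraction_of_hairpin(self):
        # deleting 89% of the hairpin in every carrier reports that fraction
        cfg = SyntheticConfig(seed=5)
        aln, ann, _, _ = generate_locus(cfg, 0)
        hp_len = ann.hairpin_length
        del_len = round(0.89 * hp_len)
        spec = EventSpec(0, "deletion", "OH", 1.0, start=ann.hairpin[0], length=del_len)
        out = inject_event(aln, ann, spec)
        events = call_indel_events(out.subset("OH"), ann)
        big = max(events, key=lambda e: e.hairpin_fraction_removed)
        assert big.hairpin_fraction_removed == pytest.approx(del_len / hp_len)
        assert big.frequency == pytest.approx(1.0)

    def test_target_outside_hairpin_rejected(self):
        cfg = SyntheticConfig(seed=6)
        aln, ann, _, _ = generate_locus(cfg, 0)
        with pytest.raises(ConfigError):
            inject_event(aln, ann, EventSpec(0, "deletion", "OH", 0.5, start=0, length=10))


class TestGenerateDataset:
    def test_files_and_truth_rows(self, tmp_path, small_dataset):
        out, cfg, manifest = small_dataset
        assert manifest["num_loci"] == 12
        assert len(manifest["alignments"]) == 12
        anns = read_annotations(out / "annotations.tsv")
        structs = read_structures(out / "structures.txt")
        assert len(anns) == 12 and len(structs) == 12
        truth_lines = (out / "truth.tsv").read_text().strip().splitlines()
        assert len(truth_lines) == 13  # header + one row per locus
        aln = read_locus_alignment(
            out / "alignments" / "synmir-001.fa", outgroup_id=manifest["outgroup_id"]
        )
        assert aln.n == 29 and aln.outgroup_sequence is not None

    def test_byte_identical_regeneration(self, tmp_path, small_dataset):
        out, cfg, _ = small_dataset
        again = tmp_path / "again"
        generate_dataset(cfg, again)
        for rel in ["annotations.tsv", "structures.txt", "truth.tsv",
                    "alignments/synmir-007.fa"]:
            assert (out / rel).read_bytes() == (again / rel).read_bytes()

    def test_refuses_nonempty_output(self, tmp_path, small_dataset):
        out, cfg, _ = small_dataset
        with pytest.raises(ConfigError):
            generate_dataset(cfg, out)

    def test_empty_dataset_valid_manifest(self, tmp_path):
        cfg = SyntheticConfig(seed=0, num_loci=0)
        manifest = generate_dataset(cfg, tmp_path / "empty")
        assert manifest["alignments"] == []
        assert json.loads((tmp_path / "empty" / "manifest.json").read_text()) == manifest


class TestPopulationStructure:
    @staticmethod
    def _mean_fst(split, seed, loci=40):
        cfg = SyntheticConfig(
            seed=seed, num_loci=loci,
            n_per_population={"A": 8, "B": 8}, split_times=(split,),
        )
        vals = []
        for i in range(loci):
            aln, ann, _, _ = generate_locus(cfg, i)
            pops = {p: aln.sequences(p) for p in aln.populations}
            f = hudson_fst(pops)
            if f is not None:
                vals.append(f)
        return float(np.mean(vals))

    def test_fst_increases_with_split_time(self):
        f0 = self._mean_fst(0.0, seed=31)
        f1 = self._mean_fst(0.5, seed=31)
        f2 = self._mean_fst(2.0, seed=31)
        assert abs(f0) < 0.05
        assert f0 < f1 < f2

    def test_domain_suppression_in_moderate_sample(self):
        """Pooled mir diversity runs well below flank diversity even at a
        reduced locus count."""
        cfg = SyntheticConfig(seed=8, num_loci=40)
        mir_pt = fl_pt = 0.0
        for i in range(cfg.num_loci):
            aln, ann, _, _ = generate_locus(cfg, i)
            seqs = aln.sequences()
            _, pt = nucleotide_diversity(
                ["".join(s[c] for c in range(*ann.mir)) for s in seqs])
            mir_pt += pt
            fl = list(range(0, ann.hairpin[0]))
            _, pt = nucleotide_diversity(["".join(s[c] for c in fl) for s in seqs])
            fl_pt += pt
        assert mir_pt / 22 < 0.3 * fl_pt / 200
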