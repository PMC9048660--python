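"""Site planning, constrained stochastic recoding and variant selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from intronless import (
    DesignConfig,
    GcTargetModel,
    GeneRecord,
    ToyGeneSpec,
    build_site_plan,
    design,
    find_restriction_matches,
    generate_cloud,
    generate_variant,
    make_toy_gene,
    remove_introns,
    score_variant,
    translate,
    vicinity_density,
)
from intronless.ese_motifs import EseSet
from intronless.optimizer import _vicinity_intervals, iupac_reverse_complement


def brute_force_iupac(seq, pattern):
    from intronless.optimizer import IUPAC_CODES

    hits = []
    for pat in {pattern, iupac_reverse_complement(pattern)}:
        for s in range(len(seq) - len(pat) + 1):
            if all(seq[s + i] in IUPAC_CODES[c] for i, c in enumerate(pat)):
                hits.append((s, s + len(pat)))
    return sorted(set(hits))


class TestFindRestrictionMatches:
    def test_palindromic_site_reported_once(self):
        assert find_restriction_matches("AAGAATTCAA", ["GAATTC"]) == [(2, 8)]

    def test_minus_strand_recognition_via_reverse_complement(self):
        # BsaI GGTCTC is absent from the plus strand but GAGACC is its
        # reverse complement
        assert find_restriction_matches("AAGAGACCAA", ["GGTCTC"]) == [(2, 8)]

    def test_ambiguity_codes_match(self):
        assert find_restriction_matches("AAGCTTGCAA", ["GCNNGC"]) == [(2, 8)]

    def test_invalid_iupac_character_named(self):
        with pytest.raises(ValueError, match="'E'"):
            find_restriction_matches("AAAA", ["GAETTC"])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.text(alphabet="ACGT", min_size=0, max_size=60),
        st.text(alphabet="ACGTRYSWKMBDHVN", min_size=2, max_size=8),
    )
    def test_matches_equal_brute_force_both_orientations(self, seq, pattern):
        assert find_restriction_matches(seq, [pattern]) == brute_force_iupac(seq, pattern)


class TestBuildSitePlan:
    def test_vicinity_window_arithmetic(self):
        gene = make_toy_gene(ToyGeneSpec([300, 300], [40], seed=2))
        proc = remove_introns(gene, keep_first=False)
        assert proc.junctions == [300]
        config = DesignConfig(
            ese_mode="decrease",
            ese_set=EseSet("t", frozenset({"GAAGAA"})),
            vicinity_nt=70,
            n_variants=1,
        )
        plan = build_site_plan(proc, config)
        eligible = {e.codon_index for e in plan.entries if e.ese_eligible}
        # codons with any nucleotide in [230, 370)
        assert eligible == set(range(230 // 3, 369 // 3 + 1))

    def test_trp_has_no_synonyms(self):
        gene = GeneRecord("g", "", ["ATGTGGAAATAA"], [])
        plan = build_site_plan(remove_introns(gene), DesignConfig(n_variants=1))
        assert not plan.entries[1].mutable
        assert plan.entries[1].protection_reason == "no_synonyms"
        assert plan.entries[2].mutable

    def test_start_and_stop_never_mutable(self):
        gene = GeneRecord("g", "", ["ATGAAATAA"], [])
        plan = build_site_plan(remove_introns(gene), DesignConfig(n_variants=1))
        reasons = [e.protection_reason for e in plan.entries]
        assert reasons == ["start", None, "stop"]

    def test_codons_overlapping_protected_match_are_frozen(self):
        #        codon: 0  1  2  3  4  5  6  7
        cds = "ATG" + "AAA" * 3 + "GAATTC" + "GGC" + "TAA"
        gene = GeneRecord("g", "", [cds], [])
        config = DesignConfig(protect_enzymes=("GAATTC",), n_variants=1)
        plan = build_site_plan(remove_introns(gene), config)
        assert plan.protected_intervals == [(12, 18)]
        frozen = {e.codon_index for e in plan.entries if e.protection_reason == "restriction"}
        assert frozen == {4, 5}

    def test_ese_mode_off_disables_eligibility_everywhere(self, two_exon_gene):
        proc = remove_introns(two_exon_gene, keep_first=False)
        plan = build_site_plan(proc, DesignConfig(ese_mode="off", n_variants=1))
        assert not any(e.ese_eligible for e in plan.entries)

    def test_ese_in_cores_extends_to_all_codons(self, two_exon_gene, toy_ese_set):
        proc = remove_introns(two_exon_gene, keep_first=False)
        config = DesignConfig(
            ese_mode="increase", ese_set=toy_ese_set, ese_in_cores=True, n_variants=1
        )
        plan = build_site_plan(proc, config)
        assert all(e.ese_eligible for e in plan.entries)

    def test_config_requires_ese_set_when_mode_active(self):
        with pytest.raises(ValueError, match="ese set required"):
            DesignConfig(ese_mode="decrease", n_variants=1)


def _variant(gene, config, model=None, seed_stream=0, keep_first=False):
    from intronless import default_model

    model = model or default_model(config.gc_strategy)
    proc = remove_introns(gene, keep_first=keep_first)
    plan = build_site_plan(proc, config)
    rng = np.random.default_rng([config.seed, seed_stream])
    return generate_variant(proc, plan, model, config, rng), proc, plan


class TestGenerateVariant:
    def test_no_mutable_sites_returns_input(self):
        gene = GeneRecord("g", "", ["ATGTGGTAA"], [])
        var, _, _ = _variant(gene, DesignConfig(gc_strategy="max_gc", n_variants=1))
        assert var.cds == "ATGTGGTAA" and var.changes == []

    def test_blacklisted_introduction_is_reverted(self):
        # under max_gc the Lys site would always pick AAG, which the
        # blacklist forbids: the site must stay AAA
        gene = GeneRecord("g", "", ["ATGAAATAA"], [])
        config = DesignConfig(gc_strategy="max_gc", avoid_motifs=("AAG",), n_variants=1)
        var, _, _ = _variant(gene, config)
        assert var.cds == "ATGAAATAA" and var.changes == []

    def test_preexisting_motif_does_not_block_unrelated_changes(self):
        gene = GeneRecord("g", "", ["ATGAAGGGATAA"], [])
        config = DesignConfig(gc_strategy="max_gc", avoid_motifs=("AAG",), n_variants=1)
        var, _, _ = _variant(gene, config)
        assert var.cds[6:9] in {"GGC", "GGG"}
        assert len(var.changes) == 1

    def test_fixed_seed_reproduces_variant(self, two_exon_gene):
        config = DesignConfig(gc_strategy="one_two_exon", n_variants=1, seed=9)
        v1, _, _ = _variant(two_exon_gene, config)
        v2, _, _ = _variant(two_exon_gene, config)
        assert v1.cds == v2.cds and v1.changes == v2.changes

    def test_ese_only_leaves_cores_untouched(self, two_exon_gene, toy_ese_set):
        config = DesignConfig(
            gc_strategy="ese_only",
            ese_mode="decrease",
            ese_set=toy_ese_set,
            ese_weight=1.0,
            n_variants=1,
        )
        var, proc, plan = _variant(two_exon_gene, config)
        eligible = {e.codon_index for e in plan.entries if e.ese_eligible}
        changed = {i for i, _, _ in var.changes}
        assert changed <= eligible


class TestScoreVariant:
    def test_on_target_sequence_scores_zero(self):
        cds = "ATGGGCGCCTAA"
        gene = GeneRecord("g", "", [cds], [])
        proc = remove_introns(gene)
        config = DesignConfig(gc_strategy="max_gc", n_variants=1)
        var = score_variant(cds, [], proc, GcTargetModel.max_gc(), config)
        assert var.objective == 0.0
        assert var.achieved_gc3 == 1.0

    def test_fewer_vicinity_matches_scores_lower_under_decrease(self):
        ese = EseSet("t", frozenset({"GAAGAA"}))
        gene = make_toy_gene(
            ToyGeneSpec([120, 120], [40], seed=13, motif_seeding=(ese, 3))
        )
        proc = remove_introns(gene, keep_first=False)
        config = DesignConfig(
            gc_strategy="ese_only", ese_mode="decrease", ese_set=ese, n_variants=1
        )
        model = GcTargetModel.ese_only()
        with_matches = score_variant(proc.cds, [], proc, model, config)
        # degrade one planted motif synonymously is fiddly; instead compare
        # against the same CDS scored with a set it cannot match
        config2 = DesignConfig(
            gc_strategy="ese_only",
            ese_mode="decrease",
            ese_set=EseSet("none", frozenset({"TTTTTT"})),
            n_variants=1,
        )
        without = score_variant(proc.cds, [], proc, model, config2)
        assert with_matches.ese_density_vicinity.match_count >= 3
        assert without.objective < with_matches.objective

    def test_vicinity_intervals_merge_and_clip(self):
        assert _vicinity_intervals([10, 30], 15, 200) == [(0, 45)]
        assert _vicinity_intervals([190], 15, 200) == [(175, 200)]
        assert _vicinity_intervals([], 70, 200) == []


class TestGenerateCloud:
    def test_single_variant_cloud(self, two_exon_gene):
        config = DesignConfig(gc_strategy="max_gc", n_variants=1, seed=3)
        cloud, _, _ = design(two_exon_gene, config)
        assert len(cloud.variants) == 1 and cloud.best_index == 0

    def test_same_seed_gives_identical_clouds(self, two_exon_gene):
        config = DesignConfig(gc_strategy="one_two_exon", n_variants=12, seed=5)
        c1, _, _ = design(two_exon_gene, config)
        c2, _, _ = design(two_exon_gene, config)
        assert [v.cds for v in c1.variants] == [v.cds for v in c2.variants]
        assert c1.best_index == c2.best_index

    def test_best_minimizes_objective_with_tiebreaks(self, two_exon_gene):
        config = DesignConfig(gc_strategy="one_two_exon", n_variants=30, seed=5)
        cloud, _, _ = design(two_exon_gene, config)
        best = cloud.best
        for k, v in enumerate(cloud.variants):
            assert (best.objective, len(best.changes), cloud.best_index) <= (
                v.objective,
                len(v.changes),
                k,
            )

    def test_decrease_ese_efficacy(self, toy_ese_set):
        gene = make_toy_gene(
            ToyGeneSpec([150, 150], [40], seed=21, motif_seeding=(toy_ese_set, 4))
        )
        config = DesignConfig(
            gc_strategy="ese_only",
            ese_mode="decrease",
            ese_set=toy_ese_set,
            ese_weight=1.0,
            keep_first_intron=False,
            n_variants=40,
            seed=8,
        )
        cloud, _, proc = design(gene, config)
        before = vicinity_density(proc.cds, proc.junctions, 70, toy_ese_set)
        assert before.match_count >= 4
        assert cloud.best.ese_density_vicinity.match_count <= before.match_count


@st.composite
def random_design_cases(draw):
    n_codons = draw(st.integers(5, 25))
    spec = ToyGeneSpec(
        exon_lengths=[3 * n_codons], intron_lengths=[], seed=draw(st.integers(0, 10**6))
    )
    strategy = draw(st.sampled_from(["max_gc", "one_two_exon", "human_usage"]))
    return spec, strategy, draw(st.integers(0, 10**6))


class TestInvariants:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(random_design_cases())
    def test_translation_is_always_preserved(self, case):
        spec, strategy, seed = case
        gene = make_toy_gene(spec)
        config = DesignConfig(gc_strategy=strategy, n_variants=2, seed=seed)
        cloud, _, proc = design(gene, config)
        for v in cloud.variants:
            assert translate(v.cds) == translate(proc.cds)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(random_design_cases())
    def test_protected_sites_survive_verbatim(self, case):
        spec, strategy, seed = case
        gene = make_toy_gene(spec)
        cds = gene.cds
        # protect an actual hexamer of the input so a match is guaranteed
        pattern = cds[6:12]
        config = DesignConfig(
            gc_strategy=strategy, protect_enzymes=(pattern,), n_variants=2, seed=seed
        )
        cloud, plan, proc = design(gene, config)
        assert plan.protected_intervals  # at least the planted occurrence
        for v in cloud.variants:
            for lo, hi in plan.protected_intervals:
                assert v.cds[lo:hi] == cds[lo:hi]

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(random_design_cases())
    def test_no_new_blacklisted_motif_ever_appears(self, case):
        spec, strategy, seed = case
        gene = make_toy_gene(spec)
        cds = gene.cds
        motif = cds[9:14]  # 5-mer guaranteed present; new copies forbidden
        config = DesignConfig(
            gc_strategy=strategy, avoid_motifs=(motif,), n_variants=2, seed=seed
        )
        cloud, _, _ = design(gene, config)
        before = {
            s for s in range(len(cds) - 4) if cds[s : s + 5] == motif
        }
        for v in cloud.variants:
            after = {
                s for s in range(len(v.cds) - 4) if v.cds[s : s + 5] == motif
            }
            assert after <= before
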