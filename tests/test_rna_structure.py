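"""Folding engine, conformation classes, seed preservation and energy filters."""

import math
import random

import pytest

from triplexkit.io_model import InputError, TargetSite, TriplexCandidate
from triplexkit.rna_structure import (
    ComplexStructure,
    Conformation,
    TriplexEnergetics,
    apply_structure_filters,
    classify_conformation,
    default_model,
    dotbracket_to_pairs,
    enumerate_structures,
    mfe_complex,
    pairs_to_dotbracket,
    score_structure,
    seed_preserved,
    tfe_cutoff,
    triplex_energetics,
)


class TestMfeComplex:
    def test_unpairable_strand_is_unstructured_at_zero(self):
        s = mfe_complex(["AAAAAA"])
        assert s.dG == 0.0 and not s.pairs
        assert s.dot_bracket == "......"

    def test_full_intermolecular_helix_sums_stack_table(self):
        model = default_model()
        s = mfe_complex(["GGGGG", "CCCCC"], model)
        expected = 4 * model.stacks[("GC", "GC")]
        assert s.dG == pytest.approx(expected)
        assert s.dot_bracket == "(((((&)))))"

    def test_more_than_three_strands_unsupported(self):
        with pytest.raises(InputError):
            mfe_complex(["AC", "GU", "AC", "GU"])

    def test_empty_strand_rejected(self):
        with pytest.raises(InputError):
            mfe_complex(["ACGU", ""])

    def test_deterministic(self):
        strands = ["GGGACGUCCCAUGC", "GCAUGGG"]
        a, b = mfe_complex(strands), mfe_complex(strands)
        assert a.pairs == b.pairs and a.dG == b.dG


class TestEnumeration:
    def test_single_short_strand_has_only_the_empty_structure(self):
        assert [p for p, _ in enumerate_structures(["ACG"])] == [frozenset()]

    def test_two_gc_strands_enumerate_all_matchings(self):
        structs = {p for p, _ in enumerate_structures(["GC", "GC"])}
        # empty, two 1-pair inter-strand matchings, and the 2-pair helix
        assert structs == {
            frozenset(),
            frozenset({(0, 3)}),
            frozenset({(1, 2)}),
            frozenset({(0, 3), (1, 2)}),
        }

    def test_refuses_oversize_input(self):
        with pytest.raises(InputError):
            list(enumerate_structures(["A" * 40]))

    def test_dp_equals_enumeration_minimum(self):
        rng = random.Random(99)
        model = default_model()
        for _ in range(60):
            k = rng.randint(1, 3)
            strands = [
                "".join(rng.choice("ACGU") for _ in range(rng.randint(3, 8)))
                for _ in range(k)
            ]
            if sum(map(len, strands)) > 20:
                continue
            best = min((e for _, e in enumerate_structures(strands, model)), default=0.0)
            got = mfe_complex(strands, model)
            assert got.dG == pytest.approx(best, abs=1e-9)
            # the traced-back structure scores to the reported energy
            assert score_structure(got.strands, got.pairs, model) == pytest.approx(
                got.dG, abs=1e-9
            )


class TestThirdStrandNeverRaisesMfe:
    def test_triplex_at_most_best_duplex(self):
        rng = random.Random(5)
        for _ in range(15):
            w = "".join(rng.choice("ACGU") for _ in range(rng.randint(10, 20)))
            m1 = "".join(rng.choice("ACGU") for _ in range(8))
            m2 = "".join(rng.choice("ACGU") for _ in range(8))
            dg_t = mfe_complex([w, m1, m2]).dG
            dg_1 = mfe_complex([w, m1]).dG
            dg_2 = mfe_complex([w, m2]).dG
            assert dg_t <= min(dg_1, dg_2) + 1e-9


class TestDotBracket:
    def test_bijection_on_enumerated_structures(self):
        strands = ["GGCAU", "AUGCC"]
        lengths = [len(s) for s in strands]
        for pairs, _ in enumerate_structures(strands):
            db = pairs_to_dotbracket(pairs, lengths)
            back, back_lengths = dotbracket_to_pairs(db)
            assert back == pairs and back_lengths == lengths

    def test_strand_separator(self):
        assert pairs_to_dotbracket(frozenset({(0, 3)}), [2, 2]) == "(.&.)"


class TestTriplexEnergeticsArithmetic:
    @pytest.mark.parametrize(
        "dg_t, dg_dmin, expected_ddg",
        [
            (-43.06, -18.98, -24.08),
            (-24.16, -23.68, -0.48),
            (-9.56, -9.78, 0.22),
        ],
    )
    def test_ddg_is_triplex_minus_best_duplex(self, dg_t, dg_dmin, expected_ddg):
        e = TriplexEnergetics(
            dG_triplex=dg_t, dG_duplex1=dg_dmin, dG_duplex2=dg_dmin + 1.5
        )
        assert e.ddG == pytest.approx(expected_ddg, abs=1e-9)
        assert e.dG_duplex_min == dg_dmin


def _three_strand_structure(pairs):
    return ComplexStructure(
        strand_ids=("win", "mir1", "mir2"),
        strands=("A" * 60, "U" * 22, "U" * 22),
        pairs=frozenset(pairs),
        dG=-1.0,
    )


class TestClassifyConformation:
    def test_both_mirnas_on_mrna_is_canonical(self):
        s = _three_strand_structure({(0, 60), (1, 61), (30, 82), (31, 83)})
        assert classify_conformation(s) is Conformation.CANONICAL_TRIPLEX

    def test_unpaired_mirna_is_duplex_plus_free(self):
        s = _three_strand_structure({(0, 60), (1, 61)})
        assert classify_conformation(s) is Conformation.DUPLEX_PLUS_FREE_MIRNA

    def test_mir_mir_pair_is_hybrid(self):
        s = _three_strand_structure({(0, 60), (30, 83), (61, 82)})
        assert classify_conformation(s) is Conformation.MIRNA_MIRNA_HYBRID

    def test_wrong_strand_count_rejected(self):
        s = ComplexStructure(("a", "b"), ("ACGU", "ACGU"), frozenset(), 0.0)
        with pytest.raises(InputError):
            classify_conformation(s)


def _candidate_for_seed_tests():
    up = TargetSite("G1", "T1", "miR-a", 9, 19, 11, 17, -0.5, 0.9)
    down = TargetSite("G1", "T1", "miR-b", 29, 39, 31, 37, -0.5, 0.9)
    return TriplexCandidate(
        gene_id="G1",
        transcript_id="T1",
        upstream_site=up,
        downstream_site=down,
        seed_distance=13,
        window_seq="A" * 60,
        window_offset=1,
    )


class TestSeedPreserved:
    # window occupies concat positions 0-59, miR1 60-81, miR2 82-103;
    # miR1 seed (nts 2-8) sits at concat 61-67, its seed match at window 10-16
    def test_all_seed_positions_on_designated_match(self):
        cand = _candidate_for_seed_tests()
        pairs = {(10 + k, 61 + k) for k in range(7)}
        s = _three_strand_structure(pairs)
        assert seed_preserved(s, cand, which_mirna=1) is True

    def test_pairing_with_the_other_sites_interval_fails(self):
        cand = _candidate_for_seed_tests()
        pairs = {(30 + k, 61 + k) for k in range(7)}  # miR2's designated match
        s = _three_strand_structure(pairs)
        assert seed_preserved(s, cand, which_mirna=1) is False

    def test_min_paired_threshold_semantics(self):
        cand = _candidate_for_seed_tests()
        pairs = {(10 + k, 61 + k) for k in range(6)}  # 6 of 7
        s = _three_strand_structure(pairs)
        assert seed_preserved(s, cand, which_mirna=1) is False
        assert seed_preserved(s, cand, which_mirna=1, min_paired=6) is True


class TestTfeCutoff:
    def test_matches_mean_minus_z_sd(self):
        x = 7.08 / math.sqrt(2.0)
        population = [-20.0 + x, -20.0 - x]  # mean -20, sample sd 7.08
        assert tfe_cutoff(population, z=3) == pytest.approx(-41.24, abs=1e-9)

    def test_z_zero_is_the_mean(self):
        assert tfe_cutoff([-10.0, -20.0, -30.0], z=0) == -20.0

    def test_degenerate_population_returns_common_value(self):
        assert tfe_cutoff([-15.0, -15.0, -15.0], z=3) == -15.0

    def test_empty_population_rejected(self):
        with pytest.raises(InputError):
            tfe_cutoff([], z=3)


class TestApplyStructureFilters:
    def rec(self, dg=-45.0, conf=Conformation.CANONICAL_TRIPLEX, seeds=(True, True)):
        return TriplexEnergetics(
            dG_triplex=dg,
            dG_duplex1=-10.0,
            dG_duplex2=-12.0,
            conformation_class=conf,
            seed_preserved_1=seeds[0],
            seed_preserved_2=seeds[1],
        )

    def test_record_at_cutoff_is_kept(self):
        kept, funnel = apply_structure_filters([self.rec(dg=-41.24)], cutoff=-41.24)
        assert len(kept) == 1 and funnel["tfe"] == 0

    def test_above_cutoff_dropped_as_tfe(self):
        kept, funnel = apply_structure_filters([self.rec(dg=-40.0)], cutoff=-41.24)
        assert not kept and funnel["tfe"] == 1

    def test_dropped_conformations_counted(self):
        recs = [
            self.rec(conf=Conformation.DUPLEX_PLUS_FREE_MIRNA),
            self.rec(conf=Conformation.MIRNA_MIRNA_HYBRID),
            self.rec(seeds=(True, False)),
        ]
        kept, funnel = apply_structure_filters(recs, cutoff=0.0)
        assert not kept and funnel["conformation"] == 2 and funnel["seed"] == 1

    def test_permissive_filters_are_identity(self):
        recs = [
            self.rec(conf=Conformation.MIRNA_MIRNA_HYBRID, seeds=(False, False)),
            self.rec(dg=5.0),
        ]
        kept, _ = apply_structure_filters(
            recs, cutoff=float("inf"), require_seed=False, drop_classes=frozenset()
        )
        assert kept == recs


class TestFoldedTriplexEnergetics:
    def test_planted_complement_folds_to_canonical_with_seeds(self):
        from triplexkit.synthetic_data import generate_toy_dataset
        from triplexkit.candidate_scan import group_sites_by_transcript, pair_sites

        ds = generate_toy_dataset(
            n_genes=1, utr_len=200, mirna_pool_size=2,
            planted_triplexes=[(20, 1.0)], rng_seed=3,
        )
        cands = pair_sites(group_sites_by_transcript(ds.sites), ds.utr_map())
        assert len(cands) == 1
        mm = ds.mirna_map()
        e = triplex_energetics(
            cands[0],
            mm[cands[0].upstream_site.mirna_id],
            mm[cands[0].downstream_site.mirna_id],
        )
        assert e.conformation_class is Conformation.CANONICAL_TRIPLEX
        assert e.seed_preserved_1 and e.seed_preserved_2
        assert e.ddG <= 0.0
        assert e.dG_triplex <= min(e.dG_duplex1, e.dG_duplex2)
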