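"""Candidate merging, exclusion criteria, and single-variant ranking."""

import numpy as np
import pytest

from thermotriage import synthetic
from thermotriage.structure import Mutation, read_structure
from thermotriage.triage import (
    PredictorCandidate,
    SingleVariantAssay,
    TriageConfig,
    apply_triage,
    candidates_from_table,
    merge_candidates,
    rank_singles,
)


def cand(predictor, mutation):
    return PredictorCandidate(predictor=predictor, mutation=Mutation.parse(mutation))


class TestMergeCandidates:
    def test_two_of_three_predictors_count(self):
        merged = merge_candidates([
            [cand("PROSS", "N257Y")],
            [cand("FireProt2", "N257W")],
            [cand("ABAUCS", "A10V")],
        ])
        by_pos = {m.position: m for m in merged}
        assert by_pos[257].consensus_count == 2
        assert by_pos[10].consensus_count == 1
        assert {str(m) for m in by_pos[257].substitutions} == {"N257Y", "N257W"}

    def test_disjoint_tables_all_single_support(self):
        merged = merge_candidates([
            [cand("P1", "A1V")], [cand("P2", "G2A")], [cand("P3", "S3T")],
        ])
        assert all(m.consensus_count == 1 for m in merged)

    def test_duplicate_rows_deduplicated_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            merged = merge_candidates([
                [cand("P1", "A1V"), cand("P1", "A1V")],
            ])
        assert merged[0].consensus_count == 1 and len(merged[0].substitutions) == 1

    def test_counts_equal_brute_force_tally(self):
        tables, truth = synthetic.make_predictor_tables(seed=12)
        lists = [candidates_from_table(t) for t in tables]
        merged = merge_candidates(lists)
        # independent tally straight off the raw tables
        tally = {}
        for t in tables:
            for mut in t["mutation"]:
                pos = int(mut[1:-1])
                tally.setdefault(pos, set())
            for pred, mut in zip(t["predictor"], t["mutation"]):
                tally[int(mut[1:-1])].add(pred)
        assert {m.position: m.consensus_count for m in merged} == \
            {p: len(s) for p, s in tally.items()}
        assert {m.position: m.consensus_count for m in merged} == truth["consensus"]


@pytest.fixture
def planted():
    """Structure with a catalytic residue, one candidate at 4.2 A and one at
    6.0 A, plus a planted salt bridge (Lys NZ)."""
    pdb, truth = synthetic.make_structure(
        seed=21, n_hbonds=0, n_salt_bridges=1, cluster_sizes=(),
        candidate_distances=(4.2, 6.0))
    return read_structure(pdb), truth


class TestApplyTriage:
    def test_single_predictor_support_excluded_first(self, planted):
        s, truth = planted
        far_pos = truth["candidates"][1]["position"]
        merged = merge_candidates([[cand("P1", f"G{far_pos}A")]])
        report = apply_triage(merged, s, TriageConfig(
            catalytic_residues={truth["catalytic"]}))
        [v] = report.verdicts
        assert v.final_status == "excluded(criterion_i)"

    def test_catalytic_proximity_excluded(self, planted):
        s, truth = planted
        near = truth["candidates"][0]  # 4.2 A < 5.0 cutoff
        merged = merge_candidates([
            [cand("P1", f"G{near['position']}A")],
            [cand("P2", f"G{near['position']}S")],
        ])
        report = apply_triage(merged, s, TriageConfig(
            catalytic_residues={truth["catalytic"]}))
        for v in report.verdicts:
            assert v.final_status == "excluded(criterion_ii)"
            assert v.min_distance_to_catalytic == pytest.approx(4.2)

    def test_far_candidate_kept(self, planted):
        s, truth = planted
        far = truth["candidates"][1]  # 6.0 A > 5.0 cutoff
        merged = merge_candidates([
            [cand("P1", f"G{far['position']}A")],
            [cand("P2", f"G{far['position']}A")],
        ])
        report = apply_triage(merged, s, TriageConfig(
            catalytic_residues={truth["catalytic"]}))
        assert report.verdicts[0].final_status == "kept"

    def test_capability_rule_conservative_substitution_kept(self, planted):
        # Lys in a salt bridge: K->R retains the positive charge (kept),
        # K->A cannot sustain it (excluded under criterion iii)
        s, truth = planted
        [[donor, _]] = truth["salt_bridges"]
        pos = int(donor[0].split(":")[1])
        merged = merge_candidates([
            [cand("P1", f"K{pos}R"), cand("P1", f"K{pos}A")],
            [cand("P2", f"K{pos}R"), cand("P2", f"K{pos}A")],
        ])
        report = apply_triage(merged, s, TriageConfig())
        by_mut = {str(v.mutation): v for v in report.verdicts}
        assert by_mut[f"K{pos}R"].final_status == "kept"
        assert by_mut[f"K{pos}A"].final_status == "excluded(criterion_iii)"
        assert by_mut[f"K{pos}A"].implicated_interactions

    def test_flag_only_mode_marks_instead_of_excluding(self, planted):
        s, truth = planted
        [[donor, _]] = truth["salt_bridges"]
        pos = int(donor[0].split(":")[1])
        merged = merge_candidates([[cand("P1", f"K{pos}A")], [cand("P2", f"K{pos}A")]])
        report = apply_triage(merged, s, TriageConfig(flag_only=True))
        assert report.verdicts[0].final_status == "kept(flagged_iii)"
        assert report.verdicts[0].kept

    def test_first_failing_criterion_reported(self, planted):
        # a candidate violating both i and ii reports i (documented order)
        s, truth = planted
        near = truth["candidates"][0]
        merged = merge_candidates([[cand("P1", f"G{near['position']}A")]])
        report = apply_triage(merged, s, TriageConfig(
            catalytic_residues={truth["catalytic"]}))
        assert report.verdicts[0].final_status == "excluded(criterion_i)"

    def test_filter_neutrality(self, planted):
        # with support=1, no catalytic set, and capability rule off,
        # everything is kept
        s, _ = planted
        tables, _ = synthetic.make_predictor_tables(seed=3, sizes=(8, 6, 7),
                                                    n_triple=2, n_pairs=(1, 1, 1))
        merged = merge_candidates([candidates_from_table(t) for t in tables])
        report = apply_triage(merged, s, TriageConfig(
            min_predictor_support=1, capability_rule_enabled=False))
        assert all(v.final_status == "kept" for v in report.verdicts)

    def test_anti_monotone_in_min_support(self, planted):
        s, _ = planted
        tables, _ = synthetic.make_predictor_tables(seed=4, sizes=(10, 8, 9),
                                                    n_triple=2, n_pairs=(2, 1, 1))
        merged = merge_candidates([candidates_from_table(t) for t in tables])
        kept = []
        for support in (1, 2, 3):
            report = apply_triage(merged, s, TriageConfig(
                min_predictor_support=support, capability_rule_enabled=False))
            kept.append({str(v.mutation) for v in report.kept})
        assert kept[2] <= kept[1] <= kept[0]

    def test_anti_monotone_in_distance_cutoff(self, planted):
        s, truth = planted
        merged = merge_candidates([
            [cand("P1", f"G{c['position']}A") for c in truth["candidates"]],
            [cand("P2", f"G{c['position']}S") for c in truth["candidates"]],
        ])
        kept = []
        for cutoff in (3.0, 5.0, 7.0):
            report = apply_triage(merged, s, TriageConfig(
                catalytic_residues={truth["catalytic"]}, distance_cutoff=cutoff))
            kept.append({str(v.mutation) for v in report.kept})
        assert kept[2] <= kept[1] <= kept[0]

    def test_missing_catalytic_residue_is_config_error(self, planted):
        s, _ = planted
        with pytest.raises(ValueError, match="catalytic"):
            apply_triage([], s, TriageConfig(catalytic_residues={"A:999"}))


class TestRankSingles:
    # the six favourable singles with their reported activities
    SIX = [
        ("N257Y", 96, 80), ("N271E", 98, 75), ("K177R", 105, 72),
        ("S67G", 101, 70), ("A220V", 109, 68), ("A279V", 106, 66),
    ]

    def _records(self, rows):
        return [SingleVariantAssay(Mutation.parse(m), rel, res)
                for m, rel, res in rows]

    def test_highest_residual_ranks_first(self):
        ranked = rank_singles(self._records(self.SIX))
        assert str(ranked[0].mutation) == "N257Y"
        assert [str(r.mutation) for r in ranked] == \
            ["N257Y", "N271E", "K177R", "S67G", "A220V", "A279V"]

    def test_tie_breaks_on_relative_then_position(self):
        ranked = rank_singles(self._records([
            ("A10V", 95, 70), ("G20A", 99, 70), ("S30T", 99, 70),
        ]))
        assert [str(r.mutation) for r in ranked] == ["G20A", "S30T", "A10V"]

    def test_low_relative_activity_deprioritized_not_dropped(self):
        ranked = rank_singles(self._records([
            ("A10V", 50, 99), ("G20A", 95, 60),
        ]))
        assert [str(r.mutation) for r in ranked] == ["G20A", "A10V"]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_sort(self, seed):
        rng = np.random.default_rng(seed)
        rows = [(f"A{p}V", float(rng.integers(85, 110)), float(rng.integers(40, 95)))
                for p in rng.choice(np.arange(1, 200), size=10, replace=False)]
        records = self._records(rows)
        expected = sorted(
            [r for r in records if r.relative_activity >= 90.0],
            key=lambda r: (-r.residual_activity, -r.relative_activity,
                           r.mutation.position),
        ) + sorted(
            [r for r in records if r.relative_activity < 90.0],
            key=lambda r: (-r.residual_activity, -r.relative_activity,
                           r.mutation.position),
        )
        assert [str(r.mutation) for r in rank_singles(records)] == \
            [str(r.mutation) for r in expected]

    def test_negative_percentage_rejected(self):
        with pytest.raises(ValueError):
            SingleVariantAssay(Mutation.parse("A1V"), -5.0, 50.0)
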