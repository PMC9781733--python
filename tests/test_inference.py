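import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protcur import fixtures as fx
from protcur import inference as inf
from protcur.io_formats import ProteinRecord, PsmRecord


def _rec(acc, seq, reviewed=False):
    return ProteinRecord(
        accession=acc, sequence=seq, db_section="reviewed" if reviewed else "unreviewed"
    )


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------


def digest_oracle(seq, max_missed, min_len, max_len):
    """Independent digestion: enumerate cut sites with a regex, then join
    consecutive segments."""
    sites = [0] + [m.end() for m in re.finditer(r"[KR](?!P)", seq) if m.end() < len(seq)]
    sites.append(len(seq))
    out = []
    for i in range(len(sites) - 1):
        for j in range(i + 1, min(i + 1 + max_missed + 1, len(sites))):
            pep = seq[sites[i] : sites[j]]
            if min_len <= len(pep) <= max_len:
                out.append((pep, sites[i] + 1))
    return sorted(out, key=lambda t: (t[1], len(t[0])))


class TestDigestTryptic:
    def test_no_cleavage_sites_returns_whole_sequence(self):
        assert inf.digest_tryptic("AAAA", min_len=1) == [("AAAA", 1)]

    def test_proline_suppresses_cleavage(self):
        # cleave after K2 (followed by R, allowed); not after R3 (before P)
        assert inf.digest_tryptic("AKRPGK", max_missed=0, min_len=1) == [
            ("AK", 1),
            ("RPGK", 3),
        ]
        with_missed = inf.digest_tryptic("AKRPGK", max_missed=1, min_len=1)
        assert ("AKRPGK", 1) in with_missed

    def test_matches_independent_oracle_on_random_sequences(self, rng):
        for _ in range(10):
            seq = fx.random_protein(200, rng)
            assert inf.digest_tryptic(seq, 3, 5, 60) == digest_oracle(seq, 3, 5, 60)

    def test_every_peptide_has_tryptic_or_terminal_boundaries(self, rng):
        seq = fx.random_protein(200, rng)
        for pep, start in inf.digest_tryptic(seq):
            end = start - 1 + len(pep)
            assert seq[start - 1 : end] == pep
            assert start == 1 or (seq[start - 2] in "KR" and seq[start - 1] != "P")
            assert end == len(seq) or (seq[end - 1] in "KR" and seq[end] != "P")


# ---------------------------------------------------------------------------
# FDR filtering
# ---------------------------------------------------------------------------


class TestFilterPsmsByFdr:
    @staticmethod
    def _psms(targets, decoys):
        return [
            PsmRecord(peptide=f"TARGET{i}K", score=s, replicate_id="R1")
            for i, s in enumerate(targets)
        ] + [
            PsmRecord(peptide=f"DECOY{i}K", score=s, replicate_id="R1", is_decoy=True)
            for i, s in enumerate(decoys)
        ]

    def test_no_decoys_accepts_all_targets_with_warning(self):
        psms = self._psms([10, 5], [])
        with pytest.warns(UserWarning, match="no decoy"):
            assert len(inf.filter_psms_by_fdr(psms)) == 2

    def test_no_targets_gives_empty(self):
        assert inf.filter_psms_by_fdr(self._psms([], [5.0])) == []

    def test_hand_enumerated_cutoffs(self):
        # targets {10,9,8,7}, decoys {8.5,6}: q-values by explicit
        # enumeration are 0, 0, 0.25, 0.25 -> only the two top targets
        # survive q <= 0.1
        psms = self._psms([10, 9, 8, 7], [8.5, 6])
        accepted = inf.filter_psms_by_fdr(psms, q_threshold=0.1)
        assert sorted(p.score for p in accepted) == [9, 10]

    def test_decoys_never_returned(self, rng):
        psms = self._psms(list(rng.normal(30, 3, 50)), list(rng.normal(8, 2.5, 20)))
        assert not any(p.is_decoy for p in inf.filter_psms_by_fdr(psms, 0.05))

    def test_realised_leakage_bounded_with_separated_scores(self):
        # false targets share the decoy score distribution; their accepted
        # fraction is controlled by the q threshold (within 2x)
        q = 0.01
        fractions = []
        for seed in range(30):
            gen = np.random.default_rng(seed)
            true_t = list(gen.normal(30, 3, 1000))
            false_t = list(gen.normal(8, 2.5, 100))
            decoys = list(gen.normal(8, 2.5, 100))
            psms = self._psms(true_t + false_t, decoys)
            accepted = inf.filter_psms_by_fdr(psms, q)
            names = {p.peptide for p in accepted}
            n_false = sum(
                1 for i in range(len(false_t)) if f"TARGET{1000 + i}K" in names
            )
            fractions.append(n_false / max(len(accepted), 1))
        assert np.mean(fractions) <= 2 * q


# ---------------------------------------------------------------------------
# Peptide mapping
# ---------------------------------------------------------------------------


def naive_tryptic_scan(peptide, seq):
    """Independent check: scan every position for a boundary-valid match."""
    for i in range(len(seq) - len(peptide) + 1):
        if seq[i : i + len(peptide)] != peptide:
            continue
        end = i + len(peptide)
        up = i == 0 or (seq[i - 1] in "KR" and seq[i] != "P")
        down = end == len(seq) or (seq[end - 1] in "KR" and seq[end] != "P")
        if up and down:
            return True
    return False


class TestMapPeptides:
    def test_peptide_equal_to_whole_protein_maps(self):
        (a,) = inf.map_peptides(["PEPTIDEK"], [_rec("P1", "PEPTIDEK")])
        assert a.protein_accs == {"P1"} and a.is_unique

    def test_published_isoform_peptides_map_as_described(self, worked_examples):
        ia, ib, ic = worked_examples["isoform_triplet"]
        pair = inf.map_peptides(
            [fx.PEPTIDE_UNIQUE_REVIEWED_ISOFORM, fx.PEPTIDE_UNIQUE_UNREVIEWED_ISOFORM],
            [ia, ib],
        )
        by_pep = {a.peptide: a for a in pair}
        # unique to the second reviewed isoform in the two-protein database
        assert by_pep[fx.PEPTIDE_UNIQUE_REVIEWED_ISOFORM].protein_accs == {ib.accession}
        # the extra peptide matches no reviewed entry of the pair
        assert by_pep[fx.PEPTIDE_UNIQUE_UNREVIEWED_ISOFORM].protein_accs == set()
        trip = inf.map_peptides([fx.PEPTIDE_UNIQUE_UNREVIEWED_ISOFORM], [ia, ib, ic])
        assert trip[0].protein_accs == {ic.accession}

    def test_interior_match_without_tryptic_boundary_rejected(self):
        # peptide occurs mid-sequence with no K/R upstream
        assert inf.map_peptides(["TIDEK"], [_rec("P1", "AAPTIDEKAA")])[0].protein_accs == set()

    def test_il_equivalence_flag(self):
        db = [_rec("P1", "PEPTLDEK")]
        assert inf.map_peptides(["PEPTIDEK"], db)[0].protein_accs == set()
        assert inf.map_peptides(["PEPTIDEK"], db, il_equivalent=True)[0].protein_accs == {"P1"}

    def test_modification_notation_stripped(self):
        db = [_rec("P1", "PEPTMDEK")]
        (a,) = inf.map_peptides(["PEPTM(+15.99)DEK"], db)
        assert a.protein_accs == {"P1"}

    def test_invalid_letters_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            inf.map_peptides(["PEP1K"], [_rec("P1", "PEPK")])

    def test_random_digests_confirmed_by_naive_scan(self, rng):
        db = [_rec(f"P{i}", fx.random_protein(150, rng)) for i in range(8)]
        peptides = [
            pep for r in db[:4] for pep, _ in inf.digest_tryptic(r.sequence, 1, 6, 30)
        ][:60]
        for a in inf.map_peptides(peptides, db):
            expected = {r.accession for r in db if naive_tryptic_scan(a.peptide, r.sequence)}
            assert a.protein_accs == expected


# ---------------------------------------------------------------------------
# Grouping + parsimony, with the exhaustive oracle
# ---------------------------------------------------------------------------


def _groups_from_sets(sets, reviewed=()):
    """Build groups through the real pipeline from a protein->peptides map."""
    db = []
    assignments = {}
    all_peps = sorted({p for s in sets.values() for p in s})
    pep_to_prot = {p: frozenset(a for a, s in sets.items() if p in s) for p in all_peps}
    asg = [
        inf.PeptideAssignment(peptide=p, protein_accs=pep_to_prot[p], is_unique=False)
        for p in all_peps
    ]
    db = [_rec(a, "ACDK", reviewed=a in reviewed) for a in sets]
    return inf.group_proteins(asg, db)


def parsimony_oracle(sets):
    """Exhaustive subset/cover classifier over raw peptide sets.

    Re-derives group structure and statuses with explicit loops, independent
    of the production code path.
    """
    # merge proteins with equal sets
    merged = {}
    for acc in sorted(sets):
        merged.setdefault(frozenset(sets[acc]), []).append(acc)
    names = {peps: min(accs) for peps, accs in merged.items()}
    status = {peps: "candidate" for peps in merged}
    for peps in merged:
        if any(peps < other for other in merged if other != peps):
            status[peps] = "subset_discarded"
    # unique peptides: appear in exactly one merged set
    def uniques(peps):
        return {
            p for p in peps if sum(1 for o in merged if p in o) == 1
        }
    while True:
        alive = [p for p in merged if status[p] not in ("subset_discarded", "intersection_discarded")]
        removable = None
        for peps in sorted(
            (p for p in alive if not uniques(p) and status[p] == "candidate"),
            key=lambda p: (len(p), names[p]),
        ):
            union = set()
            for other in alive:
                if other != peps:
                    union |= other
            if peps <= union:
                removable = peps
                break
        if removable is None:
            break
        status[removable] = "intersection_discarded"
    return {names[p]: s for p, s in status.items()}


class TestGroupProteins:
    def test_identical_sets_merge_with_reviewed_top(self):
        groups = _groups_from_sets(
            {"B": {"p1", "p2"}, "A": {"p1", "p2"}}, reviewed={"B"}
        )
        (g,) = groups
        assert g.member_accs == {"A", "B"}
        assert g.top_protein == "B"

    def test_distinct_sets_stay_separate(self):
        groups = _groups_from_sets({"A": {"p1"}, "B": {"p2"}})
        assert len(groups) == 2

    def test_grouping_matches_partition_oracle(self, rng):
        for _ in range(20):
            sets = {
                f"P{i}": set(
                    f"p{j}" for j in rng.choice(10, size=rng.integers(1, 6), replace=False)
                )
                for i in range(int(rng.integers(2, 7)))
            }
            groups = _groups_from_sets(sets)
            expected_partition = {}
            for acc, s in sets.items():
                expected_partition.setdefault(frozenset(s), set()).add(acc)
            assert {g.member_accs for g in groups} == {
                frozenset(m) for m in expected_partition.values()
            }


class TestApplyParsimony:
    def test_subset_group_dropped(self):
        groups = _groups_from_sets(
            {"A": {"p1", "p2", "p3", "p4", "p5"}, "B": {"p2", "p3"}}
        )
        inf.apply_parsimony(groups)
        status = {g.top_protein: g.status for g in groups}
        assert status == {"A": "candidate", "B": "subset_discarded"}

    def test_intersection_group_dropped(self):
        groups = _groups_from_sets(
            {"A": {"p1", "p2", "p3"}, "B": {"p4", "p5", "p6"}, "C": {"p2", "p4"}}
        )
        inf.apply_parsimony(groups)
        status = {g.top_protein: g.status for g in groups}
        assert status == {"A": "candidate", "B": "candidate", "C": "intersection_discarded"}

    def test_isoform_scenario_from_shared_peptides(self):
        # X: 12 peptides shared with Y plus one shared only with Z;
        # Y adds two unique peptides; Z adds one unique peptide.
        shared = {f"s{i}" for i in range(12)}
        groups = _groups_from_sets(
            {
                "X": shared | {"t"},
                "Y": shared | {"u1", "u2"},
                "Z": {"t", "z1"},
            }
        )
        inf.apply_parsimony(groups)
        status = {g.top_protein: g.status for g in groups}
        assert status == {
            "X": "intersection_discarded",
            "Y": "candidate",
            "Z": "candidate",
        }

    def test_coverage_never_broken(self, rng):
        for _ in range(50):
            sets = {
                f"P{i}": set(
                    f"p{j}" for j in rng.choice(12, size=rng.integers(1, 8), replace=False)
                )
                for i in range(int(rng.integers(2, 7)))
            }
            groups = _groups_from_sets(sets)
            inf.apply_parsimony(groups)
            universe = set().union(*(g.peptides for g in groups))
            alive = [
                g for g in groups
                if g.status not in ("subset_discarded", "intersection_discarded")
            ]
            assert set().union(*(g.peptides for g in alive)) == universe

    def test_statuses_match_exhaustive_oracle(self, rng):
        for _ in range(300):
            n_prot = int(rng.integers(2, 7))
            n_pep = int(rng.integers(2, 13))
            sets = {
                f"P{i}": set(
                    f"p{j:02d}"
                    for j in rng.choice(n_pep, size=rng.integers(1, n_pep + 1), replace=False)
                )
                for i in range(n_prot)
            }
            groups = _groups_from_sets(sets)
            inf.apply_parsimony(groups)
            got = {g.top_protein: g.status for g in groups}
            assert got == parsimony_oracle(sets)


class TestAcceptProteins:
    def test_single_peptide_group_rejected(self):
        groups = _groups_from_sets({"A": {"p1"}})
        inf.apply_parsimony(groups)
        assert inf.accept_proteins(groups) == []
        assert groups[0].status == "failed_min_peptides"

    def test_two_peptides_one_unique_reported(self):
        groups = _groups_from_sets({"A": {"p1", "p2"}, "B": {"p2", "p3"}})
        inf.apply_parsimony(groups)
        assert inf.accept_proteins(groups) == ["A", "B"]

    def test_reported_set_satisfies_both_predicates(self, rng):
        for _ in range(30):
            sets = {
                f"P{i}": set(
                    f"p{j}" for j in rng.choice(10, size=rng.integers(1, 6), replace=False)
                )
                for i in range(int(rng.integers(2, 6)))
            }
            groups = _groups_from_sets(sets)
            inf.apply_parsimony(groups)
            reported = inf.accept_proteins(groups, min_peptides=2)
            for g in groups:
                if g.top_protein in reported:
                    assert len(g.peptides) >= 2 and g.unique_peptides


class TestReplicateConsensus:
    @pytest.mark.parametrize(
        "presence,expected",
        [({"R1": ["A"], "R2": ["A"], "R3": ["A"]}, ["A"]),
         ({"R1": ["A"], "R2": [], "R3": []}, []),
         ({"R1": ["A", "B"], "R2": ["B"], "R3": ["A"]}, ["A", "B"])],
    )
    def test_two_of_three_rule(self, presence, expected):
        assert inf.replicate_consensus(presence, min_replicates=2) == expected

    def test_matches_counting_oracle_on_random_matrices(self, rng):
        accs = [f"P{i}" for i in range(10)]
        for _ in range(20):
            membership = {
                f"R{r}": [a for a in accs if rng.random() < 0.5] for r in range(3)
            }
            expected = sorted(
                a
                for a in accs
                if sum(a in v for v in membership.values()) >= 2
            )
            assert inf.replicate_consensus(membership, 2) == expected


# ---------------------------------------------------------------------------
# Pipeline, comparison, absence explanations
# ---------------------------------------------------------------------------


def _build_truth_instance(seed=3, n_true=12, n_db=16):
    gen = np.random.default_rng(seed)
    db = [
        _rec(f"P{i:03d}", fx.random_protein(int(gen.integers(150, 250)), gen))
        for i in range(n_db)
    ]
    true = [r.accession for r in db[:n_true]]
    psms, _ = fx.simulate_psms(true, db, n_replicates=3, detect_prob=0.85, rng=gen)
    return db, true, psms


class TestRunInference:
    def test_truth_recovered_exactly(self):
        db, true, psms = _build_truth_instance()
        result = inf.run_inference(psms, db)
        assert result.final_accessions == sorted(true)

    def test_empty_psm_table_gives_empty_result(self):
        db, _, _ = _build_truth_instance(n_true=1, n_db=2)
        result = inf.run_inference([], db)
        assert result.final_accessions == []
        assert result.per_replicate_groups == {}

    def test_row_order_does_not_change_output(self, rng):
        db, _, psms = _build_truth_instance()
        result = inf.run_inference(psms, db)
        shuffled = [psms[i] for i in rng.permutation(len(psms))]
        result2 = inf.run_inference(shuffled, db)
        assert result.final_accessions == result2.final_accessions
        assert result.to_jsonl() == result2.to_jsonl()

    def test_jsonl_round_trip(self):
        db, _, psms = _build_truth_instance()
        result = inf.run_inference(psms, db)
        again = inf.InferenceResult.from_jsonl(result.to_jsonl())
        assert again.final_accessions == result.final_accessions
        assert again.per_replicate_reported == result.per_replicate_reported
        assert again.settings == result.settings


class TestCompareSearches:
    def _result(self, accs):
        return inf.InferenceResult(
            per_replicate_groups={},
            per_replicate_reported={},
            final_accessions=sorted(accs),
            database_accessions=frozenset(accs),
            settings=inf.InferenceSettings(),
        )

    def test_identical_lists_have_empty_exclusives(self):
        venn = inf.compare_searches(self._result({"A", "B"}), self._result({"A", "B"}))
        assert venn.only_a == venn.only_b == frozenset()
        assert venn.common == {"A", "B"}

    def test_disjoint_lists_have_empty_common(self):
        venn = inf.compare_searches(self._result({"A"}), self._result({"B"}))
        assert venn.common == frozenset()
        assert venn.only_a == {"A"} and venn.only_b == {"B"}

    def test_partition_sizes_are_consistent(self):
        a, b = {"A", "B", "C"}, {"B", "C", "D", "E"}
        venn = inf.compare_searches(self._result(a), self._result(b))
        assert len(venn.only_a) + len(venn.common) == len(a)
        assert len(venn.only_b) + len(venn.common) == len(b)


class TestExplainAbsence:
    """A battery covering all six absence reasons.

    The small database holds a reviewed entry whose peptides are a subset of
    an unreviewed isoform's (the subset case), an intersection protein, a
    single-peptide protein, and a protein whose detection is replicate-flaky.
    """

    def _scenario(self):
        gen = np.random.default_rng(9)
        blocks = []
        while len(blocks) < 12:
            b = fx.random_protein(9, gen)
            if "K" not in b[:-1] and "R" not in b[:-1] and not b.startswith("P"):
                blocks.append(b[:-1] + "K")
        s = blocks  # tryptic building blocks
        reviewed_sub = _rec("SUBSET", "".join(s[0:4]), reviewed=True)
        top_iso = _rec("TOPISO", "".join(s[0:6]))
        inter_a = _rec("COVA", "".join(s[6:9]), reviewed=True)
        inter_b = _rec("COVB", "".join(s[9:11]), reviewed=True)
        intersection = _rec("INTER", s[6] + s[9], reviewed=True)
        single = _rec("SINGLE", s[11], reviewed=True)
        db_b = [reviewed_sub, top_iso, inter_a, inter_b, intersection, single]
        peptides = s[0:11] + [s[11]]

        def psm(pep, rep, score=30.0):
            return PsmRecord(peptide=pep, score=score, replicate_id=rep)

        psms = []
        for rep in ("R1", "R2", "R3"):
            psms.extend(psm(p, rep) for p in peptides)
        decoys = [
            PsmRecord(peptide="W" * 8 + "K", score=5.0, replicate_id=r, is_decoy=True)
            for r in ("R1", "R2", "R3")
        ]
        return db_b, psms + decoys

    def test_each_reason_returned_correctly(self):
        db_b, psms = self._scenario()
        res_b = inf.run_inference(psms, db_b)
        own = inf.InferenceResult(
            per_replicate_groups={},
            per_replicate_reported={},
            final_accessions=["SUBSET", "INTER", "SINGLE", "GONE", "FLAKY"],
            database_accessions=frozenset(),
            settings=inf.InferenceSettings(),
        )
        reasons = {
            acc: inf.explain_absence(acc, own, res_b, db_b).reason
            for acc in ("SUBSET", "INTER", "SINGLE", "GONE")
        }
        assert reasons == {
            "SUBSET": "subset_of_top_protein",
            "INTER": "intersection_protein",
            "SINGLE": "insufficient_peptides",
            "GONE": "absent_from_database",
        }

    def test_no_unique_peptide_reason(self):
        # three proteins in a cyclic sharing pattern: the first is discarded
        # as an intersection protein; the other two then survive parsimony
        # (coverage would break) but fail the unique-peptide requirement
        a = _rec("NOUNIQ", "AAAGGGKCCCDDDK", reviewed=True)
        b = _rec("OTHER", "AAAGGGKEEEFFFK", reviewed=True)
        c = _rec("THIRD", "CCCDDDKEEEFFFK", reviewed=True)
        psms = [
            PsmRecord(peptide=p, score=30.0, replicate_id=r)
            for r in ("R1", "R2")
            for p in ("AAAGGGK", "CCCDDDK", "EEEFFFK")
        ] + [
            PsmRecord(peptide="WWWWWWK", score=5.0, replicate_id="R1", is_decoy=True)
        ]
        res = inf.run_inference(psms, [a, b, c])
        assert res.final_accessions == []
        own = inf.InferenceResult({}, {}, ["OTHER"], frozenset(), inf.InferenceSettings())
        assert (
            inf.explain_absence("OTHER", own, res, [a, b, c]).reason
            == "no_unique_peptide"
        )
        own2 = inf.InferenceResult({}, {}, ["NOUNIQ"], frozenset(), inf.InferenceSettings())
        assert (
            inf.explain_absence("NOUNIQ", own2, res, [a, b, c]).reason
            == "intersection_protein"
        )

    def test_failed_replicate_consensus_reason(self):
        protein = _rec("FLAKY", "AAAGGGKCCCDDDK", reviewed=True)
        psms = [
            PsmRecord(peptide=p, score=30.0, replicate_id="R1")
            for p in ("AAAGGGK", "CCCDDDK")
        ] + [
            PsmRecord(peptide="WWWWWWK", score=5.0, replicate_id=r, is_decoy=True)
            for r in ("R1", "R2", "R3")
        ]
        res = inf.run_inference(psms, [protein])
        assert res.final_accessions == []  # reported in only one replicate
        own = inf.InferenceResult({}, {}, ["FLAKY"], frozenset(), inf.InferenceSettings())
        assert (
            inf.explain_absence("FLAKY", own, res, [protein]).reason
            == "failed_replicate_consensus"
        )
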