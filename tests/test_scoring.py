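"""Interface contacts, pDockQ, clashscore, and Pareto screen ranking."""

import math
import warnings

import numpy as np
import pytest

from mechanokit import synth
from mechanokit.scoring import (
    ADJACENT_EXCLUSIONS,
    CLASH_OVERLAP,
    COVALENT_GUARD,
    DEFAULT_RADIUS,
    VDW_RADII,
    compute_clashscore,
    compute_pdockq,
    find_interface_contacts,
    pdockq_sigmoid,
    rank_screen,
    screen_hits,
)
from mechanokit.structure import Atom, Chain, Residue, StructureModel


def brute_force_contacts(s, chain_a, chain_b, cutoff=8.0):
    """O(n^2) reference: representative-atom cross-chain pairs within cutoff."""
    out = []
    for ra in s.chain(chain_a).residues:
        pa = (ra.atom("CB") or ra.atom("CA")).position
        for rb in s.chain(chain_b).residues:
            pb = (rb.atom("CB") or rb.atom("CA")).position
            if np.linalg.norm(pa - pb) <= cutoff:
                out.append((ra.key, rb.key))
    return sorted(out)


def brute_force_clashes(s):
    """O(n^2) reference clash list under the same exclusion rules."""
    entries = [(r, a) for r, a in s.iter_atoms(heavy_only=True)]
    clashes = []
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            ri, ai = entries[i]
            rj, aj = entries[j]
            d = np.linalg.norm(ai.position - aj.position)
            rad_i = VDW_RADII.get(ai.element.capitalize(), DEFAULT_RADIUS)
            rad_j = VDW_RADII.get(aj.element.capitalize(), DEFAULT_RADIUS)
            if d < COVALENT_GUARD or rad_i + rad_j - d <= CLASH_OVERLAP:
                continue
            if ri.key == rj.key:
                continue
            adjacent = (
                ri.chain_id == rj.chain_id
                and ri.icode == rj.icode == ""
                and abs(ri.number - rj.number) == 1
            )
            if adjacent:
                first, second = (ri, rj) if rj.number > ri.number else (rj, ri)
                fa = ai if first is ri else aj
                sa = aj if first is ri else ai
                if (fa.name, sa.name) in ADJACENT_EXCLUSIONS:
                    continue
            clashes.append(tuple(sorted([(ri.key, ai.name), (rj.key, aj.name)])))
    return sorted(clashes)


def random_structure(rng, n_atoms=500, box=30.0):
    """Random single-atom residues in a box (no planted structure)."""
    elements = rng.choice(["C", "N", "O", "S"], size=n_atoms)
    residues = []
    for i in range(n_atoms):
        pos = rng.uniform(0, box, size=3)
        residues.append(
            Residue("A", i + 1, "UNK", atoms=[Atom("X", elements[i], pos)])
        )
    return StructureModel("rand", [Chain("A", residues)])


class TestInterfaceContacts:
    def test_planted_contacts_found_and_match_brute_force(self, planted_complex):
        s, manifest = planted_complex
        contacts = find_interface_contacts(s, "A", "B")
        assert len(contacts) == len(manifest["contacts"])
        got = sorted((c.residue_a[1], c.residue_b[1]) for c in contacts)
        assert got == sorted(manifest["contacts"])
        brute = brute_force_contacts(s, "A", "B")
        assert sorted((c.residue_a, c.residue_b) for c in contacts) == brute

    def test_disjoint_chains_give_empty_list(self):
        s, _ = synth.gen_complex(5, 5, 0, seed=0)
        assert find_interface_contacts(s, "A", "B") == []

    def test_zero_cutoff_gives_empty_list(self, planted_complex):
        s, _ = planted_complex
        assert find_interface_contacts(s, "A", "B", cutoff=0.0) == []

    def test_glycine_uses_calpha_fallback(self):
        s, manifest = synth.gen_complex(6, 6, 3, seed=5, glycine_contacts=(1,))
        contacts = find_interface_contacts(s, "A", "B")
        assert len(contacts) == 3
        gly = s.residue("A", 2)
        assert gly.name == "GLY" and gly.atom("CB") is None


class TestPdockq:
    def test_floor_at_zero_contacts(self):
        s, _ = synth.gen_complex(5, 5, 0, seed=1)
        score = compute_pdockq(s, "A", "B")
        assert score.score == pytest.approx(0.018)
        assert score.n_contacts == 0 and score.x == 0.0

    def test_asymptote(self):
        assert pdockq_sigmoid(1e9) == pytest.approx(0.742, abs=1e-9)
        assert pdockq_sigmoid(-1e9) == pytest.approx(0.018, abs=1e-9)

    def test_planted_complex_matches_direct_sigmoid(self, planted_complex):
        s, manifest = planted_complex
        score = compute_pdockq(s, "A", "B")
        x = manifest["interface_plddt"] * math.log10(len(manifest["contacts"]))
        assert score.x == pytest.approx(x)
        expected = 0.724 / (1 + math.exp(-0.052 * (x - 152.611))) + 0.018
        assert score.score == pytest.approx(expected, abs=1e-12)

    def test_refuses_non_predicted_structure(self, planted_complex):
        s, _ = planted_complex
        import copy

        s2 = copy.deepcopy(s)
        s2.predicted = False
        with pytest.raises(ValueError, match="predicted"):
            compute_pdockq(s2, "A", "B")

    def test_monotone_in_interface_plddt_and_bounded(self):
        scores = []
        for plddt in (40.0, 60.0, 80.0, 100.0):
            s, _ = synth.gen_complex(12, 12, 8, interface_plddt=plddt, seed=3)
            scores.append(compute_pdockq(s, "A", "B").score)
        assert all(a < b for a, b in zip(scores, scores[1:]))
        assert all(0.018 <= v <= 0.742 for v in scores)


class TestClashscore:
    def test_two_distant_atoms_no_clash(self):
        res = [
            Residue("A", 1, "UNK", atoms=[Atom("C1", "C", [0.0, 0, 0])]),
            Residue("A", 3, "UNK", atoms=[Atom("C1", "C", [5.0, 0, 0])]),
        ]
        report = compute_clashscore(StructureModel("t", [Chain("A", res)]))
        assert report.clashscore == 0.0 and report.clashes == []

    def test_planted_single_clash_scores_ten(self, clashed_complex):
        s, manifest = clashed_complex
        report = compute_clashscore(s)
        assert report.n_heavy_atoms == 100
        assert len(report.clashes) == 1
        assert report.clashscore == pytest.approx(10.0)
        overlap = report.clashes[0][2]
        assert overlap == pytest.approx(0.9, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_neighbor_search_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        s = random_structure(rng, n_atoms=300, box=25.0)
        report = compute_clashscore(s)
        got = sorted(
            tuple(sorted([((a[0], a[1], a[2]), a[3]), ((b[0], b[1], b[2]), b[3])]))
            for a, b, _ in report.clashes
        )
        assert got == brute_force_clashes(s)

    def test_invariant_under_rigid_motion(self, clashed_complex, rng):
        from mechanokit.structure import transform

        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        s, _ = clashed_complex
        moved = transform(s, Q, np.array([10.0, -4.0, 2.0]))
        assert compute_clashscore(moved).clashscore == pytest.approx(
            compute_clashscore(s).clashscore
        )

    def test_far_atom_dilutes_clashscore(self, clashed_complex):
        import copy

        s, _ = clashed_complex
        s2 = copy.deepcopy(s)
        s2.chains[0].residues.append(
            Residue("A", 999, "UNK", atoms=[Atom("C1", "C", [0.0, -500.0, 0.0])])
        )
        assert compute_clashscore(s2).clashscore < compute_clashscore(s).clashscore

    def test_unknown_element_warns_and_defaults(self):
        res = [
            Residue("A", 1, "UNK", atoms=[Atom("X1", "Xx", [0.0, 0, 0])]),
            Residue("A", 3, "UNK", atoms=[Atom("C1", "C", [2.5, 0, 0])]),
        ]
        with pytest.warns(UserWarning, match="unknown element"):
            report = compute_clashscore(StructureModel("t", [Chain("A", res)]))
        assert len(report.clashes) == 1  # 1.70 + 1.70 - 2.5 = 0.9 overlap


class TestRankScreen:
    def test_singleton_gets_rank_one(self):
        ranked = rank_screen([("only", 0.4, 12.0)])
        assert ranked[0].pareto_rank == 1

    def test_documented_dominance_example(self):
        ranked = rank_screen([("A", 0.7, 5.0), ("B", 0.2, 50.0), ("C", 0.6, 2.0)])
        ranks = {e.candidate_id: e.pareto_rank for e in ranked}
        assert ranks == {"A": 1, "C": 1, "B": 2}

    def test_identical_entries_all_rank_one_sorted_by_id(self):
        ranked = rank_screen([("b", 0.5, 5.0), ("a", 0.5, 5.0), ("c", 0.5, 5.0)])
        assert [e.candidate_id for e in ranked] == ["a", "b", "c"]
        assert all(e.pareto_rank == 1 for e in ranked)

    def test_nan_rejected_with_warning(self):
        with pytest.warns(UserWarning, match="non-finite"):
            ranked = rank_screen([("ok", 0.5, 5.0), ("bad", float("nan"), 1.0)])
        assert [e.candidate_id for e in ranked] == ["ok"]

    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_and_exhaustive_dominance(self, seed):
        rng = np.random.default_rng(seed)
        entries = [(f"c{i:02d}", rng.uniform(0, 0.742), rng.uniform(0, 60)) for i in range(40)]
        ranked = rank_screen(entries)
        assert sorted(e.candidate_id for e in ranked) == sorted(e[0] for e in entries)
        by_id = {e[0]: e for e in entries}
        for e in ranked:
            dominated = any(
                o[1] >= e.pdockq and o[2] <= e.clashscore and (o[1] > e.pdockq or o[2] < e.clashscore)
                for o in entries
            )
            assert (e.pareto_rank == 1) == (not dominated)

    def test_hit_designation(self):
        ranked = rank_screen([("hit", 0.65, 3.0), ("mid", 0.3, 1.0), ("low", 0.1, 40.0)])
        assert [e.candidate_id for e in screen_hits(ranked)] == ["hit"]
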