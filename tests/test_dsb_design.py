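"""Cysteine-pair scanning: enumeration, modelling, scoring, filtering, ranking."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsbdesign import dsb_design as dd
from dsbdesign.geometry import apply_rigid, random_rotation
from dsbdesign.structure_io import Atom, Residue, Structure


def brute_force_pairs(s, cfg):
    """Independent oracle: all-pairs distance screen by direct arithmetic."""
    residues = [r for r in s.residues() if r.res_name != "PRO"]
    out = []
    for ri, rj in itertools.combinations(residues, 2):
        if ri.chain_id == rj.chain_id and abs(ri.auth_seq_num - rj.auth_seq_num) < cfg.min_seq_sep:
            continue
        ci = ri.atom("CB") or (ri.atom("CA") if ri.res_name == "GLY" else None)
        cj = rj.atom("CB") or (rj.atom("CA") if rj.res_name == "GLY" else None)
        if ci is None or cj is None:
            continue
        d = math.dist(ci.coords, cj.coords)
        if d <= cfg.max_cb_cb:
            out.append((ri.key, rj.key, round(d, 9)))
    return sorted(out, key=lambda t: t[2])


def transformed(s, rng):
    out = s.copy()
    rot = random_rotation(rng)
    trans = rng.normal(size=3) * 20
    for r in out.residues():
        for a in r.atoms:
            a.coords = apply_rigid(a.coords, rot, trans)
    return out


class TestEnumeratePairs:
    def test_matches_brute_force_oracle(self, hairpin, helix):
        cfg = dd.DesignConfig()
        for s, _ in (hairpin, helix):
            got = [(ri.key, rj.key, round(d, 9)) for ri, rj, d in dd.enumerate_pairs(s, cfg)]
            assert got == brute_force_pairs(s, cfg)

    def test_planted_pair_included_and_distance_correct(self, hairpin):
        s, truth = hairpin
        pairs = {(ri.auth_seq_num, rj.auth_seq_num): d for ri, rj, d in dd.enumerate_pairs(s)}
        assert (6, 15) in pairs
        assert pairs[(6, 15)] == pytest.approx(truth.planted_pair_d_cb["6-15"], abs=1e-9)

    def test_threshold_monotonicity(self, hairpin):
        s, _ = hairpin
        keys = lambda cutoff: {
            (ri.key, rj.key)
            for ri, rj, _ in dd.enumerate_pairs(s, dd.DesignConfig(max_cb_cb=cutoff))
        }
        small, large = keys(4.3), keys(5.0)
        assert small <= large
        assert (("A", 6, ""), ("A", 15, "")) in small  # planted at 4.06 A
        assert (("A", 5, ""), ("A", 16, "")) in large - small  # 4.61 A

    def test_sorted_by_distance(self, hairpin):
        s, _ = hairpin
        d = [t[2] for t in dd.enumerate_pairs(s)]
        assert d == sorted(d)

    def test_proline_excluded(self, hairpin):
        s, _ = hairpin
        s = s.copy()
        s.get_residue("A", 6).res_name = "PRO"
        nums = {n for t in dd.enumerate_pairs(s) for n in (t[0].auth_seq_num, t[1].auth_seq_num)}
        assert 6 not in nums


class TestStrainEnergy:
    def test_zero_only_at_ideal_geometry(self):
        assert dd.strain_energy(2.05, 104.15, 104.15, 87.0) == pytest.approx(0.0, abs=1e-12)
        assert dd.strain_energy(2.05, 104.15, 104.15, -93.0) == pytest.approx(0.0, abs=1e-12)
        assert dd.strain_energy(2.2, 104.15, 104.15, 87.0) > 0

    def test_direct_evaluations(self):
        # 100 * 0.1^2 on the distance term
        assert dd.strain_energy(2.15, 104.15, 104.15, 87.0) == pytest.approx(1.0, abs=1e-9)
        # angle terms: 0.02 * (10^2 + 10^2)
        assert dd.strain_energy(2.05, 114.15, 94.15, 87.0) == pytest.approx(4.0, abs=1e-9)
        # torsion term peaks at 2 * k_tor for chi3 90 deg off ideal
        assert dd.strain_energy(2.05, 104.15, 104.15, 87.0 - 90.0) == pytest.approx(4.0, abs=1e-9)

    def test_vectorized(self):
        e = dd.strain_energy(np.array([2.05, 2.15]), 104.15, 104.15, 87.0)
        np.testing.assert_allclose(e, [0.0, 1.0], atol=1e-9)


class TestInteractionEnergy:
    @staticmethod
    def _env_structure(points):
        """Structure with environment atoms at given coordinates plus a far pair."""
        s = Structure(identifier="env")
        pair = [
            Residue("A", 1, "", "ALA", [Atom("CA", "C", [100.0, 0, 0])]),
            Residue("A", 9, "", "ALA", [Atom("CA", "C", [110.0, 0, 0])]),
        ]
        env = [
            Residue("A", 100 + k, "", "ALA", [Atom("CA", "C", p)]) for k, p in enumerate(points)
        ]
        s.chains["A"] = pair + env
        return s, (pair[0], pair[1])

    def test_empty_space_is_zero(self):
        s, pair = self._env_structure([])
        assert dd.interaction_energy(s, [0, 0, 0], [2, 0, 0], pair) == 0.0

    def test_single_clash(self):
        s, pair = self._env_structure([[2.0, 0.0, 0.0]])
        # atom 2.0 A from sg_i: 50 * (3-2)^2 = 50; also 4.0 A from sg_j: one contact -0.1
        e = dd.interaction_energy(s, [0, 0, 0], [6.0, 0, 0], pair)
        assert e == pytest.approx(50.0 - 0.1, abs=1e-9)

    def test_ten_contacts(self):
        pts = [[4.0 * math.cos(t), 4.0 * math.sin(t), 0.0] for t in np.linspace(0, 2, 10)]
        s, pair = self._env_structure(pts)
        e = dd.interaction_energy(s, [0, 0, 0], [500.0, 0, 0], pair)
        assert e == pytest.approx(-1.0, abs=1e-9)

    def test_own_pair_atoms_excluded(self):
        s, pair = self._env_structure([])
        # sg_i sits right on top of the pair's own CA: no clash counted
        assert dd.interaction_energy(s, [100.0, 0, 0], [102.0, 0, 0], pair) == 0.0


class TestClassifyQuality:
    @pytest.mark.parametrize(
        "ei, es, expected",
        [
            (-5, 10, dd.Quality.GOOD),
            (-0.001, 19.999, dd.Quality.GOOD),
            (45, 10, dd.Quality.BAD),
            (10, 45, dd.Quality.BAD),
            (25, 25, dd.Quality.BAD),
            (0, 20, dd.Quality.MEDIUM),  # Good requires strict ei < 0 and es < 20
            (0, 0, dd.Quality.MEDIUM),
            (-5, 20, dd.Quality.MEDIUM),
            (40, 20, dd.Quality.MEDIUM),  # Bad requires strictly > 40 / > 20 pairs
            (20.0, 50, dd.Quality.BAD),
            (-10, 39, dd.Quality.MEDIUM),
        ],
    )
    def test_rule_table(self, ei, es, expected):
        assert dd.classify_quality(ei, es) is expected

    @settings(max_examples=400, derandomize=True)
    @given(
        ei=st.floats(-100, 100, allow_nan=False),
        es=st.floats(-100, 100, allow_nan=False),
    )
    def test_partition_of_the_plane(self, ei, es):
        """Exactly one class fires, and it agrees with a literal restatement."""
        q = dd.classify_quality(ei, es)
        good = ei < 0 and es < 20
        bad = ei > 40 or es > 40 or (ei > 20 and es > 20)
        if good:
            assert q is dd.Quality.GOOD
        elif bad:
            assert q is dd.Quality.BAD
        else:
            assert q is dd.Quality.MEDIUM

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            dd.classify_quality(float("nan"), 0.0)


class TestModelDisulfide:
    def test_planted_pair_models_near_ideal(self, hairpin):
        s, _ = hairpin
        pair = (s.get_residue("A", 6), s.get_residue("A", 15))
        m = dd.model_disulfide(s, pair)
        assert abs(m.d_ss - 2.05) <= 0.1
        assert m.e_strain < 20

    def test_forward_placement_recovered(self, bonded_hairpin):
        """A disulfide planted at ideal geometry is recovered by the grid search."""
        s, truth = bonded_hairpin
        pair = (s.get_residue("A", 4), s.get_residue("A", 17))
        m = dd.model_disulfide(s, pair)
        assert m.d_ss == pytest.approx(truth.planted_ss_d["4-17"], abs=0.1)

    def test_distant_pair_is_strained(self, helix):
        s, _ = helix
        pair = (s.get_residue("A", 1), s.get_residue("A", 12))
        m = dd.model_disulfide(s, pair)
        d_cb = math.dist(pair[0].atom("CB").coords, pair[1].atom("CB").coords)
        assert m.d_ss >= d_cb - 2 * 1.81 - 0.1  # geometric lower bound
        assert m.e_strain > 40

    def test_rigid_motion_invariance(self, hairpin, rng):
        s, _ = hairpin
        pair = (s.get_residue("A", 6), s.get_residue("A", 15))
        m0 = dd.model_disulfide(s, pair)
        s2 = transformed(s, rng)
        pair2 = (s2.get_residue("A", 6), s2.get_residue("A", 15))
        m1 = dd.model_disulfide(s2, pair2)
        assert m1.d_ss == pytest.approx(m0.d_ss, abs=1e-6)
        assert m1.chi3 == pytest.approx(m0.chi3, abs=1e-6)
        assert m1.e_strain == pytest.approx(m0.e_strain, abs=1e-6)
        e0 = dd.interaction_energy(s, m0.sg_i, m0.sg_j, pair)
        e1 = dd.interaction_energy(s2, m1.sg_i, m1.sg_j, pair2)
        assert e1 == pytest.approx(e0, abs=1e-6)

    def test_grid_refinement_never_increases_minimum(self, hairpin):
        s, _ = hairpin
        pair = (s.get_residue("A", 6), s.get_residue("A", 15))
        coarse = dd.model_disulfide(s, pair, dd.DesignConfig(chi1_grid_step=5.0))
        fine = dd.model_disulfide(s, pair, dd.DesignConfig(chi1_grid_step=1.0))
        assert fine.e_strain <= coarse.e_strain + 1e-12


class TestDetectNativeDisulfides:
    def test_planted_bond_found_exactly(self, bonded_hairpin):
        s, _ = bonded_hairpin
        pairs = dd.detect_native_disulfides(s)
        assert [(a.auth_seq_num, b.auth_seq_num) for a, b in pairs] == [(4, 17)]

    def test_free_cysteines_far_apart_ignored(self, hairpin):
        s, _ = hairpin
        s = s.copy()
        for num in (1, 20):
            r = s.get_residue("A", num)
            r.res_name = "CYS"
            r.atoms.append(Atom("SG", "S", r.atom("CB").coords + [3.0, 0, 0]))
        # SG atoms are ~ d_cb(1,20) apart (> 2.3 A); no bond reported
        assert dd.detect_native_disulfides(s) == []

    def test_each_cysteine_in_at_most_one_pair(self):
        s = Structure(identifier="tri")
        xs = [0.0, 2.0, 4.1]
        s.chains["A"] = [
            Residue("A", 10 * (k + 1), "", "CYS", [Atom("SG", "S", [x, 0, 0])])
            for k, x in enumerate(xs)
        ]
        pairs = dd.detect_native_disulfides(s)
        assert [(a.auth_seq_num, b.auth_seq_num) for a, b in pairs] == [(10, 20)]


class TestFiltersAndRanking:
    def test_no_active_site_configured_means_no_flags(self, hairpin):
        s, _ = hairpin
        cands = [dd.DisulfideCandidate(s.get_residue("A", 6), s.get_residue("A", 15), 4.06)]
        dd.apply_filters(cands, s, dd.DesignConfig())
        assert not cands[0].flags["near_active_site"]

    def test_active_site_neighbor_flagged(self, hairpin):
        s, _ = hairpin
        cfg = dd.DesignConfig(active_site_residues=(("A", 7),), active_site_radius=10.0)
        cands = [dd.DisulfideCandidate(s.get_residue("A", 6), s.get_residue("A", 15), 4.06)]
        dd.apply_filters(cands, s, cfg)
        assert cands[0].flags["near_active_site"]

    def test_absent_active_site_is_configuration_error(self, hairpin):
        s, _ = hairpin
        with pytest.raises(dd.ConfigurationError):
            dd.apply_filters([], s, dd.DesignConfig(active_site_residues=(("A", 999),)))

    def test_native_cys_membership_flagged(self, bonded_hairpin):
        s, _ = bonded_hairpin
        native = dd.detect_native_disulfides(s)
        cands = [dd.DisulfideCandidate(s.get_residue("A", 4), s.get_residue("A", 17), 4.07)]
        dd.apply_filters(cands, s, dd.DesignConfig(), native=native)
        assert cands[0].flags["involves_native_cys"]

    def test_disorder_margin(self, hairpin):
        from dsbdesign.structure_io import DisorderedRegion

        s, _ = hairpin
        cands = [dd.DisulfideCandidate(s.get_residue("A", 6), s.get_residue("A", 15), 4.06)]
        dd.apply_filters(cands, s, dd.DesignConfig(), disordered=[DisorderedRegion("A", 8, 9)])
        assert cands[0].flags["in_disordered_region"]  # residue 6 is within +-2 of 8

    @staticmethod
    def _cand(quality, e_strain, e_int=0.0, d_cb=4.5, flags=None):
        r1 = Residue("A", 1, "", "ALA", [Atom("CA", "C", [0, 0, 0])])
        r2 = Residue("A", 9, "", "ALA", [Atom("CA", "C", [4, 0, 0])])
        c = dd.DisulfideCandidate(r1, r2, d_cb, e_strain=e_strain, e_interaction=e_int,
                                  quality=quality)
        c.flags = flags or {}
        return c

    def test_rank_by_strain_within_class(self):
        a = self._cand(dd.Quality.GOOD, 10.0)
        b = self._cand(dd.Quality.GOOD, 5.0)
        assert dd.rank_candidates([a, b]) == [b, a]

    def test_flagged_good_still_ranks_under_good(self):
        flagged_good = self._cand(dd.Quality.GOOD, 5.0, flags={"near_active_site": True})
        plain_good = self._cand(dd.Quality.GOOD, 10.0)
        medium = self._cand(dd.Quality.MEDIUM, 1.0)
        ranked = dd.rank_candidates([medium, flagged_good, plain_good])
        assert ranked == [plain_good, flagged_good, medium]

    def test_empty_input(self):
        assert dd.rank_candidates([]) == []


class TestMutateToCys:
    def test_mutation_leaves_only_backbone_cb_sg(self, hairpin):
        s, _ = hairpin
        pair = (s.get_residue("A", 6), s.get_residue("A", 15))
        m = dd.model_disulfide(s, pair)
        mutated = dd.mutate_to_cys(s, pair, m)
        r = mutated.get_residue("A", 6)
        assert r.res_name == "CYS"
        assert sorted(a.name for a in r.atoms) == ["C", "CA", "CB", "N", "O", "SG"]
        # untouched residue
        assert mutated.get_residue("A", 10).res_name == s.get_residue("A", 10).res_name

    def test_sg_distance_matches_model(self, hairpin):
        s, _ = hairpin
        pair = (s.get_residue("A", 6), s.get_residue("A", 15))
        m = dd.model_disulfide(s, pair)
        mutated = dd.mutate_to_cys(s, pair, m)
        d = math.dist(
            mutated.get_residue("A", 6).atom("SG").coords,
            mutated.get_residue("A", 15).atom("SG").coords,
        )
        assert d == pytest.approx(m.d_ss, abs=1e-9)

    def test_pipeline_closure_detects_new_bond(self, hairpin):
        s, _ = hairpin
        pair = (s.get_residue("A", 6), s.get_residue("A", 15))
        m = dd.model_disulfide(s, pair)
        assert m.d_ss <= 2.3
        mutated = dd.mutate_to_cys(s, pair, m)
        pairs = dd.detect_native_disulfides(mutated)
        assert [(a.auth_seq_num, b.auth_seq_num) for a, b in pairs] == [(6, 15)]


class TestScanStructure:
    def test_planted_pair_is_rank_one_good(self, hairpin):
        s, _ = hairpin
        cands, native = dd.scan_structure(s)
        assert native == []
        top = cands[0]
        assert (top.res_i.auth_seq_num, top.res_j.auth_seq_num) == (6, 15)
        assert top.quality is dd.Quality.GOOD
        assert abs(top.model.d_ss - 2.05) <= 0.1

    def test_candidate_invariants(self, hairpin):
        s, _ = hairpin
        cfg = dd.DesignConfig()
        cands, _ = dd.scan_structure(s, cfg)
        assert cands  # hairpin has cross-strand pairs
        for c in cands:
            assert c.d_cb <= cfg.max_cb_cb
            assert c.model.d_ss >= 0
            assert c.quality is dd.classify_quality(c.e_interaction, c.e_strain)
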