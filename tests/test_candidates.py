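"""Tag placement, merging, candidate ranking, and section construction."""

import math

import pytest

from pipic.chem import PROTON, WATER, SearchConfig, residue_mass
from pipic.candidates import (CandidateRejected, CandidatePair, Placement,
                              build_sections, classify_residues, locate_tags,
                              merge_filter_tags, rank_candidates)
from pipic.fmindex import FMDatabase, ProteinEntry
from pipic.simulate import simulate_spectrum
from pipic.spectra import normalize_intensities, theoretical_ions
from pipic.tags import Tag, tags_from_spectrum

P1 = ProteinEntry("P1", "MKGASDELNVAGLSRTTWK")


def make_placement(protein, offset, residues, start_mass=300.0, inten=10.0):
    masses = [start_mass]
    for a in residues:
        masses.append(masses[-1] + residue_mass(a))
    n = len(masses)
    return Placement(protein, offset, residues, tuple(masses),
                     tuple([inten] * n), inten * n)


class TestLocate:
    def test_single_target_placement(self, config):
        db = FMDatabase.build([("P1", "MKGASDEWNVAGWSR")], seed=0)
        tag = Tag("ASD", (300.0, 371.03711, 458.06914, 573.09608),
                  (1.0, 1.0, 1.0, 1.0), 4.0, "b")
        placements = locate_tags([tag], db, config.min_match_len)
        assert [(p.protein.accession, p.offset) for p in placements] \
            == [("P1", 3)]

    def test_decoy_placements_retained(self, config):
        # a homopolymer stretch survives shuffling, hitting both sequences
        db = FMDatabase.build([("P1", "AAAAAA")], seed=0)
        tag = Tag("AAA", (300.0, 371.03711, 442.07422, 513.11133),
                  (1.0,) * 4, 4.0, "b")
        placements = locate_tags([tag], db, config.min_match_len)
        accs = {p.protein.accession for p in placements}
        assert accs == {"P1", "DECOY_P1"}

    def test_no_match_empty(self, config):
        db = FMDatabase.build([("P1", "GGGGG")], seed=0)
        tag = Tag("WWW", (300.0, 486.07931, 672.15862, 858.23793),
                  (1.0,) * 4, 4.0, "b")
        assert locate_tags([tag], db, config.min_match_len) == []


class TestMergeFilter:
    def test_consistent_overlap_merged(self, config):
        b, _ = theoretical_ions(P1.sequence)
        lad = [PROTON] + list(b)
        p1 = Placement(P1, 2, "GASD", tuple(lad[2:7]), (10.0,) * 5, 50.0)
        p2 = Placement(P1, 3, "ASDE", tuple(lad[3:8]), (10.0,) * 5, 50.0)
        merged = merge_filter_tags([p1, p2], config.tau2)
        assert len(merged) == 1
        assert merged[0].residues == "GASDE"
        assert merged[0].offset == 2
        # union of 6 distinct boundary peaks
        assert merged[0].score == pytest.approx(60.0)

    def test_inconsistent_overlap_drops_lower_score(self, config):
        p1 = make_placement(P1, 2, "GASD", start_mass=300.0, inten=10.0)
        p2 = make_placement(P1, 3, "ASDE", start_mass=500.0, inten=5.0)
        merged = merge_filter_tags([p1, p2], config.tau2)
        assert len(merged) == 1
        assert merged[0].residues == "GASD"

    def test_non_overlapping_unchanged(self, config):
        p1 = make_placement(P1, 2, "GAS", 300.0)
        p2 = make_placement(P1, 10, "AGL", 700.0)
        merged = merge_filter_tags([p1, p2], config.tau2)
        assert [(p.offset, p.residues) for p in merged] \
            == [(2, "GAS"), (10, "AGL")]


class TestRank:
    def test_scores_sum_and_order(self):
        cfg = SearchConfig(max_candidates_per_spectrum=10)
        pa = make_placement(P1, 2, "GAS", 300.0, inten=25.0)
        p2prot = ProteinEntry("P0", "WWWGASWWW")
        pb = make_placement(p2prot, 3, "GAS", 300.0, inten=10.0)
        cands = rank_candidates([pa, pb], cfg)
        assert [c.protein.accession for c in cands[:2]] == ["P1", "P0"]
        assert cands[0].score == pytest.approx(100.0)

    def test_max_candidates_truncation(self):
        cfg = SearchConfig()
        pa = make_placement(P1, 2, "GAS", 300.0, inten=25.0)
        pb = make_placement(ProteinEntry("P0", "WWWGASWWW"), 3, "GAS", 300.0)
        ranked = rank_candidates([pa, pb], cfg, max_candidates=1)
        assert len(ranked) == 1
        assert ranked[0].protein.accession == "P1"


class TestClassify:
    def test_walkthrough_with_valines(self):
        # dm = 500, residues ~99.07 each, P_max 250, P_min -50:
        # fixed grows until the残 remainder drops to P_max, optional while
        # the remainder stays above P_min
        cfg = SearchConfig(p_min=-50.0, p_max=250.0)
        res = [(i, "V") for i in range(8)]
        fixed, optional, infeasible = classify_residues(res, 500.0, cfg)
        assert len(fixed) == 3 and len(optional) == 2
        assert [o for o, _a in fixed] == [0, 1, 2]
        assert len(infeasible) == 3

    def test_small_dm_all_optional(self):
        cfg = SearchConfig(p_min=-250.0, p_max=500.0)
        res = [(i, "G") for i in range(4)]
        fixed, optional, _inf = classify_residues(res, 120.0, cfg)
        assert fixed == []
        assert len(optional) == 4  # 4*57 = 228 <= 120 + 250

    def test_zero_window_forces_abutting_terminus(self):
        cfg = SearchConfig(p_min=0.0, p_max=0.0)
        cfg.p_min = 0.0
        fixed, optional, inf = classify_residues([(0, "G")], 0.0, cfg)
        assert fixed == [] and optional == []
        assert len(inf) == 1

    def test_partition_is_disjoint_and_ordered(self):
        cfg = SearchConfig()
        res = [(i, a) for i, a in enumerate("GAVLKWSDE")]
        f, o, i = classify_residues(res, 700.0, cfg)
        assert f + o + i == res


class TestBuildSections:
    def _candidate_for(self, backbone, pattern, protein_seq, offset,
                       registry, config, snr=math.inf):
        spec, _ = simulate_spectrum(backbone, pattern, snr, seed=4, n_noise=0)
        spec = normalize_intensities(spec)
        prot = ProteinEntry("P1", protein_seq.replace("I", "L"))
        db = FMDatabase.build([("P1", protein_seq)], seed=1)
        tags = tags_from_spectrum(spec, config.tau2)
        placements = locate_tags(tags, db, config.min_match_len)
        cands = rank_candidates([p for p in placements
                                 if not p.protein.is_decoy], config)
        return cands[0], spec

    def test_gap_dm_is_anchor_difference(self, config):
        left = make_placement(P1, 2, "GAS", 300.0)
        b_right = 561.1
        right = Placement(P1, 7, "LNV", (b_right, b_right + 113.08406,
                                         b_right + 227.12699,
                                         b_right + 326.1954),
                          (10.0,) * 4, 40.0)
        cand = CandidatePair(P1, [left, right], 80.0)
        left_end = left.peak_masses[-1]
        from pipic.spectra import Spectrum, Peak
        spectrum = Spectrum("x", [Peak(300.0, 1.0)], 2000.0, 2)
        secs = build_sections(cand, spectrum, config, [])
        gap = [s for s in secs if s.kind == "gap"][0]
        assert gap.dm == pytest.approx(b_right - left_end)
        assert [a for _o, a in gap.residues] == ["D", "E"]

    def test_n_section_dm_subtracts_proton(self, config, small_registry):
        cand, spec = self._candidate_for("GASDELNVK", [], P1.sequence, 2,
                                         small_registry, config)
        secs = build_sections(cand, spec, config, small_registry)
        n_sec = [s for s in secs if s.kind == "N"]
        if n_sec:  # tag may start after position 1
            first = cand.placements[0]
            assert n_sec[0].dm == pytest.approx(
                first.peak_masses[0] - PROTON, abs=1e-9)

    def test_section_mass_closure(self, config, small_registry):
        """Anchors plus section dm values reconstruct the precursor."""
        backbone = "GASDELNVAGLSR"
        pattern = [(2, "Phospho@S", 79.966331)]
        cand, spec = self._candidate_for(backbone, pattern, P1.sequence, 2,
                                         small_registry, config)
        secs = build_sections(cand, spec, config, small_registry)
        # total mass accounted: tags' residues + each section's dm
        tag_mass = sum(residue_mass(a) for p in cand.placements
                       for a in p.residues)
        dm_total = 0.0
        for s in secs:
            if s.kind == "gap":
                dm_total += s.dm - 0.0
        # N dm + C dm + gaps + tag residues == peptide residue mass total
        n_dm = sum(s.dm for s in secs if s.kind == "N")
        c_dm = sum(s.dm for s in secs if s.kind == "C")
        gaps = sum(s.dm for s in secs if s.kind == "gap")
        # gap dm includes residue+PTM mass between anchors
        total = n_dm + c_dm + gaps + tag_mass
        expected = spec.precursor_neutral_mass - WATER
        assert total == pytest.approx(expected, abs=config.tau1 * 4)

    def test_empty_gap_skipped_and_inconsistent_rejected(self, config):
        left = make_placement(P1, 2, "GAS", 300.0)
        # adjacent tag starting exactly at left end mass: empty gap, ok
        lm = left.peak_masses[-1]
        right = Placement(P1, 5, "DEL", (lm, lm + 115.02694,
                                         lm + 244.06953, lm + 357.15359),
                          (10.0,) * 4, 40.0)
        from pipic.spectra import Spectrum, Peak
        spectrum = Spectrum("x", [Peak(300.0, 1.0)], 2000.0, 2)
        cand = CandidatePair(P1, [left, right], 80.0)
        secs = build_sections(cand, spectrum, config, [])
        assert not [s for s in secs if s.kind == "gap"]

        # same offsets but anchor gap of +3 Da: no residue/PTM can explain
        right_bad = Placement(P1, 5, "DEL",
                              tuple(m + 3.0 for m in right.peak_masses),
                              (10.0,) * 4, 40.0)
        cand_bad = CandidatePair(P1, [left, right_bad], 80.0)
        with pytest.raises(CandidateRejected):
            build_sections(cand_bad, spectrum, config, [])
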