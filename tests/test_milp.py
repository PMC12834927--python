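"""PWC linearization, section MILPs, the exhaustive oracle, decoding."""

import math
import random

import numpy as np
import pytest

from pipic.chem import (PROTON, WATER, PTMEntry, SearchConfig, residue_mass,
                        ptms_for_residue)
from pipic.candidates import Section
from pipic.milp import (LinearModel, add_pwc_block, brute_force_characterize,
                        build_gap_model, build_section_model,
                        build_terminal_model, check_solution, decode_solution,
                        pwc_eval, pwc_intervals, score_assignment, solve_model)
from pipic.spectra import Peak, Spectrum

from conftest import gap_section, ladder_spectrum

TAU2 = 0.02


def _spec(masses, intensities, neutral=1000.0):
    return Spectrum("m", [Peak(m, i) for m, i in zip(masses, intensities)],
                    neutral, 2)


def lp_max_pwc(t, spectrum, tau2, q_extra=1.0):
    """Maximize f over the linearized PWC block at a fixed input mass."""
    m = LinearModel()
    intervals = pwc_intervals(spectrum, tau2)
    q = spectrum.peaks[-1].mass + tau2 + q_extra if spectrum.peaks else 1.0
    q = max(q, t + 1.0)
    g = max((p.intensity for p in spectrum.peaks), default=1.0)
    f = add_pwc_block(m, t, {}, intervals, q, g)
    if f is None:
        return 0.0
    status, x, obj = m.solve(10)
    assert status == "optimal", status
    return obj


class TestPWCEval:
    def test_center_returns_intensity(self):
        s = _spec([500.0], [7.0])
        assert pwc_eval(500.0, s, TAU2) == 7.0

    def test_beyond_all_windows_zero(self):
        s = _spec([500.0], [7.0])
        assert pwc_eval(600.0, s, TAU2) == 0.0

    def test_half_open_boundaries(self):
        s = _spec([500.0], [7.0])
        assert pwc_eval(500.0 - TAU2, s, TAU2) == 0.0   # left end open
        assert pwc_eval(500.0 + TAU2, s, TAU2) == 7.0   # right end closed

    def test_overlapping_windows_merge_to_max(self):
        s = _spec([500.0, 500.01], [3.0, 9.0])
        assert pwc_eval(500.0, s, TAU2) == 9.0
        assert len(pwc_intervals(s, TAU2)) == 1


class TestLinearization:
    def test_single_peak_inside(self):
        s = _spec([400.0], [5.0])
        assert lp_max_pwc(400.0, s, TAU2) == pytest.approx(5.0, abs=1e-6)

    def test_single_peak_outside(self):
        s = _spec([400.0], [5.0])
        assert lp_max_pwc(350.0, s, TAU2) == pytest.approx(0.0, abs=1e-6)

    def test_three_peak_random_scan_matches_direct_eval(self):
        rng = random.Random(5)
        s = _spec([300.0, 500.0, 500.025], [2.0, 8.0, 4.0])
        for _ in range(60):
            t = rng.uniform(250.0, 600.0)
            assert lp_max_pwc(t, s, TAU2) == pytest.approx(
                pwc_eval(t, s, TAU2), abs=1e-6)

    def test_boundary_cases_match(self):
        s = _spec([300.0, 420.0], [2.0, 6.0])
        for t in (300.0 - TAU2, 300.0 + TAU2, 420.0 - TAU2, 420.0 + TAU2):
            assert lp_max_pwc(t, s, TAU2) == pytest.approx(
                pwc_eval(t, s, TAU2), abs=1e-6)


class TestGapModel:
    def test_zero_ptm_optimal_when_mass_explained(self, small_registry):
        sec, spec = _plain_gap(small_registry)
        sol = solve_model(build_gap_model(sec, spec, SearchConfig()))
        assert sol.status == "optimal"
        assert sol.ptms == []

    def test_planted_ptm_recovered_at_supported_site(self, phospho_gap):
        sec, spec = phospho_gap
        sol = solve_model(build_gap_model(sec, spec, SearchConfig()))
        assert sol.status == "optimal"
        assert sol.ptms == [(2, "Phospho@S", 79.966331)]

    def test_nmax_zero_with_unexplained_mass_infeasible(self, phospho_gap):
        sec, spec = phospho_gap
        cfg = SearchConfig(n_max=0)
        sol = solve_model(build_gap_model(sec, spec, cfg))
        assert sol.status == "infeasible"

    def test_requires_gap_kind(self, phospho_gap):
        sec, spec = phospho_gap
        sec.kind = "N"
        with pytest.raises(ValueError):
            build_gap_model(sec, spec, SearchConfig())


def _plain_gap(registry):
    backbone = "GASDK"
    spec = ladder_spectrum(backbone)
    return gap_section(backbone, 2, 4, registry, offset0=2), spec


def _terminal_n_section(backbone, pattern, registry, config, tag_cut):
    """N-section of a simulated peptide anchored at the b-ion of tag_cut."""
    from pipic.spectra import theoretical_ions

    spec = ladder_spectrum(backbone, pattern)
    b, _ = theoretical_ions(backbone, list(pattern))
    t_anchor = float(b[tag_cut - 1])
    residues = [(i, backbone[i]) for i in range(tag_cut)]
    n_opt = tag_cut  # open boundary across the whole prefix
    sec = Section("N", residues, n_opt, PROTON, t_anchor, spec.C)
    sec.ptm_options = [ptms_for_residue(registry, a) for _o, a in residues]
    return sec, spec


class TestTerminalModel:
    def test_no_optional_reduces_to_gap_behaviour(self, small_registry):
        backbone = "GASDK"
        sec, spec = _terminal_n_section(backbone, [], small_registry,
                                        SearchConfig(), 2)
        sec.n_optional = 0  # force all-fixed: structurally a gap at proton
        model = build_terminal_model(sec, spec, SearchConfig())
        sol = solve_model(model)
        assert sol.status == "optimal" and sol.ptms == []

    def test_boundary_selected_by_mass_balance(self, small_registry):
        # anchored at b2 of GASDK: true prefix GA; model must keep both
        sec, spec = _terminal_n_section("GASDK", [], small_registry,
                                        SearchConfig(), 2)
        sol = solve_model(build_terminal_model(sec, spec, SearchConfig()))
        assert sol.status == "optimal"
        assert sol.n_absent_optional == 0
        assert sol.boundary_offset == 0

    def test_ptm_on_absent_residue_caught_by_checker(self, small_registry):
        sec, _spec2 = _terminal_n_section("SASDK", [], small_registry,
                                          SearchConfig(), 2)
        with pytest.raises(AssertionError):
            check_solution(sec, SearchConfig(), n_absent=1,
                           ptms={0: ("Phospho@S", 79.966331)})

    def test_enzyme_cut_restriction_enforced(self, small_registry):
        # disallow every cut except dropping the first optional residue
        sec, spec = _terminal_n_section("GASDK", [], small_registry,
                                        SearchConfig(), 2)
        sec.allowed_cuts = {1}
        sol = solve_model(build_terminal_model(sec, spec, SearchConfig()))
        # mass balance wants cut 0 (full prefix); cut 1 cannot absorb GA
        assert sol.status == "infeasible"


class TestSolveSemantics:
    def test_infeasible_toy(self, small_registry):
        sec, spec = _plain_gap(small_registry)
        sec.t_anchor += 5.0  # unreachable extra 5 Da
        sol = solve_model(build_gap_model(sec, spec, SearchConfig()))
        assert sol.status == "infeasible"

    def test_solution_feasibility_rechecked(self, phospho_gap):
        sec, spec = phospho_gap
        sol = solve_model(build_gap_model(sec, spec, SearchConfig()))
        check_solution(sec, SearchConfig(), sol.n_absent_optional,
                       {i: (n, m) for (o, n, m), i in
                        zip(sol.ptms, [j for j, (o2, _a) in
                                       enumerate(sec.residues)
                                       if o2 in [p[0] for p in sol.ptms]])})

    def test_decode_roundtrip_rescores_to_objective(self, phospho_gap):
        sec, spec = phospho_gap
        cfg = SearchConfig()
        model = build_gap_model(sec, spec, cfg)
        sol = solve_model(model)
        frag, ptms, _bnd = decode_solution(model, sol)
        assert frag == "SD"
        idx = {o: i for i, (o, _a) in enumerate(sec.residues)}
        rescored = score_assignment(sec, model.spectrum, cfg,
                                    sol.n_absent_optional,
                                    {idx[o]: (n, m) for o, n, m in ptms},
                                    model.intervals)
        assert rescored == pytest.approx(sol.objective, abs=1e-6)


class TestOracle:
    def test_refuses_oversized_sections(self, small_registry):
        backbone = "GASDKLRTYWAGS"
        spec = ladder_spectrum(backbone)
        sec = gap_section(backbone, 1, 12, small_registry)
        with pytest.raises(ValueError):
            brute_force_characterize(sec, spec, SearchConfig())

    def test_zero_ptm_dominates_when_unsupported(self, small_registry):
        sec, spec = _plain_gap(small_registry)
        bf = brute_force_characterize(sec, spec, SearchConfig())
        assert bf.status == "optimal" and bf.ptms == {}

    def test_agrees_with_solver_on_planted_case(self, phospho_gap):
        sec, spec = phospho_gap
        cfg = SearchConfig()
        sol = solve_model(build_gap_model(sec, spec, cfg))
        bf = brute_force_characterize(sec, spec, cfg)
        assert sol.objective == pytest.approx(bf.objective, abs=1e-6)
        decoded = tuple((o, n, m) for o, n, m in sol.ptms)
        oracle_decoded = tuple((sec.residues[i][0], n, m)
                               for i, (n, m) in sorted(bf.ptms.items()))
        assert decoded == oracle_decoded


def test_penalty_monotonicity(phospho_gap):
    sec, spec = phospho_gap
    counts = []
    for penalty in (0.0, 0.1, 1000.0):
        cfg = SearchConfig(ptm_penalty=penalty)
        sol = solve_model(build_gap_model(sec, spec, cfg))
        counts.append(len(sol.ptms) if sol.status != "infeasible" else None)
    # with a forced +80 Da the PTM can never be dropped entirely, but the
    # count must not increase as the penalty rises
    real = [c for c in counts if c is not None]
    assert real == sorted(real, reverse=True)


def random_section_and_spectrum(rng, registry, terminal=False):
    """A random small section with a spectrum of 30 random peaks.

    Half the time a feasible PTM assignment is planted (dm set to its total
    mass); otherwise dm is arbitrary and the instance may be infeasible.
    """
    letters = "ACDEFGHKLMNPQRSTVWY"
    n = rng.randint(2, 6 if terminal else 8)
    residues = [(i, rng.choice(letters)) for i in range(n)]
    options = []
    for _o, a in residues:
        pool = ptms_for_residue(registry, a)
        extra = [PTMEntry(f"rnd{rng.randrange(10**6)}@{a}",
                          round(rng.uniform(-90, 180), 6), a)
                 for _ in range(rng.randint(0, 2))]
        options.append((pool + extra)[:4])
    base = sum(residue_mass(a) for _o, a in residues)
    n_opt = rng.randint(0, n - 1) if terminal else 0
    if rng.random() < 0.5:
        k = rng.randint(0, 2)
        sites = rng.sample(range(n), min(k, n))
        planted = sum(options[i][rng.randrange(len(options[i]))].mass
                      for i in sites if options[i])
        absent = rng.randint(0, n_opt)
        absent_mass = sum(residue_mass(residues[i][1]) for i in range(absent))
        dm = base - absent_mass + planted + rng.uniform(-0.005, 0.005)
    else:
        dm = base + rng.uniform(-150, 250)
    a0 = PROTON if terminal else rng.uniform(200.0, 600.0)
    c_total = a0 + dm + rng.uniform(400.0, 900.0)
    masses = sorted(rng.uniform(100.0, c_total) for _ in range(30))
    spec = Spectrum("r", [Peak(m, rng.uniform(1.0, 100.0)) for m in masses],
                    c_total - 2 * PROTON, 2)
    sec = Section("N" if terminal else "gap", residues, n_opt, a0, a0 + dm,
                  c_total)
    sec.ptm_options = options
    return sec, spec


@pytest.mark.parametrize("terminal", [False, True])
def test_oracle_equivalence_randomized(small_registry, terminal):
    """Solver optimum equals exhaustive enumeration on random instances."""
    rng = random.Random(42 if terminal else 24)
    cfg = SearchConfig()
    n_compared = 0
    for _ in range(25):
        sec, spec = random_section_and_spectrum(rng, small_registry, terminal)
        model = build_section_model(sec, spec, cfg)
        sol = solve_model(model, time_limit=20)
        bf = brute_force_characterize(sec, spec, cfg)
        assert (sol.status == "infeasible") == (bf.status == "infeasible")
        if sol.status == "optimal":
            assert sol.objective == pytest.approx(bf.objective, abs=1e-6)
            decoded = (sol.n_absent_optional,
                       tuple((o, n, m) for o, n, m in sol.ptms))
            oracle_set = {(na, tuple((sec.residues[s][0], n2, m2)
                                     for s, n2, m2 in pat))
                          for na, pat in bf.optima}
            assert decoded in oracle_set
            if len(oracle_set) == 1:
                canonical = (bf.n_absent_optional,
                             tuple((sec.residues[i][0], n, m) for i, (n, m)
                                   in sorted(bf.ptms.items())))
                assert decoded == canonical
            n_compared += 1
    assert n_compared >= 5
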