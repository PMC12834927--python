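"""MILP models for simultaneous boundary determination and PTM assignment.

One section yields one mixed-integer linear program. Binary variables x
mark the presence of a candidate PTM on a residue; binary variables z mark
the presence of an optional residue in a terminal section (monotone toward
the anchoring tag, so the present set is a contiguous stretch ending at
the tag). The b- and y-ion masses of every residue position are affine in
x and z; each ion mass feeds a linearized piecewise-constant (PWC) lookup
of the experimental peak intensities, and the objective maximizes the
total matched intensity minus a penalty per placed PTM.

The gap-section model and the terminal-section model share one builder:
a gap is simply a section whose residues are all fixed and whose left
anchor is a tag peak rather than the terminus constant.

An exhaustive enumerator over the same feasible set serves as an
independent oracle for the solver.
"""

from __future__ import annotations


from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint
from scipy.optimize import milp as _scipy_milp

from .chem import SearchConfig, residue_mass
from .candidates import Section
from .spectra import Spectrum, normalize_intensities

# Strict-inequality tolerance of the PWC interval bounds. Must sit safely
# above the solver's scaled primal feasibility tolerance or the open interval
# ends become porous; 1e-4 Da is still far below any fragment tolerance.
EPS = 1e-4


# ---------------------------------------------------------------------------
# piecewise-constant peak-intensity function
# ---------------------------------------------------------------------------

def pwc_intervals(spectrum: Spectrum, tau2: float
                  ) -> list[tuple[float, float, float]]:
    """Half-open intensity windows ``(lo, hi, I]`` around each peak.

    Windows are ``(M - tau2, M + tau2]``; overlapping windows (peaks closer
    than 2*tau2) are merged keeping the maximum intensity so the breakpoint
    sequence stays well ordered. Exactly-touching windows stay separate
    (the left end is open).
    """
    out: list[list[float]] = []
    for p in spectrum.peaks:
        lo, hi = p.mass - tau2, p.mass + tau2
        if out and lo < out[-1][1]:
            out[-1][1] = max(out[-1][1], hi)
            out[-1][2] = max(out[-1][2], p.intensity)
        else:
            out.append([lo, hi, p.intensity])
    return [tuple(w) for w in out]


def pwc_eval(t: float, spectrum: Spectrum, tau2: float,
             intervals: list[tuple[float, float, float]] | None = None
             ) -> float:
    """Intensity of the peak window containing ``t`` (0 between windows).

    The window is open on the left and closed on the right:
    ``PWC(t) = I_e`` iff ``M_e - tau2 < t <= M_e + tau2``.
    """
    if intervals is None:
        intervals = pwc_intervals(spectrum, tau2)
    idx = bisect_left([w[1] for w in intervals], t)
    if idx < len(intervals):
        lo, hi, inten = intervals[idx]
        if lo < t <= hi:
            return inten
    return 0.0


# ---------------------------------------------------------------------------
# generic MILP container on top of scipy's HiGHS interface
# ---------------------------------------------------------------------------

class LinearModel:
    """A maximization MILP assembled row by row."""

    def __init__(self) -> None:
        self.obj: list[float] = []
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.integer: list[int] = []
        self._rows: list[tuple[dict[int, float], float, float]] = []

    @property
    def n_vars(self) -> int:
        return len(self.obj)

    def add_var(self, lb: float = 0.0, ub: float = 1.0, integer: bool = True,
                obj: float = 0.0) -> int:
        self.obj.append(obj)
        self.lb.append(lb)
        self.ub.append(ub)
        self.integer.append(1 if integer else 0)
        return len(self.obj) - 1

    def add_row(self, terms: dict[int, float], lo: float, hi: float) -> None:
        self._rows.append((terms, lo, hi))

    def solve(self, time_limit: float | None = None
              ) -> tuple[str, np.ndarray | None, float | None]:
        """Returns (status, assignment, objective); maximization sense."""
        n = self.n_vars
        data, ri, ci = [], [], []
        lo, hi = [], []
        for r, (terms, l, h) in enumerate(self._rows):
            for c, v in terms.items():
                data.append(v)
                ri.append(r)
                ci.append(c)
            lo.append(l)
            hi.append(h)
        a = sparse.csr_matrix((data, (ri, ci)), shape=(len(self._rows), n))
        options = {"time_limit": float(time_limit)} if time_limit else None
        res = _scipy_milp(
            c=-np.asarray(self.obj),
            constraints=LinearConstraint(a, np.asarray(lo), np.asarray(hi)),
            integrality=np.asarray(self.integer),
            bounds=Bounds(np.asarray(self.lb), np.asarray(self.ub)),
            options=options,
        )
        if res.status == 0:
            return "optimal", res.x, -res.fun
        if res.status == 2:
            return "infeasible", None, None
        if res.x is not None:  # hit a limit with an incumbent in hand
            return "outOfTime", res.x, -res.fun
        return "outOfTime", None, None


def add_pwc_block(model: LinearModel, const: float, terms: dict[int, float],
                  intervals: list[tuple[float, float, float]],
                  q_bound: float, g_big: float) -> int | None:
    """Constrain a fresh return variable f to equal PWC(t) at the optimum.

    ``t = const + sum(coef * var)`` is the ion-mass expression. One selector
    binary d_i per breakpoint interval (gap, window, gap, ..., final gap up
    to ``q_bound``); the selected interval must contain t and f is bounded
    by the selected interval's intensity. Since the objective maximizes f,
    f attains PWC(t) exactly. Returns the index of f (None for a peakless
    spectrum, where PWC is identically zero).
    """
    if not intervals:
        return None
    n_iv = len(intervals)
    d = [model.add_var() for _ in range(2 * n_iv + 1)]
    heights = [0.0] * (2 * n_iv + 1)
    lower = [0.0] * (2 * n_iv + 1)   # selected => t >= lower (with EPS)
    upper = [0.0] * (2 * n_iv + 1)   # selected => t <= upper
    for e, (lo, hi, inten) in enumerate(intervals, start=1):
        heights[2 * e - 1] = inten
        lower[2 * e - 1] = lo + EPS
        upper[2 * e - 1] = hi
        lower[2 * e] = hi + EPS
        upper[2 * e - 2] = lo
    upper[2 * n_iv] = q_bound

    model.add_row({v: 1.0 for v in d}, 1.0, 1.0)
    # t - sum(lower_i d_i) >= 0  and  t - sum(upper_i d_i) <= 0
    row_lo = dict(terms)
    row_hi = dict(terms)
    for i, v in enumerate(d):
        row_lo[v] = row_lo.get(v, 0.0) - lower[i]
        row_hi[v] = row_hi.get(v, 0.0) - upper[i]
    model.add_row(row_lo, -const, np.inf)
    model.add_row(row_hi, -np.inf, -const)

    h_max = max(heights)
    f = model.add_var(lb=0.0, ub=h_max, integer=False, obj=1.0)
    for i, v in enumerate(d):
        # f <= F_i + G_i (1 - d_i), with the per-interval big-M as small as
        # F_i + G_i >= max_j F_j allows (keeps solver row scaling tight)
        g_i = min(g_big, h_max - heights[i])
        if g_i <= 0:
            continue  # bound already enforced by f's upper bound
        model.add_row({f: 1.0, v: g_i}, -np.inf, heights[i] + g_i)
    return f


# ---------------------------------------------------------------------------
# section models
# ---------------------------------------------------------------------------

@dataclass
class MILPModelSpec:
    """A built model plus the variable bookkeeping needed to decode it."""

    section: Section
    spectrum: Spectrum                  # normalized copy used by the model
    config: SearchConfig
    model: LinearModel | None
    x_vars: dict[tuple[int, int], int]  # (residue idx, ptm idx) -> var
    z_vars: dict[int, int]              # residue idx -> var (optional only)
    intervals: list[tuple[float, float, float]]
    trivially_infeasible: bool = False


@dataclass
class MILPSolution:
    status: str                         # optimal | outOfTime | infeasible
    objective: float | None
    ptms: list[tuple[int, str, float]]  # (protein offset, name, mass)
    n_absent_optional: int
    boundary_offset: int | None         # protein offset of decoded terminus


def _ion_expressions(sec: Section, x_vars, z_vars):
    """Affine (const, terms) pairs for the two ion series of every residue.

    Residue index i contributes ion1_i (anchor-base side, covering model
    positions <= i) and ion2_i (anchor-peak side, covering positions > i).
    Presence of optional residues multiplies their residue mass by z.
    """
    n = len(sec.residues)
    exprs = []
    for i in range(n):
        c1, t1 = sec.a0, {}
        for j in range(i + 1):
            w = residue_mass(sec.residues[j][1])
            if j in z_vars:
                t1[z_vars[j]] = t1.get(z_vars[j], 0.0) + w
            else:
                c1 += w
            for k, p in enumerate(sec.ptm_options[j]):
                t1[x_vars[j, k]] = t1.get(x_vars[j, k], 0.0) + p.mass
        c2, t2 = sec.c_total - sec.t_anchor, {}
        for j in range(i + 1, n):
            w = residue_mass(sec.residues[j][1])
            if j in z_vars:
                t2[z_vars[j]] = t2.get(z_vars[j], 0.0) + w
            else:
                c2 += w
            for k, p in enumerate(sec.ptm_options[j]):
                t2[x_vars[j, k]] = t2.get(x_vars[j, k], 0.0) + p.mass
        exprs.append(((c1, t1), (c2, t2)))
    return exprs


def build_section_model(section: Section, spectrum: Spectrum,
                        config: SearchConfig) -> MILPModelSpec:
    """Build the MILP of one section (gap or terminal, unified form)."""
    if config.normalize:
        spectrum = normalize_intensities(spectrum)
    intervals = pwc_intervals(spectrum, config.tau2)
    spec = MILPModelSpec(section, spectrum, config, None, {}, {}, intervals)

    n = len(section.residues)
    if n == 0:
        spec.trivially_infeasible = abs(section.dm) > config.tau1
        return spec

    m = LinearModel()
    for i in range(n):
        for k, p in enumerate(section.ptm_options[i]):
            spec.x_vars[i, k] = m.add_var(obj=-config.ptm_penalty)
    for i in range(section.n_optional):
        spec.z_vars[i] = m.add_var()

    # mass balance: fixed residue masses + optional z masses + PTM masses = dm
    fixed_w = sum(residue_mass(a) for j, (_o, a) in enumerate(section.residues)
                  if j not in spec.z_vars)
    balance: dict[int, float] = {}
    for i in spec.z_vars:
        balance[spec.z_vars[i]] = residue_mass(section.residues[i][1])
    for (i, k), v in spec.x_vars.items():
        balance[v] = balance.get(v, 0.0) + section.ptm_options[i][k].mass
    target = section.dm - fixed_w
    if balance:
        m.add_row(balance, target - config.tau1, target + config.tau1)
    elif abs(target) > config.tau1:
        spec.trivially_infeasible = True
        return spec

    # optional residues: contiguous presence toward the tag; PTM gating
    for i in range(1, section.n_optional):
        m.add_row({spec.z_vars[i - 1]: 1.0, spec.z_vars[i]: -1.0},
                  -np.inf, 0.0)
    if section.allowed_cuts is not None:
        # forbid absent-prefix counts whose decoded terminus is non-enzymatic:
        # cut k corresponds to z_{k-1}=0, z_k=1
        n_opt = section.n_optional
        if not section.allowed_cuts or (n_opt == 0
                                        and 0 not in section.allowed_cuts):
            spec.trivially_infeasible = True
            return spec
        for k in range(n_opt + 1):
            if k in section.allowed_cuts:
                continue
            if k == 0:
                m.ub[spec.z_vars[0]] = 0.0
            elif k == n_opt:
                m.lb[spec.z_vars[n_opt - 1]] = 1.0
            else:
                m.add_row({spec.z_vars[k]: 1.0, spec.z_vars[k - 1]: -1.0},
                          -np.inf, 0.0)
    for i in range(n):
        row = {spec.x_vars[i, k]: 1.0
               for k in range(len(section.ptm_options[i]))}
        if not row:
            continue
        if i in spec.z_vars:
            row[spec.z_vars[i]] = -1.0
            m.add_row(row, -np.inf, 0.0)
        else:
            m.add_row(row, -np.inf, 1.0)
    if spec.x_vars:
        m.add_row({v: 1.0 for v in spec.x_vars.values()}, -np.inf,
                  float(config.n_max))

    # objective: matched intensity via one PWC block per ion expression.
    # The b+y complementarity row is algebraically identical to the mass
    # balance above, so it is not duplicated; the solution checker verifies
    # it per residue.
    last_peak = spectrum.peaks[-1].mass if spectrum.peaks else 0.0
    q_bound = max(last_peak + config.tau2,
                  section.c_total + max(config.p_max, 0.0)) + 1.0
    g_big = max((p.intensity for p in spectrum.peaks), default=1.0)
    for (c1, t1), (c2, t2) in _ion_expressions(section, spec.x_vars,
                                               spec.z_vars):
        add_pwc_block(m, c1, t1, intervals, q_bound, g_big)
        add_pwc_block(m, c2, t2, intervals, q_bound, g_big)

    spec.model = m
    return spec


def build_gap_model(section: Section, spectrum: Spectrum,
                    config: SearchConfig) -> MILPModelSpec:
    if section.kind != "gap":
        raise ValueError("expected a gap section")
    return build_section_model(section, spectrum, config)


def build_terminal_model(section: Section, spectrum: Spectrum,
                         config: SearchConfig) -> MILPModelSpec:
    if section.kind not in ("N", "C"):
        raise ValueError("expected a terminal section")
    return build_section_model(section, spectrum, config)


# ---------------------------------------------------------------------------
# scoring, decoding, validation
# ---------------------------------------------------------------------------

def score_assignment(section: Section, spectrum: Spectrum,
                     config: SearchConfig, n_absent: int,
                     ptms: dict[int, tuple[str, float]],
                     intervals=None) -> float:
    """Objective of a concrete assignment, via direct PWC evaluation.

    ``n_absent`` counts absent leading optional residues; ``ptms`` maps a
    model residue index to its (name, mass). Absent residues still
    contribute their (degenerate) ion terms, mirroring the model objective.
    """
    if intervals is None:
        intervals = pwc_intervals(spectrum, config.tau2)
    n = len(section.residues)
    if n == 0:
        return 0.0
    contrib = np.zeros(n)
    for i in range(n):
        if i >= n_absent:
            contrib[i] = residue_mass(section.residues[i][1])
        if i in ptms:
            contrib[i] += ptms[i][1]
    prefix = np.cumsum(contrib)
    total = prefix[-1] if n else 0.0
    score = 0.0
    for i in range(n):
        ion1 = section.a0 + prefix[i]
        ion2 = (section.c_total - section.t_anchor) + (total - prefix[i])
        score += pwc_eval(ion1, spectrum, config.tau2, intervals)
        score += pwc_eval(ion2, spectrum, config.tau2, intervals)
    return score - config.ptm_penalty * len(ptms)


def check_solution(section: Section, config: SearchConfig, n_absent: int,
                   ptms: dict[int, tuple[str, float]]) -> None:
    """Independent numeric re-check of every model constraint.

    Verifies the mass balance, per-residue b+y complementarity, the
    one-PTM-per-residue rule via the dict structure, the PTM count cap,
    optional-residue contiguity (implied by the prefix representation) and
    the no-PTM-on-absent-residue rule. Raises AssertionError on violation.
    """
    n = len(section.residues)
    assert 0 <= n_absent <= section.n_optional
    if section.allowed_cuts is not None:
        assert n_absent in section.allowed_cuts, "non-enzymatic boundary"
    assert len(ptms) <= config.n_max, "PTM count cap violated"
    masses = []
    for i in range(n):
        w = residue_mass(section.residues[i][1]) if i >= n_absent else 0.0
        if i in ptms:
            assert i >= n_absent, "PTM on an absent optional residue"
            w += ptms[i][1]
        masses.append(w)
    total = sum(masses)
    assert abs(total - section.dm) <= config.tau1 + 1e-9, "mass balance"
    prefix = 0.0
    for i in range(n):
        prefix += masses[i]
        b = section.a0 + prefix
        y = (section.c_total - section.t_anchor) + (total - prefix)
        assert abs(b + y - section.c_total) <= config.tau1 + 1e-9, \
            "b/y complementarity"


def _tiebreak_key(n_absent: int, ptms: dict[int, tuple[str, float]]):
    sites = tuple(sorted(ptms))
    names = tuple(ptms[s][0] for s in sites)
    return (len(ptms), sites, names, n_absent)


def _canonicalize(section: Section, spectrum: Spectrum, config: SearchConfig,
                  n_absent: int, ptms: dict[int, tuple[str, float]],
                  objective: float, intervals) -> dict[int, tuple[str, float]]:
    """Shift PTMs to tie-break-preferred equal-objective sites.

    Tries moving each chosen PTM to an earlier compatible free site (same
    entry, so the mass balance is untouched); a move is kept when the
    re-scored objective is unchanged and the tie-break key improves.
    """
    improved = True
    while improved:
        improved = False
        for i in sorted(ptms, reverse=True):
            name, mass = ptms[i]
            for j in range(n_absent, i):
                if j in ptms:
                    continue
                if not any(p.name == name for p in section.ptm_options[j]):
                    continue
                trial = dict(ptms)
                del trial[i]
                trial[j] = (name, mass)
                if _tiebreak_key(n_absent, trial) >= _tiebreak_key(n_absent, ptms):
                    continue
                if abs(score_assignment(section, spectrum, config, n_absent,
                                        trial, intervals) - objective) <= 1e-9:
                    ptms = trial
                    improved = True
                    break
            if improved:
                break
    return ptms


def solve_model(spec: MILPModelSpec, time_limit: float | None = None
                ) -> MILPSolution:
    """Solve one section model; validate and canonicalize the solution."""
    section, config = spec.section, spec.config
    if time_limit is None:
        time_limit = config.time_limit
    if spec.trivially_infeasible:
        return MILPSolution("infeasible", None, [], 0, None)
    if spec.model is None:  # empty, trivially feasible section
        return MILPSolution("optimal", 0.0, [], 0,
                            _boundary(section, 0))

    status, x, _obj = spec.model.solve(time_limit)
    if status == "infeasible" or x is None:
        return MILPSolution(status, None, [], 0, None)

    ptms: dict[int, tuple[str, float]] = {}
    for (i, k), v in spec.x_vars.items():
        if x[v] > 0.5:
            p = section.ptm_options[i][k]
            ptms[i] = (p.name, p.mass)
    n_absent = sum(1 for i, v in spec.z_vars.items() if x[v] < 0.5)

    objective = score_assignment(section, spec.spectrum, config, n_absent,
                                 ptms, spec.intervals)
    if status == "optimal":
        ptms = _canonicalize(section, spec.spectrum, config, n_absent, ptms,
                             objective, spec.intervals)
    check_solution(section, config, n_absent, ptms)

    protein_ptms = [(section.residues[i][0], name, mass)
                    for i, (name, mass) in sorted(ptms.items())]
    return MILPSolution(status, objective, protein_ptms, n_absent,
                        _boundary(section, n_absent))


def _boundary(section: Section, n_absent: int) -> int | None:
    """Decoded peptide terminus (protein offset) of a terminal section.

    For the N-section this is the offset of the first present residue; for
    the C-section, one past the last present residue. Gap sections have no
    boundary.
    """
    if section.kind == "gap":
        return None
    present = section.residues[n_absent:]
    if section.kind == "N":
        return present[0][0] if present else section.residues[-1][0] + 1
    return present[0][0] + 1 if present else section.residues[-1][0]


def decode_solution(spec: MILPModelSpec, solution: MILPSolution
                    ) -> tuple[str, list[tuple[int, str, float]], int | None]:
    """Fragment string, PTM pattern (protein offsets) and boundary offset."""
    if solution.status == "infeasible":
        raise ValueError("cannot decode an infeasible solution")
    section = spec.section
    present = section.residues[solution.n_absent_optional:]
    ordered = sorted(present)  # protein order
    fragment = "".join(a for _o, a in ordered)
    return fragment, solution.ptms, solution.boundary_offset


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

@dataclass
class BruteForceResult:
    status: str
    objective: float | None
    n_absent_optional: int
    ptms: dict[int, tuple[str, float]]
    optima: list[tuple[int, tuple]] = field(default_factory=list)
    # optima entries: (n_absent, tuple of (site, name, mass)) within 1e-9


def brute_force_characterize(section: Section, spectrum: Spectrum,
                             config: SearchConfig) -> BruteForceResult:
    """Exhaustively score every feasible assignment of one small section.

    Enumerates all contiguous optional-residue prefixes and all PTM
    assignments (at most one per residue, count capped, mass balance within
    tau1) and returns the argmax with deterministic tie-breaking: highest
    objective, then fewest PTMs, then lexicographically smallest site
    vector. Refuses sections beyond a small-instance guard.
    """
    n = len(section.residues)
    if n > 10:
        raise ValueError("oracle guard: more than 10 residues")
    space = 1
    for opts in section.ptm_options:
        space *= len(opts) + 1
    if space * (section.n_optional + 1) > 10**6:
        raise ValueError("oracle guard: assignment space too large")
    if config.normalize:
        spectrum = normalize_intensities(spectrum)
    intervals = pwc_intervals(spectrum, config.tau2)

    feasible: list[tuple[float, int, dict]] = []

    for n_absent in range(section.n_optional + 1):
        if (section.allowed_cuts is not None
                and n_absent not in section.allowed_cuts):
            continue
        present = list(range(n_absent, n))
        base = sum(residue_mass(section.residues[i][1]) for i in present)
        target = section.dm - base
        lo_bnd = [min(0.0, min((p.mass for p in section.ptm_options[i]),
                               default=0.0)) for i in present]
        hi_bnd = [max(0.0, max((p.mass for p in section.ptm_options[i]),
                               default=0.0)) for i in present]
        suf_lo = np.concatenate([np.cumsum(lo_bnd[::-1])[::-1], [0.0]])
        suf_hi = np.concatenate([np.cumsum(hi_bnd[::-1])[::-1], [0.0]])

        def rec(idx: int, acc_mass: float, count: int,
                chosen: dict[int, tuple[str, float]]) -> None:
            if count > config.n_max:
                return
            if (acc_mass + suf_lo[idx] > target + config.tau1 or
                    acc_mass + suf_hi[idx] < target - config.tau1):
                return
            if idx == len(present):
                if abs(acc_mass - target) > config.tau1:
                    return
                if len(feasible) >= 10**5:
                    raise ValueError("oracle guard: too many feasible points")
                obj = score_assignment(section, spectrum, config, n_absent,
                                       chosen, intervals)
                feasible.append((obj, n_absent, dict(chosen)))
                return
            i = present[idx]
            rec(idx + 1, acc_mass, count, chosen)
            for p in section.ptm_options[i]:
                chosen[i] = (p.name, p.mass)
                rec(idx + 1, acc_mass + p.mass, count + 1, chosen)
                del chosen[i]

        rec(0, 0.0, 0, {})

    if not feasible:
        return BruteForceResult("infeasible", None, 0, {})
    best_obj = max(o for o, _na, _ch in feasible)
    winners = [t for t in feasible if t[0] >= best_obj - 1e-9]
    winners.sort(key=lambda t: (-t[0], *_tiebreak_key(t[1], t[2])))
    obj, n_absent, chosen = winners[0]
    return BruteForceResult(
        "optimal", obj, n_absent, chosen,
        [(na, tuple((s, *ch[s]) for s in sorted(ch)))
         for _o, na, ch in winners])
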