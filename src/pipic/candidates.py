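"""Turn located tags into ranked candidates and cut them into sections.

A candidate is a protein together with a chain of non-overlapping located
tags whose anchor-peak gaps are explainable by residue masses plus a
bounded total PTM mass. The stretches of protein sequence not covered by
tags become sections: an N-section (before the first tag, unknown
N-terminal boundary), gap sections (between consecutive tags) and a
C-section (after the last tag, unknown C-terminal boundary). Each section
carries a known mass target derived from the anchoring peaks; the MILP
decides the PTM pattern (and, for terminal sections, the boundary).

All ladders here are in b-frame coordinates: peak k of a placement at
protein offset ``o`` is the b-ion covering the peptide prefix ending at
protein position ``o + k``. C-sections are handled by mirroring: residue
order reversed and the ladder read on the y-ion axis, reusing the same
model with anchor base proton + water.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import PROTON, WATER, PTMEntry, SearchConfig, residue_mass, ptms_for_residue
from .fmindex import FMDatabase, ProteinEntry, bidirectional_match
from .spectra import Spectrum
from .tags import Tag


class CandidateRejected(Exception):
    """A candidate whose anchors cannot be reconciled with any peptide."""


@dataclass(frozen=True)
class Placement:
    """One tag (possibly trimmed by fuzzy matching) located on a protein."""

    protein: ProteinEntry
    offset: int
    residues: str
    peak_masses: tuple[float, ...]      # b-frame, length len(residues)+1
    peak_intensities: tuple[float, ...]
    score: float

    @property
    def end(self) -> int:
        return self.offset + len(self.residues)


@dataclass
class CandidatePair:
    protein: ProteinEntry
    placements: list[Placement]  # sorted by offset, non-overlapping chain
    score: float


@dataclass
class Section:
    """One model-ready section with its mass target and PTM candidates.

    ``residues`` are in model order (left to right in the modelled ion
    frame); the first ``n_optional`` of them are optional with presence
    monotone toward the anchoring tag. ``dm = t_anchor - a0`` is the total
    residue-plus-PTM mass the section must explain.
    """

    kind: str                      # 'N', 'gap', 'C'
    residues: list[tuple[int, str]]  # (protein offset, residue letter)
    n_optional: int
    a0: float                      # inner/left anchor constant
    t_anchor: float                # outer/right anchor (peak-derived)
    c_total: float                 # precursor plus two protons
    ptm_options: list[list[PTMEntry]] = field(default_factory=list)
    # permitted absent-prefix counts for terminal sections under an enzyme
    # constraint (None = every cut allowed)
    allowed_cuts: set[int] | None = None

    @property
    def dm(self) -> float:
        return self.t_anchor - self.a0


def locate_tags(tags: list[Tag], db: FMDatabase, min_match_len: int = 3,
                max_positions_per_tag: int = 500) -> list[Placement]:
    """Locate every tag on target and decoy proteins, trimming via fuzzy match.

    Decoy placements are retained (required for FDR later). Tags hitting
    more than ``max_positions_per_tag`` positions are too unspecific and
    are dropped.
    """
    seen: set[tuple[str, int, str, tuple[float, ...]]] = set()
    out: list[Placement] = []
    for tag in tags:
        matches = bidirectional_match(tag.residues, db, min_match_len)
        if len(matches) > max_positions_per_tag:
            continue
        for m in matches:
            i = m.start_in_tag
            j = i + len(m.substring)
            masses = tag.peak_masses[i:j + 1]
            intens = tag.peak_intensities[i:j + 1]
            key = (m.protein.accession, m.offset, m.substring, masses)
            if key in seen:
                continue
            seen.add(key)
            out.append(Placement(m.protein, m.offset, m.substring,
                                 masses, intens, float(sum(intens))))
    return out


def _ladder_dict(p: Placement) -> dict[int, tuple[float, float]]:
    """Boundary position -> (mass, intensity) for one placement."""
    return {p.offset + k: (p.peak_masses[k], p.peak_intensities[k])
            for k in range(len(p.peak_masses))}


def merge_filter_tags(placements: list[Placement], tau2: float
                      ) -> list[Placement]:
    """Merge overlapping consistent placements; drop inconsistent low scorers.

    Two placements on the same protein overlap if they share residues;
    they are merged when their ladders agree within ``tau2`` at every
    shared boundary (the merged ladder is the union, scored by the summed
    intensity of the union). Otherwise the lower-scoring placement is
    discarded as noise.
    """
    ordered = sorted(placements, key=lambda p: (-p.score, p.offset, p.residues))
    accepted: list[dict] = []  # each: {'lo','hi','ladder','protein'}
    for p in ordered:
        ladder = _ladder_dict(p)
        merged_into = None
        drop = False
        for cl in accepted:
            if p.offset < cl["hi"] and cl["lo"] < p.end:  # residue overlap
                shared = set(ladder) & set(cl["ladder"])
                ok = all(abs(ladder[b][0] - cl["ladder"][b][0]) <= tau2
                         for b in shared)
                if ok:
                    merged_into = cl
                else:
                    drop = True
                break
        if drop:
            continue
        if merged_into is None:
            accepted.append({"lo": p.offset, "hi": p.end, "ladder": ladder,
                             "protein": p.protein})
        else:
            for b, mv in ladder.items():
                merged_into["ladder"].setdefault(b, mv)
            merged_into["lo"] = min(merged_into["lo"], p.offset)
            merged_into["hi"] = max(merged_into["hi"], p.end)

    out = []
    for cl in accepted:
        bounds = sorted(cl["ladder"])
        assert bounds == list(range(cl["lo"], cl["hi"] + 1))
        masses = tuple(cl["ladder"][b][0] for b in bounds)
        intens = tuple(cl["ladder"][b][1] for b in bounds)
        residues = cl["protein"].sequence[cl["lo"]:cl["hi"]]
        out.append(Placement(cl["protein"], cl["lo"], residues, masses,
                             intens, float(sum(intens))))
    out.sort(key=lambda p: p.offset)
    return out


def _chainable(left: Placement, right: Placement, p_min: float,
               p_max: float, tau1: float) -> bool:
    """Can two placements belong to one peptide (gap mass explainable)?"""
    gap_res = right.protein.sequence[left.end:right.offset]
    anchor = right.peak_masses[0] - left.peak_masses[-1]
    if anchor < -tau1:
        return False
    residual = anchor - sum(residue_mass(a) for a in gap_res)
    return p_min - tau1 <= residual <= p_max + tau1


def rank_candidates(placements: list[Placement], config: SearchConfig,
                    max_candidates: int | None = None
                    ) -> list[CandidatePair]:
    """Group placements per protein, merge, chain, rank by summed score.

    Alongside merged chains, every raw placement is kept as a single-tag
    fallback candidate: the merge step discards overlapping inconsistent
    tags by score, and a noise-laddered tag can outscore the true one, so
    alternatives must survive ranking. ``max_candidates`` truncates the
    ranked list when given; the search pipeline instead caps candidates at
    MILP entry, after cheap structural rejection.
    """
    by_protein: dict[str, list[Placement]] = {}
    for p in placements:
        by_protein.setdefault(p.protein.accession, []).append(p)

    candidates: list[CandidatePair] = []
    seen: set[tuple[str, tuple[int, ...]]] = set()

    def add(placements: list[Placement]) -> None:
        key = (placements[0].protein.accession,
               tuple((p.offset, len(p.residues),
                      round(p.peak_masses[0], 4)) for p in placements))
        if key not in seen:
            seen.add(key)
            candidates.append(CandidatePair(
                placements[0].protein, placements,
                sum(q.score for q in placements)))

    for acc in sorted(by_protein):
        merged = merge_filter_tags(by_protein[acc], config.tau2)
        chain: list[Placement] = []
        for p in merged:
            if chain and _chainable(chain[-1], p, config.p_min, config.p_max,
                                    config.tau1):
                chain.append(p)
            else:
                if chain:
                    add(chain)
                chain = [p]
        if chain:
            add(chain)
        # single-tag fallbacks from the raw (pre-merge) placements: a chain
        # whose sections prove infeasible, or a merge that discarded the
        # true tag, must not take the good placements with it
        for p in merged:
            add([p])
        for p in sorted(by_protein[acc],
                        key=lambda p: (-p.score, p.offset, p.residues)):
            add([p])

    candidates.sort(key=lambda c: (-c.score, c.protein.accession,
                                   c.placements[0].offset))
    if max_candidates is not None:
        candidates = candidates[:max_candidates]
    return candidates


def classify_residues(residues_outward: list[tuple[int, str]], dm: float,
                      config: SearchConfig
                      ) -> tuple[list[tuple[int, str]], list[tuple[int, str]],
                                 list[tuple[int, str]]]:
    """Split terminal-section residues into fixed / optional / infeasible.

    ``residues_outward`` runs from the anchoring tag toward the terminus.
    Fixed residues are the minimal prefix without which the remaining mass
    exceeds ``p_max``; optional residues extend while the remaining mass
    stays at or above ``p_min``; the rest are infeasible and excluded.
    """
    fixed: list[tuple[int, str]] = []
    optional: list[tuple[int, str]] = []
    total = 0.0
    i = 0
    while i < len(residues_outward) and dm - total > config.p_max:
        fixed.append(residues_outward[i])
        total += residue_mass(residues_outward[i][1])
        i += 1
    while i < len(residues_outward):
        w = residue_mass(residues_outward[i][1])
        if total + w > dm - config.p_min:
            break
        optional.append(residues_outward[i])
        total += w
        i += 1
    return fixed, optional, residues_outward[i:]


def _tryptic_cut_ok(kind: str, seq: str, boundary: int) -> bool:
    """Is a peptide terminus at protein offset ``boundary`` tryptic?

    For the N side ``boundary`` is the offset of the first peptide residue
    (valid after K/R or at the protein start); for the C side it is one
    past the last residue (valid after K/R or at the protein end).
    """
    if kind == "N":
        return boundary == 0 or seq[boundary - 1] in "KR"
    return boundary == len(seq) or seq[boundary - 1] in "KR"


def _allowed_cuts(kind: str, seq: str, model_res: list[tuple[int, str]],
                  n_optional: int, tag_boundary: int) -> set[int]:
    """Absent-prefix counts whose decoded terminus is a tryptic boundary."""
    allowed = set()
    for k in range(n_optional + 1):
        present = model_res[k:]
        if present:
            off = present[0][0]
            boundary = off if kind == "N" else off + 1
        else:
            boundary = tag_boundary
        if _tryptic_cut_ok(kind, seq, boundary):
            allowed.add(k)
    return allowed


def _terminal_section(kind: str, residues_outward: list[tuple[int, str]],
                      a0: float, t_anchor: float, c_total: float,
                      config: SearchConfig, registry: list[PTMEntry],
                      seq: str, tag_boundary: int) -> Section | None:
    dm = t_anchor - a0
    if dm < -config.tau1:
        raise CandidateRejected(f"{kind}-section anchor below base ({dm:.3f})")
    fixed, optional, _inf = classify_residues(residues_outward, dm, config)
    total_avail = sum(residue_mass(a) for _o, a in fixed + optional)
    if dm - total_avail > config.p_max + config.tau1:
        raise CandidateRejected(
            f"{kind}-section mass {dm:.3f} unexplainable within P bounds")
    if not fixed and not optional:
        if abs(dm) <= config.tau1:
            if (config.enzyme == "trypsin"
                    and not _tryptic_cut_ok(kind, seq, tag_boundary)):
                raise CandidateRejected(f"{kind}-terminus not tryptic")
            return None  # tag abuts the terminus exactly
        raise CandidateRejected(f"{kind}-section has no residues for {dm:.3f}")
    # model order: optional residues outermost-first, then fixed, anchoring
    # tag at the right end of the modelled frame
    model_res = optional[::-1] + fixed[::-1]
    sec = Section(kind, model_res, len(optional), a0, t_anchor, c_total)
    sec.ptm_options = [ptms_for_residue(registry, a) for _o, a in model_res]
    if config.enzyme == "trypsin":
        sec.allowed_cuts = _allowed_cuts(kind, seq, model_res, len(optional),
                                         tag_boundary)
        if not sec.allowed_cuts:
            raise CandidateRejected(f"no tryptic {kind}-boundary available")
    return sec


def build_sections(candidate: CandidatePair, spectrum: Spectrum,
                   config: SearchConfig,
                   registry: list[PTMEntry]) -> list[Section]:
    """Sections of one candidate; raises CandidateRejected when inconsistent."""
    seq = candidate.protein.sequence
    c_total = spectrum.C
    placements = candidate.placements
    sections: list[Section] = []

    first, last = placements[0], placements[-1]

    # N-section: residues before the first tag, outward = decreasing offset
    n_out = [(o, seq[o]) for o in range(first.offset - 1, -1, -1)]
    sec = _terminal_section("N", n_out, PROTON, first.peak_masses[0],
                            c_total, config, registry, seq, first.offset)
    if sec is not None:
        sections.append(sec)

    # gap sections between consecutive placements
    for left, right in zip(placements, placements[1:]):
        gap = [(o, seq[o]) for o in range(left.end, right.offset)]
        bl, br = left.peak_masses[-1], right.peak_masses[0]
        dm = br - bl
        if not gap:
            if abs(dm) > config.tau1:
                raise CandidateRejected(f"empty gap with residual {dm:.3f}")
            continue
        residual = dm - sum(residue_mass(a) for _o, a in gap)
        if not (config.p_min - config.tau1 <= residual
                <= config.p_max + config.tau1):
            raise CandidateRejected(f"gap residual {residual:.3f} out of bounds")
        sec = Section("gap", gap, 0, bl, br, c_total)
        sec.ptm_options = [ptms_for_residue(registry, a) for _o, a in gap]
        sections.append(sec)

    # C-section: residues after the last tag, outward = increasing offset,
    # mirrored onto the y-ion axis
    c_out = [(o, seq[o]) for o in range(last.end, len(seq))]
    sec = _terminal_section("C", c_out, PROTON + WATER,
                            c_total - last.peak_masses[-1],
                            c_total, config, registry, seq, last.end)
    if sec is not None:
        sections.append(sec)

    return sections
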