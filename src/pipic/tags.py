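"""Sequence-tag extraction from MS2 spectra via a spectrum graph.

A tag is a short, PTM-invariant residue string read off consecutive peak
mass differences. Each graph path is emitted in both ion-frame readings:
as a b-frame tag (residues left to right, raw peak masses) and as a
y-frame tag (reversed residues, peak masses complemented through
C = precursor neutral mass + 2 protons, which maps a y-ion ladder onto
b-frame coordinates). Tag scores are the summed intensities of the
involved peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import AA_MASSES, fold_il
from .spectra import Peak, Spectrum

# Canonical residue alphabet for edges: I is folded into L (isobaric).
_EDGE_MASSES = sorted(
    {fold_il(a): m for a, m in AA_MASSES.items()}.items(),
    key=lambda kv: kv[1],
)


@dataclass(frozen=True)
class Tag:
    """A scored tag with its supporting peak ladder (b-frame coordinates)."""

    residues: str
    peak_masses: tuple[float, ...]      # length len(residues) + 1, ascending
    peak_intensities: tuple[float, ...]
    score: float
    frame: str  # 'b' or 'y'

    def __post_init__(self) -> None:
        assert len(self.peak_masses) == len(self.residues) + 1
        assert all(b > a for a, b in zip(self.peak_masses, self.peak_masses[1:]))


def build_spectrum_graph(spectrum: Spectrum, tau2: float
                         ) -> dict[int, list[tuple[int, str]]]:
    """Directed graph over peak indices.

    Edge i -> j labelled with residue a iff the mass difference
    ``m_j - m_i`` matches the residue mass within ``2 * tau2``. I/L are
    collapsed to the canonical letter L.
    """
    masses = [p.mass for p in spectrum.peaks]
    adj: dict[int, list[tuple[int, str]]] = {i: [] for i in range(len(masses))}
    max_w = _EDGE_MASSES[-1][1] + 2 * tau2
    for i, mi in enumerate(masses):
        for j in range(i + 1, len(masses)):
            diff = masses[j] - mi
            if diff > max_w:
                break
            for letter, w in _EDGE_MASSES:
                if abs(diff - w) <= 2 * tau2:
                    adj[i].append((j, letter))
    return adj


def extract_tags(spectrum: Spectrum,
                 graph: dict[int, list[tuple[int, str]]],
                 min_len: int = 3, max_len: int = 7,
                 top_k: int = 50, branch_cap: int = 4) -> list[Tag]:
    """Enumerate scored tags of length ``min_len..max_len`` from the graph.

    Depth-first path enumeration with a per-node branching cap (the
    ``branch_cap`` highest-intensity successors are explored). Each path is
    emitted in both b- and y-frame readings; results are deduplicated on
    (residues, ladder) and the ``top_k`` by score are returned, sorted by
    score descending with lexicographic tie-break on residues.
    """
    if min_len < 2:
        raise ValueError("min_len must be at least 2")
    peaks = spectrum.peaks
    c = spectrum.C
    capped: dict[int, list[tuple[int, str]]] = {}
    for i, edges in graph.items():
        ranked = sorted(edges, key=lambda e: (-peaks[e[0]].intensity, peaks[e[0]].mass))
        capped[i] = ranked[:branch_cap]

    found: dict[tuple[str, tuple[float, ...], str], Tag] = {}

    def emit(path: list[int], letters: list[str]) -> None:
        ladder = tuple(peaks[i].mass for i in path)
        intens = tuple(peaks[i].intensity for i in path)
        score = sum(intens)
        residues = "".join(letters)
        b_tag = Tag(residues, ladder, intens, score, "b")
        y_ladder = tuple(c - m for m in reversed(ladder))
        y_tag = Tag(residues[::-1], y_ladder, intens[::-1], score, "y")
        for t in (b_tag, y_tag):
            key = (t.residues, t.peak_masses, t.frame)
            if key not in found:
                found[key] = t

    def dfs(path: list[int], letters: list[str]) -> None:
        if min_len <= len(letters):
            emit(path, letters)
        if len(letters) >= max_len:
            return
        for j, letter in capped[path[-1]]:
            path.append(j)
            letters.append(letter)
            dfs(path, letters)
            path.pop()
            letters.pop()

    for start in range(len(peaks)):
        dfs([start], [])

    tags = sorted(found.values(), key=lambda t: (-t.score, t.residues))
    return tags[:top_k]


def with_terminal_anchors(spectrum: Spectrum) -> Spectrum:
    """Spectrum augmented with the four zero-evidence terminal boundaries.

    The b-ladder ends b0 = proton and bn = C - proton - water, and the
    y-ladder ends y0 = proton + water and yn = C - proton, are known
    constants even though no peak is observed there; adding them as
    near-zero-intensity nodes lets tags reach the first and last residue
    of a peptide.
    """
    from .chem import PROTON, WATER

    c = spectrum.C
    anchors = [PROTON, PROTON + WATER, c - PROTON - WATER, c - PROTON]
    existing = {round(p.mass, 4) for p in spectrum.peaks}
    peaks = list(spectrum.peaks) + [Peak(m, 1e-9) for m in anchors
                                    if round(m, 4) not in existing and m > 0]
    peaks.sort()
    return Spectrum(spectrum.id, peaks, spectrum.precursor_neutral_mass,
                    spectrum.precursor_charge)


def tags_from_spectrum(spectrum: Spectrum, tau2: float, min_len: int = 3,
                       max_len: int = 7, top_k: int = 50,
                       branch_cap: int = 4,
                       terminal_anchors: bool = True) -> list[Tag]:
    """Convenience wrapper: graph construction plus tag extraction."""
    if terminal_anchors:
        spectrum = with_terminal_anchors(spectrum)
    graph = build_spectrum_graph(spectrum, tau2)
    return extract_tags(spectrum, graph, min_len, max_len, top_k, branch_cap)
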