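"""Spectrum container, MGF I/O, preprocessing, and theoretical b/y ladders.

Peak masses are on the singly-charged fragment scale (neutral fragment plus
one proton), deisotoped upstream. ``C`` denotes the precursor neutral mass
plus two protons; complementary b/y pairs of one peptide sum to ``C``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .chem import PROTON, WATER, residue_mass

log = logging.getLogger(__name__)


class Peak(NamedTuple):
    mass: float
    intensity: float


@dataclass
class Spectrum:
    """One deisotoped MS2 spectrum with a known precursor.

    Peaks are kept strictly increasing in mass; near-coincident peaks
    (within 1e-4 Da) are merged by summing intensities.
    """

    id: str
    peaks: list[Peak]
    precursor_neutral_mass: float
    precursor_charge: int

    def __post_init__(self) -> None:
        if any(p.mass <= 0 or p.intensity <= 0 for p in self.peaks):
            raise ValueError("peak masses and intensities must be positive")
        if any(b.mass < a.mass for a, b in zip(self.peaks, self.peaks[1:])):
            log.warning("spectrum %s: peaks unsorted; sorting", self.id)
            self.peaks = sorted(self.peaks)
        merged: list[Peak] = []
        for p in self.peaks:
            if merged and p.mass - merged[-1].mass < 1e-4:
                prev = merged.pop()
                merged.append(Peak(prev.mass, prev.intensity + p.intensity))
            else:
                merged.append(p)
        self.peaks = merged

    @property
    def C(self) -> float:
        """Precursor neutral mass plus two protons (b+y sum constant)."""
        return self.precursor_neutral_mass + 2.0 * PROTON

    @property
    def masses(self) -> np.ndarray:
        return np.array([p.mass for p in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file; precursor m/z is converted to neutral mass."""
    spectra = []
    with _mgf.read(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            if "pepmass" not in params:
                raise ValueError(f"spectrum {i}: missing PEPMASS")
            mz = params["pepmass"][0]
            charge = int(params.get("charge", [2])[0])
            neutral = mz * charge - charge * PROTON
            peaks = [Peak(float(m), float(z))
                     for m, z in zip(entry["m/z array"], entry["intensity array"])
                     if z > 0]
            spectra.append(Spectrum(
                id=str(params.get("title", f"index={i}")),
                peaks=peaks,
                precursor_neutral_mass=neutral,
                precursor_charge=charge,
            ))
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF with 6-decimal peaks (lossless round trip)."""
    entries = []
    for s in spectra:
        mz = (s.precursor_neutral_mass + s.precursor_charge * PROTON) / s.precursor_charge
        entries.append({
            "m/z array": s.masses,
            "intensity array": s.intensities,
            "params": {"title": s.id, "pepmass": mz,
                       "charge": f"{s.precursor_charge}+"},
        })
    # default fragment format writes full float repr -> lossless round trip
    _mgf.write(entries, str(path), file_mode="w")


def preprocess_spectrum(spectrum: Spectrum, top_n_per_window: int = 10,
                        window: float = 100.0) -> Spectrum:
    """Keep the ``top_n_per_window`` most intense peaks per mass window."""
    keep: list[Peak] = []
    by_window: dict[int, list[Peak]] = {}
    for p in spectrum.peaks:
        by_window.setdefault(int(p.mass // window), []).append(p)
    for peaks in by_window.values():
        peaks = sorted(peaks, key=lambda p: -p.intensity)[:top_n_per_window]
        keep.extend(peaks)
    keep.sort()
    return Spectrum(spectrum.id, keep, spectrum.precursor_neutral_mass,
                    spectrum.precursor_charge)


def normalize_intensities(spectrum: Spectrum, base: float = 100.0) -> Spectrum:
    """Scale intensities so the base peak equals ``base``."""
    if not spectrum.peaks:
        return spectrum
    top = max(p.intensity for p in spectrum.peaks)
    peaks = [Peak(p.mass, p.intensity / top * base) for p in spectrum.peaks]
    return Spectrum(spectrum.id, peaks, spectrum.precursor_neutral_mass,
                    spectrum.precursor_charge)


def pattern_mass_at(pattern: Sequence[tuple[int, str, float]], site: int) -> float:
    """Total PTM mass planted at ``site`` (0-based) in a PTM pattern."""
    return sum(m for s, _n, m in pattern if s == site)


def theoretical_ions(backbone: str,
                     pattern: Sequence[tuple[int, str, float]] = ()
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Singly-charged b and y ladders of a (modified) peptide.

    ``pattern`` is a list of ``(site, name, mass)`` with 0-based sites.
    Returns arrays ``b[i]``/``y[i]`` for cut positions i=1..n-1, where
    ``b[i-1]`` covers residues ``backbone[:i]`` and ``y[i-1]`` covers
    ``backbone[i:]``; every complementary pair sums to the precursor
    constant C = neutral mass + 2 protons.
    """
    n = len(backbone)
    site_mass = np.zeros(n)
    for s, _name, m in pattern:
        if not 0 <= s < n:
            raise ValueError(f"PTM site {s} outside backbone of length {n}")
        site_mass[s] += m
    residue = np.array([residue_mass(a) for a in backbone]) + site_mass
    prefix = np.cumsum(residue)
    b = PROTON + prefix[:-1]
    y = PROTON + WATER + (prefix[-1] - prefix[:-1])
    return b, y
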