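"""Shared fixtures: configs, registries, hand-built sections and spectra."""

import math

import numpy as np
import pytest

from pipic.chem import PTMEntry, SearchConfig, default_ptm_registry, ptms_for_residue
from pipic.candidates import Section
from pipic.spectra import Peak, Spectrum, theoretical_ions
from pipic.chem import WATER, residue_mass


@pytest.fixture
def config():
    return SearchConfig()


@pytest.fixture
def small_registry():
    """Ten residue-specific PTMs (termini excluded) from the default set."""
    return [p for p in default_ptm_registry()
            if p.site not in ("N-term", "C-term")][:10]


def ladder_spectrum(backbone, pattern=(), intensity=50.0, sid="fix"):
    """Noise-free spectrum containing the full b/y ladder of a peptide."""
    b, y = theoretical_ions(backbone, list(pattern))
    total = sum(residue_mass(a) for a in backbone) + WATER \
        + sum(m for _s, _n, m in pattern)
    peaks = sorted(Peak(float(m), intensity) for m in set(
        round(v, 6) for v in list(b) + list(y)))
    return Spectrum(sid, list(peaks), total, 2)


def gap_section(backbone, left_cut, right_cut, registry, pattern=(),
                offset0=0):
    """A gap section covering backbone[left_cut:right_cut] with true anchors.

    Anchors are the theoretical b-ions at the cut positions of the
    modified peptide, i.e. exactly what correctly placed tags provide.
    """
    b, _y = theoretical_ions(backbone, list(pattern))
    total = sum(residue_mass(a) for a in backbone) + WATER \
        + sum(m for _s, _n, m in pattern)
    c_total = total + 2 * 1.007276
    bl, br = float(b[left_cut - 1]), float(b[right_cut - 1])
    # offset0 = protein offset at which backbone position 0 sits
    residues = [(offset0 + i, backbone[i]) for i in range(left_cut, right_cut)]
    sec = Section("gap", residues, 0, bl, br, c_total)
    sec.ptm_options = [ptms_for_residue(registry, a) for _o, a in residues]
    return sec


@pytest.fixture
def phospho_gap(small_registry):
    """Gap 'SD' of GASDK with a planted Phospho@S, plus its spectrum."""
    backbone, pattern = "GASDK", [(2, "Phospho@S", 79.966331)]
    spec = ladder_spectrum(backbone, pattern)
    sec = gap_section(backbone, 2, 4, small_registry, pattern)
    return sec, spec
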