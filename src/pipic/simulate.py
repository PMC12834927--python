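"""Synthetic MS2 benchmark generator with recorded ground truth.

Emulates a simulated benchmark in which peptides are drawn by in-silico
tryptic digestion of template proteins, 0-4 PTMs are planted per peptide,
and full b/y ladders are embedded in noise at a controlled signal-to-noise
ratio. SNR is defined here as total signal intensity over total noise
intensity; noise intensities are rescaled so the realized ratio is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pyteomics import parser as _parser

from .chem import AA_MASSES, PTMEntry, peptide_mass, ptms_for_residue
from .spectra import Peak, Spectrum, theoretical_ions

# Approximate residue frequencies in vertebrate proteomes, used for random
# template proteins.
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_FREQ = np.array([8.3, 1.4, 5.5, 6.8, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7,
                     2.4, 4.1, 4.7, 4.0, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

#: k-PTM spectrum proportions of the reference simulated benchmark
#: (135 : 20004 : 92357 : 11263 : 489 spectra for k = 0..4, normalized).
REFERENCE_K_DISTRIBUTION: dict[int, float] = {
    k: v / 124248.0
    for k, v in enumerate((135.0, 20004.0, 92357.0, 11263.0, 489.0))
}


@dataclass(frozen=True)
class GroundTruthRecord:
    """Planted truth of one simulated spectrum."""

    spectrum_id: str
    backbone: str
    pattern: tuple[tuple[int, str, float], ...]  # (0-based site, name, mass)
    snr: float

    def __post_init__(self) -> None:
        sites = [s for s, _n, _m in self.pattern]
        if any(not 0 <= s < len(self.backbone) for s in sites):
            raise ValueError("PTM site outside backbone")
        if len(sites) != len(set(sites)):
            raise ValueError("at most one PTM per site")


def simulate_spectrum(backbone: str,
                      pattern: list[tuple[int, str, float]],
                      snr: float,
                      seed: int,
                      spectrum_id: str = "sim",
                      n_noise: int = 50,
                      charge: int = 2) -> tuple[Spectrum, GroundTruthRecord]:
    """Simulate one spectrum: full b/y ladder plus uniform noise peaks.

    Signal intensities are lognormal; noise masses are uniform on
    [min signal peak, C] and noise intensities are scaled so that
    (total signal)/(total noise) equals ``snr`` exactly. ``snr = inf`` or
    ``n_noise = 0`` yields the bare ladder. Deterministic given ``seed``.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    b, y = theoretical_ions(backbone, pattern)
    signal_masses = np.concatenate([b, y])
    signal_int = rng.lognormal(mean=math.log(50.0), sigma=0.6,
                               size=signal_masses.size)
    total_mass = peptide_mass(backbone) + sum(m for _s, _n, m in pattern)
    c = total_mass + 2 * 1.007276

    peaks = [Peak(float(m), float(i))
             for m, i in zip(signal_masses, signal_int)]
    if n_noise > 0 and math.isfinite(snr):
        lo = float(signal_masses.min())
        noise_masses = rng.uniform(lo, c, size=n_noise)
        noise_int = rng.lognormal(mean=math.log(50.0), sigma=0.6, size=n_noise)
        noise_int *= (signal_int.sum() / snr) / noise_int.sum()
        peaks += [Peak(float(m), float(i))
                  for m, i in zip(noise_masses, noise_int)]
    peaks.sort()
    spec = Spectrum(spectrum_id, peaks, precursor_neutral_mass=total_mass,
                    precursor_charge=charge)
    truth = GroundTruthRecord(spectrum_id, backbone, tuple(pattern), snr)
    return spec, truth


def tryptic_peptides(sequence: str, min_len: int = 6, max_len: int = 25,
                     missed_cleavages: int = 0) -> list[str]:
    """Unique fully-tryptic peptides of one protein, sorted for determinism."""
    pep = _parser.cleave(sequence, _parser.expasy_rules["trypsin"],
                         missed_cleavages=missed_cleavages)
    return sorted(p for p in pep if min_len <= len(p) <= max_len
                  and all(a in AA_MASSES for a in p))


def random_proteins(n: int, length: int, seed: int,
                    prefix: str = "SYN") -> list[tuple[str, str]]:
    """Random template proteins with realistic residue frequencies."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        seq = "".join(rng.choice(list(_AA), size=length, p=_AA_FREQ))
        out.append((f"{prefix}{i:03d}", seq))
    return out


def generate_benchmark(template_proteins: list[tuple[str, str]],
                       k_distribution: dict[int, float],
                       n_spectra: int,
                       ptm_registry: list[PTMEntry],
                       snr: float,
                       seed: int,
                       n_noise: int = 50,
                       ) -> tuple[list[Spectrum], list[GroundTruthRecord]]:
    """Generate a benchmark set of simulated spectra with known truth.

    Peptides come from tryptic digestion of the templates; per spectrum a
    PTM count k is drawn from ``k_distribution`` and k distinct compatible
    sites receive PTMs from the registry. Peptides with fewer compatible
    sites than the drawn k trigger a redraw of k.
    """
    ks = sorted(k_distribution)
    probs = np.array([k_distribution[k] for k in ks], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ValueError("k_distribution must be a probability distribution")
    peptides = []
    for _acc, seq in template_proteins:
        peptides.extend(tryptic_peptides(seq))
    peptides = sorted(set(peptides))
    if not peptides:
        raise ValueError("templates yielded no tryptic peptides")

    rng = np.random.default_rng(seed)
    spectra: list[Spectrum] = []
    truth: list[GroundTruthRecord] = []
    for i in range(n_spectra):
        while True:
            backbone = peptides[rng.integers(len(peptides))]
            compatible = [(j, ptms_for_residue(ptm_registry, a))
                          for j, a in enumerate(backbone)]
            compatible = [(j, opts) for j, opts in compatible if opts]
            # resample k on site-poor peptides; after a few failed draws
            # resample the peptide too (a fixed k may never fit)
            k = -1
            for _attempt in range(10):
                k = int(rng.choice(ks, p=probs))
                if k <= len(compatible):
                    break
                k = -1
            if k >= 0:
                break
        pattern: list[tuple[int, str, float]] = []
        if k:
            picks = rng.choice(len(compatible), size=k, replace=False)
            for idx in sorted(picks):
                site, opts = compatible[idx]
                p = opts[int(rng.integers(len(opts)))]
                pattern.append((site, p.name, p.mass))
        sid = f"sim_{i:05d}"
        child_seed = int(rng.integers(2**31 - 1))
        spec, rec = simulate_spectrum(backbone, pattern, snr, child_seed,
                                      spectrum_id=sid, n_noise=n_noise)
        spectra.append(spec)
        truth.append(rec)
    return spectra, truth


def write_truth_table(records: list[GroundTruthRecord], path: str | Path) -> None:
    rows = ["spectrum_id\tbackbone\tptm_sites\tptm_names\tptm_masses\tsnr"]
    for r in records:
        sites = ",".join(str(s) for s, _n, _m in r.pattern)
        names = ",".join(n for _s, n, _m in r.pattern)
        masses = ",".join(repr(m) for _s, _n, m in r.pattern)
        rows.append(f"{r.spectrum_id}\t{r.backbone}\t{sites}\t{names}\t{masses}\t{r.snr!r}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_truth_table(path: str | Path) -> list[GroundTruthRecord]:
    lines = Path(path).read_text().splitlines()
    out = []
    for line in lines[1:]:
        sid, backbone, sites, names, masses, snr = line.split("\t")
        pattern = tuple(
            (int(s), n, float(m))
            for s, n, m in zip(sites.split(",") if sites else [],
                               names.split(",") if names else [],
                               masses.split(",") if masses else [])
        )
        out.append(GroundTruthRecord(sid, backbone, pattern, float(snr)))
    return out


def write_fasta(proteins: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, seq in proteins:
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
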