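"""Mass constants, the PTM registry, and PTM combinatorics.

All masses are monoisotopic (Da). Peptide masses are neutral monoisotopic:
the sum of residue masses plus one water. Fragment ion masses carry one
proton (singly-charged, deisotoped scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

#: Monoisotopic mass of a proton (Da).
PROTON = 1.007276
#: Monoisotopic mass of water (Da).
WATER = 18.010565

#: Monoisotopic residue masses for the 20 standard amino acids (Da).
AA_MASSES: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Terminus tokens accepted as PTM specificities alongside residue letters.
N_TERM = "N-term"
C_TERM = "C-term"


def fold_il(sequence: str) -> str:
    """Map isoleucine to leucine (isobaric; indistinguishable by mass)."""
    return sequence.replace("I", "L")


def residue_mass(residue: str) -> float:
    """Monoisotopic mass of one amino-acid residue.

    Raises
    ------
    ValueError
        If ``residue`` is not one of the 20 standard one-letter codes.
    """
    try:
        return AA_MASSES[residue]
    except KeyError:
        raise ValueError(f"unknown amino-acid letter: {residue!r}") from None


def peptide_mass(sequence: str, ptm_masses: float = 0.0) -> float:
    """Neutral monoisotopic mass of a peptide: sum of residues plus water.

    ``ptm_masses`` is an optional total modification mass to add.
    """
    return sum(residue_mass(a) for a in sequence) + WATER + ptm_masses


def count_ptm_combinations(n_a: int, k: int, n: int) -> int:
    """Number of distinct k-PTM combinations on a peptide of ``n_a`` residues.

    With at most one PTM per residue and ``n`` candidate PTMs per residue on
    average, the count is ``C(n_a, k) * n**k``, computed exactly as an
    integer. This is the combinatorial explosion that makes exhaustive
    multi-PTM search intractable (order 1e11 already for n_a=20, k=4, n=100).
    """
    if k < 0 or n < 0 or n_a < 0:
        raise ValueError("arguments must be non-negative")
    if k > n_a:
        raise ValueError(f"k={k} exceeds the number of residues n_a={n_a}")
    return math.comb(n_a, k) * n**k


@dataclass(frozen=True)
class PTMEntry:
    """One modification: a name, a monoisotopic mass shift, and a specificity.

    ``site`` is a residue letter or one of the terminus tokens
    ``"N-term"`` / ``"C-term"``.
    """

    name: str
    mass: float
    site: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.mass) or abs(self.mass) >= 2000.0:
            raise ValueError(f"PTM mass out of range: {self.mass!r}")
        if self.site not in AA_MASSES and self.site not in (N_TERM, C_TERM):
            raise ValueError(f"invalid PTM specificity: {self.site!r}")


# A compact Unimod-like default registry: 18 frequently observed
# modifications and substitutions covering positive and negative shifts.
DEFAULT_PTMS: tuple[PTMEntry, ...] = (
    PTMEntry("Oxidation@M", 15.994915, "M"),
    PTMEntry("Phospho@S", 79.966331, "S"),
    PTMEntry("Phospho@T", 79.966331, "T"),
    PTMEntry("Phospho@Y", 79.966331, "Y"),
    PTMEntry("Acetyl@K", 42.010565, "K"),
    PTMEntry("Methyl@K", 14.015650, "K"),
    PTMEntry("Dimethyl@K", 28.031300, "K"),
    PTMEntry("GG@K", 114.042927, "K"),
    PTMEntry("Methyl@R", 14.015650, "R"),
    PTMEntry("Deamidation@N", 0.984016, "N"),
    PTMEntry("Deamidation@Q", 0.984016, "Q"),
    PTMEntry("Carbamidomethyl@C", 57.021464, "C"),
    PTMEntry("Trioxidation@C", 47.984744, "C"),
    PTMEntry("Dehydration@S", -18.010565, "S"),
    PTMEntry("Formyl@N-term", 27.994915, N_TERM),
    PTMEntry("Acetyl@N-term", 42.010565, N_TERM),
    PTMEntry("Amidation@C-term", -0.984016, C_TERM),
    PTMEntry("Phe->Cys@F", -44.059229, "F"),
)


def default_ptm_registry() -> list[PTMEntry]:
    """A fresh copy of the bundled 18-entry default registry."""
    return list(DEFAULT_PTMS)


def ptms_for_residue(registry: list[PTMEntry], residue: str) -> list[PTMEntry]:
    """The candidate PTM set of one residue (residue-specific entries only)."""
    return [p for p in registry if p.site == residue]


def load_ptm_registry(path: str | Path) -> list[PTMEntry]:
    """Read a registry from a TSV file with header ``name<TAB>mass<TAB>site``."""
    lines = Path(path).read_text().splitlines()
    entries: list[PTMEntry] = []
    seen: set[str] = set()
    for i, line in enumerate(lines):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if i == 0 and parts[0].lower() == "name":
            continue
        if len(parts) != 3:
            raise ValueError(f"malformed registry line {i + 1}: {line!r}")
        name, mass_s, site = parts
        if name in seen:
            raise ValueError(f"duplicate PTM name: {name!r}")
        seen.add(name)
        try:
            mass = float(mass_s)
        except ValueError:
            raise ValueError(f"unparsable PTM mass: {mass_s!r}") from None
        entries.append(PTMEntry(name, mass, site))
    return entries


def save_ptm_registry(registry: list[PTMEntry], path: str | Path) -> None:
    """Write a registry as TSV; masses use repr so float round-trips exactly."""
    out = ["name\tmass\tsite"]
    out += [f"{p.name}\t{p.mass!r}\t{p.site}" for p in registry]
    Path(path).write_text("\n".join(out) + "\n")


@dataclass
class SearchConfig:
    """All tunable parameters of the search.

    tau1 / tau2 are the precursor(section) and fragment mass tolerances in
    Da; n_max caps the number of PTMs per section; p_min / p_max bound the
    total PTM mass a section may carry; time_limit is the per-MILP wall
    limit in seconds; ptm_penalty is the objective penalty per placed PTM
    on the normalized intensity scale.
    """

    tau1: float = 0.01
    tau2: float = 0.02
    n_max: int = 4
    p_min: float = -250.0
    p_max: float = 500.0
    time_limit: float = 5.0
    ptm_penalty: float = 0.1
    max_candidates_per_spectrum: int = 10
    seed: int = 0
    # engineering knobs (tag extraction / preprocessing / retrieval)
    min_tag_len: int = 3
    max_tag_len: int = 7
    top_k_tags: int = 50
    branch_cap: int = 4
    min_match_len: int = 3
    top_n_per_window: int = 10
    window: float = 100.0
    normalize: bool = True
    enzyme: str = ""  # "" = open termini; "trypsin" restricts cuts to K/R

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("tolerances must be positive")
        if self.p_min > self.p_max:
            raise ValueError("p_min must not exceed p_max")
        if self.n_max < 0 or self.ptm_penalty < 0:
            raise ValueError("n_max and ptm_penalty must be non-negative")


_INT_FIELDS = {"n_max", "max_candidates_per_spectrum", "seed", "min_tag_len",
               "max_tag_len", "top_k_tags", "branch_cap", "min_match_len",
               "top_n_per_window"}


def load_config(path: str | Path) -> SearchConfig:
    """Parse a flat ``key=value`` text file into a SearchConfig."""
    kwargs = {}
    names = {f.name for f in fields(SearchConfig)}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in names:
            raise ValueError(f"unknown config key: {key!r}")
        if key in _INT_FIELDS:
            kwargs[key] = int(value)
        elif key == "normalize":
            kwargs[key] = value.lower() in ("1", "true", "yes")
        elif key == "enzyme":
            kwargs[key] = value
        else:
            kwargs[key] = float(value)
    return SearchConfig(**kwargs)


def save_config(config: SearchConfig, path: str | Path) -> None:
    lines = [f"{f.name}={getattr(config, f.name)}" for f in fields(SearchConfig)]
    Path(path).write_text("\n".join(lines) + "\n")
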