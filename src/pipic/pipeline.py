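"""End-to-end search, target-decoy FDR control, and benchmark evaluation.

The per-spectrum flow is: preprocess and normalize, extract tags, locate
them on the FM-indexed target+decoy database, assemble ranked candidates,
cut each into sections, solve one MILP per section, and keep the best
scoring peptide-spectrum match (PSM). Peptide-level q-values follow the
target-decoy estimate FDR = (N_d + 1) / N_t over the score-ranked list of
unique modified peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .candidates import (CandidateRejected, CandidatePair, build_sections,
                         locate_tags, rank_candidates)
from .chem import PTMEntry, SearchConfig, default_ptm_registry, fold_il
from .fmindex import FMDatabase, read_fasta
from .milp import MILPSolution, build_section_model, solve_model
from .simulate import GroundTruthRecord
from .spectra import Spectrum, normalize_intensities, preprocess_spectrum, read_mgf
from .tags import tags_from_spectrum

log = logging.getLogger(__name__)

PSM_COLUMNS = ["spectrum_id", "protein", "peptide", "ptm_sites", "ptm_names",
               "ptm_masses", "score", "q_value", "status", "is_decoy"]


@dataclass
class PSM:
    spectrum_id: str
    protein: str
    peptide: str
    ptms: list[tuple[int, str, float]]  # peptide-relative (site, name, mass)
    score: float
    is_decoy: bool
    status: str                         # 'optimal' or 'outOfTime'
    q_value: float = 1.0


def assemble_psm(spectrum: Spectrum, candidate: CandidatePair,
                 solutions: list[tuple[object, MILPSolution]]) -> PSM | None:
    """Compose one PSM from a candidate's solved sections.

    Returns None when any section is infeasible. The peptide spans from
    the decoded N boundary (or the first tag) to the decoded C boundary
    (or the last tag); its score is the sum of section objectives plus
    located tag scores.
    """
    bn = candidate.placements[0].offset
    bc = candidate.placements[-1].end
    total_obj = 0.0
    out_of_time = False
    ptms: list[tuple[int, str, float]] = []
    for section, sol in solutions:
        if sol.status == "infeasible":
            return None
        out_of_time |= sol.status == "outOfTime"
        total_obj += sol.objective or 0.0
        ptms.extend(sol.ptms)
        if section.kind == "N" and sol.boundary_offset is not None:
            bn = sol.boundary_offset
        elif section.kind == "C" and sol.boundary_offset is not None:
            bc = sol.boundary_offset
    peptide = candidate.protein.sequence[bn:bc]
    rel = sorted((off - bn, name, mass) for off, name, mass in ptms)
    score = total_obj + candidate.score
    return PSM(spectrum.id, candidate.protein.accession, peptide, rel, score,
               candidate.protein.is_decoy,
               "outOfTime" if out_of_time else "optimal")


def search_spectrum(spectrum: Spectrum, db: FMDatabase, config: SearchConfig,
                    registry: list[PTMEntry]) -> PSM | None:
    """Best PSM of one spectrum, or None if unidentified."""
    pre = preprocess_spectrum(spectrum, config.top_n_per_window, config.window)
    if config.normalize:
        pre = normalize_intensities(pre)
    tags = tags_from_spectrum(pre, config.tau2, config.min_tag_len,
                              config.max_tag_len, config.top_k_tags,
                              config.branch_cap)
    placements = locate_tags(tags, db, config.min_match_len)
    candidates = rank_candidates(placements, config)

    best: PSM | None = None
    n_solved = 0
    for cand in candidates:
        if n_solved >= config.max_candidates_per_spectrum:
            break
        try:
            sections = build_sections(cand, pre, config, registry)
        except CandidateRejected as exc:
            log.debug("spectrum %s: candidate %s rejected: %s",
                      spectrum.id, cand.protein.accession, exc)
            continue
        n_solved += 1  # structurally viable: counts toward the MILP cap
        solutions = []
        feasible = True
        for sec in sections:
            spec = build_section_model(sec, pre, config)
            sol = solve_model(spec, config.time_limit)
            if sol.status == "infeasible":
                feasible = False
                break
            solutions.append((sec, sol))
        if not feasible:
            continue
        psm = assemble_psm(spectrum, cand, solutions)
        if psm is not None and (best is None or
                                (psm.score, not psm.is_decoy) >
                                (best.score, not best.is_decoy)):
            best = psm
    return best


def psms_to_frame(psms: list[PSM]) -> pd.DataFrame:
    rows = []
    for p in psms:
        rows.append({
            "spectrum_id": p.spectrum_id,
            "protein": p.protein,
            "peptide": p.peptide,
            "ptm_sites": ",".join(str(s) for s, _n, _m in p.ptms),
            "ptm_names": ",".join(n for _s, n, _m in p.ptms),
            "ptm_masses": ",".join(f"{m:.6f}" for _s, _n, m in p.ptms),
            "score": p.score,
            "q_value": p.q_value,
            "status": p.status,
            "is_decoy": p.is_decoy,
        })
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


def compute_peptide_qvalues(psms: list[PSM]) -> list[PSM]:
    """Peptide-level q-values by the target-decoy estimate (N_d + 1) / N_t.

    PSMs are collapsed to their best-scoring instance per modified peptide
    (backbone plus PTM pattern); the ranked list is scanned top-down
    accumulating decoy and target counts, and the q-value is the running
    minimum of the FDR from the bottom up (monotone non-decreasing down
    the list). Peptides above any target (N_t = 0) get q = 1.
    """
    best_per_pep: dict[tuple, PSM] = {}
    for p in psms:
        key = (p.peptide, tuple((s, n) for s, n, _m in p.ptms), p.is_decoy)
        cur = best_per_pep.get(key)
        if cur is None or p.score > cur.score:
            best_per_pep[key] = p
    ranked = sorted(best_per_pep.items(),
                    key=lambda kv: (-kv[1].score, kv[0]))
    n_t = n_d = 0
    fdrs: list[float] = []
    for _key, p in ranked:
        if p.is_decoy:
            n_d += 1
        else:
            n_t += 1
        fdrs.append((n_d + 1) / n_t if n_t else 1.0)
    qs = fdrs[:]
    for i in range(len(qs) - 2, -1, -1):
        qs[i] = min(qs[i], qs[i + 1])
    q_by_key = {key: min(q, 1.0 + (1.0 / n_t if n_t else 0.0))
                for (key, _p), q in zip(ranked, qs)}
    for p in psms:
        key = (p.peptide, tuple((s, n) for s, n, _m in p.ptms), p.is_decoy)
        p.q_value = q_by_key[key]
    return psms


def filter_fdr(psms: list[PSM], threshold: float) -> list[PSM]:
    """Target PSMs whose peptide-level q-value passes the threshold."""
    return [p for p in psms if not p.is_decoy and p.q_value <= threshold]


@dataclass
class EvalReport:
    """Benchmark metrics against a recorded ground truth."""

    n_psms: int
    n_correct_backbone: int
    n_with_ptms_reported: int
    n_correct_pattern: int
    n_truth_modified: int
    precision: float                 # correct patterns / PSMs carrying PTMs
    sensitivity: float               # correct patterns / truth modified spectra
    backbone_rate: float             # correct backbones / PSMs
    per_k_sensitivity: dict[int, float] = field(default_factory=dict)
    per_ptm_sensitivity: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_psms": self.n_psms,
            "n_correct_backbone": self.n_correct_backbone,
            "n_with_ptms_reported": self.n_with_ptms_reported,
            "n_correct_pattern": self.n_correct_pattern,
            "n_truth_modified": self.n_truth_modified,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "backbone_rate": self.backbone_rate,
            "per_k_sensitivity": self.per_k_sensitivity,
            "per_ptm_sensitivity": self.per_ptm_sensitivity,
        }


def evaluate(psms: list[PSM], truth: list[GroundTruthRecord]) -> EvalReport:
    """Score identifications against the planted truth.

    A backbone is correct when the peptide string matches exactly (I/L
    folded); a PTM pattern is correct when, additionally, the reported
    (site, name) multiset equals the planted one. Precision divides
    correct patterns by PSMs reported as carrying PTMs; sensitivity
    divides by the number of truly modified spectra.
    """
    by_id = {t.spectrum_id: t for t in truth}
    n_backbone = n_pattern = n_with = 0
    k_correct: dict[int, int] = {}
    k_total: dict[int, int] = {}
    ptm_correct: dict[str, int] = {}
    ptm_total: dict[str, int] = {}
    for t in truth:
        k = len(t.pattern)
        k_total[k] = k_total.get(k, 0) + 1
        for _s, name, _m in t.pattern:
            ptm_total[name] = ptm_total.get(name, 0) + 1

    for p in psms:
        if p.spectrum_id not in by_id:
            raise ValueError(f"spectrum {p.spectrum_id} absent from truth")
        t = by_id[p.spectrum_id]
        backbone_ok = fold_il(p.peptide) == fold_il(t.backbone)
        if backbone_ok:
            n_backbone += 1
        if p.ptms:
            n_with += 1
        truth_set = {(s, n) for s, n, _m in t.pattern}
        found_set = {(s, n) for s, n, _m in p.ptms}
        if backbone_ok and truth_set == found_set:
            n_pattern += 1
            if t.pattern:
                k = len(t.pattern)
                k_correct[k] = k_correct.get(k, 0) + 1
                for _s, name, _m in t.pattern:
                    ptm_correct[name] = ptm_correct.get(name, 0) + 1

    n_truth_mod = sum(v for k, v in k_total.items() if k > 0)
    n_pattern_mod = sum(k_correct.values())
    return EvalReport(
        n_psms=len(psms),
        n_correct_backbone=n_backbone,
        n_with_ptms_reported=n_with,
        n_correct_pattern=n_pattern,
        n_truth_modified=n_truth_mod,
        precision=(n_pattern_mod / n_with) if n_with else 0.0,
        sensitivity=(n_pattern_mod / n_truth_mod) if n_truth_mod else 0.0,
        backbone_rate=(n_backbone / len(psms)) if psms else 0.0,
        per_k_sensitivity={k: k_correct.get(k, 0) / v
                           for k, v in sorted(k_total.items()) if k > 0},
        per_ptm_sensitivity={n: ptm_correct.get(n, 0) / v
                             for n, v in sorted(ptm_total.items())},
    )


def run_search(mgf_path: str | Path, fasta_path: str | Path,
               config: SearchConfig | None = None,
               registry: list[PTMEntry] | None = None,
               out_path: str | Path | None = None) -> pd.DataFrame:
    """End-to-end search of an MGF against a FASTA database.

    Deterministic given the config seed (decoy generation). One failing
    spectrum never aborts the run. Returns (and optionally writes) the PSM
    table including decoys and q-values; downstream filtering is left to
    the caller.
    """
    config = config or SearchConfig()
    registry = registry if registry is not None else default_ptm_registry()
    spectra = read_mgf(mgf_path)
    proteins = read_fasta(fasta_path)
    db = FMDatabase.build(proteins, seed=config.seed)

    psms: list[PSM] = []
    for s in spectra:
        try:
            psm = search_spectrum(s, db, config, registry)
        except Exception:  # spectrum-level isolation
            log.exception("spectrum %s failed; skipping", s.id)
            continue
        if psm is not None:
            psms.append(psm)
    compute_peptide_qvalues(psms)
    frame = psms_to_frame(psms)
    if out_path is not None:
        frame.to_csv(out_path, sep="\t", index=False)
    return frame


def frame_to_psms(frame: pd.DataFrame) -> list[PSM]:
    """Inverse of psms_to_frame (used by the CLI evaluate command)."""
    out = []
    for _i, r in frame.iterrows():
        sites = str(r["ptm_sites"]) if not pd.isna(r["ptm_sites"]) else ""
        names = str(r["ptm_names"]) if not pd.isna(r["ptm_names"]) else ""
        masses = str(r["ptm_masses"]) if not pd.isna(r["ptm_masses"]) else ""
        ptms = [(int(s), n, float(m))
                for s, n, m in zip(sites.split(",") if sites else [],
                                   names.split(",") if names else [],
                                   masses.split(",") if masses else [])]
        out.append(PSM(str(r["spectrum_id"]), str(r["protein"]),
                       str(r["peptide"]), ptms, float(r["score"]),
                       bool(r["is_decoy"]), str(r["status"]),
                       float(r["q_value"])))
    return out
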