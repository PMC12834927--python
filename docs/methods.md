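# Methods

This note records the model, the numerical choices, and the design
decisions behind `pipic`, including the points where the underlying method
description left the design open.

## Mass conventions

All masses are monoisotopic (proton 1.007276 Da, water 18.010565 Da).
Fragment masses live on the singly-charged, deisotoped scale: a b-ion
covering a peptide prefix has mass `proton + Σ(w_a + PTM masses)`, a y-ion
`proton + water + Σ(...)`, and every complementary pair sums to
`C = precursor neutral mass + 2·proton`. Isoleucine and leucine are
isobaric and folded to `L` everywhere (tags, database text, evaluation);
glutamine/lysine (0.036 Da apart) are *not* merged — the fragment
tolerance τ₂ decides.

## Tag extraction

The spectrum graph connects peaks whose mass difference matches a residue
mass within 2τ₂. Tag enumeration is depth-first with a branching cap of 4
successors per node (ranked by target-peak intensity), lengths 3–7, top 50
tags by score. These bounds are engineering defaults: longer minimum tags
lose short unmodified stretches, shorter ones match everywhere.

Two additions matter in practice:

- **Terminal anchors.** The ladder boundaries `b0 = proton`,
  `bn = C − proton − water`, `y0 = proton + water` and `yn = C − proton`
  are known constants even though no peak is observed there. They are
  added as near-zero-intensity nodes so a tag can include the first or
  last residue of the peptide. Without them, any peptide whose modified
  sites leave no unmodified 3-residue run with *both* flanking observed
  peaks is structurally unidentifiable; on the simulated benchmark this
  one change moves backbone recovery from ~88% to ~95%.
- **Frames.** Every graph path is emitted both as a b-frame tag and as the
  reversed, C-complemented y-frame tag. All downstream coordinates are
  b-frame.

## Retrieval and candidates

Targets are interleaved with seeded Fisher–Yates shuffles of themselves
(`target . decoy . ...`); decoys therefore conserve residue composition
and peptide mass distributions. The FM-index uses a prefix-doubling suffix
array, an occurrence table checkpointed every 128 positions, and a suffix
array sampled every 32 entries (performance choices only; correctness is
tested against naive search). Fuzzy matching walks tag suffixes backward
and keeps the longest hit; the reversed-text index covers errors at the
other end. Located substrings shorter than 3 residues are discarded as
unspecific (the method description states no floor; 3 is our choice).

Overlapping placements with agreeing ladders (within τ₂ at every shared
boundary) are merged, the union scored by summed intensity; disagreeing
overlaps drop the lower-scoring tag. Because a chimeric noise ladder can
outscore the true tag, raw single placements are retained as fallback
candidates alongside merged chains. Chains only join placements whose
anchor-mass gap minus the interleaving residue mass lies within
`[P_min, P_max]`; tags violating that cannot come from one peptide, and
one protein may therefore yield several candidates. The candidate cap
(default 10) is applied at MILP entry, after cheap structural rejection of
candidates whose sections cannot balance.

## Sections and the MILP

A candidate is cut into sections by its tags. A gap section between two
tags has `Δm = M_r,start − M_l,end` (raw anchor difference; the model
balances residue *plus* PTM mass against it). The N-section uses anchor
base `proton` and `Δm = first tag start peak − proton`; the C-section is
mirrored onto the y-ion axis (residue order reversed, anchor base
`proton + water`), which reuses the N-section model verbatim — the
mirrored "b" expressions are real y-ion masses and vice versa, so the
piecewise-constant lookups still address the observed peak list.

Terminal residues are classified walking outward from the tag: *fixed*
until the unexplained mass drops to `P_max`, then *optional* while it
stays above `P_min`, the rest infeasible and excluded. Optional presence
variables are monotone toward the tag, so the decoded peptide terminus is
the single cut point; with `--enzyme trypsin` cuts whose boundary residue
is not K/R (and not a protein terminus) are forbidden by pinning adjacent
presence variables. Open termini remain the default.

The objective sums, over every section residue, the linearized
piecewise-constant intensity of its b- and y-ion expressions, minus a
penalty of 0.1 per placed PTM. Intensities are normalized per spectrum
(base peak = 100) before model construction so the fixed penalty has a
consistent scale. Constraints: mass balance within τ₁; at most one PTM
per residue; at most `N_max` (default 4) PTMs per section; optional-
residue contiguity; no PTM on an absent residue. The per-residue b+y
complementarity constraint is algebraically identical to the mass balance
under these ladder definitions, so it is asserted by the independent
solution checker rather than duplicated as a model row.

### PWC linearization

Peak windows are `(M_e − τ₂, M_e + τ₂]` (left-open, right-closed);
overlapping windows are merged keeping the maximum intensity so the
breakpoint sequence stays ordered, and the direct evaluator uses the same
merged intervals so both routes agree by construction. Numerical
constants: the strict-inequality tolerance is ϵ = 1e-4 Da — measured as
the smallest value the solver's scaled feasibility tolerance reliably
discriminates (1e-6 is silently absorbed on rows with ~500 Da
coefficients); the mass upper bound is `Q = max(M_E + τ₂, C + P_max) + 1`
(bounding by the last peak alone would wrongly cap valid ion expressions
above the observed range); the big-M per interval is the smallest value
satisfying `F_i + G_i ≥ max_j F_j`. The ϵ-wide slivers just above each
open window end are the linearization's designed resolution: inside them
the selector has no exactly-feasible assignment.

### Solving, decoding, tie-breaks

The backend is the HiGHS branch-and-bound solver via
`scipy.optimize.milp`, with a per-model wall limit (default 5 s). Status
is `optimal`, `outOfTime` (incumbent returned and flagged; filtering left
to the user), or `infeasible`. Every returned assignment passes an
independent numeric re-check of all constraints. Reported objectives are
re-scored from the decoded assignment through the direct PWC evaluator,
which keeps them on exactly the same footing as the exhaustive oracle.
Among equal-objective optima the canonical solution has fewest PTMs, then
the lexicographically smallest site vector; solver output is normalized
post hoc by mass-preserving moves of each chosen PTM to the earliest
compatible free site, and the oracle returns the full optimal set so
tests can verify membership and, when the optimum is unique, equality.

## Pipeline and FDR

The best-scoring candidate per spectrum becomes its PSM (score = summed
section objectives + summed tag scores; the exact composition of the
final score is a package choice validated only through the synthetic
benchmark). Peptide-level q-values collapse PSMs to their best instance
per modified peptide (backbone + PTM pattern — the stricter collapse key)
and apply `FDR = (N_d + 1)/N_t` down the ranked list with a bottom-up
running minimum; filtering keeps targets with `q ≤` threshold
(inclusive). A protein-level feedback rerank is a deliberate no-op hook.

## Synthetic benchmark

The generator digests template proteins fully tryptically (6–25 residues),
draws a PTM count k per spectrum from a configurable distribution — the
default mirrors the reference mix 135 : 20004 : 92357 : 11263 : 489 for
k = 0..4 — plants k distinct residue-specific PTMs, and emits the complete
b/y ladder with lognormal intensities plus uniform noise peaks scaled so
total signal / total noise equals the requested SNR exactly. Peptides with
fewer compatible sites than the drawn k redraw k (and eventually the
peptide), so the realized k-distribution is exact only on peptides with
≥4 compatible sites; tests condition on that. Terminal-specificity
registry entries (N-term/C-term) are loaded but not planted or modelled:
with an MILP-decoded open terminus the applicable residue is itself a
variable, and gating terminal PTMs on the boundary would extend the model.

What the generator does *not* emulate: fragmentation-efficiency intensity
structure (real b/y intensities are peptide-dependent), multiply charged
or neutral-loss fragments, missed cleavages, chimeric spectra, and
retention time. Passing the recovery benchmark therefore demonstrates the
correctness of the combinatorial machinery under clean conditions, not
instrument-level performance.

The recovery benchmark uses 160 noise-free spectra over 8 random template
proteins. The size is dictated by the FDR estimate: `(N_d + 1)/N_t` cannot
reach 0.01 with fewer than 101 unique target peptides above the cut, and
repeated (peptide, pattern) draws collapse at the peptide level, so the
set is sized to leave ~145 unique modified peptides. The search runs with
`enzyme=trypsin`, matching the generator's fully tryptic digestion;
without it, remnant masses isobaric with residue extensions (GG ≡ two
glycines ≡ asparagine at +114.0429 Da) are genuinely undecidable from the
spectrum whenever the protein sequence happens to continue that way, and
one such case (an isobaric extension ending at a protein C-terminus,
where no enzyme rule applies) remains the benchmark's single wrong
backbone.

## Known limitations

- Peptides whose modified sites leave no 3-residue unmodified stretch
  (even counting terminal anchors) produce no tags and are unidentifiable
  by design; these dominate the benchmark's misses.
- Isobaric PTM/extension and PTM/PTM ambiguities are resolved only by the
  PTM-count penalty and, where enabled, the enzyme constraint.
- Sections are solved independently (their patterns are mutually
  independent given the tag anchors); no joint multi-section model.
- The registry is a bundled 18-entry subset; a full modification database
  is supplied by the user as TSV.
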