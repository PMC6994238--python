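# Methods

This note documents the models, defaults and numerical choices behind each
module, what the synthetic generators do and do not emulate, and the design
decisions taken where the procedure was genuinely open.

## Stoichiometry (RSPA)

For a stoichiometric assembly measured by label-free quantitative
proteomics, a protein's summed signal grows with both its copy number and
its size, so the copy-number proxy divides the averaged quantitative value
(AQV, arithmetic mean over replicates; the reference data are triplicates)
by molecular weight:

    RSPA = (AQV / MW) × 10

The ×10 factor is display convention only. RSPA is computed at full
precision; two-decimal rounding is formatting. Ranking is by descending
RSPA with ties broken by ascending protein id, making the order total and
reproducible. Because the packaged reference table prints MW and AQV
rounded, recomputed RSPA can differ from the printed value in the last
digit; comparisons against printed values use ±0.01.

RSPA is deliberately *rough*: it ignores peptide detectability (small
proteins yield few tryptic peptides and are under-counted — the reason an
~10 kDa protein with one copy per repeat does not appear among the top
ranks), sequence-specific ionization and digestion efficiency. It is a
ranking instrument, not an absolute copy-number estimator (no iBAQ/APEX
style modeling).

Proteins absent from a quant table get no row at all rather than RSPA = 0;
an undetected protein carries no rank information.

## Knockout differential

Each protein detected in either condition is classified:

* **missing** — zero knockout evidence (peptide counts when available,
  else quantitative values) with wild-type signal present;
* **reduced** — mean(WT)/mean(KO) ≥ threshold (default 2.0);
* **increased** — the symmetric condition;
* **unchanged** — otherwise.

Fold change uses replicate means, not per-replicate ratios. A zero KO mean
yields an infinite fold-change marker, never a pseudocount: this keeps
"missing" and "reduced" disjoint categories. Keying "missing" on peptide
counts follows the detection semantics of exclusive unique peptides — a
protein with zero assignable peptides is undetected regardless of any
residual quantitative signal.

The per-protein p-value defaults to a two-sided Welch two-sample t on the
replicate vectors and is *reported only*; categories come from fold change
alone. The reference dataset prints p-values without naming the test, and
no standard two-sample variant reproduces them from the printed replicate
values, so p-values are never treated as an oracle. The test is pluggable
(`replicate_test=` callable). No multiple-testing correction is applied by
default, matching the reference analysis; replicate-sum normalization
exists but is off because typical inputs are already normalized.

## Density-signature motif search

Signatures are token lists: a residue letter (literal), lowercase `x`
(wildcard, exactly as conventionally printed), or a bracket class like
`[FHY]`. Uppercase `X` is a literal unknown-residue match, not a wildcard.
Matching is case-insensitive over sequences and reports **all** positions,
including overlaps (implemented as a lookahead-wrapped regex; verified
against a naive sliding-window matcher in the tests).

Two trace-derived constraints:

* **Length window** — inclusive on both bounds ("between 220 and 280"
  brackets the known targets' lengths only if inclusive). Applied at scan
  time by default; a flag disables it because it is ambiguous whether such
  restrictions belong to the scan or to candidate shortlisting.
* **Direction** — when the trace direction along a density is unknown, the
  signature is also searched token-reversed (reverse of `WPxxxxxW` is
  `WxxxxxPW`). This is token reversal of the pattern, never residue
  complementation; sequences are untouched.

Coordinates are 0-based half-open in machine output, 1-based inclusive in
human-readable reports.

## Candidate screen

Criteria are evaluated per protein in a fixed documented order —
stoichiometry (top-N RSPA rank), MW window, conservation,
homolog size, localization, blacklist, knockout status — and a protein is
shortlisted iff all active criteria hold. The order affects only which
criterion is recorded as the first failure; membership is order-invariant
(a conjunction), which the tests assert.

Choices where the source procedure was implicit:

* "High stoichiometry" has no numeric RSPA cutoff; it is operationalized as
  membership in the top-N ranks, N = 35 by default (the size of the
  reference table).
* "~25 kDa minimum" style criteria become explicit inclusive windows that
  the user must set per screen; ambiguity is surfaced in config, not hidden
  in defaults.
* Localization exclusion (radial spoke, central pair, dynein, cytoplasmic)
  and a known-protein blacklist are explicit configuration: the reference
  screen applied them implicitly, since already-localized proteins were
  never tether candidates. With these, the screen recovers the published
  six tether-loop candidates; two additional proteins (FAP182, EEF1)
  satisfy the three stated criteria and are retained here, documented as
  border cases rather than silently excluded.
* "Too big" homologs are rejected when homolog MW / query MW exceeds a
  configurable ratio, default 2.0 — no published number exists; 2× is the
  smallest round factor that a single traced density clearly cannot
  accommodate. The packaged homolog sizes used to reproduce this exclusion
  are synthetic stand-ins (marked as such) constructed so that exactly the
  two reported oversized homologs exceed the ratio.

### Trace matching

`identify_from_trace` keeps knockout-supported proteins (default status
"missing") whose MW is within a fractional tolerance of the traced mass,
sorted by |MW − trace|. Default tolerance is 0.2: for a ~9 kDa trace this
admits 7.2–10.8 kDa, which separates a 10 kDa candidate from an 11 kDa
near-miss; at 0.3 the 11 kDa protein also enters the window and the match
is resolved by the distance ranking instead. The trace length in residues
is recorded context; mass is the operative filter because the quant table
provides MW, not chain length.

## Co-expression

Pearson r over the retained tissue columns of a consensus normalized
expression matrix (reference layout: 55 tissues + 7 blood cell types = 62
columns). Values are used untransformed by default (`log1p` optional);
p-values from the exact t transform of r with n−2 degrees of freedom.
Exclusion is by exact tissue-label match and requires ≥ 3 remaining
columns; zero-variance vectors raise instead of propagating NaN. The
tissue-exclusion mechanism supports the sensitivity re-analysis pattern:
a correlation driven by a few dominant tissues should survive, attenuated,
when those tissues are dropped. Real-atlas correlation values depend on
database versions and are not asserted anywhere; only the mechanism is.

## Synthetic data

The generators encode the statistical structure the analysis assumes, with
ground truth emitted next to every dataset and byte-identical output under
a fixed seed.

* **Quant tables.** Expected replicate value = copies × MW / 10, the exact
  inverse of RSPA, so the statistic reads back planted copy numbers with no
  bias by construction; at zero noise the inversion is exact. Default noise
  is mean-preserving lognormal with σ = 0.2 (≈ 20% CV, typical for
  label-free quantification); Poisson mode covers count semantics.
  Knockouts are complete ablation (all replicates zero) or k-fold mean
  reduction. Copy numbers mirror axonemal stoichiometries (small integers
  per structural repeat).
* **Proteomes.** Background sequences are uniform over the 20 residues and
  rejection-sampled to contain no accidental match of any planted
  signature in either direction, so the recorded plant list is the
  exhaustive truth. Planted instances are concrete instantiations of the
  signature placed at recorded positions; palindromic token lists are
  handled by comparing match *spans*, since direction is then undefined.
  Not emulated: realistic residue composition, homology structure, or
  length distributions — a green motif test establishes matcher
  correctness, not proteome-scale hit-rate realism.
* **Expression.** Gene pairs from a bivariate normal with planted r (via
  y = r·x + √(1−r²)·e, so r = 1 is exactly degenerate), affinely mapped to
  non-negative values (affine maps preserve r). A separate two-regime
  generator produces the dominant-tissue inflation pattern for the
  exclusion sensitivity test. Not emulated: atlas normalization artifacts,
  shared batch structure across many genes.
* **Screen world.** A 60-protein world with one planted tether protein
  that alone satisfies every criterion, plus decoy groups each engineered
  to fail exactly one (low copy number, wrong size, no homolog, oversized
  homolog, excluded localization, blacklisted). Copy-number gaps (≥ 4×)
  are large relative to the noise CV so top-N membership is stable across
  seeds; the end-to-end test requires the planted protein to be the unique
  shortlist survivor in ≥ 95% of seeded runs.

## Numerical and I/O conventions

* Sequence MW uses average (not monoisotopic) residue masses plus one
  water, matching the kDa scale of the reference tables; `X` counts as the
  unweighted mean residue mass. A printed table MW, when present, overrides
  the sequence-derived value, since the published arithmetic used printed
  MWs. Empty sequences have no defined mass and raise.
* Tabular I/O is TSV with a one-line header (CSV via flag). Missing cells
  are errors unless `absent_as_zero` is set. The absent-homolog marker is
  `"-"`, distinct from an unknown (missing) annotation.
* Reports are JSON with sorted keys; the human TSV shortlist is a pure
  projection of the JSON. Re-running a pipeline with the same config and
  seed is byte-identical.

## Known limitations

* RSPA inherits all label-free quantification biases; it ranks, it does
  not count.
* The screen reproduces an implicit expert filter with explicit config;
  different blacklist/localization choices change the shortlist, which is
  why every verdict records per-criterion flags and a first-failure reason.
* The motif searcher is a pattern matcher, not a profile/PSSM scorer, and
  does not model near-miss densities.
* Upstream quantification (spectra → protein-level values) is assumed
  done; no mzML/pepXML ingestion.
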