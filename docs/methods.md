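# Methods

## Overview

`taxocycle` maps taxonomic affiliations (with optional abundances) to
per-sample profiles of coarse-grained biogeochemical functions. The chain
is: rank-fallback resolution against a precomputed consensus-proteome
database → profile-HMM marker search → Boolean function calls →
occurrence/abundance aggregation → projection onto cycle diagrams. This
note records the model choices, defaults, numerical conventions, and
limitations.

## Taxon database and rank fallback

A database archive is a zip with a root `index.tsv`
(`taxon_name`, `rank`, `proteome_count`, `proteome_path`,
`annotation_path`) and per-taxon members `proteomes/<token>.faa`,
`annotations/<token>.tsv`. Taxon names are sanitized to filesystem-safe
tokens; the original name lives only in the index, which is the reversible
mapping. Archives are written with fixed zip timestamps so identical
inputs yield byte-identical files.

A taxon enters the archive when it is backed by **at least 5** source
proteomes (`min_proteomes=5`, configurable). Thresholding on "at least
five" rather than "more than five" was a deliberate choice between two
plausible readings of the convention used by reference databases of this
kind; the threshold is a parameter precisely so users can pick either.

Resolution walks a lineage most-specific-first and returns the first
(name, rank) pair present in the index. Matching is exact after
whitespace trimming and case-sensitive; homonyms at different ranks are
distinguished by the pair, and taxonomic synonym resolution (which would
require an external taxonomy service) is out of scope. An unresolved
observation is a normal outcome reported in the resolution table, not an
error. Lineages without explicit rank labels are assigned ranks
positionally into a 7-slot kingdom→species convention, left-anchored at
kingdom by default (`align="right"` anchors at species instead).

## Profile HMM scoring

Profiles are read and written as HMMER3/f ASCII (negative natural-log
probabilities, `*` = probability zero, GA line → sequence bit cutoff).
Written files round-trip through our parser within 1e-9 and are accepted
by the reference HMMER parser (checked in the test suite via pyhmmer).

Scoring mode is **unihit local over match states**: one contiguous run
through the match chain, entered and exited at any match state at zero
cost; no multihit J state and no begin/end entry distribution. Insert and
delete states participate in the dynamic program with their file
probabilities. The score is the summed per-state log₂-odds emission
(match or insert emission over background) plus log₂ transition terms.
This mode was chosen because it is exactly desk-verifiable: an
exhaustive path-enumeration oracle (`brute_force_score`, M ≤ 4, L ≤ 6)
reproduces it **bitwise**, which the suite checks on hundreds of seeded
random models. To make that equality exact rather than approximate, both
implementations accumulate floats in the same order,
`(prefix + transition) + emission`; the vectorized fast path used when
insert/delete branches carry zero probability applies the same
per-element operations.

Conventions: ambiguity codes B/Z/X score log-odds 0 (background-equal);
`*` in a sequence is skipped; any other non-alphabet character is an
error; a sequence none of whose residues can be emitted scores −∞ (no
finite local alignment exists). Scores are never rounded before
threshold comparison; hit tables display 3 decimals. The effective
cutoff for a profile is, in order: an explicit cutoff-table entry, the
model's GA line, then a configurable default of 40 bits (the convention
used by curated marker-HMM collections). A profile is "present" in a
proteome iff at least one sequence reaches its cutoff.

## Function rules

Functions are Boolean formulas over profile identifiers with grammar
`expr := term (OR term)*`, `term := factor (AND factor)*`,
`factor := ident | (expr)`; AND binds tighter than OR, and there is
deliberately no NOT — calls are monotone in the detected-marker set,
which the suite verifies against full truth-table enumeration. The
packaged rule set (`data/function_rules.tsv`) covers fermentation,
organic carbon and ethanol oxidation, acetogenesis via the
Wood-Ljungdahl pathway, acetate oxidation, methanogenesis (including the
methylotrophic mtaB/mtbA route), hydrogen generation/oxidation
(hycE, hydB/hydG among the markers), sulfate reduction, sulfur
oxidation, denitrification, nitrate reduction, nitrification, and iron
reduction. It is packaged *data*: the formulas are plausible
marker-to-function mappings, editable without code changes, and any
identifier lacking a profile in the searched collection evaluates false
with a single warning.

## Community profiles

For sample s with members M(s) — the **resolved** observations with
abundance strictly > 0 in s —

- occurrence(f) = |{t ∈ M(s) : f(t)}| / |M(s)|,
- relative abundance(f) = Σ_{t ∈ M(s), f(t)} a(t,s) / Σ_{t ∈ M(s)} a(t,s).

Unresolved observations are excluded from both numerator and denominator:
their function status is unknown, and counting them as "function absent"
would bias every fraction downward. They are reported separately as
`resolved_fraction` (count-based without abundances, abundance-weighted
with them). Without an abundance table a single pseudo-sample named
`community` is emitted with occurrence only. Multiple observations
resolving to the same taxon keep separate abundances, and occurrence
counts observations, not distinct database taxa.

Consequences tested as invariants: all fractions lie in [0,1]; if each
member has exactly one function from a set, both measures sum to 1 over
that set; rescaling a sample's abundance column leaves its profile
unchanged; uniform abundances reduce relative abundance to occurrence.

## Diagrams and display

Cycle diagrams are packaged data, not logic: an SVG body plus an edge map
TSV binding each function to a `<text>` anchor between substrate and
product pools. Rendering substitutes the weight as a whole percentage
with half-up rounding (0.005 → "1%"); zero weights are restyled with a
grey CSS class rather than omitted, so an absent function is visibly
absent. Stored weights are never rounded — rounding applies to labels
only. Summary plots (seaborn heatmap, matplotlib polar plot) are
presentation artifacts; the tested surface is the underlying
`heatmap_table.tsv` and `polar_summary.tsv`. The polar summary hides a
function only when it is below `min_display` (default **0.10**) in every
selected sample; threshold 0 is the identity.

## Synthetic data

The fixtures module generates complete studies with analytic ground
truth. The packaged marker profiles are synthetic stand-ins for curated
enzyme HMMs, built at load time from consensus peptides in
`data/marker_profiles.tsv`. The peptides are alternating two-letter
10-mers whose letter pairs are pairwise distinct and never mutual
reverses; with deterministic emissions this bounds any cross-profile
local alignment to a single match state (~4.32 bits), far below half the
20-bit cutoff, while a profile's own consensus scores
10·log₂20 ≈ 43.2 bits ≥ 2× cutoff. Decoy sequences are drawn uniformly
from the background (lengths 20–40) with a rejection step discarding any
candidate above 0.5× cutoff on any profile. Margins are therefore exact
by construction, and the generator re-checks them at build time.

Default study conditions for the seeded random communities: 2–8 genera
per community with 2–4 planted markers each, 5–12 decoys per proteome,
two samples with integer abundances in 1–50, proteome counts 6–20
(all above the inclusion threshold). Integer abundances keep expected
profiles exactly rational, so truth tables (computed with
`fractions.Fraction`, independently of the community module) match
pipeline output to 1e-9.

What the synthetic data does **not** emulate: sequence evolution
(planted markers are exact consensus copies, so detection is easier than
for diverged real enzymes), taxonomic assignment error, chimeras, PCR
and 16S copy-number bias, and realistic proteome sizes. Passing recovery
tests therefore demonstrates the correctness of the pipeline's
bookkeeping and scoring logic, not the sensitivity of marker detection
on real proteomes — that depends on the quality of the HMM collection
supplied.

## Pipeline and determinism

The parallel unit is one taxon's proteome; workers are mapped over taxa
in sorted name order and merged deterministically, so every data output
is byte-identical for any `cores` value and across reruns. The one
exception is `run_report.json`, which records wall-clock stage timings
for auditability and is excluded from the byte-stability contract.
Configuration is validated (paths exist, cores ≥ 1) before any work;
stage failures abort with a stage-tagged error.

Problem sizes in the shipped tests and the acceptance script — e.g.
200 oracle-equivalence cases, 20 seeded communities of ≤ 8 taxa with
≤ 12 decoys each — were chosen as the smallest sizes that exercise every
code path and branch combination; all checks on them are exact or at
1e-9, so larger sizes would add runtime without adding discrimination.

## Known limitations

- Function presence is metabolic *potential*, not activity.
- The scorer is unihit local; multihit alignment, forward/posterior
  scores and E-values are out of scope (swap in a full engine behind
  `call_hits` if needed).
- No taxonomy-synonym handling; name matching is exact.
- 16S copy-number correction and diversity/differential statistics are
  out of scope.
- The packaged marker and rule sets are synthetic/plausible defaults;
  for production analyses supply a curated HMM collection and a
  validated rule file.
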