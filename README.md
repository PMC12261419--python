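# taxocycle

Coarse-grained biogeochemical-cycle functions from taxonomic affiliations.

## The problem

Metabarcoding (e.g. 16S rRNA amplicon sequencing) tells you *who* is in an
environmental microbial community, not *what they do*. For questions about
biogeochemistry — is this community producing methane, consuming acetate,
reducing sulfate? — the taxa must be linked to metabolic functions.
`taxocycle` implements that link as a desk-scale pipeline:

1. **Resolve** each observation (OTU/ASV) against a precomputed database of
   per-taxon consensus proteomes, at the most specific taxonomic rank with
   database coverage (species → genus → family → … fallback).
2. **Search** the consensus proteome with profile HMMs for marker enzymes
   (mcrA, dsrA/dsrB, acsB, …), scoring in log₂-odds bits against a
   background model and calling hits with per-profile bit-score cutoffs.
3. **Call** coarse-grained metabolic functions per taxon with Boolean
   AND/OR formulas over marker profiles, e.g.
   `acetogenesis = acsB AND fthfs`, `methanogenesis = mcrA OR mtaB AND mtbA`.
4. **Aggregate** per sample: the *occurrence* of a function is the fraction
   of community members possessing it,

   occ(f) = |{t ∈ members : f(t)}| / |members|,

   and with an abundance table `a(t, s)` the *relative abundance* is

   ab(f, s) = Σ_{t : f(t)} a(t, s) / Σ_{t ∈ members} a(t, s).

5. **Project** profiles onto carbon/nitrogen/sulfur cycle diagrams
   (SVG templates whose edges are functions between compound pools) and
   emit heatmap/polar summary tables.

The intended users are environmental microbiologists with amplicon data
(salt caverns, aquifers, soils) who want a quantitative, reproducible
function map rather than a hand-curated literature search.

The HMM scorer is a unihit local Viterbi dynamic program over match states
with zero-cost entry/exit, validated against an exhaustive path-enumeration
oracle; it is a replaceable component, so an external HMMER-compatible
engine can be swapped in behind the same hit-calling interface.

## Worked example

Generate a seeded synthetic community (3 genera with planted marker
enzymes plus background decoy proteins, 2 samples) and run the pipeline:

```bash
taxocycle make-fixtures --seed 3 --taxa 3 --decoys 4 --out fix
taxocycle run --affiliations fix/affiliations.tsv --archive fix/database.zip \
              --abundances fix/abundances.tsv --profiles fix/profiles.hmm \
              --rules fix/rules.tsv --output out
# -> 3 observations, 0 unresolved, 3 taxa searched
taxocycle summarize-db --archive fix/database.zip
#  rank  included_taxa  proteomes
# genus              3         42
# total              3         42
```

`out/3_profiles/function_abundance.tsv` then holds the abundance-weighted
function profile (nonzero rows shown):

```
function               S1        S2
fermentation         0.435897  0.486842
methanogenesis       0.282051  0.118421
hydrogen_generation  0.717949  0.605263
hydrogen_oxidation   0.282051  0.118421
```

Reading: in sample S1, taxa carrying the methanogenesis markers account
for 28% of the community's summed abundance. The same value appears on
the rendered carbon-cycle diagram `out/4_diagrams/carbon_S1.svg` as the
label `28%` on the CO₂ → CH₄ edge. Output layout:

```
out/0_resolution/   resolution_report.tsv       (rank fallback per observation)
out/1_hits/         <taxon>.tsv                 (per-sequence bit scores)
out/2_functions/    function_presence.tsv       (taxon x function booleans)
out/3_profiles/     function_occurrence.tsv, function_abundance.tsv,
                    polar_summary.tsv, heatmap_table.tsv, resolved_fraction.tsv
out/4_diagrams/     carbon_S1.svg, nitrogen_S1.svg, sulfur_S1.svg, ...
out/run_report.json audit trail (versions, counts, warnings, timings)
```

All of this is also available as a library (`taxocycle.taxdb`,
`taxocycle.hmmscan`, `taxocycle.rules`, `taxocycle.community`,
`taxocycle.diagram`, `taxocycle.fixtures`, `taxocycle.pipeline`); the CLI
is a thin wrapper.

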