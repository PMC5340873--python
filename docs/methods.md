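# Methods

## Consensus taxonomic assignment

Hits are first reduced to one per encoded protein: the significance filter
keeps E ≤ threshold (default 10⁻⁵), then the per-gene best hit is the one
with the lowest E-value, ties broken by higher bit score and then
lexicographic subject accession, so results never depend on input order.
Reducing to one hit per protein (rather than pooling all hits) keeps the
per-scaffold hit count interpretable as "number of proteins with hits" and
matches common practice for consensus classification of contigs.

With one retained hit, the subject's full lineage is used.  With two or
more, the rank ladder (domain > phylum > class > order > family > genus >
species) is walked from the deepest rank upward; a taxon wins at a rank iff
(a) the two lowest-E hits both descend from it and (b) a strict majority
(> 50 %) of all retained hits descend from it.  "Majority" is strict: with
exactly two hits both must agree.  At any rank at most one taxon can
satisfy (a) — both top hits descend from it, and two distinct taxa of equal
rank cannot both contain the same leaf — so no tie-break between sibling
taxa is ever needed at a winning rank.  Intermediate nodes without a
canonical rank (`no_rank`) are kept for ancestry tests but can never
terminate an assignment.

Statuses: `classified` when the deepest winning rank is family or below and
the winning taxon is classified in the reference taxonomy;
`unclassified_virus` when the deepest supporting node is a named virus
flagged unclassified; `undetermined` when no consensus below order exists
(including the degenerate case where not even the domain wins, which leaves
the lineage empty); `unknown` strictly means no significant hits.  The last
point intentionally distinguishes "searched and found nothing" from
"found hits that disagree" — an `undetermined` assignment can therefore
carry an empty lineage while `unknown` always does.

The implementation is verified against an independent brute-force oracle
that tests conditions (a) and (b) at every node of the tree and picks the
deepest passing node, on thousands of random trees and hit sets, plus
permutation-invariance and monotonicity properties (adding a hit under the
current deepest node never shallows the call).

## Host inference

Bin-first: a scaffold in a genomic bin takes the bin's lineage to the
lowest level identified, and hits can never override a bin call.  Scaffolds
in bins that carry no lineage fall through to the consensus path.  Unbinned
scaffolds get a consensus truncated at domain over best per-gene hits
against the comprehensive database; hits whose subject is a virus are first
replaced by that virus's known host domain (a virus-to-host-domain map is a
required input; unmapped viral subjects are dropped with a warning).  A
failed domain consensus with purely prokaryotic hits is reported as
`prokaryote_unresolved` rather than unknown.

Prophage host calls made both ways (bin and hit consensus) are
cross-validated; the reported agreement is the percentage of prophage
scaffolds — binned, with significant hits — where the two domains match,
and disagreements resolve in favor of the bin.

## Depth-weighted fractions

Community shares are fractions of estimated *reads*, not scaffold counts:
each scaffold is weighted by mean read depth × length.  The paper-style
claim "x % of virus-affiliated reads have archaeal hosts" is exactly this
weighting, which is why it is the default; a depth-only mode
(`--depth-mode depth_only`) is provided since coverage alone is also used
in the field.  Fractions are computed over the full partition including
`unknown` and `prokaryote_unresolved`, and always sum to 1.

## CRISPR scaffold classification

The eligibility gate for unbinned scaffolds — at least 2,500 bp and at
least three annotated genes — is a pure filter: failing scaffolds are
`unknown`, never guessed.  "Annotated genes" are whatever per-gene taxon
labels the caller supplies (here: best-hit identifications); the gate
counts those labels.  Domain shares are reported over classified calls
only, with the unclassified share reported separately, so archaeal +
bacterial shares of classified sum to 100 % when no other domain occurs.

## Fluid purity and counting statistics

The mixing model is linear in the conservative tracer:
f_crustal = (Mg_sw − Mg)/(Mg_sw − Mg_crustal).  The seawater end member is
53.0 mM (the measured bottom-seawater value); the crustal end member is not
printed in the source and defaults to 2.0 mM, consistent with the most
altered samples — it is a required, configurable assumption.  Samples
outside the end-member interval are clamped with a warning; Mg ranges are
evaluated at both endpoints yielding a purity range.  Purity is reported as
an integer percentage.

Counts: concentration = mean per-field tally × (effective filter area /
field area) / volume filtered.  Summaries use the n−1 standard deviation —
the only convention that reproduces the published SD and CV values from the
published per-sample concentrations — and CV = 100·SD/mean.  Rounding
(concentrations to one significant figure, ratio bounds to two, mean ratio
to one) lives purely in the reporting layer; full precision is kept
internally.  Ratios are computed only for samples with both counts; the
filtered-only sample (flagged `excluded_from_cells`) contributes its virus
count but neither a cell count nor a ratio.

## Sequence statistics

Coordinates are 1-based half-open throughout: length = end − start.  This
is the convention under which the published prophage span (nt 116,961 →
144,621) gives exactly its published 27,660 bp; GenBank features are
1-based inclusive, and `from_genbank_coords` converts.  G+C content is
computed over unambiguous A/C/G/T only — ambiguity codes are excluded from
numerator and denominator (including them in the denominator would bias
G+C low on gappy assemblies); an all-ambiguous sequence has undefined G+C
and raises.

## Synthetic communities

The generator plants, per scaffold: a source species from the toy taxonomy
(which mirrors the study system's named lineages and viral clades), a viral
category (free virus or prophage) where applicable, bin membership, CRISPR
arrays, and per-gene hits for both reference-set roles.  Defaults are the
study conditions where stated — 80/20 archaeal/bacterial depth-weighted
viral host fractions, about a fifth of viral scaffolds prophages — and
generic otherwise: lengths log-uniform on 1–100 kb, coverages log-normal
(μ = 2, σ = 1), half of scaffolds binned, one gene per kb.  The viral and
CRISPR rates (0.2 and 0.1) are far above the per-scaffold rates of a real
assembly, deliberately: they give informative per-run counts at a few
hundred scaffolds.

Domain allocation offers two modes.  `weight_matching` (default) assigns
domains greedily and then rescales each domain group's coverages so the
planted depth-weight fractions hold exactly, making noise-free recovery a
deterministic expectation; `greedy` skips the rescaling and is accurate to
within one scaffold's weight share (≈ well under 2 % at 2,000 scaffolds).
Hit noise is controlled by the probability a hit's subject lies under the
true lineage, the per-gene no-hit probability, a log-uniform E-value range
(10⁻³⁰–10⁻⁶), and the probability an nr hit is routed through a viral
subject (exercising the host-domain substitution).  Correct hits are
assigned the most significant E-values within a gene, so the best-hit
reduction is truth-revealing at zero noise.

What passing synthetic tests shows — and does not.  They validate the
inference logic end to end: exact recovery under no noise, graceful
monotone degradation with noise, conservation, gates, determinism.  They do
not emulate assembly artifacts, chimeric scaffolds, database incompleteness
or biased binning, so they say nothing about the field accuracy of, e.g.,
an 80 % archaeal host share on real assemblies.

All randomness flows from integer seeds through a single generator per
operation; reruns are byte-identical (the run manifest excludes
timestamps).

## Problem sizes and numerical choices

Tests and the acceptance script use communities of 120–2,000 scaffolds and
1,000 random instances for the oracle property — sizes at which every
expectation is exact or provably bounded, keeping the whole suite in
seconds.  Fraction conservation is asserted to 1e-9; summary statistics are
checked against a two-pass computation to 1e-12 relative.  Degenerate
inputs raise rather than warn: empty concentration lists, identical mixing
end members, nonpositive scaffold lengths, all-ambiguous sequences.

## Known limitations

* The consensus rule's "undetermined with empty lineage" case (top hits in
  different domains) is reported conservatively rather than at the root.
* The crustal Mg²⁺ end member is an assumption (2.0 mM); purity values
  shift by ~1 % per 0.5 mM choice near the crustal end.
* The toy taxonomy is deliberately small; rank-ladder behavior with deeply
  nested `no_rank` chains is covered by random-tree property tests instead.
* Bin lineages are trusted as given; no bin-quality weighting is applied.
* Statistics of the deposited genome records can only be recomputed from
  locally downloaded copies of those records.
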