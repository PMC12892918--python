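# Methods

## PSI estimation

Percent spliced in is estimated from junction reads with effective-length
normalisation. Each splice junction admits `read_length − 2·min_anchor + 1`
read placements (defaults: read length 100, minimum anchor 1 → 99 placements
per junction). A skipped-exon inclusion form has two junctions (198
placements) versus one for the skipping form (99); retained-intron and
alternative-splice-site inclusion forms count the retained/extended region
plus one junction's placements. PSI is then

```
PSI = (IJC / L_inc) / (IJC / L_inc + SJC / L_skip)
```

An event with IJC = SJC = 0 in a sample is *unquantifiable* there — it is
excluded from the condition mean, never imputed as 0, and an event
unquantifiable across a whole condition is skipped with a recorded reason.

## Differential test

Per event, replicate counts are pooled within condition and the inclusion
fraction θ = IJC/(IJC+SJC) is compared between conditions with a
likelihood-ratio test of one shared binomial proportion versus two
condition-specific proportions — the G statistic over the pooled 2×2 table,
referred to χ²(1). ΔPSI is reported on the PSI scale as the difference of
mean per-replicate PSI (treated − control), so treatment-induced skipping is
negative. Benjamini–Hochberg correction runs across all testable events
(stable pre-sort by (p, event_id) keeps q-values order-invariant). The test
is deliberately simple and desk-verifiable rather than a reimplementation of
a splicing caller's hierarchical model; its operating characteristics are
checked by simulation — under the null the empirical type-I rate at nominal
0.05 sits in [0.03, 0.07] over 50 datasets × 200 events, and planted ΔPSI is
recovered within ±0.05 per event at ≥ 2000 reads/event (binomial error well
inside that bound).

Significance/expression gating keeps events with q < 0.05, |ΔPSI| ≥ 0.1
(inclusive), gene TPM ≥ 3 and pooled IJC+SJC ≥ 20 in *every* sample.
Expression can alternatively be gated on log₂ TPM (`tpm_log2`); both
conventions appear in practice and the threshold is a configuration value,
default linear TPM ≥ 3. Per-filter verdicts are retained for every event.

## Variant translation and neopeptide digestion

An event is realised on the annotated transcript whose exon structure carries
it; when several qualify the longest-CDS transcript wins (then lexicographic
id — deterministic). The treatment-gaining form follows the sign of ΔPSI:
skipping form for negative, inclusion (e.g. intron-retaining) form for
positive. Both isoform mRNAs are assembled strand-aware (coordinates are
0-based half-open internally; GTF I/O converts to 1-based inclusive at the
boundary) and translated from the annotated CDS start with the standard
codon table to the first stop codon.

Frame status is *frameshift* iff the net exonic-length change inside the
annotated CDS interval is not a multiple of 3. The novel residue region is
found by longest-common-prefix comparison against the reference protein —
extended to the C-terminus for frameshifts, prefix+suffix-trimmed for
in-frame changes. An in-frame deletion whose junction falls between intact
codons changes no single residue; its novel region is defined as the two
residues abutting the new junction, because the peptides unique to the
variant are exactly the k-mers bridging them. Digestion emits all unique
8–11-mers overlapping the novel region by ≥ 1 residue (windows containing
non-standard residues are dropped — binding predictors reject them), and the
self filter removes any k-mer occurring verbatim in the reference proteome.
Emitting from the novel region only is equivalent, after self subtraction,
to digesting the entire variant protein; the test suite asserts this
convergence on generated events.

## Binding consensus and ranking

Predictors are pluggable objects returning a percentile rank per
peptide–allele pair (lower = stronger; ranks must be > 0). Two ship with the
package: a table-backed lookup predictor (default rank 50 for absent pairs)
and a keyed-hash pseudo-rank predictor for structureless null experiments.
Allele spellings ("HLA-A11:01", "A1101", "A*11:01") are normalised to the
`A*11:01` form. The consensus keeps pairs at %Rank ≤ 2 (inclusive,
configurable) under both predictors, per allele; pairs covered by only one
predictor are excluded and counted.

Candidates are ordered by `score = junction_count × |ΔPSI| / %Rank`, where
junction count is the mean treated-replicate read count of the junction
private to the variant isoform (SJC for skipping-gaining events, IJC for
inclusion-gaining) — the treated condition because that is where the
neopeptide-encoding isoform is expressed. A literal signed product
−%Rank × JC × |ΔPSI| is available behind `literal_product=True` for
auditability, but it is not the default because it orders the strongest
binders (rank → 0) worst; the ratio form ranks every factor in its evident
beneficial direction and is strictly monotone in each. Ties break by lower
worst-predictor rank, higher junction count, then peptide/allele
lexicographic — a total order, so output is permutation-invariant.

## Candidate tiers

*ms_validated*: a ranked consensus binder detected in at least one treated
immunopeptidome replicate at FDR < 0.05 and in **no** control replicate.
Any control-side detection disqualifies regardless of its FDR (conservative
default; an optional gate restricts disqualification to confident control
hits). *predicted*: among the remaining ranked binders, the top-2 (by
immunogenicity score, then rank score) with immunogenicity > 0.5, restricted
to HLA-A/-B alleles — HLA-C immunogenicity predictions are excluded for lack
of reliable training data, though HLA-C pairs may still be MS-validated.
Tiers are disjoint; ms_validated takes precedence per peptide. The proteome
cross-check partitions all treatment-exclusive MS peptides into
proteome-matching (presentation changes of annotated protein) versus novel,
and reports any novel peptide absent from the predicted set as missed.

## Cross-sample comparisons

Jaccard similarity |A∩B|/|A∪B| over significant-event or peptide sets
(0 for two empty sets, by convention, with a log note), and directional
concordance: among events significant in both tables (each table's own
filter verdicts), the percentage sharing the sign of ΔPSI, with zero-ΔPSI
events excluded and counted. Zero shared events is an explicit
undefined-result error, not 0%.

## Synthetic-study generator

The generator emulates a two-condition (control/treated), duplicate-library
perturbation RNA-seq experiment at the junction-count level. Each gene gets
one 5-exon transcript on its own contig (strand drawn at random), a stop-free
random CDS starting with ATG, GT/AG intron boundaries, and a 3′ guard
carrying stops in all three frames so frameshifted read-through always
terminates. The middle exon carries the planted event: cassette length
divisible by 3 or not according to `fraction_frameshift` (default 0.5);
retained introns are built stop-free in frame for in-frame retention events.

Replicate junction counts are Binomial splits of Poisson totals
(`coverage_mean`, default 200 reads/event — a moderately expressed gene) at
the length-adjusted true PSI. Defaults plant skipping (PSI 0.75 → 0.45,
ΔPSI = −0.3, a strong but realistic switch) in 70% of 40 events; planted
neopeptides are computed by running the event-to-peptide path itself on the
planted variant form, so they are guaranteed consistent with the emitted
annotation and absent from the emitted proteome. Ten of them are planted as
strong binders (both predictor ranks uniform in (0.05, 1.95]) on HLA-A/-B,
five of those as treatment-exclusive MS detections (FDR < 0.05 in ≥ 1
treated replicate, never in control); MS background adds self-proteome
9-mers in both conditions plus a treated-only self slab that exercises the
cross-check. Every artifact is a pure function of the seed, drawn from
per-artifact child streams, so tables are individually reproducible and two
identical runs produce byte-identical output bundles.

What the generator does **not** emulate: read-level errors and mapping
artefacts, isoform-abundance deconvolution, overdispersion beyond
Poisson–Binomial sampling, biased exon architecture (cassette lengths and GC
are drawn from the same distributions in differential and unchanged events),
learned binding structure (lookup tables replace trained predictors), and MS
spectrum-level effects (FDR arrives precomputed). Passing tests therefore
demonstrate the correctness and calibration of the pipeline's logic under
its stated sampling model, not performance on real sequencing data.

## Problem sizes and numerical choices

The default study is 40 genes / 40 events at coverage 200; calibration runs
use 200 events × 50 count draws; translation checks use 200 events (30% RI,
both strands, both frame classes); recovery checks use coverage 2000. These
sizes keep every property at high statistical resolution while the full
suite runs in seconds. Degenerate inputs are explicit: 0/0 counts →
unquantifiable, empty filter output → empty (successful) downstream stages,
zero shared events → error, two empty sets → Jaccard 0. q-value ranking ties
break on event id; candidate ordering is a total order as above.
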