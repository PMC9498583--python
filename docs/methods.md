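# Methods

## Coordinates and interval geometry

All internal coordinates are 0-based half-open; GTF on disk is 1-based
inclusive, BED is 0-based half-open, and conversion happens only in the
readers/writers, which emit deterministic (chrom, start, id) ordering.
Transcript overlaps are computed on genomic spans (introns included), not
exon unions: the antisense relationship the analysis targets is defined by
transcription from opposite strands of a locus, and a spliced-overlap
variant would silently drop intron-mediated overlaps. The TSS is the
5′-most transcribed base (span start on +, span end − 1 on −); the ±w
window covers positions [TSS−w, TSS+w] inclusive and is clipped at
chromosome edges, with metaprofile normalisation dividing per offset by the
number of genes actually contributing that offset, so clipping biases
neither numerator nor denominator.

## cis-NAT pairs

Two transcripts form a pair when they sit on opposite strands of the same
chromosome and their spans overlap by **≥ 50 bp** ("more than 50 bp" read
as a minimum; the 50/49 boundary is pinned by explicit tests so the choice
is auditable). One transcript may join several pairs — no uniquification,
since the full-scale pair count exceeds the mRNA count. Discovery uses one
interval tree per (chromosome, strand); an O(n²) all-pairs scan is kept as
the test oracle.

Configuration is orientation-independent: containment ⇒ *enclosed*;
otherwise, for a partial overlap of opposite-strand spans, exactly one of
"both 3′ ends inside the overlap" (*convergent*) or "both 5′ ends inside
the overlap" (*divergent*) holds, so the classification is exhaustive and
exclusive; identical spans count as mutual containment. Orientation uses
conservation scores when both members have them and they differ, else
detection breadth (conditions whose replicate-mean TPM ≥ 1; each condition
contributes its replicates, so this matches counting samples at the
condition mean), else the lexicographically smaller id — a convention, not
biology, and flagged as such in the output (`orientation_basis`).

## lncRNA classification

The cascade order is fixed: spliced length < 200 nt (exactly 200 kept,
literal "shorter than"), then ≥ 1 bp exonic overlap with the structural-RNA
blacklist on either strand (contamination removal is conservative; no
threshold is stated upstream, so the trigger is minimal), then the external
coding label (an optional numeric score column with score > 0 ⇒ coding is
accepted). Positional classes use the known (annotated mRNA) gene set;
antisense span overlap beats intronic containment beats intergenic, because
the antisense relationship is the analysis target. Intronic containment is
tested on either strand, but note an opposite-strand intronic transcript is
always antisense first.

## Differential expression and pair response

The decision rule is fold change ≥ 2 with p < 0.05 and no multiple-testing
correction, mirroring common practice for this kind of screen. Because the
test behind the rule is a free choice, we use Welch's two-sample t on
log₂(TPM+1) replicate values (n = 3 vs 3): log-scale variance is closer to
homoscedastic, and Welch drops the equal-variance assumption. Fold change
uses group means with a 1-TPM pseudo-count — lncRNAs are low-expressed and
unguarded ratios explode at zero. Type-I error of this recipe on the null
generator lands in [0.03, 0.07] (the +1 shrinks low-TPM contrasts slightly
conservatively).

"Responsive pair" requires both members to pass in the *same*
tissue × timepoint contrast: a pair whose members respond in unrelated
organs is not a coherent pair response. The alternative reading (each
member passing in any contrast) would only enlarge the called set.
Concordance is the sign of the Pearson correlation between the members'
log₂FC vectors over all ten contrasts — fold-change space rather than raw
TPM across samples, which removes baseline-abundance confounding;
zero-variance vectors and exact zero correlation are reported
*unclassified* (a computed r whose magnitude is below 1e−12 is treated as
exactly zero to keep the sign classification stable against rounding).

## Small RNAs

A read supports a pair as nat-siRNA evidence iff its length is 20–24 nt and
its interval is fully contained in the pair's overlap, either strand: the
overlap region is double-stranded by construction, so strand is not
informative for precursor support (requiring reads on both strands is the
stricter variant we did not adopt). `min_reads` defaults to 1 — the flag
means *potential* precursor. TSS density counts reads fully inside the
window (containment, not midpoint, for determinism at boundaries) and
reports reads per gene; the per-position profile bins read starts by their
5′-most base, strand-oriented.

## Chromatin

Histone association is any-bp overlap between a peak and TSS ± 1 kb,
reported as a fraction of genes per (mark, class). Methylation change per
gene is the mean cytosine level at t minus at 0 h over gene body ∪ 1-kb
strand-aware promoter (the aggregation region is not dictated by the data
formats; body ∪ promoter captures both promoter and body signal); genes
with no cytosines at both timepoints are excluded, ties are excluded from
the up/down fractions. Context labels (CpG/CHG/CHH) are read from the
input table, never recomputed from sequence.

HSE scanning: motif families are built from the 5-bp units nGAAn / nTTCn —
canonical double nGAAnnTTCn (10 nt), canonical triple nGAAnnTTCnnGAAn and
its nTTCn-first phase (15 nt), non-canonical nGAAnnnnTTCn (12 nt). The
G/C positions are invariant; at most one conserved A across the nGAAn
units and one conserved T across the nTTCn units may be exchanged (the
"one adenine … one thymine" budget is per motif, which also keeps the
total mismatch count ≤ 2 for every family). The double and non-canonical
families are their own reverse complements, so each window is reported
once on "+"; triples carry the strand of their nGAAn-first reading. A
triple suppresses the double hits it contains to avoid double counting;
all other overlapping hits are reported.

## Synthetic data generator

The generator emulates the study conditions end to end on a toy genome
(default two 1.5-Mb chromosomes, 200 gene loci). Loci are packed with
≥ 2.3-kb gaps so TSS windows never bleed across loci; an antisense partner
is planted at a locus with probability 0.5, with configuration drawn from
{enclosed 0.645, convergent 0.20, divergent 0.155} (the enclosed share
matches the full-scale study; the convergent/divergent split of the
remainder is unreported and fixed here once) and pair type from
{mRNA–mRNA 0.034, mRNA–lncRNA 0.904, lncRNA–lncRNA 0.062}. Decoys for
every filter are emitted alongside: intergenic and intronic lncRNAs,
sub-200-nt fragments, blacklist-overlapping fragments and coding-labelled
fragments. Intronic decoys sit on the host strand — an opposite-strand
intronic transcript is, correctly, an antisense candidate. 15.2% of pairs
are heat-responsive, 81% of those concordant (both matching the full-scale
proportions); each responsive pair gets effects in 1–2 random tissues at
both treated timepoints, magnitudes uniform on the configured log₂FC range
(default [1.5, 4], with an optional 5-h attenuation factor, off by
default), sense member up, antisense sign by concordance.

Expression: TPM = exp(N(μ, σ²)) · 2^planted · log-normal noise with unit
mean and CV = `replicate_cv` (exactly 1 at CV = 0). Defaults μ = 2.0
(natural log; median ≈ 7 TPM), σ = 1.0, with lncRNAs offset by −1.5 —
lncRNAs are substantially lower-expressed than mRNAs. Members carrying a
planted *negative* effect draw their baseline from the same log-normal
truncated below at 5 TPM: repression is observable only on transcripts
expressed under control conditions, and an 8-fold knock-down of a ~1-TPM
transcript cannot clear the pseudo-counted 2-fold rule no matter the effect
size, so an untruncated generator would plant undetectable truths.

smRNA reads are Poisson: background 10 reads/kb genome-wide, and
(enrichment − 1) × rate extra reads over the union of NAT overlap regions
and the TSS ± 1 kb windows of pair members (the enrichment the data
emulate is seen both in overlap regions and NAT promoters; confining it to
the overlap would make the TSS-window class ratio structurally smaller
than the planted multiplier, since the upstream half of a TSS window can
never lie inside an enclosed overlap). Default multiplier 2.4×. Lengths
are uniform on 18–30 nt; an optional weight adds excess mass at 24 nt.
Strands are uniform. The planted multiplier is estimated by the
read-start density ratio inside/outside the enriched regions — start
counting avoids the ~read-length/region-length edge bias a containment
rule would introduce.

Chromatin: each mark covers the TSS of a configurable share of genes
(default 0.5) with a peak extending 100–800 bp on each side. Methylation
is planted on pair-member genes: 40 cytosines per gene region, contexts
drawn 0.4/0.3/0.3, levels Beta with concentration 30 around per-context
means {CpG 0.50, CHH 0.30, CHG 0.15} (ordering as observed in NAT genes),
shifted by ±0.05 at 6/12/24 h, downward for 60% of genes. With 40
cytosines the per-gene Δ standard error is ≈ 0.02, so direction recovery
is ≈ 99% per gene. Promoters are 300-nt random sequences; half receive an
exact canonical double HSE at a random position (random flanks can both
create spurious relaxed matches and extend a planted double into a triple —
tests account for both).

Determinism: each stage draws from `numpy.random.default_rng(seed + stage
index)` (annotation 1, expression 2, smRNA 3, chromatin 4, promoters 5), so
identical configs give byte-identical outputs and stages are independently
reproducible.

### What the generator does not emulate

Read-level sequencing noise, mapping ambiguity and assembly artefacts;
overdispersed counts (TPM is drawn directly, so `compute_tpm` is exercised
separately on count fixtures); correlated replicates and batch effects;
sequence-dependent methylation contexts; realistic peak shapes. Passing
recovery tests therefore demonstrates correctness of the decision rules
and estimators under the stated noise model, not robustness to upstream
artefacts of real libraries.

## Problem sizes and numerical choices

The test and acceptance workloads use a 200-locus genome (~370
transcripts, ~100 pairs) for geometry and parameter recovery, ~2,000
transcripts for null calibration, 10⁵ reads for the precursor oracle
check and 10-kb sequence for the HSE oracle check — sizes at which every
planted structure is measured with comfortable statistical margins.
Percentages are rendered at full precision plus a display precision with
round-half-up by default and a truncation mode (some published summary
percentages truncate rather than round). All writers are
atomic (write-then-rename), so a failed run never leaves partial tables.

## Known limitations

Span-level (not exon-level) overlap is an interpretation choice; both are
defensible and the 50-bp threshold applies to whichever is chosen.
Orientation by expression breadth is unstable for pairs with near-equal
breadth (the tie-break is then lexicographic and explicitly labelled).
The per-gene smRNA means depend on sequencing depth and are comparable
only within a run; only ratios between classes are meaningful. The
methylation up/down fractions ignore cytosine coverage weighting. The
HSE mismatch budget is a literal reading of the one-A/one-T exchange rule;
scanners with per-unit budgets would admit strictly more triples.
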