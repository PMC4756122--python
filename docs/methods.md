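# Methods

This note documents the models, algorithms and numerical choices behind
`avimark`, the assumptions they rest on, and what the synthetic-data
tests do and do not establish.

## Reference database filtering (`refdb`)

Records are read from GenBank flat files (Biopython parser, applied per
LOCUS…// chunk so one malformed record cannot poison its neighbours).
A record enters the database iff, tested in this fixed order,

1. its `isolation_source` qualifier contains one of the source terms
   *feces, fecal, faeces, faecal, stool* as a **case-insensitive
   substring** (so "fecal swab" passes — the permissive, recall-oriented
   reading; term list and matching are user-configurable);
2. its source organism is not classified viral or vertebrate by a
   pluggable predicate (the shipped default is a word list — "virus",
   "phage", common vertebrate binomials — standing in for a real
   taxonomy service, which users can plug in);
3. its `host` qualifier is present and non-trivial (not
   "unknown"/empty).

Each rejected record is attributed to the *first* failing rule, which
makes the filter report deterministic and the tallies sum to the input
count. The filter is idempotent.

Host names are normalized by case-insensitive exact-token lookup in a
common-name → binomial table (swine → *Sus scrofa*, dog → *Canis
lupus*, …; user-extensible). Names that already look binomial pass
through; unmatched names are *never guessed* — the record keeps its raw
host string, so every database record has a host annotation while the
normalizer itself stays conservative.

Ambiguity codes (IUPAC R, Y, N, …) are retained in sequences; every
downstream comparison treats any non-A/C/G/T symbol as a mismatch.

## Seeded local search and E-values (`seqsearch`)

`local_search` seeds on exact k-mers (default k = 11 against reference
databases, k = 8 against short reads) and computes, for every
(subject, strand) pair sharing at least one seed, a full-matrix
affine-gap Smith–Waterman alignment (match +1, mismatch −2, a gap of
length n costs −5 − 2n; numba-jitted kernels). One hit per subject is
reported: the best-scoring local alignment over both strands, '+'
preferred at ties. Using the full matrix rather than a band around the
seed diagonal trades a constant factor of speed for provable optimality
at 16S amplicon scale — which is what makes the exhaustive
dynamic-programming oracle tests meaningful. Like any seed-and-extend
search, a homolog with a passing score but no shared k-mer would be
missed; at the default cutoffs (E ≤ 10⁻¹⁰ database search) such
alignments essentially do not occur for k ≤ 11.

E-values follow Karlin–Altschul statistics, E = K·m·n·e^(−λS), with m
the query length and n the total database length. λ solves
Σ pᵢpⱼ e^(λ·sᵢⱼ) = 1 on uniform base composition; K is computed by the
lattice Spitzer-series formula
K = dλ·e^(−2σ) / (H(1 − e^(−λd))), σ = Σⱼ (1/j)(E[e^(λSⱼ); Sⱼ<0] +
P(Sⱼ ≥ 0)). For +1/−2 this yields λ = 1.3327, K = 0.6210 — the
published ungapped nucleotide values — and the implementation is tested
against them. The ungapped (λ, K) pair is reused for gapped scores, the
customary approximation; users may supply their own pair.

`greedy_cluster` is CD-HIT-style: sequences visited by descending
length (ties by id), each joining the first cluster whose
representative it matches at ≥ the identity threshold, where identity =
matching columns of a free-end-gap global alignment divided by the
shorter sequence's length (CD-HIT's convention). A short-word prescreen
(k = 8) skips alignments that provably cannot reach the threshold: at
identity ≥ t over shorter length Lₛ at most ⌊(1−t)Lₛ⌋ columns touching
the shorter sequence are non-matching, each destroying at most k of its
exact k-mers, so at least (Lₛ−k+1) − k⌊(1−t)Lₛ⌋ of them must occur in
the representative. The prescreen is applied only for t ≥ 0.9 and
Lₛ ≥ 100, with one extra word of slack.

The free-end-gap aligner allows the empty overlap (score 0), so wholly
unrelated pairs get identity 0 rather than a forced negative-scoring
alignment.

## Exclusive OTUs (`otu_select`)

OTUs are picked by greedy clustering of the pooled reads at 97%
identity (the species-level proxy); per-group read counts are tallied
per cluster and the representative is the cluster representative
(longest member). "Exclusive to one group" is read strictly: exactly
one group with a positive count, and that count ≥ 8 reads. An optional
quality pre-filter reproduces the usual amplicon rules (length > 200,
no ambiguous bases, mean quality > 25 when qualities are available);
primer-mismatch screening is omitted since primer sequences are not
part of the read input.

Verification searches each exclusive representative against every
group's reads and refutes exclusivity on *any* hit at E ≤ 10⁻³ outside
the owner group, regardless of identity (an optional identity floor is
available, default off). Two consequences are worth stating plainly:

* **In communities sharing a conserved 16S backbone this default
  refutes everything** — a conserved stretch of ~21 nt already clears
  the E ≤ 10⁻³ bar against a megabase of reads. The E-value-only
  reading is therefore discriminative only when between-group sequence
  space is genuinely disjoint; with related communities, enable the
  identity floor. The batch verifier (`verify_all`) exploits the same
  fact for speed: a shared exact word at least as long as the
  qualifying score proves a qualifying hit without dynamic programming,
  and remaining reads fall back to full Smith–Waterman; it is tested to
  reach decisions identical to the one-call API.
* The `discover` pipeline consequently treats verification as an
  annotation: table-exclusive OTUs proceed to unique-window scanning
  with their confirmation status recorded, and `--require-confirmed`
  gates on it when the input communities warrant it.

## Unique-window scanning (`unique_finder`)

Homologs of a candidate are collected at E ≤ 10⁻¹⁰; each hit's subject
subsequence (reverse-complemented for minus-strand hits) is clustered
at 95% identity and the longest representative per cluster is kept, in
order of first appearance. The surviving representatives are aligned to
the candidate by a **query-centred star alignment**: each is aligned
globally to the query with free end gaps, and the pairwise alignments
are merged on the query coordinate frame ("once a gap, always a gap"),
with columns outside the query's span trimmed. Choosing the query as
the star centre makes trimming and coordinate mapping exact at the cost
of not being a general-purpose MSA; insertion blocks are left-aligned
(the choice never affects window statistics, which use only the query
residue columns).

An 18-nt window slides over the ungapped query at step 1. For each
window and each reference row, mismatches are counted over the columns
holding the window's query residues (gap, differing symbol, or any
ambiguity code = mismatch); a row with no aligned residue in the window
counts as fully mismatched — absence of a homologous segment is itself
evidence of uniqueness. A row "differs" when it has at least
`min_mismatches` (default 2) mismatches: a single mismatch rarely
prevents probe hybridization, so difference is defined per reference
sequence rather than per column (the per-column variant of the ≥ 90%
rule was considered and rejected as a default, since it conflates one
universally polymorphic site with a genuinely unique window; neither
variant is claimed to be the original in-house rule). The window is
flagged when ≥ 90% of the reference rows differ; with zero reference
rows every window is unique by definition. Flagged-window runs merge
into candidate regions carrying min/mean difference. Raising the
difference threshold can only shrink the flagged set, raising
`min_mismatches` can only lower difference fractions, and adding
query-identical references dilutes every fraction below 1 — all tested
as invariants.

Coordinates everywhere are 0-based, half-open, on the ungapped input
query. Thermodynamic probe design and external database cross-checks
are out of scope; candidate regions are emitted as FASTA for those
tools.

## qPCR evaluation (`assay_eval`)

Standard curves are ordinary least squares of Ct on log₁₀(copies)
(≥ 3 distinct positive copy levels; undetermined wells excluded). The
slope is stored as a positive magnitude — dilution curves necessarily
fall, and assay reports customarily print |slope|. Efficiency is
(10^(1/|slope|) − 1)·100, exactly 100% at |slope| = 1/log₁₀2 ≈ 3.3219.
The LOD estimator returns the smallest tested copy level with detection
fraction ≥ 0.9 (boundary inclusive); no qualifying level yields an
explicit undefined result, not an exception. Plasmid copy numbers
derive from mass as copies = m[g]/(L·660 g·mol⁻¹·bp⁻¹)·N_A.

Confusion summaries count TP/FN over samples in the assay's target host
groups and TN/FP over the rest of the panel. Reported percentages are
**floor-truncated** (76.47 → 76; 84.78 → 84.7 at one decimal) — the
rounding rule consistent with how such panels are customarily printed —
with raw fractions always retained. Target groups are data supplied per
assay, never hard-coded, and may be absent from a panel (a
specificity-only panel of non-target hosts then gives TP+FN = 0 and an
undefined sensitivity). Binary calls from raw Ct require every
duplicate well at or below the Ct of the LOD level on the standard
curve; "detected not quantified" amplification (beyond the ROQ floor)
counts positive by default and negative under the alternative
convention. Quantity profiles report median/quartiles
(linear-interpolation definition) and 1.5×IQR outliers on copies per ng
DNA.

## Synthetic data (`synthdata`)

The generator emulates a V1–V3-style amplicon study and ships complete
ground truth; all outputs are pure functions of (spec, seed), with
per-host RNG substreams so that generating a host subset never changes
the records of the hosts kept.

* **References**: a 500-bp backbone (configurable) with three
  hypervariable regions at fractions 0.12–0.28, 0.42–0.58, 0.76–0.92 of
  the length, mutated per host at rates 0.10/0.12/0.10 (host
  signatures), plus within-host strain substitutions at 0.02 inside the
  variable regions. Planted host-unique windows (default one 24-nt
  window per host, in conserved segments, non-overlapping) are
  randomized per position for the named host only, so by construction
  they differ from every other host in ≥ 90% of positions. Records are
  emitted as GenBank text with host/isolation-source qualifiers drawn
  so a stated fraction (default 0.8) passes the database filters; the
  truth table records every fate and planted span.
* **Reads**: 5′-anchored (primer-anchored pyrosequencing), lengths
  uniform on [0.7·L, L], substitution errors at 0.001 per base — the
  substitution-specific error of quality-filtered pyrosequencing reads;
  homopolymer indels, the dominant 454 error mode, are deliberately not
  modelled, which is sufficient to exercise every algorithm here but
  means indel robustness of the window scan is only covered by the
  alignment unit tests. Error positions are part of the truth table.
* **qPCR**: Ct = intercept − |slope|·log₁₀(copies) + N(0, σ) with
  defaults |slope| = 3.4, intercept = 40.1, σ = 0.3 Ct; detection is
  Bernoulli with a logistic dropout curve in log₁₀ copies, steepness 10
  per decade and midpoint at lod_copies/4, placing detection
  probability ≈ 0.998 at the nominal LOD and ≈ 0.28 one 5-fold dilution
  below — the sharp cliff expected from Poisson template limitation at
  a few copies per reaction (at 5 copies, P(≥1 template) = 0.993).
  Steepness 0 disables dropout. The truth table records the smallest
  tested level whose theoretical detection probability reaches 0.9,
  i.e. the LOD the estimator should recover given the tested levels.

What a green synthetic test establishes: the pipeline's selectivity and
recovery under substitution-type divergence, correct bookkeeping of
counts/coordinates/fates, and estimator calibration under the stated
noise. What it does not: robustness to chimeras, homopolymer indels,
taxonomy-realistic community composition, or real between-study primer
bias.

## End-to-end recovery check

The acceptance-level pipeline test builds, for each of 20 seeds, the
six-host world with the reference database drawn from the five
non-target hosts (the MST setting), runs `discover` at default
parameters and asserts that (a) the target host's planted window is
covered by a flagged region and (b) no flagged window lies wholly in
conserved backbone — where "conserved backbone" is truth-annotated:
outside the variable regions, outside the candidate host's planted
window, and free of the representative read's recorded sequencing
errors. The last clause matters: two sequencing errors inside one
18-nt window genuinely make that window unique to the errored read, and
the scanner is *correct* to flag it (the workflow's downstream external
cross-checks exist precisely to catch such artifacts), so the check
charges the scanner only with windows whose content is truly backbone.
Hosts present in the database dilute their own planted windows below
the 90% threshold — also correct behaviour, verified in the same test.

## Known limitations

* Gapped Karlin–Altschul parameters are approximated by the ungapped
  pair; E-values near a cutoff can differ from BLAST/FASTA by a modest
  constant factor.
* The star alignment is query-anchored, not a general MSA; reference–
  reference relationships within insertion blocks are not optimized.
* Seed-and-extend search can miss homologs lacking any exact shared
  k-mer (negligible at the default cutoffs and k).
* The E-value-only verification default is meaningful only for
  disjoint between-group sequence spaces; see the identity-floor
  option.
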