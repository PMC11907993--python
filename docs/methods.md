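# Methods

## The orientation grammar

Every binding element is stored 5'→3' with its +1 guanine as the first
written base (`plus_one_offset = 0`), so "the +1 Gua adjacent to the
linker" translates into coordinates as: an upstream element contributes
a spacer-adjacent +1 Gua when it lies on the minus strand, a downstream
element when it lies on the plus strand.  Each strand assignment of a
composite therefore maps to exactly one binding mode:

| upstream strand | downstream strand | mode |
|---|---|---|
| minus | plus | back-to-back |
| plus | minus | face-to-face |
| same strand | same strand | face-to-back |

The achievable mode set of a hit is the union over all strand
assignments permitted by the two occurrences (palindromic sites carry
both strands).  This table is strand-symmetric by construction:
reverse-complementing a locus swaps the two elements and flips their
strands, which maps each assignment onto one with the same mode — the
property the test suite checks explicitly.

**Responsiveness predicate.**  A hit is `BMP_responsive` iff the spacer
is exactly 5 bp, back-to-back binding is achievable, and the element
pair is drawn from {`pGC_SBE`, `SBE`} with at least one GC palindrome.
When the only back-to-back route places the non-palindromic SBE
upstream on the minus strand (the fully antisense composite
`CAGAC-N5-GGCGCC`), the call is downgraded to `BMP_responsive_weak`:
that arrangement retains activity but measurably less than the sense
orientation.  A 5-bp spaced pSBE pair is `TGFB_responsive`.  All other
pairs — including npGC- and 5GC-containing composites, which the
scanner still detects and reports — are labelled `nonresponsive`.
Labelling npGC-containing heterocomposites nonresponsive is a modelling
choice: those composites occur in bound regions but were not
functionally assayed, so the predictor stays conservative.  Linker GC
content modulates response strength but never the class; it is visible
in the reported `spacer_seq`, not in the label.

Two written forms of the GC palindrome circulate (6-mer `GGCGCC` and a
7-mer `GGCGCCC`); the 6-mer is canonical here and the 7-mer is accepted
as a user-defined element via the element-table TSV.

**Matching.**  Occurrence detection is exact string matching of the
expanded variant set (degenerate IUPAC codes and `|`-alternatives are
expanded before matching, which keeps the matcher oracle-testable).
Palindromic sites are emitted once with `strands = both`, avoiding
double counting in screens.  `N` and soft-masked bases never match; the
screening mask policy `upper` (default) uppercases before matching,
`exclude` masks lowercase bases out.  Heterocomposite classes are
unordered by default (both `A-N5-B` and `B-N5-A` count), with an
`ordered` override.

## Screening

A region is positive for a composite class iff it carries ≥1 hit; a
region positive for several classes counts once per class (class counts
are not exclusive).  Hits are deduplicated by (upstream start,
downstream start, element pair).  How the original occurrence counting
handled overlapping matches and strand duplicates is not documented, so
absolute counts from other toolchains may differ; the policy here is
deterministic and stated.  Regions that cannot be resolved to sequence
are excluded and itemised rather than failing the screen.

## Linker profiles

Spacers are pooled across classes by default (per-class profiles are
available).  Before extraction each hit is orientation-normalised: the
locus is flipped, if necessary, so the composite reads
GC-element → spacer → partner on the plus strand; a composite carried
entirely on the minus strand is likewise flipped.  Without this a
mixed-strand hit set would average a profile with its reverse
complement.  Information content per position is `2 + Σ f·log₂ f` bits
against the uniform background (relative entropy against a supplied
background), with no small-sample correction; pseudocount defaults to 0
so counts stay exact, 0.5 is available for logo rendering.
G-enrichment at a position is a one-sided binomial test of the G count
against the background G frequency at α = 0.01.

## Genomic annotation

Regions are classified by the functional class at their midpoint with
precedence promoter > UTR > exon > intron > intergenic (an any-overlap
mode exists behind a flag).  The promoter window is −1000..+100 bp
around the TSS, strand-aware, configurable.  Genomic shares are
computed with precedence masking so each base counts for one class;
unannotated bases are intergenic.  Enrichment is the raw fraction of
positives in a class divided by that class's genomic share (1.0 =
proportional representation); `normalized_pct` rescales enrichments to
sum to 100 for plotting.  No genome-specific annotation data are
bundled.

## Hill fitting

Model: `Y = Bmax·X^h/(Kd^h + X^h)` with bounds Bmax ∈ (0, 1], Kd > 0,
h > 0 enforced by bounded trust-region least squares on the natural
scale, so standard errors (from the covariance of the fit) apply
directly to the reported parameters.  Initialisation: Bmax₀ = max(Y)
clipped to (0, 1]; Kd₀ = the concentration whose response is closest to
Bmax₀/2; h₀ = 1.  Replicates are fitted jointly by stacking points.
Non-convergence returns NaN parameters with a `no_convergence` flag;
a fitted Kd beyond 10× the largest concentration carries
`kd_extrapolated`, a response that decreases with concentration
`decreasing_response`.  Cooperativity bands (h ≥ 1.5 moderate positive,
h < 1.3 weak) are interpretive conventions for reporting, not fitted
quantities.  Concentrations are in the units declared on the curve; Kd
inherits them (rescaling nM→µM divides Kd by 1000 exactly).

## Reporter library

Insert layout: `GGTACC` (KpnI) + motif cassette + `CTCGAGATCT` + MLP,
where the 10-bp junction carries overlapping XhoI (`CTCGAG`) and BglII
(`AGATCT`) sites, so the MLP-proximal motif always ends exactly 10 bp
before the MLP (`GGGCTATAAAAGGGGGTGGGGGCGCGTTCGTCCTCACTCTCTTCC`,
present verbatim exactly once).  GC-poor spacers are drawn from {A, T}
with at most one C and never a G — a guanine-free spacer cannot
complete any element across a cassette boundary, so spacer choice can
never change a construct's label.  Spacer draws are seeded per
construct id, making the library deterministic; the exact spacer
sequences of the original non-5-bp constructs are not published, so
these stand-ins may differ in sequence (never in label).  The
enumerated series (spacing grid over {2,3,4,5,6,10,20}², homotypic
orientation sets, copy-number 1–6, ID-locus linkers TGGCT/AGAGA/AGGCT
plus the AACTT control, heterocomposite orientations, and all 18
single-nucleotide permutations of the GC palindrome) yields 89 distinct
inserts; counts are asserted as ≥65, never as an exact catalogue match.
Labels are computed by scanning the assembled insert — not by trusting
the design — so a permuted motif genuinely disappears from the
detected composites.  The bundled expected-outcome fixture encodes the
qualitative reporter results; permutation constructs are expected
non-responsive there, which subsumes "reduced" residual activities
below the predictor's two-level resolution.  Distance of the composite
to the promoter modulates response strength; no threshold is published,
so distance is exposed as construct metadata, never folded into the
label.

## Synthetic data

Backgrounds are i.i.d. bases at GC 0.41 (human-like) in 300-bp regions
(typical peak scale), each region on its own synthetic chromosome.
Regions are rejection-sampled (bounded at 10⁴ attempts) to contain no
occurrence of any screened composite class, so planting truth is exact:
scanner positivity on a planted set must equal the truth table with
zero false calls, and the tests assert precisely that.  Planting
overwrites one composite per selected region (count = round(rate·n),
chosen without replacement) at a uniform random offset, optionally as
the reverse complement; after writing, the region is re-scanned and the
plant is retried unless every prior plant survives, the new composite
is detected at its offset, and no unintended class appears.  The
default planting rates used in tests keep per-class positivity below
1%, the rarity regime observed in real bound-region screens.  All
generators are pure functions of parameters + seed.

What the synthetic data does *not* emulate: real peak-length and GC
heterogeneity, repeat structure, motif clustering with co-factor sites,
and read-level noise.  Passing the recovery tests therefore shows the
scanner and bookkeeping are exact, not that real screens are free of
ambiguous or masked loci.

## Problem sizes and numerical choices

The test suite runs the scanner-equivalence check on 200 random 1-kb
sequences over all element pairs and spacers 2–20, planted recovery on
500 × 300-bp regions at a 3% rate, and the Hill noise study on 200
seeded curves (12 concentrations, 10–3000 nM, σ = 0.03, 2 replicates) —
sizes chosen so the whole suite completes in well under a minute while
keeping the binomial/Monte-Carlo margins comfortable.  Optimiser
tolerances are set to 1e-14 so noiseless Hill recovery reaches ≤1e-5
relative error across the grid Bmax ∈ {0.5, 0.9}, Kd ∈ {100, 500,
1000}, h ∈ {1.0, 1.8}.

## Known limitations

- The predictor is exact-match and two-level (strong/weak); it does not
  score affinity, linker GC bonuses, promoter distance or copy-number
  dose effects, all of which modulate measured response magnitude.
- Degenerate 5GC elements are matched and reported but excluded from
  the default screening class set, because `GGCGC` is a substring of
  the GC palindrome and would make per-class counts non-orthogonal.
- No probabilistic PWM scanning with score thresholds; the screening is
  deliberately exact-sequence based.
- Real-genome annotation requires user-supplied class/TSS BED files;
  nothing genome-specific ships with the package.
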