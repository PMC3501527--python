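# Methods

## The measurement model

Tag-based DGE reduces each transcript to a 21-base tag: NlaIII cleaves
cDNA at every `CATG`; MmeI cleaves 17 bp downstream of the recognition
junction, releasing `CATG` + 17 bases. Because the protocol captures
the bead-bound 3′ fragment, the tag actually sequenced is the one from
the **3′-most** qualifying `CATG` site (the *canonical* tag). The
reference library built from the transcriptome nevertheless indexes
**all** qualifying sites of every gene: a clean tag can in principle
originate from any site (incomplete digestion, assembly artefacts), and
ambiguity must be judged against the full site catalogue. This
asymmetry — simulator emits canonical tags only, reference holds all
sites — is intentional and mirrors the chemistry.

Coordinates are 0-based, tags occupy the half-open interval
`[offset, offset+21)`. The default strand mode is sense-only, because
assembled unigenes carry a determined orientation; `both` is available
since assembly orientation is imperfect, with minus-strand origins
recorded in reverse-complement coordinates (the tag re-locates at its
recorded offset in `revcomp(sequence)`).

Tags containing `N` are excluded from the reference: clean tags are
N-free by construction and could never match them.

## Cleaning

Raw reads are cleaned in a fixed order: adapter-only reads (represented
by a sentinel that is never a valid 21-mer), then reads containing `N`,
then every tag whose remaining within-library copy number is exactly 1
(singletons are predominantly sequencing errors at these depths). The
order of the singleton filter relative to the others is a package
decision; it matters only marginally because N-containing sequences are
removed regardless of copy number. The conservation identity
`clean = raw − adapter − N − singletons` is asserted at run time on
every call.

Copy-number distributions default to the bins [2,5], [6,10], [11,20],
[21,50], [51,100], >100, which bracket the conventional "fewer than 5
copies" / "more than 100 copies" reporting thresholds; bins are
configurable but must partition [2, ∞). Report percentages are rounded
half-up to 2 decimals, the convention of printed summary tables; row
averages are means of the per-library values (count rows rounded to
integers, percentage rows means of the already-rounded percentages),
which is the convention that reproduces published summary tables
exactly.

## Mapping and quantification

A clean tag is matched against the reference allowing at most one
mismatch, via enumeration of its 63 Hamming-1 neighbours against a hash
index — exact and fast at tag scale; the behavioural contract is
defined by the brute-force all-pairs Hamming oracle in the test suite.
By default an exact hit preempts the mismatch search (a tag matching
gene A exactly and gene B at distance 1 is unambiguous for A); the
pooled alternative is available via `prefer_exact=False`. Tags whose
matches span exactly one gene are unambiguous and are the sole source
of expression counts; ambiguous tags count toward mapping totals but
toward no gene; unmatched tags are unknown. The identity
`mapped + unknown = clean` is asserted on every run.

TPM is `1e6 · count / denominator`. The denominator defaults to the
clean-tag total of the library ("per million clean tags");
`unambiguous_total` is offered as an alternative, under which TPMs sum
to exactly 1e6. "Per million tags" is genuinely ambiguous in the
field's usage; both conventions are therefore configuration points with
a documented default, and the DE module uses the same denominators.

## Differential expression

Conditional on count x in library 1 (total N1), the count y in library
2 (total N2) follows

    p(y|x) = (N2/N1)^y (x+y)! / ( x! y! (1+N2/N1)^(x+y+1) ),

equivalently y|x ~ NegativeBinomial(x+1, N1/(N1+N2)). All terms are
evaluated in log space with log-gamma, stable to x+y ~ 1e6. The lower
tail P(K ≤ y) is a vectorised log-sum-exp over k = 0..y; the upper tail
P(K ≥ y) is summed directly from k = y by a scaled recurrence,
terminating once the geometric remainder bound falls below 1e-14 of the
running sum (when y lies at or below the conditional mean the upper
tail is the large one and is taken as the complement instead, where no
precision is at stake). The two-sided p-value doubles the smaller
inclusive tail and caps at 1; the doubled-tail construction is the
conventional choice where the literature does not fix one. Values
within 1e-12 of 1 are reported as exactly 1 (both tails include the
observed count, so equal counts with equal totals are exactly
non-significant).

Two algebraic facts worth recording: p(y|x; N1,N2) equals
(N2/N1)·p(x|y; N2,N1), so the swap identity is exact only for
N1 = N2; and the doubled-tail two-sided p-value is not exactly
swap-symmetric even at N1 = N2 (the two constructions include different
boundary terms deep in the tails). Tests assert the identities where
they are exact.

FDR control is Benjamini–Hochberg step-up (statsmodels), with
Benjamini–Yekutieli by flag. A gene is called differentially expressed
when FDR ≤ 0.001 **and** |log₂(TPM₂/TPM₁)| ≥ 1 (both thresholds
configurable). Before the ratio, each TPM is floored at the TPM of a
single tag in its library, keeping ratios finite while preserving
order; genes with zero counts in both libraries carry no evidence and
are excluded from testing rather than inflating the number of tests.
The log₂ ratio uses TPM (equivalent to raw counts only when N1 = N2);
this is a documented choice. qRT-PCR validation support is the ΔΔCt
fold change `2^(−ΔΔCt)`.

## Enrichment

For a term annotating M of the N annotated background genes, with m of
the n (annotated) DEGs carrying it, the p-value is the hypergeometric
upper tail P(X ≥ m), summed directly with log-gamma binomial
coefficients and verified against exact rational arithmetic to 10
significant digits. m = 0 gives P = 1; impossible terms (n−i > N−M)
contribute zero. The "corrected P" is BH-adjusted by default
(Bonferroni by flag) — the correction method behind published
"corrected P-values" is rarely named, so the default here is a package
decision; the pathway-mode q-value is always the BH value. Terms
annotating fewer than 2 genes are skipped (configurable floor).
Unannotated DEGs are dropped with a logged count: the background is the
annotated universe. No ontology-graph propagation is performed — terms
are tested flat, as assigned.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analysis
assumes:

- **Transcriptome** — random sequences at 42 % GC, log-normal lengths
  (median 474 bp, log-sd 0.6, matching a typical short-read unigene
  assembly; minimum 25 bp), with an exactly controlled count of
  untaggable genes (no `CATG` with ≥ 17 downstream bases); a site is
  planted when a taggable gene lacks one by chance.
- **Expression** — log-normal base abundances (log-sd 2.0, giving the
  heavy-tailed profile in which genes above 100 copies dominate total
  tags while most distinct tags sit below 5 copies). Library 1 is the
  reference; DE genes get abundance × 2^(log₂fc) in library 2, then
  renormalisation to the simplex. DE truth is drawn from taggable
  genes only — an untaggable gene is invisible to the assay, so
  planting truth there would make recovery metrics meaningless.
  Renormalisation means the *realized* truth ratio differs from the
  assigned fold change by a common constant; recovery metrics compare
  against the realized ratio.
- **Libraries** — read-class counts (adapter-only, N-containing,
  singleton noise, genuine tags) drawn multinomially so they always sum
  to the library size exactly; genuine tags drawn multinomially from
  the (taggable-renormalised) truth; independent per-base substitution
  errors, with the ≥-1-error masks drawn by rejection (the exact
  conditional law); noise reads are unique random 21-mers distinct
  from all canonical tags. One library per condition, matching the
  replicate-free design this analysis targets.
- **Annotations** — independent Bernoulli gene–term assignment at a
  background rate, with one term planted at a higher rate on a target
  set (by default the true DE genes).

Not emulated: 49-bp raw reads with adapter context or quality strings,
PCR amplification bias, partial digestion, SNP-destroyed sites, and
biological replicate variability. Passing tests therefore demonstrate
correctness of the algorithms under the model's own assumptions — they
do not certify performance on real libraries, where overdispersion
beyond Poisson sampling would inflate the error rates of any
replicate-free exact test.

## Numerical and design notes

- Percentages: decimal half-up rounding, 2 places; zero denominators
  report 0.00 rather than erroring.
- Audic–Claverie tails: see above; accuracy verified to ≤ 1e-12
  relative error against exact rational oracles over x, y ≤ 200 and
  library-size ratios in [0.2, 5] (outside double-precision range the
  probability underflows, which only affects astronomically significant
  genes).
- One-mismatch search: neighbour enumeration is exact; ties between
  multiple distance-1 reference tags are resolved by set union of their
  gene origins (no arbitrary winner).
- Determinism: every generator and the pipeline accept a single seed;
  all output tables are written sorted with fixed float formatting, so
  reruns are byte-identical.
- Problem sizes in the validation harness: null calibration uses 5,000
  genes × 1e5 tags × 20 seeds; DE recovery 20,000 genes × 1e6 tags at
  count level (the count layer is where the statistic operates); the
  read-level end-to-end path runs at 2,000 genes × 2e5 reads. These
  sizes give stable metrics while keeping the whole suite fast.

## Known limitations

- No replicate-aware dispersion modelling (negative binomial GLMs);
  the Audic–Claverie test assumes pure Poisson sampling within a
  condition, appropriate only for the single-library-per-condition
  design.
- No probabilistic rescue of ambiguous tags and no multi-mismatch
  mapping.
- Enrichment treats terms as flat sets; GO ancestor propagation is out
  of scope.
- The simulator's error model is substitution-only (tags are fixed
  length; indels would shift the MmeI cut, not change the tag length).
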