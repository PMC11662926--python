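# Methods

## The experiment this package analyses

Nonenzymatic RNA primer extension copies a template by chemistry alone:
activated ribonucleotides (and, in some conditions, activated random-sequence
oligonucleotides) add to the 3' end of a primer annealed to a template.  The
sequencing readout uses a self-priming hairpin: a fixed 5' handle, a
random-sequence template region (18 nt here), a hairpin loop, and a fixed
primer whose 3' terminus folds back adjacent to the template.  Extension
copies the template *in cis*, so after ligating an RT handle to the product
3' end, a single paired-end read carries a matched template/product pair:

```
5'- handle5 | template | loop | primer | product | rt_handle -3'
```

All statistics are indexed in **templating order**: t_1 is the template base
directing product position +1 (the first base added), which is the *last*
base of the template region as written 5'->3' in the molecule.  The product
is antiparallel to the template; position +i is correct when
`p_i = complement(t_i)`.  Mismatches are labelled `template:product`.

## Read processing

1. **Quality filter** — a pair is rejected (`low_quality`) when either
   mate's mean Phred score is below `min_mean_q` (default 30) or any base is
   below `min_base_q` (default 20); both thresholds are inclusive.  These
   defaults are conventional Illumina practice; they are configurable and
   none of the package's recovery guarantees depend on them.
2. **Mate merging** — the reverse mate is reverse-complemented and slid
   along the forward mate over the offsets consistent with the construct's
   possible insert lengths (falling back to a full scan); the offset with
   the fewest overlap disagreements wins.  More than `max_disagreements`
   (default 0) disagreeing overlap positions rejects the pair
   (`mates_disagree`); at a retained disagreement the higher-quality base is
   kept.  A minimum overlap of 10 nt is required.
3. **Region location** — each fixed region is anchored at its expected
   offset (the whole layout may shift by up to ±3 nt) by substitution-only
   Hamming matching with a per-region tolerance (default 1).  Indel-tolerant
   alignment is deliberately not used: the insert architecture is fixed and
   substitution matching keeps the coordinate arithmetic exact.  The RT
   handle is searched over all admissible product lengths 0..18; a handle
   found beyond 18 product bases means the product ran into the template
   region's limit and the read is counted separately (`product_overrun`)
   rather than guessed at.
4. **Extraction** — the template window is reversed into templating order,
   the product window is read in order of addition, and per-position calls
   are computed.  Windows containing an ambiguous symbol are rejected
   (`template_has_ambiguity`); N in fixed regions merely consumes mismatch
   budget.  If the fixed regions are not found, the reverse complement of
   the merged insert is tried before rejecting, so mate-swapped input yields
   identical pairs.

The filter report is conservative by construction: accepted plus all
rejection reasons equals the number of input pairs.

## Composition normalization

The synthesized template region is not perfectly equimolar, so raw product
statistics confound chemistry bias with template composition.  From a
no-extension control, the position/base fractions `f(i, b)` of the template
give weights

```
w(i, b) = 0.25 / f(i, b)
```

and every composition-sensitive statistic weights each observation by the
product of `w` over *exactly* the template positions entering the statistic:
positions 1..L for positional frequency tables, the three window positions
for trimer tables.  This multiplicative scheme is the minimal one that makes
a biased template look equimolar, and it reduces to the identity under a
uniform control (a tested invariant).  A control in which some base is never
seen at some position admits no finite factor and is rejected as degenerate.

Fidelity statistics — error frequency, mismatch spectrum, product-class
fractions — are **unweighted by default**: reweighting a fidelity estimate by
template composition would conflate sequence bias with copying accuracy.  A
weighted error frequency is computed alongside as an option
(`error_frequency_weighted` in the summary).

## Statistics

* **Positional frequencies** `F(i, b)`: weighted fraction of products with
  base `b` at position +i, among all extended products or among fully
  complementary (zero-mismatch) products.  Covered rows sum to 1.
* **Trimer tables**: product-base trimers at positions 1-2-3 (products with
  L >= 3) or 4-5-6 (L >= 6), complementary products only.  The ideal uniform
  frequency is 1/64 ≈ 0.016.  The **median** is taken over all 64 trimers,
  zeros included — unrepresented trimers participate in the ordering.  The
  **max/min fold-difference** is over represented (nonzero) trimers only and
  is reported to the nearest integer.  Summaries print at 3 decimals; TSVs
  carry full precision.
* **Error frequency**: mismatched incorporations / total incorporated bases,
  over all extended products.
* **Mismatch spectrum**: the 12 `template:product` types by product
  position, normalized over all mismatches, with positional and type
  marginals.
* **Product classes**: complementary fraction (over extended products);
  among mismatch-containing products, the fraction with >1 mismatch; among
  single-mismatch products, the fraction whose mismatch is terminal (at
  position L).  Conditional fractions with empty denominators are reported
  as undefined (null), never as 0.
* **Yield and lengths**: yield = fraction of all molecules with L >= 1;
  the product-length distribution over L = 0..18; and the cumulative
  incorporation curve — per position i, the fraction of all molecules
  extended at least to i, split by the call *at position i itself* (not by
  any-mismatch-up-to-i; the alternative convention is equally defensible but
  this one keeps the split additive per position).  The curve is
  non-increasing and starts at the yield.

## The synthetic-data generator

The generator emulates the experiment end to end so every estimator can be
checked by parameter recovery. Per molecule: a template drawn
position-by-position from `template_composition` (uniform by default); with
probability `extension_prob` an extension whose length is truncated-geometric
(success probability 1/3, i.e. untruncated mean 3, capped at 18 — the
empirical length distribution is not tabulated in the main literature, so the
geometric is a stand-in, not a claim) or an explicit pmf; product bases drawn
from a 4x4 matrix `B(t, p)` whose complement-diagonal mass is the
correct-incorporation probability (default per-base error 0.063 with a
uniform spectrum); optionally a contiguous ligation block of `ligation_len`
bases with its own per-base error rate appended with probability
`ligation_prob`, the simplest mechanism producing the multi-mismatch
enrichment that oligonucleotide ligation contributes (off by default — no
generative rate is published).  Default extension fraction is 0.23, the
yield of the low-bias benchmark condition.

Reads are rendered as the first `read_len` (default 70) bases of the insert
and the reverse complement of the last `read_len` bases, in the DNA
alphabet, constant Phred quality (Q37), with independent per-base
substitution errors on each mate (default 0.001; position-dependent quality
profiles are out of scope because quality filtering is not an estimation
target).  All randomness derives from one seed; identical parameters give
byte-identical FASTQ.

**What passing recovery tests does and does not show.**  The generator
reproduces the *structure* of the data (construct layout, matched pairs,
composition bias, mismatch spectrum, ligation-like multi-mismatch tails,
uniform sequencing error) but not real instrument error profiles, indels,
RT/PCR artifacts, or hairpin secondary-structure effects.  Recovery therefore
validates the bookkeeping and estimators, not robustness to every artifact
of real libraries.

## Numerical and design choices

* Frequencies are ratios of (weighted) counts; no smoothing or priors.
* Ties in mate-merge disagreements go to the forward base; ties in
  tolerant RT-handle location go to the smallest product length.
* Degenerate inputs fail loudly: empty pair sets, controls missing a base at
  a position, statistics over empty denominators all raise (or report null)
  rather than returning 0.
* Problem sizes in the tests and the acceptance script (100,000 molecules
  for error/yield recovery, 50,000 for the trimer median) put the binomial
  standard error an order of magnitude below the stated tolerances.
* The model layer (`PrimerExtensionModel.fit()` returning
  `PrimerExtensionResults`) is a presentation choice: all statistics remain
  available as module-level functions in `nerpeseq.stats`.

## Known limitations

* Substitution-only region matching cannot rescue reads with indels in
  fixed regions; they are rejected, which biases nothing but costs depth.
* Products longer than the template region (running into the 5' handle) are
  counted (`product_overrun`) but not analysed; whether such molecules occur
  in real libraries is not established.
* The constant-Q quality model makes the quality filter essentially
  untestable against realistic quality degradation; thresholds are exposed
  but not tuned.
* The default construct's fixed-region sequences are arbitrary documented
  stand-ins with the correct region roles and lengths; analyses depend only
  on the region structure, and real constructs are supplied by YAML config.
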