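# Methods

This note records the models, parameter choices and known limitations
behind `hicplexy`, in the order the pipeline runs them.

## Coordinate model and restriction fragments

All internal coordinates are 0-based half-open; the breakpoint-table
format is 1-based inclusive and is converted at I/O, BED inputs are
taken as 0-based half-open. In-silico digestion scans the forward
strand for exact occurrences of the recognition motif (default HindIII,
`A^AGCTT`, cut offset 1); palindromic motifs make the reverse strand
redundant, and degenerate IUPAC codes are rejected rather than expanded
so that the digest is trivially checkable. Fragments are the half-open
intervals between consecutive cut points and always partition the
chromosome. Assembly gaps flag overlapping fragments (≥ 1 bp) as
unusable without trimming coordinates: the permutation test resamples
whole fragments as units, and trimming would change unit identity.

## Filtering

Duplicates are pairs with identical canonical coordinates and strands
on both mates (PCR-duplicate semantics). The "reads not anchored at a
restriction site" filter is expressed post-alignment as a
distance-to-nearest-cut-site threshold (default 1000 bp). It is off by
default in the pipeline configuration because the bundled simulator
places reads uniformly within fragments rather than at cut sites; on
real libraries it should be enabled.

## Balancing

Equal-visibility balancing is iterative proportional scaling of the
symmetric binned matrix: each iteration divides by the square root of
the ratio of each included bin's marginal to the mean marginal. The
square-root damping matters: full proportional steps oscillate
indefinitely on matrices with nearly disconnected blocks, while the
damped map contracts to the same fixed point. Convergence is declared
when the maximum relative marginal deviation falls below `tol` (1e-5
default, ≤ 200 iterations). Bins with raw marginal coverage below 10
counts are masked beforehand. The balanced matrix is rescaled so its
total equals the raw total over included bins, with the rescale folded
into the per-bin factors, so `raw ≈ balanced × f_i × f_j` always holds.

## Expected model

Intra-chromosomal expectation is the distance-decay curve: the mean
balanced count over all included bin pairs (zero cells included) at
each genomic distance, with distances grouped into log-spaced strata
(base 1.12) merged left-to-right until every stratum holds at least 50
bin pairs. Because stratum means average over all pairs at a distance,
the model reproduces observed stratum means exactly and the expected
total matches the observed total by construction. Inter-chromosomal
expectation apportions the total inter-chromosomal count by visibility:
`E(i,j) = T_inter · v_i v_j / Σ_inter v_k v_l` with `v` the balanced
marginal shares; after balancing this is nearly uniform. Whether
inter-chromosomal cells should enter the balancing at all is not
settled practice; they are included here (they carry the translocation
signal the pipeline is after, but their contribution to marginals is
small).

Ratio maps are `log2((obs+ε)/(exp+ε))` on the balanced scale with
pseudocount ε = 1 (one raw-count equivalent, since the balanced total
is calibrated to the raw total), so empty cells map to strongly
negative but finite values.

## Detection

Each eligible bin pair — inter-chromosomal pairs of included bins, plus
intra-chromosomal pairs separated by more than 25 Mb — is tested with
an upper-tail binomial: `p = P(X ≥ obs)`, `X ~ Bin(N, E_raw(i,j)/N)`
where `N` is the total retained pair count and `E_raw` the expected
model mapped back to the raw scale through the balancing factors. A
cell with zero expectation but non-zero observation is tested with one
expected pseudo-unit and flagged. Benjamini–Hochberg q-values are
computed over the full eligible family (empty cells carry p = 1 and are
never callable, so only non-empty cells need explicit p-values); calls
are q < 0.001. The binomial-on-expected construction is this package's
own statistical model for the significance step; no equivalence with
any other Hi-C caller's internals is claimed.

Significant inter-chromosomal cells are clustered per chromosome pair
by connected components, connecting cells within a gap tolerance of 2
bins on both axes. Components need at least 2 cells; an isolated cell
is kept as a candidate on its own when its q-value is below 1e-12,
because a junction landing near bin corners can concentrate nearly all
of an event's linking mass into a single cell (such cells carry
overwhelming evidence, and a null cell essentially never reaches that
level). The anchor is the cell with the highest observed/expected ratio
(ties broken by smallest bin index, for deterministic output).

## Orientation and reciprocity

Orientation is read from the enrichment gradient in a ±10-bin window
around the junction corner, using the observed-minus-expected signal on
the **raw** count scale — balancing divides the junction bins by their
signal-inflated marginals and would flatten the very gradient being
read. On each axis the junction is located as the edge of the enriched
run by the same two-rate step fit used for fragment refinement (robust
to plateau noise that defeats a simple argmax); the side of the
junction carrying the signal is the retained side, and the opposite
side is fused to the partner (`+` = fused toward higher coordinates).
An orientation is reported only when the signal side dominates the
other by a factor of 2 and exceeds a 3σ Poisson noise floor, and when
the profile decays away from the junction (a flat block carries no
orientation and is left undetermined). Reciprocal events — two
anti-diagonal enriched quadrants sharing the anchor corner — are
detected from strict quadrant masses around the anchor and flagged; the
reported orientation then describes one of the two junctions. Separate
candidates with complementary orientations and nearby anchors are
merged and flagged reciprocal.

## Breakpoint refinement

For each candidate, pairs linking the two 2 Mb windows centred on the
anchor bins are counted per restriction fragment (fragments only partly
inside a window are excluded). A single-step piecewise-constant Poisson
model (rate per bp, fragment length as exposure) is fitted over
fragment order by exhaustive scan of all step positions; the breakpoint
fragment is the first fragment on the background side of the fitted
step — the fragment "next to the junction" seen from the derivative
chromosome. If the step improves the single-rate log-likelihood by less
than 10 natural-log units the window is treated as structureless and a
coarse bin-resolution call is returned; the threshold was calibrated so
that windows with flat cross-link profiles produce coarse calls more
than 99% of the time (measured 100% at both 100- and 500-pair flat
profiles), while true junctions at a few hundred linking pairs give
improvements in the hundreds of log units. Calls with fewer than 20
linking pairs are returned as no-calls.

A resolution limit worth knowing: with mean 4 kb exponentially sized
fragments and ~500 window-linking pairs, the fragment adjacent to the
junction holds zero linking reads in roughly 15–20% of windows (the
expected count integrated over the fragment-size distribution is
`E[exp(−λl)] ≈ 0.13–0.20`), and any maximum-likelihood two-rate fit
then places the boundary one fragment off. Measured on the bundled
refinement study (50 simulations, median 500 window-linking pairs):
88–89% of breakpoint sides recover the exact junction fragment and
96–98% are within one fragment. Exact recovery above 95% needs roughly
1000–1500 window-linking pairs.

## Rearrangement graph

Breakpoint records with identical coordinates collapse into one node
(the shared-fragment case). Junction edges join the two partners of a
translocation; adjacency edges join same-chromosome breakpoints whose
midpoints are within 2 Mb (the bundled breakpoint table's co-located
pairs span 0.04–1.2 Mb, so 2 Mb covers them with margin). Chains are
connected components with at least two junction edges. Deletion
bridges: copy-number segments with log2 below −0.3 whose ends lie
within 250 kb of a breakpoint midpoint are attached to those
breakpoints, both segment ends treated symmetrically. All three
thresholds are configurable; no claim is made that they reproduce any
particular external segmentation.

## Permutation test

The observed statistic counts breakpoint fragments overlapping at least
one gene by at least 1 bp, each fragment at most once. The null draws
`k` fragments uniformly without replacement from the gap-free catalog,
`m` times, and the p-value is the conservative Monte Carlo estimator
`(b+1)/(m+1)`. Uniform sampling without replacement makes the exact
null hypergeometric, which supplies an independent closed-form check:
on a toy catalog of 5 fragments with 3 gene-overlapping, k = 2,
observed = 2, the exact tail is C(3,2)/C(5,2) = 0.3 and the Monte Carlo
estimate at m = 100,000 agrees within Monte Carlo error. Under the
null the estimator is super-uniform by construction; the validation
suite checks this with a one-sided KS statistic over 2,000 replicates
at m = 999. The genome-scale analysis (full digest of a reference
assembly plus gene annotation) is not part of the test suite — it
requires external downloads and its p-value is annotation-version
dependent — but `scripts/hg19_permutation.py` runs it for users who
supply the files.

## Simulator

The generator emulates the statistical structure of Hi-C on a
rearranged diploid genome, not its chemistry:

* cut sites from a memoryless process with mean spacing 4096 bp (the
  expectation for a 6-base recognition site); genes as non-overlapping
  intervals covering ~40% of the genome;
* karyotypes applied sequentially to one homolog of each chromosome
  (the other homolog stays intact), so chained events compose; the
  reciprocal product is kept when requested, deletions are excised
  afterwards; junctions snap to cut sites by default — sub-fragment
  junction placement is unobservable at fragment resolution, and
  snapping makes the "true junction fragment" well defined;
* contact pairs: molecule chosen proportional to length; cis distance
  `s ~ (s+s₀)^(−α)` with α = 1 (the classic contact-probability scaling
  for mammalian chromatin) and s₀ = 10 kb; a fraction τ = 0.2 of pairs
  is uniform trans background; clonal fraction f mixes tumor and normal
  karyotypes (default 1, a clonal cell line); read positions are
  re-drawn uniformly within their restriction fragment.

Not modelled: ligation artifacts (self-circles, dangling ends) beyond
an optional planted-duplicate fraction, mappability structure, GC bias,
sequence content (a FASTA emitter with planted motifs exists for
digestion round-trip tests), or locus-specific chromatin structure.
Passing the simulation studies therefore demonstrates the statistical
machinery — calibration, power at given depth, fragment-level
localisation — not robustness to alignment artifacts in real libraries.

## Validation-study designs

Fixed in `hicplexy.benchmarks` and used by both the test suite and
`scripts/acceptance.py`:

* genome of 10 chromosomes × 10 Mb at 100 kb bins (≈ 22.5 M eligible
  inter-chromosomal bin pairs across 50 simulations, desk-scale
  runtimes);
* null calibration: 50 simulations, no rearrangements, 100,000 pairs;
* power: 50 simulations, 5 translocations on distinct chromosome pairs
  covering all four orientation combinations, 200,000 pairs (≥ 1000
  realized junction-crossing pairs per event);
* refinement: 50 simulations, one translocation, 460,000 pairs tuned so
  each 2 Mb window sees ≈ 500 linking pairs; plus 100 flat-profile
  windows for the coarse-call rate;
* permutation: the toy catalog above at m = 100,000, and 2,000 null
  replicates at m = 999.

## Known limitations

* Intra-chromosomal rearrangements (inversions, copy-number events) are
  out of scope; only inter-chromosomal candidates are formed.
* Detection power depends on total depth and the FDR threshold: at
  0.001 over ~10⁵–10⁶ tests a cell needs ~5 or more raw counts, so
  events below ~200 linking pairs at 100 kb bins become unreliable.
* The fragment-level resolution limit described under refinement.
* Breakpoints are never resolved below fragment level (no junction
  sequence assembly).
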