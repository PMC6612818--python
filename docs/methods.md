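# Methods

This note documents the models and procedures implemented in `pec`, the
assumptions behind them, the tunable parameters, and the choices made
where the design was genuinely open.

## Duplicate grouping

Read pairs are grouped by `(chromosome, unclipped 5' of the
forward-oriented mate, unclipped 5' of the reverse-oriented mate,
orientation class)`. Soft-clips are arithmetically removed when computing
the 5' ends (MarkDuplicates semantics) because clipping varies among true
duplicates of one fragment. The orientation class (FR/RF/FF/RR) is part of
the key: reads derived from opposite fragment strands are never merged, so
the consensus is a single-strand consensus — this is a barcode-free
method, not a duplex one. Anomalous FF/RR pairs are grouped (by their two
5' ends in ascending order) but never merged across orientation classes.

Mates are canonicalized on input so that "mate 1" is the forward-oriented
(for FF/RR, leftmost) mate; the original read1/read2 labels are not
preserved in corrected output, where each family emits one fresh pair
named after its lexicographically first member. Orphaned mates and pairs
whose mates map to different chromosomes have no defined duplicate key;
they pass through to the output unmodified and are tallied in the log.
Secondary, supplementary, unmapped, QC-fail and duplicate-flagged records
are dropped with counts.

Families and members are canonically sorted (by key, and by pair name
within a family), which makes grouping, consensus and the whole pipeline
invariant to input order — the property a parallel implementation would
also have to guarantee, and the one the test suite checks in place of any
actual parallelism.

## Collision model

Grouping by coordinates assumes distinct fragments rarely share both end
points. With fold-coverage depth `D` (of original cfDNA molecules, not
reads) and fragment lengths modelled as Normal(μ, σ), the expected number
of length-L fragments at a locus is `M_L = D·N(L|μ,σ)`. Fragments of equal
length L have L interchangeable placements, so the chance that at least
two of M_L coincide is the birthday probability
`C_L = 1 − L!/((L−M_L)!·L^{M_L})`. Because fragments of different lengths
cannot collide, the per-locus collision probability is the length-weighted
sum `p = Σ_L C_L·N(L|μ,σ)` over integer L in μ ± 6σ (truncation error
< 1e−9 of the mass).

Numerical choices: `M_L` is real-valued, so the falling factorial is
evaluated through the log-gamma continuous extension rather than by
rounding — `p` is then smooth in D and σ. `C_L` is defined as 0 for
M_L ≤ 1 (a lone fragment cannot collide) and 1 for M_L ≥ L (pigeonhole),
and clamped to [0, 1]. Typical cfDNA values μ = 177, σ = 20, D = 300 give
p ≈ 0.046; p ≈ 0.13 at D = 500, which is why barcode-free grouping is not
recommended beyond ~500× cfDNA depth.

The Monte-Carlo cross-check draws, per simulated locus, a length L from
the discretized normal and a fragment count `floor(M_L) + Bernoulli(frac)`
(randomized rounding keeps the mean at M_L while its collision probability
interpolates the integer birthday values, matching the continuous
extension to ~1e−4), places the fragments uniformly over L slots and
counts repeats. The analytic value agrees within 3 binomial standard
errors at 10⁵ loci across a grid of D and σ.

## Consensus calling

High-depth families (duplicate depth ≥ `min_dup_depth`, default 5) are
corrected by per-column majority vote over members. Since members share
unclipped 5' coordinates, equal-length reads without discordant indels
align column-for-column in read coordinates; for such reads a positional
vote and a small de-novo assembly of the family coincide on substitutions,
and voting is exactly testable per column.

Rules, in order:

* Bases with Phred < `min_base_qual` (default 20) and N bases never vote
  and are never recorded as PCR errors — the sequencer has already
  flagged them and downstream tools handle them through quality.
* Members whose read length differs from the family's modal length, or
  whose CIGAR indel structure differs from the modal structure, do not
  vote (logged). A family with no modal length is routed to the
  representative path; indel-aware multi-alignment is deliberately out of
  scope.
* Column ties break by greater summed Phred among supporters, then by
  lexicographically smallest base — deterministic and quality-respecting.
* Columns where no base reaches the quality floor fall back to a plain
  majority over all non-N bases.
* The consensus base quality is the maximum Phred among members agreeing
  with the call (capped at 93); columns with no eligible supporter take
  the best supporting quality available. The maximum (not a sum) is
  deliberate: duplicates are copies of one template, so their errors are
  not independent draws and summing would overstate confidence.

Every member-vs-consensus mismatch among voting-eligible bases is recorded
as a corrected PCR error; the run report aggregates them into a
substitution spectrum (true>observed).

## Error k-mers and intrinsic polishing

Per high-depth family, all k-mers of the consensus are *trusted* and all
member k-mer windows spanning a corrected base are *untrusted* (windows
containing N are skipped; windows whose only mismatches were low-quality
are neither). The global error set is `⋃ untrusted \ ⋃ trusted`: a k-mer
any family's consensus vouched for can never be an error k-mer. Reads and
k-mers are kept in reference-forward orientation (the SAM SEQ convention)
with no reverse-complement canonicalization — families are
coordinate-defined, and one fixed orientation keeps the set comparisons
exact. The store is an exact hash set, adequate for targeted panels;
a probabilistic backend is an extension point, not implemented.

`k` defaults to 21: odd (no self-reverse-complement ambiguity) and
standard in k-mer error-correction practice; it is configurable because
the optimal value is panel- and read-length-dependent.

Low-depth families keep their highest-total-Phred pair as representative
(ties: smallest pair name). Scanning the representative against the error
set yields maximal runs of consecutive error-k-mer windows; a single
erroneous base must lie in every window of its run, so the implicated
positions are the intersection of the windows' spans. An interior error
with a full run of k windows is pinned to exactly one base; an error
within k−1 of a read end leaves a wider intersection, all of which is
flagged — conservative by design. Runs longer than k windows have an empty
intersection (no single base explains them) and flag nothing. Flagged
positions get their Phred set to `flag_qual` (default 5; qualities already
below it are untouched). Sequence is never modified: a wrong flag costs
one read's evidence at one base, it cannot fabricate an allele.

## Realignment

After correction the read set is ~duplicate-depth-fold smaller, so every
surviving pair is optimally realigned: affine-gap Smith–Waterman (match
+2, mismatch −2, gap open −3, gap extend −1; a length-g gap costs
open + g·extend; all configurable) against the reference window
[start − margin, end + margin], margin 50 bp by default. Traceback prefers
diagonal > up > left and the best cell with the smallest coordinates is
chosen, so scores *and* CIGARs are deterministic; unaligned flanks are
soft-clipped. If the optimal score falls below half the maximum attainable
(`min_score_frac = 0.5`), the original mapping is kept and the event
logged. Reads that match the reference verbatim at their original
coordinates skip the DP — the result is provably identical (a full-length
exact match is the unique optimum under positive match score). Mates are
realigned independently in their own windows.

## Simulator

The generator emulates the statistical structure the pipeline assumes: a
random reference (default 20 kb), fragments with Normal(177, 20) lengths
placed uniformly, geometric duplicate depths (default mean 6), and three
error channels — per-duplicate PCR substitutions at 10⁻³ with Phred ≥ 30
and a spectrum enriched for G>T/C>T; recurrent hotspot errors at fixed
loci hitting each covering duplicate independently (default probability
0.05, a realistic artifact-hotspot rate well below the majority threshold
so that deep families correct it); and sequencer errors at 10⁻³ always
carrying Phred < 20, exercising the low-quality exemption. Optional
spike-in variants are applied at the fragment level, so all duplicates
agree and consensus preserves them. Truth tables record every fragment,
family, read and injected event; every emitted read is reconstructable
from them, and a fixed seed fixes the entire output byte stream.

By default fragments are rejection-sampled to unique (start, length), so
the family partition is exactly recoverable from coordinates; with 10⁴
fragments on 20 kb the collision model itself predicts tens of genuine
collisions, which would otherwise (correctly) merge distinct fragments and
make exact-partition checks meaningless. Set `ensure_unique_keys=False` to
study that regime.

What the simulator does *not* model — and what passing tests therefore do
not show: indel errors, strand-specific (duplex) chemistry, realistic
sequencing-by-synthesis quality profiles, GC/mappability bias, and real
alignment noise (reads are placed at their true coordinates, not
re-aligned). Results on real libraries depend on those factors; the
simulation establishes correctness of the machinery, not field
performance.

## Evaluation conditions

The test suite's end-to-end evaluation uses the default fixture — 10⁴
fragments on 20 kb (≈ 6×10⁴ pairs), mean duplicate depth 6, PCR error rate
10⁻³, five hotspot loci, one fixed seed — chosen as a desk-scale analogue
of a targeted cfDNA panel. At these conditions the corrected output's
residual per-base error is roughly half the best-read baseline's (the
residual is dominated by low-depth families, which polishing flags but by
design never edits), hotspot flag recall on low-depth reads is ≥ 0.9, and
error-free reads acquire no flags. Flag *precision* against exact error
positions is lower than recall because boundary errors flag a whole
window-intersection; this is the documented conservative behaviour, and
flags only ever lower qualities.

## Known limitations

* Substitution errors only; families are not indel-corrected, and
  discordant-indel members simply do not vote.
* Single-strand consensus: errors arising before amplification (e.g. on
  the original template strand) are shared by all duplicates and cannot be
  caught without duplex information; the simulator's hotspot channel
  approximates only the recurrent-artifact part of that spectrum.
* The error-k-mer catalogue is learnt from the dataset itself; very small
  datasets (few high-depth families) yield sparse catalogues and polishing
  degrades gracefully to a no-op.
* Single-process implementation; order-invariance is guaranteed and
  tested, but large-scale parallel execution is out of scope.
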