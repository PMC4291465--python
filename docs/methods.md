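# Methods

## Measurement model

Bar-seq measures pool *composition*, not absolute viability. Every
quantity downstream of counting is a relative abundance: a mutant whose
survival equals the pool average keeps a constant pool share and scores
1, however much of the pool is dead. Scores are therefore comparisons to
the pool average, and a screen where most mutants die fast will assign
scores > 1 to merely average survivors. Interpretation of thresholds
(1.44 long-lived, 0.14 short-lived flag, both strict inequalities)
inherits this relativity.

## Database and matching

Reference entries are exactly 51 nt: 4-nt multiplex index, 18-nt
universal forward primer, 20-nt tag, 9-nt trailing universal primer. One
entry exists per decoded tag per index, so a gene with both tags decoded
contributes 2 × (number of indexes) entries. The default primers are the
gene-cassette-specific segments of the library's round-1 PCR primers
(uptag forward `GAGGCAAGCTAAGATATC`, downtag forward
`CCAGTGTCGAAAAGTATC`; trailing 9-mers `TAAATGCGA` / `CCTACGCAA`, the
read-through into the reverse-complemented reverse-primer site). The 20
default multiplex indexes are arbitrary distinct 4-mers — the original
index sequences are not published — and both indexes and primers are
configurable.

Matching is ungapped and substitution-only over the first 42 read
nucleotides (index + primer + tag); the trailing primer is constant and
uninformative, so mismatches beyond position 42 are ignored for both
candidate generation and uniqueness. One mismatch is tolerated. A
distance-0 hit beats distance-1 hits (best-unique semantics); any tie at
the best distance discards the read as ambiguous, as does a hit on a
sequence-duplicated entry. Demultiplexing is implicit — the index is
inside the matched 42-mer — with an optional strict mode requiring the
read's index to equal the sample's. The implementation indexes the
42-mer as two 21-nt halves (with ≤1 substitution at least one half is
exact), and its contract is equivalence with a brute-force Hamming scan,
which the test suite asserts on random databases.

Indels are not modeled: the 1-mismatch ungapped policy mirrors
short-read end-to-end alignment of fixed-structure amplicons, where
indel reads are rare and discarded.

## Decoding

Decode reads are segmented at fixed offsets (4/18/20/26/33). Reads are
grouped on the *exact* 20-mer barcode; sequencing-error variants are not
merged but fall below the minimum cluster size (default 2 reads).
Each cluster's flank consensus is the per-position majority over member
flanks (ties broken to the lexicographically smallest base, for
determinism), and the cluster is assigned to the gene/tag with the
closest expected flank if that distance is ≤ `d_max` (default 3,
tolerating ~1 sequencing or synthesis error while keeping cross-gene
misassignment unlikely for 33-nt flanks) and the runner-up is strictly
farther. Both the minimum cluster size and `d_max` are parameters, not
claims about the original analysis, which did not state them.

## Scoring

Fold-changes use depth-normalized counts; tag weights use **raw**
counts, following the weighting formula literally
(`w_up = (Up_i+Up_0)/(Up_i+Dn_i+Up_0+Dn_0)`). A
`normalized_weights` switch computes the weights from depth-normalized
counts instead. The distinction matters for one invariance: multiplying
a single sample's counts by a constant leaves fold-changes unchanged but
shifts raw-count weights, so scores are exactly invariant to per-sample
rescaling only in normalized-weight mode — and, in either mode, only
where the <10-read exclusion does not change state (a 2-read cell
scaled to 14 becomes valid). Under *common* rescaling of all samples,
raw-weight scores are exactly invariant away from the filter boundary.
The package default remains raw weights, as written.

The <10-read exclusion applies per tag per sample, including the
reference: a tag with an under-covered reference is unusable for the
whole replicate, since all its fold-changes share that denominator. A
gene-timepoint is valid if at least one tag survives, so single-tag
genes remain scorable. Replicate medians are taken per replicate over
valid non-reference timepoints and then averaged (in that order); genes
scorable in only one replicate use that replicate's median and are
flagged `single_replicate`. `min_valid_timepoints` (default 1) sets how
many valid timepoints a replicate needs to contribute. The minimal
requirement of one valid timepoint in one replicate defines "has a
score"; stricter provenances can be dialed in via the config.

Pearson p-values for the lifespan–growth correlation use the standard
t-approximation with n−2 degrees of freedom; gene-set enrichment is the
one-sided hypergeometric upper tail with fold = observed/expected
overlap. Per-mutant significance testing is out of scope — calls are
threshold-based, matching the screen design.

## Viability

CFU viability is `100 · (cfu_t/plated_t) / (cfu_0/plated_0)` relative to
the earliest timepoint; plating-efficiency differences cancel and values
above 100% are legal (residual early divisions in pools). Median
lifespan is the smallest real root of the least-squares order-2
polynomial minus 50 within the observed time range — the first downward
crossing convention; the crossing convention is ours, the quadratic
regression is the field's. Replicates are pooled as points for the fit
rather than averaged per timepoint, weighting replicates by their
observations. The estimate is exactly equivariant under time-unit
rescaling. With fewer than 3 distinct timepoints, or no crossing in
range, fitting/estimation raises instead of extrapolating: a quadratic
extrapolated beyond the data is not a survival model.

## Simulator

The generator reproduces the screen's statistical structure, with
defaults fixed once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_genes | 1000 | pool of order 10³ mutants |
| tag presence (both/up/dn) | 0.757 / 0.103 / 0.140 | decode-yield ratios of the real library (1871/254/348 of 2473) |
| initial abundance | lognormal(0, 0.5) | modestly uneven pooling; real pools are at least this dispersed |
| weekly survival | Beta(8, 2) bulk + 5% at s = 1 | bulk mean 0.8/wk with a perfectly surviving long-lived tail |
| growth advantage | Normal(0, 0.1) doublings/hr | small relative growth differences |
| CLS timepoints | 0, 4, 8, 12, 14 wk | screen sampling design |
| growth timepoints | 120, 230, 340, 460, 550 min | growth-run design, 120 min reference |
| replicates | 2 | biological duplicates |
| depth | 10⁶ reads/sample | deep counting run |
| tag split | Beta(10, 10) | symmetric up:dn bias, exercises the weighting |
| per-base error | 0.001 | Illumina-like substitution rate |

Expected pool shares follow `p_g(t) ∝ p_g(0)·s_g^t` (growth:
`p_g(0)·2^(a_g·t/60)`), renormalized at every timepoint; counts are a
single multinomial per sample over (gene, tag) cells. Counting-run reads
are the sample's database entry truncated to 50 nt; decode-run reads are
index+primer+barcode+spacer+flank (101 nt); both receive iid
substitutions. All randomness flows from one seed; outputs are
byte-reproducible.

What the simulator does *not* model — and hence what passing tests do
not certify about real data: PCR duplicates and amplification jackpots,
tag-specific amplification bias beyond the symmetric split, quality-score
structure, indels, cross-contamination, re-growth-on-plates bias, and
any biology of medium replacement or nitrogen recycling. Recovery
results on simulated pools are best-case statements about the
estimator under multinomial sampling, not about library artifacts.

## Calibration findings

Two boundary behaviors are worth recording. First, in an all-survivors
(zero-death) pool at depth 10⁶ the score distribution is centred on 1
with no detectable bias, but the low-abundance tail of a
lognormal(0, 0.5) pool has only ~100–200 reference reads per tag, and
the extreme deviation across 1000 mutants is then typically 0.10–0.14 —
slightly above a 0.1 band that would hold under near-uniform pooling
(~500 reads/tag). `scripts/acceptance.py` reports the measured maximum.
Second, exact depth-rescaling invariance requires normalized weights and
a non-binding read filter, as discussed above; the acceptance
computation uses a constant-composition pool where every cell clears the
filter, making the invariance exact and the reported deviation 0.

## Problem sizes

The validation computations use a 1000-gene pool at depth 10⁶ scored
directly from sampled count matrices (the count-table entry point is a
first-class input, so sequencing can be skipped), a 200-gene pool at
depth 2×10⁴ for the FASTQ round-trip through the matcher, 300 genes ×
20 reads/tag for decode recovery, and 200-entry databases for oracle
equivalence — sizes at which every property above is measurable with
comfortable margins.
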