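# Methods

## The storage model

`dmos` models a rewritable DNA "tape": a pool of blank DNA registers whose
data content is created by mutation rather than by synthesis. Each register
is one molecule carrying the same 16 *domains* in a register-specific
order. A domain is 63 bp: a 40-bp *index* sequence unique to the domain
(used to locate and identify it inside a noisy read) followed by a 23-bp
*state* section — a 20-nt protospacer plus NGG PAM that a dCas9
ribonucleoprotein can bind. Writing a 1 into a (register, domain) bit means
delivering the matching dCas9/APOBEC3A writer to that register: the
deaminase converts cytosines on the displaced strand of the R-loop to
uracil, fixed as C→T after a resolving reaction. Reading is nanopore
sequencing followed by decoding.

Design rules enforced on state sections (`tape.validate_state_sequence`):

* length 23 with NGG at positions 20–23 (0-based, half-open);
* at least two dTdCdR motifs (T-C-purine, the high-activity APOBEC3A
  substrate) whose C sits ≥ 6 nt from the PAM. Motif C's closer than 6 nt
  are modelled as strongly suppressed, reflecting the reduced deaminase
  access near the PAM; they are tracked separately (`motif_sites` vs
  `hotspot_sites`).

Coordinates are 0-based half-open throughout; "distance from the PAM" is
`20 - position` within the protospacer. References store the displaced
(mutated) strand, so every edit is a literal C→T on the stored string and
reverse-complement handling is confined to read alignment.

The shipped 16-domain set is generated deterministically
(`tape.default_domains`): protospacers with 2–3 planted hotspot motifs
(half of the domains also carry one PAM-proximal motif so that proximity
suppression is observable in simulation) and random 40-mer indexes with
pairwise edit distance ≥ 10. It is a synthetic stand-in for an
experimentally validated set; users can supply their own via
`DomainSpec.from_sequences`.

## Addressing

Three schemes map register identity onto molecules:

* **barcode** — identity domain order; identity carried by an ordered
  (forward, reverse) primer pair, n² addresses from n barcodes;
* **lexicographic** — register *a* uses the *a*-th permutation of the 16
  domains in lexicographic order. Compact but fragile: consecutive
  addresses differ only in the last few slots, so noisy reads are easily
  mis-called;
* **high-entropy** — a keyed Fisher–Yates shuffle seeded from
  (key, address). Deterministic, pairwise-distinct in practice (verified at
  block build), and consecutive addresses are nearly maximally dissimilar
  (mean adjacent Kendall-tau distance ≈ n(n−1)/4, versus ≈ 1–2 for the
  lexicographic scheme at 48 addresses).

Decoding an address ("domain-calling") maximises positional agreement
between the observed (slot, domain) order and each register's permutation;
fewer than `min_agree` (default 9/16) agreements or a tie yields
UNADDRESSED rather than a guess, since a mis-addressed read contaminates
16 bits at once.

## Error correction

The default code is an AR4JA-family protograph LDPC code (accumulate-
repeat-4-jagged-accumulate), rate 3/4, lifted with expansion factor 96:
576 message bits (72 bytes) and 768 transmitted codeword bits (96 bytes)
— exactly one codeword per 48-register block at 16 bits/register. The
rate-3/4 protograph is the standard 3×9 AR4JA base matrix (rate-1/2 core
`[[1,2,0,0,0],[0,3,1,1,1],[0,1,2,2,1]]` with two appended [0,3,1]/[0,1,3]
column pairs); the degree-6 variable class is punctured, so the lifted
graph has 864 variables of which 768 are stored on tape. Rates 1/2 and
2/3 of the same family provide the 50 % and 33 % redundancy alternatives
studied by `simulate_code_tradeoff`.

Lifting assigns each protograph edge a circulant shift drawn from a seeded
RNG; twelve candidate lifts are drawn and the full-rank one with the
fewest 4-cycles is kept, so construction is deterministic. Encoding is
systematic: message bits occupy the non-pivot columns of a GF(2)
elimination (pivots preferentially on punctured columns, so all message
bits are transmitted) and parity is solved through a precomputed inverse.
Redundant lifted rows (possible for small regular toys) are dropped from
the encoder's linear solve but kept for BP.

Decoding is sum-product belief propagation on the full 864-variable graph
(punctured bits enter as erasures, LLR 0), at most 100 iterations with
early exit on parity. LLR convention: positive favours 0; magnitude 4.0
for confident hard calls; 0 is an erasure.

**Ordered-statistics post-processing.** At 768 bits, a raw bit-error rate
of ~3 % (the regime of interest: 25 errors in 768) sits essentially at the
BP threshold of this code — plain BP converges on only about half of such
words, at any block length. Since maximum-likelihood decoding of a fixed
25-bit error pattern is essentially always correct at this rate, the
decoder therefore augments BP with an ordered-statistics (OSD) ensemble on
non-convergence: reliabilities are taken from iteration-averaged BP
posteriors, the least-reliable linearly-independent positions are solved
from parity (order 0) and order-1/2/3 flip patterns of the reliable basis
are scored exactly against the channel LLRs; further orderings come from
BP restarts whose inputs are "kicked" at the bits adjacent to the most
unsatisfied checks (sign-flip, erasure and jitter kicks in rotation). The
best-scoring candidate codeword is accepted as converged only when it lies
within 8 % disagreement of the non-erased channel decisions, and the whole
post-processor only engages when at most 15 % of inputs are erasures —
early, erasure-heavy snapshots never reach it, which both bounds runtime
and prevents confidently-wrong outputs from thin evidence. The procedure
is deterministic (internal fixed-seed RNG keyed to the call). With this
post-processing, 25-flip words are recovered in ≈ 96 % of trials versus
≈ 50 % for plain BP.

## Writer and channel simulation

`apply_writer` draws one written molecule: in targeted domains each motif
C converts with `p_site_on` (default 0.8), multiplied by
`pam_proximal_factor` (default 0.1) within 6 nt of the PAM; untargeted
domains and non-motif C's convert at `p_site_off` (default 0.005).
Conversions are independent across domains (orthogonality by
construction, and verified statistically in the tests). These defaults are
package calibration choices, not measured chemistry: they make stage-1
threshold calls separable but imperfect, so the stage-2 classifier and the
LDPC layer both do real work.

The sequencing channel applies per-base substitution/insertion/deletion
(defaults 0.03/0.02/0.03), optional truncation (probability 0.1; uniform
start, geometric length, minimum one full domain), random strand
(probability 0.5 reverse) and synthetic Gaussian quality scores
(mean 12, SD 3). Quality scores are decorative except for the decoder's
mean-q filter. PCR structure, strand-selection chemistry and signal-level
nanopore effects (homopolymers, context-dependent errors) are *not*
modelled; passing tests therefore demonstrate algorithmic correctness
under an idealised independent-error channel, not performance on real
flow-cell data.

## Decoding pipeline

1. **q-filter**: reads with mean quality < 9 are dropped.
2. **Domain location**: 12-mer lookup against the 16 index sequences;
   a domain is anchored by ≥ 3 position-consistent k-mer hits and then
   confirmed by Smith–Waterman alignment of its 40-bp index into a
   ±12 bp window (score ≥ 40 under match +2 / mismatch −1 / gap open −2 /
   gap extend −1; a length-L gap costs 2+(L−1)). Both strands are tried.
   An exhaustive full-register alignment is not needed when the k-mer
   prefilter recalls the domain; it remains available through
   `smith_waterman` directly.
3. **Domain-calling** as above, with relative slots from cumulative anchor
   spacing and an offset search for truncated reads.
4. **Observation extraction**: the 23-bp reference state section is
   locally aligned into its window; hotspot-site columns are read off as
   C, T, or absent (gap/other base), the latter reducing
   `n_sites_observed`.
5. **Stage 1**: per-bit pooled mutated fraction vs the domain's fitted
   thresholds (T_low, T_high); ≥ 5 reads required; boundary values go to
   stage 2 ("near the threshold" is uncertain by design).
6. **Stage 2**: per-read Bernoulli likelihood of the observed site states
   under the targeted (p̂₁) vs untargeted (p̂₀) signature, summed log-odds
   with prior 0.5; call 1/0 outside [δ, 1−δ] (δ = 0.1), else UNCALLED.
7. **LLRs**: ±4.0 for stage-1 calls, capped log-odds for stage-2 calls,
   0 for UNCALLED; LDPC decode; a snapshot (fraction called / correct,
   convergence, payload recovery) is recorded every 100 reads plus a
   final partial snapshot.

Signature fitting (`fit_signature_profile`) uses reads from the two
calibration conditions (all domains targeted / none targeted, mirroring
orthogonality-control experiments): p̂₁/p̂₀ per (domain, site) with
pseudocount 1; thresholds are the 99th percentile of the untargeted
read-set mutated fraction and the 1st percentile of the targeted one
(read sets of 20 reads, 200 resamples), clamped to their midpoint when
they cross.

The bootstrap analysis resamples read streams with replacement (default
250 replicates, matching standard practice for recovery curves) over a
depth grid, reporting mean ± SD of the fraction of bits called and
correct; it reuses per-read observation summaries so replicates are cheap.

## Problem sizes and numerical choices

Default study conditions: 48 registers × 16 bits, one 768-bit codeword,
4,800 reads (100 per register) per decode, 400 training reads per
calibration condition. These sizes keep a full encode→simulate→decode
round trip to tens of seconds while leaving every stage non-trivially
loaded; all are configurable (`RunConfig`). Ties in domain-calling and
stage-1 boundary hits resolve to UNADDRESSED/UNCERTAIN (never a guess);
chimeric reads are not modelled and only the best single address is kept;
probabilities inside likelihoods are clipped to [1e−6, 1−1e−6].

## Known limitations

* The domain set and all channel rates are synthetic stand-ins; absolute
  recovery-vs-depth numbers are not comparable to real MinION data.
* The OSD post-processor returns the best candidate codeword even when it
  declines to mark it converged; callers that need a hard guarantee
  should gate on the `converged` flag (the streaming decoder does).
* Multi-block demultiplexing, rewriting (1→0), and multi-state (>1 bit
  per domain) extensions are out of scope.
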