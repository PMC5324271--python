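# Methods

## The mosaic genome model

The package models a reference genome as alternating *random* and *repeat*
intervals at a working point (ℓ, d): the ℓ-mer starting at offset *o* is
random when no other location — any offset other than *o*, on either
strand — lies within Hamming distance *d* of it. Offsets are counted with
the L−ℓ convention (a window of length L carries L−ℓ ℓ-mer offsets at
step 1), coordinates are 0-based half-open throughout, and conversion to
1-based happens only at SAM emission. A hit at the query's own offset
(including the reverse-strand self-hit of a near-palindromic ℓ-mer) never
makes an offset a repeat. N bases match nothing, not even another N: this
is deliberately conservative so that assembly gaps cannot generate fake
uniqueness, and windows containing N are excluded from histogram
denominators for the same reason.

Reads inherit the mosaic of their origin, so the distribution of random
ℓ-mers per read-length window (`read_random_lmer_histogram`) predicts the
fraction of reads the anchoring stage can handle, and the distribution of
*low-repeat* ℓ-mers (list size 2..𝓛 at cap 𝓛, `low_repeat_histogram`,
computed over the windows with no random ℓ-mer at all) predicts what the
assignment stage can rescue. Histogram bin edges default to [1–80] /
[81–(L−ℓ)] and are parameters.

## The anchoring index

Queries ask for all occurrences of an ℓ-mer within Hamming distance d on
either strand, with a result cap. The index uses pigeonhole seeding: a
query allowed d mismatches is split into d+1 disjoint exact seeds of
length ⌊ℓ/(d+1)⌋ over a sorted table of genome seed hashes; any true
occurrence must contain one exact seed, so seed lookups enumerate a
candidate superset verified by a full N-aware Hamming comparison. This is
exact for Hamming ≤ d (the oracle-equivalence tests check it literally
against all-offset scans). Seed hashes are multiply-by-4 rolling values in
uint64; wraparound for seeds longer than 32 bases can only add candidates,
never lose them. Reverse-strand hits are occurrences of the query's
reverse complement, reported at their forward-strand position, which keeps
all downstream coordinate arithmetic strand-uniform. Enumeration stops as
soon as the cap is exceeded (`over_cap`), since such fragments are
discarded anyway.

## Stage 1: anchoring and the confirm rule

Reads are cut into K = ⌊L/ℓ₁⌋ non-overlapping fragments, queried
progressively with budget d₁ and cap 1 (only unique hits produce tags).
Each unique tag is normalized to the *implied read start*: ref_pos −
read_offset on the forward strand, ref_pos + read_offset + ℓ₁ − L on the
reverse. Two tags confirm when they share a strand and their implied
starts differ by at most

    Δ(span) = max(Δ_min, ⌈slack · span⌉),   span = |offset difference|,

with defaults Δ_min = 3 and slack = max(0.05, 2·ε̂_G). The slack scales
with the read span between the fragments because the positional drift
between two fragments is the net indel balance of the bases between them.
A read is anchored at the first confirming pair (early exit, so an
easily-mapped read costs exactly two index queries); if a new tag confirms
two mutually inconsistent earlier positions the read is demoted to the
assignment stage as *ambiguous* rather than multi-reported — stage 1 is
the unique-report stage.

Sliding (S₁ > 0) repeats the pass ⌈ℓ₁/S₁⌉ times with the fragment grid
shifted by (i−1)·S₁; a read anchored in an earlier pass is excluded from
later ones. Passes are independent (tags are not pooled across passes):
pooling would confirm across overlapping fragments of different phases,
which adds a little power but couples passes; independence keeps each
pass's behaviour identical to the non-sliding algorithm and was chosen for
simplicity. Sliding matters for noisy reads: at 10% i.i.d. indel error
only ≈ 0.9²⁵ ≈ 7% of 25-mers are error-free, so a single fragment grid
anchors ≈ 80% of kilobase reads while five slid grids anchor essentially
all of them.

## Local alignment and the normalized cutting distance

Anchored reads are aligned by banded Smith–Waterman with linear gap costs
(defaults match/mismatch/gap = +1/−1/−1) against the window
[anchor − ncd·L/2, anchor + L + ncd·L/2], band half-width ⌈ncd·L⌉, where
ncd ∈ [0, 2] is the normalized cutting distance (default 0.05; set to
5·ε̂_G after estimation, capped at 2). The band is centred on the
expected diagonal of the anchor; cells outside the band are treated as
score 0, which for a local alignment only permits restarts at the band
edge and never changes the optimum when the band covers the true path
(verified against an unbanded implementation in the tests). With one
substitution the score is L−2 (a lost match plus a penalty); gap costs
equal the mismatch cost, and diagonal moves win ties so isolated
substitutions are reported as mismatch columns rather than gap pairs.

## Stage 2: tables, weights, paths

Unanchored reads are refragmented with overlap (stride ℓ₁/2) and queried
with cap 𝓛_s,1 (default 10). Over-cap fragments are dropped. Raw candidate
scores are S_a = (ℓ − mismatches)·match, a monotone proxy for the hit
quality of a Hamming anchorer, and weighted S = S_a·e^(−0.5·|T|) so that a
position drawn from a large list contributes little. Chaining is greedy in
table order: each unconsumed position collects at most one best-weighted
(leftmost on ties) unconsumed confirming partner from every later table;
chains of ≥ 2 members become paths (score = sum of member weights,
consensus = member median implied start) and their members are removed, so
paths partition the consumed positions. Greedy removal-based chaining is
used rather than optimal dynamic-programming chaining; optimality is not
claimed and in practice ties between genuine repeat copies are what
matters — symmetric copies produce equal-scoring paths, all retained by
the S_th rule (keep paths ≥ s_th·best, default 0.8). Retained paths are
verified by the banded aligner; a path survives when its score reaches
min_score_frac (default 0.5) of the perfect score — at the error rates
targeted (ε ≤ 15–20%) true locations score ≈ (1−2ε)·L ≥ 0.6·L while decoy
windows score near the random-alignment baseline. Survivors are reported
best-first (primary + secondary records).

Round 2 reruns the same procedure on the leftovers with ℓ₂ = 2·ℓ₁ and cap
𝓛₂ = 4·𝓛_s,1 (defaults 50 and 40). The round-2 Hamming budget is scaled
proportionally, d₂ = round(d₁·ℓ₂/ℓ₁), keeping the per-base mismatch
allowance of round 1.

## The PE algorithm

Rates: the sample (default N_t up to 10,000 reads; the bundled experiments
use 500) is anchored at (ℓ, d) = (25, 2) without sliding, and each
anchored read is aligned with a deliberately wide band (ncd 0.5 — the
rates are unknown at this point, so the band must cover heavy indel
drift). Per read, ε̂_M is the mismatch-column count and ε̂_G the gap-column
(I+D) count divided by consumed reference bases (M+D columns ≈ template
bases); soft-clipped ends are excluded from the denominators since
terminal error clusters clipped by a local aligner would otherwise bias
the rates; alignments scoring below 0.3·L are discarded as junk anchors.
The across-read means are then bias-corrected by parametric bootstrap: an
insertion immediately followed by a deletion is string-identical to a
substitution, so any alignment-based counter converts a fraction
O(ε_G²/4) of indel pairs into apparent mismatches — an identifiability
artifact, not a scoring choice. The estimator therefore simulates a
matched read set from the reference at the raw observed rates, runs the
identical counting procedure on it, and subtracts the measured bias. One
correction round leaves only second-order residuals; on 1 Mbp genomes with
500 kilobase reads at (ε_M, ε_G) = (3%, 10%) the mean absolute error is
≈ 0.1 / 0.25 percentage points (the acceptance suite re-measures this).

Selection: for each ℓ ∈ {15, 20, …, 50}, d(ℓ) = ⌊ε̂_M·ℓ + 0.5⌋ (at
ε̂_M = 2.8% and ℓ = 25 this gives d = 1). The sample is anchored with each
pair; among candidates whose anchoring rate is within 1 percentage point
of the best (the tolerance is a package choice; "close to the maximum" is
otherwise unquantified), the ℓ with the fewest enumerated candidate
positions wins — a hardware-independent cost proxy preferred over
wall-clock so the selection is deterministic and testable. The emitted
mapping-priority set (ℓ, d+1, S₁ = max(1, round(ℓ/5))) is a reconstruction
of the relationship between the two published operating points of the
method; it reproduces the only printed instance ((25,1,–) vs (25,2,5)) but
is not asserted to be the original authors' procedure.

## The simulator and what passing tests mean

Target variation (rate α, split 2:1:1 substitution:insertion:deletion) and
sequencing error (rate ε split into ε_M substitutions and ε_G indels,
insertion/deletion equally likely, geometric lengths with mean 1) are both
i.i.d. per base. Real PacBio error is bursty; i.i.d. placement is the
*harder* case for fragment anchoring because errors hit more fragments, so
recall measured here is conservative in that respect. The simulator does
not model base-quality realism, chimeric reads, or coverage bias, and the
planted duplications in `genome_with_duplications` are exact copies —
diverged repeat families are represented only through the Hamming budget.
Passing the bundled benchmarks therefore demonstrates the mechanics of the
method under its own generative model at megabase scale, not performance
on a human genome.

Problem sizes in the bundled experiments (1 Mbp genomes, 500–1000 reads of
length 1000, 5 replicates for rate recovery) were chosen so the whole
suite runs on a laptop in a few minutes while keeping binomial sampling
error well below the tolerances being asserted.

## Numerical and degenerate-input choices

* Ties: hit lists sort by (position, strand) with forward first; path ties
  break by leftmost consensus; DP ties prefer the diagonal.
* Degenerate reads: reads shorter than ℓ₁ + slide skip stage 1; reads not
  longer than the fragment length produce empty tables and are reported
  unmapped (flag 4 pass-through records).
* Alignment windows are clipped at genome bounds; an anchor whose banded
  alignment has no positive score demotes the read to stage 2.
* All randomness flows from explicit seeds (numpy Generator); identical
  inputs and seeds give byte-identical FASTQ, truth, and SAM output.
* The pipeline aligns against the first record of a multi-record reference
  FASTA; multi-chromosome references are out of scope for the driver
  (the library operates on one `Genome` at a time).

## Known limitations

* Linear gap costs only; affine gaps would model long indels better.
* The greedy chainer can in principle split one true location into two
  paths when candidate lists are dense; the S_th shortlist plus
  verification makes this harmless in the benchmarks but it is not
  impossible.
* `classify_intervals` queries every offset individually; it is meant for
  desk-scale statistics (use `stride` for larger surveys), not
  chromosome-scale mappability tracks.
* External short-read aligners are not wrapped; the built-in index is the
  only anchorer backend.
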