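# Methods

## Scope and model

`abcfam` annotates ABC transporters in predicted unigene proteomes (one
protein per gene) and compares family sizes across taxa. The
classification model is deliberately simple and auditable: candidate
detection by NBD profile match, family assignment by consensus of
best reference hits, architecture (full vs half ABC-B) by counting
distinct NBDs, and two quality filters (protein length, proteome BUSCO
completeness). It assumes the reference database is correctly labelled
and that NBD homology is sufficient to separate families A–H; it does
not attempt tree-based classification, birth–death modelling of family
evolution, or genome-level gene calling.

## Classification rules and edge cases

- **Candidate filter**: best full-sequence E-value strictly below 10.
  The permissive cutoff favours recall; the downstream vote supplies
  specificity. The per-domain independent E-value (< 0.01) is used only
  when counting NBDs — sequence-level permissiveness for detection,
  domain-level stringency for architecture calls.
- **Voting**: the 4-of-5 rule is evaluated before the top-3 rule, and
  both before the e-value gap rule. BF/BH reference labels pool into a
  single "B" super-label so full- and half-transporter references
  reinforce each other; the candidate's own NBD count then decides BF
  (≥ 2) versus BH. With exactly 4 hits only the top-3 rule can fire —
  a 4-of-5 consensus requires 5 hits. A consensus of non-ABC background
  references never assigns a family.
- **E-value gap**: "5 orders of magnitude" is read multiplicatively and
  inclusively, e₁ ≤ e₂·10⁻⁵. The runner-up must be a different subject.
  With a single hit the rule fires whenever the hit is an ABC reference.
  When both e-values underflow to zero the ratio is undefined; the rule
  then demands a bitscore margin of ≥ 50 bits.
- **Length filter**: "under 250 residues" is strict (250 survives). The
  filter runs after classification and preserves the original rule in
  the call record, so excluded fragments remain auditable.
- **BUSCO gate**: single-copy completeness strictly below 80% excludes
  the species; 80.0 survives.
- **ABC-I**: not part of the reference vocabulary; any such label
  arriving through a hand-edited database leads to exclusion rather
  than a bare-"I" output. No output family is ever bare "B", "NONABC"
  or "I".

## Built-in search backend

The production path is external HMMER3 (`--domtblout`) and BLAST
(`-outfmt 6` 12-column) output. The built-in backend exists so the
entire chain is testable and runnable with no third-party binaries. It
is a position-specific scoring matrix (PSSM) scanned with local
Smith–Waterman alignment under affine gaps (open −11, extend −2 in
half-bit units), **not** a profile HMM: there are no insert/delete
emission states. Profile scores are per-column log-odds against a fixed
background amino-acid composition (the Robinson–Robinson frequencies,
frozen as constants), with add-pseudocount smoothing (default 0.5).
Unknown residues (`X`) score a constant −1 half-bit everywhere so runs
of ambiguity cannot seed alignments.

Multiple domain hits are found iteratively: report the best local
alignment, mask its sequence interval, re-scan; this guarantees
disjoint reported intervals. E-values are Karlin–Altschul-shaped with
fixed constants, E = 2^(−bits)·n·m for sequence length n and profile
length m. These synthetic E-values are well calibrated for ranking and
thresholding within a run but are not exchangeable with HMMER's or
BLAST's calibrated statistics; strong hits underflow to E = 0, which
the gap rule's bitscore-margin branch handles. The default domain
reporting threshold is 25 bits, at which random 150–400-residue
sequences produce no hits.

NBD counting accepts hits greedily by ascending per-domain E-value
(ties: higher bitscore, then smaller start) and rejects a hit
overlapping an accepted interval by more than half the shorter
interval's length — tandem NBDs in real transporters are well
separated, so the 0.5 overlap ceiling is not delicate.

The similarity search used by the built-in backend aligns each query
against a degenerate single-sequence PSSM per reference protein and
keeps hits with E < 10⁻⁵. Coordinates are 1-based inclusive in all
external formats and converted to 0-based half-open internally at parse
time.

## Rank-based family-size comparison

The omnibus test is the tie-corrected Kruskal–Wallis H with mid-ranks
and a chi-square upper tail on k−1 degrees of freedom. The chi-square
approximation is used at all sample sizes (no exact small-n tables);
at k=4 groups of 10 the realised type-I error is ≈ 0.044–0.049 at
nominal 0.05, i.e. slightly conservative. Post-hoc pairwise comparisons
follow Conover's rank-means procedure: groups i, j differ when
|R̄ᵢ − R̄ⱼ| exceeds t₍₁₋α′/2, N−k₎ · √(S²·(N−1−H)/(N−k)·(1/nᵢ+1/nⱼ)),
with S² the variance of all ranks. α′ is Bonferroni-adjusted over the
k(k−1)/2 pairs by default; the unadjusted per-comparison level is
selectable for compatibility with the classic R implementation's
default. Letters come from the insert-and-absorb compact-letter-display
algorithm over groups sorted by descending mean rank (highest mean rank
= "a"). When `family_size_tests` runs one test per family column (A–H
plus total, 10 tests), omnibus p-values are additionally Bonferroni
multiplied by 10; groups with fewer than 3 species are dropped with a
warning. Degenerate input (all values identical) is defined as H = 0,
p = 1 rather than an error.

## Quantification formulas

- TPM: rate_g = count_g/(length_g/1000), TPM = rate/Σrate·10⁶ per
  sample; effective gene lengths are caller-supplied (annotation is out
  of scope). Columns sum to 10⁶ by construction.
- Z-transform: per gene across samples with sample standard deviation
  (ddof = 1); zero-variance genes become all-zero rows with a warning.
- Schneider–Orelli: 100·(T−C)/(100−C); negative corrected mortality is
  clipped to 0 with a warning; C = 100 is rejected.
- ΔΔCt: fold = E^(−ΔΔCt) with E = 2 by default. Dilution-series
  amplification efficiencies are not folded in automatically; an
  efficiency parameter is exposed instead, and the choice of
  housekeeping normaliser is the caller's.

## Synthetic data: what it emulates and what it does not

Each family's NBD is a distinct ~180-residue archetype derived from one
shared random core mutated at rate 0.22 per site, giving ≈ 61% identity
between families — close enough that every family cross-hits the
reference database and the *vote*, not the e-value gap, is what
separates them, mirroring the intended rule ordering. Reference copies
diverge 5% from their archetype (> 90% within-family identity); BF
records and plants carry two NBD blocks separated by a ≥ 60-residue
random linker. Decoys are background-composition random sequences, plus
truncated (< 250 aa) fragments of planted genes that classify correctly
and must be caught by the length filter. Planted mutation is
substitution-only, targets drawn from the background excluding the
current residue, so planted coordinates stay exact for interval
assertions.

Each generator draws from a child RNG stream keyed by (seed, generator
id), so fixtures sharing a seed are mutually independent; every
generator is a pure function of its arguments and byte-deterministic.

What the fixtures do **not** emulate: indels and alignment-frameshift
noise, transmembrane-domain composition bias, shared motifs between
NBDs beyond the common core, paralogue clustering within a family, or
annotation artefacts other than simple truncation. Passing the planted
benchmarks therefore demonstrates the correctness of the rule logic and
search machinery, not field performance on real, noisier proteomes —
for real data the external HMMER/BLAST backend with the PF00005 profile
and a curated reference set remains the intended path.

## Problem sizes and determinism

The bundled end-to-end checks use 45-record reference databases
(5 per family + 5 background), proteomes of 30 planted genes across all
nine families plus 30 decoys, 20 seeds for classification properties,
100 random proteins for search-oracle equivalence, and 10⁴ simulations
for the null calibration of the rank test; the acceptance script uses
10 end-to-end seeds and 5·10³ null simulations. These sizes give stable
(±1 count) results while keeping a full run in the low minutes on one
core. All randomness flows through numpy `default_rng` seeded from the
single user-provided seed; repeated runs are byte-identical, including
batch outputs (result tables are explicitly sorted, logs carry no
timestamps).

## Known limitations

- The built-in aligner forbids direct insertion↔deletion transitions
  (standard three-state affine model); pathological score matrices
  could in principle prefer such paths.
- Synthetic E-values are not calibrated across scoring systems; do not
  mix built-in and external hit tables within one species.
- The Conover post-hoc uses the omnibus H in its variance term; with
  tiny groups (N−k < 2) it is refused rather than approximated.
- `vote_family` with fewer than 5 hits can only use the top-3 rule;
  whether a 4-of-4 consensus should count is genuinely ambiguous and
  was resolved strictly (it does not).
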