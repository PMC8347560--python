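# Methods

This note documents the models, conventions and numerical choices behind
`rg4scope`, in the order the pipeline runs them.

## Motif grammar and parsing

A canonical RG4 motif is `G_x N_{1-7} G_x N_{1-7} G_x N_{1-7} G_x` with
x ≥ 3; the minimum match length is therefore 4·3 + 3·1 = 15 nt. The
grammar leaves two things open, which we fix deterministically:

- **Tract maximality.** A G-tract is a *maximal* G-run: a run longer
  than 3 contributes its whole length to the tract, never to a loop, so
  a loop never begins or ends with a G that could extend an adjacent
  tract. The quartet number of a motif is the minimum of its four tract
  lengths (a (4,3,3,3) motif counts 3 quartets).
- **Overlap policy.** Matches are reported leftmost and non-overlapping;
  among parses sharing a start, the earliest-ending one wins. This makes
  counts well-defined and matches common G4-scanner practice. A
  `report_overlaps` flag returns one minimal parse per eligible first
  tract instead.

The scanner works on the list of maximal G-runs: chaining each eligible
first tract to the *nearest* three following runs (gap 1-7 nt each) is
provably complete — skipping a run can only widen a gap — and yields the
earliest-ending parse. The test suite checks equivalence against an
exhaustive partition enumerator on tens of thousands of random strings.

Internally the alphabet is DNA-style (ACGT); U is mapped to T on input,
since reference transcriptome FASTA files are T-based. IUPAC ambiguity
codes are accepted (they can only occur in loops); anything else is
rejected with its position.

## Reactivity

The per-position reactivity dialect is the widely used structure-probing
convention, applied per transcript:

1. scale treated and control counts to equal depth: each track divided
   by its own total and multiplied by the geometric mean of the two
   totals;
2. `raw_i = max(0, ln(t'_i + 1) − ln(c'_i + 1))` at A/C positions;
3. divide by the mean of the raw values ranked between the 2nd and 8th
   percentile from the top (2–8 % normalization);
4. clip to [0, cap], cap 7 by default.

G/U positions carry no DMS signal and are undefined (NaN). Transcripts
with a zero-total track or fewer than 10 A/C positions are skipped with
a warning. The percentile window, cap, and normalization step are all
configurable (`norm_window=None` disables step 3), because published
variants of this dialect differ in exactly these constants.

Two numerical caveats, verified by the property tests: because of the +1
pseudocount, multiplying both tracks by a common factor changes θ only
at order 1/(factor·count) — the scale-invariance test is therefore
asymptotic, not exact; and monotonicity of θ in a single treated count
holds before the 2–8 % normalization (step 3 rescales all positions
jointly).

## Fold calling

The default classifier is a protection ratio

```
score(motif) = mean θ inside the motif / (mean θ on the transcript + ε)
```

over defined A/C positions, with the motif called *observed* (OG4) when
score ≤ τ (default τ = 0.5, ε = 10⁻⁶). Motifs with no probed A/C inside
(e.g. all-G loops) cannot be assessed by DMS logic and default to
unfolded with a `no-probed-ac` flag; motifs on transcripts without a
reactivity track get a `no-data` flag. Observed and unfolded sets always
partition the putative set, and the observed set grows monotonically in
τ.

Constrained thermodynamic folding is deliberately *not* bundled: any
engine mapping (sequence, constraint vector, motifs) to per-motif
booleans can be plugged in through the adapter contract, with automatic
fallback to the protection ratio if the engine fails. This keeps the
default pipeline self-contained and deterministic.

A practical limit of the protection-ratio rule, visible in the recovery
tests: its noise floor is set by the *control* track's Poisson noise,
not by the DMS signal strength, so recovery accuracy approaches 1 only
when sequencing depth and signal grow together. At the default synthetic
conditions (protection 0.1, 20× signal-to-background, ~1 stop/nt
background depth) balanced accuracy against planted truth is ≈ 0.91.

## Positional statistics

- **Region assignment** is by motif start; boundary-spanning motifs keep
  that label and receive a `spans-boundary` flag.
- **5′-aligned relative density**: `d_i = G_i / T_i × 10³` at 1-based
  position i, with `G_i` the number of motifs covering i (occupancy
  counting, because the region-wide background `l / L × 10³` is
  occupancy-based; `count_mode="start"` offers start counting) and `T_i`
  the number of transcripts long enough to contain position i. A
  start-codon-aligned variant counts positions upstream of the CDS with
  `T_i` the number of 5′-UTRs at least i nt long. When every transcript
  reaches the window, the mean of `d_i` equals the windowed occupancy
  background — an identity the tests check numerically.
- **Metagenes**: density of feature coverage at signed offsets from a
  set of anchors, normalized per anchor still on-transcript at that
  offset. The control profile re-runs the identical computation on an
  equal number of uniform random anchors drawn from a stated region
  class with a stated seed.
- **Forming probability**: downstream of anchors, in 20-nt bins,
  `p_i = d_i(observed) / d'_i(putative)` with identical occupancy
  counting for both, so p ∈ [0,1] whenever observed ⊆ putative; bins
  with zero putative density are undefined and excluded from trend
  testing. Offsets are counted strictly downstream of the anchor
  position.
- **Mann–Kendall**: `S = Σ_{j>i} sign(x_j − x_i)`, tie-corrected
  variance `[n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18`, continuity-corrected
  `z = (S ∓ 1)/√varS`, two-sided normal p. This dialect reproduces
  p = 0.0003466 for S = 41 at n = 10 exactly to four significant
  figures, which pins down the variant among the several in circulation.

## Expression comparisons

Transcripts are filtered at TPM strictly greater than 1. The group test
is a one-sided Wilcoxon rank-sum (alternative: focal group greater),
normal approximation with tie and continuity correction. The
repeated-sampling procedure draws, per round, an equal-size comparison
set without replacement — the size being the smaller of the two groups —
and records the one-sided p; the textbook-pseudocode alternative
(sampling `|group|` items *with* replacement) is available behind
`pseudocode_literal=True`, because the literal without-replacement
reading is impossible when the pool is smaller than the group. The
per-round significance threshold defaults to 0.05. Note that rounds
share the focal group, so the fraction of significant rounds estimates
an exceedance probability *conditional on that group*; across datasets
it averages to the nominal level under the null, but its spread is wider
than binomial.

## Synthetic data generator

The generator emulates the data regime the pipeline targets, with every
stochastic choice driven by a single seed (sub-streams per stage, so
each stage is independently reproducible):

- **Transcripts**: 5′-UTR/CDS/3′-UTR lengths uniform on configurable
  ranges (defaults 150-300 / 300-900 / 300-800 nt, CDS a multiple of 3),
  background base composition at a configurable GC fraction (default
  0.45).
- **Planted motifs**: 3-G tracts with loop lengths drawn from a 1-7 nt
  distribution calibrated so ~57 % of motifs have all loops ≤ 3 nt,
  matching the composition reported for in-cell G4s. Loops contain no G
  (keeps the planted parse unambiguous) and start with A or C (keeps
  every motif probeable). One motif is planted per 5′-UTR and per 3′-UTR
  by default; each is folded with probability 0.5. Background sequence
  is rejection-sampled so no chance motif arises within 30 nt of a
  planted one, and the final truth is reconciled against a re-scan of
  the assembled sequence (chance motifs elsewhere are recorded as
  unplanted, unfolded putatives) — correctness by reconciliation rather
  than by a provably G4-free background grammar.
- **RT stops**: control ~ Poisson(λ_bg) everywhere; treated at A/C
  ~ Poisson(λ_bg + λ_dms·a) with accessibility a = protection inside
  folded planted motifs and 1 elsewhere; treated at G/T ~ Poisson(λ_bg).
  Defaults λ_bg = 1, λ_dms = 20, protection = 0.1 — a 20× accessible
  signal-to-background ratio with strong but imperfect protection.
  λ_dms = 0 is allowed as the explicit no-treatment limit. The model is
  intentionally the simplest whose moments are closed-form, so parameter
  recovery is analytically checkable.
- **Expression**: log-normal(μ = 3, σ = 1) baseline, multiplied by
  `expr_effect` (default 2) for transcripts with a folded 3′-UTR motif,
  renormalized to sum to 10⁶ (TPM-like).
- **Anchor tracks**: 7-nt miRNA sites, 60 % placed within ±50 nt of a
  planted 3′-UTR motif and the rest uniform; one poly(A) anchor per
  3′-UTR, uniform outside a 50-nt exclusion radius around every motif.
  The exclusion construction guarantees zero motif occupancy within the
  radius — the depletion shape the metagene stage must recover.

What the generator does *not* emulate: read-level artifacts (adapter
content, mapping ambiguity, ligation bias), transcript-abundance-coupled
coverage, RT drop-off along the transcript, non-canonical G4s, and any
sequence dependence of DMS beyond the A/C-vs-G/U dichotomy. Passing
tests therefore demonstrate algorithmic correctness and statistical
calibration under a clean generative model, not robustness to those
real-data artifacts.

## Problem sizes in the test suite

The default suite runs the scanner-versus-enumerator check on ≥ 10⁴
random strings, parameter recovery on 50 seeded replicates of a
40-transcript transcriptome, and calibration checks on 100-500 seeded
replicates; the full suite completes in about a minute on one core.
These sizes were chosen so each check's statistical resolution comfortably
exceeds the effect it tests.
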