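# rg4scope

Transcriptome-wide detection and positional profiling of RNA
G-quadruplexes (RG4s) from DMS-seq structure-probing data.

RNA G-quadruplexes are four-stranded structures formed by stacked
G-quartets. The canonical motif is

```
G_x N_{1-7} G_x N_{1-7} G_x N_{1-7} G_x        (x >= 3)
```

four guanine tracts of at least three Gs separated by three loops of 1-7
nucleotides, giving an analytic minimum motif length of 15 nt. Whether a
motif is actually folded in living cells can be probed chemically:
dimethyl sulfate (DMS) methylates *accessible* adenines and cytosines,
reverse transcription stalls one nucleotide before each methylated base,
and comparing RT-stop counts between a DMS-treated library and an
untreated control yields a per-position reactivity θ. A/C positions
inside a folded quadruplex are protected and show depressed θ.

`rg4scope` implements the full desk-side analysis around that idea, for
computational biologists working on RNA structure and post-transcriptional
regulation:

- **scan** — canonical motif scanner (leftmost, non-overlapping, maximal
  G-tracts), loop/quartet decomposition, observed-minus-putative
  ("unfolded") set derivation, composition summaries;
- **reactivity** — RT-stop counting and reactivity computation
  (equal-depth scaling, zero-floored `ln(t+1) − ln(c+1)`, 2–8 %
  normalization, cap at 7);
- **call** — observed (OG4) vs unfolded (UG4) classification by a
  protection-ratio score, with a pluggable adapter contract for external
  constrained-folding engines;
- **profiling** — per-region counts and per-kilobase densities, the
  5′-aligned relative density `d_i = G_i / T_i × 10³` with its
  region-wide background `l / L × 10³`, distance-to-end statistics,
  anchor metagenes (miRNA target sites, poly(A) sites), the per-bin
  forming probability `p_i = d_i / d'_i`, and a Mann–Kendall trend test
  (tie-corrected variance, continuity-corrected normal deviate);
- **sampling** — TPM > 1 expression filtering, one-sided Wilcoxon
  rank-sum comparisons, and a 10,000-round random-sampling test;
- **synthetic** — a generator of synthetic transcriptomes with planted
  motifs of known folded status, Poisson RT-stop counts, log-normal
  expression with a planted group effect, and anchor tracks with planted
  enrichment/depletion, so the whole pipeline is testable end to end
  with no external data.

## Worked example

Simulate a 100-transcript dataset and run every stage:

```
rg4scope simulate --outdir demo --seed 42
```

```python
import json
from rg4scope.pipeline import PipelineConfig, run_pipeline

out = run_pipeline(PipelineConfig(
    fasta="demo/transcripts.fa", annotation="demo/annotation.tsv",
    treated_rtsc="demo/treated.rtsc", control_rtsc="demo/control.rtsc",
    expression="demo/expression.tsv", mirna_bed="demo/mirna_sites.bed",
    polya_bed="demo/polya_sites.bed", outdir="demo/out",
    sampling_rounds=1000, seed=42))
summary = json.load(open(out / "summary.json"))
```

On this dataset the summary reports 96 called OG4s, 48 in 5′-UTRs and 48
in 3′-UTRs. Although the counts are equal, the per-kilobase densities
differ more than twofold — 2.12 OG4/kb in 5′-UTRs against 0.88 OG4/kb in
3′-UTRs — because 5′-UTRs are much shorter; this is exactly the
count-versus-density discrepancy the profiling stage is designed to
expose. 55.2 % of the called motifs have all three loops ≤ 3 nt,
matching the loop composition the generator plants. The sampling stage
compares the expression of transcripts carrying a folded 3′-UTR motif
(n = 48) against the remaining expressed transcripts: with the planted
two-fold effect, all 1,000 sampling rounds are significant at p < 0.05
(`"n_significant": 1000`).

Every stage is also exposed as a subcommand
(`rg4scope scan / reactivity / call / profile / sample-test / run`); run
any of them with `--help` for the file formats involved.

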