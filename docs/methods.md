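# Methods

## Library model

The variant universe is defined by a `MutagenesisDesign`: a reference CDS,
a degenerate codon pattern (default NNS), a set of amplicon pools, and a
numbering offset. Codon indices are 1-based and inclusive throughout,
matching the "residues 2–100" convention of pool descriptions; the offset
(default design: +338) converts a library codon index into the residue
numbering of the full-length protein, and all outputs carry both to avoid
silent drift.

NNS expands to 32 codons: all 20 amino acids (1–3 codons each) plus the
amber stop TAG. Three flags matter downstream. The codon identical to the
reference (`is_wt_codon`) is *not* a measurable variant — a read carrying
it is indistinguishable from wild type, so its molecules are tallied into
the wild-type count and its matrix cell stays missing whenever it is the
amino acid's only NNS codon. Synonymous variants (`is_wt_synonymous`,
different codon, same amino acid) are scored like any mutant and serve as
an internal near-zero control. Overlapping pools (the default design's
90–100 and 178–189) are kept as independent measurements per pool and
reconciled only in reporting.

## Counting

Amplicons are fixed-length PCR products over one pool region, so reads are
compared to the reference ungapped after being located by exact-match flank
anchors (12 nt by default, clamped to the flank so edge-codon variants
still align). Reads that fail the anchors or change length are classified
`indel_or_unaligned`, not force-aligned: indel reads are library artifacts,
not NNS variants. Any mismatched base below the quality floor (default
Q30), or an N in a mismatched codon, sends the read to `low_quality`.
Otherwise the count of mismatched codons decides: 0 → wild type, 1 → that
variant, ≥2 → `multi_variant`. Single-codon variants outside the NNS set
are tallied as `off_design` (mostly sequencing/PCR errors) and never
scored. A single mismatched base still resolves to a codon variant;
error suppression relies on the quality floor plus the downstream
input-count filter rather than consensus barcoding, which the assay does
not use.

Paired reads are merged by their best ungapped 3′ overlap (≥ 20 nt,
mismatch fraction ≤ 0.1, scored by matched bases); disagreements resolve to
the higher-quality base, ties to N. Failed pairs count as
`indel_or_unaligned`. Every count table satisfies the conservation
invariant `wt + Σ variants + off_design + Σ rejected = total_reads`, which
is asserted after every tally.

Pre-tallied TSV count tables (per-variant counts plus a class-total
summary) are accepted interchangeably with FASTQ, so the scoring stages run
on external count data without raw reads.

## Scoring

`ΔE = log10(N_sel^m/N_ref^m) − log10(N_sel^wt/N_ref^wt)`, computed per
codon and replicate. Choices:

- **Reference population.** The unselected endpoint (configurable to T0).
  Using the unselected flask controls for depletion that happens in both
  flasks, e.g. toxicity of an over-active enzyme.
- **Input filter.** Variants with input-library (T0 by default) counts
  strictly below 25 are masked (`insufficient_input`); variants never
  observed anywhere are `absent`. Both render as missing cells.
- **Pseudocount.** Default 0.5 added to all four counts symmetrically. It
  keeps the wild-type score exactly 0, bounds scores for variants that
  vanish under selection (stop codons routinely sequence to 0 reads in the
  selected flask), and at 0 reproduces the bare log-ratio, which raises an
  explicit error on zero counts instead of returning ±inf.
- **Wild-type counts** are exact-reference-sequence reads only, never
  synonymous variants.
- **Averaging order.** Mean over replicates per codon first (recording
  `n_replicates`), then mean over synonymous codons per residue × amino
  acid (recording `n_codons`). Both are plain arithmetic means, so the
  order only matters for unbalanced missingness, where per-codon
  replicate averaging weights codons equally.
- **Replicate agreement** is reported as pairwise Pearson r over
  residue-level cells scored in both replicates (synonymous codons averaged
  within each replicate first).
- **Classification.** gain / loss / neutral by a symmetric band of ±0.2
  log10 units around 0, roughly twice the replicate noise observed in
  simulated runs at 10⁶-read depth; purely a reporting default, tunable.

## Selection simulator

The generator collapses the reporter cascade into a single per-variant
selection coefficient *s*, the per-hour growth-rate difference vs wild
type, and reproduces the experiment's geometry:

1. Library inoculum: each pool's molecules are uniform over its
   position × NNS codons, plus a 5% exact-wild-type background (unmutated
   plasmid always survives library construction, and WT counts must exist
   for scoring). Molecules whose NNS draw equals the reference codon read
   as wild type.
2. 3 h induction, neutral for all variants; T0 is sequenced from this
   population.
3. Dilution through a multinomial bottleneck (default 2 × 10⁶ cells per
   flask, comfortably above the experimental >100× coverage floor) into a
   selected and an unselected flask.
4. 7 h growth: abundance `N0·exp((r_wt + s)·t)` in the selected flask
   (default r_wt = 1.0 /h, consistent with dilution to OD 0.001 and
   near-saturation in 7 h). The unselected flask grows neutrally (plus an
   optional toxicity term) and saturates logistically: all lineages share
   an effective time τ ≤ t chosen so the total just reaches the carrying
   capacity (default 2 × 10⁹), found by root-finding. This preserves the
   per-lineage exponential form while compressing fold-changes, as
   saturation does in the flask. Since all unselected lineages grow at the
   same rate by default, the compression cancels exactly in ΔE.
5. Sequencing is a multinomial draw of fixed depth (default 10⁶), so every
   sample's counts sum exactly to the depth and conservation tests are
   exact.

With `sampling=False` and `bottlenecks=False` the simulator returns
expected (float) counts, and the pipeline score equals the closed form
`ΔE = s·t/ln 10` to machine precision — the main correctness anchor.

Ground-truth effects come from a position-class mixture (`EffectModel`):
30% loss, 60% neutral, 10% gain positions, reflecting that most protein
positions tolerate mutation. Non-synonymous variants at loss (gain)
positions draw effect magnitudes from folded normals, mean 0.4 (0.25) /h,
sd 0.15 (0.1); stop codons always get s_min = −1.0 /h (with r_wt = 1.0 /h
they simply stop growing under selection); synonymous variants are neutral.
These map to ΔE ≈ −3…+1 over 7 h, the range a strong growth selection
spans.

**Rank-recovery benchmark.** Under the mixture model ~60% of true effects
are exactly 0, so a Spearman correlation between true and recovered
effects is capped by the tie group no matter how accurate the pipeline is
(a perfect estimator scores ρ = 0.849 on a 50-position draw; the pipeline
scores within 0.0002 of that ceiling). Rank recovery is therefore
benchmarked against `benchmark_fitness`, a continuous ground truth (iid
uniform s ∈ [−0.6, 0.3] per non-synonymous variant, stops at s_min) with
essentially no ties, under which the metric measures recovery error
rather than tie structure. At 50 positions, 10⁶ reads and 3 replicates
the pipeline achieves ρ ≈ 0.999.

FASTQ emission writes each sample's ledger as full-amplicon reads (or
read pairs) at constant Q37 with optional per-base substitution errors;
at error rate 0 a re-tally reproduces the ledger exactly.

## What the simulator does and does not emulate

It emulates: selection as growth-rate differences, dilution bottlenecks,
unselected-flask saturation, exactly conserved multinomial sequencing, and
variant dropout (a variant lost at the bottleneck stays absent). It does
not model PCR amplification bias or chimeras (the experimental protocol
minimized these with 2 × 20 amplification cycles), position-dependent
sequencing error, reporter-cascade kinetics or growth lag, or
co-occurring secondary mutations. Passing tests therefore certify the
analysis pipeline — counting, filtering, scoring, aggregation — under an
idealized but structurally faithful read-generating process; they do not
certify robustness to amplification artifacts in real libraries.

## Numerical and design notes

- Problem sizes in tests and the acceptance script use 8–51-codon designs
  at depths 2 × 10³–10⁶; the full 278-codon, 3-pool, 3-replicate
  configuration runs end to end in about two seconds, so the scaled runs
  are purely a convenience.
- The logistic effective time is found with Brent's method to 1e-12; the
  deterministic-limit identity holds to ≤ 1e-9 regardless because the
  unselected compression cancels in the score.
- The bundled 278-codon reference CDS is synthetic (deterministic random
  sense codons): every analysis stage is sequence-agnostic, so pool
  geometry, not sequence content, is what the default design preserves.
- Heatmap rendering always writes the lossless TSV (full precision, `NA`
  missing markers, verified round-trip); the PNG is optional, diverging
  red/blue centered at 0 with gray for missing cells, color limits
  symmetric at the matrix's max |value|.
- Pool overlaps are reconciled by the mean rule by default (invariant to
  pool order); a designated-pool rule is available when one pool's
  measurements are preferred.
- Degenerate inputs: designs may have zero mutagenized positions (empty
  variant list); empty read streams give all-zero tables; replicate pairs
  with fewer than 2 overlapping cells report an undefined correlation
  rather than a number.
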