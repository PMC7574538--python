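# Methods

`scindel` re-implements a droplet single-cell CRISPR edit-detection
workflow: barcoded amplicon reads are demultiplexed into cells, aligned
to an amplicon panel, and each cell × amplicon is summarized by the
fraction of reads carrying an indel inside a narrow window around the
predicted Cas9 cleavage site. Downstream summaries cover zygosity,
droplet doublets, multi-target edit multiplicity and combinatorial
assortment, plus a qPCR-based sgRNA presence caller. A truth-tracked
simulator makes every stage testable without sequencing data.

## The assay model

Each sequencing read is structured as three constant segments
interleaved with two 9-nt cell barcodes, followed by the amplicon
payload. The two barcode halves are concatenated into an 18-nt
composite cell barcode. Reads whose payload is shorter than 46 bp, or
whose composite barcode is shorter than 18 bp, are discarded; every
fate is tallied and the tallies always conserve the input count. The
constant segments of the commercial library are not public, so the
read structure is fully configurable and the simulator uses
self-consistent placeholder constants.

Cells are called by a fixed total-read cutoff (default 1000 reads,
matching a ~28-amplicon panel at ~26 reads/amplicon/cell). The cutoff
is inclusive and must be scaled with panel size; simulation-based tests
in this repository use 6-amplicon panels and a cutoff of 50. No
knee-point detection is attempted.

## Cut sites and quantification windows

Coordinates are 0-based; the cut site is an inter-base index. For a
forward-strand guide with the NGG PAM starting at `p`, the blunt cut
lies 3 bp 5' of the PAM: `cut = p - 3`. For a reverse-strand guide
whose reverse-complemented PAM ends at inclusive position `q`,
`cut = q + 4` (the mirror image). The quantification window is the
half-open interval `[cut - w, cut + w)` with `w = 2` by default (a
4-bp window). The PAM pattern is configurable; NGG is the default
since SpCas9 is assumed throughout. Control amplicons carry no guide,
no window, and are only ever coverage-profiled.

## Alignment

Reads are aligned to each panel amplicon in both orientations with an
affine-gap Gotoh algorithm that is global in the read and free at both
reference ends, the natural contract for amplicon reads. Default
scoring is match +2, mismatch −3, gap open −5, gap extend −1 (a gap of
length L costs 5 + L). The dynamic program is JIT-compiled with numba;
a score-only two-row kernel screens all (amplicon, orientation)
candidates and the full traceback is computed only for the winner.
Traceback tie-breaks are fixed (deletion > insertion > diagonal) and
indel runs are then left-normalized — an indel is shifted one base left
whenever the flanking base equality makes the shifted alignment
score-identical — so repeated runs produce byte-identical operation
lists. Reads are assigned to the best-scoring amplicon; a read is
dropped as ambiguous when the best score is tied across amplicons, or
as low-identity below a 0.65 identity floor (identity = matches /
aligned columns). The floor is deliberately permissive so that large
cut-site deletions survive assignment.

Within the pipeline, assignment is memoized on the payload sequence.
Droplet amplicon data is massively redundant (most reads are exact
copies of a handful of alleles), so this collapses the alignment
workload by one to two orders of magnitude without changing any
result.

## Modification calling and alleles

A read is *modified* when, after left-normalization, a deletion's
reference interval intersects the half-open window, or an insertion
point falls inside the closed window `[cut - w, cut + w]`. The closed
insertion interval treats the two window boundaries symmetrically; an
insertion exactly at the boundary counts. Substitutions are ignored by
default — the targets are NHEJ indels, and counting substitutions would
let sequencer error masquerade as editing — but a flag enables them.

Alleles are keyed by the read sequence projected onto the window plus
10 bp of flank on each side (deleted positions rendered as `-`,
inserted bases in lower case), so sequencing errors far from the cut
do not fragment allele tallies. Per (cell, amplicon), groups with
fewer than 5 reads are NO_CALL; otherwise the percent of modified
reads and the top two alleles by count (ties broken lexicographically)
are recorded. Heterozygosity is defined as the frequency of the
second-most-frequent allele, in percent.

## Zygosity

With thresholds `lower = 20` and `upper = 80` (percent, configurable):
pct_modified < 20 → WT/WT; 20 ≤ pct < 80 → WT/Mut; pct ≥ 80 with
heterozygosity ≥ 20 → Mut/Mut2 (two distinct edited alleles); pct ≥ 80
with heterozygosity < 20 → Mut/Mut. The four classes partition the
input space; boundary semantics (≥ at 20 and 80) are tested
exhaustively on a 0.1% grid. No ploidy model beyond two-allele diploid
logic is used.

## Doublets and multi-target summaries

A target is counted as edited in a cell when called and at least 20%
modified. In *admixture* designs — a pool of lines each edited at a
single locus — a barcode edited at two or more targets must contain
DNA from more than one cell and is flagged as a doublet. The flagged
rate understates the true doublet rate by the probability that both
constituents come from the same line: for line proportions `p_i` the
expected flagged rate is `doublet_rate × (1 − Σ p_i²)`, which the
package exposes as a closed-form helper. Doublet flagging is never
applied outside admixture mode, because multi-edited cells are genuine
biology in a multiplexed line. Missing (under-covered) targets count
as unedited for subset membership, but per-cell covered-target counts
are carried so users can filter. Combination tables report, for each
exact subset of edited targets, the number of cells whose edited set
equals it, together with per-gene marginal set sizes.

## sgRNA qPCR presence calling

Input is a long-format Cq table (cell, assay, replicate, Cq) with a
no-amplification sentinel (default token `999`). An sgRNA is present
in a cell when at least `min_positive_reps` (default 4 of 8)
replicates amplify at Cq ≤ `cq_max` (default 25, within the 30-cycle
protocol). The count-of-positives rule is preferred over a median Cq
because single-cell qPCR is dropout-prone and sentinels destabilize
medians. Both parameters are declared defaults, not inferred values.
Calls are monotone in `cq_max` and anti-monotone in
`min_positive_reps` by construction.

## Simulator

The simulator is first-class, tested code. Each barcode draws a
genotype from a configured population (two draws for doublets, at the
configured rate); per amplicon, coverage is drawn from a negative
binomial with mean `mean_coverage` (default 26 reads/amplicon/cell)
and dispersion 8 (Poisson available via `dispersion=None`); reads are
split uniformly across the 2 (singlet) or 4 (doublet) allele copies;
each allele copy is independently zeroed with probability `ado_rate`
(default 7.5%, the middle of the 5–10% allelic-dropout band reported
for this chemistry); substitution errors (default 0.1%/base) and
spurious indels (default 1e-5/base) are injected per base over the
whole read, so errors can also corrupt barcodes and constants and
exercise the filters. Doublet coverage is drawn once and split, i.e.
doublets are not double-depth. Programmed edits are specified relative
to the cut site; their truth "modified" flag applies the window rule to
the left-normalized placement of the programmed indel (plain string
shifting, independent of the aligner), so truth and pipeline agree
exactly in the noiseless limit. Truth tables record constituent
genotypes, doublet flags, per-allele realized read counts, dropout
events and per-read provenance; conservation (emitted reads = Σ truth
counts) holds by construction.

Two presets define the study designs. The *admixture* preset builds
six singly-edited lines in equal proportions, each line split
28%/36%/36% into WT/Mut, Mut/Mut and Mut/Mut2 sub-populations
(roughly the relative abundances of edited zygosity classes this assay
reports), using a 3-bp deletion as the canonical edit and a distinct
6-bp deletion as the second allele of Mut/Mut2. The *multiplexed*
preset acquires a homozygous 3-bp deletion independently per target
with probability `edit_prob`, producing a Binomial(6, p) multiplicity
law that the pipeline must recover. Preset panels are synthetic
(~200–260 bp amplicons, planted spacer + NGG PAM, alternating guide
strand) and are re-drawn until every programmed edit remains inside
the quantification window after left-normalization.

What the simulator does *not* emulate: PCR chimeras, ambient DNA,
barcode sequencing-error collisions between real cells, realistic
quality scores, amplicon-specific amplification bias beyond the
negative-binomial dispersion, and reference-genome variation. Passing
tests therefore demonstrate the correctness of the pipeline's
computations under the stated generative model, not performance on
real libraries.

## Problem sizes and numerical choices

Simulation-based tests use 6-target panels; 500 cells at coverage 30
for the noiseless identity check, 5000 barcodes for the doublet-rate
and multiplicity-law checks, and 400 cells per allelic-dropout level
(7.5%, 15%, 30%) for the noise-degradation check, with a cell cutoff
of 50 reads — sizes chosen to keep each stochastic check's sampling
error well below the contracted tolerances. Stochastic assertions use
fixed seeds; binomial checks use 95% CIs, the multiplicity law uses a
chi-square test at α = 0.01 with sparse top bins pooled, and the
monotone-degradation assertion allows 1% slack for simulation error.
Allele-frequency ties are broken lexicographically; alignment-score
ties across amplicons yield unassigned reads rather than arbitrary
choices; all RNG flows from a single `numpy` generator per run.

## Known limitations

* Zygosity relies solely on the 20%/80% thresholds; no statistical
  genotype likelihoods, so heterozygote misclassification rises
  directly with allelic dropout (the degradation is quantified in the
  acceptance suite).
* The aligner is per-read and quality-agnostic; no per-cell consensus
  is built before quantification.
* Barcode error correction (whitelists, Hamming-1 collapsing) is off
  by default; erroneous barcodes are simply filtered by the cell-call
  cutoff.
* Bulk mode applies the same window rule over a pooled read set and
  reports per-amplicon percentages only.
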