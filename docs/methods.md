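# Methods

## Scope and model

The package treats a chloroplast genome as its set of protein-coding
sequences and asks two questions: which synonymous codons does the genome
prefer, and do those preferences look like the product of mutation
pressure (which acts on all positions and shows up most cleanly at
third positions) or of selection (which decouples third-position usage
from the mutational background)? All statistics operate on 64-long codon
count vectors in a fixed lexicographic order over (A, C, G, T); the
standard genetic code is assumed (the plastid CDS of the target genomes
use it), with the code table data-driven so a variant code could be added.

## Quality control

A CDS enters the analysis only if it (1) has length divisible by three,
(2) starts with ATG, ends with TAA/TAG/TGA and contains no internal stop,
(3) is strictly longer than `min_len_bp` (default 300 bp), and (4) is not
a repeat of an already-accepted sequence. Rule 4 reads "repeat" as an
exact sequence duplicate, keeping the first occurrence: chloroplast
inverted repeats double-annotate genes verbatim, which is the most likely
source of repeated CDS. A gene-name deduplication mode exists for
annotations where IR copies differ by a few bases. Records containing
ambiguity codes are rejected with their own failure category, since every
downstream index needs a clean A/C/G/T alphabet. All rules are evaluated
for every record (no short-circuiting), so a filter report lists every
violated rule, and filtering is idempotent on its own output.

Alternative starts (GTG/TTG) are deliberately rejected — the acceptance
rule is ATG only — so annotations using them are excluded rather than
silently rescued.

## Index definitions and conventions

* **GC1/GC2/GC3** are computed over *all* codons of a CDS including the
  stop codon, matching the cusp convention; **GC3s** excludes Met, Trp and
  stops (their third position is fixed by the amino acid, so it carries no
  usage signal). A sequence containing only Met/Trp/stop codons has GC3s
  = NaN, never a silent 0.
* **PR2 base fractions** (a3/t3/g3/c3) default to third positions of the
  five four-fold degenerate families (Ala, Gly, Pro, Thr, Val) — the
  classical parity construction, where the third base is entirely free of
  protein-level constraint. A switch widens the set to all sense codons.
* **RSCU/RFSC** of a family that never occurs are NaN, not 0; genome-scope
  RSCU is computed on pooled counts across the filtered CDS (a
  mean-of-genes mode exists for per-gene averaging). The two indices are
  carried in one table, linked by `rscu = rfsc · n_i`.
* **ENc** follows Wright: family homozygosity is estimated only where a
  family is observed at least twice; class means are inverted and summed
  as `2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`. When the single three-fold
  class (Ile) is missing, `F̄₃ ≈ (F̄₂ + F̄₄)/2`; when any other class is
  missing or has non-positive mean F, the gene's ENc is undefined — it is
  logged and excluded from ENc-based analyses rather than guessed. Results
  are clamped to the theoretical range [20, 61]. The finite-count
  correction in F̂ is O(1/n), so ENc is scale-invariant only in the
  large-count limit: doubling counts still moves ENc by ~0.04 at ~20k
  codons and by <0.01 only beyond ~200k.
* **CAI** excludes Met, Trp and stops from the geometric mean. The
  reference set is the genome's own high-expression library (below), not
  an external organism's table — a deliberate, self-contained choice since
  no expression data for these genomes is bundled; reference codons with
  zero count are floored at w = 0.01 so genes using them are penalised
  rather than undefined.

## Expression libraries and optimal codons

Genes are ranked by ENc with a stable (ENc, gene id) sort; the
`⌈0.10·N⌉` genes with the lowest ENc form the high-expression library and
the highest-ENc tail the low library. Low ENc = high expression is the
standard proxy (strong bias accompanies high expression); note that
reversing it flips the sign of every ΔRSCU. A codon is optimal when its
high-library RSCU exceeds 1 *and* ΔRSCU = RSCU_high − RSCU_low exceeds
0.08, both strictly. The RSCU > 1 condition is applied to the
high-expression library's RSCU (configurable), which is the reading
consistent with the construction's purpose. Ties spanning a tail boundary
resolve deterministically by the sort and are logged.

High-frequency codons default to RFSC > 0.6 or RSCU ≥ 1.5 — i.e. usage at
least 1.5× the family mean. A literal mode (RFSC > 0.5 × family-mean
RFSC, i.e. > 0.5/nᵢ) is also shipped; taken at face value it flags almost
every codon of large families, which is why it is not the default.

## Sources-of-variation analyses

* **ENc-plot**: each gene's observed ENc against
  `ENc* = 2 + s + 29/(s² + (1−s)²)` at its GC3s. A gene is "on-curve"
  when |expected − observed| / expected ≤ 0.05 (configurable; the
  tolerance is a convention, so summaries should be read as brackets, not
  sharp counts). Note ENc* is itself an approximation: under an exact
  mutation-only null the true expected ENc sits ~1–2 % above the curve,
  so a small systematic "above" count is not a selection signal.
* **Neutrality plot**: ordinary least squares of GC12 on GC3 (OLS, not
  reduced major axis, matching near-universal practice), with two-sided
  Pearson correlation. The slope is reported as the mutation fraction and
  1 − slope as the selection fraction.
* **Correspondence analysis**: classical CA of the genes × 59 codon RSCU
  matrix (Met, Trp, stops excluded). Absent-family NaNs are imputed to 0
  only at this multivariate boundary, and rows are rescaled to unit sum so
  every gene carries equal mass; a counts-based mode without equalisation
  exists for sensitivity analysis. Axis inertia fractions are σ²ₖ/Σσ²;
  principal coordinates are reported for genes and codons. Axis signs are
  fixed so the codon with the largest |loading| on each axis is positive,
  making outputs reproducible across SVD implementations. A matrix with
  (numerically) zero total inertia is flagged degenerate with NaN
  fractions rather than divided through.
* **Correlations**: Pearson by default (Spearman switch) between
  {GC3s, ENc, CAI, Laa} and the first two axes, plus all pairwise index
  correlations, with stars at p < 0.05 / p < 0.01. Constant columns give
  NaN with a warning.

## Host comparison

Host tables use the Kazusa text layout (RNA alphabet, frequency per 1000
with counts); parsing requires all 64 codons exactly once. The comparison
ratio is genome-per-1000 over host-per-1000; ratios ≤ 0.5 or ≥ 2
(inclusive, symmetric under inversion) count as large differences, with
all 64 codons as the denominator for percentages. Codons a host never
uses yield an undefined ratio and are excluded from the count, logged.

The four bundled host tables are **synthetic snapshots**: hand-built from
a shared amino-acid composition and per-organism wobble-preference
profiles (plants mildly A/T-ending, E. coli G/C-leaning with strong
CTG/CCG/CGC, yeast strongly A/T-ending). They emulate each organism's
qualitative preferences well enough to rank hosts sensibly, but per-codon
values are not database measurements — comparisons against them
characterise the snapshots, not the live database. Supply a directory of
real Kazusa tables via `hosts_dir`/`--hosts` for quantitative host work.

## Synthetic data: what it emulates and what it does not

The generator draws genes as ATG + uniform (optionally plant-like) amino
acids + one stop, with codons per amino acid from a mixture
`(1−s)·uniform + s·target`. Defaults are the study conditions the
pipeline is validated under: ~50 CDS per genome, 101–1000 codons
(303–3000 bp, so every clean gene passes the length rule), and the
AT-preference target spread uniformly over each family's A/T-ending
codons. With strength s, every A/T-ending synonymous codon has expected
RSCU 1 + s and every G/C-ending one 1 − s; the default s = 0.6 was set
from the closed form GC3 ≈ (2 + 9(1−s))/20 to give GC3 ≈ 0.28, the
AT-rich regime of chloroplast genomes, and yields a realistic usage band
(~0.33–1.75 observed) with 30 preferred codons, all A/T-ending. The
mutation-only factory instead weights codons by third-base probabilities
with P(G) = P(C) = gc3/2, the ENc-plot null.

Deliberate non-features, which bound what passing tests show about real
data: amino-acid composition does not vary systematically between genes;
there is no per-gene mutational heterogeneity, so GC12 and GC3 share no
common driver and the neutrality slope of a purely synthetic genome
hovers near 0 (small negative values arise from amino-acid sampling
covariance, not biology); genes are independent, with no IR structure,
operons, or length–function correlation; and a homogeneous A/T-ending
preference is indistinguishable from AT mutation pressure in the
ENc–GC3s plane, so synthetic "selected" genomes legitimately sit near the
expected curve. Real genomes violate all of these, which is precisely
what the published-genome reproduction test (network-dependent) is for.

Planted-preference libraries for optimal-codon validation are built by
codon arithmetic on one sampled gene set: the high library rewrites
synonymous mates of each shifted codon (in sequence order, so mates lose
usage proportionally) until its RSCU rises by the requested Δ. Families
without a shifted codon are byte-identical between libraries, so recovery
tests are free of sampling noise outside the planted signal.

The ENc-plot null-classification check is evaluated on long genes
(900–1000 codons): the Wright estimator's sampling standard deviation at
~100 codons is comparable to the 5 % band itself, so short-gene
misclassification measures estimator variance, not classifier behaviour.

## Pipeline conventions

Species are processed independently and joined only for the cross-species
sets (codons with RSCU > 1 in every genome; intersection of optimal-codon
sets). All tabular artifacts are TSV with floats at 4 decimals;
`summary.json` contains only numbers recomputable from the stage TSVs.
The run configuration is echoed verbatim (`config.json`), hashed into the
log, and a MANIFEST records completed stages so partial output after a
failure is interpretable. CLI exit codes: 0 success, 2 configuration
error, 3 input error, 4 stage failure.

## Known limitations

* ENc for very short genes is noisy and occasionally undefined; such
  genes are excluded from ENc-dependent analyses with a log entry rather
  than imputed.
* CAI's internal reference makes values comparable within a genome but
  not across packages that use organism-specific reference sets.
* The bundled host snapshots are qualitative stand-ins (above).
* tRNA-adaptation indices, codon-pair bias and amino-acid-usage analyses
  beyond Laa are out of scope, as are RNA alphabets and non-standard
  genetic codes.
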