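# Methods

`zwmarker` evaluates intron-length-polymorphism PCR markers for molecular
sexing of birds, entirely in silico. Birds have ZW sex chromosomes (females
ZW, males ZZ). A sexing marker is a primer pair flanking an intron of a
gene with diverged copies (gametologs) on Z and W: if the Z and W introns
differ in length by ΔL, a female yields two PCR products and a male one,
and the sexes can be told apart on an agarose gel — provided ΔL is large
enough for the gel to separate the bands, the W copy actually exists in the
species, and no nonspecific product lands on top of a diagnostic band. The
package turns those three provisos into computable verdicts.

## Pipeline stages and their models

### Spliced exon/intron inference (`gene_structure`)

Gene structure is inferred by mapping a spliced mRNA onto genomic sequence.
Because the intended use is same-species mapping, the aligner is
deliberately minimal: maximal exact matches of at least `min_anchor` bases
(default 20) are chained co-linearly by dynamic programming maximizing
mRNA coverage; adjacent anchors whose mRNA/genome gaps are equal in length
are merged into one exon when the interior mismatches stay within
`max_mismatch_rate` (default 0.02 per exon); unequal gaps become introns.
When the same mRNA letters match on both sides of a junction the boundary
is ambiguous; it is shifted to the leftmost placement whose intron starts
with `GT` and ends with `AG` if one exists in the ambiguity window,
otherwise simply leftmost. This convention is deterministic and follows the
canonical splice motif; it is a package convention, since boundary
placement inside an ambiguity window is not observable from the alignment
alone. An mRNA whose best chain covers less than 95% of its length is
rejected as unmappable; ties between equally scoring chains raise an
explicit ambiguity error rather than picking one silently. Minus-strand
genes are handled by mapping the reverse-complemented mRNA.

Intron numbering is 1-based after the preceding exon. This matters in
practice: a primer pair named for "intron 16" of a gene can bracket intron
17 in a lineage with an extra upstream intron, and the composition report
(`E17(54 bp)/I17(801 bp)/E18(68 bp)`) makes that visible instead of
trusting the primer's name.

### In-silico PCR (`insilico_pcr`)

Primer binding sites are found by sliding each primer over both strands.
A primer base matches under IUPAC semantics (R matches A or G, etc.); an
`N` in the template matches nothing, so assembly gaps never create sites.
A site may carry at most `max_mismatch` mismatches (default 2) and none in
the `three_prime_exact` bases at the 3' end (default 3), where extension by
the polymerase is least tolerant. Products are all convergent site pairs
within `max_product` (default 5000 bp — above the largest product the
panel is expected to produce, ~3 kb). All products are enumerated, not
just the shortest: real reactions produce extra and nonspecific bands, and
the evaluation logic needs to see them. Coordinates are 1-based inclusive;
a site's position is the primer's 5'-most footprint base on the plus
strand, which makes product length exactly `pos(rev) − pos(fwd) + 1`.

Scanning is vectorized (a 256×256 primer-base × template-base match table
applied to a sliding window view), and is checked in the tests against a
position-by-position brute-force scanner.

### Homology search (`homology_search`)

Second copies of an amplicon are found by a BLAST-style seed-and-extend
search: exact 11-mer seeds clustered by position define candidate windows;
each window is resolved with an exact affine-gap Smith–Waterman (match +1,
mismatch −2, a gap of length L costs 5 + 2L), implemented as a
numba-compiled Gotoh kernel with full traceback; after the best alignment
in a window is taken, its subject-side flanks are searched recursively so
that a copy interrupted by a large indel is recovered as several local
alignments. Co-linear alignments on the same subject and strand are then
chained into one hit.

Two consequences of the chaining are load-bearing:

* **Copy length is the subject-side span end-to-end**, including any
  indel between chained alignments. A 2997 bp query whose second copy lost
  2374 bp of intron is reported as one 623 bp copy, which is the quantity a
  gel actually sees — a single gapped alignment could never bridge an
  indel that size under any sane scoring.
* **`partial` means a missing query end, not a small alignment.** Query
  cover is measured on the chained hit's query span, `(qend − qstart +
  1)/qlen`, with hits below 0.90 flagged partial. An internal deletion
  still spans the query end-to-end (cover ≈ 1, complete); a terminally
  truncated fragment — say, only query positions 398–923 of a 923 bp
  amplicon surviving at a scaffold edge — does not (cover ≈ 0.57,
  partial). Partial copies are an *incomplete longer version*, not a
  shorter variant, so no ΔL is derived from them.

Defaults (`word_size` 11, `min_identity` 0.70, `min_hit_len` 50) tolerate
gametolog divergences well below the identities typically seen between
avian Z and W intron copies (roughly 75–92%). There are no E-values; at
desk scale, score, identity and query cover are the useful statistics. The
tests hold the search to an exhaustive Smith–Waterman oracle (biopython's
`PairwiseAligner` under the identical scoring) on substitution-only
instances, where the optimum is a single local alignment.

### Copy pairing (`copy_comparison`)

The best non-Z hit by identity × query-cover becomes the second copy; ties
prefer a W-labelled subject over a scaffold (a gametolog interpretation
over a translocated/mis-assembled one), then higher identity. ΔL is the
absolute length difference between the Z amplicon and the second copy's
subject-side span; it is undefined for absent or partial copies. Role
labels (Z/W/scaffold) always come from a user-supplied side-car map, never
from sequence names — the package reports *where* a copy lies, and makes
no claim about what an unplaced scaffold is.

### Gel model (`gel_model`)

Band migration follows the standard log-size law,

    d(L) = t · V · exp(alpha(g) − beta(g) · ln L)  [mm],

with run time t in minutes, voltage gradient V = 5 V/cm, and per-gel
calibration (alpha, beta) interpolated between the standard 1/2/3%
percentages. beta increases with gel concentration (denser gels sieve
harder); the shipped values are beta = 0.6/0.9/1.2 and
e^alpha = 11/3, 35/3, 400/3 for 1/2/3%, with band half-width sigma =
0.5 mm. Two bands are *separated* when their distances differ by at least
2·sigma; pairs with 0 < |Δd| < 2·sigma are *indistinct* — one smeared
band, the look of a ~10 bp polymorphism on a 2% gel. The calibration was
fit once, by hand, to the qualitative behaviour of the marker panel — an
11 bp difference near 260–380 bp separable only at 3%; a 43 bp difference
near 500 bp separable at 2% after 60 but not 10 minutes; a 413 bp
difference at 923/510 bp separable at 1% within 10 minutes — and frozen
as package defaults. Fragments under 50 bp are outside the calibrated
range and rejected. This is an empirical mobility law, not reptation
physics; intensity, smearing and ladder compression are not modelled.

### Verdicts and sex calls (`marker_eval`)

Every copy-pair report maps to exactly one verdict: `not_found` (no Z
product), `z_only` (no second copy), `partial_copy_only`,
`unresolvable_polymorphism` (ΔL = 0, or no standard gel separates the
pair), `confounded` (a nonspecific product overlaps a diagnostic band
window at the chosen gel), or `informative` at the smallest resolving gel
percentage. The sex-call rule is deliberately asymmetric: two separable
diagnostic bands always mean female, but one band means male *only under
an informative verdict*. Anything else is indeterminate — a missing W
band can equally mean a male, an absent gametolog, an unresolvable ΔL or
degraded template, and a sexing protocol must not default to "male" in
those cases. W-dominant single-band designs are representable and are
confounded unless an internal positive control is declared, for the same
reason. Panel recommendation ranks informative markers by lowest required
gel percentage, then largest ΔL, then fewest notes, then marker id; the
ranking is invariant under input permutation.

## Synthetic data (`synthetic_data`)

The generator builds small Z/W/scaffold sequences with full ground truth:
a plus-strand multi-exon gene on Z with planted primer footprints around a
chosen intron; a second copy per marker with configurable substitution
divergence and one mid-intron indel of signed size ΔL (positive = Z
longer); optional translocated decoys, terminally truncated copies and
planted off-gene nonspecific products. Backgrounds are i.i.d. uniform
ACGT, rejection-corrected until no primer has an unintended site at the
scanner's own tolerance (≤2 mismatches, exact 3' trinucleotide), so the
planted truth is unique. Substitutions never hit primer footprints,
splice-site dinucleotides, or the junction-adjacent bases whose identity
would make an exon boundary ambiguous; second-copy footprints keep their
terminal 8 bases identical to the Z realization so that local-alignment
end-points — and hence the measured copy length — are exact. Degenerate
primer positions are realized differently on the second copy when that
does not create a self-complementary footprint (which would be an
unremovable spurious site). The random stream is partitioned per output
sequence, so enabling a scaffold does not perturb Z/W content at fixed
seed.

Random study conditions (`random_config`) draw 3–6 exons, ΔL uniformly in
±[1, 3000], divergence in [0, 0.05], and 18–24 bp primers with up to two
degenerate positions. Sizes are deliberately small (a few kb per
sequence): they exercise every code path while keeping a 100-condition
sweep in the tens of seconds. What passing on these fixtures shows is that
the *computation* is exact under its stated assumptions; it does not show
robustness to real-genome features the generator omits — repeats and
transposable elements (dense on avian W chromosomes), GC heterogeneity,
assembly errors, or sequencing artifacts.

The packaged worked example (`paper_fixture`) lays a 23-exon CHD1-like and
an 18-exon NIPBL-like gene on a 70.5 kb synthetic Z so that the
seven-marker panel's footprints fall at the published coordinates, and
plants second copies with the published female second-copy lengths (+11 bp
for the intron-22 markers on a scaffold decoy; −2374/−43 bp for introns 9
and 16; −413 bp for the NIPBL intron on W). The SPIN marker M6 has no
planted site anywhere, so the pipeline reports it `not_found`, matching
its unknown location in the assemblies this panel was designed against.
Two companion fixtures cover the remaining copy geometries: equal-length
copies (ΔL = 0) and a 526 bp terminally truncated copy on a 1255 bp
scaffold.

## Numerical and design choices

* Coordinates are 1-based inclusive internally; BED export converts to
  0-based half-open exactly once, at the boundary.
* All orderings (binding sites, products, hits, report rows) are total and
  deterministic, so reruns are byte-identical and diffs are meaningful.
* Smith–Waterman gap cost convention: a length-L gap costs open + ext·L
  (5 + 2L). The test oracle uses biopython with `open_gap_score = −7`,
  `extend_gap_score = −2`, which encodes the same convention.
* The HSP-chaining tolerances (15 bp query overlap, 6 kb maximum join gap)
  bound the indels a single copy may absorb; copies separated by more than
  the join gap are reported as distinct hits.
* `N` handling is uniformly conservative: never a primer match, never a
  seed.
* Band-to-expectation matching in sex calls uses nearest-expected
  assignment with a 5% relative tolerance, so the 378 bp band of a 367/378
  female lane is attributed to the W copy even though both lengths are
  within tolerance of each other.

## Known limitations

* The spliced mapper assumes near-identity; it is not a cross-species
  aligner and makes no attempt at micro-exons shorter than `min_anchor`.
* Thermodynamics are out of scope: no melting temperatures, primer dimers,
  hairpins, or amplification-efficiency modelling; nonspecific products
  enter the evaluation only as observed/planted band lengths.
* The gel model is calibrated to the panel's behaviour on standard
  minigels; extrapolation far outside 1–3% agarose, 50 bp–5 kb, or
  unusual voltages is unvalidated.
* The homology search reports locations against user-provided role
  labels; it cannot decide whether a scaffold is a mis-assembled W
  fragment or a genuine translocation.
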