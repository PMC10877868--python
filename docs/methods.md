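# Methods

This note documents the models and procedures `pulgate` implements, the
choices made where the underlying definitions left room, and what the
synthetic fixtures do and do not establish about real data.

## Sliding-window locus detection

Detection operates on gene ranks along a contig, not base-pair distances:
gene i is the i-th coding sequence by start coordinate. A window of
`window_length` (default 10) consecutive genes advances one gene at a time;
a window is a hit when at least `min_markers` (default 3) of its genes are
markers. Marker status is per gene: at least one GH/PL/CE family, or a
sulfatase, SusC-like, SusD-like or other-TBDT role. GT (glycosyl
transferase), CBM and AA families alone never qualify — transferases are
biosynthetic and binding modules are accessories.

Two reading choices are deliberate. First, the window step is one gene,
the maximally sensitive reading of "sliding". Second, hit windows that
overlap or abut are merged into one maximal locus, then trimmed so that the
first and last genes are markers. Merging reports loci rather than windows
and prevents double-counting; trimming makes spans deterministic and
independent of where the window happened to fall. Contigs shorter than the
window are evaluated as a single whole-contig window, so short contigs can
still host a locus. Windows never span contigs.

Implementation is a prefix-sum count over marker indicators (O(n) per
contig). Tests compare it against a brute-force all-windows enumerator on
random contigs; the two must agree exactly.

## Tier classification

Tiers use strict precedence PUL > PUL-like > CAZyme-rich > unclassified,
making the categories mutually exclusive:

* **PUL**: a *susCD* tandem plus >= 1 degradative CAZyme. A tandem is a
  SusC-like and a SusD-like gene at consecutive gene ranks, in either
  order, and — under the default `same_strand_adjacent` policy — on the
  same strand, the minimal testable form of a co-transcribed pair. The
  `adjacent_any_strand` policy drops the strand requirement. A gene whose
  strand was missing in the GFF is defaulted to "+" with a logged warning
  and disqualifies any strand-aware tandem it participates in.
* **PUL-like**: >= 1 SusC-like, SusD-like or other-TBDT gene plus >= 1
  degradative CAZyme, without a tandem ("at least one" reading; precedence
  removes the tandem case).
* **CAZyme-rich**: >= 3 degradative CAZymes. By default a multi-domain
  gene with k degradative families contributes k to this count, matching
  family-level tallies; `count_genes_not_domains=True` restores strict
  per-gene counting. Precedence guarantees emitted CAZyme-rich clusters
  contain no transporter gene.
* Sulfatase genes count as markers for detection but never as degradative
  CAZymes for the tier tests: they are not GH/PL/CE.

The tier rules are verified by exhaustive enumeration of all role/family
combinations for loci of up to five genes against an independently written
truth table.

## Substrate typing

The packaged family-to-substrate map is a curated approximation of
dbCAN-sub-style assignments over a 15-class vocabulary (beta-1,3-glucan,
alpha-glucan, alginate, xylan, fucoidan, ...). It is a plain TSV and fully
replaceable; subfamily lookups (e.g. GH13_8) fall back to the base family.
Per cluster, each substrate class is supported by the number of genes with
>= 1 degradative family mapping to it; a multi-specificity gene supports
every class it maps to, and degradative genes with no map entry pool under
a reserved "unassigned" class. Output is sorted by descending support then
label, so the headline substrate is deterministic.

The glucan typologies use base families only and ignore families outside
each scheme's hallmark alphabet, since real loci carry accessory genes:

* alpha-glucan, alphabet {GH13, GH31, GH57, GH65, GH77}: type I = {GH13};
  II = {GH13, GH65} optionally + GH31; III = {GH13, GH77, GH57};
  IV = {GH13, GH31}; otherwise none. The four labels are mutually
  exclusive (verified over all 2^5 subsets).
* beta-glucan, alphabet {GH3, GH16, GH17, GH30, GH149, GH158}: GH16-only =
  {GH16}; variant-2 = GH3 together with GH16 and/or GH17 and nothing else;
  variant-1 = at least 3 of {GH149, GH17, GH16, GH158, GH30}. The roster
  of variant-1 admits variations; "at least 3 hallmark families"
  (`variant1_min_families`, tunable) operationalizes that. Precedence
  GH16-only > variant-2 > variant-1 makes the labelling total over all 2^6
  subsets.

## Coverage-weighted gene frequencies

frequency(T) = 100 · Σ_{g∈T} c(g) / Σ_g c(g), with c(g) the per-gene
average read coverage taken as given from the input table (the package
never recomputes coverage from alignments). The statistic is scale
invariant and additive over disjoint target sets, and any partition of all
genes sums to exactly 100 (tested to 1e-9). Substrate-class profiles are
*not* a partition: a multi-specificity gene contributes its full coverage
to every class it maps to, so class frequencies may overlap; the
sum-to-100 invariant is asserted on explicit partitions only. Taxon
stratification splits each class's target set by gene taxon (missing taxa
pool under "unclassified") so components sum to the class total.

## Alpha diversity and ASV–MAG linking

Shannon uses the natural log by default (ecology convention; the base is a
parameter). Simpson returns the Gini–Simpson form 1 − Σ pᵢ²
(`form="dominance"` gives Σ pᵢ²). Chao1 defaults to the bias-corrected
form S_obs + F₁(F₁−1)/(2(F₂+1)), which is defined when F₂ = 0; the classic
F₁²/(2F₂) form is selectable. Good's coverage is 1 − F₁/N. The numerics
delegate to scikit-bio behind validating wrappers; tests check them
against direct formula evaluation. No rarefaction is applied before
estimation; a seeded subsampling helper is provided for sensitivity
checks.

An ASV links to a MAG when it occurs as an exact, mismatch-free substring
of a MAG 16S sequence on either strand — the behaviour of a perfect blastn
hit with 100% query coverage. Ambiguous N bases never match (IUPAC codes
are not expanded), so an ASV containing N cannot link. All 16S copies of a
MAG are scanned and any hit links. Exact links extend to MAGs with
ANI >= 95% (inclusive) to the anchoring MAG, one step only: extensions
never chain, because transitive ANI closure would cross species
boundaries. The ANI table must be symmetric to 1e-6.

## MAG quality tiers

Gates use the exact strict/non-strict operators of the MIMAG standard:
completeness = 90 is not HQ; completeness = 50 is MQ; contamination = 5 is
not HQ; contamination = 10 is not MQ. NEAR_COMPLETE (> 90% / < 5% without
the rRNA/tRNA requirements — the HQ thresholds minus the RNA clauses) is
kept as a separate tier rather than silently merged into HQ; a reporting
flag pools the two for downstream use. Tier assignment is total and
monotone: improving completeness or contamination never lowers the tier.

## Synthetic data

The generators emulate the input shapes of a fractionated bloom study:
Prokka-style GFF3 plus a dbCAN-style annotation TSV, per-gene coverage
TSVs, ASV count matrices with ASV and MAG-16S FASTA pools, a pairwise ANI
TSV and a MAG statistics TSV. Defaults: 5 contigs × 200 genes with five
planted clusters (two laminarin PULs, an alpha-glucan type II PUL, an
alginolytic PUL-like cluster, a xylanolytic CAZyme-rich cluster) separated
by at least one window length of non-marker genes; background markers as
per-gene Bernoulli draws, default rate 0. The background annotation
mixture is 80% degradative CAZyme families, 10% sulfatase, 8% other TBDT,
1% SusC-like, 1% SusD-like — degradative CAZymes dominate real gene pools
and *susCD* genes are comparatively rare. Planted tandems are co-oriented;
all other strands are random. Per-gene coverages are log-normal
(heavy-tailed, like real coverage distributions), then the planted target
class is rescaled so it holds exactly the planted fraction (default 7% for
beta-1,3-glucan) of total coverage — correctness rests on the rescaling,
not the distribution. The community fixture has 9 samples × 100 ASVs
(counts: Poisson of log-normal rates; fractions cycling FL/PA3/PA10),
10 ASVs cut verbatim from the 20 MAG 16S 1500-mers (half
reverse-complemented), 10 one-mismatch decoys, and an ANI table with
extension pairs including one at exactly 95.0 and one at exactly 94.9 to
pin the boundary. Realized diversity values are recorded per sample from
the sampled counts by direct formula evaluation. Each generator draws from
its own stream (master seed + fixed stream id), so outputs are
byte-identical per seed and adding a generator never perturbs another's
fixtures.

What the fixtures do not emulate: real nucleotide composition and
phylogenetic structure (16S pools are uniform random sequences — linking is
content-agnostic by design), read-level noise, assembly artifacts,
chimeric ASVs, and genuinely ambiguous cluster boundaries. Passing tests
therefore establish algorithmic correctness against the stated rules, not
robustness to annotation error in real metagenomes.

Problem sizes used by the test suite and the acceptance script — random
contigs up to 500 genes for the detector-oracle comparison, ten 5-cluster
replicates for noisy recovery, 1000-gene coverage tables, a 100-ASV/20-MAG
linking fixture — were chosen as the smallest scales at which every rule
and boundary case is exercised; all complete in seconds.

## Known limitations

* The packaged substrate map is an approximation; analyses about substrate
  identity inherit its curation. Supply `--map` to replace it.
* Tandem detection considers gene adjacency only; intervening ncRNAs or
  annotation gaps that displace gene ranks can break a biological tandem.
* The PUL-like and CAZyme-rich counts depend on the domain- versus
  gene-counting convention for multi-domain proteins (configurable, see
  above); published tallies rarely state their convention.
* ASV linking requires perfect identity; a single sequencing error or
  intragenomic 16S polymorphism breaks a link by construction.
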