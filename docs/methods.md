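# Methods

This note documents the models, procedures, parameter choices, and known
limitations of `organellekit`.

## Recombination quantification

### Model

A repeat pair is two placements of the same DNA unit R (identity 1.0 in
exact mode); an inverted pair holds the reverse complement at the second
placement. Homologous recombination between the two copies exchanges the
flanking sequence, so four local arrangements can exist around a repeat:
the two reference ("major") contexts m1 = A_up·R·A_down and
m2 = B_up·R·B_down, and the two crossover ("alternative/secondary")
products s1 = A_up·R·B_down and s2 = B_up·R·A_down. For an inverted second
copy the molecule is read on its reverse strand, i.e.
B_up = revcomp(downstream of B) and B_down = revcomp(upstream of B); the
test suite checks the s-paths against a brute-force enumeration of the
inverted-segment crossover molecule. Circular molecules supply wrap-around
flanks; at a linear molecule end the flank truncates and the truncation is
recorded in the path provenance so affected repeats can be excluded.

### Spanning-read classification

Each path is the repeat plus a `flank` (default 1000 bp) on each side. A
read can only discriminate conformations if it covers the whole path, so
classification aligns the full path into the read (edlib infix alignment,
both read orientations) and requires the overall identity **and** the
identity of each of the three path segments (upstream flank, repeat,
downstream flank) to reach `min_identity` (default 0.85). The per-segment
requirement matters for long repeats, where a missing flank would otherwise
cost only a small fraction of the global identity. Reads passing for no
path are `none`; reads whose best major-path and best alternative-path
identities differ by less than `ambiguity_margin` (default 0.02, i.e. 2
identity points) are `ambiguous` and excluded from all counts — this
implements, conservatively and reproducibly, the manual curation step of
removing ambiguous reads. The 0.85 default tolerates ~10–15% long-read
error while rejecting cross-conformation mismaps; both knobs are exposed.

### Quantification

Within each conformation class the two paths count the reads of the path
with the larger count (the two m-paths describe the same molecule
arrangement seen from the two repeat copies, so summing them would
double-count molecules). Percentages are
100·n/(n_major+n_alternative), rounded half-up to two decimals; when both
counts are zero the percentages are undefined (NA) and the repeat is
inactive. Because each class's reads split between its two paths, the
effective denominator is roughly half the spanning reads; the estimator
tests evaluate binomial intervals at that effective n. Note that two
exact-.5 percentages can both round up (99.99 or 100.01 totals occur in
published tables for the same reason).

### MTPT integration verification

A plastid-derived segment is "integrated" when at least one long read
covers the entire segment plus at least `flank` bp of mitochondrial
sequence on both sides, under the same per-segment identity rule. Reads of
plastid origin fail because the flanks are mitochondrial-specific.

## Homology search (MTPT detection)

The aligner is a classic seed-and-extend local aligner: exact
`word_size`-mer matches (default 9) on both strands are chained into
clusters (diagonal drift ≤ 12, query gap ≤ 500), and each cluster is solved
by banded affine-gap local dynamic programming (numba-compiled kernel) over
the cluster's diagonal range plus a 48-diagonal pad, with full traceback
for match/mismatch/gap counts. Windows backed by a single seed are dropped
(two-hit seeding): with ~7k random 9-mer matches between two random 30–60 kb
genomes, single-seed extension would dominate the runtime while true
homologies ≥ 60 bp always produce multiple co-diagonal seeds. When the
clustered band covers more than half of the DP matrix the extension
degenerates to full Smith–Waterman, which makes the optimum provably exact
on small dense-seeded instances — the oracle suite exploits this with
word size 4 against an independent full-DP implementation.

Scoring is reward +2 / penalty −3 with gap open 5 and gap extend 2 under
the BLAST convention (a gap of length g costs 5 + 2g; the open penalty is
charged on opening, the extend penalty on every gap column including the
first). Significance uses E = K·m·n·e^(−λS) with the published gapped
Karlin–Altschul constants for this scheme, λ = 0.625 and K = 0.410 (m, n
are the full genome lengths); hits with E > 1e-5 are discarded and
lower-scoring hits whose query and subject intervals are ≥90% covered by a
higher-scoring hit are subsumed. Low-complexity masking is off by default,
matching the homology-search configuration the pipeline emulates.

Hits are sorted by aligned length and labelled mtpt1…; minus-strand hits
report descending mitochondrial coordinates. Identity bins for reporting:
exactly 100%, ≥90%, ≥80%, <80%. A plastid gene is annotated `complete` when
its full span lies inside the hit's plastid interval and `fragment`
(`-fra`) on any partial overlap. Genome coverage is the union of hit
intervals per genome (overlaps counted once); the raw summed length is
reported alongside because duplicated regions (the plastid IR) legitimately
attract two hits, and the union/raw distinction makes the double-counting
explicit. Direction of transfer is not inferred.

## RNA-editing calling

Reads are assigned to their best-matching spliced CDS (edit distance, both
orientations, ties to the lexicographically smaller gene id) and piled up
column-wise from the alignment: insertion columns in the read are skipped,
deleted columns contribute no count. Calling is entirely on the sense
strand of the spliced CDS, so "C to U" means a sense-strand C→T excess in
RNA reads. Thresholds: minimum coverage 20× for plastid genes and 10× for
mitochondrial genes (lower copy number and expression), minimum support 10%
of depth for the most frequent non-reference base. Positions meeting the
same criteria in the WGS pileup are DNA-level SNPs and are excluded from
editing calls. Efficiency uses total depth as the denominator (all four
base counts), so sequencing-error bases depress efficiency rather than
inflating it. Ties between two non-reference bases are reported once,
flagged ambiguous, and excluded from the 12-type totals rather than
guessed. The efficiency histogram uses bins [0,0.5), [0.5,0.8), [0.8,0.9),
[0.9,1.0] (the last right-closed); the "above 90%" fraction is the top bin
over all sites, reported to two decimals. Replicate RNA libraries are
pooled into one pileup by default; low-expression genes simply fail the
coverage threshold, with no imputation.

## Repeat finder

Exact mode anchors on shared k-mers (k = min(21, min_len)), extends every
anchor to its maximal exact match (direct, or inverted via reverse
complement), deduplicates per diagonal, and suppresses pairs whose both
copies are contained in a longer pair's copies. Circular molecules are
searched on their doubled sequence with second-copy artifacts discarded, so
repeats crossing the origin are found with wrapped coordinates
(end > molecule length denotes wrapping). Near-exact mode collects exact
fragments down to the anchor size, chains co-diagonal fragments across
small gaps, and re-scores the chained span by edit-distance identity
(keep ≥ 0.9 by default); its endpoints are approximate — a chain starts at
the first ≥21 bp exact fragment, so a diverged terminus can shift the
boundary by up to a few tens of bases. It exists because repeat units need
not be fully identical to recombine, but exact mode is the default since
the quantified repeat catalogs behave as exact units. `min_len` defaults to
100 bp — comfortably below the shortest catalogued recombining repeat
(125 bp) without flooding the output. Classification labels pairs ≥1000 bp
`LR` and the rest `SR`, numbering each class by descending length with
(molecule, start) tie-breaks.

## Synthetic data generator

The generator emulates the study inputs at desk scale: two circular
mitochondrial molecules (defaults 60 kb + 40 kb) and one circular plastid
molecule (30 kb), i.i.d. background at GC 0.45, with planted

* repeat pairs spanning the catalog's shapes: 3590 bp direct, 1500 bp
  direct inter-molecular, 322 bp direct, 207 bp inverted, 125 bp direct;
* plastid-derived segments of 5142 bp (5 substitutions — the sparse
  near-identical case), 1410 bp (95% identity), 800 bp (substitutions plus
  1-bp indels), 500 bp (80% identity), 60 bp (95%);
* simple ORFs (ATG + non-stop codons + TAA; alternating strands, every
  fourth gene two-exon) as protein-coding genes;
* editing sites (C→T at codon position 2, which can never create an
  in-frame stop) with per-site efficiencies, and SNPs applied to reads only
  (the assembled reference keeps the reference base, as a real assembly
  would).

Long-read lengths are log-normal (mean 6 kb, σ 0.4) truncated to [200 bp,
molecule length]; reads start uniformly, may cross the origin of circular
molecules, come from either strand with probability 0.5, and carry per-base
substitution/insertion/deletion errors (defaults 5%/1.5%/1.5% — a
Nanopore-like placeholder profile, configurable, since the emulated dataset
documents only read-length statistics). RNA and WGS reads are full-length
copies of the spliced CDS (per-gene depth is therefore exact), with edited
bases appearing per read with the site's efficiency, SNPs in every read,
and a low short-read error rate (0.1% substitutions). FASTQ qualities are
constant placeholders; no stage uses them.

Two deliberate departures from naive random planting keep the truth
well-defined: (1) bases just outside each planted repeat copy and MTPT
junction are forced to mismatch the source continuation (1 base for exact
repeats, 6 for MTPT junctions), because otherwise maximal extension or
local alignment legitimately extends a few bases past the planted
coordinates by chance matches; (2) each planted MTPT keeps a 12 bp exact
terminus, because divergence clustered at a segment end would be trimmed by
any score-maximal local aligner, making the planted interval unrecoverable
in principle rather than in implementation. Everything derives from one
seed (separate numbered streams per stage), and identical configurations
give byte-identical FASTA/FASTQ/JSON outputs.

What the simulation does **not** model: chimeric/adapter artifacts, quality
score structure, coverage bias, heteroplasmy beyond the stated conformation
mixtures, transcript splicing variation, or real genome base composition.
Passing on synthetic data therefore demonstrates algorithmic correctness
under the declared error model, not robustness to every artifact of real
libraries.

## Numerical and reporting conventions

* Internal coordinates are 0-based half-open; all emitted tables are
  1-based inclusive with descending coordinates encoding reverse
  orientation; the conversion is tested in both directions.
* Percentages round half-up to two decimals (`decimal.Decimal`), matching
  the reporting convention of recombination tables.
* Problem sizes in tests and the acceptance script (30–100 kb genomes,
  200–1000 reads per measurement, 200 planted editing sites at 50–200×)
  are chosen so a full run completes in minutes on one core while keeping
  every binomial check well-powered.
* Dense-substitution planted segments can be reported with slightly fewer
  mismatches plus compensating 1-bp gap pairs — two gap columns cost 14,
  less than five mismatches — so exact mismatch-count assertions are made
  only for sparse-substitution segments where gaps can never pay.

## Known limitations

* The aligner reports one alignment per seed cluster; two distinct
  homologies closer than the cluster gap (500 bp on the query) merge into
  one window and only the better-scoring alignment is kept.
* Repeats with identity below the near-exact floor (0.9) are not found,
  though such sequences can recombine at low frequency.
* The conformation model is local: it quantifies arrangement frequencies
  around one repeat at a time and does not reconstruct the full population
  of subgenomic molecules.
* Whether ambiguous reads belong in the reported denominators is not
  universally agreed; this implementation excludes them and reports their
  count separately.
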