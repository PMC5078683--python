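# Methods

## Repeat model

A microsatellite locus is a maximal perfect tandem run of a primitive
unit of 1–6 bp. Three conventions pin the definition down:

* **Primitivity.** The unit must not be a whole-number concatenation
  of a shorter unit. This makes the unit-length assignment unique: a
  poly-A run is mononucleotide only, (AT)n is dinucleotide only. It is
  what keeps count columns additive — without it every dinucleotide
  run of ≥ 8 units would also be counted as a tetranucleotide.
* **Maximality.** A run is reported only if it cannot be extended by
  one full unit on either side; partial trailing units are excluded
  from the span, so `span = unit_length × repeat_count` exactly.
  Sequence boundaries satisfy maximality vacuously.
* **Phase.** The recorded unit is the rotation beginning at the run's
  leftmost base, the label a left-to-right scanner naturally produces.
  Motif classes pair that unit with its reverse complement
  (`tc/ga`; self-reverse-complementary units such as `at` keep a
  single-part label). Rotational phases are deliberately *not* merged:
  `ca/tg` and `ac/gt` stay separate classes.

Scanning is case-insensitive and `N` terminates every run (a repeat
spanning an assembly gap is not a perfect repeat); runs are split at
`N` and each side judged against the threshold on its own. Abutting
runs of different units are all reported; compound/interrupted
microsatellites are out of scope.

Detection thresholds default to **12** repeat units for
mononucleotides and **4** for di- through hexanucleotides — the
settings of genome-wide SSR surveys in palms — and are configurable
per unit length.

The scanner works per unit length k by vectorised comparison of the
sequence with itself shifted by k; a maximal block of equalities of
length m corresponds to a period-k region of m + k bases, reported
when `(m + k) // k` meets the threshold and the leading k-mer is
primitive. For every region long enough to meet a threshold the
primitivity check on the leading unit is equivalent to requiring k to
be the minimal period (a consequence of the Fine–Wilf periodicity
bound), which is what prevents double reporting across unit lengths.

## Primer design

Constraint windows (all inclusive): melting temperature 58–62 °C,
primer length 18–24 bp, GC 45–55 %, expected product 100–250 bp. The
product must contain the whole repeat and primers may never overlap
it ("flanking" is taken literally).

Melting temperatures use two-state nearest-neighbor thermodynamics
with the unified duplex parameter set, entropy-based salt correction,
50 mM monovalent cation and 50 nM oligo — conventional defaults for
primer-design software. Self-complementary oligos automatically
receive the symmetry entropy term. The Wallace 2(A+T)+4(G+C) rule is
available as a cheap alternative but is not used for constraint
checking.

The search enumerates every (forward window, reverse window, length)
combination inside the product budget, scores valid combinations by
the summed absolute distances of both primers' Tm and GC and of the
product size from their range midpoints, and breaks ties toward the
smaller product, then the leftmost forward primer, then the shorter
primers. The scoring rule is a deterministic, reproducible stand-in
for a proprietary picking heuristic; nothing downstream depends on
*which* valid pair is chosen, only on constraint satisfaction.
Failures are classified: `insufficient_flank` when fewer than 18
bases exist on either side (distinguishable because it is the
dominant failure mode near contig ends), `product_size` when the
repeat itself is too long for the product window, otherwise the
constraint (`gc_out_of_range` / `tm_out_of_range`) that rejected the
most candidate windows. No dimer/hairpin screening is performed
(out of scope).

## Electronic PCR

Stringent mode (the default, and the only mode any result depends
on): gap-free Hamming matching with at most **1 mismatch per
primer**, `N` never matching anything; amplicons are
orientation-consistent convergent site pairs (either primer may bind
either strand) whose sites do not overlap, with
`|size − expected| < 100` as a **strict** inequality. All qualifying
pairings in all records count toward copy number, classified 1 / 2 /
3 / >3; zero products means the marker failed the screen and has no
class. An optional 3'-protect window forbids mismatches in the last
bases of a primer (on the minus strand this is the window's
low-coordinate side); it defaults to 0 because only a mismatch
*count* is specified by the screening protocol this mirrors.

A permissive mode (2 mismatches, 1 gap — the classic genome-screen
defaults) is available behind `max_gaps > 0` and uses banded edit
distance with a combined substitution+gap budget; it reports
best-distance hits per end position rather than every suboptimal
alignment, which is adequate for its exploratory purpose. No
acceptance property depends on it.

The self-screen against the source genome uses the same size window
as the cross-genome screen.

## Conservation pipeline

Stage order is fixed: mine A → design → self-ePCR on A (keep pairs
with ≥ 1 product) → ePCR on B → conserved = ≥ 1 qualifying product in
both genomes. Copy-number class in B is reported, never filtered on —
multi-copy conserved markers are still conserved. Because the
headline rate's natural denominator is ambiguous (designed pairs vs
self-amplifying pairs), the report carries both
`conservation_rate_vs_designed` and
`conservation_rate_vs_self_amplifying`. Survivor counts are asserted
to form a funnel on every run. Wet-lab transferability enters only as
a calculator over a user-supplied marker × species 0/1 matrix
(missing entries drop out of that marker's denominator); the package
never simulates gels.

## Genome context

Windows of 1 Mb (so counts read directly as per-Mb densities) tile
each sequence; the final partial window keeps its true span so spans
sum to the sequence length. Features are binned by start coordinate —
the simplest convention consistent with per-Mb density tables; a
feature starting exactly on a boundary belongs to the right-hand
window (half-open intervals). Pearson correlations between the SSR
track and the gene/TE tracks are computed per chromosome over its
windows and reported as undefined when a track is constant.

Genic context is decided by the locus start position with precedence
**CDS > UTR > intron** pooled across all overlapping isoforms; inside
a gene span but in no exon is intron; outside every gene span is
intergenic. 5' and 3' UTRs are collapsed into one UTR class. GFF3 is
converted from 1-based inclusive to the package-wide 0-based
half-open convention exactly once, at parse time.

## Synthetic data generator

The generator emulates what the method needs from a genome and no
more: an i.i.d. background at a requested GC content (default 0.5),
planted SSR loci and planted primer-target cassettes at exact,
recorded coordinates. Bases immediately flanking a planted repeat are
chosen to break both a full-unit extension and any run continuing
through the boundary, so planted loci are recovered exactly as
planted; chance repeats arising in the background are legitimate loci
and the reference truth for them is the brute-force oracle, not the
planting list. Divergence applies i.i.d. substitutions (default rates
used in tests: 0–10 %) and optional geometric-length indels, with a
ledger of every event so the fate of each planted feature is
computable.

What the generator does **not** emulate: composition heterogeneity
(isochores, repeat families), TE-driven repeat expansion, assembly
artifacts, and the strongly non-uniform real motif spectrum. Passing
tests therefore demonstrate correctness of the algorithms under known
truth, not genome-scale biological statistics; the genome-scale
percentages in the acceptance outputs are recomputed from the palm
study's printed totals, which act as inputs.

## Numerical and testing choices

* Coordinates are 0-based half-open everywhere internally; 1-based
  inclusive only inside GFF3 files.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); reports reproduce bit-for-bit.
* Determinism of primer choice comes from the total ordering on
  (score, product, position, length); floating-point Tm enters the
  score but equal-score ties are broken on integers.
* Test problem sizes: oracle-equivalence suites use 200 random
  sequences of 1–10 kb (repeat finder) and 200 random
  genome × primer × mismatch-budget cases (site search); pipeline
  properties run on 12–25 kb genomes with ~24 planted loci; the
  divergence trend uses a 0–10 % substitution grid with five seeds
  per level. These sizes keep every property sharply decidable while
  the suite stays quick.
* BED parsing is a deliberate ~20-line reader so malformed lines can
  be reported with their line number; FASTA and GFF3 go through
  Biopython and gffutils respectively.

## Known limitations

* Imperfect, interrupted and compound repeats, and units > 6 bp, are
  not detected.
* The Tm model ignores divalent cations and dNTP binding; constraint
  windows, not absolute accuracy, are what matters here.
* The permissive gapped ePCR mode reports best hits only (see above).
* Conservation is defined for exactly two genomes; multi-genome joint
  screens are out of scope.
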