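# Methods

`biomemory` simulates a DNA-based associative memory: an in vitro
protocol that "learns" the sequence content of a genomic sample with
random-probe primed extension and "recalls" it by microarray
hybridization. This note records the model, its assumptions, the
parameters that matter, and the choices made where the underlying
protocol leaves the design open.

## The system being modeled

A *memory tag* is a 40-nt synthetic oligo: a fixed 20-base
non-crosshybridizing (NCH) tag carrying a 5' biotin or amine
modification, followed by a 20-base fully randomized probe (R20). The
R20 population spans 4^20 ≈ 1.1 × 10^12 distinct sequences; at 1.6 μM
in a 50 μL reaction there are ≈ 4.8 × 10^13 strands
(conc × volume × Avogadro), i.e. a few tens of copies of every
distinct probe, so essentially every stable probe-target pairing is
realized by some molecule.

Learning (A → E → D): denatured, DNase-I-digested input DNA
(~200-base single strands) is annealed (A) with the tag library; Klenow
fragment (E) trims each annealed primer's unpaired 3' tail back to the
duplex and extends it 5'→3', copying the template to its 5' terminus;
Exo I (D) digests unbound single strands; streptavidin beads retain the
5'-modified molecules. The retained pool — tag + complement of a
template suffix region — is the stored memory. Recall prints learned
pools as replicate microarray spots and hybridizes fluorescently
labeled fragments of a new sample against them; spot intensity reads
out sequence similarity.

## Duplex thermodynamics

Perfect-match duplex stability uses the unified SantaLucia-1998
nearest-neighbor table (ΔH, ΔS summed over dinucleotide stacks plus
terminal initiation penalties; self-complementary sequences detected
and given the symmetry entropy term). The melting temperature at 1 M
Na+ is

    Tm = ΔH·1000 / (ΔS + R·ln CT)   [K]

with CT the probe strand concentration (default 1.6 × 10⁻⁶ M). The
**excess-oligo convention** (R·ln CT rather than R·ln CT/4) is used
deliberately: the probe species is in large excess over any individual
genomic site, and this convention reproduces the vendor-tool stability
anchors the protocol was designed around (maximum 5-mer Tm ≈ 31 °C,
mean 7-mer Tm ≈ 26 °C at the learning condition), where the
equal-strands CT/4 convention lands ~5 °C low across the board.

Salt effects follow the Owczarzy decision tree on the 1/Tm scale:
monovalent-dominated, competitive, and magnesium-dominated regimes
selected by R = √[Mg²⁺]/[mon]. Free magnesium is `max(mg − dntp, 0)`
(dNTPs chelate Mg²⁺ stoichiometrically); at the default condition
(10 mM Na⁺, 10 mM Mg²⁺, 4 mM dNTPs) the reaction is Mg-dominated with
6 mM free Mg²⁺. The implementation is validated in the test suite
against an independent stack-by-stack manual summation (to 1e-6 °C)
and against Biopython's `Tm_NN` with the same table and correction.

Population statistics over all k-mers are exhaustive for k ≤ 10. For
larger k the mean is estimated from a seeded uniform sample, while the
exact minimum and maximum are found by exhausting the A/T-only and
G/C-only two-letter subspaces (2^k sequences; the subspace property is
verified against full enumeration for small k). Under this model the
exact population minimum for 20-mers at the learning condition is
≈ 38.5 °C (the TA-alternating repeat), a few degrees below the ~42.6 °C
figure a manual web-tool sample of random 20-mers produces — a finite
sample minimum sits above the true population minimum.
`min_stable_anchor_length(T, stat)` returns the shortest k whose
population statistic reaches T; with `stat="mean"` it answers "how long
must a typical duplex be" (7 bases at 25 °C), with `stat="max"` it is
the admissibility floor used by the annealing search (no window shorter
than this is stable at T for any composition).

## Annealing model

Annealing sites are **exact reverse-complement windows** between a
probe's R20 region and a template, with window Tm ≥ the annealing
temperature and length ≥ k_min = 5. Mismatched duplexes are not
modeled; the NCH tag region of the primer is assumed inert (only
positions ≥ 20 of the 40-mer may pair), with `nch_screen` as a guard
that reports the longest complementary match of the tag in a pool.

The search is seed-and-extend over 2-bit packed window codes with the
seed length adapted to the temperature's admissibility floor; window
lengths between the floor and the seed length are caught by auxiliary
passes that query only probe windows already stable at T (Tm lookup
tables over all 4^d d-mers, d ≤ 10). The candidate set is the set of
*maximal* matching runs, admitted by the full-window Tm;
`enumerate_annealing_sites(all_windows=True)` expands every qualifying
sub-window for oracle comparisons against brute-force enumeration.

When one tag has several admissible sites, one is drawn with Boltzmann
weights exp(−ΔG°/RT) from the window's exact NN sums at the annealing
temperature, so longer/stronger duplexes dominate. Template occupancy
is exclusive: a template interval hosts at most one primer, with tags
processed in seeded random order. Tags may also serve as templates for
other tags (the M-M by-product channel); a learning run enumerates
fragment and tag templates together so the two channels compete for
primers.

## Protocol-step semantics

* **Extension** consumes an annealed complex: the primer's 3' tail
  (bases beyond the duplex) is removed, and the template's 5' region is
  copied, giving product = primer[0, p+d) + revcomp(template[0, w)).
  Product length is therefore 25-40 nt (retained prefix) plus 0 to the
  template's full 5' overhang. Tag-on-tag extension is bounded at
  25-75 nt by the 40-nt template — inside the 5-80 nt window expected
  for these by-products and always below the >80 nt (LP_H) class, which
  is why tags-only negative controls never produce LP_H.
* **Exo I digestion** removes every molecule not protected by a stable
  duplex. Extended products and their bound templates survive;
  annealed-but-unextended complexes do not — their anchor Tm (typically
  ≤ 31 °C) is below the 37 °C digestion incubation, so they dissociate
  and are digested. This is the mechanism behind the reaction-order
  result: A→D(→E) destroys the complexes before extension can lock
  them, so digestion-first runs learn nothing, while A→E→D retains the
  extended products.
* **Bead separation** keeps molecules whose sequence begins with the
  modified NCH tag. Input-input extension products carry no 5'
  modification and are never retained (they are not materialized).
  Exo-protected template *tags* of M-M complexes are retained as 40-nt
  molecules, which is why the 40-base band persists in tags-only runs.

Digestion is modeled at molecule granularity (a duplex protects the
whole complex); single-base exonuclease kinetics, polymerase errors,
strand displacement and thermal-cycling amplification are not modeled
(the per-event copy number is 1).

Temperature behavior: absolute yields of both desired products and
tag-tag by-products fall as the annealing temperature rises (stable
anchors become rarer); by-products fall ~30-fold from 25 to 55 °C in
the default sweep, reproducing the rationale for annealing at 55 °C.
Because both channels obey the same random-match statistics, the
*relative* M-M share of extended products changes only weakly (a
window-edge effect), so purity claims are reported as absolute counts.

## Recall signal model

A labeled probe fragment contributes to a spot when it shares with some
learned product a contiguous exact-complement window of at least
`k_min_hyb = 18` bases whose Tm reaches the effective hybridization
stringency (default 55 °C). Two thresholds, two reasons: the Tm
condition is the thermodynamic stability requirement, and the length
floor encodes array specificity — retention of a long labeled target
through hybridization and washing requires extensive contiguous
complementarity, not the 8-14-base chance words that any two random
strands share in abundance. (Physically, the hybridization buffer's
37.5% formamide and the low-salt washes put the effective stringency
far above the ambient incubation temperature.) With an 18-base floor,
chance cross-matches between 10^3-product pools and 10^3-fragment probe
sets contribute a few signal units, while true product-probe overlaps
(50-200 bases, Tm ≥ 70 °C) contribute thousands — the separation that
makes the 0% titration spot dark and matching spots bright.

Expected spot signal sums, over qualifying (product, probe) pairs, the
two-state duplex occupancy θ of the best shared window times the
probe's dye count (Binomial(purines, 0.05) per fragment — purine-
targeted labeling at roughly one dye per 40 bases), scaled by the spot
dilution and saturated against a finite spot capacity (2 × 10^5 units,
Langmuir-style `cap·(1−exp(−x/cap))`). Observed intensities add
lognormal local background (mean 400 units, shape σ = 0.25); BSI is raw
minus the local background estimate, and SNR = BSI divided by the
background standard deviation, with detection at SNR > 3. The scanner
PMT gain preset multiplies raw and background alike, leaving SNR
invariant. Absolute intensity units are arbitrary (hardware-specific);
SNR-based detection is the transferable readout. The background shape
is set so blank and mismatched spots cross SNR 3 in well under 5% of
replicate scans.

## Synthetic inputs and simulation scale

The default study system is two synthetic 100-kb genomes with i.i.d.
bases at GC 0.50 and 0.43 ("strain A"/"strain B" stand-ins). At k = 14
they share < 0.2% of k-mers — far below the few-percent commonality of
real unrelated bacterial genomes, and well under the 6% premise for
discrimination. What the generator does **not** emulate: repeats, GC
skew, codon structure, shared mobile elements, or any homology between
strains. Passing tests therefore show the protocol logic discriminates
content-disjoint inputs at the modeled stringencies; real genomes with
genuine shared content would raise the cross-hybridization floor in
proportion to their long shared windows (the k-mer commonality table
quantifies exactly this risk, and the same pipeline runs on real
assemblies via FASTA input).

Fragmentation is memoryless Bernoulli nicking per backbone bond per
strand at rate 1/200 (geometric inter-nick lengths, ~200-base mean as
in the digested input), with both strands retained after denaturation.
Mixtures subsample fragments with replacement at stated mass fractions.

Simulation scale is chosen for statistical stability within desk-scale
runtimes: 10^3 tags for the reaction-order and temperature-sweep
experiments (abundant 25 °C anchors make every tag productive), and
3 × 10^4 tags with 10^3-fragment pools for recall experiments, giving
~10^3 extended products per learned pool at 55 °C. Titrations learn
each fraction three times independently (fresh mixture and tag draws)
and pool 10 replicate spots per learning, so fraction means are stable
enough for the monotonicity of expected signal in the mixture fraction
to show through shot noise. GC-richer content is preferentially
captured at high annealing stringency (stable anchors are GC-biased),
so a GC 0.50 target in a GC 0.43 background is learned slightly
super-proportionally — a real property of stringency-filtered random
priming, worth remembering when comparing strains of unequal GC.

## Numerical and degenerate-input choices

* Temperatures are °C at every API; Kelvin only internally.
* Tm of sequences shorter than 2 bases is undefined (error); k-mer
  statistics require k ≥ 2; anchor scans return a sentinel of 40 when
  no length reaches the temperature.
* Empty fragment pools are legal everywhere (negative controls); empty
  learned pools print as dark spots.
* Occupancy conflicts resample among a tag's remaining free sites;
  a tag with all sites occupied anneals nowhere that run.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; experiment drivers derive child seeds from
  one root via `SeedSequence`, so every table is bit-reproducible.
* Probe/template window codes pack 2 bits per base into int64 (k ≤ 31),
  and k-mer sets store packed codes exactly — set sizes are exact
  counts, not sketch estimates.

## Known limitations

* Exact-match annealing understates the promiscuity of real random
  priming (mismatch-tolerant duplexes); the compensating choice is the
  stability-threshold admission rule, which reproduces the protocol's
  observed temperature behavior but not absolute wet-lab yields.
* Gel-band intensities and absolute array intensities are wet-lab
  observables outside the model; only counts, length classes, and
  SNR-scale detection are simulated.
* The vendor tool used to design the original protocol implements a
  proprietary variant of the NN model; published stability figures are
  matched within a ±2 °C band except the R20 population minimum, where
  the exact subspace minimum is intrinsically below any sampled
  estimate (see the thermodynamics section).
* The NCH tag is taken as given and screened, not designed; tag-design
  algorithms are out of scope.
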