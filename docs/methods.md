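# Methods

## Overview

`sipreads` simulates the read libraries recovered from density-gradient
fractions of a DNA stable-isotope-probing (SIP) experiment. The simulation
pipeline is: shear each reference genome into fragments; place every
fragment in an equilibrium CsCl gradient (buoyant density from G+C, shifted
by isotope incorporation, broadened by diffusion, contaminated by a
diffusive boundary layer); compute each fragment's recovered abundance in
the sequenced BD window(s); and allocate and generate paired-end reads
weighted by those abundances. A shotgun control uses identical inputs but
sets each fragment's abundance to its parent reference's abundance, with no
gradient step.

The gradient is assumed to be at equilibrium; rotor acceleration profiles,
gradient formation kinetics and temperature gradients are not modeled.

## Gradient physics

**Buoyant density.** Unlabeled DNA of G+C fraction *g* bands at
ρ_t = 0.098·g + 1.66 g/ml, mapping G+C ∈ [0, 1] onto BD ∈ [1.66, 1.758].
Isotope incorporation adds A·δ, where A is the atom fraction excess and
δ = 0.036 g/ml for ¹³C, 0.016 g/ml for ¹⁵N. Atom % excess is stored
internally as a fraction in [0, 1]; user tables give percent and are divided
by 100 at parse time, so A = 1 produces the full δ shift.

**Diffusion.** The lumen population of a fragment of length *l* bp is
normal around ρ with σ = √(ρRT/(β²·G·M_c·l)), using β = 1.14×10⁹,
G = 7.87×10⁻¹⁰, M_c = 882 g/mol and R = 8.314 J/(mol·K) by default. A note
on units: with β and G in their customary CGS conventions, a gas constant in
erg/(mol·K) (8.314×10⁷) would give band widths ~3×10³ larger (σ ≈ 2×10⁻³
g/ml for a 10 kb fragment, the classic analytical-ultracentrifugation band
width). We keep the J/(mol·K) default for consistency with the constant set
above, and expose `gas_constant` in `GradientParams` and the config so
either convention can be selected explicitly. All downstream behavior
(conservation, window recovery, profile peaks) is internally consistent
under either choice; smaller σ simply makes banding sharper relative to
fraction widths.

**Model gradient.** A fragment of density ρ bands at radius
x = √(2β(ρ − D)/ω² + I²) from the axis of rotation, where D is the average
gradient density, ω the angular velocity, and I the isoconcentration point
I = √((r_min² + r_min·r_max + r_max²)/3). The model gradient is implemented
analytically as the exact algebraic inverse, ρ(x) = D + ω²(x² − I²)/(2β),
so position↔BD round-trips are identities to machine precision (< 10⁻⁹
asserted; nothing in the package asserts below 10⁻¹²). A tabulated variant
(`ModelGradientTable`, configurable step) exists for parity checks against
interpolation-based implementations. Densities below the floating point of
the gradient raise an out-of-gradient error carrying the offending ρ; such
fragments contribute zero to every window.

**Diffusive boundary layer (DBL).** During deceleration the gradient
reorients, and a thin layer of solution trapped along the tube wall does not
move with it; DNA in that layer contaminates the fractions it intersects. A
band at radius x touches the wall of the angled tube over a range of
positions measured along the tube from its bottom tip. In the cylindrical
section both bounds follow the linear wall-contact formulas; in the rounded
(hemispherical) bottom they follow the arcsine formulas. Each bound switches
independently from the cylindrical to the rounded-bottom formula when its
cylindrical value falls below the cylinder/hemisphere junction at one tube
radius from the tip — the deep bound switches at x = r_max − r_t(1 + cos θ)
and the shallow bound at x = r_max − r_t(1 − cos θ) — which makes the two
formula pairs agree exactly at the crossover (continuity is asserted to
10⁻⁶ cm and holds to rounding error). Each contact bound is then converted
to a BD by taking the extreme lumen radius present at that tube level
(tube-axis radius ± r_t·cos θ in the cylinder; the sphere cross-section
extremes in the bottom) through the model gradient; the band's own ρ is
additionally included in the range, since the trapped layer at the contact
point sits in solution of the band's density. This construction guarantees
that the DBL BD range always brackets the fragment's ρ.

The DBL mass fraction p_DBL is a single user-supplied scalar applied to all
fragments (default 0.001): empirical relationships between rotor/tube
properties and DBL size are not established, so no attempt is made to model
them. The DBL mass α·p_DBL is treated as uniform over its BD range.

## Window recovery

For a window (ρ_min, ρ_max):

- lumen: p_LR = Φ((ρ_max − ρ)/σ) − Φ((ρ_min − ρ)/σ);
  α_L = α(1 − p_DBL)·p_LR
- DBL: α_DBL = (clipped window width / DBL BD width)·α·p_DBL, where the
  window is first intersected with the DBL BD range. The literal
  (unclipped) proportionality can exceed the total DBL mass when the window
  is wider than the DBL range, so clipping is the default; the literal form
  remains available (`clip=False`) for parity runs.
- total: α_f = α_L + α_DBL. Summing α_f over a contiguous fraction set
  covering the band (±8σ) and the DBL range recovers α to 10⁻⁴ relative.

Read abundance is α_r = α_f·l_f/(2·l_r) — the number of read-pair slots on
the fragment times its window abundance. Fragments shorter than the read
length are excluded from the normalization (with a logged count), resolving
the implicit l_f ≥ l_r assumption.

## Fragmentation

Fragment lengths follow a configurable family: uniform (low/high bounds),
normal (clamped), truncated-normal, or skew-normal
(location/scale/shape), the latter two truncated by rejection with a
1000-resample cap before clamping (logged). Each pass tiles every scaffold
left-to-right from a random phase offset drawn in [0, mean length); the
sub-offset leading piece is emitted as its own fragment (merged into the
first tile when shorter than `min_bp`) and a trailing remainder shorter
than `min_bp` is merged into the final tile, so each pass covers each
scaffold exactly once and positional coverage is near-uniform. Passes
repeat, stopping at fragment granularity, once summed fragment bases reach
the requested fold coverage times the reference length — "coverage" counts
summed fragment bases over reference bases, overlaps included.

Coordinates are 0-based half-open internally; FASTA headers carry 1-based
inclusive coordinates. G+C is computed over the fragment window only, with
ambiguous bases excluded from the denominator; fragments more than 50%
ambiguous are dropped with a warning. Circular chromosomes are treated as
linear (no origin-spanning fragments). Scaffolds shorter than `min_bp`
fall back to a single whole-scaffold fragment.

## Communities, labeling, fractions

Community tables are long-format TSV (sample_id, reference_id, abundance);
abundances must sum to 1 within 10⁻⁶ (renormalized with a logged note when
off by ≤ 10⁻³, rejected otherwise). The generator draws a lognormal
rank-abundance curve (defaults: median relative abundance 2%, log-SD 0.8)
and pairwise-swaps 10% of rank positions, emulating replicate-to-replicate
variation.

Atom % excess is drawn **per fragment** from Normal(mean, SD) (defaults in
the fixture experiments: mean 90, SD 5 for labeled genomes; exactly 0 for
unlabeled), clamped — not rejection-sampled — to [0, 100] so the mean is
not biased near the boundaries; the appropriate oracle for the draw mean is
therefore the censored-normal mean. Per-fragment (rather than per-genome)
draws smear labeled peaks slightly; this is a deliberate choice, since
labeling heterogeneity exists within a population's DNA.

Fraction sets partition [ρ_min, ρ_max] into contiguous windows with widths
drawn from Normal(0.004, 0.0003) g/ml truncated at 0.002 by default,
mimicking typical empirical fraction tables; explicit boundaries can be
given instead. Fraction-based mode runs the window simulation once per
fraction, re-using one fragment set.

## Read generation

Read pairs are allocated to fragments by one multinomial draw of
`total_pairs` over normalized α_r (depth is exact, not Poisson). Insert
size is defined as total template length (the common Illumina convention),
drawn per pair from Normal(mean, SD) — case-study-style defaults 1000 ± 5
bp with 151 bp reads — rounded and clamped into [read length, fragment
length]; the template start is uniform over the admissible range. A fair
coin decides which physical template end is written as mate 1; mate 1 is
always in reference orientation and mate 2 is the reverse complement of its
window, so both mates re-extract exactly from the header coordinates.
Reads may span fragment boundaries within the template but never a scaffold
end.

Randomness is derived per (sample, window, fragment) from the master seed
via `numpy` seed sequences, so libraries are bit-identical across runs and
across worker counts; pair identifiers are assigned in fragment order after
allocation. Fragments stream per reference; the full read set is never held
in memory at once beyond a single library.

## Error model

FASTA output is error-free. FASTQ conversion applies substitution-only
errors — never indels, so read length, order and pairing are preserved —
with per-cycle probabilities from parametric curves: flat, linear ramp, or
logistic tail degradation, with presets `novaseq-like` (0.05%→0.4%),
`hiseq-like` (0.1%→0.8%), `miseq-like` (0.1%→1.2% linear) and `flat`.
These parametric curves are this package's own error model, designed to be
fully specified by a handful of numbers and testable in closed form.
Substituted bases are uniformly chosen among the three alternatives;
ambiguous bases (N) are left untouched. Quality scores are drawn per cycle
from Normal(mean, SD), clamped to Phred [2, 41], encoded Phred+33.

## Synthetic genomes

The generator emulates intra-genomic G+C heterogeneity with a blockwise
drift model: each 10 kb block's G+C target is jittered (Gaussian, default
SD 0.03) around the genome target, bases drawn independently within blocks,
and the realized whole-genome G+C corrected to within 0.5 percentage points
of target. It does **not** reproduce codon structure, repeats, k-mer
composition, operon-scale G+C features, or real inter-genome sequence
similarity — so passing tests demonstrate the gradient physics, abundance
accounting and read-generation contracts, not assembler- or binner-level
realism. Conclusions about assembly/binning performance on real communities
require real (or much richer) references.

## Default physical parameters

Standard DNA-SIP centrifugation conditions serve as defaults: 55,000 rpm,
20 °C (293.15 K), average gradient density 1.70 g/ml, and a TLA-110-like
fixed-angle rotor geometry — r_min 2.6 cm, r_max 4.85 cm, tube radius
0.65 cm, tube angle 28° from the axis of rotation. Geometry and angle units
must be declared explicitly in the config (`length_unit`, `angle_unit`);
rotor speed may be given as `rpm` or `angular_velocity`. All physics is in
double precision.

## Problem sizes in the test suite

Tests run on synthetic fixtures sized for completeness of coverage rather
than realism: communities of five 60–100 kb genomes, 10³–10⁵ read pairs per
library, 10⁶ Monte-Carlo molecule placements, and ≥10⁶ bases for error-rate
calibration. Statistical checks use 3-SE bands against exact sampling-theory
oracles (binomial for occupancy and mismatch rates, censored-normal for
clamped labeling draws).

## Known limitations

- p_DBL is constant across fragments and user-supplied; no empirical model
  of DBL size exists.
- No PacBio/Nanopore long-read simulation; no PCR duplicates, chimeras,
  adapter artifacts, or context-dependent errors.
- No phylogenetically structured community generation or time-series
  designs.
- The gradient-profile comparison against published isolate studies
  requires external genome downloads and figure digitization and is out of
  scope; profile validation here uses synthetic genomes only.
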