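# sipreads

Simulate paired-end sequencing read libraries from **metagenomic
stable-isotope-probing (SIP)** experiments.

In DNA-SIP, microbial communities are fed a substrate enriched in a heavy
isotope (¹³C or ¹⁵N). Organisms that assimilate it build denser DNA, which
bands deeper in an isopycnic CsCl gradient after ultracentrifugation.
Sequencing a *heavy* buoyant-density (BD) window — or each gradient fraction
separately — enriches for the genomes of the active organisms. Planning such
experiments is hard: banding depends on genome G+C, labeling level, gradient
conditions, and the window chosen, and real experiments are slow and
expensive. `sipreads` generates the read libraries such an experiment would
produce, so that experimental designs and downstream assembly/binning
pipelines can be tested in silico — along with matched conventional shotgun
libraries from the same community for comparison.

## Model

For a DNA fragment of G+C fraction *G+C* and length *l*:

- theoretical BD: ρ_t = 0.098 (G+C) + 1.66 (g/ml)
- isotope-adjusted BD: ρ = ρ_t + A·δ, with atom fraction excess A ∈ [0, 1]
  and δ = 0.036 g/ml (¹³C) or 0.016 g/ml (¹⁵N)
- diffusive band width: σ = √(ρRT / (β²·G·M_c·l))
- equilibrium radius: x = √(2β(ρ − D)/ω² + I²), with isoconcentration point
  I = √((r_min² + r_min·r_max + r_max²)/3); the model gradient is the exact
  inverse, ρ(x) = D + ω²(x² − I²)/(2β)

A window (ρ_min, ρ_max) recovers the **lumen** population through the normal
CDF, α_L = α(1 − p_DBL)·p_LR, and a **diffusive boundary layer (DBL)**
population smeared along the tube wall, α_DBL, computed from the wall-contact
geometry of the band in the fixed-angle tube (cylindrical and rounded-bottom
sections). The fragment's window abundance is α_f = α_L + α_DBL, its read
abundance α_r = α_f·l_f/(2 l_r), and read pairs are allocated multinomially
over fragments, placed with a normal insert model, and written as paired
multi-FASTA (or FASTQ with a substitution-only error model — no indels are
ever introduced). A shotgun control sets α_f = α, bypassing the gradient.

## Worked example

Everything needed for a run can be generated synthetically:

```bash
sipreads make-fixtures --outdir demo --seed 7 --total-pairs 50000
sipreads simulate-sip     --config demo/config.yaml
sipreads simulate-shotgun --config demo/config.yaml
```

which prints

```
sample_1	heavy	50000 pairs	sample_1_heavy_R1.fasta	sample_1_heavy_R2.fasta
sample_1	bulk	50000 pairs	sample_1_bulk_R1.fasta	sample_1_bulk_R2.fasta
```

The fixture community has five 100 kb genomes with G+C targets 35–65%; the
40% G+C genome is fully ¹³C-labeled. Tallying reads per genome from the R1
headers gives the per-genome read shares:

| genome         | shotgun | SIP 1.72–1.77 g/ml |
|----------------|---------|--------------------|
| genome_gc35_1  | 0.0858  | 0.0000             |
| genome_gc40_2 (labeled) | 0.1246 | 0.1934    |
| genome_gc50_3  | 0.0810  | 0.0001             |
| genome_gc60_4  | 0.1850  | 0.0929             |
| genome_gc65_5  | 0.5236  | 0.7136             |

The labeled 40% G+C genome is enriched in the heavy window (0.12 → 0.19): at
full labeling it bands at 1.699 + 0.036 = 1.735 g/ml, inside the window.
Unlabeled low/mid-G+C genomes all but vanish, while the unlabeled 65% G+C
genome *gains* share — high-G+C DNA bands heavy naturally, the classic
contamination that makes window choice matter. Per-fraction banding can be
inspected directly:

```bash
sipreads gradient-profile --config demo/config.yaml \
    --reference genome_gc40_2 --out demo/profile.tsv
# peak fraction F19 at BD 1.7328 g/ml
```

Each run writes a `manifest.json` with every resolved parameter, per-file
SHA-256 checksums and read counts; the same seed reproduces libraries
bit-for-bit at any worker count.

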