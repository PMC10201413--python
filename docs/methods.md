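# Methods

## The twin replacement-PCR model

`ubpseq` analyses DNA carrying the hydrophobic unnatural base pair TPT3–NaM
(X = NaM, Y = TPT3) through the signatures left by two replacement-PCR
regimes. The bridge base isoTAT pairs with both NaM and G, so amplification
with isoTAT + NaM rewrites the pair as G–C (the NaM strand reads G); NaM
alone preferentially inserts opposite A, rewriting the pair as T–A (the NaM
strand reads T). A TPT3-only regime produces no usable signature and is
modelled as a near-uniform outcome. The package represents these regimes as
`TransformationModel`s: a probability vector over {A,C,G,T} for the base
written at a sense-strand X, optionally per flanking context (upstream
3-mer, downstream 3-mer), plus a retention parameter. A pair written as Y on
the read strand is handled by symmetry: the outcome is sampled for the X on
the complementary strand (with reverse-complemented context) and
complemented back, which yields the C/A read-strand signature.

The dual-location caller compares the two product sequences (or trace base
calls) positionally; unequal lengths fall back to global alignment (match
+1, mismatch −1, gap −2) with gapped columns excluded, since the chemistry
conserves length. The verdict table is exact: (G,T) → pair on the read
strand, (C,A) → pair on the complement, equal bases → natural, anything else
→ ambiguous, with a supplied reference used to downgrade one-sided or shared
changes to ordinary mutations. Secondary trace peaks at ≥20% of the primary
(configurable) mark mixed sites — partial retention or mutation in vivo.

## Retention estimators

**Signal attenuation.** Under unnatural-base PCR, molecules still carrying
the pair terminate Sanger signal at the site. With L and R the mean
all-channel intensities over an 11-position window before and after the site
(defaults 35–45 and 100–110, 1-based, mirroring standard practice of
averaging a fixed pre-site window), retention is `F = 1 − clamp(ratio, 0,
1)` where `ratio = (R/L) / (R/L of a natural-template control)`. Ratios
slightly above 1 under noise clamp to F = 0 with a warning; absent a control
the normalisation factor is 1, also warned.

**Mixture standard curve.** Fully bridge-converted product is mixed with
natural template at fractions 100, 90, …, 20, 0 % and traced; the response
of each trace is its site C-channel signal divided by the 100% sample's
(R/L′). The curve is fit response-on-fraction by OLS and inverted for
prediction (classical calibration), clamping to [0, 100] and warning on >10%
extrapolation beyond the calibrated response range. Because only molecules
that retained the pair convert to C–G under bridge PCR while mutated
molecules carry their mutation base, the converted fraction of a recovered
plasmid's bridge product *is* its retention. Estimates are averaged over
three replicate traces, matching triplicate determination practice.

The two estimators agree exactly on noiseless synthetic traces across the
retention grid; on real data they differ (the attenuation assay loses some
unnatural bases during PCR), which the single-pair plasmid preset encodes as
a carry-through factor (retention 0.88, attenuation readout 0.82).

## Synthetic data: what it emulates, and what it does not

The generator produces the assay-design inputs:

- **Templates.** A fixed synthetic 134-mer backbone (hard-coded constant;
  the original template sequences are not public, so this is a stand-in)
  with presets 1N/2N/3N (1–3 X positions; 3N contexts GXA/TXT/CXT), UN (one
  X with NNN flanks drawn uniformly per molecule between fixed 12-mer
  anchors), replicated-plasmid presets plasmid-A (one pair, GXA, retention
  0.88) and plasmid-B (three pairs: GXA 0.72, TXT 0.76, CXT 0.075 — the
  values the assays should recover), and dU-lesion references KRAS-1U and
  134-2U (dU at T positions).
- **PCR products.** Retention is a molecule-level Bernoulli split (converted
  vs unconverted); no cycle-by-cycle amplification dynamics, since the
  statistics operate on final signal fractions only.
- **Traces.** Channel intensity = mixture fraction × peak amplitude, with
  *signal-proportional* Gaussian noise truncated at zero. Proportional noise
  was chosen over additive so zero-signal channels stay silent, as in real
  chromatograms; peak-shape rendering is out of scope. Unconverted molecules
  contribute signal only before their first unnatural site, producing the
  attenuation step.
- **UN reads.** anchor + NNN + outcome + NNN + anchor, vectorised to 10⁶
  reads; constant 'I' qualities (quality modelling out of scope). Optional
  context weights emulate context-dependent read yield (e.g. the TT/TA
  downstream enrichment of the NaM-only regime). "Context-biased" models
  down-weight G for CGG/GGG-downstream contexts (bridge) and T for all
  GGG- plus half the GGA-downstream contexts (NaM-only), leaving 160/4096 ≈
  3.9% of contexts without a (G,T) modal pattern — the magnitudes are
  configuration values, not claims about the chemistry.
- **Lesion reads.** Reference bases replaced by the signature base (C bridge
  / A NaM-only) in a per-site damage fraction of reads, over a uniform
  background error rate (default 0.5%) applied to sample and control alike.
- **Kinetics.** v = Vmax·c/(Km+c) with multiplicative Normal(0, cv) noise on
  an eight-point two-fold dilution series (default top 100 µM).

What passing tests on these data show is that the *estimators* are correct
and well-calibrated under the stated noise models; they do not certify
performance on real chromatograms (peak-width variation, dye blobs, mobility
shifts), on reads needing adapter trimming or merging, or on lesion samples
with strand asymmetry — all out of scope by design.

## Numerical choices

- Coordinates are 0-based half-open internally; trace CSVs and reports
  display 1-based positions (Sanger convention).
- Context codes are base-4 integers over the six flank digits (4096 total);
  normalisation to 10⁶ reads scales counts and rounds half-to-even per cell,
  reporting the rounding residual rather than redistributing it.
- Anchor matching is exact (no mismatch tolerance); rejected reads are
  counted by reason code. Amplicon reads are high quality, and a tolerance
  would blur the context assignment.
- Argmax base calls break ties alphabetically and set a tie flag; modal
  ("mainly converted") classification uses strict plurality with ties
  reported as unsupported.
- The dinucleotide tables use the two positions adjacent to the centre on
  each side (−2,−1 and +1,+2); with 16 dinucleotides × 2 sides this matches
  the "32 combinations" framing of upstream/downstream pair preferences.
- The Michaelis–Menten fit uses `scipy.optimize.curve_fit` initialised at
  Vmax₀ = max v, Km₀ = concentration nearest half-Vmax₀, tolerance 1e-10,
  10 000 evaluations; below a 0.5 %·min⁻¹ velocity floor (configurable) the
  result is "n.d." rather than a fit to noise. Unweighted least squares is
  the default; `weighting="1/v"` is available and is the matched estimator
  when noise is multiplicative. Parameter-recovery checks use a dilution
  series bracketing Km (top = 16·Km), the standard assay design when Km is
  far below the default series floor.
- Lesion calling subtracts control from sample ratios with clamping at zero
  (idempotent, never negative), masks positions under 100× coverage
  (configurable), and uses a default threshold of 0.02 subtracted ratio —
  the qualitative "above baseline" criterion made explicit and recorded in
  output metadata.
- All randomness flows from one top-level seed through named SHA-256
  substreams (`cli_io.substream_seed`), keeping derived seeds below 2³¹;
  every generator is bit-reproducible given its seed.

## Problem sizes

The test suite and acceptance script use 10⁶-read simulations for the
context statistics (median per-context count, read-through ratio), 10⁵ reads
for flank-neutrality checks, 50-seed ensembles for noisy retention and
lesion ROC properties, 100-seed ensembles for kinetics recovery, and
triplicate traces per retention measurement — sizes chosen to pin each
statistic well below its acceptance tolerance while keeping the whole suite
in the tens of seconds.

## Known limitations

- The 134-mer backbone, anchors and lesion references are synthetic
  stand-ins; positions and contexts are faithful to the assay designs but
  the letters are not the original oligonucleotides.
- The trace model is linear in mixture fractions with independent
  per-channel noise; it cannot express cross-channel bleed or base-dependent
  peak heights, so standard-curve slopes are exactly 0.01/% by construction
  in the noiseless limit.
- The context profiler assumes reads are already oriented to the sense (NaM)
  strand and pre-merged; orientation recovery and paired-end merging are
  upstream concerns.
- Second-order constants recomputed from rounded, printed Vmax/Km values are
  only meaningful where those printed values are self-consistent; the
  kinetics module reports computed values and does not force agreement.
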