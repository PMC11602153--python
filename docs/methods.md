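# Methods

This note documents the models behind `duskit`, the parameters that matter,
what the synthetic-data generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Domain model

A reference bundle couples tRNA sequences (FASTA) with a sidecar TSV of
annotated dihydrouridine sites; all file coordinates are 1-based with closed
intervals, matching tRNA numbering conventions. Canonical position labels
are free-text keys ("16", "17", "20", "20a"), so insertion positions need no
special casing, and the enzyme assignment follows the site-specificity rule
(16 → DusC, 17 → DusB, 20/20a → DusA). The model assumes one enzyme per
site; it does not attempt Sprinzl-numbering inference from sequence or
structure — canonical labels come from the annotation file.

Occupancy logic: a wild-type baseline profile (default 0.90 at every
annotated site — in vivo stoichiometries are not precisely known, and 0.90
leaves headroom for decreases and noise) is mapped through a strain
configuration as

    occ = baseline × [enzyme active ? 1 : 0] × [paraquat > 0 and aerobic ? retention(enzyme) : 1]

The default retention factors (DusA 1.00, DusB 0.60, DusC 0.40) encode only
the qualitative in vivo ordering — DusA essentially insensitive to paraquat,
DusC most sensitive — and are configuration values, not measurements.
Paraquat scaling applies only under oxygen because the herbicide needs
oxygen to redox-cycle and drain NADPH; anaerobic treatment is a no-op.

## AlkAnilineSeq simulator

Per simulated molecule: each annotated site breaks with probability
occupancy × `alk_cleavage_prob` (default 0.10), deprotecting a ligatable
5′-phosphate at the N+1 nucleotide; each internucleotide bond independently
breaks with probability `background_break_rate` (default 10⁻³) — the small
fraction of random hydrolysis ends that survives the dephosphorylation step
and makes null controls meaningfully nonzero; and the molecule's intact 5′
terminus stays ligatable with probability `terminal_ligatable_rate` (default
0.10). Each ligatable fragment of length ≥ 15 nt yields one read (substring
of the reference, truncated at 50 nt or the next break; constant quality).
A truth table records every read's origin and cause.

The terminal rate deserves a note. The mature tRNA 5′-monophosphate is the
single most abundant end species entering the dephosphorylation step, so
even a modest escape fraction leaves it the dominant residual ligatable end;
these full-length reads supply the spanning coverage that real libraries
show. This matters quantitatively: if *all* read starts came from the same
low background rate, the expected null stop ratio at a D-loop position would
be roughly one over the number of upstream start positions within a read
length (≈ 0.05 at positions 17–22) — independent of depth, and above the
≈ 0.04 ceiling real Dus-null libraries exhibit. With 10% terminal ligation,
simulated null libraries stay at ≈ 0.03 maximum over ~70 annotated sites at
2000 molecules per tRNA.

Not emulated: PCR duplication (one read per fragment), adapter/quality
trimming (simulated reads are clean; real-data users pre-trim), sequencing
errors (off by default), chromatographic or peak-shape detail anywhere.
Consequently, passing tests demonstrate the correctness of the scoring
arithmetic and its statistical behaviour under the stated noise model — not
robustness to real library artefacts.

The fixture reference builder emits 76-nt tRNA-like sequences, every one
annotated at 16 and 17, about half additionally at 20 and a third at 20a,
with U forced at annotated indices and pairwise edit distance ≥ 5 enforced
by rejection so the mapper can place reads unambiguously. Note a structural
consequence: with these site frequencies and a uniform baseline, DusA's
share of total D is ~29% — smaller than DusB's or DusC's — so synthetic
knockout panels show ΔdusB/ΔdusC below ΔdusA rather than the in vivo
pattern where DusA accounts for about half of all D. The decomposition
*closure* property is unaffected by the shares.

## AAS scoring pipeline

Mapping is an exhaustive end-to-end Hamming scan over every offset of every
reference (T/U unified, N always a mismatch), best placement wins, ties
discarded as multimapped, best score > 2 mismatches unmapped. This is a
deliberate desk-scale stand-in for a production aligner with deterministic
behaviour; it is verified against an independent brute-force oracle in the
tests. The stop-ratio denominator is per-position coverage, n5(i)/cov(i)
(positions with coverage < 10 are zeroed and flagged). Calls use the N+1
back-shift; the default call threshold 0.05 sits above the simulated null
ceiling. Condition comparisons report percent-of-control per position
(control = 100%); positions with zero or flagged control are reported as
undefined, never as infinity. Comparison tables carry both the stop
position and the back-shifted D index, since published score tracks label
D positions directly.

## LC–MS quantification

The simulator draws D areas proportional to summed site occupancy and
adenosine UV areas proportional to the pool's A content, both with
multiplicative lognormal noise (mean 1, CV default 0.05 — areas are positive
and CV-stable), plus a deterministic D-channel floor of 0.3% of the
reference wild-type signal emulating the marginal signal of Dus-null
samples. Relative levels are injection-invariant by construction
(within-sample D/A ratio). Replicate statistics use the classical
pooled-variance two-sample Student's t-test (Welch behind a flag); star
labels follow the 0.05/0.01/0.001 convention; no multiple-testing correction
is applied by default (per-comparison stars are the field's reporting
custom). The MRM calculator uses embedded monoisotopic element masses
(C 12, H 1.00782503207, N 14.0030740048, O 15.9949146196, P 30.97376163;
proton 1.007276467 u) and quotes nominal transitions as the integer-rounded
monoisotopic m/z. NADPH quantification uses an ordinary least-squares
external calibration line with negative predictions clamped to zero and
flagged; fold changes with a zero denominator are reported as censored
bounds against the limit of detection.

## Kinetics

Initial rates use the least-squares slope over the earliest 10% of trace
points (minimum 5) — the window is a package choice, exposed as
configuration. Michaelis–Menten fitting is multi-start nonlinear least
squares (9 log-spaced Kₘ starts spanning the substrate range, V₀ at the
maximal observed rate, non-negative bounds); direct NLS is preferred over
linearising transforms (Lineweaver–Burk), which distort the error structure;
a dense grid search survives only as a test oracle. Standard errors come
from the local curvature; a fit whose Vmax 95% interval includes zero is
reported as "no detectable activity" rather than a numeric k_cat — this is
how a DusC-like enzyme is handled. k_cat requires a user-supplied enzyme
concentration (the oxidase assay's enzyme concentration is not a package
default; the dihydrouridylation assays use 5 μM protein). Wavelength is
metadata: the package uses ε₃₄₃ = 6.21 mM⁻¹ cm⁻¹ throughout, noting that
340 nm is sometimes quoted for the same measurement.

Time courses fit D(t) = plateau·(1 − e^(−kt)) with multi-start over k;
t_half = ln 2 / k. The packaged presets (DusA k = 3 min⁻¹, DusB 0.05 min⁻¹,
DusC 0.003 min⁻¹) encode the qualitative kinetics — DusA saturating within
a minute, DusB detectable after ~5 min, DusC only after ~20 min — and yield
the activity hierarchy DusA > DusB > DusC under either ranking criterion.
The DusC NADPH-oxidase preset is a near-zero rate (k_cat 5 × 10⁻⁴ s⁻¹)
rather than exactly zero so that simulated datasets exist at all.

## Determinism and problem sizes

A single top-level seed spawns independent per-component streams keyed by
stable strings (SHA-256 of the key folded into a `SeedSequence`), so adding
a generator never perturbs another's draws; identical seeds give
byte-identical outputs, which the tests verify by re-running a full scenario
and comparing files. Default study conditions are 20 tRNA references at
2000 molecules each for sequencing, triplicate LC–MS samples (five
replicates in the knockout panel), and 8 substrate points × 3 replicates for
kinetics; tests that only exercise plumbing use smaller bundles (4–6 tRNAs,
a few hundred molecules) chosen as the package's own test sizes. Statistical
assertions use 3-standard-error bands or median-error bounds over 100–500
seeded repetitions.

## Known limitations

* The mapper is Hamming-only (no indels) and quadratic in reference count ×
  length; it is intended for tRNA-sized desk-scale references.
* Stop-ratio scores are semi-quantitative: occupancy enters nonlinearly
  through fragment survival and coverage composition, so percent-of-control
  at a site is not exactly the occupancy ratio (DusA-dependent sites can
  even rise under treatment when upstream stops vanish — as observed in
  real data).
* Only D-loop D sites are modelled; m⁷G/m³C (the assay's original targets),
  mRNA/rRNA sites and position 47 are out of scope.
* Polysome fractions are sample labels only; no sedimentation or
  translation model is implied.
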