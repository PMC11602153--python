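# duskit

Analysis toolkit for the redox biology of tRNA dihydrouridine (D) in
*Escherichia coli*.

Dihydrouridine — the only non-aromatic nucleobase known in RNA — is placed in
the tRNA D-loop by three site-specific, FMN-dependent dihydrouridine
synthases: **DusC** at position 16, **DusB** at position 17 and **DusA** at
positions 20/20a. All three draw reducing power from NADPH, which couples
their activity to the cellular redox state: oxidative stress (e.g. the
redox-cycling herbicide paraquat, in the presence of oxygen) drains NADPH and
depresses dihydrouridylation, to a different degree for each enzyme.

`duskit` implements the three measurement chains needed to study this system,
together with seeded synthetic-data generators that emulate each assay's
chemistry and noise so the entire analysis runs at desk scale:

1. **AlkAnilineSeq (AAS) stop-ratio mapping.** Mild alkali opens the
   saturated D ring and scissions the strand; after dephosphorylation erases
   background ends, aniline regenerates a ligatable 5′-phosphate at the
   nucleotide *after* the modified site (N+1). Read 5′ ends therefore mark
   D positions. The per-position score is the *stop ratio*
   `n5(i) / cov(i)` ∈ [0, 1] — reads starting at *i* over reads covering
   *i* — and a D site is reported at the back-shifted index *i* − 1.
2. **LC–MS relative quantification.** The D mass-spectrometric peak area of
   a sample is normalised to its adenosine UV (254 nm) area and expressed as
   percent of an untreated control (= 100%); single-knockout decreases
   decompose total D into per-enzyme contributions, with the closure
   residual reported. An MRM transition calculator reproduces the monitored
   masses (dihydrouridine *m/z* 247 → 115 by ribose loss; NADPH 746 → 729 by
   NH₃ loss) from molecular formulas, and external-standard calibration plus
   fold-change cover the NADPH depletion measurement.
3. **Enzyme kinetics.** Initial NADPH-oxidation rates from A₃₄₃ traces via
   Beer–Lambert (ε₃₄₃ = 6.21 mM⁻¹ cm⁻¹), multi-start nonlinear least-squares
   fits of v = V·S/(Kₘ + S) with k_cat = V/[E] and efficiency k_cat/Kₘ,
   saturating time-course fits D(t) = plateau·(1 − e^(−kt)), and enzyme
   ranking that places non-detectable activities last.

## Worked example

```python
import duskit as dk
from duskit.simulate import (AASLibraryParams, KineticsSimParams,
                             build_fixture_references, simulate_aas_library,
                             simulate_mm_dataset)
from duskit import aas, kinetics as kin

# 20 tRNA-like references annotated at D-loop positions 16/17(/20/20a)
bundle = build_fixture_references(20, seed=7)
baseline = bundle.baseline_profile()                  # 0.90 at every site
treated = dk.effective_occupancy(
    baseline, dk.strain_config("WT", paraquat_mM=0.3, aerobic=True))

def score(profile, seed):
    reads, _ = simulate_aas_library(bundle, profile, AASLibraryParams(seed=seed))
    aligned, _ = aas.map_reads([(r.read_id, r.sequence) for r in reads], bundle)
    return aas.stop_ratio(aas.tally(aligned, bundle))

summary = aas.enzyme_level_summary(
    aas.compare_conditions(score(treated, 2), score(baseline, 1)),
    bundle.annotations)
print(summary.to_string(index=False))

data = simulate_mm_dataset(KineticsSimParams(kcat=0.48, km=17.0, noise_cv=0.05, seed=1))
fit = kin.fit_michaelis_menten(data["S_uM"], data["v_uM_per_s"], enzyme_conc=1.0)
print(f"kcat = {fit.kcat:.3f} /s, Km = {fit.km:.1f} uM, kcat/Km = {fit.efficiency:.4f} /uM/s")
```

Output:

```
enzyme  n_sites  n_decreased  fraction_decreased  mean_percent_of_control
  DusA       15            0                 0.0               124.669309
  DusB       20           20                 1.0                84.372602
  DusC       20           20                 1.0                53.572504
kcat = 0.482 /s, Km = 18.7 uM, kcat/Km = 0.0258 /uM/s
```

The enzyme summary shows the differential paraquat sensitivity encoded by the
simulation (and observed in vivo): every DusC-dependent position 16 drops
(here to ~54% of the untreated control), most position-17 signals drop
moderately, while the DusA-dependent 20/20a signals are unaffected or even
relatively increased. The kinetics fit recovers the DusA-like generating
parameters (k_cat 0.48 s⁻¹, Kₘ 17 μM, efficiency 2.8 × 10⁻² μM⁻¹ s⁻¹) from
5%-noise initial-rate data.

## Command line

```bash
duskit simulate-aas --n-trnas 20 --strain WT --seed 1 --out sim/
duskit aas-score --fastq sim/reads.fastq --fasta sim/references.fasta \
       --annotations sim/annotations.tsv --out scored/
duskit lcms-quant --table nucleosides.tsv --control-prefix WT_pq0 --out quant/
duskit kinetics-fit --input mm.tsv --enzyme-conc 1.0 --out fits/
duskit run-scenario --config src/duskit/data/default_scenario.yaml --out run/
```

Scenario presets (`pilot`, `aerobic`, `anaerobic`, `knockout_panel`,
`polysome`) reproduce the study designs on synthetic data; every artifact is
byte-reproducible from the config and seed alone.

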