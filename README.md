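# cpdrepair

Photokinetic analysis of UV-induced self-repair of cyclobutane pyrimidine
dimers (CPDs) in short damaged DNA oligonucleotides.

CPDs are the most common UV photolesions in DNA: a cyclobutane ring fusing
two adjacent thymines. In specific purine-containing sequences (here the
damaged tetranucleotides T<>TAG and GAT<>T, where "<>" marks the dimerised
TT), photoexcitation of guanine can trigger sequential electron transfer
through the base stack (G → A → T<>T) that splits the dimer without any
enzyme. This package provides the complete analysis chain used to quantify
that process from steady-state irradiation experiments, plus the structural
and energetic operators that rationalise it. It is a library intended to be
used from Python; `examples/` holds one short narrative script per
capability.

## What it computes

**Forward model.** A reversible two-state photoreaction under polychromatic
irradiation. Competitive Beer–Lambert absorption partitions the photon
stream of an LED (default: Gaussian band at 285 nm, 15 nm FWHM, 0.36 mW at
the sample) among the species; each absorbed photon converts the absorber
with probability Φ:

    dc_rep/dt = [Φ_rep R_dam − (Φ_dam + Φ_side) R_rep] / (N_A V)

with R_i the per-species absorbed photon rates (inner-filter corrected)
and the absorbed energy dose D(t) integrated alongside. Under continuous
irradiation the composition tends to a photostationary state (PSS); in the
optically thin limit

    f_pss = Φ_rep ε̄_D / (Φ_rep ε̄_D + Φ_dam ε̄_R),

where ε̄ are photon-weighted mean absorption coefficients over the source
band.

**Inverse analysis.** The repair quantum yield from the initial slope of
the 266 nm absorbance recovery vs absorbed dose,

    Φ = slope[OD/J] · V N_A Ē_ph / (Δε₂₆₆ · l),

with a statistically selected linear range and a saturation correction for
data that already bend towards the plateau; the PSS level and the dose to
equilibrium from a saturating-exponential fit f(D) = f_pss(1 − e^(−D/D₀));
reported yields carry the 40% relative uncertainty convention of this kind
of irradiation/HPLC assay.

**Supporting operators.** HPLC-style chromatogram synthesis and
relative-area peak quantification (damaged 8.4 min, repaired 9.9 min);
glycosidic torsion χ, syn/anti classification and projected ring-overlap
areas for stacked bases; and validated electron-transfer energy ladders
(S₁ minima and S₁/S₀ crossing points, eV) with gap arithmetic and
channel-accessibility classification. A synthetic-data module generates
every input with known ground truth, so each stage is testable by
parameter recovery.

## Worked example

`python examples/quantum_yield_extraction.py` simulates ten one-minute
exposures of a 30 μM damaged-T<>TAG solution and re-extracts the quantum
yield from the noisy dose response:

```
true quantum yield     : 0.580 %
recovered quantum yield: 0.575 +/- 0.23 %  (40% rule)
initial slope          : 1.078 OD/J over 8 low-dose points
delta-A(266) at 10 min : 44.0 mOD
```

The yield is the probability that one absorbed photon reverses one dimer;
the 44 mOD recovery of the thymine 266 nm band within 10 minutes is the
directly observable signature of self-repair. `examples/
photostationary_state.py` continues to high doses, where repair and damage
formation balance:

```
TTAG:
  fitted plateau        : 39.0 % repaired
  analytic thin-limit   : 40.0 %
  dose to equilibrium   : 0.59 J (within 5% of plateau)
```

The other examples cover chromatogram quantification, the syn/anti
conformer census with stacking-overlap areas, and the packaged
electron-transfer ladders.

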