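# aptafret

Quantitative analysis tools for **apta-FRET** systems: pairs of fluorogenic
RNA aptamers (e.g. Broccoli/DFHBI-1T as donor, Pepper/HBC620 as acceptor)
held at designed positions on an RNA origami scaffold so that their bound
fluorophores exchange energy by FRET. The package is aimed at people who
design such scaffolds and need to (i) turn plate-reader intensities into a
crosstalk-corrected FRET statistic, (ii) predict fluorophore geometry from a
placement design string, (iii) quantify how precisely an ensemble of
structural models positions the fluorophores, and (iv) quantify SHAPE
probing gels of the aptamers.

## What it computes

**FRET output** (`aptafret.fluorometry`). From intensities measured at four
channels — donor excitation/emission (460/505 nm) and acceptor
excitation/emission (585/620 nm) — the sensitized-emission statistic

```
N    = I_DA(ex_D, em_A) − A_dir · I_DA(ex_A, em_A) − D_Leak · I_DA(ex_D, em_D)
FRET = N / (N + I_DA(ex_D, em_D))
```

where the donor-leak and direct-excitation factors are measured on
single-labelled samples: `D_Leak = I_D(ex_D,em_A) / I_D(ex_D,em_D)` and
`A_dir = I_A(ex_D,em_A) / I_A(ex_A,em_A)`. The statistic is a corrected
proximity ratio; it is reported unclamped, with replicate mean ± sample SD.

**Förster geometry** (`aptafret.forster`). Orientation factor
κ² = (d̂·â − 3(d̂·r̂)(â·r̂))² ∈ [0,4], overlap integral
J = ∫F_D(λ)ε_A(λ)λ⁴dλ / ∫F_D(λ)dλ, Förster radius
R0 = 0.02108·(κ²·n⁻⁴·Q_D·J)^(1/6) nm and E = 1/(1+(r/R0)⁶).

**Tile model** (`aptafret.scaffold`). Parses the `x,y-Bz-Pw` placement
notation (helices x, y; stem offsets z, w in bp from the crossover,
parenthesized negatives for the far side) and realizes it on an idealized
planar 3-helix tile (A-form rise 2.81 Å/bp, 11 bp/turn, 22 Å inter-helix
spacing) to predict the donor–acceptor chromophore distance and model κ².

**Ensemble precision** (`aptafret.ensemble`). Kabsch rigid-body
superposition with reflection guard; alignment of all ensemble members on
the acceptor chromophore while preserving each member's internal geometry;
per-member donor–acceptor distances, min/max/range, per-fluorophore motion
range and maximal dipole rotation.

**SHAPE quantification** (`aptafret.shape`). Gel lane profiles → per-band
baseline-subtracted peak heights → reactivities normalized to a reference
nucleotide (default C28) → protected/enhanced/unchanged calls versus the
apo lane, with reverse-transcriptase stop artifacts flagged from the mock
lane and excluded.

**Synthetic data** (`aptafret.synthetic`). Seeded generators for all input
types (spectra, intensity tables, rigid-pose PDB ensembles, gel lanes) with
machine-readable ground truth, used throughout the test suite.

## Worked example

```python
from aptafret import fluorometry as fl, scaffold as sc, synthetic as sy

# forward-model a double-labelled measurement with 1 % noise, truth 37 %
table, truth = sy.gen_intensity_table(true_sensitized=37.0, true_donor_em=63.0,
                                      donor_leak=0.05, acceptor_direct=0.02,
                                      noise_sd=0.01, seed=7)
factors = fl.factors_from_table(table)        # measured from single-label rows
res = fl.fret_replicates(table, factors)
print(f"D_Leak={factors.donor_leak:.4f}  A_dir={factors.acceptor_direct:.4f}")
print(f"FRET: {res.fret_percent:.1f} ± {res.sd_percent:.1f} %")

for design in ["1,2-B12P12", "1,3-B12P12", "1,3-B12P(-34)"]:
    print(design, f"{sc.predict_distance(design):.2f} nm")
```

prints

```
D_Leak=0.0502  A_dir=0.0200
FRET: 37.3 ± 0.2 %
1,2-B12P12 0.64 nm
1,3-B12P12 2.00 nm
1,3-B12P(-34) 16.00 nm
```

The recovered FRET output sits on the 37 % ground truth within the noise,
and the tile model places the helix-1/3 design at ~2 nm (FRET-competent)
versus ~16 nm (outside FRET range) for the far placement. The same
operations are available from the shell: `aptafret fret-calc`,
`aptafret design-model`, `aptafret ensemble-analyze`, `aptafret
shape-quant`, `aptafret forster` and `aptafret simulate`.

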