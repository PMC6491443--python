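# rhodotune

Colour-tuning analysis for microbial rhodopsins, built around the
red-shifted sodium-pump variants of KR2 (P219T, S254A and the P219T/S254A
double mutant) and their natural counterpart, the *Jannaschia seosinensis*
sodium pump.

The absorption maximum λ_max of a retinal protein is set by the S1−S0
vertical excitation energy of its protonated retinal Schiff base,

    ΔE(S1−S0) = hc/λ_max ,

which the protein tunes in two ways: *sterically*, by twisting the
conjugated polyene chain (quantified by bond-length alternation, BLA, and
dihedral distortions), and *electrostatically*, because the +1e charge of
the chromophore sits on the Schiff-base end in S0 but delocalizes toward
the β-ionone ring in S1, so any environment charge interacts differently
with the two states. `rhodotune` implements the full desk-scale analysis
chain around this picture:

- **`spectral`** — nm / cm⁻¹ / kcal·mol⁻¹ conversions, mutational shifts
  (red-shift = negative wavenumber change), additivity analysis of combined
  mutations, and the empirical ν_C=C ↔ λ_max line (≈70 cm⁻¹ per 270 nm).
- **`geometry`** — retinal chain extraction from PDB text (C5…C15, N, with
  the lysine CE when present), bond lengths, BLA (mean single − mean double
  bond), signed dihedrals and deviations from planarity.
- **`electrostatics`** — a two-state point-charge surrogate: Coulomb energy
  of S0/S1 charge sets against a residue-grouped point-charge cavity,
  decomposition ΔE_protein = ΔE_vacuum + ΔE_electrostatic, per-residue
  charge-off contributions (exactly superposable by linearity), and
  direct/indirect classification of mutation effects.
- **`kinetics`** — sequential photocycle chains (K → K/L → L/M → O) in
  closed form, transient-absorption simulation, SVD denoising, and global
  multi-exponential fitting by variable projection; the slowest lifetime is
  the turnover time.
- **`assays`** — λ_max from hydroxylamine-bleach difference spectra
  (Gaussian band fit in wavenumber) and pump activity from initial slopes
  of light-on pH traces.
- **`synth`** — generators for every input above (toy retinal PDBs with
  target BLA/twists, dipole cavities, bleach pairs, pH traces, ΔA
  matrices), so the whole pipeline runs without downloads.

## Worked example

```python
import rhodotune as rt

wt = rt.SpectralBand("KR2 WT", 525.0)
p219t = rt.compute_shift(wt, rt.SpectralBand("P219T", 542.0))
s254a = rt.compute_shift(wt, rt.SpectralBand("S254A", 545.0))
double = rt.compute_shift(wt, rt.SpectralBand("P219T/S254A", 565.0))
report = rt.additivity([p219t, s254a], double)
print(p219t.delta_wavenumber_int, s254a.delta_wavenumber_int,
      report.predicted_sum_int, report.combined_shift.delta_wavenumber_int)
```

prints

```
-597 -699 -1296 -1349
```

the P219T and S254A red-shifts in cm⁻¹, their sum, and the double mutant's
observed shift: the two mutations, acting on opposite ends of the
chromophore, combine almost additively on the energy scale.

Running `python examples/photocycle_fit.py` simulates a noisy KR2-like
transient-absorption matrix, denoises it to rank 4 and fits four shared
lifetimes:

```
  tau =   0.0300 ms +- 0.0000 ms
  tau =   0.3000 ms +- 0.0000 ms
  tau =   1.0001 ms +- 0.0000 ms
  tau =   4.7994 ms +- 0.0001 ms
turnover time: 4.80 ms (generated with 4.8 ms ground-state recovery)
turnover ratio mutant/WT: 1.71 (< 2: transport-compatible slowdown)
```

The other scripts in `examples/` walk through geometry metrics
(`geometry_bla.py`), the excitation-energy decomposition and charge-off
analysis (`charge_off_analysis.py`), and the bench assays
(`bleach_and_activity.py`); each prints the numbers it computes with a note
on what they mean.

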