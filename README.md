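# gelkit

Toolkit for constructing a virtual gelatin chain from a collagen sequence and
computing the observables used to validate an atomistic gelatin model:

- **sequence** — FASTA parsing, hydroxyproline substitution (`X`) at the Y
  position of the collagen G-X-Y repeat, simulated trypsin digestion (cut
  C-terminal to K/R, blocked by a following P), and assembly of a chain of a
  target length from the resulting peptides. A copy of the human collagen
  alpha-1(I) chain (1464 residues) is packaged for offline use.
- **structure_io** — readers/writers for PDB, (extended) XYZ, LAMMPS-dump
  style trajectories and delimited thermodynamic tables.
- **scattering** — powder WAXS intensity via the orientationally averaged
  Debye equation with Cromer–Mann atomic form factors; principal-peak
  location.
- **volumetrics** — probe-based occupied volume on a periodic voxel grid in
  three conventions (vdW union, probe-accessible, Connolly/probe-excluded via
  morphological closing) and fractional free volume FFV = (V_tot − V_occ)/V_tot.
- **thermoanalysis** — OLS with full ANOVA (DF/SSE/MSE/F/p), 95% confidence
  and prediction bands, F survival function via the incomplete-beta identity,
  isobaric expansion coefficient α_p = −d ln ρ/dT, and glass-transition
  detection as the breakpoint of a continuous two-segment fit.
- **solubility** — Hansen solubility parameter δ = √(CED) from per-frame
  nonbonded energy and volume, Flory–Huggins χ, Flory–Rehner crosslink
  density, equilibrium swelling degree, and the Fujita free-volume diffusion
  model.
- **synthetic** — seeded generators for every input class (lattices, random
  packings, ρ(T)/δ(T) series, bilinear specific-volume series, cleavage test
  sequences).

## CLI

A single `gelkit` entry point exposes the pipeline stages:

```sh
gelkit digest --fasta collagen.fasta --hydroxylate gxy --target-length 280 \
    --out gelatin.fasta --report digest.json
gelkit waxs --structure model.pdb --two-theta 5:50:0.1 --wavelength 1.54178 \
    --out profile.csv --report waxs.json
gelkit ffv --frames traj.xyz --probe 1.4 --grid 0.25 --convention connolly \
    --out ffv.csv --report ffv.json
gelkit thermo --table thermo.csv --x temperature --y density --transform log \
    --out fit.json
gelkit tg --table specific_volume.csv --out tg.json
gelkit hansen --table thermo.csv --energy-col nonbonded_energy \
    --volume-col volume --energy-unit kcal/mol --out hansen.json
gelkit swell --delta-s 47.8 --delta-p 27.2 --vsol 18 --temp 298 \
    --vs 0.25 --phi 0.01 --out swell.json
gelkit fixtures make-thermo --alpha-p 6.072e-4 --sigma 0.005 --seed 7 \
    --out thermo.csv
```

Global flags: `--config FILE` (JSON with per-subcommand defaults, unknown
keys rejected), `--log-level`, `--seed`. Reports are JSON with a schema
version; tables are CSV.

## Notes on conventions

- The Debye sum uses the isotropic kernel sinc(q·r) with q = 4π sin θ/λ;
  profiles also report s = 2 sin θ/λ. Periodic frames use minimum-image
  distances with a hard cutoff at half the shortest box edge (sharp
  truncation can leave small negative ripples; non-periodic frames are
  exactly non-negative).
- Default probe radius 1.4 Å (water), grid spacing 0.25 Å, Bondi vdW radii.
- δ is computed as the mean over frames of √(E/V) (flag available for
  √(mean E/V)); attractive (negative) nonbonded energies enter by magnitude.
- Tg is the global-SSE-minimizing knee of a continuous two-segment fit,
  refined to 0.1 K; a fractional SSE improvement below 0.5 over a single
  line flags the estimate unreliable.
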