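# qmmkit

Desk-scale Gaussian-basis Kohn–Sham DFT with electrostatic-embedding QM/MM,
real-time TDDFT electron dynamics, Born–Oppenheimer MD with umbrella-sampling
free-energy profiles, and autocorrelation-based spectra — in pure Python
(numpy/scipy, numba-compiled integral kernels).

## What's inside

| subpackage           | contents |
| -------------------- | -------- |
| `basis_integrals`    | Gaussian94 basis parser (vendored STO-3G / DZVP / 6-31G), contracted Cartesian shells up to d, Obara–Saika one-electron integrals (overlap, kinetic, point-charge attraction, dipole), Boys function, Schwarz-screened 8-fold-symmetric ERI tensor |
| `ks_dft`             | Becke fuzzy-cell grids (Gauss–Chebyshev × Lebedev, molecule-frame oriented), LDA (Slater + PW92) and PBE functionals with analytic potentials, restricted KS SCF with DIIS, damping and level shifting |
| `qmmm_coupling`      | MM point-charge regions, electrostatic-embedding core-Hamiltonian update, QM/MM Lennard-Jones, nucleus–charge Coulomb, rigid-water MM energies, three-term total-energy reports, finite-difference forces |
| `dynamics_sampling`  | velocity-Verlet and Langevin (BAOAB) integrators, distance / distance-difference reaction coordinates, harmonic umbrella restraints, WHAM with overlap diagnostics, barrier extraction |
| `rt_tddft`           | density-matrix propagation in the orthonormalized basis: leapfrog commutator scheme and truncated-Magnus exponential (order 2–50), delta-kick initialization, maximum-stable-timestep bisection |
| `spectra`            | origin-averaged autocorrelations, IR spectra (cosine transform, Hann window), finite-difference normal modes, mode-projected VDOS, delta-kick UV-vis spectra, shared-grid ensemble averaging, λmax and convergence diagnostics |
| `io_cli`             | XYZ / multi-frame XYZ, MM site tables (TSV), window manifests, spectra/profile TSV, TOML run configs with strict key validation, JSON provenance records, deterministic rigid-water solvation boxes (TIP3P/TIP4P-like), `qmmkit` CLI |

Internal units are Hartree atomic units everywhere; user surfaces speak
Å, kcal/mol, fs, nm and cm⁻¹.

## CLI

Every task reads a TOML config (`task = "..."`, flat `module.key` options)
and writes outputs plus a JSON provenance record into `output_dir`:

```bash
qmmkit scf      --config scf.toml            # (QM/MM) ground-state energy
qmmkit rt       --config rt.toml             # delta-kick absorption spectrum
qmmkit md       --config md.toml             # Born-Oppenheimer QM/MM MD
qmmkit umbrella --config window.toml         # one restrained window
qmmkit wham     --config wham.toml           # free-energy profile from windows
qmmkit ir       --config ir.toml             # IR from a dipole time series
qmmkit ensemble --config ensemble.toml       # average member spectra, lambda_max
```

Minimal example (`rt.toml`):

```toml
task = "rt"
output_dir = "out"

[system]
xyz = "h2o.xyz"          # Angstrom
basis = "dzvp"           # bundled: sto-3g, dzvp, 6-31g

[scf]
functional = "pbe"
grid = "coarse"

[rt]
dt = 0.1                 # a.u. time
nsteps = 4000
damping_fs = 2.5
```

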