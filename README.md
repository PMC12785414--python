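# fpdyn

Analysis toolkit for chromophore dynamics and pH response of β-barrel
fluorescent proteins, built around the questions raised by cysteine-containing
red FP chromophores (an mCherry M66C-type variant): how long do pocket waters
stay near the chromophore and where do they leave the barrel, how does the
acylimine carbonyl flip between conformers, how many hydrogen bonds does the
chromophore make with protein and solvent, and what pair of ionization
constants governs the absorbance spectrum across pH.

It is aimed at people who post-process MD trajectories of fluorescent
proteins and fit spectrophotometric titrations, and at anyone who needs a
planted-ground-truth generator to validate such pipelines offline.

## What it computes

**Trajectory statistics** (internal units nm/ns; Kabsch superposition, no
mass weighting):

- per-frame RMSD of a measured selection after fitting on protein Cα atoms,
  per-atom/per-residue RMSF about the time-averaged structure, ΔRMSF between
  variants, single-pair Cα distance series and fixed-width histograms;
- geometric hydrogen bonds — donor–acceptor ≤ 0.35 nm and
  hydrogen–donor–acceptor ≤ 30°, N/O typing — counted per frame and
  partitioned into {protein, water} partners;
- **water residency**: the earliest time t\* from which the water-oxygen →
  chromophore-bridge-carbon distance stays above 2 nm at every frame for at
  least 0.1 ns; waters that never leave are censored and reported as
  "> duration".  Exits are assigned to interstrand gates (Reg 1–4: the
  bulge-split strand 7 against strands 10 and 8, and strand 3 against 11) by
  the nearest gate-centroid rule at the first frame of the excursion;
- two-state segmentation of chromophore RMSD series (deterministic
  two-means) and acylimine carbonyl flip detection from the N–CA–C–O
  dihedral of residue 65.

**Titrations.** A sequential two-site ionization model for the
thiol/phenol chromophore,

    SH/OH  --pKa1-->  SH/O-  --pKa2-->  S-/O-          (420, 566, 543 nm)

with p(SH/OH) = h²/D, p(SH/O⁻) = h·K₁/D, p(S⁻/O⁻) = K₁K₂/D,
D = h² + h·K₁ + K₁K₂, h = 10^(−pH).  pKa values are estimated by fitting the
Henderson–Hasselbalch sigmoid R(pH) = R_lo + (R_hi − R_lo)/(1 + 10^(pKa−pH))
to two-wavelength absorbance ratios (numerator at the neutral-pH main peak,
denominator at an isosbestic reference wavelength; see `docs/methods.md`).

**Synthetic generator.** Trajectories with planted water escapes (through
named gates at exact grid times), carbonyl flips, scripted per-frame H-bond
counts realized geometrically, and gap-breathing schedules — plus titration
spectra from planted ionization models — all with serialized ground truth,
so every analysis stage is testable without MD engine output.

## Worked example

```python
from fpdyn import titration as ti, water as wd
from fpdyn.synthetic import TitrationSpec, TrajectorySpec, WaterPlant, gen_titration, gen_trajectory
from fpdyn.io import default_regions

# 1. pKa pair from a noiseless three-state titration (planted 5.7 / 8.8)
series, model = gen_titration(TitrationSpec(seed=0))
low = ti.fit_pka(ti.ratio_curve(series, 566, 425, window=(4.5, 8.0)))
high = ti.fit_pka(ti.ratio_curve(series, 566, 544, window=(6.0, 11.0)))
print(f"low-range pKa {low.pka:.2f}, high-range pKa {high.pka:.2f}")

# 2. water residency: plant an escape at 93.33 ns through gate Reg 2
spec = TrajectorySpec(duration_ns=100.0, water_plants=(WaterPlant("W2", 93.33, "Reg 2"),), seed=1)
traj, truth = gen_trajectory(spec)
trace = wd.distance_trace(traj, 300, wd.ResidencyCriteria())
rec = wd.residency_time(trace, wd.ResidencyCriteria(), water_id="W2")
rec = wd.classify_exit(traj, 300, rec, default_regions())
print(f"residency {rec.residency_ns:.2f} ns via {rec.exit_region}")
```

prints

```
low-range pKa 5.77, high-range pKa 8.80
residency 93.33 ns via Reg 2
```

The first line shows both ionization constants recovered from the ratio fits
(the planted model used 5.7 and 8.8; the small low-range offset is the
residual three-species crosstalk inside the pH ≤ 8 window).  The second line
shows the persistence-threshold detector returning the planted escape time
exactly — to one frame — and the gate classifier naming the planted exit
region.

The numbered drivers under `analysis/` run the full set of study-style
analyses (titration fits, the per-run residency tables and their aggregated
means/sds, chromophore state segmentation and flip detection, partitioned
H-bond frequencies, interstrand distance distributions) and write their
tables under `results/`.  The `fpdyn` console script exposes each operation
as a subcommand (`simulate`, `rmsd`, `rmsf`, `delta-rmsf`, `dist`, `hist`,
`hbond`, `residency`, `states`, `flip`, `pka`, `run`).

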