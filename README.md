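# tndyn — troponin trajectory analytics

`tndyn` quantifies how small molecules and cTnI phosphorylation reshape the
dynamics of the cardiac troponin complex, starting from trajectory frames
(multi-model PDB) and in vitro motility assay (IVMA) tables. It is aimed at
structural-bioinformatics users who have simulated troponin (wild type or
cardiomyopathy mutants such as TnC G159D, with or without bound compounds)
and want the standard per-condition readouts plus their phosphorylation
(SEP − uP) differences:

- **Interdomain hinge angle** — the angle at the TnC hinge linker between
  the C-alpha centroids of the NcTnC regulatory lobe and the quasi-rigid
  ITC core, per frame.
- **A/B interhelical angle** — the crossing angle between cTnC helices A
  and B, reporting the open/closed state of the regulatory lobe.
- Distribution summaries: mean, full width at half maximum (fwhm), and the
  fraction of frames above a threshold (e.g. A/B > 110°).
- **Ligand-contact maps** — per-residue probability that any ligand atom is
  within a cutoff (2.5 Å or 2.0 Å) of the residue, over the troponin core
  grid TnC 1–161, TnI 1–169, TnT 202–288.
- **Ionic-bond occupancy** — fraction of frames in which the TnC D159–K83
  salt bridge is formed (side-chain O/N distance < 4 Å).
- **Ligand-pose clusters** — frames are superposed on a common reference
  over protein C-alphas, ligand centers of mass are clustered with DBSCAN
  (eps 10 Å, minimum cluster size 1% of frames), and each binding site is
  reported with its occupancy and representative pose.
- **Motility dose–response** — four-parameter Hill fits
  `y = y0 + (yinf − y0)·xⁿ/(EC50ⁿ + xⁿ)` of % motile filaments versus
  [Ca²⁺] or compound concentration, and the single-point *coupling
  constant* ΔM = M(uP) − M(P) at 0.075 µM Ca²⁺, signed so normal wild-type
  coupling scores ≈ +25 and a reverse recoupler scores negative.

Because real production trajectories are far beyond desk scale, the package
ships a deterministic synthetic-data module (`tndyn.synthetic`) that
generates reduced troponin-like trajectories and motility curves with known
ground truth; every analysis stage is validated by parameter recovery
against that truth.

## Worked example

Generate a 500-frame synthetic trajectory (hinge angle ~ Normal(120°, 8°),
A/B crossing fixed at 105°, D159–K83 occupancy target 0.35, three ligand
binding sites weighted 0.90/0.07/0.03) and analyse it:

```bash
$ tndyn generate --seed 7 --n-frames 500 --out demo.pdb
wrote 500 frames to demo.pdb (truth: demo.truth.csv)

$ tndyn angles demo.pdb
hinge: mean=119.53 deg fwhm=18.87 deg frac>110=0.878
ab: mean=105.00 deg fwhm=1.83 deg frac>110=0.000

$ tndyn occupancy demo.pdb
occupancy=0.3500 (cutoff 4.0 A, 500 frames)

$ tndyn cluster demo.pdb --eps 10 --out clusters.csv
3 clusters, noise fraction 0.002 (eps 10.0 A, min_points 5, reference frame 0)
```

The hinge mean (119.53°) and fwhm (18.87°) recover the generating
distribution (mean 120°, Gaussian fwhm 2√(2 ln 2)·8 ≈ 18.84°); the bond
occupancy is exactly the generator's 0.35 target; `clusters.csv` reports the
three sites at 90/7.2/2.6% of frames with their representative frames.

Fitting a noiseless reverse-recoupling compound sweep (single-point
motility at 0.075 µM Ca²⁺ versus compound concentration):

```bash
$ tndyn dose sweep.csv --mode compound
compound EC50=67 uM; coupling at top dose -22.48 (reverse)
```

i.e. the compound half-effect concentration is 67 µM and at the top dose
phosphorylation *increases* Ca²⁺ sensitivity (negative coupling constant) —
the reverse-recoupling signature.

The full per-condition pipeline over the default synthetic study conditions
(WT and G159D, uP and SEP, compound 7r) is:

```bash
tndyn run-all --seed 1 --outdir results/
```

which writes per-condition CSVs (angles, summaries, contacts, bond,
clusters) plus `comparison.csv` — Δ mean hinge, Δ mean A/B, fraction
A/B > 110° and D159–K83 occupancy per phosphorylation pair — and
`contact_difference.csv` (per-residue SEP − uP contact probabilities).
The library API mirrors the CLI one-to-one (`tndyn.run_condition`,
`tndyn.compare_conditions`, `tndyn.hill_fit`, ...).

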