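# Methods

## Scope and data model

`tndyn` analyses trajectories of the cardiac troponin core — cTnC (residues
1–161), cTnI (1–169), cTnT (202–288) — with an optionally bound small
molecule, plus tabulated in vitro motility data. Trajectories are
multi-model PDB files (or a whitespace XYZ fixture format); residue
numbering is taken verbatim from the file, and the troponin numbering above
is expressed through a chain-role map (`chains:` in the YAML config) plus
residue ranges, never by renumbering. Atom masses come from an element
lookup; an unknown element falls back to 12.0 amu with a logged warning
(masses are only consumed by center-of-mass computations). For altLoc
fields, 'A' or blank is kept and other locations dropped — the simplest
deterministic rule.

## Angle metrics

**Hinge angle.** Per frame, H is the C-alpha centroid of the hinge linker
(default TnC 86–92), c1 and c2 the C-alpha centroids of the NcTnC lobe
(default TnC 1–85) and the ITC core (default TnC 93–161 ∪ TnI 43–79 ∪
TnI 90–135); the hinge angle is the angle at H between H→c1 and H→c2, in
degrees. This centroid–linker–centroid construction needs only C-alpha
coordinates and user-declared domain ranges, and is monotone in any rigid
rotation of one domain about the linker — the property the recovery tests
exercise. Domain boundaries are defaults to override per study; no
automatic rigid-domain detection is attempted. The ITC TnI ranges (43–79,
90–135) are the IT-arm helices in conventional cTnI numbering.

**A/B interhelical angle.** Helix A (default TnC 14–28) and helix B
(default TnC 41–48) each get an axis; the reported angle is the angle
between the two axes with an N→C sign convention, so open (>90°) and
closed conformers are distinguished. The default axis estimator is
*geometric*: second differences of consecutive C-alpha positions of an
ideal helix point radially inward, so consecutive cross products of them
lie along the axis, and their sum is exactly axial for an ideal helix of
any length ≥ 4 residues. Plain PCA (`method="pca"`) is also available but
is biased by up to a few degrees whenever the helix span is not a whole
number of turns (e.g. 2.3° for a 12-residue, 100°/turn helix), which is
why it is not the default. Angles are always in degrees in [0, 180] and
never wrap.

**Superposition.** Weighted least-squares rigid fits use
`scipy.spatial.transform.Rotation.align_vectors`, which excludes
reflections by construction (det = +1); the RMSD is recomputed explicitly
from the returned transform. Fits require ≥ 3 non-collinear points.
Trajectory alignment superposes every frame on a reference frame over the
protein C-alphas and carries all atoms (ligand included) along. The
default reference is frame 0; the exhaustive pairwise-RMSD medoid frame
("representative structure") is available on demand
(`medoid_frame`, `--reference-frame medoid`) but costs O(n_frames²)
superpositions.

## Distribution summaries

Each angle series is summarised by its arithmetic mean, a histogram over
[0, 180°] (default bin width 1°), the fraction of frames strictly above
each threshold (ties at the threshold count as *not* above, matching
"> 110°"), and the fwhm.

**fwhm estimator.** The default (`fwhm_method="density"`) convolves the
histogram with a Gaussian kernel of bandwidth h = 3 × the Silverman rule,
reads the distance between the outermost half-maximum crossings of the
global peak (linear interpolation between bin centers), and subtracts the
known broadening exactly: the smoothed histogram estimates the density
convolved with the kernel and the bin box, which for a locally Gaussian
peak adds h² + bin_width²/12 of variance, so the squared width is
corrected by that amount. The deliberate oversmoothing suppresses the
count noise that makes raw half-max crossings jitter: at the reference
condition (n = 5000 frames, σ = 8°, 1° bins) the raw-crossing rule has
≈ 3% SD and a −4% median bias against the Gaussian closed form
2√(2 ln 2)σ, while the corrected estimator is unbiased to < 0.5% with
≈ 1.8% SD — close to the 1% floor set by sampling alone. The literal rule
(`fwhm_method="crossings"`, optional 3-bin moving average, logged when
used) is retained for comparison. For *multimodal* series the density
method can merge nearby modes before measuring the global peak; use the
crossings method when modes closer than ~3 bandwidths matter. Pooling:
frames from repeat runs are pooled before summarising; per-run breakdowns
can be obtained by summarising runs separately.

**Phosphorylation deltas** are SEP − uP differences of mean and fwhm for a
fixed (genotype, ligand) condition, so a positive hinge delta means
phosphorylation increases the mean hinge angle (the wild-type behaviour);
fraction-above values are reported for both states rather than differenced.

## Contacts and the D159–K83 bond

A ligand contacts a residue in a frame when the minimum distance over all
ligand-atom/residue-atom pairs is strictly below the cutoff. The default
cutoff is 2.5 Å, with 2.0 Å exposed as `--cutoff`: both are in circulation
for this system and neither is privileged, so the cutoff is always recorded
in the output. All atoms participate, hydrogens included when present.
Profiles cover the full troponin-core residue grid; grid residues absent
from the topology are reported with count −1 (missing), not 0, so sparse
toy models cannot masquerade as zero-contact results.

The D159–K83 interdomain ionic bond is scored on Asp159 OD1/OD2 versus
Lys83 NZ with a 4.0 Å default cutoff (standard salt-bridge criterion);
occupancy is the fraction of frames with the minimum distance below the
cutoff. Whether side-chain-only atoms are the right choice is a
convention; the selections are explicit arguments, so any atom sets can be
substituted. Only distance criteria are used — no angular hydrogen-bond
terms.

## Ligand-pose clustering

After alignment, the mass-weighted ligand center of mass per frame is
clustered with DBSCAN: eps 10 Å, min_points = ceil(1% of frames). The
implementation is written for exact reproducibility — min_points counts
the point itself, points are processed in ascending frame order, border
points are assigned to the first cluster that claims them, and final
labels 0, 1, 2, … are ordered by descending occupancy (noise = −1); tests
check it label-for-label against a brute-force reimplementation and
partition-for-partition against scikit-learn's DBSCAN. Occupancy is
reported both as a fraction of all frames and renormalised over clustered
frames, since quoted site percentages can follow either convention. A
cluster's representative pose is the member frame whose center of mass is
nearest the cluster mean (ties to the lowest frame index), written as a
single-model PDB on request. eps is never chosen automatically. No
binding-energy estimation is attempted.

## Motility dose–response

Curves are fit with the four-parameter Hill model
y(x) = y0 + (yinf − y0)·xʰ/(EC50ʰ + xʰ), unweighted least squares with
replicate points entering individually, EC50 optimised on a log scale
(initialised from the concentration nearest half-max, slope 1, y0/yinf
from the response extremes). Parameterising by (y0, yinf) — response at
zero and saturating dose — lets the same machinery fit falling curves such
as the coupling-versus-compound sweep; `floor`/`ceiling` are reported as
min/max(y0, yinf) with the direction kept separately. A fit is refused as
degenerate with fewer than 4 distinct concentrations or a response range
under 5 percentage points. Fitted EC50 is scale-equivariant in the
concentration units to 1e-6 relative.

The coupling constant is ΔM = mean %motile(uP) − mean %motile(P) at the
single-point [Ca²⁺] (default 0.075 µM; 0.073 µM accepted via
configuration — both values are in use and the choice is left to the
user). Because phosphorylation lowers Ca²⁺ sensitivity, a normally
coupled filament scores positive (wild type ≈ +20 to +30); |ΔM| < 5
percentage points is classified *uncoupled* (well below the wild-type
band), and negative ΔM — phosphorylation increasing Ca²⁺ sensitivity —
is *reverse*. The raw P − uP difference is emitted alongside for
transparency. The compound dose–response fits ΔM versus compound
concentration with the same Hill machinery (≥ 4 concentrations including
zero) and reports the compound EC50 in µM.

## Synthetic data: what it emulates, and what it does not

The generators produce a reduced, C-alpha-scale troponin model: chain C
with 161 residues including ideal helices (1.5 Å rise, 2.3 Å radius,
100°/residue) at the A/B positions and side-chain markers K83 NZ and
D159 OD1/OD2; chain I with 169 residues; chain T numbered 202–288; and a
rigid 24-atom ligand. The NcTnC and ITC C-alpha centroids sit exactly
15 Å from the hinge-linker centroid, so rotating the ITC block about the
hinge realises any target hinge angle exactly; helix B is oriented so the
*measured* axis crossing equals the requested A/B angle, making the A/B
schedule (fixed value, linear ramp, or per-frame Gaussian draws) exact by
construction. Bond occupancy is realised deterministically: exactly
floor(target·n) frames get a sub-cutoff marker distance (0.7 × cutoff),
the rest 2 × cutoff, shuffled by the seed. Ligand centers of mass are
drawn from a mixture of Gaussian sites (defaults 0.90/0.07/0.03, σ = 2 Å,
centers ≥ 63 Å apart at radius 45 Å — far outside the protein envelope)
plus optional noise uniform in a 70–110 Å shell, guaranteed farther than
eps = 10 Å from every site so DBSCAN must label it noise. Motility data
follow the Hill model with additive Gaussian noise (defaults: floor 0,
ceiling 80%, Ca EC50 0.075 µM, slope 2, σ = 3 points, 3 replicates);
presets generate normally coupled wild type (coupling exactly +25 at zero
noise), uncoupled (identical curves), and reverse-recoupling sweeps
(compound EC50 67 µM, coupling running 0 → −25). Responses are clipped to
[0, 100]%, which slightly biases the floor upward at σ > 0.

Determinism contract: the seed is mandatory, every randomness source uses
its own derived stream (hinge draws, bond shuffle, global motions, poses,
A/B draws, motility noise), the same seed and spec give bit-identical
output, and every generator returns its ground truth alongside the data —
tests never re-derive truth from the data itself. Toggling the per-frame
global rigid motion changes no drawn angle, label or distance.

What the toy model does **not** emulate: force-field physics, correlated
(autocorrelated) frame-to-frame dynamics, conformation-dependent ligand
binding, multimodal angle distributions, or hydrogen atoms. Passing the
recovery tests therefore demonstrates that the *measurement pipeline* is
correct and well-conditioned — not that any biological claim about real
trajectories is reproduced. Real-trajectory headline numbers (site
occupancies near 90%, specific hinge-angle tables) depend on microsecond
simulations and wet-lab assays outside desk scale; the acceptance script
instead reports the pipeline's recovered values under the stated synthetic
conditions.

## Problem sizes and numerical choices

The shipped study conditions use 5000 frames for recovery checks (hinge,
clustering), 2000 for occupancy, 1000 for the A/B constancy check, 400 per
condition in the `run-all` demonstration set, and 200 simulated datasets
for the EC50-error statistic — sizes at which every estimator's sampling
error is comfortably inside its documented band while the full suite runs
in well under a minute per stage on one core. Report CSVs round floats to
4 significant figures so repeated runs are byte-identical across
platforms. Hinge draws are clipped to [0.5°, 179.5°] to avoid degenerate
collinear geometry; Kabsch fits reject collinear references (second
singular value ≤ 1e−8 × the first); PDB output refuses coordinates
outside the fixed-column range (−999.999 … 9999.999 Å).

## Known limitations

- The hinge-angle construction is a declared stand-in validated by
  parameter recovery, not a reimplementation of any particular published
  hinge definition; absolute values are comparable only within a fixed
  domain configuration.
- The density fwhm assumes a locally Gaussian global peak; strongly
  skewed or multimodal distributions should use `fwhm_method="crossings"`.
- Contact profiles on the C-alpha-scale toy model involve far fewer atoms
  per residue than all-atom trajectories; cutoff semantics are identical
  but absolute probabilities are not comparable.
- The coupling classification threshold (5 points) is a convention chosen
  well below the wild-type band, not a fitted noise model.
- No statistical tests across replicate runs are performed for the angle
  metrics; replicates are pooled.
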