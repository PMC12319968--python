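# Methods

This note documents the models, the synthetic data, the numerical choices,
and the limits of what the test suite demonstrates.

## Synthetic head geometry

The source space consists of three nested triangulated surfaces with
identity vertex correspondence: a deep white-matter boundary (default
radius 70 mm), a superficial pial surface (72 mm), and their mid-surface,
surrounded by a scalp surface (85 mm). All are icospheres sharing one set
of unit directions; an optional smooth radial bump field (a seeded mixture
of broad lobes, amplitude in mm) is applied identically to every layer, so
the surfaces are non-spherical but exactly parallel — the per-vertex layer
separation equals the difference of the nominal radii. The 2 mm default
separation mirrors human cortical thickness (2–5 mm). Dipole orientations
are the outward vertex normals of the mesh, so sources are
near-radial with small tangential components, as on a real cortical sheet
the orientations would be far more varied; exactly radial dipoles are
magnetically silent in a spherical conductor and receive zero beamformer
weight.

Mesh resolution is set by the icosphere subdivision level: level 3 gives
642 vertices per layer (~9.4 mm edges, used by most unit tests), level 4
gives 2562 (~4.7 mm, used for the study-condition sweeps). At level 4 a
5 mm FWHM patch covers the centre vertex plus a ring of low-weight
neighbours and occasionally degenerates to a single vertex (a warning is
emitted); this is the resolution limit of the synthetic mesh, not of the
method.

Sensors are packed on scalp vertices by a seeded greedy scan: vertices are
visited in a shuffled order and accepted when at least the requested
inter-sensor distance from all accepted sites, which yields a maximal
packing and is deterministic given the seed. Each sensor carries one to
three orthonormal measurement axes: the radial axis is the scalp normal
`r = [x, y, z]`; the first tangential axis is `normalize([y, −x, 0])`
(with the fallback `normalize(e_x − (r·e_x) r)` at the poles where the
formula vanishes); the second tangential axis is their cross product. The
tangential axes are normalised to unit length so all channels have uniform
gain. Scalp offsets reposition sensors along their radial axes from their
recorded scalp foot points, exactly.

Co-registration error is modelled as a *rigid* mis-alignment: the three
fiducials (nasion-like and two pre-auricular-like points at canonical
scalp locations) are displaced by iid Gaussian noise, and the Kabsch
least-squares rigid transform from true to displaced fiducials is applied
to all sensor positions and axes before the reconstruction lead fields are
computed (a fresh error per simulated source).

The alternative generative model (AGM) breaks the identity between
simulation and reconstruction: cortical layers are resampled from a
one-level-denser icosphere (default 10% more vertices than the
reconstruction mesh, excluding all coinciding directions, triangulated by
convex hull), and sensor positions receive 1 mm Gaussian jitter. The
reconstruction always uses the unperturbed model.

## Forward model

The magnetic field of a current dipole in a homogeneous conducting sphere
follows the Sarvas closed form; sensors are point magnetometers, and a
channel reads the field projected on its measurement axis. Units are mm /
nAm / fT throughout. The closed form makes the key physics exact:
radial dipoles produce no external field, superposition is exact, and the
field is invariant under common rigid rotations about the sphere centre —
all asserted in the tests. Realistic single-shell or boundary-element
conductors are deliberately out of scope; the forward kernel is recorded
in the lead-field metadata.

## Trial simulation

Defaults: 200 trials of 1000 ms at 200 Hz (time axis −500…+495 ms), a
20 Hz sinusoidal patch source of 5 mm FWHM and 10 nAm active during
[100, 500] ms (8 whole cycles; the window is placed to coincide with the
ROI analysis' active window — only its duration is externally
constrained). The source amplitude is arbitrary because noise is scaled to
the signal: `A_signal` is the mean across channels of the per-channel
standard deviation of the noiseless single-trial sensor matrix, and
`A_noise = A_signal · 10^(−SNR/20)` for a requested single-trial SNR in
dB. A `fixed_magnitude` mode instead sets
`A_noise = A_ref · 10^(level/20)` independent of the signal, for studies
(scalp-offset sweeps) where signal-dependent scaling would cancel the
benefit of closer sensors; the reference amplitude is a study-level choice
recorded with the run, and only the ordering of levels is meaningful.

Interfering brain noise adds five patch sources at random mid-surface
vertices whose time courses are band-limited Gaussian noise (10–30 Hz,
synthesised spectrally so out-of-band power is exactly zero) with standard
deviation 0.4 × the source-of-interest amplitude. Source locations and
amplitudes are fixed across trials; waveforms are drawn fresh per trial by
default, with a flag to repeat one waveform across trials (the stricter
reading of trial-coherent noise). Geodesic distances for all patches are
Dijkstra shortest paths over the mesh edge graph with Euclidean weights —
on these near-uniform meshes the chord-vs-arc error is sub-percent,
small against the 5 mm patch scale.

## Inversion and free energy

Data are reduced before inversion: spatial modes are the leading
eigenvectors of the summed channel Gram of the candidate lead fields
(capped at 274; with fewer channels this is a full-rank rotation), and
temporal modes (default 4) come from an SVD of the trial-averaged,
band-passed (10–30 Hz zero-phase FIR, 33 taps), optionally Hann-tapered
data. Whole-brain inversions use the Hann taper; ROI inversions do not.
When two models are compared, both use *one* spatial projector built from
both Grams, so their free energies are evaluated on identical data. The
reduced data are rescaled to unit average mode variance (the factor is
recorded); all mode-space prior components are normalised to trace = m.

ReML maximises the penalised log-likelihood of the reduced samples over
log-hyperparameters λ = log h with independent Gaussian hyperpriors
(mean −4, variance 16 — mildly informative, spanning e^(−4±8)) by Fisher
scoring with backtracking, so the objective is non-decreasing by
construction; λ is clipped to [−16, 8]. The reported free energy adds the
Laplace complexity correction ½ log det(Σ_λ Π). With hyperparameters held
fixed the same code path returns the exact Gaussian log evidence, which
the tests pin against a brute-force evaluation on an 8-channel instance.

Priors: **EBB** sets per-vertex variance `w_i ∝ 1/(l_iᵀ C_y⁻¹ l_i)` from
the regularised sample covariance (`C_y + 10⁻⁴·tr(C_y)/m·I`), normalised
to unit trace, with zero weight for magnetically silent columns. **MSP**
builds a library of rank-one patch components (default 256 centres per
layer, sampled uniformly; forced centres can be injected, e.g. the true
source vertex for matched-model runs — the idealisation that makes MSP a
best case) and greedily adds the component that most increases a short-run
free energy, stopping below a 0.01 nat improvement; ties break to the
lowest library index, making the search deterministic. **IID** is an
identity source covariance (minimum-norm-like) and **COH** a sparse local
smoother built from repeated one-ring averaging (LORETA-like); both exist
to demonstrate that non-sparse priors cannot separate layers.

## Laminar decisions

Whole-brain: ΔF = F_pial − F_white, decided by sign, significant when
|ΔF| > 3 (evidence ratio ≈ 20). ROI: per vertex and trial, band power =
variance of the band-passed posterior time course within the window
(filter half-length trimmed from the window edges); per-vertex paired t of
active-minus-baseline power over trials; per surface, vertices at or above
the 75th percentile of signed t (simulated sources only add power, so the
signed tail is the informative one; an absolute-value variant is
available) joined with their correspondence partners form the ROI; the
final statistic is a regularised paired t over trials of the
pial-minus-white mean absolute ROI power change, with variance floor
`s₀² = 10⁻⁶ ×` the mean squared ROI value guarding the degenerate
zero-variance case. Significance uses the two-tailed critical t at
df = n_trials − 1.

Both procedures are organised blockwise per layer (two-operand sums,
per-vertex-independent weights and posterior rows), which makes swapping
the pial/white labels negate ΔF and the ROI t *bit-exactly* — a structural
guarantee the tests assert, not a numerical coincidence.

## Sweeps and statistics

`SweepConfig` describes a full factorial over noise levels, inter-sensor
distances, axis counts, offsets, fiducial errors, and
(simulated, reconstructed) patch-size pairs, with 60 sources per surface
by default. Per-cell seeds are CRC32 hashes of the master seed and the
condition tuple, so adding a condition never changes other cells' draws;
source vertices are drawn per array geometry so SNR levels share sources.
Failures are recorded per row and never abort a sweep; completed cells can
be cached and resumed. Summaries report percent correct / percent pial /
percent significant with binomial standard errors; inference uses exact
two-sided binomial tests against 50%, exact McNemar tests on discordant
pairs, and logistic regressions (statsmodels MLE, Wald p, separation
flagged) of accuracy or bias on ordered condition levels.

## Problem sizes

The shipped test suite and the acceptance script run scaled-down study
conditions chosen once: level-4 meshes (2562 vertices per layer), a 35 mm
single-axis array (~85 sensors on the full synthetic scalp sphere), 50
trials, 20 (tests) or 12 (script) sources per surface per condition, and
32 MSP patch centres per layer. Full-size runs (200 trials, 60 sources,
256 centres) use the same code paths and finish in hours rather than
minutes.

## Known limitations

* The geometry is a sphere pair, not cortex: no sulci, no orientation
  variety beyond the bump field, uniform depth. Absolute classification
  percentages therefore characterise the synthetic conditions, not any
  participant's anatomy, and are expected to be optimistic (ceiling
  accuracy at moderate SNRs, near-total superficial bias for IID/COH).
  Directional findings — accuracy rising with SNR, density, axes and
  proximity, falling with co-registration error and model mismatch — are
  the meaningful outputs.
* The forward model is a spherical conductor with point magnetometers:
  no realistic skull boundary, pickup-coil integration, crosstalk, gain
  or cross-axis errors.
* Sensor noise is white and Gaussian; no environmental interference,
  drift, 1/f noise, or head movement.
* MSP here is a greedy forward selection, not the full ARD scheme; at
  desk scale the greedy search with free-energy scoring reproduces the
  behaviour that matters (selecting the generating patch when present).
* The exact form of the cited ROI variance regularisation is not public;
  the floor-based form used here is a documented stand-in, and the plain
  paired t is available for comparison.
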