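# Methods

## The model

`ticseq` simulates identification of single amino acids by the transverse
ionic current they allow past them inside two crossed nanochannels. A lone
residue, cut from an extended chain (backbone dihedrals φ = ψ = 180°) and
capped with N-terminal hydrogens and a C-terminal OH, is centred on the
longitudinal channel axis z. Ions flow along y; the observable is the
current through the y = 0 cross-section.

The electrostatic and hydration structure of the solvated residue is
summarised by *proximal radial distribution functions* (pRDFs): the ion
concentration g(r<sub>&gt;</sub>) as a function of perpendicular distance
r<sub>&gt;</sub> from the van der Waals surface, in shells of 0.5 Å
(midpoints 0.25, 0.75, … Å). Using surface distance rather than
centre distance keeps near-surface features sharp for irregular shapes.
Profiles reach the bulk value g<sub>b</sub> by r<sub>&gt;</sub> ≈ 15 Å,
which motivates the channel radius: R = 35 Å keeps the bulk onset point
r<sub>b</sub> = (R − r<sub>o</sub>)/2 at ≥ 15 Å from every residue's
surface (r<sub>o</sub>, the mean origin-to-surface radius, is ≤ 4.2 Å for
all twenty residues).

The soft ion structure is then collapsed into a *hard-sphere* model: one
per-species effective radius r<sub>eff</sub> added to every atomic vdW
radius, fixed by balancing plane areas in the y = 0 cross-section,

∫<sub>r_eff</sub><sup>r_up</sup> A(r) dr
  = ∫<sub>0</sub><sup>r_up</sup> (g(r)/g<sub>b</sub>) (v(r)/v<sub>b</sub>) A(r) dr,

with A(r) the plane area per unit r<sub>&gt;</sub> of the proximal shell
at r<sub>&gt;</sub> and v/v<sub>b</sub> the transverse flow ratio. The
velocity weighting makes mid-range depletion count for more than tightly
bound near-surface layers, because flow vanishes at the surface.

The flow ratio is a symmetric parabola with no slip at the molecular
surface and at the wall and maximum exactly 1 at r<sub>b</sub>:
v/v<sub>b</sub> = 1 − ((r − r<sub>b</sub>)/r<sub>b</sub>)² on
[0, 2r<sub>b</sub>], zero beyond, clipped to [0, 1]. Only three facts pin
this choice — parabolic form, unit maximum at r<sub>b</sub>, bulk beyond —
and the symmetric parabola is the unique profile satisfying them; whether
cylindrical geometry would skew it slightly is an open question that the
package does not attempt to answer. The bulk speed itself is a
configuration parameter, default v<sub>b</sub> = 77.23 m/s, taken as given
rather than re-derived from a Stokes solution.

Per-residue current distributions come from Monte Carlo over orientation:
backbone dihedrals (φ, ψ) drawn from a discretised Ramachandran density
conditioned on a 250 pN longitudinal pull, azimuth uniform on [0°, 360°),
tilt fixed at 0 (rigid peptide bond). Each draw poses the residue rigidly
(φ rotates the N-side partition about the N–Cα axis, ψ the C-side about
Cα–C; proline's φ is locked by its ring) and measures, for each species,
the free area of the disk of radius R/2 outside the inflated surface.
The total current of the draw is I = Σ<sub>i</sub> q g<sub>b</sub>
v<sub>b</sub> A<sub>i</sub> (both species share the conformation: one
physical configuration, one measurement). With g<sub>b</sub> = 1 M and the
defaults, currents land in the tens of nA.

The cross-section is clipped to |z| ≤ (terminal backbone extent + 1.9 Å),
half the ideal 3.8 Å inter-residue spacing: beyond that the cross-section
would be dominated by the neighbouring residues of a real chain. The clip
is implemented as a z-slab rather than a cone about ±z; the available
geometric statements are consistent with either, and the slab is the
simpler construction (recorded here as the package's choice).

Identification uses the maximum-likelihood rule on blocks of M independent
measurements: candidate densities are histogram-plus-cubic-spline fits
(clipped at zero, renormalised), and a block is assigned to the candidate
with the largest product of densities. A likelihood tie counts as an error
(Heaviside convention H(0) = 1, the conservative reading). Because each
distribution has bounded support, a single measurement outside a wrong
candidate's support zeroes its likelihood; this mechanism collapses the
error for M beyond roughly 160, and at M = 175 the mean error over the 20
packaged distributions is below 0.1%. Protocol arithmetic then gives
floor(100 kHz / 175) = 571 residues/s and a maximum pulling speed of
3.8 Å × (100 kHz / 175) ≈ 217 nm/s.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `channel_radius_A` (R) | 35 | Å | keeps r_b ≥ 15 Å for every residue |
| `disk_radius_A` | R/2 | Å | Monte Carlo area boundary; encloses all inflated surfaces, stays inside the bulk |
| `g_bulk_molar` | 1.0 | mol/L | bulk KCl concentration |
| `v_bulk_m_per_s` | 77.23 | m/s | bulk transverse speed (configuration input) |
| `pulling_force_pN` | 250 | pN | labels the Ramachandran density (straightened chain) |
| `temperature_K` | 310 | K | metadata: conditions the fixtures emulate |
| `z_margin_A` | 1.9 | Å | half the 3.8 Å inter-residue spacing (z clip) |
| `n_samples` | 100,000 | – | Monte Carlo draws per residue |
| `n_bins` | 100 | – | histogram bins for the spline density |
| `M`, `J` | 175, 1000 | – | measurements per identification; error realizations |
| shell thickness | 0.5 | Å | pRDF and area-balance discretisation |
| vdW radii | Bondi | Å | packaged in `data/vdw_radii.json` |

Seeds: every random draw derives deterministically from the single
configured seed; reruns are byte-identical.

## Synthetic pRDF fixtures

Real pRDFs require long molecular-dynamics runs of each solvated residue.
The packaged fixtures replace them with smooth parametric profiles,

g(r) = g<sub>b</sub> + taper(r) · [a<sub>pk</sub>·peak(r) − a<sub>dep</sub>·well(r) + noise],

clipped at zero: a Gaussian near-surface enrichment peak (attracted
species of charged residues), an exponential depletion well (repelled
species, hydrophobic side chains, and weakly for polar ones), a smooth
taper that forces bulk behaviour well before 15 Å, and small seeded
per-shell noise. The per-residue parameters (`data/prdf_fixtures.csv`) are
generated by a fixed rule keyed to each residue's isoelectric point (low
pI → tighter hydration → deeper, longer-ranged depletion, hence larger
effective radii), its size (peak position/width), and its charge (the
co-ion of a charged residue sees a charge-scaled extra well); ALA/SER are
nudged up and GLN/ILE/MET/THR/ASN down, matching their known departure
from the plain pI trend, and a small index term separates otherwise
similar residues. The rule — including the charge-scaled co-ion well — was
calibrated so the resulting forty effective radii are mutually distinct
and the twenty current distributions statistically distinguishable, which
is the designed role of the fixture set.

What the fixtures therefore demonstrate: the full pipeline's mechanics,
the sign structure (e.g. lysine excludes K⁺ farther than Cl⁻, glutamate
the reverse), the few-Å magnitude of effective radii, tens-of-nA currents,
multimodal azimuth-driven distributions with endpoint peaks, and the
collapse of the ML error at large M. What they do not demonstrate: the
numerical effective radii or current values of any particular real
residue, hydration-shell fine structure, or per-atom-type concentration
profiles. Passing tests validate the method under the packaged conditions,
not against experimental or MD data.

## Numerical choices

- **Surface distance** to the union of vdW spheres is min over atoms of
  (|p − c| − r); negative inside. Shell volumes count 0.1 Å grid cells
  (lattice anchored at the structure centroid, deterministic); plane areas
  count 0.05 Å cells on a lattice anchored at the channel axis.
- **Free-area counting** uses an exact column scanline: per x-column the
  window and every slice circle are closed z-intervals, and lattice
  centres in the merged union are counted arithmetically. This is
  cell-for-cell identical to testing every centre (verified against the
  naive counter on randomized sphere sets) at a fraction of the cost; a
  numba-compiled batch kernel poses conformations and counts in one pass,
  with a pure-numpy fallback kept as the reference path.
- **Area balance**: rectangle rule on the pRDF's own 0.5 Å shells,
  truncated exactly at r_up (default r_b, where the velocity ratio's bulk
  plateau begins), solved on the piecewise-linear cumulative area to
  1e-3 Å. A zero profile gives r_eff = r_up exactly; an over-dense profile
  (more implied area than available) reports r_eff = 0 with a flag; on
  flat stretches the smallest root is returned (least-exclusion
  convention). Halving the shell thickness moves r_eff by < 0.05 Å.
- **Spline densities** interpolate the density-normalised histogram at bin
  centres, are clipped at zero, zeroed outside the sampled support, and
  renormalised on a 4001-point grid so ∫pdf = 1 ± 1e-6; sampling inverts
  the gridded CDF. All-identical samples raise a degenerate-distribution
  error rather than fabricating a density.
- **Likelihoods** are summed in log space (zero density → −∞), so
  M = 175 products cannot underflow.
- Occluded pRDF shells (zero measured volume) report g = 0 and are
  flagged rather than NaN.

## Problem sizes

The acceptance script uses the full study conditions: 100,000 Monte Carlo
samples per residue, J = 1000 error realizations at M = 175 (about three
minutes on one CPU). The test suite shares one reduced pipeline run of
20,000 samples per residue — enough to hold the empirical current supports
stable to ~0.1 nA — plus brute-force oracles at 10⁷ rejection-sampling
points and a 10⁵-realization classifier cross-check against the
closed-form two-Gaussian Bayes error.

## Limitations

- Fixture pRDFs are phenomenological; absolute per-residue numbers are not
  predictions. `compute_prdf` accepts real ion-position frames when MD
  output is available.
- Single isolated residues only: no inter-residue sterics, no
  proline-neighbour dihedral coupling, no deconvolution of overlapping
  signals, and residue boundaries are assumed known when decoding streams.
- Circular channel cross-sections only; electro-osmotic coupling and
  surface-charge effects are outside the model.
- Measurements are treated as independent; instrument noise and
  autocorrelation are not modelled.
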