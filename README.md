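# ticseq

Hard-sphere simulation of **transverse ionic transport past single amino
acids in crossed nanochannels** — a model study of whether the 20
proteinogenic amino acids can be identified, one at a time, from the ionic
current they block while a polypeptide is pulled through a nanochannel
intersected by a perpendicular ion-carrying channel.

The package is aimed at people modelling nanofluidic single-molecule
sensing: it turns ion-concentration profiles around a residue into a
hard-sphere exclusion geometry, Monte Carlo samples residue orientations to
get per-residue current distributions, and quantifies identifiability with
a maximum-likelihood error analysis.

## Model

A residue sits at the intersection of a longitudinal channel (radius
R = 35 Å, the translocation axis z) and a transverse channel carrying a
1 M KCl current driven along y. The identifying observable is the ionic
current through the *area-limiting cross section* y = 0.

1. **pRDFs.** The local concentration g(r<sub>&gt;</sub>) of K⁺ and Cl⁻ is
   binned in 0.5 Å shells of perpendicular distance r<sub>&gt;</sub> from
   the residue's van der Waals surface, relaxing to g<sub>b</sub> = 1 M by
   r<sub>&gt;</sub> ≈ 15 Å. `ticseq.prdf` computes these from ion-position
   frames, or synthesizes them with the charge-dependent phenomenology
   (counter-ion enrichment, co-ion depletion, hydrophobic depletion of
   both).
2. **Effective radius.** For each residue and ion species, a single
   inflation r<sub>eff</sub> added to every atomic vdW radius reproduces
   the velocity-weighted ion deficit implied by the pRDF via the area
   balance

   ∫<sub>r_eff</sub><sup>r_up</sup> A(r) dr = ∫<sub>0</sub><sup>r_up</sup>
   (g/g<sub>b</sub>) (v/v<sub>b</sub>) A(r) dr,

   where A(r) is the y = 0 plane area per unit r<sub>&gt;</sub> of the
   proximal shell and v/v<sub>b</sub> is a parabolic no-slip flow profile
   peaking at r<sub>b</sub> = (R − r<sub>o</sub>)/2.
3. **Currents.** Monte Carlo draws of backbone dihedrals (Ramachandran
   density under a 250 pN pull), uniform azimuth, and zero tilt pose the
   residue; each draw contributes I = Σ<sub>i</sub> q g<sub>b</sub>
   v<sub>b</sub> A<sub>i</sub> over both species, where A<sub>i</sub> is
   the free area of the R/2 disk (clipped along z to half the 3.8 Å
   inter-residue spacing beyond the backbone caps) outside the inflated
   surface. Currents land in the tens of nA.
4. **Classification.** Histogram + cubic-spline densities per residue; a
   block of M independent measurements is assigned by maximum product
   likelihood. Bounded supports make wrong candidates collect zero
   likelihood as M grows, collapsing the error.

## Worked example

```python
from ticseq import (
    VelocityProfile, extended_ramachandran_density, load_residue_template,
    mean_surface_radius, sample_currents, solve_effective_radius,
)
from ticseq.pipeline import fixture_prdfs

lys = load_residue_template("LYS")
vp = VelocityProfile(r_o=mean_surface_radius(lys))
prdfs = fixture_prdfs(seed=1)
reff = {
    sp: solve_effective_radius(lys, prdfs[("LYS", sp)], vp).r_eff
    for sp in ("K+", "Cl-")
}
print(reff)
dist = sample_currents(lys, reff, extended_ramachandran_density(), vp,
                       n=20_000, seed=1)
print(f"{dist.mean():.1f} nA on [{dist.support[0]:.1f}, {dist.support[1]:.1f}]")
```

prints

```
{'K+': 7.247702868809196, 'Cl-': 5.535455054750982}
29.0 nA on [23.7, 33.5]
```

i.e. positively charged lysine excludes the repelled K⁺ about 1.7 Å
farther than the attracted Cl⁻, and its transverse current signature
spans roughly 24–34 nA depending on orientation.

The same chain for all 20 residues, plus the error analysis, runs from the
command line:

```bash
ticseq run --seed 1 --out artifacts/
ticseq report --frequency 100000 -M 175
```

The protocol report prints 571 residues/s and a 217 nm/s maximum pulling
speed for 100 kHz measurements at M = 175.

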