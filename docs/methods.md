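# Methods

## The system and the questions

The package analyses the structured hydration of a rigid, linear,
triplet-periodic peptide — the (Pro-Pro-Gly)ₙ collagen-mimetic triple
helix is the motivating case.  Each residue contributes one backbone
carbonyl oxygen as a potential water-binding site, and the three residues
of a repeat play distinct roles: the X-position carbonyl accepts an
interchain hydrogen bond from a neighbouring glycine amide and binds no
water; the G (glycine) carbonyl binds about one water; the Y-position
carbonyl binds two in the crystal-like regime and ~1.6–1.7 under fast
exchange.  The analyses quantify that pattern (occupancy), its geometry
(RDF shells, SASA), its kinetics (residence times) and the chain's shape
(Rg/Ree against an analytical bead model).

All distance criteria are distance-only: a water "belongs" to a site when
its **oxygen** is within a cutoff of the site oxygen.  Hydrogen positions
are never consulted, because water hydrogens interchange by libration
without the oxygen leaving its bound position.  No angular hydrogen-bond
criterion is applied anywhere.

## The analytical bead model

An n-triplet chain is modelled as n equal-mass points at fixed spacing l
on a line.  Writing k = ⌊n/2⌋:

- odd n = 2k+1: the center of mass coincides with the central bead,
  Ree = 2kl, and averaging the squared distances of the non-central beads
  gives Rg²/Ree² = (1/6)(k+1)(2k+1)/(2k)² via the square pyramidal number
  P_k = k(k+1)(2k+1)/6;
- even n = 2k: the nearest beads sit l/2 from the center of mass,
  Ree = (2k−1)l, and Rg²/Ree² = (1/12)(2k+1)/(2k−1).

Both branches give Rg² = (l²/12)(n+1)n (odd) or (l²/12)(n+1)(n−1) (even)
and converge to Rg/Ree = 1/√12 ≈ 0.2887 — the rigid-rod signature, well
below the ideal freely-jointed chain value 1/√6 ≈ 0.408 that the
Monte-Carlo reference ensemble reproduces.  The bead spacing is estimated
as the least-squares slope of Ree against n; for two consecutive lengths
this is their difference (81.41 − 72.56 = 8.85 Å for n = 9, 10, the
package default).  The empirical globular scaling Rg = 0.395·N^0.6 +
7.257 Å serves as the compact-protein foil.

One normalisation subtlety is preserved deliberately: the odd-branch
ratio averages over the 2k **non-central** beads (the central bead sits on
the center of mass), while the plain all-points radius of gyration
averages over everything.  The two definitions differ for odd n and the
package exposes both — `bead_convention_rg` (bead-model convention,
consistent with the closed forms to machine precision) and
`radius_of_gyration` (general purpose).  Rg is unweighted by default
(mᵢ = 1, the polymer-physics convention); mass weighting is a flag, with
zero-mass (unknown-element) atoms excluded from weighted sums.

## What the synthetic generator emulates

`generate_scaffold` builds the rigid geometry: triplet-center beads at
exact spacing l (default 8.85 Å) on the box axis, and three carbonyl-O
sites per triplet per chain on a helix of radius 4.0 Å (10 residues per
turn, chains phased 120° apart).  The X-site burial by the interchain
amide is emulated *geometrically*: four nitrogen pseudo-atoms at 2.0 Å
spread over the X oxygen's outward hemisphere, and two at 2.4 Å partially
shielding each G oxygen.  This yields the qualitative exposure ordering
Y > G > X and the period-3 SASA sawtooth.  With equal-size occluder
spheres a point-sampled SASA cannot reach exactly zero for a contact pair,
so X is "small", not zero; tests assert the ordering, not an absolute.

`generate_hydration_trajectory` attaches first-shell waters: each site of
role r carries pattern[r] slots (default 0-2-1 for X-Y-G).  Slot
occupants persist for continuous-time exponential sojourns (defaults
25.68 ps for Y, 81.72 ps for G — the two reference scales of the
residence analysis), discretised to frames by ceiling with a one-frame
minimum — mirroring how a saved trajectory samples continuous kinetics at
1–10 ps intervals.  A departing occupant is replaced immediately
(substitution) or, with probability `vacancy_prob`, leaves the slot empty
for exactly one frame.  Bound waters are single oxygen points placed
2.65 Å from the site oxygen (the first RDF maximum) in a random direction
within a 40° cap facing away from the axis, re-drawn until at least 3.6 Å
from every other site oxygen so that distance counting attributes each
water unambiguously at both the 3.225 and 3.5 Å cutoffs.  Inactive
occupants are parked on a grid of points at least 6 Å from every site.
Optional bulk water is uniform at a stated number density (0.0334 Å⁻³,
liquid water at ambient conditions, when enabled), rejected within 3.5 Å
of any site oxygen, and **static**: it normalises RDFs and populates the
second shell but never enters first-shell counts or residence statistics.

What the generator does *not* emulate — and hence what passing tests do
not show about real simulations: water diffusion and re-binding of the
same molecule, force-field energetics, water geometry (H atoms),
backbone flexibility, temperature.  Ground truth (every drawn sojourn,
the per-site occupancy ledger, censoring flags) is returned alongside the
trajectory, so recovery tests compare against the generator's own record,
not against wished-for values.

## Shell analysis

g(r) is the frame- and center-averaged pair count per spherical shell,
normalised by the shell volume and the per-frame number density of the
partner set; its running integral n(r) is the mean neighbour count within
r.  Defaults: bin width 0.05 Å, r_max 8 Å, error if r_max exceeds half
the smallest box extent (minimum-image validity).  Extrema are located on
a moving-average smoothed profile (odd window, edge-replicating pad so
monotone profiles stay extremum-free) and reported at bin centers.

Two cutoff conventions coexist, as the analysis context demands:
**3.225 Å** (first minimum of the bulk water oxygen–oxygen RDF) for
ensemble-averaged occupancy, and **3.5 Å** for single-frame or
crystal-like counts, where the slightly larger value absorbs static
disorder.  3.25 Å is treated as a rounded display value of 3.225.  The
second shell ends at 5.61 Å by default.  Second-shell coordination is
computed both ways: the n(r) annulus integral (which includes waters not
hydrogen-bonded to the first shell) and the two-hop count of *distinct*
waters within the cutoff of any first-shell water — a population, not a
bond count, so a water bridging two first-shell ligands counts once, and
a site with an empty first shell contributes zero.

Per-role occupancy tables are reported both over all sites and excluding
each chain's first and last triplet, since chain ends deviate from the
pattern; the exclusion flag is off by default.

## SASA

Shrake–Rupley-style point sampling with a deterministic golden-spiral
lattice (default 960 points; quadrupling changes cluster totals by <1%).
Radii are Bondi van der Waals values (C 1.70, N 1.55, O 1.52, H 1.20,
S 1.80 Å), configurable; the probe is 1.4 Å, a water radius.  Waters and
ions are excluded from the occluder set by default (peptide-only
surface); hydrogens occlude when present.  The SASA–occupancy relation is
summarised by a product-moment correlation with its least-squares line.

## Residence kinetics

A sojourn is a maximal run of presence of one water identity at one site
in which gaps of exactly one frame are bridged (the bridged frame counts
toward the duration); a gap of two or more frames ends the episode.  The
grace window is one **frame**, not one picosecond, and is applied per
gap, so alternating patterns like 1,0,1,0,1 merge into one episode — the
rule judges each gap individually.  Both choices are exposed (`grace`
parameter).  Episodes touching either end of the trajectory are flagged
censored and excluded from durations by default; window censoring biases
uncensored means low when sojourns approach the window length, which is
why recovery tests use windows ≫ the mean.

Durations are binned right-closed (a duration equal to a bin edge — the
common case, durations being multiples of the frame interval — falls in
the lower bin) and fitted by unweighted nonlinear least squares to
f(t) = A·exp(−t/τ) over non-empty bins; the arithmetic mean of the
durations is the second, independent estimate of τ, and the two agree
within 10% on exponential data.  The substitution fraction classifies
each departure by whether the site's occupant count in the following
frame stayed at or above the role's modal count — 1.0 for pure
substitution, 0.0 when every departure leaves a transient vacancy.

## Problem sizes and numerical choices

- Ideal-chain reference: 10⁵ chains × 10³ unit steps (≈20 s); analysis
  driver defaults to 2×10⁴ chains for interactive use.
- Occupancy/residence recovery: 10⁴ sojourns per role for fit recovery;
  the role-ordering check runs 100 seeded end-to-end pipelines of
  1 triplet × 1500 frames × 2 ps each.
- RDF flatness: 40 independent ideal-gas frames (≈36,000 molecules
  total), bins of 0.1 Å.
- Exponential fits: initial guess (max count, first-moment τ), zero-count
  bins excluded, non-convergence raises with diagnostics rather than
  returning silently.
- Minimum image: fractional wrap for orthorhombic cells; wrap plus an
  exhaustive 27-image search for triclinic cells (correct for any cell
  shape at negligible cost).
- PDB I/O is fixed-width ATOM/HETATM/MODEL/ENDMDL/CRYST1 only, with
  coordinates at the format's 0.001 Å precision; the 1 Å/90° placeholder
  cell is read as "no box".  Water residues are recognised by name
  (HOH/SOL/WAT/TIP3/TIP4/…, configurable).

## Known limitations

- Synthetic waters are points; analyses needing hydrogen positions are
  out of scope by design.
- Bulk water is static and never exchanges with the first shell, so
  second-shell kinetics are not modelled.
- The X-site burial is a geometric emulation; absolute SASA values are
  not comparable to all-atom structures, only orderings and correlations.
- The even/odd bead formulas assume a perfectly rigid, equidistant chain;
  no fitting to noisy coordinates is provided.
- Single-frame crystal counts on real structures depend on deposited
  water completeness; the package reports what is in the file.
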