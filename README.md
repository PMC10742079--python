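# hydrashell

Structured-hydration analysis of triplet-periodic (collagen-mimetic)
peptides: per-carbonyl water occupancy, radial-distribution hydration
shells, rolling-probe solvent-accessible surface area, water
residence-time kinetics, and chain-shape metrics with an analytical
equidistant-bead radius-of-gyration model.

## Who it is for

Researchers studying hydration of rigid helical peptides — the
(Pro-Pro-Gly)ₙ triple helix being the canonical case — who want the
standard battery of trajectory analyses as a tested library, exercised
end-to-end on synthetic trajectories with known ground truth.  Each
backbone carbonyl oxygen is a potential water-binding site; the three
residues of an X-Y-G repeat behave differently (X binds no water, G about
one, Y up to two), and the package quantifies that pattern, its geometric
origin, and its kinetics.

## The core models

**Equidistant-bead chain.** An n-triplet peptide is n equal-mass points
at spacing l on a line.  With k = ⌊n/2⌋:

    Rg²/Ree² = (1/6)(k+1)(2k+1)/(2k)²    (odd n = 2k+1, Ree = 2kl)
    Rg²/Ree² = (1/12)(2k+1)/(2k−1)       (even n = 2k, Ree = (2k−1)l)
    Rg²      = (l²/12) · (n+1)n  [odd]  or  (n+1)(n−1)  [even]

Both branches tend to Rg/Ree = 1/√12 ≈ 0.2887; an ideal freely-jointed
chain gives 1/√6 ≈ 0.408 (reproduced here by Monte Carlo); a globular
protein follows Rg = 0.395·N^(3/5) + 7.257 Å.

**Hydration shells.** g(r) of water oxygens around site oxygens, its
running integral n(r), first/second minima (3.225 / 5.61 Å defaults,
3.5 Å for single-frame counts), per-site occupancy, and second-shell
coordination both by annulus integration and by counting waters
hydrogen-bond-distance from the first shell.

**Residence kinetics.** Sojourns of individual water oxygens within
3.5 Å of a site, with single-frame absences bridged (grace rule), binned
into f(t) and fitted to A·exp(−t/τ).

**SASA.** Shrake–Rupley-style point sampling (deterministic golden
spiral, 960 points, Bondi radii, 1.4 Å probe) with the SASA–occupancy
correlation.

## Worked example

```python
from hydrashell import (BeadModel, bead_ratio_squared, bead_rg,
                        ScaffoldConfig, ExchangeConfig,
                        generate_scaffold, generate_hydration_trajectory,
                        site_occupancy)

m = BeadModel(10, spacing_l=8.85)
print(round(bead_ratio_squared(m), 3), round(bead_rg(m), 2))
# 0.102 25.42   -> Rg/Ree = 0.319, Rg = 25.42 Å for a 10-triplet rod

scaffold = generate_scaffold(ScaffoldConfig(n_triplets=4, chains=3))
traj, truth = generate_hydration_trajectory(
    scaffold, ExchangeConfig(n_frames=120, seed=41))
occ = site_occupancy(traj, truth.sites, cutoff=3.225)
print(occ.per_role)
# {'X': 0.0, 'Y': 2.0, 'G': 1.0}   -> the 0-2-1 first-shell pattern
```

The first two numbers are the even-branch bead-model ratio and radius of
gyration of a 10-triplet chain at the 8.85 Å spacing; the dictionary is
the frame-averaged water count per role recovered from the synthetic
trajectory, matching the generator's 0-2-1 ground truth exactly.

A full report (occupancy tables, RDF profiles with extrema, per-residue
SASA, second shell, residence fits, manifest with checksums):

```sh
hydrashell report --outdir results/report --seed 1
hydrashell simulate --out scratch/run --n-triplets 4 --n-frames 200 --seed 1
hydrashell analyze scratch/run.pdb --outdir results/analyze
```

The numbered drivers under `analysis/` walk the study: `01_bead_model.py`
(closed forms, spacing recovery), `02_ideal_chain.py` (Monte-Carlo
reference), `03_hydration_pattern.py` (0-2-1 vs liquid-like 0-1.6-1),
`04_shells_and_sasa.py` (shells, SASA sawtooth, correlation),
`05_residence_times.py` (exponential fits, substitution mechanism).
Each writes its tables under `results/`.

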