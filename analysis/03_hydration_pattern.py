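#!/usr/bin/env python
"""First-shell occupancy: the 0-2-1 pattern and the crystal/liquid contrast.

Generates a triple-chain scaffold with structured hydration and recovers
the per-role water counts in two regimes: frozen exchange (sojourns far
longer than the window — every count constant, as in a crystal structure)
and fast exchange with transient vacancies (fractional Y occupancy, the
liquid-like 0-1.x-1 pattern).  Writes results/occupancy_per_residue.csv.
"""

from pathlib import Path

import pandas as pd

from hydrashell.shells import site_occupancy
from hydrashell.synthetic import ExchangeConfig, ScaffoldConfig, generate_hydration_trajectory, generate_scaffold

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    scaffold = generate_scaffold(ScaffoldConfig(n_triplets=10, chains=3))

    frozen, truth_f = generate_hydration_trajectory(scaffold, ExchangeConfig(
        mean_sojourn={"X": 1e6, "Y": 1e6, "G": 1e6}, n_frames=50, seed=seed))
    occ_f = site_occupancy(frozen, truth_f.sites, cutoff=3.5)
    print("frozen exchange (crystal-like), cutoff 3.5 Å:",
          {r: round(v, 2) for r, v in occ_f.per_role.items()})

    # fast Y exchange with a transient vacancy after every departure: the
    # second Y water is the one that binds last and leaves first
    liquid, truth_l = generate_hydration_trajectory(scaffold, ExchangeConfig(
        mean_sojourn={"X": 25.0, "Y": 4.0, "G": 40.0}, n_frames=600,
        vacancy_prob=1.0, seed=seed))
    occ_l = site_occupancy(liquid, truth_l.sites, cutoff=3.225)
    print("fast exchange with vacancies (liquid-like), cutoff 3.225 Å:",
          {r: round(v, 2) for r, v in occ_l.per_role.items()})
    print("  excluding terminal triplets:",
          {r: round(v, 2) for r, v in occ_l.per_role_excluding_termini.items()})

    rows = [{"chain": s.chain_id, "residue_seq": s.residue_seq, "role": s.role,
             "count_frozen": occ_f.per_site[i], "mean_count_liquid": occ_l.per_site[i]}
            for i, s in enumerate(truth_l.sites)]
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "occupancy_per_residue.csv", index=False)
    print(f"wrote {OUT / 'occupancy_per_residue.csv'}")


if __name__ == "__main__":
    main()
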