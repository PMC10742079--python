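#!/usr/bin/env python
"""Analytical bead-model survey: Rg/Ree of a rigid linear triplet chain.

Tabulates the odd/even closed-form ratios and Rg(n) at the fitted bead
spacing, recovers the spacing from end-to-end distances of consecutive
chain lengths, and contrasts the linear chain with the globular scaling
law.  Writes results/bead_model.csv.
"""

import math
from pathlib import Path

import pandas as pd

from hydrashell.chain import BeadModel, bead_ratio_squared, bead_ree, bead_rg, estimate_spacing, globular_rg

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    spacing = estimate_spacing({9: 72.56, 10: 81.41})
    print(f"bead spacing from Ree(10) - Ree(9): l = {spacing:.2f} Å")

    rows = []
    for n in range(2, 21):
        m = BeadModel(n, spacing)
        rows.append({
            "n_triplets": n, "parity": m.parity,
            "ratio_squared": round(bead_ratio_squared(m), 4),
            "rg_over_ree": round(math.sqrt(bead_ratio_squared(m)), 4),
            "rg_A": round(bead_rg(m), 2), "ree_A": round(bead_ree(m), 2),
        })
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "bead_model.csv", index=False)

    nine, ten = df[df.n_triplets == 9].iloc[0], df[df.n_triplets == 10].iloc[0]
    print(f"n=9  (odd,  k=4): Rg²/Ree² = {nine.ratio_squared:.3f}, "
          f"Rg/Ree = {nine.rg_over_ree:.3f}, Rg = {nine.rg_A} Å")
    print(f"n=10 (even, k=5): Rg²/Ree² = {ten.ratio_squared:.3f}, "
          f"Rg/Ree = {ten.rg_over_ree:.3f}, Rg = {ten.rg_A} Å")
    limit = math.sqrt(bead_ratio_squared(BeadModel(2_000_001, spacing)))
    print(f"large-k limit of Rg/Ree: {limit:.4f} (= 1/sqrt(12))")
    print(f"globular reference at N=90 residues: Rg = {globular_rg(90):.1f} Å "
          f"vs linear-chain {ten.rg_A} Å -> strongly elongated")
    print(f"wrote {OUT / 'bead_model.csv'}")


if __name__ == "__main__":
    main()
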