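#!/usr/bin/env python
"""Residence-time kinetics: sojourn extraction, exponential fits, exchange
mechanism.

Generates long structured-hydration trajectories, extracts per-role
sojourns with the single-frame grace rule, fits f(t) = A·exp(-t/τ), and
measures the substitution fraction (how often a leaving water is replaced
with no vacancy).  Writes results/residence_fits.csv.
"""

from pathlib import Path

import pandas as pd

from hydrashell.kinetics import (
    fit_exponential,
    mean_residence,
    occupancy_trace,
    pool_durations,
    residence_histogram,
    sojourns,
    substitution_fraction,
)
from hydrashell.synthetic import ExchangeConfig, ScaffoldConfig, generate_hydration_trajectory, generate_scaffold

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    scaffold = generate_scaffold(ScaffoldConfig(n_triplets=4, chains=3))
    traj, truth = generate_hydration_trajectory(scaffold, ExchangeConfig(
        mean_sojourn={"X": 25.0, "Y": 25.68, "G": 81.72},
        n_frames=4000, frame_interval=2.0, vacancy_prob=0.1, seed=seed))
    trace = occupancy_trace(traj, truth.sites, cutoff=3.5)
    sets = sojourns(trace, grace=1)
    subs = substitution_fraction(trace)

    rows = []
    for role, bin_w in (("Y", 6.0), ("G", 16.0)):
        durations = pool_durations(sets, truth.sites, role)
        fit = fit_exponential(*residence_histogram(durations, bin_w))
        rows.append({
            "role": role, "n_sojourns": len(durations),
            "mean_tau_ps": round(mean_residence(durations), 2),
            "fit_A": round(fit.A, 2), "fit_tau_ps": round(fit.tau_mean, 2),
            "fit_r_squared": round(fit.r_squared, 3),
            "generator_tau_ps": {"Y": 25.68, "G": 81.72}[role],
            "substitution_fraction": round(subs[role], 3),
        })
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "residence_fits.csv", index=False)
    print(df.to_string(index=False))
    y, g = df[df.role == "Y"].iloc[0], df[df.role == "G"].iloc[0]
    print(f"ordering: τ(G) = {g.fit_tau_ps} ps > τ(Y) = {y.fit_tau_ps} ps — "
          "the singly hydrated site binds its water longer")
    print(f"wrote {OUT / 'residence_fits.csv'}")


if __name__ == "__main__":
    main()
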