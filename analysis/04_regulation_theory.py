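"""The coupling-gain theory: worked three-environment scenario, the
optimal-coupling landscape over (R, S), and the total-noise phase diagram.

The worked scenario couples one promoter (basal noise sigma = 0.1,
mismatch Y = 4) to three candidate transcription factors: an accurate one
(R = 0.95), a pure-noise one (R = 0) and a moderately correlated one
(R = 0.64) whose signal-to-noise sits above the optimum for its
correlation.  Writes

  results/theory_worked_scenario.tsv
  results/theory_landscape.tsv      max-over-X gain on an (R, S) grid
  results/theory_ridge.tsv          optimal S*(R) curve
  results/theory_phase_diagram.tsv  optimal total noise over (Y, R)
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from noisereg.regulation_theory import (
    EnvironmentEnsemble,
    fitness_landscape,
    maximize_dlogf,
    mismatch_Y,
    optimal_coupling,
    predicted_total_noise,
)
from noisereg.synthetic_data import gen_environment_and_regulator


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    # --- worked scenario: sigma = 0.1, tau = 0.03, three environments at Y = 4
    sigma2, tau, Y = 0.01, 0.03, 4.0
    d = np.sqrt(Y**2 * (sigma2 + tau**2) * 3.0 / 2.0)  # var({-d,0,+d}) = 2d^2/3
    mu_e = np.array([8.1 - d, 8.1, 8.1 + d])
    env = EnvironmentEnsemble(mu_e, tau)
    assert abs(mismatch_Y(env, sigma2) - Y) < 1e-12

    scenarios = [
        ("accurate", 0.95, None),       # high R: condition-response dominates
        ("pure-noise", 0.0, 0.05),      # R = 0: bet hedging via propagation
        ("mismatched", 0.64, 6.0),      # S far above S*(R = 0.64)
    ]
    rows = []
    for name, R, S_fixed in scenarios:
        gain_opt, X_opt, S_opt = maximize_dlogf(Y, R)
        if S_fixed is None:
            S_used, gain = S_opt, gain_opt
        else:
            from noisereg.regulation_theory import _max_over_X

            S_used = S_fixed
            gain = _max_over_X(Y, R, S_fixed, x_hi=3 * Y + 10)
        xs = optimal_coupling(Y, R)
        sigma_tot2 = predicted_total_noise(R, env, sigma2)
        rows.append(
            {
                "regulator": name,
                "R": R,
                "S": S_used,
                "gain_dlogf": gain,
                "X_star": xs,
                "sigma_tot2_at_optimum": sigma_tot2,
            }
        )
    worked = pd.DataFrame(rows)
    worked.to_csv(args.outdir / "theory_worked_scenario.tsv", sep="\t", index=False, float_format="%.6g")
    print(worked.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    pure = worked.set_index("regulator")
    if pure.loc["pure-noise", "gain_dlogf"] > pure.loc["mismatched", "gain_dlogf"]:
        print(
            "the uncorrelated noisy regulator outperforms the moderately "
            "correlated one whose S exceeds S*(R): noise-propagation acting "
            "as rudimentary regulation"
        )

    # --- landscape over (R, S) at the scenario's Y, plus the ridge S*(R)
    R_grid = np.linspace(0.0, 0.99, 34)
    S_grid = np.linspace(0.0, 8.0, 33)
    gain, ridge = fitness_landscape(Y, R_grid, S_grid)
    tidy = pd.DataFrame(
        [
            {"R": R_grid[i], "S": S_grid[j], "gain": gain[i, j]}
            for i in range(R_grid.size)
            for j in range(S_grid.size)
        ]
    )
    tidy.to_csv(args.outdir / "theory_landscape.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame({"R": R_grid, "S_star": ridge}).to_csv(
        args.outdir / "theory_ridge.tsv", sep="\t", index=False
    )
    print(
        f"landscape: gain spans {gain.min():.2f}..{gain.max():.2f} over "
        f"{R_grid.size}x{S_grid.size} (R, S) cells at Y = {Y}"
    )

    # --- phase diagram of optimal total noise over (Y, R)
    rows = []
    for Yv in np.linspace(0.25, 6.0, 31):
        var_mu = Yv**2 * (sigma2 + tau**2)
        dd = np.sqrt(var_mu * 3.0 / 2.0)
        env_y = EnvironmentEnsemble(np.array([8.1 - dd, 8.1, 8.1 + dd]), tau)
        for R in np.linspace(0.0, 0.999, 25):
            rows.append(
                {
                    "Y": Yv,
                    "R": R,
                    "sigma_tot2": predicted_total_noise(R, env_y, sigma2),
                    "regime": "basal" if (1 - R**2) * Yv**2 <= 1 else "environment-driven",
                }
            )
    phase = pd.DataFrame(rows)
    phase.to_csv(args.outdir / "theory_phase_diagram.tsv", sep="\t", index=False, float_format="%.6g")
    frac_env = (phase["regime"] == "environment-driven").mean()
    print(
        f"phase diagram: {100 * frac_env:.0f}% of the (Y, R) window sits in the "
        "environment-driven regime where extra noise is selected"
    )

    # sanity: three regulators realized exactly at their target (R, S)
    env3, reg3 = gen_environment_and_regulator(mu_e, tau, 0.64, 6.0, rng)
    from noisereg.regulation_theory import regulator_RS

    R3, S3 = regulator_RS(env3, reg3)
    print(f"constructive check: generated regulator realizes R = {R3:.3f}, S = {S3:.3f}")


if __name__ == "__main__":
    main()
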