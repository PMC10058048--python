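"""Locate the extraction conditions that maximise the predicted TPC yield.

Particle-swarm search of the ensemble-mean prediction over the
400-800 W x 20-40 min x 40-80 parts box. Writes results/optimum.csv and the
global-best convergence trace results/pso_trace.csv; prints the optimum in
practical units (whole watts, minutes and solvent parts).
"""

from pathlib import Path

import pandas as pd

import chamopt as c

OUT = Path(__file__).resolve().parents[1] / "results"
BASE_SEED = 0
SWARM_SEED = 0
BOUNDS = ((400.0, 800.0), (20.0, 40.0), (40.0, 80.0))


def main() -> None:
    data = c.load_design_table()
    ens = c.train_ensemble(data, n_nets=20, base_seed=BASE_SEED)
    opt = c.optimize_extraction(
        ens, bounds=BOUNDS, config=c.SwarmConfig(bounds=BOUNDS, seed=SWARM_SEED),
        mode="mean", snap=True,
    )
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(
        [
            {
                "power_W": opt.x[0],
                "time_min": opt.x[1],
                "solvent_parts": opt.x[2],
                "snapped_power_W": opt.snapped[0],
                "snapped_time_min": opt.snapped[1],
                "snapped_solvent_parts": opt.snapped[2],
                "predicted_tpc_mg_per_g": opt.value,
            }
        ]
    ).to_csv(OUT / "optimum.csv", index=False)
    pd.DataFrame({"iteration": range(len(opt.trace)), "gbest": opt.trace}).to_csv(
        OUT / "pso_trace.csv", index=False
    )

    print(
        f"optimum ({opt.terminated_by} after {opt.iterations} iterations): "
        f"{opt.snapped[0]:.0f} W, {opt.snapped[1]:.0f} min, 1:{opt.snapped[2]:.0f}"
    )
    print(f"predicted TPC there: {opt.value:.2f} mg/g")
    print(
        "note: the dataset's measured yields put the ridge near 1:60-1:65 at "
        "400 W / 30 min, so the solvent coordinate sits below the top of the "
        "tested range"
    )


if __name__ == "__main__":
    main()
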