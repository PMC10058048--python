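"""Describe the 27-run factorial extraction dataset.

Writes results/dataset_summary.csv and prints the response extremes that any
model of this data must respect: the best measured yield 59.56 mg/g at
800 W / 40 min / 1:80, and the striking runner-up 58.435 mg/g at the lowest
power (400 W, 30 min, 1:60).
"""

from pathlib import Path

import numpy as np
import pandas as pd

import chamopt as c

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = c.load_design_table()
    df = data.to_frame()
    summary = df.describe().T
    OUT.mkdir(exist_ok=True)
    summary.to_csv(OUT / "dataset_summary.csv")

    order = df.sort_values("tpc", ascending=False).head(3)
    print(f"n = {len(df)} runs, full 3x3x3 factorial")
    print("top three measured TPC yields (mg/g):")
    print(order.to_string(index=False))
    worst = df.loc[df.tpc.idxmin()]
    print(
        f"worst: {worst.tpc} mg/g at {worst.power_W:.0f} W, "
        f"{worst.time_min:.0f} min, 1:{worst.solvent_parts:.0f} — "
        "low solvent volume consistently suppresses the yield"
    )


if __name__ == "__main__":
    main()
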