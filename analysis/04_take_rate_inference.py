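#!/usr/bin/env python
"""Exact inference on the tumor take-rate table.

Three inoculation methods were compared for their ability to establish
orthotopic tumors: ultrasound-guided orthotopic injection (4/4 animals),
unguided orthotopic injection (0/4), and subcutaneous flank injection
(0/5). The two-tailed Freeman-Halton exact test (the r x 2 generalization
of Fisher's test) quantifies whether the methods differ; a seeded
Monte-Carlo resampling of the same null cross-checks the enumeration.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd

from dcequant import ContingencyTable, freeman_halton_exact, monte_carlo_exact, take_rate
from dcequant.stats import TAKE_RATE_TABLE_ROWS

RESULTS = ROOT / "results"


def main(seed: int = 2014) -> None:
    RESULTS.mkdir(exist_ok=True)
    table = ContingencyTable(TAKE_RATE_TABLE_ROWS)
    p = freeman_halton_exact(table)
    mc = monte_carlo_exact(table, n_draws=100_000, seed=seed)

    df = pd.DataFrame(
        [
            {"method": label, "successes": s, "failures": f, "take_rate_pct": take_rate((s, f))}
            for label, s, f in table.rows
        ]
    )
    df.to_csv(RESULTS / "take_rates.csv", index=False)
    print("Tumor take rates by inoculation method:")
    print(df.to_string(index=False))
    print(f"\nFreeman-Halton exact test (two-tailed): p = {p:.4f} "
          f"(exact enumeration, {table.grand_total} animals)")
    print(f"Monte-Carlo check ({mc.n_draws} draws, seed {seed}): "
          f"p = {mc.p:.4f} +/- {mc.se:.4f}")
    print("The three inoculation methods differ in their ability to establish tumors.")


if __name__ == "__main__":
    main()
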