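#!/usr/bin/env python
"""Hydroxyl-proton exchange: EXSY initial-rate estimation and temperature
coefficients on synthetic ground truth.

Two-site magnetization-exchange build-up curves are generated with the
exact matrix-exponential solution at the exchange rates the NMR study
reported for the alditol hydroxyls (193 to 1145 1/s), on the experimental
3-24 ms mixing-time grid.  The initial-rate estimator (through-origin fit
of cross/diagonal) is applied with a window restricted to k*t <= 0.2, and
also to the full experimental grid to show the long-mixing-time bias.

Findings: inside the linear window every rate is recovered within 1%;
fitting the whole 24 ms grid underestimates fast rates severely (the
initial-rate approximation breaks down once k*t >> 0.2).  The constructed
-11 ppb/K shift series returns a temperature coefficient of exactly
11 ppb/K.
"""

import csv
from pathlib import Path

import numpy as np

from pentitol.nmr_exchange import TempShiftSeries, exchange_rate_from_exsy, temperature_coefficient
from pentitol.synthetic import ExsyModel, simulate_exsy

OUT = Path(__file__).resolve().parent.parent / "results"

#: site label -> reported exchange rate constant (1/s)
REPORTED_RATES = {
    "ribitol OH3": 193.0,
    "ribitol OH2/OH4": 810.0,
    "d-arabitol OH4": 908.0,
    "xylitol OH4": 1145.0,
}


def main():
    OUT.mkdir(exist_ok=True)
    rows = []
    for site, k in REPORTED_RATES.items():
        # linear-regime window
        tmax = 0.2 / k
        grid = tuple(np.linspace(tmax / 8, tmax, 8))
        res_lin = exchange_rate_from_exsy(
            simulate_exsy(ExsyModel(k_ex=k, mixing_times=grid), site), window=tmax
        )
        # the experimental 3-24 ms grid, full-window fit
        res_full = exchange_rate_from_exsy(
            simulate_exsy(ExsyModel(k_ex=k), site), window=0.024
        )
        print(f"{site:18s} true {k:7.0f}  windowed {res_lin.k_ex:7.1f} "
              f"({100*(res_lin.k_ex/k-1):+5.1f}%)  full-grid {res_full.k_ex:7.1f} "
              f"({100*(res_full.k_ex/k-1):+5.1f}%)")
        rows.append({
            "site": site, "k_true": k,
            "k_windowed": round(res_lin.k_ex, 1),
            "k_full_grid": round(res_full.k_ex, 1),
        })
    with open(OUT / "exchange_rates.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=rows[0].keys())
        w.writeheader()
        w.writerows(rows)

    T = np.array([273.0, 278, 283, 288, 293, 298, 303])
    series = TempShiftSeries("ribitol OH3", T, 5.9 - 0.011 * (T - 273))
    coef = temperature_coefficient(series)
    print(f"temperature coefficient (constructed -11 ppb/K series): "
          f"{coef.magnitude_ppb_per_k:.1f} ppb/K")
    print("-> results/exchange_rates.csv")


if __name__ == "__main__":
    main()
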