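#!/usr/bin/env python
"""Select the best compartment model per animal/region by AIC (SC for ties).

Reads results/fits.csv and reports how often each model wins, reproducing
the "two-tissue model describes the kinetics best" outcome.
"""
import argparse
from pathlib import Path

import pandas as pd

from petkin.selection import select_model


class _Fit:
    def __init__(self, row):
        self.model = row.model
        self.aic, self.sc, self.msc = row.aic, row.sc, row.msc
        self.sswres = row.sswres
        self.p = {"1TCM": 2, "2TCM": 4}[row.model]
        self.converged = bool(row.converged)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fits", type=Path, default=Path("results/fits.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = pd.read_csv(args.fits)
    rows = []
    for (animal, region), grp in df.groupby(["animal_id", "region"]):
        fits = [_Fit(r) for r in grp.itertuples()]
        if sum(f.converged for f in fits) < 2:
            continue
        rep = select_model(fits)
        rows.append({"animal_id": animal, "region": region,
                     "winner": rep.winner, "rule": rep.rule,
                     "tracer": grp.tracer.iloc[0], "day": grp.day.iloc[0]})
    sel = pd.DataFrame(rows)
    sel.to_csv(args.out / "selection.csv", index=False)
    print("winning model counts per tracer/region:")
    print(sel.groupby(["tracer", "region"])["winner"]
          .value_counts().unstack(fill_value=0))


if __name__ == "__main__":
    main()
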