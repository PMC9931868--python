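#!/usr/bin/env python
"""Group statistics on the fitted rate constants.

Welch's t-tests for the published contrasts (tumor vs brain per tracer at
28 days; day 21 vs 28 within tracer) and the Pearson correlation matrix of
the mean tumor TACs across tracers.  Writes results/stats.csv and
results/pearson.csv.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from petkin.core import read_tac_table
from petkin.stats import pearson_matrix, welch_t


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fits", type=Path, default=Path("results/fits.csv"))
    ap.add_argument("--studies", type=Path, default=Path("results/studies"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = pd.read_csv(args.fits)
    df = df[df.model == "2TCM"]
    rows = []
    for tracer in df.tracer.unique():
        d28 = df[(df.tracer == tracer) & (df.day == 28)]
        for param in ("K1", "VT", "k3"):
            a = d28[d28.region == "tumor"][param].dropna()
            b = d28[d28.region == "brain"][param].dropna()
            if len(a) >= 2 and len(b) >= 2:
                cmp = welch_t(a, b, f"{tracer} tumor", f"{tracer} brain")
                rows.append({"contrast": f"{tracer} d28 tumor-vs-brain {param}",
                             **cmp.to_dict(), "stars": cmp.stars()})
        # timepoint contrast on tumor K1 (the vascularisation readout)
        t21 = df[(df.tracer == tracer) & (df.day == 21) & (df.region == "tumor")]
        t28 = d28[d28.region == "tumor"]
        if len(t21) >= 2 and len(t28) >= 2:
            cmp = welch_t(t28.K1, t21.K1, "d28", "d21")
            rows.append({"contrast": f"{tracer} tumor K1 d28-vs-d21",
                         **cmp.to_dict(), "stars": cmp.stars()})
    stats = pd.DataFrame(rows)
    stats.to_csv(args.out / "stats.csv", index=False)
    print(stats[["contrast", "mean_a", "mean_b", "p", "stars"]].round(4))

    # inter-tracer correlation of mean tumor TACs (90-min tracers share frames)
    curves, labels = [], []
    for tracer in ("FET", "fluciclovine"):
        tacs = [ {t.roi_label: t for t in read_tac_table(p)}["tumor"]
                 for p in sorted(args.studies.glob(f"tac_{tracer}_d28_*.csv")) ]
        if tacs:
            mean_vals = np.mean([t.values for t in tacs], axis=0)
            curves.append(tacs[0].with_values(mean_vals))
            labels.append(tracer)
    if len(curves) == 2:
        r = pearson_matrix(curves)
        pd.DataFrame(r, index=labels, columns=labels).to_csv(
            args.out / "pearson.csv")
        print(f"\nPearson r ({labels[0]} vs {labels[1]} mean tumor TAC): "
              f"{r[0, 1]:.2f}")


if __name__ == "__main__":
    main()
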