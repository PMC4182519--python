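#!/usr/bin/env python
"""Latent permanent-income wealth from the 37 asset items, lowest-quintile
flags, and the $1.25/day unidimensional comparator.  Writes wealth.csv."""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import mdpoverty as mp


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    hh = pd.read_csv(args.out / "households.csv")
    items = hh[[c for c in hh.columns if c.startswith("asset_")]].to_numpy()
    model = mp.fit_wealth_model(items)
    scores = mp.score_households(items, model)
    w = 1.0 / hh["sampling_probability"].to_numpy(float)
    lowest = mp.quintile_flags(scores, w)
    below = mp.below_dollar_line(hh["monthly_income_mzn"].to_numpy(float),
                                 hh["household_size"].to_numpy(float))
    pd.DataFrame({
        "household_id": hh["household_id"],
        "wealth_score": scores,
        "lowest_quintile": lowest,
        "below_125_line": below,
    }).to_csv(args.out / "wealth.csv", index=False)

    print(f"EM converged in {model.n_iter} iterations on "
          f"{len(model.kept_items)} informative items")
    print(f"weighted median wealth score: "
          f"{mp.weighted_quantile(scores, w, 0.5):.2f} "
          f"(IQR {mp.weighted_quantile(scores, w, 0.25):.2f}-"
          f"{mp.weighted_quantile(scores, w, 0.75):.2f})")
    print(f"below $1.25/day: {np.average(below, weights=w):.1%} "
          f"(vs {np.average(lowest, weights=w):.1%} in lowest wealth quintile)")

    # contrast with multidimensional poverty
    m = mp.DeprivationMatrix.from_frame(pd.read_csv(args.out / "g0.csv"))
    poor = mp.identify_poor(mp.deprivation_scores(m))
    among_poor = np.average(lowest[poor == 1], weights=w[poor == 1])
    among_nonpoor = np.average(lowest[poor == 0], weights=w[poor == 0])
    print(f"lowest wealth quintile among MPI-poor: {among_poor:.1%}; "
          f"among non-poor: {among_nonpoor:.1%}")
    print(f"wrote {args.out / 'wealth.csv'}")


if __name__ == "__main__":
    main()
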