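#!/usr/bin/env python
"""EA-level adjusted headcounts, variogram fit, and ordinary-kriged poverty
surfaces per district.  Writes ea_m0.geojson, surface.csv, surface.geojson."""

import argparse
import json
from pathlib import Path

import pandas as pd

import mdpoverty as mp
from mdpoverty.geo import points_to_geojson


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--nx", type=int, default=100)
    ap.add_argument("--ny", type=int, default=100)
    args = ap.parse_args()

    m = mp.DeprivationMatrix.from_frame(pd.read_csv(args.out / "g0.csv"))
    eas = pd.read_csv(args.out / "eas.csv")
    est = mp.aggregate_by_ea(m, ea_table=eas)
    print(f"{len(est)} EA estimates; m0 range "
          f"{est['m0'].min():.3f}-{est['m0'].max():.3f}")

    emp = mp.empirical_variogram(est[["x", "y"]].to_numpy(), est["m0"].to_numpy(),
                                 n_bins=12)
    model = mp.fit_variogram(emp)
    print(f"fitted {model.model} variogram: nugget {model.nugget:.4g}, "
          f"partial sill {model.partial_sill:.4g}, range {model.range_param:.4g}")

    grids = []
    for dname, sub in est.groupby("district", sort=True):
        surf = mp.krige(sub, model, (args.nx, args.ny))
        surf.grid["district"] = dname
        grids.append(surf.grid)
        print(f"  {dname}: {len(sub)} EAs, max |sum(weights)-1| = "
              f"{surf.max_weight_dev:.2e}")
    grid = pd.concat(grids, ignore_index=True)
    grid.to_csv(args.out / "surface.csv", index=False)
    (args.out / "surface.geojson").write_text(json.dumps(points_to_geojson(
        grid, props=["m0_pred", "m0_pred_clamped", "ok_variance", "district"])))
    (args.out / "ea_m0.geojson").write_text(json.dumps(points_to_geojson(
        est, props=["ea_id", "district", "m0", "n_households"])))
    print(f"wrote surface.csv / surface.geojson / ea_m0.geojson to {args.out}")


if __name__ == "__main__":
    main()
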