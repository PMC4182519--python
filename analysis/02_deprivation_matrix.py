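#!/usr/bin/env python
"""Apply the 11 deprivation rules to the simulated households and write the
binary deprivation matrix (g0.csv) with design columns carried through."""

import argparse
from pathlib import Path

import pandas as pd

import mdpoverty as mp


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    hh = pd.read_csv(args.out / "households.csv")
    m = mp.build_deprivation_matrix(hh)
    m.to_frame().to_csv(args.out / "g0.csv", index=False)
    print(f"wrote g0.csv: {m.n} households x {len(m.weights)} indicators")
    print("weights:", ", ".join(str(w) for w in m.weights), "(sum =",
          str(sum(m.weights)) + ")")
    counts = m.g0.sum(axis=1)
    print(f"households deprived in nothing: {(counts == 0).mean():.1%}; "
          f"in everything: {(counts == 11).mean():.1%}")


if __name__ == "__main__":
    main()
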