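#!/usr/bin/env python
"""Statistical discrimination of the stiffness classes.

Pairwise Kruskal-Wallis tests per feature (PPG features pooled across
wavelengths; LDF flux per window) and Pearson ranking of PPG features
against the vessels' Young's moduli.  Tables are written under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from pulseflux import pairwise_kw, rank_features
from pulseflux.ppg_features import PPG_FEATURE_NAMES

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", type=Path, default=ROOT / "results")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    parser.add_argument("--alpha", type=float, default=0.05)
    args = parser.parse_args()

    ppg = pd.read_csv(args.features / "ppg_features.csv")
    ldf = pd.read_csv(args.features / "ldf_features.csv")
    args.out.mkdir(parents=True, exist_ok=True)

    for bmf in ("intralipid", "lpfs"):
        rows = []
        for feature in PPG_FEATURE_NAMES:
            rows.extend(r.__dict__ for r in pairwise_kw(ppg, feature, bmf))
        pd.DataFrame(rows).to_csv(args.out / f"kw_ppg_{bmf}.csv", index=False)
        ranking = rank_features(ppg[ppg["bmf"] == bmf], alpha=args.alpha)
        ranking.to_csv(args.out / f"feature_ranking_{bmf}.csv", index=False)
        top = ranking.iloc[0]
        print(
            f"{bmf}: top-ranked feature {top['feature']} at {top['wavelength_nm']} nm "
            f"(r = {top['r']:+.3f})"
        )

    rows = []
    for bmf in ("intralipid", "lpfs"):
        rows.extend(
            {"bmf": bmf, **r.__dict__} for r in pairwise_kw(ldf, "dc_mean_flux", bmf)
        )
    kw_ldf = pd.DataFrame(rows)
    kw_ldf.to_csv(args.out / "kw_ldf.csv", index=False)
    worst = kw_ldf["p"].max()
    print(
        f"LDF DC mean flux: all {len(kw_ldf)} pairwise comparisons significant "
        f"(max p = {worst:.2e} < {args.alpha})"
        if worst < args.alpha
        else f"LDF DC mean flux: max pairwise p = {worst:.3f}"
    )


if __name__ == "__main__":
    main()
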