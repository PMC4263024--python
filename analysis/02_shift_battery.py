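"""Full 52-shift robustness battery on seeded skull-base phantoms.

For each seeded heterogeneous phantom, optimizes a lateral-opposed plan in
the requested mode, recomputes the dose under every member of the 52-shift
set (magnitudes 1 and 2 mm, frozen weights) and reports the Δ-index
population summary: medians/quartiles/extremes of ΔV95%, ΔHI and the
fraction of shifts within the 1 pp / 2 Gy(RBE) thresholds.

Writes a full report bundle under --out (planned_indices.csv, deltas.csv,
summary.json, DVH CSVs).
"""

import argparse
import json

from ionrobust import pipeline as pp


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cases", type=int, default=3)
    ap.add_argument("--species", default="carbon", choices=["carbon", "proton"])
    ap.add_argument("--mode", default="mc", choices=["uc", "sc", "mc"])
    ap.add_argument("--out", default="results/shift_battery")
    args = ap.parse_args()

    config = pp.RunConfig(
        species=args.species,
        mode=args.mode,
        beams="LR",
        phantom=pp.PhantomConfig(kind="skullbase", n_cases=args.cases,
                                 ctv_semiaxes_mm=(19.0, 18.0, 16.0)),
        magnitudes_mm=[1.0, 2.0],
        seed=args.seed,
        out_dir=args.out,
    )
    bundle = pp.run_experiment(config)
    print(json.dumps(bundle.summary, indent=2, sort_keys=True))
    deltas = bundle.deltas
    for mag, sub in deltas.groupby("magnitude_mm"):
        print(
            f"|shift| = {mag:g} mm: median ΔV95(CTV) = "
            f"{sub['d_ctv_v95'].median():+.2f} pp, worst = "
            f"{sub['d_ctv_v95'].min():+.2f} pp over {len(sub)} recomputations"
        )


if __name__ == "__main__":
    main()
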