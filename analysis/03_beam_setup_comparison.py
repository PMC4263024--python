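"""Lateral-opposed versus heterogeneity-avoiding beam setups.

For a population of seeded skull-base phantoms with a bone/air interface in
the lateral entrance channel, builds mc plans with (a) lateral-opposed
beams (LR) and (b) a two-beam setup selected by WEPL-spread heterogeneity
scoring (ROB), then compares CTV coverage loss under the 2 mm transverse
shift battery.  Expected outcome: ROB setups lose less coverage (smaller
median |ΔV95%|) for both species; the paired sign test quantifies the
difference.

Writes results/setup_comparison.csv (tidy per case x setup x shift) and
results/setup_comparison_summary.json.
"""

import argparse
import json
from pathlib import Path

from ionrobust import robustness as rb
from ionrobust import workflows as wf


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cases", type=int, default=10)
    ap.add_argument("--out", default="results/setup_comparison.csv")
    args = ap.parse_args()

    seeds = [args.seed * 1000 + i for i in range(args.cases)]
    study = wf.setup_comparison_study(seeds)
    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    study.to_csv(out, index=False)

    summary = {"n_cases": args.cases, "seeds": seeds}
    med = wf.median_abs_dv95(study).set_index(["species", "setup"])
    for species in ("carbon", "proton"):
        sub = study[study.species == species]
        key = ["case", "shift"]
        lr = sub[sub.setup == "LR"].set_index(key)["d_ctv_v95"]
        rob = sub[sub.setup == "ROB"].set_index(key)["d_ctv_v95"].reindex(lr.index)
        p = rb.sign_test(lr.abs().to_numpy(), rob.abs().to_numpy())
        m_lr = float(med.loc[(species, "LR"), "abs_dv95"])
        m_rob = float(med.loc[(species, "ROB"), "abs_dv95"])
        summary[species] = {
            "median_abs_dv95_lr_pp": m_lr,
            "median_abs_dv95_rob_pp": m_rob,
            "sign_test_p": p,
        }
        print(
            f"{species}: median |ΔV95(CTV)| under 2 mm transverse shifts — "
            f"LR {m_lr:.2f} pp vs ROB {m_rob:.2f} pp (sign test p = {p:.2e})"
        )
    with open(out.with_name("setup_comparison_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
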