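#!/usr/bin/env python
"""Chromophore hydrogen bonding, partitioned into protein and water partners.

Scripts two bonding regimes over 50 ns — a richer water shell (3-4 bonds)
versus a sparser one (2-3 bonds), each with an intermittent protein
carboxamide bond — and counts bonds per frame with the geometric detector
(0.35 nm / 30 deg).  The frequency tables mirror how bonding differences
between variants are summarised.

Writes count series, frequency tables and summary statistics under
results/hbonds/.
"""

import json
from pathlib import Path

from fpdyn.hbond import count_partitioned
from fpdyn.model import AtomSelection
from fpdyn.synthetic import TrajectorySpec, gen_trajectory

OUT = Path(__file__).resolve().parent.parent / "results" / "hbonds"
OUT.mkdir(parents=True, exist_ok=True)

GROUP = AtomSelection(res_id=(65, 66))
PARTNERS = {
    "protein": AtomSelection(chain="A", predicate=lambda a: a.res_id not in (65, 66)),
    "water": AtomSelection(res_name="HOH"),
}


def analyse(tag, water_schedule, protein_schedule, seed):
    spec = TrajectorySpec(duration_ns=50.0, frame_interval_ns=0.02,
                          noise_sd_nm=0.01,
                          hbond_water_schedule=water_schedule,
                          hbond_protein_schedule=protein_schedule, seed=seed)
    traj, truth = gen_trajectory(spec)
    counts = count_partitioned(traj, GROUP, PARTNERS)
    summary = {}
    for cls in ("protein", "water"):
        mean, sd = counts.mean_sd(cls)
        table = counts.frequency_table(cls)
        with open(OUT / f"{tag}_freq_{cls}.tsv", "w") as fh:
            fh.write("count\tframes\n")
            for k, v in sorted(table.items()):
                fh.write(f"{k}\t{v}\n")
        summary[cls] = {"mean": round(mean, 2), "sd": round(sd, 2),
                        "median": counts.median(cls)}
    exact = bool(
        (counts.counts["water"] == truth.hbond_counts_at(traj.times, "water")).all()
        and (counts.counts["protein"] == truth.hbond_counts_at(traj.times, "protein")).all()
    )
    summary["detector_matches_script"] = exact
    (OUT / f"{tag}_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def main():
    rich = analyse(
        "rich_shell",
        water_schedule=((0.0, 3), (10.0, 4), (30.0, 3), (40.0, 4)),
        protein_schedule=((0.0, 1), (25.0, 0), (35.0, 1)),
        seed=31,
    )
    sparse = analyse(
        "sparse_shell",
        water_schedule=((0.0, 2), (15.0, 3), (35.0, 2)),
        protein_schedule=((0.0, 1),),
        seed=32,
    )
    for tag, s in (("rich shell", rich), ("sparse shell", sparse)):
        print(f"{tag}: water {s['water']['mean']} +/- {s['water']['sd']} per frame "
              f"(median {s['water']['median']}), protein {s['protein']['mean']} "
              f"+/- {s['protein']['sd']}; detector == script: "
              f"{s['detector_matches_script']}")
    print(f"outputs under {OUT}")


if __name__ == "__main__":
    main()
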