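#!/usr/bin/env python
"""Chromophore conformational dynamics: two-state RMSD and the carbonyl flip.

Emulates the parent protein's switching chromophore (planted acylimine
carbonyl flips) against a stable variant (no flips), then recovers the
states from the all-atom chromophore RMSD by deterministic two-means
segmentation, locates the flip events from the carbonyl dihedral, and
contrasts per-atom chromophore RMSF and per-residue Calpha delta-RMSF.

Writes segmentations, flip events and RMSF profiles under
results/chromophore/.
"""

import json
from pathlib import Path

import numpy as np

from fpdyn import geometry as geo
from fpdyn import states as st
from fpdyn.io import write_profile_tsv, write_series_tsv
from fpdyn.model import AtomSelection
from fpdyn.synthetic import TrajectorySpec, gen_trajectory

OUT = Path(__file__).resolve().parent.parent / "results" / "chromophore"
OUT.mkdir(parents=True, exist_ok=True)

CA = AtomSelection(name="CA", chain="A")
CRO_HEAVY = AtomSelection(res_id=(65, 66), predicate=lambda a: a.element != "H")


def analyse(tag, flips, seed):
    spec = TrajectorySpec(duration_ns=100.0, frame_interval_ns=0.02,
                          noise_sd_nm=0.01, flip_times_ns=flips, seed=seed)
    traj, truth = gen_trajectory(spec)
    series = geo.rmsd_series(traj, traj.frame(0), CA, CRO_HEAVY)
    seg = st.segment_states(series)
    fl = st.flip_angle(traj)
    stride = 50  # downsample the written series to ~100 rows
    write_series_tsv(OUT / f"{tag}_cro_rmsd.tsv",
                     series.times[::stride], series.values[::stride], "rmsd_nm")
    prof_atom = geo.rmsf(traj, CRO_HEAVY, CA)
    write_profile_tsv(OUT / f"{tag}_cro_rmsf_atoms.tsv", prof_atom.keys,
                      prof_atom.values)
    prof_ca = geo.rmsf(traj, CA, CA, per_residue=True)
    report = {
        "planted_flips_ns": list(truth.flip_times_ns),
        "detected_flip_onsets_ns": [float(traj.times[i]) for i in fl.events],
        "occupancy": seg.occupancy,
        "switch_count": seg.switch_count,
        "state_levels_nm": seg.levels,
        "cro_rmsf_mean_nm": float(prof_atom.values.mean()),
    }
    (OUT / f"{tag}_states.json").write_text(json.dumps(report, indent=1))
    return report, prof_ca


def main():
    switching, ca_a = analyse("switching", flips=(22.0, 57.0, 71.0), seed=21)
    stable, ca_b = analyse("stable", flips=(), seed=22)
    delta = geo.delta_rmsf(ca_a, ca_b)
    write_profile_tsv(OUT / "delta_rmsf_ca.tsv", delta.keys, delta.values,
                      "delta_rmsf_nm")
    def gap(report):
        levels = report["state_levels_nm"]
        return levels["high"] - levels.get("low", levels["high"])

    print("switching chromophore:")
    print(f"  planted carbonyl toggles at {switching['planted_flips_ns']} ns; "
          f"detected flipped-episode onsets at "
          f"{switching['detected_flip_onsets_ns']} ns")
    print(f"  two-means occupancy low/high = "
          f"{switching['occupancy']['low']:.2f}/{switching['occupancy']['high']:.2f}, "
          f"level separation {gap(switching):.3f} nm")
    print("stable chromophore (no planted flips):")
    print(f"  level separation {gap(stable):.3f} nm (noise scale only); "
          f"mean per-atom chromophore RMSF {stable['cro_rmsf_mean_nm']:.4f} nm "
          f"vs {switching['cro_rmsf_mean_nm']:.4f} nm when switching")
    print(f"outputs under {OUT}")


if __name__ == "__main__":
    main()
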