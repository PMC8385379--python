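#!/usr/bin/env python
"""Cohort kinematics of the simulated trout and frogfish strikes.

Runs the full analysis (marker fitting, zero-phase filtering, inclusion rule,
elevation traces, joint deltas at peak, curvature profiles) on the datasets
written by 01_simulate_cohorts.py and writes per-cohort tables and figures
under results/cohorts/<species>/. Prints the cohort statistics analogous to
the study's headline numbers (peak elevation mean +/- s.e. and maximum, and
the two cranial-most joint rotations).

Run from the repository root, after 01:  python analysis/03_cohort_kinematics.py
"""
import argparse
from pathlib import Path

from axialkin import analyze_cohort
from axialkin.axial_pipeline import (StrikeRecording, curvature_table,
                                     elevation_table, joint_delta_table,
                                     summary_table)
from axialkin.io_formats import load_chain_config, read_marker_csv
from axialkin import plots


def load_cohort(root: Path):
    cfg = load_chain_config(root / "chain.yaml")
    strikes = []
    for sdir in sorted((root / "strikes").iterdir()):
        strikes.append(StrikeRecording(
            strike_id=sdir.name, individual_id=cfg.species,
            species=cfg.species, frame_rate=cfg.frame_rate, config=cfg,
            markers=read_marker_csv(sdir / "markers.csv")))
    return cfg, strikes


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/cohorts"))
    args = ap.parse_args()
    for species in ("trout", "frogfish"):
        root = args.simdir / species
        if not root.is_dir():
            print(f"{species}: no dataset at {root} (run 01 first)")
            continue
        cfg, strikes = load_cohort(root)
        result = analyze_cohort(strikes, use_markers=True, filtering=True)
        out = args.outdir / species
        out.mkdir(parents=True, exist_ok=True)
        elevation_table(result.analyses).to_csv(out / "elevation_traces.csv",
                                                index=False)
        joint_delta_table(result.included).to_csv(out / "joint_deltas.csv",
                                                  index=False)
        curvature_table(result.included).to_csv(out / "curvature.csv",
                                                index=False)
        summary_table(result).to_csv(out / "summary.csv", index=False)
        for name, fig in (("elevation", plots.fig_elevation(result)),
                          ("curvature", plots.fig_curvature(result)),
                          ("joint_deltas", plots.fig_joint_deltas(result))):
            fig.savefig(out / f"{name}.png", dpi=150)
        s = result.peak_elevation
        print(f"\n{species}: {len(result.included)} of {len(result.analyses)} "
              f"strikes included (threshold {cfg.elevation_threshold_deg} deg)")
        print(f"  peak elevation: mean {s.mean:.1f} +/- {s.se:.2f} deg s.e., "
              f"max {s.max:.1f} deg (n={s.n})")
        for k in (1, 2):
            js = result.joint_delta_summaries[k - 1]
            label = "craniovertebral" if k == 1 else "intervertebral 1"
            print(f"  joint {k} ({label}): mean {js.mean:.1f} "
                  f"+/- {js.se:.2f} deg s.e., max {js.max:.1f} deg")
        print(f"  tables and figures in {out}")


if __name__ == "__main__":
    main()
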