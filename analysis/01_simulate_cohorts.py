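#!/usr/bin/env python
"""Simulate the two study cohorts.

Generates a trout-like cohort (20 strikes, 500 fps, whole-body drift, small
multi-joint dorsal rotations) and a frogfish-like cohort (18 strikes,
1000 fps, stationary body, very large cranial-joint rotations on an initially
S-curved column), each with 0.05 mm marker noise, and writes the datasets
under results/sim/.

Run from the repository root:  python analysis/01_simulate_cohorts.py [--seed 1]
"""
import argparse
from pathlib import Path

from axialkin import NoiseModel, build_preset, preset_program, strike_cohort
from axialkin.cli import _write_ground_truth
from axialkin.io_formats import save_chain_config, write_marker_csv, write_pose_csv

COHORTS = {"trout": 20, "frogfish": 18}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    for species, n in COHORTS.items():
        chain = build_preset(species)
        jitter = 0.30 if species == "trout" else 0.20
        strikes = strike_cohort(
            chain, preset_program(species), n=n, seed=args.seed,
            amplitude_jitter_frac=jitter,
            noise=NoiseModel(sigma_mm=0.05, seed=args.seed),
            individual_id=species)
        out = args.outdir / species
        save_chain_config(chain.config(), _mk(out) / "chain.yaml")
        for st in strikes:
            sdir = _mk(out / "strikes" / st.strike_id)
            _mk(sdir / "poses")
            write_marker_csv(st.markers, sdir / "markers.csv")
            for bone, seq in st.poses.items():
                write_pose_csv(seq, sdir / "poses" / f"{bone}.csv")
            _write_ground_truth(st, sdir / "ground_truth.csv")
        print(f"{species}: wrote {n} strikes "
              f"({chain.n_vertebrae} vertebrae, {chain.frame_rate:.0f} fps, "
              f"jitter {jitter:.0%}) to {out}")


def _mk(p: Path) -> Path:
    p.mkdir(parents=True, exist_ok=True)
    return p


if __name__ == "__main__":
    main()
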