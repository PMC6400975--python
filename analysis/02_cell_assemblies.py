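"""Identify word cell assemblies in the trained networks.

For every trained network this runs the word-production readout (A1 + M1_i
word-form stimulation, 15 steps, plasticity frozen), thresholds each area's
time-averaged responses at gamma = 0.5 of the area maximum, and writes the
tidy CA count table (network x regime x word type x area) that feeds the
statistics, plus per-area membership masks for the example words.

Usage: python analysis/02_cell_assemblies.py [--seed 1] [--out results]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from lexigrow import SimConfig
from lexigrow.engine import Network
from lexigrow.readout import (count_ca_per_area, identify_assemblies,
                              membership_mask_grid)
from lexigrow.training import BLIND, SIGHTED, make_instance


def load_network(cfg, master_seed, instance, mode, run_dir):
    syn, words, _ = make_instance(cfg, master_seed, instance)
    net = Network(cfg, syn)
    dat = np.load(run_dir / f"pair{instance}_{mode}_weights.npz")
    net.w[:] = dat["w"]
    return net, words


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    out = args.out
    cfg = SimConfig.from_yaml(out / "config.yaml")
    run_dir = out / "runs"
    instances = sorted(int(p.stem.split("_")[0][4:])
                       for p in run_dir.glob("pair*_meta.json"))
    tables = []
    for i in instances:
        for mode in (SIGHTED, BLIND):
            net, words = load_network(cfg, args.seed, i, mode, run_dir)
            cas = identify_assemblies(net, words,
                                      seed=(args.seed * 1000 + i) % (2 ** 31 - 1))
            tables.append(count_ca_per_area(cas, i, mode))
            if i == instances[0]:
                # example topography masks (one object, one action word)
                for ca in (cas[0], cas[cfg.n_object]):
                    masks = {a: membership_mask_grid(ca, a, cfg.grid_size)
                             for a in ca.members}
                    np.savez_compressed(
                        out / f"masks_{mode}_word{ca.word_id}.npz", **masks)
    counts = pd.concat(tables, ignore_index=True)
    counts.to_csv(out / "ca_counts.csv", index=False)

    summary = counts.pivot_table(index="area", columns=["regime", "word_type"],
                                 values="mean_count")
    print("mean CA cells per area (averaged over instances and words):")
    print(summary.round(1))
    print(f"\nwrote {out / 'ca_counts.csv'}")


if __name__ == "__main__":
    main()
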