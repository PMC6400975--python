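"""Simulate word recognition and measure activity durations.

Presents each learned action word's auditory (A1) pattern alone to the
trained networks, follows the word's cell assembly through stimulation,
ignition and reverberation, and records the total active duration (last step
at which at least 10% of the CA members spike).  The headline comparison is
the percentage by which the blind network's activity outlasts its paired
sighted network's.

Usage: python analysis/03_recognition.py [--seed 1] [--out results]
"""

import argparse
import importlib.util
from pathlib import Path

import pandas as pd

from lexigrow import SimConfig
from lexigrow.pipeline import duration_gain_percent
from lexigrow.readout import identify_assemblies, simulate_recognition, timecourse_frame
from lexigrow.training import BLIND, SIGHTED

_loader = importlib.util.spec_from_file_location(
    "ca_step", Path(__file__).with_name("02_cell_assemblies.py"))
_ca_step = importlib.util.module_from_spec(_loader)
_loader.loader.exec_module(_ca_step)


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
    rows, frames = [], []
    for i in instances:
        for mode in (SIGHTED, BLIND):
            net, words = _ca_step.load_network(cfg, args.seed, i, mode, run_dir)
            seed = (args.seed * 1000 + i) % (2 ** 31 - 1)
            cas = identify_assemblies(net, words, seed=seed)
            for word, ca in zip(words, cas):
                if word.category != "action":
                    continue
                tc = simulate_recognition(net, word, ca, seed=seed)
                rows.append({"network": i, "regime": mode,
                             "word_id": word.word_id, "category": word.category,
                             "ca_size": ca.size,
                             "active_duration": tc.active_duration,
                             "censored": tc.censored})
                f = timecourse_frame(tc)
                f["network"], f["regime"] = i, mode
                frames.append(f)
    durations = pd.DataFrame(rows)
    durations.to_csv(out / "durations.csv", index=False)
    pd.concat(frames, ignore_index=True).to_csv(out / "timecourses.csv", index=False)

    wide = durations.pivot_table(index="network", columns="regime",
                                 values="active_duration")
    print("mean action-word CA activity duration (steps):")
    print(wide.round(1))
    gain = duration_gain_percent(durations)
    print(f"\nblind vs sighted duration gain: {gain:.1f}% "
          "(mean over pairs and action words)")


if __name__ == "__main__":
    main()
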