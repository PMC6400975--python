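"""Train paired sighted/blind networks at desk scale.

Trains the scaled preset's paired network instances (shared connectivity,
word patterns and noise per pair; the blind member simply receives no V1
input) and stores the trained weights plus per-trial telemetry under
results/runs/.  Downstream scripts (02-04) consume these runs.

Usage: python analysis/01_train_pairs.py [--seed 1] [--pairs 5] [--out results]
"""

import argparse
import json
import time
from pathlib import Path

import numpy as np

from lexigrow import SimConfig
from lexigrow.training import BLIND, SIGHTED, train_pair


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--pairs", type=int, default=None)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = SimConfig.scaled()
    n_pairs = cfg.n_instances if args.pairs is None else args.pairs
    run_dir = args.out / "runs"
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(args.out / "config.yaml")

    for i in range(n_pairs):
        t0 = time.time()
        pair = train_pair(cfg, args.seed, i)
        for mode in (SIGHTED, BLIND):
            net = getattr(pair, mode)
            np.savez_compressed(run_dir / f"pair{i}_{mode}_weights.npz", w=net.w)
            logs = pair.logs[mode]
            np.savez_compressed(
                run_dir / f"pair{i}_{mode}_logs.npz",
                word_id=np.asarray(logs.word_id),
                trial_steps=np.asarray(logs.trial_steps),
                isi_steps=np.asarray(logs.isi_steps),
                area_spikes=np.asarray(logs.area_spikes))
        meta = {"instance": i, "master_seed": args.seed,
                "config_digest": cfg.digest(),
                "n_trials": pair.logs[SIGHTED].n_trials,
                "mean_trial_steps_sighted":
                    float(np.mean(pair.logs[SIGHTED].trial_steps)),
                "train_seconds": round(time.time() - t0, 1)}
        (run_dir / f"pair{i}_meta.json").write_text(json.dumps(meta, indent=1))
        print(f"pair {i}: {meta['n_trials']} trials per network, "
              f"{meta['train_seconds']}s")
    print(f"trained {n_pairs} sighted/blind pairs -> {run_dir}")


if __name__ == "__main__":
    main()
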