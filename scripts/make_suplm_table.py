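"""Regenerate the sup-LM null quantile table shipped with the package.

The parameter-instability (fluctuation) test for a numeric partitioning
variable uses the statistic

    sup_{t in [pi, 1-pi]}  ||B_k(t)||^2 / (t (1-t))

where B_k is a k-dimensional standard Brownian bridge and pi is the trim
implied by the minimum-node-size constraint.  The limiting distribution has
no convenient closed form, so quantiles are simulated once on a fine path
grid and frozen into ``src/paikit/data/suplm_k2.json``; the test p-value is
obtained at run time by interpolation in (trim, statistic).

Usage:  python scripts/make_suplm_table.py [--reps 40000] [--grid 2000]
"""

import argparse
import json
from pathlib import Path

import numpy as np

TRIMS = [0.02, 0.05, 0.08, 0.10, 0.125, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45]
PROBS = np.concatenate(
    [
        np.arange(0.01, 0.985, 0.01),
        [0.985, 0.99, 0.9925, 0.995, 0.9975, 0.999, 0.9995, 0.9999],
    ]
)
K = 2  # node model: intercept + treatment effect


def simulate(reps: int, grid: int, seed: int = 20240917) -> dict:
    rng = np.random.default_rng(seed)
    t = np.arange(1, grid) / grid
    weights = 1.0 / (t * (1.0 - t))
    stats = {pi: [] for pi in TRIMS}
    batch = 1000
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        incr = rng.standard_normal((b, K, grid)) / np.sqrt(grid)
        w = np.cumsum(incr, axis=2)
        bridge = w[:, :, :-1] - t[None, None, :] * w[:, :, -1:]
        process = np.sum(bridge**2, axis=1) * weights[None, :]
        for pi in TRIMS:
            lo = int(np.ceil(pi * grid)) - 1
            hi = int(np.floor((1 - pi) * grid))
            stats[pi].append(process[:, lo:hi].max(axis=1))
        done += b
    return {pi: np.concatenate(v) for pi, v in stats.items()}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=40000)
    ap.add_argument("--grid", type=int, default=2000)
    ap.add_argument(
        "--out",
        default=str(
            Path(__file__).resolve().parents[1]
            / "src"
            / "paikit"
            / "data"
            / "suplm_k2.json"
        ),
    )
    args = ap.parse_args()
    draws = simulate(args.reps, args.grid)
    table = {
        "k": K,
        "probs": [round(float(p), 6) for p in PROBS],
        "trims": TRIMS,
        "quantiles": {
            str(pi): [round(float(q), 5) for q in np.quantile(draws[pi], PROBS)]
            for pi in TRIMS
        },
        "reps": args.reps,
        "grid": args.grid,
    }
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    Path(args.out).write_text(json.dumps(table))
    print(f"wrote {args.out}")
    for pi in (0.05, 0.10, 0.20):
        q = np.quantile(draws[pi], [0.90, 0.95, 0.99])
        print(f"trim {pi}: q90={q[0]:.3f} q95={q[1]:.3f} q99={q[2]:.3f}")


if __name__ == "__main__":
    main()
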