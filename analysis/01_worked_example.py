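#!/usr/bin/env python
"""Recompute the single-trial reference entropies.

The embedded example is one participant driving the straight tunnel section
with both wall and pavement delineators: a 5x5 AOI transition matrix
(rebuilt at full precision from its integer pair counts) and its
visit-probability vector.  Expected output: Ht = 1.593 bits, Hs = 2.098
bits; the eigenvector cross-check lands within 0.01 of the visit vector.
"""

import json
from pathlib import Path

import numpy as np

from scanpath_entropy import stationary_eigen, worked_example

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    res = worked_example.compute(pi_mode="empirical")
    print("Reference trial (scenario A, straight):")
    print(f"  Ht = {res['Ht_bits']:.3f} bits   (gaze-transition uncertainty)")
    print(f"  Hs = {res['Hs_bits']:.3f} bits   (spread of the visit distribution)")
    pi_stat = stationary_eigen(res["P"])
    dev = float(np.abs(pi_stat - res["pi"]).max())
    print(f"  stationary vector deviates from the visit vector by <= {dev:.4f}")
    OUT.mkdir(exist_ok=True)
    (OUT / "worked_example.json").write_text(
        json.dumps(
            {
                "Ht_bits": round(res["Ht_bits"], 3),
                "Hs_bits": round(res["Hs_bits"], 3),
                "stationary_max_dev": round(dev, 4),
            },
            indent=2,
        )
    )
    print(f"wrote {OUT / 'worked_example.json'}")


if __name__ == "__main__":
    main()
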