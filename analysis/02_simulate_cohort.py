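#!/usr/bin/env python
"""Generate the synthetic study cohort.

21 participants x 3 delineator scenarios (A: wall + pavement, B: pavement
only, C: none) x 3 alignments (straight, left curve, right curve), about
120 fixations per trial, with per-participant Dirichlet variation around
the condition templates.  Writes the fixation table in the tracker-export
dialect plus ground-truth sidecars under results/cohort/.
"""

from pathlib import Path

from scanpath_entropy import CohortConfig, run_simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 0


def main() -> None:
    artifacts = run_simulate(CohortConfig(seed=SEED), OUT)
    print(f"simulated 21 x 3 x 3 cohort (seed {SEED})")
    for name, path in artifacts.items():
        print(f"  {name}: {path}")


if __name__ == "__main__":
    main()
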