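"""Generate the reference synthetic cohort used by the later stages.

Draws a 26-athlete cohort with 320 standardised features, per-site injury
labels at the observed per-mode rates, a 2:1 traditional:MAFT compactness
ratio and within-regime interaction groups, then writes it (with its JSON
sidecar) to results/cohort.csv.
"""

import sys
from pathlib import Path

from hginjury import io
from hginjury.cohort import SimulationConfig, generate_cohort

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    cfg = SimulationConfig(seed=seed)
    cohort = generate_cohort(cfg)
    OUT.mkdir(exist_ok=True)
    io.write_cohort(cohort, OUT / "cohort.csv")
    n_maft = int((cohort.regime == "maft").sum())
    print(
        f"cohort: {cohort.n_athletes} athletes ({n_maft} maft), "
        f"{cohort.features.shape[1]} features, "
        f"{cohort.injury_labels.shape[1]} injury sites, "
        f"{len(cohort.interaction_groups)} interaction groups (seed={seed})"
    )
    print(f"written to {OUT / 'cohort.csv'} (+ .meta.json sidecar)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
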