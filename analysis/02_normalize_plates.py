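"""Normalize raw wells to viability profiles.

Reads scratch/run_default/raw_wells.csv, screens each clone/day's 32
control wells with the iterative Grubbs test, and expresses every
chemical titer as percent of the retained-control mean. Reports how many
control wells were flagged (the screen's own behaviour keeps this under
10% by construction).
"""

from pathlib import Path

import pandas as pd

from ecfctox import normalize
from ecfctox.normalize import profiles_to_frame

RUN = Path(__file__).resolve().parent.parent / "scratch" / "run_default"


def main() -> None:
    wells = pd.read_csv(RUN / "raw_wells.csv")
    profiles = normalize(wells)
    frame = profiles_to_frame(profiles)
    frame.to_csv(RUN / "normalized_profiles.csv", index=False)
    used = sum(p.n_controls_used for p in profiles)
    flagged = sum(p.n_controls_flagged for p in profiles)
    print(f"{len(profiles)} profiles (clone x chemical x day)")
    print(f"control wells flagged as outliers: {flagged} of {used + flagged} "
          f"({100 * flagged / (used + flagged):.2f}%)")
    print(f"wrote {RUN / 'normalized_profiles.csv'}")


if __name__ == "__main__":
    main()
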