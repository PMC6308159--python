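"""Simulate the full nested cytotoxicity study.

Generates raw 384-well fluorescence data for the default design — 4 donors
× 2 clones, 8 chemicals (4 toxic/nontoxic pairs) × 9 two-fold titers in
duplicate, 32 control wells per clone/plate, 3 independent days — with the
default variance components, and writes the well table plus the
ground-truth sidecar (true curve parameters and realized random-effect
shifts) under scratch/run_default/.
"""

from pathlib import Path

from ecfctox import StudyDesign, VarianceComponents, generate_study
from ecfctox.design import write_study

OUT = Path(__file__).resolve().parent.parent / "scratch" / "run_default"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = StudyDesign()
    vc = VarianceComponents()
    wells, truth = generate_study(design, vc, seed=SEED)
    write_study(wells, truth, OUT / "raw_wells.csv", OUT / "ground_truth.json")
    print(f"design: {design.n_donors} donors x {design.clones_per_donor} clones x "
          f"{design.n_days} days, {len(design.chemicals)} chemicals")
    print(f"variance components (t-scale SD): donor {vc.sd_donor}, clone {vc.sd_clone}, "
          f"day {vc.sd_day}; well noise {vc.sd_well * 100:.0f}%")
    print(f"wrote {len(wells)} wells (expected {design.expected_rows()}) -> {OUT}")


if __name__ == "__main__":
    main()
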