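"""Partition IC variation into donor / clone / day components.

For each toxic chemical and each IC level, decomposes the per-day IC
values into between-donor, between-clone-within-donor and within-clone
(day-to-day) sums of squares, and marks the dominant component. Under the
default variance components (donor SD > day SD > clone SD on the curve-
location scale) the donor share should usually lead.
"""

from pathlib import Path

import pandas as pd

from ecfctox import build_table

RUN = Path(__file__).resolve().parent.parent / "scratch" / "run_default"
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ic_long = pd.read_csv(RUN / "ic_long.csv")
    toxic = ["CdCl2", "NaAsO2", "TBT", "Menadione"]
    table = build_table(ic_long, chemicals=toxic)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "variance_partition_default_run.csv", index=False)
    print("variance shares (% of total SS) per chemical x IC level:")
    for chem in toxic:
        sub = table[table.chemical == chem]
        lead = sub["largest"].value_counts().to_dict()
        print(f"  {chem:10s} largest component by level: {lead}")
    print(f"wrote {RESULTS / 'variance_partition_default_run.csv'}")


if __name__ == "__main__":
    main()
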