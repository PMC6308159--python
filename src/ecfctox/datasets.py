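"""Reference summary tables from the ECFC cytotoxicity screen.

Two small published summary tables of the cord-blood ECFC study the package
models are bundled as worked-example inputs: the per-clone IC10/IC50 table
(eight clones, four toxicants, mean ± SD over experiment days) and the
sum-of-squares variance-partition table (between-donor / between-clone /
within-clone components at nine IC levels). They let the aggregation and
percentage arithmetic be exercised and checked on real printed numbers
without any raw plate data.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["load_clone_ic_table", "load_variance_component_table"]

# Per-clone ICs (μM): mean ± SD across available experiment days.
_CLONE_IC = """\
clone_id,n,CdCl2_IC10,CdCl2_IC10_sd,CdCl2_IC50,CdCl2_IC50_sd,NaAsO2_IC10,NaAsO2_IC10_sd,NaAsO2_IC50,NaAsO2_IC50_sd,TBT_IC10,TBT_IC10_sd,TBT_IC50,TBT_IC50_sd,Menadione_IC10,Menadione_IC10_sd,Menadione_IC50,Menadione_IC50_sd
CBs101-1P6,3,7.2,2.8,15.4,3.8,2.0,2.0,4.9,2.4,0.2,0.2,1.6,0.9,14.2,4.3,21.7,3.5
CBs101-2P6,3,4.5,3.7,12.3,4.6,1.9,1.2,5.0,1.5,0.4,0.6,1.2,0.8,6.2,4.1,14.2,4.7
CBs103-1P6,3,9.3,3.9,17.8,4.6,2.6,1.5,7.6,2.0,0.5,0.4,2.3,0.3,5.6,1.5,8.0,1.4
CBs103-2P6,2,8.6,11.7,18.0,15.1,5.0,1.1,12.1,3.6,0.4,0.2,1.7,0.4,6.5,0.9,9.3,0.5
CBs104-1P6,3,7.5,4.4,16.7,5.0,1.7,1.0,5.5,0.2,0.3,0.1,1.9,0.5,19.0,7.3,26.3,5.3
CBs104-2P6,3,5.5,4.3,17.2,3.4,2.3,1.7,7.5,4.7,0.2,0.1,1.3,0.2,11.8,4.1,22.4,5.3
CBs108-1P6,2,6.4,5.4,14.4,6.1,2.6,0.2,7.5,1.2,0.2,0.1,1.6,0.7,12.7,0.9,16.0,2.4
CBs108-2P6,3,4.2,1.1,12.3,1.6,1.1,0.5,5.3,1.4,0.3,0.2,1.7,0.4,16.4,1.3,23.1,1.3
"""

# Sum-of-squares components, (μM)^2, per chemical × IC level.
_VARIANCE_SS = """\
chemical,level,ss_donor,ss_clone,ss_within
CdCl2,10,44.82,23.17,318.68
CdCl2,20,49.81,27.05,409.96
CdCl2,30,54.87,25.90,455.62
CdCl2,40,65.05,22.48,469.36
CdCl2,50,84.83,20.51,456.26
CdCl2,60,120.98,28.20,424.30
CdCl2,70,189.38,68.41,398.68
CdCl2,80,342.03,228.40,494.96
CdCl2,90,874.86,1135.08,1726.37
NaAsO2,10,10.89,10.33,25.01
NaAsO2,20,19.97,17.55,38.76
NaAsO2,30,29.91,23.94,51.39
NaAsO2,40,41.74,30.16,65.79
NaAsO2,50,56.78,36.64,85.49
NaAsO2,60,77.44,43.89,117.34
NaAsO2,70,109.05,52.83,178.62
NaAsO2,80,166.91,65.79,328.87
NaAsO2,90,324.56,94.14,935.97
TBT,10,0.13,0.13,1.13
TBT,20,0.29,0.24,2.00
TBT,30,0.49,0.41,2.76
TBT,40,0.76,0.66,3.52
TBT,50,1.16,1.09,4.36
TBT,60,1.85,2.00,5.47
TBT,70,3.38,4.47,7.46
TBT,80,8.26,13.79,13.99
TBT,90,38.98,79.77,67.58
Menadione,10,314.56,191.48,221.03
Menadione,20,411.48,191.74,209.48
Menadione,30,501.90,186.11,200.20
Menadione,40,598.84,178.47,194.65
Menadione,50,712.20,170.08,194.52
Menadione,60,856.44,161.89,203.78
Menadione,70,1059.89,156.18,232.57
Menadione,80,1397.55,161.73,314.02
Menadione,90,2186.21,236.22,625.89
"""


def load_clone_ic_table() -> pd.DataFrame:
    """Per-clone IC10/IC50 summaries (μM) for the four toxic chemicals."""
    return pd.read_csv(io.StringIO(_CLONE_IC))


def load_variance_component_table() -> pd.DataFrame:
    """Sum-of-squares components, (μM)², per chemical × IC level."""
    return pd.read_csv(io.StringIO(_VARIANCE_SS))
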