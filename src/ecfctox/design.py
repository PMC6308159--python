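"""Synthetic cytotoxicity study generator.

Emulates a clonal ECFC (endothelial colony-forming cell) viability screen:
clones from several cord-blood donors are exposed in 384-well plates to
paired toxic/nontoxic chemicals over a two-fold serial dilution, in duplicate
wells, with untreated control wells on every plate, and the whole experiment
is repeated on independent days.

Ground truth is a Hill-type decline on the transformed concentration scale
t = log2(1 + μM):

    viability(conc) = 100 / (1 + ((2^t - 1) / (2^(m + shift) - 1))^h)

where ``m`` is the true log2(1+IC50) location and ``h`` the Hill slope.
Donor-, clone- and day-level random effects shift ``m`` additively on the
t scale (a shift of 1 is a two-fold change in 1+IC50), and well-level noise
is multiplicative on fluorescence. Because the true curves and the realized
shifts are known, every downstream stage (normalization, curve fitting, IC
extraction, variance partitioning) can be tested for recovery.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ChemicalSpec",
    "StudyDesign",
    "VarianceComponents",
    "default_chemicals",
    "true_viability",
    "generate_study",
    "t_from_um",
    "um_from_t",
]


def t_from_um(conc_um):
    """Transform concentration in μM to t = log2(1 + μM)."""
    return np.log2(1.0 + np.asarray(conc_um, dtype=float))


def um_from_t(t):
    """Back-transform t = log2(1 + μM) to μM."""
    return np.exp2(np.asarray(t, dtype=float)) - 1.0


def _serial_dilution(top_um: float, n: int = 9) -> np.ndarray:
    """Two-fold serial dilution series, ascending, ending at ``top_um``."""
    return top_um / np.exp2(np.arange(n - 1, -1, -1, dtype=float))


@dataclass(frozen=True)
class ChemicalSpec:
    """One chemical: its tested titers and its true concentration-effect curve.

    ``true_log_ic50`` is on the t = log2(1+μM) scale. Nontoxic counterparts
    get a ``true_log_ic50`` at least 2 t-units above the top tested titer so
    that not even a 10% viability loss occurs in the tested range.
    """

    name: str
    titers_um: tuple
    true_log_ic50: float
    hill_slope: float
    toxic: bool = True

    def __post_init__(self):
        t = np.asarray(self.titers_um, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            raise ValueError("titers_um must be a non-empty 1-D sequence")
        if not np.all(t > 0) or not np.all(np.diff(t) > 0):
            raise ValueError(f"{self.name}: titers must be positive and strictly increasing")
        if not self.hill_slope > 0:
            raise ValueError(f"{self.name}: hill_slope must be > 0")
        if not self.toxic:
            top_t = float(np.log2(1.0 + t[-1]))
            if self.true_log_ic50 < top_t + 2.0:
                raise ValueError(
                    f"{self.name}: nontoxic chemical needs true_log_ic50 >= 2 t-units "
                    f"above the top titer (got {self.true_log_ic50:.2f} < {top_t + 2.0:.2f})"
                )

    @property
    def max_t(self) -> float:
        return float(np.log2(1.0 + self.titers_um[-1]))


def default_chemicals() -> list[ChemicalSpec]:
    """The four toxic/nontoxic pairs of the emulated screen.

    Locations and slopes are set so the toxic chemicals land in realistic
    micromolar IC ranges (TBT sub-μM, arsenite and cadmium single to low
    double-digit μM, menadione low double-digit μM with a steep slope);
    each nontoxic counterpart shares an overlapping dilution range but has
    its true IC50 placed beyond the tested titers.
    """
    # nontoxic locations keep true viability above ~99% over the tested
    # range (the shallow-slope chemicals need a wider margin than the
    # minimum 2 t-units for a 10% loss never to occur)
    return [
        ChemicalSpec("CdCl2", tuple(_serial_dilution(50.0)), 4.00, 2.8, True),
        ChemicalSpec("ZnCl2", tuple(_serial_dilution(400.0)), 12.00, 2.8, False),
        ChemicalSpec("NaAsO2", tuple(_serial_dilution(50.0)), 3.00, 2.0, True),
        ChemicalSpec("Na2HAsO4", tuple(_serial_dilution(50.0)), 9.50, 2.0, False),
        ChemicalSpec("TBT", tuple(_serial_dilution(5.0)), 1.43, 1.3, True),
        ChemicalSpec("SnCl2", tuple(_serial_dilution(200.0)), 13.00, 1.3, False),
        ChemicalSpec("Menadione", tuple(_serial_dilution(100.0)), 4.17, 5.5, True),
        ChemicalSpec("Phytonadione", tuple(_serial_dilution(100.0)), 9.00, 5.5, False),
    ]


@dataclass(frozen=True)
class StudyDesign:
    """Nested study layout: donors × clones × days × chemicals × titers × wells.

    Defaults reproduce the emulated screen: 4 donors × 2 clones each, 8
    chemicals in toxic/nontoxic pairs, 9 two-fold titers in duplicate, 32
    untreated control wells per clone per plate, 3 independent days.
    """

    n_donors: int = 4
    clones_per_donor: int = 2
    n_days: int = 3
    chemicals: tuple = field(default_factory=lambda: tuple(default_chemicals()))
    titers_per_chemical: int = 9
    replicate_wells_per_titer: int = 2
    control_wells_per_clone: int = 32
    control_baseline: float = 30000.0

    def __post_init__(self):
        for name in ("n_donors", "clones_per_donor", "n_days", "titers_per_chemical",
                     "replicate_wells_per_titer", "control_wells_per_clone"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.control_baseline <= 0:
            raise ValueError("control_baseline must be positive")
        for chem in self.chemicals:
            if len(chem.titers_um) != self.titers_per_chemical:
                raise ValueError(
                    f"{chem.name}: {len(chem.titers_um)} titers, design declares "
                    f"{self.titers_per_chemical}"
                )

    @property
    def n_clones(self) -> int:
        return self.n_donors * self.clones_per_donor

    def donor_ids(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_donors)]

    def clone_ids(self) -> list[tuple[str, str]]:
        """(donor_id, clone_id) pairs; clone ids encode their donor."""
        out = []
        for d in self.donor_ids():
            for c in range(self.clones_per_donor):
                out.append((d, f"{d}c{c + 1}"))
        return out

    def expected_rows(self) -> int:
        per_clone_day = (len(self.chemicals) * self.titers_per_chemical
                         * self.replicate_wells_per_titer + self.control_wells_per_clone)
        return self.n_clones * self.n_days * per_clone_day


@dataclass(frozen=True)
class VarianceComponents:
    """SDs of the random effects in the generator.

    ``sd_donor``, ``sd_clone``, ``sd_day`` shift the true log2(1+IC50)
    additively (t-scale units; 1.0 = two-fold change in 1+IC50).
    ``sd_well`` is the SD of multiplicative Gaussian well noise as a
    fraction of the expected fluorescence.
    """

    sd_donor: float = 0.25
    sd_clone: float = 0.12
    sd_day: float = 0.18
    sd_well: float = 0.05

    def __post_init__(self):
        for name in ("sd_donor", "sd_clone", "sd_day", "sd_well"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0 (got {v})")


def true_viability(spec: ChemicalSpec, shift: float, conc_um) -> np.ndarray | float:
    """Ground-truth viability (%) of ``spec`` at ``conc_um`` μM.

    ``shift`` moves the log2(1+IC50) location additively; positive shifts
    make the chemical less potent. Returns 100 at zero dose and decreases
    strictly with concentration.
    """
    conc = np.asarray(conc_um, dtype=float)
    if np.any(conc < 0):
        raise ValueError("conc_um must be >= 0")
    u = conc  # 2^t - 1 == conc
    u50 = np.exp2(spec.true_log_ic50 + shift) - 1.0
    if u50 <= 0:
        raise ValueError("shifted log IC50 must stay positive on the 2^m - 1 scale")
    out = 100.0 / (1.0 + (u / u50) ** spec.hill_slope)
    return float(out) if np.isscalar(conc_um) else out


def _unit_rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: the stream for a unit depends only on (seed, name)."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def generate_study(design: StudyDesign, vc: VarianceComponents, seed: int):
    """Simulate raw plate wells for the full nested design.

    Returns ``(wells, truth)``: a DataFrame with one row per well
    (donor_id, clone_id, day, chemical, conc_um, is_control, replicate,
    fluorescence) and a ground-truth dict holding the chemical parameters and
    every realized donor/clone/day shift, for recovery tests.

    Each random-effect shift is drawn once per unit from its own named
    substream, so regeneration with the same seed is bit-identical and
    independent of iteration order. Fluorescence is
    ``control_baseline × viability/100 × (1 + ε)`` with
    ε ~ N(0, sd_well²), truncated so intensities stay nonnegative.
    """
    donor_shift = {d: float(_unit_rng(seed, f"donor/{d}").normal(0.0, vc.sd_donor))
                   for d in design.donor_ids()}
    clone_shift = {c: float(_unit_rng(seed, f"clone/{c}").normal(0.0, vc.sd_clone))
                   for _, c in design.clone_ids()}
    day_shift = {(c, day): float(_unit_rng(seed, f"day/{c}/{day}").normal(0.0, vc.sd_day))
                 for _, c in design.clone_ids() for day in range(1, design.n_days + 1)}

    rows = []
    for donor, clone in design.clone_ids():
        for day in range(1, design.n_days + 1):
            shift = donor_shift[donor] + clone_shift[clone] + day_shift[(clone, day)]
            rng = _unit_rng(seed, f"wells/{clone}/{day}")
            # control wells: viability 100% by definition
            n_ctrl = design.control_wells_per_clone
            noise = rng.normal(0.0, vc.sd_well, size=n_ctrl) if vc.sd_well > 0 else np.zeros(n_ctrl)
            fl = np.maximum(design.control_baseline * (1.0 + noise), 0.0)
            for r in range(n_ctrl):
                rows.append((donor, clone, day, "control", 0.0, True, r + 1, fl[r]))
            for chem in design.chemicals:
                viab = true_viability(chem, shift, np.asarray(chem.titers_um))
                for j, conc in enumerate(chem.titers_um):
                    nrep = design.replicate_wells_per_titer
                    noise = rng.normal(0.0, vc.sd_well, size=nrep) if vc.sd_well > 0 else np.zeros(nrep)
                    fl = np.maximum(
                        design.control_baseline * (viab[j] / 100.0) * (1.0 + noise), 0.0)
                    for r in range(nrep):
                        rows.append((donor, clone, day, chem.name, float(conc), False,
                                     r + 1, fl[r]))

    wells = pd.DataFrame(
        rows,
        columns=["donor_id", "clone_id", "day", "chemical", "conc_um",
                 "is_control", "replicate", "fluorescence"],
    )
    truth = {
        "seed": seed,
        "chemicals": [
            {"name": c.name, "titers_um": list(c.titers_um),
             "true_log_ic50": c.true_log_ic50, "hill_slope": c.hill_slope,
             "toxic": c.toxic}
            for c in design.chemicals
        ],
        "variance_components": asdict(vc),
        "donor_shift": donor_shift,
        "clone_shift": clone_shift,
        "day_shift": {f"{c}/{d}": s for (c, d), s in day_shift.items()},
    }
    return wells, truth


def write_study(wells: pd.DataFrame, truth: dict, csv_path, truth_path) -> None:
    """Write the raw well table as CSV and the ground-truth sidecar as JSON."""
    wells.to_csv(csv_path, index=False)
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2)
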