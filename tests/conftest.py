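import numpy as np
import pytest

from ecfctox import (StudyDesign, VarianceComponents, ChemicalSpec,
                     generate_study, normalize)


@pytest.fixture(scope="session")
def default_design():
    return StudyDesign()


@pytest.fixture(scope="session")
def noise_free_study(default_design):
    """Deterministic study: all random effects and well noise switched off."""
    vc = VarianceComponents(sd_donor=0.0, sd_clone=0.0, sd_day=0.0, sd_well=0.0)
    wells, truth = generate_study(default_design, vc, seed=7)
    return wells, truth


@pytest.fixture(scope="session")
def noisy_study(default_design):
    """Study at the default variance components."""
    wells, truth = generate_study(default_design, VarianceComponents(), seed=11)
    return wells, truth


@pytest.fixture(scope="session")
def noisy_profiles(noisy_study):
    wells, _ = noisy_study
    return normalize(wells)


def hill_profile(m=3.0, h=2.0, top_um=50.0, sd_well=0.0, seed=0, n_titers=9):
    """One clone/chemical/day profile sampled from a Hill ground truth."""
    from ecfctox.normalize import NormalizedProfile
    from ecfctox.design import t_from_um, true_viability

    conc = top_um / np.exp2(np.arange(n_titers - 1, -1, -1, dtype=float))
    spec = ChemicalSpec("hill", tuple(conc), m, h, True)
    viab = true_viability(spec, 0.0, conc)
    if sd_well > 0:
        rng = np.random.default_rng(seed)
        # duplicate-well design: average of two noisy replicates per titer
        noise = rng.normal(0.0, sd_well, size=(2, n_titers)).mean(axis=0)
        viab = viab * (1.0 + noise)
    return NormalizedProfile(
        clone_id="c", chemical="hill", day=1, conc_um=conc,
        t=t_from_um(conc), viability=np.maximum(viab, 0.0),
        n_controls_used=32, n_controls_flagged=0, donor_id="d")
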