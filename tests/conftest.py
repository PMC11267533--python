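import pytest

from cspscreen import (
    InterfaceAnnotation,
    PeakList,
    ResonancePeak,
    SimulationConfig,
    simulate_titration,
)


def make_peaklist(shifts, *, ligand_conc=0.0, protein_conc=100.0, label="apo"):
    """Build a PeakList from {residue: (shift_n, shift_h)}."""
    return PeakList.from_peaks(
        (ResonancePeak(f"A{res}N-H", shift_n=n, shift_h=h) for res, (n, h) in shifts.items()),
        condition_label=label,
        ligand_conc=ligand_conc,
        protein_conc=protein_conc,
    )


def make_annotation15():
    """15 observable functional residues (8 cationic + 7 catalytic)."""
    return InterfaceAnnotation(
        membrane_interface=set(range(1, 21)),
        cationic_patch=set(range(1, 9)),
        catalytic_site=set(range(9, 16)),
        unassigned=set(),
    )


@pytest.fixture
def annotation15():
    return make_annotation15()


@pytest.fixture
def clean_series():
    """Noiseless 5-residue titration at the standard design (Kd = 105 uM)."""
    functional = sorted(SimulationConfig(seed=0).functional_residues)
    cfg = SimulationConfig(
        seed=7, noise_h=0.0, noise_n=0.0, responsive_residues=set(functional[:5])
    )
    series, truth = simulate_titration(cfg, "frag_clean")
    return series, truth
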