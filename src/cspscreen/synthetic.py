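"""Synthetic titrations and screens with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
two-state fast-exchange binding, so each responsive amide moves along a
fixed direction in weighted (1H, 15N) shift space by
dmax * bound_fraction(P, L, Kd), with independent Gaussian ppm noise on
every peak in every ligand-containing condition; the reference positions,
drawn once per simulation, are the noise-free baseline.  Defaults mirror the screening design: 100 uM
protein, a 0/50/100/250/400 uM fragment ladder (400 uM = the 4:1
fragment:protein screening ratio), a 15-residue observable functional
set, an apparent Kd of 105 uM, saturation shifts of 0.02-0.10 ppm and
noise of 0.002 ppm (1H) / 0.01 ppm (15N).

Scenarios:

- ``binder`` / ``weak_binder``: depletion isotherm at ``true_kd`` on the
  responsive residues (weak binders simply carry a large ``true_kd``);
- ``nonbinder``: no displacement anywhere;
- ``nonspecific_drift``: small non-saturating drift, linear in ligand
  concentration, scattered over all residues.

Everything is driven by one seeded generator per simulation: identical
config and seed give byte-identical peak lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .csp import ALPHA_N, CSPProfile, compute_csp
from .binding import bound_fraction
from .peaklists import InterfaceAnnotation, PeakList, ResonancePeak, TitrationSeries
from .screening import MixtureRecord

__all__ = [
    "SimulationConfig",
    "TruthEntry",
    "ScreenSimulation",
    "SCENARIOS",
    "default_functional_residues",
    "default_annotation",
    "simulate_titration",
    "simulate_screen",
]

SCENARIOS = ("binder", "nonbinder", "nonspecific_drift", "weak_binder")

_AA = "ACDEFGHIKLMNPQRSTVWY"


def default_functional_residues(n_residues: int = 40, n_functional: int = 15) -> set[int]:
    """``n_functional`` residues evenly spread over 1..n_residues."""
    if n_functional > n_residues:
        raise ValueError("more functional residues than residues")
    idx = np.linspace(1, n_residues, n_functional)
    return {int(round(i)) for i in idx}


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic fragment experiment."""

    seed: int
    n_residues: int = 40
    functional_residues: set[int] = field(default_factory=default_functional_residues)
    protein_conc: float = 100.0  # uM
    ligand_concs: tuple[float, ...] = (0.0, 50.0, 100.0, 250.0, 400.0)
    true_kd: float = 105.0  # uM
    responsive_residues: set[int] | None = None  # default: 8 functional residues
    dmax_range: tuple[float, float] = (0.02, 0.10)  # ppm
    noise_h: float = 0.002  # ppm
    noise_n: float = 0.01  # ppm
    scenario: str = "binder"
    alpha: float = ALPHA_N
    drift_csp_max: float = 0.03  # ppm at L_max, nonspecific_drift only
    #: seed for the reference (apo) peak positions; defaults to ``seed``.
    #: A screen shares one protein, so all its fragments share this.
    reference_seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if self.noise_h < 0 or self.noise_n < 0:
            raise ValueError("noise sigmas must be >= 0")
        if 0.0 not in self.ligand_concs:
            raise ValueError("ligand_concs must include the zero reference point")
        if not self.functional_residues <= set(range(1, self.n_residues + 1)):
            raise ValueError("functional residues outside 1..n_residues")
        if self.responsive_residues is None and self.scenario in ("binder", "weak_binder"):
            self.responsive_residues = set(sorted(self.functional_residues)[:8])
        if self.responsive_residues:
            if not self.responsive_residues <= set(range(1, self.n_residues + 1)):
                raise ValueError("responsive residues outside 1..n_residues")
        if self.scenario in ("binder", "weak_binder") and not self.responsive_residues:
            raise ValueError(f"{self.scenario} scenario requires responsive residues")


@dataclass(frozen=True)
class TruthEntry:
    """Planted ground truth for one simulated fragment."""

    fragment_id: str
    scenario: str
    true_kd: float | None
    responsive_residues: frozenset[int]
    dmax: dict[int, float]


def default_annotation(config: SimulationConfig) -> InterfaceAnnotation:
    """Annotation consistent with the generator: functional residues split
    between cationic patch and catalytic site, plus a membrane interface
    that contains them and a few flanking residues."""
    functional = sorted(config.functional_residues)
    half = len(functional) // 2
    cationic = set(functional[:half])
    catalytic = set(functional[half:])
    extra = {r for r in range(1, config.n_residues + 1, 7)} - set(functional)
    return InterfaceAnnotation(
        membrane_interface=set(functional) | set(sorted(extra)[:5]),
        cationic_patch=cationic,
        catalytic_site=catalytic,
        unassigned=set(),
    )


def _reference_positions(rng: np.random.Generator, n_residues: int):
    """True (noise-free) amide positions and assignment labels, drawn once."""
    labels, pos_h, pos_n = [], [], []
    for res in range(1, n_residues + 1):
        aa = _AA[rng.integers(len(_AA))]
        labels.append(f"{aa}{res}N-H")
        pos_h.append(float(rng.uniform(7.0, 9.5)))
        pos_n.append(float(rng.uniform(106.0, 128.0)))
    return labels, np.array(pos_h), np.array(pos_n)


def _displacement_direction(rng: np.random.Generator, alpha: float):
    """Unit displacement in weighted shift space: moving a peak by
    (d*cos(t), d*sin(t)/alpha) in (1H, 15N) gives weighted CSP d."""
    theta = float(rng.uniform(0.0, 2.0 * math.pi))
    return math.cos(theta), math.sin(theta) / alpha


def simulate_titration(
    config: SimulationConfig, fragment_id: str = "F0001"
) -> tuple[TitrationSeries, TruthEntry]:
    """Generate a residue-matched titration series plus its truth entry."""
    ref_seed = config.reference_seed if config.reference_seed is not None else config.seed
    labels, ref_h, ref_n = _reference_positions(
        np.random.default_rng(ref_seed), config.n_residues
    )
    rng = np.random.default_rng(config.seed)
    n_res = config.n_residues
    concs = sorted(config.ligand_concs)

    # per-residue saturation shift and displacement direction
    dmax: dict[int, float] = {}
    direction: dict[int, tuple[float, float]] = {}
    if config.scenario in ("binder", "weak_binder"):
        for res in sorted(config.responsive_residues):
            dmax[res] = float(rng.uniform(*config.dmax_range))
            direction[res] = _displacement_direction(rng, config.alpha)
    elif config.scenario == "nonspecific_drift":
        for res in range(1, n_res + 1):
            dmax[res] = float(rng.uniform(0.2, 1.0)) * config.drift_csp_max
            direction[res] = _displacement_direction(rng, config.alpha)

    def magnitude(res: int, l_total: float) -> float:
        if res not in dmax or l_total == 0.0:
            return 0.0
        if config.scenario in ("binder", "weak_binder"):
            return dmax[res] * bound_fraction(config.protein_conc, l_total, config.true_kd)
        # nonspecific drift: linear, non-saturating
        return dmax[res] * l_total / max(concs)

    lists = []
    for l_total in concs:
        peaks = []
        for i, res in enumerate(range(1, n_res + 1)):
            d = magnitude(res, l_total)
            dh = dn = 0.0
            if d:
                ux, uy = direction[res]
                dh, dn = d * ux, d * uy
            # the reference list is the noise-free baseline; measurement
            # noise enters at each ligand-containing condition
            if l_total > 0.0:
                nh = rng.normal(0.0, config.noise_h) if config.noise_h else 0.0
                nn = rng.normal(0.0, config.noise_n) if config.noise_n else 0.0
            else:
                nh = nn = 0.0
            peaks.append(
                ResonancePeak(
                    labels[i],
                    shift_n=float(ref_n[i] + dn + nn),
                    shift_h=float(ref_h[i] + dh + nh),
                )
            )
        lists.append(
            PeakList.from_peaks(
                peaks,
                condition_label=f"{fragment_id}_L{l_total:g}",
                ligand_conc=l_total,
                protein_conc=config.protein_conc,
                environment="mmRM",
            )
        )
    series = TitrationSeries(
        fragment_id=fragment_id,
        reference=lists[0],
        points=lists[1:],
    )
    truth = TruthEntry(
        fragment_id=fragment_id,
        scenario=config.scenario,
        true_kd=config.true_kd if config.scenario in ("binder", "weak_binder") else None,
        responsive_residues=frozenset(config.responsive_residues or ()),
        dmax=dict(dmax) if config.scenario != "nonspecific_drift" else dict(dmax),
    )
    return series, truth


@dataclass
class ScreenSimulation:
    """A simulated mixture screen with its planted truth."""

    mixtures: list[MixtureRecord]
    annotation: InterfaceAnnotation
    truth: dict[str, TruthEntry]
    fragment_configs: dict[str, SimulationConfig]
    screen_conc: float  # uM fragment concentration at the screening stage

    @property
    def planted_binders(self) -> set[str]:
        return {f for f, t in self.truth.items() if t.scenario == "binder"}

    def titration_for(self, fragment_id: str) -> TitrationSeries:
        """Regenerate the (deterministic) titration series of one fragment."""
        series, _ = simulate_titration(self.fragment_configs[fragment_id], fragment_id)
        return series

    def deconvolution_profile(self, fragment_id: str) -> CSPProfile:
        """Single-fragment CSP profile at the screening concentration."""
        series = self.titration_for(fragment_id)
        point = max(series.points, key=lambda p: p.ligand_conc)
        return compute_csp(series.reference, point, alpha=self.fragment_configs[fragment_id].alpha)


def _partition(ids: list[str], mixture_size: int) -> list[list[str]]:
    return [ids[i : i + mixture_size] for i in range(0, len(ids), mixture_size)]


def simulate_screen(
    library_size: int,
    n_binders: int,
    mixture_size: int,
    base_config: SimulationConfig,
    binder_kds: Iterable[float] | None = None,
) -> ScreenSimulation:
    """Simulate a full mixture screen with ``n_binders`` planted binders.

    Fragments are partitioned into ceil(library_size / mixture_size)
    consecutive mixtures (the last may be smaller).  A mixture's observed
    profile comes from the strongest (lowest-Kd) planted binder it
    contains — with one protein observable, co-screened non-binders
    contribute nothing and competition between co-binders is not modeled,
    mirroring the single-fragment retest at deconvolution.
    """
    if not 0 <= n_binders <= library_size:
        raise ValueError("need 0 <= n_binders <= library_size")
    if mixture_size < 1:
        raise ValueError("mixture_size must be >= 1")
    rng = np.random.default_rng(base_config.seed)
    ids = [f"F{i:04d}" for i in range(1, library_size + 1)]
    binder_ids = sorted(rng.choice(library_size, size=n_binders, replace=False))
    binder_set = {ids[i] for i in binder_ids}
    if binder_kds is None:
        kds = [base_config.true_kd] * n_binders
    else:
        kds = list(binder_kds)
        if len(kds) != n_binders:
            raise ValueError("binder_kds length must equal n_binders")
    kd_of = dict(zip(sorted(binder_set), kds))

    configs: dict[str, SimulationConfig] = {}
    truth: dict[str, TruthEntry] = {}
    for fid in ids:
        seed = int(rng.integers(0, 2**31 - 1))
        ref_seed = (
            base_config.reference_seed
            if base_config.reference_seed is not None
            else base_config.seed
        )
        if fid in binder_set:
            cfg = replace(
                base_config,
                seed=seed,
                reference_seed=ref_seed,
                scenario="binder",
                true_kd=kd_of[fid],
            )
        else:
            cfg = replace(
                base_config,
                seed=seed,
                reference_seed=ref_seed,
                scenario="nonbinder",
                responsive_residues=set(),
            )
        configs[fid] = cfg
        _, entry = simulate_titration(cfg, fid)
        truth[fid] = entry

    screen_conc = max(base_config.ligand_concs)
    mixtures = []
    for m, members in enumerate(_partition(ids, mixture_size), start=1):
        binders_here = [f for f in members if f in binder_set]
        if binders_here:
            strongest = min(binders_here, key=lambda f: kd_of[f])
            series, _ = simulate_titration(configs[strongest], strongest)
        else:
            # pure-background mixture: a nonbinder member supplies the spectrum
            series, _ = simulate_titration(configs[members[0]], members[0])
        point = max(series.points, key=lambda p: p.ligand_conc)
        profile = compute_csp(series.reference, point, alpha=base_config.alpha)
        profile.fragment_id = f"M{m:03d}"
        mixtures.append(
            MixtureRecord(mixture_id=f"M{m:03d}", fragment_ids=members, profile=profile)
        )
    return ScreenSimulation(
        mixtures=mixtures,
        annotation=default_annotation(base_config),
        truth=truth,
        fragment_configs=configs,
        screen_conc=screen_conc,
    )
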