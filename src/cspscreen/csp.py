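"""Chemical shift perturbation (CSP) profiles and top-shifter selection.

The combined amide perturbation between a reference and an observed
spectrum is the weighted Euclidean shift

    CSP = sqrt( (dH)^2 + (alpha * dN)^2 )   [ppm]

with the field-standard 15N weighting alpha = 0.14 by default.  Some
groups use a sqrt-mean variant differing by a constant factor; because
top-shifter selection is sigma-based and Kd fitting rescales amplitudes,
downstream results are insensitive to that choice, and ``alpha`` is
exposed for the rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaklists import PeakList

__all__ = [
    "ALPHA_N",
    "CSPProfile",
    "TopShifterSet",
    "compute_csp",
    "select_top_shifters",
    "compare_conditions",
    "plot_condition_comparison",
]

logger = logging.getLogger(__name__)

#: default 15N weighting factor in the combined-shift formula
ALPHA_N = 0.14


@dataclass
class CSPProfile:
    """Per-residue weighted CSPs of one condition relative to a reference."""

    fragment_id: str
    ligand_conc: float  # uM
    values: dict[int, float]  # residue -> CSP, ppm
    alpha: float = ALPHA_N
    reference_label: str = ""
    missing_residues: set[int] = field(default_factory=set)

    @property
    def residues(self) -> set[int]:
        return set(self.values)

    def as_series(self) -> pd.Series:
        s = pd.Series(self.values, name="csp_ppm").sort_index()
        s.index.name = "residue"
        return s

    def to_csv(self, path) -> None:
        self.as_series().to_csv(path)


@dataclass(frozen=True)
class TopShifterSet:
    """Residues whose CSP is at least ``k_sigma`` SDs above the profile mean."""

    residues: frozenset[int]
    threshold: float  # ppm
    k_sigma: float


def compute_csp(reference: PeakList, observed: PeakList, alpha: float = ALPHA_N) -> CSPProfile:
    """Compute per-residue CSPs of ``observed`` relative to ``reference``.

    Residues present in only one list are omitted from the profile and
    recorded in ``missing_residues``.  Raises if the lists share no
    assignment.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    shared = reference.residues & observed.residues
    if not shared:
        raise ValueError(
            f"no shared assignments between {reference.condition_label!r} "
            f"and {observed.condition_label!r}"
        )
    values = {}
    for res in shared:
        dh = observed.peaks[res].shift_h - reference.peaks[res].shift_h
        dn = observed.peaks[res].shift_n - reference.peaks[res].shift_n
        values[res] = float(np.hypot(dh, alpha * dn))
    return CSPProfile(
        fragment_id=observed.condition_label,
        ligand_conc=observed.ligand_conc,
        values=values,
        alpha=alpha,
        reference_label=reference.condition_label,
        missing_residues=(reference.residues | observed.residues) - shared,
    )


def select_top_shifters(profile: CSPProfile, k_sigma: float = 1.0) -> TopShifterSet:
    """Residues with CSP >= mean + k_sigma * sigma (population SD, inclusive).

    With all CSPs equal, sigma is zero and every residue meets the
    inclusive threshold; this degenerate case is logged as a warning.
    """
    if k_sigma < 0:
        raise ValueError(f"k_sigma must be >= 0, got {k_sigma}")
    if len(profile.values) < 2:
        raise ValueError("need at least 2 residues to define a sigma threshold")
    arr = np.array(list(profile.values.values()))
    sigma = float(arr.std())  # population SD over residues
    threshold = float(arr.mean()) + k_sigma * sigma
    if sigma == 0.0:
        logger.warning(
            "all %d CSPs equal (sigma = 0); every residue meets the inclusive threshold",
            arr.size,
        )
    members = frozenset(r for r, v in profile.values.items() if v >= threshold)
    return TopShifterSet(residues=members, threshold=threshold, k_sigma=k_sigma)


def compare_conditions(
    profile_a: CSPProfile, profile_b: CSPProfile, residues: set[int]
) -> pd.DataFrame:
    """Pair per-residue CSPs of two conditions for a chosen residue set.

    Returns a residue-ordered table with columns ``csp_a``, ``csp_b``,
    ``difference`` (a - b); residues absent from profile_b get NaN in
    ``csp_b``/``difference`` and are marked ``absent_b``.
    """
    if not residues:
        raise ValueError("empty residue set")
    missing_a = set(residues) - profile_a.residues
    if missing_a:
        raise ValueError(f"residues {sorted(missing_a)} not in profile_a")
    rows = []
    for res in sorted(residues):
        a = profile_a.values[res]
        b = profile_b.values.get(res)
        rows.append(
            {
                "residue": res,
                "csp_a": a,
                "csp_b": b if b is not None else np.nan,
                "difference": a - b if b is not None else np.nan,
                "absent_b": b is None,
            }
        )
    return pd.DataFrame(rows).set_index("residue")


def plot_condition_comparison(table: pd.DataFrame, path, labels=("condition A", "condition B")):
    """Grouped bar plot of paired per-residue CSPs (saved to ``path``)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(table))
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(table)), 3))
    ax.bar(x - 0.2, table["csp_a"], width=0.4, label=labels[0], color="tab:blue")
    ax.bar(x + 0.2, table["csp_b"].fillna(0.0), width=0.4, label=labels[1], color="black")
    ax.set_xticks(x, [str(r) for r in table.index])
    ax.set_xlabel("residue")
    ax.set_ylabel("CSP (ppm)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
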