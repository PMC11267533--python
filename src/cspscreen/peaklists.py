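"""Assigned 2D peak lists and residue annotations.

Peak lists follow the Sparky ``.list`` dialect: whitespace-delimited
columns ``assignment  w1  w2  [height]`` with an optional single header
line.  By convention w1 is the 15N shift and w2 the 1H shift; the swapped
order found in some exports is supported via ``column_order="hn"``.

Peaks are matched across conditions by residue number parsed from the
assignment label (e.g. ``A11N-H`` -> residue 11); lists are assumed to
carry curated, transferred assignments, so no peak tracking is done.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ResonancePeak",
    "PeakList",
    "TitrationSeries",
    "InterfaceAnnotation",
    "PeakListError",
    "read_peaklist",
    "write_peaklist",
    "build_titration_series",
    "read_annotation",
    "write_annotation",
]

ENVIRONMENTS = ("mmRM", "micelle", "bicelle", "aqueous")

# amide chemical-shift sanity windows, ppm
H_RANGE = (-2.0, 14.0)
N_RANGE = (90.0, 140.0)

_ASSIGNMENT_RE = re.compile(r"^([A-Za-z]{0,3})(\d+)")


class PeakListError(ValueError):
    """Malformed peak list, annotation table, or titration design."""


@dataclass(frozen=True)
class ResonancePeak:
    """One assigned amide cross-peak: label, 15N and 1H shifts in ppm."""

    assignment: str
    shift_n: float
    shift_h: float
    height: float | None = None

    def __post_init__(self) -> None:
        if not self.assignment:
            raise PeakListError("empty assignment label")
        if not H_RANGE[0] <= self.shift_h <= H_RANGE[1]:
            raise PeakListError(
                f"{self.assignment}: 1H shift {self.shift_h} ppm outside {H_RANGE}"
            )
        if not N_RANGE[0] <= self.shift_n <= N_RANGE[1]:
            raise PeakListError(
                f"{self.assignment}: 15N shift {self.shift_n} ppm outside {N_RANGE}"
            )

    @property
    def residue(self) -> int:
        """Residue number parsed from the assignment label."""
        m = _ASSIGNMENT_RE.match(self.assignment)
        if m is None:
            raise PeakListError(f"cannot parse residue number from {self.assignment!r}")
        return int(m.group(2))

    @property
    def residue_type(self) -> str:
        """One-letter (or three-letter) residue code, possibly empty."""
        m = _ASSIGNMENT_RE.match(self.assignment)
        return m.group(1) if m else ""


@dataclass
class PeakList:
    """One 15N-HSQC measurement under a single sample condition."""

    condition_label: str
    ligand_conc: float  # uM, total
    protein_conc: float  # uM, total
    environment: str = "mmRM"
    peaks: dict[int, ResonancePeak] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ligand_conc < 0:
            raise PeakListError(f"ligand_conc {self.ligand_conc} < 0")
        if self.protein_conc <= 0:
            raise PeakListError(f"protein_conc {self.protein_conc} <= 0")
        if self.environment not in ENVIRONMENTS:
            raise PeakListError(
                f"unknown environment {self.environment!r}; expected one of {ENVIRONMENTS}"
            )

    @classmethod
    def from_peaks(cls, peaks: Iterable[ResonancePeak], **meta) -> "PeakList":
        pl = cls(peaks={}, **meta)
        for p in peaks:
            pl.add(p)
        return pl

    def add(self, peak: ResonancePeak) -> None:
        if peak.residue in self.peaks:
            raise PeakListError(
                f"duplicate assignment for residue {peak.residue} "
                f"({self.peaks[peak.residue].assignment!r} / {peak.assignment!r})"
            )
        self.peaks[peak.residue] = peak

    @property
    def residues(self) -> set[int]:
        return set(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(sorted(self.peaks.values(), key=lambda p: p.residue))


@dataclass
class TitrationSeries:
    """Concentration-ordered, residue-matched peak lists for one fragment.

    The ligand-free sample is the reference (zero point); titration points
    are sorted by ascending total ligand concentration and share the
    protein concentration of the reference.
    """

    fragment_id: str
    reference: PeakList
    points: list[PeakList]
    incomplete_residues: set[int] = field(default_factory=set)

    @property
    def protein_conc(self) -> float:
        return self.reference.protein_conc

    @property
    def ligand_concs(self) -> list[float]:
        return [p.ligand_conc for p in self.points]

    @property
    def residues(self) -> set[int]:
        """Residues observable in the reference and every titration point."""
        common = set(self.reference.residues)
        for p in self.points:
            common &= p.residues
        return common


@dataclass
class InterfaceAnnotation:
    """Residue categories used for triage, hit calling and mapping.

    ``observable_functional`` is the screening denominator: cationic-patch
    and catalytic-site residues whose resonances are observable, i.e. the
    union minus residues unassigned under the working condition.
    """

    membrane_interface: set[int] = field(default_factory=set)
    cationic_patch: set[int] = field(default_factory=set)
    catalytic_site: set[int] = field(default_factory=set)
    unassigned: set[int] = field(default_factory=set)

    @property
    def observable_functional(self) -> set[int]:
        return (self.cationic_patch | self.catalytic_site) - self.unassigned

    def category(self, residue: int) -> str:
        if residue in self.unassigned:
            return "unassigned"
        if residue in self.catalytic_site:
            return "catalytic"
        if residue in self.cationic_patch:
            return "cationic"
        if residue in self.membrane_interface:
            return "interface"
        return "other"


_CATEGORY_FIELDS: Mapping[str, str] = {
    "interface": "membrane_interface",
    "cationic": "cationic_patch",
    "catalytic": "catalytic_site",
    "unassigned": "unassigned",
}


def read_peaklist(
    path: str | Path,
    *,
    condition_label: str = "",
    ligand_conc: float = 0.0,
    protein_conc: float = 100.0,
    environment: str = "mmRM",
    column_order: str = "nh",
) -> PeakList:
    """Parse a Sparky-style ``.list`` file into a :class:`PeakList`.

    ``column_order`` is ``"nh"`` (w1 = 15N, w2 = 1H; the common Sparky
    convention) or ``"hn"`` for swapped exports.  A single non-numeric
    header line is skipped; blank lines are ignored.
    """
    if column_order not in ("nh", "hn"):
        raise PeakListError(f"column_order must be 'nh' or 'hn', got {column_order!r}")
    path = Path(path)
    pl = PeakList(
        condition_label=condition_label or path.stem,
        ligand_conc=ligand_conc,
        protein_conc=protein_conc,
        environment=environment,
    )
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.split()
            if not parts:
                continue
            if lineno == 1 and _looks_like_header(parts):
                continue
            if len(parts) < 3:
                raise PeakListError(f"{path}:{lineno}: expected >=3 columns, got {len(parts)}")
            label = parts[0]
            try:
                w1, w2 = float(parts[1]), float(parts[2])
                height = float(parts[3]) if len(parts) > 3 else None
            except ValueError as exc:
                raise PeakListError(f"{path}:{lineno}: non-numeric shift field") from exc
            shift_n, shift_h = (w1, w2) if column_order == "nh" else (w2, w1)
            pl.add(ResonancePeak(label, shift_n=shift_n, shift_h=shift_h, height=height))
    return pl


def _looks_like_header(parts: Sequence[str]) -> bool:
    if len(parts) < 3:
        return True
    try:
        float(parts[1]), float(parts[2])
    except ValueError:
        return True
    return False


def write_peaklist(pl: PeakList, path: str | Path) -> Path:
    """Write a Sparky-style ``.list`` file (w1 = 15N, w2 = 1H, 4 dp)."""
    path = Path(path)
    any_height = any(p.height is not None for p in pl)
    with path.open("w") as fh:
        header = f"{'Assignment':>12s} {'w1':>9s} {'w2':>9s}"
        if any_height:
            header += f" {'Height':>12s}"
        fh.write(header + "\n")
        for p in pl:
            line = f"{p.assignment:>12s} {p.shift_n:9.4f} {p.shift_h:9.4f}"
            if any_height:
                line += f" {p.height if p.height is not None else 0.0:12.4f}"
            fh.write(line + "\n")
    return path


def build_titration_series(
    lists: Iterable[PeakList], fragment_id: str
) -> TitrationSeries:
    """Assemble a titration series from peak lists in any input order.

    Exactly one list must have ``ligand_conc == 0`` (the reference) and all
    lists must share a protein concentration.  Residues absent from any
    point are retained but flagged in ``incomplete_residues``; they are
    excluded per-fit downstream rather than dropped here.
    """
    lists = list(lists)
    refs = [pl for pl in lists if pl.ligand_conc == 0]
    if len(refs) != 1:
        raise PeakListError(
            f"need exactly one ligand-free reference list, found {len(refs)}"
        )
    reference = refs[0]
    points = sorted(
        (pl for pl in lists if pl.ligand_conc > 0), key=lambda pl: pl.ligand_conc
    )
    concs = [p.ligand_conc for p in points]
    if len(set(concs)) != len(concs):
        raise PeakListError(f"duplicate ligand concentrations: {concs}")
    p0 = reference.protein_conc
    for pl in points:
        if pl.protein_conc != p0:
            raise PeakListError(
                f"protein_conc differs across lists: {pl.protein_conc} vs {p0} uM"
            )
    all_res: set[int] = reference.residues.union(*(p.residues for p in points))
    complete = reference.residues.intersection(*(p.residues for p in points)) if points else reference.residues
    return TitrationSeries(
        fragment_id=fragment_id,
        reference=reference,
        points=points,
        incomplete_residues=all_res - complete,
    )


def read_annotation(path: str | Path) -> InterfaceAnnotation:
    """Read a ``residue,category`` CSV into an :class:`InterfaceAnnotation`.

    Categories: ``interface``, ``cationic``, ``catalytic``, ``unassigned``.
    A residue may carry several categories (one row each).
    """
    ann = InterfaceAnnotation()
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or not row[0].strip():
                continue
            first = row[0].strip().lower()
            if lineno == 1 and first in ("residue", "res", "#residue"):
                continue
            if len(row) < 2:
                raise PeakListError(f"{path}:{lineno}: expected residue,category")
            try:
                residue = int(row[0])
            except ValueError as exc:
                raise PeakListError(f"{path}:{lineno}: bad residue number {row[0]!r}") from exc
            cat = row[1].strip().lower()
            if cat not in _CATEGORY_FIELDS:
                raise PeakListError(
                    f"{path}:{lineno}: unknown category {cat!r}; "
                    f"expected one of {sorted(_CATEGORY_FIELDS)}"
                )
            getattr(ann, _CATEGORY_FIELDS[cat]).add(residue)
    return ann


def write_annotation(ann: InterfaceAnnotation, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["residue", "category"])
        for cat, attr in _CATEGORY_FIELDS.items():
            for res in sorted(getattr(ann, attr)):
                writer.writerow([res, cat])
    return path
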