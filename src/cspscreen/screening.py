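"""Mixture triage, deconvolution hit calling, and screen statistics.

A mixture's HSQC is triaged by counting interface-region resonances
perturbed beyond a CSP threshold; flagged mixtures are deconvoluted by
retesting members singly, and a fragment is called a hit when at least
``min_count`` of the observable functional resonances (cationic patch or
catalytic site; 15 for GPx4) shift by strictly more than the threshold
(defaults 7 of 15, > 0.01 ppm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .csp import CSPProfile
from .peaklists import InterfaceAnnotation

__all__ = [
    "Priority",
    "MixtureRecord",
    "ScreenSummary",
    "DEFAULT_CSP_THRESHOLD",
    "DEFAULT_MIN_COUNT",
    "TIER_BOUNDS",
    "count_above_threshold",
    "triage_mixture",
    "call_hit_deconvolution",
    "summarize_screen",
]

#: CSP cutoff for a resonance to count as shifted, ppm (strict >)
DEFAULT_CSP_THRESHOLD = 0.01
#: minimum number of shifted functional resonances denoting a hit
DEFAULT_MIN_COUNT = 7
#: triage tier lower bounds on the shifted-resonance count: high, medium, low
TIER_BOUNDS = (5, 3, 1)


class Priority(str, Enum):
    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"
    NONE = "none"


@dataclass
class MixtureRecord:
    """One screened mixture: members, its CSP profile, and triage outcome."""

    mixture_id: str
    fragment_ids: list[str]
    profile: CSPProfile | None = None
    priority: Priority = Priority.NONE
    insoluble_flag: bool = False
    n_above_threshold: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.fragment_ids) <= 10:
            raise ValueError(
                f"{self.mixture_id}: mixtures carry 1-10 fragments, got {len(self.fragment_ids)}"
            )


@dataclass
class ScreenSummary:
    """Screen-level counts and the validated hit rate in percent."""

    library_size: int
    n_mixtures: int
    n_flagged: int
    n_deconvoluted: int
    n_validated_hits: int
    hit_rate_percent: float = field(init=False)

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.n_validated_hits > self.n_deconvoluted:
            raise ValueError("validated hits cannot exceed deconvoluted fragments")
        if self.n_deconvoluted > self.library_size:
            raise ValueError("deconvoluted fragments cannot exceed library size")
        self.hit_rate_percent = round(100.0 * self.n_validated_hits / self.library_size, 2)


def count_above_threshold(
    profile: CSPProfile, residues: Iterable[int], csp_threshold: float
) -> int:
    """Number of the given residues with CSP strictly above the threshold."""
    return sum(1 for r in residues if profile.values.get(r, 0.0) > csp_threshold)


def triage_mixture(
    profile: CSPProfile,
    annotation: InterfaceAnnotation,
    csp_threshold: float = DEFAULT_CSP_THRESHOLD,
    tier_bounds: Sequence[int] = TIER_BOUNDS,
) -> Priority:
    """Assign a priority tier by counting shifted interface-region resonances.

    Counts residues of the membrane interface plus observable functional
    set with CSP > ``csp_threshold``: >= tier_bounds[0] -> high,
    >= tier_bounds[1] -> medium, >= tier_bounds[2] -> low, else none.
    This is a quantitative surrogate for by-eye prioritization; the
    boundaries (5 / 3 / 1 by default) are configurable.
    """
    if not profile.values:
        raise ValueError("empty CSP profile")
    if not annotation.observable_functional:
        raise ValueError("annotation has no observable functional residues")
    hi, med, lo = tier_bounds
    if not hi > med > lo >= 1:
        raise ValueError(f"tier bounds must be decreasing and >= 1, got {tier_bounds}")
    interest = annotation.membrane_interface | annotation.observable_functional
    n = count_above_threshold(profile, interest, csp_threshold)
    if n >= hi:
        return Priority.HIGH
    if n >= med:
        return Priority.MEDIUM
    if n >= lo:
        return Priority.LOW
    return Priority.NONE


def call_hit_deconvolution(
    profile: CSPProfile,
    annotation: InterfaceAnnotation,
    min_count: int = DEFAULT_MIN_COUNT,
    csp_threshold: float = DEFAULT_CSP_THRESHOLD,
) -> bool:
    """Hit iff >= ``min_count`` observable functional residues shift > threshold.

    The inequality on CSP is strict (a resonance at exactly the threshold
    does not count); the count comparison is inclusive.  The denominator is
    whatever the annotation declares observable, not a hard-coded 15.
    """
    functional = annotation.observable_functional
    if not functional:
        raise ValueError("annotation has no observable functional residues")
    return count_above_threshold(profile, functional, csp_threshold) >= min_count


def summarize_screen(
    library_size: int,
    mixtures: Iterable[MixtureRecord] = (),
    deconvoluted: Iterable[str] = (),
    validated_hits: Iterable[str] = (),
    *,
    n_mixtures: int | None = None,
    n_flagged: int | None = None,
    n_deconvoluted: int | None = None,
    n_validated_hits: int | None = None,
) -> ScreenSummary:
    """Tally screen results into a :class:`ScreenSummary`.

    Counts are taken from the record collections; explicit ``n_*``
    keywords override them (useful when only totals are known).  The hit
    rate is 100 * validated hits / library size, reported to 2 decimals.
    """
    mixtures = list(mixtures)
    if n_mixtures is None:
        n_mixtures = len(mixtures)
    if n_flagged is None:
        n_flagged = sum(1 for m in mixtures if m.priority != Priority.NONE)
    if n_deconvoluted is None:
        n_deconvoluted = len(set(deconvoluted))
    if n_validated_hits is None:
        n_validated_hits = len(set(validated_hits))
    return ScreenSummary(
        library_size=library_size,
        n_mixtures=n_mixtures,
        n_flagged=n_flagged,
        n_deconvoluted=n_deconvoluted,
        n_validated_hits=n_validated_hits,
    )
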