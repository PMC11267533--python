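"""Ligand-depletion binding model, per-residue and global Kd fitting.

At fragment concentrations comparable to the protein concentration the
bound ligand depletes the free pool, so the hyperbolic isotherm is
replaced by the exact 1:1 solution in total concentrations.  With
P = total protein, L = total ligand and Kd the apparent dissociation
constant (all uM), the bound protein fraction is

    f(P, L, Kd) = ((P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L)) / (2 P)

Under fast exchange an amide resonance sits at the population-weighted
average of free and bound positions, so its CSP is dmax * f, with dmax
the saturation shift of that residue.  Residues are first fit
individually; fits with R^2 below a cutoff (0.85 by default) are
discarded, and the survivors are refit jointly with one shared Kd and
per-residue dmax.  The Kd standard error is taken from the parameter
covariance of the joint fit.

Apparent Kd values refer to totals over the whole sample; no correction
for partitioning of fragment to the membrane mimic is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import lmfit
import numpy as np

from .csp import ALPHA_N, CSPProfile, compute_csp, select_top_shifters
from .peaklists import InterfaceAnnotation, TitrationSeries

__all__ = [
    "BindingParams",
    "ResidueFit",
    "GlobalFitResult",
    "FragmentClass",
    "DEFAULT_R2_CUTOFF",
    "DEFAULT_KD_CUTOFF",
    "DEFAULT_LOCALITY_FRACTION",
    "bound_fraction",
    "predict_csp",
    "extract_residue_csps",
    "fit_residue",
    "fit_global",
    "classify_fragment",
]

#: individual fits with R^2 strictly below this are excluded from the global fit
DEFAULT_R2_CUTOFF = 0.85
#: apparent-Kd cutoff separating hits from weak binders, uM (1 mM)
DEFAULT_KD_CUTOFF = 1000.0
#: minimum fraction of top shifters in the interface/functional region for
#: binding to count as structurally localized
DEFAULT_LOCALITY_FRACTION = 0.5

_FIT_TOL = 1e-10  # relative ftol/xtol for least squares


class FragmentClass(str, Enum):
    HIT = "hit"
    WEAK = "weak"
    NONSPECIFIC = "nonspecific"


@dataclass(frozen=True)
class BindingParams:
    kd: float  # apparent dissociation constant, uM
    dmax: float  # saturation CSP, ppm

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError(f"kd must be positive, got {self.kd}")
        if self.dmax <= 0:
            raise ValueError(f"dmax must be positive, got {self.dmax}")


@dataclass
class ResidueFit:
    """Outcome of a single-residue isotherm fit."""

    residue: int
    params: BindingParams | None
    r_squared: float
    n_points: int
    ok: bool = True
    reason: str = ""


@dataclass
class GlobalFitResult:
    """Shared-Kd joint fit over the residues surviving the R^2 filter."""

    fragment_id: str
    kd: float  # uM
    kd_stderr: float  # uM
    per_residue_dmax: dict[int, float]
    residues_used: set[int]
    residues_rejected: dict[int, str] = field(default_factory=dict)
    residue_fits: dict[int, ResidueFit] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residues_used & set(self.residues_rejected):
            raise ValueError("a residue cannot be both used and rejected")


def bound_fraction(p_total, l_total, kd):
    """Fraction of protein bound at total concentrations P, L and given Kd.

    Accepts scalars or arrays for ``l_total``; the result lies in [0, 1].
    """
    p = np.asarray(p_total, dtype=float)
    l = np.asarray(l_total, dtype=float)
    if np.any(p <= 0):
        raise ValueError("protein concentration must be positive")
    if np.any(l < 0):
        raise ValueError("ligand concentration must be non-negative")
    if np.any(np.asarray(kd) <= 0):
        raise ValueError("kd must be positive")
    s = p + l + kd
    disc = s * s - 4.0 * p * l
    frac = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * p)
    frac = np.clip(frac, 0.0, 1.0)
    return float(frac) if frac.ndim == 0 else frac


def predict_csp(params: BindingParams, p_total, l_total):
    """Model CSP at the given totals: dmax times the bound fraction."""
    return params.dmax * bound_fraction(p_total, l_total, params.kd)


def extract_residue_csps(
    series: TitrationSeries, residue: int, alpha: float = ALPHA_N
) -> tuple[np.ndarray, np.ndarray]:
    """(ligand concs, CSPs) for one residue across all points where observed."""
    if residue not in series.reference.residues:
        raise ValueError(f"residue {residue} absent from the reference list")
    concs, csps = [], []
    for point in series.points:
        if residue not in point.residues:
            continue
        prof = compute_csp(series.reference, point, alpha=alpha)
        concs.append(point.ligand_conc)
        csps.append(prof.values[residue])
    return np.array(concs), np.array(csps)


def _csp_residual(params, p_total, concs, csps):
    model = params["dmax"] * bound_fraction(p_total, concs, params["kd"].value)
    return model - csps


def _r_squared(observed: np.ndarray, model: np.ndarray) -> float:
    ss_res = float(np.sum((observed - model) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return -np.inf if ss_res > 0 else 1.0
    return 1.0 - ss_res / ss_tot


def _kd_initials(l_max: float) -> np.ndarray:
    # three log-spaced starts spanning tight to loose binding
    return np.geomspace(l_max / 50.0, 10.0 * l_max, 3)


def fit_residue(
    series: TitrationSeries, residue: int, alpha: float = ALPHA_N
) -> ResidueFit:
    """Bounded least-squares fit of the depletion isotherm to one residue.

    Requires the residue at >= 3 titration points.  Kd is constrained to
    (0, 10 * L_max] and dmax to (0, 10 * max observed CSP]; three
    log-spaced Kd starts guard against local minima.  All-zero CSPs are
    rejected outright (the dmax -> 0 boundary carries no Kd information).
    """
    concs, csps = extract_residue_csps(series, residue, alpha=alpha)
    n = len(concs)
    if n < 3:
        raise ValueError(f"residue {residue}: need >= 3 titration points, have {n}")
    if np.max(csps) <= 0.0:
        return ResidueFit(residue, None, -np.inf, n, ok=False, reason="no shift (dmax -> 0)")
    l_max = float(concs.max())
    csp_max = float(csps.max())
    best = None
    for kd0 in _kd_initials(l_max):
        params = lmfit.Parameters()
        params.add("kd", value=kd0, min=1e-6, max=10.0 * l_max)
        params.add("dmax", value=csp_max, min=1e-9, max=10.0 * csp_max)
        try:
            res = lmfit.minimize(
                _csp_residual,
                params,
                args=(series.protein_conc, concs, csps),
                method="leastsq",
                ftol=_FIT_TOL,
                xtol=_FIT_TOL,
            )
        except Exception:  # pragma: no cover - solver pathology
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        return ResidueFit(residue, None, -np.inf, n, ok=False, reason="did not converge")
    kd = float(best.params["kd"].value)
    dmax = float(best.params["dmax"].value)
    model = dmax * bound_fraction(series.protein_conc, concs, kd)
    return ResidueFit(
        residue=residue,
        params=BindingParams(kd=kd, dmax=dmax),
        r_squared=_r_squared(csps, model),
        n_points=n,
    )


def _global_residual(params, p_total, data):
    out = []
    frac_cache_kd = params["kd"].value
    for residue, (concs, csps) in data.items():
        model = params[f"dmax_{residue}"] * bound_fraction(p_total, concs, frac_cache_kd)
        out.append(model - csps)
    return np.concatenate(out)


def fit_global(
    series: TitrationSeries,
    residues: set[int] | frozenset[int],
    r2_cutoff: float = DEFAULT_R2_CUTOFF,
    alpha: float = ALPHA_N,
) -> GlobalFitResult:
    """Joint fit with one shared Kd and per-residue dmax.

    Each residue is first fit individually; residues whose fit failed or
    has R^2 strictly below ``r2_cutoff`` are rejected with a reason
    (R^2 exactly at the cutoff is retained).  The survivors enter one
    weighted least-squares problem whose Kd standard error comes from the
    covariance at the optimum.
    """
    if not residues:
        raise ValueError("empty residue set")
    fits: dict[int, ResidueFit] = {}
    rejected: dict[int, str] = {}
    for residue in sorted(residues):
        fit = fit_residue(series, residue, alpha=alpha)
        fits[residue] = fit
        if not fit.ok:
            rejected[residue] = fit.reason
        elif fit.r_squared < r2_cutoff:
            rejected[residue] = f"R^2 {fit.r_squared:.4f} < {r2_cutoff}"
    used = set(residues) - set(rejected)
    if not used:
        raise ValueError("no fit-worthy resonances: all residues rejected")

    data = {r: extract_residue_csps(series, r, alpha=alpha) for r in sorted(used)}
    l_max = max(float(c.max()) for c, _ in data.values())
    kd0 = float(np.median([fits[r].params.kd for r in used]))
    params = lmfit.Parameters()
    params.add("kd", value=kd0, min=1e-6, max=10.0 * l_max)
    for r in sorted(used):
        csp_max = float(data[r][1].max())
        params.add(f"dmax_{r}", value=fits[r].params.dmax, min=1e-9, max=10.0 * csp_max)
    result = lmfit.minimize(
        _global_residual,
        params,
        args=(series.protein_conc, data),
        method="leastsq",
        ftol=_FIT_TOL,
        xtol=_FIT_TOL,
    )
    kd = float(result.params["kd"].value)
    stderr = result.params["kd"].stderr
    if stderr is None or not np.isfinite(stderr):
        stderr = _gauss_newton_kd_stderr(result, series.protein_conc, data)
    return GlobalFitResult(
        fragment_id=series.fragment_id,
        kd=kd,
        kd_stderr=float(stderr),
        per_residue_dmax={r: float(result.params[f"dmax_{r}"].value) for r in sorted(used)},
        residues_used=used,
        residues_rejected=rejected,
        residue_fits=fits,
    )


def _gauss_newton_kd_stderr(result, p_total, data) -> float:
    """Fallback stderr from a finite-difference Gauss-Newton covariance."""
    names = [p for p in result.params if result.params[p].vary]
    theta = np.array([result.params[p].value for p in names])

    def resid(vec):
        prm = result.params.copy()
        for name, v in zip(names, vec):
            prm[name].value = v
        return _global_residual(prm, p_total, data)

    r0 = resid(theta)
    n_obs, n_par = r0.size, theta.size
    jac = np.empty((n_obs, n_par))
    for j in range(n_par):
        h = 1e-6 * max(abs(theta[j]), 1e-6)
        step = np.zeros_like(theta)
        step[j] = h
        jac[:, j] = (resid(theta + step) - resid(theta - step)) / (2.0 * h)
    dof = max(n_obs - n_par, 1)
    s2 = float(r0 @ r0) / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        return float("nan")
    return float(np.sqrt(max(cov[names.index("kd"), names.index("kd")], 0.0)))


def classify_fragment(
    fit: GlobalFitResult,
    profile: CSPProfile,
    annotation: InterfaceAnnotation,
    kd_cutoff: float = DEFAULT_KD_CUTOFF,
    locality_fraction: float = DEFAULT_LOCALITY_FRACTION,
    k_sigma: float = 1.0,
) -> FragmentClass:
    """Classify a titrated fragment as hit, weak, or nonspecific.

    Specific binding shows saturable, structurally localized shifting:
    a fragment is a hit when the fitted apparent Kd is below ``kd_cutoff``
    (1 mM by default) AND at least ``locality_fraction`` of the top
    shifters (from the highest-concentration profile) fall in the
    membrane interface or functional region.  Localized but weaker
    binders are "weak"; delocalized shifting is "nonspecific".
    """
    if fit is None:
        raise ValueError("missing global fit")
    shifters = select_top_shifters(profile, k_sigma=k_sigma).residues
    if not shifters:
        return FragmentClass.NONSPECIFIC
    region = annotation.membrane_interface | annotation.observable_functional
    locality = sum(1 for r in shifters if r in region) / len(shifters)
    localized = locality >= locality_fraction
    if localized and fit.kd < kd_cutoff:
        return FragmentClass.HIT
    if localized:
        return FragmentClass.WEAK
    return FragmentClass.NONSPECIFIC
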