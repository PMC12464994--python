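"""Lorentzian least-squares deconvolution and species-integral assignment.

One component is fitted per overlap group of the assignment table (an
unresolved group is a single Lorentzian whose area is the group total),
plus a constant baseline.  Uncertainties come from the parameter covariance
at the optimum, or optionally from a seeded residual bootstrap.

The species logic downstream mirrors the published treatment of merged B
intensity: the homodimer A and B integrals are equal by symmetry, so the
heterodimer B integral can be recovered from the merged B total as
``I_B,het = I_B - I_A,homo``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .mixing import SpeciesDistribution
from .spectra import AssignmentTable, Spectrum, lorentzian_profile

__all__ = [
    "FitComponent",
    "FitResult",
    "SpeciesIntegrals",
    "fit_lorentzians",
    "assign_species_integrals",
    "plot_fit",
]

FWHM_BOUNDS = (0.02, 1.0)  # ppm
DEFAULT_FWHM_INIT = 0.15


@dataclass
class FitComponent:
    """One fitted Lorentzian with standard errors."""

    label: str
    species: tuple[str, ...]
    center: float
    fwhm: float
    area: float
    center_err: float = math.nan
    fwhm_err: float = math.nan
    area_err: float = math.nan
    at_bound: bool = False

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "species": list(self.species),
            "center": self.center,
            "fwhm": self.fwhm,
            "area": self.area,
            "center_err": self.center_err,
            "fwhm_err": self.fwhm_err,
            "area_err": self.area_err,
            "at_bound": self.at_bound,
        }


@dataclass
class FitResult:
    """Fitted components, baseline, goodness-of-fit and area covariance."""

    components: list[FitComponent]
    baseline: float
    baseline_err: float
    residual_rms: float
    reduced_chi_square: float
    converged: bool
    n_points: int
    area_covariance: np.ndarray  # over component areas, component order
    warnings: list[str] = field(default_factory=list)

    def component_for(self, species: str) -> FitComponent:
        """The single component to which ``species`` is assigned."""
        matches = [c for c in self.components if species in c.species]
        if len(matches) != 1:
            raise KeyError(
                f"species {species!r} maps to {len(matches)} components, expected 1"
            )
        return matches[0]

    def component_index(self, species: str) -> int:
        for i, c in enumerate(self.components):
            if species in c.species:
                return i
        raise KeyError(species)

    def components_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_dict() for c in self.components])

    def to_dict(self) -> dict:
        return {
            "components": [c.to_dict() for c in self.components],
            "baseline": self.baseline,
            "baseline_err": self.baseline_err,
            "residual_rms": self.residual_rms,
            "reduced_chi_square": self.reduced_chi_square,
            "converged": self.converged,
            "n_points": self.n_points,
            "area_covariance": np.asarray(self.area_covariance).tolist(),
            "warnings": list(self.warnings),
        }


def _model(params: np.ndarray, axis: np.ndarray, n_comp: int) -> np.ndarray:
    out = np.full_like(axis, params[0])
    for i in range(n_comp):
        c, w, a = params[1 + 3 * i : 4 + 3 * i]
        out = out + lorentzian_profile(c, w, a, axis)
    return out


def fit_lorentzians(
    spectrum: Spectrum,
    table: AssignmentTable,
    *,
    fwhm_init: float = DEFAULT_FWHM_INIT,
    fwhm_bounds: tuple[float, float] = FWHM_BOUNDS,
    uncertainty: str = "covariance",
    n_bootstrap: int = 500,
    seed: Optional[int] = None,
    contaminant_window: Optional[tuple[float, float]] = None,
    max_nfev: Optional[int] = None,
) -> FitResult:
    """Fit one Lorentzian per overlap group plus a constant baseline.

    Initialization is deterministic: centers at the table's expected values,
    areas from trapezoid integrals over the windows (baseline-subtracted),
    fwhm at ``fwhm_init``.  Centers are bounded to their windows, fwhm to
    ``fwhm_bounds`` and areas to be non-negative.

    ``uncertainty="bootstrap"`` replaces covariance-based standard errors by
    a seeded residual bootstrap (``n_bootstrap`` refits).
    ``contaminant_window`` adds one extra free component, excluded from all
    species assignments.

    Non-convergence never raises: the result is returned with
    ``converged=False`` and a warning.  Parameters pinned at a bound are
    also recorded as warnings.
    """
    axis, y = spectrum.axis, spectrum.intensity
    groups = table.sorted_groups()
    for group in groups:
        lo, hi = table.group_window(group)
        if lo < axis[0] or hi > axis[-1]:
            raise ValueError(
                f"spectrum [{axis[0]}, {axis[-1]}] does not cover window "
                f"[{lo}, {hi}] of group {sorted(group)}"
            )
    step = float(np.median(np.diff(axis)))
    if step > fwhm_init / 8.0:
        raise ValueError(
            f"grid too coarse: {step:.4g} ppm/point gives fewer than 8 points "
            f"per {fwhm_init} ppm linewidth"
        )

    baseline0 = float(np.median(y))
    labels: list[str] = []
    species_sets: list[tuple[str, ...]] = []
    x0 = [baseline0]
    lower = [-np.inf]
    upper = [np.inf]
    for group in groups:
        lo, hi = table.group_window(group)
        mask = (axis >= lo) & (axis <= hi)
        area0 = float(np.trapezoid(y[mask] - baseline0, axis[mask]))
        x0 += [table.group_center(group), fwhm_init, max(area0, 1e-12)]
        lower += [lo, fwhm_bounds[0], 0.0]
        upper += [hi, fwhm_bounds[1], np.inf]
        labels.append("+".join(sorted(group)))
        species_sets.append(tuple(sorted(group)))
    if contaminant_window is not None:
        lo, hi = contaminant_window
        mask = (axis >= lo) & (axis <= hi)
        area0 = float(np.trapezoid(y[mask] - baseline0, axis[mask]))
        x0 += [0.5 * (lo + hi), fwhm_init, max(area0, 1e-12)]
        lower += [lo, fwhm_bounds[0], 0.0]
        upper += [hi, fwhm_bounds[1], np.inf]
        labels.append("contaminant")
        species_sets.append(())
    n_comp = len(labels)
    x0 = np.clip(np.array(x0), lower, upper)

    result = least_squares(
        lambda p: _model(p, axis, n_comp) - y,
        x0,
        bounds=(np.array(lower), np.array(upper)),
        method="trf",
        max_nfev=max_nfev,
    )

    warnings_list: list[str] = []
    converged = bool(result.success)
    if not converged:
        warnings_list.append(f"fit did not converge: {result.message}")

    residual = result.fun
    n, p = axis.size, result.x.size
    dof = max(n - p, 1)
    s2 = float(residual @ residual) / dof
    rms = math.sqrt(float(residual @ residual) / n)

    # covariance of parameters at the optimum (Gauss-Newton approximation)
    jac = result.jac
    try:
        cov = s2 * np.linalg.pinv(jac.T @ jac)
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        cov = np.full((p, p), np.nan)
        warnings_list.append("parameter covariance could not be computed")
    perr = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    # noise estimate from residuals for the reduced chi-square
    noise = float(spectrum.metadata.get("noise_sigma") or 0.0)
    red_chi = float(residual @ residual) / (dof * noise**2) if noise > 0 else float("nan")

    at_bound_flags = []
    for i in range(1, p):
        span = (upper[i] - lower[i]) if np.isfinite(upper[i]) else max(abs(result.x[i]), 1.0)
        pinned = (
            (np.isfinite(lower[i]) and result.x[i] - lower[i] < 1e-8 * span)
            or (np.isfinite(upper[i]) and upper[i] - result.x[i] < 1e-8 * span)
        )
        at_bound_flags.append(pinned)
        if pinned:
            comp_idx, par_idx = divmod(i - 1, 3)
            par_name = ("center", "fwhm", "area")[par_idx]
            warnings_list.append(
                f"component {labels[comp_idx]!r}: {par_name} pinned at a bound"
            )

    area_idx = [1 + 3 * i + 2 for i in range(n_comp)]
    area_cov = cov[np.ix_(area_idx, area_idx)]
    perr_use = perr

    if uncertainty == "bootstrap":
        rng = np.random.default_rng(seed)
        fitted = _model(result.x, axis, n_comp)
        draws = np.empty((n_bootstrap, p))
        for b in range(n_bootstrap):
            y_b = fitted + rng.choice(residual, size=n, replace=True)
            res_b = least_squares(
                lambda q: _model(q, axis, n_comp) - y_b,
                result.x,
                bounds=(np.array(lower), np.array(upper)),
                method="trf",
            )
            draws[b] = res_b.x
        perr_use = draws.std(axis=0, ddof=1)
        area_cov = np.cov(draws[:, area_idx], rowvar=False)
        if n_comp == 1:
            area_cov = np.atleast_2d(area_cov)
    elif uncertainty != "covariance":
        raise ValueError("uncertainty must be 'covariance' or 'bootstrap'")

    components = []
    for i in range(n_comp):
        c, w, a = result.x[1 + 3 * i : 4 + 3 * i]
        ce, we, ae = perr_use[1 + 3 * i : 4 + 3 * i]
        pinned = any(at_bound_flags[3 * i : 3 * i + 3])
        components.append(
            FitComponent(
                label=labels[i],
                species=species_sets[i],
                center=float(c),
                fwhm=float(w),
                area=float(a),
                center_err=float(ce),
                fwhm_err=float(we),
                area_err=float(ae),
                at_bound=pinned,
            )
        )

    return FitResult(
        components=components,
        baseline=float(result.x[0]),
        baseline_err=float(perr_use[0]),
        residual_rms=rms,
        reduced_chi_square=red_chi,
        converged=converged,
        n_points=n,
        area_covariance=np.asarray(area_cov, dtype=float),
        warnings=warnings_list,
    )


@dataclass
class SpeciesIntegrals:
    """Named species integrals with uncertainties, ready for equilibrium math.

    ``I_B`` is the total monomer-B integral (homodimer + heterodimer).  In
    the unresolved case ``I_B_het`` is derived as ``I_B - I_A_homo`` using
    homodimer symmetry; in the resolved case it is read directly.
    ``covariance`` is the 3x3 covariance over ``(I_B, I_A_homo, I_A_het)``.
    """

    I_A_homo: float
    sigma_A_homo: float
    I_A_het: float
    sigma_A_het: float
    I_B: float
    sigma_B: float
    I_B_het: float
    sigma_B_het: float
    resolved_B: bool
    heterodimer_present: bool
    covariance: np.ndarray
    consistency: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "I_A_homo": self.I_A_homo,
            "sigma_A_homo": self.sigma_A_homo,
            "I_A_het": self.I_A_het,
            "sigma_A_het": self.sigma_A_het,
            "I_B": self.I_B,
            "sigma_B": self.sigma_B,
            "I_B_het": self.I_B_het,
            "sigma_B_het": self.sigma_B_het,
            "resolved_B": self.resolved_B,
            "heterodimer_present": self.heterodimer_present,
            "consistency": self.consistency,
            "covariance": np.asarray(self.covariance).tolist(),
        }


def assign_species_integrals(
    fit: FitResult,
    table: AssignmentTable,
    mixing: Optional[SpeciesDistribution] = None,
    *,
    het_threshold: float = 1e-3,
) -> SpeciesIntegrals:
    """Map fitted component areas to named species integrals.

    Resolved components give ``I_A,homo`` (from ``A_2F``) and ``I_A,het``
    (from ``A_1F``) directly.  If ``B_2F`` and ``B_1F`` share a component the
    group total is ``I_B`` and ``I_B,het = I_B - I_A,homo``; otherwise the
    resolved ``B_1F`` area is used as is.

    If ``mixing`` is provided, a consistency score is attached: the relative
    deviation of ``I_A,homo`` from the share predicted by the homodimer
    fraction.  ``I_B < I_A,homo`` in the unresolved case raises, signalling
    misassignment or a failed statistical-mixing assumption.  A sample whose
    heterodimer integral is below ``het_threshold`` of the total is flagged
    as homodimer-only (``heterodimer_present=False``).
    """
    if not fit.converged:
        raise ValueError("cannot assign integrals from a non-converged fit")

    comp_a_homo = fit.component_for("A_2F")
    comp_a_het = fit.component_for("A_1F")
    i_a_homo, s_a_homo = comp_a_homo.area, comp_a_homo.area_err
    i_a_het, s_a_het = comp_a_het.area, comp_a_het.area_err

    idx_a_homo = fit.component_index("A_2F")
    idx_a_het = fit.component_index("A_1F")
    cov = np.asarray(fit.area_covariance)

    b_group = table.group_for("B_1F")
    resolved = "B_2F" not in b_group
    if resolved:
        comp_b_het = fit.component_for("B_1F")
        comp_b_homo = fit.component_for("B_2F")
        i_b_het, s_b_het = comp_b_het.area, comp_b_het.area_err
        idx_b = fit.component_index("B_1F")
        idx_b_homo = fit.component_index("B_2F")
        i_b = comp_b_homo.area + i_b_het
        s_b = math.sqrt(
            comp_b_homo.area_err**2
            + s_b_het**2
            + 2.0 * cov[idx_b_homo, idx_b]
        )
    else:
        comp_b = fit.component_for("B_1F")  # same component as B_2F
        i_b, s_b = comp_b.area, comp_b.area_err
        idx_b = fit.component_index("B_1F")
        if i_b < i_a_homo:
            deficit = i_a_homo - i_b
            noise_scale = 3.0 * math.hypot(s_b, s_a_homo) + 1e-9 * (i_b + i_a_homo)
            if deficit > noise_scale:
                raise ValueError(
                    "inconsistent integrals: negative heterodimer B intensity "
                    f"(I_B={i_b:.4g} < I_A,homo={i_a_homo:.4g})"
                )
        # floor at zero: a statistically insignificant deficit is the
        # pure-homodimer limit, not an inconsistency
        i_b_het = max(i_b - i_a_homo, 0.0)
        s_b_het = math.sqrt(
            max(s_b**2 + s_a_homo**2 - 2.0 * cov[idx_b, idx_a_homo], 0.0)
        )

    total = i_a_homo + i_a_het + i_b
    het_present = total > 0 and (i_a_het + i_b_het) / total > het_threshold

    consistency = None
    if mixing is not None:
        predicted = total * mixing.f_homo / (2.0 * mixing.f_homo + mixing.f_het)
        if predicted > 0:
            consistency = abs(i_a_homo - predicted) / predicted

    if resolved:
        # covariance over (I_B, I_A_homo, I_A_het) with I_B = B_2F + B_1F
        sub = np.zeros((3, 3))
        idxs = (idx_b_homo, idx_b, idx_a_homo, idx_a_het)
        c = cov[np.ix_(idxs, idxs)]
        sub[0, 0] = c[0, 0] + c[1, 1] + 2 * c[0, 1]
        sub[0, 1] = sub[1, 0] = c[0, 2] + c[1, 2]
        sub[0, 2] = sub[2, 0] = c[0, 3] + c[1, 3]
        sub[1, 1] = c[2, 2]
        sub[1, 2] = sub[2, 1] = c[2, 3]
        sub[2, 2] = c[3, 3]
    else:
        idxs = (idx_b, idx_a_homo, idx_a_het)
        sub = cov[np.ix_(idxs, idxs)]

    return SpeciesIntegrals(
        I_A_homo=float(i_a_homo),
        sigma_A_homo=float(s_a_homo),
        I_A_het=float(i_a_het),
        sigma_A_het=float(s_a_het),
        I_B=float(i_b),
        sigma_B=float(s_b),
        I_B_het=float(i_b_het),
        sigma_B_het=float(s_b_het),
        resolved_B=resolved,
        heterodimer_present=bool(het_present),
        covariance=sub,
        consistency=consistency,
    )


def plot_fit(spectrum: Spectrum, fit: FitResult, path) -> None:
    """Diagnostic plot: data, fitted components, their sum and the residual."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    axis = spectrum.axis
    model = np.full_like(axis, fit.baseline)
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.plot(axis, spectrum.intensity, color="0.3", lw=0.8, label="data")
    for comp in fit.components:
        curve = fit.baseline + lorentzian_profile(comp.center, comp.fwhm, comp.area, axis)
        model += curve - fit.baseline
        ax.plot(axis, curve, lw=1.0, label=comp.label)
    ax.plot(axis, model, color="k", lw=1.2, ls="--", label="sum")
    offset = 1.1 * float(np.max(np.abs(spectrum.intensity - model))) or 1.0
    ax.plot(axis, spectrum.intensity - model - offset, color="tab:red", lw=0.6,
            label="residual (offset)")
    ax.invert_xaxis()  # NMR display convention: ppm decreasing to the right
    ax.set_xlabel("chemical shift (ppm)")
    ax.set_ylabel("intensity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
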