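"""Equilibrium constants, free energies, decomposition and error propagation.

Sign convention (package-wide, recorded on every :class:`FreeEnergy`):
positive values mean the distinguished monomer prefers position A.  The
equilibrium-constant helpers keep the conventional integral orientation
``K = I_B,het / I_A,het``; :func:`dg_from_k` maps a K of either orientation
onto the pinned convention via its ``orientation`` argument.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, GAS_CONSTANT_KCAL, SIGN_CONVENTION
from .deconvolution import SpeciesIntegrals

__all__ = [
    "FreeEnergy",
    "k_from_integrals",
    "k_corrected",
    "dg_from_k",
    "apparent_free_energy",
    "decompose_mutation_energy",
    "combine_replicates",
    "average_labeling_schemes",
    "fold_change",
    "propagate_integral_errors",
    "round_sig",
    "format_free_energy",
]

#: how a FreeEnergy's sigma was obtained
SIGMA_KINDS = ("none", "measurement", "replicate", "propagated")


@dataclass(frozen=True)
class FreeEnergy:
    """A signed free-energy difference in kcal/mol with uncertainty.

    ``sigma_kind`` distinguishes a single measurement's fit-derived sigma
    (``"measurement"``), replicate scatter (``"replicate"``) and first-order
    propagation through arithmetic (``"propagated"``); the kinds are never
    silently mixed.
    """

    value: float
    sigma: float = 0.0
    n_replicates: int = 1
    convention: str = SIGN_CONVENTION
    provenance: str = ""
    sigma_kind: str = "none"

    def __post_init__(self) -> None:
        if self.sigma < 0.0:
            raise ValueError("sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sigma_kind not in SIGMA_KINDS:
            raise ValueError(f"sigma_kind must be one of {SIGMA_KINDS}")
        if not self.convention:
            raise ValueError("convention tag must be present")

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "sigma": self.sigma,
            "n_replicates": self.n_replicates,
            "convention": self.convention,
            "provenance": self.provenance,
            "sigma_kind": self.sigma_kind,
        }


def k_from_integrals(I_A_het: float, I_B_het: float) -> float:
    """Equilibrium constant ``K = I_B,het / I_A,het`` from resolved integrals."""
    if I_A_het <= 0.0:
        raise ValueError(f"I_A,het must be > 0, got {I_A_het}")
    if I_B_het < 0.0:
        raise ValueError(f"I_B,het must be >= 0, got {I_B_het}")
    return I_B_het / I_A_het


def k_corrected(I_B_total: float, I_A_homo: float, I_A_het: float) -> float:
    """Overlap-corrected ``K = (I_B - I_A,homo) / I_A,het``.

    Valid because homodimer symmetry fixes ``I_B,homo = I_A,homo``, so
    subtracting the homodimer share from the merged B integral leaves the
    heterodimer B intensity.
    """
    if I_A_het <= 0.0:
        raise ValueError(f"I_A,het must be > 0, got {I_A_het}")
    if I_A_homo < 0.0:
        raise ValueError(f"I_A,homo must be >= 0, got {I_A_homo}")
    if I_B_total < I_A_homo:
        raise ValueError(
            "negative corrected intensity: "
            f"I_B={I_B_total} < I_A,homo={I_A_homo}"
        )
    return (I_B_total - I_A_homo) / I_A_het


def dg_from_k(
    K: float,
    temperature: float = DEFAULT_TEMPERATURE,
    *,
    orientation: str = "A_over_B",
    sigma_K: float = 0.0,
    n_replicates: int = 1,
    provenance: str = "RT ln K",
) -> FreeEnergy:
    """Convert an equilibrium constant to a free energy, ``|dG| = RT |ln K|``.

    ``orientation`` states which population ratio ``K`` represents so the
    result lands in the pinned sign convention: ``"A_over_B"`` gives
    ``+RT ln K`` and ``"B_over_A"`` (the orientation produced by
    :func:`k_from_integrals` / :func:`k_corrected`) gives ``-RT ln K``.
    ``K = 1`` maps to zero either way.
    """
    if K <= 0.0:
        raise ValueError(f"K must be > 0, got {K}")
    if temperature <= 0.0:
        raise ValueError("temperature must be > 0")
    if orientation not in ("A_over_B", "B_over_A"):
        raise ValueError("orientation must be 'A_over_B' or 'B_over_A'")
    rt = GAS_CONSTANT_KCAL * temperature
    sign = 1.0 if orientation == "A_over_B" else -1.0
    sigma = rt * sigma_K / K if sigma_K else 0.0
    return FreeEnergy(
        value=sign * rt * math.log(K),
        sigma=sigma,
        n_replicates=n_replicates,
        provenance=provenance,
        sigma_kind="measurement" if sigma_K else "none",
    )


def propagate_integral_errors(
    integrals: SpeciesIntegrals,
    temperature: float = DEFAULT_TEMPERATURE,
    method: str = "covariance",
    seed: Optional[int] = None,
    n_draws: int = 1000,
) -> float:
    """Uncertainty of the apparent free energy from integral uncertainties.

    ``method="covariance"`` applies first-order (delta-method) propagation
    of the ``(I_B, I_A,homo, I_A,het)`` covariance through the corrected
    equilibrium constant and the log map.  ``method="monte_carlo"`` draws
    from the integral covariance (seeded) and returns the empirical standard
    deviation of the free energy; it is also the fallback, with a warning,
    when the covariance is singular or non-finite.
    """
    if temperature <= 0.0:
        raise ValueError("temperature must be > 0")
    rt = GAS_CONSTANT_KCAL * temperature
    mean = np.array([integrals.I_B, integrals.I_A_homo, integrals.I_A_het])
    cov = np.asarray(integrals.covariance, dtype=float)
    b_het = integrals.I_B - integrals.I_A_homo
    if b_het <= 0.0 or integrals.I_A_het <= 0.0:
        raise ValueError("integrals do not define a positive equilibrium constant")

    if method == "covariance":
        bad = not np.all(np.isfinite(cov))
        if not bad:
            eigvals = np.linalg.eigvalsh(0.5 * (cov + cov.T))
            bad = eigvals.min() < -1e-12 * max(eigvals.max(), 1.0) or (
                eigvals.max() > 0 and eigvals.min() < 1e-14 * eigvals.max()
            )
        if bad:
            _warnings.warn(
                "singular or invalid integral covariance; falling back to "
                "Monte-Carlo propagation",
                RuntimeWarning,
            )
            method = "monte_carlo"
        else:
            grad = np.array([rt / b_het, -rt / b_het, -rt / integrals.I_A_het])
            return float(math.sqrt(max(grad @ cov @ grad, 0.0)))

    if method != "monte_carlo":
        raise ValueError("method must be 'covariance' or 'monte_carlo'")

    rng = np.random.default_rng(seed)
    cov = np.where(np.isfinite(cov), cov, 0.0)
    # eigenvalue clipping makes singular covariances usable
    w, v = np.linalg.eigh(0.5 * (cov + cov.T))
    sqrt_cov = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    draws = mean + rng.standard_normal((n_draws, 3)) @ sqrt_cov.T
    valid = (draws[:, 0] - draws[:, 1] > 0) & (draws[:, 2] > 0)
    if valid.sum() < n_draws // 2:
        _warnings.warn(
            "more than half of the Monte-Carlo draws were unphysical; "
            "the reported sigma may be unreliable",
            RuntimeWarning,
        )
    if valid.sum() < 2:
        return float("nan")
    d = draws[valid]
    dgs = -rt * np.log((d[:, 0] - d[:, 1]) / d[:, 2])
    return float(dgs.std(ddof=1))


def apparent_free_energy(
    integrals: SpeciesIntegrals,
    temperature: float = DEFAULT_TEMPERATURE,
    method: str = "covariance",
    seed: Optional[int] = None,
) -> FreeEnergy:
    """Apparent free energy of one sample from its assigned integrals.

    Uses the overlap-corrected equilibrium constant (which reduces to the
    direct ratio when B is resolved) and maps it onto the pinned sign
    convention; sigma comes from :func:`propagate_integral_errors`.
    """
    K = k_corrected(integrals.I_B, integrals.I_A_homo, integrals.I_A_het)
    sigma = propagate_integral_errors(integrals, temperature, method=method, seed=seed)
    fe = dg_from_k(
        K,
        temperature,
        orientation="B_over_A",
        provenance="k_corrected -> RT ln K",
    )
    return replace(fe, sigma=sigma, sigma_kind="measurement")


def decompose_mutation_energy(
    dg_app: FreeEnergy, dg_fw: FreeEnergy, label_on_mutant: bool
) -> FreeEnergy:
    """Remove the fluorine-label bias from an apparent free energy.

    Additivity gives ``dG_app = dG_mut + dG_FW`` when label and mutation sit
    on the same monomer and ``dG_app = dG_mut - dG_FW`` when they sit on
    opposite monomers; uncertainties combine in quadrature.
    """
    if dg_app.convention != dg_fw.convention:
        raise ValueError("inputs use different sign conventions")
    value = dg_app.value - dg_fw.value if label_on_mutant else dg_app.value + dg_fw.value
    return FreeEnergy(
        value=value,
        sigma=math.sqrt(dg_app.sigma**2 + dg_fw.sigma**2),
        n_replicates=dg_app.n_replicates,
        convention=dg_app.convention,
        provenance="label-bias decomposition",
        sigma_kind="propagated",
    )


def combine_replicates(values: Sequence[FreeEnergy], mode: str = "auto") -> FreeEnergy:
    """Unweighted mean of replicate free energies.

    Sigma policy (``mode="auto"``): when every input is a raw measurement
    the spread of the replicates (sample standard deviation) is reported
    with the replicate count; when any input already carries a propagated
    sigma, quadrature propagation of the input sigmas is used instead
    (``sqrt(sum sigma^2) / n``).  Force either behaviour with
    ``mode="replicate"`` or ``mode="propagated"``.
    """
    if not values:
        raise ValueError("cannot combine an empty list of free energies")
    conventions = {v.convention for v in values}
    if len(conventions) != 1:
        raise ValueError("cannot combine values with mixed sign conventions")
    vals = np.array([v.value for v in values])
    n = len(values)
    if mode == "auto":
        raw = all(v.sigma_kind in ("measurement", "none") for v in values)
        mode = "replicate" if raw else "propagated"
    if mode == "replicate":
        sigma = float(vals.std(ddof=1)) if n > 1 else values[0].sigma
        kind = "replicate" if n > 1 else values[0].sigma_kind
    elif mode == "propagated":
        sigma = math.sqrt(sum(v.sigma**2 for v in values)) / n
        kind = "propagated"
    else:
        raise ValueError("mode must be 'auto', 'replicate' or 'propagated'")
    return FreeEnergy(
        value=float(vals.mean()),
        sigma=sigma,
        n_replicates=n,
        convention=values[0].convention,
        provenance="replicate mean",
        sigma_kind=kind,
    )


def average_labeling_schemes(
    dg_app_same: FreeEnergy, dg_app_opposite: FreeEnergy
) -> FreeEnergy:
    """Average the two labeling schemes of the same mutation.

    With the label on the mutant monomer the apparent value is
    ``dG_mut + dG_FW``; with the label on the partner it is
    ``dG_mut - dG_FW``.  Their mean is therefore ``dG_mut`` with the label
    bias (and its uncertainty, which is shared between the schemes)
    cancelling exactly; only the apparent-value uncertainties propagate.
    """
    if dg_app_same.convention != dg_app_opposite.convention:
        raise ValueError("inputs use different sign conventions")
    return FreeEnergy(
        value=0.5 * (dg_app_same.value + dg_app_opposite.value),
        sigma=0.5 * math.sqrt(dg_app_same.sigma**2 + dg_app_opposite.sigma**2),
        n_replicates=2,
        convention=dg_app_same.convention,
        provenance="two-scheme average (label bias cancels)",
        sigma_kind="propagated",
    )


def fold_change(dg: FreeEnergy, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Equilibrium fold change ``exp(|dG| / (R T))`` implied by a free energy."""
    if temperature <= 0.0:
        raise ValueError("temperature must be > 0")
    return math.exp(abs(dg.value) / (GAS_CONSTANT_KCAL * temperature))


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    ndigits = sig - 1 - int(math.floor(math.log10(abs(x))))
    return round(x, ndigits)


def format_free_energy(fe: FreeEnergy) -> str:
    """Report-style string: value to 2 significant figures, sigma to 1 decimal."""
    value = round_sig(fe.value, 2)
    if fe.sigma > 0:
        sigma = round(fe.sigma, 1) if fe.sigma >= 0.05 else round_sig(fe.sigma, 1)
        s = f"{value:g} ± {sigma:g}"
    else:
        s = f"{value:g}"
    if fe.sigma_kind == "replicate":
        s += f" (n = {fe.n_replicates})"
    return s
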