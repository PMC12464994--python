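"""Forward spectral model, synthetic-sample generator and spectrum I/O.

Spectra are 1D arrays of intensity on a chemical-shift grid (ppm).  The
forward model is a sum of area-parameterized Lorentzians, one per visible
species, whose areas follow the mixing/conformer model: each 2F dimer
contributes one fluorine to the A signal and one to the B signal, each 1F
dimer contributes a single fluorine whose position follows the conformer
populations.  Areas are normalized per fluorine so a noiseless spectrum
integrates to 1.

Species nomenclature: ``A_2F``/``B_2F`` are the two signals of the doubly
labeled homodimer, ``A_1F``/``B_1F`` the signals of the single labeled
monomer of a heterodimer sitting in position A or B.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .mixing import (
    BiasParameters,
    MixingSpec,
    SpeciesDistribution,
    conformer_populations,
    dimer_species_fractions,
    heterodimer_bias,
)

__all__ = [
    "SPECIES_IDS",
    "Peak",
    "Window",
    "AssignmentTable",
    "Spectrum",
    "PRESET_TABLES",
    "get_preset_table",
    "lorentzian_profile",
    "expected_peak_areas",
    "simulate_sample_spectrum",
    "read_spectrum",
    "write_spectrum",
    "read_jcampdx",
]

SPECIES_IDS = ("A_2F", "B_2F", "A_1F", "B_1F")

DEFAULT_FWHM = 0.15  # ppm; experimental linewidths are not published
_GRID_MARGIN = 15.0  # ppm of margin on each side of the default grid
_GRID_POINTS = 16384


@dataclass(frozen=True)
class Peak:
    """One Lorentzian component: species, center (ppm), fwhm (ppm), area."""

    species_id: str
    center: float
    fwhm: float
    area: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0.0:
            raise ValueError(f"fwhm must be > 0, got {self.fwhm}")
        if self.area < 0.0:
            raise ValueError(f"area must be >= 0, got {self.area}")
        if not math.isfinite(self.center):
            raise ValueError("center must be finite")


@dataclass(frozen=True)
class Window:
    """Expected peak center and half-width of its search window (ppm)."""

    center: float
    half_width: float

    def __post_init__(self) -> None:
        if self.half_width <= 0.0:
            raise ValueError("window half_width must be > 0")

    @property
    def lo(self) -> float:
        return self.center - self.half_width

    @property
    def hi(self) -> float:
        return self.center + self.half_width


@dataclass(frozen=True)
class AssignmentTable:
    """Chemical-shift windows per species plus overlap structure.

    ``overlap_groups`` partitions the species: members of a multi-species
    group are not resolved in the spectrum and are fitted (and generated)
    as a single merged component at the group's mean center.
    """

    windows: Mapping[str, Window]
    overlap_groups: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        seen: set = set()
        for group in self.overlap_groups:
            if not group:
                raise ValueError("empty overlap group")
            for sp in group:
                if sp not in self.windows:
                    raise ValueError(f"overlap group references unknown species {sp!r}")
                if sp in seen:
                    raise ValueError(f"species {sp!r} appears in more than one group")
                seen.add(sp)
        missing = set(self.windows) - seen
        if missing:
            raise ValueError(f"species without an overlap group: {sorted(missing)}")

    @classmethod
    def build(
        cls,
        windows: Mapping[str, tuple[float, float]],
        overlap: Iterable[Iterable[str]] = (),
    ) -> "AssignmentTable":
        """Build a table from ``{species: (center, half_width)}``.

        Species not mentioned in ``overlap`` become singleton groups.
        """
        win = {sp: Window(c, hw) for sp, (c, hw) in windows.items()}
        groups = [frozenset(g) for g in overlap]
        grouped = set().union(*groups) if groups else set()
        for sp in win:
            if sp not in grouped:
                groups.append(frozenset([sp]))
        return cls(windows=dict(win), overlap_groups=tuple(groups))

    def group_for(self, species: str) -> frozenset:
        for group in self.overlap_groups:
            if species in group:
                return group
        raise KeyError(species)

    def group_center(self, group: frozenset) -> float:
        return float(np.mean([self.windows[sp].center for sp in sorted(group)]))

    def group_window(self, group: frozenset) -> tuple[float, float]:
        los = [self.windows[sp].lo for sp in group]
        his = [self.windows[sp].hi for sp in group]
        return min(los), max(his)

    def sorted_groups(self) -> list[frozenset]:
        """Groups in a stable order (ascending group center)."""
        return sorted(self.overlap_groups, key=self.group_center)

    def to_dict(self) -> dict:
        return {
            "windows": {
                sp: {"center": w.center, "half_width": w.half_width}
                for sp, w in self.windows.items()
            },
            "overlap_groups": [sorted(g) for g in self.overlap_groups],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "AssignmentTable":
        windows = {
            sp: (float(w["center"]), float(w["half_width"]))
            for sp, w in data["windows"].items()
        }
        return cls.build(windows, data.get("overlap_groups", ()))


#: Named assignment tables.  5FW centers for the single-Trp reporter are the
#: published ones; the B signals of homo- and heterodimer are unresolved and
#: therefore share one overlap group.  In the E14Q context the heterodimer B
#: signal moves to -122 ppm and is resolved.  6FW shifts are not published;
#: those defaults are invented stand-ins for synthetic work only.
PRESET_TABLES: dict[str, AssignmentTable] = {
    "5FW-W63": AssignmentTable.build(
        {
            "A_2F": (-124.8, 0.25),
            "B_2F": (-123.2, 0.25),
            "A_1F": (-125.4, 0.25),
            "B_1F": (-123.3, 0.25),
        },
        overlap=[("B_2F", "B_1F")],
    ),
    "5FW-W63-L51I": AssignmentTable.build(
        {
            "A_2F": (-124.8, 0.14),
            "B_2F": (-123.2, 0.25),
            "A_1F": (-125.1, 0.14),
            "B_1F": (-123.3, 0.25),
        },
        overlap=[("B_2F", "B_1F")],
    ),
    "5FW-W63-E14Q": AssignmentTable.build(
        {
            "A_2F": (-124.8, 0.25),
            "B_2F": (-123.2, 0.25),
            "A_1F": (-125.4, 0.25),
            "B_1F": (-122.0, 0.25),
        },
    ),
    "6FW-W63": AssignmentTable.build(
        {
            "A_2F": (-122.5, 0.2),
            "B_2F": (-124.0, 0.2),
            "A_1F": (-124.6, 0.2),
            "B_1F": (-122.6, 0.2),
        },
        overlap=[("A_2F", "B_1F")],
    ),
}


def get_preset_table(name: str) -> AssignmentTable:
    try:
        return PRESET_TABLES[name]
    except KeyError:
        raise KeyError(
            f"unknown assignment preset {name!r}; available: {sorted(PRESET_TABLES)}"
        ) from None


@dataclass
class Spectrum:
    """A 1D spectrum on a strictly monotone ppm grid.

    The axis is stored ascending internally; a descending input (the usual
    NMR display convention) is flipped on construction and recorded in
    ``metadata["original_axis_order"]``.
    """

    axis: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("axis and intensity must be 1-D")
        if self.axis.size != self.intensity.size:
            raise ValueError(
                f"axis ({self.axis.size}) and intensity ({self.intensity.size}) "
                "lengths differ"
            )
        if self.axis.size < 64:
            raise ValueError(f"spectrum too short: {self.axis.size} points (< 64)")
        if not np.all(np.isfinite(self.axis)):
            raise ValueError("axis contains non-finite values")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")
        diffs = np.diff(self.axis)
        if np.all(diffs < 0):
            self.axis = self.axis[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
            self.metadata.setdefault("original_axis_order", "descending")
        elif not np.all(diffs > 0):
            raise ValueError("axis must be strictly monotone")

    @property
    def n_points(self) -> int:
        return int(self.axis.size)

    def integral(self) -> float:
        """Trapezoid integral of the full spectrum."""
        return float(np.trapezoid(self.intensity, self.axis))

    def window_integral(self, lo: float, hi: float) -> float:
        """Trapezoid integral restricted to ``[lo, hi]`` ppm."""
        mask = (self.axis >= lo) & (self.axis <= hi)
        return float(np.trapezoid(self.intensity[mask], self.axis[mask]))


def lorentzian_profile(
    center: float, fwhm: float, area: float, axis: np.ndarray
) -> np.ndarray:
    """Area-normalized Lorentzian evaluated on a ppm grid.

    ``L(x) = (area / pi) * (fwhm/2) / ((x - center)^2 + (fwhm/2)^2)``, so the
    integral over the real line equals ``area`` and the peak height is
    ``2 * area / (pi * fwhm)``.
    """
    if fwhm <= 0.0:
        raise ValueError(f"fwhm must be > 0, got {fwhm}")
    x = np.asarray(axis, dtype=float)
    hw = 0.5 * fwhm
    return (area / np.pi) * hw / ((x - center) ** 2 + hw * hw)


def expected_peak_areas(dist: SpeciesDistribution) -> dict[str, float]:
    """Per-species signal areas, normalized to unit total fluorine.

    Each 2F dimer carries two fluorines (one at ``A_2F``, one at ``B_2F``);
    each 1F dimer carries one, at ``A_1F`` with probability ``p_A`` else
    ``B_1F``.  Equal per-nucleus response is assumed, so with the
    normalization ``w = 2 f_homo + f_het``::

        A_2F = B_2F = f_homo / w
        A_1F = f_het * p_A / w,   B_1F = f_het * p_B / w
    """
    if dist.f_het > 0.0 and not dist.has_populations:
        raise ValueError(
            "incomplete distribution: heterodimer populations p_A/p_B are unset"
        )
    p_a = dist.p_A if dist.has_populations else 0.0
    p_b = dist.p_B if dist.has_populations else 0.0
    norm = 2.0 * dist.f_homo + dist.f_het
    return {
        "A_2F": dist.f_homo / norm,
        "B_2F": dist.f_homo / norm,
        "A_1F": dist.f_het * p_a / norm,
        "B_1F": dist.f_het * p_b / norm,
    }


def default_axis(table: AssignmentTable, n_points: int = _GRID_POINTS) -> np.ndarray:
    """Default simulation grid: wide margins keep Lorentzian tail loss small."""
    centers = [w.center for w in table.windows.values()]
    return np.linspace(min(centers) - _GRID_MARGIN, max(centers) + _GRID_MARGIN, n_points)


def simulate_sample_spectrum(
    spec: MixingSpec,
    bias: BiasParameters,
    table: AssignmentTable,
    *,
    seed: int,
    axis: Optional[np.ndarray] = None,
    fwhm: float = DEFAULT_FWHM,
    noise_sigma: float = 0.0,
    snr: Optional[float] = None,
    merge_unresolved: bool = True,
    contaminant: Optional[tuple[float, float, float]] = None,
    sample_id: str = "synthetic",
) -> Spectrum:
    """Generate a synthetic 1D spectrum for a mixed sample.

    The species model is composed end to end: mixing statistics ->
    conformer populations from the total heterodimer bias -> per-species
    areas -> sum of Lorentzians plus i.i.d. Gaussian noise.  Unresolved
    overlap groups of ``table`` are emitted as a single merged Lorentzian at
    the group center (set ``merge_unresolved=False`` to place every species
    at its own center instead).

    ``snr``, if given, overrides ``noise_sigma`` and is defined as the
    maximum noiseless peak height divided by the noise standard deviation.
    ``contaminant`` optionally injects a nuisance peak ``(center, fwhm,
    area)`` outside the species model.  Identical inputs and seed produce an
    identical spectrum.
    """
    if fwhm <= 0.0:
        raise ValueError("fwhm must be > 0")
    dist = dimer_species_fractions(spec)
    dg_total = heterodimer_bias(bias)
    p_a, p_b = conformer_populations(dg_total, spec.temperature)
    dist = dist.with_populations(p_a, p_b)
    areas = expected_peak_areas(dist)

    if axis is None:
        axis = default_axis(table)
    axis = np.asarray(axis, dtype=float)

    components: list[Peak] = []
    if merge_unresolved:
        for group in table.sorted_groups():
            total = sum(areas[sp] for sp in group)
            components.append(
                Peak("+".join(sorted(group)), table.group_center(group), fwhm, total)
            )
    else:
        for sp, window in table.windows.items():
            components.append(Peak(sp, window.center, fwhm, areas[sp]))
    if contaminant is not None:
        c_center, c_fwhm, c_area = contaminant
        components.append(Peak("contaminant", c_center, c_fwhm, c_area))

    lo, hi = float(axis.min()), float(axis.max())
    for comp in components:
        if comp.center - 5.0 * comp.fwhm < lo or comp.center + 5.0 * comp.fwhm > hi:
            raise ValueError(
                f"truncated peak: grid [{lo}, {hi}] ppm does not cover "
                f"{comp.species_id} at {comp.center} ppm +/- 5 fwhm"
            )

    clean = np.zeros_like(axis)
    for comp in components:
        clean += lorentzian_profile(comp.center, comp.fwhm, comp.area, axis)

    if snr is not None:
        if snr <= 0.0:
            raise ValueError("snr must be > 0")
        noise_sigma = float(clean.max()) / snr
    rng = np.random.default_rng(seed)
    intensity = clean + rng.normal(0.0, noise_sigma, axis.size) if noise_sigma > 0 else clean.copy()

    metadata = {
        "sample_id": sample_id,
        "seed": int(seed),
        "noise_sigma": float(noise_sigma),
        "snr": None if snr is None else float(snr),
        "fwhm": float(fwhm),
        "labeled_ratio": spec.labeled_ratio,
        "incorporation_efficiency": spec.incorporation_efficiency,
        "labeled_variant": spec.labeled_variant,
        "unlabeled_variant": spec.unlabeled_variant,
        "label_kind": spec.label_kind,
        "temperature": spec.temperature,
        "dg_fw": bias.dg_fw,
        "dg_mut": bias.dg_mut,
        "label_on_mutant": bias.label_on_mutant,
        "dg_total": dg_total,
        "statistical_mixing": dist.statistical_mixing,
        "true_areas": areas,
        "merge_unresolved": bool(merge_unresolved),
        "components": [
            {"id": c.species_id, "center": c.center, "fwhm": c.fwhm, "area": c.area}
            for c in components
        ],
        "assignment": table.to_dict(),
    }
    return Spectrum(axis=axis, intensity=intensity, metadata=metadata)


# ---------------------------------------------------------------------------
# I/O: two-column TSV with '#' header lines carrying JSON metadata
# ---------------------------------------------------------------------------

_FORMAT_TAG = "fluorodimer spectrum v1"


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as tab-separated (ppm, intensity) text.

    Header lines start with ``#``; the metadata dictionary is serialized as
    JSON on the second header line.  Values are written with 17 significant
    digits so a write/read round trip is lossless.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_FORMAT_TAG}\n")
        fh.write("# " + json.dumps(spectrum.metadata, sort_keys=True) + "\n")
        for x, y in zip(spectrum.axis, spectrum.intensity):
            fh.write(f"{x:.17g}\t{y:.17g}\n")


def read_spectrum(path) -> Spectrum:
    """Read a two-column (ppm, intensity) text spectrum.

    Accepts ascending or descending ppm axes (descending input is flipped
    and flagged).  Malformed lines raise ``ValueError`` naming the line
    number.
    """
    axis: list[float] = []
    intensity: list[float] = []
    metadata: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("{"):
                    try:
                        metadata = json.loads(body)
                    except json.JSONDecodeError as exc:
                        raise ValueError(
                            f"{path}: line {lineno}: invalid metadata JSON ({exc})"
                        ) from exc
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            try:
                x, y = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric value ({exc})"
                ) from exc
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"{path}: line {lineno}: non-finite value")
            axis.append(x)
            intensity.append(y)
    if not axis:
        raise ValueError(f"{path}: no data rows found")
    try:
        return Spectrum(np.array(axis), np.array(intensity), metadata)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_jcampdx(path) -> Spectrum:
    """Minimal read-only JCAMP-DX import (fixed-format AFFN ``XYDATA``).

    Supports the common ``##XYDATA=(X++(Y..Y))`` layout with ``FIRSTX`` /
    ``LASTX`` / ``NPOINTS`` and optional ``XFACTOR`` / ``YFACTOR``.
    """
    labels: dict[str, str] = {}
    y_values: list[float] = []
    in_xydata = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                if in_xydata:
                    in_xydata = False
                key, _, value = line[2:].partition("=")
                key = key.strip().upper()
                labels[key] = value.strip()
                if key == "XYDATA":
                    in_xydata = True
                continue
            if in_xydata:
                tokens = line.replace(",", " ").split()
                try:
                    values = [float(t) for t in tokens]
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: bad XYDATA token ({exc})"
                    ) from exc
                if not values:
                    continue
                y_values.extend(values[1:])  # first token is the line's X
    try:
        firstx = float(labels["FIRSTX"])
        lastx = float(labels["LASTX"])
        npoints = int(float(labels["NPOINTS"]))
    except KeyError as exc:
        raise ValueError(f"{path}: missing required JCAMP-DX label {exc}") from exc
    if len(y_values) != npoints:
        raise ValueError(
            f"{path}: NPOINTS={npoints} but {len(y_values)} Y values parsed"
        )
    yfactor = float(labels.get("YFACTOR", 1.0))
    axis = np.linspace(firstx, lastx, npoints)
    intensity = np.array(y_values) * yfactor
    metadata = {"source": "jcamp-dx", "title": labels.get("TITLE", "")}
    return Spectrum(axis, intensity, metadata)
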