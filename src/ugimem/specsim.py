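"""Synthetic MALDI FT-ICR plate spectra with known ground truth.

For every spot of a presence matrix the generator lays down, on a uniform
m/z grid, Gaussian peaks for each present (and non-failed) compound's
[M+H]+, [M+Na]+ and [M+K]+ adducts with 13C isotope satellites, a shared
set of matrix-background peaks, a truncated-Gaussian baseline, and the
spiked reference calibrant. Peak widths follow FWHM = m/R at the
configured resolving power. Per-compound abundances are lognormal and
divided by (mixture size)**competition_exponent to emulate competitive
ionization; each spot's m/z axis carries a random multiplicative ppm
offset that the calibration stage must undo. A per-compound Bernoulli
reaction-failure mask (default rate 0.10, matching a library validation
yield of roughly 90%) silences failed compounds across the whole plate.

Everything is driven by one seed: identical (matrix, params, seed) give
byte-identical spectra.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .chemistry import CompoundLibrary, adduct_mz, isotope_envelope
from .codec import PresenceMatrix
from .specio import MassSpectrum, default_grid


@dataclass
class SimParams:
    """Knobs of the plate simulator; defaults emulate the study conditions."""

    mz_min: float = 300.0
    mz_max: float = 1000.0
    grid_step: float = 0.001  # Da
    resolving_power: float = 1.3e5  # m / FWHM at the observed mass
    adduct_ratios: dict = field(
        default_factory=lambda: {"Na": 1.0, "H": 0.3, "K": 0.2}
    )
    abundance_median: float = 300.0  # lognormal median peak amplitude (a.u.)
    abundance_sigma: float = 0.8  # lognormal shape (log-scale sd)
    p_fail: float = 0.10  # per-compound reaction failure probability
    n_background_peaks: int = 200
    background_intensity_median: float = 15.0
    background_intensity_sigma: float = 1.0
    baseline_mean: float = 10.0
    baseline_sigma: float = 2.0
    mass_offset_ppm_sigma: float = 3.0  # per-spot multiplicative offset
    competition_exponent: float = 0.5
    complex_probability: float = 0.15  # chance a compound has a reagent complex
    complex_intensity_fraction: float = 0.3
    reference_mass: float = 450.2000  # neutral mass of the spiked calibrant
    reference_intensity: float = 800.0
    n_isotope_peaks: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in ("p_fail", "complex_probability"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.resolving_power <= 0:
            raise ValueError("resolving_power must be positive")

    @classmethod
    def noiseless(cls, **overrides) -> "SimParams":
        """Deterministic limit: no noise, no failures, no offsets."""
        base = dict(
            abundance_sigma=0.0,
            p_fail=0.0,
            n_background_peaks=0,
            baseline_mean=0.0,
            baseline_sigma=0.0,
            mass_offset_ppm_sigma=0.0,
            complex_probability=0.0,
        )
        base.update(overrides)
        return cls(**base)

    def grid(self) -> np.ndarray:
        return default_grid(self.mz_min, self.mz_max, self.grid_step)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimParams":
        return cls(**json.loads(text))


def inject_failures(
    n_compounds: int, p_fail: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Plate-wide per-compound Bernoulli failure mask (True = failed).

    Failure is a property of the library well: a failed synthesis emits
    no product peaks in any spot it is dispensed to.
    """
    if not 0 <= p_fail <= 1:
        raise ValueError("p_fail must be in [0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return rng.random(n_compounds) < p_fail


def _add_gaussian(
    intensity: np.ndarray, grid: np.ndarray, center: float,
    amplitude: float, fwhm: float,
) -> None:
    """Accumulate a Gaussian peak over a +/-5 sigma window, in place."""
    sigma = fwhm / 2.3548200450309493
    lo, hi = np.searchsorted(grid, [center - 5 * sigma, center + 5 * sigma])
    if hi <= lo:
        return
    window = grid[lo:hi]
    intensity[lo:hi] += amplitude * np.exp(-0.5 * ((window - center) / sigma) ** 2)


def spike_reference(
    spectrum: MassSpectrum,
    ref_mass: float,
    intensity: float,
    resolving_power: float = 1.3e5,
    offset_ppm: float = 0.0,
    adduct: str = "Na",
) -> MassSpectrum:
    """Add the calibrant's adduct peak at the spot's offset m/z."""
    mz0 = adduct_mz(ref_mass, adduct) * (1 + offset_ppm * 1e-6)
    if not spectrum.mz[0] <= mz0 <= spectrum.mz[-1]:
        raise ValueError(f"reference m/z {mz0:.4f} outside the spectrum range")
    out = spectrum.intensity.copy()
    _add_gaussian(out, spectrum.mz, mz0, intensity, mz0 / resolving_power)
    return MassSpectrum(spectrum.mz, out, spot_id=spectrum.spot_id,
                        metadata=dict(spectrum.metadata))


def simulate_plate(
    matrix: PresenceMatrix,
    library: CompoundLibrary,
    params: SimParams | None = None,
    compound_indices: list[int] | None = None,
) -> tuple[list[MassSpectrum], PresenceMatrix]:
    """Generate one spectrum per presence-matrix row.

    ``compound_indices`` (1-based library indices) map matrix columns to
    library products; defaults to ``matrix.compound_indices`` or the
    first M products. Returns (spectra, ground-truth labels) where the
    labels are the input matrix.
    """
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)
    grid = params.grid()
    if compound_indices is None:
        compound_indices = matrix.compound_indices or list(
            range(1, matrix.n_compounds + 1)
        )
    if len(compound_indices) != matrix.n_compounds:
        raise ValueError("compound_indices length must match matrix columns")
    products = [library[i - 1] for i in compound_indices]

    # Precompute per-compound peak templates: (m/z, relative height) pairs.
    templates = []
    for prod in products:
        peaks = []
        envelope = isotope_envelope(prod.formula, params.n_isotope_peaks)
        for adduct, ratio in params.adduct_ratios.items():
            if ratio <= 0:
                continue
            base_mz = adduct_mz(prod.M, adduct)
            for offset, abundance in envelope:
                mz = base_mz + offset
                if params.mz_min <= mz <= params.mz_max:
                    peaks.append((mz, ratio * abundance))
                elif offset == 0.0:
                    warnings.warn(
                        f"[M+{adduct}]+ of product at M={prod.M:.4f} outside "
                        f"m/z range; peak dropped", stacklevel=2,
                    )
        templates.append(peaks)

    failed = inject_failures(len(products), params.p_fail, rng)

    # Reagent complexes: some compounds gain a correlated satellite peak at
    # M + (their amine's mass), sodiated — a stand-in for product/reagent
    # adduct clusters seen in raw reaction mixtures.
    has_complex = rng.random(len(products)) < params.complex_probability
    complex_mz = np.empty(len(products))
    for m, prod in enumerate(products):
        amine = library.reagents["amine"][prod.reagent_ids[0]] if library.reagents else None
        partner = amine.mass if amine is not None else 100.0
        complex_mz[m] = adduct_mz(prod.M + partner, "Na")

    # Shared matrix-background peak set (same positions on every spot).
    bg_mz = rng.uniform(params.mz_min, params.mz_max, params.n_background_peaks)
    bg_height = params.background_intensity_median * np.exp(
        params.background_intensity_sigma
        * rng.standard_normal(params.n_background_peaks)
    )

    ref_mz = adduct_mz(params.reference_mass, "Na")
    spectra = []
    for n in range(matrix.n_spots):
        offset_ppm = params.mass_offset_ppm_sigma * rng.standard_normal()
        scale = 1 + offset_ppm * 1e-6
        present = np.flatnonzero(matrix.data[n])
        n_present = max(len(present), 1)
        suppression = n_present ** params.competition_exponent
        intensity = np.zeros(grid.size)
        for m in present:
            if failed[m]:
                continue
            amplitude = params.abundance_median * np.exp(
                params.abundance_sigma * rng.standard_normal()
            ) / suppression
            for mz, height in templates[m]:
                _add_gaussian(intensity, grid, mz * scale, amplitude * height,
                              mz / params.resolving_power)
            if has_complex[m] and params.mz_min <= complex_mz[m] <= params.mz_max:
                _add_gaussian(
                    intensity, grid, complex_mz[m] * scale,
                    amplitude * params.complex_intensity_fraction,
                    complex_mz[m] / params.resolving_power,
                )
        # matrix background with mild per-spot intensity jitter
        if params.n_background_peaks:
            jitter = np.exp(0.2 * rng.standard_normal(params.n_background_peaks))
            for mz, height, j in zip(bg_mz, bg_height, jitter):
                _add_gaussian(intensity, grid, mz * scale, height * j,
                              mz / params.resolving_power)
        if params.baseline_sigma > 0:
            noise = params.baseline_mean + params.baseline_sigma * \
                rng.standard_normal(grid.size)
            intensity += np.clip(noise, 0.0, None)
        elif params.baseline_mean:
            intensity += params.baseline_mean
        # spiked reference calibrant in every spot
        _add_gaussian(intensity, grid, ref_mz * scale,
                      params.reference_intensity, ref_mz / params.resolving_power)
        spectra.append(MassSpectrum(
            grid.copy(), intensity, spot_id=f"spot{n}",
            metadata={"true_offset_ppm": offset_ppm},
        ))
    labels = PresenceMatrix(
        data=matrix.data.copy(), mapping=matrix.mapping,
        n_pad_bits=matrix.n_pad_bits,
        compound_indices=list(compound_indices),
        payload_shape=matrix.payload_shape,
    )
    return spectra, labels
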