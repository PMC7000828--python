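"""Spectrum containers, I/O, calibration, resampling, and SNR transforms.

Spectra are (m/z, intensity) arrays, one per plate spot. Before any
detection the readout pipeline (i) calibrates each spectrum against the
spiked reference compound with a single multiplicative (ppm) correction,
(ii) resamples all spectra onto one common m/z grid to form an
analysis-ready matrix, and (iii) converts intensities to signal-to-noise
ratios SNR = (I - mu) / sigma, where mu and sigma are the mean and
standard deviation of the spectrum's background. The background is
estimated by iterative one-sided 3-sigma clipping, which removes peaks
from the estimate while keeping the baseline.

Supported formats: mzML (read via pyteomics; written by a minimal
built-in writer), two-column CSV, and an HDF5 container for the resampled
matrix with datasets ``mz_grid``, ``intensities``, ``spot_ids``, and
``offsets_ppm``.
"""

from __future__ import annotations

import base64
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np


class CalibrationError(RuntimeError):
    """Reference peak not found above background in the search window."""


class DegenerateBackgroundError(RuntimeError):
    """Background sigma collapsed to zero (e.g. constant spectrum)."""


@dataclass
class MassSpectrum:
    """One spot's spectrum: ascending m/z with non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    spot_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if len(self.mz) > 1 and np.any(np.diff(self.mz) < 0):
            warnings.warn("m/z not ascending; sorting", stacklevel=2)
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]


@dataclass
class BackgroundEstimate:
    mu: float
    sigma: float
    method: str = "sigma-clip"

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class SpectralMatrix:
    """All spots resampled onto one grid; rows are spots."""

    grid: np.ndarray  # (n_grid,) ascending m/z
    data: np.ndarray  # (n_spots, n_grid)
    spot_ids: list[str] = field(default_factory=list)
    offsets_ppm: np.ndarray | None = None  # applied calibration per spot
    kind: str = "intensity"  # "intensity" | "snr"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.data.shape[1] != self.grid.size:
            raise ValueError("data columns must match grid length")
        if not self.spot_ids:
            self.spot_ids = [f"spot{i}" for i in range(self.data.shape[0])]

    @property
    def n_spots(self) -> int:
        return self.data.shape[0]

    def spectrum(self, i: int) -> MassSpectrum:
        return MassSpectrum(self.grid, np.asarray(self.data[i], dtype=float),
                            spot_id=self.spot_ids[i])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_csv(spectrum: MassSpectrum, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([spectrum.mz, spectrum.intensity]),
               delimiter=",", header="mz,intensity", comments="")


def read_csv(path: str | Path) -> MassSpectrum:
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if arr.shape[1] != 2:
        raise ValueError("expected a two-column (mz, intensity) CSV")
    return MassSpectrum(arr[:, 0], arr[:, 1], spot_id=Path(path).stem)


def _b64_floats(values: np.ndarray) -> str:
    raw = np.asarray(values, dtype="<f8").tobytes()
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


_MZML_SPECTRUM = """\
   <spectrum index="{index}" id="{sid}" defaultArrayLength="{npts}">
    <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
    <binaryDataArrayList count="2">
     <binaryDataArray encodedLength="{len_mz}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
      <binary>{b64_mz}</binary>
     </binaryDataArray>
     <binaryDataArray encodedLength="{len_int}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
      <binary>{b64_int}</binary>
     </binaryDataArray>
    </binaryDataArrayList>
   </spectrum>
"""

_MZML_SHELL = """\
<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
 <cvList count="1">
  <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
 </cvList>
 <run id="ugimem_plate">
  <spectrumList count="{count}" defaultDataProcessingRef="dp">
{spectra}  </spectrumList>
 </run>
</mzML>
"""


def write_mzml(spectra: list[MassSpectrum], path: str | Path) -> None:
    """Minimal profile-mode mzML writer (64-bit float, zlib)."""
    chunks = []
    for i, spec in enumerate(spectra):
        b64_mz = _b64_floats(spec.mz)
        b64_int = _b64_floats(spec.intensity)
        chunks.append(_MZML_SPECTRUM.format(
            index=i,
            sid=spec.spot_id or f"spot{i}",
            npts=len(spec.mz),
            len_mz=len(b64_mz), b64_mz=b64_mz,
            len_int=len(b64_int), b64_int=b64_int,
        ))
    Path(path).write_text(_MZML_SHELL.format(count=len(spectra),
                                             spectra="".join(chunks)))


def read_mzml(path: str | Path) -> list[MassSpectrum]:
    """Read profile spectra from mzML (64/32-bit float, zlib or plain)."""
    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    out = []
    for _, elem in etree.iterparse(str(path), tag=f"{ns}spectrum"):
        arrays = {}
        for bda in elem.iter(f"{ns}binaryDataArray"):
            accessions = {cv.get("accession")
                          for cv in bda.iter(f"{ns}cvParam")}
            dtype = "<f8" if "MS:1000523" in accessions else "<f4"
            node = bda.find(f"{ns}binary")
            raw = base64.b64decode(node.text or "")
            if "MS:1000574" in accessions:  # zlib compression
                raw = zlib.decompress(raw)
            values = np.frombuffer(raw, dtype=dtype).astype(float)
            if "MS:1000514" in accessions:
                arrays["mz"] = values
            elif "MS:1000515" in accessions:
                arrays["intensity"] = values
        if "mz" in arrays and "intensity" in arrays:
            out.append(MassSpectrum(arrays["mz"], arrays["intensity"],
                                    spot_id=elem.get("id", "")))
        elem.clear()
    return out


def write_hdf5(matrix: SpectralMatrix, path: str | Path) -> None:
    """HDF5 layout: /mz_grid, /intensities, /spot_ids, /offsets_ppm, attrs."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("mz_grid", data=matrix.grid)
        fh.create_dataset("intensities", data=matrix.data)
        fh.create_dataset(
            "spot_ids", data=np.array(matrix.spot_ids, dtype=h5py.string_dtype())
        )
        if matrix.offsets_ppm is not None:
            fh.create_dataset("offsets_ppm", data=matrix.offsets_ppm)
        fh.attrs["kind"] = matrix.kind


def read_hdf5(path: str | Path) -> SpectralMatrix:
    with h5py.File(path, "r") as fh:
        return SpectralMatrix(
            grid=fh["mz_grid"][:],
            data=fh["intensities"][:],
            spot_ids=[s.decode() if isinstance(s, bytes) else str(s)
                      for s in fh["spot_ids"][:]],
            offsets_ppm=fh["offsets_ppm"][:] if "offsets_ppm" in fh else None,
            kind=fh.attrs.get("kind", "intensity"),
        )


def read_spectra(path: str | Path, format: str | None = None):
    """Dispatch on format or file suffix; returns spectra or a matrix."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mzml":
        return read_mzml(path)
    if fmt == "csv":
        return read_csv(path)
    if fmt in ("hdf5", "h5"):
        return read_hdf5(path)
    raise ValueError(f"unknown spectrum format {fmt!r}")


# ---------------------------------------------------------------------------
# Processing
# ---------------------------------------------------------------------------

def estimate_background(
    spectrum: MassSpectrum | np.ndarray,
    n_sigma: float = 3.0,
    max_iter: int = 10,
) -> BackgroundEstimate:
    """Iterative one-sided sigma clipping of the intensity distribution.

    Values above mu + n_sigma * sigma are clipped and (mu, sigma)
    re-estimated until convergence or ``max_iter`` passes.
    """
    values = (spectrum.intensity if isinstance(spectrum, MassSpectrum)
              else np.asarray(spectrum, dtype=float))
    if values.size < 100:
        raise ValueError("need >= 100 points to estimate a background")
    kept = values
    for _ in range(max_iter):
        mu = float(kept.mean())
        sigma = float(kept.std())
        if sigma == 0:
            raise DegenerateBackgroundError(
                "background sigma is zero after clipping"
            )
        mask = kept <= mu + n_sigma * sigma
        if mask.all():
            break
        kept = kept[mask]
    return BackgroundEstimate(mu=mu, sigma=sigma)


def snr_transform(
    spectrum: MassSpectrum, background: BackgroundEstimate
) -> MassSpectrum:
    """Shift-and-scale: SNR = (I - mu) / sigma."""
    if background.sigma <= 0:
        raise ValueError("background sigma must be positive")
    return MassSpectrum(
        spectrum.mz,
        (spectrum.intensity - background.mu) / background.sigma,
        spot_id=spectrum.spot_id,
        metadata={**spectrum.metadata, "snr": True},
    )


def snr_normalize(
    matrix: SpectralMatrix, skip_degenerate: bool = False, **kwargs
) -> SpectralMatrix:
    """Per-spot background estimation + SNR transform of a whole matrix.

    With ``skip_degenerate`` a row whose background collapses to zero
    variance (a noise-free simulation, or a missing spot recorded as
    zeros) is passed through unscaled — its intensities already behave
    like SNR values over an exactly-zero background.
    """
    out = np.empty_like(matrix.data, dtype=np.float32)
    for i in range(matrix.n_spots):
        try:
            bg = estimate_background(np.asarray(matrix.data[i], dtype=float), **kwargs)
        except DegenerateBackgroundError:
            if not skip_degenerate:
                raise
            out[i] = matrix.data[i]
            continue
        out[i] = (matrix.data[i] - bg.mu) / bg.sigma
    return SpectralMatrix(
        grid=matrix.grid, data=out, spot_ids=list(matrix.spot_ids),
        offsets_ppm=matrix.offsets_ppm, kind="snr",
    )


def calibrate_offset(
    spectrum: MassSpectrum,
    ref_mz: float,
    window_ppm: float = 50.0,
    min_snr: float = 5.0,
) -> tuple[MassSpectrum, float]:
    """Single-point multiplicative mass calibration.

    Finds the intensity apex within ``ref_mz * (1 +/- window_ppm*1e-6)``;
    if it clears the clipped background by ``min_snr``, rescales the m/z
    axis so the apex lands on ``ref_mz``. Returns the corrected spectrum
    and the applied offset in ppm (positive = spectrum read high).
    """
    lo = ref_mz * (1 - window_ppm * 1e-6)
    hi = ref_mz * (1 + window_ppm * 1e-6)
    sel = (spectrum.mz >= lo) & (spectrum.mz <= hi)
    if not sel.any():
        raise CalibrationError(
            f"no data points within +/-{window_ppm} ppm of {ref_mz}"
        )
    window_int = spectrum.intensity[sel]
    apex_local = int(np.argmax(window_int))
    try:
        bg = estimate_background(spectrum)
        apex_snr = (window_int[apex_local] - bg.mu) / bg.sigma
    except DegenerateBackgroundError:
        # zero-variance background: any strictly positive apex is real
        apex_snr = np.inf if window_int[apex_local] > 0 else 0.0
    if apex_snr < min_snr:
        raise CalibrationError(
            f"reference peak below SNR {min_snr} near {ref_mz} "
            f"(best {apex_snr:.1f})"
        )
    apex_mz = spectrum.mz[sel][apex_local]
    offset_ppm = (apex_mz / ref_mz - 1.0) * 1e6
    corrected = MassSpectrum(
        spectrum.mz / (1.0 + offset_ppm * 1e-6),
        spectrum.intensity.copy(),
        spot_id=spectrum.spot_id,
        metadata={**spectrum.metadata, "offset_ppm": offset_ppm},
    )
    return corrected, offset_ppm


def resample_to_grid(
    spectra: list[MassSpectrum], grid: np.ndarray,
    offsets_ppm: np.ndarray | None = None,
    dtype=np.float32,
) -> SpectralMatrix:
    """Linear interpolation of each spectrum onto a shared grid.

    Points outside a spectrum's native range are set to 0.
    """
    grid = np.asarray(grid, dtype=float)
    data = np.empty((len(spectra), grid.size), dtype=dtype)
    ids = []
    for i, spec in enumerate(spectra):
        if spec.mz.size == 0:
            raise ValueError(f"empty spectrum at position {i}")
        data[i] = np.interp(grid, spec.mz, spec.intensity, left=0.0, right=0.0)
        ids.append(spec.spot_id or f"spot{i}")
    return SpectralMatrix(grid=grid, data=data, spot_ids=ids,
                          offsets_ppm=offsets_ppm)


def default_grid(mz_min: float, mz_max: float, step: float = 0.001) -> np.ndarray:
    n = int(round((mz_max - mz_min) / step)) + 1
    return mz_min + step * np.arange(n)


def peak_intensity(
    matrix: SpectralMatrix, target_mz: float, tol_ppm: float = 15.0
) -> np.ndarray:
    """Per-spot maximum value within +/-tol_ppm of ``target_mz``."""
    lo = target_mz * (1 - tol_ppm * 1e-6)
    hi = target_mz * (1 + tol_ppm * 1e-6)
    i0, i1 = np.searchsorted(matrix.grid, [lo, hi])
    if i1 <= i0:
        raise ValueError(
            f"no grid points within +/-{tol_ppm} ppm of {target_mz}"
        )
    return matrix.data[:, i0:i1].max(axis=1)
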