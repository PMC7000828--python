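"""Plate geometry, acoustic transfer lists, and end-to-end pipelines.

A data plate is a 1536-position MALDI target (32 rows x 48 columns by
default) addressed row-major: mixture n occupies spot n, named A1..AF48.
Writing a presence matrix means dispensing one 2.5 nL droplet from each
present compound's library well into the spot, then 30 nL of matrix
solution; a spot holds at most 200 nL before neighbouring spots merge.

:func:`run_write` / :func:`run_read` compose the full store/recover
pipelines from a serializable :class:`RunConfig`, and :func:`roundtrip`
chains write -> simulate -> read for fully synthetic experiments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import codebook as cb
from . import codec, detect, specio
from .chemistry import CompoundLibrary, adduct_mz, enumerate_library, load_reagents
from .codec import PresenceMatrix
from .specsim import SimParams, simulate_plate

DROPLET_NL = 2.5
MATRIX_NL = 30.0
MAX_SPOT_NL = 200.0


class PlateCapacityError(ValueError):
    pass


@dataclass
class PlateLayout:
    """Row-major mapping between mixture indices and plate wells."""

    n_mixtures: int
    rows: int = 32
    cols: int = 48
    pitch_mm: float = 2.25  # physical metadata only

    def __post_init__(self):
        if self.n_mixtures > self.capacity:
            raise PlateCapacityError(
                f"{self.n_mixtures} mixtures exceed plate capacity "
                f"{self.capacity} ({self.rows}x{self.cols})"
            )

    @property
    def capacity(self) -> int:
        return self.rows * self.cols

    @staticmethod
    def _row_name(r: int) -> str:
        # A..Z then AA, AB, ... (AF for row 32)
        name = ""
        r += 1
        while r:
            r, rem = divmod(r - 1, 26)
            name = chr(ord("A") + rem) + name
        return name

    def well_name(self, mixture: int) -> str:
        if not 0 <= mixture < self.n_mixtures:
            raise IndexError(f"mixture {mixture} out of range")
        r, c = divmod(mixture, self.cols)
        return f"{self._row_name(r)}{c + 1}"

    def mixture_of(self, well: str) -> int:
        import re

        match = re.fullmatch(r"([A-Z]+)(\d+)", well)
        if not match:
            raise ValueError(f"bad well name {well!r}")
        letters, digits = match.groups()
        r = 0
        for ch in letters:
            r = r * 26 + (ord(ch) - ord("A") + 1)
        idx = (r - 1) * self.cols + int(digits) - 1
        if not 0 <= idx < self.n_mixtures:
            raise IndexError(f"well {well} maps outside the layout")
        return idx


def layout_plate(n_mixtures: int, rows: int = 32, cols: int = 48) -> PlateLayout:
    return PlateLayout(n_mixtures=n_mixtures, rows=rows, cols=cols)


@dataclass
class TransferList:
    """Acoustic-handler transfer records (one row per droplet)."""

    records: pd.DataFrame  # SourceWell, DestinationWell, VolumeNL

    @property
    def n_product_transfers(self) -> int:
        return int((self.records["SourceWell"] != "MATRIX").sum())

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def write_transfer_list(
    matrix: PresenceMatrix,
    layout: PlateLayout,
    library_wells: list[str],
    droplet_nl: float = DROPLET_NL,
    matrix_nl: float = MATRIX_NL,
    max_spot_nl: float = MAX_SPOT_NL,
) -> TransferList:
    """One droplet per presence-matrix '1' plus one matrix addition per spot."""
    if len(library_wells) != matrix.n_compounds:
        raise ValueError("need one source well per compound column")
    per_spot = matrix.data.sum(axis=1) * droplet_nl + matrix_nl
    over = np.flatnonzero(per_spot > max_spot_nl)
    if over.size:
        raise ValueError(
            f"spot volume limit {max_spot_nl} nL exceeded at mixtures "
            f"{over[:5].tolist()} (first offender {per_spot[over[0]]:.1f} nL)"
        )
    rows = []
    for n in range(matrix.n_spots):
        dest = layout.well_name(n)
        for m in np.flatnonzero(matrix.data[n]):
            rows.append((library_wells[m], dest, droplet_nl))
        rows.append(("MATRIX", dest, matrix_nl))
    return TransferList(
        records=pd.DataFrame(rows, columns=["SourceWell", "DestinationWell", "VolumeNL"])
    )


# ---------------------------------------------------------------------------
# End-to-end pipelines
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything needed to reproduce a write/read run bit-for-bit."""

    mapping: str = "direct"  # "direct" | "sparse"
    n_compounds: int = 32  # direct: compounds per mixture
    compound_indices: list[int] | None = None  # 1-based library subset
    codebook_n: int = 512
    codebook_w: int = 32
    codebook_bits: int = 16
    codebook_d_min: int = 36
    detector: str = "single"  # "single" | "logistic" | "forest"
    train_fraction: float = 0.3
    tol_ppm: float = 15.0
    seed: int = 0
    sim: SimParams = field(default_factory=SimParams)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        sim = raw.pop("sim", None)
        config = cls(**raw)
        if sim is not None:
            config.sim = SimParams(**sim)
        return config


def default_library() -> CompoundLibrary:
    """The packaged 5 x 5 x 12 x 5 = 1500-product library."""
    return enumerate_library(load_reagents())


def _encode(bits: np.ndarray, config: RunConfig):
    """Encode bits per config; returns (matrix, codebook or None)."""
    if config.mapping == "direct":
        return codec.direct_encode(bits, config.n_compounds), None
    if config.mapping == "sparse":
        book = cb.build_codebook(
            n=config.codebook_n, w=config.codebook_w,
            K=2**config.codebook_bits, d_min=config.codebook_d_min,
            seed=config.seed,
        )
        return cb.sparse_encode(bits, book), book
    raise ValueError(f"unknown mapping {config.mapping!r}")


def run_write(bits: np.ndarray, config: RunConfig,
              library: CompoundLibrary | None = None) -> dict:
    """payload -> presence matrix -> layout -> transfer list (+ codebook)."""
    library = library or default_library()
    matrix, book = _encode(np.asarray(bits, dtype=np.uint8), config)
    if config.compound_indices is not None:
        if len(config.compound_indices) != matrix.n_compounds:
            raise ValueError("compound subset size must match mixture width")
        matrix.compound_indices = list(config.compound_indices)
    elif config.mapping == "direct":
        # single-peak readout needs mutually resolvable sodiated peaks
        from .chemistry import select_compound_subset

        matrix.compound_indices = select_compound_subset(
            library, matrix.n_compounds, tol_ppm=config.tol_ppm,
            reference_mass=config.sim.reference_mass,
        )
    else:
        # sparse mappings tolerate mass degeneracy via error correction
        matrix.compound_indices = list(range(1, matrix.n_compounds + 1))
    layout = layout_plate(matrix.n_spots)
    source_wells = [f"LIB{i}" for i in matrix.compound_indices]
    transfers = write_transfer_list(matrix, layout, source_wells)
    return {"matrix": matrix, "layout": layout, "transfers": transfers,
            "codebook": book, "library": library}


def run_read(
    spectra: list[specio.MassSpectrum],
    config: RunConfig,
    library: CompoundLibrary | None = None,
    codebook: cb.Codebook | None = None,
    train_truth: np.ndarray | None = None,
    n_pad_bits: int = 0,
    compound_indices: list[int] | None = None,
) -> dict:
    """spectra -> calibrate -> resample -> SNR -> detect -> decode.

    ``train_truth``: known presence labels for a training subset of spots
    (rows aligned with the first ``train_truth.shape[0]`` spots of the
    seeded split; see detect.split_spots). Missing spectra should be
    passed as None entries: they decode as all-absent, flagged rows.
    """
    library = library or default_library()
    if compound_indices is None:
        if config.compound_indices is not None:
            compound_indices = list(config.compound_indices)
        elif config.mapping == "direct":
            from .chemistry import select_compound_subset

            compound_indices = select_compound_subset(
                library, config.n_compounds, tol_ppm=config.tol_ppm,
                reference_mass=config.sim.reference_mass,
            )
        else:
            compound_indices = list(range(1, config.codebook_n + 1))
    products = [library[i - 1] for i in compound_indices]
    target_mz = np.array([adduct_mz(p.M, "Na") for p in products])

    missing = np.array([s is None for s in spectra], dtype=bool)
    ref_mz = adduct_mz(config.sim.reference_mass, "Na")
    grid = config.sim.grid()
    calibrated = []
    offsets = np.zeros(len(spectra))
    placeholder = specio.MassSpectrum(grid, np.zeros(grid.size))
    for i, spec in enumerate(spectra):
        if spec is None:
            calibrated.append(placeholder)
            continue
        try:
            fixed, off = specio.calibrate_offset(spec, ref_mz)
        except specio.CalibrationError:
            fixed, off = spec, np.nan
        calibrated.append(fixed)
        offsets[i] = off
    matrix = specio.resample_to_grid(calibrated, grid, offsets_ppm=offsets)
    snr = specio.snr_normalize(matrix, skip_degenerate=True)

    if config.detector == "single":
        if train_truth is not None:
            train, _ = detect.split_spots(snr.n_spots, config.train_fraction,
                                          config.seed)
            reader = detect.SinglePeakReader(
                mz_grid=snr.grid, target_mz=target_mz, tol_ppm=config.tol_ppm
            ).fit(snr.data[train], np.asarray(train_truth))
        else:
            reader = detect.SinglePeakReader(
                mz_grid=snr.grid, target_mz=target_mz, tol_ppm=config.tol_ppm,
                threshold=3.0,
            ).fit(snr.data[:1], np.zeros((1, len(target_mz))))
        predicted = reader.predict(snr.data)
    else:
        if train_truth is None:
            raise ValueError("multi-peak detection requires training labels")
        train, _ = detect.split_spots(snr.n_spots, config.train_fraction,
                                      config.seed)
        reader = detect.MultiPeakReader(
            method=config.detector, random_state=config.seed
        ).fit(snr.data[train], np.asarray(train_truth))
        predicted = reader.predict(snr.data)
    predicted[missing] = 0

    observed = PresenceMatrix(
        data=predicted,
        mapping=config.mapping,
        n_pad_bits=n_pad_bits,
        compound_indices=compound_indices,
    )
    if config.mapping == "direct":
        bits = codec.direct_decode(observed)
        distances = ambiguous = None
    else:
        if codebook is None:
            raise ValueError("sparse read requires the codebook")
        bits, distances, ambiguous = cb.sparse_decode(
            observed.data, codebook, n_pad_bits=n_pad_bits
        )
    return {"bits": bits, "observed": observed, "snr": snr, "reader": reader,
            "missing": missing, "distances": distances, "ambiguous": ambiguous}


def roundtrip(
    bits: np.ndarray,
    config: RunConfig,
    library: CompoundLibrary | None = None,
) -> dict:
    """write -> simulate -> read; returns recovered bits and a ReadReport."""
    library = library or default_library()
    written = run_write(bits, config, library=library)
    matrix = written["matrix"]
    spectra, labels = simulate_plate(matrix, library, config.sim,
                                     compound_indices=matrix.compound_indices)
    # the labeled region of the plate supplies the training ground truth
    train, _ = detect.split_spots(matrix.n_spots, config.train_fraction,
                                  config.seed)
    train_truth = matrix.data[train]
    result = run_read(
        spectra, config, library=library, codebook=written["codebook"],
        train_truth=train_truth, n_pad_bits=matrix.n_pad_bits,
        compound_indices=matrix.compound_indices,
    )
    report = detect.evaluate_read(result["observed"].data, matrix.data)
    bits = np.asarray(bits, dtype=np.uint8).reshape(-1)
    bit_accuracy = float((result["bits"] == bits).mean())
    return {**written, **result, "report": report, "bit_accuracy": bit_accuracy,
            "truth": matrix}
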