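"""Spectrum conditioning and oxonium-ion triage of glycopeptide candidates.

The conditioning chain is: denoise (relative-intensity floor), intensity
square-root transform, top-K peak selection. Triage asks whether the
HexNAc oxonium ion (~m/z 204.087) sits among the 10 most abundant peaks of
the *original* spectrum; validation looks for any of the four low-mass
HexNAc fragment ions anywhere in the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Set

import numpy as np

from . import chem
from .spectra_io import Spectrum

__all__ = [
    "PreprocessedSpectrum",
    "denoise",
    "sqrt_transform",
    "oxo_triage",
    "detect_validation_oxoniums",
    "preprocess_spectrum",
]

DEFAULT_FLOOR_FRACTION = 0.005
DEFAULT_TRIAGE_TOP_N = 10
DEFAULT_FRAGMENT_TOL_PPM = 20.0


@dataclass
class PreprocessedSpectrum:
    source_id: str
    mz: np.ndarray
    sqrt_intensity: np.ndarray
    top_k: np.ndarray  # indices of the K most intense peaks
    oxo_flag: bool
    oxonium_labels: Set[str] = field(default_factory=set)
    spectrum: Optional[Spectrum] = None

    @property
    def total_intensity(self) -> float:
        return float(self.sqrt_intensity.sum())


def _ppm_match(peaks_mz: np.ndarray, target_mz: float, tol_ppm: float) -> np.ndarray:
    if peaks_mz.size == 0:
        return np.zeros(0, dtype=bool)
    return np.abs(peaks_mz - target_mz) <= target_mz * tol_ppm * 1e-6


def denoise(spec: Spectrum, floor_fraction: float = DEFAULT_FLOOR_FRACTION) -> Spectrum:
    """Drop peaks below ``floor_fraction`` of the base-peak intensity."""
    if spec.n_peaks == 0 or floor_fraction <= 0:
        return spec
    keep = spec.intensity >= floor_fraction * spec.intensity.max()
    return Spectrum(
        id=spec.id,
        precursor_mz=spec.precursor_mz,
        charge=spec.charge,
        mz=spec.mz[keep],
        intensity=spec.intensity[keep],
        retention_time=spec.retention_time,
        metadata=spec.metadata,
    )


def sqrt_transform(spec: Spectrum) -> np.ndarray:
    """Square-root transformed intensities (rank order preserved)."""
    if np.any(spec.intensity < 0):
        raise ValueError("negative intensity")
    return np.sqrt(spec.intensity)


def oxo_triage(
    spec: Spectrum,
    tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    top_n: int = DEFAULT_TRIAGE_TOP_N,
) -> bool:
    """True iff the HexNAc oxonium ion is among the ``top_n`` most abundant
    peaks (ranked by original intensity)."""
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if spec.n_peaks == 0:
        return False
    triage_mz = next(
        ion.mz for ion in chem.oxonium_table() if ion.label == chem.TRIAGE_OXONIUM_LABEL
    )
    top = np.argsort(spec.intensity, kind="stable")[::-1][:top_n]
    return bool(_ppm_match(spec.mz[top], triage_mz, tol_ppm).any())


def detect_validation_oxoniums(
    spec: Spectrum, tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM
) -> Set[str]:
    """Labels of the four validation oxonium ions present in the spectrum
    (any intensity rank) within ``tol_ppm``."""
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    table = {ion.label: ion.mz for ion in chem.oxonium_table()}
    found = set()
    for label in chem.VALIDATION_OXONIUM_LABELS:
        if _ppm_match(spec.mz, table[label], tol_ppm).any():
            found.add(label)
    return found


def preprocess_spectrum(
    spec: Spectrum,
    floor_fraction: float = DEFAULT_FLOOR_FRACTION,
    top_k: int = 100,
    tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    triage_top_n: int = DEFAULT_TRIAGE_TOP_N,
) -> PreprocessedSpectrum:
    """Full conditioning chain producing the searchable representation."""
    flag = oxo_triage(spec, tol_ppm, triage_top_n)
    labels = detect_validation_oxoniums(spec, tol_ppm)
    clean = denoise(spec, floor_fraction)
    sq = sqrt_transform(clean)
    order = np.argsort(sq, kind="stable")[::-1][:top_k]
    return PreprocessedSpectrum(
        source_id=spec.id,
        mz=clean.mz,
        sqrt_intensity=sq,
        top_k=np.sort(order),
        oxo_flag=flag,
        oxonium_labels=labels,
        spectrum=spec,
    )
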