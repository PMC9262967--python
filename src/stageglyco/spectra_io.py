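"""Centroided MS/MS spectrum model and MGF / mzML readers.

MGF is the canonical round-trip format; mzML support is read-only and
limited to centroided MS2 scans. Both readers stream: memory use is
independent of file length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterator, Optional, Sequence

import base64
import zlib

import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf

logger = logging.getLogger("stageglyco")

__all__ = ["Spectrum", "MGFError", "read_mgf", "write_mgf", "read_mzml_subset"]


class MGFError(ValueError):
    """Raised for structurally malformed MGF input."""


@dataclass
class Spectrum:
    """A centroided tandem mass spectrum.

    Peaks are kept sorted ascending by m/z; intensities are non-negative.
    """

    id: str
    precursor_mz: float
    charge: Optional[int]
    mz: np.ndarray
    intensity: np.ndarray
    retention_time: Optional[float] = None  # seconds
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if self.charge is not None and self.charge < 1:
            raise ValueError("precursor charge must be >= 1 when known")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def precursor_neutral_mass(self, charge: Optional[int] = None) -> float:
        from .chem import PROTON_MASS

        z = charge if charge is not None else self.charge
        if z is None:
            raise ValueError("precursor charge unknown")
        return self.precursor_mz * z - z * PROTON_MASS


def _check_mgf_structure(path) -> None:
    """Validate BEGIN IONS / END IONS pairing, reporting the line number of
    the first violation."""
    depth = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip().upper()
            if token == "BEGIN IONS":
                if depth:
                    raise MGFError(f"line {lineno}: nested BEGIN IONS")
                depth = 1
            elif token == "END IONS":
                if not depth:
                    raise MGFError(f"line {lineno}: END IONS without BEGIN IONS")
                depth = 0
    if depth:
        raise MGFError("unterminated BEGIN IONS block at end of file")


def read_mgf(path) -> Iterator[Spectrum]:
    """Stream spectra from an MGF file.

    PEPMASS, CHARGE ("3+", "2-", plain int) and TITLE are honored; any
    other headers are preserved in ``Spectrum.metadata``.
    """
    _check_mgf_structure(path)
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for i, entry in enumerate(reader):
            params = dict(entry["params"])
            title = str(params.pop("title", f"spectrum_{i}"))
            pepmass = params.pop("pepmass", (0.0, None))
            precursor_mz = float(pepmass[0]) if isinstance(pepmass, (tuple, list)) else float(pepmass)
            charge = None
            if "charge" in params:
                ch = params.pop("charge")
                ch0 = ch[0] if isinstance(ch, (list, tuple)) else ch
                charge = abs(int(ch0))
            rt = params.pop("rtinseconds", None)
            yield Spectrum(
                id=title,
                precursor_mz=precursor_mz,
                charge=charge,
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
                retention_time=float(rt) if rt is not None else None,
                metadata=params,
            )


def write_mgf(spectra: Sequence[Spectrum] | Iterator[Spectrum], path) -> None:
    """Write spectra to MGF with deterministic formatting (6 dp m/z,
    1 dp intensity), so equal inputs give byte-identical files."""
    with open(path, "w") as fh:
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={spec.id}\n")
            fh.write(f"PEPMASS={spec.precursor_mz:.6f}\n")
            if spec.charge is not None:
                fh.write(f"CHARGE={spec.charge}+\n")
            if spec.retention_time is not None:
                fh.write(f"RTINSECONDS={spec.retention_time:.2f}\n")
            for key, value in sorted(spec.metadata.items()):
                fh.write(f"{str(key).upper()}={value}\n")
            for mz, inten in zip(spec.mz, spec.intensity):
                fh.write(f"{mz:.6f} {inten:.1f}\n")
            fh.write("END IONS\n")


# mzML controlled-vocabulary accessions used by the reader
_CV_MS_LEVEL = "MS:1000511"
_CV_CENTROID = "MS:1000127"
_CV_PROFILE = "MS:1000128"
_CV_SELECTED_MZ = "MS:1000744"
_CV_CHARGE = "MS:1000041"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INT_ARRAY = "MS:1000515"
_CV_F64 = "MS:1000523"
_CV_F32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_SCAN_START = "MS:1000016"


def _cv_accessions(elem) -> Dict[str, str]:
    out = {}
    for cv in elem.iter("{*}cvParam"):
        out[cv.get("accession")] = cv.get("value", "")
    return out


def _decode_binary_array(bda) -> np.ndarray:
    accs = {cv.get("accession") for cv in bda.iter("{*}cvParam")}
    node = bda.find("{*}binary")
    raw = base64.b64decode(node.text or "")
    if _CV_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _CV_F32 in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml_subset(path) -> Iterator[Spectrum]:
    """Stream centroided MS2 spectra from an mzML file.

    Minimal read-only subset: 32/64-bit float peak arrays with optional
    zlib compression. MS1 scans are skipped; MS2 scans without a
    precursor element are skipped with a logged warning; profile spectra
    are rejected.
    """
    context = etree.iterparse(str(path), events=("end",), tag="{*}spectrum")
    for _, elem in context:
        try:
            top = {cv.get("accession"): cv.get("value", "")
                   for cv in elem.findall("{*}cvParam")}
            if top.get(_CV_MS_LEVEL) != "2":
                continue
            if _CV_PROFILE in top:
                raise ValueError(f"profile spectrum not supported: {elem.get('id')}")
            ion = elem.find(".//{*}selectedIon")
            if ion is None:
                logger.warning("skipping MS2 scan without precursor: %s", elem.get("id"))
                continue
            ion_params = _cv_accessions(ion)
            if _CV_SELECTED_MZ not in ion_params:
                logger.warning("skipping MS2 scan without precursor m/z: %s", elem.get("id"))
                continue
            precursor_mz = float(ion_params[_CV_SELECTED_MZ])
            charge = ion_params.get(_CV_CHARGE)
            mz = intensity = None
            for bda in elem.iter("{*}binaryDataArray"):
                accs = {cv.get("accession") for cv in bda.iter("{*}cvParam")}
                if _CV_MZ_ARRAY in accs:
                    mz = _decode_binary_array(bda)
                elif _CV_INT_ARRAY in accs:
                    intensity = _decode_binary_array(bda)
            if mz is None or intensity is None:
                logger.warning("skipping scan without peak arrays: %s", elem.get("id"))
                continue
            rt = None
            for scan in elem.iter("{*}scan"):
                params = _cv_accessions(scan)
                if _CV_SCAN_START in params:
                    unit = next(
                        (cv.get("unitName") for cv in scan.iter("{*}cvParam")
                         if cv.get("accession") == _CV_SCAN_START),
                        "minute",
                    )
                    rt = float(params[_CV_SCAN_START])
                    rt = rt * 60.0 if unit == "minute" else rt
            yield Spectrum(
                id=str(elem.get("id")),
                precursor_mz=precursor_mz,
                charge=int(charge) if charge else None,
                mz=mz,
                intensity=intensity,
                retention_time=rt,
            )
        finally:
            # free processed subtrees so memory stays flat while streaming
            elem.clear()
            parent = elem.getparent()
            while parent is not None and elem.getprevious() is not None:
                del parent[0]
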