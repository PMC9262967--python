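"""TMT reporter quantification, normalization and differential analysis
of glycosites.

The quantification model follows the standard isobaric-label design: a
pooled reference channel anchors every row; per-channel values are
expressed as ratios to the reference, log2-transformed and median-centered
per channel; rows quantified in too few channels are dropped; group
differences are tested per row (Welch t for independent tumor/normal
groups with Benjamini-Hochberg adjustment, paired t for matched designs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import chem
from .spectra_io import Spectrum

__all__ = [
    "ChannelDesign",
    "extract_reporters",
    "normalize",
    "presence_filter",
    "differential_unpaired",
    "differential_paired",
    "cv",
]


@dataclass(frozen=True)
class ChannelDesign:
    """TMT channel layout: which channel is the pooled reference, which
    group each channel belongs to, and (for paired designs) the pairing."""

    channels: Tuple[str, ...] = chem.TMT10_CHANNELS
    reference: str = "126"
    groups: Mapping[str, str] = field(default_factory=dict)  # channel -> group name
    pairs: Mapping[str, str] = field(default_factory=dict)  # group-A channel -> group-B channel

    def __post_init__(self) -> None:
        if self.reference not in self.channels:
            raise ValueError(f"reference channel {self.reference!r} not in design")
        for ch in self.groups:
            if ch not in self.channels:
                raise ValueError(f"unknown channel in groups: {ch!r}")
        if self.groups.get(self.reference, "reference") != "reference":
            raise ValueError("reference channel cannot belong to a sample group")
        for a, b in self.pairs.items():
            if a not in self.channels or b not in self.channels:
                raise ValueError("pairing references unknown channel")

    def group_channels(self, group: str) -> List[str]:
        return [ch for ch in self.channels if self.groups.get(ch) == group]

    @property
    def sample_channels(self) -> List[str]:
        return [ch for ch in self.channels if ch != self.reference]


def extract_reporters(
    spec: Spectrum,
    design: ChannelDesign,
    tol_ppm: float = 20.0,
) -> Dict[str, Optional[float]]:
    """Reporter-region intensities: for each channel the nearest peak
    within tolerance of its computed reporter m/z, else missing."""
    reporter_mz = chem.tmt10_reporter_mz()
    out: Dict[str, Optional[float]] = {}
    for ch in design.channels:
        target = reporter_mz[ch]
        if spec.n_peaks == 0:
            out[ch] = None
            continue
        delta = np.abs(spec.mz - target)
        j = int(np.argmin(delta))
        out[ch] = float(spec.intensity[j]) if delta[j] <= target * tol_ppm * 1e-6 else None
    return out


def build_site_matrix(
    calls,
    spectra_by_id: Mapping[str, Spectrum],
    design: ChannelDesign,
    tol_ppm: float = 20.0,
) -> pd.DataFrame:
    """Glycosite x channel abundance matrix from validated site calls.

    Reporter intensities are summed over all supporting PSM spectra of a
    site; a channel missing from every supporting spectrum stays missing.
    Row index is "accession:position:class".
    """
    acc: Dict[str, Dict[str, float]] = {}
    for call in calls:
        key = f"{call.accession}:{call.position}:{call.remnant_class}"
        spec = spectra_by_id.get(call.spectrum_id)
        if spec is None:
            continue
        reporters = extract_reporters(spec, design, tol_ppm)
        row = acc.setdefault(key, {})
        for ch, value in reporters.items():
            if value is not None:
                row[ch] = row.get(ch, 0.0) + value
    matrix = pd.DataFrame.from_dict(acc, orient="index").reindex(
        columns=list(design.channels)
    )
    return matrix.sort_index()


def normalize(matrix: pd.DataFrame, design: ChannelDesign) -> pd.DataFrame:
    """Reference-ratio, log2, per-channel median centering.

    Rows with a missing or non-positive reference value become all-missing.
    After normalization every channel's median over non-missing values
    is 0 (the operation is idempotent).
    """
    out = matrix[list(design.channels)].astype(float).copy()
    ref = out[design.reference]
    bad = ~(ref > 0)
    ratio = out.div(ref, axis=0)
    ratio[bad] = np.nan
    logged = np.log2(ratio.where(ratio > 0))
    centered = logged - logged.median(axis=0, skipna=True)
    return centered


def presence_filter(
    matrix: pd.DataFrame,
    design: ChannelDesign,
    fraction: float = 0.75,
) -> pd.DataFrame:
    """Keep rows quantified in strictly more than ``fraction`` of the
    non-reference channels."""
    sample_cols = design.sample_channels
    present = matrix[sample_cols].notna().sum(axis=1)
    return matrix[present > fraction * len(sample_cols)]


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    mask = ~np.isnan(pvals)
    out = np.full_like(pvals, np.nan, dtype=float)
    if mask.sum():
        out[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
    return out


def differential_unpaired(
    matrix: pd.DataFrame,
    design: ChannelDesign,
    group_a: str = "tumor",
    group_b: str = "normal",
    fdr_level: float = 0.01,
    fold_change: float = 1.5,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Row-wise Welch two-sided t test on normalized log2 values with BH
    adjustment; effect size is median(log2 A) - median(log2 B).

    Rows with fewer than 2 observations in either group are reported
    untested (NaN p). Direction flags require FDR < ``fdr_level`` and
    |linear fold change| >= ``fold_change``.
    """
    cols_a = design.group_channels(group_a)
    cols_b = design.group_channels(group_b)
    if not cols_a or not cols_b:
        raise ValueError(f"empty group(s): {group_a!r}/{group_b!r}")
    records = []
    for idx, row in matrix.iterrows():
        a = row[cols_a].dropna().to_numpy(dtype=float)
        b = row[cols_b].dropna().to_numpy(dtype=float)
        log2_fc = (
            float(np.median(a) - np.median(b)) if a.size and b.size else np.nan
        )
        if a.size < 2 or b.size < 2:
            p = np.nan
        elif np.allclose(a, a[0] if a.size else 0) and np.allclose(b, b[0] if b.size else 0) and np.isclose(log2_fc, 0):
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
            if np.isnan(p):
                p = 1.0
        records.append({"glycosite": idx, "median_log2_fc": log2_fc, "p_value": p})
    result = pd.DataFrame(records).set_index("glycosite")
    result["fdr"] = _bh_adjust(result["p_value"].to_numpy())
    lfc_cut = np.log2(fold_change)
    sig = result["fdr"] < fdr_level
    result["direction"] = "ns"
    result.loc[sig & (result["median_log2_fc"] >= lfc_cut), "direction"] = "up"
    result.loc[sig & (result["median_log2_fc"] <= -lfc_cut), "direction"] = "down"
    result.loc[result["p_value"].isna(), "direction"] = "untested"
    return result


def differential_paired(
    matrix: pd.DataFrame,
    design: ChannelDesign,
    p_level: float = 0.05,
    fold_change: float = 1.5,
) -> pd.DataFrame:
    """Row-wise paired two-sided t test on per-pair log2 differences.

    Pairs with a missing member are dropped per row; rows with <2 complete
    pairs are untested. All-zero differences give p = 1 by convention.
    Direction requires p < ``p_level`` and |linear fold change| >
    ``fold_change`` (strict, matching the '>1.5-fold' convention for
    paired designs).
    """
    if not design.pairs:
        raise ValueError("design has no pairing map")
    records = []
    for idx, row in matrix.iterrows():
        diffs = []
        for a, b in design.pairs.items():
            va, vb = row.get(a), row.get(b)
            if pd.notna(va) and pd.notna(vb):
                diffs.append(float(va) - float(vb))
        diffs = np.asarray(diffs)
        if diffs.size < 2:
            records.append({"glycosite": idx, "median_log2_fc": np.nan, "p_value": np.nan})
            continue
        log2_fc = float(np.median(diffs))
        if np.allclose(diffs, 0):
            p = 1.0
        elif np.allclose(diffs, diffs[0]):
            # zero variance, nonzero shift: maximally significant for the test's resolution
            p = 0.0
        else:
            p = float(stats.ttest_rel(diffs, np.zeros_like(diffs)).pvalue)
        records.append({"glycosite": idx, "median_log2_fc": log2_fc, "p_value": p})
    result = pd.DataFrame(records).set_index("glycosite")
    lfc_cut = np.log2(fold_change)
    sig = result["p_value"] < p_level
    result["direction"] = "ns"
    result.loc[sig & (result["median_log2_fc"] > lfc_cut), "direction"] = "up"
    result.loc[sig & (result["median_log2_fc"] < -lfc_cut), "direction"] = "down"
    result.loc[result["p_value"].isna(), "direction"] = "untested"
    return result


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 * sd / mean (sample sd).

    Undefined (NaN) for fewer than two values or non-positive mean.
    """
    arr = np.asarray([v for v in values if v is not None and not np.isnan(v)], dtype=float)
    if arr.size < 2:
        return float("nan")
    mean = arr.mean()
    if mean <= 0:
        return float("nan")
    return float(100.0 * arr.std(ddof=1) / mean)
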