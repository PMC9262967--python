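"""Validation of remnant PSMs into core-fucosylation glycosite calls,
site aggregation, and flanking-sequence / multi-site analyses.

A remnant PSM becomes a site call only when (1) the modified asparagine
sits on an N-X-S/T sequon (X != P) checked against the parent protein,
(2) spectra supporting HexNAc-Fuc (CF) or HexNAc remnants contain at
least one of the four validation oxonium ions, and (3) the peptide does
not simultaneously carry HexNAc-Fuc and HexNAc on different sequons —
such peptides are excluded entirely because in-source fucose loss makes
the two classes indistinguishable. CF + deamidation on one peptide is a
legitimate multi-site product and both sites are called.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from . import proteo
from .proteo import PeptideForm, ProteinRecord
from .search import PSM
from .spectra_io import Spectrum

__all__ = [
    "GlycositeCall",
    "validate_and_call",
    "aggregate_sites",
    "sites_per_protein",
    "flank_analysis",
    "multi_site_report",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"


@dataclass(frozen=True)
class GlycositeCall:
    """A validated glycosite: protein accession + 1-based position +
    remnant class, with its supporting evidence."""

    accession: str
    position: int
    remnant_class: str  # "CF" | "HexNAc" | "deamidated"
    peptide_form: PeptideForm
    spectrum_id: str
    oxonium_labels: Tuple[str, ...] = ()
    shared_evidence: bool = False  # peptide maps to >1 protein


def validate_and_call(
    psms: Sequence[PSM],
    spectra: Mapping[str, Spectrum] | None,
    proteins: Mapping[str, ProteinRecord],
) -> List[GlycositeCall]:
    """Apply the sequon, oxonium and remnant-exclusion rules and convert
    peptide-local remnant positions to protein coordinates.

    ``spectra`` may be None when PSMs already carry their oxonium labels
    (as produced by the search); otherwise spectra referenced by PSMs must
    be present.
    """
    calls: List[GlycositeCall] = []
    for psm in psms:
        remnants = psm.form.remnant_positions()
        if not remnants:
            continue
        classes = set(remnants.values())
        # exclusion: CF and HexNAc simultaneously on one peptide
        if "CF" in classes and "HexNAc" in classes:
            continue
        labels = set(psm.oxonium_labels)
        if spectra is not None:
            if psm.spectrum_id not in spectra:
                raise KeyError(f"PSM references missing spectrum {psm.spectrum_id!r}")
            from .preprocess import detect_validation_oxoniums

            labels |= detect_validation_oxoniums(spectra[psm.spectrum_id])
        # oxonium evidence is required for remnants that retain sugar
        if classes & {"CF", "HexNAc"} and not labels:
            continue
        shared = len(psm.form.protein_refs) > 1
        for acc, start in psm.form.protein_refs:
            prot = proteins.get(acc)
            if prot is None:
                continue
            sequons = set(
                proteo.peptide_sequons(psm.form.sequence, prot.sequence, start)
            )
            for local_pos, cls in sorted(remnants.items()):
                if local_pos not in sequons:
                    continue
                calls.append(
                    GlycositeCall(
                        accession=acc,
                        position=start + local_pos - 1,
                        remnant_class=cls,
                        peptide_form=psm.form,
                        spectrum_id=psm.spectrum_id,
                        oxonium_labels=tuple(sorted(labels)),
                        shared_evidence=shared,
                    )
                )
    return calls


def aggregate_sites(calls: Sequence[GlycositeCall]) -> pd.DataFrame:
    """Unique (accession, position, class) table with PSM counts and the
    union of oxonium evidence labels."""
    rows: Dict[Tuple[str, int, str], Dict[str, object]] = {}
    for call in calls:
        key = (call.accession, call.position, call.remnant_class)
        row = rows.setdefault(
            key,
            {
                "accession": call.accession,
                "position": call.position,
                "remnant_class": call.remnant_class,
                "n_psms": 0,
                "oxonium_labels": set(),
                "peptides": set(),
            },
        )
        row["n_psms"] += 1
        row["oxonium_labels"].update(call.oxonium_labels)
        row["peptides"].add(call.peptide_form.sequence)
    records = []
    for key in sorted(rows):
        row = rows[key]
        records.append(
            {
                "accession": row["accession"],
                "position": row["position"],
                "remnant_class": row["remnant_class"],
                "n_psms": row["n_psms"],
                "n_peptides": len(row["peptides"]),
                "oxonium_labels": ";".join(sorted(row["oxonium_labels"])),
            }
        )
    return pd.DataFrame(
        records,
        columns=["accession", "position", "remnant_class", "n_psms", "n_peptides", "oxonium_labels"],
    )


def sites_per_protein(site_table: pd.DataFrame, remnant_class: str = "CF") -> pd.Series:
    """Histogram of sites per protein for one remnant class: index =
    site count, value = number of proteins."""
    sub = site_table[site_table["remnant_class"] == remnant_class]
    if sub.empty:
        return pd.Series(dtype=int)
    counts = sub.groupby("accession")["position"].nunique()
    return counts.value_counts().sort_index()


def flank_analysis(
    calls: Sequence[GlycositeCall],
    proteins: Mapping[str, ProteinRecord],
    window: int = 10,
    remnant_class: str = "CF",
) -> pd.DataFrame:
    """Positional residue frequencies around unique glycosites.

    Rows are the 20 residues, columns are positions -window..+window with
    the glycosite asparagine fixed at 0. Frequencies at each position are
    relative to the observed (non-gap) residues there, so each column sums
    to 1 wherever any residue was observed. The center column is N with
    frequency 1 by construction.
    """
    sites = sorted(
        {(c.accession, c.position) for c in calls if c.remnant_class == remnant_class}
    )
    positions = list(range(-window, window + 1))
    counts = {p: Counter() for p in positions}
    for acc, pos in sites:
        prot = proteins.get(acc)
        if prot is None or not (1 <= pos <= len(prot.sequence)):
            raise ValueError(f"site {acc}:{pos} outside protein")
        seq = prot.sequence
        for offset in positions:
            i = pos - 1 + offset
            if 0 <= i < len(seq):
                counts[offset][seq[i]] += 1
    data = {}
    for p in positions:
        total = sum(counts[p].values())
        data[p] = [counts[p].get(aa, 0) / total if total else 0.0 for aa in AMINO_ACIDS]
    return pd.DataFrame(data, index=list(AMINO_ACIDS))


def st_share_at_plus2(flank: pd.DataFrame) -> Dict[str, float]:
    """Share of S vs T at the +2 sequon position (fractions of S+T)."""
    s, t = flank.loc["S", 2], flank.loc["T", 2]
    tot = s + t
    if tot == 0:
        return {"S": 0.0, "T": 0.0}
    return {"S": s / tot, "T": t / tot}


def multi_site_report(calls: Sequence[GlycositeCall]) -> pd.DataFrame:
    """Non-redundant peptide forms carrying a CF site plus at least one
    other modified sequon, with per-site remnant classes."""
    by_form: Dict[str, List[GlycositeCall]] = defaultdict(list)
    for call in calls:
        by_form[call.peptide_form.form_id()].append(call)
    records = []
    for form_id in sorted(by_form):
        group = by_form[form_id]
        site_classes = sorted({(c.position, c.remnant_class, c.accession) for c in group})
        classes = {c.remnant_class for c in group}
        positions = {(c.accession, c.position) for c in group}
        if len(positions) >= 2 and "CF" in classes:
            records.append(
                {
                    "peptide": group[0].peptide_form.sequence,
                    "form_id": form_id,
                    "n_sites": len(positions),
                    "site_classes": ";".join(
                        f"{acc}:{pos}:{cls}" for pos, cls, acc in site_classes
                    ),
                }
            )
    return pd.DataFrame(records, columns=["peptide", "form_id", "n_sites", "site_classes"])
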