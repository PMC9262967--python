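"""Fragment-ion-index database search with Morpheus scoring and
target-decoy FDR.

The search path mirrors the classic glycopeptide open-search design: the
top peaks of each conditioned spectrum are looked up in a sorted index of
theoretical b/y (and remnant neutral-loss) fragment m/z values; peptide
forms accumulating at least ``min_fragment_matches`` hits are re-scored
against the full spectrum with isotope companions; the best-scoring form
becomes the PSM; the precursor-vs-peptide mass gap is interpreted against
a glycan composition database; q-values come from reversed-protein decoys.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.special

from . import chem, proteo
from .chem import PROTON_MASS, GlycanComposition
from .preprocess import PreprocessedSpectrum, preprocess_spectrum
from .proteo import PeptideForm, ProteinRecord
from .spectra_io import Spectrum

__all__ = [
    "FragmentIndex",
    "PSM",
    "default_glycan_database",
    "build_index",
    "match_spectrum",
    "score_candidates",
    "assign_mass_gap",
    "precursor_isotope_fit",
    "coverage_filter",
    "fdr_filter",
    "SearchConfig",
    "search_dataset",
]

ISOTOPE_SPACING = 1.00335483  # Da, 13C - 12C mass difference

DEFAULT_PRECURSOR_TOL_PPM = 10.0
DEFAULT_FRAGMENT_TOL_PPM = 20.0
DEFAULT_MIN_FRAGMENT_MATCHES = 6
DEFAULT_TOP_PEAKS = 100
DEFAULT_COVERAGE_FRACTION = 0.10
DEFAULT_FDR_LEVEL = 0.01
DEFAULT_MAX_DYNAMIC_MODS = 3


def default_glycan_database() -> List[GlycanComposition]:
    """Combinatorial N-glycan composition space: HexNAc 2-7, Hex 3-12,
    Fuc 0-4, NeuAc 0-4 (config-replaceable)."""
    db = [
        GlycanComposition(n, h, f, s)
        for n in range(2, 8)
        for h in range(3, 13)
        for f in range(0, 5)
        for s in range(0, 5)
    ]
    return db


@dataclass
class FragmentIndex:
    """Sorted theoretical fragment m/z array with peptide-form back-pointers."""

    mz: np.ndarray  # sorted ascending
    form_idx: np.ndarray  # parallel, index into ``forms``
    forms: List[PeptideForm]

    def query(self, mz: float, tol_ppm: float) -> np.ndarray:
        delta = mz * tol_ppm * 1e-6
        lo = np.searchsorted(self.mz, mz - delta, side="left")
        hi = np.searchsorted(self.mz, mz + delta, side="right")
        return self.form_idx[lo:hi]


def build_index(
    forms: Sequence[PeptideForm],
    max_charge: int = 2,
) -> FragmentIndex:
    """Index all backbone/neutral-loss fragments of every peptide form."""
    if not forms:
        raise ValueError("cannot build index from zero peptide forms")
    mz_chunks: List[np.ndarray] = []
    idx_chunks: List[np.ndarray] = []
    for i, form in enumerate(forms):
        arr, _ = proteo.fragment_mz_arrays(form, max_charge)
        mz_chunks.append(arr)
        idx_chunks.append(np.full(arr.size, i, dtype=np.int64))
    mz = np.concatenate(mz_chunks)
    form_idx = np.concatenate(idx_chunks)
    order = np.argsort(mz, kind="stable")
    return FragmentIndex(mz[order], form_idx[order], list(forms))


def match_spectrum(
    pre: PreprocessedSpectrum,
    index: FragmentIndex,
    tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    min_matches: int = DEFAULT_MIN_FRAGMENT_MATCHES,
) -> List[int]:
    """Candidate form indices with >= ``min_matches`` fragment hits among
    the spectrum's top peaks."""
    if len(pre.top_k) == 0:
        return []
    peaks = pre.mz[pre.top_k]
    delta = peaks * tol_ppm * 1e-6
    lo = np.searchsorted(index.mz, peaks - delta, side="left")
    hi = np.searchsorted(index.mz, peaks + delta, side="right")
    chunks = [
        np.unique(index.form_idx[l:h]) for l, h in zip(lo, hi) if h > l
    ]
    if not chunks:
        return []
    all_hits = np.concatenate(chunks)
    forms, counts = np.unique(all_hits, return_counts=True)
    return [int(f) for f in forms[counts >= min_matches]]


@dataclass
class PSM:
    """A peptide-spectrum match with Morpheus score and filter evidence."""

    spectrum_id: str
    form: PeptideForm
    score: float
    n_matched: int
    intensity_fraction: float
    precursor_mz: float
    charge: Optional[int]
    mass_gap: float = 0.0
    glycan: Optional[GlycanComposition] = None
    valid: bool = True
    q_value: float = 1.0
    oxonium_labels: Set[str] = field(default_factory=set)

    @property
    def decoy(self) -> bool:
        return self.form.is_decoy


def _score_form(
    pre: PreprocessedSpectrum,
    form: PeptideForm,
    max_charge: int,
    tol_ppm: float,
    with_isotopes: bool = True,
) -> Tuple[float, int, float]:
    """Morpheus score = matched fragment count + matched intensity fraction.

    A theoretical fragment counts as matched when its monoisotopic m/z or
    (if enabled) its +1/+2 isotope companion hits a peak within tolerance;
    the intensity fraction is the matched share of total (sqrt-transformed)
    spectrum intensity.
    """
    mzs = pre.mz
    if mzs.size == 0:
        return 0.0, 0, 0.0
    frag_mz, frag_z = proteo.fragment_mz_arrays(form, max_charge)
    n_frag = frag_mz.size
    if with_isotopes:
        targets = np.concatenate(
            [frag_mz + k * ISOTOPE_SPACING / frag_z for k in (0, 1, 2)]
        )
        n_iso = 3
    else:
        targets = frag_mz
        n_iso = 1
    delta = targets * tol_ppm * 1e-6
    lo = np.searchsorted(mzs, targets - delta, side="left")
    hi = np.searchsorted(mzs, targets + delta, side="right")
    hit = hi > lo
    frag_hit = hit.reshape(n_iso, n_frag).any(axis=0)
    n_matched = int(frag_hit.sum())
    if n_matched == 0:
        return 0.0, 0, 0.0
    matched_idx = np.unique(
        np.concatenate([np.arange(l, h) for l, h in zip(lo[hit], hi[hit])])
    )
    total = pre.sqrt_intensity.sum()
    fraction = float(pre.sqrt_intensity[matched_idx].sum() / total) if total > 0 else 0.0
    return n_matched + fraction, n_matched, fraction


def score_candidates(
    pre: PreprocessedSpectrum,
    candidates: Sequence[PeptideForm],
    max_charge: int = 2,
    tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    with_isotopes: bool = True,
) -> Optional[PSM]:
    """Score candidates and return the best PSM (ties broken by higher
    matched-intensity fraction, then lexicographically smaller sequence)."""
    if not candidates:
        return None
    spec = pre.spectrum
    best_key = None
    best_psm: Optional[PSM] = None
    for form in candidates:
        score, n_matched, fraction = _score_form(pre, form, max_charge, tol_ppm, with_isotopes)
        psm = PSM(
            spectrum_id=pre.source_id,
            form=form,
            score=score,
            n_matched=n_matched,
            intensity_fraction=fraction,
            precursor_mz=spec.precursor_mz if spec is not None else 0.0,
            charge=spec.charge if spec is not None else None,
            oxonium_labels=set(pre.oxonium_labels),
        )
        key = (-score, -fraction, form.sequence, form.form_id())
        if best_key is None or key < best_key:
            best_key, best_psm = key, psm
    return best_psm


def assign_mass_gap(
    psm: PSM,
    glycans: Sequence[GlycanComposition],
    tol_ppm: float = DEFAULT_PRECURSOR_TOL_PPM,
) -> PSM:
    """Interpret precursor-minus-peptide mass as an attached glycan.

    A gap indistinguishable from zero means a fully deglycosylated (or
    remnant-only) peptide; a gap matching a glycan composition records the
    assignment; anything else flags the PSM invalid.
    """
    if psm.charge is None:
        return replace(psm, valid=False)
    precursor_neutral = psm.precursor_mz * psm.charge - psm.charge * PROTON_MASS
    gap = precursor_neutral - psm.form.mass
    tol = precursor_neutral * tol_ppm * 1e-6
    if abs(gap) <= tol:
        return replace(psm, mass_gap=gap, glycan=None, valid=True)
    for comp in glycans:
        if abs(gap - comp.mass) <= tol:
            return replace(psm, mass_gap=gap, glycan=comp, valid=True)
    return replace(psm, mass_gap=gap, glycan=None, valid=False)


def precursor_isotope_fit(
    observed_envelope: Sequence[float],
    neutral_mass: float,
) -> float:
    """Cosine similarity between an observed precursor isotope envelope and
    an averagine-Poisson model envelope at the given mass.

    The model approximates the heavy-isotope count distribution as Poisson
    with mean lambda = (carbons per Da for averagine) x P(13C) x mass.
    """
    obs = np.asarray(observed_envelope, dtype=float)
    if obs.size == 0 or obs.sum() <= 0:
        return 0.0
    lam = 4.7547e-4 * neutral_mass  # 0.044439 C/Da * 0.0107
    k = np.arange(obs.size)
    model = np.exp(-lam) * lam**k / scipy.special.factorial(k)
    denom = np.linalg.norm(obs) * np.linalg.norm(model)
    if denom == 0:
        return 0.0
    return float(np.dot(obs, model) / denom)


def coverage_filter(psm: PSM, min_fraction: float = DEFAULT_COVERAGE_FRACTION) -> bool:
    """Keep PSMs whose matched peaks cover strictly more than
    ``min_fraction`` of total spectrum intensity."""
    return psm.intensity_fraction > min_fraction


def fdr_filter(
    psms: Sequence[PSM],
    level: float = DEFAULT_FDR_LEVEL,
    decoys_searched: bool = False,
) -> List[PSM]:
    """Target-decoy q-values; retain target PSMs with q < ``level``.

    q(s) = min over score thresholds s' <= s of #decoy(score >= s') /
    #target(score >= s'); monotone non-increasing in score. When no decoy
    PSM is present the estimate is undefined unless the caller vouches
    that a decoy database was searched (``decoys_searched``), in which
    case zero surviving decoys means q = 0 everywhere.
    """
    if not psms:
        return []
    if not any(p.decoy for p in psms) and not decoys_searched:
        raise ValueError("no decoy PSMs: FDR is undefined")
    order = sorted(range(len(psms)), key=lambda i: -psms[i].score)
    scores = np.array([psms[i].score for i in order])
    is_decoy = np.array([psms[i].decoy for i in order])
    cum_decoy = np.cumsum(is_decoy)
    cum_target = np.cumsum(~is_decoy)
    # extend counts over score ties: use counts at the last index of each tie group
    fdp = np.empty(len(psms))
    i = 0
    while i < len(psms):
        j = i
        while j + 1 < len(psms) and scores[j + 1] == scores[i]:
            j += 1
        d, t = cum_decoy[j], cum_target[j]
        fdp[i : j + 1] = d / t if t > 0 else np.inf
        i = j + 1
    q = np.minimum.accumulate(fdp[::-1])[::-1]
    out = []
    for rank, idx in enumerate(order):
        psm = psms[idx]
        psm.q_value = float(q[rank])
        if not psm.decoy and psm.q_value < level:
            out.append(psm)
    return sorted(out, key=lambda p: (p.spectrum_id, p.form.form_id()))


# --- end-to-end search ----------------------------------------------------

@dataclass
class SearchConfig:
    """Tolerances, modification policy and filter thresholds for a search."""

    precursor_tol_ppm: float = DEFAULT_PRECURSOR_TOL_PPM
    fragment_tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM
    max_missed_cleavages: int = 2
    peptide_length_range: Tuple[int, int] = (6, 50)
    max_dynamic_mods: int = DEFAULT_MAX_DYNAMIC_MODS
    max_fragment_charge: int = 2
    min_fragment_matches: int = DEFAULT_MIN_FRAGMENT_MATCHES
    top_peaks: int = DEFAULT_TOP_PEAKS
    coverage_fraction: float = DEFAULT_COVERAGE_FRACTION
    fdr_level: float = DEFAULT_FDR_LEVEL
    denoise_floor_fraction: float = 0.005
    isotope_fit_threshold: float = 0.0  # permissive unless envelopes supplied
    with_decoys: bool = True
    use_isotopes: bool = True
    min_peptides_per_protein: int = 1


def search_dataset(
    proteins: Sequence[ProteinRecord],
    spectra: Iterable[Spectrum],
    config: SearchConfig | None = None,
    glycans: Sequence[GlycanComposition] | None = None,
) -> List[PSM]:
    """Search spectra against a protein database (remnant mode).

    Static carbamidomethyl-Cys; dynamic oxidation-Met plus the three
    deglycosylation remnants on sequon asparagines. Decoys come from
    reversed proteins and share the same digestion and modification rules.
    Returns FDR-filtered target PSMs with q-values.
    """
    cfg = config or SearchConfig()
    if glycans is None:
        glycans = default_glycan_database()
    mods = chem.default_modifications()
    static = [mods["carbamidomethyl"]]
    dynamic = [mods["oxidation"], mods["deamidation"], mods["hexnac"], mods["hexnac_fuc"]]

    db = list(proteins)
    if cfg.with_decoys:
        db += [proteo.reverse_decoy(p) for p in proteins]
    prot_map = {p.accession: p for p in db}
    peptides = proteo.digest_proteins(
        db, max_missed=cfg.max_missed_cleavages, length_range=cfg.peptide_length_range
    )
    forms: List[PeptideForm] = []
    for pep in peptides:
        forms.extend(
            proteo.enumerate_modforms(
                pep, prot_map, static, dynamic, max_dynamic=cfg.max_dynamic_mods
            )
        )
    index = build_index(forms, cfg.max_fragment_charge)

    all_psms: List[PSM] = []
    for spec in spectra:
        pre = preprocess_spectrum(
            spec,
            floor_fraction=cfg.denoise_floor_fraction,
            top_k=cfg.top_peaks,
            tol_ppm=cfg.fragment_tol_ppm,
        )
        cand_idx = match_spectrum(pre, index, cfg.fragment_tol_ppm, cfg.min_fragment_matches)
        if not cand_idx:
            continue
        # charge unknown: evaluate the precursor fit under charges 2 and 3
        psm = score_candidates(
            pre,
            [index.forms[i] for i in cand_idx],
            cfg.max_fragment_charge,
            cfg.fragment_tol_ppm,
            cfg.use_isotopes,
        )
        if psm is None:
            continue
        if psm.charge is None:
            for z in (2, 3):
                trial = assign_mass_gap(replace(psm, charge=z), glycans, cfg.precursor_tol_ppm)
                if trial.valid:
                    psm = trial
                    break
            else:
                psm = replace(psm, valid=False)
        else:
            psm = assign_mass_gap(psm, glycans, cfg.precursor_tol_ppm)
        if not psm.valid:
            continue
        if not coverage_filter(psm, cfg.coverage_fraction):
            continue
        all_psms.append(psm)

    if cfg.with_decoys:
        return fdr_filter(all_psms, cfg.fdr_level, decoys_searched=True)
    for p in all_psms:
        p.q_value = 0.0
    return sorted(all_psms, key=lambda p: (p.spectrum_id, p.form.form_id()))


def protein_rollup(psms: Sequence[PSM], min_peptides: int = 1) -> Dict[str, Set[str]]:
    """Protein -> supported peptide sequences, keeping proteins with at
    least ``min_peptides`` distinct peptides (>=1 PSM per peptide holds by
    construction)."""
    by_prot: Dict[str, Set[str]] = {}
    for psm in psms:
        for acc, _ in psm.form.protein_refs:
            by_prot.setdefault(acc, set()).add(psm.form.sequence)
    return {acc: peps for acc, peps in by_prot.items() if len(peps) >= min_peptides}
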