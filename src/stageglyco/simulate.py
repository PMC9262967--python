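"""Synthetic sequential-deglycosylation datasets with known ground truth.

The generator emulates the data the pipeline consumes after the wet-lab
stages: a protein FASTA with planted N-X-S/T sequons, MS/MS spectra of
tryptic glycopeptides carrying the three remnant mass signatures
(HexNAc-Fuc +349.137, HexNAc +203.079, deamidation +0.984), b/y fragment
ions with glyco neutral-loss companions, validation oxonium ions, TMT
reporter peaks with planted group effects, and uniform noise peaks.
Entrapment proteins (present in the FASTA, never generating spectra)
allow empirical false-discovery measurement.

Everything is driven by one seed; the same seed yields byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chem, proteo
from .chem import Modification
from .proteo import PeptideForm, ProteinRecord
from .quant import ChannelDesign
from .spectra_io import Spectrum, write_mgf

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_dataset", "plant_effects", "default_design"]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def default_design() -> ChannelDesign:
    """TMT 10-plex layout: pooled reference in 126, four normal and four
    tumor channels, 131 unassigned."""
    groups = {
        "127N": "normal", "127C": "normal", "128N": "normal", "128C": "normal",
        "129N": "tumor", "129C": "tumor", "130N": "tumor", "130C": "tumor",
    }
    return ChannelDesign(reference="126", groups=groups)


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    The remnant mixture encodes the enzyme-specificity model: Endo F3
    releases CF biantennary glycans leaving +349.137 on the site;
    the remaining (non-CF or multi-antennary) glycans fall to PNGase F,
    leaving +0.984; a small residual fraction keeps a bare HexNAc
    (+203.079).
    """

    seed: int = 0
    n_proteins: int = 200
    protein_length_range: Tuple[int, int] = (150, 400)
    sequons_per_protein: float = 2.0
    cf_fraction: float = 0.50
    deamidated_fraction: float = 0.40
    hexnac_fraction: float = 0.10
    oxonium_probability: float = 0.95
    n_noise_peaks: int = 30
    noise_intensity_scale: float = 0.01  # relative to median fragment intensity
    fragment_intensity_sigma: float = 0.6  # log-normal sigma of fragment intensities
    spectra_per_site: int = 2
    n_plain_spectra: int = 100  # spectra of unmodified tryptic peptides
    entrapment_fraction: float = 0.5
    forbidden_pair_fraction: float = 0.0  # peptides carrying CF + HexNAc together
    # TMT effect model
    design: ChannelDesign = field(default_factory=default_design)
    effect_up_fraction: float = 0.15
    effect_down_fraction: float = 0.05
    effect_log2: float = 1.0
    channel_noise_sigma: float = 0.25  # log2-scale channel noise
    tmt_reporters: bool = True

    def __post_init__(self) -> None:
        mix = self.cf_fraction + self.deamidated_fraction + self.hexnac_fraction
        if not np.isclose(mix, 1.0):
            raise ValueError(f"remnant mixture must sum to 1 (got {mix})")
        for name in ("cf_fraction", "deamidated_fraction", "hexnac_fraction",
                     "oxonium_probability", "entrapment_fraction", "forbidden_pair_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sequons_per_protein <= 0 and self.cf_fraction > 0:
            raise ValueError("cannot plant CF sites with zero sequon rate")


@dataclass
class SimulatedDataset:
    proteins: List[ProteinRecord]  # targets + entrapment
    spectra: List[Spectrum]
    design: ChannelDesign
    ground_truth: pd.DataFrame  # one row per emitted spectrum
    site_effects: pd.DataFrame  # one row per planted glyco site
    config: SimulationConfig

    def write(self, out_dir) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "proteins.fasta",
            "mgf": out / "spectra.mgf",
            "design": out / "design.tsv",
            "ground_truth": out / "ground_truth.tsv",
            "site_effects": out / "site_effects.tsv",
        }
        proteo.write_fasta(self.proteins, paths["fasta"])
        write_mgf(self.spectra, paths["mgf"])
        rows = [
            {"channel": ch,
             "group": ("reference" if ch == self.design.reference
                       else self.design.groups.get(ch, ""))}
            for ch in self.design.channels
        ]
        pd.DataFrame(rows).to_csv(paths["design"], sep="\t", index=False)
        self.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
        self.site_effects.to_csv(paths["site_effects"], sep="\t", index=False)
        return paths


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _plant_sequon(seq: List[str], pos0: int, rng: np.random.Generator) -> None:
    """Overwrite a triplet starting at 0-based pos0 with N-X-S/T, X != P."""
    x = rng.choice(AMINO_ACIDS)
    while x in ("P", "K", "R"):
        x = rng.choice(AMINO_ACIDS)
    seq[pos0] = "N"
    seq[pos0 + 1] = x
    seq[pos0 + 2] = "T" if rng.random() < 0.55 else "S"


_CLASS_MOD = {"CF": "hexnac_fuc", "HexNAc": "hexnac", "deamidated": "deamidation"}


def _build_form(
    pep: PeptideForm,
    site_classes: Mapping[int, str],
    mods: Mapping[str, Modification],
) -> PeptideForm:
    """Peptide form with static carbamidomethyl plus remnant mods at the
    given peptide-local positions."""
    assigned: List[Tuple[int, Modification]] = []
    for i, aa in enumerate(pep.sequence, start=1):
        if aa == "C":
            assigned.append((i, mods["carbamidomethyl"]))
    for local_pos, cls in site_classes.items():
        assigned.append((local_pos, mods[_CLASS_MOD[cls]]))
    return replace(pep, mods=tuple(sorted(assigned, key=lambda t: (t[0], t[1].name))))


def _spectrum_for_form(
    form: PeptideForm,
    spec_id: str,
    charge: int,
    rng: np.random.Generator,
    cfg: SimulationConfig,
    reporter_intensities: Optional[Mapping[str, float]] = None,
) -> Spectrum:
    frags = proteo.theoretical_fragments(form, max_charge=1, include_oxonium=False)
    frag_mz = np.array([f.mz for f in frags])
    base = 1e5
    frag_int = base * rng.lognormal(0.0, cfg.fragment_intensity_sigma, frag_mz.size)

    mz_list = [frag_mz]
    int_list = [frag_int]

    classes = set(form.remnant_positions().values())
    if classes & {"CF", "HexNAc"}:
        oxo_mz, oxo_int = [], []
        for ion in chem.oxonium_table():
            if ion.label not in chem.VALIDATION_OXONIUM_LABELS:
                continue
            if rng.random() < cfg.oxonium_probability:
                oxo_mz.append(ion.mz)
                # triage ion must rank in the top peaks; emit it hot
                scale = 5.0 if ion.label == chem.TRIAGE_OXONIUM_LABEL else 1.5
                oxo_int.append(base * scale * rng.lognormal(0.0, 0.2))
        if oxo_mz:
            mz_list.append(np.array(oxo_mz))
            int_list.append(np.array(oxo_int))

    if reporter_intensities is not None:
        rep_mz = chem.tmt10_reporter_mz()
        chans = [ch for ch, v in reporter_intensities.items() if v is not None]
        if chans:
            mz_list.append(np.array([rep_mz[ch] for ch in chans]))
            int_list.append(np.array([reporter_intensities[ch] for ch in chans]))

    precursor_mz = form.mz(charge)
    if cfg.n_noise_peaks:
        noise_mz = rng.uniform(100.0, max(precursor_mz, 200.0), cfg.n_noise_peaks)
        noise_int = base * cfg.noise_intensity_scale * rng.lognormal(0.0, 1.0, cfg.n_noise_peaks)
        mz_list.append(noise_mz)
        int_list.append(noise_int)

    return Spectrum(
        id=spec_id,
        precursor_mz=precursor_mz,
        charge=charge,
        mz=np.concatenate(mz_list),
        intensity=np.concatenate(int_list),
    )


def plant_effects(
    n_rows: int,
    design: ChannelDesign,
    effects_log2: Sequence[float],
    sigma: float,
    seed: int,
    base_log2_abundance: float = 16.0,
) -> pd.DataFrame:
    """Quant matrix with planted per-row group effects.

    Channel abundances are log-normal around a per-row base; tumor
    channels are offset by the row's planted log2 effect; the reference
    channel is the mean of the other channels (a pooled reference).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    effects = np.asarray(effects_log2, dtype=float)
    if effects.size != n_rows:
        raise ValueError("one effect per row required")
    rng = np.random.default_rng(seed)
    sample = design.sample_channels
    data = np.empty((n_rows, len(design.channels)))
    cols = list(design.channels)
    for r in range(n_rows):
        row_base = base_log2_abundance + rng.normal(0, 1)
        values = {}
        for ch in sample:
            offset = effects[r] if design.groups.get(ch) == "tumor" else 0.0
            values[ch] = 2.0 ** (row_base + offset + rng.normal(0, sigma))
        values[design.reference] = float(np.mean([values[ch] for ch in sample]))
        data[r] = [values[ch] for ch in cols]
    return pd.DataFrame(data, columns=cols, index=[f"site_{r}" for r in range(n_rows)])


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate a full dataset: FASTA (targets + entrapment), MGF spectra,
    TMT design, and ground-truth tables."""
    rng = np.random.default_rng(cfg.seed)
    mods = chem.default_modifications()

    # --- proteins with planted sequons ---
    proteins: List[ProteinRecord] = []
    planted: List[Tuple[str, int]] = []  # (accession, protein position 1-based)
    for p in range(cfg.n_proteins):
        length = int(rng.integers(*cfg.protein_length_range))
        seq = list(_random_protein(rng, length))
        n_seq = rng.poisson(cfg.sequons_per_protein)
        used: List[int] = []
        acc = f"SIM{p:04d}"
        for _ in range(n_seq):
            for _attempt in range(20):
                pos0 = int(rng.integers(5, length - 7))
                # min spacing 4 keeps triplets disjoint while letting two
                # sequons fall inside one tryptic peptide (multi-site case)
                if all(abs(pos0 - u) > 4 for u in used):
                    break
            else:
                continue
            used.append(pos0)
            _plant_sequon(seq, pos0, rng)
        sequence = "".join(seq)
        # verify planted positions survived later substitutions
        for pos0 in used:
            if sequence[pos0] == "N" and sequence[pos0 + 1] != "P" and sequence[pos0 + 2] in "ST":
                planted.append((acc, pos0 + 1))
        proteins.append(ProteinRecord(acc, f"{acc} synthetic target protein", sequence))

    n_entrap = int(round(cfg.entrapment_fraction * cfg.n_proteins))
    for p in range(n_entrap):
        length = int(rng.integers(*cfg.protein_length_range))
        acc = f"ENTRAP{p:04d}"
        proteins.append(
            ProteinRecord(acc, f"{acc} synthetic entrapment protein", _random_protein(rng, length))
        )
    prot_map = {p.accession: p for p in proteins}

    # --- choose peptides covering planted sites ---
    target_prots = [p for p in proteins if p.accession.startswith("SIM")]
    pep_by_site: Dict[Tuple[str, int], PeptideForm] = {}
    for prot in target_prots:
        for pep in proteo.digest(prot, max_missed=0, length_range=(8, 35)):
            start = pep.protein_refs[0][1]
            for local in proteo.peptide_sequons(pep.sequence, prot.sequence, start):
                site = (prot.accession, start + local - 1)
                if site not in pep_by_site:
                    pep_by_site[site] = pep

    observable_sites = sorted(s for s in planted if s in pep_by_site)

    # group observable sites by their covering peptide: multi-sequon
    # peptides carry several sites in one analyte
    by_pep: Dict[str, List[Tuple[str, int]]] = {}
    for site in observable_sites:
        by_pep.setdefault(pep_by_site[site].form_id(), []).append(site)

    # --- assign remnant classes and quant effects ---
    class_choices = np.array(["CF", "deamidated", "HexNAc"])
    class_probs = np.array([cfg.cf_fraction, cfg.deamidated_fraction, cfg.hexnac_fraction])
    site_class: Dict[Tuple[str, int], str] = {}
    for form_id in sorted(by_pep):
        sites = sorted(by_pep[form_id])
        if len(sites) >= 2 and rng.random() < cfg.forbidden_pair_fraction:
            # deliberately emit the excluded CF + HexNAc combination
            classes = ["CF", "HexNAc"] + [
                str(c) for c in rng.choice(class_choices, size=len(sites) - 2, p=class_probs)
            ]
        else:
            while True:
                classes = rng.choice(class_choices, size=len(sites), p=class_probs)
                if not {"CF", "HexNAc"} <= set(classes):
                    break
        for site, cls in zip(sites, classes):
            site_class[site] = str(cls)

    effect_choices = np.array([cfg.effect_log2, -cfg.effect_log2, 0.0])
    effect_probs = np.array(
        [cfg.effect_up_fraction, cfg.effect_down_fraction,
         1 - cfg.effect_up_fraction - cfg.effect_down_fraction]
    )
    site_effect = {
        site: float(rng.choice(effect_choices, p=effect_probs)) for site in observable_sites
    }

    design = cfg.design
    sample_channels = design.sample_channels

    # --- emit spectra ---
    spectra: List[Spectrum] = []
    truth_rows: List[Dict[str, object]] = []
    spec_counter = 0
    for form_id in sorted(by_pep):
        sites = sorted(by_pep[form_id])
        pep = pep_by_site[sites[0]]
        start = pep.protein_refs[0][1]
        local_classes = {s[1] - start + 1: site_class[s] for s in sites}
        form = _build_form(pep, local_classes, mods)
        charge = 2 if form.mass < 2400 else 3
        # reporter model: per-site base abundance, tumor offset by effect
        effect = site_effect[sites[0]]
        for rep in range(cfg.spectra_per_site):
            sub = np.random.default_rng([cfg.seed, 1, spec_counter])
            reporters = None
            if cfg.tmt_reporters:
                row_base = 16.0 + sub.normal(0, 1)
                vals = {}
                for ch in sample_channels:
                    offset = effect if design.groups.get(ch) == "tumor" else 0.0
                    vals[ch] = 2.0 ** (row_base + offset + sub.normal(0, cfg.channel_noise_sigma))
                vals[design.reference] = float(np.mean(list(vals.values())))
                reporters = vals
            spec_id = f"scan_{spec_counter:05d}"
            spectra.append(_spectrum_for_form(form, spec_id, charge, sub, cfg, reporters))
            for s in sites:
                truth_rows.append(
                    {
                        "spectrum_id": spec_id,
                        "peptide": pep.sequence,
                        "form_id": form.form_id(),
                        "accession": s[0],
                        "position": s[1],
                        "remnant_class": site_class[s],
                        "effect_log2": site_effect[s],
                    }
                )
            spec_counter += 1

    # --- plain (non-glyco) peptide spectra ---
    plain_candidates: List[PeptideForm] = []
    for prot in target_prots:
        for pep in proteo.digest(prot, max_missed=0, length_range=(8, 25)):
            start = pep.protein_refs[0][1]
            if not proteo.peptide_sequons(pep.sequence, prot.sequence, start):
                plain_candidates.append(pep)
    plain_candidates.sort(key=lambda p: (p.sequence, p.protein_refs))
    if plain_candidates:
        picks = rng.choice(len(plain_candidates), size=min(cfg.n_plain_spectra, len(plain_candidates)), replace=False)
        for k in sorted(picks):
            pep = plain_candidates[int(k)]
            form = _build_form(pep, {}, mods)
            charge = 2 if form.mass < 2400 else 3
            sub = np.random.default_rng([cfg.seed, 2, spec_counter])
            spec_id = f"scan_{spec_counter:05d}"
            spectra.append(_spectrum_for_form(form, spec_id, charge, sub, cfg, None))
            truth_rows.append(
                {
                    "spectrum_id": spec_id,
                    "peptide": pep.sequence,
                    "form_id": form.form_id(),
                    "accession": pep.protein_refs[0][0],
                    "position": 0,
                    "remnant_class": "none",
                    "effect_log2": 0.0,
                }
            )
            spec_counter += 1

    ground_truth = pd.DataFrame(
        truth_rows,
        columns=["spectrum_id", "peptide", "form_id", "accession", "position",
                 "remnant_class", "effect_log2"],
    )
    site_effects = pd.DataFrame(
        [
            {"accession": a, "position": p, "remnant_class": site_class[(a, p)],
             "effect_log2": site_effect[(a, p)]}
            for a, p in observable_sites
        ],
        columns=["accession", "position", "remnant_class", "effect_log2"],
    )
    return SimulatedDataset(proteins, spectra, design, ground_truth, site_effects, cfg)
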