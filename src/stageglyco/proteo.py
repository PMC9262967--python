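"""In-silico proteolysis, N-glycosylation sequon detection and theoretical
fragment ions.

Digestion models Lys-C + trypsin jointly as trypsin specificity (cleave
C-terminal to K/R, not before P); Lys-C sites are a subset of tryptic
sites so the sequential digest collapses to the tryptic peptide set.
Positions are 1-based in every report, matching the field convention for
glycosites (N240, N511, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from . import chem
from .chem import Modification, PROTON_MASS

__all__ = [
    "ProteinRecord",
    "PeptideForm",
    "TheoreticalFragment",
    "read_fasta",
    "write_fasta",
    "digest",
    "digest_proteins",
    "find_sequons",
    "peptide_sequons",
    "enumerate_modforms",
    "theoretical_fragments",
    "reverse_decoy",
]


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession}")


def _accession_from_header(header: str) -> str:
    """Extract the accession from a UniProt or RefSeq-style FASTA header.

    ``sp|P02790|HEMO_HUMAN ...`` → ``P02790``; otherwise the first
    whitespace-delimited token (RefSeq ``NP_000001.1 ...`` style).
    """
    token = header.split()[0]
    if token.count("|") >= 2:
        return token.split("|")[1]
    return token


def read_fasta(path) -> List[ProteinRecord]:
    records = []
    with open(path) as fh:
        header = None
        chunks: List[str] = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(
                        ProteinRecord(_accession_from_header(header), header, "".join(chunks))
                    )
                header = line[1:]
                chunks = []
            else:
                chunks.append(line)
        if header is not None:
            records.append(ProteinRecord(_accession_from_header(header), header, "".join(chunks)))
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.description}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reverse_decoy(rec: ProteinRecord, prefix: str = "DECOY_") -> ProteinRecord:
    """Reversed-sequence decoy protein for target-decoy FDR estimation."""
    return ProteinRecord(prefix + rec.accession, prefix + rec.accession, rec.sequence[::-1])


# --- digestion ------------------------------------------------------------

_ENZYME_RESIDUES = {"trypsin": "KR", "lysc": "K"}


def _cleavage_sites(sequence: str, enzyme: str, suppress_proline: bool = True) -> List[int]:
    """0-based positions after which the backbone is cleaved."""
    try:
        residues = _ENZYME_RESIDUES[enzyme.lower().replace("-", "")]
    except KeyError:
        raise ValueError(f"unknown enzyme: {enzyme!r}") from None
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in residues and not (suppress_proline and sequence[i + 1] == "P"):
            sites.append(i)
    return sites


def digest(
    protein: ProteinRecord,
    enzyme: str = "trypsin",
    max_missed: int = 2,
    length_range: Tuple[int, int] = (6, 50),
    suppress_proline: bool = True,
) -> List["PeptideForm"]:
    """Fully specific digest with up to ``max_missed`` missed cleavages.

    Returns unmodified peptide forms, deduplicated by
    (sequence, protein, start).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    if not seq:
        return []
    sites = _cleavage_sites(seq, enzyme, suppress_proline)
    # fragment boundaries: [start, end) in 0-based coordinates
    starts = [0] + [s + 1 for s in sites]
    ends = [s + 1 for s in sites] + [len(seq)]
    lo, hi = length_range
    out: List[PeptideForm] = []
    seen = set()
    for i, start in enumerate(starts):
        for j in range(i, min(i + max_missed + 1, len(ends))):
            end = ends[j]
            pep = seq[start:end]
            if not (lo <= len(pep) <= hi):
                continue
            key = (pep, protein.accession, start + 1)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                PeptideForm(
                    sequence=pep,
                    protein_refs=((protein.accession, start + 1),),
                    missed_cleavages=j - i,
                )
            )
    return out


def digest_proteins(
    proteins: Sequence[ProteinRecord],
    enzyme: str = "trypsin",
    max_missed: int = 2,
    length_range: Tuple[int, int] = (6, 50),
) -> List["PeptideForm"]:
    """Digest many proteins, merging identical sequences into one form with
    multiple protein references."""
    by_seq: Dict[str, PeptideForm] = {}
    for prot in proteins:
        for pep in digest(prot, enzyme, max_missed, length_range):
            prev = by_seq.get(pep.sequence)
            if prev is None:
                by_seq[pep.sequence] = pep
            else:
                refs = prev.protein_refs + pep.protein_refs
                by_seq[pep.sequence] = PeptideForm(
                    sequence=prev.sequence,
                    protein_refs=tuple(sorted(set(refs))),
                    missed_cleavages=min(prev.missed_cleavages, pep.missed_cleavages),
                    mods=prev.mods,
                )
    return [by_seq[s] for s in sorted(by_seq)]


# --- sequons --------------------------------------------------------------

def find_sequons(sequence: str) -> List[int]:
    """1-based positions of N-X-S/T sequons (X != P) within ``sequence``."""
    out = []
    for i in range(len(sequence) - 2):
        if sequence[i] == "N" and sequence[i + 1] != "P" and sequence[i + 2] in "ST":
            out.append(i + 1)
    return out


def peptide_sequons(peptide: str, protein_sequence: str | None = None, start: int = 1) -> List[int]:
    """Sequon positions (1-based, peptide-local) resolving +1/+2 context
    that extends beyond the peptide against the parent protein."""
    if protein_sequence is None:
        return find_sequons(peptide)
    # check the peptide occupies the claimed region
    region = protein_sequence[start - 1 : start - 1 + len(peptide)]
    if region != peptide:
        raise ValueError("peptide does not match protein at claimed start")
    out = []
    for i, aa in enumerate(peptide):
        if aa != "N":
            continue
        p = start - 1 + i  # 0-based protein index
        if p + 2 >= len(protein_sequence):
            continue
        if protein_sequence[p + 1] != "P" and protein_sequence[p + 2] in "ST":
            out.append(i + 1)
    return out


# --- peptide forms --------------------------------------------------------

@dataclass(frozen=True)
class PeptideForm:
    """A peptide sequence plus per-position modification assignments.

    ``mods`` maps 1-based residue position (0 = N-terminus) to a
    Modification. Glyco remnant modifications are only ever assigned to
    sequon asparagines.
    """

    sequence: str
    protein_refs: Tuple[Tuple[str, int], ...] = ()
    missed_cleavages: int = 0
    mods: Tuple[Tuple[int, Modification], ...] = ()

    @property
    def mod_dict(self) -> Dict[int, Modification]:
        return dict(self.mods)

    @property
    def mass(self) -> float:
        return chem.peptide_mass(self.sequence, self.mod_dict)

    def mz(self, charge: int) -> float:
        return chem.peptide_mz(self.mass, charge)

    @property
    def is_decoy(self) -> bool:
        return all(acc.startswith("DECOY_") for acc, _ in self.protein_refs) and bool(
            self.protein_refs
        )

    def remnant_positions(self) -> Dict[int, str]:
        """Map of 1-based peptide positions to remnant class name
        (CF / HexNAc / deamidated) for glyco remnant mods."""
        out = {}
        for pos, mod in self.mods:
            cls = chem.REMNANT_MOD_NAMES.get(mod.name)
            if cls is not None:
                out[pos] = cls
        return out

    def form_id(self) -> str:
        mods = ";".join(f"{p}:{m.name}" for p, m in sorted(self.mods))
        return f"{self.sequence}|{mods}"


def enumerate_modforms(
    peptide: PeptideForm,
    proteins: Mapping[str, ProteinRecord],
    static_mods: Sequence[Modification] = (),
    dynamic_mods: Sequence[Modification] = (),
    max_dynamic: int = 3,
    glyco_mod_names: Sequence[str] = ("hexnac_fuc", "hexnac", "deamidation"),
) -> List[PeptideForm]:
    """All modified forms of a peptide.

    Static mods apply to every matching residue/terminus. Dynamic mods are
    combinatorial up to ``max_dynamic`` per peptide, with the constraint
    that glyco remnant mods (CF, HexNAc, deamidation) target only sequon
    asparagines (resolved against each parent protein's context), at most
    one mod per position.
    """
    seq = peptide.sequence
    static: List[Tuple[int, Modification]] = []
    for mod in static_mods:
        if mod.target == "N-term":
            static.append((0, mod))
        elif mod.target == "C-term":
            static.append((len(seq) + 1, mod))
        else:
            static.extend((i + 1, mod) for i, aa in enumerate(seq) if aa == mod.target)

    # sequon positions valid in at least one parent protein context
    sequon_pos: set[int] = set()
    for acc, start in peptide.protein_refs:
        prot = proteins.get(acc)
        ctx = prot.sequence if prot is not None else None
        sequon_pos.update(peptide_sequons(seq, ctx, start))
    if not peptide.protein_refs:
        sequon_pos.update(find_sequons(seq))

    # candidate (position, mod) slots for dynamic mods
    slots: List[Tuple[int, Modification]] = []
    glyco = set(glyco_mod_names)
    for mod in dynamic_mods:
        if mod.name in glyco:
            slots.extend((p, mod) for p in sorted(sequon_pos))
        elif mod.target == "N-term":
            slots.append((0, mod))
        elif mod.target == "C-term":
            slots.append((len(seq) + 1, mod))
        else:
            slots.extend((i + 1, mod) for i, aa in enumerate(seq) if aa == mod.target)

    forms: List[PeptideForm] = []
    static_positions = {p for p, _ in static}
    for k in range(0, max_dynamic + 1):
        for combo in combinations(slots, k):
            positions = [p for p, _ in combo]
            if len(set(positions)) != len(positions):
                continue
            if any(p in static_positions for p in positions):
                continue
            mods = tuple(sorted(static + list(combo), key=lambda t: (t[0], t[1].name)))
            forms.append(
                PeptideForm(
                    sequence=seq,
                    protein_refs=peptide.protein_refs,
                    missed_cleavages=peptide.missed_cleavages,
                    mods=mods,
                )
            )
    return forms


# --- theoretical fragments ------------------------------------------------

@dataclass(frozen=True)
class TheoreticalFragment:
    series: str  # "b" | "y" | "oxonium" | "precursor-loss"
    index: int
    charge: int
    neutral_loss: str  # "none" | "HexNAc" | "HexNAc-Fuc"
    mz: float


def theoretical_fragments(
    pep: PeptideForm,
    max_charge: int = 2,
    include_oxonium: bool = True,
) -> List[TheoreticalFragment]:
    """b/y fragment ions at charges 1..max_charge, with glyco neutral-loss
    companions for remnant-bearing fragments, plus reference oxonium ions.

    A fragment carrying the CF remnant (+HexNAc-Fuc) gets companions with
    loss of HexNAc and loss of the full HexNAc-Fuc disaccharide; a fragment
    carrying the HexNAc remnant gets a companion with loss of HexNAc.
    """
    seq = pep.sequence
    n = len(seq)
    mods = pep.mod_dict
    hexnac = chem.remnant_delta("HexNAc")
    hexnac_fuc = chem.remnant_delta("HexNAc-Fuc")

    # prefix residue+mod mass sums; mods at position 0 (N-term) count into b ions
    prefix = [0.0] * (n + 1)
    acc = mods[0].delta_mass if 0 in mods else 0.0
    for i, aa in enumerate(seq, start=1):
        acc += chem.AA_MASS[aa] + (mods[i].delta_mass if i in mods else 0.0)
        prefix[i] = acc
    total = prefix[n] + (mods[n + 1].delta_mass if n + 1 in mods else 0.0)

    remnant = pep.remnant_positions()

    frags: List[TheoreticalFragment] = []
    for i in range(1, n):
        b_neutral = prefix[i]  # b ion neutral fragment mass (residues + mods)
        y_neutral = total - prefix[i] + chem.WATER
        b_classes = {remnant[p] for p in remnant if p <= i}
        y_classes = {remnant[p] for p in remnant if p > i}
        for series, neutral, classes, idx in (
            ("b", b_neutral, b_classes, i),
            ("y", y_neutral, y_classes, n - i),
        ):
            losses = [("none", 0.0)]
            if classes:
                losses.append(("HexNAc", hexnac))
                if "CF" in classes:
                    losses.append(("HexNAc-Fuc", hexnac_fuc))
            for z in range(1, max_charge + 1):
                for loss_name, loss in losses:
                    frags.append(
                        TheoreticalFragment(
                            series, idx, z, loss_name,
                            (neutral - loss + z * PROTON_MASS) / z,
                        )
                    )
    if include_oxonium:
        for ion in chem.oxonium_table():
            frags.append(TheoreticalFragment("oxonium", 0, 1, "none", ion.mz))
    return frags


def fragment_mz_arrays(
    pep: PeptideForm, max_charge: int = 2
) -> Tuple["np.ndarray", "np.ndarray"]:
    """Vectorized companion of :func:`theoretical_fragments`: m/z and
    charge arrays of all b/y (and neutral-loss) fragments, without the
    per-fragment descriptors. Used on the hot search path."""
    import numpy as np

    seq = pep.sequence
    n = len(seq)
    mods = pep.mod_dict
    res = np.fromiter((chem.AA_MASS[aa] for aa in seq), dtype=float, count=n)
    for pos, mod in mods.items():
        if 1 <= pos <= n:
            res[pos - 1] += mod.delta_mass
    prefix = np.cumsum(res)
    if 0 in mods:
        prefix += mods[0].delta_mass
    total = prefix[-1] + (mods[n + 1].delta_mass if n + 1 in mods else 0.0)

    b_neutral = prefix[:-1]
    y_neutral = total - prefix[:-1] + chem.WATER

    remnant = pep.remnant_positions()
    neutrals = [b_neutral, y_neutral]
    if remnant:
        hexnac = chem.remnant_delta("HexNAc")
        hexnac_fuc = chem.remnant_delta("HexNAc-Fuc")
        pos = np.array(sorted(remnant), dtype=int)
        cf_pos = np.array([p for p in sorted(remnant) if remnant[p] == "CF"], dtype=int)
        cut = np.arange(1, n)
        b_has = (pos[None, :] <= cut[:, None]).any(axis=1)
        y_has = (pos[None, :] > cut[:, None]).any(axis=1)
        neutrals.append(b_neutral[b_has] - hexnac)
        neutrals.append(y_neutral[y_has] - hexnac)
        if cf_pos.size:
            b_cf = (cf_pos[None, :] <= cut[:, None]).any(axis=1)
            y_cf = (cf_pos[None, :] > cut[:, None]).any(axis=1)
            neutrals.append(b_neutral[b_cf] - hexnac_fuc)
            neutrals.append(y_neutral[y_cf] - hexnac_fuc)
    neutral = np.concatenate(neutrals)
    mz_parts = []
    z_parts = []
    for z in range(1, max_charge + 1):
        mz_parts.append((neutral + z * PROTON_MASS) / z)
        z_parts.append(np.full(neutral.size, z, dtype=np.int8))
    return np.concatenate(mz_parts), np.concatenate(z_parts)
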