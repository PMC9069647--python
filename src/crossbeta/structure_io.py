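"""Reading and writing protein structure coordinate sections.

PDB and mmCIF coordinate sections are parsed with gemmi into a light internal
model that keeps only what the downstream geometry needs: chain identity,
author residue numbering, residue names with one-letter codes, and C-alpha
positions, for every model of a (possibly multi-model NMR) entry.  The
experimental method is classified into NMR / XRAY / OTHER so that count
tables can be partitioned the way structural studies report them.

Alternate locations are resolved to a single conformer (highest occupancy,
ties broken by altloc identifier order).  Residues without a resolved
C-alpha stay in the chain -- they contribute to derived sequences but are
ineligible for geometric segment membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

# Experimental-method classes used to partition count tables.
NMR = "NMR"
XRAY = "XRAY"
OTHER = "OTHER"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed in the declared format."""


@dataclass
class ResidueRecord:
    """One polymer residue: identity, author numbering and C-alpha position."""

    chain_id: str
    author_seq_number: int
    insertion_code: str
    residue_name: str
    one_letter: str
    ca_position: np.ndarray | None

    def has_ca(self) -> bool:
        return self.ca_position is not None


@dataclass
class ChainModel:
    """An ordered (N- to C-terminus) list of residues of one chain."""

    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    @property
    def length(self) -> int:
        """Number of residues with a resolved C-alpha."""
        return sum(1 for r in self.residues if r.has_ca())

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def sequence(self) -> str:
        return derive_sequence(self)


@dataclass
class StructureModel:
    """Parsed coordinate-section content of one entry.

    ``models`` holds one chain list per deposited model; NMR ensembles keep
    every model.  ``seqres`` maps chain id to the SEQRES-declared sequence
    when the source file provides one (PDB format only).
    """

    entry_id: str
    method_class: str
    models: list[list[ChainModel]] = field(default_factory=lambda: [[]])
    raw_method: str | None = None
    seqres: dict[str, str] = field(default_factory=dict)

    def get_chain(self, model_index: int, chain_id: str) -> ChainModel:
        for chain in self.models[model_index]:
            if chain.chain_id == chain_id:
                return chain
        raise KeyError(f"no chain {chain_id!r} in model {model_index}")

    @property
    def n_models(self) -> int:
        return len(self.models)


def classify_method(raw_method_text: str | None) -> str:
    """Map an experimental-method string onto {NMR, XRAY, OTHER}.

    Both solution and solid-state NMR count as NMR; only X-ray diffraction
    counts as XRAY; everything else (EM, neutron, empty/absent) is OTHER.
    """
    text = (raw_method_text or "").upper()
    if "NMR" in text:
        return NMR
    if "X-RAY" in text and "DIFFRACTION" in text:
        return XRAY
    return OTHER


def derive_sequence(chain: ChainModel) -> str:
    """One-letter sequence of a chain in residue order.

    Residues lacking a C-alpha are included: the sequence serves subsequence
    search, which has no geometric prerequisites.
    """
    return "".join(r.one_letter for r in chain.residues)


def _one_letter(residue_name: str, mse_to_met: bool) -> str:
    name = residue_name.upper()
    if name in THREE_TO_ONE:
        return THREE_TO_ONE[name]
    if mse_to_met and name == "MSE":
        return "M"
    return "X"


def _is_polymer_residue(res: gemmi.Residue) -> bool:
    if res.het_flag == "A":
        return True
    info = gemmi.find_tabulated_residue(res.name)
    return info is not None and info.is_amino_acid()


def _pick_ca(res: gemmi.Residue) -> np.ndarray | None:
    candidates = [
        a for a in res
        if a.name == "CA" and a.element.name in ("C", "X", "")
    ]
    if not candidates:
        return None
    # highest occupancy wins; ties broken by altloc identifier order
    best = min(candidates, key=lambda a: (-a.occ, a.altloc))
    return np.array([best.pos.x, best.pos.y, best.pos.z], dtype=float)


def _read_seqres(path: Path) -> dict[str, str]:
    seqres: dict[str, list[str]] = {}
    try:
        text = path.read_text(errors="replace")
    except OSError:
        return {}
    for line in text.splitlines():
        if not line.startswith("SEQRES"):
            continue
        chain_id = line[11:12].strip()
        names = line[19:].split()
        seqres.setdefault(chain_id, []).extend(
            _one_letter(n, mse_to_met=True) for n in names
        )
    return {c: "".join(letters) for c, letters in seqres.items()}


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def parse_structure(
    path: str | Path,
    format: str = "auto",
    mse_to_met: bool = True,
) -> StructureModel:
    """Parse the coordinate section of a PDB or mmCIF file.

    All ATOM records with atom name CA are captured; alternate locations are
    resolved to the highest-occupancy conformer; residues represented only by
    non-polymer HETATM records (waters, ligands) are excluded.  Every model
    of a multi-model file is retained.

    A file with zero parsable polymer residues yields an empty
    :class:`StructureModel` with a warning, not an error.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}")
    if not path.exists():
        raise StructureFormatError(f"file not found: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from None

    info = dict(st.info)
    raw_method = info.get("_exptl.method") or None
    entry_id = (info.get("_entry.id") or "").strip().upper()
    if not entry_id or entry_id in ("XXXX", "MODEL"):
        entry_id = path.stem.upper()

    models: list[list[ChainModel]] = []
    for model in st:
        chains: list[ChainModel] = []
        for gchain in model:
            residues = []
            for res in gchain:
                if not _is_polymer_residue(res):
                    continue
                icode = res.seqid.icode.strip()
                residues.append(ResidueRecord(
                    chain_id=gchain.name,
                    author_seq_number=res.seqid.num,
                    insertion_code=icode,
                    residue_name=res.name,
                    one_letter=_one_letter(res.name, mse_to_met),
                    ca_position=_pick_ca(res),
                ))
            if residues:
                residues.sort(key=lambda r: (r.author_seq_number,
                                             r.insertion_code))
                chains.append(ChainModel(chain_id=gchain.name,
                                         residues=residues))
        models.append(chains)
    if not models:
        models = [[]]
    if all(len(m) == 0 for m in models):
        warnings.warn(f"{path}: no parsable polymer residues", stacklevel=2)
        models = [[]]

    seqres = _read_seqres(path) if st.input_format == gemmi.CoorFormat.Pdb else {}
    return StructureModel(
        entry_id=entry_id,
        method_class=classify_method(raw_method),
        models=models,
        raw_method=raw_method,
        seqres=seqres,
    )


_DEFAULT_METHOD_TEXT = {NMR: "SOLUTION NMR", XRAY: "X-RAY DIFFRACTION"}


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write a structure as fixed-column PDB ATOM records.

    Every residue must carry a C-alpha position (the writer targets the
    C-alpha-only synthetic structures of this package).  Multi-model
    structures get MODEL/ENDMDL blocks; EXPDTA reflects the method class.
    Chain ids that do not fit the single-column PDB field raise instead of
    being silently truncated.
    """
    path = Path(path)
    lines: list[str] = []
    entry_id = structure.entry_id
    id_field = entry_id if len(entry_id) == 4 else "    "
    lines.append(f"HEADER    {'PROTEIN':<40}{'':12}{id_field:>4}")
    method_text = structure.raw_method or _DEFAULT_METHOD_TEXT.get(
        structure.method_class)
    if method_text:
        lines.append(f"EXPDTA    {method_text}")

    multi = structure.n_models > 1
    serial = 0
    for imodel, chains in enumerate(structure.models, start=1):
        if multi:
            lines.append(f"MODEL     {imodel:>4}")
        for chain in chains:
            if len(chain.chain_id) != 1:
                raise ValueError(
                    f"chain id {chain.chain_id!r} does not fit the "
                    "single-character PDB chain field")
            for res in chain.residues:
                if res.ca_position is None:
                    raise ValueError(
                        f"residue {chain.chain_id}{res.author_seq_number} "
                        "has no C-alpha position; cannot write PDB")
                if len(res.residue_name) > 3:
                    raise ValueError(
                        f"residue name {res.residue_name!r} too long")
                x, y, z = res.ca_position
                if not all(-999.999 <= v <= 9999.999 for v in (x, y, z)):
                    raise ValueError("coordinate out of PDB fixed-column range")
                serial += 1
                if serial > 99999:
                    raise ValueError("too many atoms for PDB serial field")
                icode = res.insertion_code or " "
                lines.append(
                    f"ATOM  {serial:>5}  CA  {res.residue_name:>3} "
                    f"{chain.chain_id}{res.author_seq_number:>4}{icode}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"{'':10}{'C':>2}"
                )
            if chain.residues:
                serial += 1
                last = chain.residues[-1]
                lines.append(
                    f"TER   {serial:>5}      {last.residue_name:>3} "
                    f"{chain.chain_id}{last.author_seq_number:>4}"
                )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from None


def export_fasta(
    structures: list[StructureModel] | StructureModel,
    path: str | Path,
    use_seqres: bool = False,
) -> None:
    """Export chain sequences as FASTA with ``>{entry_id}_{chain_id}`` headers.

    By default sequences are derived from the ATOM records of the first
    model; ``use_seqres`` prefers the SEQRES-declared sequence where the
    source file provided one.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if isinstance(structures, StructureModel):
        structures = [structures]
    records = []
    for st in structures:
        chains = st.models[0] if st.models else []
        for chain in chains:
            seq = st.seqres.get(chain.chain_id) if use_seqres else None
            if not seq:
                seq = derive_sequence(chain)
            if not seq:
                continue
            records.append(SeqRecord(Seq(seq),
                                     id=f"{st.entry_id}_{chain.chain_id}",
                                     description=""))
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
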