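"""Structure reading, pLDDT extraction, and domain-to-chain mapping.

CATH domains are substrings of deposited or predicted protein chains.  To
compute a structural-alphabet string for a domain, its amino-acid sequence
is aligned to the chain read from a PDB file, and the structure is trimmed
to the aligned span.  Predicted models (AlphaFold-style) carry per-residue
pLDDT confidence in the B-factor column; the mean over a domain's residues
is the "overall pLDDT" used by the dataset filters.

Coordinates and indices are 0-based and half-open internally; PDB residue
numbering (including insertion codes) is kept only as per-residue metadata
and as the ordering key.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Optional

import gemmi
import numpy as np
from Bio import Align

from .errors import (
    ChainNotFoundError,
    ConfigurationError,
    IntegrityError,
    MappingFailureError,
    StructureParseError,
)

__all__ = [
    "Residue",
    "StructureModel",
    "AlignmentMapping",
    "read_structure",
    "write_structure",
    "extract_mean_plddt",
    "map_domain_to_chain",
    "trim_to_domain",
]


@dataclass(frozen=True)
class Residue:
    """One residue with its Cα position.

    ``seqid``/``icode`` reproduce the PDB numbering; together they form the
    ordering key. ``aa_code`` is the one-letter amino-acid code, 'X' when
    the residue name is not a standard amino acid.
    """

    seqid: int
    icode: str
    aa_code: str
    ca: tuple[float, float, float]
    bfactor: float

    @property
    def order_key(self) -> tuple[int, str]:
        return (self.seqid, self.icode)


@dataclass(frozen=True)
class StructureModel:
    """An ordered single-chain Cα trace.

    ``source_kind`` distinguishes experimental structures from predicted
    models; only the latter carry pLDDT in the B-factor column.
    """

    structure_id: str
    chain_id: str
    residues: tuple[Residue, ...]
    source_kind: str = "experimental"  # or "predicted"

    def __post_init__(self):
        if self.source_kind not in ("experimental", "predicted"):
            raise IntegrityError(
                f"source_kind must be 'experimental' or 'predicted', "
                f"got {self.source_kind!r}")
        keys = [r.order_key for r in self.residues]
        if any(a >= b for a, b in zip(keys, keys[1:])):
            raise IntegrityError(
                f"residues of {self.structure_id}/{self.chain_id} are not "
                "strictly ordered by (seqid, insertion code)")
        for r in self.residues:
            if not all(np.isfinite(r.ca)):
                raise IntegrityError(
                    f"non-finite Cα coordinates at residue {r.order_key}")
            if self.source_kind == "predicted" and not 0.0 <= r.bfactor <= 100.0:
                raise IntegrityError(
                    f"pLDDT {r.bfactor} outside [0, 100] at residue "
                    f"{r.order_key} of predicted model {self.structure_id}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa_code for r in self.residues)

    def ca_coordinates(self) -> np.ndarray:
        """(L, 3) array of Cα positions in Å."""
        return np.array([r.ca for r in self.residues], dtype=float)

    def bfactors(self) -> np.ndarray:
        return np.array([r.bfactor for r in self.residues], dtype=float)


@dataclass(frozen=True)
class AlignmentMapping:
    """Result of aligning a domain sequence onto a chain.

    ``chain_positions`` has one entry per domain position: a 0-based index
    into ``StructureModel.residues`` or ``None`` for an unaligned (gap)
    position. Non-gap entries are strictly increasing.
    """

    domain_id: str
    chain_positions: tuple[Optional[int], ...]
    coverage: float
    identity: float

    def __post_init__(self):
        nongap = [p for p in self.chain_positions if p is not None]
        if any(a >= b for a, b in zip(nongap, nongap[1:])):
            raise IntegrityError("non-gap chain positions must be strictly "
                                 f"increasing for domain {self.domain_id!r}")
        n = len(self.chain_positions)
        if n and abs(self.coverage * n - len(nongap)) > 1e-9:
            raise IntegrityError(
                f"coverage {self.coverage} inconsistent with "
                f"{len(nongap)}/{n} matched positions")

    @property
    def matched_positions(self) -> tuple[int, ...]:
        return tuple(p for p in self.chain_positions if p is not None)


def read_structure(path: str | os.PathLike, chain_id: str,
                   source_kind: str = "experimental") -> StructureModel:
    """Read one chain of a PDB file as a Cα trace.

    One residue entry is kept per residue having a Cα atom, in file order.
    The B-factor is taken from the Cα record; for the first altloc when
    several are present. HETATM residues (ligands, waters) are skipped.

    Raises :class:`StructureParseError` if the file is missing and
    :class:`ChainNotFoundError` if the chain has no Cα atoms.
    """
    if not os.path.exists(path):
        raise StructureParseError(f"structure file not found: {path}")
    st = gemmi.read_structure(os.fspath(path))
    st.setup_entities()
    if len(st) == 0:
        raise StructureParseError(f"no models in {path}")
    model = st[0]  # first MODEL only; NMR ensembles collapse to model 1
    residues = []
    for chain in model:
        if chain.name != chain_id:
            continue
        for res in chain:
            if res.het_flag == "H":
                continue
            ca = None
            for atom in res:
                if atom.name == "CA":
                    ca = atom
                    break
            if ca is None:
                continue
            info = gemmi.find_tabulated_residue(res.name)
            if info is not None and info.is_amino_acid():
                one = info.one_letter_code.upper()
            else:
                one = "X"
            residues.append(Residue(
                seqid=res.seqid.num,
                icode=res.seqid.icode.strip() or "",
                aa_code=one if one.isalpha() else "X",
                ca=(ca.pos.x, ca.pos.y, ca.pos.z),
                bfactor=ca.b_iso,
            ))
    if not residues:
        raise ChainNotFoundError(
            f"chain {chain_id!r} with Cα atoms not found in {path}")
    return StructureModel(
        structure_id=st.name or os.path.splitext(os.path.basename(path))[0],
        chain_id=chain_id,
        residues=tuple(residues),
        source_kind=source_kind,
    )


def write_structure(model: StructureModel, path: str | os.PathLike) -> None:
    """Write the Cα trace back out as a minimal PDB file.

    Used to hand trimmed structures to an external structural-alphabet
    encoder and to materialize synthetic fixtures.
    """
    st = gemmi.Structure()
    st.name = model.structure_id
    gm = gemmi.Model("1")
    chain = gemmi.Chain(model.chain_id)
    three = {v: k for k, v in _ONE_FROM_THREE.items()}
    for r in model.residues:
        res = gemmi.Residue()
        res.name = three.get(r.aa_code, "UNK")
        res.seqid = gemmi.SeqId(r.seqid, r.icode or " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*r.ca)
        atom.occ = 1.0
        atom.b_iso = r.bfactor
        res.add_atom(atom)
        chain.add_residue(res)
    gm.add_chain(chain)
    st.add_model(gm)
    st.write_pdb(os.fspath(path))


_ONE_FROM_THREE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def extract_mean_plddt(model: StructureModel,
                       mapping: Optional[AlignmentMapping] = None) -> float:
    """Mean pLDDT over the mapped residues (all residues if no mapping).

    Defined only for predicted models: experimental B-factors measure
    thermal displacement, not confidence, and mixing the two semantics in
    the pLDDT filter would be silent nonsense, so this raises instead.
    """
    if model.source_kind != "predicted":
        raise ConfigurationError(
            "pLDDT undefined for experimental structures: B-factors of "
            "experimental models are not confidence scores")
    b = model.bfactors()
    if mapping is not None:
        idx = list(mapping.matched_positions)
        if not idx:
            raise IntegrityError("mapping has no matched positions")
        if max(idx) >= len(b):
            raise IntegrityError("mapping indices exceed model length")
        b = b[idx]
    return float(np.mean(b))


def _make_aligner(match: float = 1.0, mismatch: float = -1.0,
                  gap_open: float = -5.0, gap_extend: float = -0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def map_domain_to_chain(domain_seq: str, model: StructureModel,
                        min_coverage: float = 0.9,
                        min_identity: float = 1.0,
                        domain_id: str = "") -> AlignmentMapping:
    """Align a domain sequence onto the chain and report the mapping.

    Local alignment with affine gaps (match 1, mismatch −1, open −5,
    extend −0.5): domains are substrings of chains, and local mode avoids
    penalizing chain overhangs.  The mapping is accepted only when
    coverage ≥ ``min_coverage`` and identity (over matched positions)
    ≥ ``min_identity``; otherwise :class:`MappingFailureError` carries the
    achieved values — this is how a domain becomes structure-unavailable.
    """
    if not domain_seq:
        raise IntegrityError("empty domain sequence")
    if len(model) == 0:
        raise IntegrityError("empty structure model")
    chain_seq = model.sequence
    aligner = _make_aligner()
    alignments = aligner.align(chain_seq, domain_seq)
    try:
        best = alignments[0]
    except IndexError:
        best = None
    positions: list[Optional[int]] = [None] * len(domain_seq)
    n_match = 0
    n_ident = 0
    if best is not None:
        target_blocks, query_blocks = best.aligned
        for (t0, t1), (q0, q1) in zip(target_blocks, query_blocks):
            for t, q in zip(range(t0, t1), range(q0, q1)):
                positions[q] = t
                n_match += 1
                if chain_seq[t] == domain_seq[q]:
                    n_ident += 1
    coverage = n_match / len(domain_seq)
    identity = (n_ident / n_match) if n_match else 0.0
    if coverage < min_coverage or identity < min_identity:
        raise MappingFailureError(domain_id or domain_seq[:8], coverage,
                                  identity, min_coverage, min_identity)
    return AlignmentMapping(
        domain_id=domain_id or domain_seq[:8],
        chain_positions=tuple(positions),
        coverage=coverage,
        identity=identity,
    )


def trim_to_domain(model: StructureModel,
                   mapping: AlignmentMapping) -> StructureModel:
    """Keep only the residues the domain mapped onto, original order.

    The trimmed model is what gets handed to the structural-alphabet
    encoder: its length equals coverage × domain length.
    """
    idx = mapping.matched_positions
    if idx and max(idx) >= len(model):
        raise IntegrityError(
            f"mapping for {mapping.domain_id!r} indexes residue {max(idx)} "
            f"but model has {len(model)} residues")
    return replace(model, residues=tuple(model.residues[i] for i in idx))
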