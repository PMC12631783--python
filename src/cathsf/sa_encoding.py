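"""Structural-alphabet (3Di-style) encoding of trimmed structures.

A structural alphabet discretizes 3D conformation into a 20-letter string,
one letter per residue, so structure can be processed as a 1D sequence.
The alphabet used here follows the tertiary-interaction idea: each
residue's letter describes its geometric relation to its spatially
nearest residue rather than the local backbone.

The production encoder (Foldseek's 3Di) is an external tool and is
reached through the :class:`SAEncoder` adapter contract; this module ships
a deterministic mock geometric encoder with the same interface so the
whole pipeline is testable without external binaries.  The mock imitates
the *structure* of the 3Di assignment (nearest tertiary neighbour →
letter), not its numeric states.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from typing import Iterable, Protocol, runtime_checkable

import numpy as np

from .errors import EncoderUnavailableError, IntegrityError
from .structure_io import StructureModel, write_structure

SA_ALPHABET = "ABCDEFGHIJKLMNOPQRST"  # 20 structural states, A–T

__all__ = [
    "SA_ALPHABET",
    "SAString",
    "SAEncoder",
    "MockGeometricEncoder",
    "FoldseekEncoder",
    "encode_sa",
    "write_sa_fasta",
    "read_sa_fasta",
]


@dataclass(frozen=True)
class SAString:
    """A structural-alphabet string for one domain.

    ``letters`` has exactly one character per residue of the encoded
    structure, every character drawn from :data:`SA_ALPHABET`.
    ``encoder_id`` records provenance (which encoder produced it).
    """

    domain_id: str
    letters: str
    encoder_id: str

    def __post_init__(self):
        bad = set(self.letters) - set(SA_ALPHABET)
        if bad:
            raise IntegrityError(
                f"SA string for {self.domain_id!r} contains letters outside "
                f"the 20-state alphabet: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.letters)


@runtime_checkable
class SAEncoder(Protocol):
    """Adapter contract: turn a Cα model into one letter per residue."""

    encoder_id: str

    def encode(self, model: StructureModel) -> str: ...


class MockGeometricEncoder:
    """Deterministic stand-in encoder based on nearest-neighbour distance.

    For residue *i*, find the spatially nearest Cα *j* with ``|i − j| > 1``
    (sequence-adjacent residues are excluded — the alphabet describes
    tertiary contact, not the backbone).  The letter index is::

        clamp(floor((d_ij − 3.0 Å) / 0.5 Å), 0, 19)

    so contacts at ≤ 3 Å map to 'A' and ≥ 12.5 Å to 'T'.  Residues with no
    eligible neighbour (possible only at L ≤ 2 spans) get 'A'.
    """

    encoder_id = "mock-geometric-v1"

    #: distance at/below which the first letter is assigned, in Å
    d0 = 3.0
    #: bin width in Å
    bin_width = 0.5

    def encode(self, model: StructureModel) -> str:
        if len(model) < 3:
            raise IntegrityError(
                f"mock encoder needs >= 3 residues, got {len(model)}")
        coords = model.ca_coordinates()
        n = len(coords)
        dists = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        letters = []
        for i in range(n):
            eligible = [j for j in range(n) if abs(i - j) > 1]
            if not eligible:
                letters.append(SA_ALPHABET[0])
                continue
            d = min(dists[i, j] for j in eligible)
            idx = int(np.floor((d - self.d0) / self.bin_width))
            idx = min(max(idx, 0), 19)
            letters.append(SA_ALPHABET[idx])
        return "".join(letters)


class FoldseekEncoder:
    """Adapter for an external 3Di encoder binary.

    Writes the model to a temporary PDB file and expects the tool to print
    a FASTA of 3Di letters.  Raises :class:`EncoderUnavailableError` when
    the binary is absent, so configuration problems are distinguishable
    from data problems.
    """

    def __init__(self, binary: str = "foldseek"):
        self.binary = binary
        self.encoder_id = f"external-3di:{binary}"

    def encode(self, model: StructureModel) -> str:
        if shutil.which(self.binary) is None:
            raise EncoderUnavailableError(
                f"external 3Di encoder {self.binary!r} not on PATH")
        with tempfile.TemporaryDirectory() as tmp:
            pdb = f"{tmp}/{model.structure_id}.pdb"
            write_structure(model, pdb)
            out = subprocess.run(
                [self.binary, "structureto3didescriptor", pdb, f"{tmp}/out"],
                capture_output=True, text=True)
            if out.returncode != 0:
                raise EncoderUnavailableError(
                    f"3Di encoder failed: {out.stderr.strip()}")
            with open(f"{tmp}/out") as fh:
                fields = fh.readline().rstrip("\n").split("\t")
        letters = fields[2].upper() if len(fields) > 2 else ""
        if len(letters) != len(model):
            raise IntegrityError(
                f"encoder returned {len(letters)} letters for "
                f"{len(model)} residues")
        return letters


def encode_sa(model: StructureModel, encoder: SAEncoder,
              domain_id: str | None = None) -> SAString:
    """Encode a (trimmed) structure into a structural-alphabet string.

    One letter per residue; deterministic for a fixed encoder and input.
    """
    if len(model) < 2:
        raise IntegrityError(
            f"cannot encode a structure with {len(model)} residue(s)")
    letters = encoder.encode(model).upper()
    if len(letters) != len(model):
        raise IntegrityError(
            f"encoder {encoder.encoder_id!r} returned {len(letters)} "
            f"letters for {len(model)} residues")
    return SAString(domain_id=domain_id or model.structure_id,
                    letters=letters, encoder_id=encoder.encoder_id)


def write_sa_fasta(strings: Iterable[SAString], path: str) -> None:
    """Cache SA strings as FASTA (header = domain id) for SA-aware embedders."""
    with open(path, "w") as fh:
        for s in strings:
            fh.write(f">{s.domain_id}\n{s.letters}\n")


def read_sa_fasta(path: str, encoder_id: str = "cached") -> list[SAString]:
    """Read SA strings from FASTA; lowercase letters are normalized."""
    out: list[SAString] = []
    with open(path) as fh:
        name, seq = None, []
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    out.append(SAString(name, "".join(seq).upper(), encoder_id))
                name, seq = line[1:].split()[0], []
            elif line:
                seq.append(line)
        if name is not None:
            out.append(SAString(name, "".join(seq).upper(), encoder_id))
    return out
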