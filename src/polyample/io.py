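"""Readers and writers for the package's plain-text formats.

Charge sequences use a FASTA-like text format: a header line
``>id N=.. f=.. lambda=.. seed=..`` followed by the charge string over
``{+, -, 0}`` wrapped at 60 characters per line.  The writer/reader pair
round-trips bit-exactly.  Protein FASTA files can be mapped to charge
sequences (K, R -> +1; D, E -> -1; H configurable).  Trajectories are written
as XYZ (and optionally PDB with charges in the B-factor column).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
from Bio import SeqIO

from .sequence_model import ChargeSequence, MarkovSequenceSpec

__all__ = [
    "write_sequences",
    "read_sequences",
    "protein_to_charges",
    "read_protein_fasta",
    "write_xyz",
    "read_xyz",
    "write_pdb",
]

_CHARGE_TO_CHAR = {1: "+", -1: "-", 0: "0"}
_CHAR_TO_CHARGE = {v: k for k, v in _CHARGE_TO_CHAR.items()}
_LINE_WIDTH = 60


def _format_float(x: float) -> str:
    return repr(float(x))


def write_sequences(path: Union[str, Path],
                    seqs: Iterable[ChargeSequence],
                    ids: Optional[Iterable[str]] = None) -> None:
    """Write charge sequences in the FASTA-like text format."""
    seqs = list(seqs)
    if ids is None:
        ids = [f"seq{i}" for i in range(len(seqs))]
    with open(path, "w") as fh:
        for name, seq in zip(ids, seqs):
            header = f">{name}"
            if seq.spec is not None:
                s = seq.spec
                header += (f" N={s.N} f={_format_float(s.f)}"
                           f" lambda={_format_float(s.lam)} seed={s.seed}")
            fh.write(header + "\n")
            body = "".join(_CHARGE_TO_CHAR[int(c)] for c in seq.charges)
            for i in range(0, len(body), _LINE_WIDTH):
                fh.write(body[i:i + _LINE_WIDTH] + "\n")


def read_sequences(path: Union[str, Path]) -> list[ChargeSequence]:
    """Read charge sequences written by :func:`write_sequences`."""
    out: list[ChargeSequence] = []
    header: Optional[str] = None
    body: list[str] = []

    def flush() -> None:
        if header is None:
            return
        charges = np.array([_CHAR_TO_CHARGE[c] for c in "".join(body)],
                           dtype=np.int8)
        fields = dict(
            tok.split("=", 1) for tok in header.split()[1:] if "=" in tok)
        spec = None
        if {"N", "f", "lambda", "seed"} <= fields.keys():
            spec = MarkovSequenceSpec(
                N=int(fields["N"]), f=float(fields["f"]),
                lam=float(fields["lambda"]), seed=int(fields["seed"]))
        out.append(ChargeSequence(charges=charges, spec=spec))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header, body = line, []
            else:
                body.append(line)
    flush()
    return out


def protein_to_charges(residues: str, *, his_charge: int = 0) -> np.ndarray:
    """Map a protein sequence to per-residue charges.

    Lysine and arginine map to +1, aspartate and glutamate to -1, everything
    else to 0; histidine's charge is configurable (0 by default, +1 to treat
    it as protonated).
    """
    table = {"K": 1, "R": 1, "D": -1, "E": -1, "H": his_charge}
    return np.array([table.get(r.upper(), 0) for r in residues], dtype=np.int8)


def read_protein_fasta(path: Union[str, Path], *,
                       his_charge: int = 0) -> list[ChargeSequence]:
    """Read a protein FASTA file as charge sequences (via Bio.SeqIO)."""
    return [
        ChargeSequence(charges=protein_to_charges(str(rec.seq),
                                                  his_charge=his_charge))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_xyz(path: Union[str, Path], frames: np.ndarray,
              charges: Optional[np.ndarray] = None,
              comment: str = "") -> None:
    """Write one or more frames in XYZ format.

    The element column encodes the charge (P for +1, M for -1, C for 0) so
    that standard viewers can color the chain.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    if charges is None:
        charges = np.zeros(n, dtype=int)
    sym = {1: "P", -1: "M", 0: "C"}
    with open(path, "w") as fh:
        for k, frame in enumerate(frames):
            fh.write(f"{n}\n{comment} frame={k}\n")
            for q, (x, y, z) in zip(charges, frame):
                fh.write(f"{sym[int(q)]} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: Union[str, Path]) -> tuple[np.ndarray, np.ndarray]:
    """Read an XYZ file written by :func:`write_xyz`.

    Returns ``(frames, charges)`` with frames shaped (n_frames, N, 3).
    """
    sym_to_q = {"P": 1, "M": -1, "C": 0}
    frames, charges = [], None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2:i + 2 + n]
        coords, qs = [], []
        for ln in block:
            parts = ln.split()
            qs.append(sym_to_q.get(parts[0], 0))
            coords.append([float(p) for p in parts[1:4]])
        frames.append(coords)
        charges = np.array(qs, dtype=np.int8)
        i += 2 + n
    return np.asarray(frames, dtype=float), charges


def write_pdb(path: Union[str, Path], frame: np.ndarray,
              charges: Optional[np.ndarray] = None) -> None:
    """Write a single frame as PDB; monomer charges go in the B-factor column."""
    frame = np.asarray(frame, dtype=float)
    n = len(frame)
    if charges is None:
        charges = np.zeros(n, dtype=int)
    with open(path, "w") as fh:
        for i, ((x, y, z), q) in enumerate(zip(frame, charges), start=1):
            fh.write(
                f"ATOM  {i:5d}  CA  GLY A{i % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{float(q):6.2f}"
                f"           C\n")
        for i in range(1, n):
            fh.write(f"CONECT{i:5d}{i + 1:5d}\n")
        fh.write("END\n")
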