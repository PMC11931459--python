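"""Reading AlphaFold-Multimer prediction bundles.

A "bundle" is a directory holding, per neural-network model, one two-chain
coordinate file (PDB or mmCIF, ColabFold-style) and one companion JSON score
file with the per-residue pLDDT array, the full PAE matrix and (usually)
pTM/ipTM.  This module establishes the residue-indexing contract shared by
every downstream module: residues are keyed by ``(chain_id, author seq
number)`` and the concatenated 0-based PAE index runs chain 1 then chain 2 in
file order, matching the row order the predictor emits.

pLDDT is read from the B-factor column by default (the ColabFold convention)
and can instead be taken from the score file.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

from .errors import (
    ConsistencyError,
    EmptySetError,
    FormatError,
    LookupError_,
    StructureShapeError,
)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "ModelPrediction",
    "PredictionSet",
    "read_structure_file",
    "read_confidence_file",
    "load_prediction_set",
    "pae_index",
]

DEFAULT_LENGTH_CAP = 3600

# filename pattern used by ColabFold outputs and by our fixture generator
MODEL_NUMBER_RE = re.compile(r"model[_\-.]?(\d+)")


@dataclass(frozen=True)
class AtomRecord:
    atom_name: str
    element: str
    coords: np.ndarray  # (3,) in Angstrom
    is_heavy: bool

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"bad coordinates for atom {self.atom_name}: {self.coords}")
        object.__setattr__(self, "coords", c)
        if self.is_heavy != (self.element.upper() not in ("H", "D")):
            raise ValueError(f"is_heavy inconsistent with element {self.element!r}")


@dataclass
class ResidueRecord:
    chain_id: str
    seq_index: int  # author numbering, 1-based within chain
    aa_code: str  # one-letter code
    atoms: list[AtomRecord]
    plddt: float

    def __post_init__(self):
        if not any(a.is_heavy for a in self.atoms):
            raise ValueError(
                f"residue {self.chain_id}{self.seq_index} has no heavy atom"
            )
        if not (0.0 <= self.plddt <= 100.0):
            raise ValueError(f"pLDDT {self.plddt} outside [0, 100]")

    @property
    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None


@dataclass
class ModelPrediction:
    """One AF-M model's prediction for a two-chain pair."""

    model_id: int
    chains: tuple[list[ResidueRecord], list[ResidueRecord]]
    pae: np.ndarray  # (n, n), Angstrom, 0-30
    iptm: Optional[float] = None
    ptm: Optional[float] = None

    def __post_init__(self):
        n = self.n_residues
        if self.pae is not None:
            self.pae = np.asarray(self.pae, dtype=float)
            if self.pae.shape != (n, n):
                raise ConsistencyError(
                    f"PAE shape {self.pae.shape} does not match {n} residues"
                )
            if self.pae.min() < 0 or self.pae.max() > 30:
                raise ConsistencyError("PAE values outside [0, 30]")

    @property
    def n_residues(self) -> int:
        return len(self.chains[0]) + len(self.chains[1])

    @property
    def chain_ids(self) -> tuple[str, str]:
        return (self.chains[0][0].chain_id, self.chains[1][0].chain_id)

    def residues(self) -> Iterable[ResidueRecord]:
        yield from self.chains[0]
        yield from self.chains[1]

    def sequences(self) -> tuple[str, str]:
        return tuple("".join(r.aa_code for r in ch) for ch in self.chains)


@dataclass
class PredictionSet:
    """All models predicted for one protein pair (1-5 of them)."""

    pair_id: tuple[str, str]
    models: list[ModelPrediction]
    length_cap: Optional[int] = DEFAULT_LENGTH_CAP
    source_dir: Optional[Path] = None

    def __post_init__(self):
        self.pair_id = tuple(sorted(self.pair_id))
        if not 1 <= len(self.models) <= 5:
            raise ConsistencyError(f"expected 1-5 models, got {len(self.models)}")
        seqs = {m.sequences() for m in self.models}
        if len(seqs) != 1:
            raise ConsistencyError("models disagree on chain sequences")
        if self.length_cap is not None and self.total_length > self.length_cap:
            raise ConsistencyError(
                f"total length {self.total_length} exceeds cap {self.length_cap}"
            )

    @property
    def total_length(self) -> int:
        return self.models[0].n_residues


def _one_letter(name: str) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        return info.one_letter_code.upper()
    return "X"


def read_structure_file(path, plddt_source: str = "bfactor_column"):
    """Parse a two-chain PDB/mmCIF file into two lists of :class:`ResidueRecord`.

    ``plddt_source='bfactor_column'`` fills per-residue pLDDT from the
    B-factor of the CA atom (first atom when CA is absent);
    ``'companion_file'`` leaves pLDDT at 0 for later override from the score
    file.  Hydrogens are retained but flagged ``is_heavy=False``.
    """
    path = Path(path)
    if plddt_source not in ("bfactor_column", "companion_file"):
        raise ValueError(f"unknown plddt_source {plddt_source!r}")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError on garbage
        raise FormatError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no models in structure file {path}")
    st.remove_ligands_and_waters()
    model = st[0]
    chains = [ch for ch in model if len(ch) > 0]
    if len(chains) != 2:
        raise StructureShapeError(
            f"{path} has {len(chains)} non-empty chains, expected exactly 2"
        )
    out: list[list[ResidueRecord]] = []
    for ch in chains:
        residues = []
        for res in ch:
            if res.seqid.icode not in (" ", "", "\x00"):
                raise FormatError(
                    f"insertion code {res.seqid.icode!r} at {ch.name}{res.seqid.num}: "
                    "predictor output never numbers residues with insertion codes"
                )
            atoms = [
                AtomRecord(
                    atom_name=a.name,
                    element=a.element.name,
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    is_heavy=a.element.name.upper() not in ("H", "D"),
                )
                for a in res
            ]
            if plddt_source == "bfactor_column":
                ca = res.find_atom("CA", "*")
                plddt = float(ca.b_iso if ca is not None else res[0].b_iso)
            else:
                plddt = 0.0
            residues.append(
                ResidueRecord(
                    chain_id=ch.name,
                    seq_index=res.seqid.num,
                    aa_code=_one_letter(res.name),
                    atoms=atoms,
                    plddt=plddt,
                )
            )
        out.append(residues)
    return out


def _coerce_pae(raw, n_residues: int) -> np.ndarray:
    """Accept nested-list and flattened PAE dialects."""
    arr = np.asarray(raw, dtype=float)
    if arr.ndim == 1:
        if arr.size != n_residues * n_residues:
            raise ConsistencyError(
                f"flat PAE of size {arr.size} does not square to {n_residues} residues"
            )
        arr = arr.reshape(n_residues, n_residues)
    if arr.shape != (n_residues, n_residues):
        raise ConsistencyError(
            f"PAE shape {arr.shape} inconsistent with {n_residues} residues"
        )
    return arr


def read_confidence_file(path, n_residues: int):
    """Read a ColabFold-dialect JSON score file.

    Returns ``(pae, plddt, iptm, ptm)``; iptm/ptm are ``None`` when the file
    does not carry them (never coerced to 0).
    """
    path = Path(path)
    try:
        with open(path) as fh:
            data = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read score file {path}: {exc}") from exc
    raw_pae = data.get("pae", data.get("predicted_aligned_error"))
    if raw_pae is None:
        raise FormatError(f"score file {path} lacks a PAE matrix")
    pae = _coerce_pae(raw_pae, n_residues)
    plddt = data.get("plddt")
    if plddt is not None:
        plddt = np.asarray(plddt, dtype=float)
        if plddt.shape != (n_residues,):
            raise ConsistencyError(
                f"pLDDT length {plddt.size} inconsistent with {n_residues} residues"
            )
    iptm = data.get("iptm")
    ptm = data.get("ptm")
    return pae, plddt, None if iptm is None else float(iptm), None if ptm is None else float(ptm)


def _discover_bundles(directory: Path, structure_glob: Sequence[str], score_glob: str):
    structures: dict[int, Path] = {}
    scores: dict[int, Path] = {}
    for pattern, target in [(g, structures) for g in structure_glob] + [
        (score_glob, scores)
    ]:
        for f in sorted(directory.glob(pattern)):
            m = MODEL_NUMBER_RE.search(f.name)
            if m:
                target.setdefault(int(m.group(1)), f)
    return {k: (structures[k], scores[k]) for k in sorted(structures) if k in scores}


def load_prediction_set(
    directory,
    pair_id: tuple[str, str],
    regimen: Optional[int] = None,
    seed: Optional[int] = None,
    plddt_source: str = "bfactor_column",
    length_cap: Optional[int] = DEFAULT_LENGTH_CAP,
    structure_glob: Sequence[str] = ("*.pdb", "*.cif"),
    score_glob: str = "*.json",
) -> PredictionSet:
    """Load all matched structure/score bundles for one pair from a directory.

    Models are matched to score files by the model number parsed from the
    filenames.  When more models exist than the requested ``regimen`` size
    (the screening protocol folds each pair in three of the five models),
    a reproducible random subset of ``regimen`` models is drawn with ``seed``.
    """
    directory = Path(directory)
    bundles = _discover_bundles(directory, structure_glob, score_glob)
    if not bundles:
        raise EmptySetError(f"no matched structure/score file pairs in {directory}")
    model_ids = sorted(bundles)
    if regimen is not None and len(model_ids) > regimen:
        rng = random.Random(seed)
        model_ids = sorted(rng.sample(model_ids, regimen))
    models = []
    for mid in model_ids:
        struct_path, score_path = bundles[mid]
        chains = read_structure_file(struct_path, plddt_source=plddt_source)
        n = sum(len(c) for c in chains)
        pae, plddt, iptm, ptm = read_confidence_file(score_path, n)
        if plddt_source == "companion_file":
            if plddt is None:
                raise ConsistencyError(f"{score_path} lacks plddt but was requested as source")
            flat = list(plddt)
            k = 0
            for ch in chains:
                for r in ch:
                    r.plddt = float(flat[k])
                    k += 1
        models.append(
            ModelPrediction(model_id=mid, chains=tuple(chains), pae=pae, iptm=iptm, ptm=ptm)
        )
    return PredictionSet(
        pair_id=tuple(pair_id), models=models, length_cap=length_cap, source_dir=directory
    )


def pae_index(model: ModelPrediction, chain_id: str, seq_index: int) -> int:
    """0-based offset of a residue in the concatenated (chain1 then chain2) order."""
    offset = 0
    for ch in model.chains:
        if ch and ch[0].chain_id == chain_id:
            for i, r in enumerate(ch):
                if r.seq_index == seq_index:
                    return offset + i
            break
        offset += len(ch)
    raise LookupError_(f"no residue {chain_id}/{seq_index} in model {model.model_id}")
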