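"""Synthetic prediction bundles, annotation stores and labeled datasets.

These generators produce every input the pipeline consumes, in the same
formats it reads from real predictor output, with planted ground truth:

* :func:`make_prediction_set` writes per-model PDB coordinate files and
  ColabFold-dialect JSON score files for a two-chain pair, with planted
  interfacial contacts at controlled minimum heavy-atom distances, optional
  clash pairs, per-residue pLDDT and per-pair directional PAE assignments,
  plus a ground-truth manifest of the expected valid contacts per model.
* :func:`make_classifier_dataset` draws a labeled feature table with a known
  informative-feature subset at a controlled effect size (class separation),
  pure-noise features, and missingness.
* :func:`make_annotation_store` builds an annotation store with full-length
  vectors (1,095 / 1,243 / 10 / 1,024) in which planted pairs carry
  correlated gene-effect vectors, overlapping CRISPR hit sets, matched
  localization, similar embeddings, mutual top-coexpression entries, and a
  nonzero BioGRID count; all other proteins are independent.

Residues are simplified constructs — backbone N/CA/C/O in a plane, plus a
charged-tip side-chain atom for D/E/K/R — which is sufficient for every
geometric rule under test (distance, clash, salt bridge, hydrogen bond).
Chains are laid out on widely spaced lines so the only cross-chain proximity
is the planted one: translating a residue template by (0, d, 0) makes d the
exact minimum heavy-atom distance, because all template atoms share y = 0.
PAE matrices are block-constant (background value) with per-pair directional
overrides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

from .pair_features import AnnotationStore, EXPECTED_LENGTHS

__all__ = [
    "PlantedContact",
    "PairFixtureSpec",
    "ClassifierSimSpec",
    "make_prediction_set",
    "make_classifier_dataset",
    "make_annotation_store",
]

# planar residue templates: (atom name, element, x, z); y == 0 everywhere so a
# (0, d, 0) translation realises an exact minimum inter-residue distance d
_BACKBONE = [("N", "N", -1.2, 0.0), ("CA", "C", 0.0, 0.0), ("C", "C", 1.2, 0.0), ("O", "O", 2.2, 0.0)]
_TIP_ATOMS = {"D": ("OD1", "O"), "E": ("OE1", "O"), "K": ("NZ", "N"), "R": ("NH1", "N")}


def _residue_atoms(aa: str, origin: np.ndarray):
    atoms = [(n, el, origin + np.array([x, 0.0, z])) for n, el, x, z in _BACKBONE]
    if aa in _TIP_ATOMS:
        name, el = _TIP_ATOMS[aa]
        atoms.append((name, el, origin + np.array([0.0, 0.0, 1.5])))
    return atoms


@dataclass
class PlantedContact:
    res_a: int  # 1-based index in chain 1
    res_b: int  # 1-based index in chain 2
    distance: float  # target minimum heavy-atom distance, Angstrom
    models: Optional[Sequence[int]] = None  # model ids where present (None = all)
    pae_ab: Optional[float] = None
    pae_ba: Optional[float] = None


@dataclass
class PairFixtureSpec:
    len_a: int = 10
    len_b: int = 12
    seq_a: Optional[str] = None  # defaults to poly-A with D/K sprinkled
    seq_b: Optional[str] = None
    contacts: list[PlantedContact] = field(default_factory=list)
    model_ids: Sequence[int] = (1, 2, 4)
    plddt_default: float = 90.0
    plddt_overrides: dict = field(default_factory=dict)  # (chain#1-based res) -> value
    pae_background: float = 25.0
    pae_interface: float = 8.0  # default for planted pairs without overrides
    iptm: float = 0.8
    ptm: float = 0.7
    spacing: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if self.seq_a is None:
            self.seq_a = _default_seq(self.len_a)
        if self.seq_b is None:
            self.seq_b = _default_seq(self.len_b)
        self.len_a, self.len_b = len(self.seq_a), len(self.seq_b)
        used_a, used_b = set(), set()
        for c in self.contacts:
            if not (1 <= c.res_a <= self.len_a and 1 <= c.res_b <= self.len_b):
                raise ValueError(f"planted contact {c} outside chain bounds")
            if c.distance <= 0:
                raise ValueError("planted distance must be positive")
            if c.res_a in used_a or c.res_b in used_b:
                raise ValueError("planted contacts must use distinct residues per chain")
            used_a.add(c.res_a)
            used_b.add(c.res_b)


def _default_seq(n: int) -> str:
    # alternate a few charged residues through poly-alanine
    pattern = "ADKA"
    return "".join(pattern[i % len(pattern)] for i in range(n))


def _chain_origin(chain: int, i: int, spacing: float) -> np.ndarray:
    # chain A along y=0, chain B along y=300 by default: no accidental contact
    y = 0.0 if chain == 0 else 300.0
    return np.array([i * spacing, y, 0.0])


def _build_model_coords(spec: PairFixtureSpec, model_id: int):
    """Residue origin per (chain, 1-based index) for one model."""
    origins = {}
    for i in range(spec.len_a):
        origins[(0, i + 1)] = _chain_origin(0, i, spec.spacing)
    for j in range(spec.len_b):
        origins[(1, j + 1)] = _chain_origin(1, j, spec.spacing)
    for c in spec.contacts:
        if c.models is not None and model_id not in c.models:
            continue
        origins[(1, c.res_b)] = origins[(0, c.res_a)] + np.array([0.0, c.distance, 0.0])
    return origins


def _plddt_of(spec: PairFixtureSpec, chain: int, idx: int) -> float:
    return float(spec.plddt_overrides.get((chain, idx), spec.plddt_default))


def _write_pdb(path: Path, spec: PairFixtureSpec, origins) -> None:
    st = gemmi.Structure()
    st.name = "fixture"
    model = gemmi.Model("1")
    for chain_no, (cid, seq) in enumerate([("A", spec.seq_a), ("B", spec.seq_b)]):
        chain = gemmi.Chain(cid)
        for i, aa in enumerate(seq, start=1):
            res = gemmi.Residue()
            res.name = _three_letter(aa)
            res.seqid = gemmi.SeqId(i, " ")
            for name, el, pos in _residue_atoms(aa, origins[(chain_no, i)]):
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(el)
                atom.pos = gemmi.Position(*pos)
                atom.b_iso = _plddt_of(spec, chain_no, i)
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


_THREE = {
    "A": "ALA", "D": "ASP", "E": "GLU", "K": "LYS", "R": "ARG", "G": "GLY",
    "H": "HIS", "S": "SER", "T": "THR", "N": "ASN", "Q": "GLN", "L": "LEU",
    "I": "ILE", "V": "VAL", "F": "PHE", "Y": "TYR", "W": "TRP", "M": "MET",
    "C": "CYS", "P": "PRO",
}


def _three_letter(aa: str) -> str:
    return _THREE.get(aa, "ALA")


def _build_pae(spec: PairFixtureSpec, model_id: int) -> np.ndarray:
    n = spec.len_a + spec.len_b
    pae = np.full((n, n), spec.pae_background, dtype=float)
    np.fill_diagonal(pae, 0.0)
    for c in spec.contacts:
        if c.models is not None and model_id not in c.models:
            continue
        x = c.res_a - 1
        y = spec.len_a + c.res_b - 1
        pae[x, y] = spec.pae_interface if c.pae_ab is None else c.pae_ab
        pae[y, x] = spec.pae_interface if c.pae_ba is None else c.pae_ba
    return pae


def _expected_valid(spec: PairFixtureSpec, model_id: int,
                    d_max=5.0, d_clash=1.0, plddt_min=50.0, pae_max=15.0):
    """Ground-truth valid contacts per the multi-tiered filter."""
    expected = []
    for c in spec.contacts:
        if c.models is not None and model_id not in c.models:
            continue
        if not (d_clash <= c.distance < d_max):
            continue
        if not (_plddt_of(spec, 0, c.res_a) > plddt_min and _plddt_of(spec, 1, c.res_b) > plddt_min):
            continue
        pab = spec.pae_interface if c.pae_ab is None else c.pae_ab
        pba = spec.pae_interface if c.pae_ba is None else c.pae_ba
        if not (pab < pae_max and pba < pae_max):
            continue
        expected.append([["A", c.res_a], ["B", c.res_b]])
    return expected


def make_prediction_set(spec: PairFixtureSpec, out_dir) -> dict:
    """Write the fixture bundle to ``out_dir`` and return its manifest.

    Files use the predictor's naming convention (``..._model_N...``) so the
    loader's discovery logic is exercised.  The manifest records chain
    lengths, sequences, per-model expected valid contacts under the default
    filter, and the file names.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "len_a": spec.len_a,
        "len_b": spec.len_b,
        "seq_a": spec.seq_a,
        "seq_b": spec.seq_b,
        "models": {},
    }
    for mid in spec.model_ids:
        origins = _build_model_coords(spec, mid)
        pdb_path = out_dir / f"fixture_unrelaxed_model_{mid}.pdb"
        _write_pdb(pdb_path, spec, origins)
        n = spec.len_a + spec.len_b
        plddt = [
            _plddt_of(spec, 0, i + 1) for i in range(spec.len_a)
        ] + [_plddt_of(spec, 1, j + 1) for j in range(spec.len_b)]
        scores = {
            "pae": _build_pae(spec, mid).tolist(),
            "plddt": plddt,
            "iptm": spec.iptm,
            "ptm": spec.ptm,
        }
        score_path = out_dir / f"fixture_scores_model_{mid}.json"
        score_path.write_text(json.dumps(scores))
        manifest["models"][str(mid)] = {
            "structure": pdb_path.name,
            "scores": score_path.name,
            "expected_valid_contacts": _expected_valid(spec, mid),
        }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


@dataclass
class ClassifierSimSpec:
    n_pos: int = 500
    n_neg: int = 500
    n_informative: int = 5
    effect_size: float = 3.0  # mean shift of informative features, in sd units
    n_noise: int = 5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_pos, self.n_neg, self.n_informative, self.n_noise) < 0:
            raise ValueError("counts must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")


def make_classifier_dataset(spec: ClassifierSimSpec) -> pd.DataFrame:
    """Labeled feature table with a planted informative subset.

    Positives have their informative features drawn from N(effect_size, 1),
    negatives from N(0, 1); noise features are N(0, 1) in both classes.
    Missing entries (NaN) are applied uniformly at ``missing_rate``.  Rows
    carry label ("positive"/"negative") and refset tags ("pos_synth" /
    "neg_synth").
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    cols = {}
    is_pos = np.concatenate([np.ones(spec.n_pos), np.zeros(spec.n_neg)]).astype(bool)
    for i in range(spec.n_informative):
        x = rng.normal(0.0, 1.0, n)
        x[is_pos] += spec.effect_size
        cols[f"inf_{i}"] = x
    for i in range(spec.n_noise):
        cols[f"noise_{i}"] = rng.normal(0.0, 1.0, n)
    df = pd.DataFrame(cols)
    if spec.missing_rate > 0:
        mask = rng.random(df.shape) < spec.missing_rate
        df = df.mask(mask)
    df["label"] = np.where(is_pos, "positive", "negative")
    df["refset"] = np.where(is_pos, "pos_synth", "neg_synth")
    df["pair_id"] = [f"P{i:05d}|Q{i:05d}" for i in range(n)]
    return df


def make_annotation_store(
    protein_ids: Sequence[str],
    planted_pairs: Sequence[tuple[str, str]] = (),
    seed: int = 0,
    lengths: dict = EXPECTED_LENGTHS,
) -> AnnotationStore:
    """Annotation store with planted positive-pair signal."""
    ids = list(protein_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("protein ids must be unique")
    rng = np.random.default_rng(seed)
    store = AnnotationStore()
    n_loc = lengths["deeploc"]
    for pid in ids:
        store.depmap[pid] = rng.normal(0, 1, lengths["depmap"])
        store.embedding[pid] = rng.normal(0, 1, lengths["embedding"])
        loc = rng.dirichlet(np.ones(n_loc) * 0.3)
        store.deeploc[pid] = loc
        hits = (rng.random(lengths["orcs"]) < 0.05).astype(int)
        if hits.sum() == 0:
            hits[rng.integers(lengths["orcs"])] = 1
        store.orcs[pid] = hits
        length = int(rng.integers(120, 400))
        store.missense[pid] = rng.uniform(20, 90, length)
        store.coexpress[pid] = []
    for a, b in planted_pairs:
        key = tuple(sorted((a, b)))
        store.biogrid[key] = int(rng.integers(3, 30))
        # strongly correlated gene-effect vectors
        store.depmap[b] = store.depmap[a] + rng.normal(0, 0.3, lengths["depmap"])
        # similar embeddings
        store.embedding[b] = store.embedding[a] + rng.normal(0, 0.2, lengths["embedding"])
        # same dominant compartment
        store.deeploc[b] = store.deeploc[a]
        # overlapping hit sets
        store.orcs[b] = store.orcs[a].copy()
        flip = rng.integers(0, lengths["orcs"], 5)
        store.orcs[b][flip] = 1 - store.orcs[b][flip]
        s = float(rng.uniform(2.0, 6.0))
        store.coexpress[a].append((b, s))
        store.coexpress[b].append((a, s))
    store.validate(lengths)
    return store
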