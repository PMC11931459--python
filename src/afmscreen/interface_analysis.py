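"""Interface contact detection and interface chemistry.

The multi-tiered contact filter: a cross-chain residue pair is a *valid
interfacial contact* iff

1. at least one pair of heavy atoms is closer than ``d_max`` (default 5 A),
2. both residues have pLDDT strictly above ``plddt_min`` (default 50),
3. no pair of heavy atoms is closer than ``d_clash`` (default 1 A), and
4. both directional PAE entries for the pair are strictly below ``pae_max``
   (default 15 A).

A prediction is *contact positive* (C+) when any single model yields at
least ``min_pairs`` (default 5) valid contacts.  All comparisons are strict.
Hydrogens present in the input never participate in heavy-atom logic.

Also provided: interface residue sets (distance-only, used by IF-PAE and the
pDockQ-family metrics), IF-PAE (mean PAE over both directions of all <5 A
interface residue pairs), and geometric salt-bridge / hydrogen-bond counts
between valid-contact residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfidenceMissingError
from .prediction_io import ModelPrediction, PredictionSet, pae_index

__all__ = [
    "ContactPair",
    "ContactSet",
    "find_valid_contacts",
    "is_contact_positive",
    "interface_residues",
    "if_pae",
    "count_salt_bridges",
    "count_hydrogen_bonds",
    "contact_table",
]

ResKey = tuple[str, int]  # (chain_id, author seq index)

# side-chain atoms carrying formal charge at physiological pH
ACIDIC_ATOMS = {"D": ("OD1", "OD2"), "E": ("OE1", "OE2")}
BASIC_ATOMS = {"K": ("NZ",), "R": ("NE", "NH1", "NH2"), "H": ("ND1", "NE2")}


@dataclass(frozen=True)
class ContactPair:
    res_a: ResKey
    res_b: ResKey
    min_heavy_dist: float
    min_any_dist: float
    pae_ab: float
    pae_ba: float
    plddt_a: float
    plddt_b: float
    valid: bool

    @property
    def key(self) -> frozenset:
        return frozenset((self.res_a, self.res_b))


@dataclass
class ContactSet:
    model_id: int
    contacts: list[ContactPair]
    n_candidates: int  # residue pairs passing distance/pLDDT/clash, pre-PAE

    @property
    def n_valid(self) -> int:
        return len(self.contacts)

    def keys(self) -> set[frozenset]:
        return {c.key for c in self.contacts}


def _chain_atom_arrays(chain, heavy_only=True):
    """(coords array, parallel residue-position indices) for one chain."""
    coords, res_idx = [], []
    for i, res in enumerate(chain):
        for a in res.atoms:
            if heavy_only and not a.is_heavy:
                continue
            coords.append(a.coords)
            res_idx.append(i)
    if not coords:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    return np.asarray(coords), np.asarray(res_idx, dtype=int)


def _cross_chain_min_dists(model: ModelPrediction, d_max: float, heavy_only=True):
    """Map (i, j) chain-position pairs -> min atom distance below d_max.

    Uses a k-d tree so only pairs within the cutoff are ever materialised;
    results are identical to a brute-force all-pairs scan.
    """
    ca, ra = _chain_atom_arrays(model.chains[0], heavy_only)
    cb, rb = _chain_atom_arrays(model.chains[1], heavy_only)
    out: dict[tuple[int, int], float] = {}
    if len(ca) == 0 or len(cb) == 0:
        return out
    ta, tb = cKDTree(ca), cKDTree(cb)
    # sparse matrix of atom-pair distances < d_max
    dok = ta.sparse_distance_matrix(tb, d_max, output_type="dict")
    for (ia, ib), d in dok.items():
        if d >= d_max:  # strict cutoff
            continue
        key = (int(ra[ia]), int(rb[ib]))
        if d < out.get(key, np.inf):
            out[key] = d
    return out


def find_valid_contacts(
    model: ModelPrediction,
    d_max: float = 5.0,
    d_clash: float = 1.0,
    plddt_min: float = 50.0,
    pae_max: float = 15.0,
) -> ContactSet:
    """Apply the multi-tiered contact filter to one model."""
    if model.pae is None:
        raise ConfidenceMissingError("model has no PAE matrix")
    heavy = _cross_chain_min_dists(model, d_max, heavy_only=True)
    # any-atom minima (hydrogens included) for bookkeeping only
    any_d = _cross_chain_min_dists(model, d_max, heavy_only=False)
    cha, chb = model.chains
    n1 = len(cha)
    contacts: list[ContactPair] = []
    n_candidates = 0
    for (i, j), dmin in sorted(heavy.items()):
        res_a, res_b = cha[i], chb[j]
        if not (res_a.plddt > plddt_min and res_b.plddt > plddt_min):
            continue
        if dmin < d_clash:  # any heavy-atom pair closer than the clash cutoff
            continue
        n_candidates += 1
        ia, ib = i, n1 + j
        pae_ab = float(model.pae[ia, ib])
        pae_ba = float(model.pae[ib, ia])
        valid = pae_ab < pae_max and pae_ba < pae_max
        if valid:
            contacts.append(
                ContactPair(
                    res_a=(res_a.chain_id, res_a.seq_index),
                    res_b=(res_b.chain_id, res_b.seq_index),
                    min_heavy_dist=dmin,
                    min_any_dist=any_d.get((i, j), dmin),
                    pae_ab=pae_ab,
                    pae_ba=pae_ba,
                    plddt_a=res_a.plddt,
                    plddt_b=res_b.plddt,
                    valid=True,
                )
            )
    return ContactSet(model_id=model.model_id, contacts=contacts, n_candidates=n_candidates)


def is_contact_positive(
    pset: PredictionSet,
    min_pairs: int = 5,
    contact_sets: Optional[list[ContactSet]] = None,
    **filter_kwargs,
) -> bool:
    """C+ call: true iff any single model has >= min_pairs valid contacts."""
    if contact_sets is None:
        contact_sets = [find_valid_contacts(m, **filter_kwargs) for m in pset.models]
    return any(cs.n_valid >= min_pairs for cs in contact_sets)


def interface_residues(model: ModelPrediction, d_max: float = 5.0):
    """Per-chain sets of residues with any cross-chain heavy atom < d_max.

    Distance-only definition (no pLDDT/PAE filter), as used by IF-PAE.
    """
    pairs = interface_pairs(model, d_max)
    set_a = {a for a, _ in pairs}
    set_b = {b for _, b in pairs}
    return set_a, set_b


def interface_pairs(model: ModelPrediction, d_max: float = 5.0) -> list[tuple[ResKey, ResKey]]:
    """Cross-chain residue pairs with min heavy-atom distance < d_max."""
    heavy = _cross_chain_min_dists(model, d_max, heavy_only=True)
    cha, chb = model.chains
    return [
        ((cha[i].chain_id, cha[i].seq_index), (chb[j].chain_id, chb[j].seq_index))
        for (i, j) in sorted(heavy)
    ]


def if_pae(model: ModelPrediction, d_max: float = 5.0) -> Optional[float]:
    """Mean PAE (both directions) over all interface residue pairs; None if none."""
    if model.pae is None:
        raise ConfidenceMissingError("model has no PAE matrix")
    pairs = interface_pairs(model, d_max)
    if not pairs:
        return None
    vals = []
    for (ca, ia), (cb, ib) in pairs:
        x = pae_index(model, ca, ia)
        y = pae_index(model, cb, ib)
        vals.append(model.pae[x, y])
        vals.append(model.pae[y, x])
    return float(np.mean(vals))


def _residue_by_key(model: ModelPrediction):
    return {(r.chain_id, r.seq_index): r for r in model.residues()}


def _salt_bridge_atom_pairs(res_a, res_b, cutoff: float):
    """Acidic side-chain O within cutoff of basic side-chain N, both orientations."""
    found = []
    for acid, base in ((res_a, res_b), (res_b, res_a)):
        o_names = ACIDIC_ATOMS.get(acid.aa_code, ())
        n_names = BASIC_ATOMS.get(base.aa_code, ())
        for on in o_names:
            oa = acid.atom(on)
            if oa is None:
                continue
            for nn in n_names:
                na = base.atom(nn)
                if na is None:
                    continue
                if np.linalg.norm(oa.coords - na.coords) < cutoff:
                    found.append((id(oa), id(na)))
    return found


def count_salt_bridges(
    model: ModelPrediction, contacts: ContactSet, cutoff: float = 4.0
) -> int:
    """Valid-contact residue pairs with an acidic O - basic N pair within cutoff.

    Each residue pair counts at most once regardless of how many atom pairs
    qualify.
    """
    by_key = _residue_by_key(model)
    n = 0
    for c in contacts.contacts:
        if _salt_bridge_atom_pairs(by_key[c.res_a], by_key[c.res_b], cutoff):
            n += 1
    return n


def count_hydrogen_bonds(
    model: ModelPrediction,
    contacts: ContactSet,
    cutoff: float = 3.5,
    salt_bridge_cutoff: float = 4.0,
) -> int:
    """Cross-chain N/O atom pairs within cutoff between valid-contact residues.

    Counted per atom pair; atom pairs already attributed to a salt bridge are
    excluded.  No angle criterion is applied.
    """
    by_key = _residue_by_key(model)
    n = 0
    for c in contacts.contacts:
        res_a, res_b = by_key[c.res_a], by_key[c.res_b]
        sb = set(_salt_bridge_atom_pairs(res_a, res_b, salt_bridge_cutoff))
        for aa in res_a.atoms:
            if aa.element.upper() not in ("N", "O"):
                continue
            for ab in res_b.atoms:
                if ab.element.upper() not in ("N", "O"):
                    continue
                if (id(aa), id(ab)) in sb or (id(ab), id(aa)) in sb:
                    continue
                if np.linalg.norm(aa.coords - ab.coords) < cutoff:
                    n += 1
    return n


def contact_table(contact_sets: list[ContactSet]) -> pd.DataFrame:
    """One row per valid contact across models, ready for TSV export."""
    rows = []
    for cs in contact_sets:
        for c in cs.contacts:
            rows.append(
                {
                    "model_id": cs.model_id,
                    "chain_a": c.res_a[0],
                    "res_a": c.res_a[1],
                    "chain_b": c.res_b[0],
                    "res_b": c.res_b[1],
                    "min_heavy_dist": c.min_heavy_dist,
                    "pae_ab": c.pae_ab,
                    "pae_ba": c.pae_ba,
                    "plddt_a": c.plddt_a,
                    "plddt_b": c.plddt_b,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "model_id",
            "chain_a",
            "res_a",
            "chain_b",
            "res_b",
            "min_heavy_dist",
            "pae_ab",
            "pae_ba",
            "plddt_a",
            "plddt_b",
        ],
    )
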