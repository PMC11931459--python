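"""Shared fixtures: in-memory model builders and brute-force oracles.

The oracles here re-derive results by exhaustive enumeration over residue and
atom pairs, independently of the package's spatial-index implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from afmscreen.interface_analysis import ContactPair, ContactSet
from afmscreen.prediction_io import AtomRecord, ModelPrediction, ResidueRecord


def make_residue(chain_id, seq_index, aa="A", atoms=None, plddt=90.0):
    """Residue from (name, element, xyz) atom triples; default lone CA."""
    if atoms is None:
        atoms = [("CA", "C", (0.0, 0.0, 0.0))]
    recs = [
        AtomRecord(
            atom_name=n,
            element=el,
            coords=np.asarray(xyz, dtype=float),
            is_heavy=el.upper() not in ("H", "D"),
        )
        for n, el, xyz in atoms
    ]
    return ResidueRecord(
        chain_id=chain_id, seq_index=seq_index, aa_code=aa, atoms=recs, plddt=plddt
    )


def make_model(chain_a, chain_b, pae=None, default_pae=8.0, model_id=1, iptm=None, ptm=None):
    """Two-chain model; ``pae`` may be a full matrix or {(i,j): value} overrides
    on concatenated 0-based indices applied over a constant background."""
    n = len(chain_a) + len(chain_b)
    if pae is None or isinstance(pae, dict):
        mat = np.full((n, n), default_pae, dtype=float)
        np.fill_diagonal(mat, 0.0)
        if isinstance(pae, dict):
            for (i, j), v in pae.items():
                mat[i, j] = v
    else:
        mat = np.asarray(pae, dtype=float)
    return ModelPrediction(
        model_id=model_id, chains=(list(chain_a), list(chain_b)), pae=mat, iptm=iptm, ptm=ptm
    )


def brute_force_valid_contacts(
    model, d_max=5.0, d_clash=1.0, plddt_min=50.0, pae_max=15.0
):
    """Exhaustive scan over all cross-chain residue and heavy-atom pairs."""
    cha, chb = model.chains
    n1 = len(cha)
    valid = set()
    for i, ra in enumerate(cha):
        for j, rb in enumerate(chb):
            dists = [
                float(np.linalg.norm(a.coords - b.coords))
                for a in ra.atoms
                if a.is_heavy
                for b in rb.atoms
                if b.is_heavy
            ]
            dmin = min(dists)
            if not dmin < d_max:
                continue
            if not (ra.plddt > plddt_min and rb.plddt > plddt_min):
                continue
            if any(d < d_clash for d in dists):
                continue
            if not (model.pae[i, n1 + j] < pae_max and model.pae[n1 + j, i] < pae_max):
                continue
            valid.add(
                frozenset({(ra.chain_id, ra.seq_index), (rb.chain_id, rb.seq_index)})
            )
    return valid


def random_model(rng, max_len=15, box=25.0, model_id=1):
    """Random two-chain model: residues scattered in a box, 1-3 heavy atoms
    each, random pLDDT across the filter boundary and random PAE in [0, 30]."""
    def chain(cid, n):
        residues = []
        for i in range(n):
            centre = rng.uniform(0, box, 3)
            atoms = []
            for k in range(rng.integers(1, 4)):
                name = ["CA", "CB", "CG"][k]
                atoms.append((name, "C", centre + rng.uniform(-1.5, 1.5, 3)))
            residues.append(
                make_residue(cid, i + 1, atoms=atoms, plddt=float(rng.uniform(30, 100)))
            )
        return residues
    na = int(rng.integers(3, max_len + 1))
    nb = int(rng.integers(3, max_len + 1))
    cha, chb = chain("A", na), chain("B", nb)
    n = na + nb
    pae = rng.uniform(0, 30, (n, n))
    np.fill_diagonal(pae, 0.0)
    return make_model(cha, chb, pae=pae, model_id=model_id)


def contact_set_from_keys(model_id, keys):
    """ContactSet with placeholder geometry, for agreement-metric tests."""
    contacts = [
        ContactPair(
            res_a=a, res_b=b, min_heavy_dist=3.0, min_any_dist=3.0,
            pae_ab=5.0, pae_ba=5.0, plddt_a=90.0, plddt_b=90.0, valid=True,
        )
        for a, b in keys
    ]
    return ContactSet(model_id=model_id, contacts=contacts, n_candidates=len(contacts))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
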