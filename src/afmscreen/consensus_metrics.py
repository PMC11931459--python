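"""Cross-model agreement and canonical per-model confidence metrics.

``avg_models`` quantifies how well the independently trained AF-M models
agree on the interfacial contacts: over the union U of valid contacts seen in
any model, it is the mean fraction of models supporting each contact,

    avg_models = mean_{c in U}  m(c) / M,      0 when U is empty,

so a score above 0.5 means the average contact is supported by more than
half of the models used during inference, and 1.0 means every model
reproduces every contact.  Contacts are matched by exact residue-pair
identity.

pDockQ and pDockQ2 are the published sigmoid-form interface quality
estimators; their constants are taken verbatim from the original
publications (Bryant et al. 2022 FoldDock; Zhu et al. 2023) and stored in
``PDOCKQ_PARAMS`` / ``PDOCKQ2_PARAMS``.  ipTM is never recomputed - it is a
predictor output passed through from the score files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .interface_analysis import ContactSet, find_valid_contacts, if_pae
from .prediction_io import ModelPrediction, PredictionSet, pae_index

__all__ = [
    "PairMetrics",
    "avg_models",
    "contact_count_stats",
    "pdockq",
    "pdockq2",
    "best_over_models",
    "compute_pair_metrics",
    "PDOCKQ_PARAMS",
    "PDOCKQ2_PARAMS",
]

# Bryant et al. 2022 (FoldDock): pDockQ = L / (1 + exp(-k (x - x0))) + b,
# x = <interface pLDDT> * log10(#CB-CB contacts < 8 A), CA for glycine.
PDOCKQ_PARAMS = {"L": 0.724, "k": 0.052, "x0": 152.611, "b": 0.018, "dist": 8.0}

# Zhu et al. 2023: pDockQ2 = L / (1 + exp(-k (x - x0))) + b,
# x = <interface pLDDT> * <1 / (1 + (PAE_ij / d0)^2)> over interchain
# contacts (CB < 10 A), d0 = 10 A.
PDOCKQ2_PARAMS = {"L": 1.31, "k": 0.075, "x0": 84.733, "b": 0.005, "dist": 10.0, "d0": 10.0}


def avg_models(contact_sets: list[ContactSet]) -> float:
    """Mean, over the union of contacts, of the supporting-model fraction."""
    if not contact_sets:
        raise ValueError("need at least one model's ContactSet")
    m = len(contact_sets)
    support: dict[frozenset, int] = {}
    for cs in contact_sets:
        for key in cs.keys():
            support[key] = support.get(key, 0) + 1
    if not support:
        return 0.0
    return float(np.mean([v / m for v in support.values()]))


def contact_count_stats(contact_sets: list[ContactSet]) -> tuple[int, float, int]:
    """(min, mean, max) of per-model valid-contact counts (zeros included)."""
    counts = [cs.n_valid for cs in contact_sets]
    return min(counts), float(np.mean(counts)), max(counts)


def _cb_coordinate(res) -> Optional[np.ndarray]:
    """C-beta coordinate, falling back to C-alpha (glycine, coarse models)."""
    a = res.atom("CB") or res.atom("CA")
    return None if a is None else a.coords


def _cb_contacts(model: ModelPrediction, dist: float):
    """Cross-chain residue pairs whose CB (CA fallback) atoms are < dist apart."""
    cha, chb = model.chains
    ca = [(r, _cb_coordinate(r)) for r in cha]
    cb = [(r, _cb_coordinate(r)) for r in chb]
    pairs = []
    for ra, pa in ca:
        if pa is None:
            continue
        for rb, pb in cb:
            if pb is None:
                continue
            if np.linalg.norm(pa - pb) < dist:
                pairs.append((ra, rb))
    return pairs


def pdockq(model: ModelPrediction, params: dict = PDOCKQ_PARAMS) -> float:
    """pDockQ of one model; the sigmoid floor ``b`` when there is no interface."""
    pairs = _cb_contacts(model, params["dist"])
    if not pairs:
        return params["b"]
    res = {id(r): r for ra, rb in pairs for r in (ra, rb)}
    mean_plddt = float(np.mean([r.plddt for r in res.values()]))
    x = mean_plddt * math.log10(len(pairs))
    return params["L"] / (1 + math.exp(-params["k"] * (x - params["x0"]))) + params["b"]


def pdockq2(model: ModelPrediction, params: dict = PDOCKQ2_PARAMS) -> float:
    """PAE-aware pDockQ2 of one model; the floor ``b`` when no interface."""
    if model.pae is None:
        raise ValueError("pDockQ2 requires a PAE matrix")
    pairs = _cb_contacts(model, params["dist"])
    if not pairs:
        return params["b"]
    d0 = params["d0"]
    pae_terms = []
    for ra, rb in pairs:
        x = pae_index(model, ra.chain_id, ra.seq_index)
        y = pae_index(model, rb.chain_id, rb.seq_index)
        for p in (model.pae[x, y], model.pae[y, x]):
            pae_terms.append(1.0 / (1.0 + (p / d0) ** 2))
    res = {id(r): r for ra, rb in pairs for r in (ra, rb)}
    mean_plddt = float(np.mean([r.plddt for r in res.values()]))
    x = mean_plddt * float(np.mean(pae_terms))
    return params["L"] / (1 + math.exp(-params["k"] * (x - params["x0"]))) + params["b"]


def best_over_models(
    pset: PredictionSet, metric: Callable[[ModelPrediction], Optional[float]], direction: str = "max"
) -> Optional[float]:
    """Max (goodness metrics) or min (error metrics, e.g. IF-PAE) across models."""
    vals = [metric(m) for m in pset.models]
    vals = [v for v in vals if v is not None]
    if not vals:
        return None
    return max(vals) if direction == "max" else min(vals)


@dataclass
class PairMetrics:
    """Per-pair consensus metrics, aggregated over all models."""

    pair_id: tuple[str, str]
    contact_positive: bool
    avg_models: float
    n_contacts_min: int
    n_contacts_mean: float
    n_contacts_max: int
    if_pae_best: Optional[float]
    iptm_best: Optional[float]
    pdockq_best: float
    pdockq2_best: float


def compute_pair_metrics(
    pset: PredictionSet,
    contact_sets: Optional[list[ContactSet]] = None,
    min_pairs: int = 5,
    **filter_kwargs,
) -> PairMetrics:
    if contact_sets is None:
        contact_sets = [find_valid_contacts(m, **filter_kwargs) for m in pset.models]
    cmin, cmean, cmax = contact_count_stats(contact_sets)
    return PairMetrics(
        pair_id=pset.pair_id,
        contact_positive=any(cs.n_valid >= min_pairs for cs in contact_sets),
        avg_models=avg_models(contact_sets),
        n_contacts_min=cmin,
        n_contacts_mean=cmean,
        n_contacts_max=cmax,
        if_pae_best=best_over_models(pset, if_pae, direction="min"),
        iptm_best=best_over_models(pset, lambda m: m.iptm, direction="max"),
        pdockq_best=best_over_models(pset, pdockq, direction="max"),
        pdockq2_best=best_over_models(pset, pdockq2, direction="max"),
    )
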