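"""Pair-level feature assembly: structural + pairwise biological features.

Biological annotations are consumed as prepared per-protein tables (this
package never runs DeepLoc, a language model, or DEPMAP processing itself):

* BioGRID evidence counts per unordered pair,
* DEPMAP gene-effect vectors (length 1,095: one Chronos score per cell line),
* top-500 coexpression partner lists,
* DeepLoc 10-dimensional localization probability vectors,
* 1,024-dimensional per-protein language-model embeddings,
* 1,243-dimensional binary CRISPR-screen hit vectors,
* per-residue averaged missense-pathogenicity vectors (0-100).

Every pair feature is a symmetric combination of the two proteins' values
(correlation, inner product, max, Jaccard, cosine/Euclidean, sorted chain
statistics) so the classifier cannot identify or learn protein identities
within pairs.  Missing annotations are imputed with a -1 sentinel after
min-max scaling to [0, 1] and flagged with a companion ``*_missing`` feature;
absence is itself informative (e.g. a pair never seen in BioGRID).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional
import warnings

import numpy as np
import pandas as pd

from .consensus_metrics import PairMetrics
from .interface_analysis import (
    ContactSet,
    count_hydrogen_bonds,
    count_salt_bridges,
    interface_residues,
)
from .prediction_io import PredictionSet

__all__ = [
    "AnnotationStore",
    "FeatureSchema",
    "FeatureVector",
    "DEFAULT_SCHEMA",
    "biogrid_count",
    "depmap_codependency",
    "coexpression_score",
    "colocalization_score",
    "embedding_similarity",
    "orcs_profile_similarity",
    "missense_interface_conservation",
    "assemble_features",
    "feature_table",
    "impute_and_scale",
]

EXPECTED_LENGTHS = {"depmap": 1095, "orcs": 1243, "deeploc": 10, "embedding": 1024}


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))


@dataclass
class AnnotationStore:
    """Per-protein annotation maps keyed by protein identifier."""

    biogrid: dict = field(default_factory=dict)  # (a,b) sorted tuple -> int
    depmap: dict = field(default_factory=dict)  # id -> (1095,) float
    coexpress: dict = field(default_factory=dict)  # id -> [(partner, score), ...] <= 500
    deeploc: dict = field(default_factory=dict)  # id -> (10,) probabilities
    embedding: dict = field(default_factory=dict)  # id -> (1024,) float
    orcs: dict = field(default_factory=dict)  # id -> (1243,) binary
    missense: dict = field(default_factory=dict)  # id -> per-residue float in [0,100]

    def validate(self, lengths: dict = EXPECTED_LENGTHS) -> None:
        for name in ("depmap", "orcs", "deeploc", "embedding"):
            want = lengths[name]
            for pid, vec in getattr(self, name).items():
                if len(vec) != want:
                    raise ValueError(
                        f"{name} vector for {pid} has length {len(vec)}, expected {want}"
                    )
        for pid, vec in self.deeploc.items():
            v = np.asarray(vec, dtype=float)
            if v.min() < 0 or v.max() > 1:
                raise ValueError(f"deeploc probabilities for {pid} outside [0, 1]")
        for pid, vec in self.orcs.items():
            v = np.asarray(vec)
            if not np.isin(v, (0, 1)).all():
                raise ValueError(f"orcs vector for {pid} is not binary")

    def save(self, path) -> None:
        data = {
            "biogrid": {"|".join(k): int(v) for k, v in self.biogrid.items()},
            "coexpress": {k: [[p, float(s)] for p, s in v] for k, v in self.coexpress.items()},
        }
        for name in ("depmap", "deeploc", "embedding", "orcs", "missense"):
            data[name] = {k: np.asarray(v).tolist() for k, v in getattr(self, name).items()}
        Path(path).write_text(json.dumps(data))

    @classmethod
    def load(cls, path, validate: bool = True) -> "AnnotationStore":
        data = json.loads(Path(path).read_text())
        store = cls(
            biogrid={tuple(k.split("|")): int(v) for k, v in data.get("biogrid", {}).items()},
            coexpress={
                k: [(p, float(s)) for p, s in v] for k, v in data.get("coexpress", {}).items()
            },
        )
        for name in ("depmap", "deeploc", "embedding", "missense"):
            setattr(
                store, name,
                {k: np.asarray(v, dtype=float) for k, v in data.get(name, {}).items()},
            )
        store.orcs = {k: np.asarray(v, dtype=int) for k, v in data.get("orcs", {}).items()}
        if validate:
            store.validate()
        return store


def biogrid_count(store: AnnotationStore, a: str, b: str) -> int:
    """Number of independent BioGRID experiments supporting the pair; 0 if absent."""
    return int(store.biogrid.get(_pair_key(a, b), 0))


def depmap_codependency(store: AnnotationStore, a: str, b: str) -> Optional[float]:
    """Pearson correlation of the two gene-effect vectors (pairwise-complete)."""
    va, vb = store.depmap.get(a), store.depmap.get(b)
    if va is None or vb is None:
        return None
    va = np.asarray(va, dtype=float)
    vb = np.asarray(vb, dtype=float)
    ok = np.isfinite(va) & np.isfinite(vb)
    va, vb = va[ok], vb[ok]
    if len(va) < 2 or va.std() == 0 or vb.std() == 0:
        return None
    return float(np.corrcoef(va, vb)[0, 1])


def coexpression_score(store: AnnotationStore, a: str, b: str) -> Optional[float]:
    """Max of (b's score in a's top-500 list, a's score in b's list); None if neither."""
    scores = []
    for x, y in ((a, b), (b, a)):
        for partner, s in store.coexpress.get(x, ()):
            if partner == y:
                scores.append(s)
                break
    return max(scores) if scores else None


def colocalization_score(store: AnnotationStore, a: str, b: str) -> Optional[float]:
    """Inner product of the localization probability vectors (expected
    probability that the two proteins occupy the same compartment)."""
    va, vb = store.deeploc.get(a), store.deeploc.get(b)
    if va is None or vb is None:
        return None
    return float(np.dot(np.asarray(va, float), np.asarray(vb, float)))


def embedding_similarity(store: AnnotationStore, a: str, b: str):
    """(cosine similarity, Euclidean distance) of the protein embeddings."""
    va, vb = store.embedding.get(a), store.embedding.get(b)
    if va is None or vb is None:
        return None, None
    va = np.asarray(va, float)
    vb = np.asarray(vb, float)
    dist = float(np.linalg.norm(va - vb))
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    cos = None if na == 0 or nb == 0 else float(np.dot(va, vb) / (na * nb))
    return cos, dist


def orcs_profile_similarity(store: AnnotationStore, a: str, b: str) -> Optional[float]:
    """Jaccard index of the CRISPR-screen hit sets; None if either has no hits."""
    va, vb = store.orcs.get(a), store.orcs.get(b)
    if va is None or vb is None:
        return None
    va = np.asarray(va, dtype=bool)
    vb = np.asarray(vb, dtype=bool)
    if not va.any() or not vb.any():
        return None
    union = np.logical_or(va, vb).sum()
    return float(np.logical_and(va, vb).sum() / union)


def _best_model_index(contact_sets: list[ContactSet]) -> int:
    """Model with the most valid contacts (lowest model position on ties)."""
    counts = [cs.n_valid for cs in contact_sets]
    return int(np.argmax(counts))


def missense_interface_conservation(
    pset: PredictionSet,
    store: AnnotationStore,
    contact_sets: Optional[list[ContactSet]] = None,
    d_max: float = 5.0,
):
    """Mean averaged-missense score over each chain's interface residues.

    Uses the best model's (most valid contacts) interface.  Positions beyond
    a protein's missense vector (isoform mismatch) make that chain's value
    missing with a warning.  Returns ``(mean_a, mean_b)`` in pair-id order.
    """
    from .interface_analysis import find_valid_contacts

    if contact_sets is None:
        contact_sets = [find_valid_contacts(m) for m in pset.models]
    model = pset.models[_best_model_index(contact_sets)]
    set_a, set_b = interface_residues(model, d_max)
    means = []
    for pid, resset in zip(pset.pair_id, (set_a, set_b)):
        vec = store.missense.get(pid)
        if vec is None or not resset:
            means.append(None)
            continue
        vec = np.asarray(vec, dtype=float)
        positions = [seq for _, seq in resset]
        if max(positions) > len(vec):
            warnings.warn(
                f"interface residue index beyond missense vector for {pid} "
                "(isoform mismatch); feature set to missing"
            )
            means.append(None)
            continue
        means.append(float(np.mean([vec[p - 1] for p in positions])))
    return tuple(means)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, versioned feature name list.

    The feature set is data-driven: a curated list can replace the default
    reconstruction without touching code.
    """

    names: tuple[str, ...]
    version: str = "1"

    def __contains__(self, name):
        return name in self.names


STRUCTURAL_FEATURES = (
    "avg_models",
    "n_contacts_min",
    "n_contacts_mean",
    "n_contacts_max",
    "if_pae_best",
    "iptm_best",
    "pdockq_best",
    "pdockq2_best",
    "mean_interface_plddt",
    "salt_bridges",
    "hydrogen_bonds",
    "n_interface_res_small",
    "n_interface_res_large",
)

BIOLOGICAL_FEATURES = (
    "biogrid_count",
    "depmap_codependency",
    "coexpression_score",
    "colocalization_score",
    "embedding_cosine",
    "embedding_euclidean",
    "orcs_jaccard",
    "missense_interface_min",
    "missense_interface_max",
)

DEFAULT_SCHEMA = FeatureSchema(names=STRUCTURAL_FEATURES + BIOLOGICAL_FEATURES)


@dataclass
class FeatureVector:
    pair_id: tuple[str, str]
    values: dict  # feature name -> float (present values only)
    missing: dict  # feature name -> bool
    label: Optional[str] = None  # "positive" / "negative"
    refset: Optional[str] = None
    schema: FeatureSchema = field(default=DEFAULT_SCHEMA)


def assemble_features(
    pset: PredictionSet,
    contact_sets: list[ContactSet],
    metrics: PairMetrics,
    store: AnnotationStore,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    label: Optional[str] = None,
    refset: Optional[str] = None,
) -> FeatureVector:
    """One feature row for a contact-positive pair.

    Raises if the pair is not C+ — non-C+ pairs are never featurized, only
    contact-positive pairs enter downstream analysis.
    """
    if not metrics.contact_positive:
        raise ValueError(f"pair {pset.pair_id} is not contact positive; not featurized")
    a, b = pset.pair_id
    best = _best_model_index(contact_sets)
    model = pset.models[best]
    cs = contact_sets[best]
    set_a, set_b = interface_residues(model)
    plddts = [p for c in cs.contacts for p in (c.plddt_a, c.plddt_b)]
    cos, eucl = embedding_similarity(store, a, b)
    mis_a, mis_b = missense_interface_conservation(pset, store, contact_sets)
    mis_present = [m for m in (mis_a, mis_b) if m is not None]
    raw = {
        "avg_models": metrics.avg_models,
        "n_contacts_min": metrics.n_contacts_min,
        "n_contacts_mean": metrics.n_contacts_mean,
        "n_contacts_max": metrics.n_contacts_max,
        "if_pae_best": metrics.if_pae_best,
        "iptm_best": metrics.iptm_best,
        "pdockq_best": metrics.pdockq_best,
        "pdockq2_best": metrics.pdockq2_best,
        "mean_interface_plddt": float(np.mean(plddts)) if plddts else None,
        "salt_bridges": count_salt_bridges(model, cs),
        "hydrogen_bonds": count_hydrogen_bonds(model, cs),
        # sorted so the vector is invariant to chain order
        "n_interface_res_small": min(len(set_a), len(set_b)),
        "n_interface_res_large": max(len(set_a), len(set_b)),
        "biogrid_count": biogrid_count(store, a, b),
        "depmap_codependency": depmap_codependency(store, a, b),
        "coexpression_score": coexpression_score(store, a, b),
        "colocalization_score": colocalization_score(store, a, b),
        "embedding_cosine": cos,
        "embedding_euclidean": eucl,
        "orcs_jaccard": orcs_jaccard_or_none(store, a, b),
        "missense_interface_min": min(mis_present) if len(mis_present) == 2 else None,
        "missense_interface_max": max(mis_present) if len(mis_present) == 2 else None,
    }
    values, missing = {}, {}
    for name in schema.names:
        v = raw.get(name)
        if v is None or (isinstance(v, float) and not np.isfinite(v)):
            missing[name] = True
        else:
            values[name] = float(v)
            missing[name] = False
    return FeatureVector(
        pair_id=pset.pair_id, values=values, missing=missing,
        label=label, refset=refset, schema=schema,
    )


def orcs_jaccard_or_none(store, a, b):
    return orcs_profile_similarity(store, a, b)


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame (NaN marks missing values)."""
    if not vectors:
        return pd.DataFrame()
    schema = vectors[0].schema
    rows = []
    for fv in vectors:
        row = {"pair_id": "|".join(fv.pair_id), "label": fv.label, "refset": fv.refset}
        for name in schema.names:
            row[name] = fv.values.get(name, np.nan)
            row[f"{name}_missing"] = float(fv.missing.get(name, True))
        rows.append(row)
    return pd.DataFrame(rows)


def impute_and_scale(
    df: pd.DataFrame, feature_names, sentinel: float = -1.0
) -> tuple[pd.DataFrame, dict]:
    """Min-max scale each feature to [0, 1]; impute missing with the sentinel.

    The sentinel lies outside the scaled range so a forest can split absence
    from any present value.  Returns the transformed frame and the per-feature
    (min, max) parameters so the same transform can be replayed at scoring
    time.  Present values are never overwritten.
    """
    out = df.copy()
    params = {}
    for name in feature_names:
        col = out[name].astype(float)
        lo, hi = np.nanmin(col.values), np.nanmax(col.values)
        if not np.isfinite(lo):  # entirely missing column
            lo, hi = 0.0, 1.0
        span = hi - lo if hi > lo else 1.0
        scaled = (col - lo) / span
        out[name] = scaled.fillna(sentinel)
        params[name] = (float(lo), float(hi))
    return out, params
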