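"""Reference-set construction operators.

Positive candidates come from cross-linking mass spectrometry (XLMS): a pair
is kept when at least one reported crosslink agrees with at least one model
(Calpha-Calpha distance of the linked residues within 36 A, the upper bound
of the crosslinker lengths).  Over-represented proteins are trimmed to at
most 28 appearances and flagged protein classes (e.g. histones) to at most
1% of the set.  A frequency-matched randomized negative set (same proteins,
shuffled pairings, no real pair reproduced) is built by iterative reshuffling
until >80% of proteins appear at identical frequencies.  Decoy negatives are
non-contacting chain pairs extracted from resolved multi-subunit complexes
(contact = at least 10 residue pairs with heavy atoms closer than 5 A).
Homology reduction keeps one random pair per cluster-pair group; negative
sets are additionally purged of anything homologous to an interacting pair
in the PDB.  Externally computed DockQ scores are filtered at the CAPRI
"acceptable" cutoff (strictly > 0.23 on the per-pair max over models).

Sequence clustering itself is a pluggable backend: cluster maps are accepted
as inputs (the 50%-overlap / 30%-identity parameters belong to the backend);
``greedy_kmer_clusters`` provides a small built-in fallback for tests.
"""

from __future__ import annotations

import random
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .prediction_io import ModelPrediction, PredictionSet

__all__ = [
    "CrosslinkRecord",
    "crosslink_agreement",
    "dedupe_and_trim",
    "generate_matched_randoms",
    "extract_decoy_pairs",
    "homology_reduce",
    "purge_pdb_homologs",
    "dockq_filter",
    "greedy_kmer_clusters",
]

Pair = tuple[str, str]


def _norm(a: str, b: str) -> Pair:
    return tuple(sorted((a, b)))


@dataclass(frozen=True)
class CrosslinkRecord:
    protein_a: str
    protein_b: str
    res_a: int  # 1-based sequence positions
    res_b: int
    source: str = ""

    def __post_init__(self):
        if self.res_a < 1 or self.res_b < 1:
            raise ValueError("crosslink residue positions are 1-based (>= 1)")

    @property
    def pair(self) -> Pair:
        return _norm(self.protein_a, self.protein_b)


def _ca_coords(model: ModelPrediction, protein_order: Pair):
    """chain index (0/1) per protein id in pair order, plus CA lookup."""
    lookup = []
    for ch in model.chains:
        d = {}
        for r in ch:
            ca = r.atom("CA")
            if ca is not None:
                d[r.seq_index] = ca.coords
        lookup.append(d)
    return lookup


def crosslink_agreement(
    pset: PredictionSet,
    links: Sequence[CrosslinkRecord],
    max_dist: float = 36.0,
) -> bool:
    """True iff some link is satisfied (CA-CA <= max_dist) in some model.

    Chain 1 is taken as the first protein of the order-normalized pair id.
    Links whose residue index falls outside a chain are skipped with a
    warning.
    """
    a, b = pset.pair_id
    any_in_range = False
    for model in pset.models:
        ca = _ca_coords(model, (a, b))
        for link in links:
            if link.pair != (a, b):
                continue
            if link.protein_a == a:
                ra, rb = link.res_a, link.res_b
            else:
                ra, rb = link.res_b, link.res_a
            pa = ca[0].get(ra)
            pb = ca[1].get(rb)
            if pa is None or pb is None:
                warnings.warn(
                    f"crosslink {link} references a residue outside the structure; skipped"
                )
                continue
            any_in_range = True
            if np.linalg.norm(pa - pb) <= max_dist:
                return True
    return False


def dedupe_and_trim(
    records: Sequence[CrosslinkRecord],
    cap: int = 28,
    class_ids: Optional[set] = None,
    class_frac: float = 0.01,
    seed: Optional[int] = None,
) -> list[Pair]:
    """Deduplicate crosslinks to unique pairs, then trim over-representation.

    Records are deduplicated first at the residue level, then at the pair
    level.  Then, iteratively, the most common protein has randomly chosen
    pairs removed until it appears at most ``cap`` times; finally pairs
    containing a member of ``class_ids`` are randomly removed until they make
    up at most ``class_frac`` of the set.  Idempotent and seeded.
    """
    rng = random.Random(seed)
    seen_res = set()
    pairs: list[Pair] = []
    seen_pairs = set()
    for rec in records:
        rk = (rec.pair, tuple(sorted((rec.res_a, rec.res_b))))
        if rk in seen_res:
            continue
        seen_res.add(rk)
        if rec.pair not in seen_pairs:
            seen_pairs.add(rec.pair)
            pairs.append(rec.pair)
    while True:
        counts = Counter(p for pair in pairs for p in pair)
        if not counts:
            break
        protein, n = counts.most_common(1)[0]
        if n <= cap:
            break
        holding = [p for p in pairs if protein in p]
        drop = set(
            map(id, rng.sample(holding, n - cap))
        )  # remove down to exactly cap
        pairs = [p for p in pairs if id(p) not in drop]
    if class_ids:
        class_pairs = [p for p in pairs if p[0] in class_ids or p[1] in class_ids]
        rng.shuffle(class_pairs)
        while class_pairs and len(class_pairs) > class_frac * len(pairs):
            victim = class_pairs.pop()
            pairs.remove(victim)
    return pairs


def generate_matched_randoms(
    real_pairs: Sequence[Pair],
    target_overlap: float = 0.8,
    seed: Optional[int] = None,
    max_iter: int = 1000,
) -> tuple[list[Pair], float, bool]:
    """Frequency-matched random pairings of the real set's proteins.

    Proteins are re-paired at their real frequencies; self-pairs and any real
    (unordered) pair are excluded.  Reshuffles until the fraction of proteins
    whose frequency in the random set equals their real frequency exceeds
    ``target_overlap``.  Returns ``(pairs, overlap, converged)`` — the best
    attempt is returned flagged when max_iter is exhausted.
    """
    real = {_norm(*p) for p in real_pairs}
    tokens = [p for pair in real for p in pair]
    if len(set(tokens)) < 2:
        return [], 0.0, False
    real_freq = Counter(tokens)
    rng = random.Random(seed)
    best: tuple[float, list[Pair]] = (-1.0, [])
    for _ in range(max_iter):
        rng.shuffle(tokens)
        cand = []
        for i in range(0, len(tokens) - 1, 2):
            a, b = tokens[i], tokens[i + 1]
            if a == b:
                continue
            p = _norm(a, b)
            if p in real:
                continue
            cand.append(p)
        rand_freq = Counter(p for pair in cand for p in pair)
        matched = sum(1 for p, n in real_freq.items() if rand_freq.get(p, 0) == n)
        overlap = matched / len(real_freq)
        if overlap > best[0]:
            best = (overlap, cand)
        if overlap > target_overlap:
            return cand, overlap, True
    return best[1], best[0], False


def extract_decoy_pairs(
    chains: dict[str, list],
    d_max: float = 5.0,
    min_contact_pairs: int = 10,
) -> list[tuple[str, str]]:
    """Non-contacting chain pairs of a resolved multi-chain complex.

    ``chains`` maps chain id to a list of :class:`ResidueRecord`.  Two chains
    are *in contact* when at least ``min_contact_pairs`` residue pairs have
    heavy atoms closer than ``d_max``; every unordered chain pair below that
    is emitted as a decoy candidate.
    """
    if len(chains) < 3:
        raise ValueError("decoys are extracted from complexes with >= 3 chains")
    ids = sorted(chains)
    out = []
    for i, ca in enumerate(ids):
        for cb in ids[i + 1 :]:
            n_close = _close_residue_pairs(chains[ca], chains[cb], d_max)
            if n_close < min_contact_pairs:
                out.append((ca, cb))
    return out


def _close_residue_pairs(res_a, res_b, d_max: float) -> int:
    from scipy.spatial import cKDTree

    coords_a, idx_a = [], []
    for i, r in enumerate(res_a):
        for at in r.heavy_atoms:
            coords_a.append(at.coords)
            idx_a.append(i)
    coords_b, idx_b = [], []
    for j, r in enumerate(res_b):
        for at in r.heavy_atoms:
            coords_b.append(at.coords)
            idx_b.append(j)
    if not coords_a or not coords_b:
        return 0
    dok = cKDTree(np.asarray(coords_a)).sparse_distance_matrix(
        cKDTree(np.asarray(coords_b)), d_max, output_type="dict"
    )
    pairs = {
        (idx_a[ia], idx_b[ib]) for (ia, ib), d in dok.items() if d < d_max
    }
    return len(pairs)


def homology_reduce(
    pairs: Sequence[Pair], clusters: dict[str, int], seed: Optional[int] = None
) -> list[Pair]:
    """One random survivor per unordered cluster-id pair group."""
    rng = random.Random(seed)
    groups: dict[tuple, list[Pair]] = {}
    for p in pairs:
        a, b = _norm(*p)
        for x in (a, b):
            if x not in clusters:
                raise KeyError(f"protein {x!r} missing from the cluster map")
        key = tuple(sorted((clusters[a], clusters[b])))
        groups.setdefault(key, []).append((a, b))
    survivors = [rng.choice(members) for _, members in sorted(groups.items())]
    return sorted(survivors)


def purge_pdb_homologs(
    negative_pairs: Sequence[Pair],
    interacting_cluster_pairs: set,
    clusters: dict[str, int],
) -> list[Pair]:
    """Drop negatives whose cluster-id pair matches a PDB-interacting pair."""
    out = []
    for p in negative_pairs:
        a, b = _norm(*p)
        key = tuple(sorted((clusters[a], clusters[b])))
        if key not in interacting_cluster_pairs:
            out.append((a, b))
    return out


def dockq_filter(
    pair_scores: dict[Pair, float] | Sequence[tuple[str, str, float]],
    cutoff: float = 0.23,
) -> list[Pair]:
    """Pairs whose max-over-models DockQ is strictly above the cutoff.

    DockQ itself is computed externally; this consumes the per-pair maxima.
    Pairs with a missing (None/NaN) score are dropped with a warning.
    """
    if not isinstance(pair_scores, dict):
        pair_scores = {_norm(a, b): s for a, b, s in pair_scores}
    kept = []
    for pair, s in sorted(pair_scores.items()):
        if s is None or (isinstance(s, float) and np.isnan(s)):
            warnings.warn(f"pair {pair} has no DockQ score; dropped")
            continue
        if s > cutoff:
            kept.append(_norm(*pair))
    return kept


def greedy_kmer_clusters(
    sequences: dict[str, str], k: int = 3, similarity: float = 0.3
) -> dict[str, int]:
    """Tiny greedy k-mer-Jaccard clustering fallback for tests.

    Each protein joins the first existing cluster whose representative shares
    a k-mer Jaccard similarity >= ``similarity``; otherwise it founds a new
    cluster.  This is a stand-in backend for an external sequence-clustering
    tool, adequate only for small fixtures.
    """
    def kmers(s):
        return {s[i : i + k] for i in range(max(1, len(s) - k + 1))}

    reps: list[tuple[int, set]] = []
    out = {}
    for pid in sorted(sequences):
        km = kmers(sequences[pid])
        for cid, rk in reps:
            inter = len(km & rk)
            union = len(km | rk) or 1
            if inter / union >= similarity:
                out[pid] = cid
                break
        else:
            cid = len(reps)
            reps.append((cid, km))
            out[pid] = cid
    return out
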