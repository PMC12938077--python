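"""The 12-feature representation of a pseudo two-way junction.

Features, in fixed serialization order:

==========  =====================================================  ========
name        meaning                                                units
==========  =====================================================  ========
L0          length of the loop directly connecting H1 and H2       nt
L1, L2      unpaired segments flanking the far ends of H1, H2      nt
A_L0..A_L2  consecutive-adenine statistic of each loop             nt
L_H1, L_H2  stem lengths                                           bp
N           intervening stems between H1 and H2 (parent order - 2) count
dG_H1/dG_H2 helix free energies                                    kcal/mol
dG_coax     coaxial stacking free energy of the pair               kcal/mol
==========  =====================================================  ========

Also provides the cosine feature-similarity score Fs used to relate a
query pair to training samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .secondary_structure import PseudoTwoWayJunction
from .thermodynamics import TurnerParameterSet, coaxial_stack_energy, helix_free_energy

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "consecutive_adenines",
    "extract_features",
    "features_to_frame",
    "feature_cosine_similarity",
    "rank_similar_training_samples",
]

FEATURE_NAMES = (
    "L0", "L1", "L2",
    "A_L0", "A_L1", "A_L2",
    "L_H1", "L_H2", "N",
    "dG_H1", "dG_H2", "dG_coax",
)


@dataclass(frozen=True)
class FeatureVector:
    L0: int
    L1: int
    L2: int
    A_L0: int
    A_L1: int
    A_L2: int
    L_H1: int
    L_H2: int
    N: int
    dG_H1: float
    dG_H2: float
    dG_coax: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def consecutive_adenines(loop_seq: str, mode: str = "longest_run") -> int:
    """Consecutive-adenine statistic of a loop sequence.

    ``mode="longest_run"`` (default) returns the length of the longest run of
    consecutive A's; ``mode="total"`` returns the total adenine count.  The
    default reflects the run-based reading of the statistic; the alternative
    is exposed because the definition admits either interpretation.
    """
    bad = set(loop_seq) - set("ACGU")
    if bad:
        raise ValueError(f"illegal loop characters: {sorted(bad)}")
    if mode == "total":
        return loop_seq.count("A")
    if mode != "longest_run":
        raise ValueError(f"unknown mode {mode!r}")
    best = cur = 0
    for ch in loop_seq:
        cur = cur + 1 if ch == "A" else 0
        best = max(best, cur)
    return best


def extract_features(
    pair: PseudoTwoWayJunction,
    params: TurnerParameterSet,
    adenine_mode: str = "longest_run",
) -> FeatureVector:
    """Assemble the 12-dimensional feature vector of a pseudo two-way pair."""
    return FeatureVector(
        L0=len(pair.loop0_seq),
        L1=len(pair.loop1_seq),
        L2=len(pair.loop2_seq),
        A_L0=consecutive_adenines(pair.loop0_seq, adenine_mode),
        A_L1=consecutive_adenines(pair.loop1_seq, adenine_mode),
        A_L2=consecutive_adenines(pair.loop2_seq, adenine_mode),
        L_H1=pair.h1.length_bp,
        L_H2=pair.h2.length_bp,
        N=pair.intervening_stem_count,
        dG_H1=helix_free_energy(pair.h1, params).total,
        dG_H2=helix_free_energy(pair.h2, params).total,
        dG_coax=coaxial_stack_energy(pair, params),
    )


def features_to_frame(
    pairs: list[PseudoTwoWayJunction],
    params: TurnerParameterSet,
    adenine_mode: str = "longest_run",
) -> pd.DataFrame:
    """Feature table with id/parent_order columns plus the 12 features.

    A ``label`` column is attached when every pair carries a label.
    """
    rows = []
    for p in pairs:
        fv = extract_features(p, params, adenine_mode)
        row = {"pair_id": p.pair_id, "parent_order": p.parent_order}
        row.update({name: getattr(fv, name) for name in FEATURE_NAMES})
        if p.label is not None:
            row["label"] = p.label
        rows.append(row)
    return pd.DataFrame(rows)


def feature_cosine_similarity(u, v) -> float:
    """Cosine similarity Fs in [-1, 1] between two 12-feature vectors."""
    ua = u.as_array() if isinstance(u, FeatureVector) else np.asarray(u, dtype=float)
    va = v.as_array() if isinstance(v, FeatureVector) else np.asarray(v, dtype=float)
    if not (np.isfinite(ua).all() and np.isfinite(va).all()):
        raise ValueError("non-finite feature vector")
    nu, nv = np.linalg.norm(ua), np.linalg.norm(va)
    if nu == 0 or nv == 0:
        raise ValueError("zero-norm feature vector")
    return float(np.clip(ua @ va / (nu * nv), -1.0, 1.0))


def rank_similar_training_samples(
    query,
    training_set,
    k: int,
    ids: list[str] | None = None,
    standardize: bool = True,
) -> list[tuple[str, float]]:
    """Top-k training samples by Fs, descending, stable tie-break by id.

    Mixed-unit raw features are dominated by the energy terms, so vectors
    are z-scored with training-set statistics before the cosine (disable
    with ``standardize=False``).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(training_set) == 0:
        raise ValueError("empty training set")
    X = np.vstack([
        t.as_array() if isinstance(t, FeatureVector) else np.asarray(t, dtype=float)
        for t in training_set
    ])
    q = query.as_array() if isinstance(query, FeatureVector) else np.asarray(query, dtype=float)
    if ids is None:
        ids = [str(i) for i in range(len(training_set))]
    if standardize:
        mean, std = X.mean(axis=0), X.std(axis=0)
        std[std == 0] = 1.0
        X = (X - mean) / std
        q = (q - mean) / std
        # a constant query column may land exactly on zero after z-scoring
        if np.linalg.norm(q) == 0:
            raise ValueError("query is identical to the training mean after z-scoring")
    scores = [(ids[i], feature_cosine_similarity(q, X[i])) for i in range(len(X))]
    scores.sort(key=lambda t: (-t[1], t[0]))
    if k > len(scores):
        warnings.warn(f"k={k} exceeds training-set size {len(scores)}; returning all")
        k = len(scores)
    return scores[:k]
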