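"""Dataset curation: structure-level redundancy filtering and splitting.

Junction records are deduplicated at the secondary-structure level: every
pair of dot-bracket strings is globally aligned (Needleman-Wunsch, +2
match / -1 mismatch / -2 gap) and pairs whose similarity exceeds a cutoff
(default 0.90) are grouped by single linkage, keeping one representative
per group.  The retained records are split per junction order at a
configurable training fraction (default 0.85); orders with only a handful
of members are routed wholly to the test split so that rare topologies
probe generalization rather than leak into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .reconstruction import StackingConfiguration

__all__ = [
    "JunctionRecord",
    "CurationConfig",
    "nw_align",
    "dotbracket_nw_similarity",
    "redundancy_filter",
    "split_dataset",
]


@dataclass(frozen=True)
class JunctionRecord:
    """One curated junction: sequence, dot-bracket, order, optional provenance."""

    id: str
    sequence: str
    structure: str
    order: int
    source: str = ""
    truth: Optional[StackingConfiguration] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise ValueError(f"{self.id}: sequence/structure length mismatch")


@dataclass(frozen=True)
class CurationConfig:
    structure_similarity_cutoff: float = 0.90
    nw_match: float = 2.0
    nw_mismatch: float = -1.0
    nw_gap: float = -2.0
    split_fraction: float = 0.85
    seed: int = 0
    rare_order_max: int = 3
    similarity_denominator: str = "alignment"  # or "shorter"

    def __post_init__(self) -> None:
        if not 0 < self.structure_similarity_cutoff <= 1:
            raise ValueError("cutoff must be in (0, 1]")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")


def nw_align(
    s1: str, s2: str, config: CurationConfig = CurationConfig()
) -> tuple[float, str, str]:
    """Global Needleman-Wunsch alignment with the configured scores.

    Returns (score, aligned1, aligned2) with ``-`` as the gap character.
    Traceback ties break deterministically diagonal > up > left.
    """
    if not s1 or not s2:
        raise ValueError("cannot align empty strings")
    m, g, x = config.nw_match, config.nw_gap, config.nw_mismatch
    n1, n2 = len(s1), len(s2)
    score = np.zeros((n1 + 1, n2 + 1))
    score[:, 0] = np.arange(n1 + 1) * g
    score[0, :] = np.arange(n2 + 1) * g
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            diag = score[i - 1, j - 1] + (m if s1[i - 1] == s2[j - 1] else x)
            score[i, j] = max(diag, score[i - 1, j] + g, score[i, j - 1] + g)
    a1, a2 = [], []
    i, j = n1, n2
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
            m if s1[i - 1] == s2[j - 1] else x
        ):
            a1.append(s1[i - 1]); a2.append(s2[j - 1]); i -= 1; j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + g:
            a1.append(s1[i - 1]); a2.append("-"); i -= 1
        else:
            a1.append("-"); a2.append(s2[j - 1]); j -= 1
    return float(score[n1, n2]), "".join(reversed(a1)), "".join(reversed(a2))


def dotbracket_nw_similarity(
    s1: str, s2: str, config: CurationConfig = CurationConfig()
) -> float:
    """Secondary-structure similarity: identical aligned positions over the
    alignment length (or the shorter input, per configuration)."""
    _, a1, a2 = nw_align(s1, s2, config)
    matches = sum(c1 == c2 and c1 != "-" for c1, c2 in zip(a1, a2))
    if config.similarity_denominator == "alignment":
        return matches / len(a1)
    if config.similarity_denominator == "shorter":
        return matches / min(len(s1), len(s2))
    raise ValueError("similarity_denominator must be 'alignment' or 'shorter'")


def redundancy_filter(
    records: Sequence[JunctionRecord], config: CurationConfig = CurationConfig()
) -> list[JunctionRecord]:
    """Collapse structurally redundant junctions to one representative each.

    Pairs with similarity strictly above the cutoff are linked; groups are
    the connected components (single linkage, so a chain A~B~C collapses
    even if A and C are dissimilar).  The representative is the record with
    the lexicographically smallest id; output preserves input order.
    """
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            sim = dotbracket_nw_similarity(records[i].structure, records[j].structure, config)
            if sim > config.structure_similarity_cutoff:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    keep = set()
    for members in groups.values():
        keep.add(min(members, key=lambda i: (records[i].id, i)))
    return [r for i, r in enumerate(records) if i in keep]


def split_dataset(
    records: Sequence[JunctionRecord], config: CurationConfig = CurationConfig()
) -> tuple[list[JunctionRecord], list[JunctionRecord]]:
    """Per-order stratified train/test split at ``split_fraction``.

    Orders with at most ``rare_order_max`` members go wholly to the test
    split.  Seeded and deterministic; train and test partition the input.
    """
    if not records:
        raise ValueError("empty record list")
    rng = np.random.default_rng(config.seed)
    by_order: dict[int, list[JunctionRecord]] = {}
    for r in records:
        by_order.setdefault(r.order, []).append(r)
    train: list[JunctionRecord] = []
    test: list[JunctionRecord] = []
    for order in sorted(by_order):
        members = by_order[order]
        if len(members) <= config.rare_order_max:
            test.extend(members)
            continue
        idx = rng.permutation(len(members))
        n_train = round(config.split_fraction * len(members))
        train.extend(members[i] for i in sorted(idx[:n_train]))
        test.extend(members[i] for i in sorted(idx[n_train:]))
    return train, test
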