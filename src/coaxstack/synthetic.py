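"""Synthetic junction datasets with a planted stacking rule.

Generates syntactically valid dot-bracket records realizing junctions of
orders two to seven: a closing stem enclosing ``order - 1`` hairpin stems
separated by short unpaired segments.  Stems are random complementary
duplexes with a small GU-wobble fraction; loop lengths follow a truncated
geometric distribution favoring the short connecting loops seen in real
junctions.

Ground-truth stacking is planted on the physical signal the predictor is
meant to learn: the log-odds of a pair stacking decrease with the length
of the connecting loop and with a less favorable coaxial stacking energy,

    logit P(stack) = alpha - beta_l0 * L0 - beta_dg * dG_coax.

Per-pair draws are then projected to a valid matching (greedy resolution
dropping the lower-odds member of any conflict), mimicking the physical
mutual exclusivity of stacking partners.  The intercept ``alpha`` can be
calibrated by bisection so the achieved stacked:unstacked ratio matches a
target (default 6:1, the imbalance typical of curated junction sets);
reaching that ratio requires the two-way-dominated default order mix,
since an n-way junction can stack at most floor(n/2) of its n pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .features import features_to_frame
from .reconstruction import StackingConfiguration
from .secondary_structure import (
    DbnRecord,
    Junction,
    PseudoTwoWayJunction,
    decompose_junction,
    extract_junctions,
    parse_dbn,
)
from .thermodynamics import TurnerParameterSet, coaxial_stack_energy, load_turner_params

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate_junction", "generate_dataset"]

_WC = ("AU", "UA", "CG", "GC")
_GU = ("GU", "UG")

DEFAULT_ORDER_DISTRIBUTION = {2: 0.95, 3: 0.015, 4: 0.015, 5: 0.01, 6: 0.005, 7: 0.005}
DEFAULT_RULE = {"alpha": 9.0, "beta_l0": 1.5, "beta_dg": 0.5}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic data.

    Defaults emulate a curated junction collection: orders two to seven
    with two-way junctions dominating, 2-8 bp stems with 10% GU pairs,
    geometrically distributed loop lengths (most 0-4 nt), and a planted
    rule driven by L0 and dG_coax calibrated to a 6:1 stacked:unstacked
    pair-label ratio.
    """

    seed: int
    n_junctions: int = 600
    order_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ORDER_DISTRIBUTION)
    )
    stem_length_range: tuple[int, int] = (2, 8)
    loop_length_range: tuple[int, int] = (0, 12)
    loop_geometric_p: float = 0.35
    hairpin_loop_range: tuple[int, int] = (3, 7)
    gu_fraction: float = 0.10
    planted_rule_params: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RULE))
    label_noise: float = 0.0
    class_balance_target: Optional[float] = 6.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        for lo, hi in (self.stem_length_range, self.loop_length_range, self.hairpin_loop_range):
            if lo > hi or lo < 0:
                raise ValueError("invalid range")
        if self.hairpin_loop_range[0] < 3:
            raise ValueError("hairpin loops need >= 3 nt")
        if abs(sum(self.order_distribution.values()) - 1.0) > 1e-6:
            raise ValueError("order_distribution weights must sum to 1")
        if not set(self.order_distribution) <= set(range(2, 8)):
            raise ValueError("orders must lie in 2..7")


@dataclass
class SyntheticDataset:
    records: list[DbnRecord]
    junctions: list[Junction]
    truths: list[StackingConfiguration]
    pairs: list[PseudoTwoWayJunction]
    table: pd.DataFrame
    alpha: float
    achieved_ratio: Optional[float]


def _sample_loop_len(rng: np.random.Generator, config: GeneratorConfig) -> int:
    lo, hi = config.loop_length_range
    if lo == hi:
        return lo
    k = lo + int(rng.geometric(config.loop_geometric_p)) - 1
    return min(k, hi)


def _sample_stem(rng: np.random.Generator, length: int, gu_fraction: float) -> tuple[str, str]:
    """Random duplex as (5'-strand, aligned 3'-strand)."""
    b5, b3 = [], []
    for _ in range(length):
        pool = _GU if rng.random() < gu_fraction else _WC
        pair = pool[int(rng.integers(len(pool)))]
        b5.append(pair[0])
        b3.append(pair[1])
    return "".join(b5), "".join(b3)


def _random_loop(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGU"[int(i)] for i in rng.integers(0, 4, size=length))


def _build_record(order_n: int, config: GeneratorConfig, rng: np.random.Generator,
                  rec_id: str) -> DbnRecord:
    lo_s, hi_s = config.stem_length_range
    segments = [_sample_loop_len(rng, config) for _ in range(order_n)]
    if order_n == 2 and segments[0] == 0 and segments[1] == 0:
        if config.loop_length_range[1] == 0:
            raise ValueError("infeasible geometry: two-way junction needs a nonzero loop")
        segments[1] = max(1, _sample_loop_len(rng, config))
    outer5, outer3 = _sample_stem(rng, int(rng.integers(lo_s, hi_s + 1)), config.gu_fraction)
    seq_parts = [outer5, _random_loop(rng, segments[0])]
    struct_parts = ["(" * len(outer5), "." * segments[0]]
    for k in range(order_n - 1):
        c5, c3 = _sample_stem(rng, int(rng.integers(lo_s, hi_s + 1)), config.gu_fraction)
        hp = int(rng.integers(config.hairpin_loop_range[0], config.hairpin_loop_range[1] + 1))
        seq_parts += [c5, _random_loop(rng, hp), c3[::-1], _random_loop(rng, segments[k + 1])]
        struct_parts += ["(" * len(c5), "." * hp, ")" * len(c3), "." * segments[k + 1]]
    seq_parts.append(outer3[::-1])
    struct_parts.append(")" * len(outer3))
    return DbnRecord(id=rec_id, sequence="".join(seq_parts), structure="".join(struct_parts))


def _pair_logits(
    pairs: list[PseudoTwoWayJunction],
    params: TurnerParameterSet,
    rule: dict[str, float],
) -> np.ndarray:
    """alpha-free part of the planted log-odds (add alpha to obtain logits)."""
    out = np.empty(len(pairs))
    for i, p in enumerate(pairs):
        out[i] = -rule["beta_l0"] * len(p.loop0_seq) - rule["beta_dg"] * coaxial_stack_energy(
            p, params
        )
    return out


def _project_matching(
    edges: list[tuple[int, int]], wanted: np.ndarray, probs: np.ndarray
) -> frozenset[tuple[int, int]]:
    """Greedy conflict resolution: keep wanted edges by descending odds."""
    order = sorted(
        (i for i in range(len(edges)) if wanted[i]),
        key=lambda i: (-probs[i], edges[i]),
    )
    used: set[int] = set()
    kept: set[tuple[int, int]] = set()
    for i in order:
        u, v = edges[i]
        if u not in used and v not in used:
            kept.add(edges[i])
            used.update((u, v))
    return frozenset(kept)


def _labels_for(
    alpha: float,
    base_logits: np.ndarray,
    u: np.ndarray,
    noise_u: np.ndarray,
    noise: float,
    groups: list[tuple[list[int], list[tuple[int, int]]]],
) -> tuple[np.ndarray, list[frozenset]]:
    p = 1.0 / (1.0 + np.exp(-(alpha + base_logits)))
    wanted = u < p
    if noise > 0:
        wanted = np.where(noise_u < noise, ~wanted, wanted)
    labels = np.zeros(len(p), dtype=int)
    truths: list[frozenset] = []
    for idx, edges in groups:
        kept = _project_matching(edges, wanted[idx], p[idx])
        truths.append(kept)
        for k, i in enumerate(idx):
            labels[i] = int(edges[k] in kept)
    return labels, truths


def generate_junction(
    order_n: int,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    params: Optional[TurnerParameterSet] = None,
    rec_id: str = "synthetic",
) -> tuple[DbnRecord, Junction, StackingConfiguration]:
    """One random junction record with its parsed junction and planted truth."""
    if not 2 <= order_n <= 7:
        raise ValueError("order must be in 2..7")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    params = load_turner_params() if params is None else params
    record = _build_record(order_n, config, rng, rec_id)
    junctions = extract_junctions(record)
    (junction,) = [j for j in junctions if j.order_n == order_n]
    pairs = decompose_junction(junction)
    base = _pair_logits(pairs, params, config.planted_rule_params)
    u = rng.random(len(pairs))
    noise_u = rng.random(len(pairs))
    edges = [p.stem_indices for p in pairs]
    labels, truths = _labels_for(
        config.planted_rule_params["alpha"], base, u, noise_u, config.label_noise,
        [(list(range(len(pairs))), edges)],
    )
    truth = StackingConfiguration(
        junction_id=rec_id, order_n=order_n, stacked_pairs=truths[0]
    )
    return record, junction, truth


def generate_dataset(
    config: GeneratorConfig, params: Optional[TurnerParameterSet] = None
) -> SyntheticDataset:
    """Full labeled dataset: records, truths, and the pair feature table.

    When ``class_balance_target`` is set, the planted-rule intercept is
    calibrated by bisection (reusing fixed uniform draws, so the result is
    deterministic) to bring the stacked:unstacked pair ratio to target.
    """
    rng = np.random.default_rng(config.seed)
    params = load_turner_params() if params is None else params
    orders = sorted(config.order_distribution)
    weights = np.array([config.order_distribution[o] for o in orders], dtype=float)
    sampled = rng.choice(orders, size=config.n_junctions, p=weights / weights.sum())

    records: list[DbnRecord] = []
    junctions: list[Junction] = []
    all_pairs: list[PseudoTwoWayJunction] = []
    groups: list[tuple[list[int], list[tuple[int, int]]]] = []
    for k, order in enumerate(sampled):
        rec_id = f"syn{k:05d}"
        record = _build_record(int(order), config, rng, rec_id)
        (junction,) = [j for j in extract_junctions(record) if j.order_n == order]
        pairs = decompose_junction(junction)
        idx = list(range(len(all_pairs), len(all_pairs) + len(pairs)))
        groups.append((idx, [p.stem_indices for p in pairs]))
        records.append(record)
        junctions.append(junction)
        all_pairs.extend(pairs)

    n_pairs = len(all_pairs)
    base = _pair_logits(all_pairs, params, config.planted_rule_params)
    u = rng.random(n_pairs)
    noise_u = rng.random(n_pairs)

    alpha = config.planted_rule_params["alpha"]
    if config.class_balance_target is not None and n_pairs > 0:
        target = config.class_balance_target / (1.0 + config.class_balance_target)
        lo, hi = -40.0, 40.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            frac = _labels_for(mid, base, u, noise_u, config.label_noise, groups)[0].mean()
            if frac < target:
                lo = mid
            else:
                hi = mid
        alpha = 0.5 * (lo + hi)

    labels, truth_sets = _labels_for(alpha, base, u, noise_u, config.label_noise, groups)
    labeled_pairs = [replace(p, label=int(labels[i])) for i, p in enumerate(all_pairs)]
    truths = [
        StackingConfiguration(
            junction_id=rec.id, order_n=j.order_n, stacked_pairs=truth_sets[k]
        )
        for k, (rec, j) in enumerate(zip(records, junctions))
    ]
    table = features_to_frame(labeled_pairs, params)
    if len(table):
        table.insert(0, "junction_id", [p.pair_id.split(":")[0] for p in labeled_pairs])
    n_pos = int(labels.sum())
    ratio = (n_pos / (n_pairs - n_pos)) if n_pairs > n_pos else None
    return SyntheticDataset(
        records=records,
        junctions=junctions,
        truths=truths,
        pairs=labeled_pairs,
        table=table,
        alpha=float(alpha),
        achieved_ratio=ratio,
    )
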