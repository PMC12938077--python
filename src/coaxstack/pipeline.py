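"""End-to-end inference: record -> junctions -> pairwise scores -> configuration."""

from __future__ import annotations

from typing import Optional

from .classifier import StackingPrediction, TrainedModel, predict_pairs
from .features import features_to_frame
from .reconstruction import (
    StackingConfiguration,
    build_cycle_graph,
    configuration_label,
    max_weight_matching_cycle,
)
from .secondary_structure import DbnRecord, Junction, decompose_junction, extract_junctions
from .thermodynamics import TurnerParameterSet, load_turner_params

__all__ = ["predict_junction", "predict_record"]


def predict_junction(
    junction: Junction,
    model: TrainedModel,
    params: Optional[TurnerParameterSet] = None,
    threshold: Optional[float] = None,
) -> tuple[StackingConfiguration, list[StackingPrediction]]:
    """Predict the stacking configuration of one junction.

    Decomposes the junction into its adjacent pseudo two-way pairs, scores
    each with the forest, retains edges strictly above the threshold
    (``model.threshold`` unless overridden), and solves the maximum-weight
    matching on the cycle graph.
    """
    params = load_turner_params() if params is None else params
    threshold = model.threshold if threshold is None else threshold
    pairs = decompose_junction(junction)
    table = features_to_frame(pairs, params)
    preds = predict_pairs(
        model,
        table,
        pair_ids=[p.pair_id for p in pairs],
        stem_pairs=[p.stem_indices for p in pairs],
    )
    graph = build_cycle_graph(preds, threshold=threshold, order_n=junction.order_n)
    matching = max_weight_matching_cycle(graph)
    config = StackingConfiguration(
        junction_id=junction.source_id,
        order_n=junction.order_n,
        stacked_pairs=frozenset(matching.selected_edges),
    )
    return config, preds


def predict_record(
    record: DbnRecord,
    model: TrainedModel,
    params: Optional[TurnerParameterSet] = None,
    threshold: Optional[float] = None,
) -> list[dict]:
    """Predict every junction of a record; JSON-ready per-junction dicts."""
    params = load_turner_params() if params is None else params
    out = []
    for junction in extract_junctions(record):
        config, preds = predict_junction(junction, model, params, threshold)
        out.append(
            {
                "id": record.id,
                "order": junction.order_n,
                "pair_probabilities": {
                    p.pair_id: round(p.probability, 6) for p in preds
                },
                "retained_pairs": [
                    list(p.stem_pair) for p in preds
                    if p.probability > (model.threshold if threshold is None else threshold)
                ],
                "stacked_pairs": sorted(list(e) for e in config.stacked_pairs),
                "configuration": configuration_label(config),
            }
        )
    return out
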