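"""End-to-end helper: seeds -> profiles -> ranking in one call."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .interactome import EntityTargets, Interactome, SeedVector, make_seed_vector
from .propagation import (
    DiffusionProfile,
    TransitionOperator,
    WalkParams,
    build_transition_operator,
    propagate,
    propagate_many,
)
from .ranking import RankedList, rank_entities

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    ranking: RankedList
    disease_profile: DiffusionProfile
    profiles: dict[str, DiffusionProfile]
    excluded: list[str]  # entities with zero resolved targets
    operator: TransitionOperator


def rank_against_disease(
    interactome: Interactome,
    entities: Iterable[EntityTargets],
    disease_genes: Iterable[str],
    params: WalkParams | None = None,
    disease_id: str = "disease",
) -> PipelineResult:
    """Propagate every entity and the disease, then rank by cosine similarity.

    Entities with no target resolvable against the interactome are excluded
    from the ranking and reported in ``excluded``. Entities with identical
    resolved target sets share one propagation (identical seed vectors give
    identical profiles).
    """
    params = params or WalkParams()
    operator = build_transition_operator(interactome, params)

    disease_seed = make_seed_vector(interactome, disease_genes)
    disease_profile = propagate(operator, disease_seed, params)

    kept: list[EntityTargets] = []
    excluded: list[str] = []
    seed_by_targets: dict[frozenset[str], SeedVector] = {}
    for ent in entities:
        resolved, _ = ent.resolve(interactome)
        if not resolved:
            excluded.append(ent.entity_id)
            continue
        kept.append(ent)
        if resolved not in seed_by_targets:
            seed_by_targets[resolved] = make_seed_vector(interactome, resolved)
    if excluded:
        logger.warning("%d entit(ies) had no resolvable targets: %s",
                       len(excluded), excluded)
    if not kept:
        raise ValueError("no entity has resolvable targets")

    unique_targets = list(seed_by_targets)
    unique_profiles = propagate_many(
        operator, [seed_by_targets[t] for t in unique_targets], params
    )
    profile_by_targets = dict(zip(unique_targets, unique_profiles))

    profiles = {
        ent.entity_id: profile_by_targets[ent.resolve(interactome)[0]] for ent in kept
    }
    metadata = {e.entity_id: (e.entity_name, e.entity_class) for e in kept}
    ranking = rank_entities(profiles, disease_profile, metadata, disease_id=disease_id)
    return PipelineResult(
        ranking=ranking,
        disease_profile=disease_profile,
        profiles=profiles,
        excluded=excluded,
        operator=operator,
    )
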