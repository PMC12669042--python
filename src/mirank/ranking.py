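"""Similarity ranking, elbow-cut detection, and target-set drug classes.

Candidate entities are ranked by the cosine similarity of their diffusion
profile to the disease profile. The cutoff between top candidates and the
remainder is found by elbow detection on the sorted score curve; drugs with
identical resolved target sets form one class (they have identical seed
vectors, hence identical profiles and scores).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .interactome import EntityTargets, Interactome
from .propagation import DiffusionProfile, cosine_similarity


class RankEntry(NamedTuple):
    rank: int
    entity_id: str
    entity_name: str
    similarity: float
    entity_class: str


@dataclass
class RankedList:
    """Entities sorted by similarity descending, ranks 1..n."""

    entries: list[RankEntry]
    disease_id: str = "disease"

    def __post_init__(self) -> None:
        sims = [e.similarity for e in self.entries]
        if any(b > a for a, b in zip(sims, sims[1:])):
            raise ValueError("similarities must be non-increasing")
        if [e.rank for e in self.entries] != list(range(1, len(self.entries) + 1)):
            raise ValueError("ranks must be consecutive from 1")
        ids = [e.entity_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate entity ids in ranking")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def similarities(self) -> list[float]:
        return [e.similarity for e in self.entries]

    def top_ids(self, k: int) -> set[str]:
        if k > len(self.entries):
            raise ValueError(f"k={k} exceeds ranking length {len(self.entries)}")
        return {e.entity_id for e in self.entries[:k]}


class NoElbowError(ValueError):
    """Raised when the score curve has no positive drop anywhere."""


@dataclass
class ElbowResult:
    cut_index: int  # 1-based rank after which the drop occurs
    drop_magnitude: float
    method: str


def rank_entities(
    profiles: Mapping[str, DiffusionProfile],
    disease_profile: DiffusionProfile,
    metadata: Mapping[str, tuple[str, str]] | None = None,
    disease_id: str = "disease",
) -> RankedList:
    """Rank entities by profile cosine similarity to the disease profile.

    ``metadata`` optionally maps entity_id -> (entity_name, entity_class).
    Exact score ties are broken lexicographically by entity_id so the
    ranking is deterministic and invariant to input order.
    """
    if not profiles:
        raise ValueError("empty profile map")
    scored = sorted(
        (
            (-cosine_similarity(dp, disease_profile), eid)
            for eid, dp in profiles.items()
        ),
    )
    entries = []
    for rank, (neg_sim, eid) in enumerate(scored, start=1):
        name, eclass = (metadata or {}).get(eid, (eid, "bioactive_molecule"))
        entries.append(RankEntry(rank, eid, name, -neg_sim, eclass))
    return RankedList(entries=entries, disease_id=disease_id)


def detect_elbow(scores: Sequence[float], method: str = "max_gap") -> ElbowResult:
    """Locate the cutoff drop in a non-increasing score sequence.

    ``max_gap`` (default) cuts after the largest successive difference,
    directly operationalizing a "substantial drop" in the curve; ties go to
    the smallest index. ``chord`` is a kneedle-style variant cutting at the
    point of maximum distance below the first-to-last chord, for
    sensitivity analysis.
    """
    s = np.asarray(list(scores), dtype=np.float64)
    if s.size < 3:
        raise ValueError("need at least 3 scores for elbow detection")
    diffs = -np.diff(s)
    if np.any(diffs < -1e-12):
        raise ValueError("scores must be non-increasing")
    if np.all(diffs <= 0):
        raise NoElbowError("constant score sequence: no elbow")

    if method == "max_gap":
        cut = int(np.argmax(diffs))  # 0-based position of gap (cut after rank cut+1)
        return ElbowResult(cut_index=cut + 1, drop_magnitude=float(diffs[cut]), method=method)
    if method == "chord":
        n = s.size
        x = np.arange(n, dtype=np.float64)
        # signed distance below the chord from (0, s_0) to (n-1, s_{n-1})
        chord = s[0] + (s[-1] - s[0]) * x / (n - 1)
        below = chord - s
        cut = int(np.argmax(below[:-1]))
        cut = max(cut, 1)  # a cut must leave a non-empty top group
        return ElbowResult(
            cut_index=cut, drop_magnitude=float(diffs[cut - 1]), method=method
        )
    raise ValueError(f"unknown elbow method {method!r}")


@dataclass
class TargetClass:
    """A group of entities sharing one exact resolved target set."""

    class_id: int
    member_ids: list[str]
    target_set: frozenset[str]
    similarity: float


def group_by_target_set(
    entities: Iterable[EntityTargets],
    ranked: RankedList,
    interactome: Interactome | None = None,
) -> list[TargetClass]:
    """Partition ranked entities into classes by exact target-set equality.

    Entities with identical resolved target sets have identical seed
    vectors, hence identical diffusion profiles and similarity scores; each
    class carries the shared score. Classes are ordered by similarity
    descending (ties: lexicographic smallest member id).
    """
    sim = {e.entity_id: e.similarity for e in ranked.entries}
    by_id = {e.entity_id: e for e in entities}
    groups: dict[frozenset[str], list[str]] = {}
    for entry in ranked.entries:
        ent = by_id.get(entry.entity_id)
        if ent is None:
            raise ValueError(f"ranked entity {entry.entity_id!r} has no target set")
        targets = (
            ent.resolve(interactome)[0] if interactome is not None else ent.target_ids
        )
        groups.setdefault(frozenset(targets), []).append(entry.entity_id)

    classes = []
    for targets, members in groups.items():
        members = sorted(members)
        sims = [sim[m] for m in members]
        if max(sims) - min(sims) > 1e-9:
            raise ValueError(
                f"members of one target-set class have differing scores: {members}"
            )
        classes.append(TargetClass(0, members, targets, sims[0]))
    classes.sort(key=lambda c: (-c.similarity, c.member_ids[0]))
    for i, c in enumerate(classes, start=1):
        c.class_id = i
    return classes


def write_ranking(path: str | Path, ranked: RankedList) -> None:
    """Ranking CSV: ``rank,entity_id,entity_name,entity_class,similarity``."""
    df = pd.DataFrame(ranked.entries)
    df["similarity"] = df["similarity"].map(lambda v: f"{v:.6f}")
    df[["rank", "entity_id", "entity_name", "entity_class", "similarity"]].to_csv(
        path, index=False
    )


def write_classes(path: str | Path, classes: Sequence[TargetClass]) -> None:
    rows = [
        {
            "class_id": c.class_id,
            "member_count": len(c.member_ids),
            "members": ";".join(c.member_ids),
            "target_set": ";".join(sorted(c.target_set)),
            "similarity": f"{c.similarity:.6f}",
        }
        for c in classes
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
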