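"""Statistical validation of a ranking.

Three validation instruments:

* **Benefit enrichment** — the top-of-ranking group versus the next group
  as a 2x2 contingency table of literature benefit categories, tested with
  Fisher's exact test (exact hypergeometric arithmetic, no asymptotic
  approximation).
* **Overlap baseline** — direct target/disease-gene set overlap (binary
  cosine), the standard non-propagation baseline; a molecule scores zero
  iff its targets are disjoint from the disease genes.
* **Gene-subset robustness** — the full pipeline re-run with a subset of
  the disease genes, comparing top-k membership between the two rankings.

Benefit categories follow a four-class scheme: (a) literature shows
potential therapeutic benefit, (b) found in food items showing potential
benefit, (c) harmful or not beneficial, (d) no supporting literature.
Classes {a, b} count as beneficial ("success"), {c, d} as not.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .interactome import EntityTargets, Interactome
from .ranking import RankedList

BENEFIT_CATEGORIES = ("a", "b", "c", "d")
BENEFICIAL = frozenset({"a", "b"})


@dataclass
class BenefitCategorization:
    """entity_id -> benefit category in {a, b, c, d}."""

    categories: dict[str, str]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.categories.items() if v not in BENEFIT_CATEGORIES}
        if bad:
            raise ValueError(f"invalid benefit categories: {bad}")

    def is_beneficial(self, entity_id: str) -> bool:
        return self.categories[entity_id] in BENEFICIAL

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.categories


def read_benefit_categorization(path: str | Path) -> BenefitCategorization:
    """Read a categorization TSV (``entity_id\\tcategory``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns)[:2] != ["entity_id", "category"]:
        raise ValueError(f"{path}: expected columns entity_id, category")
    return BenefitCategorization(dict(zip(df["entity_id"], df["category"])))


def write_benefit_categorization(
    path: str | Path, categorization: BenefitCategorization
) -> None:
    pd.DataFrame(
        sorted(categorization.categories.items()), columns=["entity_id", "category"]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class ContingencyTable:
    """2x2 counts: rows = (top group, next group), cols = (beneficial, not)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if np.any(self.counts.sum(axis=1) == 0):
            raise ValueError("both row sums must be positive")


def build_contingency(
    ranked: RankedList,
    categorization: BenefitCategorization,
    cut: int,
    window: int,
) -> ContingencyTable:
    """Count beneficial/not-beneficial in ranks 1..cut vs cut+1..cut+window."""
    if cut < 1 or window < 1:
        raise ValueError("cut and window must be >= 1")
    if cut + window > len(ranked):
        raise ValueError(
            f"cut+window={cut + window} exceeds ranking length {len(ranked)}"
        )
    span = ranked.entries[: cut + window]
    missing = [e.entity_id for e in span if e.entity_id not in categorization]
    if missing:
        raise ValueError(f"uncategorized entities in range: {missing}")
    counts = np.zeros((2, 2), dtype=np.int64)
    for e in span:
        row = 0 if e.rank <= cut else 1
        col = 0 if categorization.is_beneficial(e.entity_id) else 1
        counts[row, col] += 1
    return ContingencyTable(counts)


def _hypergeom_numerators(n_total: int, k_success: int, n_draw: int) -> tuple[range, list[int]]:
    """Integer numerators C(K,a)*C(N-K,n-a) over the feasible support.

    All outcomes share the denominator C(N, n), so probabilities can be
    compared and summed in exact integer arithmetic.
    """
    lo = max(0, n_draw - (n_total - k_success))
    hi = min(n_draw, k_success)
    support = range(lo, hi + 1)
    nums = [
        math.comb(k_success, a) * math.comb(n_total - k_success, n_draw - a)
        for a in support
    ]
    return support, nums


def fisher_exact(
    table: ContingencyTable | np.ndarray, alternative: str = "greater"
) -> float:
    """Exact Fisher test p-value for a 2x2 benefit table.

    ``greater``: upper-tail probability of at least the observed top-group
    beneficial count given the margins. ``two_sided``: sum of all outcome
    probabilities no larger than the observed outcome's. Computed with
    exact integer hypergeometric arithmetic (arbitrary-precision), so
    results are correctly rounded floats with no asymptotic approximation.
    """
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    a = int(counts[0, 0])
    r1 = int(counts[0, 0] + counts[0, 1])
    c1 = int(counts[0, 0] + counts[1, 0])
    n = int(counts.sum())
    if r1 == 0 or n - r1 == 0 or c1 == 0 or n - c1 == 0:
        warnings.warn("degenerate margins: Fisher p-value is 1", stacklevel=2)
        return 1.0
    support, nums = _hypergeom_numerators(n, c1, r1)
    denom = math.comb(n, r1)
    obs = nums[a - support.start]
    if alternative == "greater":
        tail = sum(num for x, num in zip(support, nums) if x >= a)
    else:
        tail = sum(num for num in nums if num <= obs)
    return float(Fraction(tail, denom))


def overlap_similarity(targets: Iterable[str], disease_genes: Iterable[str]) -> float:
    """Binary-vector cosine between a target set and the disease gene set.

    |T n D| / sqrt(|T| * |D|); zero iff the sets are disjoint, so the
    "non-zero similarity" filter depends only on direct overlap.
    """
    t, d = set(targets), set(disease_genes)
    if not t or not d:
        raise ValueError("empty input set")
    return len(t & d) / math.sqrt(len(t) * len(d))


def top_k_overlap(
    ranking_a: RankedList, ranking_b: RankedList, k_a: int, k_b: int
) -> int:
    """Size of the intersection of the two rankings' top segments."""
    return len(ranking_a.top_ids(k_a) & ranking_b.top_ids(k_b))


@dataclass
class SubsetRobustnessReport:
    """Paired full/subset rankings and their agreement statistics."""

    full_ranking: RankedList
    subset_ranking: RankedList
    overlaps: dict[tuple[int, int], int]
    full_nonzero_overlap_count: int
    subset_nonzero_overlap_count: int


def subset_robustness(
    interactome: Interactome,
    entities: list[EntityTargets],
    full_gene_list: Iterable[str],
    subset_gene_list: Iterable[str],
    params,
    k_pairs: Iterable[tuple[int, int]] = ((10, 10), (20, 10)),
) -> SubsetRobustnessReport:
    """Compare rankings from the full disease gene list and a subset.

    Runs the propagation+ranking pipeline twice (full and subset seed
    vectors), reports top-k membership overlap for each configured
    (k_full, k_subset) pair, and counts molecules with non-zero direct
    overlap baseline similarity under each gene list.
    """
    from .pipeline import rank_against_disease

    full = set(full_gene_list)
    subset = set(subset_gene_list)
    resolved_full = {g for g in full if g in interactome.node_index}
    resolved_subset = {g for g in subset if g in interactome.node_index}
    if not resolved_subset <= resolved_full:
        raise ValueError("subset gene list is not contained in the full list")

    ranking_full = rank_against_disease(interactome, entities, full, params).ranking
    ranking_subset = rank_against_disease(interactome, entities, subset, params).ranking

    overlaps = {
        (ka, kb): top_k_overlap(ranking_full, ranking_subset, ka, kb)
        for ka, kb in k_pairs
    }

    def _nonzero_count(genes: set[str]) -> int:
        count = 0
        for ent in entities:
            resolved, _ = ent.resolve(interactome)
            if resolved and len(resolved & genes) > 0:
                count += 1
        return count

    return SubsetRobustnessReport(
        full_ranking=ranking_full,
        subset_ranking=ranking_subset,
        overlaps=overlaps,
        full_nonzero_overlap_count=_nonzero_count(resolved_full),
        subset_nonzero_overlap_count=_nonzero_count(resolved_subset),
    )
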