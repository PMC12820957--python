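"""Direction-aware relative ranking and consensus schemes.

Docking programs emit scores on incompatible scales (fitness values,
docking energies, MM-GBSA binding energies), so ligands are compared by
relative rank within each scoring function: rank 1 is the most favorable
ligand under that function's direction, ties receive average (fractional)
ranks.  Two consensus schemes combine the per-function ranks:

* aggregated rank (rank-by-rank): per-ligand ranks are summed into a Borda
  count and the Borda counts are themselves ranked ascending;
* exponential consensus rank (ECR): ecr(i) = sum_j (1/sigma) exp(-r_ij/sigma),
  which rewards ligands ranked consistently high by several functions.
  sigma defaults to 10; larger ECR is more favorable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import Direction, ScoreTable, ScoringFunctionSpec

__all__ = [
    "RankTable",
    "ConsensusResult",
    "relative_ranks",
    "borda_aggregate",
    "ecr_scores",
    "consensus",
    "majority_vote_preference",
]

MissingPolicy = Literal["worst_rank", "omit"]


@dataclass
class RankTable:
    """Per-function relative ranks for one target.

    ``ranks`` is ligand x function; NaN marks a (ligand, function) pair
    omitted under the ``omit`` missing policy.  ``n_ranked`` counts ligands
    with an observed score per function.
    """

    target_id: str
    ranks: pd.DataFrame
    n_ranked: dict[str, int]


@dataclass
class ConsensusResult:
    """Borda counts, aggregated ranks and/or ECR values for one target."""

    target_id: str
    borda: pd.Series | None = None
    aggregated_rank: pd.Series | None = None
    ecr: pd.Series | None = None
    sigma: float = 10.0
    prefactor_included: bool = True
    unranked_ligands: list[str] = field(default_factory=list)


def _spec_map(specs: Sequence[ScoringFunctionSpec]) -> dict[str, ScoringFunctionSpec]:
    return {s.name: s for s in specs}


def relative_ranks(
    table: ScoreTable,
    specs: Sequence[ScoringFunctionSpec],
    missing_policy: MissingPolicy = "worst_rank",
) -> RankTable:
    """Convert scores to within-function relative ranks.

    For a ``lower_is_better`` function the lowest score gets rank 1; for
    ``higher_is_better`` the highest does.  Ties are averaged.  A missing
    score receives rank ``n_ranked + 1`` under ``worst_rank`` (a ligand
    that failed to dock must not be rewarded) or is left absent under
    ``omit``.
    """
    by_name = _spec_map(specs)
    missing_meta = [c for c in table.function_names if c not in by_name]
    if missing_meta:
        raise ValueError(
            f"no direction metadata for scoring function(s): {missing_meta}"
        )
    if missing_policy not in ("worst_rank", "omit"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    ranks = pd.DataFrame(index=table.scores.index, dtype=float)
    n_ranked: dict[str, int] = {}
    for fn in table.function_names:
        col = table.scores[fn]
        ascending = by_name[fn].direction is Direction.lower_is_better
        r = col.rank(method="average", ascending=ascending, na_option="keep")
        n = int(col.notna().sum())
        n_ranked[fn] = n
        if missing_policy == "worst_rank":
            r = r.fillna(n + 1)
        ranks[fn] = r
    return RankTable(target_id=table.target_id, ranks=ranks, n_ranked=n_ranked)


def borda_aggregate(ranks: RankTable) -> ConsensusResult:
    """Sum per-function ranks into a Borda count and rank the counts
    ascending (average ties) to obtain the aggregated consensus rank.

    Ligands with no rank at all (possible under the ``omit`` policy) are
    excluded from the aggregation and listed in ``unranked_ligands``.
    """
    if ranks.ranks.empty or ranks.ranks.shape[1] == 0:
        raise ValueError("rank table is empty")
    counts = ranks.ranks.count(axis=1)
    unranked = counts[counts == 0].index.tolist()
    ranked = ranks.ranks.loc[counts > 0]
    borda = ranked.sum(axis=1, skipna=True)
    aggregated = borda.rank(method="average", ascending=True)
    return ConsensusResult(
        target_id=ranks.target_id,
        borda=borda,
        aggregated_rank=aggregated,
        unranked_ligands=unranked,
    )


def ecr_scores(
    ranks: RankTable, sigma: float = 10.0, prefactor: bool = True
) -> ConsensusResult:
    """Exponential consensus rank: sum over functions of c*exp(-r/sigma)
    with c = 1/sigma when ``prefactor`` else 1.  Larger is more favorable."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    c = 1.0 / sigma if prefactor else 1.0
    terms = c * np.exp(-ranks.ranks / sigma)
    counts = ranks.ranks.count(axis=1)
    ecr = terms.sum(axis=1, skipna=True)
    ecr[counts == 0] = 0.0
    return ConsensusResult(
        target_id=ranks.target_id,
        ecr=ecr,
        sigma=sigma,
        prefactor_included=prefactor,
        unranked_ligands=counts[counts == 0].index.tolist(),
    )


def consensus(
    ranks: RankTable, sigma: float = 10.0, prefactor: bool = True
) -> ConsensusResult:
    """Borda count, aggregated rank and ECR in one result."""
    b = borda_aggregate(ranks)
    e = ecr_scores(ranks, sigma=sigma, prefactor=prefactor)
    return ConsensusResult(
        target_id=ranks.target_id,
        borda=b.borda,
        aggregated_rank=b.aggregated_rank,
        ecr=e.ecr,
        sigma=sigma,
        prefactor_included=prefactor,
        unranked_ligands=b.unranked_ligands,
    )


def majority_vote_preference(
    table: ScoreTable,
    specs: Sequence[ScoringFunctionSpec],
    ligand_a: str,
    ligand_b: str,
) -> dict[str, int]:
    """Count, per scoring function, which of two ligands scores more
    favorably under that function's direction.

    Returns ``{"favors_a", "favors_b", "ties", "undecided"}``; the four
    counts sum to the number of functions.  A missing score on either side
    makes that function undecided.
    """
    by_name = _spec_map(specs)
    for lig in (ligand_a, ligand_b):
        if lig not in table.scores.index:
            raise KeyError(f"unknown ligand {lig!r}")
    counts = {"favors_a": 0, "favors_b": 0, "ties": 0, "undecided": 0}
    for fn in table.function_names:
        sa = table.scores.at[ligand_a, fn]
        sb = table.scores.at[ligand_b, fn]
        if math.isnan(sa) or math.isnan(sb):
            counts["undecided"] += 1
            continue
        if sa == sb:
            counts["ties"] += 1
            continue
        higher_better = by_name[fn].direction is Direction.higher_is_better
        a_wins = (sa > sb) if higher_better else (sa < sb)
        counts["favors_a" if a_wins else "favors_b"] += 1
    return counts
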