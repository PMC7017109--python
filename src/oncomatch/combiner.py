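"""Combination-regimen enumeration, filtering and ranking.

The search space is every subset of the eligible drugs up to a maximum
combination size (default 3). At a realistic knowledge-base scale of a
few hundred drugs this is a few million candidates, which exhaustive
vectorised scoring handles in seconds — no heuristic pruning is needed
or used.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .kb import KnowledgeBase
from .profile import PatientProfile, scoreable_biomarkers
from .scoring import (
    MatchingScoreResult,
    Regimen,
    ScoringConfig,
    drug_hits,
    matching_score,
    round_half_up,
)


@dataclass(frozen=True)
class ConstraintSet:
    """Eligibility and combination constraints.

    ``max_per_class`` caps how many drugs of a pharmacological class may
    appear in one regimen; by convention at most one hormone agent is
    combined, other classes are unlimited.
    """

    max_drugs: int = 3
    require_adult_ok: bool = False
    excluded_drugs: frozenset[str] = frozenset()
    required_routes: frozenset[str] | None = None
    max_per_class: Mapping[str, int] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.max_drugs < 1:
            raise ConfigurationError("max_drugs must be >= 1")
        object.__setattr__(self, "excluded_drugs", frozenset(self.excluded_drugs))
        if self.required_routes is not None:
            object.__setattr__(self, "required_routes", frozenset(self.required_routes))
        if self.max_per_class is None:
            object.__setattr__(self, "max_per_class", {"hormone": 1})
        else:
            object.__setattr__(self, "max_per_class", dict(self.max_per_class))


@dataclass(frozen=True)
class RankedRegimen:
    rank: int
    result: MatchingScoreResult


def filter_eligible(
    kb: KnowledgeBase,
    profile: PatientProfile | None = None,
    constraints: ConstraintSet | None = None,
) -> list[str]:
    """Drug ids passing the patient-level eligibility filters, sorted.

    Removes explicitly excluded drugs, the patient's allergy list,
    adult-only drugs for pediatric patients, and drugs with no
    administration route acceptable to the patient or required by the
    constraints. Pure function of its inputs.
    """
    constraints = constraints or ConstraintSet()
    eligible = []
    # require_adult_ok forces the adult-only check even without profile metadata
    drop_adult_only = constraints.require_adult_ok or (
        profile is not None and profile.age_class == "pediatric"
    )
    for drug in kb.drugs:
        if drug.drug_id in constraints.excluded_drugs:
            continue
        if profile is not None and drug.drug_id in profile.allergies:
            continue
        if drug.adult_only and drop_adult_only:
            continue
        routes_needed = []
        if constraints.required_routes is not None:
            routes_needed.append(constraints.required_routes)
        if profile is not None and profile.accepted_routes is not None:
            routes_needed.append(profile.accepted_routes)
        if any(not (drug.routes & need) for need in routes_needed):
            continue
        eligible.append(drug.drug_id)
    return sorted(eligible)


def enumerate_regimens(
    kb: KnowledgeBase,
    constraints: ConstraintSet | None = None,
    eligible: Sequence[str] | None = None,
) -> Iterator[Regimen]:
    """Yield every eligible drug subset of size 1..max_drugs exactly once.

    Deterministic order: by size, then lexicographically by drug id.
    Subsets violating a per-class cap (e.g. two hormone agents) are
    skipped.
    """
    constraints = constraints or ConstraintSet()
    ids = sorted(eligible) if eligible is not None else kb.drug_ids
    classes = {d.drug_id: d.drug_class for d in kb.drugs}
    caps = constraints.max_per_class
    for k in range(1, constraints.max_drugs + 1):
        for combo in itertools.combinations(ids, k):
            if caps and k > 1:
                counts: dict[str, int] = {}
                bad = False
                for d in combo:
                    c = classes.get(d, "other")
                    if c in caps:
                        counts[c] = counts.get(c, 0) + 1
                        if counts[c] > caps[c]:
                            bad = True
                            break
                if bad:
                    continue
            yield Regimen(frozenset(combo), label="+".join(combo))


def count_regimens(n_eligible: int, max_drugs: int = 3) -> int:
    """Closed-form candidate count without class caps: Σ C(n, k)."""
    from math import comb

    return sum(comb(n_eligible, k) for k in range(1, max_drugs + 1))


def _contribution_matrix(
    drug_ids: Sequence[str],
    profile: PatientProfile,
    kb: KnowledgeBase,
    config: ScoringConfig,
) -> np.ndarray:
    """Per-drug, per-biomarker contribution vectors (drugs × biomarkers)."""
    biomarkers = scoreable_biomarkers(profile)
    keys = [(a.gene, a.alteration_class) for a in biomarkers]
    mat = np.zeros((len(drug_ids), len(keys)))
    for i, d in enumerate(drug_ids):
        hits = drug_hits(d, profile, kb, config)
        for j, key in enumerate(keys):
            if key in hits:
                mat[i, j] = hits[key].contribution
    return mat


def score_regimens(
    regimens: Iterable[Regimen],
    profile: PatientProfile,
    kb: KnowledgeBase,
    config: ScoringConfig | None = None,
    chunk: int = 200_000,
) -> np.ndarray:
    """Vectorised integer scores for a stream of regimens.

    Equivalent to calling :func:`oncomatch.scoring.matching_score` on each
    regimen (that equivalence is property-tested), but evaluates the
    capped per-biomarker sums with numpy so that millions of combinations
    are scored in seconds. Modifiers, when enabled, are applied through
    the scalar path.
    """
    config = config or ScoringConfig()
    if config.modifiers_enabled:
        return np.array(
            [matching_score(r, profile, kb, config).score_percent for r in regimens],
            dtype=np.int64,
        )
    biomarkers = scoreable_biomarkers(profile)
    denom = config.direct_weight * len(biomarkers)
    if denom == 0:
        from .errors import EmptyProfileError

        raise EmptyProfileError(
            f"profile {profile.patient_id!r} has no scoreable biomarkers"
        )
    index: dict[str, int] = {}
    drug_order: list[str] = []
    combos: list[tuple[int, ...]] = []
    for r in regimens:
        idx = []
        for d in r:
            if d not in index:
                index[d] = len(drug_order)
                drug_order.append(d)
            idx.append(index[d])
        combos.append(tuple(idx))
    mat = _contribution_matrix(drug_order, profile, kb, config)
    scores = np.empty(len(combos), dtype=np.int64)
    # group by regimen size for rectangular indexing
    by_size: dict[int, list[int]] = {}
    for pos, c in enumerate(combos):
        by_size.setdefault(len(c), []).append(pos)
    for size, positions in by_size.items():
        for start in range(0, len(positions), chunk):
            pos_chunk = positions[start : start + chunk]
            idx_arr = np.array([combos[p] for p in pos_chunk], dtype=np.intp)
            summed = mat[idx_arr].sum(axis=1)
            np.minimum(summed, config.per_biomarker_cap, out=summed)
            ratio = summed.sum(axis=1) / denom
            scores[pos_chunk] = np.floor(np.round(100 * ratio, 9) + 0.5).astype(
                np.int64
            )
    return scores


def rank_regimens(
    profile: PatientProfile,
    kb: KnowledgeBase,
    constraints: ConstraintSet | None = None,
    config: ScoringConfig | None = None,
    top_n: int = 10,
) -> list[RankedRegimen]:
    """Score every candidate regimen and return the top ``top_n``.

    Sort order: score descending, then fewer drugs first, then
    lexicographic label — stable and deterministic, so a truncated
    ranking always equals the prefix of the full ranking.
    """
    constraints = constraints or ConstraintSet()
    config = config or ScoringConfig()
    eligible = filter_eligible(kb, profile, constraints)
    regimens = list(enumerate_regimens(kb, constraints, eligible))
    scores = score_regimens(regimens, profile, kb, config)
    order = sorted(
        range(len(regimens)),
        key=lambda i: (-scores[i], len(regimens[i]), regimens[i].label),
    )
    ranked = []
    for rank, i in enumerate(order[:top_n], start=1):
        result = matching_score(regimens[i], profile, kb, config)
        ranked.append(RankedRegimen(rank=rank, result=result))
    return ranked
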