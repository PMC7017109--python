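"""The matching score.

A regimen's matching score expresses, as an integer percentage, how
completely it covers the pathogenic biomarkers of a tumor profile. Each
drug contributes a per-biomarker *hit*: the full direct weight when the
drug targets the altered product itself, a reduced indirect weight when it
targets a co-pathway member, and nothing otherwise. Hits are summed across
the drugs of a combination, capped per biomarker so that covering a
biomarker twice counts once, and the capped total is divided by the
maximum attainable hit score for the profile (the direct weight times the
number of scoreable biomarkers). A regimen matching every alteration
therefore scores exactly 100%.

The default weights (direct 1.0, indirect 0.5, cap 1.0) are the minimal
convention under which the packaged worked example reproduces its
published scores; the underlying clinical systems do not publish their
weight constants.

Clinical fine-tuning is exposed as a registry of named multiplicative
modifiers applied to the pre-rounding ratio; the package ships an
eligibility modifier (age class, allergies, route mismatch zero the
score) and an optional per-drug-count penalty, both off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .errors import ConfigurationError, EmptyProfileError
from .kb import KnowledgeBase, query_rules
from .profile import MolecularAlteration, PatientProfile, scoreable_biomarkers


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-point-five up."""
    return int(math.floor(round(x, 9) + 0.5))


@dataclass(frozen=True)
class ScoringConfig:
    """Weights and options of the matching score.

    direct_weight, indirect_weight
        Contribution of a direct / indirect rule hit, per biomarker.
    per_biomarker_cap
        Upper bound on a biomarker's summed contribution within a
        combination; prevents double counting.
    rounding
        Only ``"half_up"`` is defined: scores are printed as integer
        percentages.
    modifiers_enabled
        Ordered modifier ids applied to the pre-rounding ratio.
    drug_count_penalty
        Per-additional-drug factor used by the ``drug_count_penalty``
        modifier; 1.0 (no penalty) unless configured.
    """

    direct_weight: float = 1.0
    indirect_weight: float = 0.5
    per_biomarker_cap: float = 1.0
    rounding: str = "half_up"
    modifiers_enabled: tuple[str, ...] = ()
    drug_count_penalty: float = 1.0

    def __post_init__(self):
        if not (0 < self.indirect_weight <= self.direct_weight <= self.per_biomarker_cap):
            raise ConfigurationError(
                "weights must satisfy 0 < indirect_weight <= direct_weight "
                "<= per_biomarker_cap"
            )
        if self.rounding != "half_up":
            raise ConfigurationError(f"unknown rounding mode {self.rounding!r}")
        if not 0 <= self.drug_count_penalty <= 1:
            raise ConfigurationError("drug_count_penalty must lie in [0, 1]")
        object.__setattr__(self, "modifiers_enabled", tuple(self.modifiers_enabled))


@dataclass(frozen=True)
class Regimen:
    """A set of one or more distinct drugs administered together."""

    drug_ids: frozenset[str]
    label: str = ""

    def __post_init__(self):
        ids = frozenset(d.lower() for d in self.drug_ids)
        if not ids:
            raise ConfigurationError("a regimen needs at least one drug")
        object.__setattr__(self, "drug_ids", ids)
        if not self.label:
            object.__setattr__(self, "label", "+".join(sorted(ids)))

    @classmethod
    def parse(cls, text: str) -> "Regimen":
        """Parse a ``drug+drug+drug`` regimen string (case-insensitive)."""
        return cls(frozenset(t.strip().lower() for t in text.split("+") if t.strip()))

    def __len__(self) -> int:
        return len(self.drug_ids)

    def __iter__(self):
        return iter(sorted(self.drug_ids))


@dataclass(frozen=True)
class BiomarkerHit:
    drug_id: str
    match_type: str
    contribution: float


@dataclass(frozen=True)
class HitBreakdown:
    """Per-biomarker contributions of a regimen, before normalization.

    ``contributions`` maps (gene, alteration_class) to the tuple of
    individual drug hits; ``capped`` holds the per-biomarker totals after
    applying the cap. ``numerator`` is the sum of the capped totals and
    never exceeds ``denominator``.
    """

    contributions: Mapping[tuple[str, str], tuple[BiomarkerHit, ...]]
    capped: Mapping[tuple[str, str], float]
    numerator: float
    denominator: float


@dataclass(frozen=True)
class MatchingScoreResult:
    regimen: Regimen
    breakdown: HitBreakdown
    modifiers_applied: tuple[tuple[str, float], ...]
    score_percent: int

    @property
    def matched_biomarkers(self) -> list[str]:
        return sorted(
            gene for (gene, _), v in self.breakdown.capped.items() if v > 0
        )


def drug_hits(
    drug_id: str,
    profile: PatientProfile,
    kb: KnowledgeBase,
    config: ScoringConfig | None = None,
) -> dict[tuple[str, str], BiomarkerHit]:
    """Per-biomarker hit contributions of a single drug.

    For each scoreable biomarker the contribution is the direct weight if
    a direct rule matches, else the indirect weight if an indirect rule
    matches, else zero; a rule's ``weight_override`` replaces the default.
    If any resistance rule of the drug matches an alteration in the
    profile, every contribution of the drug is nullified.
    """
    config = config or ScoringConfig()
    drug_id = drug_id.lower()
    biomarkers = scoreable_biomarkers(profile)
    # resistance is checked against the whole profile, not only scoreable calls
    for alt in profile.alterations:
        if any(
            r.match_type == "resistance" for r in query_rules(kb, drug_id, alt)
        ):
            return {}
    hits: dict[tuple[str, str], BiomarkerHit] = {}
    for alt in biomarkers:
        rules = query_rules(kb, drug_id, alt)
        chosen = None
        for wanted, default in (
            ("direct", config.direct_weight),
            ("indirect", config.indirect_weight),
        ):
            for r in rules:
                if r.match_type == wanted:
                    w = default if r.weight_override is None else r.weight_override
                    chosen = BiomarkerHit(drug_id, wanted, w)
                    break
            if chosen:
                break
        if chosen and chosen.contribution > 0:
            hits[(alt.gene, alt.alteration_class)] = chosen
    return hits


def regimen_hit_score(
    regimen: Regimen,
    profile: PatientProfile,
    kb: KnowledgeBase,
    config: ScoringConfig | None = None,
) -> HitBreakdown:
    """Aggregate drug hits over a combination.

    Per biomarker, contributions of the individual drugs are summed and
    capped; the numerator is the sum of capped contributions and the
    denominator is the maximum attainable hit score,
    ``direct_weight × (number of scoreable biomarkers)``.
    """
    config = config or ScoringConfig()
    biomarkers = scoreable_biomarkers(profile)
    if not biomarkers:
        raise EmptyProfileError(
            f"profile {profile.patient_id!r} has no scoreable biomarkers; "
            "the matching score is undefined"
        )
    per_drug = {d: drug_hits(d, profile, kb, config) for d in regimen}
    contributions: dict[tuple[str, str], tuple[BiomarkerHit, ...]] = {}
    capped: dict[tuple[str, str], float] = {}
    numerator = 0.0
    for alt in biomarkers:
        key = (alt.gene, alt.alteration_class)
        hits = tuple(
            per_drug[d][key] for d in regimen if key in per_drug[d]
        )
        contributions[key] = hits
        total = min(config.per_biomarker_cap, sum(h.contribution for h in hits))
        capped[key] = total
        numerator += total
    denominator = config.direct_weight * len(biomarkers)
    return HitBreakdown(
        contributions=contributions,
        capped=capped,
        numerator=numerator,
        denominator=denominator,
    )


# ---------------------------------------------------------------------------
# Modifier registry
# ---------------------------------------------------------------------------

ModifierFn = Callable[[PatientProfile, Regimen, KnowledgeBase, ScoringConfig], float]


def _eligibility_zero(profile, regimen, kb, config) -> float:
    """Zero the score when any drug is clinically ineligible for the patient."""
    for drug_id in regimen:
        drug = kb.drug(drug_id)
        if drug.adult_only and profile.age_class == "pediatric":
            return 0.0
        if drug_id in profile.allergies:
            return 0.0
        if profile.accepted_routes is not None and not (
            drug.routes & profile.accepted_routes
        ):
            return 0.0
    return 1.0


def _drug_count_penalty(profile, regimen, kb, config) -> float:
    """Geometric penalty per drug beyond the first (1.0 = no penalty)."""
    return config.drug_count_penalty ** (len(regimen) - 1)


MODIFIERS: dict[str, ModifierFn] = {
    "eligibility_zero": _eligibility_zero,
    "drug_count_penalty": _drug_count_penalty,
}


def modifier_factors(
    profile: PatientProfile,
    regimen: Regimen,
    kb: KnowledgeBase,
    config: ScoringConfig,
) -> tuple[tuple[str, float], ...]:
    factors = []
    for mid in config.modifiers_enabled:
        try:
            fn = MODIFIERS[mid]
        except KeyError:
            raise ConfigurationError(f"unknown modifier id {mid!r}") from None
        factor = fn(profile, regimen, kb, config)
        if not 0 <= factor <= 1:
            raise ConfigurationError(
                f"modifier {mid!r} returned factor {factor} outside [0, 1]"
            )
        factors.append((mid, factor))
    return tuple(factors)


def apply_modifiers(
    result: MatchingScoreResult,
    profile: PatientProfile,
    regimen: Regimen,
    kb: KnowledgeBase,
    config: ScoringConfig,
) -> MatchingScoreResult:
    """Re-derive the final score with the configured modifiers applied.

    Each enabled modifier multiplies the pre-rounding ratio by a factor in
    [0, 1], in registry-configuration order; rounding happens once, after
    all factors.
    """
    factors = modifier_factors(profile, regimen, kb, config)
    ratio = result.breakdown.numerator / result.breakdown.denominator
    for _, f in factors:
        ratio *= f
    return MatchingScoreResult(
        regimen=result.regimen,
        breakdown=result.breakdown,
        modifiers_applied=factors,
        score_percent=round_half_up(100 * ratio),
    )


def matching_score(
    regimen: Regimen | str | Iterable[str],
    profile: PatientProfile,
    kb: KnowledgeBase,
    config: ScoringConfig | None = None,
) -> MatchingScoreResult:
    """Score a regimen against a profile.

    With the default configuration and no modifiers the score is
    ``round_half_up(100 × numerator / denominator)``; drug listing order
    never affects the result. Raises :class:`EmptyProfileError` when the
    profile has no scoreable biomarkers.
    """
    config = config or ScoringConfig()
    if isinstance(regimen, str):
        regimen = Regimen.parse(regimen)
    elif not isinstance(regimen, Regimen):
        regimen = Regimen(frozenset(regimen))
    breakdown = regimen_hit_score(regimen, profile, kb, config)
    base = MatchingScoreResult(
        regimen=regimen,
        breakdown=breakdown,
        modifiers_applied=(),
        score_percent=round_half_up(100 * breakdown.numerator / breakdown.denominator),
    )
    if not config.modifiers_enabled:
        return base
    return apply_modifiers(base, profile, regimen, kb, config)
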