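"""Shared fixtures: packaged calibration data, toy knowledge bases, and an
independent brute-force scoring oracle used for equivalence checks."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pytest

from oncomatch import (
    DrugRecord,
    KnowledgeBase,
    MatchRule,
    MolecularAlteration,
    PathwayRecord,
    PatientProfile,
    calibration_kb,
    patient51_profile,
)


@pytest.fixture(scope="session")
def kb():
    return calibration_kb()


@pytest.fixture(scope="session")
def p51():
    return patient51_profile()


@pytest.fixture
def toy_pathway_kb():
    """Three-gene pathway KB for indirect-rule derivation tests."""
    return KnowledgeBase(
        drugs=(
            DrugRecord("everolimus", drug_class="targeted_small_molecule"),
            DrugRecord("placebo", drug_class="other"),
        ),
        pathways=(PathwayRecord("PI3K_AKT_MTOR", frozenset({"MTOR", "PTEN", "AKT1"})),),
        rules=(
            MatchRule(
                "everolimus",
                "MTOR",
                "mutation_activating",
                "direct",
                evidence_tag="ic50_nanomolar",
            ),
        ),
    )


# ---------------------------------------------------------------------------
# Random toy problem generator + brute-force oracle
# ---------------------------------------------------------------------------

GENES = ["G1", "G2", "G3", "G4", "G5"]
CLASSES = [
    "mutation_activating",
    "amplification",
    "copy_loss",
    "expression_positive",
    "fusion",
]


def random_toy_problem(seed, n_drugs=6, n_biomarkers=5, with_resistance=True):
    """A random small KB + profile for oracle-equivalence testing."""
    rng = np.random.default_rng(seed)
    drug_ids = [f"d{i}" for i in range(1, rng.integers(2, n_drugs + 1) + 1)]
    drugs = tuple(DrugRecord(d) for d in drug_ids)
    rules = []
    seen = set()
    for _ in range(int(rng.integers(1, 12))):
        d = drug_ids[rng.integers(len(drug_ids))]
        g = GENES[rng.integers(len(GENES))]
        c = CLASSES[rng.integers(len(CLASSES))]
        if (d, g, c) in seen:
            continue
        seen.add((d, g, c))
        r = rng.random()
        if with_resistance and r < 0.12:
            rules.append(MatchRule(d, g, c, "resistance"))
        elif r < 0.55:
            override = float(rng.choice([1.0, 0.8, 0.3])) if rng.random() < 0.3 else None
            rules.append(
                MatchRule(
                    d, g, c, "direct",
                    weight_override=override,
                    evidence_tag="ic50_nanomolar",
                )
            )
        else:
            override = 0.25 if rng.random() < 0.3 else None
            rules.append(
                MatchRule(d, g, c, "indirect", weight_override=override,
                          evidence_tag="pathway")
            )
    kb = KnowledgeBase(drugs=drugs, rules=tuple(rules))
    n_alt = int(rng.integers(1, n_biomarkers + 1))
    picks = rng.choice(len(GENES) * len(CLASSES), size=n_alt, replace=False)
    alterations = tuple(
        MolecularAlteration(GENES[p // len(CLASSES)], CLASSES[p % len(CLASSES)])
        for p in sorted(picks)
    )
    profile = PatientProfile(patient_id=f"T{seed}", alterations=alterations)
    return kb, profile


def brute_force_score(regimen_drugs, profile, kb, direct_weight=1.0,
                      indirect_weight=0.5, cap=1.0):
    """Naive re-implementation of the matching score, kept independent of
    the package internals: iterates rule records directly and rounds via
    decimal arithmetic."""
    biomarkers = [
        a
        for a in profile.alterations
        if a.pathogenic and a.alteration_class != "expression_negative"
    ]
    numerator = Decimal(0)
    for alt in biomarkers:
        total = Decimal(0)
        for d in regimen_drugs:
            # resistance anywhere in the profile knocks the drug out
            resistant = any(
                r.drug_id == d
                and r.match_type == "resistance"
                and any(
                    r.gene == a.gene and r.alteration_class == a.alteration_class
                    for a in profile.alterations
                )
                for r in kb.rules
            )
            if resistant:
                continue
            direct = [
                r
                for r in kb.rules
                if r.drug_id == d
                and r.gene == alt.gene
                and r.alteration_class == alt.alteration_class
                and r.match_type == "direct"
            ]
            indirect = [
                r
                for r in kb.rules
                if r.drug_id == d
                and r.gene == alt.gene
                and r.alteration_class == alt.alteration_class
                and r.match_type == "indirect"
            ]
            if direct:
                w = direct[0].weight_override
                total += Decimal(str(w if w is not None else direct_weight))
            elif indirect:
                w = indirect[0].weight_override
                total += Decimal(str(w if w is not None else indirect_weight))
        numerator += min(Decimal(str(cap)), total)
    denominator = Decimal(str(direct_weight)) * len(biomarkers)
    ratio = numerator / denominator
    return int((100 * ratio).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
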