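"""Drug–biomarker knowledge base.

The knowledge base holds three record types:

* drugs — identity, pharmacological class, and the eligibility attributes
  (adult-only flag, routes, contraindication flags) used for filtering;
* pathways — gene membership sets, the substrate for indirect matches;
* match rules — (drug, gene, alteration class) triples annotated as
  *direct* (the drug hits the altered product itself: low-nanomolar IC50
  target, antibody epitope, or a validated sensitivity biomarker),
  *indirect* (the drug hits another member of the altered gene's signaling
  pathway), or *resistance* (the alteration nullifies the drug).

The canonical serialization is a single JSON document; a flat TSV export
(one file per record type) is provided for spreadsheet-friendly curation.

A small calibration knowledge base covering a hormone-positive breast
cancer case ships with the package (:func:`calibration_kb`); it is the
minimal rule set under which the worked example in the README reproduces
its published scores. The rule weights in it are package-level conventions
— source case reports print scores, never weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import UnknownDrugError, ValidationError
from .profile import ALTERATION_CLASSES, ROUTES, MolecularAlteration

DRUG_CLASSES = frozenset(
    {
        "cytotoxic",
        "targeted_small_molecule",
        "antibody",
        "hormone",
        "immunotherapy",
        "other",
    }
)

MATCH_TYPES = frozenset({"direct", "indirect", "resistance"})

EVIDENCE_TAGS = frozenset(
    {
        "ic50_nanomolar",
        "antibody_epitope",
        "pathway",
        "sensitivity_biomarker",
        "clinical",
    }
)

#: Evidence tags that justify a *direct* match.
DIRECT_EVIDENCE_TAGS = frozenset(
    {"ic50_nanomolar", "antibody_epitope", "sensitivity_biomarker"}
)

#: Alteration classes treated as pathway-activating for the purpose of
#: deriving indirect rules from pathway co-membership. Loss-of-function
#: classes are excluded: whether losing a co-pathway gene sensitises to a
#: drug is not derivable from membership alone and requires explicit
#: curation.
ACTIVATING_CLASSES = frozenset(
    {"mutation_activating", "amplification", "fusion", "expression_high"}
)


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    name: str = ""
    drug_class: str = "other"
    adult_only: bool = False
    routes: frozenset[str] = frozenset({"oral"})
    contraindication_flags: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.drug_id or self.drug_id != self.drug_id.lower():
            raise ValidationError(
                f"drug_id must be a non-empty lowercase token, got {self.drug_id!r}",
                field="drug_id",
            )
        if self.drug_class not in DRUG_CLASSES:
            raise ValidationError(
                f"unknown drug_class {self.drug_class!r}", field="drug_class"
            )
        routes = frozenset(self.routes)
        if not routes <= ROUTES:
            raise ValidationError(
                f"unknown routes {sorted(routes - ROUTES)}", field="routes"
            )
        object.__setattr__(self, "routes", routes)
        object.__setattr__(
            self, "contraindication_flags", frozenset(self.contraindication_flags)
        )


@dataclass(frozen=True)
class PathwayRecord:
    pathway_id: str
    member_genes: frozenset[str]

    def __post_init__(self):
        genes = frozenset(g.upper() for g in self.member_genes)
        if not genes:
            raise ValidationError(
                f"pathway {self.pathway_id!r} has no member genes",
                field="member_genes",
            )
        object.__setattr__(self, "member_genes", genes)


@dataclass(frozen=True)
class MatchRule:
    """One drug–biomarker matching rule.

    ``weight_override`` replaces the configured direct/indirect weight for
    this rule only; resistance rules carry no weight (they nullify the
    drug's contributions instead).
    """

    drug_id: str
    gene: str
    alteration_class: str
    match_type: str
    weight_override: float | None = None
    evidence_tag: str = "clinical"

    def __post_init__(self):
        object.__setattr__(self, "gene", self.gene.upper())
        if self.alteration_class not in ALTERATION_CLASSES:
            raise ValidationError(
                f"unknown alteration_class {self.alteration_class!r}",
                field="alteration_class",
            )
        if self.match_type not in MATCH_TYPES:
            raise ValidationError(
                f"unknown match_type {self.match_type!r}", field="match_type"
            )
        if self.evidence_tag not in EVIDENCE_TAGS:
            raise ValidationError(
                f"unknown evidence_tag {self.evidence_tag!r}", field="evidence_tag"
            )
        if self.match_type == "direct" and self.evidence_tag not in DIRECT_EVIDENCE_TAGS:
            raise ValidationError(
                f"direct rules require evidence in {sorted(DIRECT_EVIDENCE_TAGS)}, "
                f"got {self.evidence_tag!r}",
                field="evidence_tag",
            )
        if self.match_type == "resistance" and self.weight_override is not None:
            raise ValidationError(
                "resistance rules carry no weight", field="weight_override"
            )
        if self.weight_override is not None and not 0 <= self.weight_override <= 1:
            raise ValidationError(
                f"weight_override must lie in [0, 1], got {self.weight_override}",
                field="weight_override",
            )


@dataclass(frozen=True)
class KnowledgeBase:
    drugs: tuple[DrugRecord, ...]
    pathways: tuple[PathwayRecord, ...] = ()
    rules: tuple[MatchRule, ...] = ()
    version: str = "0"

    def __post_init__(self):
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "pathways", tuple(self.pathways))
        object.__setattr__(self, "rules", tuple(self.rules))
        self.validate()

    def validate(self) -> None:
        """Check referential integrity and uniqueness invariants."""
        seen_drugs: set[str] = set()
        for i, d in enumerate(self.drugs):
            if d.drug_id in seen_drugs:
                raise ValidationError(
                    f"duplicate drug_id {d.drug_id!r}", record=i, field="drug_id"
                )
            seen_drugs.add(d.drug_id)
        seen_pw: set[str] = set()
        for i, p in enumerate(self.pathways):
            if p.pathway_id in seen_pw:
                raise ValidationError(
                    f"duplicate pathway_id {p.pathway_id!r}", record=i
                )
            seen_pw.add(p.pathway_id)
        seen_rules: set[tuple[str, str, str]] = set()
        for i, r in enumerate(self.rules):
            if r.drug_id not in seen_drugs:
                raise ValidationError(
                    f"rule references unknown drug {r.drug_id!r}",
                    record=i,
                    field="drug_id",
                )
            key = (r.drug_id, r.gene, r.alteration_class)
            if key in seen_rules:
                raise ValidationError(f"duplicate rule {key}", record=i)
            seen_rules.add(key)

    # -- lookups ---------------------------------------------------------
    def drug(self, drug_id: str) -> DrugRecord:
        for d in self.drugs:
            if d.drug_id == drug_id:
                return d
        raise UnknownDrugError(drug_id)

    def has_drug(self, drug_id: str) -> bool:
        return any(d.drug_id == drug_id for d in self.drugs)

    @property
    def drug_ids(self) -> list[str]:
        return sorted(d.drug_id for d in self.drugs)

    def rules_for_drug(self, drug_id: str) -> list[MatchRule]:
        if not self.has_drug(drug_id):
            raise UnknownDrugError(drug_id)
        return sorted(
            (r for r in self.rules if r.drug_id == drug_id),
            key=lambda r: (r.gene, r.match_type),
        )

    def pathway_neighbors(self, gene: str) -> frozenset[str]:
        """Genes sharing at least one pathway with ``gene`` (gene itself excluded)."""
        gene = gene.upper()
        out: set[str] = set()
        for p in self.pathways:
            if gene in p.member_genes:
                out |= p.member_genes
        out.discard(gene)
        return frozenset(out)


def query_rules(
    kb: KnowledgeBase, drug_id: str, alteration: MolecularAlteration
) -> list[MatchRule]:
    """Rules of ``drug_id`` whose gene and alteration class match ``alteration``.

    Returned in deterministic (gene, match_type) order. Raises
    :class:`UnknownDrugError` for a drug absent from the knowledge base.
    """
    return [
        r
        for r in kb.rules_for_drug(drug_id)
        if r.gene == alteration.gene
        and r.alteration_class == alteration.alteration_class
    ]


def derive_indirect_rules(kb: KnowledgeBase) -> KnowledgeBase:
    """Expand the rule set with pathway-derived indirect rules.

    For every direct rule (drug d, gene g) and every gene g' ≠ g sharing a
    pathway with g, indirect rules (d, g', c) are added for each
    pathway-activating alteration class c — unless any explicit rule for
    (d, g') already exists, in which case curation wins. The operation is
    pure and idempotent: it never removes, reweights, or downgrades an
    explicit rule, and running it twice adds nothing new.
    """
    explicit_pairs = {(r.drug_id, r.gene) for r in kb.rules}
    existing = {(r.drug_id, r.gene, r.alteration_class) for r in kb.rules}
    derived: list[MatchRule] = []
    for rule in kb.rules:
        if rule.match_type != "direct":
            continue
        for neighbor in sorted(kb.pathway_neighbors(rule.gene)):
            if (rule.drug_id, neighbor) in explicit_pairs:
                continue
            for cls in sorted(ACTIVATING_CLASSES):
                key = (rule.drug_id, neighbor, cls)
                if key in existing:
                    continue
                existing.add(key)
                derived.append(
                    MatchRule(
                        drug_id=rule.drug_id,
                        gene=neighbor,
                        alteration_class=cls,
                        match_type="indirect",
                        evidence_tag="pathway",
                    )
                )
    if not derived:
        return kb
    return replace(kb, rules=kb.rules + tuple(derived))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def kb_to_dict(kb: KnowledgeBase) -> dict:
    return {
        "version": kb.version,
        "drugs": [
            {
                "drug_id": d.drug_id,
                "name": d.name,
                "drug_class": d.drug_class,
                "adult_only": d.adult_only,
                "routes": sorted(d.routes),
                "contraindication_flags": sorted(d.contraindication_flags),
            }
            for d in kb.drugs
        ],
        "pathways": [
            {"pathway_id": p.pathway_id, "member_genes": sorted(p.member_genes)}
            for p in kb.pathways
        ],
        "rules": [
            {
                "drug_id": r.drug_id,
                "gene": r.gene,
                "alteration_class": r.alteration_class,
                "match_type": r.match_type,
                "weight_override": r.weight_override,
                "evidence_tag": r.evidence_tag,
            }
            for r in kb.rules
        ],
    }


def kb_from_dict(payload: Mapping, source: str = "<dict>") -> KnowledgeBase:
    try:
        drugs = tuple(
            DrugRecord(
                drug_id=d["drug_id"],
                name=d.get("name", ""),
                drug_class=d.get("drug_class", "other"),
                adult_only=bool(d.get("adult_only", False)),
                routes=frozenset(d.get("routes", ("oral",))),
                contraindication_flags=frozenset(
                    d.get("contraindication_flags", ())
                ),
            )
            for d in payload.get("drugs", ())
        )
        pathways = tuple(
            PathwayRecord(p["pathway_id"], frozenset(p["member_genes"]))
            for p in payload.get("pathways", ())
        )
        rules = tuple(
            MatchRule(
                drug_id=r["drug_id"],
                gene=r["gene"],
                alteration_class=r["alteration_class"],
                match_type=r["match_type"],
                weight_override=r.get("weight_override"),
                evidence_tag=r.get("evidence_tag", "clinical"),
            )
            for r in payload.get("rules", ())
        )
    except KeyError as exc:
        raise ValidationError(f"missing field {exc}", source=source) from exc
    return KnowledgeBase(
        drugs=drugs,
        pathways=pathways,
        rules=rules,
        version=str(payload.get("version", "0")),
    )


def load_kb(path, format: str | None = None) -> KnowledgeBase:
    """Load a knowledge base from JSON (canonical) or a TSV directory.

    The TSV layout is a directory containing ``drugs.tsv``,
    ``pathways.tsv`` (one ``pathway_id``/``gene`` pair per row) and
    ``rules.tsv``; all tab-delimited with a header row, ``#`` comments
    ignored. Loading is deterministic and record order never affects
    validation.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.is_dir() else "json"
    if format == "json":
        with open(path) as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"invalid JSON: {exc}", source=str(path)) from exc
        return kb_from_dict(payload, source=str(path))
    if format == "tsv":
        read = lambda name: pd.read_csv(path / name, sep="\t", comment="#", dtype=str)
        drugs_df = read("drugs.tsv").fillna("")
        rules_df = read("rules.tsv")
        pw_df = read("pathways.tsv")
        payload = {
            "version": "0",
            "drugs": [
                {
                    "drug_id": row["drug_id"],
                    "name": row.get("name", ""),
                    "drug_class": row.get("drug_class", "other"),
                    "adult_only": str(row.get("adult_only", "false")).lower()
                    in {"true", "1", "yes"},
                    "routes": [t for t in str(row.get("routes", "oral")).split(",") if t],
                    "contraindication_flags": [
                        t
                        for t in str(row.get("contraindication_flags", "")).split(",")
                        if t
                    ],
                }
                for row in drugs_df.to_dict("records")
            ],
            "pathways": [
                {"pathway_id": pid, "member_genes": sorted(grp["gene"])}
                for pid, grp in pw_df.groupby("pathway_id", sort=True)
            ],
            "rules": [
                {
                    "drug_id": row["drug_id"],
                    "gene": row["gene"],
                    "alteration_class": row["alteration_class"],
                    "match_type": row["match_type"],
                    "weight_override": (
                        float(row["weight_override"])
                        if str(row.get("weight_override", "")).strip()
                        not in {"", "nan", "None"}
                        else None
                    ),
                    "evidence_tag": row.get("evidence_tag", "clinical"),
                }
                for row in rules_df.astype(object)
                .where(rules_df.notna(), "")
                .to_dict("records")
            ],
        }
        return kb_from_dict(payload, source=str(path))
    raise ValidationError(f"unknown KB format {format!r}", source=str(path))


def write_kb(kb: KnowledgeBase, path, format: str = "json") -> None:
    """Write the knowledge base as canonical JSON or the TSV export."""
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(kb_to_dict(kb), fh, indent=1)
            fh.write("\n")
        return
    if format == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        d = kb_to_dict(kb)
        pd.DataFrame(
            [
                {**row, "routes": ",".join(row["routes"]),
                 "contraindication_flags": ",".join(row["contraindication_flags"])}
                for row in d["drugs"]
            ]
        ).to_csv(path / "drugs.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"pathway_id": p["pathway_id"], "gene": g}
                for p in d["pathways"]
                for g in p["member_genes"]
            ],
            columns=["pathway_id", "gene"],
        ).to_csv(path / "pathways.tsv", sep="\t", index=False)
        pd.DataFrame(
            d["rules"],
            columns=[
                "drug_id",
                "gene",
                "alteration_class",
                "match_type",
                "weight_override",
                "evidence_tag",
            ],
        ).to_csv(path / "rules.tsv", sep="\t", index=False)
        return
    raise ValidationError(f"unknown KB format {format!r}")


# ---------------------------------------------------------------------------
# Packaged calibration fixture
# ---------------------------------------------------------------------------

def calibration_kb() -> KnowledgeBase:
    """The packaged 10-drug calibration knowledge base.

    Minimal rule set for a hormone-receptor-positive breast cancer case:
    tamoxifen and anastrozole match ER positivity directly (anastrozole
    additionally matches PR positivity indirectly at half weight),
    everolimus matches PTEN copy loss as a validated sensitivity
    biomarker, trastuzumab matches ERBB2 amplification via its epitope,
    and the six cytotoxics carry no rules. All weights are package
    conventions, not published values.
    """
    ref = resources.files("oncomatch.data").joinpath("calibration_kb.json")
    return kb_from_dict(json.loads(ref.read_text()), source="calibration_kb.json")
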