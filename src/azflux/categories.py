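"""Annotation-keyword functional categories and their expression profiles.

Genes are binned into functional categories (cellulases, polygalacturonases,
expansins, PR proteins, wax/suberin, ...) by case-insensitive substring
matching against their free-text descriptions.  A rule may carry a
``reassign_to`` override: genes it matches are removed from the source
category and placed in the target instead — the canonical case being
GH9A1/KORRIGAN-like cellulases, which belong with cellulose biosynthesis
rather than wall disassembly.  Category expression is aggregated as percent
of the expressed transcriptome per sample, with the dominant gene's share
reported per condition (e.g. one cellulase carrying ~75% of the family's
transcript in the abscission zone).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .differential import transcriptome_share
from .normalize import condition_means
from .types import AzfluxError, ConfigurationError, ExpressionMatrix, SampleDesign

__all__ = [
    "CategoryRule",
    "CategoryProfile",
    "load_rules",
    "default_rules",
    "assign_categories",
    "category_profile",
    "dominant_gene_share",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CategoryRule:
    """One keyword rule: which descriptions put a gene in which category."""

    name: str
    include_keywords: tuple[str, ...]
    exclude_keywords: tuple[str, ...] = ()
    reassign_to: str | None = None

    def __post_init__(self) -> None:
        if not self.include_keywords:
            raise ConfigurationError(f"rule {self.name!r} has no include keywords")

    def matches(self, description: str) -> bool:
        d = description.lower()
        if not any(k.lower() in d for k in self.include_keywords):
            return False
        return not any(k.lower() in d for k in self.exclude_keywords)


@dataclass
class CategoryProfile:
    """Aggregated category expression.

    ``percent``: category x sample percent of total expressed-transcriptome
    signal.  ``member_counts``: genes per category.  ``dominant``: per
    category x condition, the top gene and its share of the category total.
    """

    percent: pd.DataFrame
    member_counts: pd.Series
    dominant: pd.DataFrame  # columns: category, condition, gene_id, share


def _rules_from_obj(obj) -> list[CategoryRule]:
    rules = []
    for block in obj["categories"]:
        rules.append(
            CategoryRule(
                name=block["name"],
                include_keywords=tuple(block.get("include", ())),
                exclude_keywords=tuple(block.get("exclude", ())),
                reassign_to=block.get("reassign_to"),
            )
        )
    names = {r.name for r in rules}
    for r in rules:
        if r.reassign_to is not None and r.reassign_to not in names:
            raise ConfigurationError(
                f"rule {r.name!r} reassigns to undefined category {r.reassign_to!r}"
            )
    return rules


def load_rules(path) -> list[CategoryRule]:
    """Read category rules from a YAML config (one block per rule)."""
    with open(path) as fh:
        return _rules_from_obj(yaml.safe_load(fh))


def default_rules() -> list[CategoryRule]:
    """The shipped default category config (editable YAML, not code)."""
    text = resources.files("azflux").joinpath("data/default_categories.yaml").read_text()
    return _rules_from_obj(yaml.safe_load(text))


def assign_categories(
    annotations: pd.DataFrame, rules: list[CategoryRule]
) -> dict[str, set[str]]:
    """Map gene id -> set of category names.

    A gene joins a rule's category when any include keyword is a
    case-insensitive substring of its description and no exclude keyword
    is.  Rules with ``reassign_to`` then move their matches out of the
    source category into the target.  Genes matching nothing are absent
    from the mapping.  Multi-category membership is allowed.
    """
    names = {r.name for r in rules}
    for r in rules:
        if r.reassign_to is not None and r.reassign_to not in names:
            raise ConfigurationError(
                f"rule {r.name!r} reassigns to undefined category {r.reassign_to!r}"
            )
    base_rules = [r for r in rules if r.reassign_to is None]
    reassign_rules = [r for r in rules if r.reassign_to is not None]

    mapping: dict[str, set[str]] = {}
    descs = annotations.set_index("gene_id")["description"].fillna("")
    for gene_id, desc in descs.items():
        cats: set[str] = set()
        for rule in base_rules:
            if rule.matches(desc):
                cats.add(rule.name)
        for rule in reassign_rules:
            if rule.matches(desc):
                cats.discard(rule.name)
                cats.add(rule.reassign_to)
        if cats:
            mapping[gene_id] = cats
    return mapping


def members_of(mapping: dict[str, set[str]], category: str) -> list[str]:
    return sorted(g for g, cats in mapping.items() if category in cats)


def category_profile(
    matrix: ExpressionMatrix,
    mapping: dict[str, set[str]],
    design: SampleDesign,
    rules: list[CategoryRule] | None = None,
) -> CategoryProfile:
    """Percent-of-transcriptome profile per category, plus dominant genes.

    ``matrix`` should hold the floored values of the expressed genes; the
    percent denominator is the whole matrix.  Categories with no expressed
    members are reported with count 0 and 0% (logged, not an error).
    """
    if rules is not None:
        order = list(dict.fromkeys(r.reassign_to or r.name for r in rules))
    else:
        order = sorted({c for cats in mapping.values() for c in cats})
    percent = {}
    counts = {}
    dominant_rows = []
    means = condition_means(matrix, design)
    for cat in order:
        members = [g for g in members_of(mapping, cat) if g in matrix.genes]
        counts[cat] = len(members)
        if not members:
            logger.info("category %s has no expressed members", cat)
            percent[cat] = pd.Series(0.0, index=matrix.samples)
            continue
        percent[cat] = pd.Series(
            {s: transcriptome_share(matrix, members, s) for s in matrix.samples}
        )
        for cond in means.columns:
            gene, share = dominant_gene_share(means, members, cond)
            dominant_rows.append((cat, cond, gene, share))
    return CategoryProfile(
        percent=pd.DataFrame(percent).T.reindex(order),
        member_counts=pd.Series(counts).reindex(order),
        dominant=pd.DataFrame(
            dominant_rows, columns=["category", "condition", "gene_id", "share"]
        ),
    )


def dominant_gene_share(means: pd.DataFrame, members, condition: str) -> tuple[str, float]:
    """The member gene with the largest replicate-mean signal in a condition
    and its fraction of the category total; ties broken by gene id (logged)."""
    members = sorted(members)
    if not members:
        raise AzfluxError("empty category member set")
    if condition not in means.columns:
        raise AzfluxError(f"unknown condition {condition!r}")
    vals = means.loc[members, condition]
    total = float(vals.sum())
    if total <= 0:
        raise AzfluxError(f"zero category total in condition {condition!r}")
    top = float(vals.max())
    winners = vals.index[vals == top].tolist()
    if len(winners) > 1:
        logger.info("dominant-gene tie in %s: %s; taking %s", condition, winners, winners[0])
    return winners[0], top / total
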