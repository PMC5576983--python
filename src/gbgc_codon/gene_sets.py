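"""GO-like gene set handling and the proliferation/differentiation split.

Gene sets are flat, possibly overlapping, named collections of gene ids
(GMT files). Sets are filtered by size (at least 40 members by default) and
by an explicit exclusion list for uninformatively broad terms (the
'protein binding' term GO:0005515 by default). Genes are then classified
into three exclusive categories — 'proliferation', 'differentiation',
'other' — by case-insensitive keyword matching on set names; genes matched
by both categories are discarded from category analyses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

#: keyword lists defining the two broad functional categories
PROLIFERATION_KEYWORDS = (
    "chromatin modification",
    "chromatin remodeling",
    "mitotic cell cycle",
    "mRNA metabolic process",
    "negative regulation of cell cycle",
    "nucleosome assembly",
    "translation",
)
DIFFERENTIATION_KEYWORDS = (
    "development",
    "differentiation",
    "cell adhesion",
    "pattern specification",
    "multicellular organism growth",
    "angiogenesis",
)
#: set names matching this pattern are never counted as 'proliferation'
#: ('negative regulation of proliferation' is not pro-proliferative)
DEFAULT_NEGATION_PATTERN = r"negative regulation of (cell )?proliferation"

DEFAULT_EXCLUDED_SET_IDS = ("GO:0005515",)


@dataclass
class GeneSetCollection:
    """Named, possibly overlapping gene sets."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def sizes(self) -> dict[str, int]:
        return {name: len(members) for name, members in self.sets.items()}

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    @classmethod
    def read_gmt(cls, path) -> "GeneSetCollection":
        """Read a GMT file (``name<TAB>description<TAB>gene1<TAB>...``)."""
        sets: dict[str, frozenset[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"malformed GMT line: {line[:80]!r}")
                sets[fields[0]] = frozenset(g for g in fields[2:] if g)
        return cls(sets)

    def write_gmt(self, path, descriptions: Mapping[str, str] | None = None) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sets):
                desc = (descriptions or {}).get(name, "na")
                members = "\t".join(sorted(self.sets[name]))
                fh.write(f"{name}\t{desc}\t{members}\n")


def filter_sets(
    collection: GeneSetCollection,
    min_size: int = 40,
    excluded_ids: Sequence[str] = DEFAULT_EXCLUDED_SET_IDS,
) -> GeneSetCollection:
    """Drop sets smaller than ``min_size`` (inclusive bound: a 40-gene set
    stays at min_size=40) and explicitly excluded ids regardless of size.
    Idempotent."""
    excluded = set(excluded_ids)
    kept = {
        name: members
        for name, members in collection.sets.items()
        if name not in excluded and len(members) >= min_size
    }
    return GeneSetCollection(kept)


def restrict_to_universe(
    collection: GeneSetCollection, universe: Iterable[str]
) -> GeneSetCollection:
    uni = frozenset(universe)
    return GeneSetCollection(
        {name: members & uni for name, members in collection.sets.items()}
    )


def assign_categories(
    collection: GeneSetCollection,
    proliferation_keywords: Sequence[str] = PROLIFERATION_KEYWORDS,
    differentiation_keywords: Sequence[str] = DIFFERENTIATION_KEYWORDS,
    negation_pattern: str | None = DEFAULT_NEGATION_PATTERN,
    set_names: Mapping[str, str] | None = None,
) -> pd.Series:
    """Per-gene category labels: proliferation / differentiation / other /
    discarded.

    A set belongs to a category when its (descriptive) name contains any of
    the category's keywords, case-insensitively; set names matching
    ``negation_pattern`` are excluded from 'proliferation'. A gene present
    in sets of both categories is 'discarded' and must be excluded from
    downstream category analyses. The result is independent of set
    iteration order.

    ``set_names`` optionally maps set ids to descriptive names to match
    keywords against (useful when GMT names are bare GO ids).
    """
    if not proliferation_keywords or not differentiation_keywords:
        raise ValueError("keyword lists must be non-empty")
    neg = re.compile(negation_pattern, re.IGNORECASE) if negation_pattern else None

    def matches(name: str, keywords: Sequence[str]) -> bool:
        low = name.lower()
        return any(kw.lower() in low for kw in keywords)

    prolif_genes: set[str] = set()
    diff_genes: set[str] = set()
    for set_id, members in collection.sets.items():
        name = (set_names or {}).get(set_id, set_id)
        if matches(name, proliferation_keywords) and not (neg and neg.search(name)):
            prolif_genes |= members
        if matches(name, differentiation_keywords):
            diff_genes |= members

    labels = {}
    for gene in collection.universe():
        in_p, in_d = gene in prolif_genes, gene in diff_genes
        if in_p and in_d:
            labels[gene] = "discarded"
        elif in_p:
            labels[gene] = "proliferation"
        elif in_d:
            labels[gene] = "differentiation"
        else:
            labels[gene] = "other"
    return pd.Series(labels, name="category").sort_index()


def length_filter(models: Sequence, min_len: int = 5000) -> list:
    """Keep genes whose transcription unit (TSS→polyA) is at least
    ``min_len`` bp; the bound is inclusive (a 5,000-bp gene is kept)."""
    return [m for m in models if m.length >= min_len]


def default_keyword_config() -> dict:
    """The shipped category-keyword configuration."""
    with resources.files("gbgc_codon.data").joinpath("category_keywords.yaml").open() as fh:
        return yaml.safe_load(fh)
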