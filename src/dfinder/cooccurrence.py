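"""Co-occurrence filtering: turn a drug/food-constituent co-mention count
table into a DFI network.

Candidate interactions are mined by counting how often a drug name and a
food-constituent name appear together in publication abstracts.  Raw
co-occurrence is noisy, so three filters are applied before the surviving
pairs become network edges:

* **Rule 1** - keep only pairs co-occurring strictly more than a count
  threshold (default 20), dropping rare, likely-spurious co-mentions.
* **Rule 2** - drop pairs whose two names are identical after
  normalization: many food constituents (caffeine, ethanol, ...) are also
  registered drugs, and such self-pairs carry no interaction signal.
* **Rule 3** - drop pairs whose names are merely *similar* (normalized
  Levenshtein similarity at or above a threshold, default 0.8): near-
  identical names usually co-occur because they denote the same chemical,
  not because they interact.

The three predicates are pairwise independent, so the filters commute and
are idempotent; they are conventionally applied in the order 1 -> 2 -> 3.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import pandas as pd

from .graph import BipartiteDFIGraph


@dataclass(frozen=True)
class CooccurrencePair:
    """One drug / food-constituent pair with its abstract co-mention count."""

    drug_name: str
    constituent_name: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"negative co-occurrence count: {self.count}")
        if not self.drug_name.strip() or not self.constituent_name.strip():
            raise ValueError("empty name in co-occurrence pair")


def normalize_name(name: str) -> str:
    """Unicode NFC, casefold, trim and collapse internal whitespace."""
    s = unicodedata.normalize("NFC", name).casefold().strip()
    return " ".join(s.split())


def apply_rule1(
    pairs: Sequence[CooccurrencePair], threshold: int = 20
) -> list[CooccurrencePair]:
    """Keep pairs with count strictly greater than ``threshold``."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    return [p for p in pairs if p.count > threshold]


def apply_rule2(pairs: Sequence[CooccurrencePair]) -> list[CooccurrencePair]:
    """Remove pairs whose drug and constituent names coincide after
    normalization (the same chemical listed on both sides)."""
    return [
        p
        for p in pairs
        if normalize_name(p.drug_name) != normalize_name(p.constituent_name)
    ]


def name_similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity of two names in [0, 1].

    ``1 - editdistance(a, b) / max(|a|, |b|)`` on casefolded strings;
    1.0 means identical, 0.0 means every position differs.
    """
    if not a or not b:
        raise ValueError("name_similarity requires non-empty strings")
    na, nb = normalize_name(a), normalize_name(b)
    if not na or not nb:
        raise ValueError("name_similarity requires non-blank strings")
    dist = edlib.align(na, nb, task="distance")["editDistance"]
    return 1.0 - dist / max(len(na), len(nb))


def apply_rule3(
    pairs: Sequence[CooccurrencePair], sim_threshold: float = 0.8
) -> list[CooccurrencePair]:
    """Remove pairs whose name similarity is at or above ``sim_threshold``."""
    if not 0.0 <= sim_threshold <= 1.0:
        raise ValueError(f"sim_threshold must be in [0, 1], got {sim_threshold}")
    return [
        p
        for p in pairs
        if name_similarity(p.drug_name, p.constituent_name) < sim_threshold
    ]


@dataclass
class FilterReport:
    """Counts of pairs surviving each stage of the 1 -> 2 -> 3 pipeline."""

    n_input: int
    n_after_rule1: int
    n_after_rule2: int
    n_after_rule3: int

    def to_text(self) -> str:
        return (
            f"input_pairs\t{self.n_input}\n"
            f"after_rule1_count_filter\t{self.n_after_rule1}\n"
            f"after_rule2_identity_filter\t{self.n_after_rule2}\n"
            f"after_rule3_similarity_filter\t{self.n_after_rule3}\n"
        )


def filter_pairs(
    pairs: Sequence[CooccurrencePair],
    min_count: int = 20,
    sim_threshold: float = 0.8,
) -> tuple[list[CooccurrencePair], FilterReport]:
    """Run the full Rule 1 -> Rule 2 -> Rule 3 pipeline with a stage report."""
    s1 = apply_rule1(pairs, threshold=min_count)
    s2 = apply_rule2(s1)
    s3 = apply_rule3(s2, sim_threshold=sim_threshold)
    report = FilterReport(len(pairs), len(s1), len(s2), len(s3))
    return s3, report


def build_network(pairs: Iterable[CooccurrencePair]) -> BipartiteDFIGraph:
    """Construct a DFI network from (already filtered) co-occurrence pairs.

    One edge per surviving (drug, constituent) pair; duplicate pairs collapse
    to a single edge and counts are discarded.
    """
    return BipartiteDFIGraph.from_edges(
        (p.drug_name, p.constituent_name) for p in pairs
    )


def load_cooccurrence_tsv(path: str | Path) -> list[CooccurrencePair]:
    """Read a 3-column TSV (drug_name, constituent_name, count)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["drug_name", "constituent_name", "count"],
        dtype={"drug_name": str, "constituent_name": str},
    )
    if len(df) and str(df.iloc[0]["count"]).lower() in {"count", "n"}:
        df = df.iloc[1:]
    return [
        CooccurrencePair(str(r.drug_name), str(r.constituent_name), int(r.count))
        for r in df.itertuples(index=False)
    ]
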