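"""Regulatory-knowledge interaction tables.

Experimentally validated interactions (TF -> miRNA transcriptional
regulation, miRNA -> mRNA post-transcriptional repression) are read from
tab-separated tables, reconciled against the gene universe of an
expression matrix, and used as *constant edges* during structure
learning.  The module also implements the evaluation hygiene rule: an
interaction present in both the knowledge and the evaluation ground
truth is removed from the knowledge and kept only for evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "INTERACTION_TYPES",
    "KnowledgeRecord",
    "KnowledgeSet",
    "read_interactions",
    "restrict_to_universe",
    "separate_knowledge_from_ground_truth",
]

#: transcriptional (TF-coding mRNA regulates a miRNA) and
#: post-transcriptional (miRNA represses an mRNA) interaction classes
INTERACTION_TYPES = ("tf_mirna", "mirna_mrna")


@dataclass(frozen=True)
class KnowledgeRecord:
    """One validated regulator -> target interaction."""

    regulator: str
    target: str
    interaction_type: str
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.regulator == self.target:
            raise ValueError(f"self-regulation record for {self.regulator!r}")
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(
                f"unknown interaction type {self.interaction_type!r}; "
                f"expected one of {INTERACTION_TYPES}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.regulator, self.target)


class KnowledgeSet:
    """Deduplicated set of knowledge records, keyed by (regulator, target)."""

    def __init__(self, records: Iterable[KnowledgeRecord] = ()) -> None:
        self._records: dict[tuple[str, str], KnowledgeRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: KnowledgeRecord) -> None:
        # first occurrence wins; duplicates by (regulator, target) are dropped
        self._records.setdefault(record.pair, record)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[KnowledgeRecord]:
        return iter(self._records[p] for p in sorted(self._records))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self._records

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeSet):
            return NotImplemented
        return self._records == other._records

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self._records)

    def of_type(self, interaction_type: str) -> "KnowledgeSet":
        return KnowledgeSet(
            r for r in self if r.interaction_type == interaction_type
        )

    def union(self, other: "KnowledgeSet") -> "KnowledgeSet":
        out = KnowledgeSet(self)
        for rec in other:
            out.add(rec)
        return out

    def genes(self) -> set[str]:
        return {g for p in self._records for g in p}

    def __repr__(self) -> str:
        return f"KnowledgeSet({len(self)} records)"


def read_interactions(
    path, interaction_type: str | None = None, source_tag: str | None = None
) -> KnowledgeSet:
    """Read a knowledge table.

    Expected format: tab-separated with a header line ``regulator<TAB>target``.
    Extra columns are ignored, except that when ``interaction_type`` is None a
    third ``type`` column must supply the interaction class per row.
    Identifiers are whitespace-trimmed; case is preserved.
    """
    tag = source_tag if source_tag is not None else str(path)
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file, expected a header line")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 tab-separated "
                    f"columns (regulator, target)"
                )
            itype = interaction_type
            if itype is None:
                if len(fields) < 3 or not fields[2]:
                    raise ValueError(
                        f"{path}:{lineno}: no interaction_type given and no "
                        f"'type' column present"
                    )
                itype = fields[2]
            records.append(
                KnowledgeRecord(fields[0], fields[1], itype, source_tag=tag)
            )
    return KnowledgeSet(records)


def read_pairs(path) -> set[tuple[str, str]]:
    """Read just the (regulator, target) pairs of a 2+-column TSV with
    header; used for evaluation ground truth, where the interaction type
    is irrelevant (and true-edge tables may contain untyped edges)."""
    pairs = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file, expected a header line")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 tab-separated columns"
                )
            pairs.add((fields[0], fields[1]))
    return pairs


def write_interactions(knowledge: KnowledgeSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\ttype\n")
        for rec in knowledge:
            fh.write(f"{rec.regulator}\t{rec.target}\t{rec.interaction_type}\n")


def restrict_to_universe(
    knowledge: KnowledgeSet, genes: Iterable[str]
) -> KnowledgeSet:
    """Keep only records whose regulator and target both appear in ``genes``.

    Records referencing genes absent from the expression matrix (e.g.
    filtered out upstream) are dropped with a logged count rather than an
    error.
    """
    universe = set(genes)
    kept = KnowledgeSet(
        r for r in knowledge if r.regulator in universe and r.target in universe
    )
    dropped = len(knowledge) - len(kept)
    if dropped:
        logger.info(
            "dropped %d of %d knowledge records outside the gene universe",
            dropped,
            len(knowledge),
        )
    return kept


def separate_knowledge_from_ground_truth(
    knowledge: KnowledgeSet, ground_truth: KnowledgeSet
) -> KnowledgeSet:
    """Remove from ``knowledge`` every pair also present in ``ground_truth``.

    Interactions reserved as evaluation ground truth must not also steer
    the learner; ``ground_truth`` itself is untouched.
    """
    truth_pairs = ground_truth.pairs
    kept = KnowledgeSet(r for r in knowledge if r.pair not in truth_pairs)
    removed = len(knowledge) - len(kept)
    if removed:
        logger.info(
            "removed %d knowledge records overlapping the ground truth", removed
        )
    return kept
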