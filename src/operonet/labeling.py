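"""Assign operon labels to gene pairs from an experimentally validated table.

Label semantics follow the conservative convention used with curated operon
databases: a pair is labeled 1 when some operon contains both genes, 0 when
both genes are annotated but never share an operon, and 2 (unknown) when
either gene is absent from the table — absence of evidence is not evidence
of absence.  Label-2 pairs are excluded from training and kept for
prediction only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .genome_io import GenePair

logger = logging.getLogger(__name__)

LABEL_NON_OPERON = 0
LABEL_OPERON = 1
LABEL_UNKNOWN = 2


@dataclass(frozen=True)
class PairLabel:
    pair_id: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1, 2):
            raise ValueError(f"label must be 0, 1 or 2; got {self.label}")


@dataclass
class OperonTable:
    """Mapping operon_id -> ordered gene ids; genes may recur across operons."""

    operons: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for oid, genes in self.operons.items():
            if not genes:
                raise ValueError(f"operon {oid!r} has no genes")
        self._membership: dict[str, set[str]] = {}
        for oid, genes in self.operons.items():
            for gid in genes:
                self._membership.setdefault(gid, set()).add(oid)

    def operons_of(self, gene_id: str) -> set[str]:
        return self._membership.get(gene_id, set())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._membership


def read_operon_table(path: str | Path) -> OperonTable:
    """Read a TSV (``operon_id<TAB>gene_id``, one row per membership) or JSON."""
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        return OperonTable({str(k): [str(g) for g in v] for k, v in data.items()})
    operons: dict[str, list[str]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            oid, gid = line.split("\t")[:2]
            operons.setdefault(oid, []).append(gid)
    return OperonTable(operons)


def write_operon_table(table: OperonTable, path: str | Path) -> None:
    with open(path, "wt") as handle:
        for oid, genes in table.operons.items():
            for gid in genes:
                handle.write(f"{oid}\t{gid}\n")


def label_pairs(
    pairs: Sequence[GenePair], operons: OperonTable
) -> list[PairLabel]:
    """Label each pair 1 (co-operonic), 0 (different operons) or 2 (unknown)."""
    labels = []
    for pair in pairs:
        ops1 = operons.operons_of(pair.gene1.gene_id)
        ops2 = operons.operons_of(pair.gene2.gene_id)
        if not ops1 or not ops2:
            label = LABEL_UNKNOWN
        elif ops1 & ops2:
            label = LABEL_OPERON
        else:
            label = LABEL_NON_OPERON
        labels.append(PairLabel(pair_id=pair.pair_id, label=label))
    return labels


def filter_training(
    labels: Iterable[PairLabel],
) -> tuple[list[PairLabel], list[PairLabel]]:
    """Split labels into (kept 0/1, excluded label-2) for training."""
    kept = [l for l in labels if l.label in (0, 1)]
    excluded = [l for l in labels if l.label == LABEL_UNKNOWN]
    logger.info(
        "training filter: kept %d labeled pairs (%d operon, %d non-operon), "
        "excluded %d unknown",
        len(kept),
        sum(l.label == 1 for l in kept),
        sum(l.label == 0 for l in kept),
        len(excluded),
    )
    return kept, excluded
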