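"""CHEMPROT-style corpus I/O: abstracts, entity mentions, gold relations,
and prediction files.

All files are UTF-8, tab-separated, Unix newlines:

* abstracts:   ``pmid <TAB> title <TAB> body``
* entities:    ``pmid <TAB> mention_id <TAB> type <TAB> start <TAB> end <TAB> surface``
* relations:   ``pmid <TAB> group <TAB> Arg1:<chem_id> <TAB> Arg2:<gene_id>``
* predictions: ``pmid <TAB> group <TAB> Arg1:<chem_id> <TAB> Arg2:<gene_id> <TAB> score``

Character offsets are 0-based half-open into the *document text*, which is
``title + separator + body`` (separator defaults to a single tab, matching
the layout of the abstracts file itself).  ``GENE-Y``/``GENE-N`` entity types
collapse to ``GENE``; the classifier never distinguishes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

logger = logging.getLogger(__name__)

#: The five CHEMPROT relation groups that carry evaluation weight, plus the
#: "no relation" class, in fixed classifier output order.
EVALUATED_GROUPS: Tuple[str, ...] = ("CPR:3", "CPR:4", "CPR:5", "CPR:6", "CPR:9")
CLASSES: Tuple[str, ...] = ("False",) + EVALUATED_GROUPS

DEFAULT_SEPARATOR = "\t"


class CorpusError(ValueError):
    """Raised for malformed or inconsistent corpus files."""


@dataclass(frozen=True)
class AbstractRecord:
    pmid: str
    title: str
    body: str

    def text(self, separator: str = DEFAULT_SEPARATOR) -> str:
        """Document text against which entity offsets resolve."""
        return self.title + separator + self.body


@dataclass(frozen=True)
class EntityMention:
    pmid: str
    mention_id: str
    etype: str  # "CHEMICAL" or "GENE"
    start: int
    end: int
    surface: str


@dataclass(frozen=True)
class GoldRelation:
    pmid: str
    group: str
    chem_id: str
    gene_id: str


@dataclass(frozen=True)
class Prediction:
    pmid: str
    group: str
    chem_id: str
    gene_id: str
    score: float = 0.0


def _read_lines(path) -> List[List[str]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            rows.append([lineno, line.split("\t")])
    return rows


def read_abstracts(path) -> List[AbstractRecord]:
    """Read an abstracts TSV; one :class:`AbstractRecord` per line."""
    records: List[AbstractRecord] = []
    seen = set()
    for lineno, fields in _read_lines(path):
        if len(fields) < 3:
            raise CorpusError(
                f"{path}:{lineno}: abstract line needs >=3 tab-separated "
                f"fields, got {len(fields)}"
            )
        pmid, title = fields[0], fields[1]
        # a tab inside the body would have been split; re-join the remainder
        body = "\t".join(fields[2:])
        if pmid in seen:
            raise CorpusError(f"{path}:{lineno}: duplicate pmid {pmid!r}")
        seen.add(pmid)
        records.append(AbstractRecord(pmid=pmid, title=title, body=body))
    return records


def write_abstracts(path, records: Iterable[AbstractRecord]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in records:
            fh.write(f"{r.pmid}\t{r.title}\t{r.body}\n")


def read_entities(path, abstracts: Sequence[AbstractRecord],
                  separator: str = DEFAULT_SEPARATOR) -> List[EntityMention]:
    """Read entity mentions and validate offsets against document text.

    Every mention must satisfy ``0 <= start < end <= len(text)`` and its
    surface string must equal ``text[start:end]``; violations raise
    :class:`CorpusError` naming the pmid and mention id.
    """
    by_pmid = {a.pmid: a.text(separator) for a in abstracts}
    mentions: List[EntityMention] = []
    for lineno, fields in _read_lines(path):
        if len(fields) != 6:
            raise CorpusError(
                f"{path}:{lineno}: entity line needs 6 fields, got {len(fields)}"
            )
        pmid, mid, etype, start_s, end_s, surface = fields
        if etype in ("GENE-Y", "GENE-N"):
            etype = "GENE"
        if etype not in ("CHEMICAL", "GENE"):
            raise CorpusError(f"{path}:{lineno}: unknown entity type {etype!r}")
        if pmid not in by_pmid:
            raise CorpusError(f"{path}:{lineno}: unknown pmid {pmid!r}")
        start, end = int(start_s), int(end_s)
        text = by_pmid[pmid]
        if not (0 <= start < end <= len(text)):
            raise CorpusError(
                f"entity {pmid}/{mid}: offsets [{start},{end}) out of range "
                f"for document of length {len(text)}"
            )
        if text[start:end] != surface:
            raise CorpusError(
                f"entity {pmid}/{mid}: surface {surface!r} does not match "
                f"document slice {text[start:end]!r}"
            )
        mentions.append(EntityMention(pmid, mid, etype, start, end, surface))
    return mentions


def write_entities(path, mentions: Iterable[EntityMention]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for m in mentions:
            fh.write(f"{m.pmid}\t{m.mention_id}\t{m.etype}\t{m.start}\t{m.end}\t{m.surface}\n")


def read_relations(path, mentions: Sequence[EntityMention] | None = None,
                   ) -> Tuple[List[GoldRelation], int]:
    """Read gold relations, keeping only the five evaluated groups.

    Returns ``(relations, n_dropped)`` where ``n_dropped`` counts lines whose
    group is outside the evaluated set (e.g. CPR:10); those are discarded,
    mirroring the evaluation protocol that scores only five groups.
    """
    known_ids = None
    if mentions is not None:
        known_ids = {(m.pmid, m.mention_id) for m in mentions}
    relations: List[GoldRelation] = []
    dropped = 0
    for lineno, fields in _read_lines(path):
        if len(fields) != 4:
            raise CorpusError(
                f"{path}:{lineno}: relation line needs 4 fields, got {len(fields)}"
            )
        pmid, group, arg1, arg2 = fields
        chem_id = arg1.removeprefix("Arg1:")
        gene_id = arg2.removeprefix("Arg2:")
        if group not in EVALUATED_GROUPS:
            dropped += 1
            continue
        if known_ids is not None:
            for mid in (chem_id, gene_id):
                if (pmid, mid) not in known_ids:
                    raise CorpusError(
                        f"{path}:{lineno}: relation references unknown mention "
                        f"{pmid}/{mid}"
                    )
        relations.append(GoldRelation(pmid, group, chem_id, gene_id))
    if dropped:
        logger.info("read_relations: dropped %d non-evaluated relations", dropped)
    return relations, dropped


def write_relations(path, relations: Iterable[GoldRelation]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in relations:
            fh.write(f"{r.pmid}\t{r.group}\tArg1:{r.chem_id}\tArg2:{r.gene_id}\n")


def write_predictions(path, preds: Iterable[Prediction]) -> None:
    """Write predictions in canonical (pmid, chem_id, gene_id) order.

    The sort makes output bytes independent of prediction order, so files
    from different runs diff cleanly.
    """
    ordered = sorted(preds, key=lambda p: (p.pmid, p.chem_id, p.gene_id))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for p in ordered:
            fh.write(f"{p.pmid}\t{p.group}\tArg1:{p.chem_id}\tArg2:{p.gene_id}\t{p.score:.6f}\n")


def read_predictions(path) -> List[Prediction]:
    preds: List[Prediction] = []
    for lineno, fields in _read_lines(path):
        if len(fields) not in (4, 5):
            raise CorpusError(
                f"{path}:{lineno}: prediction line needs 4-5 fields, got {len(fields)}"
            )
        pmid, group, arg1, arg2 = fields[:4]
        if group not in EVALUATED_GROUPS:
            raise CorpusError(f"{path}:{lineno}: invalid predicted group {group!r}")
        score = float(fields[4]) if len(fields) == 5 else 0.0
        preds.append(Prediction(pmid, group,
                                arg1.removeprefix("Arg1:"),
                                arg2.removeprefix("Arg2:"), score))
    return preds
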