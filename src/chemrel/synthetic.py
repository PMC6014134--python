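"""Synthetic CHEMPROT-format corpora with planted relation cues.

The generator emulates the structure of the real corpus — abstracts with
character-offset entity annotations and gold relations in the five CPR
groups — without any download.  Each sentence is drawn from templates:
relation-bearing sentences plant a group-specific cue verb between a
chemical and a gene mention (CPR:3 activation words, CPR:4 inhibition
words, "agonist" for CPR:5, "antagonist" for CPR:6, substrate/product
words for CPR:9); negative sentences use neutral verbs that never occur in
any cue set, so the planted class signal is recoverable by construction.
A configurable fraction of gold relations spans two sentences (chemical in
one, gene in the next), which must yield no candidate instance downstream.

Right-branching binary parses are emitted for every candidate instance;
the models consume any binary tree, so learnability rather than linguistic
realism is what these trees provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .corpus import (
    AbstractRecord,
    DEFAULT_SEPARATOR,
    EntityMention,
    GoldRelation,
    write_abstracts,
    write_entities,
    write_relations,
)
from .features import EmbeddingTable, WORD_DIM

#: Cue lexicon per relation group; sets are mutually disjoint.
DEFAULT_CUES: Dict[str, Tuple[str, ...]] = {
    "CPR:3": ("activates", "promotes", "increases"),
    "CPR:4": ("inhibits", "blocks", "attenuates"),
    "CPR:5": ("agonist",),
    "CPR:6": ("antagonist",),
    "CPR:9": ("substrate", "product"),
}

#: Neutral verbs for negative sentences; never in any cue set.
NEUTRAL_VERBS = ("accompanies", "coexists with", "was measured alongside")

CHEMICALS = (
    "aspirin", "caffeine", "mifepristone", "cyanopindolol",
    "zinc chloride", "retinoic acid", "amitriptyline", "dexamethasone",
)
GENES = (
    "TrkA", "IL6", "histone deacetylase", "CYP2D6",
    "serotonin receptor", "p53", "LTA4H", "EGFR",
)
FILLERS = ("in", "cultured", "cells", "markedly", "primary", "neurons",
           "after", "treatment", "expression", "levels")


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic corpus."""

    n_abstracts: int = 50
    sentences_per_abstract: Tuple[int, int] = (2, 4)
    class_priors: Dict[str, float] = field(default_factory=lambda: {
        "False": 0.5, "CPR:3": 0.1, "CPR:4": 0.1,
        "CPR:5": 0.1, "CPR:6": 0.1, "CPR:9": 0.1,
    })
    distractor_entity_rate: float = 0.3
    cross_sentence_rate: float = 0.1
    cues: Dict[str, Tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CUES))
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_priors.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class priors sum to {total}, expected 1")
        if all(p == 0 for p in self.class_priors.values()):
            raise ValueError("all class priors are zero")
        seen = set()
        for group, words in self.cues.items():
            if seen & set(words):
                raise ValueError(f"cue sets are not disjoint at group {group}")
            seen |= set(words)
        if seen & set(" ".join(NEUTRAL_VERBS).split()):
            raise ValueError("neutral verbs collide with cue words")


@dataclass
class SyntheticCorpus:
    """In-memory corpus plus the config that produced it."""

    abstracts: List[AbstractRecord]
    entities: List[EntityMention]
    relations: List[GoldRelation]
    config: GeneratorConfig

    def write(self, outdir) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "abstracts": outdir / "abstracts.tsv",
            "entities": outdir / "entities.tsv",
            "relations": outdir / "relations.tsv",
            "manifest": outdir / "manifest.txt",
        }
        write_abstracts(paths["abstracts"], self.abstracts)
        write_entities(paths["entities"], self.entities)
        write_relations(paths["relations"], self.relations)
        cfg = self.config
        with open(paths["manifest"], "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"seed={cfg.seed}\n")
            fh.write(f"n_abstracts={cfg.n_abstracts}\n")
            fh.write(f"distractor_entity_rate={cfg.distractor_entity_rate}\n")
            fh.write(f"cross_sentence_rate={cfg.cross_sentence_rate}\n")
            for group, prior in sorted(cfg.class_priors.items()):
                fh.write(f"prior.{group}={prior}\n")
        return paths


class _AbstractBuilder:
    """Accumulates body text while tracking mention offsets."""

    def __init__(self, pmid: str, title: str):
        self.pmid = pmid
        self.title = title
        self.body_parts: List[str] = []
        self.body_len = 0
        self.entities: List[Tuple[str, str, int, int, str]] = []  # doc-relative later
        self.next_id = 1

    def _append(self, text: str) -> int:
        start = self.body_len
        self.body_parts.append(text)
        self.body_len += len(text)
        return start

    def add_sentence(self, parts: Sequence[Tuple[str, Optional[str]]]) -> List[str]:
        """``parts`` is a list of (text, entity_type-or-None); returns the
        mention ids created, in order."""
        ids = []
        if self.body_parts:
            self._append(" ")
        for i, (text, etype) in enumerate(parts):
            if i > 0:
                self._append(" ")
            start = self._append(text)
            if etype is not None:
                mid = f"T{self.next_id}"
                self.next_id += 1
                self.entities.append((mid, etype, start, start + len(text), text))
                ids.append(mid)
        self._append(" .")
        return ids

    def finish(self, separator: str = DEFAULT_SEPARATOR,
               ) -> Tuple[AbstractRecord, List[EntityMention]]:
        body = "".join(self.body_parts)
        record = AbstractRecord(self.pmid, self.title, body)
        offset = len(self.title) + len(separator)
        mentions = [
            EntityMention(self.pmid, mid, etype, start + offset,
                          end + offset, surface)
            for mid, etype, start, end, surface in self.entities
        ]
        return record, mentions


def make_corpus(cfg: Optional[GeneratorConfig] = None,
                separator: str = DEFAULT_SEPARATOR) -> SyntheticCorpus:
    """Generate a corpus; byte-deterministic given ``cfg.seed``."""
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    class_names = sorted(cfg.class_priors)
    priors = np.array([cfg.class_priors[c] for c in class_names])

    abstracts: List[AbstractRecord] = []
    entities: List[EntityMention] = []
    relations: List[GoldRelation] = []

    for a in range(cfg.n_abstracts):
        pmid = f"{90000000 + a}"
        builder = _AbstractBuilder(
            pmid, f"Synthetic abstract {a} on chemical gene interactions")
        lo, hi = cfg.sentences_per_abstract
        n_sent = int(rng.integers(lo, hi + 1))
        pending_cross: Optional[Tuple[str, str]] = None  # (chem_id, group)
        for _ in range(n_sent):
            label = class_names[int(rng.choice(len(class_names), p=priors))]
            chem = str(rng.choice(CHEMICALS))
            gene = str(rng.choice(GENES))
            if pending_cross is not None:
                chem_id, group = pending_cross
                ids = builder.add_sentence([
                    ("Expression of", None), (gene, "GENE"),
                    ("increased afterwards", None),
                ])
                relations.append(GoldRelation(pmid, group, chem_id, ids[0]))
                pending_cross = None
                continue
            if label == "False":
                verb = str(rng.choice(NEUTRAL_VERBS))
                parts = [(chem, "CHEMICAL"), (verb, None), (gene, "GENE")]
                if rng.random() < cfg.distractor_entity_rate:
                    kind = "CHEMICAL" if rng.random() < 0.5 else "GENE"
                    pool = CHEMICALS if kind == "CHEMICAL" else GENES
                    parts += [("and", None), (str(rng.choice(pool)), kind)]
                parts.append((f"in {rng.choice(FILLERS)} {rng.choice(FILLERS)}", None))
                builder.add_sentence(parts)
            elif rng.random() < cfg.cross_sentence_rate:
                ids = builder.add_sentence([
                    (chem, "CHEMICAL"), ("was administered daily", None),
                ])
                pending_cross = (ids[0], label)
            else:
                cue = str(rng.choice(cfg.cues[label]))
                if label in ("CPR:5", "CPR:6"):
                    parts = [(chem, "CHEMICAL"), ("is an", None), (cue, None),
                             ("of the", None), (gene, "GENE")]
                elif label == "CPR:9":
                    parts = [(chem, "CHEMICAL"), ("is a", None), (cue, None),
                             ("of", None), (gene, "GENE")]
                else:
                    lead = str(rng.choice(("markedly", "strongly", "weakly")))
                    parts = [(chem, "CHEMICAL"), (lead, None), (cue, None),
                             (gene, "GENE"),
                             (f"{rng.choice(FILLERS)} {rng.choice(FILLERS)}", None)]
                ids = builder.add_sentence(parts)
                relations.append(GoldRelation(pmid, label, ids[0], ids[1]))
        record, mentions = builder.finish(separator)
        abstracts.append(record)
        entities.extend(mentions)

    return SyntheticCorpus(abstracts=abstracts, entities=entities,
                           relations=relations, config=cfg)


def make_embeddings(tokens: Sequence[str], dim: int = WORD_DIM,
                    seed: int = 0) -> EmbeddingTable:
    """One seeded uniform(-0.1, 0.1) vector per distinct token."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(seed)
    vectors = {tok: rng.uniform(-0.1, 0.1, dim) for tok in sorted(set(tokens))}
    return EmbeddingTable(vectors=vectors, dim=dim, seed=seed)
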