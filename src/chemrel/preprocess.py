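"""Sentence splitting, candidate-pair generation, entity anonymization,
instance filtering and vocabulary construction.

The pipeline mirrors how relation-extraction corpora are conventionally
prepared: an abstract is split into sentences; every (chemical, gene) mention
pair co-occurring in a sentence becomes one candidate instance labelled with
its gold relation group or ``False``; target entities are collapsed to
single placeholder tokens so the classifier sees position, not surface form.

Two anonymization schemes are provided:

* ``challenge``: the two target entities become ``BC6ENT1``/``BC6ENT2`` in
  order of appearance; optionally, chemical surfaces from a lexicon become
  ``CHEM``.
* ``postchallenge``: the target chemical becomes ``BC6ENTC``, the target gene
  ``BC6ENTG``, and every other annotated entity in the sentence ``BC6OTHER``.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .corpus import (
    AbstractRecord,
    CorpusError,
    DEFAULT_SEPARATOR,
    EVALUATED_GROUPS,
    EntityMention,
    GoldRelation,
)

#: Placeholder tokens; always retained by the vocabulary regardless of count.
PLACEHOLDERS = ("BC6ENT1", "BC6ENT2", "BC6ENTC", "BC6ENTG", "BC6OTHER", "CHEM")

#: Reserved symbol all rare / out-of-vocabulary tokens map to.
RARE_TOKEN = "BC6RARE"

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")

# sentence terminator followed by whitespace; the guard list blocks the most
# common abbreviation false positives, incl. single capital letters ("S. aureus")
_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s)")
_ABBREVIATIONS = {
    "e.g", "i.e", "etc", "cf", "vs", "al", "fig", "figs", "dr", "st",
    "no", "approx", "ca", "sp", "spp",
}


def tokenize(text: str) -> List[str]:
    """Whitespace + punctuation tokenization; word characters stay together
    so placeholder tokens are atomic."""
    return _TOKEN_RE.findall(text)


def tokenize_with_spans(text: str) -> List[Tuple[str, int, int]]:
    return [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


@dataclass
class Sentence:
    """One sentence of a document with the entity mentions inside it.

    ``start``/``end`` are offsets into the document text; each element of
    ``mentions`` pairs an :class:`EntityMention` with its character span
    relative to the sentence.
    """

    pmid: str
    sent_index: int
    start: int
    end: int
    text: str
    mentions: List[Tuple[EntityMention, int, int]] = field(default_factory=list)

    @property
    def tokens(self) -> List[str]:
        return tokenize(self.text)

    def mention_token_span(self, mention: EntityMention) -> Tuple[int, int]:
        """Half-open token-index span covered by ``mention``."""
        for m, rs, re_ in self.mentions:
            if m is mention or (m.mention_id == mention.mention_id and m.pmid == mention.pmid):
                spans = tokenize_with_spans(self.text)
                idxs = [i for i, (_, ts, te) in enumerate(spans) if ts < re_ and te > rs]
                return (idxs[0], idxs[-1] + 1) if idxs else (0, 0)
        raise ValueError(f"mention {mention.mention_id} not in sentence")


@dataclass
class CandidateInstance:
    """A (chemical, gene) mention pair in one sentence.

    ``tokens`` and the target indices are populated by one of the anonymize
    functions; ``e1_index`` is the first-appearing target placeholder,
    ``e2_index`` the second (position features are measured from these).
    """

    pmid: str
    sent_index: int
    chem_id: str
    gene_id: str
    label: str
    tokens: Optional[List[str]] = None
    e1_index: Optional[int] = None
    e2_index: Optional[int] = None
    overlap: bool = False
    confusing: bool = False
    gold_groups: Tuple[str, ...] = ()
    sentence: Optional[Sentence] = None
    chem: Optional[EntityMention] = None
    gene: Optional[EntityMention] = None


def split_sentences(abstract: AbstractRecord,
                    mentions: Sequence[EntityMention] = (),
                    separator: str = DEFAULT_SEPARATOR) -> List[Sentence]:
    """Split a document into sentences without ever cutting inside a mention.

    Candidate boundaries come from sentence-terminal punctuation (with an
    abbreviation guard) plus the title/body separator; any boundary that
    would bisect an annotated mention span is discarded, so the sentence
    spans tile the document text and every mention lands wholly inside one
    sentence.
    """
    text = abstract.text(separator)
    doc_mentions = [m for m in mentions if m.pmid == abstract.pmid]

    boundaries = set()
    # the separator between title and body always ends the title sentence
    sep_pos = len(abstract.title)
    boundaries.add(sep_pos + len(separator))
    for m in _BOUNDARY_RE.finditer(text):
        prev = text[:m.start()].rstrip()
        last_word = prev.split()[-1] if prev.split() else ""
        bare = last_word.rstrip(".").lower()
        if bare in _ABBREVIATIONS:
            continue
        if len(bare) == 1 and bare.isalpha():
            # single-letter initialism such as the "S." of "S. aureus"
            continue
        boundaries.add(m.end())

    # never split inside a mention
    boundaries = {
        b for b in boundaries
        if not any(m.start < b < m.end for m in doc_mentions)
    }
    cuts = sorted(b for b in boundaries if 0 < b < len(text))

    sentences: List[Sentence] = []
    prev = 0
    for idx, cut in enumerate(cuts + [len(text)]):
        raw = text[prev:cut]
        # trim surrounding whitespace but keep offsets honest
        lstrip = len(raw) - len(raw.lstrip())
        rstrip = len(raw) - len(raw.rstrip())
        s_start, s_end = prev + lstrip, cut - rstrip
        if s_end <= s_start:
            prev = cut
            continue
        sent = Sentence(abstract.pmid, len(sentences), s_start, s_end,
                        text[s_start:s_end])
        for m in doc_mentions:
            if s_start <= m.start and m.end <= s_end:
                sent.mentions.append((m, m.start - s_start, m.end - s_start))
        sentences.append(sent)
        prev = cut
    return sentences


def generate_candidates(sentence: Sentence,
                        gold: Sequence[GoldRelation] = (),
                        nonevaluated_as_false: bool = True,
                        ) -> List[CandidateInstance]:
    """One candidate per (chemical, gene) pair co-occurring in the sentence.

    The label comes from the gold relation linking the pair, else ``False``.
    Pairs linked by two or more distinct gold groups are flagged
    ``confusing``; pairs whose surface spans overlap are flagged ``overlap``
    (both are removed later by :func:`filter_instances`).  Gold relations
    whose mentions lie in different sentences never produce an instance.
    """
    chems = [(m, rs, re_) for m, rs, re_ in sentence.mentions if m.etype == "CHEMICAL"]
    genes = [(m, rs, re_) for m, rs, re_ in sentence.mentions if m.etype == "GENE"]
    by_pair: Dict[Tuple[str, str, str], Set[str]] = {}
    for r in gold:
        by_pair.setdefault((r.pmid, r.chem_id, r.gene_id), set()).add(r.group)

    out: List[CandidateInstance] = []
    for chem, c_rs, c_re in chems:
        for gene, g_rs, g_re in genes:
            groups = sorted(by_pair.get((sentence.pmid, chem.mention_id, gene.mention_id), ()))
            eval_groups = [g for g in groups if g in EVALUATED_GROUPS]
            label = eval_groups[0] if len(eval_groups) == 1 else "False"
            if groups and not eval_groups and not nonevaluated_as_false:
                continue
            out.append(CandidateInstance(
                pmid=sentence.pmid,
                sent_index=sentence.sent_index,
                chem_id=chem.mention_id,
                gene_id=gene.mention_id,
                label=label,
                overlap=c_rs < g_re and g_rs < c_re,
                confusing=len(eval_groups) >= 2,
                gold_groups=tuple(groups),
                sentence=sentence,
                chem=chem,
                gene=gene,
            ))
    return out


def _substitute(text: str, subs: List[Tuple[int, int, str]]) -> str:
    """Apply non-overlapping (start, end, replacement) edits to ``text``."""
    out, prev = [], 0
    for s, e, rep in sorted(subs):
        out.append(text[prev:s])
        out.append(rep)
        prev = e
    out.append(text[prev:])
    return "".join(out)


def _target_spans(inst: CandidateInstance) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    sent = inst.sentence
    spans = {m.mention_id: (rs, re_) for m, rs, re_ in sent.mentions}
    return spans[inst.chem_id], spans[inst.gene_id]


def _finalize(inst: CandidateInstance, text: str,
              first_ph: str, second_ph: str) -> CandidateInstance:
    tokens = tokenize(text)
    e1 = tokens.index(first_ph)
    e2 = tokens.index(second_ph)
    return replace(inst, tokens=tokens, e1_index=e1, e2_index=e2)


def anonymize_challenge(inst: CandidateInstance,
                        chem_lexicon: Optional[Set[str]] = None,
                        ) -> CandidateInstance:
    """Challenge-time scheme: targets become BC6ENT1/BC6ENT2 by order of
    appearance; non-target chemical surfaces from ``chem_lexicon`` (if given)
    become CHEM."""
    if inst.sentence is None:
        raise ValueError("instance lacks its source sentence")
    (c_rs, c_re), (g_rs, g_re) = _target_spans(inst)
    if c_rs < g_re and g_rs < c_re:
        return replace(inst, overlap=True)

    first, second = sorted([(c_rs, c_re), (g_rs, g_re)])
    subs = [(first[0], first[1], "BC6ENT1"), (second[0], second[1], "BC6ENT2")]
    if chem_lexicon:
        taken = [(s, e) for s, e, _ in subs]
        for surf in sorted(chem_lexicon, key=len, reverse=True):
            for m in re.finditer(re.escape(surf), inst.sentence.text):
                span = (m.start(), m.end())
                if all(span[1] <= s or span[0] >= e for s, e in taken):
                    subs.append((span[0], span[1], "CHEM"))
                    taken.append(span)
    return _finalize(inst, _substitute(inst.sentence.text, subs), "BC6ENT1", "BC6ENT2")


def anonymize_postchallenge(inst: CandidateInstance) -> CandidateInstance:
    """Post-challenge scheme: target chemical -> BC6ENTC, target gene ->
    BC6ENTG, every other annotated entity in the sentence -> BC6OTHER."""
    if inst.sentence is None:
        raise ValueError("instance lacks its source sentence")
    (c_rs, c_re), (g_rs, g_re) = _target_spans(inst)
    if c_rs < g_re and g_rs < c_re:
        return replace(inst, overlap=True)

    subs = [(c_rs, c_re, "BC6ENTC"), (g_rs, g_re, "BC6ENTG")]
    taken = [(c_rs, c_re), (g_rs, g_re)]
    for m, rs, re_ in inst.sentence.mentions:
        if m.mention_id in (inst.chem_id, inst.gene_id):
            continue
        if all(re_ <= s or rs >= e for s, e in taken):
            subs.append((rs, re_, "BC6OTHER"))
            taken.append((rs, re_))
    first_ph, second_ph = ("BC6ENTC", "BC6ENTG") if c_rs < g_rs else ("BC6ENTG", "BC6ENTC")
    return _finalize(inst, _substitute(inst.sentence.text, subs), first_ph, second_ph)


def filter_instances(instances: Sequence[CandidateInstance],
                     ) -> Tuple[List[CandidateInstance],
                                List[CandidateInstance],
                                List[CandidateInstance]]:
    """Remove overlapping-target and confusing (multi-group) instances.

    Returns ``(kept, removed_overlap, removed_confusing)`` with
    ``len(kept) + len(removed_overlap) + len(removed_confusing) ==
    len(instances)``.
    """
    kept, overlap, confusing = [], [], []
    for inst in instances:
        if inst.overlap:
            overlap.append(inst)
        elif inst.confusing:
            confusing.append(inst)
        else:
            kept.append(inst)
    return kept, overlap, confusing


@dataclass
class Vocabulary:
    """Token -> index map with a rare-word threshold.

    Tokens seen fewer than ``min_count`` times map to :data:`RARE_TOKEN`;
    placeholder tokens are always retained.  Index assignment is
    lexicographic, hence deterministic across runs.
    """

    index: Dict[str, int]
    min_count: int
    rare_token: str = RARE_TOKEN

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __len__(self) -> int:
        return len(self.index)

    def canonical(self, token: str) -> str:
        """The token itself if in-vocabulary, else the rare symbol."""
        return token if token in self.index else self.rare_token

    def __getitem__(self, token: str) -> int:
        return self.index.get(token, self.index[self.rare_token])

    @property
    def tokens(self) -> List[str]:
        return sorted(self.index, key=self.index.get)


def build_vocab(tokens: Iterable[str], min_count: int = 3) -> Vocabulary:
    """Build a vocabulary keeping tokens with frequency >= ``min_count``."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = Counter(tokens)
    kept = {t for t, c in counts.items() if c >= min_count}
    kept.update(p for p in PLACEHOLDERS if p in counts)
    kept.add(RARE_TOKEN)
    index = {t: i for i, t in enumerate(sorted(kept))}
    return Vocabulary(index=index, min_count=min_count)


def prepare_instances(abstracts: Sequence[AbstractRecord],
                      mentions: Sequence[EntityMention],
                      relations: Sequence[GoldRelation],
                      scheme: str = "postchallenge",
                      chem_lexicon: Optional[Set[str]] = None,
                      apply_filters: bool = True,
                      separator: str = DEFAULT_SEPARATOR,
                      ) -> Tuple[List[CandidateInstance], Dict[str, int]]:
    """Full preparation pipeline: split, pair up, anonymize, filter.

    Returns the kept instances in deterministic (pmid, sent_index, chem_id,
    gene_id) order plus a stats dict with the filter counts.
    """
    if scheme not in ("challenge", "postchallenge"):
        raise ValueError(f"unknown anonymization scheme {scheme!r}")
    all_instances: List[CandidateInstance] = []
    for abstract in abstracts:
        for sentence in split_sentences(abstract, mentions, separator):
            for inst in generate_candidates(sentence, relations):
                if inst.overlap:
                    all_instances.append(inst)
                    continue
                if scheme == "challenge":
                    all_instances.append(anonymize_challenge(inst, chem_lexicon))
                else:
                    all_instances.append(anonymize_postchallenge(inst))
    all_instances.sort(key=lambda i: (i.pmid, i.sent_index, i.chem_id, i.gene_id))
    if apply_filters:
        kept, overlap, confusing = filter_instances(all_instances)
    else:
        kept, overlap, confusing = list(all_instances), [], []
    stats = {
        "total": len(all_instances),
        "kept": len(kept),
        "removed_overlap": len(overlap),
        "removed_confusing": len(confusing),
    }
    return kept, stats


def write_instances(path, instances: Sequence[CandidateInstance]) -> None:
    """Instance file: pmid, sent_index, chem_id, gene_id, label, tokens."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for inst in instances:
            if inst.tokens is None:
                raise ValueError("cannot write un-anonymized instance")
            fh.write("\t".join([
                inst.pmid, str(inst.sent_index), inst.chem_id, inst.gene_id,
                inst.label, " ".join(inst.tokens),
            ]) + "\n")


def read_instances(path) -> List[CandidateInstance]:
    out: List[CandidateInstance] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise CorpusError(f"{path}:{lineno}: instance line needs 6 fields")
            pmid, sent_index, chem_id, gene_id, label, toks = fields
            tokens = toks.split(" ")
            targets = [i for i, t in enumerate(tokens)
                       if t in ("BC6ENT1", "BC6ENT2", "BC6ENTC", "BC6ENTG")]
            if len(targets) != 2:
                raise CorpusError(
                    f"{path}:{lineno}: expected exactly 2 target placeholders, "
                    f"found {len(targets)}")
            out.append(CandidateInstance(
                pmid=pmid, sent_index=int(sent_index), chem_id=chem_id,
                gene_id=gene_id, label=label, tokens=tokens,
                e1_index=targets[0], e2_index=targets[1]))
    return out
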