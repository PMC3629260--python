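"""BioNLP-ST standoff annotation I/O.

Documents come as a ``.txt`` file plus standoff files referencing it by
character offset (0-based, half-open): ``.a1`` holds the given entities
(``T`` lines, typically ``Protein``), ``.a2`` holds event triggers
(``T`` lines) and events (``E`` lines such as
``E3\tPositive_regulation:T7 Theme:E1 Cause:E2``).

Annotations are anchored onto dependency-graph tokens by offset overlap.
Only single-sentence events are kept: an event whose trigger or any
(recursive) participant falls in a different sentence is dropped with a
logged warning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .depgraph import COPY_OFFSET, DepGraph
from .errors import IntegrityError, ParseError

logger = logging.getLogger(__name__)

THEME_ROLE = re.compile(r"^Theme\d*$")


def is_theme_role(role: str) -> bool:
    return bool(THEME_ROLE.match(role))


@dataclass
class EntityAnn:
    id: str
    type: str
    start: int
    end: int
    text: str
    sentence_index: Optional[int] = None
    head_token: Optional[int] = None  # last covered token
    tokens: tuple[int, ...] = ()


@dataclass
class TriggerAnn:
    id: str
    event_type: str
    start: int
    end: int
    text: str
    sentence_index: Optional[int] = None
    tokens: tuple[int, ...] = ()

    @property
    def head_token(self) -> Optional[int]:
        return self.tokens[-1] if self.tokens else None


@dataclass
class EventAnn:
    id: str
    event_type: str
    trigger: TriggerAnn
    args: list[tuple[str, Union["EventAnn", EntityAnn]]] = field(default_factory=list)

    @property
    def sentence_index(self) -> Optional[int]:
        return self.trigger.sentence_index


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    sentences: list[DepGraph] = field(default_factory=list)
    entities: dict[str, EntityAnn] = field(default_factory=dict)
    triggers: dict[str, TriggerAnn] = field(default_factory=dict)
    events: dict[str, EventAnn] = field(default_factory=dict)

    def sentence_entities(self, sentence_index: int) -> list[tuple[str, int]]:
        """(entity id, head token) pairs anchored in one sentence."""
        return sorted(
            (e.id, e.head_token) for e in self.entities.values()
            if e.sentence_index == sentence_index and e.head_token is not None)

    def sentence_events(self, sentence_index: int) -> list[EventAnn]:
        return sorted(
            (e for e in self.events.values()
             if e.sentence_index == sentence_index),
            key=lambda e: e.id)


# -- token alignment --------------------------------------------------------

def align_sentences(text: str, sentences: Sequence[DepGraph]) -> None:
    """Assign character offsets to sentence tokens by scanning ``text``
    left to right.  Copy tokens inherit the offsets of their base token."""
    cursor = 0
    for g in sentences:
        for i in g.node_indices():
            t = g.token(i)
            if i >= COPY_OFFSET:
                base = g.tokens.get(i % COPY_OFFSET)
                if base is not None:
                    t.start, t.end = base.start, base.end
                continue
            pos = text.find(t.surface, cursor)
            if pos < 0:
                raise IntegrityError(
                    f"cannot align token {t.surface!r} of sentence "
                    f"{g.sentence_id!r} to the document text")
            t.start, t.end = pos, pos + len(t.surface)
            cursor = t.end


def sentence_span(g: DepGraph) -> tuple[int, int]:
    starts = [t.start for t in g.tokens.values() if t.start is not None]
    ends = [t.end for t in g.tokens.values() if t.end is not None]
    if not starts:
        raise IntegrityError(f"sentence {g.sentence_id!r} has no aligned tokens")
    return min(starts), max(ends)


def anchor_span(sentence: DepGraph, start: int, end: int) -> list[int]:
    """Minimal set of tokens whose offsets intersect ``[start, end)``.

    A span splitting a token expands to the covering token.  Raises when the
    span lies outside the sentence or covers no token.
    """
    s0, s1 = sentence_span(sentence)
    if end <= s0 or start >= s1:
        raise IntegrityError(
            f"span [{start},{end}) outside sentence [{s0},{s1})")
    covered = [i for i in sentence.node_indices()
               if i < COPY_OFFSET
               and sentence.token(i).start is not None
               and sentence.token(i).start < end
               and sentence.token(i).end > start]
    if not covered:
        raise IntegrityError(f"span [{start},{end}) covers no token")
    return covered


def _locate(sentences: Sequence[DepGraph], start: int, end: int
            ) -> tuple[Optional[int], tuple[int, ...]]:
    for si, g in enumerate(sentences):
        s0, s1 = sentence_span(g)
        if start >= s0 and end <= s1:
            try:
                return si, tuple(anchor_span(g, start, end))
            except IntegrityError:
                return si, ()
    return None, ()


# -- reading ----------------------------------------------------------------

def _parse_t_line(line: str, lineno: int, text: str
                  ) -> tuple[str, str, int, int, str]:
    cols = line.split("\t")
    if len(cols) != 3:
        raise ParseError(f"a-file line {lineno}: expected 3 tab-separated "
                         f"fields in {line!r}")
    tid, span, ann_text = cols
    parts = span.split()
    if len(parts) != 3:
        raise ParseError(f"a-file line {lineno}: bad span field {span!r}")
    ttype, start, end = parts[0], int(parts[1]), int(parts[2])
    if not (0 <= start < end <= len(text)):
        raise IntegrityError(f"a-file line {lineno}: offsets [{start},{end}) "
                             "outside document text")
    if text[start:end] != ann_text:
        raise IntegrityError(
            f"a-file line {lineno}: text {ann_text!r} does not match "
            f"document slice {text[start:end]!r}")
    return tid, ttype, start, end, ann_text


def read_standoff(doc_id: str, text: str, a1: str, a2: str = "",
                  sentences: Sequence[DepGraph] = (),
                  align: bool = False) -> AnnotatedDocument:
    """Assemble an annotated document from standoff files.

    ``sentences`` are the pre-parsed dependency graphs of the document, in
    order; with ``align=True`` their token offsets are computed here by
    scanning the text, otherwise they must already carry offsets.
    """
    sentences = list(sentences)
    if align:
        align_sentences(text, sentences)
    doc = AnnotatedDocument(doc_id=doc_id, text=text, sentences=sentences)

    for lineno, raw in enumerate(a1.splitlines(), start=1):
        if not raw.strip():
            continue
        tid, ttype, start, end, ann_text = _parse_t_line(raw, lineno, text)
        si, toks = _locate(sentences, start, end)
        if sentences and (si is None or not toks):
            logger.warning("%s: entity %s spans no single sentence; dropped",
                           doc_id, tid)
            continue
        doc.entities[tid] = EntityAnn(
            id=tid, type=ttype, start=start, end=end, text=ann_text,
            sentence_index=si, head_token=toks[-1] if toks else None,
            tokens=toks)

    event_lines: list[tuple[int, str, str]] = []
    for lineno, raw in enumerate(a2.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("T"):
            tid, ttype, start, end, ann_text = _parse_t_line(raw, lineno, text)
            si, toks = _locate(sentences, start, end)
            if sentences and (si is None or not toks):
                logger.warning("%s: trigger %s spans no single sentence; "
                               "dropped", doc_id, tid)
                continue
            doc.triggers[tid] = TriggerAnn(
                id=tid, event_type=ttype, start=start, end=end, text=ann_text,
                sentence_index=si, tokens=toks)
        elif line.startswith("E"):
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(f"a2 line {lineno}: expected 2 fields")
            event_lines.append((lineno, cols[0], cols[1]))
        elif line.startswith(("M", "*", "A")):
            logger.info("%s: skipping unsupported annotation line %r",
                        doc_id, line)
        else:
            raise ParseError(f"a2 line {lineno}: unrecognized line {line!r}")

    _resolve_events(doc, event_lines)
    return doc


def _resolve_events(doc: AnnotatedDocument,
                    event_lines: list[tuple[int, str, str]]) -> None:
    raw: dict[str, tuple[int, str]] = {}
    for lineno, eid, body in event_lines:
        raw[eid] = (lineno, body)
    resolved: dict[str, Optional[EventAnn]] = {}

    def resolve(eid: str, stack: tuple[str, ...] = ()) -> Optional[EventAnn]:
        if eid in resolved:
            return resolved[eid]
        if eid in stack:
            raise IntegrityError(f"event nesting cycle at {eid}")
        if eid not in raw:
            raise IntegrityError(f"dangling event reference {eid}")
        lineno, body = raw[eid]
        parts = body.split()
        etype, _, trig_id = parts[0].partition(":")
        if trig_id not in doc.triggers:
            logger.warning("%s: event %s references dropped/unknown trigger "
                           "%s; event dropped", doc.doc_id, eid, trig_id)
            resolved[eid] = None
            return None
        trigger = doc.triggers[trig_id]
        args: list[tuple[str, Union[EventAnn, EntityAnn]]] = []
        dropped = False
        for part in parts[1:]:
            role, _, ref = part.partition(":")
            filler: Union[EventAnn, EntityAnn, None]
            if ref.startswith("E"):
                filler = resolve(ref, stack + (eid,))
                if filler is None:
                    dropped = True
                    break
                f_si = filler.sentence_index
            elif ref in doc.entities:
                filler = doc.entities[ref]
                f_si = filler.sentence_index
            else:
                raise IntegrityError(
                    f"a2 line {lineno}: dangling reference {ref} in {eid}")
            if f_si != trigger.sentence_index:
                logger.warning(
                    "%s: event %s crosses sentence boundaries; dropped",
                    doc.doc_id, eid)
                dropped = True
                break
            args.append((role, filler))
        if dropped:
            resolved[eid] = None
            return None
        if not any(is_theme_role(r) for r, _ in args):
            raise IntegrityError(f"event {eid} has no Theme argument")
        ev = EventAnn(id=eid, event_type=etype, trigger=trigger, args=args)
        resolved[eid] = ev
        return ev

    for eid in sorted(raw, key=lambda e: int(e[1:])):
        ev = resolve(eid)
        if ev is not None:
            doc.events[eid] = ev


# -- writing ----------------------------------------------------------------

def _token_span(doc: AnnotatedDocument, sentence_index: int,
                tokens: Iterable[int]) -> tuple[int, int, str]:
    g = doc.sentences[sentence_index]
    toks = [g.token(i) for i in sorted(tokens)]
    if not toks or any(t.start is None for t in toks):
        raise IntegrityError("cannot serialize an unanchored trigger")
    start, end = toks[0].start, toks[-1].end
    return start, end, doc.text[start:end]


def write_a2(doc: AnnotatedDocument, events: Sequence) -> str:
    """Serialize predicted events to a2 text.

    ``events`` are extraction-level events: objects with ``event_type``,
    ``sentence_index``, ``trigger_tokens`` and ``args`` (role, filler) where
    a filler is either an entity id string or another event object.  Ids are
    deterministic: ``T`` then ``E`` lines numbered in emission order, with
    trigger numbering continuing after the ``.a1`` entity ids.
    """
    next_t = 1 + max((int(e.id[1:]) for e in doc.entities.values()
                      if e.id[1:].isdigit()), default=0)
    t_lines: list[str] = []
    e_lines: list[str] = []
    trig_ids: dict[tuple, str] = {}
    event_ids: dict[str, str] = {}  # canonical event key -> emitted id

    def trigger_id(ev) -> str:
        nonlocal next_t
        key = (ev.event_type, ev.sentence_index, tuple(sorted(ev.trigger_tokens)))
        if key not in trig_ids:
            start, end, text = _token_span(doc, ev.sentence_index,
                                           ev.trigger_tokens)
            tid = f"T{next_t}"
            next_t += 1
            trig_ids[key] = tid
            t_lines.append(f"{tid}\t{ev.event_type} {start} {end}\t{text}")
        return trig_ids[key]

    def emit(ev) -> str:
        key = ev.key()
        if key in event_ids:
            return event_ids[key]
        tid = trigger_id(ev)
        parts = [f"{ev.event_type}:{tid}"]
        for role, filler in ev.args:
            if isinstance(filler, str):
                if filler not in doc.entities:
                    raise IntegrityError(
                        f"unanchored entity argument {filler!r}")
                parts.append(f"{role}:{filler}")
            else:
                parts.append(f"{role}:{emit(filler)}")
        eid = f"E{len(e_lines) + 1}"
        event_ids[key] = eid
        e_lines.append(f"{eid}\t{' '.join(parts)}")
        return eid

    for ev in events:
        emit(ev)
    lines = t_lines + e_lines
    return "\n".join(lines) + ("\n" if lines else "")
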