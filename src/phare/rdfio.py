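"""Minimal RDF triple store with Turtle and N-Triples serialization.

Implements exactly the profile this package emits: named IRI nodes (no blank
nodes), plain string literals, ``@prefix`` declarations, predicate lists
(``;``), object lists (``,``) and the ``a`` keyword.  Insertion order of
triples is preserved, which the ontology layer relies on to keep the
"first label is the preferred label" convention stable across round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Tuple, Union

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
OWL_NS = "http://www.w3.org/2002/07/owl#"
PHARE_NS = "http://example.org/phare#"

DEFAULT_PREFIXES = {
    "rdf": RDF_NS,
    "rdfs": RDFS_NS,
    "owl": OWL_NS,
    "phare": PHARE_NS,
}


class RdfFormatError(ValueError):
    """Raised when a document cannot be parsed; carries the offending text."""


@dataclass(frozen=True)
class IRI:
    value: str

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{self.value}>"


@dataclass(frozen=True)
class Literal:
    value: str

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f'"{self.value}"'


Term = Union[IRI, Literal]
SPO = Tuple[IRI, IRI, Term]


def _escape(s: str) -> str:
    return (
        s.replace("\\", "\\\\")
        .replace('"', '\\"')
        .replace("\n", "\\n")
        .replace("\r", "\\r")
        .replace("\t", "\\t")
    )


def _unescape(s: str) -> str:
    out = []
    i = 0
    while i < len(s):
        c = s[i]
        if c == "\\" and i + 1 < len(s):
            n = s[i + 1]
            mapping = {"\\": "\\", '"': '"', "n": "\n", "r": "\r", "t": "\t"}
            if n in mapping:
                out.append(mapping[n])
                i += 2
                continue
            if n == "u" and i + 6 <= len(s):
                out.append(chr(int(s[i + 2 : i + 6], 16)))
                i += 6
                continue
        out.append(c)
        i += 1
    return "".join(out)


class Graph:
    """An ordered, duplicate-free collection of (subject, predicate, object)."""

    def __init__(self, triples: Optional[Iterable[SPO]] = None) -> None:
        self._triples: dict[SPO, None] = {}
        if triples:
            for t in triples:
                self.add(*t)

    def add(self, s: IRI, p: IRI, o: Term) -> None:
        self._triples.setdefault((s, p, o), None)

    def __iter__(self) -> Iterator[SPO]:
        return iter(self._triples)

    def __len__(self) -> int:
        return len(self._triples)

    def __contains__(self, t: SPO) -> bool:
        return t in self._triples

    def triples(
        self,
        s: Optional[IRI] = None,
        p: Optional[IRI] = None,
        o: Optional[Term] = None,
    ) -> Iterator[SPO]:
        for ts, tp, to in self._triples:
            if s is not None and ts != s:
                continue
            if p is not None and tp != p:
                continue
            if o is not None and to != o:
                continue
            yield ts, tp, to

    def objects(self, s: IRI, p: IRI) -> list[Term]:
        return [o for _, _, o in self.triples(s, p)]

    def as_set(self) -> frozenset[SPO]:
        return frozenset(self._triples)

    # -- serialization -----------------------------------------------------

    def _qname(self, iri: IRI, prefixes: dict[str, str]) -> str:
        for pfx, ns in prefixes.items():
            if iri.value.startswith(ns):
                local = iri.value[len(ns) :]
                if local and _is_local_name(local):
                    return f"{pfx}:{local}"
        return f"<{iri.value}>"

    def _term(self, t: Term, prefixes: dict[str, str]) -> str:
        if isinstance(t, Literal):
            return f'"{_escape(t.value)}"'
        return self._qname(t, prefixes)

    def serialize(self, fmt: str = "turtle", prefixes: Optional[dict[str, str]] = None) -> str:
        if fmt in ("nt", "ntriples", "n-triples"):
            lines = []
            for s, p, o in self:
                if isinstance(o, Literal):
                    ot = f'"{_escape(o.value)}"'
                else:
                    ot = f"<{o.value}>"
                lines.append(f"<{s.value}> <{p.value}> {ot} .")
            return "\n".join(lines) + ("\n" if lines else "")
        if fmt not in ("turtle", "ttl"):
            raise ValueError(f"unsupported RDF format: {fmt!r}")
        prefixes = dict(DEFAULT_PREFIXES if prefixes is None else prefixes)
        out = [f"@prefix {pfx}: <{ns}> ." for pfx, ns in prefixes.items()]
        out.append("")
        # group consecutive triples by subject, preserving insertion order
        by_subject: dict[IRI, list[tuple[IRI, Term]]] = {}
        for s, p, o in self:
            by_subject.setdefault(s, []).append((p, o))
        rdf_type = IRI(RDF_NS + "type")
        for s, pos in by_subject.items():
            lines = []
            for p, o in pos:
                pt = "a" if p == rdf_type else self._qname(p, prefixes)
                lines.append(f"    {pt} {self._term(o, prefixes)}")
            body = " ;\n".join(lines)
            out.append(f"{self._qname(s, prefixes)}\n{body} .")
        return "\n".join(out) + "\n"

    def save(self, path, fmt: str = "turtle") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.serialize(fmt))

    # -- parsing -----------------------------------------------------------

    @classmethod
    def parse(cls, text: str, fmt: str = "turtle") -> "Graph":
        if fmt in ("nt", "ntriples", "n-triples"):
            fmt = "turtle"  # N-Triples is a syntactic subset of our Turtle profile
        if fmt not in ("turtle", "ttl"):
            raise ValueError(f"unsupported RDF format: {fmt!r}")
        return _TurtleParser(text).run()

    @classmethod
    def load(cls, path, fmt: str = "turtle") -> "Graph":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.parse(fh.read(), fmt)


_LOCAL_CHARS = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_-=.")


def _is_local_name(s: str) -> bool:
    return bool(s) and all(c in _LOCAL_CHARS for c in s) and not s.endswith(".")


class _TurtleParser:
    def __init__(self, text: str) -> None:
        self.tokens = self._tokenize(text)
        self.pos = 0
        self.prefixes: dict[str, str] = {}
        self.graph = Graph()

    def _tokenize(self, text: str) -> list[str]:
        tokens = []
        i, n = 0, len(text)
        while i < n:
            c = text[i]
            if c in " \t\r\n":
                i += 1
            elif c == "#":
                while i < n and text[i] != "\n":
                    i += 1
            elif c == '"':
                j = i + 1
                buf = []
                while j < n:
                    if text[j] == "\\" and j + 1 < n:
                        buf.append(text[j : j + 2])
                        j += 2
                    elif text[j] == '"':
                        break
                    else:
                        buf.append(text[j])
                        j += 1
                else:
                    raise RdfFormatError(f"unterminated literal near: {text[i:i+40]!r}")
                tokens.append('"' + "".join(buf) + '"')
                i = j + 1
            elif c == "<":
                j = text.find(">", i)
                if j < 0:
                    raise RdfFormatError(f"unterminated IRI near: {text[i:i+40]!r}")
                tokens.append(text[i : j + 1])
                i = j + 1
            elif c in ";,":
                tokens.append(c)
                i += 1
            elif c == ".":
                # statement terminator (local names never end with '.')
                tokens.append(c)
                i += 1
            else:
                j = i
                while j < n and text[j] not in ' \t\r\n;,"<#':
                    j += 1
                word = text[i:j]
                # a trailing '.' terminates the statement
                while word.endswith("."):
                    word = word[:-1]
                    j -= 1
                if word:
                    tokens.append(word)
                i = j if j > i else i + 1
        return tokens

    def _peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            raise RdfFormatError("unexpected end of document")
        self.pos += 1
        return tok

    def _term(self, tok: str, position: str) -> Term:
        if tok.startswith('"'):
            if position != "object":
                raise RdfFormatError(f"literal not allowed as {position}: {tok}")
            return Literal(_unescape(tok[1:-1]))
        if tok.startswith("<"):
            return IRI(tok[1:-1])
        if tok == "a":
            return IRI(RDF_NS + "type")
        if ":" in tok:
            pfx, local = tok.split(":", 1)
            if pfx not in self.prefixes:
                raise RdfFormatError(f"undeclared prefix in statement: {tok!r}")
            return IRI(self.prefixes[pfx] + local)
        raise RdfFormatError(f"cannot interpret token as RDF term: {tok!r}")

    def run(self) -> Graph:
        while self._peek() is not None:
            tok = self._next()
            if tok in ("@prefix", "PREFIX"):
                pfx = self._next()
                if not pfx.endswith(":"):
                    raise RdfFormatError(f"malformed prefix declaration: {pfx!r}")
                iri = self._next()
                if not iri.startswith("<"):
                    raise RdfFormatError(f"malformed prefix IRI: {iri!r}")
                self.prefixes[pfx[:-1]] = iri[1:-1]
                if self._peek() == ".":
                    self._next()
                continue
            subject = self._term(tok, "subject")
            if not isinstance(subject, IRI):
                raise RdfFormatError(f"subject must be an IRI: {tok!r}")
            self._predicate_object_list(subject)
        return self.graph

    def _predicate_object_list(self, subject: IRI) -> None:
        while True:
            predicate = self._term(self._next(), "predicate")
            if not isinstance(predicate, IRI):
                raise RdfFormatError("predicate must be an IRI")
            while True:
                obj = self._term(self._next(), "object")
                self.graph.add(subject, predicate, obj)
                if self._peek() == ",":
                    self._next()
                    continue
                break
            tok = self._next()
            if tok == ";":
                if self._peek() == ".":  # tolerate dangling semicolon
                    self._next()
                    return
                continue
            if tok == ".":
                return
            raise RdfFormatError(f"expected ';' or '.' but found {tok!r}")
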