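"""Readers and writers for every external file the pipeline touches.

All tables are plain TSV.  Gene and drug identifiers are opaque,
case-sensitive strings: no symbol-alias resolution is attempted, because
the source databases disagree on namespaces and any mapping would be a
silent data change.  Output tables begin with ``#``-commented header lines
naming the columns and the tool version.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import obonet

from . import __version__
from .catalogue_builder import ProteinComplex
from .cocomplex_ppi import Pair, canonical_pair
from .go_semantics import AnnotationMap, GoDag

__all__ = [
    "read_complexes",
    "write_complexes",
    "read_obo_subset",
    "read_annotations",
    "read_pairs",
    "write_pairs",
    "read_drug_targets",
    "write_drug_targets",
    "read_disease_evidence",
    "write_disease_evidence",
]

log = logging.getLogger(__name__)

_RELATIONS = ("is_a", "part_of")


def _open(path: str | Path) -> TextIO:
    return open(path, "r", encoding="utf-8")


def _data_lines(fh: TextIO):
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def _header(columns: Iterable[str]) -> str:
    cols = "\t".join(columns)
    return f"# complexcat v{__version__}\n# columns: {cols}\n"


# -- complexes ------------------------------------------------------------


def read_complexes(path: str | Path, member_delim: str = ";") -> list[ProteinComplex]:
    """One complex per line: ``complex_id<TAB>source_db<TAB>m1;m2;...``.

    Duplicate member symbols within one row collapse to a set; a duplicate
    complex id or an empty member list is a hard error.
    """
    out: list[ProteinComplex] = []
    seen: set[str] = set()
    with _open(path) as fh:
        for lineno, line in _data_lines(fh):
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            cid, source, raw_members = parts
            if cid in seen:
                raise ValueError(f"{path}: duplicate complex id {cid!r}")
            seen.add(cid)
            members = frozenset(m for m in raw_members.split(member_delim) if m)
            if not members:
                raise ValueError(f"{path}:{lineno}: complex {cid!r} has no members")
            out.append(ProteinComplex(cid, source, members))
    return out


def write_complexes(
    path: str | Path, complexes: Iterable[ProteinComplex], member_delim: str = ";"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(["complex_id", "source_db", "members"]))
        for c in complexes:
            fh.write(f"{c.id}\t{c.source}\t{member_delim.join(sorted(c.members))}\n")


# -- ontology -------------------------------------------------------------


def read_obo_subset(path: str | Path) -> GoDag:
    """Load an OBO term file into a typed DAG.

    Only ``[Term]`` stanzas are consumed, keeping ``is_a`` and
    ``relationship: part_of`` edges; obsolete terms are skipped.  An edge
    to an undeclared term or a cycle is a hard error.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    declared = _declared_term_ids(path)
    edges: list[tuple[str, str, str]] = []
    for child, parent, rel in graph.edges(keys=True):
        if rel not in _RELATIONS:
            continue
        for t in (child, parent):
            if t not in declared:
                raise ValueError(f"{path}: edge references unknown term {t!r}")
        edges.append((child, parent, rel))
    terms = [t for t in graph.nodes if t in declared]
    return GoDag(edges, terms=terms)


def _declared_term_ids(path: str | Path) -> set[str]:
    """Ids of non-obsolete [Term] stanzas, by a light textual scan."""
    ids: set[str] = set()
    current: str | None = None
    in_term = False
    with _open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("["):
                if in_term and current:
                    ids.add(current)
                in_term = line == "[Term]"
                current = None
            elif in_term:
                m = re.match(r"^id:\s*(\S+)", line)
                if m and current is None:
                    current = m.group(1)
                elif re.match(r"^is_obsolete:\s*true", line):
                    current = None
                    in_term = False
    if in_term and current:
        ids.add(current)
    return ids


def read_annotations(path: str | Path, dag: GoDag) -> AnnotationMap:
    """Two-column TSV ``gene<TAB>term_id``; terms validated against the DAG."""
    mapping: dict[str, set[str]] = {}
    with _open(path) as fh:
        for lineno, line in _data_lines(fh):
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            gene, term = parts
            mapping.setdefault(gene, set()).add(term)
    return AnnotationMap(mapping, dag)


def write_annotations(path: str | Path, annot: AnnotationMap) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(["gene", "term_id"]))
        for gene, terms in sorted(annot.items()):
            for t in sorted(terms):
                fh.write(f"{gene}\t{t}\n")


# -- pair sets ------------------------------------------------------------


def read_pairs(path: str | Path) -> set[Pair]:
    """Two-column TSV of unordered pairs; self-pairs skipped with a warning."""
    pairs: set[Pair] = set()
    with _open(path) as fh:
        for lineno, line in _data_lines(fh):
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            a, b = parts
            if a == b:
                log.warning("%s:%d: self-pair (%s,%s) skipped", path, lineno, a, b)
                continue
            pairs.add(canonical_pair(a, b))
    return pairs


def write_pairs(path: str | Path, pairs: Iterable[Pair],
                columns: tuple[str, str] = ("a", "b")) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(columns))
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


# -- drug targets ---------------------------------------------------------


def read_drug_targets(path: str | Path) -> dict[str, frozenset[str]]:
    """Long-format TSV ``drug<TAB>target``, aggregated per drug."""
    table: dict[str, set[str]] = {}
    with _open(path) as fh:
        for lineno, line in _data_lines(fh):
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            drug, target = parts
            if not target:
                raise ValueError(f"{path}:{lineno}: empty target for {drug!r}")
            table.setdefault(drug, set()).add(target)
    return {d: frozenset(t) for d, t in table.items()}


def write_drug_targets(path: str | Path, table: Mapping[str, Iterable[str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(["drug", "target"]))
        for drug, targets in sorted(table.items()):
            for t in sorted(targets):
                fh.write(f"{drug}\t{t}\n")


# -- disease evidence -----------------------------------------------------


def read_disease_evidence(path: str | Path) -> list[tuple[str, str, float]]:
    """Three-column TSV ``disease<TAB>gene<TAB>p_value`` (one row per study)."""
    out: list[tuple[str, str, float]] = []
    with _open(path) as fh:
        for lineno, line in _data_lines(fh):
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            disease, gene, p = parts
            out.append((disease, gene, float(p)))
    return out


def write_disease_evidence(
    path: str | Path, evidence: Iterable[tuple[str, str, float]]
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(["disease", "gene", "p_value"]))
        for disease, gene, p in evidence:
            fh.write(f"{disease}\t{gene}\t{p:.6g}\n")
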