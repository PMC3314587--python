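"""Readers and writers for the plain-text interchange formats.

Two evidence dialects are supported:

* the package's own 5-column TSV
  ``protein_a  protein_b  system  throughput  publication`` with ``#``
  header lines and ``throughput`` in ``{high, low, -}``;
* BioGRID TAB 2.0, read by column position (official identifiers in
  columns 6-7, experiment system in column 12, throughput in column 13,
  publication in column 14; 1-based).

Annotations are a 2-column TSV ``protein_id  labels`` where ``labels`` is a
comma-separated list; the reserved token ``ambiguous`` is accepted and makes
the protein uncharacterized even when other labels accompany it (the
accompanying labels are returned separately for audit use).
"""

from __future__ import annotations

import logging
import os
import tempfile
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .core import (
    AnnotationSet,
    EvidenceRecord,
    LocalizationVocabulary,
    Throughput,
)

__all__ = [
    "ParseError",
    "read_evidence_tsv",
    "read_biogrid_tab2",
    "read_annotations_tsv",
    "write_evidence_tsv",
    "write_annotations_tsv",
    "atomic_write_text",
]

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; carries file path and 1-based line number."""

    def __init__(self, path: str, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _throughput_token(tok: str) -> Throughput:
    if tok.strip() in ("-", ""):
        return Throughput.UNSPLIT
    return Throughput.parse(tok)


def read_evidence_tsv(path: str) -> List[EvidenceRecord]:
    """Read the 5-column evidence dialect; self-interactions are dropped."""
    records: List[EvidenceRecord] = []
    n_self = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise ParseError(
                    path, lineno, f"expected 5 tab-separated columns, got {len(cols)}"
                )
            a, b, system, thr, pub = (c.strip() for c in cols)
            if not a or not b or not system or not pub:
                raise ParseError(path, lineno, "empty field")
            if a == b:
                n_self += 1
                continue
            records.append(
                EvidenceRecord(a, b, system, _throughput_token(thr), pub)
            )
    if n_self:
        log.info("dropped %d self-interaction record(s) from %s", n_self, path)
    return records


def read_biogrid_tab2(path: str) -> List[EvidenceRecord]:
    """Read BioGRID TAB 2.0 by column position into evidence records."""
    records: List[EvidenceRecord] = []
    n_self = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 14:
                raise ParseError(
                    path, lineno, f"expected >= 14 columns, got {len(cols)}"
                )
            a, b = cols[5].strip(), cols[6].strip()
            system = cols[11].strip()
            thr = Throughput.parse(cols[12])
            pub = cols[13].strip()
            if not a or not b or a == "-" or b == "-":
                raise ParseError(path, lineno, "missing protein identifier")
            if a == b:
                n_self += 1
                continue
            records.append(EvidenceRecord(a, b, system, thr, pub))
    if n_self:
        log.info("dropped %d self-interaction record(s) from %s", n_self, path)
    return records


def read_annotations_tsv(
    path: str,
    vocabulary: Optional[LocalizationVocabulary] = None,
) -> Tuple[AnnotationSet, Dict[str, FrozenSet[int]]]:
    """Read the 2-column annotation TSV.

    Returns ``(annotations, ambiguous_residual)``.  Proteins whose label list
    contains the reserved token are uncharacterized in the returned
    :class:`AnnotationSet`; any labels listed alongside the token are
    collected in ``ambiguous_residual`` (protein -> label-index set) so
    downstream audits can still compare predictions against them.

    With ``vocabulary=None`` the vocabulary is built from the file in first
    appearance order (reserved token excluded).
    """
    rows: List[Tuple[str, List[str]]] = []
    reserved = (vocabulary.reserved_token if vocabulary else "ambiguous")
    seen_labels: List[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(
                    path, lineno, f"expected 2 tab-separated columns, got {len(cols)}"
                )
            pid, labels_field = cols[0].strip(), cols[1].strip()
            if not pid:
                raise ParseError(path, lineno, "empty protein identifier")
            names = [t.strip() for t in labels_field.split(",") if t.strip()]
            for n in names:
                if n != reserved and n not in seen_labels:
                    seen_labels.append(n)
            rows.append((pid, names))

    if vocabulary is None:
        vocabulary = LocalizationVocabulary(tuple(seen_labels), reserved)

    assignments: Dict[str, FrozenSet[int]] = {}
    ambiguous_residual: Dict[str, FrozenSet[int]] = {}
    for pid, names in rows:
        idxs = frozenset(
            vocabulary.index(n) for n in names if n != vocabulary.reserved_token
        )
        if vocabulary.reserved_token in names:
            assignments[pid] = frozenset()
            ambiguous_residual[pid] = idxs
        else:
            assignments[pid] = idxs
    return AnnotationSet(vocabulary, assignments), ambiguous_residual


# -- writers ----------------------------------------------------------------

def atomic_write_text(path: str, text: str) -> None:
    """Write via a temp file in the destination directory, then rename."""
    d = os.path.dirname(os.path.abspath(path)) or "."
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "wt", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_evidence_tsv(path: str, records: Sequence[EvidenceRecord]) -> None:
    lines = ["#protein_a\tprotein_b\tsystem\tthroughput\tpublication"]
    for r in records:
        thr = "-" if r.throughput is Throughput.UNSPLIT else r.throughput.value
        lines.append(
            f"{r.protein_a}\t{r.protein_b}\t{r.system}\t{thr}\t{r.publication}"
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_annotations_tsv(path: str, ann: AnnotationSet) -> None:
    lines = ["#protein_id\tlabels"]
    for pid in sorted(ann.assignments):
        names = ",".join(ann.label_names_of(pid))
        lines.append(f"{pid}\t{names}")
    atomic_write_text(path, "\n".join(lines) + "\n")
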