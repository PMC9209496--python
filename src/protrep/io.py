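"""Core data containers and file formats.

Three containers travel through every stage of the toolkit:

``ProteinRecord``
    an identifier plus an amino-acid sequence — the atomic input unit;
``AnnotationTable``
    the multi-label ground truth, mapping protein id -> ontology -> label set;
``RepresentationMatrix``
    protein-aligned feature vectors with a provenance tag, the common
    currency of all downstream stages (baselines, language-model
    embeddings, PCA reductions).

File formats are deliberately plain: standard FASTA for sequences, a
three-column TSV (``protein_id<TAB>ontology<TAB>label``) for annotations,
and a ``.npz`` container with a JSON sidecar for matrices.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AnnotationParseError, FastaParseError, MatrixIntegrityError

#: the 20 canonical amino-acid letters, alphabetical
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: ambiguity / non-standard letters accepted at I/O
AMBIGUOUS_AA = "BZXUOJ"
VALID_AA = set(CANONICAL_AA) | set(AMBIGUOUS_AA)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: a whitespace-free id and an upper-case sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"protein id must be non-empty and whitespace-free, got {self.id!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


class AnnotationTable:
    """Multi-label annotations: protein id -> ontology name -> set of labels.

    A protein may be absent from an ontology (unlabeled there); label sets
    are true sets, so duplicate rows collapse on ingest.
    """

    def __init__(self, entries: Mapping[str, Mapping[str, Iterable[str]]] | None = None):
        self._entries: dict[str, dict[str, set[str]]] = {}
        if entries:
            for pid, onts in entries.items():
                for ont, labels in onts.items():
                    for lab in labels:
                        self.add(pid, ont, lab)

    def add(self, protein_id: str, ontology: str, label: str) -> None:
        self._entries.setdefault(protein_id, {}).setdefault(ontology, set()).add(label)

    def labels(self, protein_id: str, ontology: str) -> frozenset[str]:
        """Labels of one protein in one ontology; empty frozenset if unlabeled."""
        return frozenset(self._entries.get(protein_id, {}).get(ontology, ()))

    def ontologies(self) -> list[str]:
        return sorted({ont for onts in self._entries.values() for ont in onts})

    def proteins(self, ontology: str | None = None) -> list[str]:
        """Ids annotated anywhere, or (if ``ontology`` given) in that ontology."""
        if ontology is None:
            return sorted(self._entries)
        return sorted(pid for pid, onts in self._entries.items() if ontology in onts)

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self._entries == other._entries

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._entries

    def merged(self, other: "AnnotationTable") -> "AnnotationTable":
        out = AnnotationTable(self._entries)
        for pid, onts in other._entries.items():
            for ont, labels in onts.items():
                for lab in labels:
                    out.add(pid, ont, lab)
        return out

    def iter_rows(self) -> Iterator[tuple[str, str, str]]:
        for pid in sorted(self._entries):
            for ont in sorted(self._entries[pid]):
                for lab in sorted(self._entries[pid][ont]):
                    yield pid, ont, lab


@dataclass
class RepresentationMatrix:
    """Dense per-protein feature vectors with method provenance.

    ``vectors[i]`` is the representation of ``ids[i]``; ``method`` records
    how the vectors were produced (``lm-mean``, ``kmer-tfidf``, ``aa-freq``,
    ``pca-reduced``).
    """

    ids: list[str]
    vectors: np.ndarray
    method: str
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")
        if len(self.ids) != self.vectors.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids but {self.vectors.shape[0]} rows of vectors"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in representation matrix")
        if not self.method:
            raise ValueError("method provenance tag must be set")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("representation matrix contains non-finite values")
        self._index = {pid: i for i, pid in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def row(self, protein_id: str) -> np.ndarray:
        try:
            return self.vectors[self._index[protein_id]]
        except KeyError:
            raise KeyError(f"unknown protein id {protein_id!r}") from None

    def subset(self, ids: Iterable[str]) -> "RepresentationMatrix":
        ids = list(ids)
        rows = [self._index[pid] for pid in ids]
        return RepresentationMatrix(ids, self.vectors[rows], self.method)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RepresentationMatrix):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.method == other.method
            and self.vectors.shape == other.vectors.shape
            and np.array_equal(self.vectors, other.vectors)
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords (order preserved).

    The id is the header token before the first whitespace; sequences are
    upper-cased. Raises :class:`FastaParseError` on a sequence line before
    any header (with the line number) or on duplicate ids.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(";"):
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before any '>' header"
                )
            break
    records = [
        ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    seen: set[str] = set()
    dups = sorted({r.id for r in records if r.id in seen or seen.add(r.id)})
    if dups:
        raise FastaParseError(f"{path}: duplicate ids: {', '.join(dups)}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Annotation TSV

_ANNOT_HEADER = ("protein_id", "ontology", "label")


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a ``protein_id<TAB>ontology<TAB>label`` TSV (optional header)."""
    path = Path(path)
    table = AnnotationTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and tuple(f.strip() for f in fields[:3]) == _ANNOT_HEADER:
                continue
            if len(fields) < 3:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns, got {len(fields)}"
                )
            pid, ont, lab = (f.strip() for f in fields[:3])
            table.add(pid, ont, lab)
    return table


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOT_HEADER) + "\n")
        for pid, ont, lab in table.iter_rows():
            fh.write(f"{pid}\t{ont}\t{lab}\n")


# ---------------------------------------------------------------------------
# Matrix container: <path>.npz holding vectors + <path>.json sidecar


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_matrix(m: RepresentationMatrix, path: str | Path) -> None:
    """Persist a matrix as ``.npz`` plus a JSON sidecar (ids, method, dim)."""
    path = Path(path)
    if not np.all(np.isfinite(m.vectors)):  # defensive; the type enforces it too
        raise MatrixIntegrityError("refusing to save matrix with non-finite values")
    np.savez(path, vectors=m.vectors)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    meta = {"ids": m.ids, "method": m.method, "dim": m.dim}
    _sidecar(path).write_text(json.dumps(meta))


def load_matrix(path: str | Path) -> RepresentationMatrix:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    side = _sidecar(path)
    if not side.exists():
        raise MatrixIntegrityError(f"missing sidecar {side}")
    try:
        meta = json.loads(side.read_text())
        with np.load(path) as npz:
            vectors = npz["vectors"]
    except (json.JSONDecodeError, OSError, ValueError, KeyError,
            zipfile.BadZipFile) as exc:
        raise MatrixIntegrityError(f"cannot load matrix at {path}: {exc}") from exc
    ids = meta.get("ids")
    if ids is None or len(ids) != vectors.shape[0] or meta.get("dim") != vectors.shape[1]:
        raise MatrixIntegrityError(f"{path}: sidecar metadata does not match stored array")
    return RepresentationMatrix(ids, vectors, meta["method"])
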