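"""OTU count tables and their tokenised corpus view.

A sample-by-taxon count table plays the role a document-term matrix plays in
text mining: samples are documents, genus-level taxa are the vocabulary, and
each sequenced count unit is one word occurrence.  The collapsed Gibbs sampler
consumes the table as a :class:`Corpus` — one flat list of taxon-index tokens
per sample, with ``counts[d][w]`` copies of token ``w`` in document ``d``.

Tables are read from and written to delimited text (TSV by default, CSV by
extension or explicit delimiter).  Sample status labels travel in a sidecar
``<name>.labels.tsv`` file with columns ``sample_id`` and ``status``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

SAMPLES_AS_ROWS = "samples_as_rows"
TAXA_AS_ROWS = "taxa_as_rows"


def _check_unique(names: Sequence[str], what: str) -> None:
    seen = set()
    dups = [n for n in names if n in seen or seen.add(n)]
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class OtuTable:
    """Sample × taxon integer count matrix with optional status labels.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``counts``.
    taxon_names : list of str
        Unique taxon (typically genus) names, one per column of ``counts``.
    counts : ndarray of shape (n_samples, n_taxa)
        Non-negative integer abundances.
    labels : dict, optional
        Map from sample id to a categorical disease-status string.  Every key
        must be a member of ``sample_ids``; unlabeled samples are allowed.
    """

    sample_ids: list[str]
    taxon_names: list[str]
    counts: np.ndarray
    labels: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_names = [str(t) for t in self.taxon_names]
        counts = np.asarray(self.counts)
        if counts.size == 0:
            counts = counts.reshape(len(self.sample_ids), len(self.taxon_names))
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.taxon_names)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.taxon_names)} taxa"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, atol=1e-9):
                raise ValidationError("counts must be integers")
            counts = rounded
        self.counts = counts.astype(np.int64)
        if self.counts.size and (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.taxon_names, "taxon names")
        if self.labels is not None:
            unknown = sorted(set(self.labels) - set(self.sample_ids))
            if unknown:
                raise ValidationError(f"labels reference unknown samples: {unknown}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.sample_ids, name="id"),
                            columns=self.taxon_names)

    def select_samples(self, keep: Sequence[int]) -> "OtuTable":
        """New table restricted to the sample rows in ``keep`` (order kept)."""
        keep = list(keep)
        ids = [self.sample_ids[i] for i in keep]
        labels = None
        if self.labels is not None:
            labels = {s: self.labels[s] for s in ids if s in self.labels}
        return OtuTable(ids, list(self.taxon_names), self.counts[keep, :], labels)

    def select_taxa(self, keep: Sequence[int]) -> "OtuTable":
        """New table restricted to the taxon columns in ``keep`` (order kept)."""
        keep = list(keep)
        names = [self.taxon_names[i] for i in keep]
        return OtuTable(list(self.sample_ids), names, self.counts[:, keep],
                        dict(self.labels) if self.labels is not None else None)

    def label_array(self) -> np.ndarray:
        """Per-sample status strings, in sample order; all samples must be labeled."""
        if self.labels is None:
            raise ValidationError("table has no labels")
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise ValidationError(f"unlabeled samples: {missing}")
        return np.array([self.labels[s] for s in self.sample_ids])


@dataclass
class Corpus:
    """Tokenised view of an :class:`OtuTable`.

    ``docs[d]`` holds one integer token per count unit of sample ``d``; token
    values index ``vocab``.  Tokens within a document are stored in ascending
    taxon index — the collapsed sampler is exchangeable over token order, so a
    fixed order only serves reproducibility.
    """

    docs: list[np.ndarray]
    vocab: list[str]
    doc_ids: list[str]

    def __post_init__(self) -> None:
        V = len(self.vocab)
        self.docs = [np.asarray(d, dtype=np.int64) for d in self.docs]
        for d, doc in enumerate(self.docs):
            if doc.size and (doc.min() < 0 or doc.max() >= V):
                raise ValidationError(f"document {d} has token outside [0, {V})")
        if len(self.docs) != len(self.doc_ids):
            raise ValidationError("docs and doc_ids length mismatch")

    @property
    def n_docs(self) -> int:
        return len(self.docs)

    @property
    def n_vocab(self) -> int:
        return len(self.vocab)

    @property
    def n_tokens(self) -> int:
        return int(sum(len(d) for d in self.docs))

    def doc_lengths(self) -> np.ndarray:
        return np.array([len(d) for d in self.docs], dtype=np.int64)

    def subset(self, indices: Sequence[int]) -> "Corpus":
        """Sub-corpus over the given document indices, vocabulary unchanged."""
        idx = list(indices)
        return Corpus([self.docs[i] for i in idx], list(self.vocab),
                      [self.doc_ids[i] for i in idx])

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated token array and parallel document-index array."""
        if self.n_tokens == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        tokens = np.concatenate([d for d in self.docs if len(d)]).astype(np.int64)
        doc_of = np.repeat(np.arange(self.n_docs, dtype=np.int64), self.doc_lengths())
        return tokens, doc_of


def _delimiter_for(path: Path, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".labels.tsv")


def read_labels(label_path: Path | str) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>status`` metadata table."""
    df = pd.read_csv(label_path, sep="\t", dtype=str)
    required = {"sample_id", "status"}
    if not required.issubset(df.columns):
        raise ParseError(f"label file {label_path} must have columns sample_id,status")
    _check_unique(list(df["sample_id"]), "label sample ids")
    return dict(zip(df["sample_id"], df["status"]))


def read_otu_table(path: Path | str, orientation: str = SAMPLES_AS_ROWS,
                   label_path: Optional[Path | str] = None,
                   delimiter: Optional[str] = None) -> OtuTable:
    """Read a delimited OTU count table.

    The file must have one header row and one leading ID column.  With
    ``orientation="taxa_as_rows"`` the matrix is transposed on read so the
    returned table is always samples × taxa.  If ``label_path`` is omitted but
    a ``<name>.labels.tsv`` sidecar exists next to the table, it is loaded.
    """
    path = Path(path)
    if orientation not in (SAMPLES_AS_ROWS, TAXA_AS_ROWS):
        raise ValidationError(f"unknown orientation {orientation!r}")
    sep = _delimiter_for(path, delimiter)
    header = pd.read_csv(path, sep=sep, header=None, nrows=1, dtype=str)
    _check_unique([str(c) for c in header.iloc[0, 1:]], "header columns")
    df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    df.index = df.index.astype(str)

    values = np.zeros(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = df.index[np.argmax(bad.values)]
            raise ParseError(f"non-numeric cell at row {row!r}, column {col!r} in {path}")
        if numeric.isna().any():
            row = df.index[np.argmax(numeric.isna().values)]
            raise ParseError(f"empty cell at row {row!r}, column {col!r} in {path}")
        frac = numeric - np.rint(numeric)
        if (np.abs(frac) > 1e-9).any():
            row = df.index[int(np.argmax((np.abs(frac) > 1e-9).values))]
            raise ParseError(f"non-integer cell at row {row!r}, column {col!r} in {path}")
        values[:, j] = np.rint(numeric.values).astype(np.int64)

    if orientation == TAXA_AS_ROWS:
        sample_ids = [str(c) for c in df.columns]
        taxon_names = [str(i) for i in df.index]
        counts = values.T
    else:
        sample_ids = [str(i) for i in df.index]
        taxon_names = [str(c) for c in df.columns]
        counts = values

    labels = None
    if label_path is None and _sidecar_path(path).exists():
        label_path = _sidecar_path(path)
    if label_path is not None:
        labels = read_labels(label_path)
    return OtuTable(sample_ids, taxon_names, counts, labels)


def write_otu_table(table: OtuTable, path: Path | str,
                    delimiter: Optional[str] = None) -> None:
    """Write a table (samples as rows) plus a label sidecar when labels exist.

    ``write_otu_table`` then :func:`read_otu_table` is the identity on the
    table, including label attachment via the sidecar.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    table.to_frame().to_csv(path, sep=sep)
    if table.labels is not None:
        rows = [(s, table.labels[s]) for s in table.sample_ids if s in table.labels]
        pd.DataFrame(rows, columns=["sample_id", "status"]).to_csv(
            _sidecar_path(path), sep="\t", index=False)


def to_corpus(table: OtuTable) -> Corpus:
    """Expand counts into per-sample token lists (ascending taxon index)."""
    if table.counts.sum() == 0:
        raise ValidationError("table contains no counts; nothing to model")
    idx = np.arange(table.n_taxa, dtype=np.int64)
    docs = [np.repeat(idx, table.counts[d]) for d in range(table.n_samples)]
    return Corpus(docs, list(table.taxon_names), list(table.sample_ids))
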