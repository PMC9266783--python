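"""Multiple-sequence-alignment loading, filtering and redundancy weighting.

Alignments are query-anchored: row 0 is the (gap-free) query, all rows are
projected onto the query's columns, and everything downstream indexes
columns by 1-based query position.  Row filtering uses a 70% minimum
coverage and a 75% maximum gap fraction by default — the thresholds applied
to the HHblits alignments that feed covariation scoring.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import STANDARD_AA1
from .errors import MsaFormatError
from .structio import SequenceRecord

log = logging.getLogger(__name__)

GAP = "-"


@dataclass
class MsaAlignment:
    """Query-anchored alignment over the 20-AA + gap alphabet."""

    query: SequenceRecord
    ids: list[str]
    rows: np.ndarray  # (n_rows, L) of single characters
    weights: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype="<U1")
        if self.rows.ndim != 2:
            raise MsaFormatError("alignment matrix must be 2-D")
        n, L = self.rows.shape
        if L != len(self.query):
            raise MsaFormatError(
                f"matrix width {L} != query length {len(self.query)}"
            )
        if "".join(self.rows[0]) != self.query.seq:
            raise MsaFormatError("row 0 must equal the ungapped query")
        if len(self.ids) != n:
            raise MsaFormatError("one id per row required")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (n,):
                raise MsaFormatError("one weight per row required")

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def length(self) -> int:
        return self.rows.shape[1]

    def gap_fraction(self) -> np.ndarray:
        return (self.rows == GAP).mean(axis=1)

    def column_gap_fraction(self) -> np.ndarray:
        return (self.rows == GAP).mean(axis=0)

    def effective_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.ones(self.n_rows)
        return self.weights


def _clean_row(seq: str) -> str:
    """Uppercase, map '.'→'-' and non-standard letters to gap."""
    out = []
    for c in seq.upper().replace(".", GAP):
        out.append(c if c in STANDARD_AA1 or c == GAP else GAP)
    return "".join(out)


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"a3m"}:
        return "a3m"
    if suffix in {"sto", "stk", "stockholm"}:
        return "stockholm"
    if suffix in {"fa", "fasta", "afa", "aln", "mfa"}:
        return "fasta"
    head = path.read_text().lstrip()[:11]
    return "stockholm" if head.startswith("# STOCKHOLM") else "fasta"


def read_msa(path: str | Path, format: str = "auto") -> MsaAlignment:
    """Read an A3M / aligned-FASTA / Stockholm alignment, query first.

    A3M lowercase insertion columns are removed; FASTA/Stockholm alignments
    are projected onto the columns where the query (row 0) is not gapped.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"cannot read alignment file: {path}")
    fmt = _detect_format(path) if format == "auto" else format

    ids: list[str] = []
    raw: list[str] = []
    if fmt == "a3m":
        header, chunks = None, []
        for line in path.read_text().splitlines():
            if line.startswith("#") and header is None:
                continue
            if line.startswith(">"):
                if header is not None:
                    ids.append(header)
                    raw.append("".join(chunks))
                header, chunks = line[1:].split()[0] if line[1:].split() else "", []
            elif header is not None:
                chunks.append(line.strip())
        if header is not None:
            ids.append(header)
            raw.append("".join(chunks))
        # drop lowercase insertion states relative to the query
        raw = ["".join(c for c in seq if not c.islower()) for seq in raw]
    elif fmt in {"fasta", "stockholm"}:
        from Bio import AlignIO

        try:
            aln = AlignIO.read(str(path), fmt)
        except ValueError as exc:
            raise MsaFormatError(f"{path}: {exc}") from exc
        ids = [rec.id for rec in aln]
        raw = [str(rec.seq) for rec in aln]
    else:
        raise MsaFormatError(f"unknown MSA format: {fmt}")

    if not raw:
        raise MsaFormatError(f"{path}: no alignment rows")
    rows = [_clean_row(seq) for seq in raw]
    if fmt in {"fasta", "stockholm"}:
        keep = [k for k, c in enumerate(rows[0]) if c != GAP]
        rows = ["".join(r[k] for k in keep) for r in rows]
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise MsaFormatError(
            f"{path}: inconsistent row lengths after projection: {sorted(widths)}"
        )
    if GAP in rows[0]:
        raise MsaFormatError(f"{path}: query row still gapped after projection")
    query = SequenceRecord(ids[0] or path.stem, rows[0])
    matrix = np.array([list(r) for r in rows], dtype="<U1")
    return MsaAlignment(query=query, ids=ids, rows=matrix)


def write_msa(m: MsaAlignment, path: str | Path) -> None:
    """Write as aligned FASTA (width = query length)."""
    with open(path, "w") as fh:
        for name, row in zip(m.ids, m.rows):
            fh.write(f">{name}\n{''.join(row)}\n")


def filter_msa(
    m: MsaAlignment,
    min_coverage: float = 0.70,
    max_row_gap: float = 0.75,
) -> MsaAlignment:
    """Drop rows with < 70% coverage or > 75% gaps (defaults).

    Coverage is the non-gap fraction relative to the query length.  The
    query row is always retained.  Idempotent at fixed thresholds.
    """
    gap_frac = m.gap_fraction()
    coverage = 1.0 - gap_frac
    keep = (coverage >= min_coverage) & (gap_frac <= max_row_gap)
    keep[0] = True
    kept = int(keep.sum())
    log.info(
        "filter_msa: %d/%d rows retained (min_coverage=%.2f, max_row_gap=%.2f)",
        kept, m.n_rows, min_coverage, max_row_gap,
    )
    if kept == 1 and m.n_rows > 1:
        log.warning("filter_msa: all non-query rows removed")
    return MsaAlignment(
        query=m.query,
        ids=[i for i, k in zip(m.ids, keep) if k],
        rows=m.rows[keep],
        weights=None if m.weights is None else m.weights[keep],
    )


def sequence_weights(
    m: MsaAlignment, identity_threshold: float = 0.8, chunk: int = 256
) -> np.ndarray:
    """Redundancy down-weighting: w_r = 1 / |{rows >= 80% identical to r}|.

    Identity is the fraction of equal characters over all aligned columns.
    The effective number of sequences is ``weights.sum()``.
    """
    if m.n_rows < 1:
        raise MsaFormatError("empty alignment")
    enc = np.frombuffer(
        "".join("".join(r) for r in m.rows).encode(), dtype=np.uint8
    ).reshape(m.n_rows, m.length)
    counts = np.zeros(m.n_rows, dtype=int)
    for start in range(0, m.n_rows, chunk):
        block = enc[start:start + chunk]
        ident = (block[:, None, :] == enc[None, :, :]).mean(axis=2)
        counts[start:start + chunk] = (ident >= identity_threshold).sum(axis=1)
    return 1.0 / counts
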