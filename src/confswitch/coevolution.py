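"""Covariation scoring of residue pairs from a filtered alignment.

Pairs are scored by weighted mutual information over smoothed 21-state
(20 amino acids + gap) joint frequency tables, de-biased with the average
product correction (APC), and normalised to a [0, 1] "prob"-like confidence
via a logistic transform of the APC z-score.  The prob scale is this
module's own; thresholds such as 0.8/0.9 apply to it, not to any external
server's score.  An externally produced pair table (TSV: i, j, prob) can be
imported instead of scoring.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InsufficientDataError, MaskedColumnError, MsaFormatError
from .msa import GAP, MsaAlignment

log = logging.getLogger(__name__)

ALPHABET = "ACDEFGHIKLMNPQRSTVWY" + GAP  # 21 states, gap last
_INDEX = {c: k for k, c in enumerate(ALPHABET)}
N_STATES = len(ALPHABET)


@dataclass
class CoevolutionPair:
    """A scored pair of query positions (1-based, i < j)."""

    i: int
    j: int
    mi_raw: float
    mi_apc: float | None = None
    prob: float | None = None


def encode(m: MsaAlignment) -> np.ndarray:
    """Integer-encode the alignment matrix over the 21-state alphabet."""
    out = np.empty(m.rows.shape, dtype=np.int8)
    for c, k in _INDEX.items():
        out[m.rows == c] = k
    return out


def column_mask(m: MsaAlignment, max_col_gap: float = 0.75) -> np.ndarray:
    """True for columns whose gap fraction exceeds ``max_col_gap``."""
    return m.column_gap_fraction() > max_col_gap


def pair_frequencies(
    m: MsaAlignment,
    i: int,
    j: int,
    pseudocount: float = 1.0,
    max_col_gap: float = 0.75,
) -> np.ndarray:
    """Weighted, pseudocount-smoothed 21×21 joint frequency table.

    ``i`` and ``j`` are 1-based query positions.  The pseudocount is spread
    uniformly over the 441 cells, so the table's marginals equal the
    single-column tables smoothed with the same total pseudocount.
    """
    mask = column_mask(m, max_col_gap)
    for pos in (i, j):
        if not 1 <= pos <= m.length:
            raise MsaFormatError(f"position {pos} outside 1..{m.length}")
        if mask[pos - 1]:
            raise MaskedColumnError(f"column {pos} is gap-masked")
    w = m.effective_weights()
    a = encode(m)[:, i - 1]
    b = encode(m)[:, j - 1]
    counts = np.zeros((N_STATES, N_STATES))
    np.add.at(counts, (a, b), w)
    counts += pseudocount / (N_STATES * N_STATES)
    return counts / counts.sum()


def _mi_from_joint(joint: np.ndarray) -> float:
    fa = joint.sum(axis=1)
    fb = joint.sum(axis=0)
    nz = joint > 0
    return float(
        (joint[nz] * np.log(joint[nz] / np.outer(fa, fb)[nz])).sum()
    )


def mutual_information(
    m: MsaAlignment,
    min_separation: int = 6,
    pseudocount: float = 1.0,
    max_col_gap: float = 0.75,
) -> list[CoevolutionPair]:
    """MI (nats) for every unmasked pair with j − i >= ``min_separation``.

    Uses the alignment's row weights if present.  Computed in one einsum
    over the weighted one-hot encoding; L = 120 with 500 rows takes well
    under a second.
    """
    w = m.effective_weights()
    neff = float(w.sum())
    if neff < 2:
        raise InsufficientDataError(
            f"effective sequence number {neff:.2f} < 2"
        )
    enc = encode(m)
    n, L = enc.shape
    onehot = np.zeros((n, L, N_STATES))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], enc] = 1.0
    joint = np.einsum("n,nia,njb->ijab", w, onehot, onehot, optimize=True)
    joint += pseudocount / (N_STATES * N_STATES)
    joint /= joint.sum(axis=(2, 3), keepdims=True)
    mask = column_mask(m, max_col_gap)
    pairs = []
    for i in range(L):
        if mask[i]:
            continue
        for j in range(i + min_separation, L):
            if mask[j]:
                continue
            pairs.append(
                CoevolutionPair(i + 1, j + 1, mi_raw=_mi_from_joint(joint[i, j]))
            )
    return pairs


def apc_correct(pairs: list[CoevolutionPair]) -> list[CoevolutionPair]:
    """Average product correction: MI_apc = MI − MI̅_i · MI̅_j / MI̅.

    Row/column means are taken over each position's scored partners.  With
    a single scored pair (or an all-zero table) the correction removes
    everything, giving mi_apc = 0.
    """
    if not pairs:
        return pairs
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for p in pairs:
        for pos in (p.i, p.j):
            sums[pos] = sums.get(pos, 0.0) + p.mi_raw
            counts[pos] = counts.get(pos, 0) + 1
    mean_all = sum(p.mi_raw for p in pairs) / len(pairs)
    for p in pairs:
        if mean_all == 0:
            p.mi_apc = 0.0
        else:
            mi = sums[p.i] / counts[p.i]
            mj = sums[p.j] / counts[p.j]
            p.mi_apc = p.mi_raw - mi * mj / mean_all
    return pairs


def normalize_prob(pairs: list[CoevolutionPair]) -> list[CoevolutionPair]:
    """Logistic z-transform of mi_apc onto [0, 1]; rank-preserving.

    Zero variance (e.g. a single pair) maps everything to 0.5.
    """
    if not pairs:
        return pairs
    x = np.array([p.mi_apc for p in pairs], dtype=float)
    sd = x.std()
    z = np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd
    probs = 1.0 / (1.0 + np.exp(-z))
    for p, pr in zip(pairs, probs):
        p.prob = float(pr)
    return pairs


def score_pairs(
    m: MsaAlignment,
    min_separation: int = 6,
    pseudocount: float = 1.0,
    max_col_gap: float = 0.75,
) -> list[CoevolutionPair]:
    """MI → APC → prob in one call."""
    return normalize_prob(
        apc_correct(
            mutual_information(m, min_separation, pseudocount, max_col_gap)
        )
    )


def write_pairs(pairs: list[CoevolutionPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\tmi_raw\tmi_apc\tprob\n")
        for p in pairs:
            fh.write(
                f"{p.i}\t{p.j}\t{p.mi_raw:.6f}\t"
                f"{'' if p.mi_apc is None else f'{p.mi_apc:.6f}'}\t"
                f"{'' if p.prob is None else f'{p.prob:.6f}'}\n"
            )


def read_pairs(path: str | Path) -> list[CoevolutionPair]:
    """Read a pair table; accepts the native 5-column TSV or an external
    3-column (i, j, prob) table such as a GREMLIN export."""
    pairs = []
    lines = Path(path).read_text().splitlines()
    for line in lines:
        parts = line.split()
        if not parts or not parts[0].lstrip("-").isdigit():
            continue
        i, j = int(parts[0]), int(parts[1])
        if i > j:
            i, j = j, i
        if len(parts) >= 5:
            pairs.append(
                CoevolutionPair(
                    i, j,
                    mi_raw=float(parts[2]),
                    mi_apc=float(parts[3]) if parts[3] else None,
                    prob=float(parts[4]) if parts[4] else None,
                )
            )
        else:
            pairs.append(
                CoevolutionPair(i, j, mi_raw=float("nan"), prob=float(parts[2]))
            )
    if not pairs:
        raise MsaFormatError(f"{path}: no pair rows")
    return pairs
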