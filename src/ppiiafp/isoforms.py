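"""Mature-sequence derivation, pairwise identity and isoform grouping.

AFP isoforms within a springtail species differ by a handful of point
substitutions and occasional small indels; families are recognised by high
global percent identity between mature sequences. Identity here is
computed from a global (Needleman–Wunsch) alignment scored match +1,
mismatch 0, linear gap −1, with percent identity defined as
100 × matches / alignment length (gap columns included in the
denominator). The same operation works over nucleotide sequences.

The alignment is written out explicitly because the percent depends on
which co-optimal alignment is chosen: the traceback deterministically
prefers a match/mismatch step over a gap in the second sequence, and that
over a gap in the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProteinRecord",
    "mature_sequence",
    "global_identity",
    "identity_matrix",
    "cluster_isoforms",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A sequence record with an optional signal-peptide annotation.

    ``signal_end`` is the 0-based exclusive end of the signal peptide; the
    mature protein is everything after it. Cleavage sites are consumed as
    annotations (e.g. from a sidecar table), never predicted.
    """

    id: str
    sequence: str
    signal_end: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.signal_end is not None:
            if not 0 <= self.signal_end < len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: signal_end {self.signal_end} outside "
                    f"sequence of length {len(self.sequence)}"
                )

    @property
    def mature(self) -> str:
        if self.signal_end:
            return self.sequence[self.signal_end :]
        return self.sequence


def mature_sequence(record: ProteinRecord) -> str:
    """Mature sequence: the precursor minus its annotated signal peptide."""
    return record.mature


def _nw_align(a: str, b: str, match: int, mismatch: int, gap: int):
    """Global DP alignment; returns (n_matches, alignment_length).

    Traceback precedence at equal score: diagonal, then gap in ``b``
    (consume a residue of ``a``), then gap in ``a``.
    """
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1), dtype=np.int64)
    score[0, :] = gap * np.arange(m + 1)
    score[:, 0] = gap * np.arange(n + 1)
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        sub = np.where(b_arr == a_arr[i - 1], match, mismatch)
        row_prev = score[i - 1]
        row = score[i]
        diag = row_prev[:-1] + sub
        up = row_prev[1:] + gap
        best = np.maximum(diag, up)
        # left-dependency forces a scalar scan
        prev = row[0]
        for j in range(1, m + 1):
            prev = max(best[j - 1], prev + gap)
            row[j] = prev
    # traceback
    i, j = n, m
    matches = 0
    length = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            if score[i, j] == diag:
                matches += a[i - 1] == b[j - 1]
                i, j = i - 1, j - 1
                length += 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] + gap:
            i -= 1
            length += 1
            continue
        j -= 1
        length += 1
    return matches, length


def global_identity(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = 0,
    gap: int = -1,
) -> float:
    """Global percent identity between two sequences (0–100)."""
    if not a or not b:
        raise ValueError("global_identity requires two non-empty sequences")
    a, b = a.upper(), b.upper()
    # canonical argument order: the tie-break picks one co-optimal
    # alignment, so identity is made symmetric by sorting the inputs
    if b < a:
        a, b = b, a
    matches, length = _nw_align(a, b, match, mismatch, gap)
    return 100.0 * matches / length


def identity_matrix(records: list[ProteinRecord], level: str = "mature") -> pd.DataFrame:
    """Symmetric percent-identity matrix over records (diagonal 100)."""
    ids = [r.id for r in records]
    seqs = [r.mature if level == "mature" else r.sequence for r in records]
    n = len(records)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = global_identity(seqs[i], seqs[j])
    return pd.DataFrame(mat, index=ids, columns=ids)


def cluster_isoforms(
    records: list[ProteinRecord],
    threshold_percent: float = 80.0,
    matrix: pd.DataFrame | None = None,
) -> list[list[str]]:
    """Single-linkage grouping of isoforms at an identity threshold.

    Two records join the same group if connected by a chain of pairs each
    with identity >= threshold. Groups are sorted by their first member id;
    members are sorted by id. Raising the threshold only ever refines the
    partition.
    """
    if not records:
        raise ValueError("cluster_isoforms requires at least one record")
    if matrix is None:
        matrix = identity_matrix(records)
    ids = [r.id for r in records]
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if matrix.loc[a, b] >= threshold_percent:
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    out = [sorted(g) for g in groups.values()]
    out.sort(key=lambda g: g[0])
    return out
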