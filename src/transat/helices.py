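"""Candidate helix enumeration and projection onto alignment columns.

A helix in a single ungapped sequence is a maximal run of at least
``min_len`` consecutive consensus base pairs (AU, UA, GC, CG, GU, UG) of
the form (p, q), (p+1, q-1), ..., with at least ``min_loop`` unpaired
nucleotides enclosed by the innermost pair.  Helices are found per sequence,
mapped to alignment columns through each row's gap structure, and
deduplicated: distinct sequences proposing the *same* column pairs merge
into one conserved helix whose support counts the contributing rows.
Overlapping-but-different column-pair sets stay separate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import CONSENSUS_PAIRS, MultipleAlignment
from .errors import ValidationError

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

#: 5x5 boolean table over sequence codes; N never pairs.
_PAIR_OK = np.zeros((5, 5), dtype=bool)
for _a, _b in CONSENSUS_PAIRS:
    _PAIR_OK[_a, _b] = True


@dataclass
class SequenceHelix:
    """A maximal helix on one ungapped sequence.

    ``pairs`` are (p, q) 0-based sequence positions with p ascending and q
    descending, strictly consecutive: the k-th pair is (p0 + k, q0 - k).
    """

    row_index: int
    pairs: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        return len(self.pairs)


@dataclass
class ConservedHelix:
    """A helix projected onto alignment columns, shared by >= 1 sequences."""

    column_pairs: tuple[tuple[int, int], ...]
    support: int = 1
    score: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        cols = [c for pair in self.column_pairs for c in pair]
        if len(set(cols)) != len(cols):
            raise ValidationError("helix column pairs are not disjoint")

    @property
    def length(self) -> int:
        return len(self.column_pairs)


def _encode(sequence: str) -> np.ndarray:
    codes = np.empty(len(sequence), dtype=np.int8)
    for k, ch in enumerate(sequence):
        code = _CODE.get(ch)
        if code is None:
            raise ValidationError(
                f"unexpected character {ch!r} in ungapped sequence "
                "(gaps must be removed before helix enumeration)"
            )
        codes[k] = code
    return codes


def enumerate_sequence_helices(
    sequence: str, min_len: int = 4, min_loop: int = 3, row_index: int = 0
) -> list[SequenceHelix]:
    """All maximal helices of one ungapped sequence.

    A run is maximal when it can be extended neither outward (the enclosing
    position pair is absent or not a consensus pair) nor inward (the next
    inner pair is not a consensus pair or would close a loop shorter than
    ``min_loop``).  Runs interrupted by ``N`` split, since N never pairs.
    """
    codes = _encode(sequence)
    n = len(codes)
    helices: list[SequenceHelix] = []
    if n < 2 * min_len + min_loop:
        return helices
    ok = _PAIR_OK[codes[:, None], codes[None, :]]
    # Pairs (p, q) with p + q = s lie on one anti-diagonal; moving inward
    # increases p.  The loop constraint q - p >= min_loop + 1 caps p.
    for s in range(min_loop + 1, 2 * n - 3):
        p_lo = max(0, s - (n - 1))
        p_hi = (s - min_loop - 1) // 2  # inclusive
        if p_hi < p_lo:
            continue
        ps = np.arange(p_lo, p_hi + 1)
        valid = ok[ps, s - ps]
        # maximal runs of consecutive True values
        padded = np.concatenate(([False], valid, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for start, stop in zip(edges[::2], edges[1::2]):
            run = stop - start
            if run < min_len:
                continue
            p0 = int(p_lo + start)
            run = int(run)
            helices.append(
                SequenceHelix(
                    row_index=row_index,
                    pairs=tuple((p0 + k, s - p0 - k) for k in range(run)),
                )
            )
    helices.sort(key=lambda h: h.pairs)
    return helices


def map_helix_to_alignment(
    seq_helix: SequenceHelix, aln: MultipleAlignment
) -> ConservedHelix:
    """Project a sequence helix onto alignment columns.

    Ungapped position p of the row maps to the column holding that row's
    (p+1)-th non-gap character; mapped columns need not be adjacent.
    """
    colmap = aln.column_map(seq_helix.row_index)
    limit = len(colmap)
    for p, q in seq_helix.pairs:
        if p >= limit or q >= limit:
            raise ValidationError(
                f"helix position beyond ungapped length {limit} of row "
                f"{seq_helix.row_index}"
            )
    return ConservedHelix(
        column_pairs=tuple(
            (int(colmap[p]), int(colmap[q])) for p, q in seq_helix.pairs
        ),
        support=1,
    )


def collect_conserved_helices(
    aln: MultipleAlignment, min_len: int = 4, min_loop: int = 3
) -> list[ConservedHelix]:
    """Union of per-row helices mapped to columns, merged by identity.

    Helices with identical column-pair lists merge; their support is the
    number of contributing rows.  Output order is canonical: by first 5'
    column, then length, then first 3' column (full pair list as the final
    tie-break), independent of row order.
    """
    support: dict[tuple[tuple[int, int], ...], int] = {}
    for r in range(aln.n_rows):
        for sh in enumerate_sequence_helices(
            aln.ungapped_row(r), min_len=min_len, min_loop=min_loop, row_index=r
        ):
            key = map_helix_to_alignment(sh, aln).column_pairs
            support[key] = support.get(key, 0) + 1
    out = [
        ConservedHelix(column_pairs=pairs, support=count)
        for pairs, count in support.items()
    ]
    out.sort(key=lambda h: (h.column_pairs[0][0], h.length, h.column_pairs[0][1],
                            h.column_pairs))
    return out
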