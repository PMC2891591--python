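"""Reading, validation and writing of alignments, structures and predictions.

The central container is :class:`MultipleAlignment`, a fixed multiple sequence
alignment of RNA sequences.  Sequences are normalized on input: ``T`` becomes
``U``, lower case is folded to upper case, ``.`` becomes ``-`` and IUPAC
ambiguity codes collapse to ``N`` (treated downstream as missing
information).  Reference secondary structures are sets of 0-based column
pairs and may contain crossing pairs (pseudoknots).

All coordinates are 0-based half-open internally; user-facing output (the
predictions TSV) is 1-based inclusive.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

from .errors import (
    AlignmentFormatError,
    LeafMismatchError,
    StructureParseError,
    ValidationError,
)

# Alphabet codes used throughout the numeric core.
CODE_A, CODE_C, CODE_G, CODE_U, CODE_N, CODE_GAP = 0, 1, 2, 3, 4, 5
ALPHABET = "ACGUN-"
_CODE_OF = {c: i for i, c in enumerate(ALPHABET)}

_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")

#: Watson-Crick plus wobble pairs, as (code, code) tuples.
CONSENSUS_PAIRS = {
    (CODE_A, CODE_U),
    (CODE_U, CODE_A),
    (CODE_G, CODE_C),
    (CODE_C, CODE_G),
    (CODE_G, CODE_U),
    (CODE_U, CODE_G),
}


def _normalize_sequence(raw: str, context: str) -> str:
    """Apply the input normalization rules; reject anything unexpected."""
    out = []
    for ch in raw.upper():
        if ch == "T":
            ch = "U"
        elif ch == ".":
            ch = "-"
        elif ch in _IUPAC_AMBIGUOUS:
            ch = "N"
        if ch not in _CODE_OF:
            raise AlignmentFormatError(
                f"illegal character {ch!r} in sequence {context}"
            )
        out.append(ch)
    return "".join(out)


@dataclass
class MultipleAlignment:
    """A fixed multiple RNA sequence alignment.

    Rows are equal-length gapped strings over ``A,C,G,U,N,-`` with unique
    identifiers.  At least two rows are required and no row may consist of
    gaps only.
    """

    row_ids: list[str]
    rows: list[str]
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.rows):
            raise ValidationError("row_ids and rows differ in length")
        if len(self.rows) < 2:
            raise ValidationError("an alignment needs at least 2 sequences")
        if len(set(self.row_ids)) != len(self.row_ids):
            dupes = {i for i in self.row_ids if self.row_ids.count(i) > 1}
            raise ValidationError(f"duplicate sequence identifiers: {sorted(dupes)}")
        n_cols = len(self.rows[0])
        for rid, row in zip(self.row_ids, self.rows):
            if len(row) != n_cols:
                raise AlignmentFormatError(
                    f"ragged alignment: row {rid!r} has length {len(row)}, "
                    f"expected {n_cols}"
                )
            if set(row) <= {"-"}:
                raise ValidationError(f"row {rid!r} contains only gaps")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def codes(self) -> np.ndarray:
        """(n_rows, n_cols) uint8 matrix over the ``ACGUN-`` code alphabet."""
        if self._codes is None:
            lookup = np.zeros(128, dtype=np.uint8)
            for ch, code in _CODE_OF.items():
                lookup[ord(ch)] = code
            flat = np.frombuffer(
                "".join(self.rows).encode("ascii"), dtype=np.uint8
            )
            self._codes = lookup[flat].reshape(self.n_rows, self.n_cols)
        return self._codes

    def ungapped_row(self, index: int) -> str:
        return self.rows[index].replace("-", "")

    def column_map(self, index: int) -> np.ndarray:
        """Map ungapped-sequence positions of one row to alignment columns."""
        return np.flatnonzero(self.codes[index] != CODE_GAP)


@dataclass(frozen=True)
class ReferenceStructure:
    """A reference secondary structure over alignment columns.

    ``pairs`` holds 0-based column pairs ``(i, j)`` with ``i < j``; each
    column belongs to at most one pair, crossing pairs are allowed.
    """

    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j):
                raise ValidationError(f"invalid structure pair ({i}, {j})")
            for col in (i, j):
                if col in seen:
                    raise ValidationError(
                        f"column {col} appears in more than one pair"
                    )
                seen.add(col)

    @property
    def paired_columns(self) -> set[int]:
        return {c for p in self.pairs for c in p}


def _sniff_format(path: str) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith("# STOCKHOLM"):
                return "stockholm"
            if line.upper().startswith("CLUSTAL"):
                return "clustal"
            if line.startswith(">"):
                return "fasta"
            break
    raise AlignmentFormatError(f"cannot determine alignment format of {path}")


def read_alignment(path: str, format: str | None = None) -> MultipleAlignment:
    """Read an aligned FASTA / Clustal / Stockholm file.

    ``format`` may be ``fasta``, ``clustal`` or ``stockholm``; when omitted
    the format is sniffed from the first non-blank line.
    """
    if not os.path.exists(path):
        raise AlignmentFormatError(f"no such file: {path}")
    if os.path.getsize(path) == 0:
        raise AlignmentFormatError(f"empty alignment file: {path}")
    fmt = format or _sniff_format(path)
    if fmt not in {"fasta", "clustal", "stockholm"}:
        raise AlignmentFormatError(f"unsupported alignment format: {fmt}")
    try:
        msa = AlignIO.read(path, fmt)
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    ids = [rec.id for rec in msa]
    rows = [_normalize_sequence(str(rec.seq), rec.id) for rec in msa]
    return MultipleAlignment(ids, rows)


def write_alignment(aln: MultipleAlignment, path: str, format: str = "fasta") -> None:
    """Write an alignment in any of the three supported formats."""
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(row), id=rid, description="")
        for rid, row in zip(aln.row_ids, aln.rows)
    ]
    AlignIO.write(MultipleSeqAlignment(records), path, format)


#: bracket tiers understood by :func:`parse_structure`; WUSS-style letter
#: tiers cover the pseudoknot annotations we emit ourselves.
_TIERS = [("(", ")"), ("<", ">"), ("[", "]"), ("{", "}"), ("A", "a"), ("B", "b")]
_OPEN = {o: k for k, (o, _) in enumerate(_TIERS)}
_CLOSE = {c: k for k, (_, c) in enumerate(_TIERS)}
_UNPAIRED_CHARS = set(".,:_-~")


def parse_structure(string: str, n_cols: int) -> ReferenceStructure:
    """Parse a dot-bracket / WUSS string into a set of column pairs.

    Supported bracket tiers: ``()``, ``<>``, ``[]``, ``{}``, ``Aa``, ``Bb``;
    crossing pairs between tiers (pseudoknots) are allowed.  Characters in
    ``.,:_-~`` are unpaired.
    """
    if len(string) != n_cols:
        raise StructureParseError(
            f"structure length {len(string)} != alignment width {n_cols}"
        )
    stacks: list[list[int]] = [[] for _ in _TIERS]
    pairs: set[tuple[int, int]] = set()
    for col, ch in enumerate(string):
        if ch in _OPEN:
            stacks[_OPEN[ch]].append(col)
        elif ch in _CLOSE:
            stack = stacks[_CLOSE[ch]]
            if not stack:
                raise StructureParseError(
                    f"unmatched closing bracket {ch!r} at column {col}"
                )
            pairs.add((stack.pop(), col))
        elif ch not in _UNPAIRED_CHARS:
            raise StructureParseError(f"unsupported structure character {ch!r}")
    for k, stack in enumerate(stacks):
        if stack:
            raise StructureParseError(
                f"unmatched opening bracket {_TIERS[k][0]!r} at column {stack[-1]}"
            )
    return ReferenceStructure(frozenset(pairs))


def structure_to_string(structure: ReferenceStructure, n_cols: int) -> str:
    """Render a structure as dot-bracket, assigning crossing helices to
    successive bracket tiers (greedy colouring)."""
    ordered = sorted(structure.pairs)
    tiers_used: list[list[tuple[int, int]]] = []
    assignment: dict[tuple[int, int], int] = {}

    def crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
        (i, j), (k, l) = a, b
        return (i < k < j < l) or (k < i < l < j)

    for pair in ordered:
        for t, members in enumerate(tiers_used):
            if not any(crosses(pair, m) for m in members):
                members.append(pair)
                assignment[pair] = t
                break
        else:
            if len(tiers_used) >= len(_TIERS):
                raise StructureParseError(
                    "structure needs more bracket tiers than supported"
                )
            tiers_used.append([pair])
            assignment[pair] = len(tiers_used) - 1
    out = ["."] * n_cols
    for (i, j), t in assignment.items():
        out[i], out[j] = _TIERS[t]
    return "".join(out)


def read_reference_structure(path: str, n_cols: int | None = None) -> ReferenceStructure:
    """Read a reference structure from a Stockholm ``#=GC SS_cons`` line or a
    plain dot-bracket file (structure on the last non-empty line)."""
    with open(path) as fh:
        text = fh.read()
    if text.startswith("# STOCKHOLM"):
        msa = AlignIO.read(io.StringIO(text), "stockholm")
        ss = msa.column_annotations.get("secondary_structure")
        if ss is None:
            raise StructureParseError(f"{path} has no #=GC SS_cons line")
        return parse_structure(ss, n_cols if n_cols is not None else len(ss))
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise StructureParseError(f"empty structure file: {path}")
    ss = lines[-1]
    return parse_structure(ss, n_cols if n_cols is not None else len(ss))


def match_leaves(aln: MultipleAlignment, tree) -> dict[str, int]:
    """Verify that tree leaves and alignment rows coincide as sets.

    Returns a mapping from row id to row index (the pairing used by the
    likelihood machinery).  Raises :class:`LeafMismatchError` naming the
    offending identifiers otherwise.
    """
    row_set = set(aln.row_ids)
    leaf_set = set(tree.leaf_labels)
    if row_set != leaf_set:
        only_aln = sorted(row_set - leaf_set)
        only_tree = sorted(leaf_set - row_set)
        raise LeafMismatchError(
            "alignment rows and tree leaves differ: "
            f"alignment-only={only_aln}, tree-only={only_tree}"
        )
    return {rid: i for i, rid in enumerate(aln.row_ids)}


PREDICTION_COLUMNS = [
    "helix",
    "length",
    "five_prime",
    "three_prime",
    "pairs",
    "log_likelihood",
    "p_value",
    "support",
]


def write_predictions(helices, path: str, header_lines: list[str] | None = None) -> None:
    """Write scored helices as a TSV, most significant first.

    One row per helix: id, length L, 1-based 5' and 3' column ranges, the
    comma-separated column pairs, log-likelihood score, p-value and the
    number of supporting sequences.  Sorted by ascending p-value, ties broken
    by descending score, then lexicographically by column pairs.
    """
    for h in helices:
        if h.score is None or h.p_value is None:
            raise ValidationError("cannot write an unscored helix")
    ordered = sorted(
        helices, key=lambda h: (h.p_value, -h.score, h.column_pairs)
    )
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for rank, h in enumerate(ordered, start=1):
            fives = [i for i, _ in h.column_pairs]
            threes = [j for _, j in h.column_pairs]
            pair_str = ",".join(f"{i + 1}:{j + 1}" for i, j in h.column_pairs)
            fh.write(
                "\t".join(
                    [
                        f"helix_{rank}",
                        str(h.length),
                        f"{min(fives) + 1}-{max(fives) + 1}",
                        f"{min(threes) + 1}-{max(threes) + 1}",
                        pair_str,
                        f"{h.score:.6f}",
                        f"{h.p_value:.6g}",
                        str(h.support),
                    ]
                )
                + "\n"
            )


def read_predictions(path: str):
    """Read a predictions TSV written by :func:`write_predictions`."""
    from .helices import ConservedHelix

    helices = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header != PREDICTION_COLUMNS:
                    raise AlignmentFormatError(
                        f"unexpected predictions header in {path}"
                    )
                continue
            fields = dict(zip(header, line.split("\t")))
            pairs = tuple(
                (int(a) - 1, int(b) - 1)
                for a, b in (p.split(":") for p in fields["pairs"].split(","))
            )
            helices.append(
                ConservedHelix(
                    column_pairs=pairs,
                    support=int(fields["support"]),
                    score=float(fields["log_likelihood"]),
                    p_value=float(fields["p_value"]),
                )
            )
    if header is None:
        raise AlignmentFormatError(f"no header found in {path}")
    return helices
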