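"""Reversible substitution models for unpaired and paired alignment columns.

Two time-continuous Markov chains drive everything downstream: a 4-state
chain over single nucleotides for unpaired columns and a 16-state chain over
ordered dinucleotides for base-paired column pairs.  The paired chain puts
most of its equilibrium mass on the six consensus pairs (Watson-Crick plus
GU/UG wobble) and allows compensatory double substitutions between them,
which is the covariation signal the helix score picks up.

The default matrices shipped under ``data/`` are synthetic: they were
constructed GTR-style (symmetric exchangeabilities times equilibrium
frequencies) and calibrated to typical RNA loop/helix composition rather
than transcribed from any published table; the data files document the
construction.  Users can substitute their own matrices via ``model_dir``.

Leaf observation vectors implement the gap semantics of the method: a gap or
``N`` in an unpaired column is missing information (all-ones vector); a
two-sided gap in a paired column is likewise missing information over all 16
pair states; a one-sided gap, however, is scored as a *non-consensus* pair —
an indicator over the 3 states that keep the observed base but cannot form a
consensus pair — because half of a base pair cannot be gained or lost alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .alignment import CODE_GAP, CODE_N, CONSENSUS_PAIRS
from .errors import ModelError

UNPAIRED_STATES = ("A", "C", "G", "U")
#: 16 dinucleotide states in row-major order AA, AC, ... UU.
PAIRED_STATES = tuple(a + b for a in UNPAIRED_STATES for b in UNPAIRED_STATES)

_REV_TOL = 1e-9


@dataclass
class SubstitutionModel:
    """A reversible CTMC core ``(states, Q, pi)``.

    The tree and branch lengths are supplied at evaluation time; together
    they complete the five-tuple (alphabet, rates, equilibrium, topology,
    branch lengths) describing the evolution of a column (or column pair).
    """

    states: tuple[str, ...]
    rates: np.ndarray
    freqs: np.ndarray
    name: str = "model"
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )
    _p_cache: dict[float, np.ndarray] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        k = len(self.states)
        self.rates = np.asarray(self.rates, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.rates.shape != (k, k) or self.freqs.shape != (k,):
            raise ModelError(f"{self.name}: shape mismatch with {k} states")
        if np.any(self.freqs <= 0):
            raise ModelError(f"{self.name}: equilibrium frequencies must be > 0")
        self.freqs = self.freqs / self.freqs.sum()
        off = self.rates.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ModelError(f"{self.name}: negative off-diagonal rate")
        if np.max(np.abs(self.rates.sum(axis=1))) > 1e-8:
            raise ModelError(f"{self.name}: rate-matrix rows do not sum to 0")
        flux = self.freqs[:, None] * self.rates
        if np.max(np.abs(flux - flux.T)) > _REV_TOL:
            raise ModelError(f"{self.name}: rate matrix is not reversible")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def _eigendecomposition(self):
        # Reversibility guarantees a real spectrum: symmetrize with
        # diag(sqrt(pi)) and use the Hermitian eigensolver.
        if self._eig is None:
            sqrt_pi = np.sqrt(self.freqs)
            sym = (sqrt_pi[:, None] * self.rates) / sqrt_pi[None, :]
            w, v = np.linalg.eigh((sym + sym.T) / 2.0)
            self._eig = (w, v, sqrt_pi)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """``P(t) = exp(Q t)``; rows sum to 1, tiny negatives clipped."""
        if t < 0:
            raise ModelError(f"negative evolutionary time t={t}")
        t = float(t)
        cached = self._p_cache.get(t)
        if cached is not None:
            return cached
        w, v, sqrt_pi = self._eigendecomposition()
        inner = (v * np.exp(w * t)) @ v.T
        p = inner / sqrt_pi[:, None] * sqrt_pi[None, :]
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        self._p_cache[t] = p
        return p


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    return model.transition_matrix(t)


def _parse_model_file(text: str, name: str) -> SubstitutionModel:
    rows = [
        line.split()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not rows:
        raise ModelError(f"{name}: empty model file")
    states = tuple(rows[0])
    k = len(states)
    if len(rows) != k + 2:
        raise ModelError(
            f"{name}: expected a state header, {k} rate rows and one "
            f"frequency row; got {len(rows)} data lines"
        )
    try:
        q = np.array([[float(x) for x in row] for row in rows[1 : k + 1]])
        pi = np.array([float(x) for x in rows[k + 1]])
    except ValueError as exc:
        raise ModelError(f"{name}: non-numeric entry ({exc})") from exc
    return SubstitutionModel(states, q, pi, name=name)


_DEFAULT_FILES = {
    "unpaired": "unpaired_rates_synthetic.dat",
    "paired": "paired_rates_synthetic.dat",
}


def load_default_models(
    model_dir: str | None = None,
) -> tuple[SubstitutionModel, SubstitutionModel]:
    """Load the (unpaired, paired) model cores from data files.

    Without ``model_dir`` the packaged synthetic defaults are used.  With
    ``model_dir``, files of the same names are read from that directory.
    Both models are validated (reversibility, zero row sums, normalized
    equilibrium) on load.
    """
    out = []
    for kind, fname in _DEFAULT_FILES.items():
        if model_dir is None:
            text = (
                resources.files("transat.data").joinpath(fname).read_text()
            )
        else:
            try:
                with open(f"{model_dir}/{fname}") as fh:
                    text = fh.read()
            except OSError as exc:
                raise ModelError(f"cannot read model file {fname}: {exc}") from exc
        model = _parse_model_file(text, name=fname)
        expected = UNPAIRED_STATES if kind == "unpaired" else PAIRED_STATES
        if model.states != expected:
            raise ModelError(
                f"{fname}: state order {model.states} does not match the "
                f"expected {expected}"
            )
        out.append(model)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Leaf observation vectors
# ---------------------------------------------------------------------------

_CONSENSUS_PARTNERS: dict[int, set[int]] = {}
for _x, _y in CONSENSUS_PAIRS:
    _CONSENSUS_PARTNERS.setdefault(_x, set()).add(_y)


def _build_unpaired_table() -> np.ndarray:
    table = np.zeros((6, 4))
    for code in range(4):
        table[code, code] = 1.0
    table[CODE_N] = 1.0
    table[CODE_GAP] = 1.0
    return table


def _build_paired_table() -> np.ndarray:
    table = np.zeros((6, 6, 16))
    for ci in range(6):
        for cj in range(6):
            i_missing = ci in (CODE_N, CODE_GAP)
            j_missing = cj in (CODE_N, CODE_GAP)
            if i_missing and j_missing:
                table[ci, cj, :] = 1.0
            elif not i_missing and not j_missing:
                table[ci, cj, 4 * ci + cj] = 1.0
            elif i_missing:
                # one-sided gap on the 5' side: any first base that does not
                # form a consensus pair with the observed 3' base
                for x in range(4):
                    if cj not in _CONSENSUS_PARTNERS.get(x, set()):
                        table[ci, cj, 4 * x + cj] = 1.0
            else:
                for y in range(4):
                    if y not in _CONSENSUS_PARTNERS.get(ci, set()):
                        table[ci, cj, 4 * ci + y] = 1.0
    return table


#: leaf vector lookup tables indexed by character code(s)
UNPAIRED_LEAF_TABLE = _build_unpaired_table()
PAIRED_LEAF_TABLE = _build_paired_table()

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4, "-": 5}


def leaf_vector_unpaired(char: str) -> np.ndarray:
    """Leaf vector for one character in an unpaired column.

    Nucleotides are one-hot; ``N`` and ``-`` are missing information.
    """
    code = _CODE.get(char)
    if code is None:
        raise ModelError(f"invalid alignment character {char!r}")
    return UNPAIRED_LEAF_TABLE[code].copy()


def leaf_vector_paired(char_i: str, char_j: str) -> np.ndarray:
    """Leaf vector for a character pair in two base-paired columns.

    Both observed: one-hot on the dinucleotide state.  Two-sided gap:
    missing information (all 16 states).  One-sided gap: indicator over the
    non-consensus pair states that retain the observed base.
    """
    ci, cj = _CODE.get(char_i), _CODE.get(char_j)
    if ci is None or cj is None:
        raise ModelError(f"invalid alignment characters ({char_i!r}, {char_j!r})")
    return PAIRED_LEAF_TABLE[ci, cj].copy()
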