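"""Simulation of structured RNA alignments down balanced phylogenies.

An artificial alignment is generated from three ingredients: a secondary
structure over sequence positions, a maximally balanced rooted binary tree
whose 2n-2 equal branches sum to a chosen total tree length, and the two
substitution models.  Root states are drawn from the equilibrium
distributions (jointly over the 16 dinucleotide states for paired
positions, per nucleotide otherwise) and evolved edge by edge with the
transition matrices, so every site is at stationarity and paired positions
carry covariation.  There are no indels: the leaf sequences are a gapless
alignment by construction, with the generating structure as its reference.

The dataset driver reproduces the two benchmark designs: nine sequence-
length bins (100-199 up to 900-999), 10 structures per bin at six total
tree lengths 0.5, 1, 2, 4, 8, 16 for the tree-length experiment (540
alignments), and 50 structures per bin at tree length 4 for the length
experiment (450 alignments); 10 sequences per alignment in both.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .alignment import MultipleAlignment, ReferenceStructure, structure_to_string
from .errors import ValidationError
from .models import SubstitutionModel
from .tree import PhyloTree

TREE_EXPERIMENT_LENGTHS = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
LENGTH_BINS = tuple((lo, lo + 99) for lo in range(100, 1000, 100))


@dataclass
class SimulationSpec:
    """One simulated alignment: structure, taxon count, diversity, seed."""

    structure: ReferenceStructure
    length: int
    n_seqs: int
    total_tree_length: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_seqs < 2:
            raise ValidationError("n_seqs must be >= 2")
        if self.total_tree_length < 0:
            raise ValidationError("total_tree_length must be >= 0")
        if self.structure.pairs and max(
            c for p in self.structure.pairs for c in p
        ) >= self.length:
            raise ValidationError("structure pairs exceed the sequence length")


def build_balanced_tree(n_seqs: int, total_length: float) -> PhyloTree:
    """Maximally balanced rooted binary tree with equal branch lengths.

    Leaf depths differ by at most one; each of the 2*n_seqs - 2 edges has
    length ``total_length / (2*n_seqs - 2)``, so the branch lengths sum to
    ``total_length`` exactly.
    """
    if n_seqs < 2:
        raise ValidationError("a tree needs at least 2 leaves")
    edge = total_length / (2 * n_seqs - 2)
    children: list[tuple[int, int] | None] = []
    lengths: list[float] = []
    labels: list[str | None] = []
    counter = iter(range(1, n_seqs + 1))

    def grow(n: int) -> int:
        if n == 1:
            children.append(None)
            lengths.append(edge)
            labels.append(f"t{next(counter)}")
        else:
            left = grow((n + 1) // 2)
            right = grow(n // 2)
            children.append((left, right))
            lengths.append(edge)
            labels.append(None)
        return len(children) - 1

    root = grow(n_seqs)
    lengths[root] = 0.0
    return PhyloTree(children, np.asarray(lengths), labels, root)


def random_structure(
    length: int,
    rng: np.random.Generator,
    target_pair_fraction: float = 0.5,
    min_helix: int = 4,
    max_helix: int = 8,
    min_loop: int = 3,
    max_failures: int = 200,
) -> ReferenceStructure:
    """Random structure: non-overlapping helices placed greedily.

    Helices of ``min_helix``..``max_helix`` pairs are dropped at random
    positions (crossing placements are allowed, i.e. pseudoknots can arise)
    until the fraction of paired positions reaches the target or
    ``max_failures`` consecutive placements fail.
    """
    if length < 12:
        raise ValidationError("random_structure needs length >= 12")
    free = np.ones(length, dtype=bool)
    pairs: set[tuple[int, int]] = set()
    failures = 0
    while failures < max_failures and 2 * len(pairs) < target_pair_fraction * length:
        l = int(rng.integers(min_helix, max_helix + 1))
        i = int(rng.integers(0, length))
        j = int(rng.integers(0, length))
        # outermost pair (i, j); innermost pair encloses >= min_loop bases
        if not (i + l - 1 < j - l + 1 - min_loop - 1 + 1 and j < length):
            failures += 1
            continue
        five = range(i, i + l)
        three = range(j - l + 1, j + 1)
        if not (free[list(five)].all() and free[list(three)].all()):
            failures += 1
            continue
        for k in range(l):
            pairs.add((i + k, j - k))
            free[i + k] = False
            free[j - k] = False
        failures = 0
    return ReferenceStructure(frozenset(pairs))


def _sample_children(
    parent_states: np.ndarray, p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one child state per site given parent states and P(branch)."""
    if parent_states.size == 0:
        return parent_states.copy()
    cum = np.cumsum(p, axis=1)
    u = rng.random(parent_states.size)
    return (cum[parent_states] < u[:, None]).sum(axis=1)


def evolve_alignment(
    spec: SimulationSpec,
    models: tuple[SubstitutionModel, SubstitutionModel],
    tree: PhyloTree | None = None,
) -> tuple[MultipleAlignment, PhyloTree]:
    """Simulate a gapless alignment under the paired/unpaired models.

    Paired positions evolve jointly in the 16-state chain, all other
    positions independently in the 4-state chain.  Returns the alignment
    (rows labeled to match the tree leaves) and the tree.
    """
    unpaired_model, paired_model = models
    if tree is None:
        tree = build_balanced_tree(spec.n_seqs, spec.total_tree_length)
    rng = np.random.default_rng(spec.seed)
    pair_list = sorted(spec.structure.pairs)
    paired_cols = spec.structure.paired_columns
    unpaired_cols = np.array(
        [c for c in range(spec.length) if c not in paired_cols], dtype=int
    )

    n_pairs, n_un = len(pair_list), unpaired_cols.size
    states: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    root_pairs = rng.choice(16, size=n_pairs, p=paired_model.freqs)
    root_un = rng.choice(4, size=n_un, p=unpaired_model.freqs)
    states[tree.root] = (root_pairs, root_un)

    # preorder traversal in reverse postorder keeps parents before children
    for node in reversed(tree.postorder()):
        kids = tree.children[node]
        if kids is None:
            continue
        parent_pairs, parent_un = states.pop(node) if node != tree.root else states[node]
        for kid in kids:
            b = tree.branch_lengths[kid]
            kid_pairs = _sample_children(
                parent_pairs, paired_model.transition_matrix(b), rng
            )
            kid_un = _sample_children(
                parent_un, unpaired_model.transition_matrix(b), rng
            )
            states[kid] = (kid_pairs, kid_un)

    nt = np.frombuffer(b"ACGU", dtype=np.uint8)
    rows: dict[str, str] = {}
    for leaf in tree.leaf_indices():
        pair_states, un_states = states[leaf]
        seq = np.empty(spec.length, dtype=np.uint8)
        if n_un:
            seq[unpaired_cols] = nt[un_states]
        for (i, j), s in zip(pair_list, pair_states):
            seq[i] = nt[s // 4]
            seq[j] = nt[s % 4]
        rows[tree.labels[leaf]] = bytes(seq).decode("ascii")

    labels = tree.leaf_labels
    aln = MultipleAlignment(labels, [rows[lab] for lab in labels])
    return aln, tree


@dataclass
class DatasetRecord:
    """One simulated benchmark alignment plus its provenance."""

    name: str
    alignment: MultipleAlignment
    tree: PhyloTree
    structure: ReferenceStructure
    length: int
    length_bin: tuple[int, int]
    total_tree_length: float
    experiment: str


def artificial_dataset_driver(
    design: str,
    seed: int = 0,
    n_seqs: int = 10,
    structures_per_bin_tree: int = 10,
    structures_per_bin_length: int = 50,
    tree_lengths: tuple[float, ...] = TREE_EXPERIMENT_LENGTHS,
    length_bins: tuple[tuple[int, int], ...] = LENGTH_BINS,
    out_dir: str | None = None,
) -> list[DatasetRecord]:
    """Generate the benchmark collections.

    ``design`` is ``tree_experiment`` (bins x structures x tree lengths),
    ``length_experiment`` (bins x structures at tree length 4) or ``both``.
    With the default design parameters this yields 540, 450 and 990
    alignments respectively.  Deterministic given ``seed``; optionally
    writes Stockholm (+SS_cons), Newick and a manifest TSV to ``out_dir``.
    """
    if design not in {"tree_experiment", "length_experiment", "both"}:
        raise ValidationError(f"unknown design {design!r}")
    from .models import load_default_models

    models = load_default_models()
    records: list[DatasetRecord] = []
    master = np.random.default_rng(seed)

    def simulate_one(name, experiment, bin_, total_tree_length):
        struct_rng = np.random.default_rng(master.integers(2**31))
        length = int(struct_rng.integers(bin_[0], bin_[1] + 1))
        structure = random_structure(length, struct_rng)
        spec = SimulationSpec(
            structure=structure,
            length=length,
            n_seqs=n_seqs,
            total_tree_length=total_tree_length,
            seed=int(master.integers(2**31)),
        )
        aln, tree = evolve_alignment(spec, models)
        records.append(
            DatasetRecord(
                name=name,
                alignment=aln,
                tree=tree,
                structure=structure,
                length=length,
                length_bin=bin_,
                total_tree_length=total_tree_length,
                experiment=experiment,
            )
        )

    if design in {"tree_experiment", "both"}:
        for bin_ in length_bins:
            for rep in range(structures_per_bin_tree):
                # one structure per replicate, reused across tree lengths
                struct_rng = np.random.default_rng(master.integers(2**31))
                length = int(struct_rng.integers(bin_[0], bin_[1] + 1))
                structure = random_structure(length, struct_rng)
                for total in tree_lengths:
                    name = f"tree_b{bin_[0]}_r{rep}_T{total:g}"
                    spec = SimulationSpec(
                        structure=structure,
                        length=length,
                        n_seqs=n_seqs,
                        total_tree_length=total,
                        seed=int(master.integers(2**31)),
                    )
                    aln, tree = evolve_alignment(spec, models)
                    records.append(
                        DatasetRecord(
                            name=name,
                            alignment=aln,
                            tree=tree,
                            structure=structure,
                            length=length,
                            length_bin=bin_,
                            total_tree_length=total,
                            experiment="tree_experiment",
                        )
                    )
    if design in {"length_experiment", "both"}:
        for bin_ in length_bins:
            for rep in range(structures_per_bin_length):
                simulate_one(
                    f"length_b{bin_[0]}_r{rep}", "length_experiment", bin_, 4.0
                )

    if out_dir is not None:
        _write_dataset(records, out_dir)
    return records


def _write_dataset(records: list[DatasetRecord], out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "manifest.tsv"), "w") as manifest:
        manifest.write(
            "name\texperiment\tlength\tlength_bin\ttotal_tree_length\t"
            "n_seqs\tn_pairs\talignment\ttree\n"
        )
        for rec in records:
            sto = os.path.join(out_dir, f"{rec.name}.sto")
            nwk = os.path.join(out_dir, f"{rec.name}.nwk")
            ss = structure_to_string(rec.structure, rec.length)
            with open(sto, "w") as fh:
                fh.write("# STOCKHOLM 1.0\n")
                for rid, row in zip(rec.alignment.row_ids, rec.alignment.rows):
                    fh.write(f"{rid}  {row}\n")
                fh.write(f"#=GC SS_cons  {ss}\n//\n")
            with open(nwk, "w") as fh:
                fh.write(rec.tree.to_newick() + "\n")
            manifest.write(
                f"{rec.name}\t{rec.experiment}\t{rec.length}\t"
                f"{rec.length_bin[0]}-{rec.length_bin[1]}\t"
                f"{rec.total_tree_length:g}\t{rec.alignment.n_rows}\t"
                f"{len(rec.structure.pairs)}\t{rec.name}.sto\t{rec.name}.nwk\n"
            )
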