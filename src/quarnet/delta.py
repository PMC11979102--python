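"""The delta-heuristic: dense weighted tf-quarnets from a sequence alignment.

Pairwise normalized Hamming distances (gap columns removed per pair) give, for
every 4-subset, three split sums; their normalized spread (the delta value)
classifies the subset as a quartet tree (delta >= lambda) or a 4-cycle
(delta < lambda), with a confidence weight growing linearly away from the
threshold.  Reticulation leaves of 4-cycles are the members with the highest
mean delta over all 4-subsets containing them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .quarnets import DenseQuarnetSet

__all__ = [
    "Alignment",
    "PairwiseHamming",
    "read_alignment",
    "pairwise_hamming",
    "delta_value",
    "infer_tf_quarnets",
    "DEFAULT_LAMBDA",
]

DEFAULT_LAMBDA = 0.3

_GAP = ord("-")


@dataclass
class Alignment:
    """Taxon-labeled, equal-length nucleotide sequences (gaps allowed)."""

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("one sequence per taxon required")
        if len(self.taxa) < 4:
            raise ValueError("need at least four taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]

    def __len__(self) -> int:
        return len(self.sequences[0])

    def matrix(self) -> np.ndarray:
        """(n_taxa, n_sites) byte matrix."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype=np.uint8
        ).reshape(len(self.taxa), -1)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, s in zip(self.taxa, self.sequences):
                fh.write(f">{t}\n{s}\n")


def read_alignment(path, fmt: str | None = None) -> Alignment:
    """Read a FASTA or NEXUS alignment (format sniffed from the first byte)."""
    from Bio import AlignIO

    if fmt is None:
        with open(path) as fh:
            first = fh.read(1)
        fmt = "nexus" if first == "#" else "fasta"
    aln = AlignIO.read(path, fmt)
    return Alignment([rec.id for rec in aln], [str(rec.seq) for rec in aln])


@dataclass
class PairwiseHamming:
    """Normalized Hamming distances with per-pair effective lengths."""

    taxa: list[str]
    h: np.ndarray  # (n, n) in [0, 1], zero diagonal
    effective: np.ndarray  # (n, n) mutually gap-free column counts

    def distance(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.h[i, j])


def pairwise_hamming(aln: Alignment) -> PairwiseHamming:
    """Gap-pairwise-deleted normalized Hamming distances.

    Any non-gap symbol pair counts as a mismatch unless the symbols are
    identical (ambiguity codes included).  A pair of taxa with no mutually
    gap-free column is an error.
    """
    mat = aln.matrix()
    n = len(aln.taxa)
    gap_free = mat != _GAP
    h = np.zeros((n, n))
    eff = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = gap_free[i] & gap_free[i + 1 :]
        eff_i = both.sum(axis=1)
        diff_i = ((mat[i] != mat[i + 1 :]) & both).sum(axis=1)
        for off, j in enumerate(range(i + 1, n)):
            if eff_i[off] == 0:
                raise ValueError(
                    f"taxa {aln.taxa[i]!r} and {aln.taxa[j]!r} share no "
                    "mutually gap-free column"
                )
            eff[i, j] = eff[j, i] = eff_i[off]
            h[i, j] = h[j, i] = diff_i[off] / eff_i[off]
    return PairwiseHamming(list(aln.taxa), h, eff)


def _split_sums(h: np.ndarray, quad: tuple[int, int, int, int]) -> np.ndarray:
    a, b, c, d = quad
    return np.array(
        [h[a, b] + h[c, d], h[a, c] + h[b, d], h[a, d] + h[b, c]]
    )


def delta_value(ph: PairwiseHamming, four) -> float:
    """The [0, 1] treelikeness statistic of a 4-subset; 0 if all sums tie."""
    idx = tuple(ph.taxa.index(t) for t in sorted(four))
    if len(set(idx)) != 4:
        raise ValueError("need four distinct taxa")
    s = np.sort(_split_sums(ph.h, idx))[::-1]
    if s[0] == s[2]:
        return 0.0
    return float((s[0] - s[1]) / (s[0] - s[2]))


def infer_tf_quarnets(
    aln: Alignment,
    lam: float = DEFAULT_LAMBDA,
    seed: int | np.random.Generator | None = 0,
) -> DenseQuarnetSet:
    """Dense weighted tf-quarnet set from an alignment.

    For each 4-subset: delta >= lam gives the quartet tree whose split has the
    highest pair sum; delta < lam gives the 4-cycle whose *opposite* pairing
    is the highest-sum split (so both smaller-sum splits arise by deleting a
    reticulation edge), with the member of highest mean delta below the
    reticulation.  Weights: |delta - lam| / lam below the threshold,
    |delta - lam| / (1 - lam) above.
    """
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must lie in (0, 1)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ph = pairwise_hamming(aln)
    order = np.argsort(np.asarray(aln.taxa))
    taxa_sorted = [aln.taxa[i] for i in order]
    h = ph.h[np.ix_(order, order)]
    n = len(taxa_sorted)
    subsets = np.array(list(itertools.combinations(range(n), 4)), dtype=np.int64)
    l0, l1, l2, l3 = (subsets[:, i] for i in range(4))
    sums = np.stack(
        [
            h[l0, l1] + h[l2, l3],
            h[l0, l2] + h[l1, l3],
            h[l0, l3] + h[l1, l2],
        ],
        axis=1,
    )
    # descending sort; ties broken toward the lexicographically first split
    ssorted = -np.sort(-sums, axis=1)
    d0, d1, d2 = ssorted[:, 0], ssorted[:, 1], ssorted[:, 2]
    spread = d0 - d2
    delta = np.where(spread > 0, (d0 - d1) / np.where(spread > 0, spread, 1.0), 0.0)
    top_split = np.argmax(sums, axis=1)  # first index attaining the max sum

    # mean delta per taxon over all subsets containing it
    delta_sums = np.zeros(n)
    for col in range(4):
        np.add.at(delta_sums, subsets[:, col], delta)
    n_each = len(subsets) * 4 / n  # = C(n-1, 3)
    delta_x = delta_sums / n_each
    tie_rank = rng.permutation(n)  # seeded tie-break for equal delta_x

    weights = np.where(
        delta <= lam, (lam - delta) / lam, (delta - lam) / (1.0 - lam)
    )
    is_quartet = delta >= lam
    codes = np.empty(len(subsets), dtype=np.int8)
    codes[is_quartet] = top_split[is_quartet]
    cyc = ~is_quartet
    if cyc.any():
        sub_c = subsets[cyc]
        dx = delta_x[sub_c]
        tr = tie_rank[sub_c]
        best = dx.max(axis=1, keepdims=True)
        tr_masked = np.where(dx == best, tr, len(subsets) * 8)
        ret_col = np.argmin(tr_masked, axis=1)  # argmax delta_x, seeded ties
        codes[cyc] = (3 + 4 * top_split[cyc] + ret_col).astype(np.int8)
    return DenseQuarnetSet(taxa_sorted, codes=codes, weights=weights)
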