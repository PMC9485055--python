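"""Global protein alignment (identity/similarity) and greedy redundancy clustering.

The alignment is a Needleman-Wunsch optimum with affine gaps, computed with
Bio.Align.PairwiseAligner.  Defaults follow EMBOSS-needle conventions:
BLOSUM62, gap open 10, gap extend 0.5.  Percent identity is identical
aligned pairs over alignment length; percent similarity is aligned residue
pairs with a positive substitution score over alignment length.

Redundancy filtering is a CD-HIT-style greedy incremental clustering
(without CD-HIT's k-mer prefilter): sequences sorted by length descending
join the first existing cluster whose seed they match at >= the identity
threshold, where identity is identical pairs over the shorter sequence
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import ProteinSequence


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float      # percent, over alignment length
    similarity: float    # percent, positive-substitution-score pairs
    n_identical: int = 0
    n_similar: int = 0

    @property
    def length(self) -> int:
        return len(self.aligned_a)


@dataclass
class Cluster:
    representative: ProteinSequence
    members: List[ProteinSequence] = field(default_factory=list)
    identities: List[float] = field(default_factory=list)  # member vs seed

    def __len__(self) -> int:
        return len(self.members)


def _make_aligner(
    matrix_name: str, gap_open: float, gap_extend: float
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # EMBOSS convention: a gap of length L costs open + L*extend, i.e. the
    # first gap position costs open+extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a: ProteinSequence,
    b: ProteinSequence,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal global alignment of two proteins with affine gap penalties.

    Raises if a residue is absent from the substitution matrix.  The
    reported alignment is PairwiseAligner's first optimum, which is
    deterministic for fixed inputs.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    mat = aligner.substitution_matrix
    alphabet = set(mat.alphabet)
    for prot in (a, b):
        missing = sorted(set(prot.residues) - alphabet)
        if missing:
            raise ValueError(
                f"sequence {prot.id!r}: residues {missing} absent from {matrix}"
            )
    alignment = aligner.align(a.residues, b.residues)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    n_ident = 0
    n_sim = 0
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            continue
        if x == y:
            n_ident += 1
        if mat[x, y] > 0:
            n_sim += 1
    alen = len(ga)
    return AlignmentResult(
        aligned_a=ga,
        aligned_b=gb,
        score=float(alignment.score),
        identity=100.0 * n_ident / alen,
        similarity=100.0 * n_sim / alen,
        n_identical=n_ident,
        n_similar=n_sim,
    )


def pairwise_identity_short(a: ProteinSequence, b: ProteinSequence, **kwargs) -> float:
    """CD-HIT-style identity: identical aligned pairs / length of the shorter sequence."""
    res = global_align(a, b, **kwargs)
    return res.n_identical / min(len(a), len(b))


def greedy_cluster(
    seqs: Sequence[ProteinSequence],
    threshold: float = 0.99,
    **align_kwargs,
) -> List[Cluster]:
    """Greedy incremental clustering at an identity threshold.

    Sequences are sorted by length descending (ties by id); the first seeds
    a cluster, and each subsequent sequence joins the first seed it matches
    at identity >= threshold, else seeds a new cluster.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(seqs, key=lambda s: (-len(s), s.id))
    clusters: List[Cluster] = []
    for seq in ordered:
        placed = False
        for cluster in clusters:
            ident = pairwise_identity_short(cluster.representative, seq, **align_kwargs)
            if ident >= threshold:
                cluster.members.append(seq)
                cluster.identities.append(ident)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=seq, members=[seq], identities=[1.0]))
    return clusters
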