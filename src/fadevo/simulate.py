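"""Mechanistic codon-model simulation and biased-genome sampling.

The simulator supplies every synthetic input of known ground truth used in
this package:

* :func:`simulate_alignment` evolves codon sequences along a tree under a
  GY94-style Markov model with per-branch omega (dN/dS), via the exact
  matrix exponential of the rate matrix (eigendecomposition of the
  reversible-similarity-transformed matrix — exact at this state-space
  size, no step-size tuning);
* :func:`sample_biased_genome` draws iid genes whose third-position
  composition is tilted toward a GC3 target, emulating an AT-rich
  *Tetrahymena*-like genome (and, with a shifted target, an "alien" gene
  set as an HGT positive control);
* :func:`duplication_scenario` bundles a two-clade tree with one relaxed
  post-duplication stem branch (omega 0.48 over a 0.06 purifying
  background by default) together with a simulated alignment and the true
  per-branch omega map.

All randomness flows from one seeded numpy Generator; identical
configurations produce identical output bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .codes import GeneticCode, genetic_code
from .seqio import CodingSequence, Phylogeny, TreeNode

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


# --------------------------------------------------------------------------- #
# Model
# --------------------------------------------------------------------------- #

def f1x4_frequencies(code: GeneticCode, gc: float = 0.5) -> np.ndarray:
    """F1x4 stationary codon frequencies from a single-nucleotide GC fraction.

    Nucleotide frequencies are G = C = gc/2 and A = T = (1-gc)/2 at all
    three positions; codon frequencies are the products, restricted to
    sense codons and renormalized.
    """
    if not (0 < gc < 1):
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    p = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    pi = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in code.sense_codons])
    return pi / pi.sum()


def uniform_frequencies(code: GeneticCode) -> np.ndarray:
    n = len(code.sense_codons)
    return np.full(n, 1.0 / n)


@dataclass
class CodonModel:
    """GY94-style codon substitution model with per-branch omega overrides."""

    code: GeneticCode
    kappa: float = 2.0
    pi: np.ndarray = None  # type: ignore[assignment]
    omega_default: float = 1.0
    omega_by_branch: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if self.omega_default < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega_default}")
        if self.pi is None:
            self.pi = uniform_frequencies(self.code)
        self.pi = np.asarray(self.pi, dtype=float)
        if len(self.pi) != len(self.code.sense_codons):
            raise ValueError("pi must have one entry per sense codon")

    def omega_for(self, branch_label: str) -> float:
        return self.omega_by_branch.get(branch_label, self.omega_default)


def build_rate_matrix(model: CodonModel, omega: Optional[float] = None) -> np.ndarray:
    """GY94 rate matrix over sense codons, scaled to unit mean rate.

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous] for codon
    pairs differing at exactly one position, 0 otherwise; the diagonal
    makes rows sum to 0 and the matrix is rescaled so the expected number
    of substitutions per codon per unit branch length is 1 at stationarity.
    """
    code = model.code
    pi = model.pi
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError(f"pi must sum to 1 (got {pi.sum():.12f})")
    if np.any(pi < 0):
        raise ValueError("pi entries must be non-negative")
    if omega is None:
        omega = model.omega_default
    codons = code.sense_codons
    n = len(codons)
    Q = np.zeros((n, n))
    for i, ci in enumerate(codons):
        aa_i = code.translate_codon(ci)
        for j, cj in enumerate(codons):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            rate = pi[j]
            if diffs[0] in _TRANSITIONS:
                rate *= model.kappa
            if code.translate_codon(cj) != aa_i:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.dot(pi, np.diag(Q))
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix (zero mean rate)")
    return Q / mean_rate


def transition_probabilities(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(tQ) via eigendecomposition of the pi-symmetrized matrix.

    The GY94 matrix is time-reversible, so D^{1/2} Q D^{-1/2} (D = diag pi)
    is symmetric and has a real eigendecomposition; the exponential is
    exact up to floating point.  Rows are clipped at 0 and renormalized to
    absorb roundoff.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if t == 0:
        return np.eye(len(pi))
    d = np.sqrt(pi)
    sym = (Q * d[:, None]) / d[None, :]
    sym = (sym + sym.T) / 2  # enforce exact symmetry against roundoff
    w, v = np.linalg.eigh(sym)
    P = (v * np.exp(w * t)) @ v.T
    P = P / d[:, None] * d[None, :]
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------- #
# Simulation along a tree
# --------------------------------------------------------------------------- #

@dataclass
class SimulationConfig:
    """Everything that determines one simulated alignment."""

    seed: int
    n_codons: int
    tree: Phylogeny
    model: CodonModel
    include_internal: bool = False


def _sample_children(P: np.ndarray, parent_states: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(len(parent_states))
    rows = cum[parent_states]
    return (rows > u[:, None]).argmax(axis=1)


def simulate_alignment(config: SimulationConfig) -> Dict[str, str]:
    """Simulate codon sequences at the tips (and optionally internal nodes).

    The root is drawn iid from pi; each branch evolves under the matrix
    exponential of (branch length x rate matrix with that branch's omega).
    Returns a map node label -> nucleotide string (gap-free).
    """
    rng = np.random.default_rng(config.seed)
    model = config.model
    codons = model.code.sense_codons
    n_states = len(codons)
    states: Dict[str, np.ndarray] = {}
    root = config.tree.root
    states[root.label] = rng.choice(n_states, size=config.n_codons, p=model.pi)
    q_cache: Dict[float, np.ndarray] = {}
    for node in config.tree.preorder():
        if node.parent is None:
            continue
        omega = model.omega_for(node.label)
        if omega not in q_cache:
            q_cache[omega] = build_rate_matrix(model, omega=omega)
        if node.length == 0:
            states[node.label] = states[node.parent.label].copy()
        else:
            P = transition_probabilities(q_cache[omega], model.pi, node.length)
            states[node.label] = _sample_children(P, states[node.parent.label], rng)
    wanted = (
        list(config.tree.preorder())
        if config.include_internal
        else config.tree.leaves()
    )
    return {
        n.label: "".join(codons[s] for s in states[n.label]) for n in wanted
    }


# --------------------------------------------------------------------------- #
# Biased-genome sampler
# --------------------------------------------------------------------------- #

def sample_biased_genome(
    n_genes: int,
    codons_per_gene: int,
    gc3_target: float,
    seed: int,
    code: Optional[GeneticCode] = None,
    id_prefix: str = "gene",
) -> List[CodingSequence]:
    """Draw iid genes with third-position composition tilted toward a GC3 target.

    Amino acids are uniform over the code's synonymous families; within a
    family the codon is chosen with third-position nucleotide weights
    G = C = gc3_target/2 and A = T = (1 - gc3_target)/2, renormalized over
    the family's available third positions.  No stop codons are produced.
    """
    if not (0 < gc3_target < 1):
        raise ValueError(f"gc3_target must be in (0, 1), got {gc3_target}")
    if code is None:
        code = genetic_code(1)
    rng = np.random.default_rng(seed)
    weight = {
        "G": gc3_target / 2, "C": gc3_target / 2,
        "A": (1 - gc3_target) / 2, "T": (1 - gc3_target) / 2,
    }
    families = [code.families[aa] for aa in sorted(code.families)]
    fam_codons: List[np.ndarray] = []
    fam_probs: List[np.ndarray] = []
    for fam in families:
        w = np.array([weight[c[2]] for c in fam])
        fam_codons.append(np.array(fam))
        fam_probs.append(w / w.sum())
    genes: List[CodingSequence] = []
    n_fam = len(families)
    for g in range(n_genes):
        fam_idx = rng.integers(0, n_fam, size=codons_per_gene)
        out = np.empty(codons_per_gene, dtype=object)
        for f in range(n_fam):
            mask = fam_idx == f
            k = int(mask.sum())
            if k:
                out[mask] = rng.choice(fam_codons[f], size=k, p=fam_probs[f])
        genes.append(
            CodingSequence(
                id=f"{id_prefix}{g:04d}",
                nucleotides="".join(out.tolist()),
                code=code,
            )
        )
    return genes


# --------------------------------------------------------------------------- #
# Duplication scenario
# --------------------------------------------------------------------------- #

@dataclass
class DuplicationBundle:
    """A duplication-scenario dataset with ground truth."""

    tree: Phylogeny
    alignment: Dict[str, str]          # leaf label -> nucleotides
    true_omega: Dict[str, float]       # branch (child label) -> omega
    stem_label: str
    model: CodonModel
    seed: int
    n_codons: int


def _ladder(labels: Sequence[str], tip_len: float, internal_len: float,
            prefix: str) -> TreeNode:
    """A ladder (caterpillar) subtree over the given tip labels."""
    node = TreeNode(label=labels[0], length=tip_len)
    for i, lab in enumerate(labels[1:], start=1):
        tip = TreeNode(label=lab, length=tip_len)
        parent = TreeNode(label=f"{prefix}{i}", length=internal_len)
        for child in (node, tip):
            child.parent = parent
            parent.children.append(child)
        node = parent
    return node


def duplication_tree(
    n_tips_per_clade: int = 10,
    stem_length: float = 0.3,
    tip_length: float = 0.05,
    internal_length: float = 0.05,
) -> Tuple[Phylogeny, str]:
    """Two-clade tree with a labeled stem branch under one clade.

    Clade A tips are a1..aN, clade B tips b1..bN; the branch leading to
    clade B (label "stem") models the post-duplication stem.  Returns
    (tree, stem label).
    """
    a = _ladder([f"a{i+1}" for i in range(n_tips_per_clade)],
                tip_length, internal_length, "A")
    b = _ladder([f"b{i+1}" for i in range(n_tips_per_clade)],
                tip_length, internal_length, "B")
    a.length = internal_length
    b.length = stem_length
    b.label = "stem" if b.children else b.label
    root = TreeNode(label="root", length=0.0)
    for child in (a, b):
        child.parent = root
        root.children.append(child)
    return Phylogeny(root), b.label


def duplication_scenario(
    seed: int,
    n_codons: int = 300,
    n_tips_per_clade: int = 10,
    background_omega: float = 0.06,
    stem_omega: float = 0.48,
    kappa: float = 2.0,
    gc3: float = 0.25,
    stem_length: float = 0.3,
) -> DuplicationBundle:
    """Simulated gene family evolved under purifying selection except for a
    relaxed post-duplication stem branch.

    Defaults follow the study conditions: background omega 0.06, stem
    omega 0.48, 300 codons, kappa 2, 20 tips, AT-rich composition.
    """
    code = genetic_code(1)
    tree, stem_label = duplication_tree(
        n_tips_per_clade=n_tips_per_clade, stem_length=stem_length
    )
    model = CodonModel(
        code=code,
        kappa=kappa,
        pi=f1x4_frequencies(code, gc=gc3),
        omega_default=background_omega,
        omega_by_branch={stem_label: stem_omega},
    )
    config = SimulationConfig(seed=seed, n_codons=n_codons, tree=tree, model=model)
    alignment = simulate_alignment(config)
    true_omega = {
        child.label: model.omega_for(child.label)
        for _, child in tree.branches()
    }
    return DuplicationBundle(
        tree=tree,
        alignment=alignment,
        true_omega=true_omega,
        stem_label=stem_label,
        model=model,
        seed=seed,
        n_codons=n_codons,
    )
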