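"""dN/dS estimation by the Nei-Gojobori (NG86) counting method.

Two layers:

* pairwise NG86 — fractional synonymous/nonsynonymous site counts per
  codon, pathway-averaged difference counts per codon pair, and
  Jukes-Cantor correction of the proportions into distances;
* a free-ratio-style per-branch screen — ancestral codon sequences are
  reconstructed by Fitch parsimony over the sense-codon state set, then
  every (parent, child) branch gets its own NG86 estimate, with named
  clades aggregated by pooling raw counts before distance correction.

This is a deliberately self-contained counting approximation to an ML
free-ratio codon-model fit: it reproduces the qualitative contrast between
a purifying background and a relaxed post-duplication stem, and is exactly
testable against enumeration oracles; numerical equality with an ML fit is
not claimed.

Stop-codon handling follows standard NG86 practice: mutational target
changes into stop codons are excluded with the remaining site mass
renormalized, and mutational pathways passing through a stop codon are
discarded (codon pairs whose every minimal pathway is blocked are skipped
and tallied).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .codes import NUCLEOTIDES, GeneticCode, genetic_code
from .seqio import CodingSequence, Phylogeny, logger


# --------------------------------------------------------------------------- #
# Site counting
# --------------------------------------------------------------------------- #

@lru_cache(maxsize=None)
def _sites_table(table_id: int) -> Dict[str, Tuple[float, float]]:
    code = genetic_code(table_id)
    out: Dict[str, Tuple[float, float]] = {}
    for codon in code.sense_codons:
        aa = code.translate_codon(codon)
        s = 0.0
        n = 0.0
        for pos in range(3):
            syn = 0
            viable = 0
            for base in NUCLEOTIDES:
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1 :]
                if code.is_stop(alt):
                    continue
                viable += 1
                if code.translate_codon(alt) == aa:
                    syn += 1
            if viable == 0:
                continue  # position contributes 0 site mass
            s += syn / viable
            n += 1 - syn / viable
        out[codon] = (s, n)
    return out


def pathway_differences(
    codon_a: str, codon_b: str, code: GeneticCode
) -> Optional[Tuple[float, float]]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for one codon pair.

    Averages over all minimal mutational pathways that avoid stop codons;
    None when every pathway is blocked.
    """
    for c in (codon_a, codon_b):
        if code.is_stop(c):
            raise ValueError(f"{c} is a stop codon under table {code.table_id}")
    return _diff_table(code.table_id)[(codon_a, codon_b)]


def ng86_sites(codon: str, code: GeneticCode) -> Tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) for one sense codon.

    Each of the three positions carries one site of mass, split by the
    fraction of viable (non-stop) single-nucleotide changes that are
    synonymous; if all three changes at a position create stops the
    position contributes nothing, so s + n <= 3.
    """
    if code.is_stop(codon):
        raise ValueError(f"{codon} is a stop codon under table {code.table_id}")
    return _sites_table(code.table_id)[codon]


# --------------------------------------------------------------------------- #
# Pathway-averaged difference counting
# --------------------------------------------------------------------------- #

@lru_cache(maxsize=None)
def _diff_table(table_id: int) -> Dict[Tuple[str, str], Optional[Tuple[float, float]]]:
    """(codon_a, codon_b) -> pathway-averaged (syn_diffs, nonsyn_diffs).

    Averaged over all minimal mutational pathways (orderings of the
    differing positions) that do not pass through a stop codon; None when
    every pathway is blocked.
    """
    code = genetic_code(table_id)
    out: Dict[Tuple[str, str], Optional[Tuple[float, float]]] = {}
    for a in code.sense_codons:
        for b in code.sense_codons:
            diff_pos = [i for i in range(3) if a[i] != b[i]]
            if not diff_pos:
                out[(a, b)] = (0.0, 0.0)
                continue
            path_counts: List[Tuple[int, int]] = []
            for order in permutations(diff_pos):
                cur = a
                sd = nd = 0
                ok = True
                for pos in order:
                    nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                    if code.is_stop(nxt):
                        ok = False
                        break
                    if code.translate_codon(nxt) == code.translate_codon(cur):
                        sd += 1
                    else:
                        nd += 1
                    cur = nxt
                if ok:
                    path_counts.append((sd, nd))
            if not path_counts:
                out[(a, b)] = None
            else:
                k = len(path_counts)
                out[(a, b)] = (
                    sum(p[0] for p in path_counts) / k,
                    sum(p[1] for p in path_counts) / k,
                )
    return out


@dataclass
class NG86Result:
    """Site counts, difference counts, corrected distances and omega."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: Optional[float]
    pN: Optional[float]
    dS: Optional[float]
    dN: Optional[float]
    omega: Optional[float]
    n_codons: int = 0
    skipped_blocked: int = 0   # codon pairs with every pathway stop-blocked
    skipped_gap: int = 0       # codon pairs dropped because of a gap


def _jc_correct(p: float, name: str) -> float:
    if p >= 0.75:
        raise ValueError(
            f"{name} correction undefined: proportion {p:.4f} >= 3/4 "
            "(sequences too divergent for Jukes-Cantor)"
        )
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86_codons(
    codons_a: Sequence[str],
    codons_b: Sequence[str],
    code: GeneticCode,
) -> NG86Result:
    """NG86 estimate from two aligned codon lists (gap codons dropped pairwise)."""
    if len(codons_a) != len(codons_b):
        raise ValueError(
            f"aligned codon lists differ in length ({len(codons_a)} vs {len(codons_b)})"
        )
    sites = _sites_table(code.table_id)
    diffs = _diff_table(code.table_id)
    sa = na = sb = nb = 0.0
    Sd = Nd = 0.0
    used = 0
    skipped_blocked = 0
    skipped_gap = 0
    for ca, cb in zip(codons_a, codons_b):
        if "-" in ca or "-" in cb:
            skipped_gap += 1
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            raise ValueError(f"stop codon in aligned pair ({ca}, {cb})")
        d = diffs[(ca, cb)]
        if d is None:
            skipped_blocked += 1
            continue
        s1, n1 = sites[ca]
        s2, n2 = sites[cb]
        sa += s1
        na += n1
        sb += s2
        nb += n2
        Sd += d[0]
        Nd += d[1]
        used += 1
    if used == 0:
        raise ValueError("no comparable codon pairs (all gapped or stop-blocked)")
    S = (sa + sb) / 2
    N = (na + nb) / 2
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    dS = _jc_correct(pS, "dS") if pS is not None else None
    dN = _jc_correct(pN, "dN") if pN is not None else None
    omega = (dN / dS) if (dS is not None and dN is not None and dS > 0) else None
    return NG86Result(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=dS, dN=dN, omega=omega,
        n_codons=used, skipped_blocked=skipped_blocked, skipped_gap=skipped_gap,
    )


def ng86_pair(a: CodingSequence, b: CodingSequence) -> NG86Result:
    """Pairwise NG86 for two equal-length coding sequences under one code."""
    if a.code.table_id != b.code.table_id:
        raise ValueError(
            f"sequences use different code tables ({a.code.table_id} vs {b.code.table_id})"
        )
    return ng86_codons(a.codons, b.codons, a.code)


# --------------------------------------------------------------------------- #
# Fitch parsimony ancestral codons
# --------------------------------------------------------------------------- #

def fitch_ancestral(
    tree: Phylogeny,
    tip_codons: Mapping[str, Sequence[str]],
    code: GeneticCode,
) -> Tuple[Dict[str, List[str]], int]:
    """Fitch parsimony codon reconstruction at every internal node.

    Per codon column, the bottom-up pass builds state sets over sense
    codons (intersection of children when non-empty, else union); the
    top-down pass assigns the root its set's lexicographically smallest
    state and each child its parent's state when possible, else its own
    set's smallest.  Columns containing a gap in any tip are dropped from
    every sequence (complete deletion, logged).

    Returns (sequences for all nodes keyed by label, total parsimony length).
    """
    leaves = tree.leaves()
    missing = [n.label for n in leaves if n.label not in tip_codons]
    if missing:
        raise ValueError(f"leaves without tip sequences: {missing}")
    lengths = {lab: len(tip_codons[lab]) for lab in (n.label for n in leaves)}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"tip codon sequences differ in length: {lengths}")
    n_cols = next(iter(lengths.values()))

    keep: List[int] = []
    for col in range(n_cols):
        gapped = False
        for leaf in leaves:
            codon = tip_codons[leaf.label][col]
            if "-" in codon:
                gapped = True
                break
            if code.is_stop(codon):
                raise ValueError(
                    f"stop codon {codon} at column {col} in tip {leaf.label!r}"
                )
            if codon not in code.codon_to_aa:
                raise ValueError(f"invalid codon {codon!r} at column {col}")
        if gapped:
            continue
        keep.append(col)
    if len(keep) < n_cols:
        logger.info("fitch_ancestral: dropped %d gapped columns of %d", n_cols - len(keep), n_cols)
    if not keep:
        raise ValueError("no gap-free codon columns to reconstruct")

    post = list(tree.postorder())
    pre = list(tree.preorder())
    assigned: Dict[str, List[str]] = {n.label: [] for n in pre}
    total_changes = 0
    for col in keep:
        state_sets: Dict[str, frozenset] = {}
        for node in post:
            if node.is_leaf:
                state_sets[node.label] = frozenset((tip_codons[node.label][col],))
            else:
                sets = [state_sets[c.label] for c in node.children]
                inter = frozenset.intersection(*sets)
                if inter:
                    state_sets[node.label] = inter
                else:
                    union = frozenset.union(*sets)
                    state_sets[node.label] = union
                    total_changes += 1
        for node in pre:
            sset = state_sets[node.label]
            if node.parent is None:
                state = min(sset)
            else:
                parent_state = assigned[node.parent.label][-1]
                state = parent_state if parent_state in sset else min(sset)
            assigned[node.label].append(state)
    return assigned, total_changes


# --------------------------------------------------------------------------- #
# Per-branch omega
# --------------------------------------------------------------------------- #

@dataclass
class BranchOmegaTable:
    """Per-branch NG86 results plus pooled clade aggregates.

    Clade aggregates pool raw S, N, Sd, Nd over member branches before the
    Jukes-Cantor correction; omegas are never averaged.
    """

    branches: pd.DataFrame
    clades: pd.DataFrame
    ancestral: Dict[str, List[str]] = field(default_factory=dict)
    parsimony_length: int = 0


def _pool_to_row(name: str, S: float, N: float, Sd: float, Nd: float,
                 n_branches: int) -> Dict[str, object]:
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    dS = _jc_correct(pS, "dS") if pS is not None else None
    dN = _jc_correct(pN, "dN") if pN is not None else None
    omega = (dN / dS) if (dS is not None and dN is not None and dS > 0) else None
    return {
        "clade": name, "n_branches": n_branches, "S": S, "N": N, "Sd": Sd,
        "Nd": Nd, "dS": dS, "dN": dN, "omega": omega,
    }


def branch_omega(
    tree: Phylogeny,
    tip_codons: Mapping[str, Sequence[str]],
    code: GeneticCode,
    clades: Optional[Mapping[str, Sequence[str]]] = None,
) -> BranchOmegaTable:
    """Free-ratio-style per-branch NG86 screen on parsimony ancestors.

    ``clades`` maps a clade name to a list of node labels (typically leaf
    labels); the clade's branch set is the induced subtree's branches and
    its pooled omega sums raw counts over those branches.  A clade name
    may also name a single branch by its child node label.
    """
    if clades:
        for name, labels in clades.items():
            bad = [lab for lab in labels if lab not in tree]
            if bad:
                raise ValueError(f"clade {name!r} names unknown node labels: {bad}")
    sequences, parsimony_length = fitch_ancestral(tree, tip_codons, code)
    rows = []
    per_branch: Dict[str, NG86Result] = {}
    for parent, child in tree.branches():
        res = ng86_codons(sequences[parent.label], sequences[child.label], code)
        per_branch[child.label] = res
        child.annotations["omega"] = res.omega
        rows.append(
            {
                "parent": parent.label, "child": child.label,
                "branch_length": child.length,
                "S": res.S, "N": res.N, "Sd": res.Sd, "Nd": res.Nd,
                "dS": res.dS, "dN": res.dN, "omega": res.omega,
            }
        )
    branch_df = pd.DataFrame(rows)
    clade_rows = []
    if clades:
        for name, labels in clades.items():
            bad = [lab for lab in labels if lab not in tree]
            if bad:
                raise ValueError(f"clade {name!r} names unknown node labels: {bad}")
            if len(labels) == 1:
                edges = [(tree.node(labels[0]).parent, tree.node(labels[0]))]
                if edges[0][0] is None:
                    raise ValueError(f"clade {name!r} names the root; it has no branch")
            else:
                edges = tree.clade_branches(list(labels))
            S = N = Sd = Nd = 0.0
            for _, child in edges:
                res = per_branch[child.label]
                S += res.S
                N += res.N
                Sd += res.Sd
                Nd += res.Nd
            clade_rows.append(_pool_to_row(name, S, N, Sd, Nd, len(edges)))
    clade_df = pd.DataFrame(
        clade_rows,
        columns=["clade", "n_branches", "S", "N", "Sd", "Nd", "dS", "dN", "omega"],
    )
    return BranchOmegaTable(
        branches=branch_df,
        clades=clade_df,
        ancestral=sequences,
        parsimony_length=parsimony_length,
    )
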