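"""Independent brute-force oracles used to validate the implementation.

Everything here is written from the definitions, deliberately avoiding the
library's own algorithms: the motif oracle enumerates element expansions
explicitly, the alignment oracle enumerates whole alignments, the NG86
oracles enumerate single-nucleotide changes and mutational pathways with
their own bookkeeping, and the Fitch oracle minimizes over all internal
labelings.
"""

from __future__ import annotations

import math
from itertools import product, permutations
from typing import Dict, List, Optional, Sequence, Tuple

from fadevo.codes import NUCLEOTIDES, GeneticCode
from fadevo.motif import PatternElement, PrositePattern
from fadevo.seqio import Phylogeny


# --------------------------------------------------------------------------- #
# Motif scanning
# --------------------------------------------------------------------------- #

def motif_matches_naive(pattern: PrositePattern, seq: str) -> List[Tuple[int, int]]:
    """All (start, end) matches, one per start, first success in
    lexicographic shortest-first expansion order.

    Recursive enumeration: element i is tried at every repeat count from
    its minimum upward, in order, and the first full-pattern success wins.
    """

    def elem_ok(el: PatternElement, piece: str) -> bool:
        return all(el.matches(c) for c in piece)

    def try_from(idx: int, pos: int) -> Optional[int]:
        if idx == len(pattern.elements):
            return pos
        el = pattern.elements[idx]
        for rep in range(el.min_repeat, el.max_repeat + 1):
            if pos + rep > len(seq):
                break
            if not elem_ok(el, seq[pos : pos + rep]):
                # a residue failing at offset k fails every expansion with
                # rep > k as well, so no longer expansion can succeed
                break
            end = try_from(idx + 1, pos + rep)
            if end is not None:
                return end
        return None

    out = []
    for start in range(len(seq) + 1):
        end = try_from(0, start)
        if end is not None:
            out.append((start, end))
    return out


# --------------------------------------------------------------------------- #
# Global alignment
# --------------------------------------------------------------------------- #

def best_alignment_score_bruteforce(
    a: str, b: str, score: Dict[Tuple[str, str], float],
    gap_open: float, gap_extend: float,
) -> float:
    """Optimal global affine-gap score by enumerating every alignment.

    A gap of length L costs gap_open + L * gap_extend (EMBOSS convention).
    Exponential; only for len <= 6.
    """
    best = [-math.inf]

    def rec(i: int, j: int, total: float, prev: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], total)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, total + score[(a[i], b[j])], "m")
        if i < len(a):
            cost = gap_extend if prev == "a" else gap_open + gap_extend
            rec(i + 1, j, total - cost, "a")
        if j < len(b):
            cost = gap_extend if prev == "b" else gap_open + gap_extend
            rec(i, j + 1, total - cost, "b")

    rec(0, 0, 0.0, "m")
    return best[0]


# --------------------------------------------------------------------------- #
# NG86
# --------------------------------------------------------------------------- #

def ng86_sites_naive(codon: str, code: GeneticCode) -> Tuple[float, float]:
    """(s, n) for one codon by direct enumeration of the 9 changes."""
    aa = code.translate_codon(codon)
    s = n = 0.0
    for pos in range(3):
        outcomes = []
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if not code.is_stop(alt):
                outcomes.append(code.translate_codon(alt) == aa)
        if outcomes:
            frac_syn = sum(outcomes) / len(outcomes)
            s += frac_syn
            n += 1.0 - frac_syn
    return s, n


def ng86_pair_naive(
    codons_a: Sequence[str], codons_b: Sequence[str], code: GeneticCode
) -> Dict[str, float]:
    """Full NG86 on two aligned codon lists, written independently.

    Pathways are generated as permutations of the differing positions;
    pathways that visit a stop codon are discarded; codon pairs with no
    surviving pathway are skipped.
    """
    S_a = N_a = S_b = N_b = 0.0
    Sd = Nd = 0.0
    skipped = 0
    used = 0
    for ca, cb in zip(codons_a, codons_b):
        positions = [p for p in range(3) if ca[p] != cb[p]]
        paths = []
        for order in permutations(positions):
            current = ca
            sd = nd = 0
            blocked = False
            for p in order:
                nxt = current[:p] + cb[p] + current[p + 1 :]
                if code.is_stop(nxt):
                    blocked = True
                    break
                if code.translate_codon(nxt) == code.translate_codon(current):
                    sd += 1
                else:
                    nd += 1
                current = nxt
            if not blocked:
                paths.append((sd, nd))
        if positions and not paths:
            skipped += 1
            continue
        used += 1
        if paths:
            Sd += sum(p[0] for p in paths) / len(paths)
            Nd += sum(p[1] for p in paths) / len(paths)
        sa, na = ng86_sites_naive(ca, code)
        sb, nb = ng86_sites_naive(cb, code)
        S_a += sa
        N_a += na
        S_b += sb
        N_b += nb
    S = (S_a + S_b) / 2
    N = (N_a + N_b) / 2
    out = {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "n_codons": used, "skipped": skipped}
    pS = Sd / S
    pN = Nd / N
    out["dS"] = -0.75 * math.log(1 - 4 * pS / 3) if pS < 0.75 else math.nan
    out["dN"] = -0.75 * math.log(1 - 4 * pN / 3) if pN < 0.75 else math.nan
    return out


# --------------------------------------------------------------------------- #
# Fitch parsimony
# --------------------------------------------------------------------------- #

def min_changes_bruteforce(
    tree: Phylogeny, tip_states: Dict[str, str], states: Sequence[str]
) -> int:
    """Minimum number of state changes over all internal-node labelings."""
    internal = [n for n in tree.preorder() if not n.is_leaf]
    best = math.inf
    for labels in product(states, repeat=len(internal)):
        assign = {n.label: s for n, s in zip(internal, labels)}
        assign.update(tip_states)
        changes = sum(
            assign[p.label] != assign[c.label] for p, c in tree.branches()
        )
        best = min(best, changes)
    return int(best)
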