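"""Sequence and tree I/O, CDS validation and translation.

FASTA reading/writing goes through Bio.SeqIO; Newick parsing goes through
dendropy, wrapped into a light :class:`Phylogeny` whose nodes carry labels,
branch lengths and free-form annotations (per-branch omega estimates live
there later).  Coordinates everywhere are 0-based, half-open.
"""

from __future__ import annotations

import io
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codes import STOP, GeneticCode, genetic_code

logger = logging.getLogger("fadevo")
if not logger.handlers:  # log to stderr, never stdout
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)

# IUPAC nucleotide letters (after U->T mapping) plus alignment gap.
_NUC_ALPHABET = set("ACGTNRYSWKMBDHV-")
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_PROT_ALPHABET = set(_AA20 + "X-")


@dataclass
class FastaRecord:
    """One FASTA record; ``id`` is the header token up to the first whitespace."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ProteinSequence:
    """A protein sequence over the 20 amino acids plus X (no stop characters)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein sequence {self.id!r} is empty")
        bad = [(i, c) for i, c in enumerate(self.residues) if c not in _PROT_ALPHABET or c == "-"]
        if bad:
            i, c = bad[0]
            raise ValueError(
                f"protein sequence {self.id!r}: illegal residue {c!r} at position {i}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class CodingSequence:
    """A validated protein-coding nucleotide sequence bound to a genetic code.

    The terminal stop codon, if present in the input, is stripped and
    recorded in ``had_terminal_stop``.  Internal stops are construction
    errors (see :func:`validate_cds`), so every codon here is a sense codon.
    """

    id: str
    nucleotides: str
    code: GeneticCode
    had_terminal_stop: bool = False

    @property
    def codons(self) -> List[str]:
        s = self.nucleotides
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    def __len__(self) -> int:
        return len(self.nucleotides)


# --------------------------------------------------------------------------- #
# FASTA
# --------------------------------------------------------------------------- #

def read_fasta(path: Union[str, Path], alphabet: str = "nucleotide") -> List[FastaRecord]:
    """Read a FASTA file, preserving record order.

    Sequences are upper-cased; for nucleotide input U is mapped to T.
    Duplicate ids and characters outside the alphabet are errors.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"alphabet must be 'nucleotide' or 'protein', got {alphabet!r}")
    allowed = _NUC_ALPHABET if alphabet == "nucleotide" else _PROT_ALPHABET
    records: List[FastaRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "nucleotide":
            seq = seq.replace("U", "T")
        for i, c in enumerate(seq):
            if c not in allowed:
                raise ValueError(
                    f"record {rec.id!r}: illegal {alphabet} character {c!r} at position {i}"
                )
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(FastaRecord(id=rec.id, seq=seq))
    return records


def write_fasta(records: Iterable[FastaRecord], path: Union[str, Path], width: int = 60) -> None:
    """Write records as FASTA (fixed line width, order preserved)."""
    seqrecords = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


# --------------------------------------------------------------------------- #
# CDS validation and translation
# --------------------------------------------------------------------------- #

def validate_cds(
    record: Union[FastaRecord, Tuple[str, str]],
    code: Union[GeneticCode, int] = 1,
) -> CodingSequence:
    """Validate a raw nucleotide sequence as a CDS under *code*.

    Rules: length divisible by 3; only A/C/G/T (ambiguity characters,
    including N, are rejected with their positions); no internal stop codon;
    a terminal stop is stripped and recorded.
    """
    if isinstance(code, int):
        code = genetic_code(code)
    seq_id, seq = (record.id, record.seq) if isinstance(record, FastaRecord) else record
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS {seq_id!r}: length {len(seq)} is not divisible by 3")
    bad = [i for i, c in enumerate(seq) if c not in "ACGT"]
    if bad:
        shown = ", ".join(str(i) for i in bad[:10])
        more = "" if len(bad) <= 10 else f" (and {len(bad) - 10} more)"
        raise ValueError(f"CDS {seq_id!r}: ambiguity/illegal characters at positions {shown}{more}")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    had_terminal_stop = False
    if codons and code.is_stop(codons[-1]):
        had_terminal_stop = True
        codons = codons[:-1]
    for idx, codon in enumerate(codons):
        if code.is_stop(codon):
            raise ValueError(
                f"CDS {seq_id!r}: internal stop codon {codon} at codon index {idx} "
                f"(table {code.table_id})"
            )
    return CodingSequence(
        id=seq_id,
        nucleotides="".join(codons),
        code=code,
        had_terminal_stop=had_terminal_stop,
    )


def translate(cds: CodingSequence) -> ProteinSequence:
    """Translate a validated CDS, one residue per codon under its bound code."""
    residues = "".join(cds.code.translate_codon(c) for c in cds.codons)
    if STOP in residues:  # unreachable for sequences built via validate_cds
        raise ValueError(f"CDS {cds.id!r} contains an internal stop codon")
    return ProteinSequence(id=cds.id, residues=residues)


# --------------------------------------------------------------------------- #
# Trees
# --------------------------------------------------------------------------- #

@dataclass
class TreeNode:
    label: str
    length: float = 0.0
    parent: Optional["TreeNode"] = None
    children: List["TreeNode"] = field(default_factory=list)
    annotations: Dict[str, object] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TreeNode({self.label!r}, length={self.length})"


class Phylogeny:
    """A rooted node-labeled tree with non-negative branch lengths.

    Internal nodes without input labels get stable generated labels
    ("N1", "N2", ... in preorder).  Leaf labels are unique and match
    sequence ids when the tree is bound to an alignment.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._index: Dict[str, TreeNode] = {}
        for node in self.preorder():
            if node.label in self._index:
                raise ValueError(f"duplicate node label {node.label!r}")
            if node.length < 0:
                raise ValueError(f"negative branch length on node {node.label!r}")
            self._index[node.label] = node

    # -- traversal ----------------------------------------------------- #

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: List[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    def leaves(self) -> List[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> List[str]:
        return [n.label for n in self.leaves()]

    def branches(self) -> List[Tuple[TreeNode, TreeNode]]:
        """All (parent, child) pairs, in preorder of the child."""
        return [(n.parent, n) for n in self.preorder() if n.parent is not None]

    def node(self, label: str) -> TreeNode:
        try:
            return self._index[label]
        except KeyError as exc:
            raise KeyError(f"no node labeled {label!r} in tree") from exc

    def __contains__(self, label: str) -> bool:
        return label in self._index

    # -- queries -------------------------------------------------------- #

    def mrca(self, labels: Sequence[str]) -> TreeNode:
        """Most recent common ancestor of the named nodes."""
        if not labels:
            raise ValueError("mrca of an empty label set")
        paths = []
        for lab in labels:
            node = self.node(lab)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        anc = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                anc = level[0]
            else:
                break
        assert anc is not None
        return anc

    def clade_branches(self, leaf_labels: Sequence[str]) -> List[Tuple[TreeNode, TreeNode]]:
        """Branches of the subtree induced by a set of leaves.

        The induced subtree is the union of paths from each named leaf up to
        their MRCA; its branches are the (parent, child) edges on those paths.
        """
        anc = self.mrca(leaf_labels)
        edges: List[Tuple[TreeNode, TreeNode]] = []
        seen = set()
        for lab in leaf_labels:
            node = self.node(lab)
            while node is not anc:
                key = node.label
                if key not in seen:
                    seen.add(key)
                    edges.append((node.parent, node))
                node = node.parent
        edges.sort(key=lambda e: e[1].label)
        return edges

    # -- serialization --------------------------------------------------- #

    def to_newick(self, include_internal_labels: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.label
            else:
                inner = ",".join(fmt(c) for c in node.children)
                lab = node.label if include_internal_labels else ""
                body = f"({inner}){lab}"
            if node.parent is None:
                return body
            return f"{body}:{node.length:.10g}"

        return fmt(self.root) + ";"


def _from_dendropy(tree: dendropy.Tree) -> Phylogeny:
    next_anon = [0]

    def label_for(dnode) -> Optional[str]:
        if dnode.taxon is not None and dnode.taxon.label:
            return dnode.taxon.label.replace(" ", "_")
        if dnode.label:
            return str(dnode.label).replace(" ", "_")
        return None

    # preorder numbering for anonymous internal nodes
    def convert(dnode, parent: Optional[TreeNode]) -> TreeNode:
        lab = label_for(dnode)
        if lab is None:
            next_anon[0] += 1
            lab = f"N{next_anon[0]}"
        length = dnode.edge.length
        if length is None:
            if parent is not None:
                logger.warning("node %r has no branch length; defaulting to 0", lab)
            length = 0.0
        node = TreeNode(label=lab, length=float(length), parent=parent)
        if parent is not None:
            parent.children.append(node)
        for child in dnode.child_nodes():
            convert(child, node)
        return node

    root = convert(tree.seed_node, None)
    return Phylogeny(root)


def read_newick(source: Union[str, Path]) -> Phylogeny:
    """Read one Newick tree from a file path or a literal Newick string."""
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("(")):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"failed to parse Newick tree: {exc}") from exc
    phylo = _from_dendropy(tree)
    leaf_labels = phylo.leaf_labels()
    if len(set(leaf_labels)) != len(leaf_labels):
        dupes = sorted({l for l in leaf_labels if leaf_labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels in tree: {dupes}")
    return phylo


def write_newick(tree: Phylogeny, path: Union[str, Path]) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
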