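"""Sequence and tree input handling.

Reads FASTA alignments and NEWICK trees, validates in-frame codon
alignments against a genetic code, and enforces the basal-trichotomy
convention (an unrooted tree represented with a degree-3 root vertex)
that the site-model likelihood machinery expects.

Coordinates are 1-based throughout: codon site 1 is alignment columns 1-3.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO

from .errors import FormatError, UnsupportedTreeError, ValidationError
from .genetic_code import STANDARD_CODE, GeneticCode

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (name, sequence) pairs, order preserved.

    The name is the header up to the first whitespace; sequences are
    upper-cased. Raises :class:`FormatError` on an empty/record-less file
    and :class:`ValidationError` on duplicate names.
    """
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    names = [n for n, _ in records]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValidationError(f"duplicate sequence names: {sorted(dupes)}")
    return records


def read_fasta_string(text: str) -> list[tuple[str, str]]:
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(io.StringIO(text), "fasta")]
    if not records:
        raise FormatError("no FASTA records found in string")
    names = [n for n, _ in records]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValidationError(f"duplicate sequence names: {sorted(dupes)}")
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Codon alignment


@dataclass(frozen=True)
class CodonAlignment:
    """Named, equal-length, in-frame codon sequences.

    ``n_sites`` counts codon columns. Codons containing gaps, Ns or other
    ambiguity codes are treated as partially observed: the likelihood
    marginalizes over every compatible sense codon. A codon whose only
    resolutions are stop codons is rejected at validation time.
    """

    taxon_names: tuple[str, ...]
    sequences: tuple[str, ...]
    code: GeneticCode = field(default=STANDARD_CODE, repr=False)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) // 3

    def codon(self, taxon: int, site: int) -> str:
        """Codon string for 1-based codon ``site`` of taxon index ``taxon``."""
        return self.sequences[taxon][3 * (site - 1) : 3 * site]

    def state_sets(self) -> list[list[list[int]]]:
        """Per taxon, per site: compatible sense-codon state indices."""
        out = []
        for seq in self.sequences:
            row = []
            for s in range(len(seq) // 3):
                row.append(self.code.expand_ambiguous(seq[3 * s : 3 * s + 3]))
            out.append(row)
        return out

    def records(self) -> list[tuple[str, str]]:
        return list(zip(self.taxon_names, self.sequences))


def validate_codon_alignment(records, code: GeneticCode = STANDARD_CODE) -> CodonAlignment:
    """Validate (name, sequence) records into a :class:`CodonAlignment`.

    Checks: nonempty, unique names, equal lengths, length divisible by 3,
    and that no codon decodes *only* to stop codons (an unambiguous TAA/TAG/
    TGA under the standard code fails; an N-containing codon that could be a
    sense codon passes and is treated as partially observed).
    """
    if hasattr(records, "items"):
        records = list(records.items())
    records = [(n, s.upper()) for n, s in records]
    if not records:
        raise ValidationError("empty record set")
    names = [n for n, _ in records]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate taxon names in alignment")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise ValidationError(f"sequences have unequal lengths: {sorted(lengths)}")
    (length,) = lengths
    if length == 0 or length % 3 != 0:
        raise ValidationError(f"alignment length {length} is not a positive multiple of 3")
    for name, seq in records:
        for s in range(length // 3):
            codon = seq[3 * s : 3 * s + 3]
            if not code.expand_ambiguous(codon):
                raise ValidationError(
                    f"stop codon {codon} at codon site {s + 1} in {name!r}"
                )
    return CodonAlignment(
        taxon_names=tuple(names), sequences=tuple(s for _, s in records), code=code
    )


def apply_name_aliases(records: list[tuple[str, str]], path) -> list[tuple[str, str]]:
    """Rename sequences via a two-column (old, new) TSV alias file.

    Names absent from the file pass through unchanged; sequence names are
    otherwise matched to tree tips by exact string equality.
    """
    aliases: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{line_no}: expected two tab-separated columns")
            aliases[parts[0]] = parts[1]
    renamed = [(aliases.get(name, name), seq) for name, seq in records]
    names = [n for n, _ in renamed]
    if len(set(names)) != len(names):
        raise ValidationError("alias mapping produces duplicate names")
    return renamed


def drop_ambiguous_columns(aln: CodonAlignment) -> CodonAlignment:
    """Remove every codon column in which any taxon is ambiguous/missing."""
    keep = []
    for s in range(1, aln.n_sites + 1):
        if all(
            set(aln.codon(t, s)) <= set("ACGT") for t in range(aln.n_taxa)
        ):
            keep.append(s)
    seqs = tuple(
        "".join(aln.codon(t, s) for s in keep) for t in range(aln.n_taxa)
    )
    if not keep:
        raise ValidationError("no unambiguous codon columns remain")
    return CodonAlignment(taxon_names=aln.taxon_names, sequences=seqs, code=aln.code)


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    label: str | None = None
    length: float | None = None  # length of the edge above this node
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self


class Phylogeny:
    """An (un)rooted phylogeny with branch lengths in expected
    substitutions per codon site.

    The likelihood machinery requires the unrooted tree to be presented
    with a degree >= 3 root vertex (the basal trichotomy); use
    :func:`unroot_to_trichotomy` to enforce that.
    """

    def __init__(self, root: TreeNode):
        self.root = root

    # -- basic queries ------------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.root.postorder() if n.is_leaf]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root_degree(self) -> int:
        return len(self.root.children)

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.root.postorder() if n is not self.root)

    def branch_lengths(self) -> list[float | None]:
        """Edge lengths in postorder (root excluded)."""
        return [n.length for n in self.root.postorder() if n is not self.root]

    def with_branch_lengths(self, lengths) -> "Phylogeny":
        """Copy of the tree with postorder edge lengths replaced."""
        new = self.copy()
        nodes = [n for n in new.root.postorder() if n is not new.root]
        if len(nodes) != len(lengths):
            raise ValidationError("branch length vector does not match tree size")
        for node, val in zip(nodes, lengths):
            node.length = float(val)
        return new

    def copy(self) -> "Phylogeny":
        def clone(node: TreeNode) -> TreeNode:
            return TreeNode(
                label=node.label,
                length=node.length,
                children=[clone(c) for c in node.children],
            )

        return Phylogeny(clone(self.root))

    def newick(self, precision: int = 6) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.label or ""
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.length is not None:
                body += f":{node.length:.{precision}g}"
            return body

        return "(" + ",".join(fmt(c) for c in self.root.children) + ");"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Phylogeny({self.n_tips} tips, root degree {self.root_degree})"


def parse_newick(text: str) -> Phylogeny:
    """Parse a NEWICK string into a :class:`Phylogeny`.

    Missing branch lengths are recorded as ``None`` (model fitting
    initializes them); negative lengths raise :class:`ValidationError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise FormatError(f"could not parse NEWICK: {exc}") from exc

    def convert(dnode) -> TreeNode:
        label = None
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
        length = dnode.edge.length
        if length is not None and length < 0:
            raise ValidationError(f"negative branch length {length}")
        return TreeNode(
            label=label,
            length=None if length is None else float(length),
            children=[convert(c) for c in dnode.child_nodes()],
        )

    root = convert(dtree.seed_node)
    root.length = None
    tips = [n.label for n in root.postorder() if n.is_leaf]
    if len(set(tips)) != len(tips):
        raise ValidationError("duplicate tip labels in tree")
    return Phylogeny(root)


def unroot_to_trichotomy(tree: Phylogeny) -> Phylogeny:
    """Collapse a binary root so the root vertex has degree >= 3.

    The two root-child edges are merged with their lengths summed, so the
    total tree length is conserved exactly. Trees that already satisfy the
    convention are returned unchanged (as a copy).
    """
    if tree.n_tips < 3:
        raise UnsupportedTreeError(
            f"need >= 3 tips for an unrooted trichotomy, got {tree.n_tips}"
        )
    new = tree.copy()
    while len(new.root.children) == 2:
        a, b = new.root.children
        # keep an internal child as the new root; at >=3 tips one exists
        keep, move = (a, b) if not a.is_leaf else (b, a)
        if keep.is_leaf:
            raise UnsupportedTreeError("degenerate two-leaf root")
        merged = (keep.length or 0.0) + (move.length or 0.0)
        move.length = merged
        keep.length = None
        keep.children.append(move)
        new.root = keep
    return new


def check_tree_alignment_match(tree: Phylogeny, aln: CodonAlignment) -> None:
    tips = set(tree.tip_labels)
    taxa = set(aln.taxon_names)
    if tips != taxa:
        missing = taxa - tips
        extra = tips - taxa
        raise ValidationError(
            f"tree/alignment taxon mismatch (missing from tree: {sorted(missing)}, "
            f"extra in tree: {sorted(extra)})"
        )
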