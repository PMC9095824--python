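"""mtDNA haplogroup tree: data model, parser, and expected variant profiles.

The tree is a rooted hierarchy of haplogroup labels, each branch annotated
with the substitutions (against the revised Cambridge Reference Sequence,
rCRS, 16,569 bp, 1-based coordinates) that define it.  A sample belonging
to a haplogroup is expected to carry every defining substitution on the
root-to-haplogroup path, with ``!``-suffixed tokens denoting back-mutations
that restore the ancestral state.

The packaged default tree is a curated stand-in subtree (63 nodes) covering
the haplogroups used by the regional-ancestry classification; deep branches
carry their well-known defining positions, terminal branches synthetic but
internally consistent ones.  Users supply the full published tree for
production work via :func:`parse_haplotree` / :func:`load_tree`.

File dialect: tab-indented lines, one node per line; indentation depth gives
the parent; the label is followed (after a tab) by space-separated variant
tokens such as ``C16223T``, ``G11719A!`` or ``16311C`` (ancestral base
implied by a supplied reference sequence).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import pandas as pd

RCRS_LENGTH = 16569
NUCLEOTIDES = frozenset("ACGT")

#: Macrohaplogroups used for deep-clade aggregation by default.
DEFAULT_MACRO_SET = frozenset(
    {"L0", "L1", "L2", "L3", "L4", "L5", "L6", "M", "N", "R"}
)

_TOKEN_RE = re.compile(r"^([ACGT])?(\d+)([ACGT])(!)?$")


class TreeFormatError(ValueError):
    """Raised when a tree file violates the documented dialect."""


class TreeStructureError(ValueError):
    """Raised when parsed nodes do not form a single rooted tree."""


class UnknownHaplogroupError(KeyError):
    """Raised when a haplogroup label is not present in the tree."""


@dataclass(frozen=True)
class Variant:
    """A single substitution against rCRS.

    ``back_mutation`` marks a reversion (``!`` notation): the derived state
    equals the state that was ancestral before an earlier mutation on the
    same lineage.
    """

    position: int
    ancestral: str
    derived: str
    back_mutation: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.position <= RCRS_LENGTH:
            raise ValueError(f"position {self.position} outside rCRS 1..{RCRS_LENGTH}")
        if self.ancestral not in NUCLEOTIDES or self.derived not in NUCLEOTIDES:
            raise ValueError(f"non-ACGT allele in variant at {self.position}")
        if self.ancestral == self.derived:
            raise ValueError(f"ancestral == derived at {self.position}")

    def token(self) -> str:
        suffix = "!" if self.back_mutation else ""
        return f"{self.ancestral}{self.position}{self.derived}{suffix}"


@dataclass
class HaploNode:
    label: str
    parent: "HaploNode | None" = None
    defining_variants: list[Variant] = field(default_factory=list)
    children: list["HaploNode"] = field(default_factory=list)

    @property
    def depth(self) -> int:
        d, node = 0, self
        while node.parent is not None:
            node = node.parent
            d += 1
        return d

    def path_from_root(self) -> list["HaploNode"]:
        path: list[HaploNode] = []
        node: HaploNode | None = self
        while node is not None:
            path.append(node)
            node = node.parent
        return path[::-1]

    def __repr__(self) -> str:  # pragma: no cover
        return f"HaploNode({self.label!r}, {len(self.defining_variants)} variants)"


@dataclass(frozen=True)
class PanelDefinition:
    """The genotyping panel: assayed rCRS positions grouped into multiplex pools."""

    sites: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.sites]
        if len(set(positions)) != len(positions):
            raise ValueError("panel positions must be unique")

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(p for p, _ in self.sites)

    def pool_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for _, pool in self.sites:
            sizes[pool] = sizes.get(pool, 0) + 1
        return sizes


@dataclass(frozen=True)
class ExpectedProfile:
    """Expected nucleotide state per position for one haplogroup.

    ``states`` holds the state after sequentially applying every defining
    variant on the root-to-haplogroup path; a back-mutation restores the
    original ancestral base, so the stored state may equal rCRS.
    """

    haplogroup: str
    states: Mapping[int, str]


class HaploTree:
    """A rooted haplogroup tree with label lookup."""

    def __init__(self, root: HaploNode):
        self.root = root
        self._by_label: dict[str, HaploNode] = {}
        for node in self._walk(root):
            if node.label in self._by_label:
                raise TreeFormatError(f"duplicate haplogroup label {node.label!r}")
            self._by_label[node.label] = node

    @staticmethod
    def _walk(node: HaploNode) -> Iterator[HaploNode]:
        yield node
        for child in node.children:
            yield from HaploTree._walk(child)

    def __iter__(self) -> Iterator[HaploNode]:
        return self._walk(self.root)

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def __len__(self) -> int:
        return len(self._by_label)

    def node(self, label: str) -> HaploNode:
        try:
            return self._by_label[label]
        except KeyError:
            raise UnknownHaplogroupError(label) from None

    @property
    def labels(self) -> list[str]:
        return list(self._by_label)

    def reference_alleles(self) -> dict[int, str]:
        """rCRS base at every position named by a tree variant.

        The reference base at a position is the ancestral allele of the
        first (shallowest) variant touching that position on any lineage;
        conflicting ancestral claims across lineages are rejected.
        """
        ref: dict[int, str] = {}

        def visit(node: HaploNode, seen: set[int]) -> None:
            newly = set()
            for v in node.defining_variants:
                if v.position not in seen:
                    prior = ref.get(v.position)
                    if prior is not None and prior != v.ancestral:
                        raise TreeStructureError(
                            f"inconsistent ancestral allele at {v.position}: "
                            f"{prior} vs {v.ancestral}"
                        )
                    ref[v.position] = v.ancestral
                    newly.add(v.position)
            for child in node.children:
                visit(child, seen | newly)

        visit(self.root, set())
        return ref


def parse_variant_token(token: str, reference: Mapping[int, str] | None = None) -> Variant:
    """Parse a token like ``C16223T``, ``G11719A!`` or ``16311C``.

    A token without an explicit ancestral base requires ``reference``
    (position -> rCRS base), e.g. from a FASTA of the reference sequence.
    """
    m = _TOKEN_RE.match(token)
    if m is None:
        raise TreeFormatError(f"malformed variant token {token!r}")
    anc, pos_s, der, bang = m.groups()
    position = int(pos_s)
    if anc is None:
        if reference is None or position not in reference:
            raise TreeFormatError(
                f"token {token!r} omits the ancestral base and no reference "
                "sequence was supplied"
            )
        anc = reference[position]
    return Variant(position=position, ancestral=anc, derived=der,
                   back_mutation=bang is not None)


def parse_haplotree(text: str, reference: Mapping[int, str] | None = None) -> HaploTree:
    """Parse the tab-indented tree dialect into a :class:`HaploTree`.

    Raises :class:`TreeFormatError` with a line number for malformed tokens
    or duplicate labels, and :class:`TreeStructureError` for indentation
    that implies multiple roots or an orphan node.
    """
    stack: list[HaploNode] = []  # stack[d] = last node at depth d
    root: HaploNode | None = None
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        depth = len(raw) - len(raw.lstrip("\t"))
        fields = raw.strip().split("\t")
        label = fields[0].strip()
        if not label:
            raise TreeFormatError(f"line {lineno}: empty haplogroup label")
        if label in seen:
            raise TreeFormatError(f"line {lineno}: duplicate label {label!r}")
        seen.add(label)
        try:
            variants = [
                parse_variant_token(tok, reference)
                for f in fields[1:]
                for tok in f.split()
            ]
        except TreeFormatError as exc:
            raise TreeFormatError(f"line {lineno}: {exc}") from None
        node = HaploNode(label=label, defining_variants=variants)
        if depth == 0:
            if root is not None:
                raise TreeStructureError(
                    f"line {lineno}: second root {label!r} (first was {root.label!r})"
                )
            root = node
        else:
            if depth > len(stack):
                raise TreeStructureError(
                    f"line {lineno}: indentation depth {depth} has no parent"
                )
            parent = stack[depth - 1]
            node.parent = parent
            parent.children.append(node)
        del stack[depth:]
        stack.append(node)
    if root is None:
        raise TreeStructureError("empty tree text")
    if root.defining_variants:
        raise TreeStructureError(
            f"root {root.label!r} must carry no defining variants"
        )
    return HaploTree(root)


def serialize_haplotree(tree: HaploTree) -> str:
    """Inverse of :func:`parse_haplotree` (canonical form: explicit ancestral bases)."""
    lines: list[str] = []

    def emit(node: HaploNode, depth: int) -> None:
        tokens = " ".join(v.token() for v in node.defining_variants)
        lines.append("\t" * depth + node.label + ("\t" + tokens if tokens else ""))
        for child in node.children:
            emit(child, depth + 1)

    emit(tree.root, 0)
    return "\n".join(lines) + "\n"


def expected_profile(tree: HaploTree, label: str) -> ExpectedProfile:
    """Sequentially apply all root-to-``label`` path variants.

    A variant followed later on the path by its back-mutation leaves the
    ancestral state in place.
    """
    node = tree.node(label)
    states: dict[int, str] = {}
    for n in node.path_from_root():
        for v in n.defining_variants:
            states[v.position] = v.derived
    return ExpectedProfile(haplogroup=label, states=states)


def macro_of(tree: HaploTree, label: str,
             macro_set: frozenset[str] | set[str] = DEFAULT_MACRO_SET) -> str:
    """Nearest ancestor (or self) whose label is a macrohaplogroup; root if none."""
    node = tree.node(label)
    current: HaploNode | None = node
    while current is not None:
        if current.label in macro_set:
            return current.label
        current = current.parent
    return tree.root.label


def parse_panel(text: str) -> PanelDefinition:
    """Parse a panel CSV with columns ``position,pool``."""
    import io

    df = pd.read_csv(io.StringIO(text))
    missing = {"position", "pool"} - set(df.columns)
    if missing:
        raise ValueError(f"panel CSV lacks columns: {sorted(missing)}")
    return PanelDefinition(
        sites=tuple((int(p), int(q)) for p, q in zip(df["position"], df["pool"]))
    )


def load_reference_fasta(path: str) -> dict[int, str]:
    """Read an rCRS FASTA into a 1-based position -> base map (for implicit tokens)."""
    from Bio import SeqIO

    record = next(SeqIO.parse(path, "fasta"))
    return {i + 1: base.upper() for i, base in enumerate(str(record.seq))}


def _read_packaged(name: str) -> str:
    return (resources.files("osteotrace") / "data" / name).read_text()


def load_default_tree() -> HaploTree:
    """The packaged curated stand-in tree (63 haplogroups)."""
    return parse_haplotree(_read_packaged("haplotree.txt"))


def load_default_panel() -> PanelDefinition:
    """The packaged 115-site panel (pools of 23, 36, 31 and 25 sites)."""
    return parse_panel(_read_packaged("panel.csv"))


def load_tree(path: str, reference_fasta: str | None = None) -> HaploTree:
    reference = load_reference_fasta(reference_fasta) if reference_fasta else None
    with open(path, encoding="utf-8") as fh:
        return parse_haplotree(fh.read(), reference)


def load_panel(path: str) -> PanelDefinition:
    with open(path, encoding="utf-8") as fh:
        return parse_panel(fh.read())
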