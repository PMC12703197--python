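"""Alignment, tree, and MAF input/output with the coordinate conventions
shared by every downstream stage.

Alignments are species-by-site character matrices. Sites are addressed
1-based everywhere in this package (a report's "site 42" is column 42);
the single exception is MAF, which keeps its native 0-based, half-open,
strand-relative convention — conversion happens only inside
:func:`extract_maf_codon`.

Ambiguity is collapsed to a single sentinel per level: amino-acid
``B/Z/J/U/O`` become ``X``, nucleotide IUPAC codes other than ``ACGT``
become ``N``. ``-`` is a first-class state, not missing data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
from Bio import AlignIO, SeqIO
from Bio.Data import CodonTable


class AlignmentError(ValueError):
    """Rows of unequal length, or an operation invalid for the alignment."""


class FormatError(ValueError):
    """Unparseable or empty input."""


class IdentityError(ValueError):
    """Duplicate or unknown taxon labels."""


class FrameError(ValueError):
    """Nucleotide alignment cannot be read in codon frame."""


class CoverageError(ValueError):
    """Requested reference interval not covered by MAF blocks."""


class Level(str, Enum):
    AMINO_ACID = "amino_acid"
    NUCLEOTIDE = "nucleotide"


# Canonical alphabets after normalization.
AA_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
NT_RESIDUES = "ACGT"
_AA_KEEP = set(AA_RESIDUES) | {"-", "X", "*"}
_NT_KEEP = set(NT_RESIDUES) | {"-", "N"}

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_CODON_TABLE.forward_table)
GENETIC_CODE.update({c: "*" for c in _CODON_TABLE.stop_codons})

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def _normalize(seq: str, level: Level) -> str:
    seq = seq.upper()
    keep = _AA_KEEP if level is Level.AMINO_ACID else _NT_KEEP
    sentinel = "X" if level is Level.AMINO_ACID else "N"
    return "".join(c if c in keep else sentinel for c in seq)


@dataclass
class MultipleAlignment:
    """Species-by-site residue matrix with stable species ordering.

    ``rows[i]`` is the full gapped sequence of ``species_ids[i]``.
    """

    species_ids: list[str]
    rows: list[str]
    level: Level

    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.level = Level(self.level)
        if len(self.species_ids) != len(self.rows):
            raise AlignmentError("species_ids and rows differ in length")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise IdentityError("duplicate species identifiers")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal row lengths: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]
        self._index = {s: i for i, s in enumerate(self.species_ids)}

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_codons(self) -> int:
        if self.level is not Level.NUCLEOTIDE:
            raise FrameError("codon view requires a nucleotide alignment")
        if self.length % 3:
            raise FrameError(f"length {self.length} not divisible by 3")
        return self.length // 3

    def row(self, species: str) -> str:
        try:
            return self.rows[self._index[species]]
        except KeyError:
            raise IdentityError(f"unknown species {species!r}") from None

    def column(self, site: int) -> str:
        """States at 1-based ``site``, in species order."""
        if not 1 <= site <= self.length:
            raise IndexError(f"site {site} outside 1..{self.length}")
        return "".join(r[site - 1] for r in self.rows)

    def codon(self, species: str, codon_site: int) -> str:
        """Codon at 1-based ``codon_site`` for one species."""
        if not 1 <= codon_site <= self.n_codons:
            raise IndexError(f"codon site {codon_site} outside 1..{self.n_codons}")
        r = self.row(species)
        return r[3 * (codon_site - 1): 3 * codon_site]


def read_fasta_alignment(path: str | Path, level: Level | str) -> MultipleAlignment:
    """Read a gapped FASTA alignment; residues normalized and uppercased."""
    level = Level(level)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise IdentityError(f"duplicate record identifiers in {path}")
    rows = [_normalize(str(r.seq), level) for r in records]
    if len({len(r) for r in rows}) > 1:
        raise AlignmentError(f"records in {path} are not aligned (unequal lengths)")
    return MultipleAlignment(ids, rows, level)


def write_fasta_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sp, row in zip(aln.species_ids, aln.rows):
            fh.write(f">{sp}\n{row}\n")


def translate_codon(codon: str) -> str:
    """Standard-code translation of one aligned codon.

    ``---`` stays a gap; any codon that is not a clean ACGT triplet
    (partial gap, ambiguity) is ``X``.
    """
    codon = codon.upper()
    if codon == "---":
        return "-"
    return GENETIC_CODE.get(codon, "X") if set(codon) <= set(NT_RESIDUES) else "X"


def translate_codon_alignment(aln: MultipleAlignment) -> MultipleAlignment:
    """In-frame translation of a codon (nucleotide) alignment."""
    if aln.level is not Level.NUCLEOTIDE:
        raise FrameError("can only translate a nucleotide alignment")
    n = aln.n_codons  # raises FrameError when frame is broken
    rows = [
        "".join(translate_codon(r[3 * i: 3 * i + 3]) for i in range(n))
        for r in aln.rows
    ]
    return MultipleAlignment(list(aln.species_ids), rows, Level.AMINO_ACID)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Missing branch lengths default to 0 with a warning; duplicate leaf
    labels are an error.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        if "duplicate" in str(exc).lower():
            raise IdentityError(f"duplicate leaf labels in {path}") from exc
        raise FormatError(f"cannot parse Newick file {path}: {exc}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise IdentityError(f"duplicate leaf labels in {path}")
    defaulted = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = 0.0
            defaulted += 1
        if node.edge.length is not None and node.edge.length < 0:
            raise FormatError(f"negative branch length in {path}")
    if defaulted:
        warnings.warn(f"{defaulted} branch length(s) missing in {path}; set to 0")
    return tree


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

@dataclass
class MafRow:
    src: str            # "species.sequence" source name
    start: int          # 0-based, strand-relative
    size: int           # ungapped length
    strand: str         # '+' or '-'
    src_size: int
    text: str           # gapped, alignment-oriented

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]


@dataclass
class MafBlockSet:
    """Ordered MAF alignment blocks (rows keep MAF's native coordinates)."""

    blocks: list[list[MafRow]]

    def __post_init__(self) -> None:
        for block in self.blocks:
            widths = {len(r.text) for r in block}
            if len(widths) > 1:
                raise FormatError("MAF block rows have unequal widths")
            for r in block:
                if len(r.text.replace("-", "")) != r.size:
                    raise FormatError(
                        f"MAF row {r.src}: size {r.size} inconsistent with text"
                    )

    @property
    def species(self) -> set[str]:
        return {r.species for b in self.blocks for r in b}


def read_maf(path: str | Path) -> MafBlockSet:
    blocks = []
    for msa in AlignIO.parse(str(path), "maf"):
        rows = []
        for rec in msa:
            ann = rec.annotations
            rows.append(
                MafRow(
                    src=rec.id,
                    start=int(ann["start"]),
                    size=int(ann["size"]),
                    strand="+" if ann["strand"] in (1, "+") else "-",
                    src_size=int(ann["srcSize"]),
                    text=str(rec.seq).upper(),
                )
            )
        blocks.append(rows)
    if not blocks:
        raise FormatError(f"no MAF blocks in {path}")
    return MafBlockSet(blocks)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MafSlice:
    """Per-species gapped subsequences over a reference interval.

    ``missing`` lists species absent from at least one covering block —
    "absent" is a different claim than "aligned with a deletion", so they
    are never silently filled with gaps.
    """

    sequences: dict[str, str]
    missing: set[str]
    n_columns: int


def _orient_to_forward(block: list[MafRow], ref_idx: int) -> list[MafRow]:
    """Flip a block so that the reference row is on the '+' strand."""
    if block[ref_idx].strand == "+":
        return block
    out = []
    for r in block:
        out.append(
            MafRow(
                src=r.src,
                start=r.src_size - r.start - r.size,
                size=r.size,
                strand="+" if r.strand == "-" else "-",
                src_size=r.src_size,
                text=reverse_complement(r.text),
            )
        )
    return out


def extract_maf_codon(
    maf: MafBlockSet,
    ref_species: str,
    ref_start: int,
    length: int,
    ref_strand: str = "+",
) -> MafSlice:
    """Pull the aligned columns over a reference interval out of MAF blocks.

    ``ref_start`` is 0-based on the reference's forward strand and the
    interval is half-open, per the MAF convention. With ``ref_strand='-'``
    all returned texts are reverse-complemented into the feature's
    orientation after extraction.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if ref_species not in maf.species:
        raise IdentityError(f"reference species {ref_species!r} not in MAF")
    want = set(range(ref_start, ref_start + length))

    covering: list[tuple[int, list[MafRow], int, list[int]]] = []
    for block in maf.blocks:
        ref_idx = next(
            (i for i, r in enumerate(block) if r.species == ref_species), None
        )
        if ref_idx is None:
            continue
        block = _orient_to_forward(block, ref_idx)
        ref = block[ref_idx]
        # forward coordinate of each alignment column's reference base
        cols: list[int] = []
        pos = ref.start
        for j, c in enumerate(ref.text):
            if c != "-":
                if pos in want:
                    cols.append(j)
                pos += 1
        if cols:
            covering.append((ref.start, block, ref_idx, cols))

    covered = set()
    for start, block, ref_idx, cols in covering:
        ref = block[ref_idx]
        pos = ref.start
        for j, c in enumerate(ref.text):
            if c != "-":
                if pos in want and j in set(cols):
                    covered.add(pos)
                pos += 1
    if covered != want:
        missing_pos = sorted(want - covered)
        raise CoverageError(
            f"reference interval not covered at positions {missing_pos[:5]}..."
        )

    covering.sort(key=lambda t: t[0])
    present: dict[str, list[str]] = {}
    seen_species: set[str] = set()
    absent_somewhere: set[str] = set()
    n_columns = 0
    for _, block, _, cols in covering:
        n_columns += len(cols)
        block_species = {}
        for r in block:
            block_species.setdefault(r.species, r)  # first row per species
        seen_species |= set(block_species)
        for sp, r in block_species.items():
            piece = "".join(r.text[j] for j in cols)
            present.setdefault(sp, []).append(piece)
        for sp in seen_species - set(block_species):
            absent_somewhere.add(sp)

    n_blocks = len(covering)
    sequences = {
        sp: "".join(parts)
        for sp, parts in present.items()
        if len(parts) == n_blocks and sp not in absent_somewhere
    }
    missing = seen_species - set(sequences)
    if ref_strand == "-":
        sequences = {sp: reverse_complement(s) for sp, s in sequences.items()}
    return MafSlice(sequences=sequences, missing=missing, n_columns=n_columns)
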