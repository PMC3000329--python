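"""Reference mitochondrial genome model.

Sequences, the gene map of the human mitochondrial reference (rCRS
numbering), projection of reference positions to codon addresses, and
translation under the vertebrate mitochondrial genetic code.

Conventions used throughout the package:

* all reference coordinates are 1-based inclusive (rCRS numbering);
* the mitochondrial genome is circular, but features spanning the
  origin are rejected (none of the loci analysed here span it);
* genes on the light strand (ND6 and several tRNAs) are read on the
  reverse complement, with codon 1 starting at the annotated ``end``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio.Data import CodonTable

__all__ = [
    "VALID_RESIDUES",
    "MITO_CODON_TABLE",
    "NucSequence",
    "GeneAnnotation",
    "MtGeneMap",
    "CodonAddress",
    "ProjectedSite",
    "AnchoredSequence",
    "GeneExtract",
    "translate_mito",
    "reverse_complement",
    "project_position",
    "extract_gene",
    "load_default_gene_map",
]

VALID_RESIDUES = frozenset("ACGTN-")

_COMPLEMENT = str.maketrans("ACGTN-acgtn", "TGCAN-tgcan")


def _build_mito_code() -> dict[str, str]:
    """Full 64-codon table for the vertebrate mitochondrial code.

    Built from NCBI translation table 2 (AGA/AGG stop, ATA=Met, TGA=Trp),
    with stop codons rendered as '*'.
    """
    table = CodonTable.unambiguous_dna_by_id[2]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


MITO_CODON_TABLE: dict[str, str] = _build_mito_code()

#: Initiation codons accepted for mitochondrial protein genes.
MITO_START_CODONS = ("ATG", "ATA", "ATT", "GTG")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_mito(codons: str) -> str:
    """Translate a coding sequence under the vertebrate mitochondrial code.

    ``codons`` must have length divisible by 3 and contain only A/C/G/T.
    Stop codons are rendered as ``*``.
    """
    if len(codons) % 3 != 0:
        raise ValueError(f"coding sequence length {len(codons)} is not a multiple of 3")
    protein = []
    for i in range(0, len(codons), 3):
        codon = codons[i : i + 3].upper()
        try:
            protein.append(MITO_CODON_TABLE[codon])
        except KeyError:
            for j, base in enumerate(codon):
                if base not in "ACGT":
                    raise ValueError(
                        f"non-ACGT character {base!r} at position {i + j + 1}"
                    ) from None
            raise
    return "".join(protein)


@dataclass(frozen=True)
class NucSequence:
    """A nucleotide sequence over the alphabet {A,C,G,T,N,-}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise ValueError("empty sequence")
        bad = set(self.residues.upper()) - VALID_RESIDUES
        if bad:
            raise ValueError(f"invalid residues in {self.id!r}: {sorted(bad)}")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated feature on the mitochondrial reference."""

    name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "H" (heavy/plus) or "L" (light/minus)
    kind: str  # "protein", "tRNA", "rRNA"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"{self.name}: bad span {self.start}-{self.end}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"{self.name}: strand must be H or L")
        if self.kind not in ("protein", "tRNA", "rRNA"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def n_full_codons(self) -> int:
        return len(self) // 3

    @property
    def incomplete_terminal(self) -> bool:
        """True when the annotated span does not divide into whole codons.

        Several mitochondrial genes end in an incomplete stop codon that is
        completed by polyadenylation of the mRNA (e.g. ND1, ND2, COX3).
        """
        return len(self) % 3 != 0


@dataclass(frozen=True)
class CodonAddress:
    """Codon-level address of a coding reference position."""

    gene: str
    codon_index: int  # 1-based, counted from the initiation codon
    codon_position: int  # 1, 2 or 3

    def __post_init__(self) -> None:
        if self.codon_index < 1 or self.codon_position not in (1, 2, 3):
            raise ValueError("invalid codon address")


@dataclass(frozen=True)
class ProjectedSite:
    """Result of projecting a reference position through the gene map.

    ``category`` is "coding", "rna" or "intergenic".  ``codon`` is set only
    for coding sites; ``incomplete_codon`` marks positions that fall in a
    trailing partial codon.
    """

    position: int
    category: str
    gene: str | None = None
    codon: CodonAddress | None = None
    incomplete_codon: bool = False


@dataclass
class MtGeneMap:
    """Ordered annotation of the (circular) mitochondrial reference."""

    reference_id: str
    length: int
    genes: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(
                    f"{g.name} ends at {g.end} beyond reference length {self.length}"
                )
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))

    def __iter__(self) -> Iterator[GeneAnnotation]:
        return iter(self.genes)

    def gene(self, name: str) -> GeneAnnotation:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    @property
    def protein_genes(self) -> list[GeneAnnotation]:
        return [g for g in self.genes if g.kind == "protein"]

    def annotations_at(self, pos: int) -> list[GeneAnnotation]:
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside reference 1..{self.length}")
        return [g for g in self.genes if g.start <= pos <= g.end]

    def genes_in_span(self, start: int, end: int) -> list[GeneAnnotation]:
        """Annotations overlapping the (non-origin-spanning) span."""
        if start > end:
            raise ValueError("origin-spanning spans are not supported")
        return [g for g in self.genes if g.start <= end and g.end >= start]

    @classmethod
    def from_tsv(cls, path, reference_id: str = "rCRS", length: int = 16569) -> "MtGeneMap":
        genes = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("name\t"):
                    continue
                name, start, end, strand, kind = line.split("\t")
                genes.append(GeneAnnotation(name, int(start), int(end), strand, kind))
        return cls(reference_id=reference_id, length=length, genes=genes)


def load_default_gene_map() -> MtGeneMap:
    """The packaged rCRS gene map (16,569 bp reference)."""
    ref = importlib.resources.files("paleonumt.data") / "rcrs_genes.tsv"
    with importlib.resources.as_file(ref) as path:
        return MtGeneMap.from_tsv(path)


def _codon_address(gene: GeneAnnotation, pos: int) -> tuple[CodonAddress, bool]:
    if gene.strand == "H":
        offset = pos - gene.start
    else:
        offset = gene.end - pos
    codon_index = offset // 3 + 1
    codon_position = offset % 3 + 1
    incomplete = codon_index > gene.n_full_codons
    return CodonAddress(gene.name, codon_index, codon_position), incomplete


def project_position(pos: int, gene_map: MtGeneMap) -> ProjectedSite:
    """Project a 1-based reference position to a codon address.

    Positions inside RNA genes return an RNA marker; positions outside any
    annotation return an intergenic marker.  Where protein genes overlap
    (ATP8/ATP6, ND4L/ND4) the earlier-starting gene wins; use
    ``MtGeneMap.annotations_at`` for the full set.
    """
    hits = gene_map.annotations_at(pos)
    proteins = [g for g in hits if g.kind == "protein"]
    if proteins:
        gene = proteins[0]
        codon, incomplete = _codon_address(gene, pos)
        return ProjectedSite(pos, "coding", gene.name, codon, incomplete)
    if hits:
        return ProjectedSite(pos, "rna", hits[0].name)
    return ProjectedSite(pos, "intergenic")


def codon_span(gene: GeneAnnotation, codon_index: int) -> tuple[int, int]:
    """Reference span (1-based inclusive) occupied by a codon of a gene.

    Inverse of :func:`project_position` restricted to the gene.
    """
    if codon_index < 1:
        raise ValueError("codon index must be >= 1")
    if gene.strand == "H":
        start = gene.start + 3 * (codon_index - 1)
        end = min(start + 2, gene.end)
        if start > gene.end:
            raise ValueError(f"codon {codon_index} beyond {gene.name}")
    else:
        end = gene.end - 3 * (codon_index - 1)
        start = max(end - 2, gene.start)
        if end < gene.start:
            raise ValueError(f"codon {codon_index} beyond {gene.name}")
    return start, end


@dataclass
class AnchoredSequence:
    """A sequence laid out against reference coordinates.

    ``columns[i]`` is the residue aligned to reference position
    ``ref_start + i`` ('-' for a deletion relative to the reference).
    Insertions relative to the reference are kept out of the coordinate
    frame, keyed by the reference position they follow.
    """

    id: str
    ref_start: int  # 1-based reference coordinate of the first column
    columns: str
    insertions: dict[int, str] = field(default_factory=dict)

    @property
    def ref_end(self) -> int:
        return self.ref_start + len(self.columns) - 1

    def covers(self, start: int, end: int) -> bool:
        return self.ref_start <= start and end <= self.ref_end

    def slice_ref(self, start: int, end: int) -> str:
        """Columns for reference span [start, end]; positions outside the
        anchored span are returned as 'N'."""
        out = []
        for pos in range(start, end + 1):
            if self.ref_start <= pos <= self.ref_end:
                out.append(self.columns[pos - self.ref_start])
            else:
                out.append("N")
        return "".join(out)

    def base_at(self, pos: int) -> str:
        if not self.ref_start <= pos <= self.ref_end:
            return "N"
        return self.columns[pos - self.ref_start]

    @classmethod
    def from_reference(cls, seq: NucSequence) -> "AnchoredSequence":
        return cls(id=seq.id, ref_start=1, columns=seq.residues)


@dataclass
class GeneExtract:
    """Strand-resolved coding sequence of one gene from an anchored row."""

    gene: str
    sequence: NucSequence
    partial: bool  # gene span not fully covered by the anchored sequence
    first_codon: int  # codon index of the first extracted codon
    covered_start: int  # reference span actually used
    covered_end: int


def extract_gene(anchored: AnchoredSequence, gene: GeneAnnotation) -> GeneExtract:
    """Extract the coding sequence of ``gene`` from an anchored row.

    Alignment gaps are preserved as '-'.  If the anchored sequence covers
    the gene only partially, extraction starts at the first codon fully
    inside the covered span and the result is flagged partial (genes cut
    at numt edges).
    """
    cov_start = max(gene.start, anchored.ref_start)
    cov_end = min(gene.end, anchored.ref_end)
    if cov_start > cov_end:
        raise ValueError(f"{gene.name} not covered by {anchored.id}")
    partial = (cov_start != gene.start) or (cov_end != gene.end)

    if gene.strand == "H":
        # advance to the first codon fully inside coverage
        first_codon = (cov_start - gene.start + 2) // 3 + 1
        start = gene.start + 3 * (first_codon - 1)
        n_codons = (cov_end - start + 1) // 3
        end = start + 3 * n_codons - 1
        if n_codons < 1:
            raise ValueError(f"{gene.name}: no complete codon covered")
        seq = anchored.slice_ref(start, end)
        return GeneExtract(gene.name, NucSequence(f"{anchored.id}|{gene.name}", seq),
                           partial, first_codon, start, end)
    # light strand: codon 1 begins at gene.end, read on the reverse complement
    first_codon = (gene.end - cov_end + 2) // 3 + 1
    end = gene.end - 3 * (first_codon - 1)
    n_codons = (end - cov_start + 1) // 3
    start = end - 3 * n_codons + 1
    if n_codons < 1:
        raise ValueError(f"{gene.name}: no complete codon covered")
    seq = reverse_complement(anchored.slice_ref(start, end))
    return GeneExtract(gene.name, NucSequence(f"{anchored.id}|{gene.name}", seq),
                       partial, first_codon, start, end)


def read_fasta(path) -> list[NucSequence]:
    from Bio import SeqIO

    return [NucSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, seqs: Iterable[NucSequence], width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")
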