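"""Synthetic hominin mtDNA panels, numts and nuclear backgrounds with truth.

The generator emulates the statistical structure the downstream analyses
assume:

* mtDNA evolves clock-like on a hominin tree with a strong transition
  bias (ts/tv about 15:1) and the 2:1:5 codon-position bias of
  constrained mitochondrial protein genes;
* a numt lineage branches off the mitochondrial tree at its insertion
  time and thereafter evolves under the nuclear regime: rate
  0.99e-9 subs/site/yr, ts/tv about 2, no codon-position bias, CpG
  hypermutability, and (optionally) indels and nonsense changes;
* nuclear background genomes with planted inserts, emitted together
  with BED truth records.

Every emitted difference is traceable to a truth record, and all output
is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mito_core import (
    MITO_CODON_TABLE,
    MtGeneMap,
    NucSequence,
    load_default_gene_map,
    reverse_complement,
    translate_mito,
)

__all__ = [
    "SimConfig",
    "SimNode",
    "SubstitutionEvent",
    "PlantedInsert",
    "SimTruth",
    "random_mito_reference",
    "hominin_tree",
    "simulate_panel",
    "degrade_numt",
    "plant_numts",
    "make_degraded_insert",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

#: Default nuclear substitution rate for noncoding, nonrepetitive DNA
#: (substitutions per site per year).
NUCLEAR_RATE = 0.99e-9


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(len(seq), dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        out[arr == ord(base)] = i
    return out


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Rates are substitutions per site per year.  ``ts_fraction`` values are
    the probability that a substitution event is a transition; 15/16
    corresponds to a ts/tv ratio of 15 (mitochondrial), 2/3 to a ratio of
    2 (nuclear).
    """

    seed: int = 0
    span: tuple[int, int] | None = None  # reference span to simulate (1-based incl.)
    rate_mt: float = 1.5e-8
    rate_nuc: float = NUCLEAR_RATE
    ts_fraction_mt: float = 15.0 / 16.0
    ts_fraction_nuc: float = 2.0 / 3.0
    codon_weights: tuple[float, float, float] = (2.0, 1.0, 5.0)
    cpg_multiplier: float = 10.0
    indel_rate_nuc: float = 0.0  # per site per year; panels are indel-free by default
    n_humans: int = 4
    human_tmrca: float = 2.0e5
    neanderthal_split: float = 5.0e5
    numt_age: float = 6.2e5
    pan_split: float = 2.5e6
    root_age: float = 6.0e6
    genome_length: int = 2_000_000
    gc: float = 0.41

    def __post_init__(self) -> None:
        if self.rate_mt <= 0 or self.rate_nuc <= 0:
            raise ValueError("rates must be positive")
        if any(w <= 0 for w in self.codon_weights):
            raise ValueError("codon weights must be positive")


@dataclass(frozen=True)
class SubstitutionEvent:
    """One substitution event on one branch (reference coordinates)."""

    position: int  # 1-based reference position
    from_base: str
    to_base: str
    branch: str
    regime: str  # "mt" or "nuclear"


@dataclass(frozen=True)
class PlantedInsert:
    """Truth record for one numt planted into a background genome."""

    contig: str
    nuc_start: int  # 1-based inclusive
    nuc_end: int
    strand: str  # "+" or "-"
    mt_start: int
    mt_end: int
    n_substitutions: int
    substituted_offsets: tuple[int, ...]  # 0-based offsets within the insert


@dataclass
class SimTruth:
    node_ages: dict[str, float] = field(default_factory=dict)
    events: list[SubstitutionEvent] = field(default_factory=list)
    inserts: list[PlantedInsert] = field(default_factory=list)


@dataclass
class SimNode:
    """Node of the simulation tree; ``age`` in years before present."""

    name: str
    age: float
    children: list["SimNode"] = field(default_factory=list)
    regime: str = "mt"  # regime of the edge above this node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["SimNode"]:
        if self.is_leaf:
            return [self]
        out: list[SimNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def to_newick(self) -> str:
        def fmt(node: SimNode, parent_age: float) -> str:
            bl = parent_age - node.age
            if node.is_leaf:
                return f"{node.name}:{bl:g}"
            inner = ",".join(fmt(c, node.age) for c in node.children)
            return f"({inner}){node.name}:{bl:g}"

        inner = ",".join(fmt(c, self.age) for c in self.children)
        return f"({inner}){self.name};"


def hominin_tree(config: SimConfig) -> SimNode:
    """Default study tree: humans + Neanderthal + numt lineage + Pan.

    The numt lineage diverges from the mitochondrial tree at
    ``config.numt_age`` (taken as the insertion time) and its terminal
    edge evolves under the nuclear regime.
    """
    if not (
        0
        < config.human_tmrca
        < config.neanderthal_split
        < config.numt_age
        < config.root_age
    ):
        raise ValueError("node ages must decrease root -> tips")

    # ladderized human clade with evenly spaced coalescences
    n = config.n_humans
    humans = SimNode("human_1", 0.0)
    for i in range(2, n + 1):
        age = config.human_tmrca * (i - 1) / (n - 1) if n > 1 else config.human_tmrca
        humans = SimNode(f"h_anc_{i}", age, [humans, SimNode(f"human_{i}", 0.0)])
    hn = SimNode("human_nea", config.neanderthal_split,
                 [humans, SimNode("neanderthal", 0.0)])
    numt = SimNode("numt", 0.0, regime="nuclear")
    homo = SimNode("homo_mrca", config.numt_age, [hn, numt])
    pan = SimNode("pan_mrca", config.pan_split,
                  [SimNode("chimp", 0.0), SimNode("bonobo", 0.0)])
    return SimNode("root", config.root_age, [homo, pan])


# ---------------------------------------------------------------------------
# synthetic reference genome with intact reading frames


def _required_codons(gene, rng) -> list[tuple[list[int], list[str]]]:
    """Required codon groups for one gene: (positions, codon options).

    The writer picks the first option compatible with already-locked
    positions, so shared bases between adjacent genes (e.g. the ATP6
    stop overlapping the COX3 start) resolve automatically.
    """
    out = []
    n_full = gene.n_full_codons
    tail = len(gene) - 3 * n_full
    starts = ["ATG", "ATA"]
    # TAA first: its terminal A can double as the start A of an adjacent
    # downstream gene (ATP6/COX3-style single-base overlap)
    stops = ["TAA", "TAG"]
    if gene.strand == "H":
        out.append(([gene.start + i for i in range(3)], starts))
        if tail == 0:
            pos0 = gene.start + 3 * (n_full - 1)
            out.append(([pos0 + i for i in range(3)], stops))
        else:  # incomplete terminal codon completed by polyadenylation
            out.append(
                ([gene.start + 3 * n_full + i for i in range(tail)],
                 ["TA"[:tail]])
            )
    else:
        out.append(
            ([gene.end - 2 + i for i in range(3)],
             [reverse_complement(c) for c in starts])
        )
        if tail == 0:
            pos0 = gene.end - 3 * n_full + 1
            out.append(
                ([pos0 + i for i in range(3)],
                 [reverse_complement(c) for c in stops])
            )
    return out


def _gene_codons(seq: list[str], gene) -> list[str]:
    raw = "".join(seq[gene.start - 1 : gene.end])
    if gene.strand == "L":
        raw = reverse_complement(raw)
    n_full = gene.n_full_codons
    return [raw[3 * i : 3 * i + 3] for i in range(n_full)]


def random_mito_reference(
    seed: int = 0, gene_map: MtGeneMap | None = None, max_iter: int = 20000
) -> NucSequence:
    """Random mitochondrial reference consistent with the packaged gene map.

    Every protein gene starts with ATG, contains no internal stop under
    the vertebrate mitochondrial code, and ends with a stop codon (or the
    conventional incomplete 'TA'/'T' terminal).  Overlapping reading
    frames (ATP8/ATP6, ATP6/COX3, ND4L/ND4) are honoured by iterative
    local resampling.  This is a synthetic stand-in for the rCRS: it has
    the rCRS gene geometry but unrelated sequence content.
    """
    gene_map = gene_map or load_default_gene_map()
    rng = np.random.default_rng(seed)
    seq = list(_decode(rng.integers(0, 4, size=gene_map.length)))
    locked = np.zeros(gene_map.length, dtype=bool)

    for gene in gene_map.protein_genes:
        for positions, options in _required_codons(gene, rng):
            chosen = None
            for codon in options:
                if all(
                    not locked[p - 1] or seq[p - 1] == b
                    for p, b in zip(positions, codon)
                ):
                    chosen = codon
                    break
            if chosen is None:
                raise RuntimeError(
                    f"conflicting required codons for {gene.name} at {positions}"
                )
            for p, b in zip(positions, chosen):
                seq[p - 1] = b
                locked[p - 1] = True

    stops = {c for c, aa in MITO_CODON_TABLE.items() if aa == "*"}
    for _ in range(max_iter):
        dirty = False
        for gene in gene_map.protein_genes:
            codons = _gene_codons(seq, gene)
            for idx, codon in enumerate(codons[:-1]):  # last full codon may be stop
                if codon in stops:
                    dirty = True
                    if gene.strand == "H":
                        pos0 = gene.start - 1 + 3 * idx
                        cols = [pos0, pos0 + 1, pos0 + 2]
                    else:
                        pos0 = gene.end - 1 - 3 * idx
                        cols = [pos0, pos0 - 1, pos0 - 2]
                    free = [c for c in cols if not locked[c]]
                    if not free:
                        raise RuntimeError("locked stop codon; regenerate with new seed")
                    c = free[int(rng.integers(0, len(free)))]
                    seq[c] = "ACGT"[int(rng.integers(0, 4))]
        if not dirty:
            break
    else:
        raise RuntimeError("reference repair did not converge")

    ref = NucSequence("synthetic_mt_ref", "".join(seq))
    _validate_reference(ref, gene_map)
    return ref


def _validate_reference(ref: NucSequence, gene_map: MtGeneMap) -> None:
    for gene in gene_map.protein_genes:
        raw = ref.residues[gene.start - 1 : gene.end]
        if gene.strand == "L":
            raw = reverse_complement(raw)
        protein = translate_mito(raw[: 3 * gene.n_full_codons])
        if "*" in protein[:-1]:
            raise AssertionError(f"internal stop in synthetic {gene.name}")


# ---------------------------------------------------------------------------
# substitution engine


def _site_weights(
    arr: np.ndarray,
    span_start: int,
    regime: str,
    config: SimConfig,
    gene_map: MtGeneMap,
) -> np.ndarray:
    """Per-site relative mutation weights for one branch.

    mt regime: codon-position weights inside protein genes, weight 1
    elsewhere.  nuclear regime: uniform, with CpG-context sites (C of CpG
    or G of CpG, computed on the current sequence) multiplied by the CpG
    rate factor.
    """
    n = arr.size
    w = np.ones(n)
    if regime == "mt":
        for gene in gene_map.protein_genes:
            lo = max(gene.start, span_start)
            hi = min(gene.end, span_start + n - 1)
            if lo > hi:
                continue
            if gene.strand == "H":
                offsets = np.arange(lo, hi + 1) - gene.start
            else:
                offsets = gene.end - np.arange(lo, hi + 1)
            pos_in_codon = offsets % 3
            w[lo - span_start : hi - span_start + 1] = np.asarray(config.codon_weights)[
                pos_in_codon
            ]
    else:
        cpg = np.zeros(n, dtype=bool)
        c_before_g = (arr[:-1] == 1) & (arr[1:] == 2)
        cpg[:-1] |= c_before_g
        cpg[1:] |= c_before_g
        w[cpg] = config.cpg_multiplier
    return w


def _mutate_branch(
    arr: np.ndarray,
    span_start: int,
    years: float,
    regime: str,
    branch: str,
    config: SimConfig,
    gene_map: MtGeneMap,
    rng: np.random.Generator,
    events: list[SubstitutionEvent],
) -> np.ndarray:
    """Apply a Poisson number of substitutions to a copy of ``arr``."""
    arr = arr.copy()
    rate = config.rate_mt if regime == "mt" else config.rate_nuc
    ts_frac = config.ts_fraction_mt if regime == "mt" else config.ts_fraction_nuc
    n_events = rng.poisson(rate * years * arr.size)
    if n_events == 0:
        return arr
    weights = _site_weights(arr, span_start, regime, config, gene_map)
    cum = np.cumsum(weights / weights.sum())
    applied = 0
    while applied < n_events:
        site = min(int(np.searchsorted(cum, rng.random())), arr.size - 1)
        old = int(arr[site])
        if rng.random() < ts_frac:
            new = old ^ 2  # A<->G, C<->T
        else:
            new = [b for b in range(4) if b != old and b != (old ^ 2)][
                int(rng.integers(0, 2))
            ]
        if regime == "mt" and _creates_stop(arr, site, new, span_start, gene_map):
            continue  # nonsense changes are purged from functional mtDNA
        arr[site] = new
        applied += 1
        events.append(
            SubstitutionEvent(
                position=span_start + site,
                from_base="ACGT"[old],
                to_base="ACGT"[new],
                branch=branch,
                regime=regime,
            )
        )
    return arr


_STOP_CODONS = frozenset(
    c for c, aa in MITO_CODON_TABLE.items() if aa == "*"
)


def _creates_stop(
    arr: np.ndarray, site: int, new: int, span_start: int, gene_map: MtGeneMap
) -> bool:
    """Would setting ``site`` to ``new`` create a stop codon in any
    protein gene reading frame covering it?"""
    pos = span_start + site
    for gene in gene_map.annotations_at(pos):
        if gene.kind != "protein":
            continue
        if gene.strand == "H":
            offset = (pos - gene.start) % 3
            lo = pos - offset
            if lo + 2 > gene.end or (pos - gene.start) // 3 >= gene.n_full_codons:
                continue
            codon = []
            for p in range(lo, lo + 3):
                i = p - span_start
                if not 0 <= i < arr.size:
                    break
                codon.append("ACGT"[new if p == pos else int(arr[i])])
            if len(codon) == 3 and "".join(codon) in _STOP_CODONS:
                return True
        else:
            offset = (gene.end - pos) % 3
            hi = pos + offset
            if hi - 2 < gene.start or (gene.end - pos) // 3 >= gene.n_full_codons:
                continue
            codon = []
            for p in range(hi, hi - 3, -1):
                i = p - span_start
                if not 0 <= i < arr.size:
                    break
                base = "ACGT"[new if p == pos else int(arr[i])]
                codon.append({"A": "T", "C": "G", "G": "C", "T": "A"}[base])
            if len(codon) == 3 and "".join(codon) in _STOP_CODONS:
                return True
    return False


def simulate_panel(
    config: SimConfig,
    tree: SimNode | None = None,
    reference: NucSequence | None = None,
    gene_map: MtGeneMap | None = None,
) -> tuple[dict[str, NucSequence], SimTruth]:
    """Evolve a sequence panel along the (hominin) tree.

    Returns aligned same-length rows keyed by leaf name, plus the truth.
    The root sequence is the synthetic reference restricted to
    ``config.span``; edges marked ``regime="nuclear"`` (the numt terminal
    edge) switch to the nuclear mutation regime.
    """
    gene_map = gene_map or load_default_gene_map()
    rng = np.random.default_rng(config.seed)
    tree = tree or hominin_tree(config)
    reference = reference or random_mito_reference(config.seed, gene_map)
    lo, hi = config.span or (1, len(reference))
    root_arr = _encode(reference.residues[lo - 1 : hi])

    truth = SimTruth()
    for node in tree.walk():
        truth.node_ages[node.name] = node.age

    out: dict[str, NucSequence] = {}

    def descend(node: SimNode, arr: np.ndarray) -> None:
        for child in node.children:
            years = node.age - child.age
            if years < 0:
                raise ValueError("child older than parent")
            child_arr = _mutate_branch(
                arr, lo, years, child.regime, child.name, config, gene_map, rng,
                truth.events,
            )
            if child.is_leaf:
                out[child.name] = NucSequence(child.name, _decode(child_arr))
            else:
                descend(child, child_arr)

    descend(tree, root_arr)
    saturation = max(config.rate_mt, config.rate_nuc) * tree.age
    if saturation > 0.75:
        import warnings

        warnings.warn(f"expected {saturation:.2f} subs/site root-to-tip: saturated")
    return out, truth


# ---------------------------------------------------------------------------
# numt decay and genome planting


def degrade_numt(
    seq: NucSequence,
    years: float,
    config: SimConfig | None = None,
    seed: int = 0,
    span_start: int = 1,
    allow_indels: bool = False,
    gene_map: MtGeneMap | None = None,
) -> tuple[NucSequence, list[SubstitutionEvent]]:
    """Let a numt decay under the nuclear regime for ``years`` years.

    The substitution count is Poisson with mean rate x years x length
    (rate 0.99e-9/site/yr by default: about one fixed change per 200,000
    years for a multi-kb numt).  CpG-context sites mutate at
    ``cpg_multiplier`` times the base rate.  Indels (1-4 bp, frameshift-
    capable) are added at ``indel_rate_nuc`` when ``allow_indels``.
    """
    if years < 0:
        raise ValueError("years must be >= 0")
    config = config or SimConfig()
    gene_map = gene_map or load_default_gene_map()
    rng = np.random.default_rng(seed)
    arr = _encode(seq.residues)
    events: list[SubstitutionEvent] = []
    arr = _mutate_branch(arr, span_start, years, "nuclear", seq.id, config,
                         gene_map, rng, events)
    residues = _decode(arr)
    if allow_indels and config.indel_rate_nuc > 0:
        n_indels = rng.poisson(config.indel_rate_nuc * years * arr.size)
        chars = list(residues)
        for _ in range(n_indels):
            pos = int(rng.integers(1, len(chars) - 1))
            size = int(rng.integers(1, 5))
            if rng.random() < 0.5:
                del chars[pos : pos + size]
            else:
                ins = _decode(rng.integers(0, 4, size=size))
                chars[pos:pos] = list(ins)
        residues = "".join(chars)
    return NucSequence(seq.id, residues), events


def make_degraded_insert(
    reference: NucSequence,
    mt_start: int,
    mt_end: int,
    years: float,
    config: SimConfig | None = None,
    seed: int = 0,
    protect_edges: int = 4,
) -> tuple[NucSequence, list[SubstitutionEvent]]:
    """A decayed copy of reference[mt_start..mt_end] for planting.

    The outermost ``protect_edges`` bases on each side are kept
    substitution-free so the planted boundary is recoverable exactly by
    an aligner (an edge substitution makes the true endpoint
    undefinable for any detector).
    """
    insert = NucSequence(
        f"numt_{mt_start}_{mt_end}", reference.residues[mt_start - 1 : mt_end]
    )
    for attempt in range(200):
        mutated, events = degrade_numt(
            insert, years, config, seed=seed + 7919 * attempt, span_start=mt_start
        )
        offsets = [e.position - mt_start for e in events]
        L = len(insert)
        if all(protect_edges <= o < L - protect_edges for o in offsets):
            return mutated, events
    raise RuntimeError("could not place substitutions away from insert edges")


def plant_numts(
    config: SimConfig,
    inserts: Sequence[tuple[NucSequence, int, int]],
    query: NucSequence | None = None,
    contig_id: str = "chr_sim",
) -> tuple[NucSequence, list[PlantedInsert]]:
    """Plant insert sequences into a random background genome.

    ``inserts`` are (sequence, mt_start, mt_end) triples, e.g. from
    :func:`make_degraded_insert`.  Placement is uniform, non-overlapping,
    with random strand.  When ``query`` (the mitochondrial sequence the
    scanner will use) is given, the two background bases flanking each
    insert are resampled to differ from the continuation of the query, so
    that the planted span is the maximal alignable span and the truth
    coordinates are exact.
    """
    rng = np.random.default_rng(config.seed)
    n = config.genome_length
    p_gc = config.gc / 2
    probs = [0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc]
    genome = list(_decode(rng.choice(4, size=n, p=probs)))
    if sum(len(s.residues) for s, _, _ in inserts) > n / 10:
        raise ValueError("inserts exceed a tenth of the genome")

    placed: list[PlantedInsert] = []
    occupied: list[tuple[int, int]] = []
    pieces: list[tuple[int, str, PlantedInsert]] = []
    for seq, mt_start, mt_end in inserts:
        L = len(seq.residues)
        for _ in range(1000):
            pos = int(rng.integers(50, n - L - 50))  # 0-based insertion point
            if all(pos + L + 100 < a or pos > b + 100 for a, b in occupied):
                break
        else:
            raise RuntimeError("could not place insert without overlap")
        occupied.append((pos, pos + L))
        strand = "+" if rng.random() < 0.5 else "-"
        residues = seq.residues if strand == "+" else reverse_complement(seq.residues)
        rec = PlantedInsert(
            contig=contig_id,
            nuc_start=pos + 1,
            nuc_end=pos + L,
            strand=strand,
            mt_start=mt_start,
            mt_end=mt_end,
            n_substitutions=0,
            substituted_offsets=(),
        )
        pieces.append((pos, residues, rec))

    # assemble: later insertions must not shift earlier coordinates, so
    # overwrite in place (background is random; overwriting keeps length)
    for pos, residues, rec in sorted(pieces):
        genome[pos : pos + len(residues)] = list(residues)
        placed.append(rec)

    if query is not None:
        q = query.residues
        circ = q + q  # circular continuation
        for rec, (pos, residues, _) in zip(placed, sorted(pieces)):
            L = len(residues)
            if rec.strand == "+":
                before = [circ[(rec.mt_start - 2 - k) % len(q)] for k in range(4)]
                after = [circ[(rec.mt_end + k) % len(q)] for k in range(4)]
            else:
                before = [
                    reverse_complement(circ[(rec.mt_end + k) % len(q)])
                    for k in range(4)
                ]
                after = [
                    reverse_complement(circ[(rec.mt_start - 2 - k) % len(q)])
                    for k in range(4)
                ]
            for k in range(4):
                i = pos - 1 - k
                if 0 <= i < n and genome[i] == before[k]:
                    genome[i] = _other_base(genome[i], rng)
                j = pos + L + k
                if 0 <= j < n and genome[j] == after[k]:
                    genome[j] = _other_base(genome[j], rng)

    return NucSequence(contig_id, "".join(genome)), placed


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]
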