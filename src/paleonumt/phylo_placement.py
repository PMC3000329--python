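"""Panel alignment, NJ tree building and numt placement classification.

The placement engine is neighbor joining on TN93 distances with optional
gamma rate heterogeneity (shape 0.2 by default, the value typically used
for mitochondrial panels), bootstrap support by column resampling, and a
purely topological verdict: does the numt branch inside the modern-human
clade, basal to the human+Neanderthal clade (the "macroclade Homo"
pattern expected for an ancestral-mtDNA numt), or with the Pan clade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import edlib
import numpy as np

from .mito_core import AnchoredSequence, NucSequence, reverse_complement

__all__ = [
    "AlignmentFailure",
    "PanelAlignment",
    "PlacementVerdict",
    "anchor_align",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "classify_placement",
]

#: ceiling distance assigned to saturated pairs
MAX_DISTANCE = 5.0

ROLES = ("human", "neanderthal", "numt", "chimp", "bonobo", "outgroup")


class AlignmentFailure(ValueError):
    pass


def anchor_align(
    seq: NucSequence, reference: NucSequence, min_identity: float = 0.70
) -> AnchoredSequence:
    """Anchor a sequence to the reference coordinate frame.

    Infix alignment with unit gap costs (edlib); indels are recorded
    relative to the reference: deletions appear as '-' columns, insertions
    are kept out of the frame keyed by the preceding reference position.
    Raises :class:`AlignmentFailure` below ``min_identity``.
    """
    res = edlib.align(seq.residues, reference.residues, mode="HW", task="path")
    start0, _end0 = res["locations"][0]
    columns: list[str] = []
    insertions: dict[int, str] = {}
    qi = 0
    ref_pos = start0  # 0-based position in reference of next column
    matches = cols = 0
    for length, op in _parse_cigar(res["cigar"]):
        cols += length
        if op in "=XM":
            for t in range(length):
                columns.append(seq.residues[qi + t])
                if seq.residues[qi + t] == reference.residues[ref_pos + t]:
                    matches += 1
            qi += length
            ref_pos += length
        elif op == "I":  # present in seq, absent from reference
            insertions[ref_pos] = insertions.get(ref_pos, "") + seq.residues[qi : qi + length]
            qi += length
        elif op == "D":  # deleted in seq relative to reference
            columns.extend("-" * length)
            ref_pos += length
    identity = matches / cols if cols else 0.0
    if identity < min_identity:
        raise AlignmentFailure(
            f"{seq.id}: identity {identity:.2f} below {min_identity:.2f}"
        )
    return AnchoredSequence(
        id=seq.id, ref_start=start0 + 1, columns="".join(columns),
        insertions=insertions,
    )


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


@dataclass
class PanelAlignment:
    """Equal-length rows with roles, columns mapped to reference coordinates."""

    labels: list[str]
    roles: dict[str, str]  # label -> role
    rows: np.ndarray  # (n, L) int8; 0..3 = ACGT, 4 = gap/N
    ref_start: int = 1  # reference coordinate of column 0

    _CODE = {b: i for i, b in enumerate("ACGT")}

    def __post_init__(self) -> None:
        if self.rows.ndim != 2 or len(self.labels) != self.rows.shape[0]:
            raise ValueError("rows/labels mismatch")
        for label, role in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for {label!r}")

    @property
    def n_sites(self) -> int:
        return self.rows.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.rows[self.labels.index(label)]

    def labels_with_role(self, role: str) -> list[str]:
        return [l for l in self.labels if self.roles.get(l) == role]

    def column_position(self, col: int) -> int:
        """Reference coordinate (1-based) of alignment column ``col``."""
        return self.ref_start + col

    @classmethod
    def from_sequences(
        cls,
        seqs: dict[str, NucSequence],
        roles: dict[str, str],
        ref_start: int = 1,
    ) -> "PanelAlignment":
        labels = list(seqs)
        lengths = {len(s.residues) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("panel rows must have equal length")
        (L,) = lengths
        rows = np.full((len(labels), L), 4, dtype=np.int8)
        for i, label in enumerate(labels):
            arr = np.frombuffer(seqs[label].residues.encode(), dtype=np.uint8)
            for base, code in cls._CODE.items():
                rows[i][arr == ord(base)] = code
        return cls(labels=labels, roles=roles, rows=rows, ref_start=ref_start)

    @classmethod
    def from_anchored(
        cls,
        anchored: list[AnchoredSequence],
        roles: dict[str, str],
        span: tuple[int, int] | None = None,
    ) -> "PanelAlignment":
        """Stack reference-anchored rows over the intersection (or ``span``)."""
        if span is None:
            lo = max(a.ref_start for a in anchored)
            hi = min(a.ref_end for a in anchored)
        else:
            lo, hi = span
        if lo > hi:
            raise ValueError("anchored rows do not overlap")
        # '-' and 'N' both become code 4 (missing) in from_sequences
        seqs = {a.id: NucSequence(a.id, a.slice_ref(lo, hi)) for a in anchored}
        return cls.from_sequences(seqs, roles, ref_start=lo)


# ---------------------------------------------------------------------------
# TN93 (+ gamma) distances


def _pair_counts(x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None):
    valid = (x < 4) & (y < 4)
    if weights is None:
        weights = np.ones(x.size)
    w = weights * valid
    n = w.sum()
    diff = (x != y) & valid
    purine = np.isin(x, (0, 2)) & np.isin(y, (0, 2))
    pyrim = np.isin(x, (1, 3)) & np.isin(y, (1, 3))
    p1 = (w * (diff & purine)).sum() / n if n else 0.0
    p2 = (w * (diff & pyrim)).sum() / n if n else 0.0
    q = (w * (diff & ~purine & ~pyrim)).sum() / n if n else 0.0
    return p1, p2, q, n


def _pair_freqs(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    valid = (x < 4) & (y < 4)
    counts = np.bincount(x[valid], minlength=4) + np.bincount(y[valid], minlength=4)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    freqs = counts / total
    return np.clip(freqs, 1e-6, None) / np.clip(freqs, 1e-6, None).sum()


def tn93_distance(
    p1: float, p2: float, q: float, freqs: np.ndarray, alpha: float | None = 0.2
) -> float:
    """Tamura-Nei (1993) distance, optionally gamma-corrected.

    ``p1``: proportion of purine transitions (A<->G), ``p2``: pyrimidine
    transitions (C<->T), ``q``: transversions.  ``alpha=None`` gives the
    uncorrected (infinite-shape) distance.
    """
    fa, fc, fg, ft = freqs
    gr, gy = fa + fg, fc + ft
    k1 = 2 * fa * fg / gr
    k2 = 2 * ft * fc / gy
    k3 = 2 * (gr * gy - fa * fg * gy / gr - ft * fc * gr / gy)
    e1 = 1 - p1 / k1 - q / (2 * gr)
    e2 = 1 - p2 / k2 - q / (2 * gy)
    e3 = 1 - q / (2 * gr * gy)
    if min(e1, e2, e3) <= 0:
        warnings.warn("saturated pair: distance set to ceiling")
        return MAX_DISTANCE
    if alpha is None or np.isinf(alpha):
        d = -k1 * np.log(e1) - k2 * np.log(e2) - k3 * np.log(e3)
    else:
        # alpha * (e^(-1/alpha) - 1) via expm1 to avoid cancellation
        d = alpha * (
            k1 * np.expm1(-np.log(e1) / alpha)
            + k2 * np.expm1(-np.log(e2) / alpha)
            + k3 * np.expm1(-np.log(e3) / alpha)
        )
    return min(float(d), MAX_DISTANCE)


def distance_matrix(
    panel: PanelAlignment,
    alpha: float | None = 0.2,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Symmetric TN93(+gamma) distance matrix with pairwise deletion."""
    n = len(panel.labels)
    if n < 2:
        raise ValueError("need at least two sequences")
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x, y = panel.rows[i], panel.rows[j]
            p1, p2, q, _ = _pair_counts(x, y, weights)
            freqs = _pair_freqs(x, y)
            dm[i, j] = dm[j, i] = tn93_distance(p1, p2, q, freqs, alpha)
    return dm


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Standard NJ agglomeration (Saitou & Nei / Studier & Keppler).

    Negative branch lengths are clamped to zero with a warning.  Ties in
    the Q criterion break to the lexicographically first label pair, so
    the result is deterministic.
    """
    dm = np.asarray(dm, dtype=float)
    n = dm.shape[0]
    if dm.shape != (n, n) or not np.allclose(dm, dm.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    if n < 3:
        raise ValueError("need at least three taxa")
    nodes = [f"{label}" for label in labels]  # newick fragments
    d = dm.copy()
    active = list(range(n))
    frag = {i: nodes[i] for i in active}
    clamped = False

    def blfmt(x: float) -> str:
        nonlocal clamped
        if x < 0:
            clamped = True
            x = 0.0
        return f"{x:.10g}"

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        qmat = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(qmat, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                key = (qmat[a, b], min(labels_key(frag[active[a]]), labels_key(frag[active[b]])),
                       max(labels_key(frag[active[a]]), labels_key(frag[active[b]])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        new_frag = f"({frag[i]}:{blfmt(li)},{frag[j]}:{blfmt(lj)})"
        new_d = 0.5 * (d[i, active] + d[j, active] - dij)
        # append new row/col
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = new_d
        d[active, k] = new_d
        active = [x for x in active if x not in (i, j)] + [k]
        frag[k] = new_frag

    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    newick = f"({frag[i]}:{blfmt(li)},{frag[j]}:{blfmt(lj)},{frag[k]}:{blfmt(lk)});"
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0")
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def labels_key(fragment: str) -> str:
    """First leaf label inside a newick fragment (deterministic tie-break)."""
    return fragment.strip("(").split(":", 1)[0].split(",", 1)[0]


# ---------------------------------------------------------------------------
# bootstrap and placement


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions as canonical frozensets.

    Each split is represented by the side not containing the
    lexicographically smallest leaf label.
    """
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    anchor = leaves[0]
    all_set = frozenset(leaves)
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = all_set - below if anchor in below else below
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


def bootstrap_support(
    panel: PanelAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    alpha: float | None = 0.2,
) -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """NJ tree with bootstrap supports in [0, 1].

    Columns are resampled with replacement ``n_reps`` times; support of
    each internal edge of the point-estimate tree is the fraction of
    replicates whose NJ tree contains the same bipartition.  Deterministic
    given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    dm0 = distance_matrix(panel, alpha)
    tree = nj_tree(dm0, panel.labels)
    focal = _bipartitions(tree)
    if np.all(dm0 == 0):
        # degenerate panel: the arbitrary resolution carries no signal
        return tree, {bp: 0.0 for bp in focal}
    counts = {bp: 0 for bp in focal}
    L = panel.n_sites
    for _ in range(n_reps):
        w = rng.multinomial(L, np.full(L, 1.0 / L)).astype(float)
        dm = distance_matrix(panel, alpha, weights=w)
        rep = nj_tree(dm, panel.labels)
        rep_bps = _bipartitions(rep)
        for bp in focal:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: counts[bp] / n_reps for bp in focal}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
        side = frozenset(leaves) - below if leaves[0] in below else below
        if side in supports:
            node.label = f"{supports[side]:.3f}"
    return tree, supports


@dataclass(frozen=True)
class PlacementVerdict:
    verdict: str  # within_human | basal_to_human_neanderthal | within_pan | unresolved
    support: float | None = None  # support of the deciding bipartition, if known


def classify_placement(
    tree: dendropy.Tree,
    roles: dict[str, str],
    numt_label: str | None = None,
    supports: dict[frozenset, float] | None = None,
) -> PlacementVerdict:
    """Topological verdict for a numt's attachment point.

    ``basal_to_human_neanderthal``: the humans+Neanderthal group is
    monophyletic without the numt, and the numt attaches on the path
    between that group and the Pan clade (the ancestral-numt signature).
    The verdict depends only on the unrooted topology and the roles.
    """
    leaf_roles = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in roles:
            raise ValueError(f"role missing for leaf {label!r}")
        leaf_roles[label] = roles[label]
    humans = {l for l, r in leaf_roles.items() if r == "human"}
    nea = {l for l, r in leaf_roles.items() if r == "neanderthal"}
    pan = {l for l, r in leaf_roles.items() if r in ("chimp", "bonobo")}
    numts = [l for l, r in leaf_roles.items() if r == "numt"]
    if numt_label is None:
        if len(numts) != 1:
            raise ValueError("specify numt_label when the panel has several numts")
        numt_label = numts[0]
    if len(humans) < 2 or len(nea) != 1 or not pan:
        raise ValueError("panel must contain >=2 humans, 1 neanderthal, >=1 pan")

    bps = _clades(tree)
    hn = humans | nea

    def present(group: set) -> bool:
        return frozenset(group) in bps

    def support_of(group: set) -> float | None:
        if supports is None:
            return None
        leaves = sorted(leaf_roles)
        side = frozenset(group)
        canon = frozenset(leaves) - side if leaves[0] in side else side
        return supports.get(canon)

    if present(hn) and present(hn | {numt_label}):
        return PlacementVerdict("basal_to_human_neanderthal", support_of(hn))

    def attaches_within(group: set) -> bool:
        # some split puts the numt together with a nonempty subset of the
        # group (and nothing else), i.e. its attachment edge is inside it
        for side in bps:
            if numt_label in side:
                inner = set(side) - {numt_label}
                if inner and inner <= group:
                    return True
        return False

    if attaches_within(humans):
        return PlacementVerdict("within_human", support_of(humans | {numt_label}))
    if attaches_within(pan):
        return PlacementVerdict("within_pan", support_of(pan | {numt_label}))
    return PlacementVerdict("unresolved")


def _clades(tree: dendropy.Tree) -> set[frozenset]:
    """All groups appearing as one side of an unrooted bipartition."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    all_set = frozenset(leaves)
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        out.add(below)
        out.add(all_set - below)
    return out


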