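"""Per-gene selection tests against an ancestral (numt-derived) sequence.

* McDonald-Kreitman 2x2 counts per protein gene: synonymous and
  nonsynonymous changes partitioned into polymorphism (variable within
  the human panel) and divergence (fixed differences between the human
  panel and the ancestral sequence), with Fisher's exact test and the
  neutrality index NI = (Pn/Ps)/(Dn/Ds);
* Fitch/Sankoff parsimony assignment of amino-acid replacements to
  branches, with ambiguous assignments counted fractionally over all
  most-parsimonious reconstructions;
* counting-based branch dN/dS with Nei-Gojobori-style site
  opportunities.

All codon arithmetic uses the vertebrate mitochondrial genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mito_core import MITO_CODON_TABLE, translate_mito
from .clock_dating import Topology

__all__ = [
    "MKCounts",
    "MKResult",
    "BranchChangeSummary",
    "classify_change",
    "mk_counts",
    "mk_test",
    "fisher_exact_2x2",
    "neutrality_index",
    "assign_changes_to_branches",
    "branch_dnds",
    "ng86_sites",
    "unique_amino_acids",
]


@dataclass(frozen=True)
class MKCounts:
    gene: str
    ds: int  # synonymous fixed differences (divergence)
    dn: int  # nonsynonymous fixed differences
    ps: int  # synonymous polymorphisms within the ingroup
    pn: int  # nonsynonymous polymorphisms
    partial: bool = False  # gene only partially covered by the ancestral row

    def __post_init__(self) -> None:
        if min(self.ds, self.dn, self.ps, self.pn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class MKResult:
    counts: MKCounts
    p_value: float
    neutrality_index: float | None  # None when undefined (Ps, Dn or Ds zero)


@dataclass(frozen=True)
class BranchChangeSummary:
    branch: str  # label of the node below the branch
    nonsynonymous: float
    synonymous: float
    dn: float | None = None
    ds: float | None = None

    @property
    def dnds(self) -> float | None:
        if self.dn is None or self.ds is None or self.ds == 0:
            return None
        return self.dn / self.ds


class ExcludedCodon(Exception):
    """Codon contains a gap or masked base and must be skipped."""


def classify_change(
    codon_context: str, position_in_codon: int, ref_base: str, alt_base: str
) -> str:
    """Classify one base change given its (consensus) codon context.

    Returns "synonymous", "nonsynonymous" or "nonsense" under the
    vertebrate mitochondrial code.  Raises :class:`ExcludedCodon` if the
    context contains a non-ACGT character.
    """
    if set(codon_context) - set("ACGT"):
        raise ExcludedCodon(codon_context)
    if position_in_codon not in (1, 2, 3):
        raise ValueError("position_in_codon must be 1..3")
    i = position_in_codon - 1
    ref_codon = codon_context[:i] + ref_base + codon_context[i + 1 :]
    alt_codon = codon_context[:i] + alt_base + codon_context[i + 1 :]
    aa_ref, aa_alt = translate_mito(ref_codon), translate_mito(alt_codon)
    if aa_alt == "*" and aa_ref != "*":
        return "nonsense"
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def _consensus_codon(codons: list[str]) -> str | None:
    votes: dict[str, int] = {}
    for c in codons:
        if set(c) <= set("ACGT"):
            votes[c] = votes.get(c, 0) + 1
    if not votes:
        return None
    return max(sorted(votes), key=lambda c: votes[c])


def mk_counts(
    human_cds: list[str],
    ancestral_cds: str,
    gene: str,
    excluded_codons: set[int] | None = None,
    partial: bool = False,
) -> MKCounts:
    """McDonald-Kreitman 2x2 counts for one codon-aligned protein gene.

    A site variable within the human rows contributes polymorphism; a
    site fixed in humans but different in the ancestral row contributes
    divergence; a site that is both variable and divergent counts as
    polymorphism only.  Changes are classified against the human
    consensus codon, decomposing multi-hit codons position 1 -> 3.
    Codons listed in ``excluded_codons`` (1-based, e.g. from the ORF
    repair log) are dropped, as are codons containing gaps.
    """
    L = len(ancestral_cds)
    if any(len(h) != L for h in human_cds) or L % 3:
        raise ValueError("rows must be codon-aligned and equal length")
    excluded_codons = excluded_codons or set()
    ds = dn = ps = pn = 0
    for ci in range(L // 3):
        if ci + 1 in excluded_codons:
            continue
        codons = [h[3 * ci : 3 * ci + 3] for h in human_cds]
        anc = ancestral_cds[3 * ci : 3 * ci + 3]
        context = _consensus_codon(codons)
        if context is None:
            continue
        for k in range(3):
            alleles = {c[k] for c in codons if c[k] in "ACGT"}
            if not alleles:
                continue
            cons_base = context[k]
            polymorphic = len(alleles) > 1
            if polymorphic:
                for allele in sorted(alleles - {cons_base}):
                    try:
                        cls = classify_change(context, k + 1, cons_base, allele)
                    except ExcludedCodon:
                        continue
                    if cls == "synonymous":
                        ps += 1
                    else:
                        pn += 1
            elif anc[k] in "ACGT" and anc[k] != cons_base:
                try:
                    cls = classify_change(context, k + 1, cons_base, anc[k])
                except ExcludedCodon:
                    continue
                if cls == "synonymous":
                    ds += 1
                else:
                    dn += 1
    return MKCounts(gene, ds, dn, ps, pn, partial=partial)


def fisher_exact_2x2(counts: MKCounts) -> float:
    """Two-tailed Fisher exact p for the MK table [[Ds, Ps], [Dn, Pn]].

    Two-tailed by summation of hypergeometric probabilities not
    exceeding that of the observed table; a zero margin gives p = 1.
    """
    table = np.array([[counts.ds, counts.ps], [counts.dn, counts.pn]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def neutrality_index(counts: MKCounts, decimals: int = 3) -> float | None:
    """NI = (Pn/Ps)/(Dn/Ds); None when Ps, Dn or Ds is zero."""
    if counts.ps == 0 or counts.dn == 0 or counts.ds == 0:
        return None
    ni = (counts.pn / counts.ps) / (counts.dn / counts.ds)
    return round(ni, decimals)


def mk_test(
    human_cds: list[str],
    ancestral_cds: str,
    gene: str,
    excluded_codons: set[int] | None = None,
    partial: bool = False,
) -> MKResult:
    counts = mk_counts(human_cds, ancestral_cds, gene, excluded_codons, partial)
    return MKResult(counts, fisher_exact_2x2(counts), neutrality_index(counts))


# ---------------------------------------------------------------------------
# parsimony assignment of changes to branches


def _site_change_fractions(
    topo: Topology, tip_states: dict[str, str]
) -> dict[int, float]:
    """Expected per-branch change counts for one site, averaged uniformly
    over all most-parsimonious labelings (Sankoff DP with solution
    counting).  Keys are node ids; the value for node v is the change
    fraction on the edge above v."""
    alphabet = sorted(set(tip_states.values()) - {"-", "N", "X", "?"})
    if len(alphabet) <= 1:
        return {}
    k = len(alphabet)
    idx = {a: i for i, a in enumerate(alphabet)}
    INF = 10**9
    cost = np.zeros((topo.n_nodes, k), dtype=np.int64)
    count = np.zeros((topo.n_nodes, k), dtype=float)  # MP labelings per state
    for node in topo.postorder:
        if topo.children[node] is None:
            s = tip_states[topo.labels[node]]
            if s in idx:
                cost[node] = INF
                cost[node, idx[s]] = 0
                count[node] = 0.0
                count[node, idx[s]] = 1.0
            else:  # missing data: free
                cost[node] = 0
                count[node] = 1.0
            continue
        for s in range(k):
            c_total, n_total = 0, 1.0
            for ch in topo.children[node]:
                # min over child states of cost + 1[change]
                opts = cost[ch] + (np.arange(k) != s)
                m = opts.min()
                c_total += int(m)
                n_total *= count[ch][opts == m].sum()
            cost[node, s] = c_total
            count[node, s] = n_total
    root = topo.root
    best = cost[root].min()
    root_states = np.nonzero(cost[root] == best)[0]
    total_solutions = count[root, root_states].sum()
    if total_solutions == 0:
        return {}

    # top-down pass: prob[node][s] = fraction of MP solutions with node=s
    prob = np.zeros((topo.n_nodes, k))
    for s in root_states:
        prob[root, s] = count[root, s] / total_solutions
    changes: dict[int, float] = {}
    for node in reversed(topo.postorder):  # preorder
        if topo.children[node] is None:
            continue
        for ch in topo.children[node]:
            frac = 0.0
            ch_prob = np.zeros(k)
            for s in range(k):
                if prob[node, s] == 0:
                    continue
                opts = cost[ch] + (np.arange(k) != s)
                m = opts.min()
                sel = opts == m
                denom = count[ch][sel].sum()
                for t in np.nonzero(sel)[0]:
                    w = prob[node, s] * count[ch, t] / denom
                    ch_prob[t] += w
                    if t != s:
                        frac += w
            prob[ch] = ch_prob
            if frac > 1e-12:
                changes[ch] = changes.get(ch, 0.0) + frac
    return changes


def assign_changes_to_branches(
    protein_rows: dict[str, str], topo: Topology
) -> list[BranchChangeSummary]:
    """Assign amino-acid replacements to branches by parsimony.

    Ambiguous reconstructions are counted fractionally over all
    most-parsimonious solutions, so homoplasy-free sites give exact
    integer counts on the generating branches.
    """
    labels = topo.tip_labels()
    lengths = {len(protein_rows[l]) for l in labels}
    if len(lengths) != 1:
        raise ValueError("protein rows must be aligned")
    (L,) = lengths
    per_branch: dict[int, float] = {}
    for col in range(L):
        tip_states = {l: protein_rows[l][col] for l in labels}
        for node, frac in _site_change_fractions(topo, tip_states).items():
            per_branch[node] = per_branch.get(node, 0.0) + frac
    names = _branch_names(topo)
    return [
        BranchChangeSummary(branch=names[node], nonsynonymous=frac, synonymous=0.0)
        for node, frac in sorted(per_branch.items())
    ]


def _branch_names(topo: Topology) -> dict[int, str]:
    leafsets = topo.clade_leafsets()
    names = {}
    for node in range(topo.n_nodes):
        if topo.labels[node]:
            names[node] = topo.labels[node]
        else:
            ls = sorted(leafsets[node])
            names[node] = f"mrca({ls[0]},{ls[-1]})"
    return names


# ---------------------------------------------------------------------------
# counting-based branch dN/dS


def ng86_sites(cds: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site opportunities of a CDS.

    Per codon position, the fraction of the three possible single-base
    changes that alter the protein (mitochondrial code); stop-creating
    changes count as nonsynonymous.  Codons with gaps are skipped.
    """
    n_sites = s_sites = 0.0
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if set(codon) - set("ACGT") or MITO_CODON_TABLE[codon] == "*":
            continue
        for k in range(3):
            syn = 0
            for b in "ACGT":
                if b == codon[k]:
                    continue
                alt = codon[:k] + b + codon[k + 1 :]
                if MITO_CODON_TABLE[alt] == MITO_CODON_TABLE[codon]:
                    syn += 1
            s_sites += syn / 3.0
            n_sites += 1 - syn / 3.0
    return n_sites, s_sites


def _fitch_states(topo: Topology, tip_states: dict[str, str]) -> dict[int, str]:
    """Deterministic most-parsimonious ancestral states for one site
    (ties broken to the alphabetically smallest state)."""
    alphabet = sorted(set(tip_states.values()) - {"-", "N", "?"})
    if not alphabet:
        return {}
    k = len(alphabet)
    idx = {a: i for i, a in enumerate(alphabet)}
    INF = 10**9
    cost = np.zeros((topo.n_nodes, k), dtype=np.int64)
    for node in topo.postorder:
        if topo.children[node] is None:
            s = tip_states[topo.labels[node]]
            if s in idx:
                cost[node] = INF
                cost[node, idx[s]] = 0
            else:
                cost[node] = 0
            continue
        for s in range(k):
            cost[node, s] = sum(
                int((cost[ch] + (np.arange(k) != s)).min())
                for ch in topo.children[node]
            )
    states: dict[int, str] = {}
    for node in reversed(topo.postorder):
        if topo.children[node] is None:
            s = tip_states[topo.labels[node]]
            states[node] = s if s in idx else states.get(topo.parent[node], alphabet[0])
            continue
        if node == topo.root:
            states[node] = alphabet[int(cost[node].argmin())]
        else:
            parent_s = idx[states[topo.parent[node]]]
            opts = cost[node] + (np.arange(k) != parent_s)
            states[node] = alphabet[int(opts.argmin())]
    return states


def branch_dnds(
    cds_rows: dict[str, str],
    topo: Topology,
    flag_level: float = 0.004,
) -> list[BranchChangeSummary]:
    """Counting-based per-branch dN/dS on a codon-aligned nucleotide panel.

    Ancestral sequences are reconstructed by per-site parsimony; each
    branch's changes are decomposed codon by codon (positions taken in
    order) and classified against the parent codon.  Opportunities are
    Nei-Gojobori site counts of the parent sequence.  A branch is
    flagged (``dnds`` left defined but reported by the caller) when its
    nonsynonymous fraction differs from the pooled fraction at the
    ``flag_level`` by a two-sided binomial test.
    """
    labels = topo.tip_labels()
    L = len(next(iter(cds_rows.values())))
    if L % 3:
        raise ValueError("rows must be codon-aligned")
    # reconstruct ancestral sequences site by site
    node_seqs = {n: [] for n in range(topo.n_nodes)}
    for col in range(L):
        tip_states = {l: cds_rows[l][col] for l in labels}
        states = _fitch_states(topo, tip_states)
        fallback = next(iter(states.values())) if states else "N"
        for n in range(topo.n_nodes):
            node_seqs[n].append(states.get(n, fallback))
    node_seqs = {n: "".join(s) for n, s in node_seqs.items()}

    names = _branch_names(topo)
    out = []
    for node in range(topo.n_nodes):
        if node == topo.root:
            continue
        parent_seq = node_seqs[topo.parent[node]]
        child_seq = node_seqs[node]
        n_changes = s_changes = 0.0
        for i in range(0, L - 2, 3):
            pc, cc = parent_seq[i : i + 3], child_seq[i : i + 3]
            if pc == cc:
                continue
            if set(pc + cc) - set("ACGT"):
                continue
            context = list(pc)
            for k in range(3):
                if pc[k] == cc[k]:
                    continue
                cls = classify_change("".join(context), k + 1, context[k], cc[k])
                if cls == "synonymous":
                    s_changes += 1
                else:
                    n_changes += 1
                context[k] = cc[k]
        n_sites, s_sites = ng86_sites(parent_seq)
        dn = n_changes / n_sites if n_sites else None
        ds = s_changes / s_sites if s_sites else None
        out.append(
            BranchChangeSummary(
                branch=names[node], nonsynonymous=n_changes, synonymous=s_changes,
                dn=dn, ds=ds,
            )
        )
    return out


def flag_heterogeneous_branches(
    summaries: list[BranchChangeSummary], level: float = 0.004
) -> list[str]:
    """Branches whose syn/nonsyn split deviates from the pooled split
    (two-sided binomial test at the Bonferroni-style ``level``)."""
    total_n = sum(s.nonsynonymous for s in summaries)
    total_s = sum(s.synonymous for s in summaries)
    if total_n + total_s == 0:
        return []
    p_pool = total_n / (total_n + total_s)
    flagged = []
    for s in summaries:
        m = int(round(s.nonsynonymous + s.synonymous))
        if m == 0:
            continue
        p = stats.binomtest(int(round(s.nonsynonymous)), m, p_pool).pvalue
        if p < level:
            flagged.append(s.branch)
    return flagged


# ---------------------------------------------------------------------------
# unique amino acids


@dataclass(frozen=True)
class UniqueResidue:
    position: int  # 1-based column in the protein alignment
    focal_residue: str
    panel_residues: str
    known_in_other_species: bool | None = None  # None = no orthologue panel


def unique_amino_acids(
    protein_rows: dict[str, str],
    focal_label: str,
    orthologue_rows: dict[str, str] | None = None,
) -> list[UniqueResidue]:
    """Residues where the focal protein differs from every panel row.

    Residues also present in a separate orthologue panel are flagged
    "known in other species" (and therefore remain candidates for a
    mitochondrial, pre-insertion origin).
    """
    focal = protein_rows[focal_label]
    others = [v for k, v in protein_rows.items() if k != focal_label]
    if any(len(o) != len(focal) for o in others):
        raise ValueError("protein rows must be aligned")
    if orthologue_rows is not None and any(
        len(v) != len(focal) for v in orthologue_rows.values()
    ):
        raise ValueError("orthologue rows must be aligned to the panel")
    out = []
    for col, res in enumerate(focal):
        if res in "-X?":
            continue
        panel_res = {o[col] for o in others if o[col] not in "-X?"}
        if not panel_res or res in panel_res:
            continue
        known = None
        if orthologue_rows is not None:
            known = any(v[col] == res for v in orthologue_rows.values())
        out.append(
            UniqueResidue(
                position=col + 1,
                focal_residue=res,
                panel_residues="".join(sorted(panel_res)),
                known_in_other_species=known,
            )
        )
    return out
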