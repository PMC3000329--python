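"""Mutation-provenance tests: did a numt's private changes arise in the
mitochondrion (before insertion) or in the nucleus (after insertion)?

Functional mitochondrial protein genes accumulate substitutions with a
2:1:5 codon-position bias and a transition bias up to 15:1; once a
sequence is a noncoding numt, new changes hit codon positions uniformly
(1:1:1), show ts/tv near 2, are enriched at CpG dinucleotides, and can
freely disrupt reading frames.  Each private substitution of a focal
sequence against a panel is therefore scored for codon position, ts/tv
class, CpG context and reading-frame impact, and the aggregate pattern
is called as a mitochondrial or nuclear signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .mito_core import (
    AnchoredSequence,
    CodonAddress,
    MtGeneMap,
    NucSequence,
    ProjectedSite,
    codon_span,
    project_position,
    translate_mito,
)
from .phylo_placement import PanelAlignment

__all__ = [
    "SubstitutionRecord",
    "OrfDisruption",
    "CodonBiasTest",
    "TsTvSummary",
    "CodonEdit",
    "ProvenanceReport",
    "call_private_substitutions",
    "codon_position_test",
    "tstv_summary",
    "orf_integrity_scan",
    "repair_disruptions",
    "cpg_check",
    "pathogenic_overlap",
    "provenance_verdict",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITIONS


@dataclass(frozen=True)
class SubstitutionRecord:
    """One private nucleotide difference of a focal row against a panel."""

    position: int  # reference coordinate, 1-based
    site: ProjectedSite
    ref_base: str  # panel consensus state
    alt_base: str  # focal state
    is_transition: bool
    cpg_context: bool | None  # None = context unknown (sequence edge)
    privacy: str  # "private_to_focal" or "shared"
    coding_class: str | None = None  # synonymous | nonsynonymous | nonsense


@dataclass(frozen=True)
class OrfDisruption:
    gene: str
    codon: CodonAddress
    kind: str  # "premature_stop" | "frameshift_indel"
    detail: str = ""
    repair: str | None = None


@dataclass(frozen=True)
class CodonBiasTest:
    counts: tuple[int, int, int]
    weights: tuple[float, float, float]
    statistic: float  # chi-square goodness-of-fit statistic
    p_value: float
    method: str  # "exact_multinomial" | "chi_square"


@dataclass(frozen=True)
class TsTvSummary:
    transitions: int
    transversions: int
    ratio: float | None  # None when transversions == 0
    infinite: bool


@dataclass(frozen=True)
class CodonEdit:
    gene: str
    codon_index: int
    action: str  # replaced_with_panel_majority | excluded_codon | masked
    old: str
    new: str | None


def _mito_codon_class(context: str, pos_in_codon: int, ref: str, alt: str) -> str:
    codon_ref = context[: pos_in_codon - 1] + ref + context[pos_in_codon:]
    codon_alt = context[: pos_in_codon - 1] + alt + context[pos_in_codon:]
    aa_ref = translate_mito(codon_ref)
    aa_alt = translate_mito(codon_alt)
    if aa_alt == "*":
        return "nonsense"
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def call_private_substitutions(
    panel: PanelAlignment,
    focal_label: str,
    gene_map: MtGeneMap,
    compare_roles: tuple[str, ...] = ("human", "neanderthal"),
) -> list[SubstitutionRecord]:
    """Substitutions of the focal row not present in any panel row.

    A site is private when the focal state is a proper base that differs
    from every (non-gap) state carried by the comparison rows; columns
    where the focal or all comparison rows are gap/N are skipped.  The
    reference state of a record is the consensus of the comparison rows.
    CpG context and syn/nonsyn class are read off the consensus
    sequence.
    """
    if focal_label not in panel.labels:
        raise ValueError(f"focal {focal_label!r} not in panel")
    focal = panel.row(focal_label)
    others = [
        panel.row(l)
        for l in panel.labels
        if l != focal_label and panel.roles.get(l) in compare_roles
    ]
    if not others:
        raise ValueError("no comparison rows with the requested roles")
    others = np.vstack(others)

    # consensus of comparison rows (most frequent proper base per column)
    consensus = np.full(panel.n_sites, 4, dtype=np.int8)
    for col in range(panel.n_sites):
        column = others[:, col]
        column = column[column < 4]
        if column.size:
            consensus[col] = np.bincount(column, minlength=4).argmax()

    records = []
    bases = "ACGT"
    for col in np.nonzero((focal < 4) & (consensus < 4) & (focal != consensus))[0]:
        column = others[:, col]
        proper = column[column < 4]
        if proper.size == 0 or np.any(proper == focal[col]):
            continue  # shared with some panel row: not private
        pos = panel.column_position(int(col))
        site = project_position(pos, gene_map)
        ref_b = bases[consensus[col]]
        alt_b = bases[focal[col]]
        cpg = _cpg_flag(consensus, int(col), ref_b, alt_b)
        coding_class = None
        if site.category == "coding" and not site.incomplete_codon:
            gene = gene_map.gene(site.gene)
            lo, hi = codon_span(gene, site.codon.codon_index)
            ctx = []
            ok = True
            for p in range(lo, hi + 1):
                c = p - panel.ref_start
                if 0 <= c < panel.n_sites and consensus[c] < 4:
                    ctx.append(bases[consensus[c]])
                else:
                    ok = False
            if ok and len(ctx) == 3:
                context = "".join(ctx)
                if gene.strand == "L":
                    from .mito_core import reverse_complement

                    context = reverse_complement(context)
                    coding_class = _mito_codon_class(
                        context,
                        site.codon.codon_position,
                        _comp(ref_b),
                        _comp(alt_b),
                    )
                else:
                    coding_class = _mito_codon_class(
                        context, site.codon.codon_position, ref_b, alt_b
                    )
        records.append(
            SubstitutionRecord(
                position=pos,
                site=site,
                ref_base=ref_b,
                alt_base=alt_b,
                is_transition=is_transition(ref_b, alt_b),
                cpg_context=cpg,
                privacy="private_to_focal",
                coding_class=coding_class,
            )
        )
    return records


def _comp(b: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[b]


def _cpg_flag(consensus: np.ndarray, col: int, ref_b: str, alt_b: str) -> bool | None:
    """C->T with a 3' G, or G->A with a 5' C, on the reference context."""
    bases = "ACGT"
    if ref_b == "C" and alt_b == "T":
        if col + 1 >= consensus.size:
            return None
        nxt = consensus[col + 1]
        return nxt < 4 and bases[nxt] == "G"
    if ref_b == "G" and alt_b == "A":
        if col - 1 < 0:
            return None
        prv = consensus[col - 1]
        return prv < 4 and bases[prv] == "C"
    return False


# ---------------------------------------------------------------------------
# codon-position bias test


def codon_position_test(
    counts: tuple[int, int, int],
    weights: tuple[float, float, float] = (2.0, 1.0, 5.0),
    exact_threshold: int = 200,
) -> CodonBiasTest:
    """Goodness of fit of substitution counts at codon positions 1/2/3.

    Exact multinomial test (sum of probabilities of outcomes no more
    probable than the observed one) for totals up to
    ``exact_threshold``; Pearson chi-square with 2 df otherwise.  The
    reported statistic is the chi-square statistic in both cases.
    """
    counts = tuple(int(c) for c in counts)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("all-zero counts")
    if any(w <= 0 for w in weights):
        raise ValueError("weights must be positive")
    p = np.asarray(weights, dtype=float)
    p = p / p.sum()
    expected = n * p
    statistic = float(((np.asarray(counts) - expected) ** 2 / expected).sum())
    if n <= exact_threshold:
        a, b = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        keep = a + b <= n
        outcomes = np.stack([a[keep], b[keep], n - a[keep] - b[keep]], axis=1)
        pmf = stats.multinomial.pmf(outcomes, n, p)
        pmf_obs = stats.multinomial.pmf(counts, n, p)
        total = pmf[pmf <= pmf_obs * (1 + 1e-9)].sum()
        return CodonBiasTest(counts, tuple(weights), statistic,
                             float(min(total, 1.0)), "exact_multinomial")
    p_value = float(stats.chi2.sf(statistic, df=2))
    return CodonBiasTest(counts, tuple(weights), statistic, p_value, "chi_square")


def tstv_summary(records: list[SubstitutionRecord]) -> TsTvSummary:
    ts = sum(1 for r in records if r.is_transition)
    tv = len(records) - ts
    if tv == 0:
        return TsTvSummary(ts, 0, None, infinite=ts > 0)
    return TsTvSummary(ts, tv, ts / tv, infinite=False)


# ---------------------------------------------------------------------------
# reading-frame integrity


def orf_integrity_scan(
    focal: AnchoredSequence, gene_map: MtGeneMap
) -> list[OrfDisruption]:
    """Premature stops and frameshifting indels in protein genes.

    Every codon that translates to '*' before the annotated terminus is
    reported, as is every indel whose length is not a multiple of three
    inside a protein gene span.
    """
    from .mito_core import extract_gene

    out: list[OrfDisruption] = []
    for gene in gene_map.protein_genes:
        if focal.ref_start > gene.end or focal.ref_end < gene.start:
            continue
        extract = extract_gene(focal, gene)
        seq = extract.sequence.residues
        for i in range(0, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            idx = extract.first_codon + i // 3
            if "-" in codon or "N" in codon:
                continue
            if translate_mito(codon) == "*" and idx < gene.n_full_codons:
                out.append(
                    OrfDisruption(
                        gene.name,
                        CodonAddress(gene.name, idx, 1),
                        "premature_stop",
                        detail=codon,
                    )
                )
        # deletions: runs of '-' in the anchored columns within the gene span
        lo = max(gene.start, focal.ref_start)
        hi = min(gene.end, focal.ref_end)
        run = 0
        for pos in range(lo, hi + 2):
            ch = focal.base_at(pos) if pos <= hi else "."
            if ch == "-":
                run += 1
            elif run:
                if run % 3 != 0:
                    addr = project_position(pos - run, gene_map)
                    codon = addr.codon or CodonAddress(gene.name, 1, 1)
                    out.append(
                        OrfDisruption(gene.name, codon, "frameshift_indel",
                                      detail=f"del{run}")
                    )
                run = 0
        # insertions relative to the reference
        for pos, ins in focal.insertions.items():
            if gene.start <= pos <= gene.end and len(ins) % 3 != 0:
                addr = project_position(pos, gene_map)
                codon = addr.codon or CodonAddress(gene.name, 1, 1)
                out.append(
                    OrfDisruption(gene.name, codon, "frameshift_indel",
                                  detail=f"ins{len(ins)}")
                )
    return out


def repair_disruptions(
    focal: AnchoredSequence,
    disruptions: list[OrfDisruption],
    panel_rows: list[AnchoredSequence],
    gene_map: MtGeneMap,
    policy: str = "replace_with_panel_majority",
) -> tuple[AnchoredSequence, list[CodonEdit]]:
    """Repair or exclude ORF disruptions before coding-sequence analyses.

    ``replace_with_panel_majority`` substitutes the panel-majority codon
    at premature stops; frameshifted codons and anything without a panel
    consensus are excluded (or masked).  The edit log records every
    altered and excluded codon so downstream analyses can drop them.
    """
    if policy not in ("replace_with_panel_majority", "exclude_codon", "mask"):
        raise ValueError(f"unknown policy {policy!r}")
    cols = list(focal.columns)
    log: list[CodonEdit] = []
    for d in disruptions:
        gene = gene_map.gene(d.gene)
        lo, hi = codon_span(gene, d.codon.codon_index)
        old = "".join(
            focal.columns[p - focal.ref_start]
            for p in range(lo, hi + 1)
            if focal.ref_start <= p <= focal.ref_end
        )
        if d.kind == "frameshift_indel" or policy == "exclude_codon":
            log.append(CodonEdit(d.gene, d.codon.codon_index, "excluded_codon",
                                 old, None))
            continue
        if policy == "mask":
            for p in range(lo, hi + 1):
                if focal.ref_start <= p <= focal.ref_end:
                    cols[p - focal.ref_start] = "N"
            log.append(CodonEdit(d.gene, d.codon.codon_index, "masked", old, None))
            continue
        votes: dict[str, int] = {}
        for row in panel_rows:
            codon = "".join(row.base_at(p) for p in range(lo, hi + 1))
            if set(codon) <= set("ACGT"):
                votes[codon] = votes.get(codon, 0) + 1
        if not votes:
            for p in range(lo, hi + 1):
                if focal.ref_start <= p <= focal.ref_end:
                    cols[p - focal.ref_start] = "N"
            log.append(CodonEdit(d.gene, d.codon.codon_index, "masked", old, None))
            continue
        best = max(sorted(votes), key=lambda c: votes[c])
        for k, p in enumerate(range(lo, hi + 1)):
            if focal.ref_start <= p <= focal.ref_end:
                cols[p - focal.ref_start] = best[k]
        log.append(
            CodonEdit(d.gene, d.codon.codon_index, "replaced_with_panel_majority",
                      old, best)
        )
    repaired = AnchoredSequence(
        id=focal.id, ref_start=focal.ref_start, columns="".join(cols),
        insertions=dict(focal.insertions),
    )
    return repaired, log


def cpg_check(records: list[SubstitutionRecord]) -> tuple[int, int]:
    """(CpG-type changes, context-unknown sites) among the records."""
    flagged = sum(1 for r in records if r.cpg_context is True)
    unknown = sum(1 for r in records if r.cpg_context is None)
    return flagged, unknown


def pathogenic_overlap(
    records: list[SubstitutionRecord], site_table: list[tuple[int, str, str]]
) -> list[tuple[SubstitutionRecord, str]]:
    """Intersect private substitutions with known pathogenic alleles.

    ``site_table`` rows are (position, pathogenic allele, label); a hit
    requires both the position and the focal allele to match.
    """
    index: dict[tuple[int, str], str] = {}
    for i, row in enumerate(site_table, start=1):
        try:
            pos, allele, label = int(row[0]), str(row[1]).upper(), str(row[2])
        except (ValueError, IndexError, TypeError) as exc:
            raise ValueError(f"malformed pathogenic-site row {i}: {row!r}") from exc
        if allele not in "ACGT" or len(allele) != 1:
            raise ValueError(f"malformed pathogenic-site row {i}: {row!r}")
        index[(pos, allele)] = label
    return [
        (r, index[(r.position, r.alt_base)])
        for r in records
        if (r.position, r.alt_base) in index
    ]


def read_pathogenic_table(path) -> list[tuple[int, str, str]]:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("position\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed pathogenic-site line {i}: {line!r}")
            rows.append((int(parts[0]), parts[1], parts[2]))
    return rows


def per_gene_report(records: list[SubstitutionRecord]):
    """Per-gene table of private substitutions: counts at codon positions
    1/2/3, both goodness-of-fit p-values, transitions and transversions."""
    import pandas as pd

    by_gene: dict[str, list[SubstitutionRecord]] = {}
    for r in records:
        if r.site.category == "coding":
            by_gene.setdefault(r.site.gene, []).append(r)
    rows = []
    for gene in sorted(by_gene):
        recs = by_gene[gene]
        counts = [0, 0, 0]
        for r in recs:
            if not r.site.incomplete_codon:
                counts[r.site.codon.codon_position - 1] += 1
        t = tstv_summary(recs)
        p215 = p111 = None
        if sum(counts) > 0:
            p215 = codon_position_test(tuple(counts), (2, 1, 5)).p_value
            p111 = codon_position_test(tuple(counts), (1, 1, 1)).p_value
        rows.append(
            {
                "gene": gene, "pos1": counts[0], "pos2": counts[1],
                "pos3": counts[2], "p_2_1_5": p215, "p_1_1_1": p111,
                "transitions": t.transitions, "transversions": t.transversions,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "pos1", "pos2", "pos3", "p_2_1_5", "p_1_1_1",
                 "transitions", "transversions"],
    )


# ---------------------------------------------------------------------------
# verdict


@dataclass
class ProvenanceReport:
    focal: str
    n_private: int
    codon_position_counts: tuple[int, int, int]
    bias_test_215: CodonBiasTest | None
    bias_test_111: CodonBiasTest | None
    tstv: TsTvSummary
    cpg_count: int
    orf_disruptions: list[OrfDisruption] = field(default_factory=list)
    pathogenic_hits: list = field(default_factory=list)
    verdict: str = "mitochondrial-signature"

    def to_dict(self) -> dict:
        return {
            "focal": self.focal,
            "n_private": self.n_private,
            "codon_position_counts": list(self.codon_position_counts),
            "p_2_1_5": self.bias_test_215.p_value if self.bias_test_215 else None,
            "p_1_1_1": self.bias_test_111.p_value if self.bias_test_111 else None,
            "transitions": self.tstv.transitions,
            "transversions": self.tstv.transversions,
            "tstv_ratio": self.tstv.ratio,
            "cpg_count": self.cpg_count,
            "orf_disruptions": [
                f"{d.gene}:{d.codon.codon_index}:{d.kind}" for d in self.orf_disruptions
            ],
            "pathogenic_hits": [label for _, label in self.pathogenic_hits],
            "verdict": self.verdict,
        }


def provenance_verdict(
    focal_label: str,
    records: list[SubstitutionRecord],
    disruptions: list[OrfDisruption] | None = None,
    pathogenic_hits: list | None = None,
    min_bias_p: float = 0.05,
    min_tstv: float = 4.0,
) -> ProvenanceReport:
    """Aggregate the per-substitution evidence into a one-line verdict.

    Thresholds are configuration, not science: with defaults, a focal
    sequence whose coding private changes are consistent with the 2:1:5
    codon bias (p >= 0.05) and transition-dominated (ts/tv >= 4, or no
    transversions at all) carries a mitochondrial signature; a clear
    2:1:5 rejection that fits 1:1:1 is a nuclear signature; anything
    else is mixed.  ORF disruptions are attributed to the nucleus but do
    not change the verdict on their own (they are repaired upstream).
    """
    disruptions = disruptions or []
    pathogenic_hits = pathogenic_hits or []
    counts = [0, 0, 0]
    for r in records:
        if r.site.category == "coding" and not r.site.incomplete_codon:
            counts[r.site.codon.codon_position - 1] += 1
    counts = tuple(counts)
    tstv = tstv_summary(records)
    if sum(counts) == 0:
        report = ProvenanceReport(
            focal=focal_label, n_private=len(records),
            codon_position_counts=counts, bias_test_215=None, bias_test_111=None,
            tstv=tstv, cpg_count=cpg_check(records)[0],
            orf_disruptions=disruptions, pathogenic_hits=pathogenic_hits,
            verdict="mitochondrial-signature",
        )
        return report
    t215 = codon_position_test(counts, (2, 1, 5))
    t111 = codon_position_test(counts, (1, 1, 1))
    ts_ok = tstv.ratio is None or tstv.ratio >= min_tstv
    if t215.p_value >= min_bias_p and ts_ok:
        verdict = "mitochondrial-signature"
    elif t215.p_value < min_bias_p and t111.p_value >= min_bias_p:
        verdict = "nuclear-signature"
    else:
        verdict = "mixed"
    return ProvenanceReport(
        focal=focal_label, n_private=len(records), codon_position_counts=counts,
        bias_test_215=t215, bias_test_111=t111, tstv=tstv,
        cpg_count=cpg_check(records)[0], orf_disruptions=disruptions,
        pathogenic_hits=pathogenic_hits, verdict=verdict,
    )
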