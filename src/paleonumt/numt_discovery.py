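"""Scan nuclear contigs for insertions of mitochondrial origin (numts).

A k-mer seeded, chained and gap-bridged local search against a circular
mitochondrial query, followed by exact alignment of each candidate span.
Candidates are filtered by the study criteria: alignment length >= 1000 bp
and >= 90% identity (both configurable).

The search is deliberately simple: exact k-mer seeds (default k=12) are
clustered by diagonal, clusters are extended by ungapped X-drop, and the
final span is rescored with a unit-cost global alignment (edlib).  Scores
are match - mismatch - gap-column totals, not BLAT scores.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import edlib
import numpy as np
import pandas as pd

from .mito_core import NucSequence, reverse_complement

__all__ = ["NumtRecord", "ScanParams", "scan_for_numts", "summarize_hits", "write_bed"]

_BASE_TO_2BIT = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _BASE_TO_2BIT[b] = i


@dataclass(frozen=True)
class NumtRecord:
    """One discovered nuclear insertion of mitochondrial origin."""

    contig: str
    nuc_start: int  # 1-based inclusive
    nuc_end: int
    nuc_strand: str  # "+" or "-"
    mt_start: int  # reference (query) coordinates, 1-based inclusive
    mt_end: int
    align_length: int  # alignment columns
    pct_identity: float  # 0-100
    score: int  # matches - mismatches - gap columns

    def __post_init__(self) -> None:
        if self.nuc_start > self.nuc_end or self.align_length < 1:
            raise ValueError("bad span")
        if not 0 <= self.pct_identity <= 100:
            raise ValueError("identity out of range")


@dataclass
class ScanParams:
    k: int = 12
    min_len: int = 1000
    min_id: float = 0.90
    gap_bridge: int = 50  # max diagonal drift within a chain (indel budget)
    chain_gap: int = 1000  # max genomic gap between chained seeds
    min_seeds: int = 5
    xdrop: int = 20
    mismatch_penalty: int = 2

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("seed length k must be >= 8")


def _codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer codes; positions containing non-ACGT get code max."""
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    valid = arr != 255
    a = np.where(valid, arr, 0).astype(np.uint64)
    code = np.zeros(n - k + 1, dtype=np.uint64)
    ok = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        code = (code << np.uint64(2)) | a[j : n - k + 1 + j]
        ok &= valid[j : n - k + 1 + j]
    code[~ok] = np.uint64(1) << np.uint64(2 * k)  # sentinel never matched
    return code


def _encode_bytes(seq: str) -> np.ndarray:
    return _BASE_TO_2BIT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _cluster_hits(gpos: np.ndarray, qpos: np.ndarray, params: ScanParams):
    """Group seed hits into chains by diagonal proximity and genomic gap."""
    diag = gpos.astype(np.int64) - qpos.astype(np.int64)
    order = np.lexsort((gpos, diag))
    clusters: list[list[int]] = []
    # sweep over diagonal bands: group consecutive hits whose diagonal is
    # within gap_bridge and genomic distance within chain_gap
    current: list[int] = []
    for idx in order:
        if not current:
            current = [idx]
            continue
        last = current[-1]
        if (
            abs(int(diag[idx]) - int(diag[last])) <= params.gap_bridge
            and 0 <= int(gpos[idx]) - int(gpos[last]) <= params.chain_gap
        ):
            current.append(idx)
        else:
            clusters.append(current)
            current = [idx]
    if current:
        clusters.append(current)
    # merge clusters on nearby diagonals that overlap in genome coordinates
    merged = True
    spans = [
        [int(gpos[c].min()), int(gpos[c].max()), int(np.median(diag[c])), c]
        for c in clusters
    ]
    while merged:
        merged = False
        spans.sort(key=lambda s: (s[2], s[0]))
        out = []
        for s in spans:
            if out and abs(s[2] - out[-1][2]) <= params.gap_bridge and s[0] <= out[-1][1] + params.chain_gap and s[1] >= out[-1][0] - params.chain_gap:
                out[-1][0] = min(out[-1][0], s[0])
                out[-1][1] = max(out[-1][1], s[1])
                out[-1][3] = out[-1][3] + s[3]
                merged = True
            else:
                out.append(s)
        spans = out
    return [s[3] for s in spans]


def _xdrop_extend(g: np.ndarray, q: np.ndarray, gi: int, qi: int, step: int,
                  params: ScanParams) -> int:
    """Ungapped X-drop extension; returns number of columns to extend."""
    best, score, best_ext, ext = 0, 0, 0, 0
    while True:
        gi += step
        qi += step
        if gi < 0 or qi < 0 or gi >= g.size or qi >= q.size:
            break
        ext += 1
        if g[gi] == q[qi] and g[gi] != 255:
            score += 1
        else:
            score -= params.mismatch_penalty
        if score >= best:  # ties extend: claim equal-scoring tails
            best, best_ext = score, ext
        if best - score > params.xdrop:
            break
    return best_ext


def _align_span(gseq: str, qseq: str) -> tuple[int, int, float]:
    """(alignment columns, score, identity fraction) by unit-cost NW.

    Match/mismatch/gap columns are counted exactly from the alignment
    path; score = matches - mismatches - gap columns.
    """
    res = edlib.align(gseq, qseq, mode="NW", task="path")
    cols = matches = 0
    gi = qi = 0
    for length, op in _parse_cigar(res["cigar"]):
        cols += length
        if op == "=" or op == "M":
            for t in range(length):
                if gseq[gi + t] == qseq[qi + t]:
                    matches += 1
            gi += length
            qi += length
        elif op == "I":  # in edlib cigar, I consumes the first ("query") seq
            gi += length
        elif op == "D":
            qi += length
        elif op == "X":
            gi += length
            qi += length
    identity = matches / cols if cols else 0.0
    score = 2 * matches - cols
    return cols, score, identity


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def scan_for_numts(
    genome: list[NucSequence] | NucSequence,
    query: NucSequence,
    params: ScanParams | None = None,
) -> list[NumtRecord]:
    """Find maximal local matches of a circular mitochondrial query.

    Both nuclear strands are searched; overlapping candidates are resolved
    by highest score (ties: leftmost nuclear start).  Records are sorted by
    contig then nuclear start.
    """
    params = params or ScanParams()
    if isinstance(genome, NucSequence):
        genome = [genome]
    L = len(query.residues)
    if L < params.k:
        raise ValueError("query shorter than seed length")
    qext = query.residues + query.residues[: params.k - 1]  # circular closure
    qarr = _encode_bytes(qext)
    qcodes = _codes(qarr, params.k)
    order = np.argsort(qcodes, kind="stable")
    sorted_codes = qcodes[order]

    records: list[NumtRecord] = []
    for contig in genome:
        for strand in "+-":
            seq = contig.residues if strand == "+" else reverse_complement(
                contig.residues
            )
            garr = _encode_bytes(seq)
            gcodes = _codes(garr, params.k)
            if gcodes.size == 0:
                continue
            left = np.searchsorted(sorted_codes, gcodes, side="left")
            right = np.searchsorted(sorted_codes, gcodes, side="right")
            mult = right - left
            hit_g = np.repeat(np.arange(gcodes.size), mult)
            if hit_g.size == 0:
                continue
            hit_q = np.concatenate(
                [order[l:r] for l, r in zip(left[mult > 0], right[mult > 0])]
            ) if np.any(mult > 0) else np.empty(0, dtype=int)
            for cluster in _cluster_hits(hit_g, hit_q, params):
                rec = _candidate_record(
                    contig.id, seq, strand, garr, qarr, qext, L,
                    hit_g[cluster], hit_q[cluster], params,
                )
                if rec is not None:
                    records.append(rec)

    records = _resolve_overlaps(records)
    records = [
        r
        for r in records
        if r.align_length >= params.min_len and r.pct_identity >= 100 * params.min_id
    ]
    return sorted(records, key=lambda r: (r.contig, r.nuc_start, r.nuc_end))


def _candidate_record(contig_id, seq, strand, garr, qarr, qext, L, gpos, qpos,
                      params: ScanParams):
    if gpos.size < params.min_seeds:
        return None
    i0 = int(np.argmin(gpos))
    i1 = int(np.argmax(gpos))
    gs, qs = int(gpos[i0]), int(qpos[i0])
    ge, qe = int(gpos[i1]) + params.k, int(qpos[i1]) + params.k
    left = _xdrop_extend(garr, qarr, gs, qs, -1, params)
    right = _xdrop_extend(garr, qarr, ge - 1, qe - 1, +1, params)
    gs, qs, ge, qe = gs - left, qs - left, ge + right, qe + right
    if ge - gs < 2 * params.k:
        return None
    cols, score, identity = _align_span(seq[gs:ge], qext[qs:qe])
    n = len(seq)
    if strand == "+":
        nuc_start, nuc_end = gs + 1, ge
    else:
        nuc_start, nuc_end = n - ge + 1, n - gs
    return NumtRecord(
        contig=contig_id,
        nuc_start=nuc_start,
        nuc_end=nuc_end,
        nuc_strand=strand,
        mt_start=qs % L + 1,
        mt_end=(qe - 1) % L + 1,
        align_length=cols,
        pct_identity=round(100 * identity, 2),
        score=score,
    )


def _resolve_overlaps(records: list[NumtRecord]) -> list[NumtRecord]:
    """Among nuclear-overlapping candidates keep the highest score."""
    kept: list[NumtRecord] = []
    for rec in sorted(records, key=lambda r: (-r.score, r.nuc_start)):
        clash = any(
            r.contig == rec.contig
            and not (rec.nuc_end < r.nuc_start or rec.nuc_start > r.nuc_end)
            for r in kept
        )
        if not clash:
            kept.append(rec)
    return kept


_TABLE_COLUMNS = [
    "name", "contig", "nuc_start", "nuc_end", "nuc_strand",
    "mt_start", "mt_end", "align_length", "score", "pct_identity",
]


def summarize_hits(records: list[NumtRecord]) -> pd.DataFrame:
    """Tabular report of the scan (one row per retained numt).

    Scores are match - mismatch - gap totals of the unit-cost rescoring
    alignment; identity and length are comparable across tools, scores
    are not.
    """
    rows = []
    for i, rec in enumerate(
        sorted(records, key=lambda r: (r.contig, r.nuc_start)), start=1
    ):
        d = asdict(rec)
        d["name"] = f"Numt-{i}"
        rows.append(d)
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_bed(records: list[NumtRecord], path) -> None:
    """BED6 (0-based half-open) for genome-browser use."""
    with open(path, "w") as fh:
        for i, rec in enumerate(
            sorted(records, key=lambda r: (r.contig, r.nuc_start)), start=1
        ):
            fh.write(
                f"{rec.contig}\t{rec.nuc_start - 1}\t{rec.nuc_end}\t"
                f"Numt-{i}\t{rec.score}\t{rec.nuc_strand}\n"
            )
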