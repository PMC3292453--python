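"""Homology annotation of TE copies: library-vs-genome scan with alignments.

For each family consensus, exact k-mer seed matches against the genome are
chained along diagonals into candidate loci (both strands), each candidate is
refined with a full edit-distance alignment against the matched consensus
span, and the alignment is trimmed to its maximum-scoring local segment under
an affine match/mismatch/gap scheme.  Hits are kept when they reach the score
cutoff and the minimum copy length; overlapping hits are resolved
best-score-first.

The default scoring scheme is match=+3, mismatch=-4, gap_open=-6,
gap_extend=-1 with a cutoff of 250, calibrated so a 100 bp exact copy (score
300) clears the cutoff while short diverged fragments do not.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass

import edlib
import numpy as np

from ._seq import encode, kmer_codes, revcomp
from .errors import ConfigError, InputError

__all__ = [
    "AnnotateConfig",
    "CopyAnnotation",
    "scan_genome",
    "resolve_overlaps",
    "annotation_stats",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class AnnotateConfig:
    match: int = 3
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    score_cutoff: int = 250
    min_copy_len: int = 100
    seed_k: int = 12
    chain_band: int = 50  # max diagonal drift within one chain
    max_seed_gap: int = 400  # max bp between consecutive seeds in a chain
    min_chain_seeds: int = 2
    margin: int = 40
    mask_low_complexity: bool = True
    mask_entropy: float = 1.0  # bits/base over mask_window
    mask_window: int = 64

    def validate(self) -> None:
        if self.score_cutoff <= 0:
            raise ConfigError("score_cutoff must be > 0")
        if self.min_copy_len <= 0:
            raise ConfigError("min_copy_len must be > 0")
        if self.match <= 0 or self.mismatch >= 0 or self.gap_open >= 0:
            raise ConfigError("require match > 0 and mismatch/gap_open < 0")


@dataclass(frozen=True)
class CopyAnnotation:
    """One annotated TE copy (0-based half-open genome coordinates).

    ``cigar`` aligns the copy (query, consensus orientation) against the
    family consensus (target); ``copy_seq`` is the copy's ungapped sequence in
    consensus orientation.
    """

    copy_id: str
    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    family_id: str
    score: int
    identity: float
    cstart: int
    cend: int
    cigar: str
    copy_seq: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def cigar_str(runs) -> str:
    return "".join(f"{n}{op}" for n, op in runs)


def _window_entropy_mask(codes: np.ndarray, window: int, threshold: float):
    """Boolean mask of low-entropy windows (True = masked for seeding)."""
    n = len(codes)
    mask = np.zeros(n, dtype=bool)
    if n < window:
        return mask
    onehot = np.zeros((4, n + 1), dtype=np.int32)
    for b in range(4):
        np.cumsum(codes == b, out=onehot[b, 1:])
    starts = np.arange(0, n - window + 1, window // 2)
    counts = onehot[:, starts + window] - onehot[:, starts]  # 4 x nwin
    tot = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / np.maximum(tot, 1)
        ent = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=0)
    for s, e in zip(starts[ent < threshold], starts[ent < threshold] + window):
        mask[s:e] = True
    return mask


class _ContigIndex:
    """Sorted k-mer index of one contig for exact seed lookup."""

    def __init__(self, codes: np.ndarray, k: int, seed_mask=None):
        vals, valid = kmer_codes(codes, k)
        if seed_mask is not None and len(vals):
            valid = valid & ~seed_mask[: len(vals)]
        pos = np.nonzero(valid)[0]
        vals = vals[pos]
        order = np.argsort(vals, kind="stable")
        self.vals = vals[order]
        self.pos = pos[order].astype(np.int64)
        self.k = k

    def matches(self, query_codes: np.ndarray):
        """(genome_pos, query_pos) for every exact k-mer shared with query."""
        qvals, qvalid = kmer_codes(query_codes, self.k)
        qidx = np.nonzero(qvalid)[0]
        qvals = qvals[qidx]
        lo = np.searchsorted(self.vals, qvals, side="left")
        hi = np.searchsorted(self.vals, qvals, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        gpos = np.empty(total, np.int64)
        qpos = np.repeat(qidx, counts)
        out = 0
        for l, h in zip(lo, hi):
            if h > l:
                gpos[out : out + h - l] = self.pos[l:h]
                out += h - l
        return gpos, qpos


def _chain(gpos, qpos, cfg: AnnotateConfig):
    """Group collinear seed matches into candidate (g0, g1, q0, q1) loci."""
    if len(gpos) == 0:
        return []
    diag = gpos - qpos
    order = np.lexsort((gpos, diag))
    gpos, qpos, diag = gpos[order], qpos[order], diag[order]
    clusters = []
    start = 0
    for i in range(1, len(gpos) + 1):
        if (
            i == len(gpos)
            or diag[i] - diag[start] > cfg.chain_band
            or gpos[i] - gpos[i - 1] > cfg.max_seed_gap
        ):
            if i - start >= cfg.min_chain_seeds:
                clusters.append(
                    (
                        int(gpos[start:i].min()),
                        int(gpos[start:i].max()) + cfg.seed_k,
                        int(qpos[start:i].min()),
                        int(qpos[start:i].max()) + cfg.seed_k,
                    )
                )
            start = i
    return _merge_intervals(clusters)


def _merge_intervals(clusters):
    """Merge candidate loci whose genome intervals overlap."""
    clusters.sort()
    merged = []
    for c in clusters:
        if merged and c[0] <= merged[-1][1]:
            p = merged[-1]
            merged[-1] = (p[0], max(p[1], c[1]), min(p[2], c[2]), max(p[3], c[3]))
        else:
            merged.append(c)
    return merged


def _run_score(n: int, op: str, cfg: AnnotateConfig) -> int:
    if op == "=":
        return n * cfg.match
    if op == "X":
        return n * cfg.mismatch
    return cfg.gap_open + (n - 1) * cfg.gap_extend


def _best_local_segment(runs, cfg: AnnotateConfig):
    """Maximum-scoring contiguous run window (Kadane at run granularity).

    Returns (i, j, score): the best window runs[i:j] and its score, or
    (0, 0, 0) if every window scores <= 0.
    """
    best = (0, 0, 0)
    cur_start, cur = 0, 0
    for idx, (n, op) in enumerate(runs):
        s = _run_score(n, op, cfg)
        if cur <= 0:
            cur_start, cur = idx, s
        else:
            cur += s
        if cur > best[2]:
            best = (cur_start, idx + 1, cur)
    i, j, score = best
    # never begin or end on a gap/mismatch run
    while i < j and runs[i][1] != "=":
        score -= _run_score(*runs[i], cfg)
        i += 1
    while j > i and runs[j - 1][1] != "=":
        score -= _run_score(*runs[j - 1], cfg)
        j -= 1
    return (i, j, score) if j > i else (0, 0, 0)


def _align_candidate(qseq: str, tseq: str, cfg: AnnotateConfig):
    """Globally align candidate copy vs consensus span, then local-trim.

    Returns (score, identity, q0, q1, t0, t1, cigar) in the coordinates of
    the two input strings, or None when nothing scores above zero.
    """
    res = edlib.align(qseq, tseq, mode="NW", task="path")
    runs = parse_cigar(res["cigar"])
    i, j, score = _best_local_segment(runs, cfg)
    if j <= i:
        return None
    q0 = sum(n for n, op in runs[:i] if op in "=XI")
    t0 = sum(n for n, op in runs[:i] if op in "=XD")
    window = list(runs[i:j])
    q1 = q0 + sum(n for n, op in window if op in "=XI")
    t1 = t0 + sum(n for n, op in window if op in "=XD")
    # edlib may place equivalent-cost edits at the margins; recover exactly
    # matching flanking bases by ungapped extension at both ends
    ext_l = 0
    while q0 > 0 and t0 > 0 and qseq[q0 - 1] == tseq[t0 - 1]:
        q0 -= 1
        t0 -= 1
        ext_l += 1
    ext_r = 0
    while q1 < len(qseq) and t1 < len(tseq) and qseq[q1] == tseq[t1]:
        q1 += 1
        t1 += 1
        ext_r += 1
    if ext_l:
        if window[0][1] == "=":
            window[0] = (window[0][0] + ext_l, "=")
        else:
            window.insert(0, (ext_l, "="))
        score += ext_l * cfg.match
    if ext_r:
        if window[-1][1] == "=":
            window[-1] = (window[-1][0] + ext_r, "=")
        else:
            window.append((ext_r, "="))
        score += ext_r * cfg.match
    ncols = sum(n for n, _ in window)
    nmatch = sum(n for n, op in window if op == "=")
    return score, nmatch / ncols, q0, q1, t0, t1, cigar_str(window)


def scan_genome(genome: dict[str, str], library, cfg: AnnotateConfig, genome_id="g"):
    """Annotate every library family in a genome (both strands).

    ``genome`` maps contig name -> sequence.  Returns CopyAnnotation hits
    with score >= score_cutoff and length >= min_copy_len, sorted by
    (contig, start).  Low-entropy genomic windows are excluded from seeding
    (they can still be spanned by an alignment).
    """
    cfg.validate()
    if not library:
        raise ConfigError("library must be non-empty")
    hits = []
    for contig in sorted(genome):
        seq = genome[contig].upper()
        codes = encode(seq)
        bad = np.nonzero((codes == 4) & (np.frombuffer(seq.encode(), np.uint8) != ord("N")))[0]
        if len(bad):
            raise InputError(
                f"contig {contig!r}: non-ACGTN character at position {int(bad[0])}"
            )
        seed_mask = None
        if cfg.mask_low_complexity:
            seed_mask = _window_entropy_mask(codes, cfg.mask_window, cfg.mask_entropy)
        index = _ContigIndex(codes, cfg.seed_k, seed_mask)
        for fam in library:
            cons = fam.consensus.upper()
            lc = len(cons)
            for strand in "+-":
                oriented = cons if strand == "+" else revcomp(cons)
                gpos, qpos = index.matches(encode(oriented))
                for g0, g1, q0, q1 in _chain(gpos, qpos, cfg):
                    m = cfg.margin
                    g0m, g1m = max(0, g0 - m), min(len(seq), g1 + m)
                    q0m, q1m = max(0, q0 - m), min(lc, q1 + m)
                    if strand == "+":
                        qseq = seq[g0m:g1m]
                        tseq = cons[q0m:q1m]
                    else:
                        qseq = revcomp(seq[g0m:g1m])
                        # oriented-consensus coords -> forward-consensus span
                        t0f, t1f = lc - q1m, lc - q0m
                        tseq = cons[t0f:t1f]
                    out = _align_candidate(qseq, tseq, cfg)
                    if out is None:
                        continue
                    score, ident, a0, a1, t0, t1, cig = out
                    if strand == "+":
                        gs, ge = g0m + a0, g0m + a1
                        cs = q0m + t0
                    else:
                        gs, ge = g1m - a1, g1m - a0
                        cs = (lc - q1m) + t0
                    ce = cs + (t1 - t0)
                    if score < cfg.score_cutoff or ge - gs < cfg.min_copy_len:
                        continue
                    copy_seq = seq[gs:ge] if strand == "+" else revcomp(seq[gs:ge])
                    hits.append(
                        CopyAnnotation(
                            copy_id="",
                            genome_id=genome_id,
                            contig=contig,
                            start=int(gs),
                            end=int(ge),
                            strand=strand,
                            family_id=fam.family_id,
                            score=int(score),
                            identity=float(ident),
                            cstart=int(cs),
                            cend=int(ce),
                            cigar=cig,
                            copy_seq=copy_seq,
                        )
                    )
    hits.sort(key=lambda h: (h.contig, h.start, h.end, h.family_id, h.strand))
    return [
        CopyAnnotation(**{**h.__dict__, "copy_id": f"{genome_id}.{i:06d}"})
        for i, h in enumerate(hits)
    ]


def resolve_overlaps(hits):
    """Best-score-first resolution of overlapping hits.

    Among hits overlapping by >= 1 bp on the same contig the highest score
    wins; ties break by longer span, then lower start, then family id.  The
    result is overlap-free and deterministic.
    """
    order = sorted(
        hits, key=lambda h: (-h.score, -(h.end - h.start), h.start, h.family_id)
    )
    kept_by_contig: dict[tuple, list] = {}
    kept = []
    for h in order:
        key = (h.genome_id, h.contig)
        intervals = kept_by_contig.setdefault(key, [])
        i = bisect_left(intervals, (h.start, h.start))
        clash = False
        if i > 0 and intervals[i - 1][1] > h.start:
            clash = True
        if i < len(intervals) and intervals[i][0] < h.end:
            clash = True
        if not clash:
            intervals.insert(i, (h.start, h.end))
            kept.append(h)
    kept.sort(key=lambda h: (h.genome_id, h.contig, h.start))
    return kept


def annotation_stats(hits, genome_len: int, class_of: dict[str, str] | None = None):
    """Per-class copy counts, copies/Mbp, and genome coverage.

    ``class_of`` maps family_id -> te_class; families absent from the map
    count as "unknown".  ``hits`` must be overlap-free.
    """
    if genome_len <= 0:
        raise ConfigError("genome_len must be > 0")
    class_of = class_of or {}
    counts: dict[str, int] = {}
    covered = 0
    for h in hits:
        cls = class_of.get(h.family_id, "unknown")
        counts[cls] = counts.get(cls, 0) + 1
        covered += h.end - h.start
    total = len(hits)
    mbp = genome_len / 1e6
    return {
        "counts": counts,
        "total": total,
        "per_mbp": {c: n / mbp for c, n in counts.items()},
        "total_per_mbp": total / mbp,
        "coverage": covered / genome_len,
        "mean_copy_len": (covered / total) if total else 0.0,
    }
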