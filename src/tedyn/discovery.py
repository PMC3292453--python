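"""De novo repeat-family discovery and library construction.

The discovery strategy is seed-and-extend: exact l-mers that recur above a
count threshold mark candidate repetitive loci; each seed's occurrences are
extended outwards column by column under a majority vote until support
collapses, yielding one consensus per candidate family.  Candidates are then
filtered (length, copy support, low complexity, tandem periodicity), merged
against a known-family library at the >80%-identity redundancy rule, and
assigned a class from purely structural signatures:

* LTR retrotransposon — direct terminal repeats,
* DNA transposon — inverted terminal repeats (TIRs),
* non-LTR retrotransposon — 3' poly-A tail without terminal repeats,
* unknown — none of the above.

Known-library entries keep their RUxxxx identifiers; surviving de novo
families are issued fresh RSxxxx identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from ._seq import (
    canonical_kmer_codes,
    code_to_kmer,
    encode,
    kmer_codes,
    revcomp,
    revcomp_codes,
    shannon_entropy,
)
from .errors import ConfigError

__all__ = [
    "TEFamily",
    "DiscoveryConfig",
    "count_seeds",
    "extend_seed",
    "filter_candidates",
    "merge_redundant",
    "classify_family",
    "discover_families",
]


@dataclass(frozen=True)
class TEFamily:
    family_id: str
    consensus: str
    te_class: str = "unknown"
    source: str = "de_novo"  # "known" | "de_novo"

    def __post_init__(self):
        if self.te_class not in ("LTR", "non-LTR", "DNA", "unknown"):
            raise ConfigError(f"unknown te_class {self.te_class!r}")
        if set(self.consensus.upper()) - set("ACGTN"):
            raise ConfigError(f"{self.family_id}: consensus has non-ACGTN characters")


@dataclass(frozen=True)
class DiscoveryConfig:
    lmer_size: int = 14
    min_seed_count: int = 5
    max_extension: int = 6000
    extension_stop_patience: int = 20
    min_consensus_len: int = 100  # conservative mode: 2000
    redundancy_identity: float = 0.80
    low_complexity_entropy: float = 1.2  # bits/base, mononucleotide
    min_copy_support: int = 3
    tandem_max_offset: int = 50
    tandem_match_frac: float = 0.80
    terminal_window_frac: float = 0.15
    terminal_min_window: int = 50
    min_terminal_repeat: int = 20
    terminal_identity: float = 0.80
    polya_min_run: int = 10
    max_families: int = 500
    max_occ_per_seed: int = 100  # occurrences sampled for the vote matrix

    def validate(self) -> None:
        if not (0.0 < self.redundancy_identity < 1.0):
            raise ConfigError("redundancy_identity must lie in (0, 1)")
        if self.lmer_size < 8:
            raise ConfigError("lmer_size must be >= 8")
        if self.min_consensus_len < self.lmer_size:
            raise ConfigError("min_consensus_len must be >= lmer_size")


@dataclass
class Candidate:
    """A raw extension product, before filtering."""

    consensus: str
    seed: str
    support: int  # number of genomic occurrences backing the consensus
    occurrences: list = field(default_factory=list)  # (contig, pos, strand)


def _contigs(genomes) -> list[tuple[str, str]]:
    """Normalize input to [(contig_name, sequence)] over one or more genomes."""
    if isinstance(genomes, str):
        return [("seq", genomes)]
    if isinstance(genomes, dict):
        return sorted(genomes.items())
    out = []
    for i, g in enumerate(genomes):
        if isinstance(g, tuple):
            out.append(g)
        elif isinstance(g, dict):
            out.extend(sorted((f"g{i}.{k}", v) for k, v in g.items()))
        else:
            out.append((f"seq{i}", g))
    return out


def count_seeds(genomes, cfg: DiscoveryConfig):
    """Exact canonical l-mer counts, descending, ties lexicographic.

    An l-mer and its reverse complement are one seed (canonical form = the
    lexicographically smaller encoding).  Windows containing N are skipped.
    Only seeds with count >= cfg.min_seed_count are returned.
    """
    cfg.validate()
    contigs = _contigs(genomes)
    if not contigs:
        raise ConfigError("genomes must be non-empty")
    k = cfg.lmer_size
    all_codes = []
    for _, seq in contigs:
        codes = encode(seq)
        vals, valid = canonical_kmer_codes(codes, k)
        if len(vals):
            all_codes.append(vals[valid])
    if not all_codes:
        import warnings

        warnings.warn(f"every contig is shorter than lmer_size={k}")
        return []
    vals = np.concatenate(all_codes)
    uniq, counts = np.unique(vals, return_counts=True)
    keep = counts >= cfg.min_seed_count
    uniq, counts = uniq[keep], counts[keep]
    order = np.lexsort((uniq, -counts))
    return [(code_to_kmer(int(u), k), int(c)) for u, c in zip(uniq[order], counts[order])]


class _SeedIndex:
    """Canonical k-mer -> genomic positions, for fast occurrence lookup."""

    def __init__(self, contigs, k: int):
        self.k = k
        self.encoded = [encode(seq) for _, seq in contigs]
        canon_all, fwd_all, ci_all, pos_all = [], [], [], []
        for ci, codes in enumerate(self.encoded):
            canon, valid = canonical_kmer_codes(codes, k)
            fwd, _ = kmer_codes(codes, k)
            pos = np.nonzero(valid)[0]
            canon_all.append(canon[pos])
            fwd_all.append(fwd[pos])
            ci_all.append(np.full(len(pos), ci, dtype=np.int32))
            pos_all.append(pos)
        if canon_all:
            canon = np.concatenate(canon_all)
            order = np.argsort(canon, kind="stable")
            self.canon = canon[order]
            self.fwd = np.concatenate(fwd_all)[order]
            self.ci = np.concatenate(ci_all)[order]
            self.pos = np.concatenate(pos_all)[order]
        else:
            self.canon = np.empty(0, np.uint64)

    def lookup(self, seed: str):
        """(contig_index, position, strand) for every occurrence of seed/rc."""
        scodes = encode(seed)
        fwd_code = kmer_codes(scodes, self.k)[0][0]
        canon_code = min(fwd_code, kmer_codes(revcomp_codes(scodes), self.k)[0][0])
        lo = np.searchsorted(self.canon, canon_code, side="left")
        hi = np.searchsorted(self.canon, canon_code, side="right")
        out = []
        for i in range(lo, hi):
            strand = "+" if self.fwd[i] == fwd_code else "-"
            out.append((int(self.ci[i]), int(self.pos[i]), strand))
        out.sort()
        return out


def _seed_occurrences(seed: str, contigs, mask=None, index: _SeedIndex | None = None):
    """All genomic loci of a seed or its reverse complement.

    Returns (contig_index, position, strand) triples; positions are the
    left end of the forward-strand window.  Loci whose window is more than
    half masked are skipped.
    """
    k = len(seed)
    if index is None:
        index = _SeedIndex(contigs, k)
    occs = index.lookup(seed)
    if mask is not None:
        occs = [
            (ci, pos, strand)
            for ci, pos, strand in occs
            if mask[ci][pos : pos + k].sum() <= k // 2
        ]
    return occs


def extend_seed(
    seed: str,
    genomes,
    cfg: DiscoveryConfig,
    mask=None,
    occurrences=None,
    encoded=None,
) -> Candidate:
    """Majority-vote extension of one seed into a family consensus.

    All occurrences are stacked at the seed offset; the consensus grows left
    and right one column at a time, taking the majority base across
    occurrences still inside their contig.  Extension stops on a side after
    ``extension_stop_patience`` consecutive columns whose majority support
    falls below half the occurrences, or at ``max_extension`` columns.
    """
    cfg.validate()
    contigs = _contigs(genomes)
    occs_all = (
        occurrences if occurrences is not None else _seed_occurrences(seed, contigs, mask)
    )
    if len(occs_all) < cfg.min_seed_count:
        raise ConfigError(
            f"seed occurs {len(occs_all)} times; min_seed_count={cfg.min_seed_count}"
        )
    n_total = len(occs_all)
    occs = occs_all[: cfg.max_occ_per_seed]
    k = len(seed)
    if encoded is None:
        encoded = [encode(seq) for _, seq in contigs]
    n = len(occs)
    half = n / 2.0

    # occurrence-aligned window matrix: row i holds the bases of occurrence i
    # at seed offsets [-max_extension, k + max_extension), oriented so the
    # seed reads forward; out-of-contig positions are 4 (missing)
    ext = cfg.max_extension
    width = 2 * ext + k
    window = np.full((n, width), 4, dtype=np.uint8)
    for i, (ci, pos, strand) in enumerate(occs):
        codes = encoded[ci]
        if strand == "+":
            lo, hi = pos - ext, pos + k + ext
            src = codes[max(0, lo) : min(len(codes), hi)]
            window[i, max(0, lo) - lo : max(0, lo) - lo + len(src)] = src
        else:
            lo, hi = pos + k - 1 + ext, pos - 1 - ext  # walk leftwards
            a, b = max(0, pos - ext - 1 + 1), min(len(codes), pos + k + ext)
            src = codes[a:b][::-1]
            src = np.where(src < 4, 3 - src, 4).astype(np.uint8)
            # offset of the first window column this slice covers
            first = (pos + k - 1 + ext) - (b - 1)
            window[i, first : first + len(src)] = src

    def column(offset: int) -> np.ndarray:
        return window[:, offset + ext]

    def grow(direction: int, start_offset: int) -> list[int]:
        out: list[int] = []
        pending: list[int] = []
        misses = 0
        off = start_offset
        for _ in range(cfg.max_extension):
            col = column(off)
            counts = np.bincount(col[col < 4], minlength=4)
            if counts.sum() == 0:
                break
            base = int(counts.argmax())
            if counts[base] >= half:
                out.extend(pending)
                pending = []
                out.append(base)
                misses = 0
            else:
                misses += 1
                pending.append(base)
                if misses >= cfg.extension_stop_patience:
                    break
            off += direction
        return out

    left = grow(-1, -1)[::-1]
    right = grow(+1, k)
    body = [int(b) for b in encode(seed)]
    consensus = "".join("ACGT"[b] for b in left + body + right)
    left_len, right_len = len(left), len(right)
    full_occs = []
    for ci, pos, strand in occs_all:
        # genomic left end of the extended element at this occurrence
        s = pos - left_len if strand == "+" else pos - right_len
        full_occs.append((contigs[ci][0], max(0, s), strand, ci))
    return Candidate(
        consensus=consensus, seed=seed, support=n_total, occurrences=full_occs
    )


def filter_candidates(candidates, cfg: DiscoveryConfig):
    """Apply the candidate filters; returns (kept, log of (seed, reason))."""
    cfg.validate()
    kept, log = [], []
    for cand in candidates:
        seq = cand.consensus
        if len(seq) < cfg.min_consensus_len:
            log.append((cand.seed, "length"))
            continue
        if cand.support < cfg.min_copy_support:
            log.append((cand.seed, "support"))
            continue
        if shannon_entropy(seq) < cfg.low_complexity_entropy:
            log.append((cand.seed, "low_complexity"))
            continue
        if _tandem_fraction(seq, cfg.tandem_max_offset) > cfg.tandem_match_frac:
            log.append((cand.seed, "tandem"))
            continue
        kept.append(cand)
    return kept, log


def _tandem_fraction(seq: str, max_offset: int) -> float:
    """Best self-match fraction at small offsets (tandem periodicity score)."""
    codes = encode(seq)
    best = 0.0
    for off in range(1, min(max_offset, len(codes) - 1) + 1):
        a, b = codes[:-off], codes[off:]
        ok = (a < 4) & (b < 4)
        if ok.sum() == 0:
            continue
        best = max(best, float(((a == b) & ok).sum() / ok.sum()))
    return best


def alignment_identity(a: str, b: str) -> float:
    """Identity of the shorter sequence aligned (either orientation) within
    the longer, via edit distance; 1 - dist/len(shorter)."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0.0
    for q in (short, revcomp(short)):
        res = edlib.align(q, long_, mode="HW", task="distance")
        if res["editDistance"] >= 0:
            best = max(best, 1.0 - res["editDistance"] / len(short))
    return best


def merge_redundant(de_novo, known, cfg: DiscoveryConfig):
    """Drop de novo candidates with more than ``redundancy_identity`` identity
    to any known family (identity measured over the shorter sequence, either
    orientation); survivors get fresh RSxxxx ids.  Output = known + survivors.
    The boundary is strict: exactly 80% identity is retained."""
    cfg.validate()
    out = list(known)
    existing = {f.family_id for f in known}
    serial = 0
    for fam in de_novo:
        if any(
            alignment_identity(fam.consensus, k.consensus) > cfg.redundancy_identity
            for k in known
        ):
            continue
        if fam.source == "known" or (fam.family_id.startswith("RS") and fam.family_id not in existing):
            new_id = fam.family_id
        else:
            while True:
                serial += 1
                new_id = f"RS{serial:04d}"
                if new_id not in existing:
                    break
        existing.add(new_id)
        out.append(
            TEFamily(
                family_id=new_id,
                consensus=fam.consensus,
                te_class=fam.te_class,
                source="de_novo",
            )
        )
    return out


def _terminal_identity(a: str, b: str) -> float:
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def classify_family(family: TEFamily, cfg: DiscoveryConfig | None = None) -> str:
    """Structural class call from the consensus alone.

    Rules, in order: direct terminal repeats -> LTR; inverted terminal
    repeats (TIRs) -> DNA; 3' poly-A run (>= polya_min_run) with no terminal
    repeat -> non-LTR; otherwise unknown.  Terminal repeats are searched at a
    range of lengths, from ``min_terminal_repeat`` up to the larger of
    ``terminal_min_window`` and ``terminal_window_frac`` of the sequence, and
    must match at ``terminal_identity`` over their full length; this detects
    both long LTRs and the short perfect TIRs typical of DNA transposons.
    """
    if cfg is None:
        cfg = DiscoveryConfig()
    seq = family.consensus
    w = max(cfg.terminal_min_window, int(cfg.terminal_window_frac * len(seq)))
    w = min(w, len(seq) // 2)
    if w >= cfg.min_terminal_repeat:
        lengths = sorted(
            set(range(cfg.min_terminal_repeat, w + 1, max(1, w // 40))) | {w}
        )
        # end-anchored comparison at each candidate repeat length
        for mode in ("direct", "inverted"):
            for tlen in lengths:
                head, tail = seq[:tlen], seq[-tlen:]
                other = tail if mode == "direct" else revcomp(tail)
                if _terminal_identity(head, other) >= cfg.terminal_identity:
                    return "LTR" if mode == "direct" else "DNA"
        # a direct repeat longer than w ends w..R bp before the 3' terminus;
        # search the 5' window within the 3' half with that much slack
        zone = seq[len(seq) // 2 :]
        res = edlib.align(seq[:w], zone, mode="HW", task="locations")
        if res["editDistance"] >= 0 and 1.0 - res["editDistance"] / w >= cfg.terminal_identity:
            end = max(loc[1] for loc in res["locations"])
            if len(zone) - 1 - end <= w:
                return "LTR"
    tail_run = len(seq) - len(seq.rstrip("A"))
    if tail_run >= cfg.polya_min_run:
        return "non-LTR"
    return "unknown"


def discover_families(genomes, cfg: DiscoveryConfig, known=()):
    """Full de novo discovery: seeds -> extension -> filters -> merge -> classify.

    Genomic loci consumed by one family are masked so later seeds cannot
    rediscover it.  Returns (library, filter_log); the library is
    known entries plus classified RSxxxx survivors, deterministically ordered.
    """
    cfg.validate()
    contigs = _contigs(genomes)
    mask = [np.zeros(len(seq), dtype=bool) for _, seq in contigs]
    index = _SeedIndex(contigs, cfg.lmer_size)
    encoded = index.encoded
    seeds = count_seeds(genomes, cfg)
    candidates = []
    for lmer, _count in seeds:
        if len(candidates) >= cfg.max_families:
            break
        occs = _seed_occurrences(lmer, contigs, mask, index)
        if len(occs) < cfg.min_seed_count:
            continue
        cand = extend_seed(lmer, genomes, cfg, mask, occurrences=occs, encoded=encoded)
        candidates.append(cand)
        clen = len(cand.consensus)
        for _, start, _, ci in cand.occurrences:
            mask[ci][start : start + clen] = True
    kept, log = filter_candidates(candidates, cfg)
    de_novo = [
        TEFamily(
            family_id=f"CAND{i:04d}",
            consensus=c.consensus,
            te_class="unknown",
            source="de_novo",
        )
        for i, c in enumerate(kept)
    ]
    merged = merge_redundant(de_novo, list(known), cfg)
    out = []
    for fam in merged:
        if fam.source == "de_novo":
            fam = TEFamily(
                family_id=fam.family_id,
                consensus=fam.consensus,
                te_class=classify_family(fam, cfg),
                source="de_novo",
            )
        out.append(fam)
    return out, log
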