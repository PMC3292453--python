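"""Insertion-time estimation from family alignment stacks via T = K/2r.

Per-copy alignments to the family consensus (from the annotation scan) are
projected onto consensus columns to form a family "stack"; bases a copy
carries in excess of the consensus are dropped (counted, not aligned).
Pairwise divergence between two rows is computed over their shared non-gap
columns; only pairs overlapping more than 200 aligned bp qualify.  Divergence
is the raw p-distance or its Jukes-Cantor correction
K = -(3/4) ln(1 - (4/3) p), and an element's age is T = K/2r to its nearest
(lowest-K) qualified neighbor.  A family's average age is the mean qualified
pairwise K divided by 2r.

Because the nearest surviving relative need not be the true source element,
T is an upper bound on the insertion age whenever the source was lost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._seq import encode
from .errors import ConfigError, InputError

__all__ = [
    "FamilyStack",
    "DivergenceRecord",
    "AgeEstimate",
    "FamilyAge",
    "stack_family",
    "pairwise_divergence",
    "element_age",
    "family_average_age",
    "export_distance_matrix",
    "jc_distance",
]

GAP = 255
DEFAULT_MIN_OVERLAP = 200  # pairs must share strictly more than this many bp
SATURATION_P = 0.75


@dataclass
class FamilyStack:
    family_id: str
    consensus_len: int
    copy_ids: list[str]
    rows: np.ndarray  # (n_copies, consensus_len) uint8; 0..3 bases, 255 gap
    insertion_counts: dict[str, int]
    genome_of: dict[str, str]

    @property
    def n(self) -> int:
        return len(self.copy_ids)

    def row_length(self, copy_id: str) -> int:
        i = self.copy_ids.index(copy_id)
        return int((self.rows[i] != GAP).sum())


@dataclass(frozen=True)
class DivergenceRecord:
    copy_a: str
    copy_b: str
    overlap: int
    p: float
    K: float  # JC (or p, under model="p"); nan when saturated
    qualified: bool
    saturated: bool = False


@dataclass(frozen=True)
class AgeEstimate:
    copy_id: str
    nearest_neighbor_id: str | None
    K: float
    overlap: int
    T: float  # Myr; nan when not qualified
    r_used: float
    qualified: bool


@dataclass(frozen=True)
class FamilyAge:
    family_id: str
    genome_id: str  # "A", "B", or "both"
    mean_pairwise_K: float
    average_insertion_time: float
    n_pairs: int


def jc_distance(p: float) -> float:
    """Jukes-Cantor distance from a p-distance; nan at/beyond saturation."""
    if p < 0:
        raise ValueError("p-distance must be >= 0")
    if p >= SATURATION_P:
        return math.nan
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def stack_family(annotations, consensus_len: int, family_id: str = "") -> FamilyStack:
    """Project per-copy alignments onto consensus columns.

    Each annotation contributes one row over [0, consensus_len): consensus
    positions the copy aligns to carry the copy base ('=' and 'X' columns),
    deletions ('D') and unaligned flanks are gaps, and copy insertions ('I')
    are dropped and tallied in ``insertion_counts``.
    """
    from .annotate import parse_cigar

    copy_ids, rows = [], []
    ins_counts, genome_of = {}, {}
    for ann in annotations:
        if ann.cend > consensus_len:
            raise InputError(
                f"{ann.copy_id}: alignment ends at consensus {ann.cend} "
                f"> consensus length {consensus_len}"
            )
        row = np.full(consensus_len, GAP, dtype=np.uint8)
        codes = encode(ann.copy_seq)
        ci, qi, ins = ann.cstart, 0, 0
        for n, op in parse_cigar(ann.cigar):
            if op in "=XM":
                row[ci : ci + n] = codes[qi : qi + n]
                ci += n
                qi += n
            elif op == "D":
                ci += n
            elif op == "I":
                ins += n
                qi += n
        copy_ids.append(ann.copy_id)
        rows.append(row)
        ins_counts[ann.copy_id] = ins
        genome_of[ann.copy_id] = ann.genome_id
    if not rows:
        raise ConfigError("stack_family needs at least one annotation")
    return FamilyStack(
        family_id=family_id or annotations[0].family_id,
        consensus_len=consensus_len,
        copy_ids=copy_ids,
        rows=np.vstack(rows),
        insertion_counts=ins_counts,
        genome_of=genome_of,
    )


def pairwise_divergence(
    stack: FamilyStack, model: str = "JC", min_overlap: int = DEFAULT_MIN_OVERLAP
):
    """Divergence records for every pair with > min_overlap shared columns.

    Pairs at or below the overlap threshold are omitted entirely; pairs whose
    p-distance is JC-saturated (p >= 0.75) are flagged and carry K = nan.
    """
    if model not in ("JC", "p"):
        raise ConfigError(f"unknown distance model {model!r}")
    if stack.n < 2:
        raise ConfigError("pairwise_divergence needs >= 2 rows")
    rows = stack.rows
    present = rows != GAP
    out = []
    for i in range(stack.n - 1):
        shared = present[i] & present[i + 1 :]
        overlap = shared.sum(axis=1)
        mism = ((rows[i] != rows[i + 1 :]) & shared).sum(axis=1)
        for dj in range(len(overlap)):
            ov = int(overlap[dj])
            if ov <= min_overlap:
                continue
            p = float(mism[dj]) / ov
            if model == "JC":
                K = jc_distance(p)
                saturated = math.isnan(K)
            else:
                K, saturated = p, False
            out.append(
                DivergenceRecord(
                    copy_a=stack.copy_ids[i],
                    copy_b=stack.copy_ids[i + 1 + dj],
                    overlap=ov,
                    p=p,
                    K=K,
                    qualified=not saturated,
                    saturated=saturated,
                )
            )
    return out


def element_age(copy_id: str, divergences, r: float) -> AgeEstimate:
    """Nearest-neighbor age of one copy: T = K_min / 2r.

    The nearest neighbor is the qualified, unsaturated pair partner with the
    lowest K (ties: lexicographically smaller partner id).  A copy with no
    qualified pair is returned unqualified with T = nan.
    """
    if r <= 0:
        raise ConfigError("substitution rate r must be > 0")
    best = None
    for rec in divergences:
        if not rec.qualified or rec.saturated:
            continue
        if rec.copy_a == copy_id:
            partner = rec.copy_b
        elif rec.copy_b == copy_id:
            partner = rec.copy_a
        else:
            continue
        if best is None or (rec.K, partner) < (best[0], best[1]):
            best = (rec.K, partner, rec.overlap)
    if best is None:
        return AgeEstimate(copy_id, None, math.nan, 0, math.nan, r, False)
    K, partner, overlap = best
    return AgeEstimate(copy_id, partner, K, overlap, K / (2.0 * r), r, True)


def family_average_age(
    stack: FamilyStack, divergences, r: float, scope: str = "both"
) -> FamilyAge:
    """Family average age = mean qualified pairwise K within scope, over 2r.

    scope "both" uses all qualified pairs (cross-genome allowed); a genome id
    restricts to pairs whose two members are both from that genome.
    """
    if r <= 0:
        raise ConfigError("substitution rate r must be > 0")
    ks = []
    for rec in divergences:
        if not rec.qualified or rec.saturated:
            continue
        if scope != "both":
            if (
                stack.genome_of.get(rec.copy_a) != scope
                or stack.genome_of.get(rec.copy_b) != scope
            ):
                continue
        ks.append(rec.K)
    if not ks:
        return FamilyAge(stack.family_id, scope, math.nan, math.nan, 0)
    mean_k = float(np.mean(ks))
    return FamilyAge(stack.family_id, scope, mean_k, mean_k / (2.0 * r), len(ks))


def export_distance_matrix(
    stack: FamilyStack,
    divergences,
    path=None,
    min_row_len: int = 200,
    missing: float = -1.0,
):
    """Square symmetric distance matrix in PHYLIP format.

    Only members with strictly more than ``min_row_len`` aligned (non-gap)
    bp are included, mirroring the exclusion of short copies from
    phylogenetic use.  Unqualified pairs are encoded as ``missing`` (-1).
    Returns (ids, matrix) or None (with fewer than 3 eligible members the
    export is skipped).
    """
    lengths = (stack.rows != GAP).sum(axis=1)
    ids = [cid for cid, ln in zip(stack.copy_ids, lengths) if ln > min_row_len]
    if len(ids) < 3:
        return None
    idx = {cid: i for i, cid in enumerate(ids)}
    n = len(ids)
    mat = np.full((n, n), missing, dtype=float)
    np.fill_diagonal(mat, 0.0)
    for rec in divergences:
        if rec.copy_a in idx and rec.copy_b in idx:
            val = rec.K if rec.qualified and not rec.saturated else missing
            i, j = idx[rec.copy_a], idx[rec.copy_b]
            mat[i, j] = mat[j, i] = val
    if path is not None:
        with open(path, "w") as fh:
            fh.write(f"{n}\n")
            for cid, row in zip(ids, mat):
                name = cid[:10].ljust(10)
                fh.write(name + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
    return ids, mat
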