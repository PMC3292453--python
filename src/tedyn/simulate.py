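"""Paired-genome transposable-element simulator with full ground truth.

Emulates the comparative scenario the rest of the pipeline is built to
analyse: a set of TE families already present in the common ancestor of two
lineages, lineage-specific transposition after the split, neutral sequence
divergence, copy fragmentation, and a recent suppression of successful
insertions in lineage A (the selfing-onset analog).

Model summary
-------------
* Each family is founded by a master element ``ancestral_depth`` Myr before
  the lineage split.  Transposition events form a Poisson process per family
  per lineage (rate ``insertion_rate_per_family`` events/Myr); the ancestral
  lineage runs from the family origin to the split, after which the two
  lineages accumulate events independently.  All copies present at the split
  are inherited by both lineages.
* A transposition event replicates the current sequence of a source element.
  By default the source is the family master (the classical master-gene
  model); with probability ``1 - p_copy_master`` the source is instead drawn
  uniformly from the copies alive at the event time.  The master lineage
  models the succession of active source elements; by default it is not
  itself emitted as a genomic copy (``emit_master=True`` places it too).
* Sequences evolve under Jukes-Cantor substitution at ``subst_rate``
  substitutions/site/Myr, sampled exactly from the JC transition matrix over
  each inter-event interval.
* In lineage A, events falling inside ``suppression_window`` (Myr before
  present) succeed with probability ``suppression_factor``.
* At observation time a copy is truncated to a random fragment of at least
  ``min_fragment_len`` bp with probability ``fragmentation_prob``, and all
  surviving copies are placed non-overlapping, random strand, in a random
  background genome of ``genome_length`` bp (one contig per lineage).

Every surviving copy carries a :class:`TruthRecord`; the full sequence
genealogy is retained so that true pairwise divergence times can be computed
exactly (:func:`coalescence_time`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import decode, encode, random_seq, revcomp
from .errors import ConfigError, PlacementError

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimResult",
    "build_family_set",
    "simulate_two_lineages",
    "simulate_event_history",
    "expected_pair_divergence",
    "coalescence_time",
]

CLASSES = ("LTR", "DNA", "non-LTR", "unknown")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a two-lineage simulation.  Times in Myr before present."""

    seed: int = 0
    genome_length: int = 3_000_000
    n_families: int = 30
    family_length_range: tuple[int, int] = (800, 3000)
    split_time: float = 5.0
    ancestral_depth: float = 5.0
    suppression_window: tuple[float, float] = (0.0, 0.413)
    suppression_factor: float = 0.2
    subst_rate: float = 0.015
    insertion_rate_per_family: float = 2.5
    fragmentation_prob: float = 0.3
    min_fragment_len: int = 200
    p_copy_master: float = 1.0
    emit_master: bool = False
    class_mix: tuple[tuple[str, float], ...] = (
        ("LTR", 0.4),
        ("DNA", 0.3),
        ("non-LTR", 0.2),
        ("unknown", 0.1),
    )

    def validate(self) -> None:
        lo, hi = self.family_length_range
        w0, w1 = self.suppression_window
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be positive")
        if self.n_families < 0:
            raise ConfigError("n_families must be >= 0")
        if not (0 < lo <= hi):
            raise ConfigError("family_length_range must satisfy 0 < lo <= hi")
        if lo < self.min_fragment_len:
            raise ConfigError("family_length_range min must be >= min_fragment_len")
        for name, val in (
            ("subst_rate", self.subst_rate),
            ("insertion_rate_per_family", self.insertion_rate_per_family),
            ("split_time", self.split_time),
            ("ancestral_depth", self.ancestral_depth),
        ):
            if val < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 <= self.suppression_factor <= 1.0):
            raise ConfigError("suppression_factor must lie in [0, 1]")
        if not (0.0 <= self.fragmentation_prob <= 1.0):
            raise ConfigError("fragmentation_prob must lie in [0, 1]")
        if not (0.0 <= self.p_copy_master <= 1.0):
            raise ConfigError("p_copy_master must lie in [0, 1]")
        if not (0.0 <= w0 <= w1 <= self.split_time):
            raise ConfigError("suppression_window must lie inside [0, split_time]")
        classes = {c for c, _ in self.class_mix}
        if any(c in classes for c in ("LTR", "DNA")) and lo < 200:
            raise ConfigError(
                "family_length_range min < 200 bp cannot host terminal-repeat "
                "structures for LTR/DNA families"
            )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one surviving genomic copy (0-based half-open)."""

    copy_id: str
    lineage: str  # "A" or "B"
    contig: str
    start: int
    end: int
    strand: str
    family_id: str
    true_insertion_time: float  # Myr before present
    parent_copy_id: str  # source element id, or "master"


@dataclass
class _Node:
    """Genealogy node: where a sequence lineage attaches to its parent's."""

    parent: str | None
    attach_time: float  # Myr at which this lineage split off the parent lineage
    insertion_time: float  # biological insertion age of the copy


@dataclass
class SimResult:
    genome_a: dict[str, str]
    genome_b: dict[str, str]
    truth: list[TruthRecord]
    genealogy: dict[str, _Node] = field(default_factory=dict)

    def __iter__(self):  # (genomeA, genomeB, truth) tuple contract
        return iter((self.genome_a, self.genome_b, self.truth))


def _class_assignment(cfg: SimConfig) -> list[str]:
    """Largest-remainder apportionment of n_families across class_mix."""
    n = cfg.n_families
    fracs = [(c, f) for c, f in cfg.class_mix]
    counts = [int(n * f) for _, f in fracs]
    rem = n - sum(counts)
    order = sorted(
        range(len(fracs)), key=lambda i: (-(n * fracs[i][1] - counts[i]), i)
    )
    for i in order[:rem]:
        counts[i] += 1
    out: list[str] = []
    for (c, _), k in zip(fracs, counts):
        out.extend([c] * k)
    return out


def build_family_set(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Generate the shared ancestral TE families with class-diagnostic termini.

    LTR families carry identical direct terminal repeats, DNA families carry
    inverted terminal repeats, non-LTR families end in a poly-A tail, and
    unknown families are structureless random sequence.  Deterministic given
    ``cfg.seed``.
    """
    from .discovery import TEFamily  # local import: discovery also imports us

    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.family_length_range
    families = []
    for i, te_class in enumerate(_class_assignment(cfg)):
        length = int(rng.integers(lo, hi + 1))
        if te_class == "LTR":
            tlen = max(100, int(0.15 * length))
            term = random_seq(rng, tlen)
            core = random_seq(rng, length - 2 * tlen)
            seq = term + core + term
        elif te_class == "DNA":
            tlen = max(60, int(0.15 * length))
            term = random_seq(rng, tlen)
            core = random_seq(rng, length - 2 * tlen)
            seq = term + core + revcomp(term)
        elif te_class == "non-LTR":
            tail = 15
            seq = random_seq(rng, length - tail) + "A" * tail
        else:
            seq = random_seq(rng, length)
        families.append(
            TEFamily(
                family_id=f"RU{i + 1:04d}",
                consensus=seq,
                te_class=te_class,
                source="known",
            )
        )
    return families


def _evolve(codes: np.ndarray, dt: float, rate: float, rng: np.random.Generator):
    """Exact Jukes-Cantor transition sampling over an interval of dt Myr."""
    if dt <= 0 or rate <= 0 or len(codes) == 0:
        return codes
    p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * dt))
    hit = rng.random(len(codes)) < p
    n = int(hit.sum())
    if n:
        codes = codes.copy()
        # replace with one of the three other bases, uniformly
        codes[hit] = (codes[hit] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return codes


def simulate_event_history(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Draw the transposition event history only (no sequences).

    Returns ``(copies, genealogy)`` where ``copies`` is a list of dicts with
    keys id/lineage/family_id/insertion_time/parent for every copy present in
    lineage A or B at observation time, and ``genealogy`` maps every node id
    (including ancestral-lineage nodes) to a :class:`_Node`.

    This is the fast path used for age-distribution power studies, and the
    first stage of :func:`simulate_two_lineages`.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rate = cfg.insertion_rate_per_family
    t_origin = cfg.split_time + cfg.ancestral_depth
    w0, w1 = cfg.suppression_window
    copies: list[dict] = []
    genealogy: dict[str, _Node] = {}

    for fidx in range(cfg.n_families):
        fam = f"RU{fidx + 1:04d}"
        master = f"{fam}.anc0000"
        genealogy[master] = _Node(None, t_origin, t_origin)
        anc_ids = [master]
        # ancestral transposition, family origin -> split
        n_anc = rng.poisson(rate * cfg.ancestral_depth)
        anc_times = np.sort(rng.uniform(cfg.split_time, t_origin, n_anc))[::-1]
        for j, t in enumerate(anc_times):
            cid = f"{fam}.anc{j + 1:04d}"
            if rng.random() < cfg.p_copy_master:
                parent = master
            else:
                parent = anc_ids[int(rng.integers(0, len(anc_ids)))]
            genealogy[cid] = _Node(parent, float(t), float(t))
            anc_ids.append(cid)
        # both lineages inherit every ancestral copy; sequences fork at split
        lineage_ids = {}
        for lin in ("A", "B"):
            inherited = []
            for aid in anc_ids:
                iid = f"{lin}.{aid}"
                genealogy[iid] = _Node(
                    aid, cfg.split_time, genealogy[aid].insertion_time
                )
                inherited.append(iid)
            lineage_ids[lin] = inherited
        # post-split transposition per lineage
        for lin in ("A", "B"):
            n_ev = rng.poisson(rate * cfg.split_time)
            times = np.sort(rng.uniform(0.0, cfg.split_time, n_ev))[::-1]
            serial = 0
            for t in times:
                if (
                    lin == "A"
                    and w0 <= t < w1
                    and rng.random() >= cfg.suppression_factor
                ):
                    continue
                serial += 1
                cid = f"{lin}.{fam}.n{serial:04d}"
                if rng.random() < cfg.p_copy_master:
                    parent = f"{lin}.{master}"
                else:
                    ids = lineage_ids[lin]
                    parent = ids[int(rng.integers(0, len(ids)))]
                genealogy[cid] = _Node(parent, float(t), float(t))
                lineage_ids[lin].append(cid)
        for lin in ("A", "B"):
            for cid in lineage_ids[lin]:
                if not cfg.emit_master and cid.endswith(".anc0000"):
                    # the master lineage abstracts the succession of active
                    # source elements; by default it is not itself emitted as
                    # an observable genomic copy
                    continue
                node = genealogy[cid]
                copies.append(
                    {
                        "id": cid,
                        "lineage": lin,
                        "family_id": fam,
                        "insertion_time": node.insertion_time,
                        "parent": node.parent,
                    }
                )
    return copies, genealogy


def simulate_two_lineages(
    families, cfg: SimConfig, rng: np.random.Generator | None = None
) -> SimResult:
    """Simulate both genomes plus truth records; see the module docstring.

    ``families`` must come from :func:`build_family_set` (or at least provide
    one consensus per family, in family-id order matching the event history).
    """
    cfg.validate()
    if not families and cfg.n_families > 0:
        raise ConfigError("families must be non-empty")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    consensus = {f.family_id: f.consensus for f in families}
    copies, genealogy = simulate_event_history(cfg, rng)

    # --- sequence evolution along the genealogy (lazy exact-JC updates) ---
    seqs: dict[str, str] = {}
    by_family: dict[str, list[str]] = {}
    for node_id in genealogy:
        stem = node_id[2:] if node_id[:2] in ("A.", "B.") else node_id
        by_family.setdefault(stem.split(".")[0], []).append(node_id)
    for fam, node_ids in by_family.items():
        if fam not in consensus:
            raise ConfigError(f"no consensus provided for family {fam}")
        # chronological processing: create each node's sequence state at its
        # attach time by evolving the parent state down to that time
        order = sorted(node_ids, key=lambda i: (-genealogy[i].attach_time, i))
        state: dict[str, tuple[np.ndarray, float]] = {}
        for nid in order:
            node = genealogy[nid]
            if node.parent is None:
                state[nid] = (encode(consensus[fam]), node.attach_time)
                continue
            pcodes, pt = state[node.parent]
            pcodes = _evolve(pcodes, pt - node.attach_time, cfg.subst_rate, rng)
            state[node.parent] = (pcodes, node.attach_time)
            state[nid] = (pcodes.copy(), node.attach_time)
        for nid in order:
            if nid.startswith(("A.", "B.")):
                codes, t = state[nid]
                seqs[nid] = decode(_evolve(codes, t, cfg.subst_rate, rng))

    # --- fragmentation ---
    final: list[tuple[dict, str]] = []
    for copy in copies:
        seq = seqs[copy["id"]]
        if (
            cfg.fragmentation_prob > 0
            and len(seq) > cfg.min_fragment_len
            and rng.random() < cfg.fragmentation_prob
        ):
            flen = int(rng.integers(cfg.min_fragment_len, len(seq) + 1))
            off = int(rng.integers(0, len(seq) - flen + 1))
            seq = seq[off : off + flen]
        final.append((copy, seq))

    # --- placement: random non-overlapping layout in one pass per lineage ---
    genomes: dict[str, dict[str, str]] = {}
    truth: list[TruthRecord] = []
    for lin in ("A", "B"):
        contig = f"chr{lin}"
        items = [(c, s) for c, s in final if c["lineage"] == lin]
        perm = rng.permutation(len(items))
        items = [items[i] for i in perm]
        total = sum(len(s) for _, s in items)
        background = cfg.genome_length - total
        if background < 0:
            raise PlacementError(
                f"lineage {lin}: {total} bp of TE copies exceed the "
                f"{cfg.genome_length} bp genome"
            )
        cuts = np.sort(rng.integers(0, background + 1, size=len(items)))
        bg = random_seq(rng, background)
        pieces: list[str] = []
        pos = 0
        prev_cut = 0
        for (copy, seq), cut in zip(items, cuts):
            cut = int(cut)
            pieces.append(bg[prev_cut:cut])
            pos += cut - prev_cut
            prev_cut = cut
            strand = "+" if rng.random() < 0.5 else "-"
            placed = seq if strand == "+" else revcomp(seq)
            pieces.append(placed)
            parent = copy["parent"] or "master"
            if parent.endswith(".anc0000"):
                parent = "master"
            truth.append(
                TruthRecord(
                    copy_id=copy["id"],
                    lineage=lin,
                    contig=contig,
                    start=pos,
                    end=pos + len(placed),
                    strand=strand,
                    family_id=copy["family_id"],
                    true_insertion_time=copy["insertion_time"],
                    parent_copy_id=parent,
                )
            )
            pos += len(placed)
        pieces.append(bg[prev_cut:])
        genomes[lin] = {contig: "".join(pieces)}
    truth.sort(key=lambda t: (t.lineage, t.contig, t.start))
    return SimResult(genomes["A"], genomes["B"], truth, genealogy)


def expected_pair_divergence(t1: float, t2: float, r: float) -> float:
    """Expected substitutions/site separating two copies.

    ``t1`` and ``t2`` are the times (Myr) each copy has evolved independently
    since their sequences were last identical, so K = r*(t1 + t2); for two
    copies dating from the same transposition event at time t this collapses
    to the dating identity K = 2rt.
    """
    if t1 < 0 or t2 < 0:
        raise ValueError("times must be >= 0")
    if r < 0:
        raise ValueError("rate must be >= 0")
    return r * (t1 + t2)


def coalescence_time(genealogy: dict, x: str, y: str) -> float:
    """True divergence time (Myr) of two copies from the simulator genealogy.

    The value is the age at which the two sequence lineages last shared a
    common path — exactly the quantity K/2r estimates in expectation.
    """
    if x == y:
        return 0.0

    def chain(z: str) -> dict[str, float]:
        out = {z: 0.0}
        node = genealogy[z]
        while node.parent is not None:
            out[node.parent] = node.attach_time
            node = genealogy[node.parent]
        return out

    cx, cy = chain(x), chain(y)
    common = set(cx) & set(cy)
    if not common:
        raise ValueError(f"{x} and {y} share no genealogical root")
    return min(max(cx[c], cy[c]) for c in common)
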