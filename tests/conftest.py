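"""Shared fixtures: simulated genome pairs at two scales, with annotations.

The "small" fixture (0.6 Mbp, 8 families) backs most module tests; the
"default-scale" fixture (3 Mbp per lineage, ~1,500 copies) backs the
recovery checks and is computed once per session.
"""

from __future__ import annotations

import bisect

import numpy as np
import pytest
from hypothesis import settings

from tedyn import (
    AnnotateConfig,
    SimConfig,
    build_family_set,
    resolve_overlaps,
    scan_genome,
    simulate_two_lineages,
)
from tedyn.pipeline import date_annotations

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


class SimBundle:
    """A simulated genome pair plus resolved annotations and dated copies."""

    def __init__(self, cfg: SimConfig, r: float = 0.015):
        self.cfg = cfg
        self.families = build_family_set(cfg)
        self.sim = simulate_two_lineages(self.families, cfg)
        acfg = AnnotateConfig()
        self.hits = {}
        for gid, genome in (("A", self.sim.genome_a), ("B", self.sim.genome_b)):
            self.hits[gid] = resolve_overlaps(scan_genome(genome, self.families, acfg, gid))
        self.all_hits = self.hits["A"] + self.hits["B"]
        self.hit_by_id = {h.copy_id: h for h in self.all_hits}
        self.ages, self.family_ages, self.stacks, self.divs = date_annotations(
            self.all_hits, self.families, r
        )
        self._truth_sorted = {}
        for t in self.sim.truth:
            self._truth_sorted.setdefault((t.lineage, t.contig), []).append(t)
        for key in self._truth_sorted:
            self._truth_sorted[key].sort(key=lambda t: t.start)

    def truth_match(self, hit):
        """The truth copy covered >50% by this hit, or None."""
        lst = self._truth_sorted.get((hit.genome_id, hit.contig), [])
        starts = [t.start for t in lst]
        i = bisect.bisect_left(starts, hit.end)
        for t in lst[max(0, i - 3) : i + 1]:
            ov = min(hit.end, t.end) - max(hit.start, t.start)
            if ov > 0.5 * (t.end - t.start):
                return t
        return None

    def matched_age_pairs(self):
        """(true_age, estimated_T) for qualified copies, same-genome scope."""
        out = []
        for gid in ("A", "B"):
            for cid, est in self.ages[gid].items():
                if not est.qualified:
                    continue
                t = self.truth_match(self.hit_by_id[cid])
                if t is not None:
                    out.append((t.true_insertion_time, est.T))
        return out


@pytest.fixture(scope="session")
def small_bundle() -> SimBundle:
    cfg = SimConfig(
        seed=1, genome_length=600_000, n_families=8, insertion_rate_per_family=2.0
    )
    return SimBundle(cfg)


@pytest.fixture(scope="session")
def default_bundle() -> SimBundle:
    """Default study conditions: two 3-Mbp lineages, ~1,500 copies."""
    return SimBundle(SimConfig(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
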