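"""End-to-end orchestration: simulate -> discover -> annotate -> date ->
compare -> agedist, with a reproducibility manifest.

All thresholds live in :class:`PipelineConfig`; every stage reads them from
there, and all randomness flows from the single configured seed.  The
manifest records the package version, the seed, a hash of the canonical
config serialization, per-stage counts, and a checksum of every output file,
so two runs with the same config produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .agedist import build_age_distribution, detect_drop, fit_exponential
from .annotate import AnnotateConfig, annotation_stats, resolve_overlaps, scan_genome
from .compare import (
    build_family_summaries,
    copy_number_table,
    partition_families,
    wilcoxon_rank_sum,
)
from .dating import (
    element_age,
    export_distance_matrix,
    family_average_age,
    pairwise_divergence,
    stack_family,
)
from .discovery import DiscoveryConfig, discover_families
from .errors import ConfigError, FitError
from .io import (
    write_alignments,
    write_bed,
    write_fasta,
    write_gff3,
    write_library_fasta,
    write_rm_out,
    write_truth_tsv,
)
from .simulate import SimConfig, build_family_set, simulate_two_lineages

log = logging.getLogger("tedyn")

__all__ = ["PipelineConfig", "run_all", "date_annotations"]


@dataclass
class PipelineConfig:
    """Single source of truth for every stage's thresholds."""

    seed: int = 0
    r: float = 0.015  # substitutions/site/Myr
    min_overlap_bp: int = 200
    conservative_mode: bool = False  # min_consensus_len -> 2000
    run_discovery: bool = True
    fit_window: tuple[float, float] = (0.0, 2.0)
    drop_window: tuple[float, float] = (0.0, 0.5)
    age_bin_width: float = 0.25
    sim: SimConfig = field(default_factory=SimConfig)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)

    def __post_init__(self):
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        if self.conservative_mode:
            self.discovery = dataclasses.replace(
                self.discovery, min_consensus_len=2000
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = {
            k: tuple(v) if isinstance(v, list) else v for k, v in d.items()
        }
        for key, sub in (
            ("sim", SimConfig),
            ("discovery", DiscoveryConfig),
            ("annotate", AnnotateConfig),
        ):
            if key in d and isinstance(d[key], dict):
                kw = dict(d[key])
                for k, v in kw.items():
                    if isinstance(v, list):
                        kw[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
                d[key] = sub(**kw)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def date_annotations(hits, library, r: float, min_overlap: int = 200):
    """Per-copy and per-family dating of resolved annotations.

    Builds one alignment stack per family across all genomes present in
    ``hits``; per-copy nearest neighbors are restricted to the same genome
    (ages in the "both" scope allow cross-genome partners); family averages
    are computed per genome and for both combined.

    Returns (ages, family_ages, stacks, divergences) where ``ages`` maps
    scope ("both" or a genome id) -> {copy_id: AgeEstimate}.
    """
    cons_len = {f.family_id: len(f.consensus) for f in library}
    by_family: dict[str, list] = {}
    for h in hits:
        by_family.setdefault(h.family_id, []).append(h)
    genomes = sorted({h.genome_id for h in hits})
    ages: dict[str, dict] = {g: {} for g in ["both", *genomes]}
    family_ages: dict[tuple, object] = {}
    stacks, divs = {}, {}
    for fam_id in sorted(by_family):
        fam_hits = by_family[fam_id]
        stack = stack_family(fam_hits, cons_len[fam_id], fam_id)
        stacks[fam_id] = stack
        if stack.n < 2:
            continue
        recs = pairwise_divergence(stack, min_overlap=min_overlap)
        divs[fam_id] = recs
        same_genome = {
            g: [
                rec
                for rec in recs
                if stack.genome_of[rec.copy_a] == g and stack.genome_of[rec.copy_b] == g
            ]
            for g in genomes
        }
        for cid in stack.copy_ids:
            g = stack.genome_of[cid]
            ages["both"][cid] = element_age(cid, recs, r)
            ages[g][cid] = element_age(cid, same_genome[g], r)
        family_ages[(fam_id, "both")] = family_average_age(stack, recs, r, "both")
        for g in genomes:
            family_ages[(fam_id, g)] = family_average_age(
                stack, same_genome[g], r, g
            )
    return ages, family_ages, stacks, divs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: PipelineConfig, output_dir) -> dict:
    """Run the full pipeline on a simulated genome pair; returns the manifest."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
    }
    stage = "simulate"
    try:
        families = build_family_set(cfg.sim)
        sim = simulate_two_lineages(families, cfg.sim)
        write_fasta(out / "genome_A.fasta", sim.genome_a)
        write_fasta(out / "genome_B.fasta", sim.genome_b)
        write_truth_tsv(out / "truth.tsv", sim.truth)
        write_bed(out / "truth.bed", sim.truth)
        write_library_fasta(out / "true_families.fasta", families)
        manifest["stages"]["simulate"] = {
            "n_families": len(families),
            "n_truth_copies": len(sim.truth),
        }
        log.info("simulate: %d families, %d copies", len(families), len(sim.truth))

        stage = "discover"
        if cfg.run_discovery:
            library, filt_log = discover_families(
                [sim.genome_a, sim.genome_b], cfg.discovery, known=families
            )
            with open(out / "filter_log.tsv", "w") as fh:
                fh.write("candidate\treason\n")
                for seed, reason in filt_log:
                    fh.write(f"{seed}\t{reason}\n")
        else:
            library, filt_log = list(families), []
        write_library_fasta(out / "library.fasta", library)
        manifest["stages"]["discover"] = {
            "library_size": len(library),
            "n_filtered": len(filt_log),
        }

        stage = "annotate"
        class_of = {f.family_id: f.te_class for f in library}
        resolved = {}
        for gid, genome in (("A", sim.genome_a), ("B", sim.genome_b)):
            raw = scan_genome(genome, library, cfg.annotate, genome_id=gid)
            hits = resolve_overlaps(raw)
            resolved[gid] = hits
            glen = sum(len(s) for s in genome.values())
            stats = annotation_stats(hits, glen, class_of)
            write_rm_out(out / f"annotations_{gid}.out", hits, class_of)
            write_gff3(out / f"annotations_{gid}.gff3", hits, class_of)
            write_bed(out / f"annotations_{gid}.bed", hits)
            write_alignments(out / f"alignments_{gid}.tsv", hits)
            manifest["stages"].setdefault("annotate", {})[gid] = {
                "raw_hits": len(raw),
                "resolved": len(hits),
                "per_mbp": round(stats["total_per_mbp"], 3),
                "coverage": round(stats["coverage"], 5),
                "mean_copy_len": round(stats["mean_copy_len"], 1),
            }

        stage = "date"
        all_hits = resolved["A"] + resolved["B"]
        ages, family_ages, stacks, divs = date_annotations(
            all_hits, library, cfg.r, cfg.min_overlap_bp
        )
        fam_of = {h.copy_id: h.family_id for h in all_hits}
        with open(out / "copy_ages.tsv", "w") as fh:
            fh.write("copy_id\tfamily_id\tgenome\tK\toverlap\tT\tqualified\tscope\n")
            for scope in sorted(ages):
                for cid in sorted(ages[scope]):
                    est = ages[scope][cid]
                    fam = fam_of[cid]
                    g = cid.split(".")[0]
                    fh.write(
                        f"{cid}\t{fam}\t{g}\t{est.K:.6f}\t{est.overlap}\t"
                        f"{est.T:.6f}\t{est.qualified}\t{scope}\n"
                    )
        with open(out / "family_ages.tsv", "w") as fh:
            fh.write("family_id\tscope\tmean_K\tavg_insertion_time\tn_pairs\n")
            for (fam, scope), fa in sorted(family_ages.items()):
                fh.write(
                    f"{fam}\t{scope}\t{fa.mean_pairwise_K:.6f}\t"
                    f"{fa.average_insertion_time:.6f}\t{fa.n_pairs}\n"
                )
        dist_dir = out / "distances"
        dist_dir.mkdir(exist_ok=True)
        n_matrices = 0
        for fam_id, stack in stacks.items():
            if fam_id in divs and export_distance_matrix(
                stack, divs[fam_id], dist_dir / f"{fam_id}.dist"
            ):
                n_matrices += 1
        manifest["stages"]["date"] = {
            "n_families_dated": len(divs),
            "n_matrices": n_matrices,
        }

        stage = "compare"
        glen_a = sum(len(s) for s in sim.genome_a.values())
        glen_b = sum(len(s) for s in sim.genome_b.values())
        summaries = build_family_summaries(
            library, resolved["A"], resolved["B"], glen_a, glen_b, family_ages
        )
        partition = partition_families(summaries)
        table = copy_number_table(summaries, by_class=True)
        xa = [s.count_A for s in summaries if s.status != "absent"]
        xb = [s.count_B for s in summaries if s.status != "absent"]
        if xa and xb:
            w, p = wilcoxon_rank_sum(xa, xb, mode="normal")
        else:
            w, p = math.nan, math.nan
        with open(out / "family_summaries.tsv", "w") as fh:
            fh.write(
                "family_id\tte_class\tcount_A\tcount_B\tdensity_A\tdensity_B"
                "\tstatus\tavg_age_A\tavg_age_B\tavg_age_both\n"
            )
            for s in summaries:
                fh.write(
                    f"{s.family_id}\t{s.te_class}\t{s.count_A}\t{s.count_B}\t"
                    f"{s.density_A:.3f}\t{s.density_B:.3f}\t{s.status}\t"
                    f"{s.avg_age_A:.4f}\t{s.avg_age_B:.4f}\t{s.avg_age_both:.4f}\n"
                )
        manifest["stages"]["compare"] = {
            "partition": partition,
            "copy_table_all": {k: round(v, 4) for k, v in table["all"].items()},
            "wilcoxon_p": float(f"{p:.6g}") if not math.isnan(p) else None,
        }

        stage = "agedist"
        age_block = {}
        for gid in ("A", "B"):
            t = np.array(
                [est.T for est in ages[gid].values() if est.qualified], dtype=float
            )
            dist = build_age_distribution(t, cfg.age_bin_width, "all", gid)
            info = {"n": int(dist.n_total), "mean_age": round(dist.mean_age, 4)}
            try:
                fit = fit_exponential(t, cfg.fit_window)
                info["half_life"] = round(fit.half_life, 4)
            except FitError as exc:
                info["fit_error"] = str(exc)
            try:
                drop = detect_drop(t, cfg.drop_window)
                info["drop"] = {
                    "observed": drop.observed,
                    "expected": round(drop.expected, 2),
                    "ratio": round(drop.ratio, 4),
                    "detected": drop.drop_detected,
                }
            except (FitError, ConfigError) as exc:
                info["drop_error"] = str(exc)
            age_block[gid] = info
            with open(out / f"age_distribution_{gid}.tsv", "w") as fh:
                fh.write("bin_start\tbin_end\tcount\tpercent\n")
                for i, c in enumerate(dist.counts):
                    fh.write(
                        f"{dist.bin_edges[i]:.3f}\t{dist.bin_edges[i + 1]:.3f}\t"
                        f"{int(c)}\t{dist.percent[i]:.4f}\n"
                    )
        manifest["stages"]["agedist"] = age_block
    except Exception:
        log.error("pipeline aborted in stage %r; partial outputs kept in %s", stage, out)
        raise

    manifest["files"] = {
        p.name if p.parent == out else f"{p.parent.name}/{p.name}": _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
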