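"""Stage orchestration: config, the two analysis tracks, and the manifest.

The chimera track runs merge -> trim -> contiguity filter -> arm search ->
chimera calling; the IP track runs merge -> end-to-end placement ->
TAR/NT3UTR counting -> TMM -> local enrichment -> KO-vs-WT ranking.  The
combined report cross-references chimera-supported transcripts with
enrichment ranks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .aligner import (
    AlignParams,
    ContiguousMatcher,
    SubjectIndex,
    filter_contiguous,
    local_align,
    place_reads,
    refine_junction_overlaps,
)
from .chimera import aggregate_hybrids, call_chimeras, select_mirna_hybrids
from .enrichment import (
    build_region_pairs,
    compute_enrichment,
    count_regions,
    library_scales,
    rank_targets,
    tmm_factors,
)
from .read_prep import AdapterSpec, MergeParams, prepare_reads, read_fastq_pairs, write_fastq
from .reference_io import (
    load_references,
    write_chimera_table,
    write_hit_table,
    write_table,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class IPSample:
    sample_id: str
    genotype: str  # IPWT | IPKO
    r1: str
    r2: str


@dataclass
class PipelineConfig:
    mirna_fasta: str
    transcript_fasta: str
    utr_table: str
    site_table: str
    output_dir: str = "clashpipe_out"
    seed: int = 0

    clash_r1: str | None = None
    clash_r2: str | None = None
    mirna_of_interest: str | None = None
    ip_samples: list[IPSample] = field(default_factory=list)

    merge: MergeParams = field(default_factory=MergeParams)
    adapters: AdapterSpec | None = field(default_factory=AdapterSpec)
    align_mirna: AlignParams = field(default_factory=lambda: AlignParams(evalue_max=10.0))
    align_mrna: AlignParams = field(default_factory=lambda: AlignParams(evalue_max=0.1))
    contiguity_max_mismatch_rate: float = 0.06
    chimera_max_gap: int = 10
    chimera_all_pairs: bool = False
    ip_trim_adapters: bool = False

    tar_width: int = 100
    pseudocount: float = 0.5
    m_trim: float = 0.30
    a_trim: float = 0.05
    use_tmm: bool = True
    per_kb: bool = False
    filter_mode: str = "wt_min"
    le_filter_threshold: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        try:
            refs = raw.get("references", {})
            kwargs = dict(
                mirna_fasta=refs["mirna_fasta"],
                transcript_fasta=refs["transcript_fasta"],
                utr_table=refs["utr_table"],
                site_table=refs["site_table"],
            )
        except KeyError as exc:
            raise ConfigError(f"missing reference path: {exc}") from exc
        kwargs["output_dir"] = raw.get("output_dir", "clashpipe_out")
        kwargs["seed"] = int(raw.get("seed", 0))
        clash = raw.get("clash") or {}
        kwargs["clash_r1"] = clash.get("r1")
        kwargs["clash_r2"] = clash.get("r2")
        kwargs["mirna_of_interest"] = clash.get("mirna_of_interest")
        kwargs["ip_samples"] = [IPSample(**s) for s in raw.get("ip_samples", [])]
        if "merge" in raw:
            kwargs["merge"] = MergeParams(**raw["merge"])
        if "adapters" in raw:
            ad = raw["adapters"]
            kwargs["adapters"] = None if ad is None else AdapterSpec(**ad)
        if "align_mirna" in raw:
            kwargs["align_mirna"] = AlignParams(**{"evalue_max": 10.0, **raw["align_mirna"]})
        if "align_mrna" in raw:
            kwargs["align_mrna"] = AlignParams(**{"evalue_max": 0.1, **raw["align_mrna"]})
        for key in (
            "contiguity_max_mismatch_rate", "chimera_max_gap", "chimera_all_pairs",
            "ip_trim_adapters", "tar_width", "pseudocount", "m_trim", "a_trim",
            "use_tmm", "per_kb", "filter_mode", "le_filter_threshold",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def validate(self, mode: str) -> None:
        paths = [self.mirna_fasta, self.transcript_fasta, self.utr_table, self.site_table]
        if mode in ("clash", "all"):
            if not self.clash_r1 or not self.clash_r2:
                raise ConfigError("clash mode needs clash.r1 and clash.r2")
            paths += [self.clash_r1, self.clash_r2]
        if mode in ("ip-enrich", "all"):
            if not self.ip_samples:
                raise ConfigError("ip-enrich mode needs ip_samples")
            for s in self.ip_samples:
                paths += [s.r1, s.r2]
        for p in paths:
            if not Path(p).exists():
                raise ConfigError(f"missing input file: {p}")

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_clash_track(config: PipelineConfig, refs, out_dir: Path) -> dict:
    pairs = read_fastq_pairs(config.clash_r1, config.clash_r2)
    reads, prep_stats = prepare_reads(pairs, config.merge, config.adapters)
    write_fastq(reads, out_dir / "merged_trimmed.fastq")

    survivors = filter_contiguous(reads, refs, config.contiguity_max_mismatch_rate)
    mirna_idx = SubjectIndex.for_class(refs, "miRNA", config.align_mirna)
    mrna_idx = SubjectIndex.for_class(refs, "mRNA", config.align_mrna)
    arms_by_read = {}
    all_hits = []
    for r in survivors:
        arms = (
            local_align(r, refs, config.align_mirna, "miRNA", mirna_idx)
            + local_align(r, refs, config.align_mrna, "mRNA", mrna_idx)
        )
        if arms:
            arms_by_read[r.id] = arms
            all_hits.extend(arms)
    write_hit_table(all_hits, out_dir / "arm_hits.tsv")

    arms_by_read = refine_junction_overlaps(
        arms_by_read, config.align_mirna, config.align_mrna
    )
    calls = call_chimeras(arms_by_read, config.chimera_max_gap, config.chimera_all_pairs)
    write_chimera_table(calls, out_dir / "chimeras.tsv")
    write_table(aggregate_hybrids(calls), out_dir / "hybrid_counts.tsv")
    if config.mirna_of_interest:
        subset = select_mirna_hybrids(calls, config.mirna_of_interest)
        write_chimera_table(subset, out_dir / f"hybrids_{config.mirna_of_interest}.tsv")

    return {
        **prep_stats,
        "post_contiguity": len(survivors),
        "reads_with_arms": len(arms_by_read),
        "chimera_calls": len(calls),
        "_calls": calls,
    }


def run_ip_track(config: PipelineConfig, refs, out_dir: Path) -> dict:
    placements = []
    genotypes = {}
    adapters = config.adapters if config.ip_trim_adapters else None
    for sample in config.ip_samples:
        pairs = read_fastq_pairs(sample.r1, sample.r2)
        reads, _ = prepare_reads(pairs, config.merge, adapters)
        placed = place_reads(reads, refs, config.contiguity_max_mismatch_rate)
        placements.extend((sample.sample_id, tx, iv) for _rid, tx, iv in placed)
        genotypes[sample.sample_id] = sample.genotype
    return enrich_from_placements(config, refs, placements, genotypes, out_dir)


def enrich_from_placements(config, refs, placements, genotypes, out_dir: Path) -> dict:
    regions = build_region_pairs(refs, config.tar_width)
    matrix = count_regions(placements, regions, genotypes)
    write_table(
        matrix.values.reset_index().rename(columns={"index": "region"}),
        out_dir / "region_counts.tsv",
    )
    if config.use_tmm:
        factors = tmm_factors(matrix, config.m_trim, config.a_trim)
        scales = library_scales(matrix, factors)
        write_table(
            pd.DataFrame({"sample": factors.index, "tmm_factor": factors.to_numpy(),
                          "scale": scales.to_numpy()}),
            out_dir / "tmm_factors.tsv",
        )
    else:
        scales = None
    records = compute_enrichment(matrix, regions, config.pseudocount, scales, config.per_kb)
    table = rank_targets(records, matrix, config.le_filter_threshold, config.filter_mode)
    write_table(table, out_dir / "enrichment.tsv")
    return {
        "placements": len(placements),
        "regions": len(regions),
        "ranked_sites": len(table),
        "_table": table,
    }


def combined_report(clash_stats: dict, ip_stats: dict, out_dir: Path) -> pd.DataFrame:
    """Join enrichment ranks with per-TAR chimera support."""
    calls = clash_stats.get("_calls", [])
    table = ip_stats.get("_table", pd.DataFrame())
    rows = []
    for _, rec in table.iterrows():
        tar = (int(rec["tar_start"]), int(rec["tar_end"]))
        support = [
            c for c in calls
            if c.mrna_arm.subject_id == rec["transcript_id"]
            and c.mrna_arm.subject_interval[0] < tar[1]
            and tar[0] < c.mrna_arm.subject_interval[1]
        ]
        mirnas = sorted({c.mirna_arm.subject_id for c in support})
        rows.append({
            "site_id": rec["site_id"],
            "transcript_id": rec["transcript_id"],
            "rank": int(rec["rank"]),
            "delta": rec["delta"],
            "chimera_support": len(support),
            "supporting_mirnas": ",".join(mirnas) if mirnas else ".",
        })
    df = pd.DataFrame(
        rows, columns=["site_id", "transcript_id", "rank", "delta",
                       "chimera_support", "supporting_mirnas"],
    )
    write_table(df, out_dir / "combined_report.tsv")
    return df


def run_pipeline(config: PipelineConfig, mode: str = "all") -> Path:
    """Run the configured stages; returns the output directory.

    Raises :class:`ConfigError` on validation problems and
    :class:`StageError` when a stage fails.
    """
    if mode not in ("clash", "ip-enrich", "all"):
        raise ConfigError(f"unknown mode {mode!r}")
    config.validate(mode)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        refs = load_references(
            config.mirna_fasta, config.transcript_fasta,
            config.utr_table, config.site_table,
        )
    except Exception as exc:
        raise StageError("load_references", str(exc)) from exc

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "mode": mode,
        "counts": {
            "mirnas": len(refs.mirnas),
            "transcripts": len(refs.transcripts),
            "sites": len(refs.sites),
        },
    }
    clash_stats = ip_stats = None
    if mode in ("clash", "all"):
        try:
            clash_stats = run_clash_track(config, refs, out_dir)
        except Exception as exc:
            raise StageError("clash", str(exc)) from exc
        manifest["counts"].update({k: v for k, v in clash_stats.items()
                                   if not k.startswith("_")})
    if mode in ("ip-enrich", "all"):
        try:
            ip_stats = run_ip_track(config, refs, out_dir)
        except Exception as exc:
            raise StageError("ip-enrich", str(exc)) from exc
        manifest["counts"].update({k: v for k, v in ip_stats.items()
                                   if not k.startswith("_")})
    if mode == "all":
        combined_report(clash_stats, ip_stats, out_dir)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out_dir
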