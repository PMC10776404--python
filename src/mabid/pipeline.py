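"""Stage orchestration: simulate/demux -> count -> normalize -> segment -> metrics.

Stages exchange plain files on disk and append to a JSON manifest carrying
inputs, seeds and output checksums, so any run is inspectable and
reproducible given (inputs, config, seeds).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger("mabid")


@dataclass
class PipelineConfig:
    out_dir: str = "mabid_out"
    fastq: str | None = None  # None -> simulate input reads
    scheme: str | None = None  # YAML path; None -> built-in default scheme
    keep_classes: tuple[int, ...] = (1, 2)
    chemistry: str = "TTAA"
    bin_size: int = 5_000
    umi_cap: int = 1_000
    min_mapq: int = 10
    pseudocount: float = 1.0
    control_epitope: str = "control"
    hmm_states: int = 3
    n_perm: int = 200
    seed: int = 0
    n_reads: int = 50_000
    stages: tuple[str, ...] = ("simulate", "demux", "count", "normalize", "segment", "metrics")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        for key in ("keep_classes", "stages"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_yaml(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    config: dict
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, outputs: list[Path], extra: dict | None = None) -> None:
        self.stages.append(
            {
                "stage": stage,
                "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "outputs": {str(p): _sha256(p) for p in outputs if p.exists()},
                **(extra or {}),
            }
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps({"config": self.config, "stages": self.stages}, indent=2))


def run_pipeline(config: PipelineConfig) -> Manifest:
    """Execute the enabled stages in order and write a provenance manifest.

    A stage failure halts the run with the stage name in the raised error.
    """
    from .scheme import BarcodeScheme, default_scheme

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config={k: list(v) if isinstance(v, tuple) else v
                                for k, v in config.__dict__.items()})
    scheme = (
        BarcodeScheme.from_yaml(config.scheme)
        if config.scheme
        else default_scheme(
            n_samples=1,
            epitopes=[("H3K27me3", config.chemistry), ("control", config.chemistry)],
        )
    )
    state: dict = {"scheme": scheme}
    order = ["simulate", "demux", "count", "normalize", "segment", "metrics"]
    try:
        for stage in order:
            if stage not in config.stages:
                continue
            logger.info("stage %s started", stage)
            _STAGES[stage](config, state, out, manifest)
            logger.info("stage %s finished", stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline halted in stage {stage!r}: {exc}") from exc
    manifest.write(out / "manifest.json")
    return manifest


def _stage_simulate(config, state, out, manifest):
    from . import simulate

    import numpy as np

    from .genome import MotifIndex

    sim = simulate.SimConfig(seed=config.seed)
    genome = simulate.simulate_genome(sim)
    rng = np.random.default_rng(sim.seed + 1)

    motif_index = MotifIndex.from_genome(genome)
    epitopes = [e.epitope for e in state["scheme"].abbc_whitelist if e.epitope != config.control_epitope]
    domains = simulate.simulate_domains(sim, epitopes, rng)
    accessibility = simulate.simulate_accessibility(sim, rng)
    records, truth = simulate.simulate_reads(
        sim, state["scheme"], genome, motif_index, domains, accessibility,
        n_reads=config.n_reads, control_epitope=config.control_epitope, rng=rng,
    )
    fastq = out / "simulated.fastq"
    simulate.write_fastq(records, fastq)
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    motif_path = out / "motifs.tsv"
    motif_index.to_tsv(motif_path)
    state.update(
        genome=genome, motif_index=motif_index, truth=truth, fastq=fastq,
        domains=domains, accessibility=accessibility, sim=sim,
    )
    manifest.record("simulate", [fastq, truth_path, motif_path], {"seed": config.seed})


def _stage_demux(config, state, out, manifest):
    from . import barcodes

    fastq = state.get("fastq") or config.fastq
    demux_dir = out / "demux"
    stats = barcodes.demultiplex_fastq(
        fastq, state["scheme"], demux_dir, keep_classes=config.keep_classes
    )
    stats_path = out / "demux_stats.json"
    barcodes.write_stats(stats, stats_path, out / "demux_stats.tsv")
    state["demux_stats"] = stats
    state["demux_dir"] = demux_dir
    manifest.record("demux", sorted(demux_dir.glob("*.fastq")) + [stats_path])


def _stage_count(config, state, out, manifest):
    from . import simulate, sites

    truth = state["truth"]
    scheme = state["scheme"]
    sim = state["sim"]
    alignments = simulate.truth_to_alignments(truth, scheme, sim.read_length)
    chemistry = {e.epitope: e.chemistry for e in scheme.abbc_whitelist}
    table, rejects = sites.count_sites(
        alignments, state["motif_index"], chemistry,
        min_mapq=config.min_mapq, umi_cap=config.umi_cap,
    )
    table_path = out / "site_counts.tsv"
    table.to_tsv(table_path)
    tracks_by = sites.bin_counts(table, state["genome"].chrom_sizes, config.bin_size)
    state["site_table"] = table
    state["binned"] = tracks_by
    manifest.record("count", [table_path], {"rejected": rejects})


def _stage_normalize(config, state, out, manifest):
    from . import tracks

    binned = state["binned"]
    controls = {s: t for (s, e), t in binned.items() if e == config.control_epitope}
    outputs = []
    normalized = {}
    for (sample, epitope), track in binned.items():
        if epitope == config.control_epitope or sample not in controls:
            continue
        norm = tracks.logcounts(
            track, controls[sample], pseudocount=config.pseudocount,
            sample_id=f"{sample}:{epitope}", control_id=f"{sample}:control",
        )
        path = out / f"normalized_{sample}_{epitope}.bedgraph"
        tracks.export_browser_track(norm, path)
        normalized[(sample, epitope)] = norm
        outputs.append(path)
    state["normalized"] = normalized
    manifest.record("normalize", outputs)


def _stage_segment(config, state, out, manifest):
    from . import tracks

    outputs = []
    segmentations = {}
    spec = tracks.HmmSpec.normalized() if config.hmm_states == 3 else tracks.HmmSpec.raw()
    for (sample, epitope), norm in state["normalized"].items():
        seg = tracks.hmm_segment(norm, spec, seed=config.seed)
        path = out / f"domains_{sample}_{epitope}.bed"
        seg.domains.to_bed(path)
        segmentations[(sample, epitope)] = seg
        outputs.append(path)
    state["segmentations"] = segmentations
    manifest.record("segment", outputs)


def _stage_metrics(config, state, out, manifest):
    from . import enrichment

    results = {}
    chrom_sizes = state["genome"].chrom_sizes
    for (sample, epitope), norm in state["normalized"].items():
        regions = state["domains"].get(epitope)
        if regions is None or len(regions) == 0:
            continue
        raw = state["binned"][(sample, epitope)]
        results[f"{sample}:{epitope}"] = {
            "frip": enrichment.frip(raw, regions),
            "seip_scaled": enrichment.seip_scaled(
                norm, regions, chrom_sizes, n_perm=config.n_perm, seed=config.seed
            ).scaled,
        }
    path = out / "metrics.json"
    path.write_text(json.dumps(results, indent=2))
    state["metrics"] = results
    manifest.record("metrics", [path])


_STAGES = {
    "simulate": _stage_simulate,
    "demux": _stage_demux,
    "count": _stage_count,
    "normalize": _stage_normalize,
    "segment": _stage_segment,
    "metrics": _stage_metrics,
}
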