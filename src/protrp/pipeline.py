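"""End-to-end pipeline: translate -> detect -> filter -> cluster ->
network -> classify, with reproducible configuration.

Every stage writes a self-describing TSV into the output directory and
the run ends with a JSON manifest recording package/library versions,
the seed, a hash of the effective configuration, and per-stage counts.
Re-running with an identical configuration reproduces identical output
bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .autosome_tr import (EngineParams, QCParams, autosome_tr_cluster,
                          canonical_rotation, clusters_to_table)
from .filters import (FilterParams, dedup_canonical, filter_report,
                      is_clusterable, is_gpi_anchored, is_pro_rich,
                      is_tr_module, passes_secretion)
from .network import (NetworkParams, annotate_nodes, build_network,
                      node_table, write_graphml, write_sif)
from .seqio import (SequenceRecord, extract_orf, load_annotations,
                    load_species_table, read_fasta,
                    translate_forward_frames)
from .taxonomy import (assign_classes, load_class_definitions,
                       periodicity_histogram)
from .trdetect import TRParams, detect_repeats, domains_to_table

logger = logging.getLogger(__name__)

NT_ALPHABET_SET = frozenset("ACGTN")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name (and record id when one
    is implicated)."""

    def __init__(self, stage: str, message: str,
                 record_id: str | None = None):
        self.stage = stage
        self.record_id = record_id
        loc = f"stage {stage!r}"
        if record_id:
            loc += f", record {record_id!r}"
        super().__init__(f"{loc}: {message}")


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths and the global seed.

    Defaults equal the published screen's parameter values throughout.
    """

    protein_fasta: str | None = None
    nucleotide_fasta: str | None = None
    annotation_tsv: str | None = None
    species_tsv: str | None = None
    class_definitions: str | None = None
    output_dir: str = "protrp_out"
    seed: int = 0
    log_level: str = "INFO"
    require_secretion: bool = True
    tr: TRParams = field(default_factory=TRParams)
    filters: FilterParams = field(default_factory=FilterParams)
    qc: QCParams = field(default_factory=QCParams)
    engine: EngineParams = field(default_factory=EngineParams)
    stage2_engine: EngineParams = field(
        default_factory=lambda: EngineParams(grid=(10, 10)))
    network: NetworkParams = field(default_factory=NetworkParams)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return _to_plain(dataclasses.asdict(self))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        for name, sub_cls in (("tr", TRParams), ("filters", FilterParams),
                              ("qc", QCParams), ("engine", EngineParams),
                              ("stage2_engine", EngineParams),
                              ("network", NetworkParams)):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = _build_dataclass(sub_cls, kwargs[name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _build_dataclass(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def _load_inputs(config: PipelineConfig) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    if config.protein_fasta:
        records.extend(read_fasta(config.protein_fasta))
    if config.nucleotide_fasta:
        nt_records = read_fasta(config.nucleotide_fasta,
                                alphabet=NT_ALPHABET_SET)
        for nt in nt_records:
            frames = translate_forward_frames(nt.sequence)
            best = None
            for fr, aa in enumerate(frames, start=1):
                orf = extract_orf(aa, parent_id=nt.id)
                if orf is None:
                    continue
                key = (orf.has_stop, len(orf.sequence), -fr)
                if best is None or key > best[0]:
                    best = (key, fr, orf)
            if best is None:
                logger.info("no ORF for EST %s", nt.id)
                continue
            _, fr, orf = best
            records.append(SequenceRecord(
                id=nt.id, sequence=orf.sequence,
                source_tier=nt.source_tier, frame=fr))
    if not records:
        raise PipelineError("input", "no input sequences: provide "
                            "protein_fasta and/or nucleotide_fasta")
    return records


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written
    to ``manifest.json`` in the output directory)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    records = _load_inputs(config)
    counts["input_sequences"] = len(records)

    annotations = {}
    if config.annotation_tsv:
        ann_path = Path(config.annotation_tsv)
        if not ann_path.exists():
            raise PipelineError(
                "filter", f"annotation file not found: {ann_path}")
        annotations = load_annotations(ann_path)
    elif config.require_secretion:
        raise PipelineError(
            "filter", "secretion filtering requires annotation_tsv "
            "(set require_secretion: false to skip)")

    species_by_id: dict[str, str] = {
        r.id: r.species for r in records if r.species}
    if config.species_tsv:
        sp = load_species_table(config.species_tsv)
        species_by_id.update(dict(zip(sp["id"], sp["species"])))

    # detection
    try:
        all_domains = []
        lengths = {r.id: len(r) for r in records}
        for r in records:
            all_domains.extend(detect_repeats(r, config.tr))
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("detect", str(exc)) from exc
    counts["tr_domains"] = len(all_domains)
    domains_to_table(all_domains).to_csv(
        outdir / "tr_domains.tsv", sep="\t", index=False)

    # filter cascade
    fp = config.filters
    stage_counts = {"detected": len(all_domains)}
    pro = [d for d in all_domains if is_pro_rich(d, fp)]
    stage_counts["pro_rich"] = len(pro)
    modules = [d for d in pro
               if is_tr_module(d.length, lengths[d.parent_id], fp)]
    stage_counts["tr_module"] = len(modules)
    if config.require_secretion:
        secreted = [d for d in modules
                    if passes_secretion(annotations.get(d.parent_id), fp)]
    else:
        secreted = list(modules)
    stage_counts["secreted"] = len(secreted)
    gpi_ids = sorted({d.parent_id for d in secreted
                      if is_gpi_anchored(annotations.get(d.parent_id), fp)})
    clusterable = [d for d in secreted if is_clusterable(d, fp)]
    stage_counts["clusterable"] = len(clusterable)
    parents_by_motif: dict[str, set[str]] = {}
    for d in clusterable:
        parents_by_motif.setdefault(
            canonical_rotation(d.consensus), set()).add(d.parent_id)
    unique = dedup_canonical(clusterable)
    stage_counts["unique_motifs"] = len(unique)
    filter_report(stage_counts).to_csv(
        outdir / "filter_report.tsv", sep="\t", index=False)
    counts.update({f"filter_{k}": v for k, v in stage_counts.items()})
    counts["gpi_anchored_proteins"] = len(gpi_ids)

    # clustering
    engine = dataclasses.replace(config.engine, seed=config.seed)
    stage2 = dataclasses.replace(config.stage2_engine, seed=config.seed)
    clusters, singletons = autosome_tr_cluster(
        unique, qc=config.qc, engine=engine, stage2_engine=stage2)
    counts["clusters"] = len(clusters)
    counts["clustered_motifs"] = sum(c.size for c in clusters)
    counts["singleton_motifs"] = len(singletons)
    clusters_to_table(clusters).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame({"singleton_consensus":
                  [unique[i].consensus for i in singletons]}).to_csv(
        outdir / "singletons.tsv", sep="\t", index=False)

    # taxonomy
    class_defs = load_class_definitions(config.class_definitions)
    assignments = assign_classes(unique, class_defs)
    assignments.to_csv(outdir / "class_assignments.tsv", sep="\t",
                       index=False)
    counts["classified_motifs"] = int(
        assignments.loc[assignments.matched, "index"].nunique())
    hist, fractions = periodicity_histogram(unique, gap_free=True)
    hist.rename("count").to_frame().to_csv(
        outdir / "periodicity.tsv", sep="\t")
    counts.update({f"period_fraction_{k}": round(v, 4)
                   for k, v in fractions.items()})

    # network
    net_params = dataclasses.replace(config.network, seed=config.seed)
    eligible = [c for c in clusters
                if c.size >= net_params.min_cluster_members]
    if len(eligible) >= 2:
        g = build_network(clusters, net_params)
        annotate_nodes(g, clusters, species_by_id=species_by_id,
                       class_defs=class_defs,
                       parents_by_motif=parents_by_motif)
        write_graphml(g, outdir / "network.graphml")
        write_sif(g, outdir / "network.sif")
        node_table(g).to_csv(outdir / "network_nodes.tsv", sep="\t",
                             index=False)
        counts["network_nodes"] = g.number_of_nodes()
        counts["network_edges"] = g.number_of_edges()
        counts["network_removed_edges"] = g.graph["n_removed_edges"]
        counts["network_removed_nodes"] = g.graph["n_removed_nodes"]
    else:
        logger.info("fewer than two eligible clusters: network skipped")
        counts["network_nodes"] = 0
        counts["network_edges"] = 0

    manifest = {
        "protrp_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "config.yaml", "w") as fh:
        fh.write(config.to_yaml())
    return manifest
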