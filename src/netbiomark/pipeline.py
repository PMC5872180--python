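"""End-to-end orchestration: network build → centrality → per-dataset DE →
concordance → landscapes, from a single YAML config, with a provenance
manifest (parameter values, input paths, output hashes, seeds) so a rerun with
the same config and seeds reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .concordance import (
    aggregate_calls,
    concordance_frame,
    nominate_biomarkers,
    write_nominations_json,
)
from .diffexpr import run_de
from .interactome import (
    augment_with_connectors,
    filter_interactions,
    induced_subgraph,
    write_connectors_json,
    write_edge_list,
    write_graphml,
)
from .io import read_expression_dataset, read_interactions, read_seeds, write_de_table
from .landscape import compute_layout, gaussian_landscape, render_landscape, write_grid_tsv
from .topology import centrality_table, write_centrality_tsv, write_summary_json

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class DatasetSpec:
    dataset_id: str
    matrix: Path
    groups: Path


@dataclass
class PipelineConfig:
    """Validated inputs and parameters for one pipeline run.

    Defaults mirror the reference analysis: evidence channels
    {experimental, database}, minimum combined confidence 0.400, FDR alpha
    0.05, replication in >= 2 datasets, landscape kernel sigma 0.04.
    """

    interactions: Path
    seeds: list[Path]
    datasets: list[DatasetSpec]
    out_dir: Path
    channels: tuple[str, ...] = ("experimental", "database")
    min_score: float = 0.400
    alpha: float = 0.05
    min_datasets: int = 2
    de_method: str = "moderated"
    sigma: float = 0.04
    resolution: int = 256
    layout_seed: int = 1
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def resolve(p) -> Path:
            p = Path(p)
            return p if p.is_absolute() else base / p

        datasets = [
            DatasetSpec(
                dataset_id=d["id"],
                matrix=resolve(d["matrix"]),
                groups=resolve(d["groups"]),
            )
            for d in raw["datasets"]
        ]
        return cls(
            interactions=resolve(raw["interactions"]),
            seeds=[resolve(p) for p in raw["seeds"]],
            datasets=datasets,
            out_dir=resolve(raw["out_dir"]),
            channels=tuple(raw.get("channels", ("experimental", "database"))),
            min_score=float(raw.get("min_score", 0.400)),
            alpha=float(raw.get("alpha", 0.05)),
            min_datasets=int(raw.get("min_datasets", 2)),
            de_method=raw.get("de_method", "moderated"),
            sigma=float(raw.get("sigma", 0.04)),
            resolution=int(raw.get("resolution", 256)),
            layout_seed=int(raw.get("layout_seed", 1)),
        )

    def validate(self) -> None:
        missing = [
            str(p)
            for p in [self.interactions, *self.seeds]
            + [d.matrix for d in self.datasets]
            + [d.groups for d in self.datasets]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 <= self.min_score <= 1:
            raise ValueError(f"min_score must be in [0, 1], got {self.min_score}")
        if self.min_datasets < 1 or self.min_datasets > len(self.datasets):
            raise ValueError(
                f"min_datasets must be in [1, {len(self.datasets)}], "
                f"got {self.min_datasets}"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the provenance manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "build-network"
        interactions = read_interactions(config.interactions)
        filtered = filter_interactions(interactions, config.channels, config.min_score)
        seed_sets = [read_seeds(p) for p in config.seeds]
        seed_graph = induced_subgraph(filtered, seed_sets, channels=config.channels)
        result = augment_with_connectors(filtered, seed_graph, channels=config.channels)
        graph = result.graph
        write_edge_list(graph, out / "network_edges.tsv")
        write_graphml(graph, out / "network.graphml")
        write_connectors_json(result, out / "connectors.json")
        outputs["network_edges"] = out / "network_edges.tsv"
        outputs["network_graphml"] = out / "network.graphml"
        outputs["connectors"] = out / "connectors.json"

        stage = "centrality"
        records, summaries = centrality_table(graph)
        write_centrality_tsv(records, out / "centrality.tsv")
        write_summary_json(summaries, out / "centrality_summary.json")
        outputs["centrality"] = out / "centrality.tsv"
        outputs["centrality_summary"] = out / "centrality_summary.json"

        stage = "differential-expression"
        de_tables = {}
        for spec in config.datasets:
            dataset = read_expression_dataset(spec.matrix, spec.groups, spec.dataset_id)
            table = run_de(dataset, alpha=config.alpha, method=config.de_method)
            de_tables[spec.dataset_id] = table
            path = out / f"de_{spec.dataset_id}.tsv"
            write_de_table(table, path)
            outputs[f"de_{spec.dataset_id}"] = path

        stage = "concordance"
        records_conc = aggregate_calls(de_tables, alpha=config.alpha)
        concordance_frame(records_conc).to_csv(
            out / "concordance.tsv", sep="\t", float_format="%.10g"
        )
        nominations = nominate_biomarkers(
            records_conc, records, min_datasets=config.min_datasets
        )
        write_nominations_json(nominations, out / "nominations.json")
        outputs["concordance"] = out / "concordance.tsv"
        outputs["nominations"] = out / "nominations.json"

        stage = "landscape"
        layout = compute_layout(graph, seed=config.layout_seed)
        for spec in config.datasets:
            values = de_tables[spec.dataset_id]["log_fc"]
            values = {n: float(values[n]) for n in graph.nodes if n in values.index}
            grid = gaussian_landscape(
                layout, values, sigma=config.sigma, resolution=config.resolution
            )
            grid_path = out / f"landscape_{spec.dataset_id}.tsv"
            png_path = out / f"landscape_{spec.dataset_id}.png"
            write_grid_tsv(grid, grid_path)
            render_landscape(grid, png_path, layout=layout, title=spec.dataset_id)
            outputs[f"landscape_grid_{spec.dataset_id}"] = grid_path
            outputs[f"landscape_png_{spec.dataset_id}"] = png_path
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("pipeline stage %r failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc

    manifest = {
        "tool": "netbiomark",
        "version": __version__,
        "parameters": {
            "channels": list(config.channels),
            "min_score": config.min_score,
            "alpha": config.alpha,
            "min_datasets": config.min_datasets,
            "de_method": config.de_method,
            "sigma": config.sigma,
            "resolution": config.resolution,
            "layout_seed": config.layout_seed,
        },
        "inputs": {
            "interactions": str(config.interactions),
            "seeds": [str(p) for p in config.seeds],
            "datasets": {
                d.dataset_id: {"matrix": str(d.matrix), "groups": str(d.groups)}
                for d in config.datasets
            },
        },
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
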