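"""End-to-end orchestration: mine -> network -> ECs -> PADs (-> artifacts).

:func:`analyze` is the in-memory pipeline used by the stability protocol,
the examples and the CLI; :func:`run_pipeline` adds file IO around it and
writes a run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from . import io as pio
from .equivalence import EquivalenceClass, compute_dec, compute_gec, compute_sec, build_ec_network
from .mining import SupportIndex, mine
from .model import Dataset
from .network import PharmNetwork, build_network
from .quality import PertinenceRecord, network_quality, select_pads

__all__ = ["PipelineConfig", "AnalysisResult", "analyze", "run_pipeline"]

_NETWORK_LEVELS = ("pharmacophore", "sec")


@dataclass
class PipelineConfig:
    """Configuration for one full run; flags mirror these fields 1:1."""

    input: str | None = None
    input_format: str = "feature-json"  # "feature-json" | "smiles-tsv"
    activity_cutoff: float = 100.0
    min_support: int = 10
    max_order: int = 7
    delta: float = 1.64
    network_level: str = "sec"
    knn_k: int = 2
    folds: int = 10
    seed: int = 0
    output_dir: str = "padmine_out"

    def __post_init__(self) -> None:
        for name in ("activity_cutoff", "min_support", "max_order", "delta", "knn_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.network_level not in _NETWORK_LEVELS:
            raise ValueError(f"network_level must be one of {_NETWORK_LEVELS}")
        if self.input_format not in ("feature-json", "smiles-tsv"):
            raise ValueError(f"unknown input format {self.input_format!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class AnalysisResult:
    """In-memory outputs of one pipeline run."""

    index: SupportIndex
    network: PharmNetwork
    gecs: list[EquivalenceClass]
    decs: list[EquivalenceClass]
    secs: list[EquivalenceClass]
    sec_network: PharmNetwork
    scored_network: PharmNetwork  # the network PADs were selected on
    quality: dict[str, float]  # GR_N per scored vertex
    records: list[PertinenceRecord]

    @property
    def pads(self) -> list[PertinenceRecord]:
        return [r for r in self.records if r.is_pad]

    @property
    def counts(self) -> dict[str, int]:
        pos = sum(1 for r in self.pads if (r.pertinence or 0) > 0)
        return {
            "n_molecules": len(self.index.dataset) if self.index.dataset else 0,
            "n_pharmacophores": len(self.index),
            "n_gecs": len(self.gecs),
            "n_decs": len(self.decs),
            "n_secs": len(self.secs),
            "n_pads": len(self.pads),
            "n_pads_pos": pos,
            "n_pads_neg": len(self.pads) - pos,
        }


def analyze(
    dataset: Dataset,
    min_support: int = 10,
    max_order: int = 7,
    delta: float = 1.64,
    network_level: str = "sec",
) -> AnalysisResult:
    """Run mine -> Hasse network -> GEC/DEC/SEC -> GR_N -> PAD selection.

    ``network_level`` chooses where pertinence is evaluated: on the raw
    pharmacophore network, or (default) on the condensed SEC network,
    where an EC's quality is the GR_N of its shared support.
    """
    index = mine(dataset, min_support=min_support, max_order=max_order)
    if len(index) == 0:
        raise ValueError(
            f"no pharmacophore reaches min_support={min_support}; nothing to analyze"
        )
    net = build_network(index)
    gecs = compute_gec(net)
    decs = compute_dec(net)
    secs = compute_sec(net)
    sec_net = build_ec_network(secs, net)
    scored = sec_net if network_level == "sec" else net
    qual = {v: q.gr_n for v, q in network_quality(scored, dataset).items()}
    records = select_pads(scored, qual, delta=delta)
    return AnalysisResult(index, net, gecs, decs, secs, sec_net, scored, qual, records)


def run_pipeline(config: PipelineConfig, dataset: Dataset | None = None) -> dict:
    """Execute the full pipeline and write artifacts under the output
    directory; returns (and writes) the run manifest.

    Artifacts: pharmacophores.tsv, network.graphml, ecs.tsv, pads.tsv,
    pad_network.graphml (when a similarity matrix can be built from
    supports is *not* attempted here — PAD-network export needs an
    explicit molecule similarity matrix, see :mod:`padmine.padnet`),
    stability.tsv, manifest.json.  On a stage failure, partial outputs
    are removed and the error names the stage.
    """
    from .stability import run_stability  # local import to avoid a cycle

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load"
    try:
        if dataset is None:
            if config.input is None:
                raise ValueError("no input path and no in-memory dataset given")
            if config.input_format == "feature-json":
                dataset = pio.load_feature_graph_json(config.input, config.activity_cutoff)
            else:
                dataset = pio.read_smiles_tsv(config.input, config.activity_cutoff)
        if config.min_support > len(dataset):
            raise ValueError(
                f"min_support={config.min_support} exceeds dataset size {len(dataset)}"
            )

        stage = "analyze"
        res = analyze(
            dataset,
            min_support=config.min_support,
            max_order=config.max_order,
            delta=config.delta,
            network_level=config.network_level,
        )

        stage = "write"
        p = outdir / "pharmacophores.tsv"
        pio.write_pharmacophores_tsv(res.index, p)
        written.append(p)
        p = outdir / "network.graphml"
        res.network.write_graphml(p)
        written.append(p)
        p = outdir / "ecs.tsv"
        pio.write_ec_tsv(res.secs, p)
        written.append(p)
        p = outdir / "pads.tsv"
        pio.write_pad_tsv(res.records, res.scored_network, p)
        written.append(p)

        stage = "stability"
        report = run_stability(
            dataset,
            params=dict(
                min_support=config.min_support,
                max_order=config.max_order,
                delta=config.delta,
                network_level=config.network_level,
            ),
            k=config.folds,
            seed=config.seed,
        )
        p = outdir / "stability.tsv"
        pio.write_stability_tsv(report, p)
        written.append(p)

        stage = "manifest"
        manifest = {
            "config": dataclasses.asdict(config),
            "counts": res.counts,
            "stability": {
                "n_folds": report.n_folds,
                "per_fold": report.per_fold,
            },
        }
        p = outdir / "manifest.json"
        with open(p, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(p)
        return manifest
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
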