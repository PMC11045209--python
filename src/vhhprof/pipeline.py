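"""End-to-end orchestration: generate/parse, then the selected analyses.

Every exported CSV carries a provenance comment header (tool version, config
hash, seed) so a run is reproducible from its outputs.  Stages execute in
dependency order; a stage failure aborts the run with the stage named,
leaving a ``FAILED`` marker next to any partial outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .bridges import profile_dataset
from .boruta_select import boruta
from .dataset import SequenceDataset
from .io import parse_numbered_table, write_numbered_table
from .metrics import distribution_frame, species_summary
from .motifs import frequency_matrix
from .physchem import build_feature_table, residue_class_difference
from .stats import run_selection_pipeline
from .synthetic import GeneratorConfig, config_to_dict, generate

ALL_STAGES = ("lengths", "motifs", "bridges", "features", "model", "boruta")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """One reproduction run: an input (file or generator) plus stage choices."""

    out_dir: str | Path
    input_path: str | Path | None = None
    generator: GeneratorConfig | None = None
    n_per_class: dict[str, int] | None = None
    analyses: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    mode: str = "collective"
    vif_threshold: float = 10.0
    alpha: float = 0.05
    boruta_iterations: int = 50
    boruta_forest: int = 200
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = {
            "input_path": str(self.input_path) if self.input_path else None,
            "generator": config_to_dict(self.generator) if self.generator else None,
            "n_per_class": self.n_per_class,
            "analyses": list(self.analyses),
            "seed": self.seed,
            "mode": self.mode,
            "vif_threshold": self.vif_threshold,
            "alpha": self.alpha,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(cfg: RunConfig) -> list[str]:
    return [
        f"vhhprof {__version__}",
        f"seed={cfg.seed}",
        f"config_hash={cfg.config_hash()}",
    ]


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in _provenance(cfg):
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=index)


def _load_input(cfg: RunConfig) -> SequenceDataset:
    if cfg.input_path is not None:
        path = Path(cfg.input_path)
        if not path.exists():
            raise PipelineError(f"input path does not exist: {path}")
        return parse_numbered_table(path)
    if cfg.generator is not None:
        return generate(cfg.generator, cfg.n_per_class, seed=cfg.seed)
    raise PipelineError("config needs either input_path or a generator block")


def run_all(cfg: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; returns the map of written outputs."""
    unknown = set(cfg.analyses) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown analyses: {sorted(unknown)}")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    stage = "input"
    try:
        ds = _load_input(cfg)
        if cfg.generator is not None:
            path = out_dir / "dataset.tsv"
            write_numbered_table(ds, path, provenance_comments=_provenance(cfg))
            outputs["dataset"] = path

        if "lengths" in cfg.analyses:
            stage = "lengths"
            summary = species_summary(ds)
            _write_csv(summary.table, out_dir / "lengths_summary.csv", cfg)
            _write_csv(distribution_frame(ds), out_dir / "lengths_histogram.csv", cfg)
            outputs["lengths"] = out_dir / "lengths_summary.csv"

        if "motifs" in cfg.analyses:
            stage = "motifs"
            for domain_class in ds.classes():
                lm = frequency_matrix(ds, class_filter=domain_class)
                path = out_dir / f"logo_{domain_class}.csv"
                _write_csv(lm.to_frame(), path, cfg)
                outputs[f"motifs_{domain_class}"] = path

        if "bridges" in cfg.analyses:
            stage = "bridges"
            table = profile_dataset(ds)
            _write_csv(table.disulfide.reset_index(), out_dir / "disulfide_counts.csv", cfg)
            _write_csv(table.salt.reset_index(), out_dir / "salt_bridge_counts.csv", cfg)
            _write_csv(table.per_sequence, out_dir / "bridges_per_sequence.csv", cfg)
            outputs["bridges"] = out_dir / "salt_bridge_counts.csv"

        features = None
        if {"features", "model", "boruta"} & set(cfg.analyses):
            stage = "features"
            features = build_feature_table(ds)
            if "features" in cfg.analyses:
                _write_csv(features.reset_index(), out_dir / "features.csv", cfg)
                if len(ds.classes()) == 2:
                    diff = residue_class_difference(ds)
                    _write_csv(diff, out_dir / "residue_class_difference.csv", cfg)
                outputs["features"] = out_dir / "features.csv"

        model_table = None
        if features is not None and {"model", "boruta"} & set(cfg.analyses):
            model_table = features.drop(columns=["species"])

        if "model" in cfg.analyses:
            stage = "model"
            report = run_selection_pipeline(
                model_table, mode=cfg.mode,
                vif_threshold=cfg.vif_threshold, alpha=cfg.alpha,
            )
            for name, frame in report.summaries().items():
                path = out_dir / f"model_{name}.csv"
                _write_csv(frame.reset_index(names="term"), path, cfg)
                outputs[f"model_{name}"] = path
                metrics = {
                    "McFadden R2": frame.attrs["McFadden R2"],
                    "AUC": frame.attrs["AUC"],
                    "AIC": frame.attrs["AIC"],
                }
                (out_dir / f"model_{name}.json").write_text(
                    json.dumps(metrics, indent=2)
                )

        if "boruta" in cfg.analyses:
            stage = "boruta"
            result = boruta(
                model_table,
                n_iterations=cfg.boruta_iterations,
                forest_size=cfg.boruta_forest,
                alpha=cfg.alpha,
                seed=cfg.seed,
            )
            _write_csv(result.to_frame().reset_index(), out_dir / "boruta_decisions.csv", cfg)
            _write_csv(result.z_history, out_dir / "boruta_z_history.csv", cfg)
            _write_csv(result.shadow_stats, out_dir / "boruta_shadow_stats.csv", cfg)
            outputs["boruta"] = out_dir / "boruta_decisions.csv"
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return outputs
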