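"""End-to-end pipeline orchestration: simulate -> tabulate -> train -> score.

Every artifact written by the pipeline carries a provenance header (package
version, configuration hash, input checksums) so a report can be traced back
to the exact run that produced it. No stage mutates its inputs; reruns with
the same configuration produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .errors import ConfigError, PanelMismatchError
from .msi_scorer import (
    THRESHOLD_CONSERVATIVE,
    THRESHOLD_LENIENT,
    fit_control_model,
    read_control_model,
    score_sample,
    write_control_model,
    write_score_report,
)
from .panel_io import (
    load_panel,
    panel_hash,
    read_counts_table,
    read_table_metadata,
    write_counts_table,
    write_panel,
)
from .read_processor import (
    DEFAULT_MIN_CONSENSUS_FRACTION,
    DEFAULT_MIN_FAMILY_SIZE,
    DEFAULT_MIN_MARKER_FAMILIES,
    process_fastq,
)
from .reporting import write_report
from .msi_scorer import read_score_report
from .synthetic_data import (
    SimulationConfig,
    simulate_fastq,
    simulate_frequency_cohort,
    synthetic_panel,
)

__all__ = ["RunConfig", "run_pipeline", "provenance", "check_panel_compatibility"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a full synthetic-cohort pipeline run."""

    seed: int
    out_dir: str | Path
    n_train_controls: int = 40
    n_eval_controls: int = 3
    n_cmmrd: int = 1
    n_markers: int = 24
    use_fastq: bool = False
    fit_method: str = "moments"
    threshold_lenient: float = THRESHOLD_LENIENT
    threshold_conservative: float = THRESHOLD_CONSERVATIVE
    min_family_size: int = DEFAULT_MIN_FAMILY_SIZE
    min_consensus_fraction: float = DEFAULT_MIN_CONSENSUS_FRACTION
    min_marker_families: int = DEFAULT_MIN_MARKER_FAMILIES
    mean_depth: float = 3642.0
    depth_sd: float = 1659.0
    report_format: str = "markdown"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def provenance(config: object, inputs: dict[str, Path] | None = None) -> dict:
    """Provenance block embedded in every artifact header."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        # hash what was computed, not where it was written
        payload = {
            k: str(v) for k, v in dataclasses.asdict(config).items() if k != "out_dir"
        }
    else:
        payload = {"config": str(config)}
    blob = json.dumps(payload, sort_keys=True)
    meta = {
        "tool": f"msiscope {__version__}",
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
    }
    if inputs:
        meta["inputs"] = {name: _sha256(Path(p)) for name, p in inputs.items()}
    return meta


def check_panel_compatibility(model_meta: dict | str | None, counts_meta: dict | str | None) -> None:
    """Raise :class:`PanelMismatchError` when model and counts carry different panel hashes.

    Accepts metadata dicts or bare hash strings; silently passes when either
    side carries no panel annotation (externally produced tables).
    """
    def _hash(meta):
        if meta is None:
            return None
        if isinstance(meta, str):
            return meta
        return meta.get("panel_hash")

    h_model, h_counts = _hash(model_meta), _hash(counts_meta)
    if h_model and h_counts and h_model != h_counts:
        raise PanelMismatchError(
            f"control model panel ({h_model}) differs from counts panel ({h_counts}); "
            "the model must be trained on the same marker panel it scores"
        )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run simulate -> tabulate -> train -> score -> report on synthetic cohorts.

    The training cohort is simulated at the counts level; evaluation samples
    go through FASTQ and the full read processor when ``use_fastq`` is set.
    Returns the paths of all artifacts written.
    """
    if config.n_train_controls < 2:
        raise ConfigError("need at least 2 training controls")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim = SimulationConfig(
        seed=config.seed,
        n_markers=config.n_markers,
        mean_depth=config.mean_depth,
        depth_sd=config.depth_sd,
    )
    panel = synthetic_panel(config.n_markers, config.seed)
    phash = panel_hash(panel)
    paths = {
        "panel_bed": out / "panel.bed",
        "panel_meta": out / "panel.tsv",
        "train_counts": out / "controls_train.tsv",
        "eval_counts": out / "samples.tsv",
        "model": out / "model.tsv",
        "report": out / "report.tsv",
        "report_markers": out / "report_per_marker.tsv",
        "report_rendered": out / f"report.{'md' if config.report_format == 'markdown' else config.report_format}",
    }
    write_panel(panel, paths["panel_bed"], paths["panel_meta"])
    base_meta = provenance(config) | {"panel_hash": phash, "seed": config.seed}

    # training cohort (counts level)
    train, _ = simulate_frequency_cohort(
        sim, "control", config.n_train_controls, panel=panel, stream=10,
        min_marker_families=config.min_marker_families,
    )
    write_counts_table(train, paths["train_counts"], metadata=base_meta)

    # evaluation cohorts
    eval_samples: dict[str, list] = {}
    for group, n, stream in (("control", config.n_eval_controls, 20), ("cmmrd", config.n_cmmrd, 30)):
        if n == 0:
            continue
        counts, truth = simulate_frequency_cohort(
            sim, group, n, panel=panel, stream=stream,
            min_marker_families=config.min_marker_families,
        )
        if config.use_fastq:
            for i, sample_id in enumerate(truth.index):
                fq = out / f"{sample_id}.fastq.gz"
                simulate_fastq(sim, truth.loc[sample_id], panel, fq, stream=stream + 1 + i)
                mc, _qc = process_fastq(
                    fq,
                    panel,
                    min_family_size=config.min_family_size,
                    min_consensus_fraction=config.min_consensus_fraction,
                    min_marker_families=config.min_marker_families,
                )
                eval_samples[str(sample_id)] = mc
        else:
            eval_samples.update(counts)
    write_counts_table(eval_samples, paths["eval_counts"], metadata=base_meta)

    # train
    model = fit_control_model(
        read_counts_table(paths["train_counts"]),
        fit_method=config.fit_method,
        panel_hash=read_table_metadata(paths["train_counts"]).get("panel_hash"),
    )
    write_control_model(
        model, paths["model"], metadata=provenance(config, {"counts": paths["train_counts"]})
    )

    # score
    model = read_control_model(paths["model"])
    counts_meta = read_table_metadata(paths["eval_counts"])
    check_panel_compatibility(model.panel_hash, counts_meta)
    scores = [
        score_sample(
            model,
            mcs,
            sample_id=sid,
            threshold_lenient=config.threshold_lenient,
            threshold_conservative=config.threshold_conservative,
        )
        for sid, mcs in sorted(read_counts_table(paths["eval_counts"]).items())
    ]
    write_score_report(
        scores,
        paths["report"],
        per_marker_path=paths["report_markers"],
        metadata=provenance(config, {"model": paths["model"], "counts": paths["eval_counts"]}),
    )
    write_report(
        read_score_report(paths["report"]), paths["report_rendered"],
        config.report_format, panel_size=config.n_markers,
    )
    return paths
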