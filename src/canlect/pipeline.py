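"""End-to-end orchestration: features -> ranking -> selection -> SVM -> report.

A pipeline run reads two FASTA files, encodes tripeptide compositions,
ranks tripeptides by binomial confidence level, picks a feature subset
(by CL threshold, incremental feature selection, or an explicit list),
optionally tunes (c, g), trains the final RBF-SVM, evaluates it
(jackknife by default) and writes every artifact plus a machine-readable
manifest into the output directory.  Identical config + inputs + seed
produce identical artifacts (timestamps appear only in the log).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .evaluation import EvalReport, jackknife, kfold_cv
from .features import FeatureMatrix, build_matrix
from .io import LabeledDataset, load_labeled
from .selection import (
    confidence_levels,
    filter_by_cl,
    incremental_feature_selection,
    tabulate_counts,
)
from .svm import SvmConfig, grid_search, save_model, train_svm


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    positive_fasta: str = ""
    negative_fasta: str = ""
    policy: str = "strict"
    selection_mode: str = "threshold"        # threshold | ifs | explicit
    cl_threshold: float = 0.99
    explicit_features: list[str] = field(default_factory=list)
    ifs_folds: int = 7
    ifs_group_ties: bool = True
    ifs_max_size: int | None = None
    ifs_chosen_size: int | None = None       # None -> argmax of the curve
    tune: bool = False
    svm_c: float = 2.0 ** 11
    svm_g: float = 2.0 ** -13
    eval_protocol: str = "jackknife"         # jackknife | kfold
    eval_folds: int = 7
    seed: int = 0
    output_dir: str = "canlect_run"

    def __post_init__(self) -> None:
        if self.selection_mode not in ("threshold", "ifs", "explicit"):
            raise ValueError(f"unknown selection mode {self.selection_mode!r}")
        if self.eval_protocol not in ("jackknife", "kfold"):
            raise ValueError(f"unknown evaluation protocol {self.eval_protocol!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _file_fingerprint(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def version_and_provenance(config: PipelineConfig) -> str:
    """Human-readable provenance block embedded in every run manifest."""
    lines = [
        f"canlect version\t{__version__}",
        f"config hash\t{config.config_hash()}",
        f"seed\t{config.seed}",
    ]
    for role, path in (
        ("positive input", config.positive_fasta),
        ("negative input", config.negative_fasta),
    ):
        if path and Path(path).exists():
            lines.append(f"{role}\t{path}\t{_file_fingerprint(path)}")
    return "\n".join(lines) + "\n"


def run_pipeline(
    config: PipelineConfig, dataset: LabeledDataset | None = None
) -> Path:
    """Execute all stages; returns the run directory.

    On a stage failure the partial outputs are retained alongside a
    ``FAILED`` marker naming the stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    stage = "load"
    try:
        if dataset is None:
            dataset = load_labeled(
                config.positive_fasta, config.negative_fasta, config.policy
            )
        log(f"loaded {len(dataset)} sequences "
            f"({int(dataset.labels.sum())} positive, "
            f"{int((1 - dataset.labels).sum())} negative)")

        stage = "features"
        matrix = build_matrix(dataset, config.policy)
        matrix.save_tsv(outdir / "features.tsv", labels=dataset.labels)
        log(f"feature matrix: {matrix.shape[0]} x {matrix.shape[1]}")

        stage = "rank"
        table = tabulate_counts(dataset, config.policy)
        ranking = confidence_levels(table)
        ranking.save_tsv(outdir / "ranking.tsv")
        log(f"ranked {len(ranking.order)} observed tripeptides")

        stage = "select"
        if config.selection_mode == "threshold":
            selected = filter_by_cl(ranking, config.cl_threshold)
            log(f"threshold {config.cl_threshold}: {len(selected)} features")
        elif config.selection_mode == "explicit":
            selected = list(config.explicit_features)
            log(f"explicit list: {len(selected)} features")
        else:  # ifs
            ifs = incremental_feature_selection(
                dataset,
                ranking,
                folds=config.ifs_folds,
                svm_params=(config.svm_c, config.svm_g),
                group_ties=config.ifs_group_ties,
                seed=config.seed,
                policy=config.policy,
                matrix=matrix,
                max_size=config.ifs_max_size,
            )
            ifs.save_tsv(outdir / "ifs_curve.tsv")
            selected = ifs.chosen_features(config.ifs_chosen_size)
            log(f"IFS argmax size {ifs.argmax_size}; chose {len(selected)} features")
        if not selected:
            raise PipelineError("selection produced an empty feature subset")
        (outdir / "selected_features.txt").write_text("\n".join(selected) + "\n")

        stage = "tune"
        svm_config = SvmConfig(c=config.svm_c, g=config.svm_g, seed=config.seed,
                               cv_folds=config.eval_folds)
        sub = matrix.select(selected)
        if config.tune:
            (best_c, best_g), tune_table = grid_search(sub, dataset.labels, svm_config)
            svm_config.c, svm_config.g = best_c, best_g
            tune_table.to_csv(outdir / "tuning.tsv", sep="\t", index=False,
                              float_format="%.12g")
            log(f"grid search best: c={best_c}, g={best_g}")

        stage = "train"
        model = train_svm(sub, dataset.labels, svm_config)
        save_model(model, outdir / "model.joblib")
        log(f"trained final SVM (c={svm_config.c}, g={svm_config.g})")

        stage = "evaluate"
        if config.eval_protocol == "jackknife":
            report: EvalReport = jackknife(dataset, selected, svm_config,
                                           config.policy, matrix)
        else:
            report = kfold_cv(dataset, selected, svm_config, k=config.eval_folds,
                              seed=config.seed, policy=config.policy, matrix=matrix)
        report.save(outdir / "evaluation.txt")
        report.save_roc_tsv(outdir / "roc.tsv")
        log(f"{report.protocol}: Acc={report.acc:.4f} Sn={report.sn:.4f} "
            f"Sp={report.sp:.4f} AUC={report.auc:.4f}")

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "n_sequences": len(dataset),
            "n_selected_features": len(selected),
            "metrics": {"acc": report.acc, "sn": report.sn,
                        "sp": report.sp, "auc": report.auc},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        (outdir / "provenance.txt").write_text(version_and_provenance(config))
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        (outdir / "run.log").write_text("\n".join(log_lines) + f"\nFAILED at {stage}: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return outdir
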