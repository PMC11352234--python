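"""End-to-end orchestration: simulate -> preprocess -> describe -> train -> score.

A :class:`PipelineConfig` (optionally loaded from YAML, unknown keys
rejected) drives the two-stage design: first the triplet encoder is
trained on all but the held-out subjects' epochs, then the held-out
subjects' resting epochs are used as queries against the training
database to produce per-pair similarities and the QB_DAT report.  Every
stage seeds its randomness from the master seed through a documented
fan-out, so rerunning a config reproduces byte-identical outputs; a
manifest records the config hash and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarker import cohort_report, permutation_pvalue, score_pairs
from .eeg_io import write_recording
from .model import SiameseModel, TrainConfig
from .preprocess import bandpass, epoch_signal, notch, reject_artifacts
from .selfaffine import crossover_summary, detect_crossover, saa_curve
from .spectral import band_powers, welch_psd
from .synthetic import CohortSpec, generate_cohort

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "make_fixtures",
           "stage_seed"]

log = logging.getLogger("datbio")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (int(master_seed) * 100003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    n_subjects: int = 4
    durations_s: tuple[float, float, float] = (60.0, 300.0, 60.0)
    fs: float = 512.0
    # preprocessing
    filter_low: float = 0.5
    filter_high: float = 60.0
    notch_freq: float = 60.0
    window_s: float = 4.0
    overlap: float = 0.0
    reject_uv: float = 100.0
    # spectral / self-affine summaries
    segment_s: float = 2.0
    spectral_overlap: float = 0.5
    saa_scales: int = 32
    saa_mode: str = "first_crossing"
    # training / scoring
    mode: str = "triplet"
    train: TrainConfig = field(default_factory=TrainConfig)
    holdout_subjects: int = 1
    permutations: int = 1000

    def __post_init__(self) -> None:
        if self.holdout_subjects >= self.n_subjects:
            raise ValueError("holdout_subjects must leave at least one "
                             "training subject")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        train_raw = raw.pop("train", {})
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        train_known = {f.name for f in dataclasses.fields(TrainConfig)}
        bad = set(train_raw) - train_known
        if bad:
            raise ValueError(f"unknown train config keys: {sorted(bad)}")
        if "durations_s" in raw:
            raw["durations_s"] = tuple(raw["durations_s"])
        return cls(train=TrainConfig(**train_raw), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["durations_s"] = list(d["durations_s"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def _preprocess_cohort(recordings, config: PipelineConfig):
    epochs = []
    for rec in recordings:
        rec = rec.stabilized()
        rec = bandpass(rec, config.filter_low, config.filter_high)
        if config.notch_freq < rec.fs / 2.0:
            rec = notch(rec, config.notch_freq)
        eps = epoch_signal(rec, window_s=config.window_s, overlap=config.overlap)
        epochs.extend(reject_artifacts(eps, config.reject_uv))
    return epochs


def _describe(recordings, config: PipelineConfig, out: Path) -> None:
    """Write per-recording band powers and crossover summaries."""
    band_rows, saa_rows = [], []
    crossings: dict[tuple[str, str], int] = {}
    for rec in recordings:
        rec_f = bandpass(rec.stabilized(), config.filter_low, config.filter_high)
        bp = band_powers(welch_psd(rec_f, segment_s=config.segment_s,
                                   overlap=config.spectral_overlap))
        row = {"subject": rec.subject_id, "phase": rec.phase}
        row.update({f"rel_{k}": v for k, v in bp.relative.items()})
        band_rows.append(row)
        curve = saa_curve(rec_f.samples, n_scales=config.saa_scales)
        c, found = detect_crossover(curve, mode=config.saa_mode)
        crossings[(rec.subject_id, rec.phase)] = c
        saa_rows.append({"subject": rec.subject_id, "phase": rec.phase,
                         "crossover": c, "found": found,
                         "slope": curve.slope})
    pd.DataFrame(band_rows).to_csv(out / "band_powers.tsv", sep="\t", index=False)
    pd.DataFrame(saa_rows).to_csv(out / "saa.tsv", sep="\t", index=False)
    summary_rows = []
    for sid in sorted({s for s, _ in crossings}):
        cs = crossover_summary(crossings[(sid, "before")],
                               crossings[(sid, "during")],
                               crossings[(sid, "after")])
        summary_rows.append({"subject": sid, "C_B": cs.C_B, "C_D": cs.C_D,
                             "C_A": cs.C_A, "S_BA": cs.S_BA, "S_DR": cs.S_DR})
    pd.DataFrame(summary_rows).to_csv(out / "crossover_summary.tsv", sep="\t",
                                      index=False)


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the full pipeline; returns the artifact directory.

    On stage failure, partial outputs are moved under ``failed/`` and a
    :class:`StageError` naming the stage is raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        stage = "simulate"
        spec = CohortSpec(n_subjects=config.n_subjects,
                          durations_s=config.durations_s, fs=config.fs,
                          seed=stage_seed(config.seed, "simulate"))
        recordings = generate_cohort(spec)
        log.info("simulated %d recordings", len(recordings))

        stage = "describe"
        _describe(recordings, config, out)

        stage = "preprocess"
        epochs = _preprocess_cohort(recordings, config)
        if not epochs:
            raise ValueError("preprocessing produced no epochs")

        stage = "train"
        holdout_ids = {f"S{i + 1:02d}"
                       for i in range(config.n_subjects - config.holdout_subjects,
                                      config.n_subjects)}
        train_epochs = [e for e in epochs if e.subject_id not in holdout_ids]
        held_epochs = [e for e in epochs if e.subject_id in holdout_ids]
        tcfg = dataclasses.replace(config.train,
                                   seed=stage_seed(config.seed, "train"))
        model = SiameseModel.from_epochs(train_epochs, config=tcfg)
        results = model.fit(mode=config.mode)
        results.save(out / "model")
        log.info("trained %s model, final loss %.4f", config.mode,
                 results.final_loss())

        stage = "score"
        db_rest = [e for e in train_epochs if e.phase != "during"]
        db_during = [e for e in train_epochs if e.phase == "during"]
        frames = []
        for sid in sorted(holdout_ids):
            queries = [e for e in held_epochs
                       if e.subject_id == sid and e.phase != "during"]
            frames.append(score_pairs(results, queries, db_rest,
                                      group="rest_vs_rest", subject=sid))
            frames.append(score_pairs(results, queries, db_during,
                                      group="rest_vs_DAT", subject=sid))
        pairs = pd.concat(frames, ignore_index=True)
        report = cohort_report(pairs)
        pairs_out = pairs.copy()
        pairs_out["S"] = pairs_out["S"].round(9)
        pairs_out["QB_dB"] = pairs_out["QB_dB"].round(9)
        pairs_out.to_csv(out / "report.tsv", sep="\t", index=False)
        rr = pairs.loc[pairs["group"] == "rest_vs_rest", "S"].to_numpy()
        rd = pairs.loc[pairs["group"] == "rest_vs_DAT", "S"].to_numpy()
        pval = permutation_pvalue(rr, rd, n_permutations=config.permutations,
                                  seed=stage_seed(config.seed, "permute"))
        summary = {
            "aggregates": report.aggregates.to_dict(orient="records"),
            "permutation_p_rest_gt_dat": pval,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "config_sha256": config.digest(),
            "seed": config.seed,
            "versions": {"datbio": __version__,
                         "numpy": np.__version__,
                         "python": sys.version.split()[0]},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for item in out.iterdir():
            if item.name != "failed":
                item.rename(failed / item.name)
        raise StageError(stage, exc) from exc
    return out


#: worked-example crossover triples (before, during, after) for two
#: subjects over three therapy sessions, with their similarity statistics
EXAMPLE_CROSSOVERS = [
    ("P1", 1, 210, 193, 203),
    ("P1", 2, 173, 135, 167),
    ("P1", 3, 116, 170, 149),
    ("P2", 1, 146, 187, 132),
    ("P2", 2, 181, 103, 167),
    ("P2", 3, 156, 151, 159),
]


def make_fixtures(seed: int, out_dir) -> Path:
    """Write a miniature test corpus: a tiny cohort plus example triples.

    Two subjects with 10-second phases, written through the CSV writer,
    and a TSV of the worked-example crossover triples with their S_BA and
    S_DR values for regression tests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(n_subjects=2, durations_s=(10.0, 10.0, 10.0), seed=seed)
    for rec in generate_cohort(spec):
        write_recording(rec, out / f"{rec.subject_id}_{rec.phase}.csv")
    rows = []
    for subject, day, cb, cd, ca in EXAMPLE_CROSSOVERS:
        cs = crossover_summary(cb, cd, ca)
        rows.append({"subject": subject, "day": day, "C_B": cb, "C_D": cd,
                     "C_A": ca, "S_BA": cs.S_BA, "S_DR": cs.S_DR})
    pd.DataFrame(rows).to_csv(out / "crossover_examples.tsv", sep="\t",
                              index=False)
    return out
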