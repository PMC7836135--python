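"""End-to-end orchestration: simulate -> preprocess -> analyze -> report.

Every stage reads and writes plain CSV (plus the BrainVision triplets for
raw EEG) under a single output directory, is driven by a serializable
:class:`RunConfig`, and is deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth
from .brainvision import read_brainvision, write_brainvision
from .csd import apply_laplacian, build_kernel
from .mlm import TwoStageMLM, bootstrap_corr
from .montage import make_montage
from .preprocess import preprocess_recording
from .spectral import build_psd_table, ssvep_power
from .synth import CohortParams, PlantedModel, SessionSpec

__all__ = ["RunConfig", "run_pipeline"]

MODES = ("simulate", "preprocess", "analyze", "report", "all")


@dataclass
class RunConfig:
    """Serializable description of a full pipeline run."""

    output_dir: str = "ssvepmod_out"
    eeg_dir: str | None = None  # defaults to <output_dir>/eeg
    mode: str = "all"
    seed: int = 0
    n_participants: int = 147
    # preprocessing
    hp_cutoff: float = 1.0
    hp_transition: float = 2.0
    target_rate: float = 256.0
    line_freq: float = 60.0
    window: float = 2.0
    overlap: float = 1.0
    reject_threshold: float = 100.0
    # CSD
    csd_m: int = 4
    csd_n_terms: int = 50
    csd_lambda: float = 1e-5
    csd_head_radius_cm: float = 10.0
    # spectral / stats
    stim_freq: float = 25.0
    db_of_mean: bool = True
    psd_centering: str = "within"
    a_priori_channel: str = "Oz"
    fdr_alpha: float = 0.05
    bootstrap_b: int = 2000
    # generator condition overrides (kept nested for serializability)
    session: dict = field(default_factory=dict)
    planted: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    # -- serialization ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    # -- derived objects -------------------------------------------------

    def session_spec(self) -> SessionSpec:
        return SessionSpec(**self.session)

    def planted_model(self) -> PlantedModel:
        return PlantedModel(**self.planted)

    def cohort_params(self) -> CohortParams:
        return CohortParams(n_participants=self.n_participants, **self.cohort)

    @property
    def out(self) -> Path:
        return Path(self.output_dir)

    @property
    def eeg(self) -> Path:
        return Path(self.eeg_dir) if self.eeg_dir else self.out / "eeg"


def _log(lines: list[str], msg: str) -> None:
    lines.append(msg)


def stage_simulate(config: RunConfig, log: list[str]) -> None:
    """Generate the cohort, EEG sessions (BrainVision) and ratings."""
    out = config.out
    config.eeg.mkdir(parents=True, exist_ok=True)
    spec = config.session_spec()
    planted = config.planted_model()
    montage = make_montage(config.a_priori_channel)
    kernel = build_kernel(
        montage, config.csd_m, config.csd_n_terms,
        config.csd_lambda, config.csd_head_radius_cm,
    )
    root = np.random.default_rng(config.seed)
    participants = synth.generate_cohort(config.cohort_params(), seed=int(root.integers(2**31)))
    ratings_frames = []
    for _, prow in participants.iterrows():
        rec, targets = synth.generate_session_eeg(
            prow, planted, spec, seed=int(root.integers(2**31)),
            montage=montage, kernel=kernel, return_targets=True,
        )
        pid = int(prow["participant"])
        write_brainvision(rec, config.eeg / f"sub-{pid:03d}.vhdr")
        ratings_frames.append(
            synth.generate_ratings(prow, targets, planted, seed=int(root.integers(2**31)))
        )
    participants.to_csv(out / "participants.csv", index=False)
    pd.concat(ratings_frames, ignore_index=True).to_csv(out / "ratings.csv", index=False)
    _log(log, f"simulate: wrote {len(participants)} sessions to {config.eeg}")


def stage_preprocess(config: RunConfig, log: list[str]) -> None:
    """EEG -> cleaned CSD epochs -> long 25 Hz PSD table."""
    montage = make_montage(config.a_priori_channel)
    kernel = build_kernel(
        montage, config.csd_m, config.csd_n_terms,
        config.csd_lambda, config.csd_head_radius_cm,
    )
    spec = config.session_spec()
    vhdrs = sorted(config.eeg.glob("*.vhdr"))
    if not vhdrs:
        raise FileNotFoundError(f"no .vhdr files in {config.eeg}")
    tables = []
    n_kept = n_total = 0
    for vhdr in vhdrs:
        pid = int(vhdr.stem.split("-")[-1])
        rec = read_brainvision(vhdr, participant=pid)
        eset = preprocess_recording(
            rec,
            hp_cutoff=config.hp_cutoff,
            hp_transition=config.hp_transition,
            target_rate=config.target_rate,
            line_freq=config.line_freq,
            window=config.window,
            overlap=config.overlap,
            block_duration=spec.block_duration,
            reject_threshold=config.reject_threshold,
        )
        n_total += len(eset.epoch_meta)
        n_kept += eset.n_kept()
        csd = apply_laplacian(eset, kernel)
        tables.append(ssvep_power(csd, f0=config.stim_freq, db_of_mean=config.db_of_mean))
    table = build_psd_table(tables)
    table.to_csv(config.out / "psd_table.csv", index=False)
    _log(
        log,
        f"preprocess: {len(vhdrs)} sessions, kept {n_kept}/{n_total} epochs "
        f"({n_total - n_kept} rejected at +/-{config.reject_threshold:g} uV)",
    )


def stage_analyze(config: RunConfig, log: list[str]) -> None:
    """Fit both two-stage analyses and the moderator correlation table."""
    out = config.out
    psd_table = pd.read_csv(out / "psd_table.csv")
    participants = pd.read_csv(out / "participants.csv")
    ratings = pd.read_csv(out / "ratings.csv")

    m1 = TwoStageMLM.from_tables(psd_table, a_priori_channel=config.a_priori_channel)
    r1 = m1.fit()
    r1.level1.to_csv(out / "analysis1_level1.csv", index=False)
    r1.level2.to_csv(out / "analysis1_level2.csv", index=False)

    m2 = TwoStageMLM.from_tables(
        psd_table,
        participants=participants,
        ratings=ratings,
        moderators=synth.COVARIATES,
        psd_centering=config.psd_centering,
        a_priori_channel=config.a_priori_channel,
    )
    r2 = m2.fit()
    r2.level1.to_csv(out / "analysis2_level1.csv", index=False)
    r2.level2.to_csv(out / "analysis2_level2.csv", index=False)
    for msg in r1.log + r2.log:
        _log(log, f"analyze: {msg}")

    rows = []
    pairs = [
        ("menstrual_pain", "bladder_pain"),
        ("bladder_pain", "somatic_symptoms"),
        ("somatic_symptoms", "menstrual_pain"),
    ]
    rng = np.random.default_rng(config.seed + 1)
    for v1, v2 in pairs:
        bc = bootstrap_corr(
            participants[v1], participants[v2],
            n_boot=config.bootstrap_b, seed=int(rng.integers(2**31)),
        )
        rows.append(
            {
                "variable_1": v1,
                "variable_2": v2,
                "r": bc.r,
                "ci_lo": bc.ci_lo,
                "ci_hi": bc.ci_hi,
                "p": bc.p,
                "mean_1": participants[v1].mean(),
                "sd_1": participants[v1].std(),
                "sem_1": participants[v1].sem(),
                "min_1": participants[v1].min(),
                "max_1": participants[v1].max(),
            }
        )
    pd.DataFrame(rows).to_csv(out / "correlations.csv", index=False)
    _log(log, "analyze: wrote level-1/level-2 tables and bootstrap correlations")


def stage_report(config: RunConfig, log: list[str]) -> None:
    """Topographic value exports and the a-priori electrode summary."""
    out = config.out
    for analysis in (1, 2):
        path = out / f"analysis{analysis}_level2.csv"
        if not path.exists():
            raise FileNotFoundError(f"{path} missing; run analyze first")
        level2 = pd.read_csv(path)
        topo = level2.pivot_table(
            index="electrode", columns=["model", "term"], values="b"
        )
        topo.columns = [f"{m}__{t}" for m, t in topo.columns]
        topo.to_csv(out / f"topography_analysis{analysis}.csv")
    a2 = pd.read_csv(out / "analysis2_level2.csv")
    oz = a2[a2["electrode"] == config.a_priori_channel]
    cols = ["model", "term", "b", "ci_lo", "ci_hi", "se", "ss", "mse", "f", "p", "p_fdr", "eta_p2"]
    (out / "oz_summary.txt").write_text(oz[cols].to_string(index=False) + "\n")
    _log(log, "report: wrote topography CSVs and Oz summary")


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages; returns the output directory.

    Any stage failure raises with the stage named in the message.
    """
    config.out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config: {json.dumps(dataclasses.asdict(config), sort_keys=True)}"]
    stages = {
        "simulate": stage_simulate,
        "preprocess": stage_preprocess,
        "analyze": stage_analyze,
        "report": stage_report,
    }
    order = list(stages) if config.mode == "all" else [config.mode]
    for name in order:
        try:
            stages[name](config, log)
        except Exception as exc:
            log.append(f"{name}: FAILED ({exc})")
            (config.out / "run_log.txt").write_text("\n".join(log) + "\n")
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    (config.out / "run_log.txt").write_text("\n".join(log) + "\n")
    return config.out
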