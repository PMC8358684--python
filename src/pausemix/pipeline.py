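"""End-to-end orchestration: corpus in, stage artifacts out.

Stages run in the fixed order simulate/load -> clean -> fit -> select ->
correlate, one analysis context per run.  Every stage writes a
machine-readable artifact (JSON/JSONL/CSV) so any stage can be re-run
from the previous stage's output, and a manifest records the seed, the
config hash and artifact checksums; two runs with the same config and
seed produce identical checksums.

Per-essay problems (non-convergence, inestimable fits) are recorded and
never abort a corpus run; only structural failures (unreadable inputs,
an empty post-cleaning corpus) stop the pipeline.
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

from .association import parameter_score_correlations, parameter_score_table
from .cleaning import CleaningConfig, filter_essays
from .core import CONTEXTS, EssayRecord, ValidationError, select_context
from .em import EMConfig, MixtureFit, fit_k_sweep
from .keystroke import extract_pauses, read_keystroke_csv
from .selection import (
    NoModelSelectedError,
    SelectionRecord,
    SeparationConfig,
    convergence_census,
    pairwise_mean_distances,
    select_model,
    separation_summary,
)
from .synthetic import (
    CorpusConfig,
    generate_corpus,
    read_corpus_jsonl,
    write_corpus_jsonl,
    write_truth_csv,
)

log = logging.getLogger("pausemix")


class EmptyCorpusError(RuntimeError):
    """No essays survived cleaning; nothing to model."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run (one context, one corpus)."""

    mode: str = "synthetic"  # synthetic | pause-table | keystroke-log
    context: str = "WithinWord"
    k_min: int = 2
    k_max: int = 5
    analysis_k: int = 3
    out_dir: str = "pausemix-run"
    seed: int = 0
    em: EMConfig = field(default_factory=EMConfig)
    separation: SeparationConfig = field(default_factory=SeparationConfig)
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    input_corpus: str | None = None
    input_keystrokes: str | None = None
    input_scores: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "pause-table", "keystroke-log"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.context not in CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}")
        if not (1 <= self.k_min <= self.k_max <= 10):
            raise ValidationError("K range must satisfy 1 <= k_min <= k_max <= 10")
        if not (self.k_min <= self.analysis_k <= self.k_max):
            raise ValidationError("analysis_k must lie in the K range")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("em", EMConfig), ("separation", SeparationConfig), ("cleaning", CleaningConfig), ("corpus", CorpusConfig)):
            if key in d and isinstance(d[key], dict):
                sub_d = dict(d[key])
                for tup_key in ("mu", "sigma", "pi_base", "ability_support"):
                    if tup_key in sub_d and isinstance(sub_d[tup_key], list):
                        sub_d[tup_key] = tuple(sub_d[tup_key])
                d[key] = sub(**sub_d)
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _essay_em_config(base: EMConfig, run_seed: int, index: int) -> EMConfig:
    sub = int(np.random.SeedSequence(entropy=run_seed, spawn_key=(7, index)).generate_state(1)[0] % 2**31)
    return dataclasses.replace(base, seed=sub)


def load_corpus(config: RunConfig) -> tuple[list[EssayRecord], pd.DataFrame | None]:
    """Acquire the input corpus for the configured mode."""
    if config.mode == "synthetic":
        corpus_cfg = dataclasses.replace(config.corpus, seed=config.seed)
        return generate_corpus(corpus_cfg)
    if config.mode == "pause-table":
        if not config.input_corpus:
            raise ValidationError("pause-table mode requires input_corpus")
        return read_corpus_jsonl(config.input_corpus), None
    return corpus_from_keystroke_files(config.input_keystrokes, config.input_scores), None


def corpus_from_keystroke_files(log_path, scores_path) -> list[EssayRecord]:
    """Build essays from a multi-essay keystroke CSV plus a scores CSV.

    The log CSV needs columns essay_id, timestamp_ms, action, key (rows
    in stream order within each essay); the scores CSV needs essay_id,
    strand1, strand3.  Characters typed = press events that are not
    BACKSPACE.
    """
    if not log_path or not scores_path:
        raise ValidationError("keystroke-log mode requires input_keystrokes and input_scores")
    df = pd.read_csv(log_path)
    scores = pd.read_csv(scores_path).set_index("essay_id")
    from .core import KeystrokeEvent

    corpus = []
    for essay_id, grp in df.groupby("essay_id", sort=False):
        stream = [
            KeystrokeEvent(int(r.timestamp_ms), str(r.action), "" if pd.isna(r.key) else str(r.key))
            for r in grp.itertuples()
        ]
        pauses = extract_pauses(stream)
        n_chars = sum(1 for ev in stream if ev.action == "press" and ev.key != "BACKSPACE")
        if essay_id not in scores.index:
            raise ValidationError(f"no scores for essay {essay_id!r}")
        row = scores.loc[essay_id]
        corpus.append(EssayRecord(str(essay_id), pauses, n_chars, int(row.strand1), int(row.strand3)))
    return corpus


def fit_corpus(
    corpus: list[EssayRecord], config: RunConfig
) -> tuple[dict[str, dict[int, MixtureFit | None]], dict[str, int]]:
    """Fit the K sweep to each essay's selected-context latencies."""
    k_values = range(config.k_min, config.k_max + 1)
    fits: dict[str, dict[int, MixtureFit | None]] = {}
    n_context: dict[str, int] = {}
    for i, essay in enumerate(corpus):
        lat = select_context(essay.pauses, config.context)
        n_context[essay.essay_id] = len(lat)
        cfg = _essay_em_config(config.em, config.seed, i)
        fits[essay.essay_id] = (
            fit_k_sweep(lat, k_values, cfg) if lat else {K: None for K in k_values}
        )
    return fits, n_context


def select_corpus(
    fits: dict[str, dict[int, MixtureFit | None]], n_context: dict[str, int]
) -> tuple[dict[str, SelectionRecord], list[str]]:
    records: dict[str, SelectionRecord] = {}
    unselected: list[str] = []
    for essay_id, sweep in fits.items():
        try:
            records[essay_id] = select_model(sweep, max(n_context[essay_id], 1), essay_id)
        except NoModelSelectedError:
            unselected.append(essay_id)
    return records, unselected


def selection_table(records: dict[str, SelectionRecord], fits) -> pd.DataFrame:
    rows = []
    for essay_id, rec in records.items():
        row: dict = {"essay_id": essay_id, "N": rec.n_events}
        for K, d in rec.per_k.items():
            for key in ("loglik", "aic", "bic", "converged"):
                row[f"{key}_K{K}"] = d[key]
        row["chosen_k_aic"] = rec.chosen_k_aic
        row["chosen_k_bic"] = rec.chosen_k_bic
        row["agreement"] = rec.agreement
        for K in (3, 4):
            fit = fits[essay_id].get(K)
            row[f"min_distance_K{K}"] = (
                min(pairwise_mean_distances(fit.spec)) if fit is not None else None
            )
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the artifact set to ``config.out_dir``.

    Returns a report dict with artifact paths and headline numbers.
    Raises :class:`EmptyCorpusError` if cleaning removes every essay.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # --- acquire
    corpus, truth = load_corpus(config)
    if not corpus:
        raise EmptyCorpusError("input corpus is empty")
    if config.mode == "synthetic":
        write_corpus_jsonl(out / "corpus.jsonl", corpus)
        artifacts["corpus"] = out / "corpus.jsonl"
        if truth is not None:
            write_truth_csv(out / "truth.csv", truth)
            artifacts["truth"] = out / "truth.csv"

    # --- clean
    kept, removed, clean_report = filter_essays(corpus, config.cleaning)
    (out / "cleaning_report.json").write_text(json.dumps(clean_report, indent=2))
    artifacts["cleaning_report"] = out / "cleaning_report.json"
    if not kept:
        raise EmptyCorpusError("no essays survived cleaning")
    log.info("cleaning: kept %d / %d essays", len(kept), len(corpus))

    # --- fit
    fits, n_context = fit_corpus(kept, config)
    with open(out / "fits.jsonl", "w") as fh:
        for essay_id, sweep in fits.items():
            fh.write(
                json.dumps(
                    {
                        "essay_id": essay_id,
                        "context": config.context,
                        "n_events": n_context[essay_id],
                        "fits": {str(K): (f.to_dict() if f else None) for K, f in sweep.items()},
                    }
                )
                + "\n"
            )
    artifacts["fits"] = out / "fits.jsonl"

    # --- select
    records, unselected = select_corpus(fits, n_context)
    if not records:
        raise EmptyCorpusError("no essay produced a converged fit")
    sel_df = selection_table(records, fits)
    sel_df.to_csv(out / "selection.csv", index=False)
    artifacts["selection"] = out / "selection.csv"

    flags = {
        eid: {K: (sweep[K] is not None and sweep[K].converged) for K in sweep}
        for eid, sweep in fits.items()
    }
    census = convergence_census(flags, k_values=range(config.k_min, config.k_max + 1))
    tallies = {
        "bic": {int(K): int((sel_df["chosen_k_bic"] == K).sum()) for K in range(config.k_min, config.k_max + 1)},
        "aic": {int(K): int((sel_df["chosen_k_aic"] == K).sum()) for K in range(config.k_min, config.k_max + 1)},
        "agreement_rate": float(sel_df["agreement"].mean()),
        "n_unselected": len(unselected),
    }
    (out / "census.json").write_text(json.dumps({"census": census, "selection_tallies": tallies}, indent=2))
    artifacts["census"] = out / "census.json"

    separation: dict = {}
    for K in (3, 4):
        if config.k_min <= K <= config.k_max:
            conv = [sweep[K] for sweep in fits.values() if sweep.get(K) is not None and sweep[K].converged]
            if conv:
                separation[f"K{K}"] = {
                    unit: separation_summary(conv, config.separation, unit=unit)
                    for unit in ("essays", "pairs")
                }
    (out / "separation.json").write_text(json.dumps(separation, indent=2))
    artifacts["separation"] = out / "separation.json"

    # --- correlate
    k_fits = {eid: sweep.get(config.analysis_k) for eid, sweep in fits.items()}
    table, dropped = parameter_score_table(kept, k_fits, config.analysis_k)
    corr_summary: dict = {"analysis_k": config.analysis_k, "n_essays": len(table), "n_dropped": dropped}
    if len(table) >= 4 and table["strand1"].nunique() > 1 and table["strand3"].nunique() > 1:
        corr = parameter_score_correlations(table)
        corr.to_csv(out / "correlations.csv", index=False)
        artifacts["correlations"] = out / "correlations.csv"
        pi1 = corr.set_index("parameter").loc["pi_1"]
        corr_summary["r_pi1_strand1"] = float(pi1["r_strand1"])
        corr_summary["r_pi1_strand3"] = float(pi1["r_strand3"])
    else:
        log.warning("correlation stage skipped: too few usable essays or constant scores")

    # --- manifest
    import pausemix

    manifest = {
        "package": "pausemix",
        "version": pausemix.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
        "config_sha256": _config_hash(config),
        "artifacts": {name: {"path": p.name, "sha256": _sha256(p)} for name, p in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "out_dir": str(out),
        "n_input": clean_report["n_input"],
        "n_kept": clean_report["n_kept"],
        "n_removed": clean_report["n_removed"],
        "census": census,
        "selection_tallies": tallies,
        "separation": separation,
        "correlation": corr_summary,
        "artifacts": {name: str(p) for name, p in artifacts.items()},
        "manifest": str(out / "manifest.json"),
    }
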