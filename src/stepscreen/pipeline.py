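"""End-to-end orchestration: simulate/load -> annotate -> cohort -> screens.

``run_pipeline`` executes every stage in a fixed order, optionally
writing all result tables (tab-separated) plus a JSON run manifest to an
output directory.  Identical configuration and seed give byte-identical
result tables.  Any stage failure raises :class:`PipelineStageError`
naming the stage; when an output directory is set, a manifest marking
the run incomplete is left behind.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    assign_subgroups,
    cohort_counts,
    discover_seed_queries,
    final_month_window,
    identify_cohort,
    load_seed_urls,
)
from .lexicon import SymptomLexicon, default_lexicon, load_lexicon, symptom_hits
from .log_model import SearchLog, read_log, write_log
from .synthetic_logs import GroundTruth, SimConfig, default_seed_urls, simulate_logs
from .temporal_stats import (
    DEFAULT_WINDOWS,
    WindowSpec,
    classify_persistence,
    probability_ratio_screen,
    temporal_screen,
)

logger = logging.getLogger("stepscreen")

RESULT_FILES = ("cohort.tsv", "ratios.tsv", "windows.tsv", "persistence.tsv")
_FLOAT_FORMAT = "%.12g"


class PipelineError(RuntimeError):
    pass


class PipelineStageError(PipelineError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulate`` (a :class:`SimConfig`) and ``input_log``
    (a path or in-memory :class:`SearchLog`) must be set.  ``lexicon``
    and ``seed_urls`` accept paths or in-memory objects and default to
    the packaged fixtures.
    """

    simulate: SimConfig | None = None
    input_log: str | Path | SearchLog | None = None
    lexicon: str | Path | SymptomLexicon | None = None
    seed_urls: str | Path | Mapping[str, str] | None = None
    outdir: str | Path | None = None
    alpha: float = 0.05
    min_users: int = 50
    baseline: str = "pre_leadup"
    continuity: bool = False
    meeting_only: bool = False
    write_log_file: bool = False
    windows: tuple[WindowSpec, ...] = DEFAULT_WINDOWS
    rng_seed: int | None = None  # overrides simulate.rng_seed when set

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_log is None):
            raise PipelineError("exactly one of simulate / input_log must be set")
        if self.simulate is not None and self.rng_seed is not None:
            self.simulate = dataclasses.replace(self.simulate, rng_seed=int(self.rng_seed))

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        windows = raw.pop("windows", None)
        kwargs = dict(raw)
        if sim is not None:
            kwargs["simulate"] = SimConfig.from_dict(sim)
        if windows is not None:
            kwargs["windows"] = tuple(
                WindowSpec(w["label"], w["start_days"], w["end_days"]) for w in windows
            )
        if seed is not None:
            kwargs["rng_seed"] = seed
        return cls(**kwargs)

    def manifest_dict(self) -> dict:
        return {
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "input_log": str(self.input_log)
            if isinstance(self.input_log, (str, Path))
            else ("<in-memory>" if self.input_log is not None else None),
            "lexicon": str(self.lexicon)
            if isinstance(self.lexicon, (str, Path))
            else ("<packaged default>" if self.lexicon is None else "<in-memory>"),
            "seed_urls": str(self.seed_urls)
            if isinstance(self.seed_urls, (str, Path))
            else ("<packaged default>" if self.seed_urls is None else "<in-memory>"),
            "alpha": self.alpha,
            "min_users": self.min_users,
            "baseline": self.baseline,
            "continuity": self.continuity,
            "meeting_only": self.meeting_only,
            "windows": [dataclasses.asdict(w) for w in self.windows],
            "rng_seed": self.rng_seed,
        }


@dataclasses.dataclass
class RunReport:
    """Everything one pipeline run computed, plus provenance."""

    cohort: pd.DataFrame
    cohort_counts: dict[str, int]
    n_symptoms_tested: int
    corrected_threshold: float
    ratios: pd.DataFrame
    windows: pd.DataFrame
    persistence: pd.DataFrame
    provenance: dict

    def assert_consistent(self) -> None:
        c = self.cohort_counts
        if c["AA"] + c["NA"] + c["BOTH"] != c["target"]:
            raise PipelineError(
                "cohort subgroup counts do not partition the target cohort: "
                f"{c['AA']} + {c['NA']} + {c['BOTH']} != {c['target']}"
            )


def _resolve_lexicon(spec) -> SymptomLexicon:
    if spec is None:
        return default_lexicon()
    if isinstance(spec, SymptomLexicon):
        return spec
    return load_lexicon(spec)


def _resolve_seed_urls(spec) -> dict[str, str]:
    if spec is None:
        return default_seed_urls()
    if isinstance(spec, Mapping):
        return dict(spec)
    return load_seed_urls(spec)


class _Stage:
    """Context manager: logs stage timing, wraps failures with the stage name."""

    def __init__(self, name: str, timings: dict):
        self.name = name
        self.timings = timings

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        self.timings[self.name] = round(dt, 4)
        if exc is not None:
            logger.error("stage %s: failed after %.2fs (%s)", self.name, dt, exc)
            if not isinstance(exc, PipelineStageError):
                raise PipelineStageError(self.name, exc) from exc
            return False
        logger.info("stage %s: done in %.2fs", self.name, dt)
        return False


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full screen and return (and optionally write) the report."""
    timings: dict[str, float] = {}
    outdir = Path(config.outdir) if config.outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    try:
        report = _run_stages(config, timings, outdir)
    except PipelineStageError as err:
        if outdir is not None:
            manifest = {
                "status": "incomplete",
                "failed_stage": err.stage,
                "error": str(err.cause),
                "config": config.manifest_dict(),
                "version": __version__,
            }
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    return report


def _run_stages(config, timings, outdir) -> RunReport:
    ground_truth: GroundTruth | None = None
    with _Stage("load", timings):
        lexicon = _resolve_lexicon(config.lexicon)
        seed_urls = _resolve_seed_urls(config.seed_urls)
        if config.simulate is not None:
            log, ground_truth = simulate_logs(config.simulate)
        elif isinstance(config.input_log, SearchLog):
            log = config.input_log
        else:
            log = read_log(config.input_log)
        logger.info("log: %d events, %d users", log.n_events, log.n_users)

    with _Stage("discover_seeds", timings):
        seeds = discover_seed_queries(log, seed_urls, min_users=config.min_users)
        logger.info("seed queries retained: %d", len(seeds))

    with _Stage("cohort", timings):
        index_window = final_month_window(log.span_start, log.span_end)
        assignments = identify_cohort(log, seeds, index_window)
        assignments = assign_subgroups(assignments, log, seeds, index_window)
        counts = cohort_counts(assignments)
        logger.info("cohort: %s", counts)

    with _Stage("annotate", timings):
        hits = symptom_hits(log, lexicon)

    target_mask = assignments["role"].eq("target")
    if config.meeting_only:
        target_mask &= assignments["meeting_subsample"]
    target_users = assignments.loc[target_mask, "user_id"]
    comparison_users = assignments.loc[assignments["role"].eq("comparison"), "user_id"]
    index_times = pd.Series(
        assignments.loc[target_mask, "index_time"].to_numpy(), index=target_users
    )

    with _Stage("ratio_screen", timings):
        if len(target_users) and len(comparison_users):
            ratios = probability_ratio_screen(
                hits[hits["user_id"].isin(target_users)],
                hits[hits["user_id"].isin(comparison_users)],
                symptoms=lexicon.symptoms,
                target_users=target_users,
                comparison_users=comparison_users,
            )
        else:
            ratios = pd.DataFrame(
                columns=["symptom", "p_target", "p_comparison", "ratio", "rank"]
            )

    with _Stage("temporal_screen", timings):
        if len(target_users):
            screen = temporal_screen(
                hits[hits["user_id"].isin(target_users)],
                index_times,
                symptoms=lexicon.symptoms,
                windows=config.windows,
                alpha=config.alpha,
                baseline=config.baseline,
                continuity=config.continuity,
                span_start=log.span_start,
            )
            windows_table = screen.table
            corrected = screen.corrected_alpha
        else:
            windows_table = pd.DataFrame(
                columns=[
                    "symptom", "window", "A", "B", "C", "D", "p_window",
                    "p_baseline", "chi_square", "p_value", "degenerate", "significant",
                ]
            )
            corrected = config.alpha / (lexicon.size * len(config.windows))

    with _Stage("classify", timings):
        if len(windows_table):
            persistence = classify_persistence(windows_table, config.windows)
        else:
            persistence = pd.DataFrame(columns=["symptom", "category", "significant_windows"])

    report = RunReport(
        cohort=assignments,
        cohort_counts=counts,
        n_symptoms_tested=lexicon.size,
        corrected_threshold=corrected,
        ratios=ratios,
        windows=windows_table,
        persistence=persistence,
        provenance={
            "version": __version__,
            "config": config.manifest_dict(),
            "seed_queries": [dataclasses.asdict(s) for s in seeds],
            "n_events": int(log.n_events),
            "n_users": int(log.n_users),
            "timings_s": timings,
            "duration_note": (
                "window and baseline exposure durations are equal under "
                "baseline=pre_leadup; under baseline=full_history they are not, "
                "which biases p_baseline upward for long observation spans"
            ),
        },
    )
    with _Stage("finalize", timings):
        report.assert_consistent()
        if outdir is not None:
            _write_report(report, outdir, log, ground_truth, config)
    return report


def _write_table(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S").fillna("")
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def _write_report(report, outdir: Path, log, ground_truth, config) -> None:
    _write_table(report.cohort, outdir / "cohort.tsv")
    _write_table(report.ratios, outdir / "ratios.tsv")
    _write_table(report.windows, outdir / "windows.tsv")
    _write_table(report.persistence, outdir / "persistence.tsv")
    if config.write_log_file:
        write_log(log, outdir / "log.tsv")
        if ground_truth is not None:
            ground_truth.write(outdir / "ground_truth.tsv")
    manifest = {
        "status": "complete",
        "version": __version__,
        "config": report.provenance["config"],
        "cohort_counts": report.cohort_counts,
        "n_symptoms_tested": report.n_symptoms_tested,
        "corrected_threshold": report.corrected_threshold,
        "seed_queries": report.provenance["seed_queries"],
        "timings_s": report.provenance["timings_s"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def summarize(report: RunReport, top: int = 10) -> str:
    """Human-readable digest: cohort counts, threshold, top ratios, taxonomy."""
    c = report.cohort_counts
    lines = [
        "stepscreen run summary",
        f"  target users: {c.get('target', 0)} "
        f"(AA {c.get('AA', 0)}, NA {c.get('NA', 0)}, both {c.get('BOTH', 0)}; "
        f"meeting subsample {c.get('meeting', 0)})",
        f"  comparison users: {c.get('comparison', 0)}; excluded: {c.get('excluded', 0)}",
        f"  symptoms tested: {report.n_symptoms_tested}",
        f"  Bonferroni-corrected threshold: {report.corrected_threshold:.6g}",
    ]
    if c.get("target", 0) == 0:
        lines.append("  zero target users: no screens were run")
        return "\n".join(lines)
    ranked = report.ratios.dropna(subset=["ratio"]).head(top)
    if len(ranked):
        lines.append(f"  top {len(ranked)} between-group probability ratios:")
        for row in ranked.itertuples(index=False):
            lines.append(
                f"    {int(row.rank):3d}. {row.symptom}: ratio {row.ratio:.3g} "
                f"(target {row.p_target:.4g} vs comparison {row.p_comparison:.4g})"
            )
    for cat in ("persistent", "near_persistent", "immediate", "distal", "middle_only"):
        syms = report.persistence.loc[
            report.persistence["category"].eq(cat), "symptom"
        ].tolist()
        if syms:
            lines.append(f"  {cat}: {', '.join(syms)}")
    n_sig = int(report.windows["significant"].sum()) if len(report.windows) else 0
    lines.append(f"  significant (symptom, window) pairs: {n_sig}")
    return "\n".join(lines)
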