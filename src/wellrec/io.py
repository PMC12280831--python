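"""File formats, validation, run configuration, and the full pipeline.

Interchange formats are deliberately plain:

* **library CSV/JSON** — ``session_id, guide_id, mood_w1..3, intent_w1..3``.
* **records CSV** — one completed session per row: ``user_id, session_id,
  order_index, osl_pre, osl_post, srs_pre, srs_post, mood_words_pre,
  mood_words_post`` with mood-board selections semicolon-joined.  SRM is
  derived from the words on load, never stored.
* **lexicon CSV** — ``word, quadrant``.

Loading applies the study's inclusion rule: only users with at least
``min_records`` complete records (all three measures pre and post) are
retained, and each retained user's records are renumbered to a gapless
chronological 1..n.  Hard violations (out-of-range values, duplicate
(user, order_index) pairs, session ids missing from the library) abort the
run; soft issues are reported.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .lexicon import MoodLexicon, default_lexicon
from .measures import (
    Cohort,
    MEASURES,
    SessionLibrary,
    SessionMeta,
    SessionRecord,
    UserHistory,
    score_mood_board,
)
from .evaluate import (
    DEFAULT_EVAL_CONFIG,
    EvalConfig,
    bootstrap_cv,
    delta_correlations,
    efficacy_curve,
    overlap_analysis,
    paired_comparison,
    anova_points,
)
from .recommend import DEFAULT_CONFIG, RecommenderConfig
from .synthetic import SynthConfig, gen_cohort

logger = logging.getLogger(__name__)

DEFAULT_MIN_RECORDS = 28

RECORD_COLUMNS = [
    "user_id", "session_id", "order_index",
    "osl_pre", "osl_post", "srs_pre", "srs_post",
    "mood_words_pre", "mood_words_post",
]


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# --- library ----------------------------------------------------------------

def load_library(path) -> SessionLibrary:
    path = Path(path)
    if path.suffix.lower() == ".json":
        entries = json.loads(path.read_text())
        metas = [
            SessionMeta(
                session_id=str(e["session_id"]),
                guide_id=str(e["guide_id"]),
                mood_words=tuple(e["mood_words"]),
                intent_words=tuple(e["intent_words"]),
            )
            for e in entries
        ]
    else:
        frame = pd.read_csv(path, dtype=str)
        required = {"session_id", "guide_id", "mood_w1", "mood_w2", "mood_w3",
                    "intent_w1", "intent_w2", "intent_w3"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"library {path}: missing columns {sorted(missing)}")
        metas = [
            SessionMeta(
                session_id=row.session_id,
                guide_id=row.guide_id,
                mood_words=(row.mood_w1, row.mood_w2, row.mood_w3),
                intent_words=(row.intent_w1, row.intent_w2, row.intent_w3),
            )
            for row in frame.itertuples()
        ]
    return SessionLibrary.from_metas(metas)


def write_library(library: SessionLibrary, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        entries = [
            {
                "session_id": m.session_id, "guide_id": m.guide_id,
                "mood_words": list(m.mood_words), "intent_words": list(m.intent_words),
            }
            for m in library
        ]
        path.write_text(json.dumps(entries, indent=1) + "\n")
        return
    rows = [
        {
            "session_id": m.session_id, "guide_id": m.guide_id,
            "mood_w1": m.mood_words[0], "mood_w2": m.mood_words[1],
            "mood_w3": m.mood_words[2],
            "intent_w1": m.intent_words[0], "intent_w2": m.intent_words[1],
            "intent_w3": m.intent_words[2],
        }
        for m in library
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# --- records ----------------------------------------------------------------

def records_frame(cohort: Cohort) -> pd.DataFrame:
    rows = [
        {
            "user_id": r.user_id, "session_id": r.session_id,
            "order_index": r.order_index,
            "osl_pre": r.osl_pre, "osl_post": r.osl_post,
            "srs_pre": r.srs_pre, "srs_post": r.srs_post,
            "mood_words_pre": ";".join(r.mood_words_pre),
            "mood_words_post": ";".join(r.mood_words_post),
        }
        for history in cohort.values()
        for r in history
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(cohort: Cohort, path) -> None:
    records_frame(cohort).to_csv(path, index=False, float_format="%.6f")


@dataclass
class ValidationReport:
    """What the loader saw and what it kept."""

    n_rows: int = 0
    n_complete: int = 0
    n_incomplete: int = 0
    n_users_in: int = 0
    n_users_retained: int = 0
    dropped_users: list = field(default_factory=list)
    messages: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_records(
    path,
    library: SessionLibrary,
    lexicon: MoodLexicon | None = None,
    min_records: int = DEFAULT_MIN_RECORDS,
) -> tuple[Cohort, ValidationReport]:
    """Load, validate, and filter a records CSV into a cohort.

    Incomplete rows (any missing measure) are excluded and the user's
    remaining records renumbered chronologically; users falling below
    ``min_records`` complete records are dropped.  Range violations,
    duplicate (user, order_index) pairs and unresolved session ids are hard
    errors.
    """
    lexicon = lexicon or default_lexicon()
    frame = pd.read_csv(path, dtype={"user_id": str, "session_id": str})
    report = ValidationReport(n_rows=len(frame))
    missing_cols = set(RECORD_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise ValidationError(f"records {path}: missing columns {sorted(missing_cols)}")

    unresolved = sorted(set(frame["session_id"]) - set(library.session_ids))
    if unresolved:
        raise ValidationError(
            f"records {path}: {len(unresolved)} unresolved session ids, e.g. {unresolved[:5]}"
        )
    dupes = frame.duplicated(subset=["user_id", "order_index"], keep=False)
    if dupes.any():
        bad = frame.loc[dupes, ["user_id", "order_index"]].head()
        raise ValidationError(f"records {path}: duplicate (user, order_index) pairs:\n{bad}")

    for col, (lo, hi) in {
        "osl_pre": (0, 1), "osl_post": (0, 1), "srs_pre": (0, 10), "srs_post": (0, 10),
    }.items():
        values = frame[col].dropna()
        bad = values[(values < lo) | (values > hi)]
        if len(bad):
            raise ValidationError(
                f"records {path}: {len(bad)} out-of-range values in {col} "
                f"(rows {list(bad.index[:5])})"
            )

    numeric = ["osl_pre", "osl_post", "srs_pre", "srs_post"]
    words_ok = frame["mood_words_pre"].notna() & frame["mood_words_post"].notna()
    complete = frame[numeric].notna().all(axis=1) & words_ok
    report.n_complete = int(complete.sum())
    report.n_incomplete = int((~complete).sum())
    if report.n_incomplete:
        report.messages.append(f"excluded {report.n_incomplete} incomplete rows")
    frame = frame[complete]

    cohort: dict[str, UserHistory] = {}
    report.n_users_in = frame["user_id"].nunique()
    for user_id, group in frame.groupby("user_id", sort=True):
        group = group.sort_values("order_index")
        if len(group) < min_records:
            report.dropped_users.append(str(user_id))
            continue
        records = []
        for new_index, row in enumerate(group.itertuples(), start=1):
            records.append(
                SessionRecord.from_mood_words(
                    user_id=str(user_id),
                    session_id=row.session_id,
                    order_index=new_index,
                    osl_pre=row.osl_pre,
                    osl_post=row.osl_post,
                    srs_pre=row.srs_pre,
                    srs_post=row.srs_post,
                    mood_words_pre=str(row.mood_words_pre).split(";"),
                    mood_words_post=str(row.mood_words_post).split(";"),
                    lexicon=lexicon,
                )
            )
        cohort[str(user_id)] = UserHistory(user_id=str(user_id), records=tuple(records))
    report.n_users_retained = len(cohort)
    if report.dropped_users:
        report.messages.append(
            f"dropped {len(report.dropped_users)} users below {min_records} complete records"
        )
    logger.info(
        "loaded %d users (%d records) from %s", len(cohort), report.n_complete, path
    )
    return cohort, report


# --- run configuration and pipeline ----------------------------------------

def _stat_dict(stat) -> dict:
    return {
        "kind": stat.kind, "statistic": stat.statistic, "df": list(stat.df),
        "p_value": stat.p_value, "effect_size": stat.effect_size,
    }


@dataclass
class RunConfig:
    """Everything one pipeline run needs; fully serializable."""

    out_dir: str = "wellrec_out"
    seed: int = 0
    measures: tuple[str, ...] = ("osl", "srs", "srm")
    records_path: str | None = None   # None => simulate a cohort
    library_path: str | None = None
    lexicon_path: str | None = None
    min_records: int = DEFAULT_MIN_RECORDS
    recommender: RecommenderConfig = field(default_factory=RecommenderConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    synthetic: SynthConfig = field(default_factory=SynthConfig)
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "recommender" in kwargs:
            kwargs["recommender"] = RecommenderConfig(**kwargs["recommender"])
        if "evaluation" in kwargs:
            ev = dict(kwargs["evaluation"])
            for key in ("k_range_efficacy", "k_range_overlap"):
                if key in ev:
                    ev[key] = tuple(ev[key])
            kwargs["evaluation"] = EvalConfig(**ev)
        if "synthetic" in kwargs:
            sy = dict(kwargs["synthetic"])
            for key in ("mood_vocab", "intent_vocab", "planted_mood_words",
                        "planted_intent_words"):
                if key in sy:
                    sy[key] = tuple(sy[key])
            kwargs["synthetic"] = SynthConfig(**sy)
        if "measures" in kwargs:
            kwargs["measures"] = tuple(kwargs["measures"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def evaluate_measure(
    cohort: Cohort,
    library: SessionLibrary,
    measure: str,
    rec_config: RecommenderConfig = DEFAULT_CONFIG,
    eval_config: EvalConfig = DEFAULT_EVAL_CONFIG,
) -> dict:
    """Run the full per-measure evaluation; returns a results bundle."""
    curve = efficacy_curve(cohort, library, measure, rec_config, eval_config)
    points = anova_points(cohort, library, measure, rec_config, eval_config)
    anova = paired_comparison(points)
    boot = bootstrap_cv(cohort, library, measure, rec_config, eval_config)
    overlap = overlap_analysis(cohort, library, measure, rec_config, eval_config)
    return {
        "curve": curve,
        "anova": anova,
        "anova_n_users": len(points),
        "bootstrap": boot,
        "overlap": overlap,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate (optional) -> evaluate -> overlap -> correlate and
    write every artifact plus a checksum manifest into ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lexicon = (
        MoodLexicon.from_csv(config.lexicon_path)
        if config.lexicon_path else default_lexicon()
    )

    manifest: dict = {"run_config": config.to_dict(), "inputs": {}, "outputs": {}}
    if config.records_path is None:
        library, cohort, synth_manifest = gen_cohort(config.synthetic, config.seed, lexicon)
        manifest["synthetic"] = synth_manifest
        write_library(library, out / "library.csv")
        write_records(cohort, out / "records.csv")
    else:
        if config.library_path is None:
            raise ValidationError("a records path requires a library path")
        library = load_library(config.library_path)
        cohort, report = load_records(
            config.records_path, library, lexicon, config.min_records
        )
        manifest["validation"] = report.to_dict()
        for path in (config.records_path, config.library_path):
            manifest["inputs"][str(path)] = sha256_of(path)

    corr = delta_correlations(cohort)
    corr.to_csv(out / "delta_correlations.csv")

    stats_json: dict = {"measures": {}}
    for measure in config.measures:
        results = evaluate_measure(
            cohort, library, measure, config.recommender, config.evaluation
        )
        curve = results["curve"]
        overlap = results["overlap"]
        curve.per_k.to_csv(out / f"efficacy_curve_{measure}.csv", index=False)
        overlap.per_k.to_csv(out / f"overlap_{measure}.csv", index=False)
        if config.make_plots:
            from .plots import plot_efficacy_curve, plot_overlap

            plot_efficacy_curve(curve, out / f"efficacy_curve_{measure}.png")
            plot_overlap(overlap, out / f"overlap_{measure}.png")
        boot = results["bootstrap"]
        stats_json["measures"][measure] = {
            "efficacy_regression": _stat_dict(curve.regression),
            "paired_anova": _stat_dict(results["anova"]),
            "anova_n_users": results["anova_n_users"],
            "bootstrap_agreement": boot.agreement,
            "bootstrap_fold_f": [f.stat.statistic for f in boot.folds],
            "overlap_anova": _stat_dict(overlap.anova),
            "overlap_quadratic": _stat_dict(overlap.quadratic),
        }
    stats_json["delta_correlations"] = corr.to_dict()
    (out / "stats.json").write_text(json.dumps(stats_json, indent=1, default=float))

    for artifact in sorted(out.iterdir()):
        if artifact.name != "manifest.json" and artifact.is_file():
            manifest["outputs"][artifact.name] = sha256_of(artifact)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return stats_json
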