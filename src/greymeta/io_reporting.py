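"""Corpus readers/writers, report generation and packaged reference tables.

The corpus file format is tabular: a reviews table (one row per review)
plus a studies table (one row per study), either as two CSV files in a
directory (``reviews.csv`` / ``studies.csv``) or as a single JSON document
with ``reviews`` and ``studies`` arrays.  All files are UTF-8; CSVs are
comma-separated with a mandatory header and ``.`` decimal separator, and
writers emit byte-identical output for identical inputs (stable column and
row order).

The module also ships two small published reference tables: the reported
with/without pooled estimates of 32 sensitivity re-analyses of Cochrane
child-health meta-analyses (grey-literature exclusions), and the matching
searching/inclusion count table.  These serve as fixed, text-only inputs
for the estimate-pair reproduction checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .corpus_summary import (
    CorpusSummary,
    ReviewGroup,
    ReviewRecord,
    StudyRecord,
)
from .impact_analysis import (
    ImpactMetrics,
    StudyTypeLabel,
    round_half_away,
)
from .meta_engine import (
    ContinuousArms,
    DichotomousArms,
    EffectEstimate,
    PoolingMethod,
    PoolingModel,
    SummaryMeasure,
)

__all__ = [
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "write_reports",
    "ReferenceRow",
    "load_reference_rows",
    "load_reference_counts",
]


class CorpusFormatError(ValueError):
    """Schema violation in a corpus file; names file, row and column."""

    def __init__(self, file: str, row, column: str, message: str):
        self.file, self.row, self.column = file, row, column
        super().__init__(f"{file}: row {row}, column {column!r}: {message}")


REVIEW_COLUMNS = [
    "review_id",
    "group",
    "measure",
    "model",
    "method",
    "searched_non_english",
    "searched_unpublished",
    "searched_dissertations",
    "year",
]
STUDY_COLUMNS = [
    "review_id",
    "study_id",
    "is_non_english",
    "is_unpublished",
    "is_dissertation",
    "n_participants",
    "outcome_kind",
    "events_t",
    "total_t",
    "events_c",
    "total_c",
    "mean_t",
    "sd_t",
    "n_t",
    "mean_c",
    "sd_c",
    "n_c",
    "effect",
    "variance",
    "language",
]

_LABEL_COLS = {
    StudyTypeLabel.non_english: "is_non_english",
    StudyTypeLabel.unpublished: "is_unpublished",
    StudyTypeLabel.dissertation: "is_dissertation",
}
_SEARCHED_COLS = {
    StudyTypeLabel.non_english: "searched_non_english",
    StudyTypeLabel.unpublished: "searched_unpublished",
    StudyTypeLabel.dissertation: "searched_dissertations",
}


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def _parse_bool(value, file: str, row, column: str) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str) and value.strip().lower() in ("true", "false"):
        return value.strip().lower() == "true"
    raise CorpusFormatError(file, row, column, f"expected true/false, got {value!r}")


def _parse_enum(enum_cls, value, file: str, row, column: str):
    try:
        return enum_cls(value)
    except ValueError:
        allowed = [e.value for e in enum_cls]
        raise CorpusFormatError(
            file, row, column, f"{value!r} not one of {allowed}"
        ) from None


def _study_outcome(rec: dict, file: str, row):
    kind = rec.get("outcome_kind")
    if kind == "dichotomous":
        cols = ("events_t", "total_t", "events_c", "total_c")
        vals = []
        for col in cols:
            if _is_missing(rec.get(col)):
                raise CorpusFormatError(file, row, col, "required for dichotomous")
            vals.append(int(float(rec[col])))
        return DichotomousArms(*vals)
    if kind == "continuous":
        cols = ("mean_t", "sd_t", "n_t", "mean_c", "sd_c", "n_c")
        vals = []
        for col in cols:
            if _is_missing(rec.get(col)):
                raise CorpusFormatError(file, row, col, "required for continuous")
            vals.append(float(rec[col]))
        return ContinuousArms(
            vals[0], vals[1], int(vals[2]), vals[3], vals[4], int(vals[5])
        )
    if kind == "effect":
        for col in ("effect", "variance"):
            if _is_missing(rec.get(col)):
                raise CorpusFormatError(file, row, col, "required for effect")
        return EffectEstimate(float(rec["effect"]), float(rec["variance"]))
    raise CorpusFormatError(
        file, row, "outcome_kind",
        f"{kind!r} not one of ['dichotomous', 'continuous', 'effect']",
    )


def _records_to_corpus(
    review_rows: list, study_rows: list, rev_file: str, stu_file: str
) -> list:
    studies_by_review: dict[str, list[StudyRecord]] = {}
    review_ids = {r.get("review_id") for r in review_rows}
    for i, rec in enumerate(study_rows):
        rid = rec.get("review_id")
        if rid not in review_ids:
            raise CorpusFormatError(
                stu_file, i, "review_id", f"references unknown review {rid!r}"
            )
        labels = set()
        for label, col in _LABEL_COLS.items():
            if _parse_bool(rec.get(col), stu_file, i, col):
                labels.add(label)
        n_part = rec.get("n_participants")
        if _is_missing(n_part):
            raise CorpusFormatError(stu_file, i, "n_participants", "required")
        language = rec.get("language")
        studies_by_review.setdefault(rid, []).append(
            StudyRecord(
                study_id=str(rec.get("study_id")),
                labels=frozenset(labels),
                n_participants=int(float(n_part)),
                outcome=_study_outcome(rec, stu_file, i),
                language=None if _is_missing(language) else str(language),
            )
        )
    corpus = []
    for i, rec in enumerate(review_rows):
        rid = rec.get("review_id")
        studies = studies_by_review.get(rid, [])
        if not studies:
            raise CorpusFormatError(
                rev_file, i, "review_id", f"review {rid!r} has no studies"
            )
        searched = {
            label: _parse_bool(rec.get(col), rev_file, i, col)
            for label, col in _SEARCHED_COLS.items()
        }
        year = rec.get("year")
        corpus.append(
            ReviewRecord(
                review_id=str(rid),
                group=_parse_enum(ReviewGroup, rec.get("group"), rev_file, i, "group"),
                measure=_parse_enum(
                    SummaryMeasure, rec.get("measure"), rev_file, i, "measure"
                ),
                model=_parse_enum(
                    PoolingModel, rec.get("model"), rev_file, i, "model"
                ),
                method=_parse_enum(
                    PoolingMethod, rec.get("method"), rev_file, i, "method"
                ),
                studies=sorted(studies, key=lambda s: s.study_id),
                searched=searched,
                year=None if _is_missing(year) else int(float(year)),
            )
        )
    return sorted(corpus, key=lambda r: r.review_id)


def read_corpus(path) -> list:
    """Read and validate a corpus from a JSON file or a CSV directory."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return _records_to_corpus(
            doc.get("reviews", []), doc.get("studies", []), str(path), str(path)
        )
    rev_file, stu_file = path / "reviews.csv", path / "studies.csv"
    reviews = pd.read_csv(rev_file, dtype=str, keep_default_na=False)
    studies = pd.read_csv(stu_file, dtype=str, keep_default_na=False)
    return _records_to_corpus(
        reviews.to_dict("records"),
        studies.to_dict("records"),
        str(rev_file),
        str(stu_file),
    )


def _corpus_to_records(corpus: list) -> tuple[list, list]:
    review_rows, study_rows = [], []
    for review in sorted(corpus, key=lambda r: r.review_id):
        row = {
            "review_id": review.review_id,
            "group": review.group.value,
            "measure": review.measure.value,
            "model": review.model.value,
            "method": review.method.value,
            "year": review.year,
        }
        for label, col in _SEARCHED_COLS.items():
            row[col] = review.searched[label]
        review_rows.append(row)
        for study in sorted(review.studies, key=lambda s: s.study_id):
            rec = {
                "review_id": review.review_id,
                "study_id": study.study_id,
                "n_participants": study.n_participants,
                "language": study.language,
            }
            for label, col in _LABEL_COLS.items():
                rec[col] = label in study.labels
            o = study.outcome
            if isinstance(o, DichotomousArms):
                rec.update(
                    outcome_kind="dichotomous",
                    events_t=o.events_treatment,
                    total_t=o.total_treatment,
                    events_c=o.events_control,
                    total_c=o.total_control,
                )
            elif isinstance(o, ContinuousArms):
                rec.update(
                    outcome_kind="continuous",
                    mean_t=o.mean_treatment,
                    sd_t=o.sd_treatment,
                    n_t=o.n_treatment,
                    mean_c=o.mean_control,
                    sd_c=o.sd_control,
                    n_c=o.n_control,
                )
            else:
                rec.update(
                    outcome_kind="effect", effect=o.value, variance=o.variance
                )
            study_rows.append(rec)
    return review_rows, study_rows


def _fmt_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_corpus(corpus: list, path) -> None:
    """Write a corpus as JSON (``.json`` path) or a CSV directory."""
    path = Path(path)
    review_rows, study_rows = _corpus_to_records(corpus)
    if path.suffix == ".json":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"reviews": review_rows, "studies": study_rows},
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")
        return
    path.mkdir(parents=True, exist_ok=True)
    for name, rows, columns in (
        ("reviews.csv", review_rows, REVIEW_COLUMNS),
        ("studies.csv", study_rows, STUDY_COLUMNS),
    ):
        lines = [",".join(columns)]
        for row in rows:
            lines.append(",".join(_fmt_cell(row.get(col)) for col in columns))
        (path / name).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _fmt_pct(value: Optional[float]) -> str:
    return "NA" if value is None else f"{round_half_away(value, 1):.1f}"


def _fmt_est(result) -> str:
    if not result.estimable:
        return "NA"
    return (
        f"{round_half_away(result.point, 2):.2f} "
        f"({round_half_away(result.ci_low, 2):.2f}, "
        f"{round_half_away(result.ci_high, 2):.2f})"
    )


def _summary_frame(summary: CorpusSummary) -> pd.DataFrame:
    frame = summary.to_frame()
    for col in ("pct_searched", "pct_included", "pct_studies_of_type"):
        frame[col] = [
            "NA" if v is None else f"{v:.1f}" for v in frame[col]
        ]
    return frame


def _impact_frame(impacts: list) -> pd.DataFrame:
    rows = []
    for m in sorted(impacts, key=lambda m: (m.label.value, m.review_id)):
        rows.append(
            {
                "study_type": m.label.value,
                "review_id": m.review_id,
                "n_studies_with": m.n_studies_with,
                "n_studies_without": m.n_studies_without,
                "pct_studies_lost": _fmt_pct(m.pct_studies_lost),
                "n_participants_with": m.n_participants_with,
                "n_participants_without": m.n_participants_without,
                "pct_participants_lost": _fmt_pct(m.pct_participants_lost),
                "pooled_with": _fmt_est(m.with_result),
                "summary_measure": m.with_result.measure.value,
                "pooled_without": _fmt_est(m.without_result),
                "pct_change_point": _fmt_pct(m.pct_change_point),
                "pct_change_ci_width": _fmt_pct(m.pct_change_ci_width),
                "category": m.category.value,
                "significance_flip": m.significance_flip.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "study_type",
            "review_id",
            "n_studies_with",
            "n_studies_without",
            "pct_studies_lost",
            "n_participants_with",
            "n_participants_without",
            "pct_participants_lost",
            "pooled_with",
            "summary_measure",
            "pooled_without",
            "pct_change_point",
            "pct_change_ci_width",
            "category",
            "significance_flip",
        ],
    )


def _to_markdown(frame: pd.DataFrame) -> str:
    cols = list(frame.columns)
    lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for _, row in frame.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def write_reports(summary: CorpusSummary, impacts: list, outdir) -> dict:
    """Write the searching/inclusion summary and the impact rows.

    Produces ``summary.csv``/``summary.md`` and ``impacts.csv``/
    ``impacts.md`` under ``outdir``; output bytes are deterministic for
    identical inputs.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for stem, frame in (
        ("summary", _summary_frame(summary)),
        ("impacts", _impact_frame(impacts)),
    ):
        csv_path, md_path = outdir / f"{stem}.csv", outdir / f"{stem}.md"
        csv_path.write_text(frame.to_csv(index=False), encoding="utf-8")
        md_path.write_text(_to_markdown(frame), encoding="utf-8")
        paths[f"{stem}_csv"], paths[f"{stem}_md"] = csv_path, md_path
    return paths


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceRow:
    """One published with/without sensitivity re-analysis row."""

    study_type: StudyTypeLabel
    review_id: str
    group: str
    title: str
    n_studies_with: int
    n_studies_without: int
    pct_studies_lost_printed: float
    n_participants_with: Optional[int]
    n_participants_without: Optional[int]
    pct_participants_lost_printed: Optional[float]
    measure: SummaryMeasure
    with_point: float
    with_ci: tuple
    without_point: Optional[float]
    without_ci: Optional[tuple]
    pct_change_point_printed: str
    pct_change_ci_width_printed: str
    category_printed: str
    sig_flip_printed: str

    @property
    def all_removed(self) -> bool:
        return self.n_studies_without == 0


def _opt_float(value) -> Optional[float]:
    return None if _is_missing(value) or value == "NA" else float(value)


def _reference_path(name: str):
    return resources.files("greymeta").joinpath("data", name)


def load_reference_rows() -> list:
    """The 32 published with/without rows (grey-literature exclusions)."""
    with resources.as_file(_reference_path("grey_impact_reference.csv")) as p:
        frame = pd.read_csv(p, dtype=str, keep_default_na=False)
    rows = []
    for _, r in frame.iterrows():
        wo_pt = _opt_float(r["without_point"])
        wo_lo, wo_hi = _opt_float(r["without_low"]), _opt_float(r["without_high"])
        rows.append(
            ReferenceRow(
                study_type=StudyTypeLabel(r["study_type"]),
                review_id=r["review_id"],
                group=r["group"],
                title=r["title"],
                n_studies_with=int(r["n_studies_with"]),
                n_studies_without=int(r["n_studies_without"]),
                pct_studies_lost_printed=float(r["pct_studies_lost_printed"]),
                n_participants_with=(
                    None
                    if _is_missing(r["n_participants_with"])
                    else int(r["n_participants_with"])
                ),
                n_participants_without=(
                    None
                    if _is_missing(r["n_participants_without"])
                    else int(r["n_participants_without"])
                ),
                pct_participants_lost_printed=_opt_float(
                    r["pct_participants_lost_printed"]
                ),
                measure=SummaryMeasure(r["measure"]),
                with_point=float(r["with_point"]),
                with_ci=(float(r["with_low"]), float(r["with_high"])),
                without_point=wo_pt,
                without_ci=None if wo_lo is None else (wo_lo, wo_hi),
                pct_change_point_printed=r["pct_change_point_printed"],
                pct_change_ci_width_printed=r["pct_change_ci_width_printed"],
                category_printed=r["category_printed"],
                sig_flip_printed=r["sig_flip_printed"],
            )
        )
    return rows


def load_reference_counts() -> pd.DataFrame:
    """Published searching/inclusion counts per group and study type."""
    with resources.as_file(
        _reference_path("search_inclusion_reference.csv")
    ) as p:
        frame = pd.read_csv(p)
    return frame
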