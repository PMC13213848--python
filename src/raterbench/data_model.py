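"""Core data structures and I/O for multi-reader probabilistic assessment studies.

A *study* is a complete subjects × raters grid in which every observer (an
automated classifier or a human reader) assigns one probability vector over a
fixed set of diagnostic categories to every subject, and every subject carries
a ground-truth label.  The default category set is the seven-way dementia
differential (CN, AD, bvFTD, SD, PNFA, PSP, DLB) with binary truth restricted
to CN vs AD.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_CODES: tuple[str, ...] = ("CN", "AD", "BVFTD", "SD", "PNFA", "PSP", "DLB")

_ID_COLUMNS = ("subject_id", "rater_id")


class UndefinedStatistic(Exception):
    """A statistic that is mathematically undefined on the given data.

    Carries a machine-readable ``reason`` so reports can serialize the field
    as an explicit null instead of silently dropping it.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class CategorySet:
    """Ordered diagnostic categories plus the binary-collapse convention.

    ``positive`` is the disease class and ``negative`` the normal class used
    whenever a seven-way assessment is collapsed to a binary CN-vs-AD metric.
    """

    codes: tuple[str, ...] = DEFAULT_CODES
    positive: str = "AD"
    negative: str = "CN"

    def __post_init__(self) -> None:
        if len(self.codes) == 0:
            raise ValueError("category set must be non-empty")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("category codes must be unique")
        if self.positive == self.negative:
            raise ValueError("positive and negative classes must differ")
        for code in (self.positive, self.negative):
            if code not in self.codes:
                raise ValueError(f"{code!r} is not a member of the category set")

    @property
    def n(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        return self.codes.index(code)

    @property
    def positive_index(self) -> int:
        return self.index(self.positive)

    @property
    def negative_index(self) -> int:
        return self.index(self.negative)

    def match_column(self, name: str) -> str | None:
        """Case-insensitive lookup of a column name against the codes."""
        lowered = {c.lower(): c for c in self.codes}
        return lowered.get(name.strip().lower())


def normalize_probs(
    values: Sequence[float] | np.ndarray,
    *,
    expected_total: float = 1.0,
    tol: float = 0.005,
) -> np.ndarray:
    """Validate and renormalize one probability vector to sum exactly 1.

    ``tol`` is relative to ``expected_total`` (default 0.5% of total mass), so
    percent-scale rows summing to 99.8 pass under the default tolerance.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("probability vector must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError("probability vector contains non-finite values")
    if np.any(arr < 0):
        raise ValueError("negative probability")
    total = float(arr.sum())
    if total <= 0:
        raise ValueError("no normalizable mass (all-zero probability vector)")
    if abs(total - expected_total) > tol * expected_total:
        raise ValueError(
            f"vector sum {total:g} deviates from expected total "
            f"{expected_total:g} by more than tolerance {tol:g}"
        )
    return arr / total


@dataclass
class AssessmentTable:
    """Complete N subjects × R raters grid of category-probability vectors.

    ``probs`` is indexed by (subject_id, rater_id) with one column per
    category code, each row summing to 1; ``truth`` maps subject_id to a
    category code.
    """

    categories: CategorySet
    subjects: tuple[str, ...]
    raters: tuple[str, ...]
    truth: pd.Series
    probs: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        subjects: Sequence[str],
        raters: Sequence[str],
        truth: Mapping[str, str] | Sequence[str],
        probs: Mapping[str, np.ndarray],
        categories: CategorySet | None = None,
    ) -> "AssessmentTable":
        """Build a table from per-rater (n_subjects × n_categories) arrays."""
        categories = categories or CategorySet()
        subjects = tuple(str(s) for s in subjects)
        raters = tuple(str(r) for r in raters)
        if not isinstance(truth, Mapping):
            truth = dict(zip(subjects, truth))
        index = pd.MultiIndex.from_product(
            [subjects, raters], names=["subject_id", "rater_id"]
        )
        mats = {r: np.asarray(probs[r], dtype=float) for r in raters}
        rows = [mats[rater][i] for i in range(len(subjects)) for rater in raters]
        frame = pd.DataFrame(rows, index=index, columns=list(categories.codes))
        truth_series = pd.Series(
            [str(truth[s]) for s in subjects], index=list(subjects), name="truth"
        )
        return cls(categories, subjects, raters, truth_series, frame)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        codes = self.categories.codes
        if tuple(self.probs.columns) != codes:
            raise ValueError("probability columns do not match the category set")
        expected = pd.MultiIndex.from_product(
            [self.subjects, self.raters], names=["subject_id", "rater_id"]
        )
        if len(self.probs) != len(expected) or not self.probs.index.equals(expected):
            # order-insensitive completeness check with a precise error
            have = set(self.probs.index)
            want = set(expected)
            missing = want - have
            extra = have - want
            if missing or extra or len(self.probs) != len(expected):
                raise ValueError(
                    f"incomplete subject × rater grid "
                    f"(missing {len(missing)}, unexpected {len(extra)})"
                )
            self.probs = self.probs.reindex(expected)
        values = self.probs.to_numpy()
        if np.any(values < -1e-12):
            raise ValueError("negative probability in assessment table")
        sums = values.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("probability vectors must sum to 1 within 1e-6")
        for subject, label in self.truth.items():
            if label not in codes:
                raise ValueError(f"truth label {label!r} for {subject!r} not in category set")
        if set(self.truth.index) != set(self.subjects):
            raise ValueError("truth table does not cover exactly the study subjects")

    # -- accessors --------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def rater_probs(self, rater: str) -> np.ndarray:
        """(n_subjects × n_categories) array for one rater, in subject order."""
        if rater not in self.raters:
            raise KeyError(f"unknown rater {rater!r}")
        sub = self.probs.xs(rater, level="rater_id")
        return sub.loc[list(self.subjects)].to_numpy()

    def positive_scores(self, rater: str) -> np.ndarray:
        """Continuous disease-class (AD) probability channel for one rater."""
        return self.rater_probs(rater)[:, self.categories.positive_index]

    def truth_labels(self) -> np.ndarray:
        return np.asarray([self.truth[s] for s in self.subjects])

    def binary_truth(self) -> np.ndarray:
        """1 for the positive (AD) class, 0 for the negative (CN) class."""
        pos, neg = self.categories.positive, self.categories.negative
        labels = self.truth_labels()
        bad = set(labels) - {pos, neg}
        if bad:
            raise ValueError(
                f"binary metrics require truth restricted to "
                f"{{{neg}, {pos}}}; found {sorted(bad)}"
            )
        return (labels == pos).astype(int)

    @property
    def n_pos(self) -> int:
        return int(self.binary_truth().sum())

    @property
    def n_neg(self) -> int:
        return self.n_subjects - self.n_pos


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _resolve_scale(scale: str, row_sums: np.ndarray) -> float:
    if scale == "percent":
        return 100.0
    if scale == "fraction":
        return 1.0
    if scale == "auto":
        # explicit opt-in: decide from the median row total
        return 100.0 if float(np.median(row_sums)) > 50.0 else 1.0
    raise ValueError("scale must be 'percent', 'fraction' or 'auto'")


def read_assessments(
    csv_path,
    truth_path,
    *,
    categories: CategorySet | None = None,
    scale: str = "fraction",
    sum_tol: float = 0.005,
) -> AssessmentTable:
    """Read an assessment grid and its truth table from CSV files.

    The assessment CSV must have columns ``subject_id, rater_id`` plus exactly
    one column per category code (matched case-insensitively; extra columns
    are an error).  ``scale`` declares whether probabilities are recorded as
    percentages or fractions; ``"auto"`` (an explicit opt-in) infers the scale
    from the median row total.  Rows are renormalized to sum exactly 1 after a
    tolerance check of ``sum_tol`` (relative to the declared total mass).
    """
    categories = categories or CategorySet()
    df = pd.read_csv(csv_path, dtype={"subject_id": str, "rater_id": str})

    colmap: dict[str, str] = {}
    for col in df.columns:
        if col.strip().lower() in _ID_COLUMNS:
            colmap[col] = col.strip().lower()
            continue
        code = categories.match_column(col)
        if code is None:
            raise ValueError(f"unexpected column {col!r} in assessment table")
        colmap[col] = code
    df = df.rename(columns=colmap)
    missing_cols = [c for c in (*_ID_COLUMNS, *categories.codes) if c not in df.columns]
    if missing_cols:
        raise ValueError(f"assessment table is missing columns {missing_cols}")

    dup = df.duplicated(subset=["subject_id", "rater_id"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["subject_id", "rater_id"]].tolist()
        raise ValueError(f"duplicate (subject, rater) row: {tuple(pair)}")

    raw = df[list(categories.codes)].to_numpy(dtype=float)
    total = _resolve_scale(scale, raw.sum(axis=1))
    vectors = np.vstack(
        [normalize_probs(row, expected_total=total, tol=sum_tol) for row in raw]
    )

    subjects = tuple(dict.fromkeys(df["subject_id"]))
    raters = tuple(dict.fromkeys(df["rater_id"]))
    index = pd.MultiIndex.from_frame(df[["subject_id", "rater_id"]])
    probs = pd.DataFrame(vectors, index=index, columns=list(categories.codes))
    # reorder subject-major for the canonical grid layout
    expected = pd.MultiIndex.from_product(
        [subjects, raters], names=["subject_id", "rater_id"]
    )
    if set(probs.index) != set(expected):
        raise ValueError("incomplete subject × rater grid in assessment table")
    probs = probs.reindex(expected)

    tdf = pd.read_csv(truth_path, dtype=str)
    tdf.columns = [c.strip().lower() for c in tdf.columns]
    if list(tdf.columns) != ["subject_id", "truth"]:
        raise ValueError("truth table must have columns subject_id,truth")
    labels = {}
    for _, row in tdf.iterrows():
        code = categories.match_column(row["truth"])
        if code is None:
            raise ValueError(f"truth label {row['truth']!r} not in category set")
        labels[row["subject_id"]] = code
    truth = pd.Series([labels[s] for s in subjects], index=list(subjects), name="truth")
    return AssessmentTable(categories, subjects, raters, truth, probs)


def write_assessments(table: AssessmentTable, csv_path, truth_path) -> None:
    """Write a study back to CSV (fraction scale, full float precision)."""
    out = table.probs.reset_index()
    with open(csv_path, "w") as fh:
        fh.write(",".join(["subject_id", "rater_id", *table.categories.codes]) + "\n")
        for _, row in out.iterrows():
            vals = [repr(float(row[c])) for c in table.categories.codes]
            fh.write(",".join([row["subject_id"], row["rater_id"], *vals]) + "\n")
    with open(truth_path, "w") as fh:
        fh.write("subject_id,truth\n")
        for subject in table.subjects:
            fh.write(f"{subject},{table.truth[subject]}\n")


# ---------------------------------------------------------------------------
# Metric report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Container for every statistic a full evaluation run produces.

    Sections are plain (JSON-serializable) nested dicts; statistics that are
    undefined on the data appear as ``None`` accompanied by a sibling
    ``<name>_reason`` string.  Serialization is canonical (sorted keys) so
    identical runs produce byte-identical files.
    """

    provenance: dict[str, Any] = field(default_factory=dict)
    classification: dict[str, Any] = field(default_factory=dict)
    agreement: dict[str, Any] = field(default_factory=dict)
    discrimination: dict[str, Any] = field(default_factory=dict)
    delong: dict[str, Any] = field(default_factory=dict)
    decision_reference: dict[str, Any] = field(default_factory=dict)
    power: dict[str, Any] | None = None

    _SECTIONS = (
        "provenance",
        "classification",
        "agreement",
        "discrimination",
        "delong",
        "decision_reference",
        "power",
    )

    def to_dict(self) -> dict[str, Any]:
        return {name: getattr(self, name) for name in self._SECTIONS}

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "MetricReport":
        return cls(**{name: data.get(name) or ({} if name != "power" else None)
                      for name in cls._SECTIONS})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, allow_nan=False)


def write_report(report: MetricReport, path) -> None:
    """Serialize a report as canonical JSON (deterministic byte layout)."""
    with open(path, "w") as fh:
        fh.write(report.to_json())
        fh.write("\n")


def read_report(path) -> MetricReport:
    with open(path) as fh:
        return MetricReport.from_dict(json.load(fh))


def config_digest(config: Mapping[str, Any]) -> str:
    """Stable SHA-256 digest of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
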