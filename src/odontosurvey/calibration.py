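"""Examiner calibration against team consensus via weighted kappa.

Before field work, every examiner re-examines the same mouths and their
per-tooth ratings are compared with the rating the team agrees on (the
consensus technique).  Agreement is measured with Cohen's weighted
kappa,

    kappa_w = 1 - (sum_ij w_ij O_ij / n) / (sum_ij w_ij E_ij / n)

where O is the observed cross-tabulation, E_ij = row_i * col_j / n the
expected table under independence, and the disagreement weights are
w_ij = |i - j| / (K - 1) (linear, the default), ((i - j) / (K - 1))^2
(quadratic), or the 0/1 indicator (unweighted).  An examiner passes
when kappa reaches the acceptance threshold (default 0.65, inclusive).

Ratings are ordinal: categories are ordered by severity (for dental
calibration, the crown-code alphabet order), which also supplies the
consensus tie-break — ties go to the more severe category, the
conservative choice for a screening instrument.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Literal, Mapping, Sequence

import numpy as np

from .model import SurveyValidationError

WeightScheme = Literal["linear", "quadratic", "unweighted"]

DEFAULT_KAPPA_THRESHOLD = 0.65


@dataclass(frozen=True)
class AgreementTable:
    """Examiner-vs-reference cross-tabulation over ordered categories."""

    categories: tuple[Hashable, ...]
    counts: np.ndarray  # (K, K); entry (i, j): examiner said i, reference j

    def __post_init__(self) -> None:
        k = len(self.categories)
        if k < 2:
            raise SurveyValidationError("need at least 2 rating categories")
        if self.counts.shape != (k, k):
            raise SurveyValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{k} categories"
            )
        if (self.counts < 0).any():
            raise SurveyValidationError("negative cell count")
        if self.counts.sum() <= 0:
            raise SurveyValidationError("empty agreement table")

    @property
    def n_items(self) -> int:
        return int(self.counts.sum())


def build_agreement_table(
    examiner_ratings: Sequence[Hashable],
    reference_ratings: Sequence[Hashable],
    categories: Sequence[Hashable],
) -> AgreementTable:
    """Cross-tabulate paired rating vectors over an ordered category list."""
    if len(examiner_ratings) != len(reference_ratings):
        raise SurveyValidationError(
            f"rating vectors differ in length: {len(examiner_ratings)} vs "
            f"{len(reference_ratings)}"
        )
    index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)), dtype=np.int64)
    for e, r in zip(examiner_ratings, reference_ratings):
        if e not in index:
            raise SurveyValidationError(f"examiner rating {e!r} not a category")
        if r not in index:
            raise SurveyValidationError(f"reference rating {r!r} not a category")
        counts[index[e], index[r]] += 1
    return AgreementTable(tuple(categories), counts)


def disagreement_weights(k: int, scheme: WeightScheme) -> np.ndarray:
    """K x K disagreement-weight matrix: 0 on the diagonal, growing with
    category distance under the linear and quadratic schemes."""
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if scheme == "linear":
        return np.abs(i - j) / (k - 1)
    if scheme == "quadratic":
        return ((i - j) / (k - 1)) ** 2
    if scheme == "unweighted":
        return (i != j).astype(float)
    raise SurveyValidationError(f"unknown weight scheme: {scheme!r}")


@dataclass(frozen=True)
class KappaResult:
    """Weighted kappa with its disagreement decomposition."""

    kappa: float
    scheme: WeightScheme
    observed_disagreement: float
    expected_disagreement: float
    n_items: int
    degenerate: bool = False  # all mass in one cell: kappa defined as 1

    def passes(self, threshold: float = DEFAULT_KAPPA_THRESHOLD) -> bool:
        return self.kappa >= threshold


def weighted_kappa(
    table: AgreementTable, scheme: WeightScheme = "linear"
) -> KappaResult:
    """Cohen's weighted kappa from an agreement table.

    A degenerate table (all mass in one cell, expected disagreement 0)
    has no chance correction to make; the result is kappa = 1 with the
    ``degenerate`` flag set.
    """
    n = table.n_items
    p = table.counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    expected = np.outer(row, col)
    w = disagreement_weights(len(table.categories), scheme)
    observed_dis = float((w * p).sum())
    expected_dis = float((w * expected).sum())
    if expected_dis == 0.0:
        return KappaResult(1.0, scheme, observed_dis, expected_dis, n, True)
    return KappaResult(
        1.0 - observed_dis / expected_dis, scheme, observed_dis, expected_dis, n
    )


def consensus_rating(
    votes: Sequence[Hashable], severity_order: Sequence[Hashable]
) -> Hashable:
    """Consensus category for one item: majority vote, ties broken by the
    more severe category under the given ordering."""
    if not votes:
        raise SurveyValidationError("no votes for item")
    rank = {c: i for i, c in enumerate(severity_order)}
    for v in votes:
        if v not in rank:
            raise SurveyValidationError(f"vote {v!r} not in severity order")
    tally = Counter(votes)
    best = max(tally)  # placeholder, replaced below
    best_count = -1
    best_rank = -1
    for cat, count in tally.items():
        r = rank[cat]
        if count > best_count or (count == best_count and r > best_rank):
            best, best_count, best_rank = cat, count, r
    return best


def consensus_ratings(
    votes_per_item: Sequence[Sequence[Hashable]],
    severity_order: Sequence[Hashable],
) -> list[Hashable]:
    """Per-item consensus over a whole calibration session."""
    return [consensus_rating(v, severity_order) for v in votes_per_item]


@dataclass
class CalibrationReport:
    """Pass/fail gate over per-(examiner, age group, condition) kappas."""

    threshold: float
    entries: list[tuple[tuple[str, str, str], KappaResult, bool]] = field(
        default_factory=list
    )

    @property
    def failing(self) -> list[tuple[str, str, str]]:
        return [key for key, _, ok in self.entries if not ok]

    @property
    def all_pass(self) -> bool:
        return not self.failing

    def to_rows(self) -> list[dict]:
        return [
            {
                "examiner": key[0],
                "age_group": key[1],
                "condition": key[2],
                "kappa": res.kappa,
                "scheme": res.scheme,
                "n_items": res.n_items,
                "passes": ok,
            }
            for key, res, ok in self.entries
        ]

    def write_csv(self, path: str | Path) -> None:
        rows = self.to_rows()
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]) if rows else [
                "examiner", "age_group", "condition", "kappa", "scheme",
                "n_items", "passes",
            ])
            writer.writeheader()
            writer.writerows(rows)


def calibration_gate(
    results: Mapping[tuple[str, str, str], KappaResult],
    threshold: float = DEFAULT_KAPPA_THRESHOLD,
) -> CalibrationReport:
    """Apply the acceptance threshold to per-stratum kappa results.

    The threshold is inclusive: kappa equal to the minimum acceptable
    limit passes.
    """
    if not -1.0 <= threshold <= 1.0:
        raise SurveyValidationError(f"threshold {threshold} outside [-1, 1]")
    report = CalibrationReport(threshold=threshold)
    for key in sorted(results):
        res = results[key]
        report.entries.append((key, res, res.passes(threshold)))
    return report


def read_ratings_csv(
    path: str | Path,
) -> dict[str, dict[str, str]]:
    """Read calibration ratings from CSV (item_id, examiner_id, category).

    Returns ``{examiner_id: {item_id: category}}``.
    """
    out: dict[str, dict[str, str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"item_id", "examiner_id", "category"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise SurveyValidationError(
                f"ratings CSV must have columns {sorted(required)}"
            )
        for row in reader:
            out.setdefault(row["examiner_id"], {})[row["item_id"]] = row[
                "category"
            ]
    return out


def calibrate_from_ratings(
    ratings: Mapping[str, Mapping[str, Hashable]],
    categories: Sequence[Hashable],
    scheme: WeightScheme = "linear",
    threshold: float = DEFAULT_KAPPA_THRESHOLD,
    age_group: str = "all",
    condition: str = "caries",
) -> CalibrationReport:
    """Full consensus calibration: build the per-item consensus from all
    examiners' votes, then gate each examiner's kappa against it."""
    items = sorted({i for per in ratings.values() for i in per})
    if not items:
        raise SurveyValidationError("no rated items")
    consensus: dict[str, Hashable] = {}
    for item in items:
        votes = [per[item] for per in ratings.values() if item in per]
        consensus[item] = consensus_rating(votes, categories)
    results: dict[tuple[str, str, str], KappaResult] = {}
    for examiner, per in ratings.items():
        rated = [i for i in items if i in per]
        table = build_agreement_table(
            [per[i] for i in rated],
            [consensus[i] for i in rated],
            categories,
        )
        results[(examiner, age_group, condition)] = weighted_kappa(
            table, scheme
        )
    return calibration_gate(results, threshold)
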