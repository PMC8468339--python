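"""Questionnaire scoring, reliability, item selection and group inference.

The classroom evaluation uses a 20-item multiple-choice instrument (four
options plus an explicit "I do not know" answer) administered before and
after the intervention to a control and an experimental group.  Items 1-10
cover the theoretical lecture (the "T part") and items 11-20 the practical
one (the "P part").

Two ratings are supported:

* **hits** — the number of correct answers;
* **null-expectation (NE)** — +1 per hit, -1/3 per error, 0 per
  "I do not know", so a uniformly guessing responder (4 options) scores
  zero on average.

Reliability is KR-20 for the binary hits rating and Cronbach's alpha for
the numeric NE rating; group comparisons gate a pooled two-sample t-test on
per-group Shapiro-Wilk normality, falling back to the two-sided
Mann-Whitney rank test, and report Cohen's d with the pooled standard
deviation.  A synthetic response generator emulating the deposited
23-column response file supports testing and calibration studies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RESPONSES",
    "ResponseTable",
    "PartDef",
    "GroupComparison",
    "T_PART",
    "P_PART",
    "REDUCED_T_ITEMS",
    "REDUCED_P_ITEMS",
    "ParseError",
    "UndefinedReliabilityError",
    "score_hits",
    "score_null_expectation",
    "score_table",
    "hits_matrix",
    "ne_matrix",
    "kr20",
    "cronbach_alpha",
    "corrected_item_total",
    "select_items",
    "gain",
    "cohen_d",
    "cohen_d_from_stats",
    "compare_groups",
    "generate_responses",
    "latent_shift_for_effect",
    "read_responses",
    "write_responses",
    "analysis_report",
]

logger = logging.getLogger(__name__)

RESPONSES = ("hit", "error", "dontknow")
N_ITEMS = 20
ITEM_COLUMNS = [f"item_{i:02d}" for i in range(1, N_ITEMS + 1)]

#: Item subsets of the reduced 10-item instrument (1-based indices).
REDUCED_T_ITEMS = (4, 5, 6, 8, 10)
REDUCED_P_ITEMS = (11, 12, 13, 17, 20)


class ParseError(ValueError):
    """A response file or cell could not be interpreted."""


class UndefinedReliabilityError(ValueError):
    """Reliability is undefined (zero total-score variance)."""


@dataclass(frozen=True)
class PartDef:
    """A named subset of the instrument's items (1-based indices)."""

    name: str
    item_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.item_indices:
            raise ValueError("a part needs at least one item")
        if any(not (1 <= i <= N_ITEMS) for i in self.item_indices):
            raise ValueError(f"item indices must lie in 1..{N_ITEMS}: {self.item_indices}")
        if len(set(self.item_indices)) != len(self.item_indices):
            raise ValueError("item indices must be distinct")

    @property
    def columns(self) -> list[str]:
        return [ITEM_COLUMNS[i - 1] for i in self.item_indices]


T_PART = PartDef("T", tuple(range(1, 11)))
P_PART = PartDef("P", tuple(range(11, 21)))


class ResponseTable:
    """Per-participant questionnaire responses for one or both test phases.

    Wraps a DataFrame with columns ``participant_id``, ``phase``
    (pre/post), ``group`` (control/experimental) and 20 item columns with
    values in ``{"hit", "error", "dontknow"}`` — mirroring the 23-column
    layout of the deposited response spreadsheet.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        required = ["participant_id", "phase", "group", *ITEM_COLUMNS]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ParseError(f"missing columns: {missing}")
        df = df[required].copy()
        bad_phase = set(df["phase"]) - {"pre", "post"}
        if bad_phase:
            raise ParseError(f"unknown phase values: {sorted(bad_phase)}")
        bad_group = set(df["group"]) - {"control", "experimental"}
        if bad_group:
            raise ParseError(f"unknown group values: {sorted(bad_group)}")
        for col in ITEM_COLUMNS:
            bad = set(df[col]) - set(RESPONSES)
            if bad:
                raise ParseError(f"column {col}: unknown response tokens {sorted(bad)}")
        dup = df.duplicated(subset=["participant_id", "phase"])
        if dup.any():
            raise ParseError(
                f"duplicated (participant, phase) rows: {df.loc[dup, 'participant_id'].tolist()}"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def phase(self, phase: Literal["pre", "post"]) -> pd.DataFrame:
        return self.df[self.df["phase"] == phase]


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_hits(row: Mapping[str, str], part: PartDef) -> int:
    """Number of correct answers among the part's items."""
    score = 0
    for col in part.columns:
        resp = row[col]
        if resp not in RESPONSES:
            raise ParseError(f"unknown response token {resp!r} in {col}")
        score += resp == "hit"
    return score

def score_null_expectation(row: Mapping[str, str], part: PartDef) -> float:
    """+1 per hit, -1/3 per error, 0 per "I do not know"."""
    score = 0.0
    for col in part.columns:
        resp = row[col]
        if resp not in RESPONSES:
            raise ParseError(f"unknown response token {resp!r} in {col}")
        if resp == "hit":
            score += 1.0
        elif resp == "error":
            score -= 1.0 / 3.0
    return score


def score_table(
    table: ResponseTable,
    part: PartDef,
    rating: Literal["hits", "ne"] = "hits",
) -> pd.DataFrame:
    """Per-row scores: columns participant_id, phase, group, score."""
    raw = table.df[part.columns].to_numpy()
    if rating == "hits":
        scores = (raw == "hit").sum(axis=1).astype(int)
    else:
        scores = np.where(raw == "hit", 1.0, np.where(raw == "error", -1.0 / 3.0, 0.0)).sum(axis=1)
    out = table.df[["participant_id", "phase", "group"]].copy()
    out["score"] = scores
    return out


def hits_matrix(table: ResponseTable, part: PartDef, phase: str) -> np.ndarray:
    """Binary participants x items matrix (1 = hit) for one phase."""
    sub = table.phase(phase)  # type: ignore[arg-type]
    return (sub[part.columns].to_numpy() == "hit").astype(float)


def ne_matrix(table: ResponseTable, part: PartDef, phase: str) -> np.ndarray:
    """Numeric participants x items matrix under the NE rating."""
    sub = table.phase(phase)  # type: ignore[arg-type]
    raw = sub[part.columns].to_numpy()
    return np.where(raw == "hit", 1.0, np.where(raw == "error", -1.0 / 3.0, 0.0))


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------

def _total_variance(matrix: np.ndarray) -> float:
    totals = matrix.sum(axis=1)
    var = float(np.var(totals, ddof=1))
    if var <= 0:
        raise UndefinedReliabilityError("total-score variance is zero; reliability undefined")
    return var


def kr20(matrix: np.ndarray) -> float:
    """Kuder-Richardson formula 20 on a binary participants x items matrix.

    Uses item proportions ``p_i`` computed with n and the unbiased (n-1)
    variance of the total scores:
    ``KR20 = k/(k-1) * (1 - sum(p_i q_i) / var(total))``.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 participants and 2 items")
    if not np.isin(matrix, (0.0, 1.0)).all():
        raise ValueError("kr20 requires a binary (0/1) matrix")
    p = matrix.mean(axis=0)
    pq = p * (1 - p)
    return k / (k - 1) * (1 - pq.sum() / _total_variance(matrix))


def cronbach_alpha(matrix: np.ndarray, ddof_items: int = 1) -> float:
    """Cronbach's alpha on a numeric participants x items matrix.

    ``alpha = k/(k-1) * (1 - sum(var_i) / var(total))`` with the unbiased
    (n-1) convention throughout by default.  ``ddof_items=0`` switches the
    item variances to the biased (n) convention, under which alpha on a
    binary matrix coincides exactly with :func:`kr20` (whose ``p_i q_i``
    terms are biased Bernoulli variances).
    """
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 participants and 2 items")
    item_vars = np.var(matrix, axis=0, ddof=ddof_items)
    return k / (k - 1) * (1 - item_vars.sum() / _total_variance(matrix))


def corrected_item_total(matrix: np.ndarray, item: int) -> float:
    """Pearson correlation of one item with the total of the other items."""
    matrix = np.asarray(matrix, dtype=float)
    x = matrix[:, item]
    rest = matrix.sum(axis=1) - x
    if np.std(x) == 0 or np.std(rest) == 0:
        return -np.inf
    return float(np.corrcoef(x, rest)[0, 1])


def select_items(
    matrix: np.ndarray,
    part: PartDef,
    target_size: int,
) -> PartDef:
    """Greedy backward elimination maximizing KR-20.

    ``matrix`` holds the binary post-test hits for the part's items (in the
    part's column order).  Items are dropped one at a time — each step
    removing the item whose removal maximizes KR-20 of the remainder — until
    ``target_size`` remain.  Ties are broken by the lowest corrected
    item-total correlation, then by the lowest original item index.
    """
    matrix = np.asarray(matrix, dtype=float)
    if target_size > len(part.item_indices):
        raise ValueError("target_size exceeds the part size")
    keep = list(range(len(part.item_indices)))
    while len(keep) > target_size:
        best: tuple | None = None
        for pos, _ in enumerate(keep):
            remaining = [c for i, c in enumerate(keep) if i != pos]
            try:
                rel = kr20(matrix[:, remaining])
            except UndefinedReliabilityError:
                rel = -np.inf
            r_it = corrected_item_total(matrix[:, keep], pos)
            # maximize rel; tie -> lowest item-total r; tie -> lowest index
            key = (-round(rel, 12), round(r_it, 12), part.item_indices[keep[pos]])
            if best is None or key < best[0]:
                best = (key, pos)
        assert best is not None
        del keep[best[1]]
    return PartDef(part.name, tuple(part.item_indices[i] for i in keep))


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Two-group comparison summary mirroring the evaluation tables."""

    test_used: Literal["t", "rank"]
    p_value: float
    median_eg: float
    median_cg: float
    mean_eg: float
    mean_cg: float
    sd_eg: float
    sd_cg: float
    effect_size_d: float
    n_eg: int
    n_cg: int


def gain(
    post_scores: pd.DataFrame | pd.Series,
    pre_scores: pd.DataFrame | pd.Series,
) -> pd.Series:
    """Per-participant gain = post - pre, matched on participant id.

    Accepts either the output of :func:`score_table` (one phase each) or
    Series indexed by participant id.  Unmatched participants are excluded
    with a logged count.
    """
    def as_series(obj) -> pd.Series:
        if isinstance(obj, pd.DataFrame):
            return obj.set_index("participant_id")["score"]
        return obj

    post = as_series(post_scores)
    pre = as_series(pre_scores)
    common = post.index.intersection(pre.index)
    dropped = len(set(post.index).symmetric_difference(pre.index))
    if len(common) == 0:
        raise ValueError("no participants present in both phases")
    if dropped:
        logger.info("gain: excluded %d unmatched participants", dropped)
    return (post.loc[common] - pre.loc[common]).astype(float)


def cohen_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation (x = EG, y = CG)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return cohen_d_from_stats(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def cohen_d_from_stats(
    mean_eg: float, sd_eg: float, n_eg: int,
    mean_cg: float, sd_cg: float, n_cg: int,
) -> float:
    """Cohen's d from group summary statistics.

    ``d = (m_EG - m_CG) / sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2))``;
    with equal n the denominator reduces to ``sqrt((s1^2 + s2^2)/2)``.
    """
    pooled = math.sqrt(
        ((n_eg - 1) * sd_eg**2 + (n_cg - 1) * sd_cg**2) / (n_eg + n_cg - 2)
    )
    if pooled == 0:
        return 0.0
    return (mean_eg - mean_cg) / pooled


def compare_groups(
    eg_scores: Iterable[float],
    cg_scores: Iterable[float],
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sided unpaired comparison of experimental vs control scores.

    A Shapiro-Wilk test is run on each group; if both pass at ``alpha`` a
    pooled-variance two-sample t-test is used, otherwise the two-sided
    Mann-Whitney rank test.  Descriptives (median, mean, unbiased SD) and
    pooled-SD Cohen's d are always reported.
    """
    eg = np.asarray(list(eg_scores), dtype=float)
    cg = np.asarray(list(cg_scores), dtype=float)
    if len(eg) < 3 or len(cg) < 3:
        raise ValueError("each group needs at least 3 observations for the normality gate")
    normal = all(
        np.ptp(g) > 0 and stats.shapiro(g).pvalue > alpha for g in (eg, cg)
    )
    if normal:
        test_used: Literal["t", "rank"] = "t"
        p = float(stats.ttest_ind(eg, cg, equal_var=True).pvalue)
    else:
        test_used = "rank"
        p = float(stats.mannwhitneyu(eg, cg, alternative="two-sided").pvalue)
    return GroupComparison(
        test_used=test_used,
        p_value=p,
        median_eg=float(np.median(eg)),
        median_cg=float(np.median(cg)),
        mean_eg=float(eg.mean()),
        mean_cg=float(cg.mean()),
        sd_eg=float(eg.std(ddof=1)),
        sd_cg=float(cg.std(ddof=1)),
        effect_size_d=cohen_d(eg, cg),
        n_eg=len(eg),
        n_cg=len(cg),
    )


# ---------------------------------------------------------------------------
# Synthetic response generation
# ---------------------------------------------------------------------------

#: Default latent abilities per (group, phase), calibrated so that mean
#: scores on a 5-item part resemble the classroom study (low pre-test
#: scores, moderate post-test scores with an experimental-group advantage).
DEFAULT_ABILITY: dict[tuple[str, str], float] = {
    ("control", "pre"): -0.7,
    ("experimental", "pre"): -0.7,
    ("control", "post"): 0.85,
    ("experimental", "post"): 1.95,
}


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def generate_responses(
    n_per_group: int = 30,
    difficulties: Sequence[float] | float = 1.0,
    ability: Mapping[tuple[str, str], float] | None = None,
    dontknow: float = 0.3,
    seed: int = 0,
    ability_sd: float = 0.0,
) -> ResponseTable:
    """Synthetic two-group, two-phase response table (deposited-file schema).

    Per item the responder answers "I do not know" with probability
    ``dontknow``; otherwise the answer is a hit with probability
    ``logistic(ability - difficulty)`` and an error otherwise.  ``ability``
    maps (group, phase) to the latent ability; the default emulates the
    classroom conditions (both groups start low, both improve, the
    experimental group more).  ``ability_sd`` adds a per-participant ability
    trait (constant across phases), which induces the inter-item correlation
    real cohorts show; the default 0 keeps responders exchangeable, under
    which the score distribution of a shift has a closed form (see
    :func:`latent_shift_for_effect`).  Deterministic given the seed.
    """
    if not (0 <= dontknow <= 1):
        raise ValueError("dontknow propensity must lie in [0, 1]")
    diffs = np.broadcast_to(np.asarray(difficulties, dtype=float), (N_ITEMS,))
    ability = dict(DEFAULT_ABILITY if ability is None else ability)
    rng = np.random.default_rng(seed)
    frames = []
    pid_base = 0
    for group in ("experimental", "control"):
        ids = [f"S{pid_base + i + 1:04d}" for i in range(n_per_group)]
        trait = rng.normal(0.0, ability_sd, n_per_group) if ability_sd > 0 else 0.0
        for phase in ("pre", "post"):
            a = ability[(group, phase)] + trait
            u = rng.random((n_per_group, N_ITEMS))
            v = rng.random((n_per_group, N_ITEMS))
            is_dk = u < dontknow
            is_hit = ~is_dk & (v < _logistic(np.subtract.outer(a, diffs) if np.ndim(a) else a - diffs))
            resp = np.where(is_dk, "dontknow", np.where(is_hit, "hit", "error"))
            block = pd.DataFrame(resp, columns=ITEM_COLUMNS)
            block.insert(0, "participant_id", ids)
            block.insert(1, "phase", phase)
            block.insert(2, "group", group)
            frames.append(block)
        pid_base += n_per_group
    return ResponseTable(pd.concat(frames, ignore_index=True))


def latent_shift_for_effect(
    d_target: float,
    part: PartDef,
    difficulties: Sequence[float] | float = 1.0,
    base_ability: float = 0.85,
    dontknow: float = 0.3,
) -> float:
    """Latent ability shift producing a given score-scale Cohen's d.

    Under the generator's response model the part score is a sum of
    independent Bernoulli hits with probabilities
    ``q_i = (1 - dontknow) * logistic(ability - b_i)``, so the population
    mean and variance of both groups — and hence the population Cohen's d
    of a shift — have closed forms; the shift is solved numerically.
    """
    diffs = np.broadcast_to(np.asarray(difficulties, dtype=float), (N_ITEMS,))
    b = diffs[[i - 1 for i in part.item_indices]]

    def moments(a: float) -> tuple[float, float]:
        q = (1 - dontknow) * _logistic(a - b)
        return float(q.sum()), float((q * (1 - q)).sum())

    m0, v0 = moments(base_ability)

    def d_of(delta: float) -> float:
        m1, v1 = moments(base_ability + delta)
        return (m1 - m0) / math.sqrt((v0 + v1) / 2.0)

    if d_target == 0:
        return 0.0
    return float(optimize.brentq(lambda x: d_of(x) - d_target, -20, 20))


# ---------------------------------------------------------------------------
# Response-file I/O (23-column deposited layout)
# ---------------------------------------------------------------------------

_PHASE_ALIASES = {"pre": "pre", "pre-test": "pre", "pretest": "pre",
                  "post": "post", "post-test": "post", "posttest": "post"}
_GROUP_ALIASES = {"control": "control", "c": "control", "cg": "control",
                  "experimental": "experimental", "e": "experimental",
                  "eg": "experimental", "x": "experimental"}


def _parse_cell(value, row: int, col: int) -> str:
    """Decode a response cell: 1 -> hit, -1/3 -> error, 0/none -> dontknow."""
    if value is None:
        return "dontknow"
    if isinstance(value, str):
        text = value.strip().lower()
        if text in ("", "none", "nan"):
            return "dontknow"
        if text in ("-1/3", "−1/3"):
            return "error"
        try:
            value = float(text)
        except ValueError:
            raise ParseError(f"row {row}, column {col}: unrecognized cell value {value!r}")
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}, column {col}: unrecognized cell value {value!r}")
    if math.isnan(x):
        return "dontknow"
    if abs(x - 1.0) < 1e-9:
        return "hit"
    if abs(x) < 1e-9:
        return "dontknow"
    if abs(x + 1.0 / 3.0) < 5e-3:
        return "error"
    raise ParseError(f"row {row}, column {col}: unrecognized cell value {value!r}")


def read_responses(path: str | Path) -> ResponseTable:
    """Read a 23-column response file (xlsx or delimited text).

    Layout: participant id, test phase, group, then 20 response cells
    encoded as 1 (hit), -1/3 (error) or 0/none ("I do not know").
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path, header=0, dtype=object)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        raw = pd.read_csv(path, sep=sep, header=0, dtype=object)
    if raw.shape[1] != 3 + N_ITEMS:
        raise ParseError(
            f"expected {3 + N_ITEMS} columns (id, test, group, {N_ITEMS} responses), "
            f"got {raw.shape[1]}"
        )
    errors: list[str] = []
    rows = []
    for r, rec in enumerate(raw.itertuples(index=False, name=None)):
        pid, phase_raw, group_raw = rec[0], rec[1], rec[2]
        phase = _PHASE_ALIASES.get(str(phase_raw).strip().lower())
        if phase is None:
            errors.append(f"row {r}: unknown test phase {phase_raw!r}")
        group = _GROUP_ALIASES.get(str(group_raw).strip().lower())
        if group is None:
            errors.append(f"row {r}: unknown group {group_raw!r}")
        items = {}
        for c, cell in enumerate(rec[3:], start=3):
            try:
                items[ITEM_COLUMNS[c - 3]] = _parse_cell(cell, r, c)
            except ParseError as exc:
                errors.append(str(exc))
        if phase and group:
            rows.append({"participant_id": str(pid), "phase": phase, "group": group, **items})
    if errors:
        raise ParseError("response file errors:\n  " + "\n  ".join(errors))
    return ResponseTable(pd.DataFrame(rows))


def write_responses(table: ResponseTable, path: str | Path) -> Path:
    """Write a table in the 23-column layout (csv/tsv or xlsx by extension)."""
    path = Path(path)
    encode = {"hit": "1", "error": "-1/3", "dontknow": "0"}
    out = table.df.copy()
    for col in ITEM_COLUMNS:
        out[col] = out[col].map(encode)
    if path.suffix.lower() in (".xlsx", ".xls"):
        out.to_excel(path, index=False)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        out.to_csv(path, sep=sep, index=False)
    return path


# ---------------------------------------------------------------------------
# Full analysis (structure of the evaluation tables)
# ---------------------------------------------------------------------------

def analysis_report(
    table: ResponseTable,
    parts: Sequence[PartDef] = (
        PartDef("T", REDUCED_T_ITEMS),
        PartDef("P", REDUCED_P_ITEMS),
    ),
    rating: Literal["hits", "ne"] = "hits",
    alpha: float = 0.05,
) -> dict:
    """Reliability + pre/post/gain group comparisons per part.

    Mirrors the structure of the evaluation tables: for each part, the
    post-test reliability (KR-20 for hits, Cronbach's alpha for NE) and a
    :class:`GroupComparison` for the pre-test scores, post-test scores and
    per-participant gains.
    """
    report: dict = {"rating": rating, "parts": {}}
    for part in parts:
        scores = score_table(table, part, rating)
        by = {
            (phase, group): scores[(scores["phase"] == phase) & (scores["group"] == group)]
            for phase in ("pre", "post")
            for group in ("control", "experimental")
        }
        matrix = (
            hits_matrix(table, part, "post") if rating == "hits" else ne_matrix(table, part, "post")
        )
        reliability = kr20(matrix) if rating == "hits" else cronbach_alpha(matrix)
        comparisons = {}
        for phase in ("pre", "post"):
            comparisons[phase] = compare_groups(
                by[(phase, "experimental")]["score"],
                by[(phase, "control")]["score"],
                alpha=alpha,
            )
        gains = {
            group: gain(by[("post", group)], by[("pre", group)])
            for group in ("experimental", "control")
        }
        comparisons["gain"] = compare_groups(gains["experimental"], gains["control"], alpha=alpha)
        report["parts"][part.name] = {
            "items": part.item_indices,
            "reliability_post": reliability,
            "comparisons": comparisons,
        }
    return report
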