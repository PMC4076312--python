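"""Handedness vs language-dominance association statistics.

Covers Edinburgh laterality-quotient scoring, its 3- and 7-level ordinal
categorizations, contingency tables, chance-corrected agreement (Cohen's
kappa with the Fleiss large-sample null standard error), Fisher exact tests
(2x2 and r x c), Spearman rank correlation, and the linear regression of
atypical-lateralization occurrence on manual-preference category mid-values.

The central scientific point these statistics serve: with ~90% right-handers
and ~90% left-language-dominance in the population, raw concordance between
hand and language dominance is high *by chance alone* (~81%), so only a
chance-corrected statistic such as kappa can tell whether the two traits are
actually coupled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "KappaResult",
    "AssociationResult",
    "FisherResult",
    "MPS7_MIDVALUES",
    "edinburgh_lq",
    "mps3",
    "mps7",
    "contingency",
    "collapse_dominance",
    "cohen_kappa",
    "fisher_exact",
    "spearman",
    "occurrence_regression",
]

MPS3_LABELS = ("Strong L", "Moderate", "Strong R")

# Mid-values of the 7 ordinal manual-preference categories, category 1
# (exclusive left) through 7 (exclusive right).
MPS7_MIDVALUES = {1: -100.0, 2: -87.0, 3: -50.0, 4: 0.0, 5: 50.0, 6: 87.0, 7: 100.0}


# ---------------------------------------------------------------------------
# Edinburgh scoring and categorization
# ---------------------------------------------------------------------------


def edinburgh_lq(right_tally: float, left_tally: float) -> float:
    """Edinburgh laterality quotient 100*(R - L)/(R + L) from item tallies."""
    total = right_tally + left_tally
    if total <= 0:
        raise ValueError("laterality quotient undefined without any tallies")
    return 100.0 * (right_tally - left_tally) / total


def _check_score(score: float) -> float:
    score = float(score)
    if not (-100.0 <= score <= 100.0):
        raise ValueError(f"manual preference score must lie in [-100, 100], got {score}")
    return score


def mps3(score: float) -> str:
    """3-level categorization: Strong L for score <= -55, Strong R only for a
    perfect +100, Moderate otherwise.  The asymmetry mirrors how the terciles
    fall in a handedness-balanced cohort: a full third of subjects score
    exactly +100."""
    score = _check_score(score)
    if score <= -55.0:
        return "Strong L"
    if score == 100.0:
        return "Strong R"
    return "Moderate"


def mps7(score: float) -> int:
    """7-level ordinal categorization (1 = exclusive left ... 7 = exclusive
    right).  The extreme categories are the single points -100 and +100;
    interior interval boundaries are resolved downward (a score of -75 falls
    in category 2, not 3)."""
    score = _check_score(score)
    if score == -100.0:
        return 1
    if score == 100.0:
        return 7
    # right-closed interior bins: (-100,-75], (-75,-25], (-25,25], (25,75], (75,100)
    edges = (-75.0, -25.0, 25.0, 75.0)
    return 2 + int(np.sum(score > np.asarray(edges)))


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------


@dataclass
class ContingencyTable:
    """Labeled count matrix with derived margins."""

    counts: np.ndarray
    row_labels: tuple
    col_labels: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be nonnegative integers")
            self.counts = self.counts.astype(int)
        self.row_labels = tuple(self.row_labels)
        self.col_labels = tuple(self.col_labels)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match the count matrix shape")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def fractions(self) -> np.ndarray:
        return self.counts / self.total

    def drop_empty(self) -> "ContingencyTable":
        """Remove all-zero rows and columns (they carry no information)."""
        rk = self.row_margins > 0
        ck = self.col_margins > 0
        return ContingencyTable(
            self.counts[np.ix_(rk, ck)],
            tuple(np.asarray(self.row_labels, dtype=object)[rk]),
            tuple(np.asarray(self.col_labels, dtype=object)[ck]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


def contingency(cohort: pd.DataFrame, row_var: str, col_var: str) -> ContingencyTable:
    """Cross-tabulate two categorical cohort columns."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    ct = pd.crosstab(cohort[row_var], cohort[col_var], dropna=False)
    return ContingencyTable(ct.to_numpy(), tuple(ct.index), tuple(ct.columns))


def collapse_dominance(
    cohort: pd.DataFrame, include_strongly_atypical: bool = True
) -> ContingencyTable:
    """2x2 hemisphere-dominance concordance table.

    Rows: hemisphere contralateral to the preferred hand (Left for
    right-handers, non-Left for left-handers).  Columns: language-dominant
    hemisphere (Left for Typical, non-Left for Ambilateral and
    Strongly-atypical pooled).  Optionally drops the Strongly-atypical
    subjects before tabulating.
    """
    df = cohort
    if not include_strongly_atypical:
        df = df[df["lat_type"] != "Strongly-atypical"]
    hand_left = df["handedness"].astype(str) == "RH"
    lang_left = df["lat_type"].astype(str) == "Typical"
    counts = np.array(
        [
            [int((hand_left & lang_left).sum()), int((hand_left & ~lang_left).sum())],
            [int((~hand_left & lang_left).sum()), int((~hand_left & ~lang_left).sum())],
        ]
    )
    return ContingencyTable(counts, ("hand Left", "hand non-Left"),
                            ("language Left", "language non-Left"))


# ---------------------------------------------------------------------------
# Kappa
# ---------------------------------------------------------------------------


@dataclass
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    se: float
    p: float


def cohen_kappa(table: ContingencyTable) -> KappaResult:
    """Unweighted Cohen's kappa on a square table with aligned categories.

    Chance agreement is the product of the margins; significance uses the
    Fleiss large-sample standard error of kappa under the null of
    independence, with a two-sided normal test.
    """
    c = table.counts
    if c.shape[0] != c.shape[1]:
        raise ValueError("kappa needs a square table with matched categories")
    n = table.total
    if n == 0:
        raise ValueError("kappa undefined on an empty table")
    po = float(np.trace(c)) / n
    pr = table.row_margins / n
    pc = table.col_margins / n
    pe = float(pr @ pc)
    if pe >= 1.0:
        raise ValueError("degenerate margins: chance agreement is 1, kappa undefined")
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss-Cohen-Everitt null variance
    var0 = (pe + pe**2 - float(np.sum(pr * pc * (pr + pc)))) / (n * (1.0 - pe) ** 2)
    se = float(np.sqrt(max(var0, 0.0)))
    if se == 0.0:
        p = np.nan
    else:
        p = 2.0 * stats.norm.sf(abs(kappa) / se)
    return KappaResult(float(kappa), po, pe, se, float(p))


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------


@dataclass
class FisherResult:
    p: float
    method: str  # "closed-form", "enumeration" or "monte-carlo"
    n_tables: int = 0
    mc_se: float = float("nan")


def _log_table_prob(counts: np.ndarray, row_m: np.ndarray, col_m: np.ndarray,
                    n: int) -> float:
    """log P(table | margins) under the multivariate hypergeometric null."""
    return float(
        gammaln(row_m + 1).sum()
        + gammaln(col_m + 1).sum()
        - gammaln(n + 1)
        - gammaln(counts + 1).sum()
    )


def _enumerate_tables(row_m, col_m, max_tables):
    """Yield all nonnegative integer matrices with the given margins.

    Rows are filled one at a time; the last row is forced by the column
    margins.  Raises RuntimeError past ``max_tables`` visited tables.
    """
    r = len(row_m)
    count = 0

    def rows_for(remaining_cols, row_total):
        # all ways to split row_total across columns within remaining margins
        c = len(remaining_cols)

        def rec(j, left):
            if j == c - 1:
                if left <= remaining_cols[j]:
                    yield (left,)
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                for rest in rec(j + 1, left - v):
                    yield (v,) + rest

        yield from rec(0, row_total)

    def build(i, remaining_cols, rows):
        nonlocal count
        if i == r - 1:
            last = tuple(remaining_cols)
            if sum(last) == row_m[i]:
                count += 1
                if count > max_tables:
                    raise RuntimeError("enumeration limit exceeded")
                yield rows + [last]
            return
        for row in rows_for(remaining_cols, row_m[i]):
            yield from build(
                i + 1, [rc - v for rc, v in zip(remaining_cols, row)], rows + [row]
            )

    yield from build(0, list(col_m), [])


def fisher_exact(
    table: ContingencyTable,
    max_tables: int = 2_000_000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> FisherResult:
    """Fisher exact test of independence on an r x c count table.

    2x2 tables use the closed-form hypergeometric test.  Larger tables are
    handled by complete enumeration of all margin-consistent tables when that
    stays below ``max_tables``; otherwise by seeded Monte-Carlo sampling of
    the conditional null (>= ``n_mc`` tables) with a reported standard error.
    The p-value is the total null probability of tables no more probable than
    the observed one.
    """
    c = table.drop_empty().counts
    if c.size == 0 or min(c.shape) < 2:
        return FisherResult(1.0, "closed-form", 1)
    if c.shape == (2, 2):
        _, p = stats.fisher_exact(c)
        return FisherResult(float(p), "closed-form", 0)

    row_m, col_m = c.sum(axis=1), c.sum(axis=0)
    n = int(c.sum())
    log_p_obs = _log_table_prob(c, row_m, col_m, n)
    tol = 1e-10 * abs(log_p_obs)

    try:
        total = 0.0
        n_tables = 0
        for t in _enumerate_tables(row_m, col_m, max_tables):
            n_tables += 1
            lp = _log_table_prob(np.asarray(t), row_m, col_m, n)
            if lp <= log_p_obs + tol:
                total += np.exp(lp)
        return FisherResult(float(min(total, 1.0)), "enumeration", n_tables)
    except RuntimeError:
        pass

    # Monte-Carlo: random permutations of the column labels realize the
    # conditional-on-margins null exactly.
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(len(row_m)), row_m)
    col_labels = np.repeat(np.arange(len(col_m)), col_m)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(col_labels)
        sim = np.zeros_like(c)
        np.add.at(sim, (row_labels, perm), 1)
        if _log_table_prob(sim, row_m, col_m, n) <= log_p_obs + tol:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    se = float(np.sqrt(p * (1 - p) / n_mc))
    return FisherResult(float(p), "monte-carlo", n_mc, se)


# ---------------------------------------------------------------------------
# Correlation and regression
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    kind: str
    estimate: dict


def spearman(x, y) -> AssociationResult:
    """Spearman rank correlation with midrank ties and t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length samples of at least 3 values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return AssociationResult("spearman", {"rho": np.nan, "p": np.nan,
                                              "defined": False})
    rho, p = stats.spearmanr(x, y)
    return AssociationResult(
        "spearman", {"rho": float(rho), "p": float(p), "defined": True}
    )


def occurrence_regression(cohort: pd.DataFrame) -> AssociationResult:
    """Regress atypical-lateralization occurrence on preference mid-values.

    Per 7-level manual-preference category, the occurrence (%) of atypical
    subjects (Ambilateral and Strongly-atypical pooled) is regressed by
    ordinary least squares on the category mid-values.  Needs the cohort
    columns ``mps7`` and ``lat_type``; empty categories are skipped.
    """
    if "mps7" not in cohort or "lat_type" not in cohort:
        raise ValueError("cohort needs mps7 and lat_type columns")
    atypical = cohort["lat_type"].astype(str).isin(["Ambilateral", "Strongly-atypical"])
    mids, occs, ns = [], [], []
    for cat, sub in cohort.groupby("mps7"):
        if len(sub) == 0:
            continue
        mids.append(MPS7_MIDVALUES[int(cat)])
        occs.append(100.0 * atypical[sub.index].mean())
        ns.append(len(sub))
    if len(mids) < 2:
        raise ValueError("need at least two nonempty categories")
    res = stats.linregress(mids, occs)
    return AssociationResult(
        "occurrence-regression",
        {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "p": float(res.pvalue),
            "r": float(res.rvalue),
            "category_midvalues": mids,
            "category_occurrence_pct": occs,
            "category_n": ns,
        },
    )
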