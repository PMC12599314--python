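"""Differential signal calling, class aggregation and profile-level tests.

Produced signals are called by paired t-tests of culture vs blank replicate
concentrations with Benjamini-Hochberg FDR control (signals with Q > 0.1
are removed) and a direction gate (culture above blank). Depleted signals
are called the same way on coculture vs axenic contrasts, restricted to the
produced set, with the per-signal effect normalized to the bacterial cell
density of the coculture. Profile structure across treatments is examined
by Pearson-correlation-distance clustering, PCA and PERMANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .quantify import per_cell_normalize
from .signal_table import SignalTable

__all__ = [
    "CompoundRecord",
    "DepletionResult",
    "ProfileTestResult",
    "paired_t",
    "benjamini_hochberg",
    "call_production",
    "call_depletion",
    "classify_compound",
    "aggregate_by_class",
    "correlation_cluster",
    "permanova",
    "pca_scores",
]

CLASSES = ("hydrocarbon", "O-containing", "N-containing", "S-containing", "unidentified")


@dataclass
class CompoundRecord:
    """An m/z signal with optional formula and functional-group class."""

    signal_label: str
    formula: dict[str, int] | None = None
    klass: str | None = None

    def __post_init__(self):
        if self.klass is None:
            self.klass = classify_compound(self.formula)
        if self.klass not in CLASSES:
            raise ValueError(f"unknown class {self.klass!r}")


@dataclass
class DepletionResult:
    signal_label: str
    mean_axenic: float  # nM
    mean_coculture: float  # nM
    p: float
    q: float
    significant: bool
    percell_depletion: float  # fmol per bacterial cell

    def __post_init__(self):
        if not (0 <= self.p <= 1 and 0 <= self.q <= 1):
            raise ValueError("p and q must be probabilities")


@dataclass
class ProfileTestResult:
    statistic: float
    p: float
    n_permutations: int
    seed: int


# ---------------------------------------------------------------------------
# univariate testing
# ---------------------------------------------------------------------------

def paired_t(x, y) -> tuple[float, float]:
    """Two-sided paired t-test; replicate i of x is paired with replicate i
    of y. Zero variance of the differences returns (0, 1) — a degenerate
    case rather than an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired series must have equal length >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0  # degenerate: no information
        # constant nonzero difference: unbounded evidence
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (Q values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _paired_tests(table_a: SignalTable, table_b: SignalTable) -> pd.DataFrame:
    """Per-signal paired t between two tables with matched columns order."""
    if list(table_a.signals) != list(table_b.signals):
        raise ValueError("tables must share the same signal rows")
    if table_a.data.shape[1] != table_b.data.shape[1]:
        raise ValueError("tables must have matched replicate columns")
    rows = []
    for lbl in table_a.signals:
        t, p = paired_t(table_a.data.loc[lbl].values, table_b.data.loc[lbl].values)
        rows.append(
            {
                "signal": lbl,
                "mean_a": float(table_a.data.loc[lbl].mean()),
                "mean_b": float(table_b.data.loc[lbl].mean()),
                "t": t,
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["signal", "mean_a", "mean_b", "t", "p"]
    ).set_index("signal")
    out["q"] = benjamini_hochberg(out["p"].values)
    return out


def call_production(
    table: SignalTable,
    blank_table: SignalTable,
    alpha: float = 0.05,
    q_max: float = 0.1,
) -> pd.DataFrame:
    """Signals produced by the culture: above the media blank.

    Two-sided paired t per signal, B-H across signals, then the one-sided
    direction gate: retained iff mean(culture) > mean(blank), p <= alpha and
    q <= q_max. Returns a per-signal frame with a ``produced`` flag.
    """
    if table.level != blank_table.level:
        raise ValueError("culture and blank tables must share a level")
    res = _paired_tests(table, blank_table)
    res = res.rename(columns={"mean_a": "mean_culture", "mean_b": "mean_blank"})
    res["produced"] = (
        (res["mean_culture"] > res["mean_blank"])
        & (res["p"] <= alpha)
        & (res["q"] <= q_max)
    )
    return res


def call_depletion(
    axenic: SignalTable,
    coculture: SignalTable,
    bacteria_density: float,
    alpha: float = 0.05,
    q_max: float = 0.1,
) -> list[DepletionResult]:
    """Signals depleted in a coculture relative to the axenic culture.

    Operates on nM-level tables restricted to the produced signal set.
    Per-cell depletion is the axenic-minus-coculture mean (mol/l) normalized
    to the effective bacterial density (fmol per bacterial cell). A signal
    is significant only when depleted in direction (coculture < axenic).
    """
    if axenic.level != "nM" or coculture.level != "nM":
        raise ValueError("depletion calling operates on nM-level tables")
    if bacteria_density <= 0:
        raise ValueError("bacterial cell density must be > 0")
    res = _paired_tests(coculture, axenic)
    results = []
    for lbl, row in res.iterrows():
        mean_co, mean_ax = row["mean_a"], row["mean_b"]
        delta_molar = (mean_ax - mean_co) * 1e-9
        percell = per_cell_normalize(delta_molar, bacteria_density)
        significant = bool(
            row["p"] <= alpha and row["q"] <= q_max and mean_co < mean_ax
        )
        results.append(
            DepletionResult(
                signal_label=str(lbl),
                mean_axenic=float(mean_ax),
                mean_coculture=float(mean_co),
                p=float(row["p"]),
                q=float(row["q"]),
                significant=significant,
                percell_depletion=float(percell),
            )
        )
    return results


# ---------------------------------------------------------------------------
# classification and aggregation
# ---------------------------------------------------------------------------

def classify_compound(formula: dict[str, int] | None) -> str:
    """Functional-group class from elemental makeup.

    No formula -> unidentified; otherwise precedence
    S-containing > N-containing > O-containing > hydrocarbon (C and H only).
    """
    if formula is None:
        return "unidentified"
    if formula.get("S", 0) > 0:
        return "S-containing"
    if formula.get("N", 0) > 0:
        return "N-containing"
    if formula.get("O", 0) > 0:
        return "O-containing"
    return "hydrocarbon"


def aggregate_by_class(values: dict[str, float], records) -> pd.DataFrame:
    """Class totals and fractions of per-signal production/depletion values.

    ``values`` maps signal labels to per-cell amounts; ``records`` supplies
    the class of each signal. Fractions sum to 1 (all zeros when the value
    set is empty)."""
    klass_of = {r.signal_label: r.klass for r in records}
    totals = {k: 0.0 for k in CLASSES}
    for lbl, v in values.items():
        if lbl not in klass_of:
            raise KeyError(f"no compound record for signal {lbl!r}")
        totals[klass_of[lbl]] += v
    grand = sum(totals.values())
    out = pd.DataFrame(
        {
            "total": pd.Series(totals),
            "fraction": pd.Series(
                {k: (v / grand if grand > 0 else 0.0) for k, v in totals.items()}
            ),
        }
    )
    out.index.name = "class"
    return out


# ---------------------------------------------------------------------------
# multivariate structure
# ---------------------------------------------------------------------------

def correlation_cluster(matrix: pd.DataFrame):
    """Average-linkage hierarchical clustering of the columns under the
    Pearson correlation distance d = 1 - r. Returns (linkage matrix,
    column labels)."""
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 columns to cluster")
    var = matrix.var(axis=0)
    dead = [str(c) for c in matrix.columns[var.values == 0]]
    if dead:
        raise ValueError(f"zero-variance column(s): {', '.join(dead)}")
    d = pdist(matrix.T.values, metric="correlation")
    return linkage(d, method="average"), list(matrix.columns)


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """PERMANOVA pseudo-F from a squared Euclidean distance matrix."""
    n = labels.size
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    k = groups.size
    ss_between = ss_total - ss_within
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(
    matrix,
    groups,
    n_permutations: int = 9999,
    seed: int = 0,
) -> ProfileTestResult:
    """One-way PERMANOVA on Euclidean distances between sample rows.

    The pseudo-F statistic partitions the total sum of squared distances
    into between- and within-group components; significance comes from
    random permutations of the group labels, with
    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(groups)
    if X.shape[0] != labels.size:
        raise ValueError("one group label per sample row required")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need >= 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 samples")
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    f_obs = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    count = 0
    perm = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if _pseudo_f(d2, perm) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return ProfileTestResult(float(f_obs), float(p), n_permutations, seed)


def pca_scores(matrix):
    """Centered PCA of sample rows: (scores, explained-variance fractions)."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples for PCA")
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
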