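"""Marker-positive fractions and the within-state vs composition decomposition.

The focal quantity is the fraction of keratinocytes positive for a marker
gene, where *positive* means raw UMI count > 0. Writing the overall fraction
in condition ``c`` as ``P^c = sum_s pi_s^c p_s^c`` (``pi_s``: proportion of
cells in state ``s``; ``p_s``: positive rate within state ``s``), the
between-condition difference ``P^B - P^A`` is split exactly into

* a **within-state** component  ``sum_s pibar_s (p_s^B - p_s^A)`` and
* a **composition** component   ``sum_s pbar_s (pi_s^B - pi_s^A)``

with cross-condition averages ``pibar_s = (pi_s^A + pi_s^B)/2`` and
``pbar_s = (p_s^A + p_s^B)/2`` as weights (the symmetric, interaction-free
Kitagawa two-fold convention). The identity ``within + composition = delta``
holds to machine precision for any valid input.

Donor-level inference uses a paired Student t-test on per-donor fractions,
implemented from the definition with the p-value obtained through the
regularized incomplete beta function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import betainc

from kerastate.errors import KerastateError

__all__ = [
    "DecompositionResult",
    "PairedTestResult",
    "fraction_positive",
    "build_fraction_table",
    "kitagawa_decompose",
    "paired_t_test",
    "donor_paired_summary",
]

#: Columns required of a fraction table.
FRACTION_COLUMNS = ("donor", "condition", "state", "n_cells", "n_positive")


@dataclass(frozen=True)
class DecompositionResult:
    """Two-fold split of a difference in marker-positive fractions.

    All quantities are on the fraction scale (0-1); the ``*_pp`` properties
    convert to percentage points for reporting.
    """

    condition_a: str
    condition_b: str
    p_a: float
    p_b: float
    delta_total: float
    within_component: float
    composition_component: float
    #: per-state rows: state, pi_a, pi_b, p_a, p_b, within, composition
    per_state: pd.DataFrame = field(repr=False, compare=False)
    mode: str = "pooled"

    @property
    def delta_total_pp(self) -> float:
        return 100.0 * self.delta_total

    @property
    def within_pp(self) -> float:
        return 100.0 * self.within_component

    @property
    def composition_pp(self) -> float:
        return 100.0 * self.composition_component

    def to_dict(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "mode": self.mode,
            "p_a": self.p_a,
            "p_b": self.p_b,
            "delta_total": self.delta_total,
            "within_component": self.within_component,
            "composition_component": self.composition_component,
            "delta_total_pp": self.delta_total_pp,
            "within_pp": self.within_pp,
            "composition_pp": self.composition_pp,
            "per_state": self.per_state.to_dict(orient="records"),
        }


@dataclass(frozen=True)
class PairedTestResult:
    """Paired two-sided Student t-test on donor-aligned values."""

    mean_difference: float
    t_statistic: float
    df: int
    p_value: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "mean_difference": self.mean_difference,
            "t_statistic": self.t_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "degenerate": self.degenerate,
        }


def fraction_positive(counts, cell_subset, gene_index: int) -> float:
    """Fraction of the subset with raw UMI > 0 for one gene.

    ``counts`` is a cells x genes matrix of raw UMIs (sparse or dense);
    positivity is evaluated on raw counts, never on normalized values.
    ``cell_subset`` is a boolean mask or integer index array over cells.
    """
    subset = np.asarray(cell_subset)
    if subset.dtype == bool:
        subset = np.flatnonzero(subset)
    if subset.size == 0:
        raise KerastateError("fraction_positive: empty cell subset")
    if not 0 <= gene_index < counts.shape[1]:
        raise KerastateError(
            f"fraction_positive: gene index {gene_index} outside 0..{counts.shape[1] - 1}"
        )
    if sp.issparse(counts):
        col = np.asarray(counts[:, gene_index].todense()).ravel()
    else:
        col = np.asarray(counts)[:, gene_index]
    return float(np.count_nonzero(col[subset] > 0) / subset.size)


def build_fraction_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-cell positivity into (donor, condition, state) counts.

    ``cells`` needs columns donor, condition, state and a boolean ``positive``.
    Every (donor, condition, state) combination over the observed level sets
    is present in the output, absent combinations with ``n_cells = 0``.
    """
    required = ("donor", "condition", "state", "positive")
    for col in required:
        if col not in cells.columns:
            raise KerastateError(f"build_fraction_table: missing column {col!r}")
        if cells[col].isna().any():
            bad = cells.index[cells[col].isna()][0]
            raise KerastateError(
                f"build_fraction_table: cell {bad!r} has missing {col!r}"
            )
    grouped = (
        cells.assign(positive=cells["positive"].astype(int))
        .groupby(["donor", "condition", "state"], observed=True, sort=True)["positive"]
        .agg(n_cells="size", n_positive="sum")
        .reset_index()
    )
    full = pd.MultiIndex.from_product(
        [
            sorted(cells["donor"].unique()),
            sorted(cells["condition"].unique()),
            sorted(cells["state"].unique()),
        ],
        names=["donor", "condition", "state"],
    )
    table = (
        grouped.set_index(["donor", "condition", "state"])
        .reindex(full, fill_value=0)
        .reset_index()
    )
    table[["n_cells", "n_positive"]] = table[["n_cells", "n_positive"]].astype(int)
    return table


def _pooled_pi_p(table: pd.DataFrame, condition: str, states) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool cells over donors; return (pi, p, n_cells) aligned to ``states``.

    p is NaN for states with no cells in this condition.
    """
    sub = table[table["condition"] == condition]
    agg = sub.groupby("state", observed=True)[["n_cells", "n_positive"]].sum()
    n = agg["n_cells"].reindex(states, fill_value=0).to_numpy(dtype=float)
    pos = agg["n_positive"].reindex(states, fill_value=0).to_numpy(dtype=float)
    total = n.sum()
    if total == 0:
        raise KerastateError(f"kitagawa_decompose: condition {condition!r} has zero cells")
    pi = n / total
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, pos / np.maximum(n, 1), np.nan)
    return pi, p, n


def _decompose_arrays(
    states, pi_a, p_a, pi_b, p_b, condition_a, condition_b, mode
) -> DecompositionResult:
    """Symmetric two-fold decomposition from aligned pi/p arrays.

    A state unobserved in one condition enters with pi = 0 there and its p
    taken from the observed condition, which keeps the additivity identity
    exact. States unobserved in both conditions contribute nothing.
    """
    pi_a = np.asarray(pi_a, dtype=float)
    pi_b = np.asarray(pi_b, dtype=float)
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    p_a_f = np.where(np.isnan(p_a), np.where(np.isnan(p_b), 0.0, p_b), p_a)
    p_b_f = np.where(np.isnan(p_b), np.where(np.isnan(p_a), 0.0, p_a), p_b)
    overall_a = float(np.dot(pi_a, p_a_f))
    overall_b = float(np.dot(pi_b, p_b_f))
    pi_bar = 0.5 * (pi_a + pi_b)
    p_bar = 0.5 * (p_a_f + p_b_f)
    within_s = pi_bar * (p_b_f - p_a_f)
    comp_s = p_bar * (pi_b - pi_a)
    per_state = pd.DataFrame(
        {
            "state": list(states),
            "pi_a": pi_a,
            "pi_b": pi_b,
            "p_a": p_a_f,
            "p_b": p_b_f,
            "within": within_s,
            "composition": comp_s,
        }
    )
    return DecompositionResult(
        condition_a=condition_a,
        condition_b=condition_b,
        p_a=overall_a,
        p_b=overall_b,
        delta_total=overall_b - overall_a,
        within_component=float(within_s.sum()),
        composition_component=float(comp_s.sum()),
        per_state=per_state,
        mode=mode,
    )


def kitagawa_decompose(
    table: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    mode: str = "pooled",
) -> DecompositionResult:
    """Decompose the difference in overall positive fraction between conditions.

    ``mode="pooled"`` pools cells over donors within each condition before
    computing state proportions and rates; ``mode="per_donor"`` decomposes
    each donor separately (donors must carry both conditions) and averages
    the components with equal donor weights.
    """
    for cond in (condition_a, condition_b):
        if cond not in set(table["condition"]):
            raise KerastateError(f"kitagawa_decompose: condition {cond!r} absent from table")
    states = sorted(table["state"].unique())
    if mode == "pooled":
        pi_a, p_a, _ = _pooled_pi_p(table, condition_a, states)
        pi_b, p_b, _ = _pooled_pi_p(table, condition_b, states)
        return _decompose_arrays(states, pi_a, p_a, pi_b, p_b, condition_a, condition_b, mode)
    if mode == "per_donor":
        donors = sorted(table["donor"].unique())
        results = []
        for donor in donors:
            sub = table[table["donor"] == donor]
            if not {condition_a, condition_b} <= set(
                sub.loc[sub["n_cells"] > 0, "condition"]
            ):
                raise KerastateError(
                    f"kitagawa_decompose: donor {donor!r} lacks cells in both conditions"
                )
            results.append(
                kitagawa_decompose(sub, condition_a, condition_b, mode="pooled")
            )
        per_state = results[0].per_state.copy()
        numeric = per_state.columns.drop("state")
        per_state[numeric] = np.mean([r.per_state[numeric].to_numpy() for r in results], axis=0)
        return DecompositionResult(
            condition_a=condition_a,
            condition_b=condition_b,
            p_a=float(np.mean([r.p_a for r in results])),
            p_b=float(np.mean([r.p_b for r in results])),
            delta_total=float(np.mean([r.delta_total for r in results])),
            within_component=float(np.mean([r.within_component for r in results])),
            composition_component=float(np.mean([r.composition_component for r in results])),
            per_state=per_state,
            mode=mode,
        )
    raise KerastateError(f"kitagawa_decompose: unknown mode {mode!r}")


def paired_t_test(x, y) -> PairedTestResult:
    """Two-sided paired Student t-test on donor-aligned value pairs.

    t = mean(d) / (sd(d)/sqrt(n)) with d = y - x and the n-1 sd denominator;
    the p-value is I_{df/(df+t^2)}(df/2, 1/2) via the regularized incomplete
    beta function. Degenerate inputs get defined outputs rather than NaN:
    zero mean difference with zero variance (or n < 2) yields t = 0, p = 1;
    a nonzero difference with zero variance yields p = 0 flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise KerastateError("paired_t_test: x and y must be 1-D and equal length")
    n = x.size
    d = y - x
    mean_d = float(d.mean()) if n else 0.0
    if n < 2:
        return PairedTestResult(mean_d, 0.0, max(n - 1, 0), 1.0, degenerate=True)
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean_d == 0.0:
            return PairedTestResult(0.0, 0.0, df, 1.0)
        t = np.inf if mean_d > 0 else -np.inf
        return PairedTestResult(mean_d, float(t), df, 0.0, degenerate=True)
    t = mean_d / (sd / np.sqrt(n))
    p = float(betainc(df / 2.0, 0.5, df / (df + t * t)))
    return PairedTestResult(mean_d, float(t), df, min(max(p, 0.0), 1.0))


def donor_paired_summary(
    table: pd.DataFrame, condition_a: str, condition_b: str
) -> tuple[pd.DataFrame, PairedTestResult]:
    """Per-donor overall positive fractions and the donor-level paired test.

    Returns a frame with one row per donor (fraction in each condition and
    the difference) plus the paired t-test over donors. Pooled condition
    means are attached as frame attrs ``pooled_a`` / ``pooled_b``.
    """
    rows = []
    for donor in sorted(table["donor"].unique()):
        sub = table[table["donor"] == donor]
        fracs = {}
        for cond in (condition_a, condition_b):
            csub = sub[sub["condition"] == cond]
            n = int(csub["n_cells"].sum())
            if n == 0:
                raise KerastateError(
                    f"donor_paired_summary: donor {donor!r} has no cells in condition {cond!r}"
                )
            fracs[cond] = float(csub["n_positive"].sum() / n)
        rows.append(
            {
                "donor": donor,
                f"fraction_{condition_a}": fracs[condition_a],
                f"fraction_{condition_b}": fracs[condition_b],
                "difference": fracs[condition_b] - fracs[condition_a],
            }
        )
    per_donor = pd.DataFrame(rows)
    test = paired_t_test(
        per_donor[f"fraction_{condition_a}"], per_donor[f"fraction_{condition_b}"]
    )
    for cond, key in ((condition_a, "pooled_a"), (condition_b, "pooled_b")):
        csub = table[table["condition"] == cond]
        per_donor.attrs[key] = float(csub["n_positive"].sum() / csub["n_cells"].sum())
    return per_donor, test
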