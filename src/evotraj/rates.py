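"""Per-generation mutation-accumulation rates.

Under constant accumulation with no initial mutations, the total summed
mutation frequency in a sample grows linearly through the origin:

    M_s = sum_k  r_k * f_k,s * g_s

where r_k is lineage k's accumulation rate (mutations per generation),
f_k,s its fraction of the population at sample s, and g_s the elapsed
generations.  Treatments without mutator lineages use the single-rate
special case ``M_s = r * g_s`` (f = 1).  Fits are ordinary least squares
with the intercept constrained to zero; the mouse-host design decomposes
M_s over three lineages (ancestral nonmutator plus the two mutS mutator
lineages) whose fractions come from the marker-allele trajectories.

The model treats both mutator lineages as having arisen near the start of
the experiment with one constant rate each; lineage fractions enter only
at sampled time points (no integration of the fraction history between
samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class RatePoint:
    """One sample's contribution to a rate fit."""

    sample_id: str
    generations: float
    summed_frequency: float
    fractions: dict[str, float] = field(default_factory=dict)


@dataclass
class RateFit:
    """Through-origin least-squares fit of accumulation rates."""

    lineages: tuple[str, ...]
    rates: np.ndarray
    standard_errors: np.ndarray | None
    rss: float
    fitted: np.ndarray
    covariance: np.ndarray | None
    n: int

    @property
    def p(self) -> int:
        return len(self.lineages)

    def rate(self, lineage: str) -> float:
        return float(self.rates[self.lineages.index(lineage)])

    def standard_error(self, lineage: str) -> float | None:
        if self.standard_errors is None:
            return None
        return float(self.standard_errors[self.lineages.index(lineage)])


@dataclass
class ModelComparison:
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    constraint: str
    degenerate: bool = False


class RankDeficientDesignError(ValueError):
    """The lineage design matrix does not have full column rank."""


def normalize_lineage_fractions(
    f_a41t: float, f_d1303: float
) -> tuple[float, float, float]:
    """Normalize the two marker fractions and derive the ancestral share.

    Marker frequencies estimated independently from reads can sum to
    slightly more than 1; in that case both are rescaled proportionally to
    sum to 1 and the ancestral (nonmutator) fraction is 0.  Otherwise the
    ancestral fraction is the remainder.
    """
    if f_a41t < 0 or f_d1303 < 0:
        raise ValueError("negative lineage fraction")
    total = f_a41t + f_d1303
    if total > 1.0:
        return f_a41t / total, f_d1303 / total, 0.0
    return f_a41t, f_d1303, 1.0 - total


def _design(points: list[RatePoint], lineages: tuple[str, ...]) -> np.ndarray:
    x = np.zeros((len(points), len(lineages)))
    for i, pt in enumerate(points):
        for j, lin in enumerate(lineages):
            f = pt.fractions.get(lin)
            if f is None:
                raise KeyError(
                    f"point {pt.sample_id!r} lacks a fraction for "
                    f"lineage {lin!r}"
                )
            x[i, j] = f * pt.generations
    return x


def fit_multirate(
    points: list[RatePoint], lineages: tuple[str, ...] | list[str]
) -> RateFit:
    """Zero-intercept least squares of M_s on the columns f_k,s * g_s.

    Standard errors use the through-origin convention: residual variance
    RSS/(n-p) with p = number of rates (no intercept degree of freedom).
    With one lineage at fraction 1 everywhere this reduces exactly to the
    single-rate fit.
    """
    lineages = tuple(lineages)
    if not points:
        raise ValueError("no rate points")
    if len(points) < len(lineages):
        raise ValueError(
            f"{len(points)} points cannot identify {len(lineages)} rates"
        )
    x = _design(points, lineages)
    y = np.array([pt.summed_frequency for pt in points], dtype=float)
    dead = np.flatnonzero(~x.any(axis=0))
    if dead.size:
        raise RankDeficientDesignError(
            f"lineage(s) never observed (all-zero design column): "
            f"{[lineages[j] for j in dead]}"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < len(lineages):
        raise RankDeficientDesignError(
            f"design matrix has rank {rank} < {len(lineages)}; lineage "
            f"columns {list(lineages)} are collinear"
        )
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    rss = float(((y - fitted) ** 2).sum())
    n, p = len(points), len(lineages)
    if n > p:
        sigma2 = rss / (n - p)
        cov = sigma2 * np.linalg.inv(x.T @ x)
        se = np.sqrt(np.diag(cov))
    else:
        cov = None
        se = None
    return RateFit(lineages, beta, se, rss, fitted, cov, n)


def fit_single_rate(points: list[RatePoint]) -> RateFit:
    """Through-origin fit of one accumulation rate: M_s ~ r * g_s.

    Closed form: r = sum(M*g)/sum(g^2); SE = sqrt((RSS/(n-1))/sum(g^2)),
    undefined (None) for a single point.
    """
    if not points:
        raise ValueError("no rate points")
    g = np.array([pt.generations for pt in points], dtype=float)
    if not (g > 0).any():
        raise ValueError("all points have zero elapsed generations")
    unit = [
        RatePoint(pt.sample_id, pt.generations, pt.summed_frequency, {"rate": 1.0})
        for pt in points
    ]
    return fit_multirate(unit, ("rate",))


def compare_rates_ftest(
    points: list[RatePoint],
    lineages: tuple[str, ...] | list[str],
    constrain_equal: tuple[str, str],
) -> ModelComparison:
    """F-test of the constraint r_a = r_b against the free multi-rate model.

    The constrained model merges the two lineages' design columns (their
    summed f*g products share one rate).  A zero residual in the full
    model makes the statistic infinite; this degenerate case is reported
    with p clamped to 0 and a warning.
    """
    lineages = tuple(lineages)
    a, b = constrain_equal
    if a not in lineages or b not in lineages:
        raise ValueError(f"constraint names unknown lineages: {a!r}, {b!r}")
    if len(lineages) < 2:
        raise ValueError("nothing to compare in a single-lineage model")
    full = fit_multirate(points, lineages)
    merged_label = f"{a}+{b}"
    reduced_points = []
    for pt in points:
        fr = {
            lin: pt.fractions[lin] for lin in lineages if lin not in (a, b)
        }
        fr[merged_label] = pt.fractions[a] + pt.fractions[b]
        reduced_points.append(
            RatePoint(pt.sample_id, pt.generations, pt.summed_frequency, fr)
        )
    reduced_lineages = tuple(
        lin for lin in lineages if lin not in (a, b)
    ) + (merged_label,)
    reduced = fit_multirate(reduced_points, reduced_lineages)
    n, p1, p0 = full.n, full.p, reduced.p
    df1, df2 = p1 - p0, n - p1
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom in the full model")
    constraint = f"equal({a}, {b})"
    y_scale = max(1.0, sum(pt.summed_frequency**2 for pt in points))
    if full.rss <= 1e-20 * y_scale:
        warnings.warn(
            "full model fits exactly (RSS = 0); F-statistic is degenerate",
            stacklevel=2,
        )
        degenerate = reduced.rss > full.rss
        return ModelComparison(
            np.inf if degenerate else 0.0,
            df1,
            df2,
            0.0 if degenerate else 1.0,
            constraint,
            degenerate=True,
        )
    f_stat = ((reduced.rss - full.rss) / df1) / (full.rss / df2)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, df1, df2))
    return ModelComparison(f_stat, df1, df2, p, constraint)


def fold_change(r_num: float, r_den: float, rounded: bool = False) -> float:
    """Ratio of two rates, optionally rounded to the nearest integer."""
    if r_den <= 0:
        raise ValueError("denominator rate must be positive")
    ratio = r_num / r_den
    return float(round(ratio)) if rounded else ratio


def generation_time(t1: float, t2: float, x1: float, x2: float) -> float:
    """Generation (doubling) time from two abundance measurements.

    gt = log10(2) * (t2 - t1) / (log10 X2 - log10 X1), in the units of t.
    Declining abundance (X2 < X1) yields a negative value and a warning.
    """
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    if x1 <= 0 or x2 <= 0:
        raise ValueError("abundances must be positive")
    if x2 == x1:
        raise ValueError("zero growth: X2 equals X1")
    gt = np.log10(2.0) * (t2 - t1) / (np.log10(x2) - np.log10(x1))
    if x2 < x1:
        warnings.warn(
            "population declined between measurements; generation time is "
            "negative",
            stacklevel=2,
        )
    return float(gt)


def build_rate_points(
    sample_ids,
    generations,
    summed,
    fraction_columns: dict[str, np.ndarray] | None = None,
    ancestral_label: str = "ancestral",
) -> list[RatePoint]:
    """Assemble RatePoints from parallel per-sample arrays.

    ``fraction_columns`` maps mutator lineage labels to fraction arrays;
    the ancestral fraction is derived by normalizing the (up to two)
    mutator fractions to sum at most 1.  Without fraction columns each
    point gets the trivial single-lineage design (fraction 1).
    """
    points = []
    generations = np.asarray(generations, dtype=float)
    summed = np.asarray(summed, dtype=float)
    for i, sid in enumerate(sample_ids):
        if fraction_columns:
            labels = list(fraction_columns)
            if len(labels) == 2:
                fa, fb, anc = normalize_lineage_fractions(
                    float(fraction_columns[labels[0]][i]),
                    float(fraction_columns[labels[1]][i]),
                )
                fr = {labels[0]: fa, labels[1]: fb, ancestral_label: anc}
            else:
                fr = {
                    lab: float(fraction_columns[lab][i]) for lab in labels
                }
                fr[ancestral_label] = max(0.0, 1.0 - sum(fr.values()))
        else:
            fr = {}
        points.append(RatePoint(sid, generations[i], summed[i], fr))
    return points
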