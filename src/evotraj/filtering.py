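"""Candidate-mutation filtering cascade.

Candidates exported by a polymorphism caller contain real segregating
mutations mixed with systematic mapping artifacts and sequencing noise.
Three stages separate them, applied in a fixed order:

1. **Poisson likelihood-ratio test + Benjamini-Hochberg.**  For each
   candidate, mutant-supporting read counts across samples are modelled as
   Poisson with the per-sample total read count as an offset.  A real
   sweeping mutation has a per-sample rate (frequency) that varies between
   samples; sequencing noise does not.  The LRT compares the one-rate null
   against per-sample rates (one observation per sample, so the
   alternative is the saturated model) and candidates that fail BH at
   FDR q = 0.01 are dropped.
2. **Ubiquity filter.**  Candidates at >= 5% frequency in at least half of
   all samples pooled over treatments are systematic artifacts (a real
   mutation confined to one treatment cannot be everywhere) and are
   removed.
3. **Persistence filter.**  Within a treatment, keep candidates whose
   frequency range exceeds 20 percentage points, or that peak above 10%
   while appearing in at most half of the treatment's samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import FrequencyMatrix, SampleSheet, VariantTable, compute_frequencies

_P_FLOOR = np.finfo(float).tiny  # p-values are never reported as exact zero


@dataclass
class LrtResult:
    mutation_id: str
    statistic: float
    df: int
    p_value: float


def poisson_lrt(
    mutant_counts, total_counts, mutation_id: str = ""
) -> LrtResult:
    """Likelihood-ratio test for between-sample variation in mutant rate.

    Null: one common rate lambda with expected mutant count ``lambda*t_i``
    (MLE ``sum(m)/sum(t)``).  Alternative: a free rate per sample (the
    saturated model, ``lambda_i = m_i/t_i``).  The deviance is

        2 * sum_i m_i * ln(m_i / (lambda_hat * t_i))      (0*ln 0 = 0)

    on ``S_eff - 1`` degrees of freedom, where S_eff counts samples with
    nonzero total reads; zero-coverage samples are excluded from the fit.
    """
    m = np.asarray(mutant_counts, dtype=float)
    t = np.asarray(total_counts, dtype=float)
    if m.shape != t.shape:
        raise ValueError("count vectors differ in length")
    if (m < 0).any() or (t < 0).any():
        raise ValueError("negative counts")
    if (m > t).any():
        raise ValueError("mutant count exceeds total count")
    usable = t > 0
    if not usable.any():
        raise ValueError("all samples have zero total reads")
    m, t = m[usable], t[usable]
    df = int(usable.sum()) - 1
    if df == 0:
        return LrtResult(mutation_id, 0.0, 0, 1.0)
    lam = m.sum() / t.sum()
    if lam == 0:
        return LrtResult(mutation_id, 0.0, df, 1.0)
    pos = m > 0
    statistic = 2.0 * float(np.sum(m[pos] * np.log(m[pos] / (lam * t[pos]))))
    statistic = max(statistic, 0.0)
    p = max(float(stats.chi2.sf(statistic, df)), _P_FLOOR)
    return LrtResult(mutation_id, statistic, df, p)


def bh_adjust(p_values, fdr_q: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p-values)."""
    if not 0 < fdr_q < 1:
        raise ValueError("fdr_q must be in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=fdr_q, method="fdr_bh")
    return reject, p_adj


def ubiquity_filter(
    freqs: FrequencyMatrix,
    freq_thr: float = 0.05,
    sample_fraction: float = 0.5,
) -> np.ndarray:
    """Removal mask for candidates ubiquitous across all pooled samples.

    A mutation is removed iff the number of samples (masked cells not
    counted) where its frequency is >= ``freq_thr`` reaches
    ``ceil(sample_fraction * S_total)`` -- "at least half", so with an
    even sample count exactly half triggers removal.
    """
    vals = freqs.values.to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError("empty frequency matrix")
    n_samples = vals.shape[1]
    need = math.ceil(sample_fraction * n_samples)
    hits = np.nansum(vals >= freq_thr, axis=1)
    return hits >= need


def persistence_filter(
    freqs: FrequencyMatrix,
    range_thr: float = 0.20,
    peak_thr: float = 0.10,
    presence_thr: float = 0.0,
    sample_fraction: float = 0.5,
) -> np.ndarray:
    """Keep mask for candidates showing real dynamics within one treatment.

    Keep iff (max - min of unmasked frequencies) > ``range_thr``, OR the
    peak exceeds ``peak_thr`` while the mutation appears in at most
    ``floor(sample_fraction * S)`` samples.  "Appears" means frequency
    strictly above ``presence_thr`` when that is 0 (any nonzero
    frequency), else >= ``presence_thr``.
    """
    vals = freqs.values.to_numpy(dtype=float)
    if vals.shape[1] == 0:
        raise ValueError("no samples in treatment")
    allowed = math.floor(sample_fraction * vals.shape[1])
    with np.errstate(all="ignore"):
        peak = np.nanmax(vals, axis=1)
        trough = np.nanmin(vals, axis=1)
    peak = np.nan_to_num(peak, nan=0.0)
    trough = np.nan_to_num(trough, nan=0.0)
    if presence_thr == 0.0:
        present = np.nansum(vals > 0.0, axis=1)
    else:
        present = np.nansum(vals >= presence_thr, axis=1)
    ranged = (peak - trough) > range_thr
    peaked = (peak > peak_thr) & (present <= allowed)
    return ranged | peaked


@dataclass
class FilterReport:
    """Per-mutation outcomes of the cascade plus telescoping stage counts."""

    frame: pd.DataFrame  # indexed by mutation_id
    stage_counts: dict[str, int]

    def kept_ids(self) -> list[str]:
        return list(self.frame.index[self.frame["final_kept"]])


def filter_pipeline(
    table: VariantTable,
    sheet: SampleSheet,
    fdr_q: float = 0.01,
    ubiquity_thr: float = 0.05,
    ubiquity_sample_fraction: float = 0.5,
    range_thr: float = 0.20,
    peak_thr: float = 0.10,
    presence_thr: float = 0.0,
    persistence_sample_fraction: float = 0.5,
    treatments=None,
) -> tuple[VariantTable, FilterReport]:
    """Run the full three-stage cascade in its fixed order.

    BH is applied pooled over all candidates in the run; the ubiquity
    filter pools all samples; the persistence filter is evaluated within
    each targeted treatment (default: every treatment on the sheet) and a
    mutation is kept if it passes in at least one of them.
    """
    table.validate()
    sheet.validate()
    sample_ids = [s for s in sheet.sample_ids if s in table.sample_ids]
    if not sample_ids:
        raise ValueError("sheet and table share no samples")
    n = table.n_mutations
    if n == 0:
        report = FilterReport(
            pd.DataFrame(
                columns=[
                    "p_value",
                    "p_adjusted",
                    "bh_significant",
                    "removed_by_ubiquity",
                    "kept_by_persistence",
                    "final_kept",
                ]
            ),
            {
                "input": 0,
                "after_bh": 0,
                "after_ubiquity": 0,
                "after_persistence": 0,
            },
        )
        return table, report

    mut = table.mut[sample_ids].to_numpy()
    tot = table.tot[sample_ids].to_numpy()
    lrt = [
        poisson_lrt(mut[i], tot[i], mid)
        for i, mid in enumerate(table.mutation_ids)
    ]
    p_values = np.array([r.p_value for r in lrt])
    significant, p_adj = bh_adjust(p_values, fdr_q)

    freqs = compute_frequencies(table).restrict(sample_ids)
    ubiquitous = ubiquity_filter(freqs, ubiquity_thr, ubiquity_sample_fraction)

    if treatments is None:
        treatments = sheet.treatments()
    persistent = np.zeros(n, dtype=bool)
    for treatment in treatments:
        tr_samples = [s for s in sheet.samples_in(treatment) if s in sample_ids]
        if not tr_samples:
            continue
        persistent |= persistence_filter(
            freqs.restrict(tr_samples),
            range_thr,
            peak_thr,
            presence_thr,
            persistence_sample_fraction,
        )

    final = significant & ~ubiquitous & persistent
    frame = pd.DataFrame(
        {
            "p_value": p_values,
            "p_adjusted": p_adj,
            "bh_significant": significant,
            "removed_by_ubiquity": ubiquitous,
            "kept_by_persistence": persistent,
            "final_kept": final,
        },
        index=pd.Index(table.mutation_ids, name="mutation_id"),
    )
    stage_counts = {
        "input": n,
        "after_bh": int(significant.sum()),
        "after_ubiquity": int((significant & ~ubiquitous).sum()),
        "after_persistence": int(final.sum()),
    }
    kept = [mid for mid, keep in zip(table.mutation_ids, final) if keep]
    return table.subset(kept), FilterReport(frame, stage_counts)
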