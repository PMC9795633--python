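"""Shared test utilities: small table builders and a brute-force LRT oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from evotraj.tables import FrequencyMatrix, VariantTable


def make_freq_matrix(values, sample_ids=None, mutation_ids=None):
    """FrequencyMatrix from a 2-D array; NaN cells become masked."""
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    n, s = arr.shape
    sample_ids = sample_ids or [f"s{j}" for j in range(s)]
    mutation_ids = mutation_ids or [f"m{i}" for i in range(n)]
    idx = pd.Index(mutation_ids, name="mutation_id")
    values_df = pd.DataFrame(arr, index=idx, columns=sample_ids)
    mask = pd.DataFrame(np.isnan(arr), index=idx, columns=sample_ids)
    return FrequencyMatrix(values_df, mask)


def make_variant_table(mut, tot, sample_ids=None, genes=None, classes=None,
                       refs=None, alts=None):
    """VariantTable from mutant/total count arrays (mutations x samples)."""
    mut = np.atleast_2d(np.asarray(mut, dtype=np.int64))
    tot = np.atleast_2d(np.asarray(tot, dtype=np.int64))
    n, s = mut.shape
    sample_ids = sample_ids or [f"s{j}" for j in range(s)]
    mids = [f"m{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "mutation_id": mids,
            "contig": "contig_1",
            "position": np.arange(1, n + 1) * 100,
            "ref_allele": refs if refs is not None else ["A"] * n,
            "alt_allele": alts if alts is not None else ["G"] * n,
            "gene": genes if genes is not None else [f"g{i}" for i in range(n)],
            "mutation_class": classes if classes is not None else ["snv"] * n,
        }
    )
    idx = pd.Index(mids, name="mutation_id")
    return VariantTable(
        meta,
        pd.DataFrame(mut, index=idx, columns=sample_ids),
        pd.DataFrame(tot, index=idx, columns=sample_ids),
    ).validate()


def lrt_oracle(mutant_counts, total_counts):
    """Deviance by direct numeric maximization of both Poisson likelihoods.

    Independent of the closed-form implementation: the common-rate null and
    each saturated per-sample rate are found with bounded scalar
    optimization of the Poisson log-likelihood (log m! terms cancel).
    """
    m = np.asarray(mutant_counts, dtype=float)
    t = np.asarray(total_counts, dtype=float)
    use = t > 0
    m, t = m[use], t[use]

    def ll(lam, mi, ti):
        if mi == 0:
            return -lam * ti
        return mi * np.log(lam * ti) - lam * ti

    def maximize(fun):
        res = minimize_scalar(
            lambda x: -fun(x),
            bounds=(1e-14, 1.0),
            method="bounded",
            options={"xatol": 1e-15},
        )
        return -res.fun

    ll_null = maximize(lambda lam: sum(ll(lam, mi, ti) for mi, ti in zip(m, t)))
    ll_alt = sum(maximize(lambda lam, mi=mi, ti=ti: ll(lam, mi, ti))
                 for mi, ti in zip(m, t))
    return 2.0 * (ll_alt - ll_null)
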