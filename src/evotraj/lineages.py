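"""Hypermutator lineage assignment and base-substitution spectra.

In a population carrying two competing mutator lineages, mutations that
arose inside a lineage hitchhike with it, so their allele-frequency
trajectories track the trajectory of the lineage's defining marker allele.
Mutations are therefore assigned to the lineage whose marker trajectory is
closest in total Manhattan distance, provided that distance falls below a
cutoff (default 0.4); everything else stays unassigned.

Point mutations are folded into the six strand-symmetric substitution
classes (e.g. both A->G and T->C are "A:T->G:C") and counted per group to
give the base-substitution spectrum, the classic readout of a
mismatch-repair-deficient mutator (strong A:T->G:C bias).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The six strand-symmetric base-substitution classes, in display order.
SUBSTITUTION_CLASSES = (
    "A:T->G:C",
    "A:T->C:G",
    "A:T->T:A",
    "C:G->T:A",
    "C:G->A:T",
    "C:G->G:C",
)

#: The two ordered (ref, alt) representations of each class.
CLASS_TO_PAIRS = {
    "A:T->G:C": (("A", "G"), ("T", "C")),
    "A:T->C:G": (("A", "C"), ("T", "G")),
    "A:T->T:A": (("A", "T"), ("T", "A")),
    "C:G->T:A": (("C", "T"), ("G", "A")),
    "C:G->A:T": (("C", "A"), ("G", "T")),
    "C:G->G:C": (("C", "G"), ("G", "C")),
}

_PAIR_TO_CLASS = {
    pair: cls for cls, pairs in CLASS_TO_PAIRS.items() for pair in pairs
}

UNASSIGNED = "unassigned"


def substitution_class(ref_base: str, alt_base: str) -> str:
    """Six-class label of a base substitution (strand-symmetric)."""
    try:
        return _PAIR_TO_CLASS[(ref_base.upper(), alt_base.upper())]
    except KeyError:
        raise ValueError(
            f"not a base substitution: {ref_base!r} -> {alt_base!r}"
        ) from None


def manhattan_distance(traj_a, traj_b) -> float:
    """Total Manhattan distance between two frequency trajectories.

    Sums |a_s - b_s| over the samples where both trajectories are observed
    (NaN marks a masked sample and is dropped pairwise).
    """
    a = np.asarray(traj_a, dtype=float)
    b = np.asarray(traj_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("trajectories differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    if not ok.any():
        raise ValueError("no common unmasked samples")
    return float(np.abs(a[ok] - b[ok]).sum())


@dataclass
class LineageAssignment:
    mutation_id: str
    distances: dict[str, float]
    assigned: str  # lineage label or UNASSIGNED
    cutoff: float
    tie: bool = False


def assign_lineage(
    mutation_id: str,
    mutation_traj,
    marker_trajs: dict[str, np.ndarray],
    cutoff: float = 0.4,
) -> LineageAssignment:
    """Assign one mutation to the nearest marker trajectory below ``cutoff``.

    Exact ties below the cutoff are left unassigned with ``tie=True``.
    """
    if not marker_trajs:
        raise ValueError("at least one marker trajectory required")
    distances = {
        label: manhattan_distance(mutation_traj, traj)
        for label, traj in marker_trajs.items()
    }
    dmin = min(distances.values())
    nearest = [k for k, v in distances.items() if v == dmin]
    if dmin < cutoff and len(nearest) == 1:
        return LineageAssignment(mutation_id, distances, nearest[0], cutoff)
    return LineageAssignment(
        mutation_id, distances, UNASSIGNED, cutoff,
        tie=dmin < cutoff and len(nearest) > 1,
    )


def assign_lineages(
    freqs,
    marker_trajs: dict[str, np.ndarray],
    cutoff: float = 0.4,
    exclude=(),
) -> pd.DataFrame:
    """Assign every mutation in a :class:`FrequencyMatrix` to a lineage.

    ``exclude`` lists mutation_ids (typically the marker rows themselves)
    whose assignment is forced to their own label when it matches a marker
    label, or skipped otherwise.  Returns a DataFrame with one row per
    mutation: the distance to each marker, the assigned label, and a tie
    flag.
    """
    rows = []
    for mid in freqs.mutation_ids:
        if mid in exclude:
            continue
        a = assign_lineage(mid, freqs.row(mid), marker_trajs, cutoff)
        row = {"mutation_id": mid}
        row.update({f"dist_{k}": v for k, v in a.distances.items()})
        row["assigned"] = a.assigned
        row["tie"] = a.tie
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SpectrumCounts:
    """Six-class substitution counts for one group of mutations."""

    group: str
    counts: dict[str, int]
    n_excluded_non_snv: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, float] | None:
        n = self.total
        if n == 0:
            return None
        return {c: k / n for c, k in self.counts.items()}


def spectrum_counts(
    table, group_of: dict[str, str] | None = None
) -> dict[str, SpectrumCounts]:
    """Base-substitution spectrum per group of mutations.

    ``group_of`` maps mutation_id -> group label (e.g. a treatment or a
    lineage assignment); unmapped mutations go to group "all".  Only SNV
    rows contribute; indel/other rows are excluded and tallied in
    ``n_excluded_non_snv``.  Each mutation counts once (spectra are
    unweighted by frequency).
    """
    results: dict[str, SpectrumCounts] = {}

    def bucket(group: str) -> SpectrumCounts:
        if group not in results:
            results[group] = SpectrumCounts(
                group, {c: 0 for c in SUBSTITUTION_CLASSES}
            )
        return results[group]

    meta = table.meta
    for _, row in meta.iterrows():
        group = (group_of or {}).get(row["mutation_id"], "all")
        b = bucket(group)
        if row["mutation_class"] != "snv":
            b.n_excluded_non_snv += 1
            continue
        cls = substitution_class(row["ref_allele"], row["alt_allele"])
        b.counts[cls] += 1
    return results


def spectra_frame(spectra: dict[str, SpectrumCounts]) -> pd.DataFrame:
    """Long-format table of spectra: group, class, count, proportion, N."""
    rows = []
    for group, sc in spectra.items():
        props = sc.proportions
        for cls in SUBSTITUTION_CLASSES:
            rows.append(
                {
                    "group": group,
                    "class": cls,
                    "count": sc.counts[cls],
                    "proportion": np.nan if props is None else props[cls],
                    "N": sc.total,
                    "n_excluded_non_snv": sc.n_excluded_non_snv,
                }
            )
    return pd.DataFrame(rows)
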