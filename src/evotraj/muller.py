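"""Genotype nesting and Muller-plot export.

Whole-population sequencing estimates every mutation's frequency
independently, with no linkage information.  Under purely asexual
reproduction a new mutation arises inside an existing genotype, so its
frequency trajectory must fit within its parent's; and a lineage that
already carries a mutation in a gene is unlikely to sustain a second hit
in the same gene while the background mutation rate stays low.  These two
rules drive a deterministic greedy reconstruction:

* order candidate mutations by descending peak frequency (ties: earlier
  first appearance, then mutation_id);
* a mutation whose trajectory is indistinguishable (within a containment
  tolerance ``eps``, both directions) from an existing genotype's joins
  that genotype: identical trajectories are the signature of mutations in
  the same genetic background, so genotypes are sets of mutations;
* otherwise the mutation is nested under the deepest existing genotype
  whose trajectory contains it everywhere (within ``eps``) and whose path
  to the root carries no mutation in the same gene; failing that it
  founds a new root-level genotype.

Because per-site frequency estimates are noisy, the raw genotype
frequencies are then corrected: children are capped at their parent's
frequency, and sibling groups whose total exceeds their parent (or 1.0 at
the root) are rescaled proportionally.  Both corrections are reported; a
correction of 0.10 or more is flagged as suspicious.  The export format
(an edges table and a Generation/Identity/Population table of exclusive
frequencies) is directly consumable by the ggmuller R package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import FrequencyMatrix, SampleSheet

ROOT = "ancestor"
ADJUSTMENT_FLAG_THRESHOLD = 0.10


@dataclass
class Genotype:
    """One genotype: the mutations defining it plus its trajectory.

    ``own_mutations`` are the mutations this genotype added on top of its
    parent; the full (cumulative) mutation set is ``mutations``.  ``raw``
    is the element-wise mean of the member mutations' observed frequency
    trajectories.
    """

    identity: str
    own_mutations: frozenset[str]
    parent: str  # identity of parent genotype (ROOT for top level)
    raw: np.ndarray
    corrected: np.ndarray | None = None


@dataclass
class GenotypeTree:
    """Single-parent forest of genotypes over one population's samples."""

    sample_ids: list[str]
    genotypes: dict[str, Genotype] = field(default_factory=dict)

    def children(self, identity: str) -> list[str]:
        return [
            g.identity
            for g in self.genotypes.values()
            if g.parent == identity
        ]

    def depth(self, identity: str) -> int:
        d = 0
        while identity != ROOT:
            identity = self.genotypes[identity].parent
            d += 1
        return d

    def path_mutations(self, identity: str) -> frozenset[str]:
        """Cumulative mutation set of a genotype (its own + ancestors')."""
        out: set[str] = set()
        while identity != ROOT:
            g = self.genotypes[identity]
            out |= g.own_mutations
            identity = g.parent
        return frozenset(out)

    def roots(self) -> list[str]:
        return self.children(ROOT)


@dataclass
class CorrectionReport:
    frame: pd.DataFrame  # genotype x sample adjustment magnitudes
    max_adjustment: float

    @property
    def flagged(self) -> bool:
        return self.max_adjustment >= ADJUSTMENT_FLAG_THRESHOLD


def select_muller_mutations(
    freqs: FrequencyMatrix, thr: float = 0.10, exclusions=()
) -> list[str]:
    """Mutations that ever reach frequency >= ``thr``, minus exclusions.

    The boundary is inclusive ("at least").  ``exclusions`` lists
    mutation_ids to drop regardless of frequency (e.g. calls known to be
    unresolved structural-variant artifacts).
    """
    excluded = set(exclusions)
    keep = []
    vals = freqs.values
    for mid in freqs.mutation_ids:
        if mid in excluded:
            continue
        row = vals.loc[mid].to_numpy(dtype=float)
        if np.nansum(~np.isnan(row)) and np.nanmax(row) >= thr:
            keep.append(mid)
    return keep


def _first_appearance(row: np.ndarray, detect_thr: float) -> int:
    """First sample where the trajectory clears the detection threshold.

    The threshold keeps stray sequencing-error reads (one or two mutant
    reads at an otherwise absent site) from scrambling the insertion
    order.
    """
    nz = np.flatnonzero(np.nan_to_num(row, nan=0.0) >= detect_thr)
    return int(nz[0]) if nz.size else len(row)


def infer_genotype_nesting(
    freqs: FrequencyMatrix,
    gene_of: dict[str, str],
    eps: float = 0.02,
    detect_thr: float = 0.05,
    read_depth: float | None = None,
    z: float = 5.0,
) -> GenotypeTree:
    """Greedy containment reconstruction of genotype nesting.

    Trajectory B is contained in trajectory A when, at every sample where
    both are observed, ``B <= A + tol``.  The tolerance is ``eps`` plus,
    when ``read_depth`` is given, ``z`` binomial standard deviations of
    the difference of the two frequency estimates at that depth -- so
    containment is judged against read-sampling noise rather than a fixed
    band.  Trajectories contained in each other are the signature of
    mutations in the same genetic background and are merged into one
    genotype (whose trajectory is the running mean of its members').
    Masked samples are non-constraining; any input yields a forest, and
    mutations that fit nowhere become root-level genotypes.
    """
    tree = GenotypeTree(sample_ids=list(freqs.sample_ids))
    rows = {mid: freqs.row(mid) for mid in freqs.mutation_ids}
    members: dict[str, list[np.ndarray]] = {}
    creation_rank: dict[str, int] = {}

    def contained(inner: np.ndarray, outer: np.ndarray) -> bool:
        ok = ~(np.isnan(inner) | np.isnan(outer))
        if not ok.any():
            return False
        a, b = outer[ok], inner[ok]
        tol = eps
        if read_depth is not None:
            tol = eps + z * np.sqrt(
                (a * (1 - a) + b * (1 - b)) / read_depth
            )
        return not (b > a + tol).any()

    # candidate hosts must be inserted before the mutations they contain:
    # a parent is detected no later than any mutation arising inside it,
    # so first detected appearance is the primary key.  Peak ordering
    # would be scrambled by read noise whenever parent and child sweep to
    # nearly the same peak.
    order = sorted(
        freqs.mutation_ids,
        key=lambda mid: (
            _first_appearance(rows[mid], detect_thr),
            -np.nanmax(np.nan_to_num(rows[mid], nan=0.0)),
            mid,
        ),
    )
    for mid in order:
        row = rows[mid]
        gene = gene_of.get(mid, "")
        best = None
        for g in tree.genotypes.values():
            if not contained(row, g.raw):
                continue
            if gene and any(
                gene_of.get(m, "") == gene
                for m in tree.path_mutations(g.identity)
            ):
                continue
            if best is None:
                best = g
            else:
                # deepest wins; ties go to the earlier-created genotype
                if (
                    tree.depth(g.identity),
                    -creation_rank[g.identity],
                ) > (
                    tree.depth(best.identity),
                    -creation_rank[best.identity],
                ):
                    best = g
        if best is not None and contained(best.raw, row):
            # mutual containment: same genetic background
            best.own_mutations = best.own_mutations | {mid}
            members[best.identity].append(np.nan_to_num(row, nan=0.0))
            best.raw = np.mean(members[best.identity], axis=0)
            continue
        identity = f"gt_{mid}"
        tree.genotypes[identity] = Genotype(
            identity=identity,
            own_mutations=frozenset({mid}),
            parent=ROOT if best is None else best.identity,
            raw=np.nan_to_num(row, nan=0.0),
        )
        members[identity] = [np.nan_to_num(row, nan=0.0)]
        creation_rank[identity] = len(creation_rank)
    return tree


def correct_genotype_frequencies(
    tree: GenotypeTree,
) -> tuple[GenotypeTree, CorrectionReport]:
    """Apply the two frequency corrections, top-down.

    Pass 1 caps every genotype at its (already corrected) parent's
    frequency per sample; pass 2 rescales sibling groups proportionally
    wherever their per-sample total exceeds the parent's frequency (1.0
    for root-level genotypes).  After correction, child <= parent and the
    per-sample conservation invariants hold exactly.  Idempotent.
    """
    n = len(tree.sample_ids)

    def parent_value(identity: str) -> np.ndarray:
        if identity == ROOT:
            return np.ones(n)
        return tree.genotypes[identity].corrected

    def process(identity: str) -> None:
        limit = parent_value(identity)
        kids = tree.children(identity)
        for k in kids:
            g = tree.genotypes[k]
            g.corrected = np.minimum(g.raw, limit)
        if kids:
            total = np.sum(
                [tree.genotypes[k].corrected for k in kids], axis=0
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = np.where(total > limit, limit / np.where(
                    total > 0, total, 1.0), 1.0)
            for k in kids:
                tree.genotypes[k].corrected = (
                    tree.genotypes[k].corrected * scale
                )
        for k in kids:
            process(k)

    process(ROOT)

    adj_rows = {}
    for identity, g in tree.genotypes.items():
        adj_rows[identity] = np.abs(g.raw - g.corrected)
    frame = pd.DataFrame.from_dict(
        adj_rows, orient="index", columns=tree.sample_ids
    )
    max_adj = float(frame.to_numpy().max()) if len(frame) else 0.0
    return tree, CorrectionReport(frame, max_adj)


def export_muller_tables(
    tree: GenotypeTree, sheet: SampleSheet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ggmuller-compatible edges (Parent, Identity) and population tables.

    Population is the genotype's exclusive frequency: its corrected
    frequency minus the sum of its children's.  The ancestor row carries
    the remainder, so per-generation Population values sum to exactly 1.
    """
    if any(g.corrected is None for g in tree.genotypes.values()):
        raise ValueError("tree must be corrected before export")
    gens = sheet.generations(tree.sample_ids)
    edges = pd.DataFrame(
        [
            {"Parent": g.parent, "Identity": g.identity}
            for g in tree.genotypes.values()
        ],
        columns=["Parent", "Identity"],
    )
    pop_rows = []
    for s, (sid, gen) in enumerate(zip(tree.sample_ids, gens)):
        root_total = 0.0
        for identity, g in tree.genotypes.items():
            kid_total = sum(
                tree.genotypes[k].corrected[s] for k in tree.children(identity)
            )
            exclusive = g.corrected[s] - kid_total
            if exclusive < -1e-9:
                raise ValueError(
                    f"negative exclusive frequency for {identity!r} in "
                    f"sample {sid!r}: corrections failed to prevent it"
                )
            pop_rows.append(
                {
                    "Generation": gen,
                    "Identity": identity,
                    "Population": max(exclusive, 0.0),
                }
            )
            if g.parent == ROOT:
                root_total += g.corrected[s]
        pop_rows.append(
            {
                "Generation": gen,
                "Identity": ROOT,
                "Population": max(1.0 - root_total, 0.0),
            }
        )
    populations = pd.DataFrame(
        pop_rows, columns=["Generation", "Identity", "Population"]
    )
    return edges, populations
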