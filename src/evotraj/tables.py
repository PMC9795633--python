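"""Tabular formats for evolve-and-resequence trajectory analysis.

The primary data are per-candidate, per-sample read counts exported by an
upstream polymorphism caller: for every candidate mutation and every
sequenced population sample, the number of reads supporting the mutant
allele and the total number of reads covering the site.  Frequencies are
never stored on disk; they are always derived from counts, because the
downstream Poisson test operates on the counts themselves.

Formats (UTF-8 TSV, one header line):

* variant table -- fixed columns ``mutation_id``, ``contig``, ``position``
  (1-based), ``ref_allele``, ``alt_allele``, ``gene``, ``mutation_class``
  followed by one ``<sample_id>:mut`` / ``<sample_id>:tot`` column pair per
  sample.  A mutation absent from a sample's caller output is encoded as
  ``mut = 0`` with the observed total, not as missing; zero coverage is
  encoded as ``tot = 0``.
* sample sheet -- columns ``sample_id``, ``treatment``, ``replicate``,
  ``generations`` plus optional marker-allele frequency columns
  ``f_A41T`` / ``f_D1303`` (blank cells mean "not measured").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = [
    "mutation_id",
    "contig",
    "position",
    "ref_allele",
    "alt_allele",
    "gene",
    "mutation_class",
]
MUTATION_CLASSES = ("snv", "indel", "other")
MARKER_COLUMNS = ("f_A41T", "f_D1303")


class TableValidationError(ValueError):
    """A variant table or sample sheet violates a format invariant."""


@dataclass
class VariantTable:
    """Candidate mutations with per-sample mutant/total read counts.

    Attributes
    ----------
    meta:
        One row per mutation, columns :data:`META_COLUMNS`, indexed 0..n-1.
    mut, tot:
        Integer DataFrames (mutations x samples) of mutant-supporting and
        total read counts, indexed by ``mutation_id``.
    """

    meta: pd.DataFrame
    mut: pd.DataFrame
    tot: pd.DataFrame

    @property
    def mutation_ids(self) -> list[str]:
        return list(self.meta["mutation_id"])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mut.columns)

    @property
    def n_mutations(self) -> int:
        return len(self.meta)

    def validate(self) -> "VariantTable":
        ids = self.meta["mutation_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise TableValidationError(
                f"duplicate mutation_id: {sorted(set(dup))}"
            )
        if list(self.mut.columns) != list(self.tot.columns):
            raise TableValidationError("mut/tot sample columns differ")
        if (self.mut.to_numpy() < 0).any() or (self.tot.to_numpy() < 0).any():
            raise TableValidationError("negative read counts")
        excess = self.mut.to_numpy() > self.tot.to_numpy()
        if excess.any():
            i, j = np.argwhere(excess)[0]
            raise TableValidationError(
                f"mutant_reads > total_reads for mutation "
                f"{self.mut.index[i]!r} in sample {self.mut.columns[j]!r}"
            )
        bad_class = ~self.meta["mutation_class"].isin(MUTATION_CLASSES)
        if bad_class.any():
            raise TableValidationError(
                f"unknown mutation_class: "
                f"{sorted(set(self.meta.loc[bad_class, 'mutation_class']))}"
            )
        return self

    def subset(self, mutation_ids) -> "VariantTable":
        """Row subset preserving the given order of ``mutation_ids``."""
        keep = list(mutation_ids)
        meta = (
            self.meta.set_index("mutation_id")
            .loc[keep]
            .reset_index()[META_COLUMNS]
        )
        return VariantTable(meta, self.mut.loc[keep], self.tot.loc[keep])


@dataclass
class SampleSheet:
    """Sample metadata: treatment, replicate, elapsed generations, markers.

    ``generations`` is the number of bacterial generations elapsed from the
    start of the experiment to the sample.  Marker columns hold the observed
    frequencies of the lineage-defining alleles (the two mutS alleles in the
    source design) and may be absent.
    """

    frame: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def has_markers(self) -> bool:
        return all(c in self.frame.columns for c in MARKER_COLUMNS)

    def generations(self, sample_ids=None) -> np.ndarray:
        f = self.frame.set_index("sample_id")
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        return f.loc[ids, "generations"].to_numpy(dtype=float)

    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.frame["treatment"]))

    def samples_in(self, treatment: str) -> list[str]:
        f = self.frame
        return list(f.loc[f["treatment"] == treatment, "sample_id"])

    def marker_frequencies(self, column: str, sample_ids=None) -> np.ndarray:
        if column not in self.frame.columns:
            raise KeyError(f"marker column {column!r} absent from sheet")
        f = self.frame.set_index("sample_id")
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        return f.loc[ids, column].to_numpy(dtype=float)

    def validate(self) -> "SampleSheet":
        f = self.frame
        dup = f["sample_id"][f["sample_id"].duplicated()]
        if len(dup):
            raise TableValidationError(f"duplicate sample_id: {sorted(set(dup))}")
        if (f["generations"].to_numpy(dtype=float) < 0).any():
            raise TableValidationError("negative generations")
        for col in MARKER_COLUMNS:
            if col in f.columns:
                v = f[col].to_numpy(dtype=float)
                v = v[~np.isnan(v)]
                if ((v < 0) | (v > 1)).any():
                    raise TableValidationError(
                        f"marker frequency outside [0, 1] in column {col!r}"
                    )
        return self


@dataclass
class FrequencyMatrix:
    """Mutations x samples allele-frequency matrix with a missing-data mask.

    ``values[i, s] = mut[i, s] / tot[i, s]`` wherever ``tot > 0``; cells with
    zero coverage are masked (``mask`` True) and carry value NaN.
    """

    values: pd.DataFrame
    mask: pd.DataFrame  # True where total_reads == 0 (no observation)

    @property
    def mutation_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def row(self, mutation_id: str) -> np.ndarray:
        """Frequency trajectory of one mutation (NaN where masked)."""
        return self.values.loc[mutation_id].to_numpy(dtype=float)

    def restrict(self, sample_ids) -> "FrequencyMatrix":
        ids = list(sample_ids)
        return FrequencyMatrix(self.values[ids], self.mask[ids])

    def subset_rows(self, mutation_ids) -> "FrequencyMatrix":
        ids = list(mutation_ids)
        return FrequencyMatrix(self.values.loc[ids], self.mask.loc[ids])


_SAMPLE_COL = re.compile(r"^(?P<sid>.+):(?P<kind>mut|tot)$")


def read_variant_table(path) -> VariantTable:
    """Read and validate a variant-table TSV.

    The header must contain all of :data:`META_COLUMNS` and, for every
    sample, both ``<sample_id>:mut`` and ``<sample_id>:tot``.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"contig": str, "gene": str})
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise TableValidationError(f"missing columns: {missing}")
    pairs: dict[str, set[str]] = {}
    for col in frame.columns:
        m = _SAMPLE_COL.match(col)
        if m:
            pairs.setdefault(m["sid"], set()).add(m["kind"])
    incomplete = sorted(s for s, kinds in pairs.items() if kinds != {"mut", "tot"})
    if incomplete:
        raise TableValidationError(
            f"sample columns without a mut/tot pair: {incomplete}"
        )
    sample_ids = [
        _SAMPLE_COL.match(c)["sid"]
        for c in frame.columns
        if c.endswith(":mut")
    ]
    meta = frame[META_COLUMNS].copy()
    meta["gene"] = meta["gene"].fillna("")
    idx = pd.Index(meta["mutation_id"], name="mutation_id")
    mut = pd.DataFrame(
        {s: frame[f"{s}:mut"].to_numpy(dtype=np.int64) for s in sample_ids},
        index=idx,
    )
    tot = pd.DataFrame(
        {s: frame[f"{s}:tot"].to_numpy(dtype=np.int64) for s in sample_ids},
        index=idx,
    )
    return VariantTable(meta, mut, tot).validate()


def write_variant_table(table: VariantTable, path) -> None:
    table.validate()
    out = table.meta.copy()
    for s in table.sample_ids:
        out[f"{s}:mut"] = table.mut[s].to_numpy()
        out[f"{s}:tot"] = table.tot[s].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", dtype={"replicate": str})
    required = ["sample_id", "treatment", "replicate", "generations"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableValidationError(f"sample sheet missing columns: {missing}")
    for col in MARKER_COLUMNS:
        if col in frame.columns and frame[col].isna().all():
            frame = frame.drop(columns=[col])
    return SampleSheet(frame).validate()


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.validate().frame.to_csv(path, sep="\t", index=False)


def compute_frequencies(table: VariantTable) -> FrequencyMatrix:
    """Derive the allele-frequency matrix mut/tot; zero coverage is masked."""
    table.validate()
    tot = table.tot.to_numpy(dtype=float)
    mut = table.mut.to_numpy(dtype=float)
    mask = tot == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(mask, np.nan, mut / np.where(mask, 1.0, tot))
    values = pd.DataFrame(vals, index=table.mut.index, columns=table.sample_ids)
    return FrequencyMatrix(values, pd.DataFrame(
        mask, index=table.mut.index, columns=table.sample_ids))


def summed_frequency(freqs: FrequencyMatrix, sample: str) -> float:
    """Total summed frequency M_s of all (retained) mutations in one sample.

    Masked cells contribute zero; an all-masked column sums to zero.
    """
    if sample not in freqs.values.columns:
        raise KeyError(f"unknown sample {sample!r}")
    col = freqs.values[sample].to_numpy(dtype=float)
    return float(np.nansum(col))


def summed_frequencies(freqs: FrequencyMatrix, sample_ids=None) -> np.ndarray:
    ids = freqs.sample_ids if sample_ids is None else list(sample_ids)
    return np.array([summed_frequency(freqs, s) for s in ids])


def read_genomediff_ra(paths: dict[str, str]) -> VariantTable:
    """Convert per-sample GenomeDiff read-alignment (RA) evidence to a table.

    ``paths`` maps sample_id -> GenomeDiff file.  Only RA lines are used;
    the union of (seq_id, position, ref, alt) across samples defines the
    candidate list, and per-sample support is taken from the ``ref_cov`` /
    ``new_cov`` key-value fields (forward/reverse read counts summed).
    Sites a sample does not report are encoded as zero coverage.  This is a
    deliberately minimal importer; full GenomeDiff semantics are out of
    scope.
    """
    support: dict[tuple, dict[str, tuple[int, int]]] = {}
    for sid, path in paths.items():
        with open(path) as fh:
            for line in fh:
                if not line.startswith("RA\t"):
                    continue
                fields = line.rstrip("\n").split("\t")
                seq_id, position = fields[3], int(fields[4])
                ref, alt = fields[6], fields[7]
                kv = dict(
                    f.split("=", 1) for f in fields[8:] if "=" in f
                )
                new = sum(int(x) for x in kv.get("new_cov", "0/0").split("/"))
                refc = sum(int(x) for x in kv.get("ref_cov", "0/0").split("/"))
                key = (seq_id, position, ref, alt)
                support.setdefault(key, {})[sid] = (new, new + refc)
    keys = sorted(support)
    sample_ids = list(paths)
    meta = pd.DataFrame(
        {
            "mutation_id": [
                f"{c}_{p}_{r}_{a}".replace(".", "") for c, p, r, a in keys
            ],
            "contig": [k[0] for k in keys],
            "position": [k[1] for k in keys],
            "ref_allele": [k[2] for k in keys],
            "alt_allele": [k[3] for k in keys],
            "gene": "",
            "mutation_class": [
                "snv" if len(k[2]) == 1 == len(k[3]) and k[2] != "." and k[3] != "."
                else "indel"
                for k in keys
            ],
        }
    )
    idx = pd.Index(meta["mutation_id"], name="mutation_id")
    mut = pd.DataFrame(0, index=idx, columns=sample_ids, dtype=np.int64)
    tot = pd.DataFrame(0, index=idx, columns=sample_ids, dtype=np.int64)
    for key, per_sample in support.items():
        mid = meta["mutation_id"][keys.index(key)]
        for sid, (m, t) in per_sample.items():
            mut.loc[mid, sid] = m
            tot.loc[mid, sid] = t
    return VariantTable(meta, mut, tot).validate()
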