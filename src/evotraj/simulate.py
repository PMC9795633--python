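"""Synthetic evolve-and-resequence experiments.

The generator emulates whole-population sequencing of an asexual bacterial
population in which one or more lineages accumulate mutations at constant
per-generation rates while their share of the population (the lineage
fraction) changes over time under clonal interference.  Each mutation that
arises inside a lineage hitchhikes neutrally with it: its population
frequency at every later sample equals the lineage fraction at that sample.
Observed read counts are binomial draws at a configurable mean depth, with
a per-base sequencing error rate, on top of negative-binomial depth
variation.  Sequencing-noise false positives appear as sites with one
latent low frequency that is constant across all samples of the run --
exactly the signature the downstream ubiquity filter removes.

Two switches trade stochasticity for exactness:

* ``deterministic_counts`` replaces Poisson mutation arrivals with their
  expectations.  The fractional part of the expected arrivals in a
  sampling interval is carried by a single partial-weight hitchhiker, so
  the summed true frequency contributed by lineage k at sample s equals
  ``r_k * f_k,s * g_s`` exactly.
* ``observation="exact"`` replaces binomial read sampling with an exact
  integer encoding of each true frequency (numerator/denominator from the
  reduced fraction), so observed frequencies reproduce true frequencies to
  machine precision while counts stay integral.

Together these make the generator -> tables -> rates chain an exact
identity, which is what the noise-free parameter-recovery checks rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .lineages import CLASS_TO_PAIRS, SUBSTITUTION_CLASSES
from .tables import SampleSheet, VariantTable

UNIFORM_WEIGHTS = tuple(1.0 / 6.0 for _ in SUBSTITUTION_CLASSES)


class SimulationConfigError(ValueError):
    """A simulation configuration violates an invariant."""


@dataclass
class LineageSpec:
    """One lineage: a constant accumulation rate and a fraction schedule.

    ``fraction_schedule`` gives the lineage's share of the population at
    each sample time (length must match the treatment's sample times).
    ``marker`` optionally names the lineage-defining allele; when set, the
    marker is emitted as an ordinary variant row whose true frequency
    equals the lineage fraction.  ``spectrum_weights`` are the six-class
    substitution probabilities for mutations arising in this lineage.
    """

    label: str
    rate_per_generation: float
    fraction_schedule: tuple[float, ...]
    marker: str | None = None
    marker_gene: str = ""
    marker_class: str = "snv"
    spectrum_weights: tuple[float, ...] = UNIFORM_WEIGHTS

    def validate(self, n_samples: int) -> "LineageSpec":
        if self.rate_per_generation < 0:
            raise SimulationConfigError(
                f"lineage {self.label!r}: negative rate"
            )
        f = np.asarray(self.fraction_schedule, dtype=float)
        if len(f) != n_samples:
            raise SimulationConfigError(
                f"lineage {self.label!r}: fraction schedule length {len(f)} "
                f"!= number of sample times {n_samples}"
            )
        if ((f < 0) | (f > 1)).any():
            raise SimulationConfigError(
                f"lineage {self.label!r}: fractions outside [0, 1]"
            )
        w = np.asarray(self.spectrum_weights, dtype=float)
        if len(w) != 6 or (w < 0).any() or abs(w.sum() - 1) > 1e-9:
            raise SimulationConfigError(
                f"lineage {self.label!r}: spectrum weights must be 6 "
                "nonnegative values summing to 1"
            )
        return self


@dataclass
class TreatmentSpec:
    """One evolution treatment: sampling design, lineages, noise model."""

    name: str
    sample_times: tuple[float, ...]
    lineages: tuple[LineageSpec, ...] = ()
    replicate: str = "1"
    depth_mean: float = 150.0
    depth_dispersion: float = 0.0
    seq_error_rate: float = 0.0
    n_false_positives: int = 0
    fp_freq_mean: float = 0.04
    fp_freq_concentration: float = 300.0

    def validate(self) -> "TreatmentSpec":
        g = np.asarray(self.sample_times, dtype=float)
        if len(g) == 0 or (g < 0).any() or (np.diff(g) <= 0).any():
            raise SimulationConfigError(
                f"treatment {self.name!r}: sample times must be "
                "nonnegative and strictly increasing"
            )
        if self.depth_mean <= 0:
            raise SimulationConfigError("depth_mean must be positive")
        if self.depth_dispersion < 0:
            raise SimulationConfigError("depth_dispersion must be >= 0")
        if not 0 <= self.seq_error_rate <= 1:
            raise SimulationConfigError("seq_error_rate must be in [0, 1]")
        if self.n_false_positives < 0:
            raise SimulationConfigError("n_false_positives must be >= 0")
        if not 0 <= self.fp_freq_mean <= 1:
            raise SimulationConfigError("fp_freq_mean must be in [0, 1]")
        for lin in self.lineages:
            lin.validate(len(g))
        total = np.zeros(len(g))
        for lin in self.lineages:
            total += np.asarray(lin.fraction_schedule, dtype=float)
        if (total > 1 + 1e-9).any():
            s = int(np.argmax(total))
            raise SimulationConfigError(
                f"treatment {self.name!r}: lineage fractions sum to "
                f"{total[s]:.4f} > 1 at sample index {s}"
            )
        return self

    def sample_ids(self) -> list[str]:
        return [
            f"{self.name}_{i + 1:02d}" for i in range(len(self.sample_times))
        ]


@dataclass
class SimConfig:
    treatments: tuple[TreatmentSpec, ...]
    seed: int = 0
    genome_length: int = 3_300_000
    gene_size: int = 1_500
    deterministic_counts: bool = False
    observation: str = "binomial"  # or "exact"

    def validate(self) -> "SimConfig":
        if self.observation not in ("binomial", "exact"):
            raise SimulationConfigError(
                f"unknown observation mode {self.observation!r}"
            )
        if not self.treatments:
            raise SimulationConfigError("at least one treatment required")
        names = [t.name for t in self.treatments]
        if len(set(names)) != len(names):
            raise SimulationConfigError("duplicate treatment names")
        for t in self.treatments:
            t.validate()
        return self


@dataclass
class TruthRecord:
    """Simulation ground truth for parameter-recovery checks.

    ``mutations`` has one row per emitted variant (originating treatment
    and lineage, false-positive flag, hitchhiker weight); ``frequencies``
    holds every variant's true per-sample population frequency; ``rates``
    maps treatment -> {lineage label: generating rate}.
    """

    mutations: pd.DataFrame
    frequencies: pd.DataFrame
    rates: dict[str, dict[str, float]]
    lineage_fractions: dict[str, pd.DataFrame] = field(default_factory=dict)

    def true_summed_frequencies(self, sample_ids=None) -> pd.Series:
        """Per-sample sum of true frequencies over non-false-positive rows."""
        real = self.mutations.loc[
            ~self.mutations["is_false_positive"], "mutation_id"
        ]
        cols = (
            list(self.frequencies.columns)
            if sample_ids is None
            else list(sample_ids)
        )
        return self.frequencies.loc[real, cols].sum(axis=0)


def sample_read_counts(
    true_freq: float, depth: int, seq_error_rate: float, rng
) -> tuple[int, int]:
    """Binomial observation of an allele frequency at a given depth.

    The per-read probability of supporting the mutant allele is
    ``p = f(1-e) + (1-f)e``: a true mutant read survives with probability
    1-e and a reference read miscalls with probability e.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= true_freq <= 1:
        raise ValueError("true_freq must be in [0, 1]")
    p = true_freq * (1 - seq_error_rate) + (1 - true_freq) * seq_error_rate
    return int(rng.binomial(depth, p)), int(depth)


def exact_read_counts(
    true_freq: float, max_denominator: int = 10**6
) -> tuple[int, int]:
    """Encode a frequency as an exact mutant/total integer pair."""
    if not 0 <= true_freq <= 1:
        raise ValueError("true_freq must be in [0, 1]")
    frac = Fraction(true_freq).limit_denominator(max_denominator)
    return frac.numerator, frac.denominator


def draw_substitution(lineage_weights, rng) -> tuple[str, str]:
    """Draw an ordered (ref, alt) base pair from six-class weights.

    Within a class the two ordered strand representations are
    equiprobable.
    """
    w = np.asarray(lineage_weights, dtype=float)
    if len(w) != 6:
        raise ValueError("expected 6 class weights")
    if (w < 0).any():
        raise ValueError("negative spectrum weights")
    total = w.sum()
    if total <= 0:
        raise ValueError("spectrum weights sum to zero")
    cls = SUBSTITUTION_CLASSES[int(rng.choice(6, p=w / total))]
    pair = CLASS_TO_PAIRS[cls][int(rng.integers(2))]
    return pair


def _draw_depth(spec: TreatmentSpec, rng) -> int:
    """Per-site, per-sample sequencing depth (>= 1).

    Negative binomial with mean ``depth_mean`` and variance
    ``mean + dispersion * mean**2``; dispersion 0 gives constant depth.
    """
    m = spec.depth_mean
    if spec.depth_dispersion == 0:
        return max(1, int(round(m)))
    k = 1.0 / spec.depth_dispersion  # shape (number of failures)
    p = k / (k + m)
    return max(1, int(rng.negative_binomial(k, p)))


def simulate_experiment(
    config: SimConfig,
) -> tuple[VariantTable, SampleSheet, TruthRecord]:
    """Generate a complete synthetic experiment.

    Returns the variant table (all treatments' samples as columns), the
    sample sheet (with marker-allele frequency columns filled from the
    observed marker rows where markers are defined), and the ground truth.
    Fully reproducible: identical config (including seed) gives identical
    outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    all_samples: list[str] = []
    sheet_rows: list[dict] = []
    for spec in config.treatments:
        sids = spec.sample_ids()
        all_samples.extend(sids)
        for sid, g in zip(sids, spec.sample_times):
            sheet_rows.append(
                {
                    "sample_id": sid,
                    "treatment": spec.name,
                    "replicate": spec.replicate,
                    "generations": float(g),
                }
            )

    # --- true mutations, markers, false positives -------------------------
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []
    true_freq_rows: list[np.ndarray] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"mut_{counter:05d}"

    def add_row(
        mid, treatment, lineage, freqs, weight, is_fp, ref, alt, cls, gene=None
    ):
        position = int(rng.integers(1, config.genome_length + 1))
        if gene is None:
            gene = f"gene_{(position - 1) // config.gene_size:05d}"
        meta_rows.append(
            {
                "mutation_id": mid,
                "contig": "contig_1",
                "position": position,
                "ref_allele": ref,
                "alt_allele": alt,
                "gene": gene,
                "mutation_class": cls,
            }
        )
        truth_rows.append(
            {
                "mutation_id": mid,
                "treatment": treatment,
                "lineage": lineage,
                "weight": weight,
                "is_false_positive": is_fp,
            }
        )
        true_freq_rows.append(freqs)

    n_total = len(all_samples)
    offsets = {}
    pos = 0
    for spec in config.treatments:
        offsets[spec.name] = pos
        pos += len(spec.sample_times)

    rates: dict[str, dict[str, float]] = {}
    fractions: dict[str, pd.DataFrame] = {}
    for spec in config.treatments:
        off = offsets[spec.name]
        n_s = len(spec.sample_times)
        g = np.asarray(spec.sample_times, dtype=float)
        rates[spec.name] = {
            lin.label: lin.rate_per_generation for lin in spec.lineages
        }
        fractions[spec.name] = pd.DataFrame(
            {
                lin.label: np.asarray(lin.fraction_schedule, dtype=float)
                for lin in spec.lineages
            },
            index=spec.sample_ids(),
        )

        for lin in spec.lineages:
            f = np.asarray(lin.fraction_schedule, dtype=float)
            if lin.marker is not None:
                freqs = np.zeros(n_total)
                freqs[off : off + n_s] = f
                if lin.marker_class == "snv":
                    ref, alt = draw_substitution(lin.spectrum_weights, rng)
                else:
                    ref, alt = "N", "."
                add_row(
                    f"marker_{spec.name}_{lin.label}",
                    spec.name,
                    lin.label,
                    freqs,
                    1.0,
                    False,
                    ref,
                    alt,
                    lin.marker_class,
                    gene=lin.marker_gene or f"gene_{lin.label}",
                )
            # mutation arrivals per inter-sample interval
            g_prev = 0.0
            for s in range(n_s):
                lam = lin.rate_per_generation * (g[s] - g_prev)
                g_prev = g[s]
                if lam <= 0:
                    continue
                if config.deterministic_counts:
                    n_full = int(np.floor(lam + 1e-12))
                    partial = lam - n_full
                    weights = [1.0] * n_full
                    if partial > 1e-12:
                        weights.append(partial)
                else:
                    weights = [1.0] * int(rng.poisson(lam))
                for w in weights:
                    freqs = np.zeros(n_total)
                    freqs[off + s : off + n_s] = w * f[s:]
                    ref, alt = draw_substitution(lin.spectrum_weights, rng)
                    add_row(
                        next_id(), spec.name, lin.label, freqs, w, False,
                        ref, alt, "snv",
                    )

        # false positives: one latent frequency, constant across the run
        for _ in range(spec.n_false_positives):
            m = spec.fp_freq_mean
            if m in (0.0, 1.0):
                latent = m
            else:
                c = spec.fp_freq_concentration
                latent = float(rng.beta(m * c, (1 - m) * c))
            freqs = np.full(n_total, latent)
            ref, alt = draw_substitution(UNIFORM_WEIGHTS, rng)
            add_row(
                next_id(), spec.name, "", freqs, 1.0, True, ref, alt, "snv"
            )

    # --- observation ------------------------------------------------------
    meta = pd.DataFrame(
        meta_rows,
        columns=[
            "mutation_id",
            "contig",
            "position",
            "ref_allele",
            "alt_allele",
            "gene",
            "mutation_class",
        ],
    )
    ids = pd.Index(meta["mutation_id"], name="mutation_id")
    true_freqs = pd.DataFrame(
        np.array(true_freq_rows).reshape(len(meta_rows), n_total),
        index=ids,
        columns=all_samples,
    )
    mut = pd.DataFrame(0, index=ids, columns=all_samples, dtype=np.int64)
    tot = pd.DataFrame(0, index=ids, columns=all_samples, dtype=np.int64)
    spec_of = {
        sid: spec for spec in config.treatments for sid in spec.sample_ids()
    }
    for sid in all_samples:
        spec = spec_of[sid]
        for mid in ids:
            f = float(true_freqs.loc[mid, sid])
            if config.observation == "exact":
                m, t = exact_read_counts(f)
            else:
                depth = _draw_depth(spec, rng)
                m, t = sample_read_counts(f, depth, spec.seq_error_rate, rng)
            mut.loc[mid, sid] = m
            tot.loc[mid, sid] = t

    # marker-frequency columns on the sheet (observed marker trajectories)
    sheet = pd.DataFrame(sheet_rows)
    for spec in config.treatments:
        for lin in spec.lineages:
            if lin.marker is None:
                continue
            col = f"f_{lin.label.removeprefix('mutS_')}"
            mid = f"marker_{spec.name}_{lin.label}"
            if col not in sheet.columns:
                sheet[col] = np.nan
            for sid in spec.sample_ids():
                t = int(tot.loc[mid, sid])
                sheet.loc[sheet["sample_id"] == sid, col] = (
                    float(mut.loc[mid, sid]) / t if t else np.nan
                )

    table = VariantTable(meta, mut, tot).validate()
    truth = TruthRecord(
        mutations=pd.DataFrame(truth_rows).set_index("mutation_id", drop=False)
        if truth_rows
        else pd.DataFrame(
            columns=[
                "mutation_id",
                "treatment",
                "lineage",
                "weight",
                "is_false_positive",
            ]
        ),
        frequencies=true_freqs,
        rates=rates,
        lineage_fractions=fractions,
    )
    return table, SampleSheet(sheet).validate(), truth


def write_truth(truth: TruthRecord, path) -> None:
    """Write ground truth as a TSV (one row per mutation, freq_<sample>)."""
    out = truth.mutations.reset_index(drop=True).copy()
    for sid in truth.frequencies.columns:
        out[f"freq_{sid}"] = truth.frequencies[sid].to_numpy()
    out.to_csv(path, sep="\t", index=False)
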