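"""Published study designs and fitted rates, as simulation inputs.

These constants encode the sampling schedules and reported per-generation
mutation-accumulation rates of the source experiments -- a gut commensal
(*Lactiplantibacillus plantarum*) evolved in a mouse intestine vs. the
mouse diet, and in *Drosophila* vs. the fly diet.  They parameterize the
synthetic-experiment generator and the noise-free parameter-recovery
checks; nothing here is a fitted output of this package.
"""

from __future__ import annotations

import numpy as np

from .simulate import LineageSpec, SimConfig, TreatmentSpec

# --- sampling schedules (elapsed bacterial generations) -------------------

#: Mouse-host sampling schedule: 15 whole-population sequencing time points
#: across five mouse generations (F0-F4) over ten months.
MOUSE_HOST_GENERATIONS = (
    30.0, 60.0, 63.0, 90.0, 93.0, 110.0, 120.0, 150.0,
    170.0, 200.0, 230.0, 240.0, 260.0, 280.0, 286.0,
)

#: Mouse-diet schedule: transfers 2 and 14 (~20 generations per transfer).
MOUSE_DIET_GENERATIONS = (40.0, 280.0)

#: Fly host/diet schedule: evolution cycles 2, 8, 14, 20 at ~88
#: generations per cycle.
FLY_GENERATIONS = (176.0, 704.0, 1232.0, 1760.0)

# --- reported per-generation accumulation rates ---------------------------

RATE_MUTS_A41T = 2.453   # mouse host, mutS A41T mutator lineage
RATE_MUTS_D1303 = 0.310  # mouse host, mutS del-1303 mutator lineage
RATE_MOUSE_DIET = 0.0076  # mouse diet (implied by the 323-/41-fold factors)
RATE_FLY_HOST = 0.00177
RATE_FLY_DIET = 0.00150

# --- mouse-host lineage-fraction schedules --------------------------------
# Clonal-interference trajectories of the two mutS mutator lineages across
# the 15 samples: A41T rises first (up to ~90% in F0), collapses by month
# 10 while del-1303 sweeps; in F1 neither exceeds 20%, in F2 both reach
# ~40-50% then crash, in F3/F4 del-1303 fixes.

A41T_FRACTIONS = (
    0.30, 0.70, 0.10, 0.90, 0.15, 0.40, 0.10, 0.45,
    0.02, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00,
)
D1303_FRACTIONS = (
    0.00, 0.05, 0.10, 0.05, 0.10, 0.45, 0.15, 0.50,
    0.03, 0.60, 0.90, 0.95, 1.00, 1.00, 1.00,
)
ANCESTRAL_FRACTIONS = tuple(
    round(1.0 - a - d, 10)
    for a, d in zip(A41T_FRACTIONS, D1303_FRACTIONS)
)

#: Six-class substitution weights: mismatch-repair-deficient mutator
#: lineages are dominated by A:T->G:C transitions ...
MUTATOR_SPECTRUM = (0.90, 0.02, 0.02, 0.04, 0.01, 0.01)
#: ... while nonmutator populations show mostly C:G->A:T / C:G->T:A.
NONMUTATOR_SPECTRUM = (0.08, 0.05, 0.05, 0.40, 0.37, 0.05)

#: Mean sequencing depth within the range reported for the study (124-193).
DEFAULT_DEPTH = 150.0


def mouse_host_treatment(
    depth_mean: float = DEFAULT_DEPTH,
    depth_dispersion: float = 0.01,
    seq_error_rate: float = 0.001,
    n_false_positives: int = 30,
    fp_freq_mean: float = 0.04,
) -> TreatmentSpec:
    """Mouse-host treatment: two mutS mutator lineages plus nonmutators."""
    return TreatmentSpec(
        name="mouse_host",
        sample_times=MOUSE_HOST_GENERATIONS,
        lineages=(
            LineageSpec(
                label="mutS_A41T",
                rate_per_generation=RATE_MUTS_A41T,
                fraction_schedule=A41T_FRACTIONS,
                marker="mutS_A41T",
                marker_gene="mutS",
                spectrum_weights=MUTATOR_SPECTRUM,
            ),
            LineageSpec(
                label="mutS_D1303",
                rate_per_generation=RATE_MUTS_D1303,
                fraction_schedule=D1303_FRACTIONS,
                marker="mutS_D1303",
                marker_gene="mutS",
                marker_class="indel",
                spectrum_weights=MUTATOR_SPECTRUM,
            ),
            LineageSpec(
                label="ancestral",
                rate_per_generation=RATE_MOUSE_DIET,
                fraction_schedule=ANCESTRAL_FRACTIONS,
                spectrum_weights=NONMUTATOR_SPECTRUM,
            ),
        ),
        depth_mean=depth_mean,
        depth_dispersion=depth_dispersion,
        seq_error_rate=seq_error_rate,
        n_false_positives=n_false_positives,
        fp_freq_mean=fp_freq_mean,
    )


def mouse_diet_treatment(
    depth_mean: float = DEFAULT_DEPTH,
    depth_dispersion: float = 0.01,
    seq_error_rate: float = 0.001,
    n_false_positives: int = 10,
    fp_freq_mean: float = 0.04,
) -> TreatmentSpec:
    """Mouse-diet treatment: a single nonmutator population."""
    n = len(MOUSE_DIET_GENERATIONS)
    return TreatmentSpec(
        name="mouse_diet",
        sample_times=MOUSE_DIET_GENERATIONS,
        lineages=(
            LineageSpec(
                label="population",
                rate_per_generation=RATE_MOUSE_DIET,
                fraction_schedule=(1.0,) * n,
                spectrum_weights=NONMUTATOR_SPECTRUM,
            ),
        ),
        depth_mean=depth_mean,
        depth_dispersion=depth_dispersion,
        seq_error_rate=seq_error_rate,
        n_false_positives=n_false_positives,
        fp_freq_mean=fp_freq_mean,
    )


def fly_treatment(
    name: str,
    rate: float,
    depth_mean: float = DEFAULT_DEPTH,
    depth_dispersion: float = 0.01,
    seq_error_rate: float = 0.001,
    n_false_positives: int = 10,
    fp_freq_mean: float = 0.04,
) -> TreatmentSpec:
    """Fly host or diet treatment: a single nonmutator population."""
    n = len(FLY_GENERATIONS)
    return TreatmentSpec(
        name=name,
        sample_times=FLY_GENERATIONS,
        lineages=(
            LineageSpec(
                label="population",
                rate_per_generation=rate,
                fraction_schedule=(1.0,) * n,
                spectrum_weights=NONMUTATOR_SPECTRUM,
            ),
        ),
        depth_mean=depth_mean,
        depth_dispersion=depth_dispersion,
        seq_error_rate=seq_error_rate,
        n_false_positives=n_false_positives,
        fp_freq_mean=fp_freq_mean,
    )


def mouse_study_config(seed: int = 0, **kwargs) -> SimConfig:
    """Mouse host + diet treatments in one simulated run."""
    return SimConfig(
        treatments=(
            mouse_host_treatment(**kwargs),
            mouse_diet_treatment(**kwargs),
        ),
        seed=seed,
    )


def fly_study_config(seed: int = 0, **kwargs) -> SimConfig:
    """Fly host + diet treatments in one simulated run."""
    return SimConfig(
        treatments=(
            fly_treatment("fly_host", RATE_FLY_HOST, **kwargs),
            fly_treatment("fly_diet", RATE_FLY_DIET, **kwargs),
        ),
        seed=seed,
    )


def expected_summed_frequencies(
    generations, rates: dict[str, float], fractions: dict[str, np.ndarray]
) -> np.ndarray:
    """Noise-free model prediction M_s = sum_k r_k * f_k,s * g_s."""
    g = np.asarray(generations, dtype=float)
    m = np.zeros_like(g)
    for label, rate in rates.items():
        m += rate * np.asarray(fractions[label], dtype=float) * g
    return m
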