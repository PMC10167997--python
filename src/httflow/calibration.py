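"""Monte-Carlo validation routines for the detection, dating and driver stages.

These run the pipeline end to end on seeded synthetic data at the study
conditions (30 reference genes of 300 codons; two lineages split deep enough
for a mean reference dS near 0.6; transfers young enough for a TE dS near or
below 0.1) and report operating characteristics: empirical type-I error and
power of the horizontal-transfer test, dating recovery of injected
transfers, and selection behaviour of the ecological driver model.
"""

from __future__ import annotations

import numpy as np

from .core_io import SpeciesTree
from .divergence_stats import pair_stats
from .eco_drivers import fit_driver_model
from .htt_detection import fit_reference_model, vhica_test
from .htt_events import calibrate_rate, date_event
from .synthetic_data import (
    SimConfig,
    TEFamilySpec,
    TransferSpec,
    evolve_genes,
    evolve_te_family,
    simulate_driver_dataset,
)

#: deep split giving mean reference dS = 2 x 0.02 x 15 = 0.6
_SPLIT_MYA = 15.0
_RATE = 0.02
N_GENES = 30
N_CODONS = 300


def _two_species_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(f"(A:{_SPLIT_MYA},B:{_SPLIT_MYA});")


def _one_replicate(seed: int, transfer_time: float | None):
    """Simulate one reference set plus one TE and run the contrast."""
    tree = _two_species_tree()
    cfg = SimConfig(
        tree=tree, seed=seed, rate=_RATE, n_genes=N_GENES, n_codons=N_CODONS
    )
    rng = np.random.default_rng(seed)
    refs = evolve_genes(cfg, rng)
    transfer = (
        None
        if transfer_time is None
        else TransferSpec(donor="A", acceptor="B", time=transfer_time)
    )
    te = evolve_te_family(cfg, TEFamilySpec(name="te", transfer=transfer), rng)
    model = fit_reference_model(refs, ("A", "B"))
    return refs, te, model, vhica_test(model, pair_stats(te, "A", "B"))


def null_type_one_rate(n_reps: int = 1000, seed: int = 1) -> float:
    """Empirical rejection rate at alpha = 0.05 for vertical TEs.

    The TE is generated by the same process as the reference genes (same
    tree, rate and bias distribution), so every rejection is a false
    positive.
    """
    base = (seed * 1_000_003) % 2**31
    rejections = 0
    for rep in range(n_reps):
        *_, signal = _one_replicate((base + rep) % 2**31, transfer_time=None)
        rejections += signal.significant
    return rejections / n_reps


def detection_power(n_reps: int = 50, seed: int = 1) -> float:
    """Detection rate for transfers with pair dS ~ 0.1 (t = 2.5 Myr)."""
    base = (seed * 2_000_003) % 2**31
    detected = 0
    for rep in range(n_reps):
        *_, signal = _one_replicate((base + rep) % 2**31, transfer_time=2.5)
        detected += signal.significant
    return detected / n_reps


def dating_recovery(
    n_reps: int = 50, seed: int = 1, t_star: float = 5.0
) -> float:
    """Mean dated age of transfers injected at ``t_star`` Mya.

    The rate is re-calibrated per replicate from the simulated reference
    genes and the (known) split age, mirroring the real workflow.
    """
    base = (seed * 3_000_017) % 2**31
    dates = []
    for rep in range(n_reps):
        refs, te, model, signal = _one_replicate(
            (base + rep) % 2**31, transfer_time=t_star
        )
        cal = calibrate_rate(refs, "A", "B", calibration_age=_SPLIT_MYA)
        st = pair_stats(te, "A", "B")
        dates.append(date_event(st.ds, cal.rate))
    return float(np.mean(dates))


def driver_recovery(n_reps: int = 100, seed: int = 1) -> tuple[float, float]:
    """Recovery of a true positive abiotic effect over seeded replicates.

    Returns ``(beta_positive_rate, retention_rate)``: the fraction of
    replicates in which the estimated abiotic coefficient (REML fit of the
    highest-ranked model containing the predictor) is positive, and the
    fraction in which the abiotic predictor appears in the
    delta-AICc <= 2 best set.
    """
    from ._lmm import fit_lmm_crossed

    base = (seed * 4_000_037) % 2**31
    beta_positive = retained = 0
    for rep in range(n_reps):
        data = simulate_driver_dataset(seed=(base + rep) % 2**31, beta_abiotic=0.5)
        result = fit_driver_model(data)
        retained += any(
            "abiotic" in m.split("+") for m in result.best_models
        )
        top_with_abiotic = next(
            m for m in result.ranking.model if "abiotic" in m.split("+")
        )
        predictors = top_with_abiotic.split("+")
        x = np.column_stack(
            [np.ones(len(data))] + [data[p].to_numpy() for p in predictors]
        )
        refit = fit_lmm_crossed(
            data.logit_dij.to_numpy(), x, data.acting.to_numpy(),
            data.target.to_numpy(), reml=True,
        )
        beta_positive += refit.params[1 + predictors.index("abiotic")] > 0
    return beta_positive / n_reps, retained / n_reps


def driver_null_rate(n_reps: int = 100, seed: int = 1) -> float:
    """Fraction of pure-noise replicates keeping the null model in the
    delta-AICc <= 2 best set."""
    base = (seed * 5_000_011) % 2**31
    ok = 0
    for rep in range(n_reps):
        data = simulate_driver_dataset(seed=(base + rep) % 2**31, beta_abiotic=0.0)
        result = fit_driver_model(data)
        ok += "null" in result.best_models
    return ok / n_reps
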