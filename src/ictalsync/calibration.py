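"""Replicated simulation studies calibrating the terminal-hypersync detector.

Two studies validate the full chain (simulation → windowing → connectivity →
baseline adjustment → mixed model → Dunnett contrasts → calls):

* a *null* study on cohorts with no lagged coupling at all, where every
  phase is exchangeable: the interaction-term rejection rate and the
  per-location-family Dunnett familywise error rate should sit at the
  nominal alpha, and the (stricter) all-contrasts call rate below it;
* a *power* study on cohorts with one coupled pair whose gain is boosted
  threefold in the terminal window: both coupled electrodes should be
  called, and no occipital electrode.

Studies run on deliberately scaled-down cohorts (64 Hz sampling — the bands
of interest end at 8 Hz — with ~30 s seizures on a ~60 s cycle and 11-min
inter-ictal lead-in/lead-out segments supplying baseline windows) so that
hundreds of replicates complete on one CPU; the statistical structure the
detector relies on is unchanged.
"""

from __future__ import annotations

import numpy as np

from .pipeline import build_synchrony_table
from .simulate import CoupledPair, SimConfig, simulate_cohort
from .stats import (
    ModelSpec,
    call_terminal_hypersync,
    dunnett_vs_termination,
    fit_lmm,
    type2_wald,
)

INTERACTION_TERM = "C(phase, Sum):C(location, Sum)"


def reduced_sim_config(
    n_seizures: int,
    terminal_boost: float,
    coupled_pairs: tuple[CoupledPair, ...],
    seed: int,
) -> SimConfig:
    """Scaled-down cohort for replicated studies (see module docstring)."""
    return SimConfig(
        fs=64.0,
        n_seizures=n_seizures,
        cycle_period_s=60.0,
        cycle_sd_s=5.0,
        duration_mean_s=30.0,
        duration_sd_s=3.0,
        coupled_pairs=coupled_pairs,
        terminal_boost=terminal_boost,
        seed=seed,
    )


def _cohort_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _analyze_cohort(cfg: SimConfig, level: str, dunnett_seed: int, alpha: float):
    recording, truth = simulate_cohort(cfg)
    table = build_synchrony_table(recording, truth.markers, patient_id="sim")
    fit = fit_lmm(table, ModelSpec(), level=level)
    wald = type2_wald(fit)
    dunnett = dunnett_vs_termination(fit, seed=dunnett_seed)
    calls = call_terminal_hypersync(dunnett, alpha=alpha, rule="all")
    return wald, dunnett, calls


def null_calibration(
    n_cohorts: int = 200,
    n_seizures: int = 30,
    level: str = "region",
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I behavior on exchangeable null cohorts (no coupling, no boost).

    Returns the interaction-term rejection rate (should be ≈ alpha), the
    per-location-family Dunnett familywise error rate (any contrast rejected;
    the quantity Dunnett's adjustment calibrates to alpha), and the
    all-contrasts terminal-call rate (strictly below alpha by construction).
    """
    seeds = _cohort_seeds(seed, n_cohorts)
    interaction_rejections = 0
    families = 0
    family_hits = 0
    call_hits = 0
    for cohort_seed in seeds:
        cfg = reduced_sim_config(n_seizures, 1.0, (), int(cohort_seed))
        wald, dunnett, calls = _analyze_cohort(cfg, level, int(cohort_seed), alpha)
        p_int = float(wald.loc[wald["term"] == INTERACTION_TERM, "p"].iloc[0])
        interaction_rejections += p_int < alpha
        for _, sub in dunnett.table.groupby("location", sort=False):
            families += 1
            family_hits += bool((sub["p_adj"] < alpha).any())
        call_hits += sum(calls.values())
    return {
        "n_cohorts": n_cohorts,
        "n_families": families,
        "interaction_rejection_rate": interaction_rejections / n_cohorts,
        "family_fwer": family_hits / families,
        "call_rate": call_hits / families,
    }


def power_study(
    n_cohorts: int = 100,
    n_seizures: int = 60,
    terminal_boost: float = 3.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Detection power and localization with one boosted coupled pair.

    Electrode-level calls on cohorts coupling C3–C4 with the default lag and
    gain, boosted in the terminal window. Reports the rate at which both
    coupled electrodes are called, at least one is, and any occipital
    electrode is (localization false positives).
    """
    pair = CoupledPair("C3", "C4")
    seeds = _cohort_seeds(seed, n_cohorts)
    both = either = occipital = 0
    per_electrode: dict[str, int] = {}
    for cohort_seed in seeds:
        cfg = reduced_sim_config(n_seizures, terminal_boost, (pair,), int(cohort_seed))
        _, _, calls = _analyze_cohort(cfg, "electrode", int(cohort_seed), alpha)
        both += calls["C3"] and calls["C4"]
        either += calls["C3"] or calls["C4"]
        occipital += calls["O1"] or calls["O2"]
        for lab, hit in calls.items():
            per_electrode[lab] = per_electrode.get(lab, 0) + hit
    return {
        "n_cohorts": n_cohorts,
        "power_both_coupled": both / n_cohorts,
        "power_any_coupled": either / n_cohorts,
        "occipital_false_call_rate": occipital / n_cohorts,
        "per_electrode_call_rate": {k: v / n_cohorts for k, v in per_electrode.items()},
    }


def binomial_ci(p: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Central binomial proportion interval around a hypothesized rate ``p``.

    The acceptance band for an observed rate over ``n`` independent
    replicates when the true rate is ``p``.
    """
    from scipy import stats as sps

    lo = sps.binom.ppf((1 - level) / 2, n, p) / n
    hi = sps.binom.ppf(1 - (1 - level) / 2, n, p) / n
    return float(lo), float(hi)
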