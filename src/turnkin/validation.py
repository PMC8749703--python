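"""Quantitative self-checks of the pipeline on synthetic cohorts.

These routines regenerate synthetic trials from the group profiles, run
the full segmentation/extraction path, and score it against the exact
ground truth; plus statistical-calibration and filter-response checks.
They back both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math

import numpy as np

from . import reference_values as ref
from .group_stats import pct_change_symmetric, pct_diff_reference, ttest_unpaired
from .pipeline import PipelineConfig, analyze_trial
from .preprocess import FilterSpec, cumulative_rotation, lowpass
from .synthetic import GroupProfile, generate_trial
from .temporal_segmentation import stance_fraction, turn_duration


def whole_turn_contrasts() -> dict:
    """Percent differences between group means of the whole-turn parameters.

    Recomputes, from the published group means, the headline contrasts
    (cycle count, turn duration and flexion–extension angular velocities)
    using the plain reference convention.
    """
    out = {}
    for item in ref.REFERENCE_PCT_DIFFS:
        key = (item["parameter"], item["placement"], item["direction"])
        larger = ref.temporal_mean(*key, item["larger"])
        other = ref.temporal_mean(*key, "HI" if item["larger"] == "SS" else "SS")
        name = key[0] if key[0] in ("n_cycles", "turn_duration") else \
            f"{key[1]}_{key[2]}_av"
        out[name] = pct_diff_reference(larger, other)
    return out


def partition_comparison_check() -> dict:
    """Recompute every published partition-comparison cell.

    Returns the worked-example cells plus the share of all cells whose
    symmetric percent change, recomputed from the printed partition means,
    lands within ±1 of the printed integer.
    """
    total = 0
    within = 0
    for row in ref.ALL_SPATIAL_ROWS:
        cells = [(row["k2"][0], row["k2"][1], row["k2_cmp"][0])]
        cells += [(row["k4"][j], row["k4"][j + 1], row["k4_cmp"][j])
                  for j in range(3)]
        for x1, x2, printed in cells:
            total += 1
            if abs(pct_change_symmetric(x1, x2) - printed) <= 1.0:
                within += 1

    def cell(rows, placement, direction, parameter, group):
        for r in rows:
            if (r["placement"], r["direction"], r["parameter"], r["group"]) \
                    == (placement, direction, parameter, group):
                return r
        raise KeyError((placement, direction, parameter, group))

    av = ref.SPATIAL_ANGULAR_VELOCITY
    rom = ref.SPATIAL_ROM
    examples = {
        "sternum_av_halves_ss": pct_change_symmetric(
            *cell(av, "sternum", "flexext", "angular_velocity", "SS")["k2"]),
        "trailing_av_halves_hi": pct_change_symmetric(
            *cell(av, "shank_trailing", "flexext", "angular_velocity",
                  "HI")["k2"]),
        "leading_av_q2_vs_q1_hi": pct_change_symmetric(
            *cell(av, "shank_leading", "flexext", "angular_velocity",
                  "HI")["k4"][:2]),
        "trailing_rot_av_halves_hi": pct_change_symmetric(
            *cell(av, "shank_trailing", "rotation", "angular_velocity",
                  "HI")["k2"]),
        "leading_rom_halves_hi": pct_change_symmetric(
            *cell(rom, "shank_leading", "flexext", "rom", "HI")["k2"]),
    }
    examples["cells_within_1_pct"] = within / total * 100.0
    examples["n_cells"] = total
    return examples


def recovery_metrics(n_per_group: int = 100, seed: int = 0,
                     config: PipelineConfig | None = None) -> dict:
    """Score segmentation recovery against ground truth on fresh cohorts.

    Generates ``n_per_group`` trials per group at the default (noisy)
    profiles and reports: the percentage of trials whose detected cycle
    count equals the ground truth, the mean absolute stance-fraction error
    in percentage points, the mean relative turn-duration error, and the
    mean/95th-percentile absolute deviation of internal partition-boundary
    angles from their targets ``j × total / k``.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    cycle_hits = 0
    stance_err, dur_err, boundary_err = [], [], []
    n_total = 0
    for group in ("SS", "HI"):
        profile = GroupProfile.for_group(group)
        seeds = rng.integers(0, 2**31 - 1, size=n_per_group)
        for s in seeds:
            trial = generate_trial(profile, int(s))
            gt = trial.ground_truth
            events, partitions, _ = analyze_trial(trial, config)
            n_total += 1
            if events.n_swings == gt.n_cycles:
                cycle_hits += 1
            stance_err.append(abs(stance_fraction(events)[1]
                                  - gt.stance_fraction[0] * 100.0))
            dur_err.append(abs(turn_duration(events) - gt.turn_duration)
                           / gt.turn_duration * 100.0)
            for k, ps in partitions.items():
                for j in range(1, k):
                    boundary_err.append(abs(
                        ps.boundary_angles[j] - j * ps.total_rotation / k))
    boundary_err = np.asarray(boundary_err)
    return {
        "n_trials": n_total,
        "cycle_detection_accuracy_pct": cycle_hits / n_total * 100.0,
        "stance_mae_pp": float(np.mean(stance_err)),
        "duration_mean_rel_err_pct": float(np.mean(dur_err)),
        "boundary_angle_mae_deg": float(boundary_err.mean()),
        "boundary_angle_p95_deg": float(np.quantile(boundary_err, 0.95)),
    }


def type_one_error_rate(n_replicates: int = 500, n_per_group: int = 14,
                        alpha: float = 0.05, seed: int = 0) -> dict:
    """Significance rate when both groups share one generator profile.

    Draws the stance-fraction parameter of the SS profile for both groups
    of each replicate cohort and counts rejections of the (true) null; the
    rate should match alpha within Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    dist = GroupProfile.for_group("SS").stance_fraction
    hits = 0
    for _ in range(n_replicates):
        a = [dist.sample(rng) for _ in range(n_per_group)]
        b = [dist.sample(rng) for _ in range(n_per_group)]
        if ttest_unpaired(a, b, alpha)[2]:
            hits += 1
    rate = hits / n_replicates
    se = math.sqrt(alpha * (1 - alpha) / n_replicates)
    return {"rate": rate, "alpha": alpha, "n_replicates": n_replicates,
            "two_se": 2 * se}


def ttest_oracle_deviation(n_samples: int = 1000, seed: int = 0) -> float:
    """Max |Δt| + |Δp| between the t-test and a textbook recomputation."""
    from scipy.stats import t as tdist

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_samples):
        na, nb = rng.integers(2, 12, size=2)
        a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), na)
        b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), nb)
        t, p, _ = ttest_unpaired(a, b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) \
            / (na + nb - 2)
        t0 = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        p0 = 2 * tdist.sf(abs(t0), na + nb - 2)
        worst = max(worst, abs(t - t0) + abs(p - p0))
    return worst


def filter_response_check(fs: float = 60.0) -> dict:
    """Measured zero-phase Butterworth gain vs the analytic response."""
    spec = FilterSpec()
    out = {}
    t = np.arange(int(30 * fs)) / fs
    mid = slice(t.size // 4, 3 * t.size // 4)
    for freq in (0.5, 20.0):
        y = lowpass(np.sin(2 * np.pi * freq * t), fs, spec)
        measured = float(np.max(np.abs(y[mid])))
        analytic = (1.0 / (1.0 + (freq / spec.cutoff) ** (2 * spec.order)))
        out[f"gain_{freq:g}hz"] = measured
        out[f"gain_{freq:g}hz_analytic"] = analytic
    # wrapped-ramp recovery
    tt = np.linspace(0, 6, 361)
    wrapped = (350.0 * tt / 6.0 + 180.0) % 360.0 - 180.0
    out["unwrapped_total_deg"] = float(
        cumulative_rotation(wrapped, "ccw")[-1])
    return out
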