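"""Condition-level simulation campaigns and summary statistics.

The model's predictions are reported as per-condition aggregates over
repeated blocks of simulated trials (the reference campaign size is 30
blocks of 1000 trials).  Rates of the change-of-mind categories are
computed over *included* trials only: early responses, misses and
double changes of mind are excluded, mirroring the behavioural
analysis.  Reaction times are averaged over included trials with a
correct perceptual response.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .engine import simulate_free, simulate_trials
from .network import NetworkParams
from .params import ParameterVector
from .task import TargetLayout, TaskParams, close_layout, far_layout

SUMMARY_FIELDS = (
    "n_trials", "n_included", "rt", "accuracy",
    "com_p", "com_p_i", "vertical", "double_com",
    "early", "miss", "colour_accuracy_initial",
)


@dataclass(frozen=True)
class SummaryStats:
    """Per-condition aggregates; percentages in [0, 100], RT in ms."""

    n_trials: int
    n_included: int
    rt: float                      # mean RT over included correct trials
    accuracy: float                # % perceptual accuracy over included
    com_p: float                   # % of included trials
    com_p_i: float
    vertical: float
    double_com: float              # % of all trials (an exclusion category)
    early: float                   # % of all trials
    miss: float                    # % of all trials
    colour_accuracy_initial: float  # % of included trials

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(df: pd.DataFrame) -> SummaryStats:
    """Aggregate a trial table into condition-level summary statistics."""
    n = len(df)
    if n == 0:
        raise ValueError("empty trial table")
    excluded = df["early"] | df["miss"] | (df["outcome"] == "double_com")
    inc = df[~excluded]
    n_inc = len(inc)

    def pct(mask) -> float:
        return 100.0 * float(np.sum(mask)) / n_inc if n_inc else float("nan")

    correct = inc[inc["perceptual_correct"]]
    return SummaryStats(
        n_trials=n,
        n_included=n_inc,
        rt=float(correct["rt"].mean()) if len(correct) else float("nan"),
        accuracy=pct(inc["perceptual_correct"]),
        com_p=pct(inc["outcome"] == "com_p"),
        com_p_i=pct(inc["outcome"] == "com_p_i"),
        vertical=pct(inc["outcome"] == "vertical"),
        double_com=100.0 * float(np.sum(df["outcome"] == "double_com")) / n,
        early=100.0 * float(np.sum(df["early"])) / n,
        miss=100.0 * float(np.sum(df["miss"])) / n,
        colour_accuracy_initial=pct(inc["colour_correct_initial"]),
    )


@dataclass
class CampaignResult:
    """Across-run mean and dispersion of a simulation campaign."""

    condition: str
    n: int
    n_runs: int
    mean: SummaryStats
    sd: dict                     # across-run SD per summary field
    runs: list                   # per-run SummaryStats

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n": self.n,
            "n_runs": self.n_runs,
            "mean": self.mean.to_dict(),
            "sd": dict(self.sd),
        }


def simulate_condition(
    pv: ParameterVector,
    condition: str = "test",
    n: int = 1000,
    n_runs: int = 30,
    seed: int | None = None,
    *,
    layout: TargetLayout | None = None,
    net: NetworkParams | None = None,
    task: TaskParams | None = None,
    return_trials: bool = False,
):
    """Run ``n_runs`` independent blocks of ``n`` trials each.

    Block seeds derive deterministically from the master ``seed`` via
    seed-sequence spawning, so identical calls reproduce identical
    statistics.  With ``return_trials=True`` the concatenated trial
    table is returned alongside the campaign summary.
    """
    if n < 1 or n_runs < 1:
        raise ValueError("n and n_runs must be at least 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_runs)
    runs = []
    tables = []
    for ss in child_seeds:
        df = simulate_trials(pv, n, condition, layout, net=net, task=task,
                             rng=np.random.default_rng(ss))
        runs.append(summarize(df))
        if return_trials:
            tables.append(df)
    mean_vals = {}
    sd_vals = {}
    for name in SUMMARY_FIELDS:
        vals = np.array([getattr(r, name) for r in runs], dtype=float)
        mean_vals[name] = float(np.nanmean(vals))
        sd_vals[name] = float(np.nanstd(vals, ddof=1)) if n_runs > 1 else 0.0
    mean_stats = SummaryStats(
        n_trials=int(n * n_runs), n_included=int(sum(r.n_included for r in runs)),
        **{k: mean_vals[k] for k in SUMMARY_FIELDS if k not in ("n_trials", "n_included")},
    )
    result = CampaignResult(condition=condition, n=n, n_runs=n_runs,
                            mean=mean_stats, sd=sd_vals, runs=runs)
    if return_trials:
        return result, pd.concat(tables, ignore_index=True)
    return result


def decompose_colour_errors(df: pd.DataFrame) -> dict:
    """Decompose colour-switch categories by initial colour correctness.

    Among vertical switches: the fraction that corrected an initial
    colour error (wrong colour first, right colour last).  Among
    perceptual+intentional changes of mind: the fractions that began
    with a colour error vs. with a correct initial colour choice.
    Fractions are percentages; an empty category yields ``None``.
    """
    excluded = df["early"] | df["miss"] | (df["outcome"] == "double_com")
    inc = df[~excluded]
    out: dict[str, float | None] = {}

    vert = inc[inc["outcome"] == "vertical"]
    if len(vert):
        correcting = (~vert["colour_correct_initial"]) & vert["colour_correct_final"]
        out["vertical_correcting_colour_error"] = 100.0 * correcting.mean()
    else:
        out["vertical_correcting_colour_error"] = None

    cpi = inc[inc["outcome"] == "com_p_i"]
    if len(cpi):
        err = ~cpi["colour_correct_initial"]
        out["com_p_i_with_colour_error"] = 100.0 * err.mean()
        out["com_p_i_with_correct_colour"] = 100.0 * cpi["colour_correct_initial"].mean()
    else:
        out["com_p_i_with_colour_error"] = None
        out["com_p_i_with_correct_colour"] = None
    return out


def intention_strength_sweep(
    pv: ParameterVector,
    col_grid=None,
    n: int = 1000,
    n_runs: int = 4,
    seed: int | None = None,
    *,
    net: NetworkParams | None = None,
    task: TaskParams | None = None,
) -> pd.DataFrame:
    """Sweep intention strength: CoM rates and the conflict RT cost.

    For each intention strength on the grid, test trials give the two
    change-of-mind rates while easy and conflict trials give the RT cost
    of intention-evidence conflict (mean conflict RT minus mean easy
    RT); all other parameters stay fixed.  The default grid spans six
    evenly spaced points from 0 to twice the fitted intention strength.
    """
    if col_grid is None:
        col_grid = np.linspace(0.0, min(2 * pv.col, 100.0), 6)
    col_grid = np.asarray(col_grid, dtype=float)
    if (col_grid < 0).any() or (col_grid > 100).any():
        raise ValueError("intention strengths must lie in [0, 100] %")
    ss = np.random.SeedSequence(seed).spawn(len(col_grid))
    rows = []
    for col, child in zip(col_grid, ss):
        s1, s2, s3 = child.spawn(3)
        pv_c = pv.replace(col=float(col))
        test = simulate_condition(pv_c, "test", n, n_runs,
                                  seed=s1, net=net, task=task)
        easy = simulate_condition(pv_c, "easy", n, n_runs,
                                  seed=s2, net=net, task=task)
        conflict = simulate_condition(pv_c, "conflict", n, n_runs,
                                      seed=s3, net=net, task=task)
        rows.append({
            "col": float(col),
            "com_p": test.mean.com_p,
            "com_p_i": test.mean.com_p_i,
            "vertical": test.mean.vertical,
            "rt_easy": easy.mean.rt,
            "rt_conflict": conflict.mean.rt,
            "rt_cost": conflict.mean.rt - easy.mean.rt,
        })
    return pd.DataFrame(rows)


def target_distance_sweep(
    pv: ParameterVector,
    n: int = 1000,
    n_runs: int = 30,
    seed: int | None = None,
    *,
    net: NetworkParams | None = None,
    task: TaskParams | None = None,
) -> dict:
    """Test-trial campaigns under the two horizontal-distance layouts.

    Identical parameters, only the target geometry changes: horizontally
    far targets make the intention-switching (horizontal) movement
    expensive, close targets make it cheap.  The two campaigns share
    their block seeds (common random numbers), so the paired per-block
    difference isolates the geometry effect from trial-sampling noise.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    shared = int(ss.generate_state(1)[0] % 2**31)
    return {
        "far": simulate_condition(pv, "test", n, n_runs, seed=shared,
                                  layout=far_layout(), net=net, task=task),
        "close": simulate_condition(pv, "test", n, n_runs, seed=shared,
                                    layout=close_layout(), net=net, task=task),
    }


def steady_state_check(
    pv: ParameterVector,
    duration: float = 5000.0,
    n_runs: int = 30,
    seed: int | None = None,
    *,
    net: NetworkParams | None = None,
    task: TaskParams | None = None,
) -> dict:
    """Zero all external inputs and measure background action firing."""
    return simulate_free(pv, duration, n_runs, net=net, task=task, seed=seed)
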