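"""Shared-control estimation statistics for fertility assays.

Each genotype is compared to the single wild-type control via the mean
difference in adult progeny, with a bias-corrected and accelerated (BCa)
bootstrap 95% confidence interval and a label-permutation p-value for the
absolute mean difference. Significance is read as an effect size whose
confidence interval excludes zero; no multiplicity correction is applied
across the genotype comparisons.

Resampling protocol (documented because reproducibility depends on it):
``rng = numpy.random.default_rng(seed)``; the control resample index matrix
of shape (n_boot, n_control) is drawn first, then the group matrix of shape
(n_boot, n_group); the permutation test then draws ``rng.permuted`` rows of
the pooled data. Same seed, same inputs -> identical results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger("gscortho")

DEFAULT_N_BOOT = 5000
DEFAULT_N_PERM = 10000


@dataclass
class PermutationResult:
    """Permutation p-value; ``is_bound`` marks the '< 1/(n_perm+1)' case."""

    p: float
    is_bound: bool
    n_perm: int

    def __str__(self) -> str:
        return f"p < {self.p:g}" if self.is_bound else f"p = {self.p:g}"


@dataclass
class EffectSizeResult:
    comparison: str
    delta_mean: float
    ci_low: float
    ci_high: float
    n_boot: int
    p_perm: PermutationResult
    seed: int
    ci_method: str = "BCa"

    @property
    def significant(self) -> bool:
        """Effect size whose 95% CI excludes zero."""
        return not (self.ci_low <= 0.0 <= self.ci_high)


def mean_difference(control: Sequence[float], group: Sequence[float]) -> float:
    """mean(group) - mean(control); positive means more progeny than control."""
    control, group = np.asarray(control, float), np.asarray(group, float)
    if control.size == 0 or group.size == 0:
        raise ValueError("empty group")
    return float(group.mean() - control.mean())


def _jackknife_acceleration(control: np.ndarray, group: np.ndarray) -> float:
    """Acceleration from leave-one-out mean differences over both groups."""
    jack = []
    for i in range(control.size):
        jack.append(group.mean() - np.delete(control, i).mean())
    for j in range(group.size):
        jack.append(np.delete(group, j).mean() - control.mean())
    jack = np.asarray(jack)
    dev = jack.mean() - jack
    denom = (dev**2).sum() ** 1.5
    if denom == 0:
        return 0.0
    return float((dev**3).sum() / (6.0 * denom))


def bootstrap_deltas(
    control: np.ndarray, group: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Independent with-replacement resamples of each group; see protocol above."""
    c_idx = rng.integers(0, control.size, size=(n_boot, control.size))
    g_idx = rng.integers(0, group.size, size=(n_boot, group.size))
    return group[g_idx].mean(axis=1) - control[c_idx].mean(axis=1)


def bootstrap_ci(
    control: Sequence[float],
    group: Sequence[float],
    n_boot: int = DEFAULT_N_BOOT,
    level: float = 0.95,
    method: str = "BCa",
    seed: int = 0,
) -> tuple[float, float]:
    """BCa bootstrap confidence interval for the mean difference.

    Falls back to the percentile interval with a warning when the
    bias-correction is degenerate (every resampled delta on one side of the
    observed value). All-constant inputs give a zero-width interval at the
    observed delta.
    """
    control, group = np.asarray(control, float), np.asarray(group, float)
    if control.size < 2 or group.size < 2:
        raise ValueError("need n >= 2 in each group")
    observed = float(group.mean() - control.mean())
    rng = np.random.default_rng(seed)
    deltas = bootstrap_deltas(control, group, n_boot, rng)
    if np.ptp(deltas) == 0:
        warnings.warn("degenerate all-constant groups: zero-width interval")
        return (observed, observed)
    alpha = 1.0 - level
    if method.lower() == "percentile":
        lo, hi = np.quantile(deltas, [alpha / 2, 1 - alpha / 2])
        return (float(lo), float(hi))
    frac_below = float((deltas < observed).mean())
    if frac_below in (0.0, 1.0):
        warnings.warn("degenerate bias correction; falling back to percentile")
        lo, hi = np.quantile(deltas, [alpha / 2, 1 - alpha / 2])
        return (float(lo), float(hi))
    z0 = norm.ppf(frac_below)
    accel = _jackknife_acceleration(control, group)
    qs = []
    for z in (norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z) / (1.0 - accel * (z0 + z))
        qs.append(float(norm.cdf(adj)))
    lo, hi = np.quantile(deltas, qs)
    return (float(lo), float(hi))


def permutation_p(
    control: Sequence[float],
    group: Sequence[float],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Label-permutation p for the absolute mean difference.

    p = (1 + #{permuted |delta| >= observed}) / (n_perm + 1); when no
    permutation reaches the observed statistic the value is reported as the
    bound 1/(n_perm+1).
    """
    control, group = np.asarray(control, float), np.asarray(group, float)
    if control.size < 2 or group.size < 2:
        raise ValueError("need n >= 2 in each group")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
    observed = abs(float(group.mean() - control.mean()))
    rng = rng if rng is not None else np.random.default_rng(seed)
    pool = np.concatenate([control, group])
    nc = control.size
    perms = rng.permuted(np.tile(pool, (n_perm, 1)), axis=1)
    stats = np.abs(perms[:, nc:].mean(axis=1) - perms[:, :nc].mean(axis=1))
    tol = 1e-12 * max(1.0, observed)
    count = int((stats >= observed - tol).sum())
    if count == 0:
        return PermutationResult(p=1.0 / (n_perm + 1), is_bound=True, n_perm=n_perm)
    return PermutationResult(
        p=(1 + count) / (n_perm + 1), is_bound=False, n_perm=n_perm
    )


def effect_size(
    control: Sequence[float],
    group: Sequence[float],
    comparison: str = "group vs control",
    n_boot: int = DEFAULT_N_BOOT,
    n_perm: int = DEFAULT_N_PERM,
    level: float = 0.95,
    seed: int = 0,
) -> EffectSizeResult:
    """Mean difference with BCa CI and permutation p for one comparison."""
    delta = mean_difference(control, group)
    ci_low, ci_high = bootstrap_ci(
        control, group, n_boot=n_boot, level=level, seed=seed
    )
    perm = permutation_p(control, group, n_perm=n_perm, seed=seed + 1)
    return EffectSizeResult(
        comparison=comparison,
        delta_mean=delta,
        ci_low=ci_low,
        ci_high=ci_high,
        n_boot=n_boot,
        p_perm=perm,
        seed=seed,
    )


def shared_control_analysis(
    data: pd.DataFrame,
    control_label: str = "wildtype",
    genotype_col: str = "genotype",
    value_col: str = "progeny",
    n_boot: int = DEFAULT_N_BOOT,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> list[EffectSizeResult]:
    """Compare every genotype to the single shared control.

    Each comparison gets its own derived seed so the full analysis is
    reproducible from one integer. No multiplicity correction is applied.
    """
    if control_label not in set(data[genotype_col]):
        raise ValueError(f"control label {control_label!r} not in data")
    control = data.loc[data[genotype_col] == control_label, value_col].to_numpy(float)
    results = []
    others = sorted(g for g in data[genotype_col].unique() if g != control_label)
    for i, genotype in enumerate(others):
        group = data.loc[data[genotype_col] == genotype, value_col].to_numpy(float)
        results.append(
            effect_size(
                control,
                group,
                comparison=f"{genotype} vs {control_label}",
                n_boot=n_boot,
                n_perm=n_perm,
                seed=seed + 1000 * (i + 1),
            )
        )
    return results


def results_to_frame(results: Sequence[EffectSizeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "comparison": r.comparison,
                "delta_mean": r.delta_mean,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_boot": r.n_boot,
                "p_perm": r.p_perm.p,
                "p_is_bound": r.p_perm.is_bound,
                "significant": r.significant,
            }
            for r in results
        ]
    )
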