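"""Paired estimation statistics and repeated-measures ANOVA.

The paired machinery follows estimation-statistics practice: the effect
size is the paired mean difference, its uncertainty is a bias-corrected and
accelerated (BCa) bootstrap confidence interval over resampled pairs, and
the p-value comes from a two-sided permutation test that exchanges the two
condition labels independently within each pair (equivalently, flips the
sign of each paired difference).  All resampling is seeded and the seed is
recorded in the result.

The two-way mixed / repeated-measures ANOVA (a standard method, not this
package's contribution) is delegated to pingouin; post hoc paired
comparisons use an exact Sidak correction implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as ss

__all__ = [
    "PairedSample",
    "BCaResult",
    "PairedContrast",
    "paired_mean_difference",
    "bca_bootstrap_ci",
    "permutation_p",
    "paired_contrast",
    "sidak_adjust",
    "pairwise_sidak",
    "two_way_rm_anova",
    "contrast_table",
]


@dataclass
class PairedSample:
    """Paired measurements under two conditions, indexed by subject.

    ``values_a`` is the reference (control) condition and ``values_b`` the
    test condition; positive effects mean b > a.
    """

    values_a: np.ndarray
    values_b: np.ndarray
    labels: tuple = ("a", "b")
    stratum: Optional[dict] = None

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.ndim != 1 or self.values_b.ndim != 1:
            raise ValueError("paired values must be 1-D")
        if len(self.values_a) != len(self.values_b):
            raise ValueError(
                f"length mismatch: {len(self.values_a)} vs {len(self.values_b)}"
            )
        if len(self.values_a) < 2:
            raise ValueError("paired statistics need at least 2 pairs")
        if not (np.isfinite(self.values_a).all() and np.isfinite(self.values_b).all()):
            raise ValueError("paired values contain non-finite entries")

    @property
    def diffs(self) -> np.ndarray:
        return self.values_b - self.values_a

    @property
    def n(self) -> int:
        return len(self.values_a)


def paired_mean_difference(s: PairedSample) -> float:
    """Mean of (b − a) over pairs; positive ⇒ second condition larger."""
    return float(s.diffs.mean())


@dataclass
class BCaResult:
    """A BCa bootstrap interval with its resampling distribution."""

    ci_low: float
    ci_high: float
    distribution: np.ndarray
    z0: float
    acceleration: float
    level: float = 0.95


def bca_bootstrap_ci(
    s: PairedSample,
    n_boot: int = 5000,
    level: float = 0.95,
    seed=None,
) -> BCaResult:
    """Bias-corrected and accelerated bootstrap CI for the paired mean difference.

    Pairs are resampled with replacement ``n_boot`` times; the bias
    correction z₀ comes from the fraction of resampled estimates below the
    point estimate and the acceleration a from the skewness of leave-one-out
    jackknife estimates.  Degenerate input (all differences equal d) yields
    the point interval [d, d]; zero jackknife variance is handled as a = 0.
    """
    if s.n < 3:
        raise ValueError("BCa interval needs at least 3 pairs (jackknife acceleration)")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is very small for a bootstrap interval")
    d = s.diffs
    theta = float(d.mean())
    n = s.n
    if np.ptp(d) == 0:
        return BCaResult(theta, theta, np.full(n_boot, theta), 0.0, 0.0, level)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = d[idx].mean(axis=1)

    prop = np.mean(boots < theta)
    prop = min(max(prop, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
    z0 = float(ss.norm.ppf(prop))

    jack = (d.sum() - d) / (n - 1)  # leave-one-out means
    u = jack.mean() - jack
    denom = (u**2).sum() ** 1.5
    accel = float((u**3).sum() / (6.0 * denom)) if denom > 0 else 0.0

    alpha = 1.0 - level
    z = ss.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
    adj = ss.norm.cdf(z0 + (z0 + z) / (1.0 - accel * (z0 + z)))
    adj = np.clip(adj, 0.0, 1.0)
    lo, hi = np.quantile(boots, adj)
    return BCaResult(float(lo), float(hi), boots, z0, accel, level)


def _exact_sign_flip_p(d: np.ndarray, obs: float, tol: float) -> float:
    """Exact two-sided sign-flip p by full enumeration of the 2**n patterns."""
    n = len(d)
    if n > 20:
        raise ValueError("exact enumeration supported for n <= 20")
    total = 1 << n
    count = 0
    bits = np.arange(n, dtype=np.int64)
    chunk = 1 << 16
    for start in range(0, total, chunk):
        codes = np.arange(start, min(start + chunk, total), dtype=np.int64)
        signs = 1.0 - 2.0 * ((codes[:, None] >> bits) & 1)
        null = np.abs(signs @ d) / n
        count += int((null >= obs - tol).sum())
    return count / total


def permutation_p(
    s: PairedSample,
    n_perm: int = 5000,
    seed=None,
    mode: str = "sampled",
) -> float:
    """Two-sided permutation p-value for the paired mean difference.

    The null distribution swaps the two condition labels independently
    within each pair, i.e. flips the sign of each paired difference; the
    statistic is |mean difference|.  In ``sampled`` mode (default),
    p = (1 + #{null ≥ observed}) / (1 + n_perm); ``exact`` mode enumerates
    all 2ⁿ sign patterns (n ≤ 20) and returns the exact tail fraction.
    """
    d = s.diffs
    obs = abs(float(d.mean()))
    tol = 1e-12 * max(1.0, obs)
    if mode == "exact":
        return _exact_sign_flip_p(d, obs, tol)
    if mode != "sampled":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, s.n)) * 2.0 - 1.0
    null = np.abs(signs @ d) / s.n
    return float((1 + (null >= obs - tol).sum()) / (1 + n_perm))


@dataclass
class PairedContrast:
    """Full estimation-statistics result for one paired contrast."""

    mean_diff: float
    ci_low: float
    ci_high: float
    bootstrap_distribution: np.ndarray
    p_perm: float
    n: int
    n_boot: int = 5000
    n_perm: int = 5000
    level: float = 0.95
    rng_seed: Optional[int] = None
    labels: tuple = ("a", "b")
    stratum: Optional[dict] = None


def paired_contrast(
    s: PairedSample,
    n_boot: int = 5000,
    n_perm: int = 5000,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> PairedContrast:
    """Paired mean difference with BCa interval and permutation p, seeded."""
    ss_root = np.random.SeedSequence(seed)
    boot_ss, perm_ss = ss_root.spawn(2)
    bca = bca_bootstrap_ci(s, n_boot=n_boot, level=level, seed=boot_ss)
    p = permutation_p(s, n_perm=n_perm, seed=perm_ss)
    return PairedContrast(
        mean_diff=paired_mean_difference(s),
        ci_low=bca.ci_low,
        ci_high=bca.ci_high,
        bootstrap_distribution=bca.distribution,
        p_perm=p,
        n=s.n,
        n_boot=n_boot,
        n_perm=n_perm,
        level=level,
        rng_seed=seed,
        labels=s.labels,
        stratum=s.stratum,
    )


def sidak_adjust(p, m: int):
    """Exact Sidak correction for m comparisons: 1 − (1 − p)^m."""
    p = np.asarray(p, dtype=float)
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


def pairwise_sidak(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    by: Optional[str] = None,
) -> pd.DataFrame:
    """Sidak-corrected paired t comparisons between within-factor levels.

    Comparisons run between every pair of ``within`` levels, optionally
    within each level of ``by``; the correction multiplicity m is the total
    number of comparisons performed.
    """
    groups = [(None, data)] if by is None else list(data.groupby(by, observed=True))
    rows = []
    for gname, g in groups:
        wide = g.pivot_table(index=subject, columns=within, values=dv)
        for a, b in combinations(sorted(wide.columns), 2):
            pair = wide[[a, b]].dropna()
            t, p = ss.ttest_rel(pair[b], pair[a])
            rows.append(
                {
                    **({} if by is None else {by: gname}),
                    "level_a": a,
                    "level_b": b,
                    "n": len(pair),
                    "mean_diff": float((pair[b] - pair[a]).mean()),
                    "t": float(t),
                    "p_uncorrected": float(p),
                }
            )
    out = pd.DataFrame(rows)
    out["p_sidak"] = sidak_adjust(out["p_uncorrected"].to_numpy(), len(out))
    return out


def _check_balanced(data, dv, subject, within_list, between) -> None:
    cells = (
        data.groupby([subject] + within_list, observed=True)[dv]
        .size()
        .unstack(within_list if len(within_list) > 1 else within_list[0])
    )
    if cells.isna().any().any() or (cells != 1).any().any():
        raise ValueError(
            "design must be balanced and complete (one value per subject per "
            f"within-cell); observed cell counts:\n{cells.fillna(0).astype(int)}"
        )
    if between:
        per_subject = data.groupby(subject, observed=True)[between].nunique()
        if (per_subject != 1).any():
            bad = per_subject[per_subject != 1].index.tolist()
            raise ValueError(f"subject(s) {bad} appear in more than one {between} group")
        sizes = data.drop_duplicates(subject).groupby(between, observed=True).size()
        if sizes.nunique() > 1:
            raise ValueError(f"unbalanced between-subject groups:\n{sizes}")


def two_way_rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within,
    between: Optional[str] = None,
    posthoc: bool = True,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Two-way mixed or fully repeated-measures ANOVA with Sidak post hocs.

    ``design="mixed"`` corresponds to passing one ``within`` factor plus a
    ``between`` factor; passing a list of two ``within`` factors (and no
    ``between``) gives the fully within-subjects two-way RM ANOVA.  Effects
    are returned in pingouin's table format (Source, F, p-unc, DF...); an
    all-constant response returns F = 0, p = 1 for every effect.
    """
    within_list = [within] if isinstance(within, str) else list(within)
    factors = within_list + ([between] if between else [])
    if len(factors) != 2:
        raise ValueError("exactly two factors are required (within [+ between])")
    _check_balanced(data, dv, subject, within_list, between)

    if data[dv].nunique() <= 1:
        sources = factors + [f"{factors[0]} * {factors[1]}" if not between else "Interaction"]
        aov = pd.DataFrame({"Source": sources, "F": 0.0, "p_unc": 1.0})
    else:
        import pingouin as pg

        if between:
            aov = pg.mixed_anova(
                data=data, dv=dv, within=within_list[0], between=between, subject=subject
            )
        else:
            aov = pg.rm_anova(data=data, dv=dv, within=within_list, subject=subject, detailed=True)
        aov = aov.rename(columns={"p-unc": "p_unc"})

    ph = None
    if posthoc:
        ph = pairwise_sidak(data, dv, within_list[0], subject, by=between or (within_list[1] if len(within_list) > 1 else None))
    return aov, ph


def contrast_table(
    energy_tbl: pd.DataFrame,
    numerator: str,
    denominator: str,
    contrast_name: Optional[str] = None,
    n_boot: int = 5000,
    n_perm: int = 5000,
    level: float = 0.95,
    seed: int = 0,
    on_error: str = "skip",
) -> pd.DataFrame:
    """Estimation statistics per band × time bin (× age) from an energy table.

    For every stratum, subjects with both conditions are aligned and the
    paired contrast numerator − denominator is summarized (mean difference,
    BCa interval, permutation p).  Per-stratum seeds are derived
    deterministically from ``seed`` and the stratum labels, so results do
    not depend on stratum evaluation order.
    """
    import zlib

    name = contrast_name or f"{numerator}_vs_{denominator}"
    rows = []
    failures = []
    strata = energy_tbl.groupby(
        ["age_group", "band", "bin_start_ms", "bin_end_ms"], observed=True, sort=True
    )
    for (age, band, b0, b1), g in strata:
        wide = g.pivot_table(index="subject_id", columns="condition", values="normalized_energy")
        stratum_seed = int(
            np.random.SeedSequence(
                [
                    seed,
                    zlib.crc32(name.encode()),
                    zlib.crc32(str(age).encode()),
                    zlib.crc32(str(band).encode()),
                    int(b0),
                ]
            ).generate_state(1)[0]
            & 0x7FFFFFFF
        )
        try:
            if numerator not in wide.columns or denominator not in wide.columns:
                raise ValueError(f"missing condition(s) in stratum {(age, band, b0)}")
            pair = wide[[denominator, numerator]].dropna()
            s = PairedSample(
                pair[denominator].to_numpy(),
                pair[numerator].to_numpy(),
                labels=(denominator, numerator),
                stratum={"age_group": age, "band": band, "bin_start_ms": b0},
            )
            res = paired_contrast(s, n_boot=n_boot, n_perm=n_perm, level=level, seed=stratum_seed)
        except Exception as exc:  # noqa: BLE001 — stratum-level failures are enumerated
            if on_error == "raise":
                raise
            failures.append(((age, band, b0, b1), str(exc)))
            continue
        rows.append(
            {
                "contrast": name,
                "age_group": age,
                "band": band,
                "bin_start_ms": b0,
                "bin_end_ms": b1,
                "n": res.n,
                "mean_diff": res.mean_diff,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_perm": res.p_perm,
                "n_boot": n_boot,
                "n_perm": n_perm,
                "seed": stratum_seed,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["failures"] = failures
    return out
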