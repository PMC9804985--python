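"""Group-comparison workflow: log10 transform, assumption gates, Dunnett.

The workflow mirrors a common comparative-histology analysis: per-animal
metrics are log10 transformed, checked for variance homogeneity (Bartlett)
and normality (Shapiro-Wilk), then each non-control group is compared with
the control using the two-sided single-step Dunnett procedure at alpha=0.05.
Raw-scale mean +- sd summaries accompany every comparison.

The Dunnett adjusted p-value is the tail probability of the maximum absolute
component of an equicorrelated multivariate t variate.  It is evaluated here
by deterministic quadrature over the factor representation

    T_j = (c_j X_j + lambda_j X0) / q,   q = sqrt(chi2_df / df),
    lambda_j = sqrt(n_j / (n_j + n_c)),  c_j = sqrt(1 - lambda_j^2),

(Gauss-Hermite in the shared factor, adaptive quadrature in the scale), with
a seeded Monte-Carlo fallback for many treatment groups.  For one treatment
the procedure reduces exactly to the classical pooled two-sample t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(160)
_GH_Z = _GH_NODES * math.sqrt(2.0)
_GH_W = _GH_WEIGHTS / math.sqrt(math.pi)


def log10_transform(values, offset: float | None = None,
                    ids=None) -> np.ndarray:
    """Elementwise log10 of positive values.

    Non-positive entries raise a ValueError naming the offending items
    (pass ``ids`` for readable names); supplying ``offset`` adds a fixed
    constant before transforming instead.
    """
    arr = np.asarray(values, dtype=float)
    if offset is not None:
        arr = arr + offset
    bad = ~(arr > 0)
    if bad.any():
        labels = (np.asarray(ids)[bad].tolist() if ids is not None
                  else np.flatnonzero(bad).tolist())
        raise ValueError(
            f"log10 undefined for non-positive values at {labels}; "
            "exclude these animals or use a fixed offset")
    return np.log10(arr)


@dataclass(frozen=True)
class AssumptionCheck:
    """Bartlett homogeneity and per-group Shapiro-Wilk normality results."""

    bartlett_stat: float
    bartlett_p: float
    shapiro_w: dict[str, float]
    shapiro_p: dict[str, float]
    passed: bool  # all p-values > alpha
    alpha: float = ALPHA_DEFAULT


def check_assumptions(groups: dict[str, np.ndarray],
                      alpha: float = ALPHA_DEFAULT) -> AssumptionCheck:
    """Variance homogeneity (Bartlett) and normality (Shapiro-Wilk) gates.

    ``passed`` means every p-value exceeds ``alpha``.  A failed gate does not
    halt the pipeline; it is reported alongside the comparison results.
    Requires n >= 3 per group.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, s in samples.items():
        if len(s) < 3:
            raise ValueError(f"group {name!r} has n={len(s)} < 3")
    bt = sps.bartlett(*samples.values())
    sw = {name: sps.shapiro(s) for name, s in samples.items()}
    shapiro_p = {name: float(r.pvalue) for name, r in sw.items()}
    passed = (float(bt.pvalue) > alpha
              and all(p > alpha for p in shapiro_p.values()))
    return AssumptionCheck(
        bartlett_stat=float(bt.statistic), bartlett_p=float(bt.pvalue),
        shapiro_w={name: float(r.statistic) for name, r in sw.items()},
        shapiro_p=shapiro_p, passed=passed, alpha=alpha)


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparison


@dataclass(frozen=True)
class DunnettComparison:
    treatment: str
    diff: float  # treatment mean - control mean (transformed scale)
    se: float
    t_value: float
    p_adjusted: float
    df: int


def _dunnett_max_abs_sf(t_obs: float, df: int, lambdas: np.ndarray) -> float:
    """P(max_j |T_j| >= t_obs) for the equicorrelated multivariate t."""
    t_obs = abs(float(t_obs))
    if t_obs == 0.0:
        return 1.0
    lam = np.asarray(lambdas, dtype=float)
    c = np.sqrt(1.0 - lam**2)

    def inner(q: float) -> float:
        # E_z prod_j [Phi((t q - lam z)/c) - Phi((-t q - lam z)/c)]
        upper = (t_obs * q - np.outer(_GH_Z, lam)) / c
        lower = (-t_obs * q - np.outer(_GH_Z, lam)) / c
        probs = np.prod(sps.norm.cdf(upper) - sps.norm.cdf(lower), axis=1)
        return float(_GH_W @ probs)

    sqrt_df = math.sqrt(df)

    def integrand(q: float) -> float:
        return sps.chi.pdf(q * sqrt_df, df) * sqrt_df * inner(q)

    # q concentrates around 1 with sd ~ 1/sqrt(2 df); an upper cut far in the
    # chi tail keeps quad's breakpoint support while losing < 1e-12 mass
    q_hi = float(sps.chi.ppf(1.0 - 1e-13, df) / sqrt_df) if df < 10_000 else 2.0
    val, _ = integrate.quad(integrand, 0.0, q_hi, epsabs=1e-12,
                            epsrel=1e-10, limit=300, points=[1.0])
    return min(max(1.0 - val, 0.0), 1.0)


def _dunnett_max_abs_sf_mc(t_obs: float, df: int, lambdas: np.ndarray,
                           n_draws: int, rng: np.random.Generator) -> float:
    lam = np.asarray(lambdas, dtype=float)
    c = np.sqrt(1.0 - lam**2)
    x0 = rng.standard_normal(n_draws)
    q = np.sqrt(rng.chisquare(df, n_draws) / df)
    max_abs = np.zeros(n_draws)
    for j in range(len(lam)):
        tj = np.abs(c[j] * rng.standard_normal(n_draws) + lam[j] * x0) / q
        np.maximum(max_abs, tj, out=max_abs)
    return float(np.mean(max_abs >= abs(t_obs)))


def dunnett_test(control, treatments, alpha: float = ALPHA_DEFAULT,
                 names: list[str] | None = None, method: str = "auto",
                 n_mc_draws: int = 500_000,
                 rng: np.random.Generator | None = None
                 ) -> list[DunnettComparison]:
    """Two-sided single-step Dunnett comparison of each treatment vs control.

    Uses the pooled within-group variance across all groups; the adjusted
    p-value for comparison j is P(max_k |T_k| >= |t_j|) under the joint null
    with the Dunnett correlation structure implied by the group sizes.
    ``method='auto'`` uses quadrature up to 8 treatments and seeded
    Monte-Carlo beyond.
    """
    control = np.asarray(control, dtype=float)
    samples = [np.asarray(t, dtype=float) for t in treatments]
    if len(samples) == 0:
        raise ValueError("need at least one treatment group")
    if len(control) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("every group needs n >= 2")
    if names is None:
        names = [f"treatment_{j + 1}" for j in range(len(samples))]

    all_groups = [control] + samples
    n = np.array([len(g) for g in all_groups])
    df = int(n.sum() - len(all_groups))
    ss = sum(float(((g - g.mean()) ** 2).sum()) for g in all_groups)
    s2 = ss / df
    if s2 <= 0:
        raise ValueError("zero pooled variance; comparisons undefined")

    n_c = n[0]
    lambdas = np.sqrt(n[1:] / (n[1:] + n_c))
    use_mc = method == "mc" or (method == "auto" and len(samples) > 8)
    if method not in ("auto", "quadrature", "mc"):
        raise ValueError(f"unknown method {method!r}")
    if use_mc and rng is None:
        rng = np.random.default_rng(0)

    out = []
    mean_c = control.mean()
    for j, (name, t_sample) in enumerate(zip(names, samples)):
        diff = float(t_sample.mean() - mean_c)
        se = math.sqrt(s2 * (1.0 / len(t_sample) + 1.0 / n_c))
        t_val = diff / se
        if use_mc:
            p = _dunnett_max_abs_sf_mc(t_val, df, lambdas, n_mc_draws, rng)
        else:
            p = _dunnett_max_abs_sf(t_val, df, lambdas)
        out.append(DunnettComparison(treatment=name, diff=diff, se=se,
                                     t_value=t_val, p_adjusted=p, df=df))
    return out


# ---------------------------------------------------------------------------
# cohort-level workflow


@dataclass(frozen=True)
class GroupSummary:
    name: str
    n: int
    raw_mean: float
    raw_sd: float


@dataclass
class GroupComparisonResult:
    """One metric's full comparison record.

    With one non-control group the adjusted p equals the classical pooled
    two-sample two-sided t-test p-value.
    """

    metric: str
    transform: str
    groups: list[GroupSummary]
    bartlett_p: float
    shapiro_p: dict[str, float]
    assumptions_pass: bool
    comparisons: list[DunnettComparison]
    alpha: float = ALPHA_DEFAULT
    notes: list[str] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        """Flatten to one CSV row per comparison."""
        summary = {f"{g.name}_n": g.n for g in self.groups}
        summary.update({f"{g.name}_raw_mean": g.raw_mean for g in self.groups})
        summary.update({f"{g.name}_raw_sd": g.raw_sd for g in self.groups})
        rows = []
        for cmp_ in self.comparisons:
            rows.append({
                "metric": self.metric,
                "transform": self.transform,
                "treatment": cmp_.treatment,
                "diff": cmp_.diff,
                "se": cmp_.se,
                "t_value": cmp_.t_value,
                "p_adjusted": cmp_.p_adjusted,
                "df": cmp_.df,
                "alpha": self.alpha,
                "bartlett_p": self.bartlett_p,
                "assumptions_pass": self.assumptions_pass,
                **{f"shapiro_p_{k}": v for k, v in self.shapiro_p.items()},
                **summary,
                "notes": "; ".join(self.notes),
            })
        return rows


def compare_cohort(table: pd.DataFrame, metrics: list[str], control: str,
                   alpha: float = ALPHA_DEFAULT, transform: str = "log10",
                   zero_policy: str = "error", zero_offset: float | None = None,
                   ) -> list[GroupComparisonResult]:
    """Run the full per-metric workflow on a per-animal cohort table.

    ``table`` needs columns ``animal_id``, ``group`` and each metric.
    ``zero_policy`` controls non-positive values under the log10 transform:
    ``error`` (default, with guidance), ``exclude`` (drop those animals,
    recorded in the result notes) or ``offset`` (add ``zero_offset``; when
    None, half the smallest positive value of that metric).
    """
    if transform not in ("log10", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    if zero_policy not in ("error", "exclude", "offset"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if control not in set(table["group"]):
        raise ValueError(f"control group {control!r} absent from table")

    group_names = sorted(set(table["group"]))
    treatment_names = [g for g in group_names if g != control]

    results = []
    for metric in metrics:
        if metric not in table.columns:
            logger.warning("metric %r absent from cohort table; skipped", metric)
            continue
        sub = table[["animal_id", "group", metric]].copy()
        notes: list[str] = []

        n_missing = int(sub[metric].isna().sum())
        if n_missing:
            dropped = sub.loc[sub[metric].isna(), "animal_id"].tolist()
            notes.append(f"excluded {n_missing} animals with missing values: "
                         f"{dropped}")
            sub = sub.dropna(subset=[metric])

        if transform == "log10":
            nonpos = sub[metric] <= 0
            if nonpos.any():
                if zero_policy == "error":
                    log10_transform(sub[metric].to_numpy(),
                                    ids=sub["animal_id"].to_numpy())
                elif zero_policy == "exclude":
                    dropped = sub.loc[nonpos, "animal_id"].tolist()
                    notes.append(f"excluded non-positive values before log10: "
                                 f"{dropped}")
                    sub = sub[~nonpos]
                else:
                    off = zero_offset
                    if off is None:
                        pos = sub.loc[~nonpos, metric]
                        off = float(pos.min()) / 2 if len(pos) else 1e-6
                    notes.append(f"added offset {off:g} before log10")
                    sub[metric] = sub[metric] + off

        # sorted values make every downstream statistic exactly invariant to
        # the order animals appear in the table
        present = {g: np.sort(sub.loc[sub["group"] == g, metric]
                              .to_numpy(dtype=float))
                   for g in group_names}
        empty = [g for g, v in present.items() if len(v) < 2]
        if empty:
            logger.warning("metric %r skipped: group(s) %s lack data",
                           metric, empty)
            continue

        raw = present
        if transform == "log10":
            data = {g: np.log10(v) for g, v in raw.items()}
        else:
            data = raw

        try:
            check = check_assumptions(data, alpha=alpha)
            bartlett_p, shapiro_p, passed = (check.bartlett_p, check.shapiro_p,
                                             check.passed)
        except ValueError as exc:
            notes.append(f"assumption checks unavailable: {exc}")
            bartlett_p, shapiro_p, passed = float("nan"), {}, False

        comparisons = dunnett_test(
            data[control], [data[g] for g in treatment_names], alpha=alpha,
            names=treatment_names)
        summaries = [GroupSummary(name=g, n=len(raw[g]),
                                  raw_mean=float(np.mean(raw[g])),
                                  raw_sd=float(np.std(raw[g], ddof=1)))
                     for g in [control] + treatment_names]
        results.append(GroupComparisonResult(
            metric=metric, transform=transform, groups=summaries,
            bartlett_p=bartlett_p, shapiro_p=shapiro_p,
            assumptions_pass=passed, comparisons=comparisons, alpha=alpha,
            notes=notes))
    return results


def results_to_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    rows = [row for res in results for row in res.to_rows()]
    return pd.DataFrame(rows)
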