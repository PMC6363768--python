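"""Differential isomiR expression.

Two complementary tests are computed per isomiR and condition pair:

**Mapping-based statistic** (Audic–Claverie): compares a read count x in
library A (total N1 clean reads) with count y in library B (total N2).
Conditional on x, the count in B follows

    p(k | x) = (N2/N1)^k * (x+k)! / (x! k! (1 + N2/N1)^(x+k+1)),

a negative-binomial-form distribution depending on the libraries only
through the ratio N2/N1.  The reported p-value is the smaller of the two
tails, both including k = y:

    p = min( sum_{k<=y} p(k|x),  sum_{k>=y} p(k|x) ).

Terms are evaluated by the multiplicative recurrence

    p(k+1|x) = p(k|x) * q * (x+k+1) / (k+1),   q = N2/(N1+N2),

carried in linear space with an explicit power-of-two scale factor so
that the extreme underflow regime (large x, skewed library ratio) stays
exact to double precision.  ``audic_claverie_p`` returns the classic
min-of-tails form by default.  Note that rejecting when that min tail is
below a level alpha is a test of size up to 2*alpha; the pipeline
(:func:`run_differential`) therefore reports the conventional doubled
two-sided p-value by default so that the mapping test is calibrated at
its nominal level, and exposes ``double_tails=False`` for the raw
min-tail convention.

**Model-based test**: a deliberately simple negative-binomial Wald test
on replicated counts — median-of-ratios size factors, method-of-moments
per-isomiR dispersion (floored at the Poisson limit), and a t reference
with residual degrees of freedom to keep the small-replicate null
calibrated.  It is a lightweight companion for two-group designs, not a
general GLM framework.

Fold change is reported on the reads-per-million scale with a
pseudocount: log2( ((y+c)/N2) / ((x+c)/N1) ), positive meaning higher in
condition B (stress) than condition A (control/reference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_ABS_LOG2FC = 1.0
DEFAULT_PSEUDOCOUNT = 0.5
_DISPERSION_FLOOR = 1e-8
_TINY = 5e-324  # smallest subnormal double; p is clamped into (0, 1]


@dataclass(frozen=True)
class ComparisonPair:
    """One condition-vs-condition comparison within an experiment."""

    experiment: str
    condition_a: str  # reference (control, or the previous stress level)
    condition_b: str
    N1: int = 0  # total clean reads pooled over condition_a samples
    N2: int = 0

    def __post_init__(self) -> None:
        if self.condition_a == self.condition_b:
            raise ValueError("comparison of a condition with itself")


def enumerate_comparisons(
    design: pd.DataFrame, totals: dict[str, int] | None = None
) -> list[ComparisonPair]:
    """Build the comparison list from a sample design table.

    ``design`` columns: ``sample``, ``condition``, ``experiment``,
    ``is_control`` (truthy for control samples).  Within each experiment
    with control C and stress conditions S1..Sn (in order of first
    appearance in the table) the pairs are (C, Si) for every i plus the
    consecutive ladder (S_{i-1}, S_i) for i >= 2.  Pairs never cross
    experiments.
    """
    required = {"sample", "condition", "experiment", "is_control"}
    if not required.issubset(design.columns):
        raise ValueError(f"design table must have columns {sorted(required)}")
    pairs: list[ComparisonPair] = []
    for experiment in pd.unique(design["experiment"]):
        sub = design[design["experiment"] == experiment]
        controls = list(pd.unique(sub.loc[sub["is_control"].astype(bool), "condition"]))
        if len(controls) != 1:
            raise ValueError(
                f"experiment {experiment!r}: expected exactly one control condition, got {controls}"
            )
        control = controls[0]
        stresses = [c for c in pd.unique(sub["condition"]) if c != control]
        if not stresses:
            raise ValueError(f"experiment {experiment!r}: no stress condition")

        def _total(cond: str) -> int:
            if totals is None:
                return 0
            return sum(totals[s] for s in sub.loc[sub["condition"] == cond, "sample"])

        for s in stresses:
            pairs.append(ComparisonPair(experiment, control, s, _total(control), _total(s)))
        for prev, cur in zip(stresses, stresses[1:]):
            pairs.append(ComparisonPair(experiment, prev, cur, _total(prev), _total(cur)))
    return pairs


def _scaled_terms_upto(x: int, q: float, y: int):
    """Conditional pmf terms p(k|x) for k = 0..y in scaled linear space.

    Returns (terms, scale_log2) with ``p(k|x) = terms[k] * 2**scale_log2``
    per-element... terms are kept on a *common* scale so they can be
    summed directly.  The common scale is chosen so the running maximum
    stays representable; terms that underflow the common scale contribute
    nothing to double-precision tail sums, which is exact behaviour.
    """
    log2_p0 = (x + 1) * math.log2(1.0 - q)
    scale = 0
    if log2_p0 < -900:
        # Start below the representable range: walk the recurrence on the
        # scale counter until the term magnitude is representable.
        scale = int(log2_p0) + 200
    t = 2.0 ** (log2_p0 - scale)
    terms = [t]
    for k in range(y):
        t *= q * (x + k + 1) / (k + 1)
        if t > 1e280:  # renormalize: shift 2^-512 onto the scale
            t *= 2.0**-512
            for i in range(len(terms)):
                terms[i] *= 2.0**-512
            scale += 512
        terms.append(t)
    return terms, scale


def audic_claverie_p(
    x: int, y: int, n1: float, n2: float, double_tails: bool = False
) -> float:
    """Two-sided Audic–Claverie p-value for count x (library size n1)
    versus count y (library size n2).

    Depends on the libraries only through n2/n1 (scale invariant).  The
    result is clamped into (0, 1].
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    x, y = int(x), int(y)
    r = n2 / n1
    q = r / (1.0 + r)
    terms, scale = _scaled_terms_upto(x, q, y)
    factor = 2.0**scale
    lower = math.fsum(terms) * factor
    # Upper tail sum_{k>=y}: complement of the strictly-lower tail unless
    # cancellation would destroy it, in which case sum forward directly.
    upper = 1.0 - (math.fsum(terms[:-1]) * factor)
    if upper < 1e-9:
        mode = int((x + 1) * q / (1.0 - q)) + 1
        t = terms[-1]
        acc = t
        k = y
        while True:
            t *= q * (x + k + 1) / (k + 1)
            acc += t
            k += 1
            # Stop past the mode once further terms are negligible; t can
            # pin at the subnormal floor, where multiplication no longer
            # decreases it, so treat anything below 1e-300 as exhausted.
            if k > mode and (t < acc * 1e-17 or t < 1e-300):
                break
        upper = acc * factor
    p = min(lower, upper)
    if double_tails:
        p = 2.0 * p
    return min(max(p, _TINY), 1.0)


def conditional_pmf(x: int, n1: float, n2: float, tol: float = 1e-13) -> np.ndarray:
    """The conditional distribution p(k|x) as a dense vector, truncated
    adaptively once the omitted upper tail is below ``tol``.

    Exposed mainly so the normalization of the statistic's kernel can be
    checked; uses the same scaled recurrence as the p-value.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    r = n2 / n1
    q = r / (1.0 + r)
    mode = int((x + 1) * q / (1.0 - q)) + 1
    log2_p0 = (x + 1) * math.log2(1.0 - q)
    scale = 0
    if log2_p0 < -900:
        scale = int(log2_p0) + 200
    t = 2.0 ** (log2_p0 - scale)
    out = [t]
    acc = t
    k = 0
    while True:
        t *= q * (x + k + 1) / (k + 1)
        if t > 1e280:  # renormalize the common scale
            shift = 2.0**-512
            t *= shift
            out = [v * shift for v in out]
            acc *= shift
            scale += 512
        out.append(t)
        acc += t
        k += 1
        if k > mode and t < acc * tol * 1e-3:
            break
    return np.array(out) * 2.0**scale


def log2_fold_change(
    x: float, y: float, n1: float, n2: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """log2 of the RPM ratio, condition B over condition A."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if pseudocount <= 0 and (x == 0 or y == 0):
        raise ValueError("zero count requires a positive pseudocount")
    return math.log2(((y + pseudocount) / n2) / ((x + pseudocount) / n1))


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors (columns = samples).

    The reference is the per-isomiR geometric mean over samples,
    restricted to isomiRs with all-positive counts; if fewer than two
    such isomiRs exist the factors fall back to total-count ratios.
    """
    counts = np.asarray(counts, dtype=float)
    positive = np.all(counts > 0, axis=1)
    if positive.sum() >= 2:
        logc = np.log(counts[positive])
        ref = logc.mean(axis=1)
        sf = np.exp(np.median(logc - ref[:, None], axis=0))
    else:
        tot = counts.sum(axis=0)
        sf = tot / np.exp(np.mean(np.log(np.maximum(tot, 1.0))))
    return sf / np.exp(np.mean(np.log(sf)))


def nb_model_test(
    counts_a: np.ndarray, counts_b: np.ndarray, sf: np.ndarray | None = None
) -> pd.DataFrame:
    """Negative-binomial Wald test per isomiR on replicated counts.

    ``counts_a``/``counts_b`` are (isomiRs x replicates) count matrices.
    Requires >= 2 replicates on each side.  Returns a frame with
    normalized group means, the log2 fold change of the means, the
    method-of-moments dispersion and the two-sided p-value (NaN for
    all-zero isomiRs, which cannot be tested).

    The Wald statistic divides the log mean difference by the delta-rule
    NB standard error sqrt((1/mu_a + alpha)/n_a + (1/mu_b + alpha)/n_b)
    and is referred to a t distribution with n_a + n_b - 2 degrees of
    freedom: with 2-3 replicates the moment dispersion estimate is noisy
    and a normal reference is visibly anti-conservative.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    na, nb = counts_a.shape[1], counts_b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("nb_model_test requires >= 2 replicates per condition")
    all_counts = np.hstack([counts_a, counts_b])
    if sf is None:
        sf = size_factors(all_counts)
    norm = all_counts / sf
    norm_a, norm_b = norm[:, :na], norm[:, na:]
    mu_a = norm_a.mean(axis=1)
    mu_b = norm_b.mean(axis=1)
    # Pooled within-group variance, residual df = na + nb - 2.
    ss = ((norm_a - mu_a[:, None]) ** 2).sum(axis=1) + ((norm_b - mu_b[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    s2 = ss / df
    grand = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - grand) / grand**2
    alpha = np.where(np.isfinite(alpha), alpha, _DISPERSION_FLOOR)
    alpha = np.maximum(alpha, _DISPERSION_FLOOR)
    c = DEFAULT_PSEUDOCOUNT
    beta = np.log((mu_b + c) / (mu_a + c))
    se = np.sqrt(
        (1.0 / np.maximum(mu_a, c) + alpha) / na + (1.0 / np.maximum(mu_b, c) + alpha) / nb
    )
    with np.errstate(invalid="ignore"):
        wald = beta / se
    p = 2.0 * stats.t.sf(np.abs(wald), df)
    testable = (mu_a + mu_b) > 0
    p = np.where(testable, np.clip(p, _TINY, 1.0), np.nan)
    return pd.DataFrame(
        {
            "mu_a": mu_a,
            "mu_b": mu_b,
            "log2fc_model": beta / math.log(2),
            "dispersion": alpha,
            "p_model": p,
        }
    )


def run_differential(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    totals: dict[str, int],
    alpha: float = DEFAULT_ALPHA,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    double_tails: bool = True,
    bh_correct: bool = False,
) -> dict[ComparisonPair, pd.DataFrame]:
    """Differential expression for every comparison pair.

    ``counts``: isomiR x sample count matrix (index = isomir_id, columns
    = sample ids as in the design table).  The mapping-based statistic
    pools replicate counts within each condition (x = sum over condition
    A samples, N1 = pooled clean-read total); the model-based test runs
    whenever both conditions have >= 2 replicates, otherwise ``p_model``
    is absent (NaN) and only the mapping flag contributes.

    isomiRs with x = y = 0 in a pair are excluded from that pair's table.
    """
    missing = [s for s in design["sample"] if s not in counts.columns]
    if missing:
        raise ValueError(f"design samples missing from count matrix: {missing}")
    pairs = enumerate_comparisons(design, totals)
    results: dict[ComparisonPair, pd.DataFrame] = {}
    cond_samples = {
        (e, c): list(sub["sample"])
        for (e, c), sub in design.groupby(["experiment", "condition"], sort=False)
    }
    for pair in pairs:
        samples_a = cond_samples[(pair.experiment, pair.condition_a)]
        samples_b = cond_samples[(pair.experiment, pair.condition_b)]
        x = counts[samples_a].sum(axis=1).to_numpy()
        y = counts[samples_b].sum(axis=1).to_numpy()
        keep = (x + y) > 0
        idx = counts.index[keep]
        x, y = x[keep], y[keep]
        n1, n2 = pair.N1, pair.N2
        p_map = np.array(
            [audic_claverie_p(int(xi), int(yi), n1, n2, double_tails) for xi, yi in zip(x, y)]
        )
        lfc = np.array(
            [log2_fold_change(xi, yi, n1, n2, pseudocount) for xi, yi in zip(x, y)]
        )
        table = pd.DataFrame(
            {
                "isomir_id": idx,
                "x": x,
                "y": y,
                "rpm_a": x / n1 * 1e6,
                "rpm_b": y / n2 * 1e6,
                "log2fc": lfc,
                "p_mapping": p_map,
            }
        )
        if len(samples_a) >= 2 and len(samples_b) >= 2:
            model = nb_model_test(
                counts.loc[idx, samples_a].to_numpy(),
                counts.loc[idx, samples_b].to_numpy(),
            )
            table["p_model"] = model["p_model"].to_numpy()
        else:
            table["p_model"] = np.nan
        p_map_eff = table["p_mapping"].to_numpy()
        p_mod_eff = table["p_model"].to_numpy()
        if bh_correct:
            p_map_eff = _bh_adjust(p_map_eff)
            p_mod_eff = _bh_adjust(p_mod_eff)
        big_fc = np.abs(table["log2fc"].to_numpy()) >= min_abs_log2fc
        table["significant_mapping"] = (p_map_eff <= alpha) & big_fc
        table["significant_model"] = (
            np.nan_to_num(p_mod_eff, nan=1.0) <= alpha
        ) & big_fc
        table["in_intersection"] = table["significant_mapping"] & table["significant_model"]
        results[pair] = table.reset_index(drop=True)
    return results


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv)
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[mask] = adj
    return out


def rollup(results: dict[ComparisonPair, pd.DataFrame]) -> pd.DataFrame:
    """Per-comparison counts of differential isomiRs by method and their
    intersection (the intersection can never exceed either method)."""
    rows = []
    for pair, table in results.items():
        rows.append(
            {
                "experiment": pair.experiment,
                "condition_a": pair.condition_a,
                "condition_b": pair.condition_b,
                "n_mapping": int(table["significant_mapping"].sum()),
                "n_model": int(table["significant_model"].sum()),
                "n_intersection": int(table["in_intersection"].sum()),
            }
        )
    return pd.DataFrame(rows)
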