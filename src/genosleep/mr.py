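"""One- and two-sample Mendelian randomisation from summary statistics.

The causal effect of an exposure on an outcome is estimated from per-variant
marginal associations by the Wald ratio (single instrument), the
inverse-variance-weighted (IVW) average of ratios, and the weighted median
of ratios (consistent while valid instruments carry a majority of weight).

Exposure and outcome tables are first harmonized so outcome effects are
expressed per copy of the exposure's effect allele; strand flips are
resolved by complementing, and palindromic (A/T, C/G) variants whose allele
frequency is too close to 0.5 to disambiguate are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MREstimate",
    "MRReport",
    "WeakInstrumentError",
    "harmonize",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "mr_analysis",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_PALINDROME_MAF = 0.42
DEFAULT_N_BOOT = 1000
DEFAULT_BOOT_SEED = 20230421


class WeakInstrumentError(ValueError):
    """Gene-exposure association is zero; the ratio estimate is undefined."""


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate with normal-theory CI and p-value."""

    method: str
    beta: float
    se: float
    n_instruments: int
    seed: int | None = None

    @property
    def ci_low(self) -> float:
        return self.beta - 1.96 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + 1.96 * self.se

    @property
    def pval(self) -> float:
        if self.se == 0:
            return 0.0 if self.beta != 0 else 1.0
        return 2.0 * stats.norm.sf(abs(self.beta / self.se))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_instruments": self.n_instruments,
            "seed": self.seed,
        }


@dataclass
class MRReport:
    estimates: list[MREstimate]
    instruments: pd.DataFrame
    dropped: pd.DataFrame
    errors: dict[str, str] = field(default_factory=dict)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def _check_columns(df: pd.DataFrame, label: str) -> None:
    required = {"variant_id", "effect_allele", "other_allele", "beta", "se"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{label} table lacks columns {sorted(missing)}")


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_maf: float = DEFAULT_PALINDROME_MAF,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align outcome effects to the exposure's effect allele.

    Variants are intersected on ``variant_id``.  Outcome rows whose alleles
    are swapped relative to the exposure get their beta sign and eaf flipped;
    strand flips (complement alleles) are resolved before comparison.
    Palindromic variants are dropped when min(eaf, 1-eaf) > ``palindrome_maf``
    on either side (frequency too close to 0.5 to orient the strand), and
    incompatible allele pairs are dropped.

    Returns ``(harmonized, dropped)``.  ``harmonized`` has columns
    variant_id, effect_allele, other_allele, eaf_exposure, beta_exposure,
    se_exposure, eaf_outcome, beta_outcome, se_outcome, harmonized;
    ``dropped`` lists (variant_id, reason).
    """
    _check_columns(exposure, "exposure")
    _check_columns(outcome, "outcome")
    merged = exposure.merge(
        outcome, on="variant_id", suffixes=("_exposure", "_outcome"), how="inner"
    )
    if merged.empty:
        raise ValueError("no shared variants between exposure and outcome tables")
    if (merged["se_exposure"] <= 0).any() or (merged["se_outcome"] <= 0).any():
        raise ValueError("standard errors must be positive")

    rows, dropped = [], []
    for rec in merged.itertuples(index=False):
        e1, e2 = rec.effect_allele_exposure, rec.other_allele_exposure
        o1, o2 = rec.effect_allele_outcome, rec.other_allele_outcome
        eaf_exp = getattr(rec, "eaf_exposure", math.nan)
        eaf_out = getattr(rec, "eaf_outcome", math.nan)
        beta_out, se_out = rec.beta_outcome, rec.se_outcome

        if _is_palindromic(e1, e2):
            freqs = [f for f in (eaf_exp, eaf_out) if not (f is None or math.isnan(f))]
            if any(min(f, 1 - f) > palindrome_maf for f in freqs) or not freqs:
                dropped.append((rec.variant_id, "palindromic_ambiguous"))
                continue

        if (o1, o2) == (e1, e2):
            pass
        elif (o1, o2) == (e2, e1):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if not math.isnan(eaf_out) else eaf_out
        elif (o1, o2) == (_COMPLEMENT.get(e1), _COMPLEMENT.get(e2)):
            pass  # strand flip, same orientation
        elif (o1, o2) == (_COMPLEMENT.get(e2), _COMPLEMENT.get(e1)):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if not math.isnan(eaf_out) else eaf_out
        else:
            dropped.append((rec.variant_id, "incompatible_alleles"))
            continue

        rows.append(
            {
                "variant_id": rec.variant_id,
                "effect_allele": e1,
                "other_allele": e2,
                "eaf_exposure": eaf_exp,
                "beta_exposure": rec.beta_exposure,
                "se_exposure": rec.se_exposure,
                "eaf_outcome": eaf_out,
                "beta_outcome": beta_out,
                "se_outcome": se_out,
                "harmonized": True,
            }
        )
    dropped_df = pd.DataFrame(dropped, columns=["variant_id", "reason"])
    return pd.DataFrame(rows), dropped_df


def _ratio_and_se(
    beta_exp: np.ndarray,
    se_exp: np.ndarray,
    beta_out: np.ndarray,
    se_out: np.ndarray,
    second_order: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant Wald ratios with delta-method SEs.

    First order: se^2 = se_out^2/beta_exp^2 + beta_out^2*se_exp^2/beta_exp^4
    (the |ratio|*sqrt(se_out^2/beta_out^2 + se_exp^2/beta_exp^2) form, written
    so the beta_out = 0 limit se = se_out/|beta_exp| falls out directly).
    Second order adds the next Taylor term.
    """
    beta_exp = np.asarray(beta_exp, dtype=float)
    if np.any(beta_exp == 0):
        raise WeakInstrumentError("beta_exposure of 0 gives an undefined Wald ratio")
    se_exp = np.asarray(se_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    ratio = beta_out / beta_exp
    var = se_out**2 / beta_exp**2 + beta_out**2 * se_exp**2 / beta_exp**4
    if second_order:
        var = var + se_out**2 * se_exp**2 / beta_exp**4
    return ratio, np.sqrt(var)


def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    second_order: bool = False,
) -> MREstimate:
    """Single-instrument causal estimate: gene-outcome over gene-exposure."""
    ratio, se = _ratio_and_se(
        np.array([beta_exp]), np.array([se_exp]), np.array([beta_out]), np.array([se_out]),
        second_order=second_order,
    )
    return MREstimate(method="wald", beta=float(ratio[0]), se=float(se[0]), n_instruments=1)


def _pooled_ratio_weights(
    be: np.ndarray, se_e: np.ndarray, bo: np.ndarray, se_o: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ratios with delta-method variances using a pooled plug-in effect.

    The exposure-uncertainty term of the per-variant delta variance is
    evaluated at a pilot pooled estimate (IVW with outcome-only weights)
    instead of each variant's own noisy ratio:

        s_j^2 = se_out_j^2/beta_exp_j^2 + theta_pilot^2 * se_exp_j^2/beta_exp_j^2

    Using the per-variant outcome beta there makes the weights correlate
    with the estimates (downweighting upward fluctuations), which biases the
    weighted mean and breaks CI coverage; the pooled plug-in removes that.
    With a single instrument theta_pilot = bo/be, so s^2 reduces exactly to
    the Wald-ratio first-order delta variance.
    """
    if np.any(be == 0):
        raise WeakInstrumentError("beta_exposure of 0 gives an undefined Wald ratio")
    ratios = bo / be
    w0 = be**2 / se_o**2
    pilot = float((w0 * ratios).sum() / w0.sum())
    var = se_o**2 / be**2 + pilot**2 * se_e**2 / be**2
    return ratios, np.sqrt(var), np.full_like(ratios, pilot)


def _extract(stats_df: pd.DataFrame) -> tuple[np.ndarray, ...]:
    cols = ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome")
    missing = [c for c in cols if c not in stats_df.columns]
    if missing:
        raise ValueError(f"harmonized table lacks columns {missing}")
    return tuple(stats_df[c].to_numpy(dtype=float) for c in cols)


def ivw(stats_df: pd.DataFrame, mode: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted average of per-instrument Wald ratios.

    fixed: se = (sum w_j)^(-1/2) with w_j the inverse squared delta-method
    ratio SEs (pooled plug-in variant, see :func:`_pooled_ratio_weights`).
    random: multiplicative overdispersion, the fixed SE inflated by
    max(1, sqrt(Q/(J-1))) where Q is Cochran's heterogeneity statistic —
    never deflated below the fixed-effect SE.  With one instrument this is
    numerically identical to :func:`wald_ratio`.
    """
    if mode not in ("fixed", "random"):
        raise ValueError("mode must be 'fixed' or 'random'")
    be, se_e, bo, se_o = _extract(stats_df)
    j = len(be)
    if j == 0:
        raise ValueError("no instruments")
    ratios, ses, _ = _pooled_ratio_weights(be, se_e, bo, se_o)
    w = 1.0 / ses**2
    beta = float((w * ratios).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    method = f"ivw_{mode}"
    if mode == "random" and j > 1:
        q = float((w * (ratios - beta) ** 2).sum())
        se *= max(1.0, math.sqrt(q / (j - 1)))
    return MREstimate(method=method, beta=beta, se=se, n_instruments=j)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weight-0.5 percentile of the ratios by midpoint interpolation."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    midpoints = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, midpoints, r))


def weighted_median(
    stats_df: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_BOOT_SEED,
) -> MREstimate:
    """Weighted median of Wald ratios; SE by seeded parametric bootstrap.

    Each bootstrap replicate redraws every beta_exposure and beta_outcome
    from normal distributions centred on the observed values with their
    stated SEs, recomputes ratios, delta-method weights and the weighted
    median; the SE is the SD over replicates.  Requires >= 3 instruments.
    """
    be, se_e, bo, se_o = _extract(stats_df)
    j = len(be)
    if j < 3:
        raise ValueError(f"weighted median needs >= 3 instruments, got {j}")
    ratios, ses, _ = _pooled_ratio_weights(be, se_e, bo, se_o)
    beta = _weighted_median(ratios, 1.0 / ses**2)

    rng = np.random.default_rng(seed)
    be_star = rng.normal(be, se_e, size=(n_boot, j))
    bo_star = rng.normal(bo, se_o, size=(n_boot, j))
    be_star[be_star == 0.0] = np.finfo(float).tiny  # degenerate resample guard
    r_star = bo_star / be_star
    w0 = be_star**2 / se_o**2
    pilot = (w0 * r_star).sum(axis=1, keepdims=True) / w0.sum(axis=1, keepdims=True)
    var_star = se_o**2 / be_star**2 + pilot**2 * se_e**2 / be_star**2
    w_star = 1.0 / var_star
    order = np.argsort(r_star, axis=1)
    r_sorted = np.take_along_axis(r_star, order, axis=1)
    w_sorted = np.take_along_axis(w_star, order, axis=1)
    w_sorted = w_sorted / w_sorted.sum(axis=1, keepdims=True)
    mids = np.cumsum(w_sorted, axis=1) - w_sorted / 2.0
    boots = np.array(
        [np.interp(0.5, mids[i], r_sorted[i]) for i in range(n_boot)]
    )
    se = float(boots.std(ddof=1))
    return MREstimate(
        method="weighted_median", beta=beta, se=se, n_instruments=j, seed=seed
    )


def mr_analysis(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    methods: tuple[str, ...] = ("ivw_fixed", "weighted_median"),
    palindrome_maf: float = DEFAULT_PALINDROME_MAF,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_BOOT_SEED,
) -> MRReport:
    """Harmonize, then run every requested estimator.

    Single-instrument inputs route automatically to the Wald ratio (IVW on
    one instrument is numerically identical to it).  Per-method failures are
    recorded in ``report.errors`` without aborting the other methods.
    """
    harmonized, dropped = harmonize(exposure, outcome, palindrome_maf=palindrome_maf)
    if harmonized.empty:
        raise ValueError("no instruments survived harmonization")
    be, se_e, bo, se_o = _extract(harmonized)
    ratios, ses, _ = _pooled_ratio_weights(be, se_e, bo, se_o)
    instruments = harmonized.assign(ratio=ratios, ratio_se=ses, weight=1.0 / ses**2)

    single = len(harmonized) == 1
    estimates: list[MREstimate] = []
    errors: dict[str, str] = {}
    for method in methods:
        try:
            if method == "wald" or (single and method.startswith("ivw")):
                if not single and method == "wald":
                    raise ValueError("wald ratio requires exactly one instrument")
                est = wald_ratio(float(be[0]), float(se_e[0]), float(bo[0]), float(se_o[0]))
                est = MREstimate(
                    method=method, beta=est.beta, se=est.se, n_instruments=1
                )
            elif method in ("ivw", "ivw_fixed"):
                est = ivw(harmonized, mode="fixed")
            elif method == "ivw_random":
                est = ivw(harmonized, mode="random")
            elif method in ("weighted_median", "wmedian"):
                est = weighted_median(harmonized, n_boot=n_boot, seed=seed)
            else:
                raise ValueError(f"unknown method {method!r}")
        except ValueError as exc:
            errors[method] = str(exc)
            continue
        estimates.append(est)
    return MRReport(
        estimates=estimates, instruments=instruments, dropped=dropped, errors=errors
    )
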