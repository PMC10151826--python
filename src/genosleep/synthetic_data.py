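"""Simulators with known ground truth.

Every generator here is a pure function of its parameters and an explicit
integer seed; no global RNG state is touched.  The outputs use the same
table dialects the analysis modules consume, so the full pipeline can be
exercised without any external data:

* genotype TSV: ``individual_id`` plus one integer dosage column per variant;
* phenotype TSV: ``individual_id``, ``exposure``, ``outcome``, covariates;
* GWAS summary-stats TSV: ``variant_id``, ``effect_allele``, ``other_allele``,
  ``eaf``, ``beta``, ``se``, ``pval``, ``n``;
* activity-monitor files: see :mod:`genosleep.dam`.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from genosleep.dam import BIN_SECONDS, ActivityRecord

__all__ = [
    "SnpSpec",
    "GenotypeMatrix",
    "GroundTruth",
    "CovariateSpec",
    "ActivityProfile",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_summary_stats",
    "simulate_activity",
    "make_assay_fixtures",
    "random_snp_panel",
    "write_genotypes_tsv",
    "write_phenotypes_tsv",
    "write_summary_stats_tsv",
    "read_summary_stats_tsv",
]

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpSpec:
    """One biallelic variant and its true effects.

    ``beta_exposure != 0`` makes the variant a relevant instrument;
    ``beta_direct_outcome == 0`` makes it a *valid* one (no direct,
    exposure-bypassing effect on the outcome).
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    maf: float
    beta_exposure: float = 0.0
    beta_direct_outcome: float = 0.0

    def __post_init__(self) -> None:
        if self.effect_allele not in _NUCLEOTIDES or self.other_allele not in _NUCLEOTIDES:
            raise ValueError(
                f"{self.variant_id}: alleles must be single nucleotides, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"{self.variant_id}: maf must lie in (0, 0.5], got {self.maf}")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive effect-allele dosages in {0, 1, 2}."""

    dosages: np.ndarray
    snps: list[SnpSpec]
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-d array")
        n, m = self.dosages.shape
        if m != len(self.snps):
            raise ValueError(f"{m} dosage columns but {len(self.snps)} SNP specs")
        if n != len(self.individual_ids):
            raise ValueError(f"{n} dosage rows but {len(self.individual_ids)} individual ids")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must all be in {0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return [s.variant_id for s in self.snps]


@dataclass(frozen=True)
class GroundTruth:
    """The known answer recorded alongside every simulated cohort.

    ``confounder_effects`` are the loadings (a, b) of one latent standard
    Gaussian U on exposure and outcome; ``noise_sds`` are the SDs of the
    independent Gaussian residuals of exposure and outcome.
    """

    theta: float
    confounder_effects: tuple[float, float] = (0.0, 0.0)
    noise_sds: tuple[float, float] = (1.0, 1.0)
    seed: int = 0


@dataclass(frozen=True)
class CovariateSpec:
    """One generated covariate column.

    dist: 'normal' (loc, scale) or 'bernoulli' (p).  ``effect_exposure`` and
    ``effect_outcome`` are additive loadings on the two traits.
    """

    name: str
    dist: str = "normal"
    params: tuple[float, ...] = (0.0, 1.0)
    effect_exposure: float = 0.0
    effect_outcome: float = 0.0


def simulate_genotypes(
    n_individuals: int, snps: Sequence[SnpSpec], seed: int
) -> GenotypeMatrix:
    """Draw Hardy-Weinberg dosages, Binomial(2, maf), independent across SNPs.

    No linkage disequilibrium is simulated: columns are mutually independent.
    Deterministic given ``seed``.
    """
    if n_individuals < 1:
        raise ValueError(f"n_individuals must be >= 1, got {n_individuals}")
    snps = list(snps)
    if not snps:
        raise ValueError("need at least one SnpSpec")
    rng = np.random.default_rng(seed)
    mafs = np.array([s.maf for s in snps])
    dosages = rng.binomial(2, mafs, size=(n_individuals, len(snps)))
    ids = [f"ind{i:06d}" for i in range(n_individuals)]
    return GenotypeMatrix(dosages=dosages, snps=snps, individual_ids=ids)


def simulate_cohort(
    genotypes: GenotypeMatrix,
    truth: GroundTruth,
    covariate_plan: Sequence[CovariateSpec] = (),
) -> pd.DataFrame:
    """Build exposure/outcome traits from the structural model.

    exposure_i = sum_j beta_exposure_j * g_ij + a*U_i + sum_c c_eff*x_ic + eps_i
    outcome_i  = theta*exposure_i + sum_j beta_direct_j * g_ij + b*U_i
                 + sum_c c_eff*x_ic + eta_i

    U, eps, eta are independent Gaussians (U standard; eps, eta scaled by
    ``truth.noise_sds``).  The latent confounder is retained in the returned
    table purely for testing.  Randomness is governed by ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    n = genotypes.n_individuals
    g = genotypes.dosages.astype(float)
    beta_exp = np.array([s.beta_exposure for s in genotypes.snps])
    beta_dir = np.array([s.beta_direct_outcome for s in genotypes.snps])
    a, b = truth.confounder_effects
    sd_eps, sd_eta = truth.noise_sds
    if sd_eps < 0 or sd_eta < 0:
        raise ValueError("noise SDs must be non-negative")

    u = rng.standard_normal(n)
    eps = rng.standard_normal(n) * sd_eps
    eta = rng.standard_normal(n) * sd_eta

    table = pd.DataFrame({"individual_id": genotypes.individual_ids})
    cov_exposure = np.zeros(n)
    cov_outcome = np.zeros(n)
    for spec in covariate_plan:
        if spec.dist == "normal":
            loc, scale = spec.params
            x = rng.normal(loc, scale, size=n)
        elif spec.dist == "bernoulli":
            (p,) = spec.params
            x = rng.binomial(1, p, size=n).astype(float)
        else:
            raise ValueError(f"unknown covariate distribution {spec.dist!r}")
        table[spec.name] = x
        cov_exposure += spec.effect_exposure * x
        cov_outcome += spec.effect_outcome * x

    exposure = g @ beta_exp + a * u + cov_exposure + eps
    outcome = truth.theta * exposure + g @ beta_dir + b * u + cov_outcome + eta
    table["exposure"] = exposure
    table["outcome"] = outcome
    table["confounder"] = u  # latent; for parameter-recovery tests only
    return table


def _marginal_stats(y: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorised per-column simple OLS of y on each dosage column.

    Returns (beta, se, pval) arrays.  Matches association.fit_linear_model
    with design [1, g_j] up to floating point (tested).
    """
    from scipy import stats

    n = len(y)
    yc = y - y.mean()
    gc = g - g.mean(axis=0)
    ssg = (gc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gc.T @ yc / ssg
        rss = (yc**2).sum() - beta**2 * ssg
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / ssg)
        t = beta / se
    pval = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return beta, se, pval


def simulate_summary_stats(
    snps: Sequence[SnpSpec],
    truth: GroundTruth,
    n_exposure: int,
    n_outcome: int,
    seed: int,
    covariate_plan: Sequence[CovariateSpec] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sample GWAS summary statistics from independent cohorts.

    Simulates one cohort of ``n_exposure`` individuals for the exposure GWAS
    and an independent cohort of ``n_outcome`` for the outcome GWAS, then
    computes per-SNP marginal regression estimates in each.  Returns
    (exposure_stats, outcome_stats) in the summary-stats TSV dialect.
    """
    snps = list(snps)
    base = np.random.default_rng(seed)
    seed_a, seed_b = (int(s) for s in base.integers(0, 2**63 - 1, size=2))

    geno_a = simulate_genotypes(n_exposure, snps, seed_a)
    cohort_a = simulate_cohort(geno_a, dataclasses.replace(truth, seed=seed_a), covariate_plan)
    geno_b = simulate_genotypes(n_outcome, snps, seed_b)
    cohort_b = simulate_cohort(geno_b, dataclasses.replace(truth, seed=seed_b), covariate_plan)

    out = []
    for geno, cohort, trait, n in (
        (geno_a, cohort_a, "exposure", n_exposure),
        (geno_b, cohort_b, "outcome", n_outcome),
    ):
        beta, se, pval = _marginal_stats(cohort[trait].to_numpy(), geno.dosages.astype(float))
        out.append(
            pd.DataFrame(
                {
                    "variant_id": geno.variant_ids,
                    "effect_allele": [s.effect_allele for s in snps],
                    "other_allele": [s.other_allele for s in snps],
                    "eaf": geno.dosages.mean(axis=0) / 2.0,
                    "beta": beta,
                    "se": se,
                    "pval": pval,
                    "n": n,
                }
            )
        )
    return out[0], out[1]


def random_snp_panel(
    n_snps: int,
    seed: int,
    maf_range: tuple[float, float] = (0.1, 0.5),
    beta_exposure_mean: float = 0.2,
    beta_exposure_sd: float = 0.05,
    n_pleiotropic: int = 0,
    beta_direct: float = 0.0,
    alleles: tuple[str, str] = ("A", "G"),
) -> list[SnpSpec]:
    """Convenience panel: instrument effects ~ N(mean, sd), MAF ~ U(range).

    The first ``n_pleiotropic`` variants get a direct outcome effect of
    ``beta_direct`` (invalid instruments); the rest are valid.
    """
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(*maf_range, size=n_snps)
    betas = rng.normal(beta_exposure_mean, beta_exposure_sd, size=n_snps)
    return [
        SnpSpec(
            variant_id=f"rs{i:05d}",
            effect_allele=alleles[0],
            other_allele=alleles[1],
            maf=float(mafs[i]),
            beta_exposure=float(betas[i]),
            beta_direct_outcome=beta_direct if i < n_pleiotropic else 0.0,
        )
        for i in range(n_snps)
    ]


# ---------------------------------------------------------------------------
# fly activity
# ---------------------------------------------------------------------------

#: bins per 24 h at the native 30-s resolution
BINS_PER_DAY = 24 * 3600 // BIN_SECONDS


@dataclass(frozen=True)
class ActivityProfile:
    """Sleep-architecture parameters for simulated flies.

    Bout lengths are geometric (memoryless) in 30-s bins around the stated
    means; sleep bouts are always generated at >= ``min_sleep_bout_min`` so
    that every generated bout is detectable by the standard 5-min rule and
    the generator's ground truth is exactly recoverable.  A mean sleep bout
    of 0 in a phase disables sleep in that phase.  Waking bins always carry
    at least one beam-break count, so no spurious sleep is ever generated.
    """

    mean_wake_bout_min_day: float = 40.0
    mean_sleep_bout_min_day: float = 20.0
    mean_wake_bout_min_night: float = 15.0
    mean_sleep_bout_min_night: float = 60.0
    day_activity_rate: float = 2.0
    night_activity_rate: float = 1.0
    morning_peak: float = 2.0
    evening_peak: float = 2.5
    min_sleep_bout_min: float = 5.0
    lights_on_hour: float = 8.0
    light_hours: float = 12.0


def _bout_bins(rng: np.random.Generator, mean_min: float, minimum_bins: int) -> int:
    """Geometric bout length in bins with the given floor."""
    mean_bins = mean_min * 60.0 / BIN_SECONDS
    excess = max(mean_bins - minimum_bins, 1e-9)
    return minimum_bins + rng.geometric(min(1.0, 1.0 / (1.0 + excess))) - 1


def _wake_rate(profile: ActivityProfile, zt_hours: np.ndarray) -> np.ndarray:
    """Expected counts per waking bin, bimodal under 12:12 LD."""
    zt = np.mod(zt_hours, 24.0)
    is_day = zt < profile.light_hours
    base = np.where(is_day, profile.day_activity_rate, profile.night_activity_rate)
    morning = profile.morning_peak * np.exp(-0.5 * ((zt - 0.5) / 0.75) ** 2)
    evening = profile.evening_peak * np.exp(
        -0.5 * ((zt - (profile.light_hours - 0.5)) / 0.75) ** 2
    )
    return base + morning + evening


def simulate_activity(
    n_flies: int,
    days: int,
    profile: ActivityProfile | None = None,
    death_times_h: Sequence[float | None] | None = None,
    seed: int = 0,
) -> tuple[list[ActivityRecord], pd.DataFrame]:
    """Simulate per-fly 30-s binned activity under a light/dark cycle.

    Returns ``(records, truth)``.  ``truth`` has one row per fly with the
    generator's ground-truth sleep minutes per 24 h (total/day/night,
    averaged over the recorded window, counting only bins before any death)
    and the death time in hours from record start (NaN if none).

    Records start exactly at lights-on (ZT0).  All counts after a fly's
    death time are zero.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    profile = profile or ActivityProfile()
    if death_times_h is not None and len(death_times_h) != n_flies:
        raise ValueError("death_times_h must have one entry per fly")

    rng = np.random.default_rng(seed)
    n_bins = days * BINS_PER_DAY
    zt = np.arange(n_bins) * (BIN_SECONDS / 3600.0)
    zt_mod = np.mod(zt, 24.0)
    is_day = zt_mod < profile.light_hours
    rates = _wake_rate(profile, zt)
    min_bins = max(1, int(round(profile.min_sleep_bout_min * 60.0 / BIN_SECONDS)))
    start = _dt.datetime(2023, 4, 21, int(profile.lights_on_hour), 0, 0)

    records: list[ActivityRecord] = []
    truth_rows = []
    for f in range(n_flies):
        asleep = np.zeros(n_bins, dtype=bool)
        pos = 0
        sleeping = False
        while pos < n_bins:
            day_here = bool(is_day[pos])
            if sleeping:
                mean = (
                    profile.mean_sleep_bout_min_day
                    if day_here
                    else profile.mean_sleep_bout_min_night
                )
                if mean > 0:
                    length = _bout_bins(rng, mean, min_bins)
                    asleep[pos : pos + length] = True
                    pos += length
            else:
                mean = (
                    profile.mean_wake_bout_min_day
                    if day_here
                    else profile.mean_wake_bout_min_night
                )
                pos += _bout_bins(rng, mean, 1)
            sleeping = not sleeping

        # a sleep bout truncated by the record end can fall below the
        # detectable minimum; wake those bins so ground truth stays exact
        tail = 0
        while tail < n_bins and asleep[n_bins - 1 - tail]:
            tail += 1
        if 0 < tail < min_bins:
            asleep[n_bins - tail :] = False

        counts = np.zeros(n_bins, dtype=int)
        awake = ~asleep
        # waking bins always register >= 1 count
        counts[awake] = 1 + rng.poisson(np.maximum(rates[awake] - 1.0, 0.0))

        death = None if death_times_h is None else death_times_h[f]
        if death is not None:
            death_bin = int(np.ceil(death * 3600.0 / BIN_SECONDS))
            counts[death_bin:] = 0
            alive = np.arange(n_bins) < death_bin
            # ground truth follows the last-waking-activity definition: the
            # recorded death time is the end of the last nonzero bin
            nonzero = np.flatnonzero(counts)
            death = (
                (int(nonzero[-1]) + 1) * BIN_SECONDS / 3600.0 if len(nonzero) else 0.0
            )
        else:
            alive = np.ones(n_bins, dtype=bool)

        fly_id = f"fly{f:03d}"
        records.append(
            ActivityRecord(
                fly_id=fly_id,
                channel=(f % 32) + 1,
                start=start,
                counts=counts,
                lights_on_hour=profile.lights_on_hour,
                light_hours=profile.light_hours,
            )
        )
        sleep_bins = asleep & alive
        to_min = BIN_SECONDS / 60.0
        day_min = (sleep_bins & is_day).sum() * to_min / days
        night_min = (sleep_bins & ~is_day).sum() * to_min / days
        truth_rows.append(
            {
                "fly_id": fly_id,
                "sleep_min_total": day_min + night_min,  # composed as scored
                "sleep_min_day": day_min,
                "sleep_min_night": night_min,
                "death_time_h": np.nan if death is None else float(death),
            }
        )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# assay fixtures
# ---------------------------------------------------------------------------


def make_assay_fixtures(
    kind: str, params: dict | None = None, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Small fixture tables in the dialects the assay/survival code consumes.

    kind='climbing': params {'counts': [n0..n5]} -> one-row table echoing them.
    kind='cafe':     params {'displacements_mm', 'mm_per_ul', 'n_flies',
                     'duration_h'} -> one row per capillary.
    kind='qpcr':     params {'groups': {name: n_samples}, 'genes',
                     'reference_gene', 'ct_spread', 'group_shifts'} -> long
                     table (sample_id, group, gene, ct) with triplicates.
    kind='survival': params {'times', 'events', 'group'} -> SurvivalData table.

    Returns (table, ground_truth).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)

    if kind == "climbing":
        counts = list(params.get("counts", [2, 3, 5, 4, 1, 0]))
        if len(counts) != 6:
            raise ValueError("climbing fixture needs exactly six chamber counts n0..n5")
        table = pd.DataFrame([{f"n{i}": c for i, c in enumerate(counts)}])
        total = sum(counts)
        truth = {
            "counts": counts,
            "index": sum(i * c for i, c in enumerate(counts)) / (5.0 * total)
            if total
            else np.nan,
        }
        return table, truth

    if kind == "cafe":
        disp = list(params.get("displacements_mm", [4.0, 5.5, 3.0, 6.0, 2.5, 4.5]))
        mm_per_ul = float(params.get("mm_per_ul", 6.0))
        n_flies = int(params.get("n_flies", 8))
        duration_h = float(params.get("duration_h", 19.0))
        table = pd.DataFrame(
            {
                "capillary": np.arange(1, len(disp) + 1),
                "displacement_mm": disp,
                "mm_per_ul": mm_per_ul,
                "n_flies": n_flies,
                "duration_h": duration_h,
            }
        )
        total_ul = sum(disp) / mm_per_ul
        truth = {"total_ul": total_ul, "per_fly_ul": total_ul / n_flies}
        return table, truth

    if kind == "qpcr":
        groups = params.get("groups", {"control": 4, "treated": 4})
        genes = list(params.get("genes", ["target"]))
        reference_gene = params.get("reference_gene", "rp49")
        ct_spread = float(params.get("ct_spread", 0.05))
        group_shifts = dict(params.get("group_shifts", {"treated": -1.0}))
        rows = []
        for group, n_samples in groups.items():
            for s in range(n_samples):
                sample = f"{group}_{s}"
                for gene in [reference_gene] + genes:
                    base = 18.0 if gene == reference_gene else 24.0
                    shift = 0.0 if gene == reference_gene else group_shifts.get(group, 0.0)
                    for _ in range(3):
                        rows.append(
                            {
                                "sample_id": sample,
                                "group": group,
                                "gene": gene,
                                "ct": base + shift + rng.normal(0.0, ct_spread),
                            }
                        )
        table = pd.DataFrame(rows)
        truth = {
            "reference_gene": reference_gene,
            "expected_fold_change": {
                g: 2.0 ** (-shift) for g, shift in group_shifts.items()
            },
        }
        return table, truth

    if kind == "survival":
        times = list(params.get("times", [5.0] * 8))
        events = list(params.get("events", [1] * len(times)))
        group = params.get("group", "control")
        table = pd.DataFrame(
            {
                "subject_id": [f"s{i:03d}" for i in range(len(times))],
                "time": times,
                "event": events,
                "group": group,
            }
        )
        return table, {"times": times, "events": events}

    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        genotypes.dosages, columns=genotypes.variant_ids
    )
    df.insert(0, "individual_id", genotypes.individual_ids)
    df.to_csv(path, sep="\t", index=False)


def write_phenotypes_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def write_summary_stats_tsv(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> GenotypeMatrix:
    """Read a genotype TSV back into a GenotypeMatrix.

    Allele annotations are not stored in the dosage TSV, so the rebuilt
    SnpSpecs carry placeholder A/G alleles and the *empirical* effect-allele
    frequency folded into (0, 0.5] (floored just above 0 for monomorphic
    columns).  Dosage data round-trip exactly.
    """
    df = pd.read_csv(path, sep="\t")
    if "individual_id" not in df.columns:
        raise ValueError(f"genotype file {path} lacks an individual_id column")
    ids = df["individual_id"].astype(str).tolist()
    variant_ids = [c for c in df.columns if c != "individual_id"]
    dosages = df[variant_ids].to_numpy(dtype=int)
    snps = []
    for j, vid in enumerate(variant_ids):
        freq = dosages[:, j].mean() / 2.0
        maf = min(freq, 1.0 - freq)
        snps.append(
            SnpSpec(
                variant_id=vid,
                effect_allele="A",
                other_allele="G",
                maf=max(maf, 1e-9),
            )
        )
    return GenotypeMatrix(dosages=dosages, snps=snps, individual_ids=ids)


def read_summary_stats_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "effect_allele", "other_allele", "beta", "se"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary-stats file {path} lacks columns {sorted(missing)}")
    return df
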