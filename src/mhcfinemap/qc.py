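"""Sample- and variant-level quality control for case-control genotype data.

Implements the array-QC filters of the fine-mapping pipeline as pure,
order-explicit operations: per-cohort sample and variant call-rate
filters, cross-cohort allele-frequency discordance, a within-case
batch-association filter, indel/duplicate-position metadata filters,
method-of-moments relatedness (PI_HAT), PCA outlier exclusion (with
recomputation of components on survivors), minor-allele-frequency and
Hardy-Weinberg exact-test filters.

Every filter returns an explicit report fragment; :func:`run_qc` applies
them in the study's order and reconciles the counts. Re-running the full
QC on its own output excludes nothing further (idempotence).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .association import fit_logistic
from .data import CAT_SNV, ConfigurationError, DosageMatrix
from scipy.stats import chi2

__all__ = [
    "QCThresholds",
    "QCReport",
    "filter_sample_call_rate",
    "filter_variant_call_rate",
    "filter_freq_discordance",
    "filter_case_batch_association",
    "filter_variant_metadata",
    "hard_genotypes",
    "hwe_exact_test",
    "filter_hwe",
    "filter_maf",
    "pi_hat",
    "relatedness_filter",
    "ld_prune",
    "pca_outliers",
    "run_qc",
]


@dataclass
class QCThresholds:
    """All QC cutoffs, defaulting to the study's values.

    Call-rate minima are per cohort; ``freq_discordance_max`` is the
    largest tolerated pairwise allele-frequency difference between
    cohorts; ``batch_assoc_p_min`` the floor for the within-case
    batch-association p-value; ``pi_hat_max`` the relatedness bound;
    ``maf_min``/``hwe_p_min`` the variant frequency and Hardy-Weinberg
    floors; ``pca_sd`` the outlier cutoff in SD units on the top
    components.
    """

    sample_call_rate_min: dict = field(
        default_factory=lambda: {"BBJ": 0.99, "Aichi1": 0.95, "Aichi2": 0.97})
    variant_call_rate_min: dict = field(
        default_factory=lambda: {"BBJ": 0.99, "Aichi1": 0.97, "Aichi2": 0.97})
    freq_discordance_max: float = 0.20
    batch_assoc_p_min: float = 1.0e-7
    pi_hat_max: float = 0.125
    maf_min: float = 0.01
    hwe_p_min: float = 1.0e-6
    hwe_controls_only: bool = False
    pca_sd: float = 6.0
    pca_components: int = 10
    pca_report_components: int = 20
    ld_prune_r2: float = 0.2
    min_overlap_variants: int = 500
    genotype_round_tol: float = 0.1

    def validate(self) -> "QCThresholds":
        for d in (self.sample_call_rate_min, self.variant_call_rate_min):
            for k, v in d.items():
                if not 0 < v <= 1:
                    raise ConfigurationError(f"call-rate threshold for {k} outside (0,1]")
        if not 0 < self.maf_min < 0.5:
            raise ConfigurationError("maf_min outside (0, 0.5)")
        return self


@dataclass
class QCReport:
    """Exclusions with reason codes plus an ordered log of applied filters.

    Each excluded entity carries exactly one primary reason: the first
    filter that removed it.
    """

    excluded_samples: dict = field(default_factory=dict)   # id -> reason
    excluded_variants: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)             # filter name -> n newly excluded
    log: list = field(default_factory=list)

    def add_samples(self, name: str, ids) -> None:
        new = [s for s in ids if s not in self.excluded_samples]
        for s in new:
            self.excluded_samples[s] = name
        self.counts[name] = self.counts.get(name, 0) + len(new)
        self.log.append(f"{name}: excluded {len(new)} samples")

    def add_variants(self, name: str, ids) -> None:
        new = [v for v in ids if v not in self.excluded_variants]
        for v in new:
            self.excluded_variants[v] = name
        self.counts[name] = self.counts.get(name, 0) + len(new)
        self.log.append(f"{name}: excluded {len(new)} variants")

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.excluded_samples), "reason": list(self.excluded_samples.values())}
        )

    def variants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variant_id": list(self.excluded_variants), "reason": list(self.excluded_variants.values())}
        )


def _cohort_thresholds(cohorts: pd.Series, table: dict) -> pd.Series:
    unknown = set(cohorts.unique()) - set(table)
    if unknown:
        raise ConfigurationError(f"no call-rate threshold for cohort(s) {sorted(unknown)}")
    return cohorts.map(table)


def filter_sample_call_rate(dosages: pd.DataFrame, cohorts: pd.Series,
                            thresholds: QCThresholds) -> list[str]:
    """Samples with call rate below their cohort's minimum (strict <)."""
    rate = dosages.notna().mean(axis=1)
    cut = _cohort_thresholds(cohorts.loc[dosages.index], thresholds.sample_call_rate_min)
    return list(rate.index[rate < cut])


def filter_variant_call_rate(dosages: pd.DataFrame, cohorts: pd.Series,
                             thresholds: QCThresholds) -> list[str]:
    """Variants below their call-rate minimum in any cohort (strict <)."""
    _cohort_thresholds(cohorts.loc[dosages.index], thresholds.variant_call_rate_min)
    bad: set[str] = set()
    for name, sub in dosages.groupby(cohorts.loc[dosages.index]):
        cut = thresholds.variant_call_rate_min[name]
        rate = sub.notna().mean(axis=0)
        bad.update(rate.index[rate < cut])
    return sorted(bad)


def filter_freq_discordance(dosages: pd.DataFrame, cohorts: pd.Series,
                            thresholds: QCThresholds,
                            log: list | None = None) -> list[str]:
    """Variants whose allele frequency differs by more than the cutoff
    between any pair of cohorts (strict >). Pairs where one cohort has no
    observed calls for the variant are skipped and logged."""
    labs = cohorts.loc[dosages.index]
    names = sorted(labs.unique())
    if len(names) < 2:
        raise ConfigurationError("frequency-discordance filter needs >= 2 cohorts")
    freqs = {name: dosages[labs == name].mean(axis=0) / 2.0 for name in names}
    counts = {name: dosages[labs == name].notna().sum(axis=0) for name in names}
    bad: set[str] = set()
    skipped = 0
    for a, b in itertools.combinations(names, 2):
        observed = (counts[a] > 0) & (counts[b] > 0)
        skipped += int((~observed).sum())
        diff = (freqs[a] - freqs[b]).abs()
        bad.update(diff.index[observed & (diff > thresholds.freq_discordance_max)])
    if log is not None and skipped:
        log.append(f"freq_discordance: skipped {skipped} variant-pairs with no observed calls")
    return sorted(bad)


def filter_case_batch_association(case_dosages: pd.DataFrame, datasets: pd.Series,
                                  thresholds: QCThresholds,
                                  log: list | None = None) -> list[str]:
    """Variants associated with case data-set membership (batch artifacts).

    Likelihood-ratio test of a logistic model of data-set membership on
    dosage among cases; with more than two data sets, one-vs-rest over
    data sets with the minimum p taken. Exclusion at p < threshold,
    strictly. A single data set makes this a logged no-op.
    """
    labs = datasets.loc[case_dosages.index]
    names = sorted(labs.unique())
    if len(names) < 2:
        if log is not None:
            log.append("case_batch_association: single data set, no-op")
        return []
    contrasts = [(labs == names[0]).to_numpy(dtype=float)] if len(names) == 2 else \
        [(labs == n).to_numpy(dtype=float) for n in names]
    bad = []
    for vid in case_dosages.columns:
        d = case_dosages[vid].to_numpy(dtype=float)
        ok = ~np.isnan(d)
        if ok.sum() < 2 or np.nanvar(d) == 0:
            continue
        p_min = 1.0
        for yv in contrasts:
            X0 = pd.DataFrame({"intercept": np.ones(ok.sum())})
            X1 = X0.assign(dosage=d[ok])
            dev = 2.0 * (fit_logistic(yv[ok], X1).loglik - fit_logistic(yv[ok], X0).loglik)
            p_min = min(p_min, float(chi2.sf(max(dev, 0.0), 1)))
        if p_min < thresholds.batch_assoc_p_min:
            bad.append(vid)
    return bad


def filter_variant_metadata(variants: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Indels (REF/ALT longer than one base) and duplicated (chrom, pos).

    Duplicate positions are only meaningful for positional (SNV) markers:
    derived HLA markers deliberately share their gene's coordinate, so
    when a ``category`` column is present the duplicate check is
    restricted to the SNV category. On duplicates the first occurrence is
    kept. Returns (indels, dups).
    """
    ref = variants.get("ref", pd.Series("A", index=variants.index)).fillna("A").astype(str)
    alt = variants.get("alt", pd.Series("T", index=variants.index)).fillna("T").astype(str)
    indels = list(variants.index[(ref.str.len() > 1) | (alt.str.len() > 1)])
    if "category" in variants.columns:
        positional = variants[variants["category"] == CAT_SNV]
    else:
        positional = variants
    dup_mask = positional.duplicated(subset=["chrom", "pos"], keep="first")
    dups = list(positional.index[dup_mask])
    return indels, dups


def hard_genotypes(dosages: pd.DataFrame, tol: float = 0.1) -> pd.DataFrame:
    """Round dosages to 0/1/2 when within ``tol`` of an integer, else missing.

    Genotype-based tests (HWE, PI_HAT) are defined on hard calls; on array
    data before imputation the dosages are already integral.
    """
    arr = dosages.to_numpy(dtype=float)
    rounded = np.round(arr)
    out = np.where(np.abs(arr - rounded) <= tol, rounded, np.nan)
    out[(out < 0) | (out > 2)] = np.nan
    return pd.DataFrame(out, index=dosages.index, columns=dosages.columns)


def _hwe_log_probs(n_a: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of heterozygote counts given margins.

    Returns (feasible het counts, their log-probabilities) for ``n``
    diploids with ``n_a`` copies of the A allele: the standard
    P(h | n, n_a) proportional to 2^h n! / (n_AA! n_aa! h!) with the
    normalizer n_a! n_b! / (2n)! choose-based form, computed via
    log-gamma.
    """
    n_b = 2 * n - n_a
    h_min = n_a % 2
    h_max = min(n_a, n_b)
    hs = np.arange(h_min, h_max + 1, 2)
    n_aa = (n_a - hs) // 2
    n_bb = (n_b - hs) // 2
    logp = (
        hs * math.log(2.0)
        + gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(n_bb + 1) - gammaln(hs + 1)
        + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)
    )
    return hs, logp


def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Exact Hardy-Weinberg test from genotype counts (hom, het, hom).

    p is the total conditional probability, given the allele-count
    margins, of all heterozygote counts no more probable than the
    observed one. Raises on an empty table.
    """
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("HWE test undefined for all-zero genotype counts")
    n_a = 2 * n0 + n1
    hs, logp = _hwe_log_probs(n_a, n)
    p_obs = logp[np.searchsorted(hs, n1)]
    probs = np.exp(logp - logp.max())
    mass = probs[logp <= p_obs + 1e-12].sum() / probs.sum()
    return float(min(mass, 1.0))


def filter_hwe(dosages: pd.DataFrame, thresholds: QCThresholds,
               status: pd.Series | None = None) -> tuple[list[str], list[str]]:
    """Variants out of Hardy-Weinberg equilibrium (exact p < floor, strict).

    Computed on hard genotype calls, over all samples by default
    (``hwe_controls_only`` restricts to controls). Returns (excluded,
    flagged-undefined).
    """
    sub = dosages
    if thresholds.hwe_controls_only and status is not None:
        sub = dosages[status.loc[dosages.index] == 0]
    geno = hard_genotypes(sub, thresholds.genotype_round_tol)
    bad, undefined = [], []
    for vid in geno.columns:
        g = geno[vid].dropna()
        counts = [int((g == k).sum()) for k in (0, 1, 2)]
        if sum(counts) == 0:
            undefined.append(vid)
            continue
        if hwe_exact_test(*counts) < thresholds.hwe_p_min:
            bad.append(vid)
    return bad, undefined


def filter_maf(dosages: pd.DataFrame, status: pd.Series,
               thresholds: QCThresholds) -> list[str]:
    """Variants with MAF below the floor in either cases or controls (strict <)."""
    st = status.loc[dosages.index]
    bad: set[str] = set()
    for group in (0, 1):
        p = dosages[st == group].mean(axis=0) / 2.0
        maf = np.minimum(p, 1.0 - p)
        bad.update(maf.index[maf < thresholds.maf_min])
    return sorted(bad)


def pi_hat(g1, g2, freqs, min_overlap: int = 500) -> float:
    """Method-of-moments IBD sharing P(IBD=1)/2 + P(IBD=2) for one pair.

    The PLINK formulation: observed identity-by-state counts are compared
    with their expectations given allele frequencies to solve for the IBD
    state probabilities, which are clamped to [0, 1] and renormalized.
    Returns NaN (pair skipped) when fewer than ``min_overlap`` variants
    are non-missing in both samples.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    p = np.asarray(freqs, dtype=float)
    ok = ~(np.isnan(g1) | np.isnan(g2)) & (p > 0) & (p < 1)
    m = int(ok.sum())
    if m < min_overlap:
        return float("nan")
    g1, g2, p = g1[ok], g2[ok], p[ok]
    q = 1.0 - p
    ibs = 2.0 - np.abs(g1 - g2)
    # IBS=0 only between opposite homozygotes
    ibs[(ibs == 0) & ~(((g1 == 0) & (g2 == 2)) | ((g1 == 2) & (g2 == 0)))] = 1.0
    n0 = float((ibs == 0).sum())
    n1 = float((ibs == 1).sum())
    n2 = float((ibs == 2).sum())
    e00 = float(np.sum(2 * p**2 * q**2))
    e10 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e20 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e11 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e21 = float(np.sum(p**3 + q**3 + p**2 * q + p * q**2))
    p0 = n0 / e00 if e00 > 0 else 0.0
    p1 = (n1 - p0 * e10) / e11 if e11 > 0 else 0.0
    p2 = (n2 - p0 * e20 - p1 * e21) / m
    probs = np.clip([p0, p1, p2], 0.0, 1.0)
    total = probs.sum()
    if total > 0:
        probs = probs / max(total, 1.0)
    return float(probs[1] / 2.0 + probs[2])


def relatedness_filter(genotypes: pd.DataFrame, freqs, thresholds: QCThresholds,
                       log: list | None = None) -> list[str]:
    """Exclude one member of each pair with PI_HAT above the bound.

    The member with the lower call rate goes; ties keep the
    lexicographically smaller id. Pairs already covered by an earlier
    exclusion are skipped.
    """
    ids = list(genotypes.index)
    if genotypes.shape[1] < thresholds.min_overlap_variants:
        # no pair can reach the overlap floor; every pair would be skipped
        if log is not None:
            log.append(
                f"relatedness: skipped ({genotypes.shape[1]} variants < "
                f"min_overlap {thresholds.min_overlap_variants})")
        return []
    call_rate = genotypes.notna().mean(axis=1)
    excluded: list[str] = []
    excluded_set: set[str] = set()
    skipped = 0
    geno = genotypes.to_numpy(dtype=float)
    for i, j in itertools.combinations(range(len(ids)), 2):
        a, b = ids[i], ids[j]
        if a in excluded_set or b in excluded_set:
            continue
        ph = pi_hat(geno[i], geno[j], freqs,
                    thresholds.min_overlap_variants)
        if np.isnan(ph):
            skipped += 1
            continue
        if ph > thresholds.pi_hat_max:
            if call_rate[a] < call_rate[b]:
                out = a
            elif call_rate[b] < call_rate[a]:
                out = b
            else:
                out = max(a, b)
            excluded.append(out)
            excluded_set.add(out)
    if log is not None and skipped:
        log.append(f"relatedness: skipped {skipped} pairs with insufficient overlap")
    return excluded


def ld_prune(dosages: pd.DataFrame, positions: pd.Series, r2_max: float = 0.2) -> list[str]:
    """Greedy LD pruning by genomic position: keep a variant only if its
    dosage r-squared with every previously kept variant stays below the cap."""
    order = list(positions.loc[dosages.columns].sort_values(kind="stable").index)
    kept: list[str] = []
    arr = {}
    for vid in order:
        x = dosages[vid].to_numpy(dtype=float)
        if np.nanvar(x) == 0:
            continue
        x = np.where(np.isnan(x), np.nanmean(x), x)
        xc = (x - x.mean())
        keep = True
        for kv in kept:
            y = arr[kv]
            r = (xc @ y) / math.sqrt((xc @ xc) * (y @ y))
            if r * r >= r2_max:
                keep = False
                break
        if keep:
            kept.append(vid)
            arr[vid] = xc
    return kept


@dataclass
class PCAResult:
    scores_initial: pd.DataFrame
    outliers: list
    scores_final: pd.DataFrame
    kept_variants: list


def pca_outliers(dosages: pd.DataFrame, positions: pd.Series,
                 thresholds: QCThresholds) -> PCAResult:
    """PCA on frequency-standardized dosages with SD-based outlier flags.

    Variants are LD-pruned first; columns are centered at 2p and scaled by
    sqrt(2p(1-p)); missing entries are mean-imputed. Samples beyond
    ``pca_sd`` standard deviations on any of the top ``pca_components``
    axes are flagged, and components are recomputed on the survivors.
    """
    kept = ld_prune(dosages, positions, thresholds.ld_prune_r2)
    n_comp = min(thresholds.pca_report_components, len(kept), len(dosages) - 1)
    if len(dosages) <= thresholds.pca_components:
        raise ValueError("fewer samples than requested principal components")

    def _scores(df: pd.DataFrame) -> pd.DataFrame:
        arr = df[kept].to_numpy(dtype=float)
        p = np.nanmean(arr, axis=0) / 2.0
        p = np.clip(p, 1e-6, 1 - 1e-6)
        z = (arr - 2 * p) / np.sqrt(2 * p * (1 - p))
        z = np.where(np.isnan(z), 0.0, z)
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        sc = u[:, :n_comp] * s[:n_comp]
        return pd.DataFrame(sc, index=df.index,
                            columns=[f"pc{k + 1}" for k in range(sc.shape[1])])

    scores = _scores(dosages)
    flag_comp = min(thresholds.pca_components, scores.shape[1])
    sd = scores.iloc[:, :flag_comp].std(ddof=1)
    flagged = scores.index[
        (scores.iloc[:, :flag_comp].abs() > thresholds.pca_sd * sd).any(axis=1)
    ]
    survivors = dosages.index.difference(flagged, sort=False)
    scores_final = _scores(dosages.loc[survivors])
    return PCAResult(scores, list(flagged), scores_final, kept)


def run_qc(dosages: DosageMatrix, cohort: pd.DataFrame,
           thresholds: QCThresholds | None = None,
           case_batch_labels: pd.Series | None = None,
           max_rounds: int = 25) -> tuple[DosageMatrix, QCReport]:
    """Apply the full QC pipeline in the study's order, to a fixed point.

    Order within a round: per-cohort sample call rate; per-cohort variant
    call rate; cross-cohort frequency discordance; within-case batch
    association; indel and duplicated-position metadata filters;
    relatedness (PI_HAT); PCA outliers (components recomputed on
    survivors and attached to the report); MAF; HWE. PCA is computed on
    the study matrix alone.

    Removing samples changes the per-variant statistics the variant
    filters see (and vice versa), so a single pass is not a fixed point:
    the round is repeated until a pass excludes nothing (at most
    ``max_rounds``), which makes the pipeline idempotent — running it on
    its own output excludes nothing.
    """
    thresholds = (thresholds or QCThresholds()).validate()
    report = QCReport()
    report.log.append("pca_reference: study matrix alone (no external panel projection)")
    dm = dosages
    for round_no in range(1, max_rounds + 1):
        before = len(report.excluded_samples) + len(report.excluded_variants)
        dm = _qc_pass(dm, cohort, thresholds, case_batch_labels, report)
        newly = len(report.excluded_samples) + len(report.excluded_variants) - before
        report.log.append(f"round {round_no}: excluded {newly} entities")
        if newly == 0:
            break
    else:
        report.log.append(f"not at a fixed point after {max_rounds} rounds")

    report.log.append(
        f"retained {len(dm.sample_ids)} samples, {len(dm.variant_ids)} variants"
    )
    return dm, report


def _qc_pass(dm: DosageMatrix, cohort: pd.DataFrame, thresholds: QCThresholds,
             case_batch_labels: pd.Series | None, report: QCReport) -> DosageMatrix:
    """One pass of every filter in study order; updates ``report`` in place."""
    cohorts = cohort["cohort"]
    status = cohort["status"]

    report.add_samples("sample_call_rate",
                       filter_sample_call_rate(dm.dosages, cohorts, thresholds))
    dm = dm.drop_samples(list(report.excluded_samples))

    report.add_variants("variant_call_rate",
                        filter_variant_call_rate(dm.dosages, cohorts, thresholds))
    dm = dm.drop_variants(list(report.excluded_variants))

    if cohorts.loc[dm.sample_ids].nunique() >= 2:
        report.add_variants("freq_discordance",
                            filter_freq_discordance(dm.dosages, cohorts, thresholds,
                                                    report.log))
        dm = dm.drop_variants(list(report.excluded_variants))

    case_ids = dm.sample_ids[status.loc[dm.sample_ids] == 1]
    if len(case_ids):
        labels = (case_batch_labels if case_batch_labels is not None else cohorts).loc[case_ids]
        report.add_variants("case_batch_association",
                            filter_case_batch_association(dm.dosages.loc[case_ids],
                                                          labels, thresholds, report.log))
        dm = dm.drop_variants(list(report.excluded_variants))

    indels, dups = filter_variant_metadata(dm.variants)
    report.add_variants("indel", indels)
    report.add_variants("duplicated_position", dups)
    dm = dm.drop_variants(list(report.excluded_variants))

    geno = hard_genotypes(dm.dosages, thresholds.genotype_round_tol)
    freqs = (geno.mean(axis=0) / 2.0).to_numpy()
    report.add_samples("relatedness",
                       relatedness_filter(geno, freqs, thresholds, report.log))
    dm = dm.drop_samples(list(report.excluded_samples))

    try:
        pca = pca_outliers(dm.dosages, dm.variants["pos"], thresholds)
        report.add_samples("pca_outlier", pca.outliers)
        report.pca = pca
        dm = dm.drop_samples(list(report.excluded_samples))
    except ValueError as err:
        report.log.append(f"pca: skipped ({err})")

    report.add_variants("maf", filter_maf(dm.dosages, status, thresholds))
    dm = dm.drop_variants(list(report.excluded_variants))

    hwe_bad, hwe_undef = filter_hwe(dm.dosages, thresholds, status)
    report.add_variants("hwe", hwe_bad)
    if hwe_undef:
        report.log.append(f"hwe: {len(hwe_undef)} variants undefined (no calls)")
    dm = dm.drop_variants(list(report.excluded_variants))
    return dm
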