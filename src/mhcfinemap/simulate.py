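"""Case-control cohort simulator for MHC fine-mapping.

Generates datasets with the statistical structure the association pipeline
assumes: a haplotype panel over an MHC-like window on chromosome 6 carrying
a common risk HLA allele on a long-range haplotype tagged by a SNV at a
chosen LD r-squared, covariates, retrospective case-control sampling at a
configurable odds ratio, and imputation noise with a per-variant
estimated-r-squared quality statistic.

Defaults mirror the study the pipeline was built for: 704 cases vs 39 556
controls, a causal 4-digit allele at control frequency 0.109 with allelic
odds ratio 1.60, and a tag SNV at haplotype LD r-squared 0.90.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import truncnorm

from .data import (
    CAT_HLA_4D,
    CAT_SNV,
    ConfigurationError,
    DosageMatrix,
    ProteinDictionary,
    UNKNOWN_RESIDUE,
    validate_cohort,
    write_dosage_tsv,
    write_pheno_tsv,
    write_truth_json,
    write_vcf,
)

__all__ = [
    "SimulationConfig",
    "HaplotypePanel",
    "SimulatedCohort",
    "SimulationError",
    "ELIGIBLE_CASE_COUNTS",
    "ELIGIBLE_CONTROL_COUNTS",
    "build_haplotype_panel",
    "build_protein_dictionary",
    "sample_genotypes",
    "make_covariates",
    "assign_status",
    "estimated_r2",
    "add_imputation_noise",
    "generate_cohort",
    "simulate_array_genotypes",
    "simulate_related_pair",
    "add_missingness",
]


class SimulationError(RuntimeError):
    """Simulation could not satisfy its sampling quotas."""


#: Eligible participants per recruiting data set after sample QC; used to
#: label simulated cases/controls with realistic cohort proportions.
ELIGIBLE_CASE_COUNTS = {"BBJ": 538, "Aichi1": 94, "Aichi2": 72}
ELIGIBLE_CONTROL_COUNTS = {"BBJ": 39556}

#: GRCh37 anchor coordinates (chromosome 6).
HLA_B_POS = 31_323_000
TAG_SNV_POS = 31_350_608
MHC_START, MHC_END = 24_000_000, 36_000_000

_OTHER_ALLELES = ["B*15:01", "B*35:01", "B*40:02", "B*44:03", "B*51:01", "B*54:01"]


@dataclass
class SimulationConfig:
    """Generating parameters for one simulated case-control dataset.

    ``causal_or`` is the allele-level odds ratio per dosage unit on the
    log-odds scale; ``control_freq_target`` the causal-allele frequency in
    the source population (matching the control group of a rare disease);
    ``tag_r2_target`` the haplotype-level LD r-squared between the tag SNV
    and causal-allele carriage. ``covariate_effects`` maps covariate names
    (``age``, ``age2``, ``bmi``) to log-odds coefficients per unit;
    defaults are zero so confounding is opt-in.
    """

    n_cases: int = 704
    n_controls: int = 39_556
    causal_allele: str = "B*52:01"
    causal_or: float = 1.60
    control_freq_target: float = 0.109
    tag_r2_target: float = 0.90
    tag_freq: float | None = None
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    baseline_prevalence: float = 0.01
    imputation_quality: float | Mapping[str, float] = 0.98
    n_snvs: int = 25
    n_pcs: int = 20
    age_range: tuple[float, float] = (18.0, 100.0)
    bmi_mean: float = 22.5
    bmi_sd: float = 3.5
    bmi_range: tuple[float, float] = (11.4, 55.2)
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.causal_or <= 0:
            raise ConfigurationError("causal_or must be positive")
        if not 0 < self.control_freq_target < 1:
            raise ConfigurationError("control_freq_target must lie in (0,1)")
        if not 0 <= self.tag_r2_target <= 1:
            raise ConfigurationError("tag_r2_target must lie in [0,1]")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigurationError("n_cases and n_controls must be >= 1")
        if not 0 < self.baseline_prevalence < 1:
            raise ConfigurationError("baseline_prevalence must lie in (0,1)")
        if self.n_snvs < 20:
            raise ConfigurationError("n_snvs must be >= 20")
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("age_range", "bmi_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariate_effects"] = dict(self.covariate_effects)
        if not isinstance(self.imputation_quality, (int, float)):
            d["imputation_quality"] = dict(self.imputation_quality)
        return d


@dataclass
class HaplotypePanel:
    """Population haplotypes over one HLA gene plus flanking SNVs.

    Each haplotype carries one 4-digit allele of ``gene`` and a 0/1 allele
    at each of S SNV sites; ``frequencies`` are population haplotype
    frequencies (summing to one). Column 0 of ``snv_haplotypes`` is the
    designated tag SNV.
    """

    alleles: list[str]
    snv_haplotypes: np.ndarray
    frequencies: np.ndarray
    snv_positions: np.ndarray
    snv_ids: list[str]
    gene: str = "HLA-B"
    gene_pos: int = HLA_B_POS
    tag_index: int = 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.snv_haplotypes = np.asarray(self.snv_haplotypes, dtype=np.int8)
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("haplotype frequencies must sum to 1")
        if (self.frequencies < 0).any():
            raise ValueError("haplotype frequencies must be nonnegative")
        if self.snv_haplotypes.shape != (len(self.alleles), len(self.snv_positions)):
            raise ValueError("snv_haplotypes shape inconsistent with panel")

    @property
    def n_haplotypes(self) -> int:
        return len(self.alleles)

    @property
    def n_snvs(self) -> int:
        return self.snv_haplotypes.shape[1]

    @property
    def allele_labels(self) -> list[str]:
        return sorted(set(self.alleles))

    @property
    def tag_snv_id(self) -> str:
        return self.snv_ids[self.tag_index]

    def allele_freq(self, label: str) -> float:
        mask = np.array([a == label for a in self.alleles])
        return float(self.frequencies[mask].sum())

    def snv_freq(self, j: int) -> float:
        return float(self.frequencies @ self.snv_haplotypes[:, j])

    def ld_r2(self, allele_label: str, snv_index: int) -> float:
        """Analytic haplotype-level LD r-squared, no sampling involved."""
        x = np.array([a == allele_label for a in self.alleles], dtype=float)
        y = self.snv_haplotypes[:, snv_index].astype(float)
        w = self.frequencies
        ex, ey = w @ x, w @ y
        cov = w @ (x * y) - ex * ey
        vx, vy = ex * (1 - ex), ey * (1 - ey)
        if vx <= 0 or vy <= 0:
            return float("nan")
        return float(cov * cov / (vx * vy))


def build_protein_dictionary(causal_allele: str = "B*52:01") -> ProteinDictionary:
    """Residue table for the simulated HLA-B alleles.

    Position 171 carries the Tyr/His dimorphism with His on the risk
    allele; positions 45, 97 and 156 are multiallelic (m = 4, 5, 3) so the
    omnibus test has groups with m >= 3; position 9 is monomorphic and
    position 63 contains an unknown residue, exercising the encoder's
    degenerate paths.
    """
    residues = {
        #        pos:   9    45   63   97   156  171
        causal_allele: ["Y", "E", "N", "R", "L", "H"],
        "B*15:01":     ["Y", "M", "E", "S", "W", "Y"],
        "B*35:01":     ["Y", "T", "N", "N", "R", "Y"],
        "B*40:02":     ["Y", "K", "E", "T", "L", "Y"],
        "B*44:03":     ["Y", "K", "N", "W", "R", "Y"],
        "B*51:01":     ["Y", "E", "E", "R", "L", "Y"],
        "B*54:01":     ["Y", "T", UNKNOWN_RESIDUE, "S", "W", "Y"],
    }
    table = pd.DataFrame.from_dict(residues, orient="index", columns=[9, 45, 63, 97, 156, 171])
    table.index.name = "allele"
    return ProteinDictionary(gene="HLA-B", table=table)


def build_haplotype_panel(config: SimulationConfig) -> HaplotypePanel:
    """Construct a panel realizing the configured allele frequency and LD.

    The causal allele (frequency ``p_A``) and tag SNV (frequency ``p_B``,
    default ``p_A``) are coupled through the disequilibrium coefficient D
    solved from r2 = D^2 / (p_A (1-p_A) p_B (1-p_B)); the four
    (allele-carriage x tag) haplotype classes get frequencies
    p_A p_B + D, p_A (1-p_B) - D, (1-p_A) p_B - D, (1-p_A)(1-p_B) + D,
    and the non-causal classes are split over six further 4-digit alleles.
    Zero-frequency classes are dropped.
    """
    config.validate()
    p_a = config.control_freq_target
    p_b = p_a if config.tag_freq is None else config.tag_freq
    if not 0 < p_b < 1:
        raise ConfigurationError("tag_freq must lie in (0,1)")
    d = math.sqrt(config.tag_r2_target * p_a * (1 - p_a) * p_b * (1 - p_b))
    d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    if d > d_max + 1e-12:
        raise ConfigurationError(
            f"tag_r2_target={config.tag_r2_target} infeasible for allele "
            f"frequencies p_A={p_a}, p_B={p_b}: required D={d:.6f} exceeds "
            f"the Lewontin bound min(p_A(1-p_B), (1-p_A)p_B)={d_max:.6f}"
        )
    f11 = p_a * p_b + d          # causal allele, tag=1
    f10 = p_a * (1 - p_b) - d    # causal allele, tag=0
    f01 = (1 - p_a) * p_b - d    # other allele, tag=1
    f00 = (1 - p_a) * (1 - p_b) + d

    alleles: list[str] = []
    tags: list[int] = []
    freqs: list[float] = []
    causal = config.causal_allele

    def _push(label: str, tag: int, f: float) -> None:
        if f > 1e-12:
            alleles.append(label)
            tags.append(tag)
            freqs.append(f)

    _push(causal, 1, f11)
    _push(causal, 0, f10)
    w00 = np.array([0.28, 0.22, 0.18, 0.14, 0.10, 0.08])
    for label, w in zip(_OTHER_ALLELES, w00 / w00.sum()):
        _push(label, 0, f00 * w)
    w01 = np.array([0.5, 0.3, 0.2])
    for label, w in zip(_OTHER_ALLELES[:3], w01 / w01.sum()):
        _push(label, 1, f01 * w)

    freq_arr = np.array(freqs)
    freq_arr = freq_arr / freq_arr.sum()
    # renormalization is a pure floating-point correction; classes were
    # constructed to sum to one exactly.

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xBA5E]))
    n_snvs = config.n_snvs
    other_pos = np.sort(
        rng.choice(np.arange(MHC_START, MHC_END, 997), size=n_snvs - 1, replace=False)
    )
    positions = np.concatenate([[TAG_SNV_POS], other_pos])
    snv_ids = [f"snv_6_{p}" if i else f"tag_6_{p}" for i, p in enumerate(positions)]
    bg_freqs = rng.uniform(0.05, 0.5, size=n_snvs - 1)
    hap = np.zeros((len(alleles), n_snvs), dtype=np.int8)
    hap[:, 0] = tags
    hap[:, 1:] = rng.random((len(alleles), n_snvs - 1)) < bg_freqs

    panel = HaplotypePanel(
        alleles=alleles,
        snv_haplotypes=hap,
        frequencies=freq_arr,
        snv_positions=positions,
        snv_ids=snv_ids,
    )
    assert abs(panel.allele_freq(causal) - p_a) < 1e-9
    return panel


def _panel_variant_info(panel: HaplotypePanel) -> pd.DataFrame:
    rows = []
    for label in panel.allele_labels:
        rows.append({
            "variant_id": label, "chrom": "6", "pos": panel.gene_pos,
            "category": CAT_HLA_4D, "gene": panel.gene, "aa_pos": np.nan,
            "residue": "", "est_r2": np.nan,
        })
    for vid, pos in zip(panel.snv_ids, panel.snv_positions):
        rows.append({
            "variant_id": vid, "chrom": "6", "pos": int(pos),
            "category": CAT_SNV, "gene": "", "aa_pos": np.nan,
            "residue": "", "est_r2": np.nan,
        })
    return pd.DataFrame(rows).set_index("variant_id")


def sample_genotypes(panel: HaplotypePanel, n: int, seed) -> DosageMatrix:
    """Draw n diploid individuals: two independent haplotypes per person.

    Dosage of a 4-digit allele is the number of carried haplotypes bearing
    it; dosage of a SNV its allele count. Per individual the 4-digit allele
    dosages of the gene sum to 2 exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(panel.n_haplotypes, size=(n, 2), p=panel.frequencies)
    labels = panel.allele_labels
    onehot = np.zeros((panel.n_haplotypes, len(labels)))
    for h, a in enumerate(panel.alleles):
        onehot[h, labels.index(a)] = 1.0
    allele_dos = onehot[idx[:, 0]] + onehot[idx[:, 1]]
    snv_dos = (panel.snv_haplotypes[idx[:, 0]] + panel.snv_haplotypes[idx[:, 1]]).astype(float)
    info = _panel_variant_info(panel)
    mat = pd.DataFrame(
        np.hstack([allele_dos, snv_dos]),
        columns=labels + panel.snv_ids,
        index=pd.Index([f"S{i:07d}" for i in range(n)], name="sample_id"),
    )
    return DosageMatrix(mat[list(info.index)], info)


def make_covariates(n: int, config: SimulationConfig, seed) -> pd.DataFrame:
    """Draw covariates: age uniform, BMI truncated normal, PCs standard normal."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(*config.age_range, size=n)
    a, b = (np.array(config.bmi_range) - config.bmi_mean) / config.bmi_sd
    bmi = truncnorm.rvs(a, b, loc=config.bmi_mean, scale=config.bmi_sd,
                        size=n, random_state=rng)
    cov = pd.DataFrame({"age": age, "bmi": bmi})
    pcs = rng.standard_normal((n, config.n_pcs))
    for k in range(config.n_pcs):
        cov[f"pc{k + 1}"] = pcs[:, k]
    return cov


def _linear_predictor(dosages: DosageMatrix, covariates: pd.DataFrame,
                      config: SimulationConfig) -> np.ndarray:
    if config.causal_allele not in dosages.variant_ids:
        raise ValueError(f"causal allele {config.causal_allele!r} absent from dosage columns")
    eta = math.log(config.causal_or) * dosages.dosages[config.causal_allele].to_numpy()
    for name, beta in config.covariate_effects.items():
        if beta == 0:
            continue
        col = covariates["age"].to_numpy() ** 2 if name == "age2" else covariates[name].to_numpy()
        eta = eta + beta * col
    return eta


def solve_intercept(eta: np.ndarray, prevalence: float, tol: float = 1e-6) -> float:
    """Bisect the logistic intercept so mean risk equals ``prevalence``."""
    lo, hi = -40.0, 40.0
    f = lambda a: float(np.mean(expit(a + eta))) - prevalence
    if f(lo) > 0 or f(hi) < 0:
        raise SimulationError("target prevalence not bracketable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        v = f(mid)
        if abs(v) <= tol:
            return mid
        if v < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def assign_status(dosages: DosageMatrix, covariates: pd.DataFrame,
                  config: SimulationConfig, seed) -> tuple[pd.DataFrame, np.ndarray]:
    """Label a sampled pool and select case/control quotas retrospectively.

    Disease status is Bernoulli with logit alpha + ln(OR) * causal dosage +
    covariate terms, alpha solved by bisection so the marginal prevalence
    over the pool equals ``baseline_prevalence`` within 1e-6. The first
    ``n_cases`` cases and ``n_controls`` controls in pool order are kept
    (rejection sampling against quotas, the retrospective design).

    Returns the cohort table of selected samples and their positional
    indices into the pool. Raises :class:`SimulationError` if the pool
    cannot fill both quotas.
    """
    config.validate()
    eta = _linear_predictor(dosages, covariates, config)
    alpha = solve_intercept(eta, config.baseline_prevalence)
    rng = np.random.default_rng(seed)
    status = rng.random(len(eta)) < expit(alpha + eta)
    case_idx = np.flatnonzero(status)[: config.n_cases]
    ctrl_idx = np.flatnonzero(~status)[: config.n_controls]
    if len(case_idx) < config.n_cases or len(ctrl_idx) < config.n_controls:
        raise SimulationError(
            f"pool of {len(eta)} draws yielded {status.sum()} cases / "
            f"{(~status).sum()} controls; quotas {config.n_cases}/{config.n_controls} unmet"
        )
    sel = np.concatenate([case_idx, ctrl_idx])
    case_names = list(ELIGIBLE_CASE_COUNTS)
    case_p = np.array(list(ELIGIBLE_CASE_COUNTS.values()), dtype=float)
    cohort_lab = np.concatenate([
        rng.choice(case_names, size=len(case_idx), p=case_p / case_p.sum()),
        np.full(len(ctrl_idx), "BBJ"),
    ])
    table = covariates.iloc[sel].reset_index(drop=True)
    table.insert(0, "status", np.r_[np.ones(len(case_idx), dtype=int),
                                    np.zeros(len(ctrl_idx), dtype=int)])
    table.insert(3, "cohort", cohort_lab)
    table.index = pd.Index([f"S{i:07d}" for i in range(len(sel))], name="sample_id")
    table.attrs["alpha"] = alpha
    return validate_cohort(table), sel


def estimated_r2(dosage: np.ndarray) -> float:
    """Minimac-style imputation quality: Var(dosage) / (2 p (1-p)), capped at 1.

    p is estimated as mean(dosage)/2 from the dosages alone. Undefined
    (NaN) for a monomorphic variant (p in {0, 1}).
    """
    d = np.asarray(dosage, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        return float("nan")
    p = d.mean() / 2.0
    if p <= 0.0 or p >= 1.0:
        return float("nan")
    return float(min(d.var() / (2.0 * p * (1.0 - p)), 1.0))


def add_imputation_noise(dosages: DosageMatrix,
                         quality: float | Mapping[str, float],
                         seed) -> DosageMatrix:
    """Blend dosages toward their mean with Gaussian noise, emulating
    posterior-mean imputed dosages of a target quality.

    For target quality q the true dosage x (variance V) becomes
    ``mean + q (x - mean) + sqrt(q (1-q) V) Z``, clamped to [0, 2]: the
    squared correlation between true and noisy dosage is q, and the noisy
    variance is q V — so the variance-ratio estimated-r2 statistic
    recovers approximately q, as a dosage imputed at that quality would.
    q = 1 returns the column unchanged. The returned matrix carries the
    estimated-r2 of each noisy column in its variant metadata;
    monomorphic columns get NaN and a ``monomorphic`` flag.
    """
    rng = np.random.default_rng(seed)
    get_q = (lambda v: float(quality)) if isinstance(quality, (int, float)) \
        else (lambda v: float(quality.get(v, 1.0)))
    noisy = dosages.dosages.copy()
    info = dosages.variants.copy()
    flags = []
    est = []
    for vid in dosages.variant_ids:
        q = get_q(vid)
        if not 0 < q <= 1:
            raise ConfigurationError(f"imputation quality for {vid!r} must lie in (0,1]")
        x = noisy[vid].to_numpy(dtype=float)
        if q < 1.0:
            v = x.var()
            mu = x.mean()
            x = mu + q * (x - mu) + math.sqrt(q * (1.0 - q) * v) * rng.standard_normal(x.shape)
            x = np.clip(x, 0.0, 2.0)
            noisy[vid] = x
        r2 = estimated_r2(x)
        est.append(r2)
        flags.append("monomorphic" if np.isnan(r2) else "")
    info["est_r2"] = est
    info["flag"] = flags
    return DosageMatrix(noisy, info)


@dataclass
class SimulatedCohort:
    """Everything one simulated study comprises, plus the generating truth."""

    config: SimulationConfig
    panel: HaplotypePanel
    dictionary: ProteinDictionary
    true_dosages: DosageMatrix
    dosages: DosageMatrix
    cohort: pd.DataFrame
    truth: dict


def generate_cohort(config: SimulationConfig, out_prefix: str | None = None) -> SimulatedCohort:
    """Run the full generator: panel, pool, quotas, noise, optional files.

    Draws a pool of individuals from the panel under Hardy-Weinberg at the
    haplotype level, labels disease status retrospectively, keeps exactly
    ``n_cases`` + ``n_controls`` samples, and injects imputation noise.
    All randomness descends from ``config.seed``; the same seed reproduces
    the bundle bit for bit.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    s_geno, s_cov, s_status, s_noise = root.spawn(4)
    panel = build_haplotype_panel(config)
    dictionary = build_protein_dictionary(config.causal_allele)

    prev = config.baseline_prevalence
    pool_n = int(1.3 * max(config.n_cases / prev, config.n_controls / (1 - prev))) + 100
    last_err: SimulationError | None = None
    for attempt in range(8):
        geno = sample_genotypes(panel, pool_n, s_geno.spawn(1)[0])
        cov = make_covariates(pool_n, config, s_cov.spawn(1)[0])
        try:
            cohort, sel = assign_status(geno, cov, config, s_status.spawn(1)[0])
            break
        except SimulationError as err:  # pool too small: double and redraw
            last_err = err
            pool_n *= 2
    else:
        raise SimulationError(f"case/control quotas unreachable: {last_err}")

    true_sel = DosageMatrix(
        geno.dosages.iloc[sel].set_index(cohort.index), geno.variants.copy()
    )
    noisy = add_imputation_noise(true_sel, config.imputation_quality, s_noise.spawn(1)[0])

    truth = {
        "causal_allele": config.causal_allele,
        "causal_or": config.causal_or,
        "causal_beta": math.log(config.causal_or),
        "control_freq_target": config.control_freq_target,
        "causal_freq_panel": panel.allele_freq(config.causal_allele),
        "tag_snv": panel.tag_snv_id,
        "tag_r2_target": config.tag_r2_target,
        "tag_r2_panel": panel.ld_r2(config.causal_allele, panel.tag_index),
        "alpha": cohort.attrs["alpha"],
        "config": config.to_dict(),
    }
    bundle = SimulatedCohort(config, panel, dictionary, true_sel, noisy, cohort, truth)
    if out_prefix is not None:
        write_vcf(noisy, f"{out_prefix}.vcf")
        write_dosage_tsv(noisy, f"{out_prefix}.dosages.tsv", f"{out_prefix}.variants.tsv")
        write_pheno_tsv(cohort, f"{out_prefix}.pheno.tsv")
        dictionary.to_tsv(f"{out_prefix}.dictionary.tsv")
        write_truth_json(truth, f"{out_prefix}.truth.json")
    return bundle


# ---------------------------------------------------------------------------
# Genome-wide array emulation: unlinked biallelic genotypes for the QC stage
# ---------------------------------------------------------------------------

def simulate_array_genotypes(n: int, n_variants: int, seed,
                             freq_range: tuple[float, float] = (0.05, 0.5),
                             ) -> tuple[pd.DataFrame, np.ndarray]:
    """Unlinked hard genotypes (0/1/2) at Hardy-Weinberg proportions.

    Emulates a genotyping-array panel for relatedness / HWE / PCA testing.
    Returns (genotypes samples x variants, true allele frequencies).
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*freq_range, size=n_variants)
    geno = rng.binomial(1, freqs, size=(n, n_variants)) \
        + rng.binomial(1, freqs, size=(n, n_variants))
    cols = [f"arr{j:05d}" for j in range(n_variants)]
    idx = pd.Index([f"S{i:07d}" for i in range(n)], name="sample_id")
    return pd.DataFrame(geno.astype(float), index=idx, columns=cols), freqs


def simulate_related_pair(freqs: np.ndarray, n_shared: int, seed
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Genotypes for a pair sharing 0, 1 or 2 haplotypes at unlinked sites.

    ``n_shared`` = 0 gives an unrelated pair, 1 a parent-offspring-like
    pair (expected PI_HAT 0.5), 2 a duplicate/MZ pair (PI_HAT 1).
    """
    if n_shared not in (0, 1, 2):
        raise ValueError("n_shared must be 0, 1 or 2")
    rng = np.random.default_rng(seed)
    h = [rng.binomial(1, freqs) for _ in range(4)]
    if n_shared >= 1:
        h[2] = h[0]
    if n_shared == 2:
        h[3] = h[1]
    return (h[0] + h[1]).astype(float), (h[2] + h[3]).astype(float)


def add_missingness(dosages: pd.DataFrame, rate: float, seed) -> pd.DataFrame:
    """Mask a random fraction of entries as missing (NaN)."""
    rng = np.random.default_rng(seed)
    arr = dosages.to_numpy(dtype=float, copy=True)
    arr[rng.random(arr.shape) < rate] = np.nan
    return pd.DataFrame(arr, index=dosages.index, columns=dosages.columns)
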