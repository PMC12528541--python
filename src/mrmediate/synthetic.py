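"""Synthetic GWAS summary-statistics triples with planted causal structure.

The generator emulates the three summary-statistics sources of a two-sample
mediation MR study design — a quantitative exposure GWAS (a gut microbial
abundance trait), a quantitative mediator GWAS (a circulating metabolite) and
a binary-outcome GWAS (a disease, on the log-odds scale) — so that every
pipeline stage can be exercised and checked against known truth without any
external downloads.

Causal diagram (per-SNP effects on the additive scale):

    SNP_j --gamma_j--> exposure X --theta1--> mediator M --theta2--> outcome Y
                                  \\------------- direct ------------/

* ``n_snps`` exposure-associated SNPs carry effects ``gamma_j ~ N(0,
  gamma_sd^2)`` on X, hence ``theta1*gamma_j`` on M and ``theta_total*
  gamma_j`` on Y (``theta_total`` is the *total* X->Y effect, so the mediated
  path is already included).  A fraction of them additionally receives a
  horizontal-pleiotropy offset ``alpha_j`` acting directly on Y.
* ``n_mediator_snps`` mediator-specific SNPs carry effects ``delta_j ~ N(0,
  delta_sd^2)`` on M and ``theta2*delta_j`` on Y, and nothing on X.  These
  are the instruments that identify theta2 in the mediator->outcome MR, just
  as a metabolite's own loci do in real data.

Estimated betas are the true effects plus sampling noise at the closed-form
standard error for an allelic regression on a unit-variance trait,
``se = 1/sqrt(2*maf*(1-maf)*n)``; for the binary outcome ``n`` is the
effective sample size ``4/(1/n_cases + 1/n_controls)``.  SNPs are simulated
in linkage equilibrium; exposure, mediator and outcome samples are
non-overlapping by construction.  The defaults mirror the study conditions
this package targets: MiBioGen-scale exposure (n = 18,340), GWAS-Catalog
metabolite scale (n = 8,299) and a FinnGen-scale rare outcome
(1,316 cases / 313,392 controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import CANONICAL_FIELDS, MIN_PVALUE

__all__ = ["SimConfig", "SimTruth", "simulate_triple", "effective_sample_size"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
# ordered non-complementary allele pairs / palindromic pairs
_NONPAL_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def effective_sample_size(n_cases: int, n_controls: int) -> float:
    """Quantitative-trait-equivalent sample size of a case-control GWAS."""
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated exposure/mediator/outcome triple.

    Defaults are the study conditions the package targets: a planted total
    effect ``theta_total = -0.5`` decomposed as ``theta1*theta2 = -0.055``
    (proportion mediated 0.11) at the real consortia's sample sizes.
    """

    n_snps: int = 60
    n_mediator_snps: int = 40
    n_exposure: int = 18_340
    n_mediator: int = 8_299
    n_cases: int = 1_316
    n_controls: int = 313_392
    theta_total: float = -0.5
    theta1: float = 0.22
    theta2: float = -0.25
    maf_range: tuple[float, float] = (0.1, 0.5)
    gamma_sd: float = 0.08
    delta_sd: float = 0.12
    frac_pleiotropic: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    frac_palindromic: float = 0.05
    frac_strand_flipped: float = 0.05
    seed: int = 42
    exposure_id: str = "taxon_1"
    mediator_id: str = "metabolite_1"
    outcome_id: str = "outcome"

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.n_mediator_snps < 0:
            raise ValueError("n_mediator_snps must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("frac_pleiotropic", "frac_palindromic", "frac_strand_flipped"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("n_exposure", "n_mediator", "n_cases", "n_controls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.gamma_sd <= 0:
            raise ValueError("gamma_sd must be positive")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be non-negative")

    @property
    def direct_effect(self) -> float:
        return self.theta_total - self.theta1 * self.theta2

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SimTruth:
    """Planted parameters a recovery test checks against."""

    snp_ids: list[str]
    gamma: np.ndarray           # true SNP->exposure effects (0 for mediator SNPs)
    delta: np.ndarray           # true SNP->mediator direct effects
    alpha: np.ndarray           # horizontal-pleiotropy offsets on the outcome
    theta_total: float
    theta1: float
    theta2: float
    outlier_ids: list[str] = field(default_factory=list)
    palindromic_ids: list[str] = field(default_factory=list)
    strand_flipped_ids: list[str] = field(default_factory=list)
    mediator_snp_ids: list[str] = field(default_factory=list)

    @property
    def proportion_mediated(self) -> float:
        return self.theta1 * self.theta2 / self.theta_total


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, MIN_PVALUE, 1.0)


def _table(snp_ids, chrom, pos, ea, oa, beta, se, eaf, n, trait_id) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": pd.array(chrom, dtype="string"),
            "pos": pd.array(pos, dtype="Int64"),
            "effect_allele": ea,
            "other_allele": oa,
            "beta": beta,
            "se": se,
            "pvalue": _two_sided_p(np.asarray(beta), np.asarray(se)),
            "eaf": eaf,
            "n": int(n),
            "trait_id": trait_id,
        }
    )
    return df[list(CANONICAL_FIELDS)]


def simulate_triple(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate one (exposure, mediator, outcome) summary-statistics triple.

    Returns the three canonical-column tables plus the planted truth.  Fully
    reproducible from ``config.seed``: identical configs produce
    byte-identical tables.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_snps + cfg.n_mediator_snps

    snp_ids = [f"rs{1_000_000 + i}" for i in range(m)]
    chrom = [str(i % 22 + 1) for i in range(m)]
    pos = [20_000_000 * (i // 22 + 1) + 1 for i in range(m)]

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    gamma = np.zeros(m)
    gamma[: cfg.n_snps] = rng.normal(0.0, cfg.gamma_sd, size=cfg.n_snps)
    delta = np.zeros(m)
    if cfg.n_mediator_snps:
        delta[cfg.n_snps:] = rng.normal(0.0, cfg.delta_sd, size=cfg.n_mediator_snps)

    # horizontal pleiotropy: offsets on the outcome for a fraction of
    # exposure SNPs (invalid instruments).  A non-zero pleiotropy_mean is
    # directional *relative to the exposure-increasing allele* (the
    # orientation MR-Egger uses), so the offset is applied along sign(gamma);
    # for mean 0 the sign is irrelevant (symmetric draw).
    alpha = np.zeros(m)
    n_out = int(round(cfg.frac_pleiotropic * cfg.n_snps))
    outlier_idx = np.sort(rng.choice(cfg.n_snps, size=n_out, replace=False)) if n_out else np.array([], dtype=int)
    if n_out:
        draws = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd or 0.0, size=n_out)
        orient = np.where(gamma[outlier_idx] < 0, -1.0, 1.0)
        alpha[outlier_idx] = orient * draws

    var_term = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(var_term * cfg.n_exposure)
    se_m = 1.0 / np.sqrt(var_term * cfg.n_mediator)
    n_eff = effective_sample_size(cfg.n_cases, cfg.n_controls)
    se_y = 1.0 / np.sqrt(var_term * n_eff)

    beta_x = gamma + rng.normal(0.0, se_x)
    beta_m = cfg.theta1 * gamma + delta + rng.normal(0.0, se_m)
    beta_y = cfg.theta_total * gamma + cfg.theta2 * delta + alpha + rng.normal(0.0, se_y)

    # allele pairs: a frac_palindromic share complementary (A/T, C/G)
    n_pal = int(round(cfg.frac_palindromic * m))
    pal_idx = np.sort(rng.choice(m, size=n_pal, replace=False)) if n_pal else np.array([], dtype=int)
    is_pal = np.zeros(m, dtype=bool)
    is_pal[pal_idx] = True
    ea = np.empty(m, dtype=object)
    oa = np.empty(m, dtype=object)
    pal_choice = rng.integers(0, len(_PAL_PAIRS), size=m)
    nonpal_choice = rng.integers(0, len(_NONPAL_PAIRS), size=m)
    for i in range(m):
        ea[i], oa[i] = (
            _PAL_PAIRS[pal_choice[i]] if is_pal[i] else _NONPAL_PAIRS[nonpal_choice[i]]
        )

    # a frac_strand_flipped share of outcome records written on the opposite
    # strand: complemented alleles, beta unchanged
    n_flip = int(round(cfg.frac_strand_flipped * m))
    flip_idx = np.sort(rng.choice(m, size=n_flip, replace=False)) if n_flip else np.array([], dtype=int)
    ea_y = ea.copy()
    oa_y = oa.copy()
    for i in flip_idx:
        ea_y[i] = _COMPLEMENT[ea[i]]
        oa_y[i] = _COMPLEMENT[oa[i]]

    exposure = _table(snp_ids, chrom, pos, ea, oa, beta_x, se_x, maf,
                      cfg.n_exposure, cfg.exposure_id)
    mediator = _table(snp_ids, chrom, pos, ea, oa, beta_m, se_m, maf,
                      cfg.n_mediator, cfg.mediator_id)
    outcome = _table(snp_ids, chrom, pos, ea_y, oa_y, beta_y, se_y, maf,
                     cfg.n_cases + cfg.n_controls, cfg.outcome_id)

    truth = SimTruth(
        snp_ids=snp_ids,
        gamma=gamma,
        delta=delta,
        alpha=alpha,
        theta_total=cfg.theta_total,
        theta1=cfg.theta1,
        theta2=cfg.theta2,
        outlier_ids=[snp_ids[i] for i in outlier_idx],
        palindromic_ids=[snp_ids[i] for i in pal_idx],
        strand_flipped_ids=[snp_ids[i] for i in flip_idx],
        mediator_snp_ids=snp_ids[cfg.n_snps:],
    )
    return exposure, mediator, outcome, truth
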