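"""Synthetic multi-tissue cohorts with known ground truth.

The generator embodies the inter-tissue coherence question as a tunable
latent-trait model.  Each subject carries a standard-normal latent trait
``z`` (their systemic propensity for mitochondrial investment) and an
archetype label (their multi-tissue investment pattern).  For subject *i*
in tissue *t* the mtDNA transcript fraction is drawn on the log-odds scale

    logit(f_mt) = logit(mu_t) + lambda_t * z_i + shift(c_i, t) + eps,
    eps ~ Normal(0, sigma_t^2),

so the between-tissue Pearson correlation of the latent investments is
``lambda_s * lambda_t / sqrt((lambda_s^2 + sigma_s^2)(lambda_t^2 + sigma_t^2))``
and the coherence of any monotone index of it follows the bivariate-normal
Spearman expectation ``(6/pi) * arcsin(rho/2)``.  The nuclear-mito fraction
is drawn the same way around ``nu_t`` with a Gaussian-copula coupling of
Pearson strength ``p_t`` (the tissue's proliferation parameter) to the
mtDNA fraction, giving the proliferation-driven mtDNA/nuclear coupling a
planted monotone relationship.  Regulator genes receive a within-tissue
correlation ``beta_t`` (either sign) with the nuclear-mito latent.

Gene-level abundances are log-normal within each class (mtDNA,
nuclear-mito, other) and rescaled exactly so that class sums hit the drawn
fractions and every sample totals 1e6 — transcript-share indices computed
from the matrix therefore recover the drawn fractions to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigError
from .io import ExpressionMatrix, GeneCatalog

REGULATOR_GENES = ("PPARGC1A", "NRF1", "NRF2", "TFAM", "POLG")
ISR_GENES = ("ATF4", "ATF5", "DDIT3", "GDF15")
PROLIFERATION_GENES = ("KI67", "TOP2A", "RRM2")
SPECIAL_GENES = REGULATOR_GENES + ISR_GENES + PROLIFERATION_GENES

ENZYME_FEATURES = ("CI", "CII", "CIV", "CS", "mtDNA_density")


@dataclass(frozen=True)
class TissueSpec:
    """Per-tissue generative parameters.

    mu / nu are the population-typical mtDNA and nuclear-mito transcript
    fractions (0..1); ``lam`` is the loading on the shared subject trait
    (coherence dial), ``sigma`` the tissue-specific noise SD on the
    log-odds scale, ``proliferation`` the coupling parameter p_t in [0, 1],
    ``beta`` the regulator-to-mito effect in [-1, 1], ``missing`` the
    probability that a subject lacks this tissue.
    """

    name: str
    tissue_class: str = "body"
    mu: float = 0.3
    nu: float = 0.12
    lam: float = 0.3
    sigma: float = 0.6
    proliferation: float = 0.2
    beta: float = 0.0
    missing: float = 0.0

    def validate(self) -> None:
        if not 0 < self.mu < 1:
            raise ConfigError(f"{self.name}: mu must be in (0,1)")
        if not 0 < self.nu < 1:
            raise ConfigError(f"{self.name}: nu must be in (0,1)")
        if self.lam ** 2 + self.sigma ** 2 <= 0:
            raise ConfigError(f"{self.name}: lam^2 + sigma^2 must be > 0")
        if not 0 <= self.proliferation <= 1:
            raise ConfigError(f"{self.name}: proliferation must be in [0,1]")
        if not -1 <= self.beta <= 1:
            raise ConfigError(f"{self.name}: beta must be in [-1,1]")
        if not 0 <= self.missing <= 1:
            raise ConfigError(f"{self.name}: missing must be in [0,1]")


@dataclass(frozen=True)
class ClusterSpec:
    """Planted subject archetypes.

    ``shifts`` maps archetype index -> {tissue name -> log-odds investment
    shift}, applied to both the mtDNA and nuclear-mito fractions so that
    archetypes are recoverable from either index.  ``clinical`` maps a
    binary variable name to its per-archetype positivity probability.
    """

    probs: tuple[float, ...] = (1.0,)
    shifts: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    clinical: Mapping[str, Sequence[float]] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.probs)

    def validate(self) -> None:
        if not math.isclose(sum(self.probs), 1.0, abs_tol=1e-9):
            raise ConfigError("archetype probabilities must sum to 1")
        for var, probs in self.clinical.items():
            if len(probs) != self.k:
                raise ConfigError(f"clinical {var!r}: needs {self.k} probabilities")
            if not all(0 <= p <= 1 for p in probs):
                raise ConfigError(f"clinical {var!r}: probabilities in [0,1]")


def default_tissues() -> tuple[TissueSpec, ...]:
    """A 12-tissue panel: 5 brain regions and 7 body tissues.

    Brain regions get high mtDNA fractions and a shared-trait loading; body
    tissues span the digestive tract, heart, muscle and gland tissues with
    mostly idiosyncratic (low-loading) investment and a range of
    proliferative activity.
    """
    brain = [
        TissueSpec(name, "brain", mu=0.55, nu=0.12, lam=0.5,
                   sigma=math.sqrt(0.75), proliferation=0.05)
        for name in ("brain_cortex", "brain_hippocampus", "brain_putamen",
                     "brain_amygdala", "brain_cerebellum")
    ]
    body = [
        TissueSpec("heart_left_ventricle", "body", mu=0.5, nu=0.18, lam=0.2,
                   sigma=0.9, proliferation=0.05, beta=0.6),
        TissueSpec("muscle_skeletal", "body", mu=0.4, nu=0.15, lam=0.2,
                   sigma=0.9, proliferation=0.05, beta=0.5),
        TissueSpec("adrenal_gland", "body", mu=0.3, nu=0.17, lam=0.1,
                   sigma=0.95, proliferation=0.2, beta=-0.4),
        TissueSpec("colon_transverse", "body", mu=0.2, nu=0.1, lam=0.2,
                   sigma=0.9, proliferation=0.8, beta=0.5),
        TissueSpec("adipose_subcutaneous", "body", mu=0.15, nu=0.09, lam=0.2,
                   sigma=0.9, proliferation=0.3, beta=-0.3),
        TissueSpec("liver", "body", mu=0.35, nu=0.16, lam=0.1,
                   sigma=0.95, proliferation=0.15),
        TissueSpec("whole_blood", "body", mu=0.05, nu=0.07, lam=0.2,
                   sigma=0.9, proliferation=0.7),
    ]
    return tuple(brain + body)


@dataclass(frozen=True)
class CohortConfig:
    """Full configuration of a synthetic transcriptomic cohort."""

    n_subjects: int = 200
    tissues: tuple[TissueSpec, ...] = field(default_factory=default_tissues)
    n_mtdna: int = 37
    n_mito_nuclear: int = 1133
    n_other: int = 18000
    gene_sd: float = 1.0
    within_sample_sd: float = 0.2
    rin_mean: float = 7.5
    rin_sd: float = 1.2
    clusters: ClusterSpec = field(default_factory=ClusterSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        names = [t.name for t in self.tissues]
        if len(names) != len(set(names)):
            raise ConfigError("duplicate tissue names")
        for t in self.tissues:
            t.validate()
        self.clusters.validate()
        if self.n_other < len(SPECIAL_GENES):
            raise ConfigError(
                f"n_other must be >= {len(SPECIAL_GENES)} to hold the named genes"
            )
        if self.n_mtdna < 1 or self.n_mito_nuclear < 1:
            raise ConfigError("gene class counts must be >= 1")


class ExpectedCorrelation(NamedTuple):
    pearson: float
    spearman: float


def expected_pair_correlation(
    lam_s: float, lam_t: float, sig_s: float, sig_t: float
) -> ExpectedCorrelation:
    """Analytic between-tissue correlation implied by the latent-trait model.

    Pearson: ``lam_s*lam_t / sqrt((lam_s^2+sig_s^2)(lam_t^2+sig_t^2))``.
    Spearman (bivariate normal): ``(6/pi) * arcsin(pearson / 2)`` — exact
    for any monotone transform of the latents, hence for the fraction
    indices themselves.
    """
    if lam_s ** 2 + sig_s ** 2 <= 0 or lam_t ** 2 + sig_t ** 2 <= 0:
        raise ConfigError("lam^2 + sigma^2 must be > 0 for both tissues")
    rho = lam_s * lam_t / math.sqrt(
        (lam_s ** 2 + sig_s ** 2) * (lam_t ** 2 + sig_t ** 2)
    )
    return ExpectedCorrelation(rho, (6.0 / math.pi) * math.asin(rho / 2.0))


@dataclass
class GroundTruth:
    """What the generator actually drew: the recovery targets."""

    z: pd.Series                 # latent trait per subject
    archetypes: pd.Series        # archetype label per subject
    f_mt: pd.DataFrame           # subject x tissue mtDNA fraction (NaN = missing)
    f_nuc: pd.DataFrame          # subject x tissue nuclear-mito fraction
    config: CohortConfig


class Cohort(NamedTuple):
    expression: ExpressionMatrix
    samples: pd.DataFrame
    catalog: GeneCatalog
    clinical: pd.DataFrame
    truth: GroundTruth


def _gene_ids(config: CohortConfig) -> tuple[list[str], list[str], list[str]]:
    mt = [f"MT-G{i:04d}" for i in range(config.n_mtdna)]
    nmito = [f"NMITO{i:05d}" for i in range(config.n_mito_nuclear)]
    other = list(SPECIAL_GENES) + [
        f"OTH{i:05d}" for i in range(config.n_other - len(SPECIAL_GENES))
    ]
    return mt, nmito, other


def _catalog(config: CohortConfig) -> GeneCatalog:
    mt, nmito, _ = _gene_ids(config)
    named = {
        "isr": frozenset(ISR_GENES),
        "proliferation": frozenset(PROLIFERATION_GENES),
    }
    named.update({g: frozenset({g}) for g in REGULATOR_GENES})
    return GeneCatalog(
        mtdna_genes=frozenset(mt),
        mito_nuclear_genes=frozenset(nmito),
        named_sets=named,
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full synthetic cohort (expression, metadata, catalog, clinical, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    subjects = [f"S{i:04d}" for i in range(n)]
    tissues = config.tissues

    z = rng.standard_normal(n)
    archetypes = rng.choice(config.clusters.k, size=n, p=list(config.clusters.probs))

    mt_ids, nmito_ids, other_ids = _gene_ids(config)
    gene_ids = mt_ids + nmito_ids + other_ids
    # per-gene baseline abundances, drawn once per cohort
    base = {
        "mt": rng.lognormal(0.0, config.gene_sd, size=len(mt_ids)),
        "nmito": rng.lognormal(0.0, config.gene_sd, size=len(nmito_ids)),
        "other": rng.lognormal(0.0, config.gene_sd, size=len(other_ids)),
    }
    special_idx = {g: other_ids.index(g) for g in SPECIAL_GENES}

    f_mt = pd.DataFrame(np.nan, index=subjects, columns=[t.name for t in tissues])
    f_nuc = f_mt.copy()
    sample_rows = []
    columns: dict[str, np.ndarray] = {}

    for t in tissues:
        scale = math.sqrt(t.lam ** 2 + t.sigma ** 2)
        eps = rng.normal(0.0, t.sigma, size=n)
        d = t.lam * z + eps
        d_hat = d / scale
        shift = np.array([
            config.clusters.shifts.get(int(c), {}).get(t.name, 0.0)
            for c in archetypes
        ])
        fmt = expit(logit(t.mu) + shift + d)
        # nuclear-mito fraction: Gaussian copula of strength p_t with f_mt
        w = rng.standard_normal(n)
        e = t.proliferation * d_hat + math.sqrt(1 - t.proliferation ** 2) * w
        fnc = expit(logit(t.nu) + shift + scale * e)
        # regulator latent: correlation beta_t with the nuclear-mito latent
        v = rng.standard_normal((len(SPECIAL_GENES), n))
        missing = rng.random(n) < t.missing
        rin = np.clip(rng.normal(config.rin_mean, config.rin_sd, size=n), 1.0, 10.0)

        present = np.flatnonzero(~missing)
        f_mt.loc[:, t.name] = np.where(missing, np.nan, fmt)
        f_nuc.loc[:, t.name] = np.where(missing, np.nan, fnc)

        # gene-level raw weights per present sample
        m = len(present)
        raw_mt = base["mt"][:, None] * rng.lognormal(
            0.0, config.within_sample_sd, size=(len(mt_ids), m))
        raw_nm = base["nmito"][:, None] * rng.lognormal(
            0.0, config.within_sample_sd, size=(len(nmito_ids), m))
        raw_ot = base["other"][:, None] * rng.lognormal(
            0.0, config.within_sample_sd, size=(len(other_ids), m))
        # regulator and ISR genes track the nuclear-mito latent with strength
        # beta_t; the 1/(1 - f_nuc) factor cancels the compositional shrinkage
        # of the non-mito share so beta is the planted association, not
        # beta plus a closure artifact
        for gi, g in enumerate(REGULATOR_GENES + ISR_GENES):
            b = t.beta
            lat = b * e + math.sqrt(1 - b ** 2) * v[gi]
            raw_ot[special_idx[g], :] *= np.exp(0.5 * lat[present]) / (1.0 - fnc[present])
        # proliferation genes scale with the tissue's proliferation parameter
        for g in PROLIFERATION_GENES:
            raw_ot[special_idx[g], :] *= t.proliferation

        fmt_p = fmt[present]
        fnc_p = fnc[present]
        mt_target = 1e6 * fmt_p
        nm_target = 1e6 * (1 - fmt_p) * fnc_p
        ot_target = 1e6 * (1 - fmt_p) * (1 - fnc_p)
        mat = np.vstack([
            raw_mt * (mt_target / raw_mt.sum(axis=0)),
            raw_nm * (nm_target / raw_nm.sum(axis=0)),
            raw_ot * (ot_target / raw_ot.sum(axis=0)),
        ])
        for j, si in enumerate(present):
            sid = f"{subjects[si]}-{t.name}"
            columns[sid] = mat[:, j]
            sample_rows.append(
                (sid, subjects[si], t.name, t.tissue_class, float(rin[si]))
            )

    data = pd.DataFrame(columns, index=gene_ids)
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "subject_id", "tissue", "tissue_class", "rin"]
    )
    clinical = pd.DataFrame({"subject_id": subjects})
    for var, probs in config.clusters.clinical.items():
        p = np.asarray(probs)[archetypes]
        clinical[var] = (rng.random(n) < p).astype(int)
    truth = GroundTruth(
        z=pd.Series(z, index=subjects, name="z"),
        archetypes=pd.Series(archetypes, index=subjects, name="archetype"),
        f_mt=f_mt,
        f_nuc=f_nuc,
        config=config,
    )
    return Cohort(ExpressionMatrix(data), samples, _catalog(config), clinical, truth)


def default_enzymatic_tissues() -> tuple[TissueSpec, ...]:
    """22 mouse tissues: 17 brain regions plus 5 peripheral tissues.

    Brain regions share a modest trait loading (within-organ coherence);
    peripheral tissues are idiosyncratic.
    """
    brain_names = (
        "cerebellum", "nucleus_accumbens", "ca3", "periaqueductal_gray",
        "dentate_gyrus_dorsal", "dentate_gyrus_ventral", "prefrontal_cortex",
        "caudoputamen", "motor_cortex", "vestibular_nucleus", "thalamus",
        "ventral_tegmental_area", "orbitofrontal_cortex", "hypothalamus",
        "amygdala", "visual_cortex", "substantia_nigra",
    )
    body_names = ("soleus", "white_gastrocnemius", "heart", "liver", "adrenal_gland")
    brain = [
        TissueSpec(nm, "brain", lam=0.5, sigma=math.sqrt(0.75)) for nm in brain_names
    ]
    body = [TissueSpec(nm, "body", lam=0.0, sigma=1.0) for nm in body_names]
    return tuple(brain + body)


@dataclass(frozen=True)
class EnzymaticConfig:
    """Configuration of a synthetic enzymatic-activity cohort.

    Defaults mirror the shape of a 27-animal, 22-tissue, 5-feature panel
    (OxPhos complexes I, II, IV, citrate synthase and mtDNA density).
    """

    n_subjects: int = 27
    tissues: tuple[TissueSpec, ...] = field(default_factory=default_enzymatic_tissues)
    features: tuple[str, ...] = ENZYME_FEATURES
    feature_loading: Mapping[str, float] = field(default_factory=dict)
    activity_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        for t in self.tissues:
            t.validate()


def generate_enzymatic_cohort(config: EnzymaticConfig) -> pd.DataFrame:
    """Draw a (subject, tissue) x feature table of log-normal activities.

    Each feature shares the subject trait through the tissue loading
    (optionally modulated per feature via ``feature_loading``); within-
    tissue noise is feature-specific.  Returns a feature table directly
    consumable by the coherence machinery.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    subjects = [f"M{i:03d}" for i in range(n)]
    z = rng.standard_normal(n)
    rows = []
    for t in config.tissues:
        missing = rng.random(n) < t.missing
        values = {}
        for feat in config.features:
            mult = config.feature_loading.get(feat, 1.0)
            eps = rng.normal(0.0, t.sigma, size=n)
            latent = mult * t.lam * z + eps
            values[feat] = np.exp(config.activity_sd * latent)
        for i in range(n):
            if missing[i]:
                continue
            rows.append(
                {"subject_id": subjects[i], "tissue": t.name,
                 **{f: float(values[f][i]) for f in config.features}}
            )
    return pd.DataFrame(rows)


#: tissue panel used for the multi-tissue phenotyping demonstrations
ARCHETYPE_PANEL = ("muscle_skeletal", "heart_atrial", "brain_cortex",
                   "adipose_subcutaneous")


def archetype_config(n_subjects: int = 120, seed: int = 0) -> CohortConfig:
    """Three planted investment archetypes over a four-tissue panel.

    Archetypes: muscle-high, brain-high, balanced.  The planted shift is
    1.5 units on the log2 inter-tissue ratio scale against a within-cluster
    ratio-feature noise SD of 0.5 units (logit shift 1.18, tissue noise
    sigma 0.28), so discriminating ratio features separate archetype
    centroids by three within-cluster SDs.  Clinical variables have
    archetype-dependent positivity probabilities (high / low / low and
    low / high / low patterns plus a flat control).
    """
    shift = 1.18
    shifts = {0: {"muscle_skeletal": shift}, 1: {"brain_cortex": shift}, 2: {}}
    tissues = tuple(
        TissueSpec(name, "brain" if name.startswith("brain") else "body",
                   mu=0.3, nu=0.12, lam=0.0, sigma=0.28)
        for name in ARCHETYPE_PANEL
    )
    clinical = {
        "condition_a": (0.8, 0.2, 0.2),
        "condition_b": (0.1, 0.7, 0.1),
        "condition_flat": (0.4, 0.4, 0.4),
    }
    return CohortConfig(
        n_subjects=n_subjects,
        tissues=tissues,
        n_mtdna=10, n_mito_nuclear=50, n_other=300,
        clusters=ClusterSpec(probs=(1 / 3, 1 / 3, 1 / 3), shifts=shifts,
                             clinical=clinical),
        seed=seed,
    )


def brain_tissue_names(tissues: Sequence[TissueSpec]) -> frozenset[str]:
    return frozenset(t.name for t in tissues if t.tissue_class == "brain")


def two_tissue_config(
    lam: float, n_subjects: int = 2000, seed: int = 0, **kwargs
) -> CohortConfig:
    """Two-tissue cohort with loading ``lam`` and noise sqrt(1 - lam^2).

    The implied between-tissue Pearson correlation of the latent
    investments is exactly ``lam**2``.
    """
    sigma = math.sqrt(max(1.0 - lam ** 2, 0.0))
    tissues = (
        TissueSpec("tissue_a", "body", mu=0.3, nu=0.12, lam=lam, sigma=sigma),
        TissueSpec("tissue_b", "body", mu=0.25, nu=0.1, lam=lam, sigma=sigma),
    )
    defaults = dict(n_mtdna=10, n_mito_nuclear=50, n_other=200)
    defaults.update(kwargs)
    return CohortConfig(n_subjects=n_subjects, tissues=tissues, seed=seed, **defaults)
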