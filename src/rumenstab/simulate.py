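"""Synthetic longitudinal microbiome studies with known ground truth.

The generator emulates the design of a growing-finishing beef-cattle trial:
20 animals, each sampled at six timepoints roughly a month apart, on one of
two basal diets (concentrate CON vs forage FOR), of two breeds, with a feed
additive assigned within diet (CTL/NIT/RSC). Each microbial feature i has a
latent Gaussian log-abundance

    eta_ijt = mu_i + delta_i*1[diet=CON] + kappa_i*1[breed] + tau_it
              + u_ij + eps_ijt

with a per-animal effect u_ij ~ N(0, sigma2_w_i) and residual
eps_ijt ~ N(0, sigma2_e_i) whose ratio fixes the feature's true
repeatability rpt_i = sigma2_w_i / (sigma2_w_i + sigma2_e_i). Counts are
drawn multinomially per sample with probabilities softmax_i(eta) and a
library size drawn log-uniformly — deep-sequencing depths at which
multinomial noise is minor relative to the biological residual.

Host traits are built from a planted biomarker set B: each trait combines
the biomarker animal effects sum_{i in B} beta_ik u_ij, an allocation-day
weight contribution, a polygenic breeding value from simulated genotypes,
and Gaussian noise; every trait's sample mean and sd are then calibrated
exactly to the descriptives of the emulated trial (e.g. FCR 8.29 +/- 1.69),
so the phenotype table reproduces those printed moments by construction
while the correlation structure carries the planted signal.

The truth record (per-feature variances, u, biomarker membership and signs,
true breeding values) gives every downstream stage a parameter-recovery test.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_MOMENTS",
    "SimulationParams",
    "SimulatedStudy",
    "stage_seed",
    "simulate_feature_tensor",
    "simulate_traits",
    "simulate_genotypes_and_bv",
    "simulate_study",
]

# trait name -> (mean, sd) of the emulated trial's printed descriptives
TRAIT_MOMENTS: dict[str, tuple[float, float]] = {
    "FCR": (8.29, 1.69),
    "ADG": (1.42, 0.32),
    "DFI": (11.30, 1.27),
    "RFI": (-0.08, 0.65),
    "CH4P": (183.12, 53.12),
    "CH4Y": (19.53, 5.32),
}
ALLOCATION_WEIGHT = (414.1, 35.7)  # kg, mean and sd on allocation day


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class SimulationParams:
    """Knobs of the synthetic study; defaults are the emulated trial's design."""

    n_animals: int = 20
    n_timepoints: int = 6
    n_features: int = 400
    # per-feature repeatability targets; None -> drawn Uniform(rpt_range)
    rpt: np.ndarray | None = None
    rpt_range: tuple[float, float] = (0.02, 0.8)
    total_variance: float = 1.0
    mu_sd: float = 1.5  # spread of baseline log-abundances
    diet_effect_fraction: float = 0.1
    diet_effect_sd: float = 0.5
    breed_effect_fraction: float = 0.1
    breed_effect_sd: float = 0.3
    timepoint_drift_sd: float = 0.0  # per-feature linear drift; default none
    n_biomarkers: int = 30
    trait_noise_sd: float = 0.5  # on the standardized-signal scale
    genetic_weight: float = 0.5  # polygenic contribution on the same scale
    weight_weight: float = 0.3  # allocation-weight contribution
    library_size_range: tuple[float, float] = (5e4, 5e5)
    n_markers: int = 1000
    h2: float = 0.25  # heritability used when scaling breeding values
    # half-sib families in the genotype panel (None = unrelated animals);
    # variation in relatedness is what identifies the genomic variance ratio
    n_families: int | None = None
    seed: int = 0


@dataclass
class SimulatedStudy:
    counts: pd.DataFrame  # sample x feature, index = sample ids
    metadata: pd.DataFrame  # per sample
    phenotypes: pd.DataFrame  # per animal
    genotypes: pd.DataFrame  # animal x marker
    eta: pd.DataFrame  # latent log-abundances, (animal_id, timepoint) index
    truth: dict = field(default_factory=dict)


def _design(params: SimulationParams) -> pd.DataFrame:
    animals = [f"A{j+1:02d}" for j in range(params.n_animals)]
    diets = ["CON" if j < params.n_animals // 2 else "FOR" for j in range(params.n_animals)]
    breeds = ["Charolais" if j % 2 == 0 else "Luing" for j in range(params.n_animals)]
    additives = [["CTL", "NIT", "RSC"][j % 3] for j in range(params.n_animals)]
    return pd.DataFrame(
        {"animal_id": animals, "diet": diets, "breed": breeds, "additive": additives}
    )


def _resolve_rpt(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    if params.rpt is not None:
        rpt = np.asarray(params.rpt, dtype=float)
        if len(rpt) != params.n_features:
            raise ValueError("rpt vector length must equal n_features")
    else:
        rpt = rng.uniform(*params.rpt_range, size=params.n_features)
    if (rpt < 0).any() or (rpt >= 1).any():
        raise ValueError("repeatability targets must lie in [0, 1)")
    return rpt


def simulate_feature_tensor(
    params: SimulationParams, rng: np.random.Generator | None = None
):
    """Draw the latent log-abundance tensor and multinomial counts.

    Returns (eta, counts, truth) where eta and counts are samples x features
    frames with a (animal_id, timepoint) MultiIndex and truth holds the
    per-feature variance components, the animal effects u, fixed-effect
    sizes and the animal design.
    """
    if rng is None:
        rng = np.random.default_rng(stage_seed(params.seed, "features"))
    design = _design(params)
    rpt = _resolve_rpt(params, rng)
    s2w = rpt * params.total_variance
    s2e = (1.0 - rpt) * params.total_variance

    nf, na, nt = params.n_features, params.n_animals, params.n_timepoints
    mu = rng.normal(0.0, params.mu_sd, size=nf)
    delta = np.where(
        rng.random(nf) < params.diet_effect_fraction,
        rng.normal(0.0, params.diet_effect_sd, size=nf),
        0.0,
    )
    kappa = np.where(
        rng.random(nf) < params.breed_effect_fraction,
        rng.normal(0.0, params.breed_effect_sd, size=nf),
        0.0,
    )
    if params.timepoint_drift_sd > 0:
        slope = rng.normal(0.0, params.timepoint_drift_sd, size=nf)
        tgrid = np.linspace(-0.5, 0.5, nt)
        tau = np.outer(tgrid, slope)  # nt x nf
    else:
        tau = np.zeros((nt, nf))

    u = rng.normal(0.0, 1.0, size=(na, nf)) * np.sqrt(s2w)
    is_con = (design["diet"] == "CON").to_numpy(float)
    is_breed = (design["breed"] == design["breed"].iloc[0]).to_numpy(float)

    timepoints = [f"T{t+1}" for t in range(nt)]
    index = pd.MultiIndex.from_product(
        [design["animal_id"], timepoints], names=["animal_id", "timepoint"]
    )
    eta = np.empty((na * nt, nf))
    counts = np.empty((na * nt, nf), dtype=np.int64)
    lo, hi = params.library_size_range
    row = 0
    for j in range(na):
        base = mu + delta * is_con[j] + kappa * is_breed[j] + u[j]
        for t in range(nt):
            eps = rng.normal(0.0, 1.0, size=nf) * np.sqrt(s2e)
            e_row = base + tau[t] + eps
            eta[row] = e_row
            lib = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            p = np.exp(e_row - e_row.max())
            counts[row] = rng.multinomial(lib, p / p.sum())
            row += 1

    feats = [f"F{i+1:04d}" for i in range(nf)]
    eta_df = pd.DataFrame(eta, index=index, columns=feats)
    counts_df = pd.DataFrame(counts, index=index, columns=feats)
    truth = {
        "rpt": rpt,
        "sigma2_w": s2w,
        "sigma2_e": s2e,
        "mu": mu,
        "delta": delta,
        "kappa": kappa,
        "tau": tau,
        "u": pd.DataFrame(u, index=design["animal_id"], columns=feats),
        "design": design,
    }
    return eta_df, counts_df, truth


def simulate_genotypes_and_bv(
    params: SimulationParams, rng: np.random.Generator | None = None
):
    """Polygenic genotypes and true breeding values.

    Allele frequencies ~ Uniform(0.1, 0.9); dosages ~ Binomial(2, p_m);
    breeding values are sums of per-marker effects on the standardised
    dosages, themselves standardised to unit sample variance (the trait
    builder then scales them by the requested heritability).
    """
    if params.n_markers < 50:
        raise ValueError("need at least 50 markers")
    if not (0.0 <= params.h2 < 1.0):
        raise ValueError("h2 must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(stage_seed(params.seed, "genotypes"))
    design = _design(params)
    p = rng.uniform(0.1, 0.9, size=params.n_markers)
    if params.n_families:
        # sibling families (shared sire and dam): within-family relatedness
        # ~0.5 provides the relatedness variation that identifies h2
        fam = np.arange(params.n_animals) % params.n_families
        sires = rng.binomial(2, p, size=(params.n_families, params.n_markers))
        dams = rng.binomial(2, p, size=(params.n_families, params.n_markers))
        paternal = rng.binomial(1, sires[fam] / 2.0)
        maternal = rng.binomial(1, dams[fam] / 2.0)
        X = (paternal + maternal).astype(float)
    else:
        X = rng.binomial(2, p, size=(params.n_animals, params.n_markers)).astype(float)
    # drop markers that came out monomorphic in this sample
    obs_p = X.mean(axis=0) / 2.0
    poly = (obs_p > 0) & (obs_p < 1)
    X, p = X[:, poly], p[poly]
    alpha = rng.normal(0.0, 1.0, size=X.shape[1])
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    a = Z @ alpha
    if params.h2 == 0.0:
        a = np.zeros_like(a)
    elif a.std(ddof=1) > 0:
        a = (a - a.mean()) / a.std(ddof=1)
    markers = [f"M{m+1:05d}" for m in range(X.shape[1])]
    geno = pd.DataFrame(X.astype(int), index=design["animal_id"], columns=markers)
    return geno, pd.Series(a, index=design["animal_id"], name="true_bv")


def simulate_traits(
    params: SimulationParams,
    truth: dict,
    true_bv: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-animal phenotypes with planted biomarker, weight and genetic signal.

    Each trait k is built as

        raw_jk = std(sum_{i in B} beta_ik u_ij) + g * std(a_j)
                 + w * std(weight_j) + noise_sd * z_jk

    and then calibrated so its sample mean/sd equal the emulated trial's
    printed descriptives exactly. Biomarker memberships, per-trait weights
    and signs are recorded into ``truth``.
    """
    if rng is None:
        rng = np.random.default_rng(stage_seed(params.seed, "traits"))
    design = truth["design"]
    u = truth["u"]
    na = len(design)
    if params.n_biomarkers > u.shape[1]:
        raise ValueError("more biomarkers than features")
    # biomarkers drawn among reasonably repeatable features so their animal
    # effects carry usable signal
    rpt = truth["rpt"]
    eligible = np.argsort(-rpt)[: max(params.n_biomarkers * 3, params.n_biomarkers)]
    bio_idx = np.sort(rng.choice(eligible, size=params.n_biomarkers, replace=False))
    bio_ids = [u.columns[i] for i in bio_idx]

    weight = rng.normal(ALLOCATION_WEIGHT[0], ALLOCATION_WEIGHT[1], size=na)

    def std(v):
        v = np.asarray(v, dtype=float)
        s = v.std(ddof=1)
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    a = true_bv.loc[design["animal_id"]].to_numpy() if true_bv is not None else np.zeros(na)
    g_scale = np.sqrt(params.h2 / (1 - params.h2)) if params.h2 > 0 else 0.0

    beta = {}
    out = {"animal_id": design["animal_id"].to_list()}
    for trait, (mean, sd) in TRAIT_MOMENTS.items():
        # every planted biomarker gets a material effect: random sign,
        # magnitude bounded away from zero
        b = rng.choice([-1.0, 1.0], size=params.n_biomarkers) * rng.uniform(
            0.5, 1.5, size=params.n_biomarkers
        )
        beta[trait] = b
        signal = u.iloc[:, bio_idx].to_numpy() @ b
        raw = (
            std(signal)
            + params.genetic_weight * g_scale * std(a)
            + params.weight_weight * std(weight)
            + params.trait_noise_sd * rng.standard_normal(na)
        )
        out[trait] = mean + sd * std(raw)
    pheno = pd.DataFrame(out).set_index("animal_id")
    pheno["allocation_weight"] = weight
    pheno["diet"] = design.set_index("animal_id")["diet"]
    pheno["breed"] = design.set_index("animal_id")["breed"]
    truth["biomarkers"] = bio_ids
    truth["biomarker_beta"] = pd.DataFrame(beta, index=bio_ids)
    truth["biomarker_sign"] = truth["biomarker_beta"].apply(np.sign)
    return pheno


def simulate_study(params: SimulationParams | None = None) -> SimulatedStudy:
    """Full synthetic study: counts, metadata, phenotypes, genotypes, truth."""
    if params is None:
        params = SimulationParams()
    eta, counts, truth = simulate_feature_tensor(params)
    geno, true_bv = simulate_genotypes_and_bv(params)
    pheno = simulate_traits(params, truth, true_bv=true_bv)
    truth["true_bv"] = true_bv

    meta = counts.index.to_frame(index=False)
    design = truth["design"].set_index("animal_id")
    meta = meta.merge(design, left_on="animal_id", right_index=True, how="left")
    meta["sample_id"] = meta["animal_id"] + "_" + meta["timepoint"]
    meta = meta.set_index("sample_id")
    flat_counts = counts.copy()
    flat_counts.index = meta.index
    return SimulatedStudy(
        counts=flat_counts,
        metadata=meta,
        phenotypes=pheno,
        genotypes=geno,
        eta=eta,
        truth=truth,
    )
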