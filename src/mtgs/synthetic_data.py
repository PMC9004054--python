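"""Synthetic marker panels and multi-environment augmented-trial phenotypes.

The generator emulates the statistical structure of a soft-wheat elite panel
evaluated in augmented designs across several environments: an additive
infinitesimal genetic model with breeding values drawn MVN(0, Sigma (x) K)
on the realized genomic relationship K, independent per-(line, env, trait)
G-by-E deviations, random block effects, an anthesis-date covariate with an
additive effect on every trait, and iid plot residuals.  Every simulated
component is recorded in a :class:`SimTruth` so downstream estimators can be
checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .kinship import KinshipMatrix, MarkerMatrix, additive_relationship, impute_missing

TRIAL_COLUMNS = ["env", "block", "entry_id", "is_check", "check_id", "days_to_anthesis"]

#: Default trait panel: five primary agronomic traits plus two physiological
#: secondary traits (NDVI, canopy temperature), with broad-sense
#: heritabilities and scales typical of a ~236-line soft wheat panel.
WHEAT_TRAITS = ["HI", "GY", "GN", "SPI", "FE", "NDVI", "CT"]
WHEAT_H2 = {"HI": 0.38, "GY": 0.34, "GN": 0.28, "SPI": 0.26, "FE": 0.25, "NDVI": 0.64, "CT": 0.37}
WHEAT_MEANS = {"HI": 0.44, "GY": 4752.0, "GN": 10630.0, "SPI": 0.28, "FE": 41.6, "NDVI": 0.62, "CT": 27.1}
WHEAT_SDS = {"HI": 0.07, "GY": 680.0, "GN": 2600.0, "SPI": 0.05, "FE": 10.0, "NDVI": 0.07, "CT": 1.4}
# genetic correlations of both signs: positive among yield-related traits,
# negative between canopy temperature and everything else
WHEAT_GCOR = np.array(
    [  # HI     GY     GN     SPI    FE     NDVI   CT
        [1.00, 0.59, 0.42, 0.29, 0.35, 0.41, -0.11],
        [0.59, 1.00, 0.82, 0.25, 0.32, 0.36, -0.24],
        [0.42, 0.82, 1.00, 0.23, 0.47, 0.20, -0.31],
        [0.29, 0.25, 0.23, 1.00, -0.32, 0.13, -0.07],
        [0.35, 0.32, 0.47, -0.32, 1.00, 0.12, -0.08],
        [0.41, 0.36, 0.20, 0.13, 0.12, 1.00, 0.09],
        [-0.11, -0.24, -0.31, -0.07, -0.08, 0.09, 1.00],
    ]
)


@dataclass
class DesignSpec:
    """Augmented-trial layout: unreplicated entries plus repeated checks."""

    n_lines: int = 236
    n_checks: int = 3
    # ~20 test entries + checks per block, typical augmented-block size;
    # check replication (n_checks x blocks) is what identifies block effects
    # and the anthesis covariate slope
    n_blocks_per_env: int = 12
    environments: tuple[str, ...] = ("Q17", "Q18", "C18")
    n_rep: int = 1  # replications of test entries per env (augmented => 1)
    train_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.n_lines < 2 or self.n_checks < 0 or self.n_blocks_per_env < 1:
            raise ValueError("invalid design dimensions")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")

    @property
    def n_total(self) -> int:
        return self.n_lines + self.n_checks


@dataclass
class SimParams:
    """Trait architecture for the simulator (defaults: wheat panel)."""

    trait_names: tuple[str, ...] = tuple(WHEAT_TRAITS)
    heritabilities: dict[str, float] = field(default_factory=lambda: dict(WHEAT_H2))
    trait_means: dict[str, float] = field(default_factory=lambda: dict(WHEAT_MEANS))
    trait_sds: dict[str, float] = field(default_factory=lambda: dict(WHEAT_SDS))
    genetic_correlations: np.ndarray = field(default_factory=lambda: WHEAT_GCOR.copy())
    # sigma2_GxE / sigma2_e per trait; physiological traits show little GxE
    gxe_to_resid: dict[str, float] = field(
        default_factory=lambda: {t: (0.2 if t in ("NDVI", "CT") else 1.0) for t in WHEAT_TRAITS}
    )
    env_effect_sd_scale: float = 1.0  # env main effect SD, in units of trait SD
    block_sd_scale: float = 0.3
    covariate_slope_scale: float = 0.3  # per-trait slope = scale * sd / anthesis SD
    anthesis_mean: float = 100.0
    anthesis_sd: float = 5.0  # genotype-level spread of flowering date
    # plot-to-plot anthesis variation within a genotype; this is what
    # identifies the covariate slope in a fixed-genotype model with
    # unreplicated entries (only checks are replicated)
    anthesis_plot_sd: float = 2.0

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)


@dataclass
class SimTruth:
    """Ground-truth components behind one simulated trial."""

    trait_names: list[str]
    genetic_covariance: np.ndarray  # t x t, trait units squared
    gxe_variances: np.ndarray  # length t
    residual_variances: np.ndarray  # length t
    env_effects: pd.DataFrame  # env x trait
    block_effects: pd.DataFrame  # (env, block) x trait
    breeding_values: pd.DataFrame  # line x trait (includes checks)
    trait_means: np.ndarray
    covariate_slope: np.ndarray  # per-trait effect of anthesis days
    anthesis_values: pd.Series  # genotype-level anthesis dates
    n_env: int
    n_rep: int
    seed: int

    @property
    def heritabilities(self) -> np.ndarray:
        """Broad-sense H2 implied by the stored variance components."""
        g = np.diag(self.genetic_covariance)
        return g / (g + self.gxe_variances / self.n_env + self.residual_variances / (self.n_env * self.n_rep))

    def genetic_correlations(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.genetic_covariance))
        return self.genetic_covariance / np.outer(d, d)

    def to_yaml(self, path) -> None:
        payload = {
            "trait_names": list(self.trait_names),
            "genetic_covariance": self.genetic_covariance.tolist(),
            "gxe_variances": self.gxe_variances.tolist(),
            "residual_variances": self.residual_variances.tolist(),
            "env_effects": {str(k): v for k, v in self.env_effects.T.to_dict("list").items()},
            "block_effects": {f"{e}|{b}": v for (e, b), v in self.block_effects.T.to_dict("list").items()},
            "breeding_values": {str(k): v for k, v in self.breeding_values.T.to_dict("list").items()},
            "trait_means": self.trait_means.tolist(),
            "covariate_slope": self.covariate_slope.tolist(),
            "anthesis_values": {str(k): float(v) for k, v in self.anthesis_values.items()},
            "n_env": int(self.n_env),
            "n_rep": int(self.n_rep),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        traits = d["trait_names"]
        env_eff = pd.DataFrame(d["env_effects"], index=traits).T
        blk_idx = [tuple(k.split("|", 1)) for k in d["block_effects"]]
        blk = pd.DataFrame(list(d["block_effects"].values()), columns=traits,
                           index=pd.MultiIndex.from_tuples(blk_idx, names=["env", "block"]))
        bv = pd.DataFrame(d["breeding_values"], index=traits).T
        return cls(
            trait_names=traits,
            genetic_covariance=np.asarray(d["genetic_covariance"]),
            gxe_variances=np.asarray(d["gxe_variances"]),
            residual_variances=np.asarray(d["residual_variances"]),
            env_effects=env_eff,
            block_effects=blk,
            breeding_values=bv,
            trait_means=np.asarray(d["trait_means"]),
            covariate_slope=np.asarray(d["covariate_slope"]),
            anthesis_values=pd.Series(d["anthesis_values"]),
            n_env=d["n_env"],
            n_rep=d["n_rep"],
            seed=d["seed"],
        )


def simulate_markers(
    n_lines: int,
    n_markers: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> MarkerMatrix:
    """Draw biallelic SNP genotypes under Hardy-Weinberg equilibrium.

    Per-marker minor allele frequency is uniform on ``maf_range``; genotypes
    are coded +1 (major homozygote), 0 (heterozygote), -1 (minor homozygote),
    with missing calls dropped uniformly at ``missing_rate``.
    """
    if n_lines < 2 or n_markers < 1:
        raise ValueError("need at least 2 lines and 1 marker")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_markers)
    # minor-allele dosage per line under HWE
    dosage = rng.binomial(2, maf, size=(n_lines, n_markers)).astype(float)
    codes = 1.0 - dosage  # 0 copies of minor -> +1, 1 -> 0, 2 -> -1
    if missing_rate > 0:
        codes[rng.random(codes.shape) < missing_rate] = np.nan
    line_ids = [f"L{i + 1:03d}" for i in range(n_lines)]
    marker_ids = [f"M{j + 1:05d}" for j in range(n_markers)]
    return MarkerMatrix(line_ids, marker_ids, codes)


def _variance_split(h2: float, total_var: float, q_gxe: float, n_env: int, n_rep: int):
    """Partition plot variance into (sigma2_G, sigma2_GxE, sigma2_e) hitting
    a requested broad-sense H2 = sG / (sG + sGxE/n + se/(n r))."""
    if not 0 < h2 < 1:
        raise ValueError("heritability must lie in (0, 1)")
    # with sGxE = q * se:  sG = h2 * se * (q/n + 1/(n r)) / (1 - h2)
    coef = h2 * (q_gxe / n_env + 1.0 / (n_env * n_rep)) / (1.0 - h2)
    se = total_var / (coef + q_gxe + 1.0)
    return coef * se, q_gxe * se, se


def _matrix_sqrt_psd(m: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    lam, vec = np.linalg.eigh(m)
    if lam[0] < -tol * max(1.0, lam[-1]):
        raise ValueError(f"matrix not PSD (min eigenvalue {lam[0]:.3g})")
    return vec @ np.diag(np.sqrt(np.clip(lam, 0.0, None)))


def simulate_trial(
    markers: MarkerMatrix,
    design: DesignSpec,
    params: SimParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a multi-environment augmented trial on a marker panel.

    The last ``design.n_checks`` marker rows are the repeated checks; the
    rest are unreplicated test entries.  Returns the long-format plot table
    and the full ground truth.
    """
    params = params or SimParams()
    if markers.n_lines != design.n_total:
        raise ValueError(
            f"markers have {markers.n_lines} lines; design needs "
            f"{design.n_lines} entries + {design.n_checks} checks"
        )
    t = params.n_traits
    corr = np.asarray(params.genetic_correlations, dtype=float)
    if corr.shape != (t, t) or not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("genetic_correlations must be a symmetric t x t matrix")
    if np.linalg.eigvalsh(corr)[0] < -1e-8:
        raise ValueError("requested genetic covariance is not positive semi-definite")

    rng = np.random.default_rng(seed)
    n_env = len(design.environments)
    sg = np.empty(t)
    sgxe = np.empty(t)
    se = np.empty(t)
    for j, tr in enumerate(params.trait_names):
        sg[j], sgxe[j], se[j] = _variance_split(
            params.heritabilities[tr], params.trait_sds[tr] ** 2,
            params.gxe_to_resid[tr], n_env, design.n_rep,
        )
    d = np.sqrt(sg)
    sigma_true = np.clip(corr, -1, 1) * np.outer(d, d)

    filled = impute_missing(markers, "mean") if markers.missing_mask.any() else markers
    kin = additive_relationship(filled)
    lk = _matrix_sqrt_psd(kin.values)
    lsig = _matrix_sqrt_psd(sigma_true)
    # breeding values G = L_K Z L_Sigma', so Cov(vec(G')) = Sigma (x) K
    bv = lk @ rng.standard_normal((design.n_total, t)) @ lsig.T
    bv_df = pd.DataFrame(bv, index=markers.line_ids, columns=list(params.trait_names))

    means = np.array([params.trait_means[tr] for tr in params.trait_names])
    sds = np.array([params.trait_sds[tr] for tr in params.trait_names])
    slopes = params.covariate_slope_scale * sds / params.anthesis_sd
    anth = pd.Series(
        rng.normal(params.anthesis_mean, params.anthesis_sd, design.n_total),
        index=markers.line_ids,
    )
    env_eff = pd.DataFrame(
        rng.normal(0.0, params.env_effect_sd_scale * sds, (n_env, t)),
        index=list(design.environments), columns=list(params.trait_names),
    )
    blocks = [f"B{b + 1}" for b in range(design.n_blocks_per_env)]
    blk_index = pd.MultiIndex.from_product(
        [design.environments, blocks], names=["env", "block"]
    )
    blk_eff = pd.DataFrame(
        rng.normal(0.0, params.block_sd_scale * sds, (len(blk_index), t)),
        index=blk_index, columns=list(params.trait_names),
    )
    gxe = {
        env: rng.normal(0.0, np.sqrt(sgxe), (design.n_total, t))
        for env in design.environments
    }

    entry_ids = markers.line_ids[: design.n_lines]
    check_ids = markers.line_ids[design.n_lines:]
    records = []
    for env in design.environments:
        order = rng.permutation(design.n_lines)
        for rep in range(design.n_rep):
            for pos, line_idx in enumerate(order):
                # replicates shift one block over so they land in distinct blocks
                block = blocks[(pos + rep) % design.n_blocks_per_env]
                records.append((env, block, entry_ids[line_idx], False, None))
        for block in blocks:
            for chk in check_ids:
                records.append((env, block, chk, True, chk))

    rows = []
    line_pos = {lid: i for i, lid in enumerate(markers.line_ids)}
    for env, block, lid, is_check, chk in records:
        i = line_pos[lid]
        days = float(anth[lid] + rng.normal(0.0, params.anthesis_plot_sd))
        resid = rng.normal(0.0, np.sqrt(se))
        y = (
            means
            + env_eff.loc[env].to_numpy()
            + blk_eff.loc[(env, block)].to_numpy()
            + bv[i]
            + gxe[env][i]
            + slopes * (days - params.anthesis_mean)
            + resid
        )
        rows.append([env, block, lid, is_check, chk, days, *y])
    trial = pd.DataFrame(rows, columns=TRIAL_COLUMNS + list(params.trait_names))

    truth = SimTruth(
        trait_names=list(params.trait_names),
        genetic_covariance=sigma_true,
        gxe_variances=sgxe,
        residual_variances=se,
        env_effects=env_eff,
        block_effects=blk_eff,
        breeding_values=bv_df,
        trait_means=means,
        covariate_slope=slopes,
        anthesis_values=anth,
        n_env=n_env,
        n_rep=design.n_rep,
        seed=seed,
    )
    return trial, truth


def simulate_blues(
    kin: KinshipMatrix,
    heritabilities: np.ndarray,
    genetic_correlations: np.ndarray,
    trait_sds: np.ndarray | None = None,
    trait_names: list[str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate adjusted genotype means directly at the GEBV-model level.

    y_j = mu_j + g_j + e_j per trait, with g ~ MVN(0, Sigma (x) K) and iid
    residuals; per-trait h2 = sigma2_g / (sigma2_g + sigma2_e).  Useful for
    parameter-recovery and cross-validation studies where the plot-level
    trial structure is not the object under test.
    """
    h2 = np.asarray(heritabilities, dtype=float)
    t = h2.size
    corr = np.asarray(genetic_correlations, dtype=float)
    if np.linalg.eigvalsh(corr)[0] < -1e-8:
        raise ValueError("requested genetic covariance is not positive semi-definite")
    sds = np.ones(t) if trait_sds is None else np.asarray(trait_sds, dtype=float)
    names = trait_names or [f"T{j + 1}" for j in range(t)]
    sg = h2 * sds**2
    se = (1.0 - h2) * sds**2
    dvec = np.sqrt(sg)
    sigma = np.clip(corr, -1, 1) * np.outer(dvec, dvec)
    rng = np.random.default_rng(seed)
    n = kin.n_lines
    g = _matrix_sqrt_psd(kin.values) @ rng.standard_normal((n, t)) @ _matrix_sqrt_psd(sigma).T
    y = g + rng.standard_normal((n, t)) * np.sqrt(se)
    blues = pd.DataFrame(y, index=kin.line_ids, columns=names)
    truth = {
        "genetic_values": pd.DataFrame(g, index=kin.line_ids, columns=names),
        "Sigma": sigma,
        "residual_variances": se,
        "heritabilities": h2,
    }
    return blues, truth


def write_trial_csv(trial: pd.DataFrame, path) -> None:
    trial.to_csv(path, index=False)


def read_trial_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["is_check"] = df["is_check"].astype(bool)
    df["check_id"] = df["check_id"].where(df["check_id"].notna(), None)
    return df


def write_vcf(markers: MarkerMatrix, path) -> None:
    """Write the coded panel as a minimal diploid VCFv4.2.

    +1 (major homozygote) -> 0/0 against a major-allele REF; -1 -> 1/1;
    0 -> 0/1; missing -> ./.  Positions are synthetic 1-based coordinates.
    """
    gt_map = {1.0: "0/0", 0.0: "0/1", -1.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(markers.line_ids) + "\n")
        for j, mid in enumerate(markers.marker_ids):
            gts = [
                "./." if np.isnan(c) else gt_map[float(c)] for c in markers.codes[:, j]
            ]
            fh.write(f"1\t{j + 1}\t{mid}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
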