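"""Synthetic cross-population generator with planted window-level heterosis.

The generator emulates the study design the package targets: a pool of
~50 homozygous female (CMS) lines crossed full-factorially to ~8
homozygous male (restorer) lines, grown in 3 environments x 3 replicates
and scored for 6 agronomic traits, with hybrid vigor driven partly by
window-level parental divergence.

Genomes: per chromosome, SNP positions are drawn at the configured
density with reference-allele frequencies from a Beta(0.5, 0.5) truncated
to [0.05, 0.95]; a pool of founder haplotypes is sampled from those
frequencies, and each inbred parent is a homozygous mosaic of founder
haplotypes in segments of the configured length. Segment length defaults
to 100 kb, matching the short-range linkage disequilibrium of the
semi-winter rapeseed populations this design mirrors.

Phenotypes: hybrid genetic value = mu + GCA_f + GCA_m + sum_w beta_w *
PGSI_w(cross); parent genetic value = mu + 2*GCA_p - delta (inbreeding
depression), so hybrids exceed the midparent on average. Observed value =
genetic value + environment offset + replicate noise. Planted window
effects are scaled so they explain a configured fraction of the hybrid
genetic variance; replicate noise is scaled to a configured
BLUE-level heritability. Everything is reproducible from one seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pgsihet.genotype_io import CrossPlan, ParentalGenotypeMatrix
from pgsihet.windows_pgsi import GenomeWindows, compute_pgsi_matrix, make_windows

log = logging.getLogger(__name__)

NUCLEOTIDES = np.array(["A", "C", "G", "T"], dtype=object)

#: trait base mean and genetic SD on field scales (cm, counts, g, g/plot)
TRAIT_SCALES: dict[str, tuple[float, float]] = {
    "PH": (180.0, 12.0),
    "NBP": (8.0, 1.0),
    "NSP": (300.0, 40.0),
    "NSS": (22.0, 2.5),
    "TSW": (4.0, 0.35),
    "GY": (3000.0, 350.0),
}


@dataclass
class SimulationConfig:
    """Study-shaped defaults; every stochastic step flows from ``seed``."""

    seed: int
    n_females: int = 50
    n_males: int = 8
    n_test_males: int = 0  # extra held-out males for external validation
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {c: 5_000_000 for c in ("A01", "A02", "C01", "C02")}
    )
    snp_density: float = 0.001  # SNPs per bp (1 per kb)
    founder_pool_size: int = 16
    segment_length: int = 100_000  # LD block scale of the emulated populations
    effect_window_width: int = 100_000
    n_positive_effect_windows: int = 10
    n_negative_effect_windows: int = 10
    pgsi_variance_fraction: float = 0.5  # of hybrid genetic variance
    delta_sd: float = 0.5  # inbreeding depression, in trait genetic SD
    n_environments: int = 3
    n_replicates: int = 3
    env_sd: float = 0.5  # environment offset scale, in trait genetic SD
    heritability: float = 0.7  # at the BLUE (entry-mean) level
    traits: tuple[str, ...] = tuple(TRAIT_SCALES)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_females", "n_males", "founder_pool_size", "segment_length",
                     "n_environments", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.pgsi_variance_fraction <= 1:
            raise ValueError("pgsi_variance_fraction must be in [0, 1]")
        if not 0 < self.heritability <= 1:
            raise ValueError("heritability must be in (0, 1]")
        unknown = [t for t in self.traits if t not in TRAIT_SCALES]
        if unknown:
            raise ValueError(f"traits without a configured scale: {unknown}")

    @property
    def female_ids(self) -> list[str]:
        return [f"F{i:02d}" for i in range(1, self.n_females + 1)]

    @property
    def male_ids(self) -> list[str]:
        return [f"M{i:02d}" for i in range(1, self.n_males + 1)]

    @property
    def test_male_ids(self) -> list[str]:
        return [f"T{i:02d}" for i in range(1, self.n_test_males + 1)]

    @property
    def parent_ids(self) -> list[str]:
        return self.female_ids + self.male_ids + self.test_male_ids


def napus_shape_config(seed: int, **overrides) -> SimulationConfig:
    """A 19-chromosome A/C-prefixed genome for naming/subgenome logic tests.

    Chromosome count and labels mirror *B. napus* (A01-A10, C01-C09);
    lengths stay small so runs remain quick.
    """
    chroms = {f"A{i:02d}": 2_000_000 for i in range(1, 11)}
    chroms.update({f"C{i:02d}": 2_000_000 for i in range(1, 10)})
    return SimulationConfig(seed=seed, chromosomes=chroms, **overrides)


@dataclass
class SimTruth:
    """The generative ground truth, serializable for recovery scoring."""

    window_effects: dict[str, pd.DataFrame]  # trait -> (window_key, chrom, start, end, beta)
    gca: dict[str, pd.Series]  # trait -> per-parent GCA
    env_offsets: dict[str, pd.Series]  # trait -> per-environment offset
    mu: dict[str, float]
    delta: dict[str, float]
    replicate_sd: dict[str, float]
    effect_window_width: int

    def planted_keys(self, trait: str) -> list[str]:
        return list(self.window_effects[trait]["window_key"])

    def to_json(self, path) -> None:
        payload = {
            "effect_window_width": self.effect_window_width,
            "mu": self.mu,
            "delta": self.delta,
            "replicate_sd": self.replicate_sd,
            "window_effects": {
                t: df.to_dict(orient="records") for t, df in self.window_effects.items()
            },
            "gca": {t: s.to_dict() for t, s in self.gca.items()},
            "env_offsets": {t: s.to_dict() for t, s in self.env_offsets.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            window_effects={
                t: pd.DataFrame(rows) for t, rows in payload["window_effects"].items()
            },
            gca={t: pd.Series(d) for t, d in payload["gca"].items()},
            env_offsets={t: pd.Series(d) for t, d in payload["env_offsets"].items()},
            mu=payload["mu"],
            delta=payload["delta"],
            replicate_sd=payload["replicate_sd"],
            effect_window_width=payload["effect_window_width"],
        )


def _truncated_beta(rng: np.random.Generator, n: int, lo=0.05, hi=0.95) -> np.ndarray:
    out = np.empty(0)
    while out.size < n:
        draw = rng.beta(0.5, 0.5, size=2 * (n - out.size) + 16)
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return out[:n]


def simulate_parent_genomes(
    config: SimulationConfig,
) -> tuple[ParentalGenotypeMatrix, dict[str, int]]:
    """Draw founder haplotypes and homozygous parental mosaics."""
    rng = np.random.default_rng([config.seed, 1])
    chroms_all, pos_all, ref_all, alt_all, calls_all = [], [], [], [], []
    parents = config.parent_ids
    n_par = len(parents)
    for chrom, length in config.chromosomes.items():
        n_sites = int(round(length * config.snp_density))
        if n_sites < 1:
            raise ValueError(
                f"snp_density x length yields no SNPs on chromosome {chrom!r}"
            )
        pos = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1  # 1-based
        p_alt = _truncated_beta(rng, n_sites)
        founders = (rng.random((n_sites, config.founder_pool_size)) < p_alt[:, None]).astype(
            np.int8
        )
        # mosaic: founder index per segment per parent
        n_seg = math.ceil(length / config.segment_length)
        seg_of_site = (pos - 1) // config.segment_length
        founder_choice = rng.integers(0, config.founder_pool_size, size=(n_seg, n_par))
        alleles = founders[np.arange(n_sites)[:, None], founder_choice[seg_of_site]]
        ref_nt_idx = rng.integers(0, 4, size=n_sites)
        alt_shift = rng.integers(1, 4, size=n_sites)
        ref_nt = NUCLEOTIDES[ref_nt_idx]
        alt_nt = NUCLEOTIDES[(ref_nt_idx + alt_shift) % 4]
        calls = np.stack([alleles, alleles], axis=2).astype(np.int8)
        chroms_all.append(np.full(n_sites, chrom, dtype=object))
        pos_all.append(pos.astype(np.int64))
        ref_all.append(ref_nt)
        alt_all.extend((a,) for a in alt_nt)
        calls_all.append(calls)
    matrix = ParentalGenotypeMatrix(
        chrom=np.concatenate(chroms_all),
        pos=np.concatenate(pos_all),
        ref=np.concatenate(ref_all),
        alts=alt_all,
        samples=parents,
        calls=np.concatenate(calls_all, axis=0),
    )
    return matrix, dict(config.chromosomes)


def make_cross_plan(config: SimulationConfig) -> tuple[CrossPlan, CrossPlan | None]:
    """Full-factorial training plan, plus a held-out-male test plan if any."""

    def factorial(males: list[str]) -> pd.DataFrame:
        rows = [
            (f, m, f"{f}x{m}") for f in config.female_ids for m in males
        ]
        return pd.DataFrame(rows, columns=["female_id", "male_id", "hybrid_id"])

    train = CrossPlan(factorial(config.male_ids))
    test = CrossPlan(factorial(config.test_male_ids)) if config.n_test_males else None
    return train, test


def plant_window_effects(
    windows: GenomeWindows, config: SimulationConfig
) -> dict[str, pd.DataFrame]:
    """Choose disjoint effect windows per trait with signed raw effects.

    Negative coefficients (dissimilarity-favoring) and positive ones are
    planted in the configured counts; magnitudes are |N(0,1)| + 0.5 and
    are rescaled later against the realized PGSI variance.
    """
    rng = np.random.default_rng([config.seed, 2])
    n_eff = config.n_negative_effect_windows + config.n_positive_effect_windows
    if n_eff > len(windows):
        raise ValueError(f"cannot plant {n_eff} effects in {len(windows)} windows")
    keys = np.array(windows.keys(), dtype=object)
    wf = windows.frame
    out = {}
    for trait in config.traits:
        idx = rng.choice(len(windows), size=n_eff, replace=False)
        mags = np.abs(rng.standard_normal(n_eff)) + 0.5
        signs = np.array(
            [-1.0] * config.n_negative_effect_windows
            + [1.0] * config.n_positive_effect_windows
        )
        df = pd.DataFrame(
            {
                "window_key": keys[idx],
                "chrom": wf["chrom"].to_numpy()[idx],
                "start": wf["start"].to_numpy()[idx],
                "end": wf["end"].to_numpy()[idx],
                "beta": mags * signs,
            }
        ).sort_values(["chrom", "start"], ignore_index=True)
        out[trait] = df
    return out


def simulate_phenotypes(
    parents: ParentalGenotypeMatrix,
    plan: CrossPlan,
    window_effects: dict[str, pd.DataFrame],
    config: SimulationConfig,
    windows: GenomeWindows,
) -> tuple[pd.DataFrame, SimTruth]:
    """Replicate-level phenotype records for hybrids and all parents.

    Scales the raw planted effects so the PGSI term explains the
    configured fraction of hybrid genetic variance, then finalizes the
    truth object.
    """
    rng = np.random.default_rng([config.seed, 3])
    pgsi = compute_pgsi_matrix(parents, plan, windows)
    feats = pgsi.to_frame()
    envs = [f"E{i}" for i in range(1, config.n_environments + 1)]
    all_parents = config.parent_ids

    gca, env_offsets, mu_d, delta_d, rep_sd_d = {}, {}, {}, {}, {}
    scaled_effects = {}
    records = []
    hybrid_f = plan.frame["female_id"].to_numpy()
    hybrid_m = plan.frame["male_id"].to_numpy()
    for trait in config.traits:
        mu, sd_g = TRAIT_SCALES[trait]
        eff = window_effects[trait].copy()
        s_raw = feats[eff["window_key"]].to_numpy() @ eff["beta"].to_numpy()
        var_target = config.pgsi_variance_fraction * sd_g**2
        v = float(np.var(s_raw))
        scale = math.sqrt(var_target / v) if v > 0 and var_target > 0 else 0.0
        eff["beta"] = eff["beta"] * scale
        # the nonzero mean of the PGSI term is absorbed into the intercept
        s = (s_raw - float(np.mean(s_raw))) * scale
        scaled_effects[trait] = eff

        gca_sd = math.sqrt((1.0 - config.pgsi_variance_fraction) / 2.0) * sd_g
        g_par = pd.Series(rng.normal(0.0, gca_sd, size=len(all_parents)), index=all_parents)
        gca[trait] = g_par
        delta = config.delta_sd * sd_g
        g_hyb = mu + g_par[hybrid_f].to_numpy() + g_par[hybrid_m].to_numpy() + s
        g_parents = mu + 2.0 * g_par - delta

        var_g = float(np.var(g_hyb))
        # replicate noise calibrated so entry-mean (BLUE) heritability hits target
        n_obs = config.n_environments * config.n_replicates
        rep_sd = math.sqrt(var_g * (1.0 - config.heritability) / config.heritability * n_obs)
        rep_sd_d[trait] = rep_sd
        env_off = pd.Series(rng.normal(0.0, config.env_sd * sd_g, size=len(envs)), index=envs)
        env_offsets[trait] = env_off
        mu_d[trait] = mu
        delta_d[trait] = delta

        genetic = pd.concat(
            [pd.Series(g_hyb, index=plan.hybrid_ids), g_parents]
        )
        n_ind = len(genetic)
        noise = rng.normal(
            0.0, rep_sd, size=(n_ind, config.n_environments, config.n_replicates)
        )
        for ei, env in enumerate(envs):
            for rep in range(1, config.n_replicates + 1):
                vals = genetic.to_numpy() + env_off[env] + noise[:, ei, rep - 1]
                records.append(
                    pd.DataFrame(
                        {
                            "sample_id": genetic.index,
                            "environment": env,
                            "replicate": rep,
                            "trait": trait,
                            "value": vals,
                        }
                    )
                )
    table = pd.concat(records, ignore_index=True)
    truth = SimTruth(
        window_effects=scaled_effects,
        gca=gca,
        env_offsets=env_offsets,
        mu=mu_d,
        delta=delta_d,
        replicate_sd=rep_sd_d,
        effect_window_width=config.effect_window_width,
    )
    return table, truth


@dataclass
class SyntheticDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    config: SimulationConfig
    parents: ParentalGenotypeMatrix
    chrom_sizes: dict[str, int]
    plan: CrossPlan  # training crosses
    test_plan: CrossPlan | None
    phenotypes: pd.DataFrame
    truth: SimTruth

    @property
    def full_plan(self) -> CrossPlan:
        if self.test_plan is None:
            return self.plan
        return CrossPlan(
            pd.concat([self.plan.frame, self.test_plan.frame], ignore_index=True)
        )


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate genomes, cross plans and phenotypes in one deterministic pass.

    Phenotypes cover the training hybrids, the test hybrids (when
    ``n_test_males`` > 0) and every parent line.
    """
    parents, chrom_sizes = simulate_parent_genomes(config)
    plan, test_plan = make_cross_plan(config)
    windows = make_windows(chrom_sizes, config.effect_window_width)
    effects = plant_window_effects(windows, config)
    all_plan = plan if test_plan is None else CrossPlan(
        pd.concat([plan.frame, test_plan.frame], ignore_index=True)
    )
    phenos, truth = simulate_phenotypes(parents, all_plan, effects, config, windows)
    return SyntheticDataset(config, parents, chrom_sizes, plan, test_plan, phenos, truth)


def write_vcf(matrix: ParentalGenotypeMatrix, path) -> None:
    """Write the genotype matrix as an uncompressed VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chrom_order = dict.fromkeys(str(c) for c in matrix.chrom)
        for c in chrom_order:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for s in range(matrix.n_sites):
            alt = ",".join(matrix.alts[s])
            gts = []
            for j in range(matrix.n_samples):
                a1, a2 = matrix.calls[s, j]
                gts.append("./." if a1 < 0 or a2 < 0 else f"{a1}/{a2}")
            fh.write(
                f"{matrix.chrom[s]}\t{matrix.pos[s]}\t.\t{matrix.ref[s]}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_chrom_sizes(chrom_sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for c, l in chrom_sizes.items():
            fh.write(f"{c}\t{l}\n")
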