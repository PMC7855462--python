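"""Synthetic genotypes, gene models, feature groups and phenotypes.

The generator emulates the statistical structure of a fully homozygous
diversity panel phenotyped on an automated imaging platform:

* ~344 inbred accessions genotyped at up to ~200k biallelic markers coded
  0/2, with an allele-frequency spectrum that includes rare alleles and
  local LD produced by a block-copy model (markers within one
  ``ld_block_span`` share an ancestral haplotype and differ by per-marker
  mutations, so adjacent-marker |r| is elevated);
* gene models with non-degenerate ORF intervals on the simulated
  chromosomes, and overlapping gene groups of widely varying size standing
  in for GO terms / co-expression clusters;
* replicate-level phenotypes built from a trait with target heritability,
  an optional genomic feature carrying a chosen fraction of the genetic
  variance, 1-4 replicates per accession, additive random design effects
  (spatial row x, column y, image position, sowing block), and timepoints
  whose genetic and residual values follow an AR(1) with high serial
  correlation.

Every operation is deterministic given its config's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError
from .features import FeatureSet, GeneModel, map_genes_to_markers
from .qc import MISSING, GenotypeMatrix, recode_to_minor

#: per-marker probability of deviating from the block haplotype; sets the
#: strength of local LD (smaller = stronger adjacent-marker correlation)
MUTATION_RATE = 0.05
#: baseline phenotypic mean, arbitrary trait units
BASELINE_MEAN = 10.0
#: plants per camera image on the simulated platform
PLANTS_PER_IMAGE = 12
#: number of sowing blocks
N_SOWING_BLOCKS = 4


@dataclass
class SimulationConfig:
    """Panel-level simulation parameters.

    Defaults describe the emulated study population: 344 homozygous
    accessions, 200k markers over 5 chromosomes with MAF down to 0.01,
    ~10 kb LD blocks, 25k genes and overlapping feature groups.
    """

    n_accessions: int = 344
    n_markers: int = 200_000
    n_chromosomes: int = 5
    maf_range: tuple = (0.01, 0.5)
    ld_block_span: int = 10_000
    n_genes: int = 25_000
    orf_length_range: tuple = (500, 5_000)
    n_features: int = 1_000
    feature_size_range: tuple = (1, 2_500)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_accessions", "n_markers", "n_chromosomes",
                     "ld_block_span", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_features < 0:
            raise ConfigError("n_features must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_markers < self.n_chromosomes:
            raise ConfigError("n_markers must be >= n_chromosomes")
        if self.orf_length_range[0] < 1 or \
                self.orf_length_range[0] > self.orf_length_range[1]:
            raise ConfigError("invalid orf_length_range")
        if self.feature_size_range[0] < 1 or \
                self.feature_size_range[0] > self.feature_size_range[1]:
            raise ConfigError("invalid feature_size_range")
        if self.feature_size_range[1] > self.n_genes:
            raise ConfigError("feature_size_range upper bound exceeds n_genes")


@dataclass
class TraitConfig:
    """Trait architecture and experimental-design parameters.

    ``h2_target`` is the heritability on the accession level:
    var(g) / (var(g) + residual_sd^2). When ``feature_id`` is set,
    ``hf2_share`` of the genetic variance is carried by causal markers
    inside that feature. Serial correlation applies to both genetic values
    and plant-level residuals across timepoints (AR(1)), matching the high
    correlation between subsequent measurements on an imaging platform.
    """

    h2_target: float = 0.3
    feature_id: str | None = None
    hf2_share: float = 0.0
    n_causal: int = 500
    n_replicates: int = 4
    design_effect_sds: dict = field(default_factory=lambda: {
        "x": 0.25, "y": 0.25, "image_position": 0.5, "sowing_block": 0.5,
    })
    residual_sd: float = 1.0
    n_timepoints: int = 1
    serial_correlation: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_target <= 1.0:
            raise DomainError("h2_target must lie in [0, 1]")
        if not 0.0 <= self.hf2_share <= 1.0:
            raise ConfigError("hf2_share must lie in [0, 1]")
        if self.feature_id is None and self.hf2_share != 0.0:
            raise ConfigError("hf2_share must be 0 when feature_id is None")
        if not 1 <= self.n_replicates <= 4:
            raise ConfigError("n_replicates must lie in 1..4")
        if self.n_causal <= 0:
            raise ConfigError("n_causal must be positive")
        if self.residual_sd < 0:
            raise ConfigError("residual_sd must be >= 0")
        if self.n_timepoints < 1:
            raise ConfigError("n_timepoints must be >= 1")
        if not 0.0 <= self.serial_correlation < 1.0:
            raise ConfigError("serial_correlation must lie in [0, 1)")


@dataclass
class TraitSimulation:
    """Ground truth and observable output of one simulated trait."""

    effects: np.ndarray  # (n_causal, n_timepoints) marker effects
    causal_markers: np.ndarray  # (n_causal,) marker indices
    genomic_values: np.ndarray  # (n_accessions, n_timepoints)
    phenotypes: pd.DataFrame  # replicate-level rows


# ---------------------------------------------------------------------------
# Genotypes and gene models
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig):
    """Generate (GenotypeMatrix, list[GeneModel]).

    Markers are laid out with ~500 bp mean spacing; each LD block of
    ``ld_block_span`` shares a latent ancestral haplotype that individual
    markers copy with probability 1 - MUTATION_RATE. Genotypes are fully
    homozygous (0 or 2).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_accessions

    per_chrom = np.full(config.n_chromosomes, config.n_markers // config.n_chromosomes)
    per_chrom[: config.n_markers % config.n_chromosomes] += 1

    chroms, positions, cols = [], [], []
    chrom_lengths = {}
    for c in range(config.n_chromosomes):
        name = f"chr{c + 1}"
        mc = int(per_chrom[c])
        spacing = rng.integers(100, 1000, size=mc)
        pos = np.cumsum(spacing)
        chrom_lengths[name] = int(pos[-1] + 1000)
        chroms.append(np.full(mc, name))
        positions.append(pos)

        block = pos // config.ld_block_span
        for b in np.unique(block):
            bidx = np.where(block == b)[0]
            p_b = rng.uniform(*config.maf_range)
            latent = rng.random(n) < p_b  # ancestral haplotype per accession
            flips = rng.random((n, bidx.size)) < MUTATION_RATE
            alleles = latent[:, None] ^ flips
            cols.append((2 * alleles).astype(np.int8))

    calls = np.concatenate(cols, axis=1)
    geno = GenotypeMatrix(
        accession_ids=np.array([f"acc{i:04d}" for i in range(n)]),
        marker_ids=np.array([
            f"{c}:{p}" for c, p in zip(np.concatenate(chroms), np.concatenate(positions))
        ]),
        calls=calls,
        chrom=np.concatenate(chroms),
        pos=np.concatenate(positions),
    )
    geno = recode_to_minor(geno)

    genes = _simulate_gene_models(config, rng, chrom_lengths)
    return geno, genes


def _simulate_gene_models(config, rng, chrom_lengths) -> list:
    names = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in names], dtype=float)
    probs = lengths / lengths.sum()
    genes = []
    chosen = rng.choice(len(names), size=config.n_genes, p=probs)
    for i in range(config.n_genes):
        c = names[chosen[i]]
        span = int(rng.integers(config.orf_length_range[0],
                                config.orf_length_range[1] + 1))
        start = int(rng.integers(1, max(chrom_lengths[c] - span, 2)))
        genes.append(GeneModel(
            gene_id=f"gene{i:05d}",
            chrom=c,
            orf_start=start,
            orf_end=start + span - 1,
            strand="+" if rng.random() < 0.5 else "-",
        ))
    return genes


def simulate_feature_sets(genes, config: SimulationConfig, geno=None) -> list:
    """Overlapping gene groups with sizes drawn within ``feature_size_range``.

    A gene may belong to several features. When ``geno`` is given, marker
    indices are derived from the gene ORFs against its marker map.
    """
    if config.feature_size_range[1] > len(genes):
        raise ConfigError("feature_size_range upper bound exceeds gene count")
    rng = np.random.default_rng(config.seed + 1)
    gene_ids = np.array([g.gene_id for g in genes])
    by_id = {g.gene_id: g for g in genes}
    out = []
    for i in range(config.n_features):
        size = int(rng.integers(config.feature_size_range[0],
                                config.feature_size_range[1] + 1))
        members = rng.choice(gene_ids, size=size, replace=False)
        markers = np.empty(0, dtype=np.int64)
        if geno is not None:
            markers = map_genes_to_markers(
                [by_id[g] for g in members], geno.chrom, geno.pos
            )
        out.append(FeatureSet(f"feat{i:04d}", "CUSTOM", frozenset(members), markers))
    return out


# ---------------------------------------------------------------------------
# Traits and phenotypes
# ---------------------------------------------------------------------------

def _draw_genomic_values(rng, zc, scale_cols, target_var_f, target_var_r, in_feat):
    """One draw of (effects, g) rescaled so realized component variances hit
    their targets exactly."""
    beta = rng.standard_normal(zc.shape[1]) * scale_cols
    g_f = zc[:, in_feat] @ beta[in_feat] if in_feat.any() else np.zeros(zc.shape[0])
    g_r = zc[:, ~in_feat] @ beta[~in_feat] if (~in_feat).any() else np.zeros(zc.shape[0])
    for part, target, sel in ((g_f, target_var_f, in_feat),
                              (g_r, target_var_r, ~in_feat)):
        v = part.var()
        if target == 0.0 or v == 0.0:
            factor = 0.0 if target == 0.0 else 1.0
        else:
            factor = np.sqrt(target / v)
        part *= factor
        beta[sel] *= factor
    return beta, g_f + g_r


def simulate_trait(
    geno: GenotypeMatrix,
    features,
    trait: TraitConfig,
) -> TraitSimulation:
    """Simulate causal effects, true genomic values and replicate phenotypes.

    Causal effects are normal with per-marker scale 1/sqrt(2 p (1 - p)), so
    every causal marker contributes equal expected variance; realized
    component variances are rescaled exactly to the targets implied by
    ``h2_target`` and ``hf2_share``. Genetic values and plant-level
    residuals evolve over timepoints as stationary AR(1) processes with
    parameter ``serial_correlation``; design effects are additive random
    draws per factor level, constant over time.
    """
    rng = np.random.default_rng(trait.seed)
    n = geno.n_accessions
    t_points = trait.n_timepoints
    rho = trait.serial_correlation

    # --- target variances -------------------------------------------------
    if trait.h2_target >= 1.0:
        if trait.residual_sd > 0:
            raise DomainError("h2_target = 1 requires residual_sd = 0")
        sigma_g2 = 1.0
    elif trait.h2_target == 0.0:
        sigma_g2 = 0.0
    else:
        if trait.residual_sd == 0:
            raise DomainError("residual_sd = 0 only allowed with h2_target in {0, 1}")
        sigma_g2 = trait.h2_target / (1.0 - trait.h2_target) * trait.residual_sd ** 2
    var_f = trait.hf2_share * sigma_g2
    var_r = (1.0 - trait.hf2_share) * sigma_g2

    # --- causal marker selection -----------------------------------------
    feature_markers = np.empty(0, dtype=np.int64)
    if trait.feature_id is not None:
        by_id = {f.feature_id: f for f in features}
        if trait.feature_id not in by_id:
            raise ConfigError(f"unknown feature_id {trait.feature_id!r}")
        feature_markers = by_id[trait.feature_id].marker_indices
    n_f = int(round(trait.n_causal * trait.hf2_share)) if trait.feature_id else 0
    polymorphic = np.where(geno.maf > 0)[0]
    feature_pool = np.intersect1d(feature_markers, polymorphic)
    if n_f > feature_pool.size:
        raise ConfigError(
            f"feature {trait.feature_id!r} has {feature_pool.size} polymorphic "
            f"markers, fewer than the {n_f} causal markers it must host"
        )
    causal_f = rng.choice(feature_pool, size=n_f, replace=False) \
        if n_f else np.empty(0, dtype=np.int64)
    pool = np.setdiff1d(polymorphic, feature_markers)
    n_r = trait.n_causal - n_f
    if n_r > pool.size:
        raise ConfigError("not enough non-feature polymorphic markers for n_causal")
    causal_r = rng.choice(pool, size=n_r, replace=False) if n_r else \
        np.empty(0, dtype=np.int64)
    causal = np.concatenate([causal_f, causal_r])
    in_feat = np.zeros(causal.size, dtype=bool)
    in_feat[: causal_f.size] = True

    # --- genomic values per timepoint (AR(1) across time) -----------------
    z = geno.calls[:, causal].astype(np.float64)
    p = z.mean(axis=0) / 2.0
    zc = z - 2.0 * p
    scale_cols = 1.0 / np.sqrt(2.0 * p * (1.0 - p))

    effects = np.zeros((causal.size, t_points))
    gvals = np.zeros((n, t_points))
    beta, g = _draw_genomic_values(rng, zc, scale_cols, var_f, var_r, in_feat)
    effects[:, 0], gvals[:, 0] = beta, g
    for t in range(1, t_points):
        beta_new, g_new = _draw_genomic_values(
            rng, zc, scale_cols, var_f, var_r, in_feat
        )
        effects[:, t] = rho * effects[:, t - 1] + np.sqrt(1 - rho ** 2) * beta_new
        gvals[:, t] = rho * gvals[:, t - 1] + np.sqrt(1 - rho ** 2) * g_new

    # --- experimental design ----------------------------------------------
    n_rep = rng.integers(1, trait.n_replicates + 1, size=n)
    acc_idx = np.repeat(np.arange(n), n_rep)
    rep_no = np.concatenate([np.arange(1, r + 1) for r in n_rep])
    n_plants = acc_idx.size
    order = rng.permutation(n_plants)  # randomized layout
    n_cols = int(np.ceil(np.sqrt(n_plants)))
    x_coord = order // n_cols + 1
    y_coord = order % n_cols + 1
    image_pos = order // PLANTS_PER_IMAGE + 1
    sowing = order * N_SOWING_BLOCKS // n_plants + 1

    def level_effects(levels, sd):
        vals = rng.normal(0.0, sd, size=int(levels.max()) + 1)
        return vals[levels]

    sds = trait.design_effect_sds
    design = (
        level_effects(x_coord, sds.get("x", 0.0))
        + level_effects(y_coord, sds.get("y", 0.0))
        + level_effects(image_pos, sds.get("image_position", 0.0))
        + level_effects(sowing, sds.get("sowing_block", 0.0))
    )

    # --- plant-level residuals, AR(1) across timepoints --------------------
    resid = np.zeros((n_plants, t_points))
    resid[:, 0] = rng.normal(0.0, trait.residual_sd, size=n_plants)
    for t in range(1, t_points):
        resid[:, t] = rho * resid[:, t - 1] + np.sqrt(1 - rho ** 2) * rng.normal(
            0.0, trait.residual_sd, size=n_plants
        )

    rows = []
    for t in range(t_points):
        rows.append(pd.DataFrame({
            "accession": geno.accession_ids[acc_idx],
            "replicate": rep_no,
            "timepoint": f"t{t + 1}",
            "x": x_coord,
            "y": y_coord,
            "image_position": image_pos,
            "sowing_block": sowing,
            "value": BASELINE_MEAN + gvals[acc_idx, t] + design + resid[:, t],
        }))
    phenotypes = pd.concat(rows, ignore_index=True)
    return TraitSimulation(effects, causal, gvals, phenotypes)


# ---------------------------------------------------------------------------
# Writers (plain-text formats)
# ---------------------------------------------------------------------------

def write_tsv(geno: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(
        geno.calls.astype(object), index=geno.accession_ids, columns=geno.marker_ids
    )
    df[geno.calls == MISSING] = "NA"
    df.to_csv(path, sep="\t", index_label="accession")


def write_plink_text(geno: GenotypeMatrix, prefix: str) -> None:
    """Write ``prefix``.ped / ``prefix``.map (counted allele = 'A')."""
    with open(prefix + ".map", "w") as fh:
        for c, mid, p in zip(geno.chrom, geno.marker_ids, geno.pos):
            fh.write(f"{c}\t{mid}\t0\t{p}\n")
    code = {0: "B B", 1: "A B", 2: "A A", MISSING: "0 0"}
    with open(prefix + ".ped", "w") as fh:
        for i, acc in enumerate(geno.accession_ids):
            alleles = " ".join(code[int(v)] for v in geno.calls[i])
            fh.write(f"{acc} {acc} 0 0 0 -9 {alleles}\n")


def write_vcf(geno: GenotypeMatrix, path: str) -> None:
    """Minimal VCF 4.2 with GT only (REF=B, ALT=A; counted allele = ALT)."""
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(geno.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(geno.accession_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in range(geno.n_markers):
            gts = "\t".join(gt_code[int(v)] for v in geno.calls[:, j])
            fh.write(
                f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.marker_ids[j]}"
                f"\tG\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_gff3(genes, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tgfblup-sim\tgene\t{g.orf_start}\t{g.orf_end}"
                f"\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_phenotypes(phenotypes: pd.DataFrame, path: str) -> None:
    cols = ["accession", "replicate", "timepoint", "x", "y",
            "image_position", "sowing_block", "value"]
    phenotypes[cols].to_csv(path, sep="\t", index=False)
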