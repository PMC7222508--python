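"""Synthetic multi-passage PDX cohorts with planted structure.

The generator emulates the study design the pipeline is built for:
five serial passages (generations g1..g5) with three replicate mice
each, whole-exome genotypes, gene and miRNA expression, miRNA->target
pairs, an immune gene list and caliper growth curves.  Every planted
signal is recorded in truth tables so that each pipeline stage can be
scored for recovery.

Layers
------
* Genotypes: each locus is neutral (constant latent frequency drawn
  uniformly) or selected (a latent frequency path sweeping monotonically
  from <= 1/3 to >= 2/3, or the mirror).  Latent paths live on the
  6-chromosome grid (multiples of 1/6), matching the granularity of the
  observed frequencies of a 3-mouse passage.  With ``noise_sd > 0`` each
  mouse's dosage is drawn Binomial(2, latent freq); with ``noise_sd = 0``
  the per-generation allele counts are allocated deterministically and
  trajectories are exact.
* Expression: log2(FPKM + 1) is baseline + planted effects + Gaussian
  noise (sd ``noise_sd``).  Planted DEGs get a monotone per-generation
  gradient; planted eQTL genes add ``eqtl_slope`` per alternate allele of
  their linked (selected) locus.
* miRNAs and pairs: a configurable number of pairs is planted with
  matching monotone trends in miRNA and target gene; the rest are flat.
* Growth: vehicle tumors grow exponentially from baselines uniform in
  [100, 300] mm^3; treatment endpoints are constructed so the expected
  TGI of each passage equals the configured response profile (default:
  the responsive-then-resistant profile 44.62, 43.93, -44.04, 7.42).

All randomness flows from ``SimConfig.seed`` through independent named
streams, so every layer is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneAnnotation,
    GenotypeMatrix,
    GrowthRecord,
    SampleSheet,
    write_bed,
    write_expression_tsv,
    write_gene_set,
    write_growth_csv,
    write_pairs_tsv,
    write_sample_sheet,
    write_vcf,
)

__all__ = [
    "SimConfig",
    "simulate_annotation",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_mirna_and_pairs",
    "simulate_growth",
    "simulate_cohort",
    "write_cohort",
]

_GENE_SPAN = 10_000  # bp tile per gene on the synthetic chromosome
_GENE_LEN = 5_000


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort; the seed is mandatory."""

    seed: int
    n_generations: int = 5
    n_replicates: int = 3
    n_loci: int = 2000
    frac_selected_up: float = 0.01
    frac_selected_down: float = 0.01
    n_genes: int = 500
    n_planted_degs: int = 30
    deg_effect_sd_units: float = 2.0
    n_eqtl_links: int = 15
    eqtl_slope: float = 2.0
    n_mirnas: int = 50
    n_target_pairs: int = 50
    n_concordant_pairs: int = 16
    n_immune_genes: int = 100
    n_immune_candidates: int = 10
    noise_sd: float = 0.1
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.0
    growth_baseline_mm3: tuple[float, float] = (100.0, 300.0)
    response_tgi_percent: tuple[float, ...] = (44.62, 43.93, -44.04, 7.42)
    passage_days: tuple[int, ...] = (21, 24, 35, 21)
    vehicle_endpoint_mm3: float = 1200.0

    def __post_init__(self) -> None:
        for frac in (self.frac_selected_up, self.frac_selected_down):
            if not 0 <= frac <= 1:
                raise ValueError("selected fractions must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_concordant_pairs > self.n_target_pairs:
            raise ValueError("n_concordant_pairs cannot exceed n_target_pairs")
        if self.n_immune_candidates > self.n_eqtl_links:
            raise ValueError("immune candidates are drawn from eQTL genes")
        if self.n_concordant_pairs > self.n_planted_degs:
            raise ValueError("concordant targets are drawn from planted DEGs")
        if self.n_target_pairs > self.n_mirnas:
            raise ValueError("each pair uses a distinct miRNA")
        if len(self.response_tgi_percent) != len(self.passage_days):
            raise ValueError("one endpoint day per response-profile entry")

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_replicates

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _gene_id(i: int) -> str:
    return f"gene{i + 1:04d}"


def simulate_annotation(cfg: SimConfig) -> list[GeneAnnotation]:
    """Tile ``n_genes`` non-overlapping genes along one chromosome."""
    return [
        GeneAnnotation(_gene_id(i), "chr1", i * _GENE_SPAN, i * _GENE_SPAN + _GENE_LEN)
        for i in range(cfg.n_genes)
    ]


def _monotone_counts(rng: np.random.Generator, cfg: SimConfig, up: bool) -> np.ndarray:
    """A monotone allele-count path on the 6-chromosome grid satisfying
    the boundary conditions of the trajectory filter."""
    six = cfg.n_chromosomes
    lo_max = six // 3  # counts <= 1/3
    hi_min = six - lo_max  # counts >= 2/3
    c1 = int(rng.integers(0, lo_max + 1))
    c5 = int(rng.integers(hi_min, six + 1))
    mids = np.sort(rng.integers(c1, c5 + 1, size=cfg.n_generations - 2))
    path = np.concatenate([[c1], mids, [c5]])
    return path if up else path[::-1]


def _allocate_dosages(count: int, n_samples: int) -> np.ndarray:
    """Greedy allocation of an allele count onto diploid samples."""
    out = np.zeros(n_samples)
    left = count
    for i in range(n_samples):
        d = min(2, left)
        out[i] = d
        left -= d
    return out


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Genotype matrix plus a truth table of each locus's class.

    The truth table columns are ``locus_id``, ``class`` (neutral /
    selected_up / selected_down), ``eqtl_gene`` (the linked gene id for
    the loci designated as eQTL sources, else empty) and the latent
    per-generation allele counts.
    """
    rng = cfg.rng(0)
    sheet = SampleSheet.default(cfg.n_generations, cfg.n_replicates)
    n_up = round(cfg.frac_selected_up * cfg.n_loci)
    n_down = round(cfg.frac_selected_down * cfg.n_loci)
    if cfg.n_eqtl_links > n_up + n_down:
        raise ValueError("n_eqtl_links exceeds the number of selected loci")
    classes = np.array(
        ["selected_up"] * n_up
        + ["selected_down"] * n_down
        + ["neutral"] * (cfg.n_loci - n_up - n_down)
    )
    rng.shuffle(classes)
    selected_idx = np.flatnonzero(classes != "neutral")
    eqtl_loci = rng.choice(selected_idx, size=cfg.n_eqtl_links, replace=False)
    eqtl_genes = rng.choice(cfg.n_genes, size=cfg.n_eqtl_links, replace=False)
    eqtl_gene_of = {int(l): int(g) for l, g in zip(eqtl_loci, eqtl_genes)}

    # positions: eQTL loci inside their linked gene; every other locus is
    # kept out of eQTL gene intervals so no second locus shares an eQTL
    # gene's expression signal (it falls in other genes or between genes)
    span = cfg.n_genes * _GENE_SPAN
    eqtl_tiles = set(int(g) for g in eqtl_genes)
    positions = np.zeros(cfg.n_loci, dtype=int)
    used: set[int] = set()
    for li, gi in eqtl_gene_of.items():
        pos = int(gi * _GENE_SPAN + rng.integers(0, _GENE_LEN)) + 1  # 1-based
        while pos in used:
            pos += 1
        used.add(pos)
        positions[li] = pos
    for li in range(cfg.n_loci):
        if positions[li]:
            continue
        while True:
            pos = int(rng.integers(0, span)) + 1
            tile, off = divmod(pos - 1, _GENE_SPAN)
            if pos not in used and not (tile in eqtl_tiles and off < _GENE_LEN):
                break
        used.add(pos)
        positions[li] = pos

    six = cfg.n_chromosomes
    dosages = np.zeros((cfg.n_loci, len(sheet)))
    latent_counts = np.zeros((cfg.n_loci, cfg.n_generations), dtype=int)
    for li in range(cfg.n_loci):
        if classes[li] == "neutral":
            p0 = rng.uniform(0.0, 1.0)
            latent_counts[li] = int(round(six * p0))
            latent_p = np.full(cfg.n_generations, p0)
        else:
            path = _monotone_counts(rng, cfg, up=classes[li] == "selected_up")
            latent_counts[li] = path
            latent_p = path / six
        for g in range(cfg.n_generations):
            cols = slice(g * cfg.n_replicates, (g + 1) * cfg.n_replicates)
            if cfg.noise_sd > 0:
                dosages[li, cols] = rng.binomial(2, latent_p[g], size=cfg.n_replicates)
            else:
                dosages[li, cols] = _allocate_dosages(
                    int(latent_counts[li, g]), cfg.n_replicates
                )

    order = np.argsort(positions)
    loci = pd.DataFrame(
        {
            "locus_id": [f"chr1:{positions[i]}:A:G" for i in order],
            "chrom": "chr1",
            "pos": positions[order],
            "ref": "A",
            "alt": "G",
        }
    )
    truth = pd.DataFrame(
        {
            "locus_id": loci["locus_id"].to_numpy(),
            "class": classes[order],
            "eqtl_gene": [
                _gene_id(eqtl_gene_of[i]) if i in eqtl_gene_of else ""
                for i in order
            ],
            **{
                f"latent_count_g{g + 1}": latent_counts[order, g]
                for g in range(cfg.n_generations)
            },
        }
    )
    return GenotypeMatrix(loci, dosages[order], sheet), truth


def simulate_expression(
    cfg: SimConfig, genotypes: GenotypeMatrix, truth_loci: pd.DataFrame
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Gene expression matrix (FPKM-like) plus the gene truth table.

    Planted DEGs receive a monotone per-generation gradient in log2
    space of ``deg_effect_sd_units`` noise SDs per generation step
    (at ``noise_sd = 0`` a reference SD of 0.5 log2-units keeps the
    planted structure non-trivial).  Planted eQTL genes add
    ``eqtl_slope`` log2-units per alternate allele of their linked
    locus.  DEG and eQTL gene sets are disjoint.
    """
    rng = cfg.rng(1)
    sheet = genotypes.sample_sheet
    eqtl_rows = truth_loci[truth_loci["eqtl_gene"] != ""]
    eqtl_gene_ids = list(eqtl_rows["eqtl_gene"])
    locus_of_gene = dict(zip(eqtl_rows["eqtl_gene"], eqtl_rows["locus_id"]))
    # DEG genes are drawn from genes hosting no selected locus: a sweeping
    # locus inside a generation-dependent gene would be a real (unplanted)
    # association and blur the truth tables
    selected = truth_loci.loc[truth_loci["class"] != "neutral", "locus_id"]
    swept_tiles = {
        (int(lid.split(":")[1]) - 1) // _GENE_SPAN for lid in selected
    }
    free = [
        g
        for g in range(cfg.n_genes)
        if _gene_id(g) not in set(eqtl_gene_ids) and g not in swept_tiles
    ]
    deg_gene_ids = [_gene_id(i) for i in rng.choice(free, cfg.n_planted_degs, False)]

    effect = cfg.deg_effect_sd_units * (cfg.noise_sd if cfg.noise_sd > 0 else 0.5)
    gen_idx = sheet.generation_index()
    gradient = (gen_idx - 1).astype(float)  # per-step gradient 0..4

    locus_row = {lid: i for i, lid in enumerate(genotypes.locus_ids)}
    n_samples = len(sheet)
    y = np.zeros((cfg.n_genes, n_samples))
    directions = {}
    for gi in range(cfg.n_genes):
        gid = _gene_id(gi)
        if gid in set(deg_gene_ids) or gid in locus_of_gene:
            base = rng.normal(cfg.baseline_log2_mean + 1.0, 0.5)
        else:
            base = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd)
        row = np.full(n_samples, base)
        if gid in locus_of_gene:
            dos = np.nan_to_num(genotypes.dosages[locus_row[locus_of_gene[gid]]])
            row = row + cfg.eqtl_slope * dos
        elif gid in set(deg_gene_ids):
            # the first n_concordant_pairs planted DEGs trend upward so
            # they can serve as concordant miRNA targets; the rest alternate
            k = deg_gene_ids.index(gid)
            direction = 1 if (k < cfg.n_concordant_pairs or k % 2 == 0) else -1
            directions[gid] = direction
            row = row + direction * effect * gradient
        if cfg.noise_sd > 0:
            row = row + rng.normal(0.0, cfg.noise_sd, size=n_samples)
        y[gi] = row
    fpkm = np.maximum(np.exp2(y) - 1.0, 0.0)
    values = pd.DataFrame(
        fpkm,
        index=[_gene_id(i) for i in range(cfg.n_genes)],
        columns=list(sheet.sample_ids),
    )
    expr = ExpressionMatrix(values, sheet, "gene")
    truth = pd.DataFrame(
        {
            "gene_id": [_gene_id(i) for i in range(cfg.n_genes)],
            "is_planted_deg": [
                _gene_id(i) in set(deg_gene_ids) for i in range(cfg.n_genes)
            ],
            "deg_direction": [
                directions.get(_gene_id(i), 0) for i in range(cfg.n_genes)
            ],
            "eqtl_locus": [
                locus_of_gene.get(_gene_id(i), "") for i in range(cfg.n_genes)
            ],
        }
    )
    return expr, truth


def simulate_mirna_and_pairs(
    cfg: SimConfig, truth_genes: pd.DataFrame
) -> tuple[ExpressionMatrix, list[tuple[str, str]], pd.DataFrame]:
    """miRNA matrix, miRNA->target pairs and the pair truth table.

    The first ``n_concordant_pairs`` pairs link an upward-trending miRNA
    to an upward-trending planted DEG (concordant under mode="same");
    the remaining pairs link flat miRNAs to non-trending genes.
    """
    rng = cfg.rng(2)
    sheet = SampleSheet.default(cfg.n_generations, cfg.n_replicates)
    gen_idx = sheet.generation_index()
    gradient = (gen_idx - 1).astype(float)
    effect = cfg.deg_effect_sd_units * (cfg.noise_sd if cfg.noise_sd > 0 else 0.5)

    mirna_ids = [f"mir{i + 1:03d}" for i in range(cfg.n_mirnas)]
    y = np.zeros((cfg.n_mirnas, len(sheet)))
    for mi in range(cfg.n_mirnas):
        base = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd / 2)
        row = np.full(len(sheet), base)
        if mi < cfg.n_concordant_pairs:
            row = row + effect * gradient
        if cfg.noise_sd > 0:
            row = row + rng.normal(0.0, cfg.noise_sd, size=len(sheet))
        y[mi] = row
    fpkm = np.maximum(np.exp2(y) - 1.0, 0.0)
    mirna = ExpressionMatrix(
        pd.DataFrame(fpkm, index=mirna_ids, columns=list(sheet.sample_ids)),
        sheet,
        "mirna",
    )

    up_degs = list(
        truth_genes.loc[
            (truth_genes["is_planted_deg"]) & (truth_genes["deg_direction"] > 0),
            "gene_id",
        ]
    )
    null_genes = list(
        truth_genes.loc[
            (~truth_genes["is_planted_deg"]) & (truth_genes["eqtl_locus"] == ""),
            "gene_id",
        ]
    )
    pairs: list[tuple[str, str]] = []
    planted: list[bool] = []
    for i in range(cfg.n_concordant_pairs):
        pairs.append((mirna_ids[i], up_degs[i]))
        planted.append(True)
    fillers = rng.choice(null_genes, cfg.n_target_pairs - cfg.n_concordant_pairs, False)
    for j, gene in enumerate(fillers):
        pairs.append((mirna_ids[cfg.n_concordant_pairs + j], str(gene)))
        planted.append(False)
    truth = pd.DataFrame(
        {
            "mirna_id": [m for m, _ in pairs],
            "gene_id": [g for _, g in pairs],
            "planted_concordant": planted,
        }
    )
    return mirna, pairs, truth


def simulate_immune_list(cfg: SimConfig, truth_genes: pd.DataFrame) -> set[str]:
    """Immune gene set: a planted subset of the eQTL target genes plus
    non-candidate decoys from the gene universe."""
    rng = cfg.rng(3)
    eqtl_genes = list(truth_genes.loc[truth_genes["eqtl_locus"] != "", "gene_id"])
    planted = [str(g) for g in rng.choice(eqtl_genes, cfg.n_immune_candidates, False)]
    decoy_pool = list(
        truth_genes.loc[
            (~truth_genes["is_planted_deg"]) & (truth_genes["eqtl_locus"] == ""),
            "gene_id",
        ]
    )
    n_decoys = max(cfg.n_immune_genes - cfg.n_immune_candidates, 0)
    decoys = [str(g) for g in rng.choice(decoy_pool, n_decoys, False)]
    return set(planted) | set(decoys)


def simulate_growth(cfg: SimConfig) -> list[GrowthRecord]:
    """Caliper growth curves for passages P2.. matching the TGI profile.

    Vehicle animals grow exponentially from their baseline to the
    configured endpoint volume; treatment growth is constructed so that
    the group-mean TGI at the endpoint day equals the profile value
    exactly when ``noise_sd = 0`` (multiplicative lognormal measurement
    noise otherwise).
    """
    rng = cfg.rng(4)
    records: list[GrowthRecord] = []
    n = cfg.n_replicates
    lo, hi = cfg.growth_baseline_mm3
    for pi, (tgi, endpoint) in enumerate(
        zip(cfg.response_tgi_percent, cfg.passage_days)
    ):
        passage = pi + 2  # profile covers P2..P5
        days = sorted(set(range(0, endpoint + 1, 7)) | {endpoint})
        vb = rng.uniform(lo, hi, size=n)
        tb = rng.uniform(lo, hi, size=n)
        # vehicle: exponential from baseline to the common endpoint volume
        v_end = np.full(n, cfg.vehicle_endpoint_mm3)
        mean_vehicle_growth = float(v_end.mean() - vb.mean())
        t_growth = (1.0 - tgi / 100.0) * mean_vehicle_growth
        t_end = tb + t_growth
        if (t_end < 0).any():
            raise ValueError("response profile drives treatment volume negative")
        for group, base, end in (("vehicle", vb, v_end), ("treatment", tb, t_end)):
            for a in range(n):
                for day in days:
                    if group == "vehicle":
                        vol = base[a] * (end[a] / base[a]) ** (day / endpoint)
                    else:
                        vol = base[a] + (end[a] - base[a]) * day / endpoint
                    if day > 0 and cfg.noise_sd > 0:
                        vol *= float(np.exp(rng.normal(0.0, cfg.noise_sd)))
                    records.append(
                        GrowthRecord(
                            animal_id=f"P{passage}-{group[0].upper()}{a + 1}",
                            group=group,
                            day=day,
                            volume_mm3=float(vol),
                        )
                    )
    return records


#: the canonical selected-allele sweep on the 6-chromosome grid:
#: frequencies 0, 1/6, 2/6, 2/6, 4/6 across g1..g5
CANONICAL_SWEEP_COUNTS = (0, 1, 2, 2, 4)


def sweep_genotypes(
    counts: tuple[int, ...] = CANONICAL_SWEEP_COUNTS,
    n_replicates: int = 3,
    locus_id: str = "chr1:1000:A:G",
) -> GenotypeMatrix:
    """A 1-locus cohort whose per-generation alternate-allele counts are
    exactly ``counts``, allocated greedily onto diploid samples."""
    sheet = SampleSheet.default(len(counts), n_replicates)
    dosages = np.concatenate(
        [_allocate_dosages(c, n_replicates) for c in counts]
    )[None, :]
    chrom, pos, ref, alt = locus_id.split(":")
    loci = pd.DataFrame(
        [
            {
                "locus_id": locus_id,
                "chrom": chrom,
                "pos": int(pos),
                "ref": ref,
                "alt": alt,
            }
        ]
    )
    return GenotypeMatrix(loci, dosages, sheet)


def passage_of_animal(animal_id: str) -> int:
    """Passage number encoded in simulated animal ids like ``P4-T2``."""
    return int(animal_id.split("-")[0].lstrip("P"))


@dataclass
class Cohort:
    """One fully simulated multi-omic cohort with its truth tables."""

    config: SimConfig
    sample_sheet: SampleSheet
    genotypes: GenotypeMatrix
    gene_expr: ExpressionMatrix
    mirna_expr: ExpressionMatrix
    annotation: list[GeneAnnotation]
    pairs: list[tuple[str, str]]
    immune_genes: set[str]
    growth: list[GrowthRecord]
    truth_loci: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_pairs: pd.DataFrame
    truth_immune: set[str] = field(default_factory=set)


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate every layer of a cohort under one seed."""
    genotypes, truth_loci = simulate_genotypes(cfg)
    gene_expr, truth_genes = simulate_expression(cfg, genotypes, truth_loci)
    mirna_expr, pairs, truth_pairs = simulate_mirna_and_pairs(cfg, truth_genes)
    immune = simulate_immune_list(cfg, truth_genes)
    eqtl_genes = set(truth_genes.loc[truth_genes["eqtl_locus"] != "", "gene_id"])
    return Cohort(
        config=cfg,
        sample_sheet=genotypes.sample_sheet,
        genotypes=genotypes,
        gene_expr=gene_expr,
        mirna_expr=mirna_expr,
        annotation=simulate_annotation(cfg),
        pairs=pairs,
        immune_genes=immune,
        growth=simulate_growth(cfg),
        truth_loci=truth_loci,
        truth_genes=truth_genes,
        truth_pairs=truth_pairs,
        truth_immune=immune & eqtl_genes,
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write every cohort layer to disk in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sample_sheet": outdir / "samples.tsv",
        "vcf": outdir / "variants.vcf",
        "gene_expr": outdir / "genes.tsv",
        "mirna_expr": outdir / "mirna.tsv",
        "annotation": outdir / "genes.bed",
        "pairs": outdir / "pairs.tsv",
        "immune": outdir / "immune.txt",
        "growth": outdir / "growth.csv",
        "truth_loci": outdir / "truth_loci.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_pairs": outdir / "truth_pairs.tsv",
    }
    write_sample_sheet(cohort.sample_sheet, paths["sample_sheet"])
    write_vcf(cohort.genotypes, paths["vcf"])
    write_expression_tsv(cohort.gene_expr, paths["gene_expr"])
    write_expression_tsv(cohort.mirna_expr, paths["mirna_expr"])
    write_bed(cohort.annotation, paths["annotation"])
    write_pairs_tsv(cohort.pairs, paths["pairs"])
    write_gene_set(cohort.immune_genes, paths["immune"])
    write_growth_csv(cohort.growth, paths["growth"])
    cohort.truth_loci.to_csv(paths["truth_loci"], sep="\t", index=False)
    cohort.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    cohort.truth_pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)
    return paths
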