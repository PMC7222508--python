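"""Joint analysis of the variant and expression layers.

Filter-passing loci are mapped to the genes whose intervals contain
them, each (locus, gene) pair is tested for an eQTL-style association
between alternate-allele dosage and expression, the candidate genes are
intersected with an immune gene set, and miRNA/target pairs are scored
for concordant temporal trends across passages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exprdyn import TrendCall, trend_classify
from .io import ExpressionMatrix, GeneAnnotation, GenotypeMatrix

__all__ = [
    "LocusGenePair",
    "AssociationRecord",
    "MirTargetPair",
    "map_loci_to_genes",
    "genotype_expression_association",
    "associate_pairs",
    "select_candidates",
    "immune_intersection",
    "mirna_target_concordance",
]

_P_DEGENERATE = 5e-324


@dataclass(frozen=True)
class LocusGenePair:
    locus_id: str
    gene_id: str
    relation: str = "contained"


@dataclass(frozen=True)
class AssociationRecord:
    """Additive-model association between one locus and one gene."""

    locus_id: str
    gene_id: str
    slope: float  # log2-expression units per alt allele
    f_stat: float
    p_value: float
    n_used: int
    degenerate: bool = False


@dataclass(frozen=True)
class MirTargetPair:
    mirna_id: str
    gene_id: str
    concordant: bool
    mirna_trend: TrendCall
    gene_trend: TrendCall


def map_loci_to_genes(
    g: GenotypeMatrix, annotation: Sequence[GeneAnnotation]
) -> tuple[list[LocusGenePair], int]:
    """Map each locus to every gene whose interval contains it.

    A locus inside two overlapping genes yields two pairs; loci inside
    no gene are dropped, and their count is returned alongside.
    """
    pairs: list[LocusGenePair] = []
    unmapped = 0
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for ann in annotation:
        by_chrom.setdefault(ann.chrom, []).append(ann)
    for row in g.loci.itertuples(index=False):
        hits = [
            ann
            for ann in by_chrom.get(row.chrom, ())
            if ann.contains(row.chrom, row.pos)
        ]
        if not hits:
            unmapped += 1
        for ann in hits:
            pairs.append(LocusGenePair(row.locus_id, ann.gene_id))
    return pairs, unmapped


def genotype_expression_association(
    dosages: np.ndarray,
    expression: np.ndarray,
    locus_id: str = "",
    gene_id: str = "",
    log_transform: bool = True,
) -> AssociationRecord | None:
    """Simple linear regression of expression on additive dosage.

    Expression is log2(x + 1)-transformed by default; samples with a
    missing genotype are dropped.  The P value is the F-test of the
    regression (equivalently the two-sided t-test of the slope).
    Returns None when the locus is monomorphic among the usable samples
    or fewer than three samples remain.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(expression, dtype=float)
    ok = ~np.isnan(d)
    d, y = d[ok], y[ok]
    if log_transform:
        y = np.log2(y + 1.0)
    if len(d) < 3 or len(np.unique(d)) < 2:
        return None
    if np.all(y == y[0]):  # constant expression: no signal (ulp-safe check)
        return AssociationRecord(locus_id, gene_id, 0.0, 0.0, 1.0, len(d))
    n = len(d)
    # least squares on [1, dosage]
    dm = d - d.mean()
    ym = y - y.mean()
    sxx = float((dm**2).sum())
    slope = float((dm * ym).sum()) / sxx
    ss_tot = float((ym**2).sum())
    ss_res = float(((ym - slope * dm) ** 2).sum())
    df_res = n - 2
    if ss_tot == 0.0:
        # expression constant: no association signal at all
        return AssociationRecord(locus_id, gene_id, 0.0, 0.0, 1.0, n)
    # residuals at the rounding floor (~1e-32 relative, squared) are a
    # perfect fit, not a finite F statistic
    if ss_res <= 1e-20 * ss_tot:
        return AssociationRecord(
            locus_id, gene_id, slope, float("inf"), _P_DEGENERATE, n, degenerate=True
        )
    f = (ss_tot - ss_res) / (ss_res / df_res)
    p = float(stats.f.sf(f, 1, df_res))
    return AssociationRecord(locus_id, gene_id, slope, float(f), max(p, _P_DEGENERATE), n)


def associate_pairs(
    g: GenotypeMatrix,
    e: ExpressionMatrix,
    pairs: Sequence[LocusGenePair],
    log_transform: bool = True,
) -> tuple[list[AssociationRecord], list[tuple[LocusGenePair, str]]]:
    """Run the association test for every (locus, gene) pair.

    Pairs whose gene is absent from the expression matrix (e.g. removed
    by the presence filter) or whose locus is monomorphic are skipped;
    the skipped pairs are returned with a reason.
    """
    locus_row = {lid: i for i, lid in enumerate(g.locus_ids)}
    records: list[AssociationRecord] = []
    skipped: list[tuple[LocusGenePair, str]] = []
    for pair in pairs:
        if pair.gene_id not in e.values.index:
            skipped.append((pair, "gene not in expression matrix"))
            continue
        if pair.locus_id not in locus_row:
            skipped.append((pair, "locus not in genotype matrix"))
            continue
        rec = genotype_expression_association(
            g.dosages[locus_row[pair.locus_id]],
            e.values.loc[pair.gene_id].to_numpy(dtype=float),
            locus_id=pair.locus_id,
            gene_id=pair.gene_id,
            log_transform=log_transform,
        )
        if rec is None:
            skipped.append((pair, "monomorphic or too few callable samples"))
        else:
            records.append(rec)
    return records, skipped


def select_candidates(
    records: Sequence[AssociationRecord], alpha: float = 0.01
) -> tuple[list[str], list[str]]:
    """Loci with association P < alpha and the de-duplicated gene list.

    Several loci can sit in one gene, so the gene list is never longer
    than the locus list.
    """
    if not records:
        raise ValueError("no association records")
    hits = sorted(
        (r for r in records if r.p_value < alpha),
        key=lambda r: (r.p_value, r.locus_id, r.gene_id),
    )
    loci = []
    genes = []
    for r in hits:
        loci.append(r.locus_id)
        if r.gene_id not in genes:
            genes.append(r.gene_id)
    return loci, genes


def immune_intersection(candidate_genes: set[str], immune_genes: set[str]) -> list[str]:
    """Candidate genes that are also in the immune set, lexically sorted."""
    return sorted(set(candidate_genes) & set(immune_genes))


def mirna_target_concordance(
    mirna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
    mode: str = "same",
    alpha: float = 0.05,
) -> tuple[list[MirTargetPair], list[tuple[tuple[str, str], str]]]:
    """Score miRNA/target pairs for concordant temporal trends.

    Both members are trend-classified against the passage index; a pair
    is concordant when both trends are non-none and equal (mode="same")
    or opposite (mode="inverse", the canonical repression expectation).
    Pairs with a member absent from its matrix are skipped with a reason.
    """
    if mode not in ("same", "inverse"):
        raise ValueError(f"unknown concordance mode {mode!r}")
    groups = gene_expr.sample_sheet.generation_index()
    out: list[MirTargetPair] = []
    skipped: list[tuple[tuple[str, str], str]] = []
    for mirna_id, gene_id in pairs:
        if mirna_id not in mirna_expr.values.index:
            skipped.append(((mirna_id, gene_id), "miRNA not in matrix"))
            continue
        if gene_id not in gene_expr.values.index:
            skipped.append(((mirna_id, gene_id), "gene not in matrix"))
            continue
        mt = trend_classify(
            mirna_expr.values.loc[mirna_id].to_numpy(dtype=float),
            mirna_expr.sample_sheet.generation_index(),
            alpha=alpha,
            feature_id=mirna_id,
        )
        gt = trend_classify(
            gene_expr.values.loc[gene_id].to_numpy(dtype=float),
            groups,
            alpha=alpha,
            feature_id=gene_id,
        )
        both = mt.trend != "none" and gt.trend != "none"
        if mode == "same":
            conc = both and mt.trend == gt.trend
        else:
            conc = both and mt.trend != gt.trend
        out.append(MirTargetPair(mirna_id, gene_id, conc, mt, gt))
    return out, skipped
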