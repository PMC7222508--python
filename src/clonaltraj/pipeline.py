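"""End-to-end orchestration: growth -> variant trajectories -> expression
dynamics -> multi-omic integration, from a single config to a
machine-readable report.

Stage outputs are written to disk as TSV/JSON and are the sole
interface between stages; re-running a later stage alone reproduces its
output from the files.  The report records the counts at every stage,
the config hash and the seed, so a run is reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import exprdyn, growth as growth_mod, integrate, io, vartraj
from .simgen import passage_of_animal

logger = logging.getLogger("clonaltraj")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    sample_sheet: str
    vcf: str
    gene_expr: str
    mirna_expr: str
    annotation: str
    pairs: str
    immune: str
    growth: str
    outdir: str
    seed: int = 0
    presence_threshold: float = 5.0
    mirna_presence_threshold: float = 1.0
    deg_alpha: float = 0.05
    deg_alpha_strict: float = 0.001
    association_alpha: float = 0.01
    maf_low: float = 1.0 / 3.0
    maf_high: float = 2.0 / 3.0
    resistance_threshold: float = 30.0
    mds_k: int = 4
    concordance_mode: str = "same"

    def __post_init__(self) -> None:
        for name in ("deg_alpha", "deg_alpha_strict", "association_alpha"):
            a = getattr(self, name)
            if not 0 <= a <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.maf_low < self.maf_high <= 1:
            raise ValueError("need 0 <= maf_low < maf_high <= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the analysis-relevant settings (the output directory
        does not change what is computed)."""
        d = asdict(self)
        d.pop("outdir")
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _growth_stage(cfg: RunConfig, outdir: Path) -> dict:
    records = io.read_growth_csv(cfg.growth)
    by_passage: dict[int, list[io.GrowthRecord]] = {}
    for r in records:
        try:
            p = passage_of_animal(r.animal_id)
        except (ValueError, IndexError):
            p = 0  # unlabelled cohort: single comparison
        by_passage.setdefault(p, []).append(r)
    rows = []
    for p in sorted(by_passage):
        recs = by_passage[p]
        days = sorted({r.day for r in recs})
        baseline, endpoint = days[0], days[-1]
        comp = growth_mod.comparison_from_records(recs, baseline, endpoint)
        eff = growth_mod.efficacy(comp)
        mean_t, sd_t, n_t = growth_mod.group_summary(recs, "treatment", endpoint)
        mean_v, sd_v, n_v = growth_mod.group_summary(recs, "vehicle", endpoint)
        rows.append(
            {
                "passage": p,
                "day": endpoint,
                "treatment_mean_mm3": mean_t,
                "treatment_sd_mm3": sd_t,
                "vehicle_mean_mm3": mean_v,
                "vehicle_sd_mm3": sd_v,
                "t_over_c_percent": eff.t_over_c_percent,
                "tgi_percent": eff.tgi_percent,
                "call": growth_mod.resistance_call(eff, cfg.resistance_threshold),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "growth_efficacy.tsv", sep="\t", index=False)
    return {
        "n_records": len(records),
        "per_passage": rows,
    }


def _vartraj_stage(cfg: RunConfig, sheet: io.SampleSheet, outdir: Path) -> dict:
    from fractions import Fraction

    geno = io.read_vcf(cfg.vcf, sheet)
    trajectories = vartraj.per_generation_maf(geno)
    low = Fraction(cfg.maf_low).limit_denominator(10**6)
    high = Fraction(cfg.maf_high).limit_denominator(10**6)
    rows = []
    passing = []
    n_undefined = 0
    for t in trajectories:
        if not t.defined:
            n_undefined += 1
            continue
        v = vartraj.trajectory_filter(t, low, high)
        if v.passes:
            passing.append(t.locus_id)
        rows.append(
            {
                "locus_id": t.locus_id,
                **{f"g{i + 1}_freq": f for i, f in enumerate(t.freqs)},
                "passes": v.passes,
                "direction": v.direction,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "trajectories.tsv", sep="\t", index=False)

    d_all = vartraj.hamming_distance(geno)
    emb_all = vartraj.classical_mds(d_all, k=cfg.mds_k)
    result = {
        "n_variants": geno.n_loci,
        "n_undefined": n_undefined,
        "n_passing": len(passing),
        "passing_loci": passing,
        "separation_all": vartraj.separation_score(emb_all, sheet, {5}),
    }
    if len(passing) >= 2:
        d_f = vartraj.hamming_distance(geno, scope_locus_ids=passing)
        emb_f = vartraj.classical_mds(d_f, k=cfg.mds_k)
        result["separation_filtered"] = vartraj.separation_score(emb_f, sheet, {5})
        coords = pd.DataFrame(
            emb_f.coords,
            index=list(emb_f.sample_ids),
            columns=[f"C{i + 1}" for i in range(emb_f.coords.shape[1])],
        )
        coords.to_csv(outdir / "mds_filtered.tsv", sep="\t", index_label="sample_id")
        np.savetxt(outdir / "mds_eigenvalues.tsv", emb_f.eigenvalues)
    return result


def _exprdyn_stage(cfg: RunConfig, sheet: io.SampleSheet, outdir: Path) -> dict:
    out = {}
    for kind, path, thr in (
        ("gene", cfg.gene_expr, cfg.presence_threshold),
        ("mirna", cfg.mirna_expr, cfg.mirna_presence_threshold),
    ):
        e = io.read_expression_tsv(path, sheet, kind)
        kept = exprdyn.presence_filter(e, thr)
        results = exprdyn.anova_table(kept)
        degs = exprdyn.select_degs(results, cfg.deg_alpha) if results else []
        degs_strict = (
            exprdyn.select_degs(results, cfg.deg_alpha_strict) if results else []
        )
        table = pd.DataFrame(
            {
                "feature_id": [r.feature_id for r in results],
                "f_stat": [r.f_stat for r in results],
                "p_value": [r.p_value for r in results],
                "degenerate": [r.degenerate or "" for r in results],
            }
        )
        table.to_csv(outdir / f"anova_{kind}.tsv", sep="\t", index=False)
        cluster_features = degs_strict if len(degs_strict) >= 2 else degs
        info = {
            "n_features": e.n_features,
            "n_expressed": kept.n_features,
            "n_degs": len(degs),
            "n_degs_strict": len(degs_strict),
            "degs": degs,
            "degs_strict": degs_strict,
        }
        if len(cluster_features) >= 2:
            assignment, _, degenerate = exprdyn.cluster_samples(kept, cluster_features)
            pd.Series(assignment, name="cluster").to_csv(
                outdir / f"clusters_{kind}.tsv", sep="\t", index_label="sample_id"
            )
            info["clusters"] = assignment
            info["cluster_degenerate"] = degenerate
        out[kind] = info
    return out


def _integrate_stage(
    cfg: RunConfig, sheet: io.SampleSheet, passing_loci: list[str], outdir: Path
) -> dict:
    geno = io.read_vcf(cfg.vcf, sheet).subset_loci(passing_loci)
    ann = io.read_bed(cfg.annotation)
    pairs, n_unmapped = integrate.map_loci_to_genes(geno, ann)
    gene_e = exprdyn.presence_filter(
        io.read_expression_tsv(cfg.gene_expr, sheet, "gene"), cfg.presence_threshold
    )
    records, skipped = integrate.associate_pairs(geno, gene_e, pairs)
    if records:
        loci, genes = integrate.select_candidates(records, cfg.association_alpha)
    else:
        loci, genes = [], []
    pd.DataFrame(
        {
            "locus_id": [r.locus_id for r in records],
            "gene_id": [r.gene_id for r in records],
            "slope": [r.slope for r in records],
            "f_stat": [r.f_stat for r in records],
            "p_value": [r.p_value for r in records],
            "n_used": [r.n_used for r in records],
        }
    ).to_csv(outdir / "associations.tsv", sep="\t", index=False)

    immune = io.read_gene_set(cfg.immune) if Path(cfg.immune).exists() else set()
    overlap = integrate.immune_intersection(set(genes), immune)

    mirna_e = exprdyn.presence_filter(
        io.read_expression_tsv(cfg.mirna_expr, sheet, "mirna"),
        cfg.mirna_presence_threshold,
    )
    target_pairs = io.read_pairs_tsv(cfg.pairs)
    conc, conc_skipped = integrate.mirna_target_concordance(
        mirna_e, gene_e, target_pairs, mode=cfg.concordance_mode
    )
    pd.DataFrame(
        {
            "mirna_id": [c.mirna_id for c in conc],
            "gene_id": [c.gene_id for c in conc],
            "mirna_trend": [c.mirna_trend.trend for c in conc],
            "gene_trend": [c.gene_trend.trend for c in conc],
            "concordant": [c.concordant for c in conc],
        }
    ).to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    return {
        "n_locus_gene_pairs": len(pairs),
        "n_unmapped_loci": n_unmapped,
        "n_associations": len(records),
        "n_skipped_pairs": len(skipped),
        "candidate_loci": loci,
        "candidate_genes": genes,
        "n_candidate_loci": len(loci),
        "n_candidate_genes": len(genes),
        "immune_overlap": overlap,
        "n_immune_overlap": len(overlap),
        "n_target_pairs_scored": len(conc),
        "concordant_pairs": [[c.mirna_id, c.gene_id] for c in conc if c.concordant],
        "n_concordant_pairs": sum(c.concordant for c in conc),
    }


def run_all(cfg: RunConfig) -> dict:
    """Execute all stages in order and write the run report.

    Any stage failure aborts with the stage name; outputs of earlier
    stages stay on disk.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sheet = io.read_sample_sheet(cfg.sample_sheet)
    report: dict = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "stages": {},
    }
    stages = (
        ("growth", lambda: _growth_stage(cfg, outdir)),
        ("vartraj", lambda: _vartraj_stage(cfg, sheet, outdir)),
        ("exprdyn", lambda: _exprdyn_stage(cfg, sheet, outdir)),
    )
    for name, fn in stages:
        logger.info("running stage %s", name)
        try:
            report["stages"][name] = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    try:
        report["stages"]["integrate"] = _integrate_stage(
            cfg, sheet, report["stages"]["vartraj"]["passing_loci"], outdir
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'integrate' failed: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_summary(report, outdir / "report.txt")
    return report


def _write_summary(report: dict, path: Path) -> None:
    s = report["stages"]
    lines = [
        f"config {report['config_digest']} seed {report['seed']}",
        f"variants: {s['vartraj']['n_variants']} in, "
        f"{s['vartraj']['n_passing']} passing the trajectory filter",
        f"genes: {s['exprdyn']['gene']['n_expressed']} expressed, "
        f"{s['exprdyn']['gene']['n_degs']} DEGs, "
        f"{s['exprdyn']['gene']['n_degs_strict']} strict DEGs",
        f"candidates: {s['integrate']['n_candidate_loci']} loci on "
        f"{s['integrate']['n_candidate_genes']} genes; "
        f"{s['integrate']['n_immune_overlap']} immune; "
        f"{s['integrate']['n_concordant_pairs']} concordant miRNA pairs",
    ]
    for row in s["growth"]["per_passage"]:
        lines.append(
            f"passage P{row['passage']}: TGI {row['tgi_percent']:.2f}% "
            f"({row['call']})"
        )
    path.write_text("\n".join(lines) + "\n")
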