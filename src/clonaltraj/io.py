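"""Readers, writers and the shared data model.

The pipeline ingests a multi-sample VCF of called variants, gene- and
miRNA-level expression matrices (TSV, features x samples), a BED gene
annotation, a plain-text gene set, a two-column miRNA->target pair list
and a CSV of caliper measurements.  Everything is validated into a small
set of in-memory containers shared by the analysis stages.

Conventions
-----------
* VCF coordinates are 1-based; internal annotation intervals are 0-based
  half-open.  The conversion happens exactly once, at read time.
* Diploid genotypes are encoded as alternate-allele dosage 0/1/2 with
  ``NaN`` for missing calls; multi-allelic records are split per alt
  allele, the locus id suffixed with the allele.
* All writers emit a deterministic column order.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleSheet",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "GeneAnnotation",
    "GrowthRecord",
    "ConfigurationError",
    "FormatError",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_vcf",
    "write_vcf",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_growth_csv",
    "write_growth_csv",
    "read_gene_set",
    "write_gene_set",
    "read_bed",
    "write_bed",
    "read_pairs_tsv",
    "write_pairs_tsv",
]


class ConfigurationError(ValueError):
    """Inputs are individually well-formed but mutually inconsistent."""


class FormatError(ValueError):
    """A file violates its format contract."""


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSheet:
    """Assignment of each sample to a passage generation and replicate.

    The study design is five serial passages (generations g1..g5) with
    three replicate mice sequenced per passage: 15 samples in total.
    """

    sample_ids: tuple[str, ...]
    generations: tuple[int, ...]
    replicates: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ConfigurationError("sample ids must be unique")
        if not (len(self.sample_ids) == len(self.generations) == len(self.replicates)):
            raise ConfigurationError("sample sheet columns must be equal length")
        for g in self.generations:
            if not 1 <= g <= 5:
                raise ConfigurationError(f"generation {g} outside 1..5")
        counts = {}
        for g in self.generations:
            counts[g] = counts.get(g, 0) + 1
        if len(set(counts.values())) > 1:
            raise ConfigurationError(
                f"unbalanced design: replicate counts per generation {counts}"
            )

    @classmethod
    def default(cls, n_generations: int = 5, n_replicates: int = 3) -> "SampleSheet":
        """The canonical 5x3 design with ids g{G}r{R}."""
        ids, gens, reps = [], [], []
        for g in range(1, n_generations + 1):
            for r in range(1, n_replicates + 1):
                ids.append(f"g{g}r{r}")
                gens.append(g)
                reps.append(r)
        return cls(tuple(ids), tuple(gens), tuple(reps))

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_generations(self) -> int:
        return len(set(self.generations))

    def generation_of(self, sample_id: str) -> int:
        return self.generations[self.sample_ids.index(sample_id)]

    def generation_index(self) -> np.ndarray:
        """Generation label per sample, aligned with ``sample_ids``."""
        return np.asarray(self.generations, dtype=int)

    def samples_of_generation(self, g: int) -> list[str]:
        return [s for s, gg in zip(self.sample_ids, self.generations) if gg == g]

    def reordered(self, sample_ids: Sequence[str]) -> "SampleSheet":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return SampleSheet(
            tuple(self.sample_ids[i] for i in idx),
            tuple(self.generations[i] for i in idx),
            tuple(self.replicates[i] for i in idx),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "generation": self.generations,
                "replicate": self.replicates,
            }
        )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "generation", "replicate"):
        if col not in df.columns:
            raise FormatError(f"sample sheet missing column {col!r}")
    return SampleSheet(
        tuple(df["sample_id"].astype(str)),
        tuple(int(g) for g in df["generation"]),
        tuple(int(r) for r in df["replicate"]),
    )


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Loci x samples alternate-allele dosages with sample metadata.

    ``dosages`` is a float array with values in {0, 1, 2} and NaN for
    missing calls; ``loci`` carries chrom/pos/ref/alt per row and the
    derived unique ``locus_id`` (chrom:pos:ref:alt).
    """

    loci: pd.DataFrame  # columns: locus_id, chrom, pos (1-based), ref, alt
    dosages: np.ndarray  # (n_loci, n_samples) float, NaN = missing
    sample_sheet: SampleSheet

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.loci), len(self.sample_sheet)):
            raise ConfigurationError("dosage matrix shape mismatch")
        if self.loci["locus_id"].duplicated().any():
            dup = self.loci.loc[self.loci["locus_id"].duplicated(), "locus_id"].iloc[0]
            raise FormatError(f"duplicate locus id {dup!r}")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise FormatError("dosages must be 0, 1, 2 or missing")

    @property
    def locus_ids(self) -> list[str]:
        return list(self.loci["locus_id"])

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset_loci(self, locus_ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = set(locus_ids)
        mask = self.loci["locus_id"].isin(wanted).to_numpy()
        return GenotypeMatrix(
            self.loci.loc[mask].reset_index(drop=True),
            self.dosages[mask],
            self.sample_sheet,
        )


def _parse_gt(gt: str, record_id: str) -> list[int]:
    alleles = gt.replace("|", "/").split("/")
    if len(alleles) != 2:
        raise FormatError(f"non-diploid GT {gt!r} at {record_id}")
    out = []
    for a in alleles:
        out.append(-1 if a == "." else int(a))
    return out


def read_vcf(path: str | Path, sample_sheet: SampleSheet) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Diploid GT fields are parsed to alt-allele dosage (0/0 -> 0, 0/1 or
    1/0 -> 1, 1/1 -> 2, ./. -> missing); phased separators are accepted.
    Multi-allelic records are split into one row per alt allele with the
    locus id carrying that allele.  Columns are reordered to the sample
    sheet's order regardless of the on-disk order.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    header_samples = list(vcf.samples)
    missing = [s for s in sample_sheet.sample_ids if s not in header_samples]
    if missing:
        raise ConfigurationError(f"samples absent from VCF header: {missing}")
    col_idx = [header_samples.index(s) for s in sample_sheet.sample_ids]

    rows = []
    dosage_rows: list[np.ndarray] = []
    for rec in vcf:
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        alleles = []
        for s_i, gt in enumerate(gts):
            if len(gt) != 3:  # cyvcf2: [a0, a1, phased] for diploid
                raise FormatError(
                    f"non-diploid GT for sample {header_samples[s_i]!r} "
                    f"at {rec.CHROM}:{rec.POS}"
                )
            alleles.append((gt[0], gt[1]))
        for alt_i, alt in enumerate(rec.ALT, start=1):
            row_dos = np.full(len(sample_sheet), np.nan)
            for out_j, in_j in enumerate(col_idx):
                a0, a1 = alleles[in_j]
                if a0 < 0 or a1 < 0:
                    continue
                row_dos[out_j] = float((a0 == alt_i) + (a1 == alt_i))
            locus_id = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            rows.append(
                {
                    "locus_id": locus_id,
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": alt,
                }
            )
            dosage_rows.append(row_dos)
    vcf.close()
    loci = pd.DataFrame(rows, columns=["locus_id", "chrom", "pos", "ref", "alt"])
    dosages = (
        np.vstack(dosage_rows) if dosage_rows else np.empty((0, len(sample_sheet)))
    )
    return GenotypeMatrix(loci, dosages, sample_sheet)


_DOSAGE_TO_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT fields reproducing the dosages.

    Split multi-allelic rows are written as independent biallelic
    records; heterozygous calls are emitted as ``0/1``.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = g.loci["chrom"].drop_duplicates()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_sheet.sample_ids)
            + "\n"
        )
        for i, row in enumerate(g.loci.itertuples(index=False)):
            gts = [
                "./." if math.isnan(d) else _DOSAGE_TO_GT[d] for d in g.dosages[i]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.locus_id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Features x samples non-negative abundances (FPKM-like units)."""

    values: pd.DataFrame  # index: feature ids; columns: sample ids
    sample_sheet: SampleSheet
    feature_kind: str = "gene"  # or "mirna"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("gene", "mirna"):
            raise ConfigurationError(f"unknown feature kind {self.feature_kind!r}")
        if list(self.values.columns) != list(self.sample_sheet.sample_ids):
            raise ConfigurationError("expression columns must match sample sheet order")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise FormatError("expression values must be finite")
        if (arr < 0).any():
            raise FormatError("expression values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_features(self) -> int:
        return len(self.values)

    def subset(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [f for f in self.feature_ids if f in set(feature_ids)]
        return ExpressionMatrix(
            self.values.loc[keep], self.sample_sheet, self.feature_kind
        )


def read_expression_tsv(
    path: str | Path, sample_sheet: SampleSheet, kind: str = "gene"
) -> ExpressionMatrix:
    """Read a features-x-samples TSV; first column is the feature id.

    Columns are reordered to the sample sheet order, so any on-disk
    sample order yields an identical matrix.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    missing = [s for s in sample_sheet.sample_ids if s not in df.columns]
    if missing:
        raise ConfigurationError(f"samples absent from expression matrix: {missing}")
    df = df[list(sample_sheet.sample_ids)]
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric expression cell: {exc}") from exc
    return ExpressionMatrix(df, sample_sheet, kind)


def write_expression_tsv(e: ExpressionMatrix, path: str | Path) -> None:
    e.values.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# gene annotation (BED)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval; 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """Positional containment of a 1-based variant coordinate."""
        return self.chrom == chrom and self.start <= pos_1based - 1 < self.end


def read_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED(6) annotation; columns beyond the 6th are ignored."""
    out = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"BED line with <4 columns: {line!r}")
            chrom, start, end, name = parts[:4]
            strand = parts[5] if len(parts) >= 6 else "."
            if name in seen:
                raise FormatError(f"duplicate gene id {name!r} in BED")
            seen.add(name)
            out.append(GeneAnnotation(name, chrom, int(start), int(end), strand))
    return out


def write_bed(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# gene sets and pair lists
# ---------------------------------------------------------------------------


def read_gene_set(path: str | Path) -> set[str]:
    """One id per line; '#' comments and blank lines skipped; de-duplicated."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.add(line)
    if not out:
        warnings.warn(f"gene set {path} is empty", stacklevel=2)
    return out


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(g + "\n")


def read_pairs_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Two-column miRNA -> target gene pair list (header optional)."""
    pairs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"pair line with <2 columns: {line!r}")
            if i == 0 and parts[0].lower() in ("mirna", "mirna_id"):
                continue
            pairs.append((parts[0], parts[1]))
    return pairs


def write_pairs_tsv(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tgene_id\n")
        for m, g in pairs:
            fh.write(f"{m}\t{g}\n")


# ---------------------------------------------------------------------------
# growth records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthRecord:
    """One caliper measurement of one animal on one study day."""

    animal_id: str
    group: str  # "treatment" or "vehicle"
    day: int
    volume_mm3: float
    length_mm: float | None = None
    width_mm: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("treatment", "vehicle"):
            raise FormatError(f"unknown group label {self.group!r}")
        if self.volume_mm3 < 0:
            raise FormatError("tumor volume must be non-negative")
        if self.length_mm is not None and self.width_mm is not None:
            expected = self.length_mm * self.width_mm**2 / 2.0
            if abs(expected - self.volume_mm3) > 1e-9:
                raise FormatError(
                    f"animal {self.animal_id} day {self.day}: volume "
                    f"{self.volume_mm3} inconsistent with (L x W^2)/2 = {expected}"
                )


def read_growth_csv(path: str | Path) -> list[GrowthRecord]:
    """Read caliper measurements; volume is derived from length/width
    via the hemi-ellipsoid formula (L x W^2)/2 when not given."""
    from .growth import tumor_volume

    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"animal_id", "group", "day"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"growth CSV must have columns {sorted(required)}")
        for row in reader:
            length = float(row["length_mm"]) if row.get("length_mm") else None
            width = float(row["width_mm"]) if row.get("width_mm") else None
            if row.get("volume_mm3"):
                volume = float(row["volume_mm3"])
            elif length is not None and width is not None:
                volume = tumor_volume(length, width)
            else:
                raise FormatError(
                    f"row for animal {row['animal_id']!r} has neither volume "
                    "nor length/width"
                )
            records.append(
                GrowthRecord(
                    animal_id=str(row["animal_id"]),
                    group=str(row["group"]),
                    day=int(row["day"]),
                    volume_mm3=volume,
                    length_mm=length,
                    width_mm=width,
                )
            )
    return records


def write_growth_csv(records: Sequence[GrowthRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["animal_id", "group", "day", "volume_mm3", "length_mm", "width_mm"]
        )
        for r in records:
            writer.writerow(
                [
                    r.animal_id,
                    r.group,
                    r.day,
                    repr(r.volume_mm3),
                    "" if r.length_mm is None else repr(r.length_mm),
                    "" if r.width_mm is None else repr(r.width_mm),
                ]
            )
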