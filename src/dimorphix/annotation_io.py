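"""Gene annotation, PAR handling, promoter regions, and shared file I/O.

Coordinate convention: all coordinates are 0-based, half-open. The
transcription start site (TSS) of a gene on the ``+`` strand is its
``start``; on the ``-`` strand it is ``end - 1`` (the last base of the
half-open span).

Gene annotations are read from a "GTF-lite" tab-separated table with the
columns ``gene_id, chromosome, start, end, strand`` -- full GTF attribute
parsing is deliberately out of scope. Chromosome gene sets place every
annotated gene in exactly one set named after its chromosome, except that
genes whose TSS falls inside a pseudoautosomal region (PAR) are assigned to
a separate ``"PAR"`` set instead of ``"X"``/``"Y"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CANONICAL_CHROMOSOMES",
    "GRCH38_PAR",
    "GeneAnnotation",
    "ParIntervals",
    "FeatureMatrix",
    "read_gene_annotation",
    "build_promoter_regions",
    "build_chromosome_gene_sets",
    "read_gmt",
    "write_gmt",
    "read_feature_matrix",
    "write_feature_matrix",
    "write_bed",
]

CANONICAL_CHROMOSOMES = tuple(str(c) for c in range(1, 23)) + ("X", "Y", "MT")

#: GRCh38 pseudoautosomal intervals (0-based, half-open).  PAR1/PAR2 on both
#: X and Y; used as the default when no intervals are configured.
GRCH38_PAR = (
    ("X", 10_000, 2_781_479),
    ("X", 155_701_382, 156_030_895),
    ("Y", 10_000, 2_781_479),
    ("Y", 56_887_902, 57_217_415),
)

VALID_MODALITIES = (
    "promoter_meth",
    "gene_meth",
    "rna_counts",
    "rna_logexpr",
    "protein_npx",
)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: chromosome, 0-based half-open span, strand, derived TSS."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.chromosome not in CANONICAL_CHROMOSOMES:
            raise ValueError(
                f"unknown chromosome {self.chromosome!r} for gene {self.gene_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for gene {self.gene_id!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span [{self.start}, {self.end}) for gene {self.gene_id!r}"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class ParIntervals:
    """Pseudoautosomal intervals: (chromosome in {X, Y}, start, end), half-open."""

    intervals: tuple = GRCH38_PAR

    def __post_init__(self) -> None:
        by_chrom: dict = {}
        for chrom, start, end in self.intervals:
            if chrom not in ("X", "Y"):
                raise ValueError(f"PAR interval on non-sex chromosome {chrom!r}")
            if not start < end:
                raise ValueError(f"empty PAR interval [{start}, {end}) on {chrom}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping PAR intervals on {chrom}")

    def contains(self, chromosome: str, position: int) -> bool:
        return any(
            chrom == chromosome and start <= position < end
            for chrom, start, end in self.intervals
        )


@dataclass
class FeatureMatrix:
    """Features x samples values for one modality.

    ``values`` is a pandas DataFrame indexed by feature id with sample-id
    columns. Methylation modalities carry fractions in [0, 1]; ``rna_counts``
    carries non-negative counts; the remaining modalities are log2-scale.
    """

    values: pd.DataFrame
    modality: str

    def __post_init__(self) -> None:
        if self.modality not in VALID_MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.values.to_numpy(dtype=float)
        if self.modality in ("promoter_meth", "gene_meth"):
            finite = vals[~pd.isna(vals)]
            if finite.size and ((finite < 0).any() or (finite > 1).any()):
                raise ValueError("methylation fractions must lie in [0, 1]")
        elif self.modality == "rna_counts":
            if (vals < 0).any():
                raise ValueError("counts must be non-negative")

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)


def read_gene_annotation(path) -> list[GeneAnnotation]:
    """Read a GTF-lite TSV (gene_id, chromosome, start, end, strand).

    Duplicate gene ids, unknown chromosome labels (anything off the
    canonical 1-22/X/Y/MT vocabulary, e.g. unplaced contigs), unknown
    strands and malformed spans are all errors.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "chromosome", "start", "end", "strand"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"annotation file missing columns: {missing}")
    genes: list[GeneAnnotation] = []
    seen: set = set()
    for row in table.itertuples(index=False):
        if row.gene_id in seen:
            raise ValueError(f"duplicate gene_id {row.gene_id!r}")
        seen.add(row.gene_id)
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed coordinates for gene {row.gene_id!r}") from exc
        genes.append(
            GeneAnnotation(
                gene_id=str(row.gene_id),
                chromosome=str(row.chromosome),
                start=start,
                end=end,
                strand=str(row.strand),
            )
        )
    return genes


def write_gene_annotation(genes: list[GeneAnnotation], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chromosome": [g.chromosome for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def build_promoter_regions(
    genes: list[GeneAnnotation], upstream: int = 2000, downstream: int = 200
) -> pd.DataFrame:
    """Promoter windows of ``upstream`` bp anti-transcription-ward of the TSS
    plus ``downstream`` bp beginning at the TSS, strand-aware, clipped at 0.

    Returns a DataFrame (gene_id, chromosome, start, end, strand); regions
    are 0-based half-open and have length upstream+downstream unless clipped.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("window sizes must be non-negative")
    rows = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - upstream, g.tss + downstream
        else:
            # downstream runs leftward from the TSS (transcription direction),
            # upstream rightward; the window still covers upstream+downstream bp.
            start, end = g.tss - downstream + 1, g.tss + upstream + 1
        rows.append((g.gene_id, g.chromosome, max(start, 0), end, g.strand))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"])


def build_chromosome_gene_sets(
    genes: list[GeneAnnotation], par: ParIntervals | None = None
) -> dict[str, set]:
    """Partition genes into chromosome sets, with PAR-TSS genes in ``"PAR"``.

    Every annotated gene lands in exactly one set; a gene is pseudoautosomal
    iff its TSS lies inside a configured PAR interval.
    """
    par = par if par is not None else ParIntervals()
    sets: dict[str, set] = {name: set() for name in CANONICAL_CHROMOSOMES + ("PAR",)}
    for g in genes:
        if g.chromosome in ("X", "Y") and par.contains(g.chromosome, g.tss):
            sets["PAR"].add(g.gene_id)
        else:
            sets[g.chromosome].add(g.gene_id)
    return sets


def read_gmt(path) -> dict[str, set]:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line {line_no}")
            name = fields[0]
            if not name:
                raise ValueError(f"blank set name at GMT line {line_no}")
            if name in sets:
                raise ValueError(f"duplicate set name {name!r} at GMT line {line_no}")
            sets[name] = set(m for m in fields[2:] if m)
    return sets


def write_gmt(sets: dict[str, set], path, descriptions: dict | None = None) -> None:
    """Write gene sets as GMT; ``read_gmt(write_gmt(s)) == s``."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            if not name:
                raise ValueError("blank set name")
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_feature_matrix(path, modality: str) -> FeatureMatrix:
    """Read a features-x-samples TSV (first column feature id, header row
    of sample ids) into a FeatureMatrix."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureMatrix(values=values, modality=modality)


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def write_bed(regions: pd.DataFrame, path) -> None:
    """Write promoter regions as BED3+name (chrom, start, end, gene_id)."""
    regions[["chromosome", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )
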