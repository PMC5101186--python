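"""Readers, writers and validated in-memory containers for every external file format.

All tabular formats are plain TSV; genomic intervals are BED3+ with 0-based
half-open coordinates; protein class sets use a GMT-like dialect (class name,
description, tab-separated member ids).  Every reader/writer pair round-trips
losslessly on valid files.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DesignError, ParseError

CHANNELS = ("light", "heavy", "none")

# Class names with reserved meaning in specificity scoring.  `bait` is the
# IP'd protein itself, `affinity_reagent` collects IgG chains / protein A.
RESERVED_CLASSES = (
    "bait",
    "histone",
    "known_interactor",
    "chromatin_dna_binder",
    "ribosomal",
    "ribonucleoprotein",
    "cytoplasmic_other",
    "affinity_reagent",
)


@dataclass(frozen=True)
class SampleDescriptor:
    """One MS sample/channel: label is the column key in the quant table."""

    label: str
    channel: str = "none"
    replicate: int = 1
    condition: str = ""
    role: str = ""  # free-form, e.g. "bait" or "control"

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise DesignError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.replicate < 1:
            raise DesignError(f"replicate index must be >= 1, got {self.replicate}")


@dataclass
class ProteinQuantTable:
    """Per-protein MS intensities and peptide counts across samples.

    ``intensity`` and ``peptide_count`` are protein x sample frames sharing
    index (protein_id) and columns (sample labels).  Intensity 0 encodes
    "not detected"; there is no NA sentinel.
    """

    intensity: pd.DataFrame
    peptide_count: pd.DataFrame
    samples: list[SampleDescriptor]
    gene_symbol: pd.Series | None = None

    def __post_init__(self):
        labels = [s.label for s in self.samples]
        if len(labels) == 0:
            raise DesignError("a quant table needs at least one sample")
        if len(set(labels)) != len(labels):
            raise DesignError("duplicate sample labels")
        if list(self.intensity.columns) != labels or list(self.peptide_count.columns) != labels:
            raise DesignError("intensity/peptide_count columns must match sample labels in order")
        if self.intensity.index.has_duplicates:
            dup = self.intensity.index[self.intensity.index.duplicated()][0]
            raise ParseError(f"duplicate protein_id {dup!r}")
        if (self.intensity.to_numpy() < 0).any():
            raise ParseError("negative intensity")
        pc = self.peptide_count.to_numpy()
        if (pc < 0).any():
            raise ParseError("negative peptide count")
        # peptide_count == 0 implies intensity == 0
        bad = (pc == 0) & (self.intensity.to_numpy() > 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParseError(
                f"protein {self.intensity.index[i]!r} sample {labels[j]!r}: "
                "intensity > 0 with peptide_count 0"
            )
        if self.gene_symbol is None:
            self.gene_symbol = pd.Series(self.intensity.index, index=self.intensity.index)

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensity.index

    def sample(self, label: str) -> SampleDescriptor:
        for s in self.samples:
            if s.label == label:
                return s
        raise KeyError(label)

    def equals(self, other: "ProteinQuantTable") -> bool:
        return (
            self.samples == other.samples
            and self.intensity.equals(other.intensity)
            and self.peptide_count.equals(other.peptide_count)
            and self.gene_symbol.equals(other.gene_symbol)
        )


@dataclass
class AnnotationCatalog:
    """Named protein classes (GMT-like): class name -> set of protein ids."""

    classes: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        for name in self.classes:
            if not name:
                raise ParseError("empty class name")
        self.classes = {k: set(v) for k, v in self.classes.items()}

    def members(self, name: str) -> set[str]:
        return self.classes.get(name, set())

    def __eq__(self, other):
        return isinstance(other, AnnotationCatalog) and self.classes == other.classes


@dataclass
class PeakSet:
    """Genomic intervals, 0-based half-open, with optional per-peak numeric columns."""

    df: pd.DataFrame  # columns: chrom, start, end, name [, enrichment, extras...]

    REQUIRED = ("chrom", "start", "end", "name")

    def __post_init__(self):
        df = self.df.reset_index(drop=True).copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                if col == "name":
                    df["name"] = [f"peak_{i}" for i in range(len(df))]
                else:
                    raise ParseError(f"missing required column {col!r}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise ParseError("negative interval start")
        bad = df.index[df["start"] >= df["end"]]
        if len(bad):
            raise ParseError("interval start >= end", line=int(bad[0]) + 1)
        if df[list(self.REQUIRED)].isna().any().any():
            raise ParseError("NaN in required column")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def equals(self, other: "PeakSet") -> bool:
        return self.df.equals(other.df)


@dataclass
class GeneAnnotation:
    """Gene TSS positions; strand is used only to locate the TSS upstream."""

    df: pd.DataFrame  # columns: gene_id, chrom, tss, strand

    def __post_init__(self):
        df = self.df.reset_index(drop=True).copy()
        for col in ("gene_id", "chrom", "tss", "strand"):
            if col not in df.columns:
                raise ParseError(f"missing required column {col!r}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ParseError(f"duplicate gene_id {dup!r}")
        df["tss"] = df["tss"].astype(np.int64)
        if (df["tss"] < 0).any():
            raise ParseError("negative TSS coordinate")
        if not df["strand"].isin(["+", "-"]).all():
            raise ParseError("strand must be '+' or '-'")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts with a knockdown design.

    ``design`` maps sample label -> (condition, replicate).
    """

    counts: pd.DataFrame
    design: dict[str, tuple[str, int]]

    def __post_init__(self):
        if list(self.counts.columns) != list(self.design):
            raise DesignError("count columns must match design sample labels in order")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.mod(arr, 1) == 0):
                raise ParseError("non-integer count cell")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ParseError("negative count")
        conditions = self.conditions
        for cond, labels in conditions.items():
            if len(labels) < 1:
                raise DesignError(f"condition {cond!r} has no samples")

    @property
    def conditions(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for label, (cond, _rep) in self.design.items():
            out.setdefault(cond, []).append(label)
        return out

    def equals(self, other: "CountMatrix") -> bool:
        return self.design == other.design and self.counts.equals(other.counts)


# ---------------------------------------------------------------------------
# Quant tables


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"empty or malformed file: {exc}") from exc


def _is_float(v: str) -> bool:
    try:
        float(v)
        return True
    except ValueError:
        return False


def read_quant_table(path, sample_spec: list[SampleDescriptor]) -> ProteinQuantTable:
    """Read a protein quantification TSV.

    The file has columns ``protein_id``, ``gene_symbol`` and per sample
    ``intensity.<label>`` / ``peptides.<label>``.  Missing intensity cells are
    read as 0 (not detected).
    """
    df = _read_tsv(path)
    if "protein_id" not in df.columns:
        raise ParseError("malformed header: missing 'protein_id' column", line=1)
    dup = df["protein_id"].duplicated()
    if dup.any():
        raise ParseError(
            f"duplicate protein_id {df.loc[dup, 'protein_id'].iloc[0]!r}",
            line=int(dup.idxmax()) + 2,
        )
    index = pd.Index(df["protein_id"], name="protein_id")
    labels = [s.label for s in sample_spec]
    inten = {}
    pep = {}
    for lab in labels:
        icol, pcol = f"intensity.{lab}", f"peptides.{lab}"
        if icol not in df.columns:
            raise ParseError(f"malformed header: missing column {icol!r}", line=1)
        raw = df[icol].replace("", "0")
        try:
            # exact float parsing (pd.to_numeric is not bit round-trippable)
            ivals = raw.astype(np.float64)
        except ValueError:
            bad = next(i for i, v in enumerate(raw) if not _is_float(v))
            raise ParseError(f"non-numeric intensity in {icol!r}", line=bad + 2) from None
        neg = ivals < 0
        if neg.any():
            raise ParseError(f"negative intensity in {icol!r}", line=int(neg.idxmax()) + 2)
        if pcol in df.columns:
            pvals = pd.to_numeric(df[pcol].replace("", "0"), errors="coerce")
            if pvals.isna().any() or not np.all(np.mod(pvals.to_numpy(), 1) == 0):
                raise ParseError(f"non-integer peptide count in {pcol!r}")
            pvals = pvals.astype(np.int64)
        else:
            pvals = (ivals > 0).astype(np.int64)
        inten[lab] = ivals.to_numpy(dtype=float)
        pep[lab] = pvals.to_numpy()
    gene = df["gene_symbol"] if "gene_symbol" in df.columns else df["protein_id"]
    return ProteinQuantTable(
        intensity=pd.DataFrame(inten, index=index),
        peptide_count=pd.DataFrame(pep, index=index),
        samples=list(sample_spec),
        gene_symbol=pd.Series(gene.to_numpy(), index=index, name="gene_symbol"),
    )


def write_quant_table(table: ProteinQuantTable, path) -> None:
    out = pd.DataFrame({"protein_id": table.protein_ids, "gene_symbol": table.gene_symbol.to_numpy()})
    for s in table.samples:
        out[f"intensity.{s.label}"] = table.intensity[s.label].to_numpy()
        out[f"peptides.{s.label}"] = table.peptide_count[s.label].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Annotation catalogs (GMT-like)


def read_annotation_catalog(path) -> AnnotationCatalog:
    classes: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            name = fields[0]
            if not name:
                raise ParseError("empty class name", line=lineno)
            ids = {f for f in fields[2:] if f}
            classes.setdefault(name, set()).update(ids)
    return AnnotationCatalog(classes=classes)


def write_annotation_catalog(catalog: AnnotationCatalog, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(catalog.classes):
            ids = "\t".join(sorted(catalog.classes[name]))
            fh.write(f"{name}\t.\t{ids}\n" if ids else f"{name}\t.\n")


# ---------------------------------------------------------------------------
# BED intervals


def read_bed(path) -> PeakSet:
    """Read a BED3+ file: chrom, start, end [, name, enrichment, extras...]."""
    rows = []
    n_extra = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("BED line with < 3 columns", line=lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", line=lineno) from exc
            if start >= end:
                raise ParseError(f"start >= end ({start} >= {end})", line=lineno)
            rows.append(fields)
            n_extra = max(n_extra, len(fields) - 5)
    records = []
    for fields in rows:
        rec = {
            "chrom": fields[0],
            "start": int(fields[1]),
            "end": int(fields[2]),
            "name": fields[3] if len(fields) > 3 else f"peak_{len(records)}",
        }
        if len(fields) > 4:
            rec["enrichment"] = float(fields[4])
        for k in range(5, 5 + n_extra):
            if len(fields) > k:
                rec[f"extra_{k - 4}"] = fields[k]
        records.append(rec)
    cols = ["chrom", "start", "end", "name"]
    if any("enrichment" in r for r in records):
        cols.append("enrichment")
    cols += [f"extra_{k}" for k in range(1, n_extra + 1)]
    df = pd.DataFrame(records, columns=cols)
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end", "name"]).astype(
            {"start": np.int64, "end": np.int64}
        )
    return PeakSet(df=df)


def write_bed(peaks: PeakSet, path) -> None:
    df = peaks.df
    with open(path, "w") as fh:
        extra_cols = [c for c in df.columns if c not in ("chrom", "start", "end", "name", "enrichment")]
        for row in df.itertuples(index=False):
            d = row._asdict()
            fields = [str(d["chrom"]), str(d["start"]), str(d["end"]), str(d["name"])]
            if "enrichment" in d and not pd.isna(d["enrichment"]):
                fields.append(f"{d['enrichment']:.17g}")
            for c in extra_cols:
                fields.append(str(d[c]))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Count matrices


def read_counts(path, design_spec: dict[str, tuple[str, int]]) -> CountMatrix:
    """Read a gene x sample integer count TSV; design_spec maps sample -> (condition, replicate)."""
    df = _read_tsv(path)
    if "gene_id" not in df.columns:
        raise ParseError("malformed header: missing 'gene_id' column", line=1)
    if df["gene_id"].duplicated().any():
        raise ParseError("duplicate gene_id")
    index = pd.Index(df["gene_id"], name="gene_id")
    data = {}
    for lab in design_spec:
        if lab not in df.columns:
            raise DesignError(f"design names sample {lab!r} absent from file")
        vals = pd.to_numeric(df[lab], errors="coerce")
        if vals.isna().any():
            raise ParseError(f"non-numeric count in column {lab!r}",
                             line=int(vals.isna().idxmax()) + 2)
        if not np.all(np.mod(vals.to_numpy(), 1) == 0):
            bad = np.mod(vals.to_numpy(), 1) != 0
            raise ParseError(f"non-integer count in column {lab!r}",
                             line=int(np.argmax(bad)) + 2)
        data[lab] = vals.astype(np.int64).to_numpy()
    return CountMatrix(counts=pd.DataFrame(data, index=index), design=dict(design_spec))


def write_counts(matrix: CountMatrix, path) -> None:
    out = matrix.counts.reset_index()
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene annotations


def read_gene_annotation(path) -> GeneAnnotation:
    df = _read_tsv(path)
    for col in ("gene_id", "chrom", "tss", "strand"):
        if col not in df.columns:
            raise ParseError(f"malformed header: missing {col!r} column", line=1)
    tss = pd.to_numeric(df["tss"], errors="coerce")
    if tss.isna().any():
        raise ParseError("non-integer tss", line=int(tss.isna().idxmax()) + 2)
    df = df.assign(tss=tss.astype(np.int64))
    return GeneAnnotation(df=df[["gene_id", "chrom", "tss", "strand"]])


def write_gene_annotation(genes: GeneAnnotation, path) -> None:
    genes.df.to_csv(path, sep="\t", index=False)
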