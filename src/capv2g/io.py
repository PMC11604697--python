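"""Readers and writers for the pipeline's external formats.

Supported carriers: BED3 / narrowPeak regions, ibed-like contact tables
(the standard output dialect of Capture-C interaction callers), TSV or
VCF-lite variant tables, JASPAR-counts PWMs, TSV expression matrices,
ChromHMM segmentation BED and FASTA.

Files are 1-based where the native format is (VCF positions, the gene
table TSS column); everything is converted to the package's 0-based
half-open convention on read.  Every reader/writer pair is a lossless
round trip on valid files, and readers reject coordinate violations with
the offending line number rather than silently clamping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GeneModel, GenomicInterval

__all__ = [
    "VariantRecord",
    "PWMRecord",
    "read_regions",
    "write_regions",
    "as_intervals",
    "read_contacts_ibed",
    "write_contacts_ibed",
    "read_variants",
    "write_variants",
    "read_expression",
    "write_expression",
    "log2_tpm1",
    "read_pwm_jaspar",
    "write_pwm_jaspar",
    "read_chromhmm",
    "read_genes",
    "write_genes",
    "read_fasta",
    "write_fasta",
    "write_bed",
]

_BASES = {"A", "C", "G", "T"}

IBED_COLUMNS = [
    "bait_chr", "bait_start", "bait_end", "bait_name",
    "oe_chr", "oe_start", "oe_end", "oe_name",
    "n_reads", "score",
]

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signal_value", "p_value", "q_value", "summit",
]


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class VariantRecord:
    """A sentinel or LD-proxy SNV.  ``pos0`` is 0-based.

    Only single-nucleotide substitutions are supported: the allele-delta
    motif scoring is defined for substitutions, so indel proxies are
    rejected at parse time.
    """

    variant_id: str
    chrom: str
    pos0: int
    ref: str
    alt: str
    role: str = "proxy"  # {"sentinel", "proxy"}
    sentinel_id: str | None = None
    r2: float = 1.0

    def __post_init__(self):
        if self.role not in {"sentinel", "proxy"}:
            raise ValueError(f"invalid role {self.role!r}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(
                f"{self.variant_id}: only single-nucleotide ACGT alleles "
                f"are supported (got ref={self.ref!r} alt={self.alt!r})"
            )
        if self.ref == self.alt:
            raise ValueError(f"{self.variant_id}: ref and alt must differ")
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"{self.variant_id}: r2 must be in [0, 1]")
        if self.pos0 < 0:
            raise ValueError(f"{self.variant_id}: negative position")
        if self.role == "proxy" and not self.sentinel_id:
            raise ValueError(f"proxy {self.variant_id} lacks a sentinel_id")
        if self.role == "sentinel" and self.sentinel_id is None:
            object.__setattr__(self, "sentinel_id", self.variant_id)


def read_variants(path: str | Path, dialect: str = "tsv") -> list[VariantRecord]:
    """Read variants from a TSV or VCF-lite file (1-based positions).

    VCF-lite columns: ``#CHROM POS ID REF ALT INFO`` with INFO keys
    ``ROLE``, ``SENTINEL`` and ``R2``.  A sentinel without an ``R2`` key
    defaults to r2 = 1.0 with itself.
    """
    path = Path(path)
    records: list[VariantRecord] = []
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"variant_id", "chrom", "pos", "ref", "alt", "role"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing variant columns {sorted(missing)}")
        for i, row in df.iterrows():
            sentinel = row.get("sentinel_id")
            if pd.isna(sentinel) or sentinel in ("", "."):
                sentinel = None
            r2 = row.get("r2")
            r2 = 1.0 if (r2 is None or pd.isna(r2) or r2 == ".") else float(r2)
            records.append(
                VariantRecord(
                    variant_id=row["variant_id"],
                    chrom=row["chrom"],
                    pos0=int(row["pos"]) - 1,
                    ref=str(row["ref"]).upper(),
                    alt=str(row["alt"]).upper(),
                    role=row["role"],
                    sentinel_id=sentinel,
                    r2=r2,
                )
            )
    elif dialect == "vcf":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("##"):
                    continue
                if line.startswith("#CHROM"):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: malformed VCF-lite line")
                chrom, pos, vid, ref, alt = fields[:5]
                if "," in alt:
                    raise ValueError(
                        f"{path}:{lineno}: multi-allelic ALT not supported"
                    )
                info = dict(
                    kv.split("=", 1) for kv in fields[-1].split(";") if "=" in kv
                )
                role = info.get("ROLE", "proxy")
                records.append(
                    VariantRecord(
                        variant_id=vid,
                        chrom=chrom,
                        pos0=int(pos) - 1,
                        ref=ref.upper(),
                        alt=alt.upper(),
                        role=role,
                        sentinel_id=info.get("SENTINEL"),
                        r2=float(info.get("R2", 1.0)),
                    )
                )
    else:
        raise ValueError(f"unknown variant dialect {dialect!r}")
    return records


def write_variants(
    variants: Sequence[VariantRecord], path: str | Path, dialect: str = "tsv"
) -> None:
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("variant_id\tchrom\tpos\tref\talt\trole\tsentinel_id\tr2\n")
            for v in variants:
                fh.write(
                    f"{v.variant_id}\t{v.chrom}\t{v.pos0 + 1}\t{v.ref}\t{v.alt}\t"
                    f"{v.role}\t{v.sentinel_id or '.'}\t{v.r2:g}\n"
                )
    elif dialect == "vcf":
        with open(path, "w") as fh:
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tINFO\n")
            for v in variants:
                info = f"ROLE={v.role};SENTINEL={v.sentinel_id};R2={v.r2:g}"
                fh.write(
                    f"{v.chrom}\t{v.pos0 + 1}\t{v.variant_id}\t{v.ref}\t{v.alt}\t{info}\n"
                )
    else:
        raise ValueError(f"unknown variant dialect {dialect!r}")


# ---------------------------------------------------------------------------
# regions (BED3 / narrowPeak) and ChromHMM
# ---------------------------------------------------------------------------

def _parse_region_line(fields, lineno, path, n_min):
    if len(fields) < n_min:
        raise ValueError(f"{path}:{lineno}: expected >= {n_min} columns")
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    if not (0 <= start < end):
        raise ValueError(
            f"{path}:{lineno}: invalid coordinates {chrom}:{start}-{end}"
        )
    return chrom, start, end


def read_regions(path: str | Path, dialect: str = "bed3") -> pd.DataFrame:
    """Read regions as a DataFrame of 0-based half-open intervals.

    ``bed3`` yields columns ``chrom/start/end`` (extra columns, if any,
    are kept); ``narrowPeak`` yields the full ten-column schema with the
    extra columns preserved as metadata.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if dialect == "bed3":
                chrom, start, end = _parse_region_line(fields, lineno, path, 3)
                row = {"chrom": chrom, "start": start, "end": end}
                if len(fields) > 3:
                    row["name"] = fields[3]
                if len(fields) > 4:
                    row["score"] = fields[4]
                if len(fields) > 5:
                    row["strand"] = fields[5]
                rows.append(row)
            elif dialect == "narrowPeak":
                chrom, start, end = _parse_region_line(fields, lineno, path, 10)
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "name": fields[3],
                        "score": int(fields[4]),
                        "strand": fields[5],
                        "signal_value": float(fields[6]),
                        "p_value": float(fields[7]),
                        "q_value": float(fields[8]),
                        "summit": int(fields[9]),
                    }
                )
            else:
                raise ValueError(f"unknown region dialect {dialect!r}")
    columns = (
        NARROWPEAK_COLUMNS if dialect == "narrowPeak" else ["chrom", "start", "end"]
    )
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)


def write_regions(
    df: pd.DataFrame, path: str | Path, dialect: str = "bed3"
) -> None:
    path = Path(path)
    cols = NARROWPEAK_COLUMNS if dialect == "narrowPeak" else list(df.columns)
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fh.write("\t".join(str(row[c]) for c in cols if c in df.columns) + "\n")


def as_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def read_chromhmm(path: str | Path) -> pd.DataFrame:
    """ChromHMM segmentation BED: chrom/start/end with the state label in
    the name column."""
    df = read_regions(path, dialect="bed3")
    if "name" not in df.columns:
        if len(df):
            raise ValueError(f"{path}: segmentation BED needs a state name column")
        df["name"] = pd.Series(dtype=str)
    return df.rename(columns={"name": "state"})[["chrom", "start", "end", "state"]]


def write_bed(
    intervals: Iterable,
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence | None = None,
    header_comment: str | None = None,
) -> None:
    """Write intervals (objects with chrom/start/end, or tuples) as BED."""
    rows = []
    for iv in intervals:
        if isinstance(iv, tuple):
            rows.append(iv[:3])
        else:
            rows.append((iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for i, (chrom, start, end) in enumerate(rows):
            extra = ""
            if names is not None:
                extra += f"\t{names[i]}"
            if scores is not None:
                extra += f"\t{scores[i]}"
            fh.write(f"{chrom}\t{start}\t{end}{extra}\n")


# ---------------------------------------------------------------------------
# contacts (ibed-like)
# ---------------------------------------------------------------------------

def read_contacts_ibed(
    path: str | Path,
    resolution: str | None = None,
    cell_type: str | None = None,
) -> pd.DataFrame:
    """Read an ibed-like contact table.

    Requires a header with the ten standard columns; ``resolution`` and
    ``cell_type`` columns are honoured when present and can otherwise be
    supplied as arguments.  Negative scores are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(IBED_COLUMNS) - set(df.columns)
    if "score" in missing:
        raise ValueError(f"{path}: contact table lacks a score column")
    if missing:
        raise ValueError(f"{path}: missing contact columns {sorted(missing)}")
    if (df["score"] < 0).any():
        bad = int(df.index[df["score"] < 0][0]) + 2  # +1 header, +1 1-based
        raise ValueError(f"{path}:{bad}: negative interaction score")
    for prefix in ("bait", "oe"):
        bad = df[f"{prefix}_start"] >= df[f"{prefix}_end"]
        if bad.any():
            lineno = int(df.index[bad][0]) + 2
            raise ValueError(f"{path}:{lineno}: invalid {prefix} coordinates")
    if "resolution" not in df.columns:
        df["resolution"] = resolution or "1frag"
    if "cell_type" not in df.columns:
        df["cell_type"] = cell_type or "."
    return df


def write_contacts_ibed(df: pd.DataFrame, path: str | Path) -> None:
    cols = IBED_COLUMNS + [
        c for c in ("resolution", "cell_type") if c in df.columns
    ]
    out = df[cols].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%g")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """TPM table: gene_id index, one column per cell type."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative TPM values")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%g")


def log2_tpm1(values) -> np.ndarray:
    """The log2(TPM + 1) transform used for expression comparisons."""
    return np.log2(np.asarray(values, dtype=float) + 1.0)


# ---------------------------------------------------------------------------
# PWMs (JASPAR counts dialect)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PWMRecord:
    """A position count matrix, rows in A, C, G, T order."""

    matrix_id: str
    tf_name: str
    counts: np.ndarray  # shape (4, L)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(f"{self.matrix_id}: counts must be 4 x L with L >= 1")
        if (counts < 0).any():
            raise ValueError(f"{self.matrix_id}: negative counts")
        if (counts.sum(axis=0) == 0).any():
            raise ValueError(f"{self.matrix_id}: all-zero column")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


def read_pwm_jaspar(path: str | Path) -> list[PWMRecord]:
    """Parse a JASPAR-style counts file (``>ID NAME`` then A/C/G/T rows)."""
    path = Path(path)
    records: list[PWMRecord] = []
    header: tuple[str, str] | None = None
    rows: dict[str, list[float]] = {}

    def flush():
        nonlocal header, rows
        if header is None:
            return
        missing = [b for b in "ACGT" if b not in rows]
        if missing:
            raise ValueError(f"{path}: matrix {header[0]} missing rows {missing}")
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"{path}: matrix {header[0]} rows of unequal length")
        counts = np.array([rows[b] for b in "ACGT"])
        records.append(PWMRecord(header[0], header[1], counts))
        header, rows = None, {}

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                header = (parts[0], parts[1] if len(parts) > 1 else parts[0])
            else:
                base, rest = line[0].upper(), line[1:]
                rest = rest.replace("[", " ").replace("]", " ")
                rows[base] = [float(x) for x in rest.split()]
    flush()
    return records


def write_pwm_jaspar(pwms: Sequence[PWMRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.matrix_id} {pwm.tf_name}\n")
            for base, row in zip("ACGT", pwm.counts):
                vals = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# genes and FASTA
# ---------------------------------------------------------------------------

def read_genes(path: str | Path) -> list[GeneModel]:
    """Gene table TSV with a 1-based ``tss`` column (GTF-like convention),
    converted to 0-based on read."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "gene_name": str})
    return [
        GeneModel(r.gene_id, r.gene_name, r.chrom, int(r.tss) - 1, r.strand)
        for r in df.itertuples(index=False)
    ]


def write_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgene_name\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.gene_name}\t{g.chrom}\t{g.tss + 1}\t{g.strand}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
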