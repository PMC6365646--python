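"""Table I/O, FASTQ barcode extraction and arrayed-pool deconvolution.

Coordinates are 1-based inclusive throughout (GFF convention). All tables are
plain TSV; FASTQ may be plain or gzip-compressed.
"""

from __future__ import annotations

import gzip
import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, ValidationError
from .synthdata import BARCODE_LENGTH, GENE_COLUMNS, POOL_COLUMNS, GenomeAnnotation, ReadDesign

_ACGT = set("ACGT")


# ---------------------------------------------------------------------------
# count table
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Barcode x sample read counts with Time0 pairing metadata.

    ``counts`` is indexed by barcode with one integer column per sample id;
    ``samples`` has columns sample, condition, t0set, is_time0. Every
    non-Time0 sample's t0set must match at least one Time0 sample.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        needed = {"sample", "condition", "t0set", "is_time0"}
        if not needed.issubset(self.samples.columns):
            raise ConsistencyError(f"sample metadata needs columns {sorted(needed)}")
        meta_ids = list(self.samples["sample"])
        if set(self.counts.columns) != set(meta_ids):
            extra = set(self.counts.columns) - set(meta_ids)
            missing = set(meta_ids) - set(self.counts.columns)
            raise ConsistencyError(
                f"counts/metadata sample mismatch (extra={sorted(extra)}, missing={sorted(missing)})"
            )
        if (self.counts.to_numpy() < 0).any():
            raise ConsistencyError("negative counts")
        t0sets_with_t0 = set(self.samples.loc[self.samples["is_time0"], "t0set"])
        unpaired = self.samples.loc[
            ~self.samples["is_time0"] & ~self.samples["t0set"].isin(t0sets_with_t0), "sample"
        ]
        if len(unpaired):
            raise ConsistencyError(f"samples without a Time0 control: {list(unpaired)}")

    @property
    def experiments(self) -> list[str]:
        """Non-Time0 sample ids, in metadata order."""
        return list(self.samples.loc[~self.samples["is_time0"], "sample"])

    def time0_samples(self, t0set: str) -> list[str]:
        mask = self.samples["is_time0"] & (self.samples["t0set"] == t0set)
        return list(self.samples.loc[mask, "sample"])

    def sample_row(self, sample: str) -> pd.Series:
        rows = self.samples[self.samples["sample"] == sample]
        if rows.empty:
            raise ConsistencyError(f"unknown sample {sample!r}")
        return rows.iloc[0]


# ---------------------------------------------------------------------------
# pool TSV
# ---------------------------------------------------------------------------

def write_pool(pool: pd.DataFrame, path) -> None:
    df = pool.copy()
    df["locus_tag"] = df["locus_tag"].fillna("")
    df.to_csv(path, sep="\t", index=False, columns=POOL_COLUMNS)


def read_pool(path) -> pd.DataFrame:
    """Read and validate a pool TSV; errors name the offending 1-based line."""
    df = pd.read_csv(path, sep="\t", dtype={"locus_tag": "string"}, keep_default_na=True)
    missing = [c for c in POOL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pool file missing columns {missing}")
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 is the header
        bc = row.barcode
        if not isinstance(bc, str) or len(bc) != BARCODE_LENGTH or set(bc) - _ACGT:
            raise FormatError(f"bad barcode {bc!r}", line=i)
        if bc in seen:
            raise FormatError(f"duplicate barcode {bc} (first at line {seen[bc]})", line=i)
        seen[bc] = i
        if row.strand not in ("+", "-"):
            raise FormatError(f"bad strand {row.strand!r}", line=i)
        genic = isinstance(row.locus_tag, str) and row.locus_tag != ""
        frac_present = not pd.isna(row.fraction)
        if genic != frac_present:
            raise FormatError("fraction must be present iff locus_tag is present", line=i)
        if frac_present and not (0.0 <= row.fraction <= 1.0):
            raise FormatError(f"fraction {row.fraction} outside [0, 1]", line=i)
    df["locus_tag"] = df["locus_tag"].replace("", pd.NA)
    df["locus_tag"] = df["locus_tag"].astype(object).where(df["locus_tag"].notna(), None)
    return df[POOL_COLUMNS]


# ---------------------------------------------------------------------------
# counts / metadata TSV
# ---------------------------------------------------------------------------

def write_counts(table: CountTable, counts_path, metadata_path) -> None:
    out = table.counts.copy()
    out.insert(0, "barcode", out.index)
    out.to_csv(counts_path, sep="\t", index=False)
    write_metadata(table.samples, metadata_path)


def write_metadata(samples: pd.DataFrame, path) -> None:
    df = samples.copy()
    df["is_time0"] = df["is_time0"].map({True: "TRUE", False: "FALSE"})
    df.to_csv(path, sep="\t", index=False, columns=["sample", "condition", "t0set", "is_time0"])


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["sample", "condition", "t0set", "is_time0"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing columns {missing}")
    df["is_time0"] = df["is_time0"].str.upper().map({"TRUE": True, "FALSE": False})
    if df["is_time0"].isna().any():
        raise FormatError("is_time0 must be TRUE or FALSE")
    return df[needed]


def read_counts(counts_path, metadata_path) -> CountTable:
    counts = pd.read_csv(counts_path, sep="\t")
    if "barcode" not in counts.columns:
        raise FormatError("counts file missing 'barcode' column")
    counts = counts.set_index("barcode")
    samples = read_metadata(metadata_path)
    return CountTable(counts=counts, samples=samples)


# ---------------------------------------------------------------------------
# gene table
# ---------------------------------------------------------------------------

def write_genes(genome: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        for sid, length in genome.scaffolds:
            fh.write(f"# scaffold\t{sid}\t{length}\n")
        genome.genes.to_csv(fh, sep="\t", index=False, columns=GENE_COLUMNS)


def read_genes(path) -> GenomeAnnotation:
    scaffolds = []
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            parts = line[1:].strip().split("\t")
            if parts[0] == "scaffold":
                scaffolds.append((parts[1], int(parts[2])))
    genes = pd.read_csv(path, sep="\t", skiprows=header_lines)
    return GenomeAnnotation(scaffolds=scaffolds, genes=genes)


# ---------------------------------------------------------------------------
# FASTQ + barcode extraction
# ---------------------------------------------------------------------------

def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def iter_fastq_seqs(source) -> Iterator[str]:
    """Yield read sequences from a FASTQ path/handle or an iterable of strings."""
    if isinstance(source, (str, Path)):
        opener = gzip.open if str(source).endswith(".gz") else open
        with opener(source, "rt") as fh:
            yield from _seqs_from_handle(fh)
    elif isinstance(source, io.TextIOBase):
        yield from _seqs_from_handle(source)
    else:
        for item in source:
            if isinstance(item, str):
                yield item
            else:  # (read_id, seq, qual) record
                yield item[1]


def _seqs_from_handle(fh) -> Iterator[str]:
    while True:
        header = fh.readline()
        if not header:
            return
        seq = fh.readline().strip()
        plus = fh.readline()
        qual = fh.readline()
        if not header.startswith("@") or not plus.startswith("+"):
            raise FormatError("malformed FASTQ record")
        yield seq


@dataclass
class DemuxReport:
    """Per-file demultiplexing tally; counted + no_flank + bad_barcode +
    index_mismatch always equals total."""

    total: int = 0
    counted: int = 0
    no_flank: int = 0
    bad_barcode: int = 0
    index_mismatch: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "counted": self.counted,
            "no_flank": self.no_flank,
            "bad_barcode": self.bad_barcode,
            "index_mismatch": self.index_mismatch,
        }


def extract_barcodes(
    source,
    design: ReadDesign,
    expected_index: str | None = None,
    known_barcodes: set[str] | None = None,
) -> tuple[Counter, DemuxReport]:
    """Count barcodes from reads, exact-matching the flanks of ``design``.

    A read is counted iff ``pre_flank`` occurs at a dialect-legal offset, the
    following 20 bases are ACGT-only (and in ``known_barcodes`` if given), the
    ``post_flank`` prefix follows, and — for the inline-index dialect when
    ``expected_index`` is given — the bases immediately before ``pre_flank``
    end with the reverse of ``expected_index``. Malformed reads are tallied,
    never fatal.
    """
    if expected_index is not None:
        if len(expected_index) != design.index_length or set(expected_index) - _ACGT:
            raise ValidationError(f"expected_index must be {design.index_length} nt ACGT")
    pre = design.pre_flank
    post = design.post_flank
    lo, hi = design.n_range
    index_shift = design.index_length if design.dialect == "inline_index" else 0
    rev_index = expected_index[::-1] if expected_index is not None else None

    counts: Counter = Counter()
    report = DemuxReport()
    for seq in iter_fastq_seqs(source):
        report.total += 1
        offset = -1
        for m in range(lo, hi + 1):
            o = m + index_shift
            if seq[o : o + len(pre)] == pre:
                offset = o
                break
        if offset < 0:
            report.no_flank += 1
            continue
        if design.dialect == "inline_index" and rev_index is not None:
            if not seq[:offset].endswith(rev_index):
                report.index_mismatch += 1
                continue
        bc_start = offset + len(pre)
        barcode = seq[bc_start : bc_start + design.barcode_length]
        following = seq[bc_start + design.barcode_length : bc_start + design.barcode_length + len(post)]
        ok = (
            len(barcode) == design.barcode_length
            and not (set(barcode) - _ACGT)
            and following == post
            and (known_barcodes is None or barcode in known_barcodes)
        )
        if ok:
            counts[barcode] += 1
            report.counted += 1
        else:
            report.bad_barcode += 1
    return counts, report


# ---------------------------------------------------------------------------
# arrayed-collection deconvolution
# ---------------------------------------------------------------------------

AMBIGUOUS = "ambiguous"
UNLOCATED = "unlocated"


def deconvolve_arrayed(
    presence: Mapping[str, Iterable[str]],
    row_labels: Iterable[str],
    column_labels: Iterable[str],
    plate_labels: Iterable[str],
) -> dict[str, tuple[str, str, str] | str]:
    """Locate barcodes in an arrayed collection from row/column/plate pools.

    A barcode is assigned the well (plate, row, column) iff it occurs in
    exactly one pool of each type; more than one pool of any type makes it
    ``"ambiguous"``, zero pools of any type ``"unlocated"``.
    """
    rows = set(row_labels)
    cols = set(column_labels)
    plates = set(plate_labels)
    overlap = (rows & cols) | (rows & plates) | (cols & plates)
    if overlap:
        raise ValidationError(f"pool labels used for more than one type: {sorted(overlap)}")

    out: dict[str, tuple[str, str, str] | str] = {}
    for barcode, labels in presence.items():
        labels = set(labels)
        unknown = labels - rows - cols - plates
        if unknown:
            raise ValidationError(f"unknown pool labels {sorted(unknown)} for barcode {barcode}")
        r, c, p = labels & rows, labels & cols, labels & plates
        if max(len(r), len(c), len(p)) > 1:
            out[barcode] = AMBIGUOUS
        elif min(len(r), len(c), len(p)) == 0:
            out[barcode] = UNLOCATED
        else:
            out[barcode] = (next(iter(p)), next(iter(r)), next(iter(c)))
    return out


# ---------------------------------------------------------------------------
# results output
# ---------------------------------------------------------------------------

def write_fitness_tables(
    outdir,
    fitness: pd.DataFrame,
    t: pd.DataFrame,
    n_strains: pd.DataFrame | None = None,
    calls: pd.DataFrame | None = None,
) -> None:
    """Write gene x experiment fitness/t matrices and the long-form calls table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in (("fitness", fitness), ("t", t), ("n_strains", n_strains)):
        if df is None:
            continue
        out = df.copy()
        out.insert(0, "locus_tag", out.index)
        out.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, na_rep="NA")
    if calls is not None:
        calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return df.set_index("locus_tag")
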