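"""Synthetic data generation for pooled barcoded-transposon fitness assays.

Everything downstream of this module (demultiplexing, fitness estimation,
phenotype calling, operon grouping) is exercised against data produced here:
a genome annotation with operon structure, a pool of barcoded insertion
mutants, planted per-condition log2 fitness effects, multinomially sampled
read-count tables, and raw multiplexed FASTQ in two amplicon dialects.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
arguments and seed give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError, InvalidParameterError, ValidationError

BASES = np.array(list("ACGT"))

#: Sequence flanking the 5' side of the barcode in the amplicon (the bases of
#: the P1 primer that follow the random N spacer).
PRE_FLANK = "GTCGACCTGCAGCGTACG"

#: First 9 nt read after the barcode: the reverse complement of the 3'
#: terminus of the no-index P2 primer. Only this prefix is required to match
#: because read length truncates the remainder.
POST_FLANK = "AGAGACCTC"

BARCODE_LENGTH = 20
INDEX_LENGTH = 6

GENE_COLUMNS = ["locus_tag", "scaffold", "strand", "start", "end", "operon", "description"]
POOL_COLUMNS = ["barcode", "scaffold", "strand", "position", "locus_tag", "fraction"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeAnnotation:
    """Scaffolds plus a gene table (1-based inclusive coordinates).

    ``genes`` columns: locus_tag, scaffold, strand (+/-), start, end,
    operon (integer id of the transcription unit the gene was generated in),
    description. Genes on a scaffold are non-overlapping.
    """

    scaffolds: list[tuple[str, int]]
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        g = self.genes
        missing = [c for c in GENE_COLUMNS if c not in g.columns and c != "operon"]
        if missing:
            raise ValidationError(f"gene table missing columns: {missing}")
        if g["locus_tag"].duplicated().any():
            raise ValidationError("duplicate locus_tags in gene table")
        lengths = dict(self.scaffolds)
        for _, row in g.iterrows():
            if not (1 <= row["start"] <= row["end"] <= lengths[row["scaffold"]]):
                raise ValidationError(
                    f"gene {row['locus_tag']} coordinates outside scaffold"
                )
        for _, sub in g.groupby("scaffold"):
            sub = sub.sort_values("start")
            if (sub["start"].values[1:] <= sub["end"].values[:-1]).any():
                raise ValidationError("overlapping genes on a scaffold")

    @property
    def locus_tags(self) -> list[str]:
        return list(self.genes["locus_tag"])


@dataclass
class SyntheticTruth:
    """Planted per-(gene, condition) log2 fitness effects and baseline abundances.

    ``effects`` maps (locus_tag, condition) to the planted total log2 change
    in relative abundance over one growth experiment; unlisted pairs are 0.
    ``baseline`` maps barcode to relative abundance (sums to 1).
    """

    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    baseline: pd.Series | None = None

    def effect(self, locus_tag: str | None, condition: str | None) -> float:
        if locus_tag is None or condition is None:
            return 0.0
        return self.effects.get((locus_tag, condition), 0.0)


@dataclass(frozen=True)
class ReadDesign:
    """Layout of a BarSeq read under one of the two P1 primer dialects.

    ``classic``: [m random bases, m in n_range] + pre_flank + barcode + post_flank.
    ``inline_index``: [m random bases] + reverse(sample index) + pre_flank +
    barcode + post_flank. The inline index is the *reverse* of the 6-nt sample
    index, not its reverse complement.
    """

    dialect: str = "classic"
    pre_flank: str = PRE_FLANK
    post_flank: str = POST_FLANK
    n_range: tuple[int, int] = (2, 5)
    index_length: int = INDEX_LENGTH
    barcode_length: int = BARCODE_LENGTH

    def __post_init__(self) -> None:
        if self.dialect not in ("classic", "inline_index"):
            raise InvalidParameterError(f"unknown dialect {self.dialect!r}")
        for flank in (self.pre_flank, self.post_flank):
            if not flank or any(b not in "ACGT" for b in flank):
                raise InvalidParameterError("flanks must be nonempty uppercase ACGT")
        if self.barcode_length != BARCODE_LENGTH:
            raise InvalidParameterError("barcode_length must be 20")
        lo, hi = self.n_range
        if not (0 <= lo <= hi):
            raise InvalidParameterError("invalid n_range")

    @classmethod
    def classic(cls) -> "ReadDesign":
        return cls(dialect="classic", n_range=(2, 5))

    @classmethod
    def inline_index(cls) -> "ReadDesign":
        return cls(dialect="inline_index", n_range=(1, 4))


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def generate_genome(
    n_scaffolds: int,
    n_genes: int,
    mean_gene_len: int = 900,
    operon_geometric_p: float = 0.5,
    seed: int = 0,
) -> GenomeAnnotation:
    """Lay genes left-to-right on each scaffold in geometric-sized operons.

    Genes within an operon share a strand and are separated by short gaps
    (5-50 bp); consecutive operons are separated by gaps larger than the
    default operon-grouping threshold (350-800 bp) so that generated operon
    boundaries are recoverable by gap-based grouping.
    """
    if n_scaffolds < 1 or n_genes < 1 or mean_gene_len < 10:
        raise InvalidParameterError("n_scaffolds, n_genes and mean_gene_len must be positive")
    if not (0 < operon_geometric_p <= 1):
        raise InvalidParameterError("operon_geometric_p must be in (0, 1]")
    rng = np.random.default_rng(seed)

    per_scaffold = [n_genes // n_scaffolds] * n_scaffolds
    for i in range(n_genes % n_scaffolds):
        per_scaffold[i] += 1

    rows = []
    scaffolds: list[tuple[str, int]] = []
    gene_i = 0
    operon_i = 0
    for s_i, n_here in enumerate(per_scaffold):
        sid = f"scaffold{s_i + 1}"
        pos = 1
        placed = 0
        while placed < n_here:
            size = min(int(rng.geometric(operon_geometric_p)), n_here - placed)
            strand = "+" if rng.random() < 0.5 else "-"
            pos += int(rng.integers(350, 801))  # inter-operon gap
            for j in range(size):
                if j > 0:
                    pos += int(rng.integers(5, 51))  # intra-operon gap
                length = int(rng.integers(mean_gene_len // 2, mean_gene_len * 3 // 2 + 1))
                rows.append(
                    {
                        "locus_tag": f"g{gene_i:05d}",
                        "scaffold": sid,
                        "strand": strand,
                        "start": pos,
                        "end": pos + length - 1,
                        "operon": operon_i,
                        "description": "hypothetical protein",
                    }
                )
                pos += length
                gene_i += 1
            operon_i += 1
            placed += size
        scaffolds.append((sid, pos + int(rng.integers(350, 801))))

    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return GenomeAnnotation(scaffolds=scaffolds, genes=genes)


# ---------------------------------------------------------------------------
# mutant pool generation
# ---------------------------------------------------------------------------

def _random_barcodes(n: int, rng: np.random.Generator, max_rounds: int = 50) -> list[str]:
    seen: dict[str, None] = {}
    rounds = 0
    while len(seen) < n:
        if rounds >= max_rounds:
            raise GenerationError("could not generate unique barcodes within retry budget")
        need = n - len(seen)
        draws = rng.integers(0, 4, size=(need, BARCODE_LENGTH))
        for row in draws:
            bc = "".join(BASES[row])
            if bc not in seen:
                seen[bc] = None
                if len(seen) == n:
                    break
        rounds += 1
    return list(seen)


def gene_fraction(strand: str, start: int, end: int, position: int) -> float:
    """Within-gene insertion fraction measured from the start codon.

    ``(position - start + 1) / length`` on the + strand and
    ``(end - position + 1) / length`` on the - strand, so 0 is the 5' end of
    the coding sequence regardless of strand.
    """
    length = end - start + 1
    if strand == "+":
        return (position - start + 1) / length
    return (end - position + 1) / length


def generate_pool(
    genome: GenomeAnnotation,
    n_strains: int,
    genic_fraction: float = 0.75,
    abundance_sigma: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a pool of uniquely barcoded insertion strains plus baseline abundances.

    Each strain gets a unique random 20-mer barcode and an insertion position:
    with probability ``genic_fraction`` inside a gene (gene chosen
    length-weighted, position uniform within the gene), otherwise uniform in
    an intergenic interval. Baseline relative abundances are lognormal with
    log10 standard deviation ``abundance_sigma``, normalized to sum to 1.

    Returns ``(pool, baseline)`` where ``pool`` has columns barcode, scaffold,
    strand, position, locus_tag (None for intergenic) and fraction (NaN for
    intergenic), and ``baseline`` is indexed by barcode.
    """
    if n_strains < 1:
        raise InvalidParameterError("n_strains must be >= 1")
    if not (0 <= genic_fraction <= 1):
        raise InvalidParameterError("genic_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    barcodes = _random_barcodes(n_strains, rng)

    genes = genome.genes
    gene_lengths = (genes["end"] - genes["start"] + 1).to_numpy(float)
    gene_p = gene_lengths / gene_lengths.sum()

    # intergenic intervals per scaffold (may be empty if genes tile everything)
    intervals: list[tuple[str, int, int]] = []
    for sid, slen in genome.scaffolds:
        sub = genes[genes["scaffold"] == sid].sort_values("start")
        prev_end = 0
        for _, row in sub.iterrows():
            if row["start"] > prev_end + 1:
                intervals.append((sid, prev_end + 1, row["start"] - 1))
            prev_end = row["end"]
        if prev_end < slen:
            intervals.append((sid, prev_end + 1, slen))
    iv_lengths = np.array([b - a + 1 for _, a, b in intervals], dtype=float)

    rows = []
    for bc in barcodes:
        genic = rng.random() < genic_fraction if iv_lengths.size else True
        if genic:
            gi = rng.choice(len(genes), p=gene_p)
            g = genes.iloc[gi]
            position = int(rng.integers(g["start"], g["end"] + 1))
            rows.append(
                {
                    "barcode": bc,
                    "scaffold": g["scaffold"],
                    "strand": g["strand"],
                    "position": position,
                    "locus_tag": g["locus_tag"],
                    "fraction": gene_fraction(g["strand"], g["start"], g["end"], position),
                }
            )
        else:
            ii = rng.choice(len(intervals), p=iv_lengths / iv_lengths.sum())
            sid, a, b = intervals[ii]
            rows.append(
                {
                    "barcode": bc,
                    "scaffold": sid,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "position": int(rng.integers(a, b + 1)),
                    "locus_tag": None,
                    "fraction": np.nan,
                }
            )
    pool = pd.DataFrame(rows, columns=POOL_COLUMNS)

    log_abund = rng.normal(0.0, abundance_sigma, size=n_strains)
    abund = np.power(10.0, log_abund)
    baseline = pd.Series(abund / abund.sum(), index=pool["barcode"].to_numpy(), name="abundance")
    return pool, baseline


# ---------------------------------------------------------------------------
# planted effects
# ---------------------------------------------------------------------------

def plant_effects(
    genome: GenomeAnnotation,
    design: Mapping[str, Sequence[tuple[str, float]]],
    baseline: pd.Series | None = None,
) -> SyntheticTruth:
    """Record planted log2 effects; (gene, condition) pairs not listed are 0.

    ``design`` maps condition label to a list of (locus_tag, effect). Negative
    effects are growth defects; positive effects are gains in relative
    abundance.
    """
    known = set(genome.locus_tags)
    effects: dict[tuple[str, str], float] = {}
    for condition, pairs in design.items():
        for locus_tag, e in pairs:
            if locus_tag not in known:
                raise ValidationError(f"unknown locus_tag {locus_tag!r} in design")
            effects[(locus_tag, condition)] = float(e)
    return SyntheticTruth(effects=effects, baseline=baseline)


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def simulate_counts(
    pool: pd.DataFrame,
    truth: SyntheticTruth,
    condition: str | None,
    depth: int,
    seed: int = 0,
) -> pd.Series:
    """Multinomial read counts for one sample of the pooled growth assay.

    Post-growth relative abundance of a strain is proportional to its baseline
    abundance times 2**e, where e is the planted effect of its gene under
    ``condition``; intergenic strains and ``condition=None`` (Time0) use e=0.
    ``depth`` total reads are then drawn multinomially.
    """
    if depth < 0:
        raise InvalidParameterError("depth must be nonnegative")
    if truth.baseline is None:
        raise ValidationError("truth has no baseline abundances")
    rng = np.random.default_rng(seed)

    barcodes = pool["barcode"].to_numpy()
    base = truth.baseline.reindex(barcodes).to_numpy(float)
    if np.isnan(base).any():
        raise ValidationError("baseline missing some pool barcodes")
    e = np.array(
        [truth.effect(lt if isinstance(lt, str) else None, condition) for lt in pool["locus_tag"]]
    )
    weights = base * np.power(2.0, e)
    p = weights / weights.sum()
    counts = rng.multinomial(depth, p)
    return pd.Series(counts, index=barcodes, name=condition or "Time0")


def build_count_table(
    pool: pd.DataFrame,
    truth: SyntheticTruth,
    samples: pd.DataFrame,
    depth: int,
    seed: int = 0,
):
    """Simulate a full barcode x sample count table.

    ``samples`` needs columns sample, condition, t0set, is_time0 and may carry
    an optional ``truth_condition`` column overriding which planted-effect
    label a sample draws from (used to plant single-experiment artifacts).
    Returns a :class:`fitcaller.bcio.CountTable`.
    """
    from .bcio import CountTable  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    cols = {}
    for _, row in samples.iterrows():
        if row["is_time0"]:
            cond = None
        elif "truth_condition" in samples.columns and isinstance(row.get("truth_condition"), str):
            cond = row["truth_condition"]
        else:
            cond = row["condition"]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cols[row["sample"]] = simulate_counts(pool, truth, cond, depth, seed=sub_seed)
    counts = pd.DataFrame(cols)
    meta = samples[["sample", "condition", "t0set", "is_time0"]].reset_index(drop=True)
    return CountTable(counts=counts, samples=meta)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    sample_counts: pd.Series,
    design: ReadDesign,
    sample_index: str,
    bleed_rate: float = 0.0,
    seed: int = 0,
    foreign_indices: Sequence[str] = (),
) -> tuple[dict[str, list[tuple[str, str, str]]], pd.DataFrame]:
    """Expand a count vector into FASTQ records, with optional bleed-through.

    Each count unit becomes one read laid out per ``design``. With probability
    ``bleed_rate`` a read is emitted into a uniformly chosen *foreign* sample's
    file while retaining its true inline index (the minimal model of
    between-sample bleed-through on patterned flow cells).

    Returns ``(files, truth)``: ``files`` maps sample index -> list of
    (read_id, sequence, quality) records; ``truth`` has one row per read with
    columns read_id, barcode, true_index, assigned_index.
    """
    _check_index(sample_index, design)
    for ix in foreign_indices:
        _check_index(ix, design)
    if not (0 <= bleed_rate < 1):
        raise InvalidParameterError("bleed_rate must be in [0, 1)")
    if bleed_rate > 0 and not foreign_indices:
        raise InvalidParameterError("bleed_rate > 0 requires foreign_indices")

    rng = np.random.default_rng(seed)
    lo, hi = design.n_range
    files: dict[str, list[tuple[str, str, str]]] = {sample_index: []}
    for ix in foreign_indices:
        files.setdefault(ix, [])
    truth_rows = []
    read_i = 0
    for barcode, count in sample_counts.items():
        for _ in range(int(count)):
            m = int(rng.integers(lo, hi + 1))
            spacer = "".join(BASES[rng.integers(0, 4, size=m)]) if m else ""
            if design.dialect == "inline_index":
                prefix = spacer + sample_index[::-1]
            else:
                prefix = spacer
            seq = prefix + design.pre_flank + barcode + design.post_flank
            assigned = sample_index
            if bleed_rate > 0 and rng.random() < bleed_rate:
                assigned = foreign_indices[int(rng.integers(0, len(foreign_indices)))]
            read_id = f"{sample_index}:{read_i}"
            files[assigned].append((read_id, seq, "I" * len(seq)))
            truth_rows.append(
                {
                    "read_id": read_id,
                    "barcode": barcode,
                    "true_index": sample_index,
                    "assigned_index": assigned,
                }
            )
            read_i += 1
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "barcode", "true_index", "assigned_index"]
    )
    return files, truth


def _check_index(index: str, design: ReadDesign) -> None:
    if len(index) != design.index_length or any(b not in "ACGT" for b in index):
        raise ValidationError(f"sample index must be {design.index_length} nt of ACGT, got {index!r}")
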