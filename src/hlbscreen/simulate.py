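"""Synthetic tandem-array reference and ChIP/input read simulation.

The simulator stands in for the public ChIP datasets a real screen would
download: it builds a reference of ~100 identical copies of the 5 kb histone
repeat unit embedded in random flanking background, then draws error-free
single-end reads whose per-base start probabilities encode one of six
scenarios the classifier must distinguish:

``NONE``
    no enrichment anywhere (a factor that does not target the locus);
``TRUE_PROMOTER``
    genuine ChIP enrichment (fold weight on one target element, input flat);
``GENE_BODY_BIAS``
    library/alignment bias inflating gene bodies in BOTH ChIP and input;
``INTERGENIC_DEPLETION``
    bias depleting intergenic regions in both roles;
``INPUT_IDENTICAL``
    the same "enrichment" in ChIP and input (cancels after normalization —
    the looked-identical false positive);
``GA_ARTIFACT``
    short pure-(GA)n reads injected into the ChIP library, emulating the
    multimapping pileup over the H3/H4-promoter GA elements seen in
    datasets with read lengths ≤ 50 bp.

Every read carries a ground-truth origin (copy index and unit offset, or
``flank`` / ``ga_synthetic``), serialized through FASTQ so the whole
pipeline can be scored against truth. Identical configs (including seed)
produce byte-identical output.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .annotation import ArrayAnnotation
from .dna import decode, encode, ga_pattern


class SimMode(str, enum.Enum):
    NONE = "NONE"
    TRUE_PROMOTER = "TRUE_PROMOTER"
    GENE_BODY_BIAS = "GENE_BODY_BIAS"
    INTERGENIC_DEPLETION = "INTERGENIC_DEPLETION"
    INPUT_IDENTICAL = "INPUT_IDENTICAL"
    GA_ARTIFACT = "GA_ARTIFACT"


#: origin sentinel for reads drawn from flanking background
FLANK = "flank"
#: origin sentinel for injected pure-GA artifact reads
GA_SYNTHETIC = "ga_synthetic"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated ChIP/input pair.

    Defaults are the screen's reference conditions: ~100 tandem copies,
    50,000 reads per role, 75 bp reads, 8-fold enrichment on the H3/H4
    promoter, bias weight 3 (gene-body) or 0.2 (intergenic — pass
    explicitly), 5% artifact reads in GA mode.
    """

    mode: SimMode = SimMode.NONE
    n_copies: int = 100
    flank_length: int = 10_000
    n_reads_chip: int = 50_000
    n_reads_input: int = 50_000
    read_length: int = 75
    enrichment_fold: float = 8.0
    bias_weight: float = 3.0
    target_element: str = "H3_H4_promoter"
    artifact_read_fraction: float = 0.05
    flank_read_fraction: float = 0.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if not 0 <= self.artifact_read_fraction <= 1:
            raise ValueError("artifact_read_fraction must be in [0, 1]")
        if not 0 <= self.flank_read_fraction <= 1:
            raise ValueError("flank_read_fraction must be in [0, 1]")
        if self.bias_weight <= 0:
            raise ValueError("bias_weight must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class Read:
    """One simulated (or parsed) read with its optional ground-truth origin."""

    id: str
    sequence: str
    truth_origin: tuple[int, int] | str | None = None


@dataclass
class ReadSet:
    """A collection of equal-length reads for one role (chip or input).

    Sequences are stored as an encoded (n, read_length) uint8 matrix for
    vectorized mapping; :meth:`__iter__` yields :class:`Read` objects.
    ``truth_copy``/``truth_offset`` are -1 for non-array origins, which are
    distinguished by ``truth_kind`` (0 = array, 1 = flank, 2 = ga_synthetic,
    3 = unknown/parsed-without-truth).
    """

    role: str
    ids: list[str]
    seqs: np.ndarray
    truth_kind: np.ndarray
    truth_copy: np.ndarray
    truth_offset: np.ndarray
    config: SimConfig | None = None

    TRUTH_ARRAY, TRUTH_FLANK, TRUTH_GA, TRUTH_UNKNOWN = 0, 1, 2, 3

    def __post_init__(self) -> None:
        n = len(self.ids)
        if not (len(self.seqs) == len(self.truth_kind) == len(self.truth_copy)
                == len(self.truth_offset) == n):
            raise ValueError("ReadSet arrays have inconsistent lengths")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def read_length(self) -> int:
        return self.seqs.shape[1]

    def truth_of(self, i: int) -> tuple[int, int] | str | None:
        k = int(self.truth_kind[i])
        if k == self.TRUTH_ARRAY:
            return (int(self.truth_copy[i]), int(self.truth_offset[i]))
        if k == self.TRUTH_FLANK:
            return FLANK
        if k == self.TRUTH_GA:
            return GA_SYNTHETIC
        return None

    def __iter__(self):
        for i in range(len(self)):
            yield Read(self.ids[i], decode(self.seqs[i]), self.truth_of(i))


def build_reference(
    annotation: ArrayAnnotation,
    n_copies: int = 100,
    flank_length: int = 10_000,
    seed: int = 0,
) -> tuple[str, list[int]]:
    """Tandem-repeat reference: flank + n identical unit copies + flank.

    Bases under ga_repeat features are a perfect (GA)n dinucleotide repeat
    (phase anchored at the feature start); all other unit and flank bases
    are i.i.d. uniform over ACGT from the seeded RNG. Returns the sequence
    and the start offset of each copy.
    """
    rng = np.random.default_rng(seed)
    L = annotation.unit_length
    unit = rng.integers(0, 4, size=L, dtype=np.uint8)
    for f in annotation.by_kind("ga_repeat"):
        unit[f.start : f.end] = ga_pattern(f.length)
    left = rng.integers(0, 4, size=flank_length, dtype=np.uint8)
    right = rng.integers(0, 4, size=flank_length, dtype=np.uint8)
    seq = np.concatenate([left] + [unit] * n_copies + [right])
    offsets = [flank_length + i * L for i in range(n_copies)]
    return decode(seq), offsets


def position_weights(
    annotation: ArrayAnnotation,
    mode: SimMode,
    config: SimConfig,
    role: str = "chip",
) -> np.ndarray:
    """Per-base read-start sampling weights over one unit, normalized to sum 1.

    ``role`` is ``chip`` or ``input``; the bias modes apply to both roles,
    TRUE_PROMOTER enriches the ChIP only, INPUT_IDENTICAL enriches both.
    """
    if role not in ("chip", "input"):
        raise ValueError(f"role must be 'chip' or 'input', got {role!r}")
    L = annotation.unit_length
    w = np.ones(L, dtype=float)
    mode = SimMode(mode)
    if mode in (SimMode.TRUE_PROMOTER, SimMode.INPUT_IDENTICAL):
        enrich = mode is SimMode.INPUT_IDENTICAL or role == "chip"
        if enrich:
            t = annotation.feature(config.target_element)
            w[t.start : t.end] = config.enrichment_fold
    elif mode is SimMode.GENE_BODY_BIAS:
        w[annotation.mask("gene")] = config.bias_weight
    elif mode is SimMode.INTERGENIC_DEPLETION:
        w[~annotation.mask("gene", "promoter")] = config.bias_weight
    # NONE and GA_ARTIFACT: uniform (artifact reads are injected separately)
    return w / w.sum()


def _array_reads(
    rng: np.random.Generator,
    unit: np.ndarray,
    weights: np.ndarray,
    n: int,
    read_length: int,
    n_copies: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw n array-origin reads; returns (seqs, copies, offsets).

    Sequences are taken from the unit treated circularly: for interior
    copies this is byte-identical to slicing the tandem reference (copies
    are identical), and it keeps junction-spanning reads within the locus.
    """
    L = len(unit)
    offsets = rng.choice(L, size=n, p=weights)
    copies = rng.integers(0, n_copies, size=n)
    idx = (offsets[:, None] + np.arange(read_length)) % L
    seqs = unit[idx]
    # fragments come off either strand; reverse-complement half of them
    flip = rng.random(n) < 0.5
    seqs[flip] = (3 - seqs[flip])[:, ::-1]
    return seqs, copies, offsets


def simulate_pair(
    reference: str,
    annotation: ArrayAnnotation,
    config: SimConfig,
) -> tuple[ReadSet, ReadSet]:
    """Simulate a matched ChIP/input read pair under ``config.mode``.

    Deterministic for a fixed config (seed included). The reference must
    have the geometry implied by the config (two flanks of
    ``flank_length`` around ``n_copies`` unit copies).
    """
    L = annotation.unit_length
    if config.read_length > L:
        raise ValueError(
            f"read_length {config.read_length} exceeds unit_length {L}"
        )
    expected = 2 * config.flank_length + config.n_copies * L
    if len(reference) != expected:
        raise ValueError(
            f"reference length {len(reference)} does not match config "
            f"(expected {expected})"
        )
    ref_enc = encode(reference)
    unit = ref_enc[config.flank_length : config.flank_length + L]
    rng = np.random.default_rng(config.seed)
    out = []
    for role, n_total in (("chip", config.n_reads_chip), ("input", config.n_reads_input)):
        n_art = 0
        if config.mode is SimMode.GA_ARTIFACT and role == "chip":
            n_art = round(config.artifact_read_fraction * n_total)
        n_flank = round(config.flank_read_fraction * (n_total - n_art))
        n_array = n_total - n_art - n_flank

        w = position_weights(annotation, config.mode, config, role)
        seqs, copies, offsets = _array_reads(
            rng, unit, w, n_array, config.read_length, config.n_copies
        )
        kind = np.full(n_total, ReadSet.TRUTH_ARRAY, dtype=np.int8)
        copy_col = np.full(n_total, -1, dtype=np.int64)
        off_col = np.full(n_total, -1, dtype=np.int64)
        copy_col[:n_array] = copies
        off_col[:n_array] = offsets

        blocks = [seqs]
        if n_flank:
            lo_max = config.flank_length - config.read_length
            starts = rng.integers(0, lo_max + 1, size=n_flank)
            side = rng.integers(0, 2, size=n_flank).astype(bool)
            starts = np.where(side, starts + config.flank_length + config.n_copies * L, starts)
            idx = starts[:, None] + np.arange(config.read_length)
            blocks.append(ref_enc[idx])
            kind[n_array : n_array + n_flank] = ReadSet.TRUTH_FLANK
        if n_art:
            blocks.append(
                np.tile(ga_pattern(config.read_length), (n_art, 1))
            )
            kind[n_array + n_flank :] = ReadSet.TRUTH_GA

        all_seqs = np.concatenate(blocks) if len(blocks) > 1 else blocks[0]
        if config.error_rate > 0:
            hit = rng.random(all_seqs.shape) < config.error_rate
            shift = rng.integers(1, 4, size=all_seqs.shape).astype(np.uint8)
            all_seqs = np.where(hit, (all_seqs + shift) % 4, all_seqs)
        ids = [f"{role}_{i:07d}" for i in range(n_total)]
        out.append(
            ReadSet(role, ids, all_seqs.astype(np.uint8), kind, copy_col, off_col, config)
        )
    return out[0], out[1]


# -- FASTQ / FASTA / truth-table interchange -------------------------------


def _truth_suffix(rs: ReadSet, i: int) -> str:
    k = int(rs.truth_kind[i])
    if k == ReadSet.TRUTH_ARRAY:
        return f"|copy={rs.truth_copy[i]};offset={rs.truth_offset[i]}"
    if k == ReadSet.TRUTH_FLANK:
        return f"|{FLANK}"
    if k == ReadSet.TRUTH_GA:
        return f"|{GA_SYNTHETIC}"
    return ""


def write_fastq(readset: ReadSet, path) -> None:
    """4-line FASTQ with constant quality 'I'; truth origin after '|' in the id."""
    qual = "I" * readset.read_length
    with open(path, "w") as fh:
        for i in range(len(readset)):
            fh.write(
                f"@{readset.ids[i]}{_truth_suffix(readset, i)}\n"
                f"{decode(readset.seqs[i])}\n+\n{qual}\n"
            )


def _parse_truth(tag: str) -> tuple[int, int, int]:
    """Returns (kind, copy, offset) from an id truth suffix."""
    if tag == FLANK:
        return ReadSet.TRUTH_FLANK, -1, -1
    if tag == GA_SYNTHETIC:
        return ReadSet.TRUTH_GA, -1, -1
    if tag.startswith("copy="):
        copy_s, off_s = tag.split(";")
        return (
            ReadSet.TRUTH_ARRAY,
            int(copy_s.removeprefix("copy=")),
            int(off_s.removeprefix("offset=")),
        )
    raise ValueError(f"unrecognized truth tag {tag!r}")


def read_fastq(path, role: str = "unknown") -> ReadSet:
    """Parse FASTQ back into a ReadSet, recovering truth tags from read ids.

    All reads must share one length (the screen operates on uniform-length
    libraries); malformed records raise ValueError with the record index.
    """
    ids: list[str] = []
    seq_rows: list[np.ndarray] = []
    kinds: list[int] = []
    copies: list[int] = []
    offs: list[int] = []
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"{path}: record {index}: {exc}") from exc
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: record {index}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            name = title.split()[0]
            if "|" in name:
                rid, tag = name.split("|", 1)
                k, c, o = _parse_truth(tag)
            else:
                rid, (k, c, o) = name, (ReadSet.TRUTH_UNKNOWN, -1, -1)
            try:
                row = encode(seq)
            except ValueError as exc:
                raise ValueError(f"{path}: record {index}: {exc}") from exc
            if seq_rows and len(row) != len(seq_rows[0]):
                raise ValueError(
                    f"{path}: record {index}: read length {len(row)} differs "
                    f"from first record ({len(seq_rows[0])})"
                )
            ids.append(rid)
            seq_rows.append(row)
            kinds.append(k)
            copies.append(c)
            offs.append(o)
            index += 1
    seqs = np.vstack(seq_rows) if seq_rows else np.empty((0, 0), dtype=np.uint8)
    return ReadSet(
        role,
        ids,
        seqs,
        np.array(kinds, dtype=np.int8),
        np.array(copies, dtype=np.int64),
        np.array(offs, dtype=np.int64),
    )


def write_fasta(name: str, sequence: str, path, wrap: int = 80) -> None:
    """FASTA with an 80-column line wrap (the pipeline's normalized dialect)."""
    from Bio.Seq import Seq
    from Bio.SeqIO.FastaIO import FastaWriter
    from Bio.SeqRecord import SeqRecord

    with open(path, "w") as fh:
        FastaWriter(fh, wrap=wrap).write_file([SeqRecord(Seq(sequence), id=name, description="")])


def read_fasta(path) -> tuple[str, str]:
    """Read the single record of a FASTA file; returns (name, sequence)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(path, "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    return records[0].id, str(records[0].seq)


def write_truth_table(readset: ReadSet, path) -> None:
    """Truth table as TSV: read_id, copy_index, offset, origin."""
    origin_names = {
        ReadSet.TRUTH_ARRAY: "array",
        ReadSet.TRUTH_FLANK: FLANK,
        ReadSet.TRUTH_GA: GA_SYNTHETIC,
        ReadSet.TRUTH_UNKNOWN: "unknown",
    }
    with open(path, "w") as fh:
        fh.write("read_id\tcopy_index\toffset\torigin\n")
        for i in range(len(readset)):
            fh.write(
                f"{readset.ids[i]}\t{readset.truth_copy[i]}\t"
                f"{readset.truth_offset[i]}\t{origin_names[int(readset.truth_kind[i])]}\n"
            )


def subsampled(config: SimConfig, **overrides) -> SimConfig:
    """Convenience: a copy of ``config`` with fields replaced."""
    return replace(config, **overrides)
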