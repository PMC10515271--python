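import numpy as np
import pytest

from hlbscreen.annotation import build_default_annotation
from hlbscreen.align import KmerIndex
from hlbscreen.recovery import PipelineContext
from hlbscreen.simulate import build_reference


@pytest.fixture(scope="session")
def annotation():
    return build_default_annotation()


@pytest.fixture(scope="session")
def small_reference(annotation):
    """3-copy tandem reference with short flanks: enough for collapse tests."""
    ref, offsets = build_reference(annotation, n_copies=3, flank_length=1000, seed=7)
    return ref, offsets


@pytest.fixture(scope="session")
def unit_sequence(small_reference, annotation):
    ref, offsets = small_reference
    return ref[offsets[0] : offsets[0] + annotation.unit_length]


@pytest.fixture(scope="session")
def index(unit_sequence):
    return KmerIndex(unit_sequence)


@pytest.fixture(scope="session")
def full_context():
    """100-copy context at the reference study conditions (shared: it is
    deterministic and read-only)."""
    return PipelineContext.build(seed=0)


def build_cohort(out_dir, n_reads=20_000, seed=500):
    """Six-candidate synthetic cohort, one per simulation mode, on disk.

    Writes unit FASTA, annotation BED, per-candidate ChIP/input FASTQ and a
    TSV manifest; returns the manifest path.
    """
    from hlbscreen.annotation import UNIT_NAME, write_bed
    from hlbscreen.recovery import reference_config
    from hlbscreen.simulate import (
        SimMode,
        build_reference,
        simulate_pair,
        write_fasta,
        write_fastq,
    )

    out_dir.mkdir(parents=True, exist_ok=True)
    ann = build_default_annotation()
    n_copies, flank = 25, 2000
    ref, offsets = build_reference(ann, n_copies, flank, seed=seed)
    unit_fa = out_dir / "unit.fasta"
    write_fasta(UNIT_NAME, ref[offsets[0] : offsets[0] + ann.unit_length], unit_fa)
    bed = out_dir / "annotation.bed"
    write_bed(ann, bed)
    rows = []
    for i, mode in enumerate(SimMode):
        cfg = reference_config(
            mode, seed=seed + 1 + i, n_copies=n_copies, flank_length=flank,
            n_reads_chip=n_reads, n_reads_input=n_reads,
        )
        chip, inp = simulate_pair(ref, ann, cfg)
        cp = out_dir / f"{mode.value}_chip.fastq"
        ip = out_dir / f"{mode.value}_input.fastq"
        write_fastq(chip, cp)
        write_fastq(inp, ip)
        rows.append(f"{mode.value}\t{cp}\t{ip}\t{cfg.read_length}")
    manifest = out_dir / "manifest.tsv"
    manifest.write_text(
        f"#unit_fasta={unit_fa}\n#annotation_bed={bed}\n"
        "name\tchip\tinput\tread_length\n" + "\n".join(rows) + "\n"
    )
    return manifest


@pytest.fixture(scope="session")
def cohort_manifest(tmp_path_factory):
    return build_cohort(tmp_path_factory.mktemp("cohort"))
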