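from __future__ import annotations

import numpy as np
import pytest

from exosrna import preprocess
from exosrna.refs import ReferenceSet, revcomp
from exosrna.simulate import SimConfig, generate_degradome_reads, \
    generate_references, generate_srna_reads, plant_truth


def naive_scan(read_counts, refs) -> set[tuple[str, str, int, int, str]]:
    """Independent mapping oracle: per-strand str.find scan of every reference.

    Returns the set of (read, ref_id, start, end, strand) occurrences with
    full-length 100% identity, mirroring an exhaustive scan over every
    (reference, offset, strand) triple.
    """
    rows = set()
    for seq in read_counts:
        if not seq or set(seq) - set("ACGT"):
            continue
        for ref_id, ref_seq in refs.items():
            for strand, probe in (("+", seq), ("-", revcomp(seq))):
                start = ref_seq.find(probe)
                while start != -1:
                    rows.add((seq, ref_id, start, start + len(seq), strand))
                    start = ref_seq.find(probe, start + 1)
    return rows


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def sim(small_config):
    """Default-size simulated dataset shared across tests (do not mutate)."""
    refs = generate_references(small_config)
    truth = plant_truth(refs, small_config)
    srna_records, srna_truth = generate_srna_reads(refs, truth, small_config)
    deg_records, deg_truth = generate_degradome_reads(refs, truth, small_config)
    return {
        "config": small_config,
        "refs": refs,
        "truth": truth,
        "srna_records": srna_records,
        "srna_truth": srna_truth,
        "deg_records": deg_records,
        "deg_truth": deg_truth,
    }


@pytest.fixture(scope="session")
def srna_libs(sim):
    """Demultiplexed, trimmed, size-selected, decontaminated sRNA libraries."""
    cfg = sim["config"]
    demux = preprocess.demultiplex_and_trim(
        [seq for _rid, seq in sim["srna_records"]], cfg.barcode_map, cfg.adapter3
    )
    libs = {}
    for cond, lib in demux.libraries.items():
        lib = preprocess.size_filter(lib, 16, 32)
        lib = preprocess.remove_contaminants(lib, sim["refs"].contaminant)
        libs[cond] = lib
    return libs


@pytest.fixture(scope="session")
def deg_libs(sim):
    """Preprocessed degradome libraries (poly-A trimmed, 25-45 nt)."""
    cfg = sim["config"]
    demux = preprocess.demultiplex_and_trim(
        [seq for _rid, seq in sim["deg_records"]], cfg.barcode_map, cfg.adapter3
    )
    libs = {}
    for cond, lib in demux.libraries.items():
        lib = preprocess.trim_polya(lib, 4)
        lib = preprocess.size_filter(lib, 25, 45)
        libs[cond] = lib
    return libs


@pytest.fixture
def tiny_refs() -> ReferenceSet:
    rng = np.random.default_rng(11)
    seqs = {
        f"ref_{i}": "".join("ACGT"[b] for b in rng.integers(0, 4, size=200))
        for i in range(4)
    }
    return ReferenceSet("genome", seqs)
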