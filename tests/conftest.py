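import numpy as np
import pytest

from itdscan.simulate import (
    SimConfig,
    apply_tandem_duplication,
    emulate_alignment,
    generate_paired_reads,
)


def random_seq(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def reference_4kb() -> str:
    return random_seq(4000, seed=11)


@pytest.fixture(scope="session")
def simulated_locus(reference_4kb):
    """A 60-bp tandem duplication sequenced at ~100x, 50% VAF,
    error-free, with emulated alignments."""
    ref = reference_4kb
    mut, truth = apply_tandem_duplication(ref, 1800, 60, chrom="c", event_id="e0")
    cfg = SimConfig(read_length=100, depth=100, vaf=0.5, error_rate=0.0, seed=21)
    reads = generate_paired_reads(ref, mut, cfg)
    records = emulate_alignment(reads, {"c": ref})
    return {"reference": {"c": ref}, "mutant": mut, "truth": truth,
            "reads": reads, "records": records}
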