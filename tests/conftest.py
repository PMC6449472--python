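import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def study_run():
    """One partition run at the study operating point (2 Mb, 2.35% SNP
    heterozygosity, 10% repeats, 60% allelic fraction), shared by the
    partition-level tests."""
    from hapsever import as_detect, repeat_mask, synthetic_data as sd

    params = sd.SimulationParams(seed=20)
    hap0, hap1, variants = sd.simulate_diploid(params)
    contigs, truths = sd.fragment_to_contigs(hap0, hap1, variants, params)
    matches = sd.simulate_self_matches(contigs)
    mask, _ = repeat_mask.merge_masks(
        repeat_mask.mask_by_kmer_frequency(contigs),
        contig_lengths={c.id: len(c) for c in contigs},
    )
    classifications, summary = as_detect.partition_contigs(contigs, matches, mask)
    return {
        "params": params,
        "contigs": contigs,
        "truths": truths,
        "matches": matches,
        "mask": mask,
        "classifications": classifications,
        "summary": summary,
    }
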