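import pytest

from trigger_forge.synth import SynthSpec, generate_transcriptome


@pytest.fixture(scope="session")
def small_transcriptome():
    """Ten ORF-bearing synthetic transcripts plus their ORF annotations."""
    return generate_transcriptome(SynthSpec(seed=42, n_transcripts=10))


@pytest.fixture(scope="session")
def long_orf():
    """One long ORF (~1.65 kb) used as the base for ortholog triplets."""
    recs, orfs = generate_transcriptome(
        SynthSpec(seed=11, n_transcripts=1, length_range=(1800, 1900), min_orf_nt=1650)
    )
    orf = orfs[0]
    return recs[0].residues[orf.start : orf.end]
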