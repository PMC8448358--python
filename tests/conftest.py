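import pytest

from kskid import msa
from kskid.simulate import SimulationConfig, simulate_reference_set


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic reference panel under the default study conditions."""
    return simulate_reference_set(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_alignment(default_dataset):
    return msa.progressive_msa(default_dataset.records)


def _toy_alignment(states_per_member, background="ACGTACGTAC",
                   positions=(2, 5, 8)):
    """Alignment whose rows share a background except at the given
    0-based columns, where each member shows its own state."""
    ids, rows = [], []
    for member, states in states_per_member.items():
        row = list(background)
        for pos, state in zip(positions, states):
            row[pos] = state
        ids.append(member)
        rows.append("".join(row))
    return msa.Alignment(ids=ids, rows=rows)


@pytest.fixture
def sa_haplotype_alignment():
    """The published S. axillaris variation pattern: two substitution
    columns and one indel column, heterozygotes recorded as IUPAC codes,
    eight accessions in four haplotypes of sizes 1, 5, 1, 1."""
    states = {
        "SA3": ("G", "T", "-"),
        "SA1": ("G", "Y", "-"),
        "SA2": ("G", "Y", "-"),
        "SA4": ("G", "Y", "-"),
        "SA5": ("G", "Y", "-"),
        "SA6": ("G", "Y", "-"),
        "SA7": ("G", "Y", "C"),
        "SA8": ("R", "C", "C"),
    }
    return _toy_alignment(states)


@pytest.fixture
def za_haplotype_alignment():
    """The published Z. attopensis pattern: three substitution columns,
    four accessions in four singleton haplotypes."""
    states = {
        "ZA1": ("T", "C", "R"),
        "ZA3": ("W", "Y", "R"),
        "ZA4": ("T", "Y", "R"),
        "ZA2": ("T", "Y", "A"),
    }
    return _toy_alignment(states)
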